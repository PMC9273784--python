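"""Secondary-structure assignment from Calpha geometry.

Helices and beta-strands leave distinct signatures in the pseudo bond
angle ``theta`` (triplet ``i-1, i, i+1``) and pseudo dihedral ``tau``
(quadruplet ``i-1, i, i+1, i+2``) of a Calpha trace: an ideal alpha-helix
sits near ``theta ~ 90 deg, tau ~ +50 deg`` while extended strands show
open angles and near-trans dihedrals.  Residues whose ``(theta, tau)``
fall inside the helix window are *helix candidates*; a maximal candidate
run ``[a, b]`` marks residues ``[a-1, b+2]`` (the span of all triplets
and quadruplets involved) as helical, so the shortest detectable helix is
4 residues.  Extended candidates are expanded the same way and become
sheet residues only when they pair with another extended residue across
space with a consistent register over at least two consecutive pairs,
i.e. a beta-sheet cannot be smaller than two 2-residue strands.

Angle windows are calibrated on ideal helix/strand geometry (they are
exposed in :class:`SSParams`); no hydrogen bonds or side chains are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import bond_angles, pseudo_dihedrals
from .io_ensemble import Conformation, EnsembleHandle
from .constants import SS_REGION

__all__ = [
    "SSParams", "SheetPair", "SSAssignment", "SSCounts",
    "DEFAULT_SS_PARAMS", "backbone_geometry", "helix_candidates",
    "strand_candidates", "assign_ss", "detect_sheet_pairings",
    "count_ss_region", "split_B_HB", "cumulative_dos_curve",
    "orientation_percentages", "OrientationStats",
]


@dataclass(frozen=True)
class SSParams:
    """Angle windows (degrees) and size rules of the assignment."""

    helix_theta: tuple[float, float] = (80.0, 105.0)
    helix_tau: tuple[float, float] = (30.0, 70.0)
    strand_theta: tuple[float, float] = (100.0, 155.0)
    strand_abs_tau_min: float = 140.0
    min_helix_len: int = 4
    min_strand_len: int = 2
    pairing_cutoff: float = 5.5  # A, Calpha-Calpha between paired residues
    min_intra_pair_sep: int = 5  # sequence separation for intrachain pairs


DEFAULT_SS_PARAMS = SSParams()


@dataclass(frozen=True)
class SheetPair:
    """One residue-residue pairing inside a beta-sheet."""

    chain_a: str
    res_a: int  # 1-based
    chain_b: str
    res_b: int
    orientation: str  # "parallel" | "antiparallel"
    scope: str  # "intra" | "inter"


@dataclass
class SSAssignment:
    """Per-residue labels (H/E/C) per chain plus the sheet pairings."""

    labels: dict[str, np.ndarray]  # chain_id -> array of 'H'/'E'/'C'
    sheet_pairs: list[SheetPair]

    def residues_in_sheets(self, orientation: str | None = None,
                           scope: str | None = None
                           ) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for p in self.sheet_pairs:
            if orientation is not None and p.orientation != orientation:
                continue
            if scope is not None and p.scope != scope:
                continue
            out.add((p.chain_a, p.res_a))
            out.add((p.chain_b, p.res_b))
        return out


@dataclass(frozen=True)
class SSCounts:
    """Number of helix and sheet residues inside a sequence region."""

    alpha: int
    beta: int
    region: tuple[int, int]


def backbone_geometry(coords: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue ``(theta, tau)`` of one chain; NaN where undefined.

    Raises for chains shorter than 4 residues (no dihedral exists).
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 4:
        raise ValueError(
            f"chain of {len(coords)} residues is too short for a pseudo "
            "dihedral (needs >= 4)"
        )
    return bond_angles(coords), pseudo_dihedrals(coords)


def _in_window(x: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (x >= window[0]) & (x <= window[1])


def helix_candidates(coords: np.ndarray,
                     params: SSParams = DEFAULT_SS_PARAMS) -> np.ndarray:
    theta, tau = backbone_geometry(coords)
    return _in_window(theta, params.helix_theta) & \
        _in_window(tau, params.helix_tau)


def strand_candidates(coords: np.ndarray,
                      params: SSParams = DEFAULT_SS_PARAMS) -> np.ndarray:
    theta, tau = backbone_geometry(coords)
    with np.errstate(invalid="ignore"):
        tau_ok = np.abs(tau) >= params.strand_abs_tau_min
    return _in_window(theta, params.strand_theta) & tau_ok


def _expand_runs(candidates: np.ndarray) -> np.ndarray:
    """Expand each maximal candidate run [a, b] to the span [a-1, b+2]."""
    mask = np.zeros(len(candidates), dtype=bool)
    n = len(candidates)
    i = 0
    while i < n:
        if candidates[i]:
            j = i
            while j + 1 < n and candidates[j + 1]:
                j += 1
            mask[max(0, i - 1): min(n, j + 3)] = True
            i = j + 1
        else:
            i += 1
    return mask


def assign_ss(conf: Conformation,
              params: SSParams = DEFAULT_SS_PARAMS) -> SSAssignment:
    """Assign H/E/C labels and sheet pairings to every chain.

    Helix takes precedence over strand where expanded spans overlap
    (candidate windows themselves are disjoint in ``tau``).
    """
    helix_masks: dict[str, np.ndarray] = {}
    extended_masks: dict[str, np.ndarray] = {}
    for ch in conf.chains:
        h = _expand_runs(helix_candidates(ch.ca_coords, params))
        e = _expand_runs(strand_candidates(ch.ca_coords, params)) & ~h
        helix_masks[ch.chain_id] = h
        extended_masks[ch.chain_id] = e
    pairs = detect_sheet_pairings(conf, extended_masks, params)
    in_sheet: dict[str, set[int]] = {ch.chain_id: set() for ch in conf.chains}
    for p in pairs:
        in_sheet[p.chain_a].add(p.res_a)
        in_sheet[p.chain_b].add(p.res_b)
    labels: dict[str, np.ndarray] = {}
    for ch in conf.chains:
        lab = np.full(ch.n_residues, "C", dtype="U1")
        lab[helix_masks[ch.chain_id]] = "H"
        if in_sheet[ch.chain_id]:
            idx = np.fromiter(in_sheet[ch.chain_id], dtype=int) - 1
            lab[idx] = "E"
        labels[ch.chain_id] = lab
    return SSAssignment(labels=labels, sheet_pairs=pairs)


def detect_sheet_pairings(conf: Conformation,
                          extended_mask: dict[str, np.ndarray],
                          params: SSParams = DEFAULT_SS_PARAMS
                          ) -> list[SheetPair]:
    """Pair extended residues into sheets with a consistent register.

    Residues ``i`` (chain X) and ``j`` (chain Y) pair when both are
    extended candidates, their Calpha distance is below the pairing
    cutoff, and the pairing propagates over >= ``min_strand_len``
    consecutive residues with register ``+1`` (parallel: the partner
    index increases with ``i``) or ``-1`` (antiparallel).  Intrachain
    pairs additionally require a sequence separation that excludes
    trivially close neighbours.
    """
    chains = conf.chains
    # candidate close pairs per chain pair, canonical order
    close: set[tuple[int, int, int, int]] = set()  # (ci, i, cj, j), 0-based
    for a in range(len(chains)):
        for b in range(a, len(chains)):
            ma = extended_mask[chains[a].chain_id]
            mb = extended_mask[chains[b].chain_id]
            ia = np.where(ma)[0]
            ib = np.where(mb)[0]
            if len(ia) == 0 or len(ib) == 0:
                continue
            d = cdist(chains[a].ca_coords[ia], chains[b].ca_coords[ib])
            for k, m in zip(*np.where(d < params.pairing_cutoff)):
                i, j = int(ia[k]), int(ib[m])
                if a == b:
                    if j - i < params.min_intra_pair_sep:
                        continue
                close.add((a, i, b, j))

    min_run = params.min_strand_len
    pairs: list[SheetPair] = []
    seen: set[tuple[int, int, int, int, str]] = set()
    for (a, i, b, j) in close:
        for step, orientation in ((1, "parallel"), (-1, "antiparallel")):
            run = 1
            k = 1
            while (a, i + k, b, j + step * k) in close:
                run += 1
                k += 1
            k = 1
            while (a, i - k, b, j - step * k) in close:
                run += 1
                k += 1
            if run >= min_run:
                key = (a, i, b, j, orientation)
                if key in seen:
                    continue
                seen.add(key)
                pairs.append(SheetPair(
                    chain_a=chains[a].chain_id, res_a=i + 1,
                    chain_b=chains[b].chain_id, res_b=j + 1,
                    orientation=orientation,
                    scope="intra" if a == b else "inter"))
    pairs.sort(key=lambda p: (p.chain_a, p.res_a, p.chain_b, p.res_b,
                              p.orientation))
    return pairs


def count_ss_region(assignment: SSAssignment,
                    region: tuple[int, int] = SS_REGION) -> SSCounts:
    """Count helix and sheet residues in ``region`` over all chains."""
    lo, hi = region
    any_len = max(len(v) for v in assignment.labels.values())
    if not (1 <= lo <= hi <= any_len):
        raise ValueError(f"invalid region {region} for {any_len} residues")
    alpha = beta = 0
    for lab in assignment.labels.values():
        window = lab[lo - 1: hi]
        alpha += int(np.sum(window == "H"))
        beta += int(np.sum(window == "E"))
    return SSCounts(alpha=alpha, beta=beta, region=region)


def split_B_HB(counts: Sequence[SSCounts]
               ) -> tuple[np.ndarray, dict, dict]:
    """Split snapshots into the no-helix state B and the rest (HB).

    Returns per-snapshot state labels ("B"/"HB"), the 1D probability of
    the sheet-residue count within B, and the 2D (alpha, beta)
    probability within HB (integer-resolution histograms as
    ``{"values"/"alpha"/"beta": ..., "p": ...}`` dicts).
    """
    alphas = np.array([c.alpha for c in counts])
    betas = np.array([c.beta for c in counts])
    states = np.where(alphas == 0, "B", "HB")
    b_mask = alphas == 0
    b_density: dict = {"beta": np.array([], dtype=int),
                       "p": np.array([])}
    if b_mask.any():
        vals, freq = np.unique(betas[b_mask], return_counts=True)
        b_density = {"beta": vals, "p": freq / freq.sum()}
    hb_density: dict = {"alpha": np.array([], dtype=int),
                        "beta": np.array([], dtype=int),
                        "p": np.zeros((0, 0))}
    if (~b_mask).any():
        a_vals = np.arange(alphas[~b_mask].min(), alphas[~b_mask].max() + 1)
        b_vals = np.arange(betas[~b_mask].min(), betas[~b_mask].max() + 1)
        h = np.zeros((len(a_vals), len(b_vals)))
        for a, b in zip(alphas[~b_mask], betas[~b_mask]):
            h[a - a_vals[0], b - b_vals[0]] += 1
        hb_density = {"alpha": a_vals, "beta": b_vals, "p": h / h.sum()}
    return states, b_density, hb_density


def cumulative_dos_curve(counts: Sequence[SSCounts],
                         cutoffs: np.ndarray) -> np.ndarray:
    """Fraction of snapshots within a free-energy cutoff of state B's mode.

    The joint ``(alpha, beta)`` probability is histogrammed at integer
    resolution; the reference probability is the maximum on the
    ``alpha = 0`` axis (the most probable no-helix state), and each
    snapshot contributes at the effective free energy
    ``-ln(P(bin)/Pmax)`` of its own bin.  The curve is non-decreasing
    and reaches 1.  Raises when no snapshot has ``alpha = 0`` (the
    reference state is then undefined).
    """
    alphas = np.array([c.alpha for c in counts])
    betas = np.array([c.beta for c in counts])
    if not np.any(alphas == 0):
        raise ValueError("no alpha = 0 snapshot: reference state undefined")
    keys = {}
    for a, b in zip(alphas, betas):
        keys[(a, b)] = keys.get((a, b), 0) + 1
    total = len(alphas)
    p = {k: v / total for k, v in keys.items()}
    pmax = max(v for (a, _b), v in p.items() if a == 0)
    f_of_bin = {k: -np.log(v / pmax) for k, v in p.items()}
    f_per_snapshot = np.array([f_of_bin[(a, b)]
                               for a, b in zip(alphas, betas)])
    cutoffs = np.asarray(cutoffs, dtype=float)
    return np.array([(f_per_snapshot <= c).mean() for c in cutoffs])


@dataclass(frozen=True)
class OrientationStats:
    """Percentages of residues in parallel / antiparallel sheets."""

    parallel: float
    antiparallel: float
    by_scope: dict = field(default_factory=dict)
    n_residues_total: int = 0


def orientation_percentages(assignments: Sequence[SSAssignment],
                            n_residues_per_snapshot: int | None = None
                            ) -> OrientationStats:
    """Percentage of all residues in parallel / antiparallel sheets.

    A residue found in both orientations counts once per orientation;
    the denominator is the total residue count over chains and
    snapshots.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("empty ensemble")
    total = 0
    hits = {"parallel": 0, "antiparallel": 0}
    by_scope = {(o, s): 0 for o in ("parallel", "antiparallel")
                for s in ("intra", "inter")}
    for asg in assignments:
        total += sum(len(v) for v in asg.labels.values())
        for orientation in ("parallel", "antiparallel"):
            hits[orientation] += len(asg.residues_in_sheets(orientation))
            for scope in ("intra", "inter"):
                by_scope[(orientation, scope)] += len(
                    asg.residues_in_sheets(orientation, scope))
    if n_residues_per_snapshot is not None:
        total = n_residues_per_snapshot * len(assignments)
    return OrientationStats(
        parallel=100.0 * hits["parallel"] / total,
        antiparallel=100.0 * hits["antiparallel"] / total,
        by_scope={f"{o}_{s}": 100.0 * v / total
                  for (o, s), v in by_scope.items()},
        n_residues_total=total)
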