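"""Two-chain Calpha ensembles with planted, labelled structure.

The generator emulates the statistical features of coarse-grained dimer
trajectories that the downstream analyses consume, with exact ground
truth attached to every snapshot:

* chains of 140 residues with 3.8 A virtual bonds;
* planted ideal alpha-helix, beta-strand and self-avoiding coil
  segments;
* planted intermolecular beta-sheet interfaces at fibril-like 4.8 A
  spacing, in-register or register-shifted, parallel or antiparallel;
* a tunable mixture of free-monomer, disordered-dimer and
  pre-fibrillar (in-register) dimer snapshots;
* per-chain radius-of-gyration values drawn from a configurable
  Gaussian mixture, realised by biasing the coil growth toward or away
  from the running centroid (virtual bonds stay at 3.8 A; coordinates
  are never rescaled).

Coil steps are rejected whenever they would complete a helix-window
``(theta, tau)`` quadruplet, so the planted labels and the geometry seen
by the secondary-structure assignment stay mutually consistent.  All
randomness derives from integer seeds; generation is bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import CA_BOND_LENGTH, FIBRIL_SPACING, N_RESIDUES
from .geometry import kabsch, rigid_transform
from .io_ensemble import ChainRecord, Conformation, EnsembleHandle
from .cutabi import DEFAULT_SS_PARAMS, helix_candidates

__all__ = [
    "SegmentSpec", "DimerPlantSpec", "EnsembleSpec", "PlantError",
    "build_segment", "assemble_chain", "plant_dimer", "sample_ensemble",
]

_MIN_NONBONDED = 4.0  # A, self-avoidance floor for non-bonded residues
_HALF_SPACE_MARGIN = 1.5  # A, bulk-to-interface-plane clearance


class PlantError(RuntimeError):
    """Raised when a chain or dimer interface cannot be built sterically."""


@dataclass(frozen=True)
class SegmentSpec:
    """A planted secondary-structure segment inside one chain."""

    kind: str  # "helix" | "strand" | "coil"
    start: int  # 1-based first residue
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand", "coil"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if self.start < 1:
            raise ValueError("segment start is 1-based")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class DimerPlantSpec:
    """Geometry of a planted intermolecular sheet interface."""

    interface_kind: str = "in_register_parallel"
    interface_start: int = 78
    interface_length: int = 18
    register_shift: int = 0
    interchain_spacing: float = FIBRIL_SPACING

    def __post_init__(self) -> None:
        kinds = ("in_register_parallel", "shifted_parallel",
                 "antiparallel", "none")
        if self.interface_kind not in kinds:
            raise ValueError(f"interface_kind must be one of {kinds}")
        if self.interchain_spacing <= 0:
            raise ValueError("interchain spacing must be positive")
        if self.interface_kind == "in_register_parallel" \
                and self.register_shift != 0:
            raise ValueError("in-register interface implies shift 0")


@dataclass(frozen=True)
class EnsembleSpec:
    """Study conditions of one synthetic ensemble.

    Defaults emulate wild-type study conditions:
    31% of snapshots are dimers, 8.33% of those carry an in-register
    native-contact run (interface residues 78-95, 18 contacts at 4.8 A),
    and per-chain radii of gyration follow the two-component mixture
    0.6 N(33.5, 2.5^2) + 0.4 N(42.2, 2.5^2) (A).
    """

    n_snapshots: int = 100
    dimer_fraction: float = 0.31
    dfncs_fraction_of_dimers: float = 0.0833
    n_residues: int = N_RESIDUES
    segments_a: tuple[SegmentSpec, ...] = ()
    segments_b: tuple[SegmentSpec, ...] = ()
    rg_mixture: tuple[tuple[float, float, float], ...] = (
        (33.5, 2.5, 0.6), (42.2, 2.5, 0.4))
    dfncs_interface: DimerPlantSpec = field(
        default_factory=DimerPlantSpec)
    dimer_interface: DimerPlantSpec = field(
        default_factory=lambda: DimerPlantSpec(
            interface_kind="shifted_parallel", interface_start=70,
            interface_length=12, register_shift=1))
    monomer_separation: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        for frac in (self.dimer_fraction, self.dfncs_fraction_of_dimers):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        w = sum(c[2] for c in self.rg_mixture)
        if abs(w - 1.0) > 1e-6:
            raise ValueError("Rg mixture weights must sum to 1")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# ideal segment geometry

def _helix_coords(n: int) -> np.ndarray:
    # radius 2.3 A, rise 1.5 A per residue, 100 deg per residue
    i = np.arange(n)
    t = np.radians(100.0 * i)
    return np.c_[2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * i]


def _strand_coords(n: int, phase: int = 1) -> np.ndarray:
    # planar zig-zag: 3.3 A axial rise, lateral offset chosen so that
    # the virtual bond is exactly 3.8 A; `phase` flips the first offset
    rise = 3.3
    off = np.sqrt(CA_BOND_LENGTH ** 2 - rise ** 2) / 2.0
    i = np.arange(n)
    return np.c_[rise * i, phase * ((-1.0) ** i) * off, np.zeros(n)]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def build_segment(kind: str, n: int, seed: int = 0,
                  compactness: float = 0.0) -> np.ndarray:
    """Ideal Calpha geometry of one segment, starting near the origin.

    ``helix``: alpha-helix parametrisation (radius 2.3 A, rise 1.5 A per
    residue, 100 deg per residue); ``strand``: extended zig-zag with
    3.8 A virtual bonds; ``coil``: seeded self-avoiding random walk with
    3.8 A bonds and a 4.0 A non-bonded floor.
    """
    if n < 1:
        raise ValueError("segment needs at least 1 residue")
    if kind == "helix":
        return _helix_coords(n)
    if kind == "strand":
        return _strand_coords(n)
    if kind == "coil":
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xC01])
        pts = _grow_coil(np.zeros((0, 3)), n, rng, compactness)
        if pts is None:
            raise PlantError(f"coil walk of {n} residues got stuck")
        return pts
    raise ValueError(f"unknown segment kind {kind!r}")


def _completes_helix_quadruplet(last3: np.ndarray, cand: np.ndarray,
                                reverse: bool = False) -> np.ndarray:
    """For each candidate next point, would the completed quadruplet
    carry a helix-window (theta, tau) residue?

    Growing forward, the candidate fixes ``tau`` of the residue two
    steps back whose ``theta`` is already known.  Growing a reversed
    trace, the candidate fixes *both* ``theta`` and ``tau`` of its
    neighbouring residue (the signed dihedral is invariant under order
    reversal, so it is evaluated on the reversed quadruplet directly).
    """
    p0, p1, p2 = last3
    t_lo, t_hi = DEFAULT_SS_PARAMS.helix_theta
    if reverse:
        # theta at the residue next to the candidate: (cand, p2, p1)
        u = cand - p2
        v = p1 - p2
        nu = np.linalg.norm(u, axis=1)
        cosang = (u @ v) / (nu * np.linalg.norm(v))
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        theta_ok = (theta >= t_lo) & (theta <= t_hi)
        if not np.any(theta_ok):
            return np.zeros(len(cand), dtype=bool)
    else:
        u = p0 - p1
        v = p2 - p1
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if not (t_lo <= theta <= t_hi):
            return np.zeros(len(cand), dtype=bool)
        theta_ok = np.ones(len(cand), dtype=bool)
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = cand - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1_hat = b1 / np.linalg.norm(b1)
    x = n2 @ n1
    y = np.cross(np.broadcast_to(n1, n2.shape), n2) @ b1_hat
    tau = np.degrees(np.arctan2(y, x))
    tau_lo, tau_hi = DEFAULT_SS_PARAMS.helix_tau
    return theta_ok & (tau >= tau_lo) & (tau <= tau_hi)


def _grow_coil(existing: np.ndarray, n_new: int, rng: np.random.Generator,
               compactness: float = 0.0,
               half_space: tuple[np.ndarray, float] | None = None,
               n_candidates: int = 24,
               reverse: bool = False,
               tracker: dict | None = None) -> np.ndarray | None:
    """Continue a trace by ``n_new`` self-avoiding 3.8 A steps.

    ``compactness`` biases each step toward (positive) or away from
    (negative) the running centroid, which tunes the radius of gyration
    without touching bond lengths.  When a ``tracker`` dict with keys
    ``target`` (A) and ``n_total`` is given, each step instead picks the
    feasible candidate whose partial radius of gyration best follows the
    growth profile ``target * (k / n_total) ** nu`` -- a per-step growth
    bias that realises a prescribed chain Rg exactly, again without
    touching bond lengths.  ``half_space = (normal, offset)`` confines
    new points to ``point . normal >= offset``.  Returns only the new
    points, or None when the walk jams.
    """
    pts = list(np.asarray(existing, dtype=float))
    new_pts = []
    centroid = np.mean(pts, axis=0) if pts else np.zeros(3)
    s1 = np.sum(pts, axis=0) if pts else np.zeros(3)
    s2 = float(sum(p @ p for p in pts))
    for _ in range(n_new):
        if not pts:
            start = np.zeros(3)
            if half_space is not None:
                normal, offset = half_space
                start = start + normal * max(0.0, offset)
            pts.append(start)
            new_pts.append(start)
            centroid = start.copy()
            s1 = s1 + start
            s2 += float(start @ start)
            continue
        cur = pts[-1]
        chosen = None
        for _resample in range(4):
            dirs = rng.normal(size=(n_candidates, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            if compactness != 0.0 and len(pts) > 1:
                attractor = centroid
                if half_space is not None and compactness > 0.0:
                    # pull toward a point safely inside the allowed
                    # half-space, not against its boundary
                    normal, offset = half_space
                    depth = attractor @ normal
                    if depth < offset + 3.0:
                        attractor = attractor + (offset + 3.0 - depth) \
                            * normal
                radial = attractor - cur
                norm = np.linalg.norm(radial)
                if norm > 1e-9:
                    dirs = dirs + compactness * radial / norm
                    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            cand = cur + CA_BOND_LENGTH * dirs
            feasible = np.ones(n_candidates, dtype=bool)
            if len(pts) > 1:
                d = cdist(cand, np.asarray(pts[:-1]))
                feasible &= np.all(d >= _MIN_NONBONDED, axis=1)
            if half_space is not None:
                normal, offset = half_space
                feasible &= cand @ normal >= offset
            if len(pts) >= 3:
                # keep the coil geometrically coil: never complete a
                # helix-window (theta, tau) quadruplet
                feasible &= ~_completes_helix_quadruplet(
                    np.asarray(pts[-3:]), cand, reverse=reverse)
            idx = np.where(feasible)[0]
            if len(idx):
                if tracker is not None:
                    k = len(pts) + 1
                    prof = tracker["target"] * \
                        (k / tracker["n_total"]) ** tracker.get("nu", 0.55)
                    new_s1 = s1 + cand[idx]
                    new_s2 = s2 + np.einsum("ij,ij->i", cand[idx],
                                            cand[idx])
                    rg2 = new_s2 / k - np.einsum(
                        "ij,ij->i", new_s1 / k, new_s1 / k)
                    rg_cand = np.sqrt(np.maximum(rg2, 0.0))
                    chosen = cand[idx[np.argmin(np.abs(rg_cand - prof))]]
                else:
                    chosen = cand[idx[0]]
                break
        if chosen is None:
            return None
        pts.append(chosen)
        new_pts.append(chosen)
        centroid = centroid + (chosen - centroid) / len(pts)
        s1 = s1 + chosen
        s2 += float(chosen @ chosen)
    return np.asarray(new_pts)


def _attach_segment(existing: np.ndarray, local: np.ndarray,
                    rng: np.random.Generator,
                    half_space: tuple[np.ndarray, float] | None = None,
                    n_tries: int = 24) -> np.ndarray | None:
    """Rigidly place a segment continuing from the last existing point."""
    if len(existing) == 0:
        return rigid_transform(local, _random_rotation(rng), np.zeros(3))
    cur = existing[-1]
    for _ in range(n_tries):
        rot = _random_rotation(rng)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        placed = rigid_transform(local, rot, np.zeros(3))
        placed = placed - placed[0] + cur + CA_BOND_LENGTH * d
        if len(existing) > 1:
            dist = cdist(placed, existing[:-1])
            if dist.min() < _MIN_NONBONDED:
                continue
        if half_space is not None:
            normal, offset = half_space
            if np.any(placed @ normal < offset):
                continue
        return placed
    return None


def _normalize_segments(segments: Sequence[SegmentSpec], n_total: int
                        ) -> list[SegmentSpec]:
    segs = sorted(segments, key=lambda s: s.start)
    prev_end = 0
    for s in segs:
        if s.start <= prev_end:
            raise ValueError(f"overlapping segments at residue {s.start}")
        if s.end > n_total:
            raise ValueError(
                f"segment {s.kind} {s.start}-{s.end} exceeds chain "
                f"length {n_total}")
        prev_end = s.end
    return segs


def _spurious_helix(coords: np.ndarray,
                    helix_segments: list[SegmentSpec]) -> bool:
    """Any helix-window candidate outside planted helix interiors?"""
    cand = helix_candidates(coords, DEFAULT_SS_PARAMS)
    allowed = np.zeros(len(coords), dtype=bool)
    for s in helix_segments:
        allowed[s.start - 1: s.end] = True
    return bool(np.any(cand & ~allowed))


def assemble_chain(segments: Sequence[SegmentSpec], n_total: int,
                   seed: int = 0, chain_id: str = "A",
                   compactness: float = 0.0, rg_target: float | None = None,
                   max_retries: int = 40,
                   anchor: SegmentSpec | None = None,
                   anchor_phase: int = 1
                   ) -> tuple[ChainRecord, np.ndarray]:
    """Build one chain with planted segments; gaps become coil.

    Returns the chain record together with the ground-truth per-residue
    label vector (``H``/``E``/``C``); junction (unlisted) residues are
    coil in the ground truth.

    When ``anchor`` names one of the strand segments, that segment is
    laid out first at a canonical pose (along +x, zig-zag in the xy
    plane, first lateral offset set by ``anchor_phase``) and the rest of
    the chain is grown into the ``z > 0`` half-space.  This leaves the
    ``z < 0`` face of the anchor strand free for an intermolecular
    sheet partner.

    ``rg_target`` steers every coil step so that the final chain radius
    of gyration lands on the requested value (A).
    """
    segs = _normalize_segments(segments, n_total)
    labels = np.full(n_total, "C", dtype="U1")
    code = {"helix": "H", "strand": "E", "coil": "C"}
    for s in segs:
        labels[s.start - 1: s.end] = code[s.kind]
    helix_segs = [s for s in segs if s.kind == "helix"]
    if anchor is not None and anchor not in segs:
        raise ValueError("anchor must be one of the planted segments")

    tracker = None if rg_target is None else \
        {"target": float(rg_target), "n_total": n_total}
    for attempt in range(max_retries):
        rng = np.random.default_rng(
            [int(seed) & 0x7FFFFFFF, 0xA55, attempt])
        if anchor is None:
            coords = _build_chain_geometry(segs, n_total, rng, compactness,
                                           tracker=tracker)
        else:
            coords = _build_anchored_geometry(segs, n_total, rng,
                                              compactness, anchor,
                                              anchor_phase,
                                              tracker=tracker)
        if coords is None:
            continue
        if _spurious_helix(coords, helix_segs):
            continue
        return (ChainRecord(chain_id=chain_id, ca_coords=coords), labels)
    raise PlantError(
        f"could not assemble a consistent chain after {max_retries} tries")


def _segment_local(s: SegmentSpec) -> np.ndarray | None:
    if s.kind == "helix":
        return _helix_coords(s.length)
    if s.kind == "strand":
        return _strand_coords(s.length)
    return None


def _build_chain_geometry(segs: list[SegmentSpec], n_total: int,
                          rng: np.random.Generator, compactness: float,
                          half_space: tuple[np.ndarray, float] | None = None,
                          tracker: dict | None = None
                          ) -> np.ndarray | None:
    coords = np.zeros((0, 3))
    pos = 1  # next residue to place, 1-based
    for s in segs + [None]:  # trailing None flushes the final coil
        gap_end = n_total if s is None else s.start - 1
        if gap_end >= pos:
            new = _grow_coil(coords, gap_end - pos + 1, rng, compactness,
                             half_space, tracker=tracker)
            if new is None:
                return None
            coords = np.vstack([coords, new]) if len(coords) else new
            pos = gap_end + 1
        if s is None:
            break
        local = _segment_local(s)
        if local is None:
            new = _grow_coil(coords, s.length, rng, compactness,
                             half_space, tracker=tracker)
        else:
            new = _attach_segment(coords, local, rng, half_space)
        if new is None:
            return None
        coords = np.vstack([coords, new]) if len(coords) else new
        pos = s.end + 1
    return coords


def _build_anchored_geometry(segs: list[SegmentSpec], n_total: int,
                             rng: np.random.Generator, compactness: float,
                             anchor: SegmentSpec, anchor_phase: int,
                             tracker: dict | None = None
                             ) -> np.ndarray | None:
    """Anchor strand at canonical pose; grow both tails into z > 0."""
    half = (np.array([0.0, 0.0, 1.0]), _HALF_SPACE_MARGIN)
    anchor_coords = _strand_coords(anchor.length, phase=anchor_phase)

    # forward part: residues after the anchor, grown left to right
    after = [s for s in segs if s.start > anchor.end]
    coords = anchor_coords
    pos = anchor.end + 1
    for s in after + [None]:
        gap_end = n_total if s is None else s.start - 1
        if gap_end >= pos:
            new = _grow_coil(coords, gap_end - pos + 1, rng, compactness,
                             half, tracker=tracker)
            if new is None:
                return None
            coords = np.vstack([coords, new])
            pos = gap_end + 1
        if s is None:
            break
        local = _segment_local(s)
        new = (_grow_coil(coords, s.length, rng, compactness, half,
                          tracker=tracker)
               if local is None
               else _attach_segment(coords, local, rng, half))
        if new is None:
            return None
        coords = np.vstack([coords, new])
        pos = s.end + 1

    # backward part: residues before the anchor, grown on the reversed
    # trace (theta and signed tau are invariant under order reversal)
    before = [s for s in segs if s.end < anchor.start]
    rev = coords[::-1]
    pos = anchor.start - 1
    for s in list(reversed(before)) + [None]:
        gap_start = 1 if s is None else s.end + 1
        if pos >= gap_start:
            new = _grow_coil(rev, pos - gap_start + 1, rng, compactness,
                             half, reverse=True, tracker=tracker)
            if new is None:
                return None
            rev = np.vstack([rev, new])
            pos = gap_start - 1
        if s is None:
            break
        local = _segment_local(s)
        new = (_grow_coil(rev, s.length, rng, compactness, half,
                          reverse=True, tracker=tracker)
               if local is None
               else _attach_segment(rev, local[::-1], rng, half))
        if new is None:
            return None
        rev = np.vstack([rev, new])
        pos = s.start - 1
    return rev[::-1]


# ---------------------------------------------------------------------------
# dimer planting

def _interface_indices(spec: DimerPlantSpec, n_residues: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """0-based paired residue indices (chain A, chain B)."""
    s0 = spec.interface_start - 1
    idx_a = np.arange(s0, s0 + spec.interface_length)
    if spec.interface_kind in ("in_register_parallel", "shifted_parallel"):
        idx_b = idx_a + spec.register_shift
    elif spec.interface_kind == "antiparallel":
        idx_b = idx_a[::-1] + spec.register_shift
    else:
        raise ValueError("no interface for kind 'none'")
    if idx_a[0] < 0 or idx_a[-1] >= n_residues or idx_b.min() < 0 \
            or idx_b.max() >= n_residues:
        raise ValueError("interface does not fit in both chains")
    return idx_a, idx_b


def plant_dimer(chain_a: ChainRecord, chain_b: ChainRecord,
                spec: DimerPlantSpec, clearance: float = 6.0,
                spacing_tol: float = 0.1) -> Conformation:
    """Place chain B against chain A forming the requested interface.

    The paired residues of B are superposed onto A's interface
    translated by the interchain spacing along the normal of A's strand
    plane (pointing away from the bulk of chain A), so every paired
    Calpha-Calpha distance equals the spacing exactly when both
    interfaces are ideal strands.  All other interchain distances must
    exceed ``clearance``; both normal directions are tried before
    giving up.
    """
    if spec.interface_kind == "none":
        return _place_apart(chain_a, chain_b, max(spec.interchain_spacing,
                                                  25.0))
    na = chain_a.n_residues
    if chain_b.n_residues != na:
        raise ValueError("chains must have equal length")
    idx_a, idx_b = _interface_indices(spec, na)
    iface_a = chain_a.ca_coords[idx_a]
    centred = iface_a - iface_a.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[-1] / np.linalg.norm(vt[-1])
    other = np.delete(chain_a.ca_coords, idx_a, axis=0)
    away = iface_a.mean(axis=0) - other.mean(axis=0)
    if np.dot(normal, away) < 0:
        normal = -normal

    best: tuple[float, np.ndarray] | None = None
    for sign in (1.0, -1.0):
        targets = iface_a + sign * spec.interchain_spacing * normal
        rot, t = kabsch(chain_b.ca_coords[idx_b], targets)
        moved = rigid_transform(chain_b.ca_coords, rot, t)
        pair_d = np.linalg.norm(moved[idx_b] - iface_a, axis=1)
        if np.any(np.abs(pair_d - spec.interchain_spacing) > spacing_tol):
            continue
        d = cdist(chain_a.ca_coords, moved)
        mask = np.ones_like(d, dtype=bool)
        mask[np.ix_(idx_a, idx_b)] = False
        min_other = d[mask].min()
        if best is None or min_other > best[0]:
            best = (min_other, moved)
    if best is None:
        raise PlantError(
            "paired interfaces are not congruent: cannot realise the "
            "requested spacing")
    min_other, moved = best
    if min_other <= clearance:
        raise PlantError(
            f"steric clash: closest non-interface interchain distance "
            f"{min_other:.2f} A <= clearance {clearance:.2f} A")
    return Conformation(
        chains=[chain_a,
                ChainRecord(chain_id=chain_b.chain_id, ca_coords=moved)],
        meta={"interface_kind": spec.interface_kind,
              "interface_start": spec.interface_start,
              "interface_length": spec.interface_length,
              "register_shift": spec.register_shift})


def _place_apart(chain_a: ChainRecord, chain_b: ChainRecord,
                 separation: float) -> Conformation:
    """Translate B so the minimum interchain distance is >= separation."""
    ca = chain_a.ca_coords.mean(axis=0)
    cb = chain_b.ca_coords.mean(axis=0)
    d = cb - ca
    norm = np.linalg.norm(d)
    direction = d / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    ra = np.max(np.linalg.norm(chain_a.ca_coords - ca, axis=1))
    rb = np.max(np.linalg.norm(chain_b.ca_coords - cb, axis=1))
    shift = (ra + rb + separation) * direction + ca - cb
    moved = chain_b.ca_coords + shift
    return Conformation(
        chains=[chain_a,
                ChainRecord(chain_id=chain_b.chain_id, ca_coords=moved)],
        meta={"interface_kind": "none"})


# ---------------------------------------------------------------------------
# radius-of-gyration targeting

def _rg(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


def _chain_with_target_rg(segments, n_total, seed, chain_id, target,
                          anchor=None, anchor_phase=1):
    """Build one chain whose radius of gyration realises ``target`` (A)."""
    target = float(np.clip(target, 22.0, 52.0))
    return assemble_chain(segments, n_total, seed=seed, chain_id=chain_id,
                          rg_target=target, anchor=anchor,
                          anchor_phase=anchor_phase)


# ---------------------------------------------------------------------------
# ensemble sampling

def _draw_rg(rng: np.random.Generator,
             mixture: Sequence[tuple[float, float, float]]) -> float:
    weights = np.array([c[2] for c in mixture])
    k = rng.choice(len(mixture), p=weights / weights.sum())
    mean, sd, _w = mixture[k]
    return float(rng.normal(mean, sd))


def sample_ensemble(spec: EnsembleSpec
                    ) -> tuple[EnsembleHandle, pd.DataFrame]:
    """Generate a labelled ensemble under the study conditions of `spec`.

    Exactly ``round(n * dimer_fraction)`` snapshots are dimers, of which
    ``round(. * dfncs_fraction_of_dimers)`` carry the in-register
    native-contact interface; the rest are register-shifted (disordered)
    dimers.  Monomer snapshots are placed with interchain separation
    above 10 A.  Returns the ensemble and a tidy ground-truth table with
    one row per (snapshot, chain, residue).
    """
    n = spec.n_snapshots
    n_dimer = _round_half_up(n * spec.dimer_fraction)
    n_dfncs = _round_half_up(n_dimer * spec.dfncs_fraction_of_dimers)
    kinds = (["dfncs"] * n_dfncs
             + ["dimer"] * (n_dimer - n_dfncs)
             + ["monomer"] * (n - n_dimer))
    order_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0x0D1])
    order = order_rng.permutation(n)
    kinds = [kinds[i] for i in np.argsort(order)]

    confs: list[Conformation] = []
    rows: list[dict] = []
    for snap, kind in enumerate(kinds):
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0x5A9, snap])
        conf, labels_ab = _build_snapshot(spec, kind, rng, snap)
        conf.meta.update({"snapshot_index": snap,
                          "source_tag": "synthetic",
                          "planted_kind": kind})
        confs.append(conf)
        for ch, labels in zip(conf.chains, labels_ab):
            for r in range(ch.n_residues):
                rows.append({
                    "snapshot": snap, "chain": ch.chain_id,
                    "residue": r + 1, "planted_label": labels[r],
                    "is_dimer": kind != "monomer",
                    "is_dfncs": kind == "dfncs"})
    table = pd.DataFrame(rows)
    return EnsembleHandle(confs, provenance="synthetic"), table


def _build_snapshot(spec: EnsembleSpec, kind: str,
                    rng: np.random.Generator, snap: int
                    ) -> tuple[Conformation, list[np.ndarray]]:
    if kind == "dfncs":
        iface = spec.dfncs_interface
    elif kind == "dimer":
        iface = spec.dimer_interface
    else:
        iface = None

    target_a = _draw_rg(rng, spec.rg_mixture)
    target_b = _draw_rg(rng, spec.rg_mixture)
    base = (spec.seed & 0xFFFF) * 100003 + snap * 29

    if iface is None:
        chain_a, lab_a = _chain_with_target_rg(
            tuple(spec.segments_a), spec.n_residues, seed=base + 1,
            chain_id="A", target=target_a)
        chain_b, lab_b = _chain_with_target_rg(
            tuple(spec.segments_b), spec.n_residues, seed=base + 2,
            chain_id="B", target=target_b)
        conf = _place_apart(chain_a, chain_b, spec.monomer_separation)
        return conf, [lab_a, lab_b]

    anchor_a = SegmentSpec(kind="strand", start=iface.interface_start,
                           length=iface.interface_length)
    shift = 0 if iface.interface_kind == "antiparallel" \
        else iface.register_shift
    anchor_b = SegmentSpec(kind="strand",
                           start=iface.interface_start + shift,
                           length=iface.interface_length)
    segs_a = tuple(spec.segments_a) + (anchor_a,)
    segs_b = tuple(spec.segments_b) + (anchor_b,)

    chain_a, lab_a = _chain_with_target_rg(
        segs_a, spec.n_residues, seed=base + 1, chain_id="A",
        target=target_a, anchor=anchor_a)
    last_err: Exception | None = None
    for attempt in range(8):
        for phase in (1, -1):
            chain_b, lab_b = _chain_with_target_rg(
                segs_b, spec.n_residues, seed=base + 2 + 13 * attempt,
                chain_id="B", target=target_b, anchor=anchor_b,
                anchor_phase=phase)
            try:
                conf = plant_dimer(chain_a, chain_b, iface)
                return conf, [lab_a, lab_b]
            except PlantError as err:
                last_err = err
    raise PlantError(
        f"snapshot {snap}: dimer placement failed after bounded retries "
        f"({last_err})")
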