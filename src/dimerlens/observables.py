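"""Experiment-facing observables of dimer ensembles.

Radius of gyration (SAXS), Gaussian-mixture clustering of its
distribution, the residue-90 intermolecular distance monitored in
single-molecule FRET experiments, the approximated FRET efficiency
``E = 1 / (1 + (d/R0)^6)``, Chou-Fasman beta-sheet propensity profiles,
and the population-partition arithmetic that converts dimer and
pre-fibrillar fractions into molecule counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .constants import CHOU_FASMAN_BETA
from .fibril import classify_dfncs
from .io_ensemble import Conformation, EnsembleHandle

__all__ = [
    "GMMFit", "FretRecord", "PopulationPartition",
    "radius_of_gyration", "fit_rg_mixture",
    "residue_pair_distance_distribution", "fret_efficiency",
    "chou_fasman_profile", "population_partition",
]


@dataclass
class GMMFit:
    """Gaussian-mixture decomposition of a radius-of-gyration sample."""

    components: list[tuple[float, float, float]]  # (mean A, sd A, weight)
    ensemble_average: float  # A
    n_components: int
    fit_seed: int
    selection_score: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class FretRecord:
    """Approximated FRET efficiency for one Calpha-Calpha distance."""

    ca_distance: float  # A
    dye_distance: float  # A (= ca_distance + offset)
    efficiency: float
    r0: float  # A, Foerster distance
    offset: float  # A, twice the dye-centre-to-Calpha distance


@dataclass(frozen=True)
class PopulationPartition:
    """Molecule counts implied by dimer and pre-fibrillar fractions."""

    n_chains: int
    n_conformers: int
    disordered_dimers: int
    dfncs: int
    free_monomers: int


def radius_of_gyration(conf: Conformation, scope: str = "dimer",
                       chain_id: str | None = None) -> float:
    """Unweighted RMS Calpha distance from the Calpha centroid (A).

    ``scope="dimer"`` pools all chains; ``scope="chain"`` uses a single
    chain (the first, unless ``chain_id`` is given).
    """
    if scope == "dimer":
        coords = conf.all_coords()
    elif scope == "chain":
        ch = conf.chains[0] if chain_id is None else conf.chain(chain_id)
        coords = ch.ca_coords
    else:
        raise ValueError("scope must be 'dimer' or 'chain'")
    if len(coords) == 0:
        raise ValueError("empty coordinate scope")
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


def fit_rg_mixture(samples: Sequence[float], k_max: int = 4,
                   seed: int = 0) -> GMMFit:
    """EM fits for k = 1..k_max; k chosen by the Bayesian information
    criterion with 10 seeded restarts per k."""
    x = np.asarray(list(samples), dtype=float).reshape(-1, 1)
    if len(x) < 50:
        raise ValueError(f"need >= 50 samples, got {len(x)}")
    scores: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in range(1, k_max + 1):
        g = GaussianMixture(n_components=k, n_init=10, random_state=seed)
        g.fit(x)
        scores[k] = float(g.bic(x))
        fits[k] = g
    best_k = min(scores, key=scores.get)
    g = fits[best_k]
    comps = sorted(
        zip(g.means_.ravel(), np.sqrt(g.covariances_.ravel()),
            g.weights_),
        key=lambda c: -c[2])
    return GMMFit(
        components=[(float(m), float(s), float(w)) for m, s, w in comps],
        ensemble_average=float(x.mean()),
        n_components=best_k,
        fit_seed=seed,
        selection_score=scores)


def residue_pair_distance_distribution(
        ensemble: EnsembleHandle | Sequence[Conformation],
        residue: int = 90) -> dict[str, np.ndarray]:
    """Interchain same-residue distances, split by pre-fibrillar status.

    One distance per dimer snapshot: between the Calpha atoms of
    ``residue`` on the two chains.  Returns samples under the keys
    ``"disordered"`` and ``"dfncs"``.
    """
    from .contacts import classify_dimer

    confs = [c for c in ensemble if classify_dimer(c).is_dimer]
    if not confs:
        raise ValueError("no dimer snapshots in the ensemble")
    n = confs[0].chains[0].n_residues
    if not 1 <= residue <= n:
        raise ValueError(f"residue {residue} outside chain 1..{n}")
    out: dict[str, list[float]] = {"disordered": [], "dfncs": []}
    for conf in confs:
        a, b = conf.chains
        d = float(np.linalg.norm(a.ca_coords[residue - 1]
                                 - b.ca_coords[residue - 1]))
        key = "dfncs" if classify_dfncs(conf).is_dfncs else "disordered"
        out[key].append(d)
    return {k: np.asarray(v) for k, v in out.items()}


def fret_efficiency(ca_distance: float, r0: float = 60.0,
                    offset: float = 20.0) -> FretRecord:
    """Approximated FRET efficiency from a Calpha-Calpha distance.

    The dye-to-dye distance is the Calpha distance plus ``offset``
    (twice the estimated dye-centre-to-Calpha distance) and
    ``E = 1 / (1 + (d/R0)^6)``; E = 0.5 exactly at ``d = R0``.
    """
    if r0 <= 0:
        raise ValueError("Foerster distance must be positive")
    if ca_distance < 0:
        raise ValueError("distance must be non-negative")
    d = ca_distance + offset
    e = 1.0 / (1.0 + (d / r0) ** 6)
    return FretRecord(ca_distance=float(ca_distance),
                      dye_distance=float(d), efficiency=float(e),
                      r0=float(r0), offset=float(offset))


def chou_fasman_profile(sequence: str, window: int = 15,
                        edge_weight: float = 0.10) -> np.ndarray:
    """Smoothed Chou-Fasman beta-sheet propensity along a sequence.

    A sliding window of odd size with weights interpolated linearly
    from ``edge_weight`` at the edges to 1.0 at the centre, normalised
    by the weight sum; termini use truncated windows.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    sequence = sequence.upper()
    unknown = sorted(set(sequence) - set(CHOU_FASMAN_BETA))
    if unknown:
        raise ValueError(f"unknown residue letters: {unknown}")
    vals = np.array([CHOU_FASMAN_BETA[a] for a in sequence])
    n = len(vals)
    half = window // 2
    weights = np.array([edge_weight + (1.0 - edge_weight)
                        * (1.0 - abs(k) / half)
                        for k in range(-half, half + 1)])
    prof = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = weights[lo - i + half: hi - i + half]
        prof[i] = float(np.dot(w, vals[lo:hi]) / w.sum())
    return prof


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def population_partition(n_chains: int, dimer_fraction: float,
                         dfncs_fraction_of_dimers: float
                         ) -> PopulationPartition:
    """Molecule counts implied by the two measured fractions.

    ``dimer_fraction`` is the fraction of dimers among *conformers*
    (free monomers + dimers), so ``n_chains = C (1 + dimer_fraction)``
    fixes the conformer count ``C``; the pre-fibrillar count is the
    rounded share of the dimers.
    """
    if not 0 <= dimer_fraction <= 1 or not \
            0 <= dfncs_fraction_of_dimers <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    conformers = _round_half_up(n_chains / (1.0 + dimer_fraction))
    dimers = _round_half_up(conformers * dimer_fraction)
    dfncs = _round_half_up(dimers * dfncs_fraction_of_dimers)
    return PopulationPartition(
        n_chains=n_chains,
        n_conformers=conformers,
        disordered_dimers=dimers - dfncs,
        dfncs=dfncs,
        free_monomers=conformers - dimers)
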