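"""Contact statistics, dimer classification and effective landscapes.

A contact is a pair of Calpha atoms of different residues at a distance
strictly below 6 A.  A snapshot of two chains is a *dimer* when more
than 10 residue pairs have an intermolecular Calpha distance below 5 A
(the in-register spacing of fibril sheets motivates the tighter
cutoff).  Ensembles of dimers are summarised by per-residue mean
intermolecular contacts, contact probability maps, and the
dimensionless effective free-energy landscape ``-ln(P/Pmax)`` over the
(n_inter, n_intra) histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import convolve
from scipy.spatial.distance import cdist, pdist, squareform

from .constants import (CONTACT_CUTOFF, DIMER_CUTOFF, DIMER_MIN_PAIRS)
from .io_ensemble import Conformation, EnsembleHandle

__all__ = [
    "Contact", "ContactSet", "DimerLabel", "LandscapeGrid",
    "compute_contacts", "classify_dimer", "mean_intermolecular_contacts",
    "contact_probability_maps", "effective_landscape", "find_minima",
]


@dataclass(frozen=True)
class Contact:
    chain_i: str
    res_i: int  # 1-based
    chain_j: str
    res_j: int
    distance: float  # A


@dataclass
class ContactSet:
    """All contacts of one snapshot, split into inter- and intrachain."""

    contacts: list[Contact]
    n_inter: int
    n_intra: int


@dataclass(frozen=True)
class DimerLabel:
    is_dimer: bool
    n_close_pairs: int


@dataclass
class LandscapeGrid:
    """2D probability histogram with its effective free energy.

    ``F = -ln(P / Pmax)`` is dimensionless (kT units), zero at the most
    probable bin and ``+inf`` on empty bins.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    P: np.ndarray
    F: np.ndarray
    minima: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


def compute_contacts(conf: Conformation,
                     cutoff: float = CONTACT_CUTOFF,
                     min_seq_sep: int = 1) -> ContactSet:
    """All residue-pair contacts of a 1- or 2-chain snapshot.

    A pair is stored iff its distance is strictly below ``cutoff``;
    intrachain pairs additionally require a sequence separation of at
    least ``min_seq_sep`` (1 keeps bonded neighbours, matching the
    literal contact definition; 3 focuses on sheet-like contacts).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if conf.n_chains not in (1, 2):
        raise ValueError("contacts are defined for 1 or 2 chains")
    contacts: list[Contact] = []
    n_intra = 0
    for ch in conf.chains:
        d = squareform(pdist(ch.ca_coords))
        n = ch.n_residues
        ii, jj = np.triu_indices(n, k=max(min_seq_sep, 1))
        close = d[ii, jj] < cutoff
        for i, j in zip(ii[close], jj[close]):
            contacts.append(Contact(ch.chain_id, i + 1, ch.chain_id,
                                    j + 1, float(d[i, j])))
        n_intra += int(close.sum())
    n_inter = 0
    if conf.n_chains == 2:
        a, b = conf.chains
        d = cdist(a.ca_coords, b.ca_coords)
        ii, jj = np.where(d < cutoff)
        for i, j in zip(ii, jj):
            contacts.append(Contact(a.chain_id, i + 1, b.chain_id,
                                    j + 1, float(d[i, j])))
        n_inter = len(ii)
    return ContactSet(contacts=contacts, n_inter=n_inter, n_intra=n_intra)


def classify_dimer(conf: Conformation,
                   cutoff: float = DIMER_CUTOFF,
                   min_pairs: int = DIMER_MIN_PAIRS) -> DimerLabel:
    """Dimer iff more than ``min_pairs`` interchain pairs are < cutoff."""
    if conf.n_chains != 2:
        raise ValueError(
            f"dimer classification needs exactly 2 chains, got "
            f"{conf.n_chains}")
    a, b = conf.chains
    d = cdist(a.ca_coords, b.ca_coords)
    n_close = int((d < cutoff).sum())
    return DimerLabel(is_dimer=n_close > min_pairs, n_close_pairs=n_close)


def _dimer_pair_matrix(conf: Conformation, cutoff: float) -> np.ndarray:
    a, b = conf.chains
    return cdist(a.ca_coords, b.ca_coords) < cutoff


def mean_intermolecular_contacts(ensemble: EnsembleHandle | Sequence[
        Conformation], cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Mean number of intermolecular contacts per residue.

    For residue ``r`` this is the average, over snapshots and over the
    two chain copies, of the number of residues on the other chain
    within the contact cutoff of ``r``.
    """
    confs = list(ensemble)
    if not confs:
        raise ValueError("empty (dimer) ensemble")
    total = None
    for conf in confs:
        m = _dimer_pair_matrix(conf, cutoff)
        per_res = 0.5 * (m.sum(axis=1) + m.sum(axis=0))
        total = per_res if total is None else total + per_res
    return total / len(confs)


def contact_probability_maps(ensemble: EnsembleHandle | Sequence[
        Conformation], cutoff: float = CONTACT_CUTOFF,
        min_seq_sep: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair contact frequencies: (interchain map, intrachain map).

    The interchain map is symmetrised over chain exchange; the
    intrachain map pools both chains.  Cell values are fractions of
    snapshots in [0, 1].
    """
    confs = list(ensemble)
    if not confs:
        raise ValueError("empty (dimer) ensemble")
    n = confs[0].chains[0].n_residues
    inter = np.zeros((n, n))
    intra = np.zeros((n, n))
    for conf in confs:
        m = _dimer_pair_matrix(conf, cutoff).astype(float)
        inter += 0.5 * (m + m.T)
        for ch in conf.chains:
            d = squareform(pdist(ch.ca_coords))
            c = d < cutoff
            sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
            c &= sep >= max(min_seq_sep, 1)
            intra += 0.5 * c
    return inter / len(confs), intra / len(confs)


def effective_landscape(samples: Iterable[tuple[float, float]],
                        bin_width: float = 5.0) -> LandscapeGrid:
    """Histogram (x, y) samples and convert to ``-ln(P/Pmax)``."""
    pts = np.asarray(list(samples), dtype=float)
    if pts.size == 0:
        raise ValueError("no samples")
    x, y = pts[:, 0], pts[:, 1]

    def edges(v: np.ndarray) -> np.ndarray:
        lo = np.floor(v.min() / bin_width) * bin_width
        hi = np.floor(v.max() / bin_width) * bin_width + bin_width
        return np.arange(lo, hi + 0.5 * bin_width, bin_width)

    xe, ye = edges(x), edges(y)
    h, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    p = h / h.sum()
    with np.errstate(divide="ignore"):
        f = np.where(p > 0, -np.log(p / p.max()), np.inf)
    return LandscapeGrid(x_edges=xe, y_edges=ye, P=p, F=f)


#: 3x3 binomial kernel used to smooth P before minimum detection; its
#: centre weight preserves strict local extrema of isolated peaks.
_SMOOTH_KERNEL = np.array([[1.0, 2.0, 1.0],
                           [2.0, 4.0, 2.0],
                           [1.0, 2.0, 1.0]]) / 16.0


def find_minima(grid: LandscapeGrid, depth_window: float = 1.0
                ) -> list[tuple[float, float, float]]:
    """Local free-energy minima within ``depth_window`` of the global one.

    ``P`` is smoothed with a 3x3 binomial kernel, the effective free
    energy is recomputed, and occupied cells strictly below all 8
    neighbours are reported as ``(x_center, y_center, F)`` sorted by
    ``F`` ascending (ties broken lexicographically on (x, y)); the
    global minimum has ``F = 0``.
    """
    p_s = convolve(grid.P, _SMOOTH_KERNEL, mode="constant", cval=0.0)
    with np.errstate(divide="ignore"):
        f_s = np.where(p_s > 0, -np.log(p_s / p_s.max()), np.inf)
    occupied = grid.P > 0
    nx, ny = f_s.shape
    minima = []
    for i in range(nx):
        for j in range(ny):
            if not occupied[i, j] or not np.isfinite(f_s[i, j]):
                continue
            nb = f_s[max(0, i - 1): i + 2, max(0, j - 1): j + 2]
            if np.sum(f_s[i, j] < nb) == nb.size - 1:  # strictly below all
                if f_s[i, j] <= depth_window:
                    minima.append((float(grid.x_centers[i]),
                                   float(grid.y_centers[j]),
                                   float(f_s[i, j])))
    minima.sort(key=lambda m: (m[2], m[0], m[1]))
    grid.minima = minima
    return minima
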