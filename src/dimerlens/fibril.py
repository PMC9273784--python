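"""Native fibril contacts (Nfcs) and pre-fibrillar dimer detection.

In amyloid fibrils the chains stack as in-register parallel beta-sheets:
residue ``r`` of one chain sits directly above residue ``r`` of the
next, about 4.8 A away.  A *native fibril contact* of a dimer is an
intermolecular contact between residues with the same sequence index at
a distance below 5 A; a dimer carrying at least 5 consecutive Nfcs is a
pre-fibrillar dimer (Dfncs).  The module also estimates the AFM-style
contour length of the stretchable tails outside the Nfc region and
extracts the same-index spacing from multi-chain fibril reference
structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import CA_BOND_LENGTH, NFC_CUTOFF, NFC_MIN_RUN, N_RESIDUES
from .cutabi import DEFAULT_SS_PARAMS, SSParams, assign_ss
from .io_ensemble import ChainRecord, Conformation, EnsembleHandle

__all__ = [
    "NfcSegment", "DfncsLabel", "native_fibril_contacts",
    "classify_dfncs", "nfc_profile", "contour_length_estimate",
    "fibril_reference_sheets",
]


@dataclass(frozen=True)
class NfcSegment:
    """Maximal run of consecutive same-index intermolecular contacts."""

    start: int  # 1-based, inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DfncsLabel:
    is_dfncs: bool
    segments: list[NfcSegment]

    @property
    def max_run(self) -> int:
        return max((s.length for s in self.segments), default=0)


def native_fibril_contacts(conf: Conformation,
                           cutoff: float = NFC_CUTOFF) -> np.ndarray:
    """Boolean vector: same-index interchain distance strictly < cutoff."""
    if conf.n_chains != 2:
        raise ValueError("native fibril contacts need exactly 2 chains")
    a, b = conf.chains
    if a.n_residues != b.n_residues:
        raise ValueError(
            f"chains have unequal lengths ({a.n_residues} vs "
            f"{b.n_residues})")
    d = np.linalg.norm(a.ca_coords - b.ca_coords, axis=1)
    return d < cutoff


def _runs(mask: np.ndarray) -> list[NfcSegment]:
    segs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            segs.append(NfcSegment(start=start + 1, end=i))
            start = None
    if start is not None:
        segs.append(NfcSegment(start=start + 1, end=len(mask)))
    return segs


def classify_dfncs(conf: Conformation, cutoff: float = NFC_CUTOFF,
                   min_run: int = NFC_MIN_RUN) -> DfncsLabel:
    """Pre-fibrillar iff any gapless Nfc run reaches ``min_run``."""
    segments = _runs(native_fibril_contacts(conf, cutoff))
    is_dfncs = any(s.length >= min_run for s in segments)
    return DfncsLabel(is_dfncs=is_dfncs, segments=segments)


def nfc_profile(ensemble: EnsembleHandle | Sequence[Conformation],
                cutoff: float = NFC_CUTOFF
                ) -> tuple[np.ndarray, dict]:
    """Per-residue Nfc probability and the longest run of the ensemble.

    Returns ``(profile, record)`` where ``record`` holds the length,
    start, end and snapshot index of the globally longest gapless run
    (first snapshot wins ties).
    """
    confs = list(ensemble)
    if not confs:
        raise ValueError("empty (dimer) ensemble")
    total = None
    best = {"length": 0, "start": None, "end": None, "snapshot": None}
    for k, conf in enumerate(confs):
        vec = native_fibril_contacts(conf, cutoff)
        total = vec.astype(float) if total is None else total + vec
        for seg in _runs(vec):
            if seg.length > best["length"]:
                best = {"length": seg.length, "start": seg.start,
                        "end": seg.end,
                        "snapshot": conf.meta.get("snapshot_index", k)}
    return total / len(confs), best


def contour_length_estimate(first_nfc_residue: int,
                            chain_length: int = N_RESIDUES,
                            bond: float = CA_BOND_LENGTH) -> int:
    """AFM-style contour length (A), rounded to the nearest Angstrom.

    Twice (once per monomer) the backbone length from the C-terminus to
    the first residue of the native-contact region, at ``bond`` A per
    virtual bond: ``L = 2 (chain_length - r + 1) bond``.
    """
    r = int(first_nfc_residue)
    if not 1 <= r <= chain_length:
        raise ValueError(
            f"residue {r} outside chain 1..{chain_length}")
    return int(round(2.0 * (chain_length - r + 1) * bond))


def fibril_reference_sheets(ref: Conformation,
                            params: SSParams = DEFAULT_SS_PARAMS,
                            ) -> tuple[float, list[tuple[int, int]]]:
    """Same-index interchain spacing inside the sheets of a fibril stack.

    Chains are ordered along the fibril axis (the principal axis of the
    chain centroids) and each is paired with its successor.  Residues
    that the Calpha-trace assignment marks as interchain sheet members
    in both chains of a pair contribute one same-index distance.
    Returns the mean distance (A) and the contiguous residue windows
    involved.
    """
    if ref.n_chains < 2:
        raise ValueError("a fibril reference needs at least 2 chains")
    centroids = np.array([ch.ca_coords.mean(axis=0) for ch in ref.chains])
    centred = centroids - centroids.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    order = np.argsort(centroids @ axis)
    chains: list[ChainRecord] = [ref.chains[i] for i in order]

    assignment = assign_ss(ref, params)
    inter_sheet = {
        ch.chain_id: {r for (c, r) in
                      assignment.residues_in_sheets(scope="inter")
                      if c == ch.chain_id}
        for ch in chains
    }
    distances = []
    residues_used: set[int] = set()
    for a, b in zip(chains[:-1], chains[1:]):
        n = min(a.n_residues, b.n_residues)
        common = (inter_sheet[a.chain_id] & inter_sheet[b.chain_id]
                  & set(range(1, n + 1)))
        for r in sorted(common):
            d = float(np.linalg.norm(a.ca_coords[r - 1]
                                     - b.ca_coords[r - 1]))
            distances.append(d)
            residues_used.add(r)
    if not distances:
        raise ValueError(
            "no interchain sheet residues found in the reference")
    windows = [(s.start, s.end) for s in _runs(
        np.isin(np.arange(1, max(residues_used) + 1),
                sorted(residues_used)))]
    return float(np.mean(distances)), windows
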