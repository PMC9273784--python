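"""Shared fixtures: ideal geometries and small planted conformations."""

from __future__ import annotations

import numpy as np
import pytest

from dimerlens.io_ensemble import ChainRecord, Conformation
from dimerlens.synthetic import (DimerPlantSpec, SegmentSpec,
                                 assemble_chain, plant_dimer)


def ideal_helix(n: int) -> np.ndarray:
    i = np.arange(n)
    t = np.radians(100.0 * i)
    return np.c_[2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * i]


def ideal_strand(n: int, phase: int = 1) -> np.ndarray:
    rise = 3.3
    off = np.sqrt(3.8 ** 2 - rise ** 2) / 2.0
    i = np.arange(n)
    return np.c_[rise * i, phase * ((-1.0) ** i) * off, np.zeros(n)]


def straight_line(n: int, start: np.ndarray, direction: np.ndarray,
                  step: float = 3.8) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    return np.asarray(start) + step * np.outer(np.arange(n), d)


@pytest.fixture(scope="session")
def interface_chains():
    """Two seeded 140-residue chains carrying an 18-residue strand at
    residues 78-95, ready for in-register planting."""
    seg = SegmentSpec(kind="strand", start=78, length=18)
    a, lab_a = assemble_chain([seg], 140, seed=101, chain_id="A",
                              anchor=seg)
    b, lab_b = assemble_chain([seg], 140, seed=102, chain_id="B",
                              anchor=seg, anchor_phase=-1)
    return a, b, lab_a, lab_b


@pytest.fixture(scope="session")
def in_register_dimer(interface_chains):
    a, b, _, _ = interface_chains
    return plant_dimer(a, b, DimerPlantSpec())


@pytest.fixture(scope="session")
def clean_interface_dimer():
    """A dimer whose only non-trivial geometry is the planted interface:
    residues 78-95 are ideal strands paired in register at 4.8 A, all
    other residues lie on straight lines pointing away (a straight trace
    has no strand- or helix-window dihedral, so nothing else can pair)."""
    def make_chain(cid: str, z: float, side: float) -> ChainRecord:
        iface = ideal_strand(18)
        pre_dir = np.array([-1.0, 0.6 * side, 0.8 * side])
        post_dir = np.array([1.0, 0.6 * side, 0.8 * side])
        pre = straight_line(77, iface[0] + 3.8 * pre_dir
                            / np.linalg.norm(pre_dir), pre_dir)[::-1]
        post = straight_line(45, iface[-1] + 3.8 * post_dir
                             / np.linalg.norm(post_dir), post_dir)
        coords = np.vstack([pre, iface, post]) + np.array([0, 0, z])
        return ChainRecord(chain_id=cid, ca_coords=coords)

    a = make_chain("A", 0.0, +1.0)
    b = make_chain("B", 4.8, -1.0)
    return Conformation(chains=[a, b], meta={"source_tag": "fixture"})
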