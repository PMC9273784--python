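"""Read and write coarse-grained Calpha conformations.

Two file dialects are supported:

* multi-model PDB files in which ``MODEL``/``ENDMDL`` blocks delimit
  snapshots, chain identifiers delimit chains, and only ``CA`` atom
  records are consumed;
* a minimal XYZ dialect for coarse-grained traces: one snapshot is a
  header line with the per-chain residue counts (``N_chainA N_chainB``)
  followed by one ``chain_id x y z`` line per residue, chains in order.

Residue numbering is re-indexed to ``1..N`` per chain on load; the
author numbering of the source file is kept in the chain record.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
import biotite.sequence.io.fasta as fastaio

from .constants import CA_BOND_WINDOW

__all__ = [
    "ChainRecord",
    "Conformation",
    "EnsembleHandle",
    "read_structures",
    "write_structures",
    "load_fibril_reference",
    "read_sequence",
]


@dataclass
class ChainRecord:
    """Ordered Calpha trace of one chain."""

    chain_id: str
    ca_coords: np.ndarray  # (N, 3) float, Angstrom
    author_numbering: np.ndarray | None = None  # original residue ids

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be an (N, 3) array")
        if len(self.ca_coords) < 2:
            raise ValueError(
                f"chain {self.chain_id!r} needs at least 2 residues"
            )

    @property
    def n_residues(self) -> int:
        return len(self.ca_coords)

    @property
    def residue_indices(self) -> np.ndarray:
        """1-based contiguous residue indices."""
        return np.arange(1, self.n_residues + 1)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.ca_coords, axis=0), axis=1)


@dataclass
class Conformation:
    """One snapshot: ordered Calpha coordinates of one or more chains."""

    chains: list[ChainRecord]
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def chain(self, chain_id: str) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r}")

    def all_coords(self) -> np.ndarray:
        return np.concatenate([ch.ca_coords for ch in self.chains])

    def is_physical_trace(self, window: tuple[float, float] = CA_BOND_WINDOW
                          ) -> bool:
        """True when all consecutive Calpha distances fall in `window` (A).

        A validation flag, not a hard constraint: coarse-grained snapshots
        with distorted virtual bonds still load.
        """
        lo, hi = window
        return all(
            bool(np.all((b >= lo) & (b <= hi)))
            for b in (ch.bond_lengths() for ch in self.chains)
        )


class EnsembleHandle:
    """Deterministically re-iterable sequence of conformations."""

    def __init__(self, conformations: Sequence[Conformation],
                 provenance: str = "") -> None:
        self._conformations = list(conformations)
        if not self._conformations:
            raise ValueError("an ensemble must hold at least one snapshot")
        self.provenance = provenance

    @property
    def count(self) -> int:
        return len(self._conformations)

    def __len__(self) -> int:
        return self.count

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self._conformations)

    def __getitem__(self, i: int) -> Conformation:
        return self._conformations[i]

    def subset(self, indices: Iterable[int], tag: str = "subset"
               ) -> "EnsembleHandle":
        return EnsembleHandle([self._conformations[i] for i in indices],
                              provenance=f"{self.provenance}:{tag}")


# ---------------------------------------------------------------------------
# PDB

def _conformation_from_atom_array(atoms: struc.AtomArray, model: int,
                                  source: str) -> Conformation:
    chains: list[ChainRecord] = []
    # chains ordered by first appearance
    seen: list[str] = []
    for cid in atoms.chain_id:
        if cid not in seen:
            seen.append(cid)
    for cid in seen:
        sub = atoms[atoms.chain_id == cid]
        res_ids = np.unique(sub.res_id)
        coords = np.empty((len(res_ids), 3))
        for k, rid in enumerate(res_ids):
            ca = sub[(sub.res_id == rid) & (sub.atom_name == "CA")]
            if ca.array_length() == 0:
                raise ValueError(
                    f"missing CA atom (model {model}, chain {cid}, "
                    f"residue {rid}) in {source}"
                )
            coords[k] = ca.coord[0]
        chains.append(ChainRecord(chain_id=str(cid), ca_coords=coords,
                                  author_numbering=res_ids.copy()))
    return Conformation(chains=chains,
                        meta={"snapshot_index": model - 1,
                              "source_tag": source})


def read_structures(path: str | os.PathLike, format: str | None = None
                    ) -> EnsembleHandle:
    """Read a multi-snapshot ensemble from a PDB or XYZ-dialect file.

    Parameters
    ----------
    path
        Input file. Must exist.
    format
        ``"pdb"`` or ``"xyz"``; inferred from the extension when omitted.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "xyz" if path.lower().endswith(".xyz") else "pdb"
    if format == "pdb":
        confs = _read_pdb(path)
    elif format == "xyz":
        confs = _read_xyz(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not confs:
        raise ValueError(f"no models found in {path}")
    return EnsembleHandle(confs, provenance=path)


def _read_pdb(path: str) -> list[Conformation]:
    pdb_file = pdbio.PDBFile.read(path)
    n_models = pdb_file.get_model_count()
    confs = []
    for m in range(1, n_models + 1):
        atoms = pdb_file.get_structure(model=m)
        confs.append(_conformation_from_atom_array(atoms, m, path))
    return confs


def _read_xyz(path: str) -> list[Conformation]:
    confs = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    pos = 0
    model = 1
    while pos < len(lines):
        counts = [int(tok) for tok in lines[pos].split()]
        pos += 1
        chains = []
        for count in counts:
            block = lines[pos:pos + count]
            if len(block) < count:
                raise ValueError(f"truncated snapshot {model} in {path}")
            pos += count
            cid = block[0].split()[0]
            coords = np.array(
                [[float(x) for x in ln.split()[1:4]] for ln in block]
            )
            chains.append(ChainRecord(chain_id=cid, ca_coords=coords))
        confs.append(Conformation(
            chains=chains,
            meta={"snapshot_index": model - 1, "source_tag": path}))
        model += 1
    return confs


def _atom_array_from_conformation(conf: Conformation) -> struc.AtomArray:
    n = sum(ch.n_residues for ch in conf.chains)
    atoms = struc.AtomArray(n)
    k = 0
    for ch in conf.chains:
        for i in range(ch.n_residues):
            atoms.chain_id[k] = ch.chain_id
            atoms.res_id[k] = i + 1
            atoms.res_name[k] = "ALA"
            atoms.atom_name[k] = "CA"
            atoms.element[k] = "C"
            atoms.coord[k] = ch.ca_coords[i]
            k += 1
    atoms.hetero[:] = False
    return atoms


def write_structures(conformations: Sequence[Conformation] | EnsembleHandle,
                     path: str | os.PathLike,
                     format: str | None = None) -> None:
    """Write an ensemble as a multi-model PDB or XYZ-dialect file.

    All snapshots must share one chain topology (multi-model PDB
    requirement).
    """
    path = os.fspath(path)
    confs = list(conformations)
    if not confs:
        raise ValueError("nothing to write")
    if format is None:
        format = "xyz" if path.lower().endswith(".xyz") else "pdb"
    if format == "pdb":
        arrays = [_atom_array_from_conformation(c) for c in confs]
        stack = struc.stack(arrays)
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(path)
    elif format == "xyz":
        with open(path, "w") as fh:
            for conf in confs:
                fh.write(" ".join(str(ch.n_residues)
                                  for ch in conf.chains) + "\n")
                for ch in conf.chains:
                    for xyz in ch.ca_coords:
                        fh.write(f"{ch.chain_id} {xyz[0]:.3f} "
                                 f"{xyz[1]:.3f} {xyz[2]:.3f}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_fibril_reference(path: str | os.PathLike,
                          model: int = 1) -> Conformation:
    """Load a multi-chain fibril structure (first model by default).

    NMR-style entries deposit several models; fibril geometry analysis
    treats the structure as a single geometry, so one model is selected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    pdb_file = pdbio.PDBFile.read(path)
    atoms = pdb_file.get_structure(model=model)
    conf = _conformation_from_atom_array(atoms, model, path)
    if conf.n_chains < 2:
        raise ValueError(
            f"{path} holds {conf.n_chains} chain(s); fibril analysis needs "
            "the intermolecular geometry of at least 2 chains"
        )
    return conf


def read_sequence(path: str | os.PathLike) -> str:
    """Read the first record of a FASTA file as an upper-case string."""
    fasta = fastaio.FastaFile.read(os.fspath(path))
    for _header, seq in fasta.items():
        return str(seq).upper()
    raise ValueError(f"no sequence record in {path}")
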