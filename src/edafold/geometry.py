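"""Torsion-space decoys, Cartesian backbones, CARMSD and PDB I/O.

Decoys live in torsion space: a protein model is a sequence of per-residue
(phi, psi, omega) triplets plus, for residues last written by a 9-mer
insertion, the fragment key recording where the torsions came from.
Cartesian N/CA/C backbones are rebuilt deterministically from torsions with
ideal bond geometry whenever scoring or comparison needs them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.SVDSuperimposer import SVDSuperimposer

from . import _kernels

UNATTRIBUTED = -1


@dataclass
class TorsionDecoy:
    """A candidate solution: torsions plus per-residue fragment provenance."""

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    provenance: np.ndarray = None
    energy: float | None = None
    iteration_born: int = 0

    def __post_init__(self):
        L = len(self.sequence)
        self.phi = np.ascontiguousarray(self.phi, dtype=float)
        self.psi = np.ascontiguousarray(self.psi, dtype=float)
        self.omega = np.ascontiguousarray(self.omega, dtype=float)
        if self.provenance is None:
            self.provenance = np.full(L, UNATTRIBUTED, dtype=np.int64)
        else:
            self.provenance = np.ascontiguousarray(self.provenance, dtype=np.int64)
        for name in ("phi", "psi", "omega", "provenance"):
            if getattr(self, name).shape != (L,):
                raise ValueError(f"{name} must have length {L}")

    @property
    def L(self) -> int:
        return len(self.sequence)

    def copy(self) -> "TorsionDecoy":
        return TorsionDecoy(
            sequence=self.sequence,
            phi=self.phi.copy(),
            psi=self.psi.copy(),
            omega=self.omega.copy(),
            provenance=self.provenance.copy(),
            energy=self.energy,
            iteration_born=self.iteration_born,
        )


@dataclass
class BackboneCoords:
    """Per-residue N, CA, C coordinates in Angstrom."""

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray

    @property
    def L(self) -> int:
        return self.ca.shape[0]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "BackboneCoords":
        """From a (L, 3, 3) array with atom axis ordered (N, CA, C)."""
        return cls(
            n=np.ascontiguousarray(arr[:, 0, :]),
            ca=np.ascontiguousarray(arr[:, 1, :]),
            c=np.ascontiguousarray(arr[:, 2, :]),
        )


def build_backbone(decoy: TorsionDecoy) -> BackboneCoords:
    """Deterministic torsion -> Cartesian chain extension (ideal geometry).

    The first residue sits in a canonical frame (N at the origin, CA on +x,
    C in the xy plane) so identical torsions give identical coordinates.
    """
    if decoy.L == 0:
        empty = np.empty((0, 3))
        return BackboneCoords(n=empty.copy(), ca=empty.copy(), c=empty.copy())
    arr = _kernels.nerf_backbone(decoy.phi, decoy.psi, decoy.omega)
    return BackboneCoords.from_array(arr)


def _ca_array(x) -> np.ndarray:
    ca = x.ca if isinstance(x, BackboneCoords) else np.asarray(x, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("expected (L, 3) CA coordinates or BackboneCoords")
    return ca


def carmsd(a, b) -> float:
    """CA-only RMSD after optimal rigid superposition (Kabsch, no reflection).

    Accepts :class:`BackboneCoords` or raw (L, 3) CA arrays.  Symmetric,
    non-negative, and invariant under rigid transforms of either argument.
    """
    ca_a = _ca_array(a)
    ca_b = _ca_array(b)
    if ca_a.shape != ca_b.shape:
        raise ValueError(f"length mismatch: {ca_a.shape[0]} vs {ca_b.shape[0]}")
    if ca_a.shape[0] < 3:
        raise ValueError("need at least 3 residues for superposition")
    sup = SVDSuperimposer()
    sup.set(ca_a, ca_b)
    sup.run()
    return float(sup.get_rms())


_PDB_ATOMS = (("N", "N"), ("CA", "C"), ("C", "C"))

_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def write_pdb(decoy: TorsionDecoy, coords: BackboneCoords, path) -> None:
    """Write N/CA/C ATOM records, chain A, 1-based numbering."""
    if decoy.L == 0:
        raise ValueError("cannot write an empty decoy")
    if coords.L != decoy.L:
        raise ValueError("coords/decoy length mismatch")
    serial = 1
    with open(path, "w") as fh:
        for i in range(decoy.L):
            resname = _THREE_LETTER.get(decoy.sequence[i], "UNK")
            for (name, element), xyz in zip(
                _PDB_ATOMS, (coords.n[i], coords.ca[i], coords.c[i])
            ):
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s}{resname:>3s} A{i + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def read_pdb_ca(path) -> np.ndarray:
    """CA coordinates of the first model/chain as an (L, 3) array."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("x", path)
    try:
        model = next(iter(structure))
        chain = next(iter(model))
    except StopIteration:
        raise IOError(f"{path}: no model/chain found")
    cas = [res["CA"].get_coord() for res in chain if "CA" in res]
    if not cas:
        raise IOError(f"{path}: no CA atoms found")
    return np.asarray(cas, dtype=float)
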