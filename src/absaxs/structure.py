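"""Coarse-grained bead models of (glyco)proteins.

One bead stands for one amino-acid residue or one monosaccharide. Each bead
carries a position (Angstrom), a dimensionless scattering weight (glycan beads
carry an excess weight relative to protein beads, since glycans scatter more
strongly per unit mass than protein), a chain id, a residue index, and a label
that assigns it to a named rigid body (e.g. ``Fab1``) or a flexible set
(hinges, tailpieces, glycan chains).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = ["StructureModel", "KIND_PROTEIN", "KIND_GLYCAN"]

KIND_PROTEIN = "protein"
KIND_GLYCAN = "glycan"


@dataclass
class StructureModel:
    """A set of scattering beads with rigid-body / flexibility annotations.

    Attributes
    ----------
    coords : (N, 3) ndarray
        Bead centres in Angstrom.
    weights : (N,) ndarray
        Scattering weight per bead (dimensionless, > 0).
    kinds : (N,) ndarray of str
        ``"protein"`` or ``"glycan"``.
    chains : (N,) ndarray of str
        Chain identifier (single character for PDB round-trips).
    resids : (N,) ndarray of int
        1-based residue index within the chain.
    labels : (N,) ndarray of str
        Rigid-body name or flexible-set name; every bead has exactly one.
    """

    coords: np.ndarray
    weights: np.ndarray
    kinds: np.ndarray
    chains: np.ndarray
    resids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = self.coords.shape[0]
        if n == 0 or self.coords.shape[1] != 3:
            raise ValueError("coords must be a non-empty (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,) or np.any(self.weights <= 0):
            raise ValueError("weights must be positive and one per bead")
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.chains = np.asarray(self.chains, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        for arr, name in [(self.kinds, "kinds"), (self.chains, "chains"),
                          (self.resids, "resids"), (self.labels, "labels")]:
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per bead")

    # ------------------------------------------------------------ basics
    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "StructureModel":
        return StructureModel(self.coords.copy(), self.weights.copy(), self.kinds.copy(),
                              self.chains.copy(), self.resids.copy(), self.labels.copy())

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def label_set(self) -> list[str]:
        seen: dict[str, None] = {}
        for lb in self.labels:
            seen.setdefault(lb)
        return list(seen)

    def centroid(self) -> np.ndarray:
        """Scattering-weight-weighted centre of mass."""
        return np.average(self.coords, axis=0, weights=self.weights)

    def rg(self) -> float:
        """Weight-weighted root-mean-square distance from the weighted centroid."""
        d2 = np.sum((self.coords - self.centroid()) ** 2, axis=1)
        return float(np.sqrt(np.average(d2, weights=self.weights)))

    def dmax(self) -> float:
        """Maximal bead-centre pair distance."""
        from scipy.spatial.distance import pdist

        if self.n_beads == 1:
            return 0.0
        return float(pdist(self.coords).max())

    # --------------------------------------------------------------- I/O
    def to_pdb(self, path: str | Path) -> None:
        """Write one CA-named ATOM/HETATM record per bead.

        Glycan beads become HETATM records (residue name GLC); the scattering
        weight is stored in the occupancy column and the label mapping in
        REMARK-style comments is intentionally omitted — labels are restored
        heuristically on read (HETATM -> glycan) or kept by the caller.
        """
        arr = struc.AtomArray(self.n_beads)
        arr.coord = self.coords.astype(np.float32)
        arr.atom_name = np.full(self.n_beads, "CA")
        arr.element = np.full(self.n_beads, "C")
        arr.res_name = np.where(self.kinds == KIND_GLYCAN, "GLC", "ALA")
        arr.hetero = self.kinds == KIND_GLYCAN
        arr.chain_id = self.chains.astype("U4")
        arr.res_id = self.resids
        arr.set_annotation("occupancy", self.weights.astype(float))
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))

    @classmethod
    def from_pdb(cls, path: str | Path, default_label: str = "body") -> "StructureModel":
        """Read beads from a PDB file (one atom record -> one bead).

        The scattering weight is taken from the occupancy column (1.0 where
        absent); HETATM records are classified as glycan beads. Rigid-body
        labels are not stored in PDB, so all beads receive ``default_label``.
        """
        f = pdb.PDBFile.read(str(path))
        arr = f.get_structure(model=1, extra_fields=["occupancy"])
        n = arr.array_length()
        if n == 0:
            raise ValueError(f"{path}: no atoms")
        weights = np.asarray(arr.occupancy, dtype=float)
        weights[weights <= 0] = 1.0
        kinds = np.where(arr.hetero, KIND_GLYCAN, KIND_PROTEIN).astype(object)
        return cls(np.asarray(arr.coord, dtype=float), weights, kinds,
                   np.asarray(arr.chain_id, dtype=object), np.asarray(arr.res_id, dtype=int),
                   np.full(n, default_label, dtype=object))
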