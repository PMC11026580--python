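"""Rigid-body conformational sampling over flexible regions.

The sampler explores antibody Fab-Fc arrangements by randomized pivot moves:
for every bead of a flexible linker (hinge, tailpiece, glycan chain) a random
rotation (Gaussian angle, random axis) is applied to everything downstream of
that bead within its arm or chain. Each Fab arm and each glycan chain is
perturbed independently; candidates with steric clashes between bodies are
rejected and redrawn. Rigid-body internal coordinates are copied unchanged,
so all conformers share exact intra-body geometry with the seed model. Pivot
sampling plays the role that brief very-high-temperature dynamics plays in
MD-based samplers: it decorrelates conformers and keeps the arms from being
trapped near the starting arrangement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .profiles import ScatteringProfile, default_q_grid
from .structure import StructureModel
from .debye import debye_profile

__all__ = ["FlexibilityDefinition", "Ensemble", "sample_ensemble", "ensemble_rg_span"]

RIGID_BODIES = ("Fab1", "Fab2", "Fc")


@dataclass
class FlexibilityDefinition:
    """Which beads are rigid and which may move.

    ``rigid_bodies`` maps body names to bead indices. ``linkers`` are ordered
    bead-index chains pivoted from their first (anchored) bead; each linker
    carries the set of downstream bead indices that ride along with it (the
    arm: its Fab plus arm-anchored glycans, or nothing for a free-ended
    tail). ``branches`` are glycan chains pivoted internally.
    """

    rigid_bodies: dict[str, np.ndarray]
    linkers: list[dict]      # {"chain": idx array (ordered), "payload": idx array}
    branches: list[np.ndarray]
    branch_parents: list[str] = field(default_factory=list)  # body a glycan is anchored on

    @classmethod
    def from_model(cls, model: StructureModel) -> "FlexibilityDefinition":
        """Derive the flexibility layout from the builder's bead labels."""
        labels = model.label_set()
        rigid = {b: model.indices(b) for b in RIGID_BODIES if b in labels}
        if not rigid:
            raise ValueError("model has no recognised rigid-body labels")
        linkers = []
        for hc, fab in (("A", "Fab1"), ("B", "Fab2")):
            hl = f"hinge_{hc}"
            if hl not in labels:
                continue
            hinge = model.indices(hl)
            hinge = hinge[np.argsort(model.resids[hinge])]
            payload = [model.indices(fab)] if fab in labels else []
            hinge_hi = int(model.resids[hinge].max())
            for lab in labels:
                if lab.startswith("glycan_") and lab.endswith(f"_{hc}"):
                    g = model.indices(lab)
                    # glycans anchored on the arm ride with it; Fc glycans do not
                    if int(model.resids[g[0]]) <= hinge_hi:
                        payload.append(g)
            attach = -1
            if fab in labels:
                attach = _proximal_pole_bead(model, model.indices(fab),
                                             model.coords[hinge[0]])
            linkers.append({"chain": hinge,
                            "payload": np.concatenate(payload) if payload else np.empty(0, int),
                            "attach": attach})
        for hc in ("A", "B"):
            tl = f"tail_{hc}"
            if tl in labels:
                tail = model.indices(tl)
                tail = tail[np.argsort(model.resids[tail])]
                linkers.append({"chain": tail, "payload": np.empty(0, int)})
        branches = [model.indices(lab) for lab in labels if lab.startswith("glycan_")]
        parents = []
        hinge_ends = {hc: int(model.resids[model.labels == f"hinge_{hc}"].max())
                      for hc in ("A", "B") if f"hinge_{hc}" in labels}
        for g in branches:
            hc = str(model.chains[g[0]])
            res = int(model.resids[g[0]])
            if res <= hinge_ends.get(hc, 235):
                parents.append("Fab1" if hc == "A" else "Fab2")
            else:
                parents.append("Fc")
        return cls(rigid, linkers, branches, parents)


def _proximal_pole_bead(model: StructureModel, fab_idx: np.ndarray,
                        anchor: np.ndarray) -> int:
    """Bead at the hinge-proximal pole of a Fab's long axis.

    This is the coarse-grained analogue of the CH1 C-terminus where the
    hinge exits the Fab: the extreme bead of the principal axis on the side
    facing the hinge anchor.
    """
    pts = model.coords[fab_idx]
    ctr = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - ctr, full_matrices=False)
    proj = (pts - ctr) @ vt[0]
    lo, hi = int(np.argmin(proj)), int(np.argmax(proj))
    d_lo = np.sum((pts[lo] - anchor) ** 2)
    d_hi = np.sum((pts[hi] - anchor) ** 2)
    return int(fab_idx[lo if d_lo <= d_hi else hi])


@dataclass
class Ensemble:
    """A pool of conformers with per-conformer Rg and theoretical profiles."""

    models: list[StructureModel]
    rgs: np.ndarray
    q: np.ndarray | None = None
    profiles: np.ndarray | None = None     # (n_conformers, n_q)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        # profile-only ensembles (e.g. reloaded from disk) carry no models
        return len(self.models) if self.models else int(self.rgs.size)

    def profile(self, i: int) -> ScatteringProfile:
        if self.profiles is None:
            raise ValueError("ensemble was generated without profiles")
        return ScatteringProfile(self.q, self.profiles[i])

    @classmethod
    def from_models(cls, models: list[StructureModel], q: np.ndarray | None = None,
                    metadata: dict | None = None) -> "Ensemble":
        """Build an ensemble from explicit conformers (profiles computed)."""
        if q is None:
            q = default_q_grid()
        rgs = np.array([m.rg() for m in models])
        profs = np.vstack([debye_profile(m, q).I for m in models])
        return cls(list(models), rgs, q=q, profiles=profs,
                   metadata=metadata or {})

    def concat(self, other: "Ensemble") -> "Ensemble":
        """Pool two ensembles (same q-grid) into one."""
        if (self.profiles is None) != (other.profiles is None):
            raise ValueError("cannot pool ensembles with and without profiles")
        if self.q is not None and other.q is not None and not np.allclose(self.q, other.q):
            raise ValueError("ensembles on different q-grids")
        profs = None
        if self.profiles is not None:
            profs = np.vstack([self.profiles, other.profiles])
        meta = {"pooled": [self.metadata, other.metadata]}
        return Ensemble(self.models + other.models,
                        np.concatenate([self.rgs, other.rgs]),
                        q=self.q, profiles=profs, metadata=meta)

    # -------------------------------------------------------- persistence
    def save(self, directory: str | Path) -> None:
        """Persist as a directory of PDB files + profile matrix + manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.models):
            m.to_pdb(d / f"conformer_{i:05d}.pdb")
        if self.profiles is not None:
            np.savetxt(d / "profiles.dat",
                       np.column_stack([self.q, self.profiles.T]),
                       header="q then one intensity column per conformer")
        manifest = {"n": len(self.models), "rg": self.rgs.tolist(),
                    "metadata": self.metadata}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _random_rotation_matrix(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.normal(0.0, sigma_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def _pivot_chain(coords: np.ndarray, chain: np.ndarray, payload: np.ndarray,
                 rng: np.random.Generator, sigma_deg: float) -> None:
    """Random pivot at every chain bead, rotating all downstream beads."""
    for j in range(chain.size):
        pivot = coords[chain[j]]
        R = _random_rotation_matrix(rng, sigma_deg)
        downstream = chain[j + 1:]
        idx = np.concatenate([downstream, payload]) if payload.size else downstream
        if idx.size == 0:
            continue
        coords[idx] = (coords[idx] - pivot) @ R.T + pivot


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * (K @ K)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _rebuild_arm(coords: np.ndarray, linker: dict, rng: np.random.Generator,
                 sigma_deg: float, step: float = 3.8) -> None:
    """One Fab-arm move: re-aim, re-extend, then fold.

    The arm direction is redrawn around the seed direction (rotation angle
    ~ N(0, 3 sigma)); the hinge is laid at full backbone contour length
    along it; the payload (Fab plus arm glycans) is rotated rigidly so the
    Fab's proximal pole continues the chain, with a random roll about the
    arm axis; finally every hinge bead applies a Gaussian pivot
    (~ N(0, sigma)) to everything downstream, folding the arm back. The
    re-aim/re-extend step is the pool-decorrelation device: pivots alone
    cannot lengthen a linker that the seed model lays short, so without it
    the ensemble could never reach fully splayed arms.
    """
    chain, payload, attach = linker["chain"], linker["payload"], linker["attach"]
    anchor = coords[chain[0]]
    # worm-like hinge: initial direction uniform on the sphere (each arm
    # explores all orientations independently), then a per-step wobble of
    # 2 sigma
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    p = anchor.copy()
    for i in range(1, chain.size):
        u = _random_rotation_matrix(rng, 2.0 * sigma_deg) @ u
        p = p + step * u
        coords[chain[i]] = p
    if payload.size and attach >= 0:
        u = _random_rotation_matrix(rng, 2.0 * sigma_deg) @ u
        a_new = p + step * u
        a_old = coords[attach].copy()
        ctr = coords[payload].mean(axis=0)
        v = ctr - a_old
        if np.linalg.norm(v) < 1e-9:
            v = u
        R = _rotation_between(v, u)
        roll_ang = np.deg2rad(rng.uniform(0.0, 360.0))
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        roll = np.eye(3) + np.sin(roll_ang) * K + (1 - np.cos(roll_ang)) * (K @ K)
        # rotate about the attachment bead (which stays fixed), then
        # translate it onto the new chain end
        coords[payload] = (coords[payload] - a_old) @ (roll @ R).T + a_old
        coords[payload] += a_new - a_old


def _clashes(model: StructureModel, flexdef: FlexibilityDefinition,
             coords: np.ndarray, cutoff: float) -> bool:
    bodies = list(flexdef.rigid_bodies.items())
    for i in range(len(bodies)):
        for j in range(i + 1, len(bodies)):
            if cdist(coords[bodies[i][1]], coords[bodies[j][1]]).min() < cutoff:
                return True
    # glycan chains against rigid bodies other than their anchor body
    for g, parent in zip(flexdef.branches, flexdef.branch_parents):
        for name, bidx in bodies:
            if name == parent:
                continue
            if cdist(coords[g], coords[bidx]).min() < cutoff:
                return True
    return False


def sample_ensemble(model: StructureModel,
                    flexdef: FlexibilityDefinition | None = None,
                    n: int = 1000, move_sigma_deg: float = 25.0,
                    clash_cutoff: float = 1.5, max_retries: int = 100,
                    seed: int = 0, q: np.ndarray | None = None,
                    compute_profiles: bool = True) -> Ensemble:
    """Generate ``n`` clash-free conformers by randomized pivot moves.

    Parameters
    ----------
    model : StructureModel
        Seed model with rigid/flexible labels (an open-ish conformer gives
        the broadest coverage of compact through splayed arrangements).
    move_sigma_deg : float
        Gaussian width of each pivot rotation angle in degrees.
    clash_cutoff : float
        Minimal allowed bead-centre distance between different bodies (A).
        The default (1.5 A) is a hard-core limit: with one bead per residue,
        surface beads of two domains in genuine contact interleave well
        below the backbone spacing, so a cutoff near the bead diameter
        would veto the compact half of the conformational space.
    q : ndarray, optional
        q-grid for the per-conformer Debye profiles (default pipeline grid).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    flexdef = flexdef or FlexibilityDefinition.from_model(model)
    rng = np.random.default_rng(seed)
    if q is None:
        q = default_q_grid()
    models: list[StructureModel] = []
    rgs = np.empty(n)
    profs = np.empty((n, q.size)) if compute_profiles else None
    for i in range(n):
        for attempt in range(max_retries):
            coords = model.coords.copy()
            if move_sigma_deg > 0:
                for linker in flexdef.linkers:
                    if linker["payload"].size:
                        _rebuild_arm(coords, linker, rng, move_sigma_deg)
                    else:
                        _pivot_chain(coords, linker["chain"], linker["payload"],
                                     rng, move_sigma_deg)
                for g in flexdef.branches:
                    _pivot_chain(coords, g, np.empty(0, int), rng, move_sigma_deg)
            if move_sigma_deg == 0 or not _clashes(model, flexdef, coords, clash_cutoff):
                break
        else:
            raise RuntimeError(
                f"no clash-free conformer in {max_retries} retries "
                f"(sigma={move_sigma_deg} deg, cutoff={clash_cutoff} A)")
        conf = StructureModel(coords, model.weights.copy(), model.kinds.copy(),
                              model.chains.copy(), model.resids.copy(),
                              model.labels.copy())
        models.append(conf)
        rgs[i] = conf.rg()
        if compute_profiles:
            profs[i] = debye_profile(conf, q).I
    meta = {"seed": seed, "n": n, "move_sigma_deg": move_sigma_deg,
            "clash_cutoff": clash_cutoff}
    return Ensemble(models, rgs, q=q, profiles=profs, metadata=meta)


def ensemble_rg_span(ensemble: Ensemble, bin_width: float = 1.0
                     ) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """(min Rg, max Rg, histogram) of an ensemble's Rg values."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    rgs = ensemble.rgs
    lo, hi = float(rgs.min()), float(rgs.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    hist, edges = np.histogram(rgs, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    return lo, hi, (hist, edges)
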