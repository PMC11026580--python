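"""Synthetic data with known ground truth for the whole analysis chain.

This module builds a coarse-grained IgA2-like monomer — two Fab domains and
one Fc domain as ellipsoidal bead clusters of standard immunoglobulin-fold
dimensions, joined by flexible hinge linkers, with C-terminal tailpieces and
N-glycan bead chains — and simulates every measurement the pipeline consumes:
noisy mixture scattering profiles, SEC-SAXS frame stacks, SPR sensorgrams and
thermal melting curves. Everything is seeded and bit-reproducible.

Geometry is calibrated so that the closed, open and extended conformers land
at radii of gyration of roughly 44, 53 and 64-65 Angstrom respectively — the
windows typical of compact and splayed IgA monomers — and so a closed/open
mixture shows an overall Guinier Rg near 48-49 Angstrom and a maximal
dimension around 160-170 Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profiles import ScatteringProfile, default_q_grid
from .structure import StructureModel, KIND_PROTEIN, KIND_GLYCAN
from .kinetics import BindingTrace, MeltCurve

__all__ = [
    "GlycanSite", "AntibodySpec", "MixtureTruth",
    "make_toy_antibody", "make_conformer", "simulate_experiment",
    "simulate_secsaxs_frames", "simulate_spr_trace", "simulate_melt_curve",
    "write_truth_sidecar", "CONFORMER_MODES",
]

CONFORMER_MODES = ("closed", "open", "extended")

# ----------------------------------------------------------------- geometry
# Ellipsoid semi-axes (Angstrom). A Fab of ~96 x 59 x 48 A and an Fc of
# ~59 x 50 x 72 A give per-domain radii of gyration of ~25 and ~24 A,
# inside the 20-27 A range of immunoglobulin domains.
_FAB_SEMI = np.array([48.0, 29.5, 24.0])   # long axis first (local x here)
_FC_SEMI = np.array([29.5, 25.0, 36.0])    # long axis along z (vertical)
_HINGE_ANCHOR_X = 8.0                       # lateral offset of hinge anchors
_CA_STEP = 3.8                              # Angstrom per residue bead
_GLYCAN_STEP = 3.5                          # Angstrom per sugar bead

# Per-mode Fab placement: arm-1 centre (arm 2 mirrored in x and y) and the
# direction of the Fab long axis. Calibrated to the target Rg windows.
_MODE_GEOM: dict[str, dict[str, np.ndarray]] = {
    "closed": {"center": np.array([39.3, 10.0, 25.0]),
               "axis": np.array([0.15, 0.0, 0.99])},
    "open": {"center": np.array([52.16, 0.0, 38.51]),
             "axis": np.array([-0.45, 0.0, 0.89])},
    "extended": {"center": np.array([73.91, 0.0, 25.92]),
                 "axis": np.array([1.0, 0.0, 0.03])},
}
_MODE_JITTER_DEG = 2.0     # small seeded wobble of the arm direction


@dataclass(frozen=True)
class GlycanSite:
    """One N-glycosylation sequon on the heavy chain.

    ``residue`` indexes the heavy chain (1-based sequential numbering);
    ``chain_len`` is the number of monosaccharide beads; ``occupancy`` is the
    fraction of molecules carrying the glycan at this site.
    """

    label: str
    residue: int
    chain_len: int = 9
    occupancy: float = 1.0


def _default_glycan_sites() -> tuple[GlycanSite, ...]:
    # Five sequons per heavy chain: two in the Fab arm (NLT, NVS), two in the
    # CH2 region of Fc (NVT, NSS) and one on the tailpiece (NIT). NVS carries
    # a short, mostly unoccupied glycan.
    return (
        GlycanSite("NLT", 166, 9, 1.0),
        GlycanSite("NVS", 211, 5, 0.2),
        GlycanSite("NVT", 263, 9, 1.0),
        GlycanSite("NSS", 337, 9, 1.0),
        GlycanSite("NIT", 459, 9, 1.0),
    )


@dataclass(frozen=True)
class AntibodySpec:
    """Parameters of the coarse-grained antibody builder."""

    n_res_fab: int = 440
    n_res_fc: int = 450
    hinge_range: tuple[int, int] = (228, 235)
    tail_range: tuple[int, int] = (449, 466)
    glycan_sites: tuple[GlycanSite, ...] = field(default_factory=_default_glycan_sites)
    glycan_weight_ratio: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res_fab < 10 or self.n_res_fc < 10:
            raise ValueError("domain residue counts must be at least 10")
        for lo, hi in (self.hinge_range, self.tail_range):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty, 1-based intervals")
        h, t = self.hinge_range, self.tail_range
        if not (h[1] < t[0]):
            raise ValueError("hinge and tail ranges overlap or are out of order")
        if self.glycan_weight_ratio < 1.0:
            raise ValueError("glycan_weight_ratio must be >= 1")
        for s in self.glycan_sites:
            if not 0.0 <= s.occupancy <= 1.0:
                raise ValueError(f"occupancy of site {s.label} outside [0, 1]")
            if s.chain_len < 0:
                raise ValueError("glycan chain length must be >= 0")

    @property
    def n_hinge(self) -> int:
        return self.hinge_range[1] - self.hinge_range[0] + 1

    @property
    def n_tail(self) -> int:
        return self.tail_range[1] - self.tail_range[0] + 1


@dataclass(frozen=True)
class MixtureTruth:
    """Ground truth of a synthetic two-state (or k-state) measurement."""

    conformers: tuple[str, ...] = ("closed", "open")
    weights: tuple[float, ...] = (0.45, 0.55)
    noise: float = 0.02             # relative sigma at q -> 0
    noise_slope: float = 5.0        # Angstrom; sigma grows as (1 + slope*q)
    q_min: float = 0.01
    q_max: float = 0.45
    n_points: int = 220

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if len(self.conformers) != w.size:
            raise ValueError("one weight per conformer required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")

    def q_grid(self) -> np.ndarray:
        return default_q_grid(self.q_min, self.q_max, self.n_points)


# ------------------------------------------------------------------ helpers

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = _unit(np.cross(a, [1.0, 0.0, 0.0]) if abs(a[0]) < 0.9
                     else np.cross(a, [0.0, 1.0, 0.0]))
        return _axis_angle(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _random_rotation(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    axis = _unit(rng.normal(size=3))
    return _axis_angle(axis, np.deg2rad(rng.normal(0.0, sigma_deg)))


def _fill_ellipsoid(n: int, semi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random points inside an ellipsoid (rejection from a cube)."""
    pts = np.empty((0, 3))
    while pts.shape[0] < n:
        cand = rng.uniform(-1, 1, size=(2 * n, 3))
        cand = cand[np.sum(cand ** 2, axis=1) <= 1.0]
        pts = np.vstack([pts, cand])
    return pts[:n] * semi


def _ellipsoid_surface_point(p: np.ndarray, semi: np.ndarray) -> np.ndarray:
    """Radial projection of an interior point onto the ellipsoid surface."""
    t = np.sqrt(np.sum((p / semi) ** 2))
    if t < 1e-9:
        return np.array([0.0, 0.0, semi[2]])
    return p / t


def _grow_chain(start: np.ndarray, direction: np.ndarray, n: int, step: float,
                rng: np.random.Generator, wobble_deg: float = 25.0) -> np.ndarray:
    """Self-avoiding-ish random walk: each step deviates from the previous
    direction by a seeded random rotation."""
    pts = np.empty((n, 3))
    d = _unit(direction)
    p = start.copy()
    for i in range(n):
        p = p + d * step
        pts[i] = p
        d = _unit(_random_rotation(rng, wobble_deg) @ d)
    return pts


# ------------------------------------------------------------------ builder

def make_toy_antibody(spec: AntibodySpec | None = None) -> StructureModel:
    """Build the coarse-grained IgA2-like monomer in its closed conformation.

    One bead per residue / monosaccharide. Rigid-body labels ``Fab1``,
    ``Fab2``, ``Fc``; flexible labels ``hinge_A``/``hinge_B``,
    ``tail_A``/``tail_B`` and ``glycan_<site>_<chain>``. Heavy chains are
    ``A`` and ``B`` (1-based sequential numbering; hinge and tailpiece
    intervals refer to this scheme), light chains ``C`` and ``D``.
    """
    spec = spec or AntibodySpec()
    rng = np.random.default_rng(spec.seed)

    coords: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    kinds: list[np.ndarray] = []
    chains: list[np.ndarray] = []
    resids: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    def add(xyz, w, kind, chain, resid, label):
        n = xyz.shape[0]
        coords.append(xyz)
        weights.append(np.full(n, w) if np.isscalar(w) else w)
        kinds.append(np.full(n, kind, dtype=object))
        chains.append(np.asarray(chain, dtype=object) if not isinstance(chain, str)
                      else np.full(n, chain, dtype=object))
        resids.append(np.asarray(resid, dtype=int))
        labels.append(np.full(n, label, dtype=object))

    hinge_lo, hinge_hi = spec.hinge_range
    tail_lo, tail_hi = spec.tail_range
    n_fd = hinge_lo - 1                   # heavy-chain part of the Fab
    n_light = spec.n_res_fab - n_fd       # light-chain part

    # ---- Fc core at the origin, long axis vertical (z)
    fc_local = _fill_ellipsoid(spec.n_res_fc, _FC_SEMI, rng)
    n_a = spec.n_res_fc // 2
    fc_res = np.concatenate([np.arange(hinge_hi + 1, hinge_hi + 1 + n_a),
                             np.arange(hinge_hi + 1, hinge_hi + 1 + (spec.n_res_fc - n_a))])
    fc_chain = np.array(["A"] * n_a + ["B"] * (spec.n_res_fc - n_a), dtype=object)
    add(fc_local, 1.0, KIND_PROTEIN, fc_chain, fc_res, "Fc")

    # ---- tailpieces hanging from the bottom pole of Fc
    for sgn, hc, lab in ((1.0, "A", "tail_A"), (-1.0, "B", "tail_B")):
        start = np.array([sgn * 4.0, 0.0, -_FC_SEMI[2] + 2.0])
        down = _unit(np.array([sgn * 0.2, 0.0, -1.0]))
        pts = _grow_chain(start, down, spec.n_tail, _CA_STEP, rng, wobble_deg=50.0)
        add(pts, 1.0, KIND_PROTEIN, hc, np.arange(tail_lo, tail_hi + 1), lab)

    # ---- Fab arms (closed placement) + hinge linkers
    geom = _MODE_GEOM["closed"]
    anchors = {}
    for k, (sgn, hc, lc) in enumerate((((1.0), "A", "C"), ((-1.0), "B", "D"))):
        mirror = np.array([sgn, sgn, 1.0])
        center = geom["center"] * mirror
        axis = _unit(geom["axis"] * mirror)
        anchor = _ellipsoid_surface_point(
            np.array([sgn * _HINGE_ANCHOR_X, 0.0, _FC_SEMI[2] * 0.9]), _FC_SEMI)
        anchors[f"Fab{k + 1}"] = anchor

        local = _fill_ellipsoid(spec.n_res_fab, _FAB_SEMI, rng)
        R = _rotation_between(np.array([1.0, 0.0, 0.0]), axis)  # long axis -> arm axis
        fab = local @ R.T + center
        fab_chain = np.array([hc] * n_fd + [lc] * n_light, dtype=object)
        fab_res = np.concatenate([np.arange(1, n_fd + 1), np.arange(1, n_light + 1)])
        add(fab, 1.0, KIND_PROTEIN, fab_chain, fab_res, f"Fab{k + 1}")

        # hinge: bead at hinge_lo pinned to the anchor, the rest evenly
        # spaced toward the nearest point of the Fab surface
        prox = _nearest_point_on_beads(fab, anchor)
        ts = np.linspace(0.0, 1.0, spec.n_hinge, endpoint=False)
        hinge = anchor[None, :] + ts[:, None] * (prox - anchor)[None, :]
        add(hinge, 1.0, KIND_PROTEIN, hc, np.arange(hinge_lo, hinge_hi + 1), f"hinge_{hc}")

    model = StructureModel(np.vstack(coords), np.concatenate(weights),
                           np.concatenate(kinds), np.concatenate(chains),
                           np.concatenate(resids), np.concatenate(labels))

    # ---- glycans: per heavy-chain copy, drawn present with prob = occupancy
    model = _attach_glycans(model, spec, rng)
    return model


def _nearest_point_on_beads(beads: np.ndarray, p: np.ndarray) -> np.ndarray:
    return beads[np.argmin(np.sum((beads - p) ** 2, axis=1))]


def _attach_glycans(model: StructureModel, spec: AntibodySpec,
                    rng: np.random.Generator) -> StructureModel:
    coords = [model.coords]
    weights = [model.weights]
    kinds = [model.kinds]
    chains = [model.chains]
    resids = [model.resids]
    labels = [model.labels]
    for hc in ("A", "B"):
        for site in spec.glycan_sites:
            occupied = bool(rng.random() < site.occupancy)
            if not occupied or site.chain_len == 0:
                continue
            sel = np.flatnonzero((model.chains == hc) & (model.resids == site.residue)
                                 & (model.kinds == KIND_PROTEIN))
            if sel.size == 0:
                raise ValueError(f"glycan site {site.label}: residue {site.residue} "
                                 f"not found on chain {hc}")
            anchor_idx = int(sel[0])
            parent = model.labels[anchor_idx]
            anchor = model.coords[anchor_idx]
            # grow outward from the surface of the parent domain
            domain = model.coords[model.labels == parent]
            ctr = domain.mean(axis=0)
            out = anchor - ctr
            if np.linalg.norm(out) < 1e-6:
                out = np.array([0.0, 0.0, 1.0])
            start = ctr + _unit(out) * (np.linalg.norm(anchor - ctr) + 2.0)
            pts = _grow_chain(start, out, site.chain_len, _GLYCAN_STEP, rng,
                              wobble_deg=40.0)
            n = site.chain_len
            coords.append(pts)
            weights.append(np.full(n, spec.glycan_weight_ratio))
            kinds.append(np.full(n, KIND_GLYCAN, dtype=object))
            chains.append(np.full(n, hc, dtype=object))
            # sugar beads share the residue index of their anchor sequon
            resids.append(np.full(n, site.residue))
            labels.append(np.full(n, f"glycan_{site.label}_{hc}", dtype=object))
    return StructureModel(np.vstack(coords), np.concatenate(weights),
                          np.concatenate(kinds), np.concatenate(chains),
                          np.concatenate(resids), np.concatenate(labels))


# ------------------------------------------------------------- conformers

def _arm_members(model: StructureModel, k: int) -> np.ndarray:
    """Indices of everything that moves with Fab arm k (1 or 2): the Fab
    rigid body, its hinge, and glycans anchored on that arm."""
    hc = "A" if k == 1 else "B"
    fab = f"Fab{k}"
    mask = (model.labels == fab) | (model.labels == f"hinge_{hc}")
    for lab in model.label_set():
        if lab.startswith("glycan_") and lab.endswith(f"_{hc}"):
            # glycan follows the arm iff its anchor residue sits in the arm:
            # arm residues are those below the hinge end on the heavy chain
            site_res = _glycan_anchor_residue(model, lab)
            if site_res is not None and site_res <= _hinge_hi(model, hc):
                mask |= model.labels == lab
    return np.flatnonzero(mask)


def _glycan_anchor_residue(model: StructureModel, glabel: str) -> int:
    # sugar beads carry the residue index of their anchor sequon
    return int(model.resids[model.labels == glabel][0])


def _hinge_hi(model: StructureModel, hc: str) -> int:
    h = model.resids[model.labels == f"hinge_{hc}"]
    return int(h.max()) if h.size else 235


def make_conformer(model: StructureModel, mode: str, seed: int = 0) -> StructureModel:
    """Reposition the Fab arms of an antibody model into a named conformation.

    ``closed`` targets a compact Y (Rg ~ 43-47 A), ``open`` a partially
    extended arrangement (Rg ~ 52-54 A) and ``extended`` a maximally splayed
    one (Rg ~ 63-66 A). Intra-rigid-body geometry is copied unchanged (the
    arms move as rigid units); hinge beads are re-laid along the new
    anchor-to-Fab path. Seeded: identical seeds give identical coordinates.
    """
    if mode not in CONFORMER_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {CONFORMER_MODES}")
    rng = np.random.default_rng(seed)
    out = model.copy()
    geom = _MODE_GEOM[mode]
    for k, (sgn, hc) in enumerate(((1.0, "A"), (-1.0, "B")), start=1):
        mirror = np.array([sgn, sgn, 1.0])
        target_center = geom["center"] * mirror
        target_axis = _unit(geom["axis"] * mirror)
        jit = _random_rotation(rng, _MODE_JITTER_DEG)
        target_axis = _unit(jit @ target_axis)

        fab_idx = out.indices(f"Fab{k}")
        arm_idx = _arm_members(out, k)
        hinge_idx = out.indices(f"hinge_{hc}")
        move_idx = np.setdiff1d(arm_idx, hinge_idx)

        anchor = out.coords[hinge_idx[np.argmin(out.resids[hinge_idx])]]
        target_center = anchor + jit @ (target_center - anchor)

        fab = out.coords[fab_idx]
        ctr = np.average(fab, axis=0, weights=out.weights[fab_idx])
        cur_axis = _principal_axis(fab, ctr)
        if np.dot(cur_axis, ctr - anchor) < 0:
            cur_axis = -cur_axis
        R = _rotation_between(cur_axis, target_axis)
        spin = _axis_angle(target_axis, rng.normal(0.0, np.deg2rad(10.0)))
        R = spin @ R
        out.coords[move_idx] = (out.coords[move_idx] - ctr) @ R.T + target_center

        # re-lay the hinge from its pinned anchor to the nearest Fab point
        prox = _nearest_point_on_beads(out.coords[fab_idx], anchor)
        ts = np.linspace(0.0, 1.0, hinge_idx.size, endpoint=False)
        order = np.argsort(out.resids[hinge_idx])
        out.coords[hinge_idx[order]] = anchor[None, :] + ts[:, None] * (prox - anchor)[None, :]
    return out


def _principal_axis(points: np.ndarray, ctr: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(points - ctr, full_matrices=False)
    return vt[0]


# ------------------------------------------------------------- experiments

def simulate_experiment(truth: MixtureTruth,
                        conformer_profiles: dict[str, ScatteringProfile] | list[ScatteringProfile],
                        seed: int = 0) -> ScatteringProfile:
    """Noisy weighted-mixture profile: I = sum_k w_k I_k + eps.

    eps is Gaussian with sigma(q) = noise * I(q) * (1 + noise_slope * q),
    mimicking the relative error growth of detector data at high q. With
    noise = 0 the weighted sum is returned exactly; the recorded sigma column
    then uses a nominal 1% relative error so that downstream fits remain
    weighted.
    """
    if isinstance(conformer_profiles, dict):
        profs = [conformer_profiles[c] for c in truth.conformers]
    else:
        profs = list(conformer_profiles)
    if len(profs) != len(truth.conformers):
        raise ValueError("one profile per truth conformer required")
    for p in profs[1:]:
        profs[0].require_same_grid(p)
    q = profs[0].q
    I = np.zeros_like(q)
    for w, p in zip(truth.weights, profs):
        I = I + w * p.I
    rel = truth.noise if truth.noise > 0 else 0.01
    sigma = rel * I * (1.0 + truth.noise_slope * q)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=q.size) * sigma if truth.noise > 0 else 0.0
    return ScatteringProfile(q, I + noise, sigma)


def simulate_secsaxs_frames(truth: MixtureTruth,
                            conformer_profiles: dict[str, ScatteringProfile] | list[ScatteringProfile],
                            n_buffer: int = 10, n_peak: int = 30,
                            peak_center: float | None = None,
                            peak_width: float = 5.0,
                            peak_concentration: float = 1.0,
                            background_level: float = 0.3,
                            seed: int = 0) -> tuple[list[ScatteringProfile], dict]:
    """Simulate a SEC-SAXS elution as a stack of exposure frames.

    The first ``n_buffer`` frames contain background-only scattering; the
    following ``n_peak`` frames add the mixture signal scaled by a Gaussian
    elution concentration profile. Returns (frames, info) where ``info``
    records the per-frame concentration and the buffer frame indices.
    """
    if n_buffer < 2:
        raise ValueError("need at least 2 buffer frames")
    if isinstance(conformer_profiles, dict):
        profs = [conformer_profiles[c] for c in truth.conformers]
    else:
        profs = list(conformer_profiles)
    q = profs[0].q
    I_mix = np.zeros_like(q)
    for w, p in zip(truth.weights, profs):
        I_mix = I_mix + w * p.I
    bg = background_level * float(np.mean(I_mix))
    centre = peak_center if peak_center is not None else n_buffer + n_peak / 2.0
    rng = np.random.default_rng(seed)
    rel = truth.noise if truth.noise > 0 else 0.01
    frames = []
    conc = []
    n_frames = n_buffer + n_peak
    for f in range(n_frames):
        c = 0.0 if f < n_buffer else peak_concentration * float(
            np.exp(-0.5 * ((f - centre) / peak_width) ** 2))
        conc.append(c)
        I_f = bg + c * I_mix
        sigma = rel * np.maximum(I_f, bg) * (1.0 + truth.noise_slope * q)
        noise = rng.normal(0.0, 1.0, size=q.size) * sigma if truth.noise > 0 else 0.0
        frames.append(ScatteringProfile(q, I_f + noise, sigma))
    info = {"concentration": np.array(conc), "buffer_frames": np.arange(n_buffer),
            "background": bg}
    return frames, info


def simulate_spr_trace(ka: float, kd: float, rmax: float,
                       concentrations: list[float] | np.ndarray | None = None,
                       t_assoc: float = 60.0, t_dissoc: float = 60.0,
                       noise: float = 0.5, seed: int = 0,
                       dt: float = 0.5) -> BindingTrace:
    """Single-cycle SPR sensorgram for a 1:1 interaction.

    Sequential injections of increasing analyte concentration (default a
    2-fold ladder topping out at 400 nM), each followed by a dissociation
    phase; the response obeys dR/dt = ka C (Rmax - R) - kd R, integrated
    exactly per constant-concentration segment. ``noise`` is the additive
    Gaussian sigma in response units.
    """
    if ka <= 0 or kd <= 0 or rmax <= 0:
        raise ValueError("ka, kd and Rmax must be positive")
    if concentrations is None:
        concentrations = [25e-9, 50e-9, 100e-9, 200e-9, 400e-9]
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(np.diff(concentrations) <= 0):
        raise ValueError("concentration schedule must be strictly increasing")
    segments = []
    for c in concentrations:
        segments.append((float(c), t_assoc))
        segments.append((0.0, t_dissoc))
    t_all, r_all, c_all = [], [], []
    t0, r0 = 0.0, 0.0
    for conc, dur in segments:
        tt = np.arange(0.0, dur, dt)
        k_obs = ka * conc + kd
        r_eq = ka * conc * rmax / k_obs
        rr = r_eq + (r0 - r_eq) * np.exp(-k_obs * tt)
        t_all.append(t0 + tt)
        r_all.append(rr)
        c_all.append(np.full(tt.size, conc))
        r0 = r_eq + (r0 - r_eq) * np.exp(-k_obs * dur)
        t0 += dur
    t = np.concatenate(t_all)
    r = np.concatenate(r_all)
    c = np.concatenate(c_all)
    if noise > 0:
        r = r + np.random.default_rng(seed).normal(0.0, noise, size=r.size)
    return BindingTrace(t, r, c)


def simulate_melt_curve(tm: float, width: float = 2.5,
                        baseline_pre: tuple[float, float] = (1.0, -0.001),
                        baseline_post: tuple[float, float] = (2.0, -0.002),
                        t_min: float = 15.0, t_max: float = 90.0,
                        dt: float = 0.5, noise: float = 0.0,
                        seed: int = 0, increasing: bool = True) -> MeltCurve:
    """Two-state thermal unfolding curve with linear pre/post baselines.

    Signal = (1 - f) * (a0 + a1 T) + f * (b0 + b1 T), with unfolded fraction
    f(T) = 1 / (1 + exp(-(T - tm)/width)). ``increasing=False`` flips the
    transition direction (e.g. ellipticity melts downward).
    """
    T = np.arange(t_min, t_max + 0.5 * dt, dt)
    if not (T[0] < tm < T[-1]):
        raise ValueError("tm must lie inside the temperature grid")
    f = 1.0 / (1.0 + np.exp(-(T - tm) / width))
    if not increasing:
        f = 1.0 - f
    a0, a1 = baseline_pre
    b0, b1 = baseline_post
    y = (1.0 - f) * (a0 + a1 * T) + f * (b0 + b1 * T)
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise, size=T.size)
    return MeltCurve(T, y)


# ----------------------------------------------------------------- sidecar

def write_truth_sidecar(path: str | Path, truth: MixtureTruth, **extra) -> None:
    """Write ground-truth parameters as a plain-text key=value sidecar."""
    lines = [f"conformers={','.join(truth.conformers)}",
             f"weights={','.join(f'{w:g}' for w in truth.weights)}",
             f"noise={truth.noise:g}", f"noise_slope={truth.noise_slope:g}",
             f"q_min={truth.q_min:g}", f"q_max={truth.q_max:g}",
             f"n_points={truth.n_points}"]
    for k, v in extra.items():
        lines.append(f"{k}={v}")
    Path(path).write_text("\n".join(lines) + "\n")
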