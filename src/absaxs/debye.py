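"""Theoretical scattering profiles from bead models via the Debye formula.

The orientation-averaged intensity of N point scatterers is

    I(q) = sum_i sum_j f_i f_j sin(q r_ij) / (q r_ij)

with the i == j and q r -> 0 terms equal to f_i f_j, so that
I(0) = (sum_i f_i)^2 exactly. Bead form factors are q-independent
(coarse-grained beads, not atoms); glycan beads simply carry a larger weight.

The double sum is evaluated either exactly (all pair distances) or, by
default, through a weighted pair-distance histogram with 0.25 Angstrom bins,
which is accurate to well below 0.5% on the default q-grid and turns the cost
from O(N^2 * n_q) into O(N^2 + n_bins * n_q).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

from .profiles import ScatteringProfile
from .structure import StructureModel

__all__ = ["debye_profile", "model_rg", "chi2", "pair_histogram"]

_DEFAULT_BIN = 0.25  # Angstrom


def pair_histogram(model: StructureModel, bin_width: float = _DEFAULT_BIN
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted histogram of distinct pair distances.

    Returns (bin centres, sum of f_i*f_j per bin, sum_i f_i^2).
    Pair weights count each unordered pair once; the Debye sum doubles them.
    """
    w = model.weights
    self_term = float(np.sum(w * w))
    if model.n_beads == 1:
        return np.empty(0), np.empty(0), self_term
    d = pdist(model.coords)
    iu, ju = np.triu_indices(model.n_beads, k=1)
    fw = w[iu] * w[ju]
    n_bins = max(1, int(np.ceil(d.max() / bin_width)))
    rng = (0.0, n_bins * bin_width)
    hist, _ = np.histogram(d, bins=n_bins, range=rng, weights=fw)
    dsum, _ = np.histogram(d, bins=n_bins, range=rng, weights=fw * d)
    keep = hist > 0
    # weight-averaged distance per bin cancels the first-order binning error
    centres = dsum[keep] / hist[keep]
    return centres, hist[keep], self_term


def _sinc(x: np.ndarray) -> np.ndarray:
    # sin(x)/x with the x -> 0 limit; np.sinc is sin(pi x)/(pi x)
    return np.sinc(x / np.pi)


def debye_profile(model: StructureModel, q: np.ndarray,
                  binned: bool = True, bin_width: float = _DEFAULT_BIN,
                  hydration_factor: float = 1.0) -> ScatteringProfile:
    """Debye-formula intensity of a bead model on grid ``q``.

    Parameters
    ----------
    model : StructureModel
    q : array of momentum transfer values (>= 0), 1/Angstrom, ascending.
    binned : bool
        Use the pair-distance-histogram acceleration (default). The exact
        path evaluates every pair distance separately.
    hydration_factor : float
        Optional single multiplicative factor applied to the whole intensity
        to stand in for a hydration-layer contrast adjustment; default 1
        (off).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    if model.n_beads == 0:
        raise ValueError("empty model")
    w = model.weights
    if binned:
        centres, pair_w, self_term = pair_histogram(model, bin_width)
        # I(q) = self + 2 * sum_bins fw_b sinc(q r_b)
        I = self_term + 2.0 * (pair_w[None, :] * _sinc(np.outer(q, centres))).sum(axis=1)
    else:
        d = pdist(model.coords)
        fw = (w[:, None] * w[None, :])[np.triu_indices(model.n_beads, k=1)]
        self_term = float(np.sum(w * w))
        if d.size:
            I = self_term + 2.0 * (fw[None, :] * _sinc(np.outer(q, d))).sum(axis=1)
        else:
            I = np.full(q.shape, self_term)
    # enforce the exact forward limit on any q == 0 grid point
    I = np.where(q == 0.0, float(np.sum(w)) ** 2, I)
    return ScatteringProfile(q, hydration_factor * I)


def model_rg(model: StructureModel) -> float:
    """Weight-weighted radius of gyration of a bead model (Angstrom)."""
    return model.rg()


def chi2(exp: ScatteringProfile, theo: ScatteringProfile) -> tuple[float, float]:
    """Reduced chi-square of a theoretical profile against data.

    The scale factor c minimising sum[((I_exp - c I_theo)/sigma)^2] is found
    in closed form; chi2 is that sum divided by the number of points M.
    Returns (chi2, c).
    """
    exp.require_same_grid(theo)
    if exp.sigma is None:
        raise ValueError("experimental profile must carry sigma")
    y = exp.I / exp.sigma
    x = theo.I / exp.sigma
    denom = float(x @ x)
    if denom == 0.0:
        raise ValueError("theoretical profile is identically zero")
    c = float(x @ y) / denom
    resid = y - c * x
    return float(resid @ resid) / len(exp), c
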