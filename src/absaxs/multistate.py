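"""Multistate ensemble fitting and state counting.

An experimental profile is represented as a weighted sum of k conformer
profiles; the non-negative weights and the overall scale minimise the
reduced chi-square. Candidate k-subsets are ranked exhaustively for k = 1
and by best-first beam search for k >= 2 (the beam equals exhaustive
enumeration whenever the pool is no larger than the beam width). The number
of conformational states in solution is estimated from the weighted Rg
distribution of the top fits: each main peak of the smoothed density is one
state, and peak positions/areas describe where the Fab arms sit and how
mobile they are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .profiles import ScatteringProfile
from .sampling import Ensemble

__all__ = ["MultiStateFit", "StateCountReport", "MultiStateModel",
           "MultiStateResults", "fit_weights", "multistate_search", "state_count"]


@dataclass
class MultiStateFit:
    """A k-state model: conformer ids, simplex weights, scale and chi2."""

    ids: tuple[int, ...]
    weights: np.ndarray
    scale: float
    chi2: float
    rg_mean: float | None = None      # weight-averaged conformer Rg

    @property
    def k(self) -> int:
        return len(self.ids)


def _nnls_fit(y: np.ndarray, sig: np.ndarray, cols: np.ndarray
              ) -> tuple[np.ndarray, float, float]:
    """NNLS of y against conformer intensity columns, sigma-weighted.

    Returns (simplex weights, scale, chi2). The raw non-negative
    coefficients a_k are split into the total scale c = sum(a) and weights
    w = a / c on the simplex.
    """
    X = cols / sig[:, None]
    b = y / sig
    a, _ = nnls(X, b)
    total = a.sum()
    if total <= 0:
        raise ValueError("degenerate fit: all-zero solution")
    resid = b - X @ a
    chi2 = float(resid @ resid) / y.size
    return a / total, float(total), chi2


def fit_weights(exp: ScatteringProfile, conformer_profiles: np.ndarray | list,
                ids: tuple[int, ...] | None = None,
                rgs: np.ndarray | None = None) -> MultiStateFit:
    """Fit non-negative, sum-to-one weights of a fixed conformer subset.

    ``conformer_profiles`` is a (k, n_q) array (or list of profiles /
    intensity vectors) on the experimental q-grid; the overall magnitude is
    absorbed by the scale factor.
    """
    if exp.sigma is None:
        raise ValueError("experimental profile must carry sigma")
    rows = []
    for p in conformer_profiles:
        if isinstance(p, ScatteringProfile):
            exp.require_same_grid(p)
            rows.append(p.I)
        else:
            rows.append(np.asarray(p, float))
    cols = np.column_stack(rows)
    if cols.shape[0] != len(exp):
        raise ValueError("conformer profiles not on the experimental grid")
    w, c, chi2 = _nnls_fit(exp.I, exp.sigma, cols)
    ids = ids if ids is not None else tuple(range(cols.shape[1]))
    rg_mean = float(np.dot(w, rgs)) if rgs is not None else None
    return MultiStateFit(ids, w, c, chi2, rg_mean)


def _score_subset(subset: tuple[int, ...], y, sig, profiles, rgs) -> MultiStateFit:
    # column_stack (not a transposed view) so the scoring path is bitwise
    # identical to fit_weights regardless of memory layout
    cols = np.column_stack([profiles[i] for i in subset])
    w, c, chi2 = _nnls_fit(y, sig, cols)
    rg_mean = float(np.dot(w, rgs[list(subset)]))
    return MultiStateFit(subset, w, c, chi2, rg_mean)


def _sort_key(f: MultiStateFit):
    # chi2, then smaller weighted-mean Rg, then lexicographic ids
    return (f.chi2, f.rg_mean if f.rg_mean is not None else 0.0, f.ids)


def multistate_search(exp: ScatteringProfile, ensemble: Ensemble,
                      k_max: int = 3, top_n: int = 300,
                      beam_width: int = 100) -> dict[int, list[MultiStateFit]]:
    """Rank k-state models for k = 1..k_max.

    k = 1 is exhaustive over the pool. For k >= 2 a best-first beam search
    extends each of the ``beam_width`` best (k-1)-subsets with every pool
    conformer and rescores; duplicate subsets are collapsed. When the pool
    has at most ``beam_width`` conformers this enumerates every subset, so
    the beam is exact there. Returns the ``top_n`` fits per k sorted by
    chi2 (ties toward smaller weighted-mean Rg, then lexicographic ids).
    """
    if ensemble.profiles is None:
        raise ValueError("ensemble carries no profiles")
    if len(ensemble) < k_max:
        raise ValueError("ensemble smaller than k_max")
    if exp.sigma is None:
        raise ValueError("experimental profile must carry sigma")
    if not np.allclose(exp.q, ensemble.q):
        raise ValueError("experimental profile and ensemble on different q-grids")
    y, sig = exp.I, exp.sigma
    profiles, rgs = ensemble.profiles, ensemble.rgs
    n_pool = len(ensemble)

    results: dict[int, list[MultiStateFit]] = {}
    singles = [_score_subset((i,), y, sig, profiles, rgs) for i in range(n_pool)]
    singles.sort(key=_sort_key)
    results[1] = singles[:top_n]

    frontier = singles
    for k in range(2, k_max + 1):
        seen: set[tuple[int, ...]] = set()
        fits: list[MultiStateFit] = []
        for base in frontier[:beam_width]:
            for j in range(n_pool):
                if j in base.ids:
                    continue
                subset = tuple(sorted(base.ids + (j,)))
                if subset in seen:
                    continue
                seen.add(subset)
                fits.append(_score_subset(subset, y, sig, profiles, rgs))
        fits.sort(key=_sort_key)
        results[k] = fits[:top_n]
        frontier = fits
    return results


# ============================================================ state count

@dataclass
class StateCountReport:
    """Estimated number of states from a weighted Rg density of top fits."""

    rg_grid: np.ndarray
    density: np.ndarray
    peaks: list[tuple[float, float]]     # (position A, mass fraction)
    n_states: int

    def plot(self, ax=None, **kwargs):
        """Plot the smoothed weighted Rg density with its peaks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.rg_grid, self.density, **kwargs)
        for pos, mass in self.peaks:
            ax.axvline(pos, ls="--", lw=0.8)
        ax.set_xlabel(r"$R_g$ ($\AA$)")
        ax.set_ylabel("weighted density (peak-normalized)")
        return ax

    def summary(self) -> str:
        lines = [f"State count: {self.n_states} state(s)"]
        for pos, mass in self.peaks:
            lines.append(f"  peak at Rg = {pos:.1f} A, mass {mass:.2f}")
        return "\n".join(lines)


def state_count(fits: list[MultiStateFit], rgs: np.ndarray,
                bin_width: float = 1.0, smoothing: float = 2.0,
                min_peak_frac: float = 0.10,
                chi2_tolerance: float = 0.05) -> StateCountReport:
    """Count conformational states from the pooled Rg distribution of fits.

    Only fits of the same quality are pooled: those whose chi2 lies
    within ``chi2_tolerance`` (relative, default 5%) of the best fit — the
    "top models with the same goodness-of-fit". A looser tolerance admits
    fits that are statistically far worse (a 20% chi2 excess over ~200
    points is a huge likelihood gap) and smears the state structure with
    mid-Rg compromise pairs. Each retained fit
    contributes its conformers' Rg values weighted by the state weights w
    (fit ranks weighted uniformly). The histogram (``bin_width`` in A) is
    smoothed with a Gaussian of ``smoothing`` A; peaks are local maxima
    above ``min_peak_frac`` of the global maximum, and each histogram mass
    is attributed to its nearest peak.
    """
    if not fits:
        raise ValueError("no fits supplied")
    best = min(f.chi2 for f in fits)
    pool = [f for f in fits if f.chi2 <= best * (1.0 + chi2_tolerance) + 1e-12]
    vals, ws = [], []
    for f in pool:
        for cid, w in zip(f.ids, f.weights):
            vals.append(rgs[cid])
            ws.append(w / len(pool))
    vals = np.asarray(vals)
    ws = np.asarray(ws)
    lo = np.floor(vals.min()) - 3 * smoothing - bin_width
    hi = np.ceil(vals.max()) + 3 * smoothing + bin_width
    n_bins = max(3, int(np.ceil((hi - lo) / bin_width)))
    hist, edges = np.histogram(vals, bins=n_bins, range=(lo, lo + n_bins * bin_width),
                               weights=ws)
    centres = 0.5 * (edges[:-1] + edges[1:])
    dens = gaussian_filter1d(hist, smoothing / bin_width)
    if dens.max() <= 0:
        raise ValueError("empty density")
    pk, _ = find_peaks(dens, height=min_peak_frac * dens.max())
    if pk.size == 0:
        pk = np.array([int(np.argmax(dens))])
    positions = centres[pk]
    # attribute each bin's mass to the nearest peak
    masses = np.zeros(pk.size)
    total = dens.sum()
    for i, c in enumerate(centres):
        masses[int(np.argmin(np.abs(positions - c)))] += dens[i]
    masses /= total
    peaks = [(float(p), float(m)) for p, m in zip(positions, masses)]
    return StateCountReport(centres, dens / dens.max(), peaks, len(peaks))


# ======================================================= model/results

class MultiStateModel:
    """Multistate ensemble model of an experimental scattering profile.

    Statsmodels-style front end: construct from the data (profile) and the
    conformer pool, call :meth:`fit`, inspect the returned results object.
    """

    def __init__(self, exp: ScatteringProfile, ensemble: Ensemble):
        self.exp = exp
        self.ensemble = ensemble

    def fit(self, k_max: int = 3, top_n: int = 300, beam_width: int = 100,
            improvement_threshold: float = 0.15) -> "MultiStateResults":
        fits = multistate_search(self.exp, self.ensemble, k_max=k_max,
                                 top_n=top_n, beam_width=beam_width)
        # accept k+1 over k only on a sufficiently large chi2 improvement
        best_k = 1
        for k in range(2, k_max + 1):
            prev = fits[best_k][0].chi2
            cur = fits[k][0].chi2
            if prev > 0 and (prev - cur) / prev > improvement_threshold:
                best_k = k
            else:
                break
        return MultiStateResults(self, fits, best_k, improvement_threshold)


@dataclass
class MultiStateResults:
    model: MultiStateModel
    fits: dict[int, list[MultiStateFit]]
    best_k: int
    improvement_threshold: float
    _state_report: StateCountReport | None = field(default=None, repr=False)

    def best(self, k: int | None = None) -> MultiStateFit:
        return self.fits[k if k is not None else self.best_k][0]

    def state_report(self, k: int | None = None, **kwargs) -> StateCountReport:
        k = k if k is not None else self.best_k
        return state_count(self.fits[k], self.model.ensemble.rgs, **kwargs)

    def summary(self) -> str:
        lines = ["Multistate fit"]
        for k in sorted(self.fits):
            b = self.fits[k][0]
            wtxt = ", ".join(f"{w:.2f}" for w in b.weights)
            lines.append(f"  k={k}: chi2 = {b.chi2:.3f}  ids = {b.ids}  w = ({wtxt})")
        lines.append(f"  selected k = {self.best_k} "
                     f"(>{self.improvement_threshold:.0%} chi2 improvement rule)")
        rep = self.state_report()
        lines.append(rep.summary())
        return "\n".join(lines)

    def to_table(self, k: int | None = None, n: int | None = None) -> str:
        """Tab-separated table of the top fits for one k."""
        k = k if k is not None else self.best_k
        rows = ["k\tchi2\tids\tweights\trg_mean"]
        for f in self.fits[k][: (n or len(self.fits[k]))]:
            rows.append(f"{f.k}\t{f.chi2:.5f}\t" +
                        ",".join(map(str, f.ids)) + "\t" +
                        ",".join(f"{w:.4f}" for w in f.weights) + "\t" +
                        (f"{f.rg_mean:.2f}" if f.rg_mean is not None else ""))
        return "\n".join(rows)
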