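"""Model-free SAXS reductions.

Frame processing (buffer subtraction, elution-peak merging), the Guinier
approximation I(q) = I(0) exp(-q^2 Rg^2 / 3) with an iterative
self-consistent q*Rg < 1.5 window, the pair distribution function P(r) by
Tikhonov-regularized indirect Fourier transform with a non-negativity
constraint (the approach of classical IFT programs), a Dmax scan, and the
dimensionless Kratky representation (q Rg)^2 I / I(0) vs q Rg with a
peak/shoulder feature detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.signal import savgol_filter, find_peaks

from .profiles import ScatteringProfile
from .structure import StructureModel
from .debye import pair_histogram

__all__ = [
    "GuinierModel", "GuinierResults", "guinier_fit",
    "IFTModel", "PairDistribution", "ift_pr", "pr_from_model", "dmax_scan",
    "KratkyCurve", "kratky_dimensionless",
    "subtract_buffer", "merge_frames", "find_features",
]

LOW_Q_LIMIT = 0.01  # 1/Angstrom, lower edge of usable data


# ===================================================== feature detection

def find_features(x: np.ndarray, y: np.ndarray, window: int = 11,
                  min_height_frac: float = 0.10
                  ) -> list[tuple[float, str]]:
    """Locate peaks and shoulders of a smooth 1-D curve.

    Peaks are local maxima of the Savitzky-Golay-smoothed curve above
    ``min_height_frac`` of the global maximum. Shoulders are downward
    zero-crossings of the smoothed second derivative on a descending flank
    (local maxima of the first derivative where the slope stays negative):
    the flat ledges a curve develops where an unresolved sub-peak sits.

    Returns a list of (position, kind) with kind in {"peak", "shoulder"},
    ordered by position.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = y.size
    win = min(window if window % 2 else window + 1, n if n % 2 else n - 1)
    win = max(win, 5)
    dx = float(np.median(np.diff(x)))
    ys = savgol_filter(y, win, 3)
    d1 = savgol_filter(y, win, 3, deriv=1, delta=dx)
    d2 = savgol_filter(y, win, 3, deriv=2, delta=dx)

    feats: list[tuple[float, str]] = []
    top = float(ys.max())
    pk, _ = find_peaks(ys, height=min_height_frac * top)
    for i in pk:
        feats.append((_parabolic(x, ys, i), "peak"))

    # shoulders: d2 crosses + -> - while the curve is descending
    guard = max(2, win // 2)
    for i in range(guard, n - guard - 1):
        if d2[i] > 0 >= d2[i + 1] and d1[i] < 0 and ys[i] > min_height_frac * top:
            pos = x[i] + dx * d2[i] / (d2[i] - d2[i + 1])
            if all(abs(pos - p) > 2 * dx for p, _ in feats):
                feats.append((pos, "shoulder"))
    feats.sort(key=lambda t: t[0])
    return feats


def _parabolic(x: np.ndarray, y: np.ndarray, i: int) -> float:
    if i == 0 or i == y.size - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i])
    return float(x[i] + 0.5 * (y0 - y2) / denom * (x[i + 1] - x[i]))


# ============================================================== Guinier

@dataclass
class GuinierResults:
    """Result of a Guinier fit: Rg, I(0), the q-window used and fit quality."""

    rg: float
    i0: float
    q_window: tuple[float, float]
    r_squared: float
    qrg_max: float
    n_points: int

    def summary(self) -> str:
        return ("Guinier fit\n"
                f"  Rg       = {self.rg:.2f} A\n"
                f"  I(0)     = {self.i0:.4g}\n"
                f"  window   = [{self.q_window[0]:.4f}, {self.q_window[1]:.4f}] 1/A"
                f"  ({self.n_points} pts)\n"
                f"  qRg max  = {self.qrg_max:.3f}\n"
                f"  R^2      = {self.r_squared:.5f}")


class GuinierModel:
    """Weighted linear fit of ln I vs q^2 over a self-consistent low-q window.

    Starting from the lowest usable q (leading non-positive intensities are
    skipped), the window is iterated so that q_max * Rg stays below the
    configured limit, extending to the widest window that satisfies it.
    """

    def __init__(self, profile: ScatteringProfile, qrg_limit: float = 1.5,
                 q_min: float = LOW_Q_LIMIT, min_points: int = 5):
        self.profile = profile
        self.qrg_limit = qrg_limit
        self.q_min = q_min
        self.min_points = min_points

    def fit(self, max_iter: int = 50) -> GuinierResults:
        q, I = self.profile.q, self.profile.I
        sigma = self.profile.sigma
        usable = q >= self.q_min
        # skip leading points with non-positive intensity
        pos = I > 0
        first = np.argmax(usable & pos)
        if not (usable & pos)[first]:
            raise ValueError("no positive intensities in the usable low-q range")
        idx0 = int(first)
        n = self.min_points
        if idx0 + n > q.size:
            raise ValueError("fewer than min_points usable low-q points")

        def wls(stop: int):
            qq = q[idx0:stop]
            II = I[idx0:stop]
            if np.any(II <= 0):
                raise ValueError("non-positive intensity inside the Guinier window")
            x = qq ** 2
            y = np.log(II)
            if sigma is not None:
                w = (II / sigma[idx0:stop]) ** 2
            else:
                w = np.ones_like(x)
            W = np.sum(w)
            xm = np.sum(w * x) / W
            ym = np.sum(w * y) / W
            sxx = np.sum(w * (x - xm) ** 2)
            if sxx == 0:
                raise ValueError("degenerate Guinier window")
            slope = np.sum(w * (x - xm) * (y - ym)) / sxx
            inter = ym - slope * xm
            yhat = inter + slope * x
            ss_res = np.sum(w * (y - yhat) ** 2)
            ss_tot = np.sum(w * (y - ym) ** 2)
            r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
            if slope >= 0:
                raise ValueError("non-decreasing low-q intensity: Guinier slope >= 0")
            return float(np.sqrt(-3.0 * slope)), float(np.exp(inter)), float(r2)

        stop = idx0 + n
        rg, i0, r2 = wls(stop)
        for _ in range(max_iter):
            limit_q = self.qrg_limit / rg
            new_stop = int(np.searchsorted(q, limit_q, side="right"))
            new_stop = max(new_stop, idx0 + self.min_points)
            new_stop = min(new_stop, q.size)
            new_rg, new_i0, new_r2 = wls(new_stop)
            converged = abs(new_rg - rg) <= 1e-3 * rg and new_stop == stop
            rg, i0, r2, stop = new_rg, new_i0, new_r2, new_stop
            if converged:
                break
        # shrink if the final window still violates the limit
        while q[stop - 1] * rg > self.qrg_limit and stop - idx0 > self.min_points:
            stop -= 1
            rg, i0, r2 = wls(stop)
        return GuinierResults(rg=rg, i0=i0, q_window=(float(q[idx0]), float(q[stop - 1])),
                              r_squared=r2, qrg_max=float(q[stop - 1] * rg),
                              n_points=stop - idx0)


def guinier_fit(profile: ScatteringProfile, qrg_limit: float = 1.5) -> GuinierResults:
    """Convenience wrapper: ``GuinierModel(profile, qrg_limit).fit()``."""
    return GuinierModel(profile, qrg_limit=qrg_limit).fit()


# ======================================================== P(r) via IFT

@dataclass
class PairDistribution:
    """p(r) on [0, Dmax] with quantities derived from its moments.

    Rg^2 = Int r^2 p dr / (2 Int p dr); I(0) = 4 pi Int p dr (with the
    forward-transform convention used by the IFT operator). ``chi2`` is the
    reduced data misfit of the IFT solution (None for histograms computed
    directly from a model).
    """

    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg: float
    i0: float
    chi2: float | None = None
    alpha: float | None = None
    flags: list[str] = field(default_factory=list)

    def normalized(self) -> np.ndarray:
        """p(r) normalized at the maximum."""
        m = float(self.p.max())
        return self.p / m if m > 0 else self.p

    def features(self, window: int = 21) -> list[tuple[float, str]]:
        """Peaks and shoulders of p(r), ordered by r.

        The default smoothing window (21 grid points) suits p(r) histograms
        on ~1 A bins, where bead-level granularity adds short-range wiggle.
        """
        return find_features(self.r, self.normalized(), window=window)

    def first_peak(self) -> float:
        for pos, kind in self.features():
            if kind == "peak":
                return pos
        raise ValueError("no peak found in p(r)")

    def interdomain_shoulder(self, min_height: float = 0.45) -> float:
        """Position of the inter-domain shoulder beyond the first maximum.

        Multidomain particles develop ledges on the decaying side of p(r)
        wherever a recurrent domain-domain distance sits. The inter-domain
        separation is the *largest* such recurrent distance, so this returns
        the outermost detected feature that still carries substantial pair
        mass (normalized p above ``min_height``); weaker ripples further out
        belong to the single-pair tail, not to a domain-distance population.
        """
        fp = self.first_peak()
        pn = self.normalized()
        cands = []
        for pos, kind in self.features():
            if pos <= fp + 1e-9:
                continue
            h = float(np.interp(pos, self.r, pn))
            if h >= min_height:
                cands.append(pos)
        if not cands:
            raise ValueError("no inter-domain feature beyond the first peak")
        return cands[-1]

    def plot(self, ax=None, **kwargs):
        """Plot p(r) normalized at the maximum; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.r, self.normalized(), **kwargs)
        ax.set_xlabel(r"r ($\AA$)")
        ax.set_ylabel("p(r) / max")
        return ax

    def summary(self) -> str:
        lines = ["Pair distribution",
                 f"  Dmax = {self.dmax:.1f} A",
                 f"  Rg   = {self.rg:.2f} A",
                 f"  I(0) = {self.i0:.4g}"]
        if self.chi2 is not None:
            lines.append(f"  chi2 = {self.chi2:.3f}")
        if self.alpha is not None:
            lines.append(f"  alpha = {self.alpha:.3g}")
        for pos, kind in self.features():
            lines.append(f"  {kind} at r = {pos:.1f} A")
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def _derived_from_p(r: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    dr = float(r[1] - r[0]) if r.size > 1 else 1.0
    s0 = float(np.sum(p) * dr)
    if s0 <= 0:
        return 0.0, 0.0
    s2 = float(np.sum(r ** 2 * p) * dr)
    return float(np.sqrt(s2 / (2.0 * s0))), 4.0 * np.pi * s0


class IFTModel:
    """Regularized indirect Fourier transform of a scattering profile.

    Solves  min || (A p - I_exp) / sigma ||^2 + alpha || D2 p ||^2  with
    p >= 0 and p(0) = p(Dmax) = 0, where A encodes
    I(q) = 4 pi sum_j p(r_j) sinc(q r_j) dr and D2 is the second-difference
    operator. ``alpha=None`` selects the regularization weight by the
    L-curve corner over a log-spaced grid.
    """

    def __init__(self, profile: ScatteringProfile, dmax: float, n_r: int = 201,
                 tie_end: bool = True):
        if dmax <= 0:
            raise ValueError("Dmax must be positive")
        self.profile = profile
        self.dmax = float(dmax)
        self.n_r = n_r
        self.tie_end = tie_end
        self.r = np.linspace(0.0, self.dmax, n_r)
        self.dr = self.r[1] - self.r[0]
        q = profile.q
        self.A = 4.0 * np.pi * np.sinc(np.outer(q, self.r) / np.pi) * self.dr
        if profile.sigma is not None:
            self._sig = profile.sigma
        else:
            self._sig = 0.01 * np.maximum(np.abs(profile.I), 1e-12 * np.max(np.abs(profile.I)))

    def _solve(self, alpha: float) -> tuple[np.ndarray, float, float]:
        free = slice(1, self.n_r - 1) if self.tie_end else slice(1, self.n_r)
        Aw = self.A[:, free] / self._sig[:, None]
        yw = self.profile.I / self._sig
        n_free = Aw.shape[1]
        # second differences of the full vector (zeros at tied ends included)
        D2 = np.zeros((self.n_r - 2, n_free))
        for row in range(self.n_r - 2):
            for j, col in enumerate(range(row, row + 3)):
                cidx = col - 1  # full-grid index col maps to free index col-1
                if 0 <= cidx < n_free:
                    D2[row, cidx] = (1.0, -2.0, 1.0)[j]
        stacked = np.vstack([Aw, np.sqrt(alpha) * D2])
        rhs = np.concatenate([yw, np.zeros(self.n_r - 2)])
        sol, _ = nnls(stacked, rhs, maxiter=10 * n_free)
        p = np.zeros(self.n_r)
        p[free] = sol
        resid = Aw @ sol - yw
        rho = float(resid @ resid)
        eta = float(np.sum((D2 @ sol) ** 2))
        return p, rho, eta

    def fit(self, alpha: float | None = None,
            alpha_grid: np.ndarray | None = None) -> PairDistribution:
        if alpha is None:
            grid = alpha_grid if alpha_grid is not None else np.logspace(-6, 4, 15)
            alpha = self._l_curve_corner(grid)
        p, rho, _ = self._solve(alpha)
        chi2 = rho / len(self.profile)
        rg, i0 = _derived_from_p(self.r, p)
        flags = []
        if chi2 > 3.0:
            flags.append("poor fit: Dmax too small or profile inconsistent")
        tail = p[-5:].max() / p.max() if p.max() > 0 else 0.0
        if not self.tie_end and tail > 0.01:
            flags.append("p(r) does not vanish at Dmax")
        return PairDistribution(self.r, p, self.dmax, rg, i0, chi2=chi2,
                                alpha=float(alpha), flags=flags)

    def _l_curve_corner(self, grid: np.ndarray) -> float:
        rhos, etas = [], []
        for a in grid:
            _, rho, eta = self._solve(float(a))
            rhos.append(max(rho, 1e-300))
            etas.append(max(eta, 1e-300))
        lr = np.log(rhos)
        le = np.log(etas)
        # discrete curvature of the (log rho, log eta) curve
        best, best_k = -np.inf, len(grid) // 2
        for k in range(1, len(grid) - 1):
            v1 = np.array([lr[k] - lr[k - 1], le[k] - le[k - 1]])
            v2 = np.array([lr[k + 1] - lr[k], le[k + 1] - le[k]])
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-12 or n2 < 1e-12:
                continue
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            curv = cross / (n1 * n2)
            if curv > best:
                best, best_k = curv, k
        return float(grid[best_k])


def ift_pr(profile: ScatteringProfile, dmax: float, alpha: float | None = None,
           n_r: int = 201) -> PairDistribution:
    """Convenience wrapper: ``IFTModel(profile, dmax).fit(alpha)``."""
    return IFTModel(profile, dmax, n_r=n_r).fit(alpha=alpha)


def pr_from_model(model: StructureModel, bin_width: float = 1.0) -> PairDistribution:
    """Exact weighted pair-distance histogram of a bead model.

    The histogram is normalized at its maximum (the convention used when
    comparing P(r) curves of different constructs); Rg and I(0) are derived
    from the raw (unnormalized) moments.
    """
    centres, pair_w, _ = pair_histogram(model, bin_width)
    if centres.size == 0:
        raise ValueError("model has a single bead: p(r) undefined")
    dmax = model.dmax()
    n_bins = int(np.ceil(dmax / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    grid = 0.5 * (edges[:-1] + edges[1:])
    p = np.zeros(grid.size)
    idx = np.searchsorted(edges, centres, side="right") - 1
    np.add.at(p, idx, pair_w)
    r = np.concatenate([[0.0], grid])
    p = np.concatenate([[0.0], p])
    dr = bin_width
    s0 = float(np.sum(p) * dr)
    s2 = float(np.sum(r ** 2 * p) * dr)
    rg = np.sqrt(s2 / (2.0 * s0))
    i0 = 2.0 * s0 + float(np.sum(model.weights ** 2)) * dr  # Debye I(0) analogue
    pmax = p.max()
    return PairDistribution(r, p / pmax, float(dmax), float(rg), i0, chi2=None)


def dmax_scan(profile: ScatteringProfile, dmax_range: tuple[float, float],
              n_candidates: int = 25, alpha: float | None = None,
              tail_frac: float = 0.01) -> tuple[float, list[str]]:
    """Estimate Dmax: the smallest support length whose free-endpoint IFT
    solution both fits the data and decays below ``tail_frac`` of the peak.

    Candidates below the true Dmax misfit systematically (chi2 blows up);
    candidates above it fit equally well with a vanishing tail. Ties break
    toward smaller Dmax. Returns (dmax, flags).
    """
    lo, hi = dmax_range
    if not (0 < lo < hi):
        raise ValueError("invalid Dmax bracket")
    cands = np.linspace(lo, hi, n_candidates)
    results = []
    for d in cands:
        m = IFTModel(profile, float(d), tie_end=False)
        a = alpha if alpha is not None else 1.0
        p, rho, _ = m._solve(a)
        chi2 = rho / len(profile)
        tail = float(p[-3:].max() / p.max()) if p.max() > 0 else 1.0
        results.append((float(d), chi2, tail))
    chis = np.array([r[1] for r in results])
    best = float(chis.min())
    flags: list[str] = []
    tol = max(1.2 * best, best + 0.5)
    for d, chi2, tail in results:
        if chi2 <= tol and tail <= tail_frac:
            if d <= cands[0] + 1e-9:
                flags.append("degenerate: Dmax at scan lower bound (point-like scatterer?)")
            return d, flags
    flags.append("no candidate satisfied fit+tail criteria; returning best-fit Dmax")
    return float(cands[int(np.argmin(chis))]), flags


# ========================================================= Kratky curve

@dataclass
class KratkyCurve:
    """Dimensionless Kratky representation (q Rg)^2 I/I(0) vs q Rg."""

    x: np.ndarray
    y: np.ndarray

    def maximum(self) -> tuple[float, float]:
        """(position, height) of the global maximum, parabola-refined."""
        i = int(np.argmax(self.y))
        return _parabolic(self.x, self.y, i), float(self.y[i])

    def features(self, window: int = 11) -> list[tuple[float, str]]:
        return find_features(self.x, self.y, window=window)

    def shoulders(self, window: int = 11) -> list[float]:
        return [p for p, k in self.features(window) if k == "shoulder"]

    def plot(self, ax=None, **kwargs):
        """Plot the dimensionless Kratky curve; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x, self.y, **kwargs)
        ax.axhline(3 / np.e, ls=":", lw=0.5)
        ax.axvline(np.sqrt(3.0), ls=":", lw=0.5)
        ax.set_xlabel(r"q $R_g$")
        ax.set_ylabel(r"$(qR_g)^2\, I/I(0)$")
        return ax

    def shoulder_after_maximum(self, window: int = 11) -> float:
        """First feature (shoulder or secondary peak) beyond the main max."""
        xmax, _ = self.maximum()
        for pos, kind in self.features(window):
            if pos > xmax + 0.3:
                return pos
        raise ValueError("no secondary Kratky feature found")

    def domain_feature(self, compact_limit: float = 2.5,
                       plateau_frac: float = 0.985) -> float:
        """Position of the domain-separation feature in q*Rg units.

        Compact particles peak near q*Rg ~ 1.7 and show the domain feature
        as a distinct shoulder at higher q*Rg. Strongly extended conformers
        instead develop one broad domain-scale hump that *is* the global
        maximum; a point estimate of its apex is ill-conditioned on the flat
        top, so the feature position is then taken as the centroid of the
        plateau (the region within ``1 - plateau_frac`` of the maximum).
        """
        xmax, ymax = self.maximum()
        if xmax <= compact_limit:
            return self.shoulder_after_maximum()
        mask = self.y >= plateau_frac * float(np.max(self.y))
        return float(np.mean(self.x[mask]))


def kratky_dimensionless(profile: ScatteringProfile, guinier: GuinierResults
                         ) -> KratkyCurve:
    """Dimensionless Kratky curve using Guinier-derived Rg and I(0).

    For a globular particle the curve peaks near q Rg = sqrt(3) ~ 1.73 at a
    height of 3/e ~ 1.10; shoulders at higher q Rg indicate separated
    domains or extended conformers.
    """
    x = profile.q * guinier.rg
    y = x ** 2 * profile.I / guinier.i0
    return KratkyCurve(x, y)


# ===================================================== frame processing

def subtract_buffer(frames: list[ScatteringProfile],
                    buffer_indices: np.ndarray | list[int]
                    ) -> list[ScatteringProfile]:
    """Subtract the averaged buffer profile from every frame.

    Uncertainties propagate in quadrature: the buffer average has
    sigma_b = sqrt(sum sigma_i^2)/n, and each subtracted frame carries
    sqrt(sigma_f^2 + sigma_b^2).
    """
    buffer_indices = np.asarray(buffer_indices, dtype=int)
    if buffer_indices.size < 1:
        raise ValueError("need at least one buffer frame")
    for f in frames[1:]:
        frames[0].require_same_grid(f)
    buf = frames[buffer_indices[0]].q * 0.0
    var = buf.copy()
    for i in buffer_indices:
        buf = buf + frames[i].I
        if frames[i].sigma is not None:
            var = var + frames[i].sigma ** 2
    n = buffer_indices.size
    buf /= n
    sig_b2 = var / n ** 2
    out = []
    for f in frames:
        sig2 = (f.sigma ** 2 if f.sigma is not None else 0.0) + sig_b2
        out.append(ScatteringProfile(f.q, f.I - buf, np.sqrt(np.maximum(sig2, 1e-300))))
    return out


def merge_frames(frames: list[ScatteringProfile], rg_tolerance: float = 0.05,
                 min_integral_frac: float = 0.3
                 ) -> tuple[ScatteringProfile, np.ndarray]:
    """Average the stable elution-peak frames of a subtracted stack.

    The apex is the frame with the largest integrated intensity. Frames are
    kept if their integral exceeds ``min_integral_frac`` of the apex
    integral and their Guinier Rg lies within ``rg_tolerance`` (relative) of
    the apex Rg; frames whose Guinier fit fails are dropped. Returns the
    averaged profile (sigma propagated as sqrt(sum sigma^2)/n) and the
    indices of the merged frames.
    """
    integrals = np.array([float(np.trapezoid(f.I, f.q)) for f in frames])
    apex = int(np.argmax(integrals))
    apex_rg = GuinierModel(frames[apex]).fit().rg
    selected = []
    for i, f in enumerate(frames):
        if integrals[i] < min_integral_frac * integrals[apex]:
            continue
        try:
            rg = GuinierModel(f).fit().rg
        except (ValueError, RuntimeError):
            continue
        if abs(rg - apex_rg) <= rg_tolerance * apex_rg:
            selected.append(i)
    if not selected:
        selected = [apex]
    sel = np.asarray(selected, dtype=int)
    q = frames[0].q
    I = np.mean([frames[i].I for i in sel], axis=0)
    var = np.sum([frames[i].sigma ** 2 for i in sel], axis=0) / sel.size ** 2
    return ScatteringProfile(q, I, np.sqrt(var)), sel
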