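"""Auxiliary biophysical fits: SPR 1:1 kinetics and melting temperatures.

The SPR model is the 1:1 (Langmuir) interaction

    dR/dt = ka * C(t) * (Rmax - R) - kd * R,      K_D = kd / ka,

fitted globally across a single-cycle sensorgram (sequential injections of
increasing analyte concentration without surface regeneration). The melting
temperature is the extremum of the smoothed first derivative of a thermal
signal (fluorescence, 350/330 nm ratio, or ellipticity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
import lmfit

__all__ = ["BindingTrace", "MeltCurve", "SPRKineticsModel", "SPRKineticsResults",
           "fit_spr_1to1", "compute_tm", "delta_tm"]


@dataclass
class BindingTrace:
    """An SPR sensorgram with its analyte concentration schedule.

    ``concentration`` holds the molar analyte concentration at each time
    point (zero during dissociation phases).
    """

    time: np.ndarray
    response: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.response = np.asarray(self.response, float)
        self.concentration = np.asarray(self.concentration, float)
        if not (self.time.shape == self.response.shape == self.concentration.shape):
            raise ValueError("time, response, concentration must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly ascending")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be >= 0")

    def segments(self) -> list[tuple[int, int, float]]:
        """Constant-concentration runs as (start, stop, C) index intervals."""
        c = self.concentration
        breaks = np.flatnonzero(np.diff(c) != 0) + 1
        starts = np.concatenate([[0], breaks])
        stops = np.concatenate([breaks, [c.size]])
        return [(int(a), int(b), float(c[a])) for a, b in zip(starts, stops)]

    def n_injections(self) -> int:
        return sum(1 for _, _, c in self.segments() if c > 0)


def _integrate_1to1(trace: BindingTrace, ka: float, kd: float, rmax: float) -> np.ndarray:
    """Exact piecewise solution of the 1:1 model over the trace's schedule."""
    t = trace.time
    out = np.empty_like(t)
    r0 = 0.0
    for a, b, c in trace.segments():
        k_obs = ka * c + kd
        r_eq = ka * c * rmax / k_obs
        tt = t[a:b] - t[a]
        out[a:b] = r_eq + (r0 - r_eq) * np.exp(-k_obs * tt)
        # state at the end of the segment (continuous time to next start)
        t_end = (t[b] if b < t.size else t[b - 1]) - t[a]
        r0 = r_eq + (r0 - r_eq) * np.exp(-k_obs * t_end)
    return out


class SPRKineticsModel:
    """1:1 kinetic model for a single-cycle SPR sensorgram.

    Parameters
    ----------
    trace : BindingTrace
        Must contain at least two injection phases for the rate constants to
        be identifiable.
    """

    def __init__(self, trace: BindingTrace):
        if trace.n_injections() < 2:
            raise ValueError("single-cycle fit needs at least 2 injection phases")
        self.trace = trace

    def fit(self, ka0: float | None = None, kd0: float | None = None,
            rmax0: float | None = None, multistart: bool = True) -> "SPRKineticsResults":
        """Nonlinear least squares over the whole trace.

        Rate constants are fitted on a log scale. Unless initial guesses are
        supplied, a coarse multistart grid over (ka, kd) avoids local minima.
        """
        tr = self.trace
        r_scale = max(float(np.max(np.abs(tr.response))), 1e-9)
        c_max = float(tr.concentration.max())

        def residual(params):
            ka = 10.0 ** params["log_ka"].value
            kd = 10.0 ** params["log_kd"].value
            return tr.response - _integrate_1to1(tr, ka, kd, params["rmax"].value)

        starts: list[tuple[float, float]]
        if ka0 is not None and kd0 is not None:
            starts = [(np.log10(ka0), np.log10(kd0))]
        elif multistart:
            starts = [(lka, lkd) for lka in (4.0, 5.0, 6.0) for lkd in (-3.0, -2.0, -1.0)]
        else:
            starts = [(5.0, -2.0)]
        best = None
        for lka, lkd in starts:
            p = lmfit.Parameters()
            p.add("log_ka", value=lka, min=0.0, max=9.0)
            p.add("log_kd", value=lkd, min=-6.0, max=1.0)
            p.add("rmax", value=rmax0 or 1.5 * r_scale, min=1e-6 * r_scale)
            try:
                res = lmfit.minimize(residual, p, method="leastsq")
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("SPR fit failed from every start")
        ka = 10.0 ** best.params["log_ka"].value
        kd = 10.0 ** best.params["log_kd"].value
        rmax = best.params["rmax"].value
        rmsd = float(np.sqrt(best.chisqr / tr.time.size))
        # identifiability: without sub-saturating injections ka and kd are
        # only constrained through their ratio
        kdiss = kd / ka
        c_min_nonzero = min((c for _, _, c in tr.segments() if c > 0), default=c_max)
        ident_warn = c_min_nonzero > 10.0 * kdiss if kdiss > 0 else True
        if ident_warn:
            warnings.warn("all injections saturating (C >> K_D): ka and kd are "
                          "strongly correlated; only Rmax and K_D order of "
                          "magnitude are reliable", RuntimeWarning, stacklevel=2)
        return SPRKineticsResults(self, ka=ka, kd=kd, rmax=rmax, rmsd=rmsd,
                                  lmfit_result=best, saturating=bool(ident_warn))


@dataclass
class SPRKineticsResults:
    model: SPRKineticsModel
    ka: float
    kd: float
    rmax: float
    rmsd: float
    lmfit_result: object
    saturating: bool

    @property
    def kD(self) -> float:
        return self.kd / self.ka

    def predicted(self) -> np.ndarray:
        return _integrate_1to1(self.model.trace, self.ka, self.kd, self.rmax)

    def equilibrium_response(self, concentration: float) -> float:
        """Plateau response Rmax C / (C + K_D) at a given molar concentration."""
        return self.rmax * concentration / (concentration + self.kD)

    def plot(self, ax=None):
        """Plot the sensorgram with the fitted 1:1 curve; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.model.trace
        ax.plot(tr.time, tr.response, ".", ms=2, label="data")
        ax.plot(tr.time, self.predicted(), "-", lw=1.2, label="1:1 fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = ["SPR 1:1 kinetic fit",
                 f"  ka   = {self.ka:.4g} 1/(M s)",
                 f"  kd   = {self.kd:.4g} 1/s",
                 f"  K_D  = {self.kD * 1e9:.4g} nM",
                 f"  Rmax = {self.rmax:.4g} RU",
                 f"  rmsd = {self.rmsd:.4g} RU"]
        if self.saturating:
            lines.append("  warning: saturating schedule, ka/kd correlated")
        return "\n".join(lines)


def fit_spr_1to1(trace: BindingTrace, ka0: float | None = None,
                 kd0: float | None = None, rmax0: float | None = None
                 ) -> SPRKineticsResults:
    """Convenience wrapper: ``SPRKineticsModel(trace).fit(...)``."""
    return SPRKineticsModel(trace).fit(ka0=ka0, kd0=kd0, rmax0=rmax0)


# ---------------------------------------------------------------- melting

@dataclass
class MeltCurve:
    """A thermal-denaturation signal vs temperature (degrees C, ascending)."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, float)
        self.signal = np.asarray(self.signal, float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must have equal length")
        if self.temperature.size < 20:
            raise ValueError("melt curve needs at least 20 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly ascending")


def compute_tm(curve: MeltCurve, smoothing_window: int = 21) -> float:
    """Melting temperature: peak of the smoothed first derivative.

    The derivative is taken on the Savitzky-Golay-smoothed signal; the sign
    of the transition (rising fluorescence vs falling ellipticity) is
    handled by locating the extremum of |dS/dT|. A monotone or flat signal
    (no interior extremum above the derivative noise floor) raises.
    """
    T, y = curve.temperature, curve.signal
    win = min(smoothing_window if smoothing_window % 2 else smoothing_window + 1,
              y.size if y.size % 2 else y.size - 1)
    win = max(win, 5)
    dT = float(np.median(np.diff(T)))
    dy = savgol_filter(y, window_length=win, polyorder=3, deriv=1, delta=dT)
    mag = np.abs(dy)
    i = int(np.argmax(mag))
    interior = max(1, win // 2)
    if i < interior or i >= mag.size - interior:
        raise ValueError("no interior derivative extremum: curve has no transition")
    span = float(np.ptp(y))
    if span <= 0 or mag[i] < 3.0 * np.median(mag) or mag[i] * (T[-1] - T[0]) < 0.1 * span:
        raise ValueError("derivative peak indistinct: curve is flat or linear")
    # the derivative peak has a broad top, so a point argmax is noisy;
    # report the centroid of the contiguous region above 80% of the peak
    thresh = 0.8 * mag[i]
    lo = i
    while lo > 0 and mag[lo - 1] >= thresh:
        lo -= 1
    hi = i
    while hi < mag.size - 1 and mag[hi + 1] >= thresh:
        hi += 1
    w = mag[lo:hi + 1] - thresh
    return float(np.sum(w * T[lo:hi + 1]) / np.sum(w))


def delta_tm(curve_a: MeltCurve, curve_b: MeltCurve, smoothing_window: int = 21) -> float:
    """Tm(a) - Tm(b) in degrees C."""
    return compute_tm(curve_a, smoothing_window) - compute_tm(curve_b, smoothing_window)
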