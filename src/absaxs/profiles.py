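"""1-D solution-scattering profiles.

A profile is the orientation-averaged intensity I(q) on an ascending grid of
momentum transfer q = 4*pi*sin(theta)/lambda (inverse Angstrom), optionally
with per-point experimental uncertainties sigma(q). Profiles are exchanged on
disk as whitespace-delimited three-column text (``q I sigma``), the dialect
used by most SAXS reduction software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ScatteringProfile", "default_q_grid"]


def default_q_grid(q_min: float = 0.01, q_max: float = 0.45, n_points: int = 220) -> np.ndarray:
    """Linear q-grid over the measurable window of a typical SEC-SAXS setup."""
    return np.linspace(q_min, q_max, n_points)


@dataclass
class ScatteringProfile:
    """Intensity vs momentum transfer, with optional uncertainties.

    Parameters
    ----------
    q : ndarray
        Momentum transfer in 1/Angstrom, strictly ascending.
    I : ndarray
        Intensity, arbitrary units.
    sigma : ndarray, optional
        1-sigma uncertainty of I, same units. ``None`` for theoretical curves.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if self.q.size and np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly ascending")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("I must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return self.q.size

    def same_grid(self, other: "ScatteringProfile", rtol: float = 1e-9) -> bool:
        return self.q.shape == other.q.shape and np.allclose(self.q, other.q, rtol=rtol, atol=0)

    def require_same_grid(self, other: "ScatteringProfile") -> None:
        if not self.same_grid(other):
            raise ValueError("profiles are not on the same q-grid")

    def copy(self) -> "ScatteringProfile":
        return ScatteringProfile(
            self.q.copy(), self.I.copy(), None if self.sigma is None else self.sigma.copy()
        )

    def crop(self, q_min: float = -np.inf, q_max: float = np.inf) -> "ScatteringProfile":
        m = (self.q >= q_min) & (self.q <= q_max)
        return ScatteringProfile(self.q[m], self.I[m], None if self.sigma is None else self.sigma[m])

    def plot(self, ax=None, logy: bool = True, **kwargs):
        """Plot I(q) (log scale by default); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.sigma is not None:
            ax.errorbar(self.q, self.I, yerr=self.sigma, fmt=".", ms=2,
                        elinewidth=0.5, **kwargs)
        else:
            ax.plot(self.q, self.I, **kwargs)
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel(r"q ($\AA^{-1}$)")
        ax.set_ylabel("I(q)")
        return ax

    # ------------------------------------------------------------------ I/O
    def write_dat(self, path: str | Path, header: str | None = None) -> None:
        """Write as 3-column (or 2-column, if no sigma) whitespace text."""
        path = Path(path)
        cols = [self.q, self.I] if self.sigma is None else [self.q, self.I, self.sigma]
        head = header or ("# q I" if self.sigma is None else "# q I sigma")
        np.savetxt(path, np.column_stack(cols), header=head.lstrip("# "), comments="# ")

    @classmethod
    def read_dat(cls, path: str | Path) -> "ScatteringProfile":
        data = np.loadtxt(path, comments="#")
        data = np.atleast_2d(data)
        if data.shape[1] < 2:
            raise ValueError(f"{path}: expected at least two columns (q, I)")
        sigma = data[:, 2] if data.shape[1] >= 3 else None
        return cls(data[:, 0], data[:, 1], sigma)
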