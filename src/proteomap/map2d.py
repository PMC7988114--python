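"""The virtual 2-D proteome map: binned pI × molecular-mass density.

An in-silico analog of 2-D gel electrophoresis: every protein of a pooled
proteome is placed on a plane with isoelectric point on the x-axis and
molecular mass (kDa, log-spaced) on the y-axis, and the plane is binned into
a count grid.  The 1-D pI profile (the map's marginal over mass) is smoothed
with a centered moving average and scanned for modes, which is how the
bimodality of proteome-wide pI distributions is assessed: proteins cluster
into an acidic and a basic population with a sparse neutral valley near the
cytoplasmic pH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

DEFAULT_PI_RANGE = (1.0, 14.0)
DEFAULT_PI_BINWIDTH = 0.1
DEFAULT_MW_RANGE_KDA = (0.1, 3000.0)
DEFAULT_MW_BINS = 60
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MIN_PROMINENCE = 0.1


@dataclass
class Map2DGrid:
    """Binned (pI × MW) counts.  Bins are half-open [lo, hi), last bin closed."""

    pi_edges: np.ndarray   # ascending, pH units
    mw_edges: np.ndarray   # ascending, kDa (log10-spaced by default)
    counts: np.ndarray     # shape (n_pi_bins, n_mw_bins), integers
    total: int             # proteins inside the grid range
    n_out_of_range: int = 0

    def pi_marginal(self) -> np.ndarray:
        """Counts per pI bin, marginalized over the mass axis."""
        return self.counts.sum(axis=1)

    def to_frame(self):
        """Long-format frame: pi_bin_lo, mw_bin_lo, count (nonzero cells only)."""
        import pandas as pd
        ii, jj = np.nonzero(self.counts)
        return pd.DataFrame({
            "pi_bin_lo": self.pi_edges[ii],
            "mw_bin_lo": self.mw_edges[jj],
            "count": self.counts[ii, jj],
        })


@dataclass
class PiProfile:
    """1-D pI histogram with its smoothed density and detected modes."""

    bin_centers: np.ndarray
    density: np.ndarray            # raw integer counts per bin
    smoothed: np.ndarray           # centered moving average of density
    modes: list[tuple[float, float]] = field(default_factory=list)
    n_out_of_range: int = 0


def _pi_edges(binwidth: float, pi_range: tuple[float, float]) -> np.ndarray:
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    lo, hi = pi_range
    n = int(np.ceil((hi - lo) / binwidth - 1e-9))
    return lo + binwidth * np.arange(n + 1)


def build_map(pi: np.ndarray, mw_kda: np.ndarray,
              pi_binwidth: float = DEFAULT_PI_BINWIDTH,
              pi_range: tuple[float, float] = DEFAULT_PI_RANGE,
              mw_range_kda: tuple[float, float] = DEFAULT_MW_RANGE_KDA,
              mw_bins: int = DEFAULT_MW_BINS,
              log_mw: bool = True) -> Map2DGrid:
    """Bin pooled (pI, MW) points into the virtual 2-D map grid."""
    pi = np.asarray(pi, dtype=float)
    mw = np.asarray(mw_kda, dtype=float)
    if pi.size == 0:
        raise ValueError("no proteins to map")
    if pi.shape != mw.shape:
        raise ValueError("pi and mw arrays must be aligned")
    pi_edges = _pi_edges(pi_binwidth, pi_range)
    if log_mw:
        mw_edges = np.logspace(np.log10(mw_range_kda[0]),
                               np.log10(mw_range_kda[1]), mw_bins + 1)
    else:
        mw_edges = np.linspace(mw_range_kda[0], mw_range_kda[1], mw_bins + 1)
    counts, _, _ = np.histogram2d(pi, mw, bins=(pi_edges, mw_edges))
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    n_out = int(pi.size - total)
    if n_out:
        logger.info("2-D map: %d of %d proteins outside the grid range",
                    n_out, pi.size)
    return Map2DGrid(pi_edges=pi_edges, mw_edges=mw_edges, counts=counts,
                     total=total, n_out_of_range=n_out)


def _moving_average(density: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge bins average over the bins available."""
    if window == 1:
        return density.astype(float)
    kernel = np.ones(window)
    sums = np.convolve(density.astype(float), kernel, mode="same")
    coverage = np.convolve(np.ones_like(density, dtype=float), kernel, mode="same")
    return sums / coverage


def pi_profile(pi: np.ndarray,
               binwidth: float = DEFAULT_PI_BINWIDTH,
               pi_range: tuple[float, float] = DEFAULT_PI_RANGE,
               smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> PiProfile:
    """Histogram the pooled pI values and smooth with a moving average.

    ``smooth_window`` is an odd bin count; 1 disables smoothing.  Raw counts
    are kept alongside the smoothed density so integer identities against the
    2-D map marginal stay exact.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd count >= 1")
    pi = np.asarray(pi, dtype=float)
    edges = _pi_edges(binwidth, pi_range)
    density, _ = np.histogram(pi, bins=edges)
    smoothed = _moving_average(density, smooth_window)
    return PiProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=density.astype(np.int64),
        smoothed=smoothed,
        n_out_of_range=int(pi.size - density.sum()),
    )


def detect_modes(profile: PiProfile,
                 min_prominence: float = DEFAULT_MIN_PROMINENCE) -> list[tuple[float, float]]:
    """Local maxima of the smoothed profile, sorted by pI.

    A mode must have prominence at least ``min_prominence`` times the maximum
    smoothed density.  Plateau maxima report their center bin; maxima at the
    profile boundary count (the profile is padded below zero so a monotone
    profile yields its single boundary mode).
    """
    y = np.asarray(profile.smoothed, dtype=float)
    if y.size == 0:
        raise ValueError("empty profile")
    if y.max() <= 0:
        return []
    padded = np.concatenate([[-1.0], y, [-1.0]])
    idx, _ = find_peaks(padded, prominence=min_prominence * y.max())
    idx = idx - 1
    modes = [(float(profile.bin_centers[i]), float(y[i])) for i in idx]
    modes.sort(key=lambda m: m[0])
    profile.modes = modes
    return modes


def render_map(grid: Map2DGrid, path) -> None:
    """Convenience PNG/SVG rendering of the 2-D map; the CSV is the contract."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    with np.errstate(divide="ignore"):
        z = np.log10(np.where(grid.counts > 0, grid.counts, np.nan))
    mesh = ax.pcolormesh(grid.pi_edges, grid.mw_edges, z.T, cmap="viridis")
    ax.set_yscale("log")
    ax.set_xlabel("isoelectric point (pI)")
    ax.set_ylabel("molecular mass (kDa)")
    fig.colorbar(mesh, ax=ax, label="log10 protein count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
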