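"""1-D weighted-histogram analysis of umbrella-sampling windows.

Each window carries scalar samples of a reaction coordinate — either the
mass-weighted ligand RMSD ξ (Å) or the protein–ligand separation r (Å) —
collected under a harmonic bias k/2·(x − c)².  The self-consistent WHAM
equations recover the unbiased density ρ(x) and hence the potential of mean
force w(x) = −kBT·ln ρ(x):

    ρ(b)        = Σ_i n_i(b) / Σ_i N_i · exp(β f_i) · c_i(b)
    exp(−β f_i) = Σ_b c_i(b) · ρ(b) · Δx

with c_i(b) the Boltzmann factor of window i's bias at bin b.  Iteration
stops when the largest change in any window offset f_i falls below ``tol``.

No autocorrelation correction is applied: sample counts enter raw, and
uncertainty estimation is out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError

KB_KCAL = 1.9872e-3

COORDINATE_KINDS = ("xi", "r")

#: Bins with fewer pooled samples than this are flagged as poorly sampled:
#: the statistical error of −kBT·ln(n) is roughly kBT/√n, i.e. ≲0.105
#: kcal/mol at 300 K for n ≥ 32.
DEFAULT_MIN_BIN_COUNT = 32


@dataclass
class UmbrellaWindow:
    """One umbrella-sampling window: bias metadata plus raw samples."""

    coordinate_kind: str
    bias_center: float
    force_constant: float  # kcal/mol/Ų
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.coordinate_kind not in COORDINATE_KINDS:
            raise ValidationError(
                f"coordinate_kind must be one of {COORDINATE_KINDS}, got {self.coordinate_kind!r}"
            )
        if self.force_constant < 0:
            raise ValidationError("force_constant must be >= 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D series")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite")
        if self.samples.size < 50:
            warnings.warn(
                f"window at center {self.bias_center} has only {self.samples.size} samples",
                stacklevel=2,
            )

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(x, dtype=float) - self.bias_center) ** 2


@dataclass
class PMFCurve:
    """A 1-D free-energy profile on uniform bin centers.

    ``values`` are kcal/mol with NaN marking bins that received no samples
    (never silently zero).  ``well_sampled`` additionally marks bins with at
    least ``min_bin_count`` pooled samples, over which recovery statistics
    should be evaluated.
    """

    coordinate_kind: str
    grid: np.ndarray
    values: np.ndarray
    zero_convention: str = "min_zero"
    counts: np.ndarray | None = None
    well_sampled: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValidationError("grid must be 1-D with >= 2 bins")
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if self.grid.shape != self.values.shape:
            raise ValidationError("grid and values must have the same shape")
        if self.zero_convention not in ("min_zero", "bulk_plateau_zero", "none"):
            raise ValidationError(f"unknown zero_convention {self.zero_convention!r}")
        if self.well_sampled is None:
            self.well_sampled = np.isfinite(self.values)

    @property
    def supported(self) -> np.ndarray:
        return np.isfinite(self.values)


def _apply_zero(values: np.ndarray, grid: np.ndarray, mask: np.ndarray,
                convention: str) -> np.ndarray:
    out = values.copy()
    if convention == "none" or not mask.any():
        return out
    if convention == "min_zero":
        out -= np.nanmin(values[mask])
    elif convention == "bulk_plateau_zero":
        g = grid[mask]
        tail = grid >= g[-1] - 0.1 * (g[-1] - g[0])
        out -= float(np.nanmean(values[mask & tail]))
    return out


def wham_1d(windows: list[UmbrellaWindow], bin_width: float = 0.05,
            temperature: float = 300.0, tol: float = 1e-7, max_iter: int = 100_000,
            zero_convention: str = "min_zero",
            min_bin_count: int = DEFAULT_MIN_BIN_COUNT) -> PMFCurve:
    """Run self-consistent WHAM over the given windows.

    Returns a :class:`PMFCurve` under the requested zero convention, with the
    iteration count and residual trace in ``meta``.
    """
    if not windows:
        raise ValidationError("at least one window is required")
    kinds = {w.coordinate_kind for w in windows}
    if len(kinds) > 1:
        raise ValidationError(f"windows mix coordinate kinds: {sorted(kinds)}")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")

    kBT = KB_KCAL * temperature
    beta = 1.0 / kBT

    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    start = math.floor(lo / bin_width) * bin_width
    n_bins = int(math.ceil((hi - start) / bin_width)) + 1
    edges = start + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_win = len(windows)
    hist = np.empty((n_win, n_bins))
    N = np.empty(n_win)
    for i, w in enumerate(windows):
        hist[i], _ = np.histogram(w.samples, bins=edges)
        N[i] = w.samples.size

    if n_win >= 2:
        order = np.argsort([w.bias_center for w in windows])
        for a, b in zip(order[:-1], order[1:]):
            shared = int(np.sum((hist[a] > 0) & (hist[b] > 0)))
            if shared == 0:
                raise ValidationError(
                    "non-overlapping neighbor histograms between windows centered at "
                    f"{windows[a].bias_center} and {windows[b].bias_center}"
                )

    counts = hist.sum(axis=0)
    populated = counts > 0

    bias = np.stack([w.bias_energy(centers) for w in windows])  # (n_win, n_bins)
    log_c = -beta * bias

    f = np.zeros(n_win)  # window free-energy offsets, kcal/mol
    residuals: list[float] = []
    logN = np.log(N)
    with np.errstate(divide="ignore"):
        log_hist_tot = np.where(populated, np.log(counts), -np.inf)

    for iteration in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_i [ log N_i + beta f_i + log c_i(b) ]
        a = logN[:, None] + beta * f[:, None] + log_c
        a_max = a.max(axis=0)
        log_denom = a_max + np.log(np.exp(a - a_max).sum(axis=0))
        log_rho = log_hist_tot - log_denom  # unnormalised density (per bin width)
        # new offsets: exp(-beta f_i) = sum_b c_i(b) rho(b) * dx
        b_mat = np.where(populated, log_c + log_rho, -np.inf)
        b_max = b_mat.max(axis=1)
        log_z = b_max + np.log(np.exp(b_mat - b_max[:, None]).sum(axis=1)) + math.log(bin_width)
        f_new = -kBT * log_z
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        residuals.append(residual)
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations; residual {residuals[-1]:.3e}"
        )

    values = np.full(n_bins, np.nan)
    values[populated] = -kBT * log_rho[populated]
    well = counts >= min_bin_count
    values = _apply_zero(values, centers, well if well.any() else populated, zero_convention)

    return PMFCurve(
        coordinate_kind=windows[0].coordinate_kind,
        grid=centers,
        values=values,
        zero_convention=zero_convention,
        counts=counts,
        well_sampled=well,
        meta={
            "temperature": temperature,
            "iterations": iteration,
            "residuals": residuals,
            "bin_width": bin_width,
            "min_bin_count": min_bin_count,
        },
    )


def check_overlap(windows: list[UmbrellaWindow], bin_width: float = 0.05,
                  min_shared: int = 3) -> pd.DataFrame:
    """Histogram-overlap diagnostics for adjacent window pairs.

    Returns a table with one row per adjacent pair (sorted by bias center):
    shared populated bin count and a pass flag at ``>= min_shared``.
    """
    if len(windows) < 2:
        raise ValidationError("need at least 2 windows for overlap diagnostics")
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    start = math.floor(lo / bin_width) * bin_width
    n_bins = int(math.ceil((hi - start) / bin_width)) + 1
    edges = start + bin_width * np.arange(n_bins + 1)
    order = sorted(range(len(windows)), key=lambda i: windows[i].bias_center)
    rows = []
    for a, b in zip(order[:-1], order[1:]):
        ha, _ = np.histogram(windows[a].samples, bins=edges)
        hb, _ = np.histogram(windows[b].samples, bins=edges)
        shared = int(np.sum((ha > 0) & (hb > 0)))
        rows.append({
            "center_lo": windows[a].bias_center,
            "center_hi": windows[b].bias_center,
            "shared_bins": shared,
            "pass": shared >= min_shared,
        })
    return pd.DataFrame(rows)
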