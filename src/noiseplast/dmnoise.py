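"""Mean-compensated noise: the V_pop-vs-E_pop trend and its DM residuals.

Cell-to-cell expression noise depends on the mean expression level: at low
means the intrinsic (birth/death counting) component makes the log-scale SD
fall as the mean rises, while at high means an extrinsic floor makes it
mean-independent.  Comparing noise between genes with different expression
levels therefore requires removing the mean dependence.  The standard
"distance to median" (DM) construction does this non-parametrically: pool all
(gene, condition) points, sort by mean, take a running median of the SDs in a
sliding window (robust to the long-tailed outliers typical of expression
data), smooth the running-median sequence with a cubic smoothing spline, and
define each point's DM as the vertical residual of its SD from the smoothed
trend.  Averaging DM over conditions yields one mean-compensated noise value
per gene.

The same operation applies unchanged to any (mean, SD) table — e.g. log2
mRNA means/SDs across environments, giving a transcriptional-plasticity
residual — via :func:`dm_from_table`.

The trend fit is exposed statsmodels-style::

    res = NoiseTrendModel(e, v, keys=keys).fit()
    res.residuals      # DM per point
    res.predict(e_new) # trend evaluation
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline, make_smoothing_spline


def default_window(n_points: int) -> int:
    """Running-median window: odd number nearest 15% of the point count.

    Bounded to [11, 101]; additionally capped so that at least two full
    windows of points exist (fit precondition).
    """
    w = int(round(0.15 * n_points))
    w = min(101, max(11, w | 1))
    cap = n_points // 2
    if w > cap:
        w = max(3, cap if cap % 2 == 1 else cap - 1)
    return w


def running_median(v_sorted: np.ndarray, window: int) -> np.ndarray:
    """Centred running median with symmetric truncation at the edges.

    At index i the window spans ``[i-k, i+k]`` with
    ``k = min((window-1)//2, i, n-1-i)``: near the extremes the window
    shrinks symmetrically rather than extrapolating beyond the data.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    n = len(v_sorted)
    half = (window - 1) // 2
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = np.median(v_sorted[i - k : i + k + 1])
    return out


def _bin_knots(x: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a knot sequence onto at most k equal-count bins (means)."""
    n = len(x)
    if n <= k:
        return x, y
    edges = np.linspace(0, n, k + 1).astype(int)
    bx = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    by = np.array([y[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    # means of consecutive chunks of a sorted sequence can tie only if the
    # underlying x values tie, which np.unique has already ruled out
    return bx, by


def _fit_smoothing_spline(x: np.ndarray, y: np.ndarray, lam: float | None):
    """Cubic smoothing spline of the running-median knots.

    Long knot sequences with nearly coincident abscissae make the GCV
    normal equations ill-conditioned, so dense sequences are collapsed onto
    equal-count bins first (the running median is already smooth at that
    resolution); if the solver still fails, progressively coarser binnings
    are tried, ending with a plain interpolant of a coarse binning.
    """
    if len(x) < 5:
        return make_interp_spline(x, y, k=min(3, len(x) - 1))
    for k_bins in (512, 256, 64):
        bx, by = _bin_knots(x, y, k_bins)
        if len(bx) < 5:
            break
        try:
            return make_smoothing_spline(bx, by, lam=lam)
        except Exception:
            continue
    bx, by = _bin_knots(x, y, 64)
    return make_interp_spline(bx, by, k=min(3, len(bx) - 1))


@dataclass
class NoiseTrendResult:
    """Fitted noise trend with per-point DM residuals.

    Attributes
    ----------
    e, v : arrays in the fitted (sorted) order.
    keys : point identifiers, typically (gene_id, condition_id) tuples.
    trend_values : trend evaluated at each point; ``residuals = v - trend``.
    knots : (e, running-median) sequence the spline was fitted to, after
        collapsing duplicate e values by averaging.
    """

    e: np.ndarray
    v: np.ndarray
    keys: list
    window: int
    smoothing: float | str
    trend_values: np.ndarray
    running_median_values: np.ndarray
    knots: tuple[np.ndarray, np.ndarray]
    _spline: object = field(repr=False, default=None)

    @property
    def residuals(self) -> np.ndarray:
        return self.v - self.trend_values

    def residuals_by_key(self) -> dict:
        return dict(zip(self.keys, self.residuals))

    def predict(self, e_new: np.ndarray | float) -> np.ndarray:
        """Trend value at new mean levels (constant beyond the data range)."""
        e_new = np.asarray(e_new, dtype=np.float64)
        clipped = np.clip(e_new, self.e[0], self.e[-1])
        return np.asarray(self._spline(clipped), dtype=np.float64)

    def frame(self) -> pd.DataFrame:
        """Tidy per-point table: key columns, e, v, trend, dm."""
        keys = self.keys
        if keys and isinstance(keys[0], tuple) and len(keys[0]) == 2:
            base = pd.DataFrame(keys, columns=["gene_id", "condition_id"])
        else:
            base = pd.DataFrame({"key": keys})
        base["e"] = self.e
        base["v"] = self.v
        base["trend"] = self.trend_values
        base["dm"] = self.residuals
        return base

    def mean_dm_per_gene(self) -> pd.DataFrame:
        """Unweighted mean DM per gene across its conditions.

        Keys must be (gene_id, condition_id) tuples.  Genes supported by a
        single condition are retained but flagged via ``n_conditions``.
        """
        df = self.frame()
        if "gene_id" not in df.columns:
            raise ValueError("mean_dm_per_gene requires (gene, condition) keys")
        out = (
            df.groupby("gene_id", observed=True, sort=True)
            .agg(mean_dmv=("dm", "mean"), n_conditions=("dm", "size"))
            .reset_index()
        )
        return out

    def summary(self) -> str:
        dm = self.residuals
        lines = [
            "Noise trend (running median + smoothing spline)",
            "=" * 48,
            f"points fitted        {len(self.e)}",
            f"window (points)      {self.window}",
            f"smoothing            {self.smoothing}",
            f"mean-level range     [{self.e[0]:.4f}, {self.e[-1]:.4f}]",
            f"DM residual SD       {np.std(dm, ddof=1):.5f}",
            f"DM residual range    [{dm.min():.5f}, {dm.max():.5f}]",
        ]
        return "\n".join(lines)


class NoiseTrendModel:
    """Model for the dependence of expression SD on expression mean.

    Parameters
    ----------
    e, v
        Per-point mean and SD (e.g. replicate-averaged E_pop and V_pop of
        every (gene, condition) pair, pooled over all genes and conditions).
    keys
        Optional per-point identifiers; (gene_id, condition_id) tuples enable
        :meth:`NoiseTrendResult.mean_dm_per_gene`.
    window
        Odd running-median window in points, or ``"auto"`` (see
        :func:`default_window`).
    smoothing
        Smoothing-spline penalty: ``"auto"`` selects it by generalised
        cross-validation; ``0`` makes the trend interpolate the running-median
        knots exactly (at the data points the trend then *is* the naive
        running median); a positive float is used as the penalty directly.
    """

    def __init__(
        self,
        e: Sequence[float],
        v: Sequence[float],
        keys: Sequence[Hashable] | None = None,
        window: int | str = "auto",
        smoothing: float | str = "auto",
    ) -> None:
        e = np.asarray(e, dtype=np.float64)
        v = np.asarray(v, dtype=np.float64)
        if e.shape != v.shape or e.ndim != 1:
            raise ValueError("e and v must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(v))):
            raise ValueError("e and v must be finite")
        if np.any(v < 0):
            raise ValueError("standard deviations must be non-negative")
        if keys is None:
            keys = list(range(len(e)))
        keys = list(keys)
        if len(keys) != len(e):
            raise ValueError("keys must align with e and v")

        if window == "auto":
            window = default_window(len(e))
        window = int(window)
        if len(e) < 2 * window:
            raise ValueError(
                f"need at least {2 * window} points for window {window}; "
                f"got {len(e)} — use a smaller window"
            )

        # deterministic stable sort by (e, key)
        order = sorted(range(len(e)), key=lambda i: (e[i], repr(keys[i])))
        self.e = e[np.asarray(order)]
        self.v = v[np.asarray(order)]
        self.keys = [keys[i] for i in order]
        self.window = window
        self.smoothing = smoothing

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        e_col: str = "e_pop_mean",
        v_col: str = "v_pop_mean",
        key_cols: Sequence[str] = ("gene_id", "condition_id"),
        **kwargs,
    ) -> "NoiseTrendModel":
        keys = list(df[list(key_cols)].itertuples(index=False, name=None))
        return cls(df[e_col], df[v_col], keys=keys, **kwargs)

    def fit(self) -> NoiseTrendResult:
        med = running_median(self.v, self.window)

        # spline fitting needs strictly increasing abscissae; collapse
        # duplicate e by averaging their running-median values
        uniq_e, inverse = np.unique(self.e, return_inverse=True)
        sums = np.bincount(inverse, weights=med)
        counts = np.bincount(inverse)
        knot_y = sums / counts

        interpolating = self.smoothing == 0
        if interpolating:
            if len(uniq_e) >= 4:
                spline = make_interp_spline(uniq_e, knot_y, k=3)
            else:
                spline = make_interp_spline(uniq_e, knot_y, k=1)
            # at the data points the interpolated trend equals the running
            # median itself; use it directly so the residual identity with a
            # naive running median is exact even under duplicate e values
            trend = med.copy()
        else:
            lam = None if self.smoothing == "auto" else float(self.smoothing)
            spline = _fit_smoothing_spline(uniq_e, knot_y, lam)
            trend = np.asarray(spline(self.e), dtype=np.float64)

        return NoiseTrendResult(
            e=self.e,
            v=self.v,
            keys=self.keys,
            window=self.window,
            smoothing=self.smoothing,
            trend_values=trend,
            running_median_values=med,
            knots=(uniq_e, knot_y),
            _spline=spline,
        )


def fit_noise_trend(
    e: Sequence[float],
    v: Sequence[float],
    keys: Sequence[Hashable] | None = None,
    window: int | str = "auto",
    smoothing: float | str = "auto",
) -> NoiseTrendResult:
    """Convenience wrapper: build a :class:`NoiseTrendModel` and fit it."""
    return NoiseTrendModel(e, v, keys=keys, window=window, smoothing=smoothing).fit()


def mean_dmv_per_gene(result: NoiseTrendResult) -> pd.DataFrame:
    """Per-gene unweighted mean of DM residuals across conditions."""
    return result.mean_dm_per_gene()


def dm_from_table(
    keys: Sequence[Hashable],
    means: Sequence[float],
    sds: Sequence[float],
    window: int | str = "auto",
    smoothing: float | str = "auto",
) -> dict:
    """DM residuals for an arbitrary (mean, SD) table.

    Same algorithm as the fluorescence noise trend; usable e.g. on log-scale
    mRNA means/SDs across environments to obtain a mean-compensated
    transcriptional-plasticity residual per gene.
    """
    res = fit_noise_trend(means, sds, keys=keys, window=window, smoothing=smoothing)
    return res.residuals_by_key()
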