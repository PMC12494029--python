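"""Temporal dynamics of single focal adhesions.

Per-FA time series of traction force, FAK activity (donor/cFRET ratio) and
integrated area (area x mean brightness) are standardized by temporal
z-scoring pooled per cell, differentiated to per-minute rates, and analysed
for oscillation structure:

* autocorrelation of the force rate exposes the mechanochemical-wave period
  (first significant positive-lag peak);
* pairwise cross-correlation between rate z-scores yields a peak
  correlation and a lead-lag time per FA, with parabolic interpolation
  through the peak for sub-frame lags (positive lag means the first series
  leads);
* rolling-window linear regression of the raw force trace classifies FAs
  as increasing / steady / decreasing force.

Ensemble summaries aggregate per-FA lags across the cell population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

#: canonical trace-table columns
TRACE_COLUMNS = ["cell_id", "fa_id", "frame", "time_s", "force_nN", "fak_ratio", "area_um2"]
METRICS = ["force_nN", "fak_ratio", "area_um2"]


def zscore_by_cell(
    df: pd.DataFrame,
    metrics: list[str] = METRICS,
    cell_col: str = "cell_id",
    per_fa: bool = False,
) -> pd.DataFrame:
    """Temporal z-score normalization pooled per cell.

    For each metric, all FA-time observations of one cell are pooled and
    standardized to mean 0 / SD 1; new columns ``z_<metric>`` are added.
    ``per_fa=True`` standardizes each FA independently instead (exposed as
    an option; pooled-per-cell is the default convention).

    Raises if any group has fewer than 2 observations or zero SD.
    """
    out = df.copy()
    keys = [cell_col, "fa_id"] if per_fa else [cell_col]
    for metric in metrics:
        g = out.groupby(keys, sort=False)[metric]
        n = g.transform("size")
        if (n < 2).any():
            raise ValueError(f"z-scoring needs >= 2 observations per group for {metric}")
        mu = g.transform("mean")
        sd = g.transform("std", ddof=0)
        if (sd == 0).any():
            bad = out.loc[sd == 0, keys[0]].iloc[0]
            raise ValueError(f"zero SD for metric {metric!r} in cell {bad!r}")
        out[f"z_{metric}"] = (out[metric] - mu) / sd
    return out


def rate_of_change(series: np.ndarray, dt_s: float) -> np.ndarray:
    """Finite-difference rate in per-minute units.

    Central differences on the interior, one-sided at the ends; O(dt^2)
    accurate on smooth signals.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("rate_of_change needs at least 3 points")
    return np.gradient(x, dt_s) * 60.0


def add_rates(df: pd.DataFrame, dt_s: float, metrics: list[str] = METRICS) -> pd.DataFrame:
    """Per-FA rate columns ``rate_<metric>`` (units/min) for a trace table."""
    out = df.sort_values(["cell_id", "fa_id", "frame"]).copy()
    for metric in metrics:
        out[f"rate_{metric}"] = out.groupby(["cell_id", "fa_id"], sort=False)[
            metric
        ].transform(lambda s: rate_of_change(s.to_numpy(), dt_s))
    return out


def rolling_slope_classify(
    force_nn: np.ndarray,
    dt_s: float,
    window_s: float = 300.0,
    slope_min_nn_per_min: float = 0.01,
    min_fraction: float = 0.5,
) -> str:
    """Classify one FA's force trace as increasing / steady / decreasing.

    An ordinary-least-squares slope is fitted in every rolling window of
    ``window_s`` (default 5 min).  The FA is labelled ``increasing`` when at
    least ``min_fraction`` of the windows have slope >= 0.01 nN/min, and
    symmetrically ``decreasing``; otherwise ``steady``.
    """
    f = np.asarray(force_nn, dtype=float)
    w = int(round(window_s / dt_s)) + 1  # window spans window_s of time
    if f.size < w:
        raise ValueError(
            f"trace ({f.size} frames) shorter than rolling window ({w} frames)"
        )
    t_min = np.arange(w) * dt_s / 60.0
    t_c = t_min - t_min.mean()
    denom = float((t_c**2).sum())
    slopes = np.array(
        [float((t_c * (f[i : i + w] - f[i : i + w].mean())).sum()) / denom
         for i in range(f.size - w + 1)]
    )
    frac_up = np.mean(slopes >= slope_min_nn_per_min)
    frac_dn = np.mean(slopes <= -slope_min_nn_per_min)
    if frac_up >= min_fraction and frac_up >= frac_dn:
        return "increasing"
    if frac_dn >= min_fraction:
        return "decreasing"
    return "steady"


def autocorr_period(
    series: np.ndarray,
    dt_s: float,
    max_lag_s: float = 600.0,
    alpha: float = 0.05,
) -> float | None:
    """Oscillation period from the autocorrelation of a (z-scored) rate.

    The period is the lag of the first local maximum at positive lag whose
    autocorrelation exceeds the white-noise significance band, with
    parabolic refinement through the peak.  The band is the per-lag normal
    bound ``z / sqrt(N)`` with ``z`` Bonferroni-corrected for the number of
    searched lags, so the family-wise false-peak rate on white noise stays
    at ``alpha``.  Returns None when no peak is significant.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    max_lag = int(round(max_lag_s / dt_s))
    if n < 2 * max_lag:
        raise ValueError("series too short for the requested max lag")
    x = x - x.mean()
    denom = float((x**2).sum())
    if denom == 0:
        return None
    acf = np.array([float((x[: n - k] * x[k:]).sum()) / denom for k in range(max_lag + 1)])
    z = norm.ppf(1.0 - alpha / (2 * max_lag))
    band = z / np.sqrt(n)
    for k in range(1, max_lag):
        if acf[k] > acf[k - 1] and acf[k] >= acf[k + 1] and acf[k] > band:
            return (k + _parabolic_offset(acf[k - 1], acf[k], acf[k + 1])) * dt_s
    return None


def _parabolic_offset(ym1: float, y0: float, yp1: float) -> float:
    """Sub-sample offset of a parabola's vertex through three points."""
    denom = ym1 - 2 * y0 + yp1
    if denom == 0:
        return 0.0
    off = 0.5 * (ym1 - yp1) / denom
    return float(np.clip(off, -0.5, 0.5))


@dataclass(frozen=True)
class LagResult:
    """Peak cross-correlation between two series.

    ``lag_s`` > 0 means the first series leads the second; ``r`` is the
    (interpolated) peak correlation; the search was bounded at
    ``max_lag_s``.
    """

    pair: str
    lag_s: float
    r: float
    max_lag_s: float

    def __post_init__(self) -> None:
        assert abs(self.lag_s) <= self.max_lag_s + 1e-9
        assert -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9


def ccf_curve(
    a: np.ndarray, b: np.ndarray, dt_s: float, max_lag_s: float = 150.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation function over integer lags.

    At each lag k in [-max_lag, +max_lag] the Pearson correlation of the
    overlapping segments is computed with both segments re-centred and
    re-scaled on the overlap, so an exact integer shift of a series
    against itself reaches r = 1 at that lag.  Returns (lags_in_frames,
    correlations).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.shape != xb.shape or xa.ndim != 1:
        raise ValueError("series must be equal-length 1D arrays")
    if xa.std() == 0 or xb.std() == 0:
        raise ValueError("cross-correlation undefined for zero-variance input")
    n = xa.size
    max_lag = int(round(max_lag_s / dt_s))
    if max_lag >= n - 2:
        raise ValueError("max lag too large for series length")
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            u, v = xa[: n - k], xb[k:]
        else:
            u, v = xa[-k:], xb[: n + k]
        su, sv = u.std(), v.std()
        cc[i] = 0.0 if su == 0 or sv == 0 else float(
            ((u - u.mean()) * (v - v.mean())).mean() / (su * sv)
        )
    return lags, cc


def crosscorr_lag(
    a: np.ndarray,
    b: np.ndarray,
    dt_s: float,
    max_lag_s: float = 150.0,
    pair: str = "a:b",
) -> LagResult:
    """Lead-lag between two equal-length series by peak cross-correlation.

    For each integer lag k in [-max_lag, +max_lag] the Pearson correlation
    of the overlapping segments is computed (both segments re-centred on
    the overlap, so an exact integer shift of a series against itself gives
    r = 1 at that lag).  The peak is refined by parabolic interpolation
    through its two neighbours for sub-frame resolution.  Positive lag
    means ``a`` leads ``b``.
    """
    lags, cc = ccf_curve(a, b, dt_s, max_lag_s)
    ipk = int(np.argmax(cc))
    if cc[ipk] >= 1.0 - 1e-12:
        # a perfect correlation is already at an exact alignment; the
        # parabola vertex would overshoot the bound
        off, r_pk = 0.0, cc[ipk]
    elif 0 < ipk < cc.size - 1:
        off = _parabolic_offset(cc[ipk - 1], cc[ipk], cc[ipk + 1])
        # peak value of the fitted parabola
        r_pk = cc[ipk] - 0.25 * (cc[ipk - 1] - cc[ipk + 1]) * off
    else:
        off, r_pk = 0.0, cc[ipk]
    lag = float(np.clip((lags[ipk] + off) * dt_s, -max_lag_s, max_lag_s))
    return LagResult(pair=pair, lag_s=lag, r=float(np.clip(r_pk, -1.0, 1.0)), max_lag_s=max_lag_s)


#: rate-column pairs for the three headline couplings
PAIR_COLUMNS = {
    "force:fak": ("rate_force_nN", "rate_fak_ratio"),
    "fak:area": ("rate_fak_ratio", "rate_area_um2"),
    "force:area": ("rate_force_nN", "rate_area_um2"),
}


def _pair_series(
    df: pd.DataFrame,
    pair: str,
    use_zscores: bool = True,
    max_gap_frames: int = 1,
):
    """Yield the (a, b) rate series of one pair for every usable FA.

    z-scored rate columns (``z_rate_*``) are used when present.  FAs whose
    series have internal gaps longer than ``max_gap_frames`` are dropped;
    shorter gaps are linearly interpolated.
    """
    col_a, col_b = PAIR_COLUMNS[pair]
    if use_zscores and f"z_{col_a}" in df.columns:
        col_a, col_b = f"z_{col_a}", f"z_{col_b}"
    for (_, _), g in df.groupby(["cell_id", "fa_id"], sort=False):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        gaps = np.diff(frames) - 1
        if len(frames) < 3 or (gaps > max_gap_frames).any():
            continue
        full = np.arange(frames[0], frames[-1] + 1)
        a = np.interp(full, frames, g[col_a].to_numpy())
        b = np.interp(full, frames, g[col_b].to_numpy())
        yield a, b


def per_fa_lags(
    df: pd.DataFrame,
    pair: str,
    dt_s: float,
    max_lag_s: float = 150.0,
    use_zscores: bool = True,
    max_gap_frames: int = 1,
) -> list[LagResult]:
    """Run :func:`crosscorr_lag` for one pair on every FA of a trace table.

    The table must carry rate columns (see :func:`add_rates`); degenerate
    (zero-variance) FAs are skipped.
    """
    results = []
    for a, b in _pair_series(df, pair, use_zscores, max_gap_frames):
        try:
            results.append(crosscorr_lag(a, b, dt_s, max_lag_s, pair=pair))
        except ValueError:
            continue
    return results


def ensemble_ccf(
    df: pd.DataFrame,
    pair: str,
    dt_s: float,
    max_lag_s: float = 150.0,
    use_zscores: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlogram averaged over FAs, on a common lag axis.

    Because every FA shares the population lead-lag, averaging the per-FA
    correlograms *before* peak extraction suppresses the noise that makes
    per-FA peak heights biased upward (a maximum over lags of a noisy
    curve), giving a nearly unbiased estimate of the correlation at
    alignment.  Returns (lags_in_frames, mean_ccf).
    """
    curves = []
    lags = None
    for a, b in _pair_series(df, pair, use_zscores):
        try:
            lags, cc = ccf_curve(a, b, dt_s, max_lag_s)
        except ValueError:
            continue
        curves.append(cc)
    if not curves:
        raise ValueError(f"no usable FA for pair {pair!r}")
    return lags, np.mean(curves, axis=0)


def ensemble_lag_summary(
    df: pd.DataFrame,
    pair: str,
    dt_s: float,
    max_lag_s: float = 150.0,
    min_n: int = 5,
) -> dict:
    """Population summary of per-FA lags for one pair.

    Lags are summarised from the per-FA peak-lag estimates (mean, median,
    SD, IQR).  The headline coupling strength ``ensemble_peak_r`` is the
    peak of the FA-averaged cross-correlogram (see :func:`ensemble_ccf`);
    the mean/median of the per-FA peak heights are also reported, but they
    carry an upward max-over-lags bias on short traces.  Raises when fewer
    than ``min_n`` FAs yield a valid lag.
    """
    lags = per_fa_lags(df, pair, dt_s, max_lag_s)
    if len(lags) < min_n:
        raise ValueError(
            f"only {len(lags)} valid lag estimates for pair {pair!r} (need >= {min_n})"
        )
    lag_vals = np.array([L.lag_s for L in lags])
    r_vals = np.array([L.r for L in lags])
    q1, q3 = np.percentile(lag_vals, [25, 75])
    lag_axis, mean_cc = ensemble_ccf(df, pair, dt_s, max_lag_s)
    ipk = int(np.argmax(mean_cc))
    if 0 < ipk < mean_cc.size - 1:
        off = _parabolic_offset(mean_cc[ipk - 1], mean_cc[ipk], mean_cc[ipk + 1])
        ens_r = mean_cc[ipk] - 0.25 * (mean_cc[ipk - 1] - mean_cc[ipk + 1]) * off
    else:
        off, ens_r = 0.0, mean_cc[ipk]
    return {
        "pair": pair,
        "n": int(lag_vals.size),
        "mean_lag_s": float(lag_vals.mean()),
        "median_lag_s": float(np.median(lag_vals)),
        "sd_lag_s": float(lag_vals.std(ddof=1)),
        "iqr_lag_s": float(q3 - q1),
        "ensemble_peak_r": float(ens_r),
        "ensemble_peak_lag_s": float((lag_axis[ipk] + off) * dt_s),
        "mean_peak_r": float(r_vals.mean()),
        "median_peak_r": float(np.median(r_vals)),
    }


def lag_significance(
    df: pd.DataFrame,
    pair: str,
    dt_s: float,
    max_lag_s: float = 150.0,
    n_surrogates: int = 99,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Surrogate test for whether a pair's lag structure is significant.

    The null distribution of the ensemble-CCF peak is estimated by
    circularly shifting each FA's second series by an independent random
    offset (destroying the cross-coupling while preserving each series'
    autocorrelation) and recomputing the ensemble peak.  The permutation
    p-value is ``(1 + #{null >= observed}) / (1 + n_surrogates)``;
    ``significant`` means p <= ``alpha`` (conservative default 0.01, so a
    coupling claim needs the observed peak to clear essentially the whole
    null distribution).
    """
    rng = np.random.default_rng(seed)
    pairs = list(_pair_series(df, pair))
    if not pairs:
        raise ValueError(f"no usable FA for pair {pair!r}")

    def ensemble_peak(series_pairs) -> float:
        curves = []
        for a, b in series_pairs:
            try:
                _, cc = ccf_curve(a, b, dt_s, max_lag_s)
            except ValueError:
                continue
            curves.append(cc)
        return float(np.max(np.mean(curves, axis=0))) if curves else 0.0

    observed = ensemble_peak(pairs)
    null_peaks = []
    for _ in range(n_surrogates):
        shifted = []
        for a, b in pairs:
            k = rng.integers(len(b) // 4, 3 * len(b) // 4)
            shifted.append((a, np.roll(b, int(k))))
        null_peaks.append(ensemble_peak(shifted))
    null_peaks = np.asarray(null_peaks)
    p_value = float((1 + (null_peaks >= observed).sum()) / (1 + n_surrogates))
    return {
        "pair": pair,
        "observed_peak_r": observed,
        "null_95_r": float(np.percentile(null_peaks, 95)),
        "p_value": p_value,
        "significant": bool(p_value <= alpha),
    }


def classify_tracks(
    df: pd.DataFrame, dt_s: float, window_s: float = 300.0,
    slope_min_nn_per_min: float = 0.01,
) -> pd.DataFrame:
    """Per-FA force-trend classification table (cell_id, fa_id, force_class,
    mean_force_nN)."""
    rows = []
    for (cell, fa), g in df.groupby(["cell_id", "fa_id"], sort=False):
        f = g.sort_values("frame")["force_nN"].to_numpy()
        rows.append(
            {
                "cell_id": cell,
                "fa_id": fa,
                "force_class": rolling_slope_classify(
                    f, dt_s, window_s, slope_min_nn_per_min
                ),
                "mean_force_nN": float(f.mean()),
            }
        )
    return pd.DataFrame(rows)


def proportion_increasing(classes: pd.DataFrame) -> float:
    """Fraction of FAs with increasing or steady-high traction force.

    ``steady-high`` = classified steady with mean force above the cell's
    median mean force; flat-at-baseline FAs therefore do not count.
    """
    if len(classes) == 0:
        return 0.0
    med = classes.groupby("cell_id")["mean_force_nN"].transform("median")
    active = (classes["force_class"] == "increasing") | (
        (classes["force_class"] == "steady") & (classes["mean_force_nN"] > med)
    )
    return float(active.mean())
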