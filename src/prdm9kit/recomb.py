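"""Crossover-interval windowing and recombination-rate landscapes.

Crossovers are observed as ancestry-switch intervals in hybrid genomes:
the stretch over which the inferred parental ancestry changes state.  The
pipeline converts a set of such intervals into a relative recombination
rate per fixed-width genomic window (default 10 kb) — the proportion of
all retained events assigned to the window, not a per-meiosis rate — and
then characterises rate as a function of distance to annotated features
(TSS, CpG islands, H3K4me3 peaks, predicted binding motifs).

Filtering follows the event-resolution logic of ancestry inference: both
events and windows within 10 kb of a contig edge are excluded, and an
event whose interval spans several windows is assigned uniformly at random
to one of the retained windows it overlaps.

All genomic coordinates are 0-based half-open (BED convention).  Events,
windows, features and peaks travel as pandas DataFrames with at least
``chrom``, ``start``, ``end`` columns.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BED_COLUMNS = ["chrom", "start", "end"]

#: Quantile interpolation used for all summaries (numpy "linear": the
#: even-count median is the midpoint of the two central order statistics).
QUANTILE_METHOD = "linear"


@dataclasses.dataclass
class SmoothedProfile:
    """Binned rate-vs-distance curve with loess smoothing and bootstrap CI."""

    grid: np.ndarray          # bin midpoints (bp)
    mean: np.ndarray          # raw mean rate per bin
    loess: np.ndarray         # Gaussian local-linear fit at grid points
    scaled: np.ndarray        # loess / loess[-1]; last point exactly 1
    ci_lo: np.ndarray         # bootstrap 2.5% of per-bin mean
    ci_hi: np.ndarray         # bootstrap 97.5%
    se: np.ndarray            # bootstrap standard error per bin
    B: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance": self.grid,
                "mean_rate": self.mean,
                "loess": self.loess,
                "scaled": self.scaled,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "se": self.se,
            }
        )


@dataclasses.dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    controls: list[str]


def _check_bed(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in BED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} lacks columns {missing}")
    return df


def make_windows(
    contig_sizes: Mapping[str, int],
    width: int = 10_000,
    edge_buffer: int = 10_000,
) -> pd.DataFrame:
    """Tile each contig from coordinate 0 in fixed steps of ``width``.

    Trailing partial windows are dropped, as are windows lying within
    ``edge_buffer`` of either contig end (start < buffer or end > size -
    buffer), matching the edge exclusion applied to events.
    """
    rows = []
    for chrom, size in contig_sizes.items():
        n = int(size) // width
        for i in range(n):
            start, end = i * width, (i + 1) * width
            if start < edge_buffer or end > size - edge_buffer:
                continue
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def filter_events(
    events: pd.DataFrame,
    contig_sizes: Mapping[str, int],
    edge_buffer: int = 10_000,
) -> pd.DataFrame:
    """Drop events whose interval lies within ``edge_buffer`` of a contig edge.

    Breakpoints near contig edges are suspect (assembly and mapping
    artefacts inflate apparent switches there), so only events entirely
    inside ``[buffer, size - buffer]`` are retained.
    """
    events = _check_bed(events, "events")
    unknown = set(events["chrom"]) - set(contig_sizes)
    if unknown:
        raise ValueError(f"events on unknown contig(s): {sorted(unknown)}")
    sizes = events["chrom"].map(contig_sizes)
    keep = (events["start"] >= edge_buffer) & (events["end"] <= sizes - edge_buffer)
    return events[keep].reset_index(drop=True)


def resolution_summary(
    events: pd.DataFrame,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> dict:
    """Summarise event-interval lengths (the resolution of each crossover)."""
    events = _check_bed(events, "events")
    if len(events) == 0:
        raise ValueError("no events")
    lengths = (events["end"] - events["start"]).to_numpy(dtype=float)
    table = {
        q: float(np.quantile(lengths, q, method=QUANTILE_METHOD))
        for q in quantiles
    }
    return {
        "median": float(np.quantile(lengths, 0.5, method=QUANTILE_METHOD)),
        "q75": float(np.quantile(lengths, 0.75, method=QUANTILE_METHOD)),
        "quantiles": table,
        "n": int(len(lengths)),
        "quantile_method": QUANTILE_METHOD,
    }


def assign_events_to_windows(
    events: pd.DataFrame,
    windows: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Assign each event to exactly one retained window it overlaps.

    Events spanning several windows go to one of them uniformly at random;
    events overlapping no retained window are dropped (their count is
    returned).  Rates are counts normalised by the total number of
    assigned events, so retained-window rates sum to 1.
    """
    rng = np.random.default_rng(rng)
    events = _check_bed(events, "events")
    windows = _check_bed(windows, "windows").reset_index(drop=True)

    counts = np.zeros(len(windows), dtype=int)
    n_dropped = 0
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy())
        idx = grp.index.to_numpy()[order]
        starts = grp["start"].to_numpy()[order]
        ends = grp["end"].to_numpy()[order]
        by_chrom[chrom] = (starts, ends, idx)

    for chrom, e_start, e_end in events[BED_COLUMNS].itertuples(index=False):
        if chrom not in by_chrom:
            n_dropped += 1
            continue
        starts, ends, idx = by_chrom[chrom]
        lo = np.searchsorted(ends, e_start, side="right")
        hi = np.searchsorted(starts, e_end, side="left")
        if hi <= lo:
            n_dropped += 1
            continue
        pick = idx[lo + rng.integers(hi - lo)]
        counts[pick] += 1

    out = windows.copy()
    out["count"] = counts
    total = counts.sum()
    out["rate"] = counts / total if total > 0 else 0.0
    return out, n_dropped


def _nearest_distance(
    points_or_intervals: np.ndarray,
    f_starts: np.ndarray,
    f_ends: np.ndarray,
    query_ends: np.ndarray | None = None,
) -> np.ndarray:
    """Distance from query intervals (or points) to nearest feature interval.

    Features must be sorted by start.  Overlap gives 0.  Uses a running
    maximum of feature ends so overlapping/nested features are handled.
    """
    q_start = points_or_intervals
    q_end = query_ends if query_ends is not None else points_or_intervals
    cummax_end = np.maximum.accumulate(f_ends)
    # nearest feature to the right of the query end
    j = np.searchsorted(f_starts, q_end, side="left")
    right = np.where(j < len(f_starts), f_starts[np.minimum(j, len(f_starts) - 1)] - q_end, np.inf)
    right = np.where(j < len(f_starts), np.maximum(right, 0.0), np.inf)
    # nearest feature starting at or before the query end: gap on the left
    k = np.searchsorted(f_starts, q_end, side="right") - 1
    has_left = k >= 0
    left_end = np.where(has_left, cummax_end[np.maximum(k, 0)], -np.inf)
    left = np.where(has_left, np.maximum(q_start - left_end, 0.0), np.inf)
    # a feature with start <= q_end and cummax end >= q_start overlaps: left = 0
    return np.minimum(left, right)


def window_feature_distance(
    windows: pd.DataFrame,
    features: pd.DataFrame,
    mode: str = "interval",
) -> np.ndarray:
    """Distance from each window to its nearest feature.

    ``interval`` mode measures the minimum gap between the window interval
    and the nearest feature interval (0 when they overlap) — the
    closest-feature convention.  ``midpoint`` mode measures from the
    window's midpoint instead, as used when comparing landscapes across
    species.  Windows on chromosomes with no features get NaN.
    """
    if mode not in ("interval", "midpoint"):
        raise ValueError(f"unknown mode {mode!r}")
    windows = _check_bed(windows, "windows")
    features = _check_bed(features, "features")
    out = np.full(len(windows), np.nan)
    feats = {
        chrom: grp.sort_values("start")
        for chrom, grp in features.groupby("chrom", sort=False)
    }
    w_start = windows["start"].to_numpy(dtype=float)
    w_end = windows["end"].to_numpy(dtype=float)
    for chrom in windows["chrom"].unique():
        mask = (windows["chrom"] == chrom).to_numpy()
        if chrom not in feats:
            continue
        fs = feats[chrom]["start"].to_numpy(dtype=float)
        fe = feats[chrom]["end"].to_numpy(dtype=float)
        if mode == "interval":
            out[mask] = _nearest_distance(w_start[mask], fs, fe, w_end[mask])
        else:
            mid = (w_start[mask] + w_end[mask]) / 2.0
            out[mask] = _nearest_distance(mid, fs, fe)
    return out


def rate_by_distance(
    distance: np.ndarray,
    rate: np.ndarray,
    bin_width: int = 10_000,
    max_distance: int = 100_000,
) -> pd.DataFrame:
    """Mean rate per distance bin [i*w, (i+1)*w), up to ``max_distance``.

    Windows farther than ``max_distance`` from any feature (and NaN
    distances) are dropped, keeping the profile anchored to windows near a
    representative element.
    """
    distance = np.asarray(distance, dtype=float)
    rate = np.asarray(rate, dtype=float)
    ok = np.isfinite(distance)
    if not ok.any():
        raise ValueError("all window distances are NA")
    distance, rate = distance[ok], rate[ok]
    bins = (distance // bin_width).astype(int)
    n_bins = max_distance // bin_width
    keep = bins < n_bins
    bins, rate = bins[keep], rate[keep]
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=rate, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width,
            "bin_mid": np.arange(n_bins) * bin_width + bin_width / 2,
            "mean_rate": means,
            "n_windows": counts,
        }
    )


def gaussian_loess(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = 0.3,
) -> np.ndarray:
    """Local linear regression with a Gaussian kernel.

    The bandwidth is ``span`` times the range of ``x``.  Weighted linear
    least squares is solved at each grid point, so an exactly linear
    relationship is reproduced exactly whatever the bandwidth.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 5:
        raise ValueError("need at least 5 points for loess")
    xrange = x.max() - x.min()
    if xrange == 0:
        raise ValueError("degenerate input: all distances equal")
    h = span * xrange
    out = np.empty(len(grid))
    for i, g in enumerate(np.asarray(grid, dtype=float)):
        w = np.exp(-0.5 * ((x - g) / h) ** 2)
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        slope = (w * (x - xm) * (y - ym)).sum() / sxx if sxx > 0 else 0.0
        out[i] = ym + slope * (g - xm)
    return out


def loess_scale(
    distance: np.ndarray,
    rate: np.ndarray,
    span: float = 0.3,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth rate vs distance and scale so the last grid point equals 1.

    Returns ``(grid, loess, scaled)``.  Scaling by the value at the last
    (most distant) point expresses the curve as a fold change relative to
    the background rate far from the feature.
    """
    distance = np.asarray(distance, dtype=float)
    if grid is None:
        ok = np.isfinite(distance)
        grid = np.linspace(distance[ok].min(), distance[ok].max(), 50)
    grid = np.asarray(grid, dtype=float)
    fit = gaussian_loess(distance, rate, grid, span=span)
    last = fit[-1]
    if last == 0:
        raise ValueError("loess value at last grid point is 0; cannot scale")
    return grid, fit, fit / last


def bootstrap_binned_means(
    distance: np.ndarray,
    rate: np.ndarray,
    bin_width: int = 10_000,
    max_distance: int = 100_000,
    B: int = 500,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Bootstrap windows with replacement; percentile CI of per-bin means.

    Every resample redraws the full window set and recomputes each bin's
    mean rate; the 2.5/97.5 percentiles and the standard deviation across
    resamples give the CI and SE per bin.
    """
    rng = np.random.default_rng(rng)
    distance = np.asarray(distance, dtype=float)
    rate = np.asarray(rate, dtype=float)
    ok = np.isfinite(distance) & (distance < max_distance)
    distance, rate = distance[ok], rate[ok]
    n = len(distance)
    if n == 0:
        raise ValueError("no windows within max_distance")
    bins = (distance // bin_width).astype(int)
    n_bins = max_distance // bin_width
    boot = np.full((B, n_bins), np.nan)
    for b in range(B):
        idx = rng.integers(0, n, n)
        rb = rate[idx]
        bb = bins[idx]
        counts = np.bincount(bb, minlength=n_bins)
        sums = np.bincount(bb, weights=rb, minlength=n_bins)
        boot[b] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanquantile(boot, 0.025, axis=0)
        hi = np.nanquantile(boot, 0.975, axis=0)
        se = np.nanstd(boot, axis=0, ddof=1)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width,
            "ci_lo": lo,
            "ci_hi": hi,
            "se": se,
        }
    )


def smoothed_profile(
    distance: np.ndarray,
    rate: np.ndarray,
    bin_width: int = 10_000,
    max_distance: int = 100_000,
    span: float = 0.3,
    B: int = 500,
    rng: np.random.Generator | int | None = None,
) -> SmoothedProfile:
    """Full rate-vs-distance profile: binned means, loess fit, bootstrap CI."""
    binned = rate_by_distance(distance, rate, bin_width, max_distance)
    ok = np.isfinite(distance) & (np.asarray(distance) < max_distance)
    grid = binned["bin_mid"].to_numpy()
    _, fit, scaled = loess_scale(
        np.asarray(distance)[ok], np.asarray(rate)[ok], span=span, grid=grid
    )
    ci = bootstrap_binned_means(distance, rate, bin_width, max_distance, B, rng)
    return SmoothedProfile(
        grid=grid,
        mean=binned["mean_rate"].to_numpy(),
        loess=fit,
        scaled=scaled,
        ci_lo=ci["ci_lo"].to_numpy(),
        ci_hi=ci["ci_hi"].to_numpy(),
        se=ci["se"].to_numpy(),
        B=B,
    )


def correlate(
    rate: np.ndarray,
    distance: np.ndarray,
    controls: Mapping[str, np.ndarray] | None = None,
) -> CorrelationResult:
    """Spearman correlation of rate with distance, optionally partial.

    Without controls this is plain Spearman rho with its two-sided p.
    With controls, every variable is rank-transformed, the control ranks
    are regressed out of both target vectors by least squares, and the
    Pearson correlation of the residuals is reported — the standard
    construction of a partial Spearman correlation.  Used e.g. to ask how
    much of the rate–peak-distance association survives after accounting
    for distance to TSSs and CpG islands.
    """
    rate = np.asarray(rate, dtype=float)
    distance = np.asarray(distance, dtype=float)
    controls = dict(controls or {})
    ok = np.isfinite(rate) & np.isfinite(distance)
    for v in controls.values():
        ok &= np.isfinite(np.asarray(v, dtype=float))
    rate, distance = rate[ok], distance[ok]
    ctrl = {k: np.asarray(v, dtype=float)[ok] for k, v in controls.items()}
    n = len(rate)
    if n < 4:
        raise ValueError("need at least 4 complete observations")
    if np.ptp(rate) == 0 or np.ptp(distance) == 0:
        warnings.warn("zero-variance input; correlation undefined")
        return CorrelationResult(np.nan, np.nan, n, sorted(ctrl))

    if not ctrl:
        rho, p = stats.spearmanr(rate, distance)
        return CorrelationResult(float(rho), float(p), n, [])

    r_rate = stats.rankdata(rate)
    r_dist = stats.rankdata(distance)
    design = np.column_stack(
        [np.ones(n)] + [stats.rankdata(v) for v in ctrl.values()]
    )
    res_rate = r_rate - design @ np.linalg.lstsq(design, r_rate, rcond=None)[0]
    res_dist = r_dist - design @ np.linalg.lstsq(design, r_dist, rcond=None)[0]
    rho, p = stats.pearsonr(res_rate, res_dist)
    return CorrelationResult(float(rho), float(p), n, sorted(ctrl))


def peak_overlap_bp(windows: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Total base pairs of each window covered by peaks (clipped to window).

    Peaks are merged per chromosome first, so overlapping peaks are not
    double-counted.  The result is the standard correlate() input for the
    bp-overlap-vs-event-count association.
    """
    windows = _check_bed(windows, "windows")
    peaks = _check_bed(peaks, "peaks")
    out = np.zeros(len(windows), dtype=float)
    merged: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in peaks.groupby("chrom", sort=False):
        ivs = grp[["start", "end"]].sort_values("start").to_numpy(dtype=float)
        ms, me = [], []
        for s, e in ivs:
            if me and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        ms_a, me_a = np.array(ms), np.array(me)
        cum = np.concatenate([[0.0], np.cumsum(me_a - ms_a)])
        merged[chrom] = (ms_a, me_a, cum)

    def coverage_to(x: np.ndarray, ms, me, cum) -> np.ndarray:
        """Covered bp in [0, x)."""
        j = np.searchsorted(ms, x, side="right") - 1
        jc = np.maximum(j, 0)
        return np.where(
            j >= 0,
            cum[jc] + np.clip(x - ms[jc], 0.0, me[jc] - ms[jc]),
            0.0,
        )

    for chrom in windows["chrom"].unique():
        mask = (windows["chrom"] == chrom).to_numpy()
        if chrom not in merged:
            continue
        ms, me, cum = merged[chrom]
        ws = windows["start"].to_numpy(dtype=float)[mask]
        we = windows["end"].to_numpy(dtype=float)[mask]
        out[mask] = coverage_to(we, ms, me, cum) - coverage_to(ws, ms, me, cum)
    return out
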