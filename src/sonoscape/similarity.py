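"""Soundscape similarity between land-use classes via 1-D optimal transport.

At every retained time-frequency intersection (a 10-min bin crossed with a
1-kHz band), each land-use class contributes an empirical distribution of
ΣPMN values (one value per site and minute, averaged across days).  The
order-1 Wasserstein (earth-mover's) distance x between two classes'
distributions is scaled to a similarity y = e^(−kx) with k = 0.00001, so 1
means complete overlap and values near 0 mean strong dissimilarity.  Skew
ratios — similarity-to-reference-forest over similarity-to-pasture —
summarize whether a treatment class sounds more like intact forest than
like pasture.  Differences across time bins are tested with a Friedman
repeated-measures test and Wilcoxon signed-rank post hocs under Bonferroni
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_K = 0.00001
FOCAL_RANGE = (1000.0, 9000.0)
DAWN_BINS = range(30, 39)  # 10-min bins starting 05:00 .. 06:20 (< 06:30)


@dataclass(frozen=True)
class Intersection:
    """One retained 10-min bin crossed with one 1-kHz frequency band."""

    time_bin: int
    band_lo_hz: float
    band_hi_hz: float


def one_khz_bands(freq_range=FOCAL_RANGE) -> list[tuple[float, float]]:
    """The 1-kHz analysis bands tiling ``freq_range`` ([1, 9) kHz -> 8 bands)."""
    lo, hi = freq_range
    edges = np.arange(lo, hi + 1, 1000.0)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def build_intersections(retained_bins, freq_range=FOCAL_RANGE) -> list[Intersection]:
    """Cartesian product of retained 10-min bins and 1-kHz bands.

    110 retained bins over the 1-9 kHz focal range give the 880
    time-frequency intersections at which class comparisons are made.
    """
    retained_bins = sorted(set(int(b) for b in retained_bins))
    if not retained_bins:
        raise ValueError("retained bin set is empty")
    return [Intersection(b, lo, hi)
            for b in retained_bins for lo, hi in one_khz_bands(freq_range)]


def class_distribution(records: pd.DataFrame, intersection: Intersection,
                       land_use: str, value_col: str | None = None) -> np.ndarray:
    """Pooled ΣPMN sample of one class at one intersection.

    ``records`` holds cross-day mean ΣPMN per (site, minute-of-day) with one
    column per 1-kHz band (``band_1000`` etc.) and a land_use column.  The
    sample pools the minutes of the bin across the class's sites — one value
    per site-minute, per the distribution-granularity convention.
    """
    if value_col is None:
        value_col = f"band_{int(intersection.band_lo_hz)}"
    minutes = range(intersection.time_bin * 10, intersection.time_bin * 10 + 10)
    sel = records.loc[(records["land_use"] == land_use)
                      & records["minute_of_day"].isin(minutes), value_col]
    return sel.to_numpy(float)


def wasserstein_1d(a: np.ndarray, b: np.ndarray) -> float:
    """Order-1 Wasserstein distance between two empirical 1-D samples.

    Quantile-function-integral formulation (scipy), which handles unequal
    sample sizes exactly and deterministically; symmetric, zero iff the
    empirical distributions coincide, and shifts by |c| under a constant
    translation of one sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample passed to wasserstein_1d")
    return float(stats.wasserstein_distance(a, b))


def similarity(x: float, k: float = DEFAULT_K) -> float:
    """Inverse-exponential similarity y = e^(−kx) of a transport distance."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("distance must be non-negative")
    return float(np.exp(-k * x)) if np.isscalar(x) else np.exp(-k * np.asarray(x))


def distance_table(records: pd.DataFrame, intersections,
                   class_pairs=None, k: float = DEFAULT_K) -> pd.DataFrame:
    """Wasserstein distance and similarity for class pairs at intersections.

    One row per (intersection, unordered class pair); intersections where a
    class has no data are skipped and logged.
    """
    classes = sorted(records["land_use"].unique())
    if class_pairs is None:
        class_pairs = list(combinations(classes, 2))
    rows, n_skipped = [], 0
    cache: dict[tuple, np.ndarray] = {}
    for inter in intersections:
        for cls_a, cls_b in class_pairs:
            key_a, key_b = (inter, cls_a), (inter, cls_b)
            for key, cls in ((key_a, cls_a), (key_b, cls_b)):
                if key not in cache:
                    cache[key] = class_distribution(records, inter, cls)
            a, b = cache[key_a], cache[key_b]
            if a.size == 0 or b.size == 0:
                n_skipped += 1
                continue
            x = wasserstein_1d(a, b)
            rows.append({"time_bin": inter.time_bin,
                         "band_lo_hz": inter.band_lo_hz,
                         "band_hi_hz": inter.band_hi_hz,
                         "class_a": cls_a, "class_b": cls_b,
                         "wasserstein": x, "similarity": similarity(x, k),
                         "n_a": a.size, "n_b": b.size})
    if n_skipped:
        logger.info("distance_table: skipped %d empty class/intersection cells",
                    n_skipped)
    return pd.DataFrame(rows)


def pair_similarity(distances: pd.DataFrame, cls_x: str, cls_y: str) -> pd.DataFrame:
    lo, hi = sorted([cls_x, cls_y])
    m = (((distances["class_a"] == lo) & (distances["class_b"] == hi))
         | ((distances["class_a"] == hi) & (distances["class_b"] == lo)))
    return distances.loc[m]


def skew_ratios(distances: pd.DataFrame,
                treatment_classes=("natural_regeneration", "plantation"),
                reference: str = "reference_forest",
                baseline: str = "pasture",
                log_ratio: bool = False):
    """Skew toward reference forest for each treatment class.

    Per intersection, skew = sim(treatment, reference forest) /
    sim(treatment, pasture): 1 means equidistant, > 1 a soundscape closer to
    intact forest.  Returns (per-intersection table, per-time-bin means,
    grand means per class).  ``log_ratio`` averages log-skews instead of raw
    ratios (and reports their exponential).
    """
    rows = []
    for cls in treatment_classes:
        to_ref = pair_similarity(distances, cls, reference)
        to_base = pair_similarity(distances, cls, baseline)
        keys = ["time_bin", "band_lo_hz"]
        merged = to_ref.merge(to_base, on=keys, suffixes=("_ref", "_base"))
        if len(merged) == 0:
            raise ValueError(f"no paired similarities for class {cls!r}")
        skew = merged["similarity_ref"] / merged["similarity_base"]
        rows.append(pd.DataFrame({
            "time_bin": merged["time_bin"], "band_lo_hz": merged["band_lo_hz"],
            "treatment_class": cls, "skew": skew}))
    per_intersection = pd.concat(rows, ignore_index=True)

    def _mean(s):
        return float(np.exp(np.mean(np.log(s)))) if log_ratio else float(np.mean(s))

    per_bin = (per_intersection.groupby(["treatment_class", "time_bin"])["skew"]
               .apply(_mean).reset_index())
    grand = {cls: _mean(grp["skew"])
             for cls, grp in per_intersection.groupby("treatment_class")}
    return per_intersection, per_bin, grand


def friedman_across_bins(table: pd.DataFrame) -> tuple[float, float]:
    """Friedman repeated-measures test: blocks = time bins, columns = series.

    ``table`` is a complete bins x treatments matrix (e.g., the per-bin mean
    distances of each class comparison); missing cells raise an error naming
    the offending bin.  If every treatment is identical in every block the
    statistic is 0 by convention (scipy degenerates there).
    """
    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)][0]
        raise ValueError(f"incomplete design: missing value in time bin {bad}")
    if table.shape[1] < 3:
        raise ValueError("Friedman test needs >= 3 treatment series")
    arr = table.to_numpy(float)
    if np.all(arr == arr[:, [0]]):
        warnings.warn("all treatments identical in every block; statistic = 0")
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*[arr[:, j] for j in range(arr.shape[1])])
    return float(stat), float(p)


def pairwise_wilcoxon(table: pd.DataFrame, pairs=None) -> pd.DataFrame:
    """Wilcoxon signed-rank post hoc over column pairs, Bonferroni adjusted.

    Adjusted p = min(1, raw p × number of pairs).  A pair whose paired
    differences are all zero gets p = 1 with a warning.
    """
    cols = list(table.columns)
    if pairs is None:
        pairs = list(combinations(cols, 2))
    rows = []
    for a, b in pairs:
        d = table[a].to_numpy(float) - table[b].to_numpy(float)
        if np.all(d == 0):
            warnings.warn(f"all paired differences zero for ({a}, {b}); p = 1")
            stat, p_raw = 0.0, 1.0
        else:
            stat, p_raw = stats.wilcoxon(table[a], table[b])
        rows.append({"a": a, "b": b, "statistic": float(stat),
                     "p_raw": float(p_raw),
                     "p_adjusted": min(1.0, float(p_raw) * len(pairs))})
    return pd.DataFrame(rows)


def similarity_summary(distances: pd.DataFrame, mode: str = "focal") -> pd.DataFrame:
    """Mean similarity per class pair across intersections.

    ``mode='focal'`` averages the table as given (retained bins, focal
    bands); ``'dawn_only'`` restricts to the 05:00-06:30 bins;
    ``'full_spectrum'`` uses every bin and band present at or above 1 kHz.
    """
    if mode == "focal":
        df = distances
    elif mode == "dawn_only":
        df = distances.loc[distances["time_bin"].isin(DAWN_BINS)]
    elif mode == "full_spectrum":
        df = distances.loc[distances["band_lo_hz"] >= 1000.0]
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    out = (df.groupby(["class_a", "class_b"], as_index=False)
             .agg(mean_similarity=("similarity", "mean"),
                  mean_wasserstein=("wasserstein", "mean"),
                  n_intersections=("similarity", "size")))
    out.insert(0, "mode", mode)
    return out
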