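"""Sonotype annotation tables, taxon frequency ranges and partition tests.

Annotations are manual selections of individual sound elements (sonotypes)
made in Raven selection tables: one row per element with its minimum and
maximum frequency and a taxon label (humans/domestic animals, mammals,
amphibians, birds, insects, or unknown).  From them we estimate the
frequency range occupied by each taxon — the central 90% of call extents —
the pooled biophonic range, and whether taxa partition the frequency axis
(one-way ANOVA on a mean frequency characteristic with Bonferroni-corrected
pairwise post hoc tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BIOPHONY_TAXA = ("mammal", "amphibian", "bird", "insect")
KNOWN_TAXA = ("human_domestic", "mammal", "amphibian", "bird", "insect")

REQUIRED_COLUMNS = ("Low Freq (Hz)", "High Freq (Hz)", "taxon")


class SelectionTableError(ValueError):
    """Raised when a selection table is malformed."""


@dataclass
class TaxonRange:
    """Central-``coverage`` frequency range occupied by one taxon's calls."""

    taxon: str
    lo_hz: float
    hi_hz: float
    coverage: float
    n_annotations: int


def read_selection_table(path) -> pd.DataFrame:
    """Parse a Raven selection table (TSV) into an annotation frame.

    Returns columns f_min_hz, f_max_hz, taxon, is_unknown plus any of
    site_id / minute_of_day / diel_class / Begin Time (s) / End Time (s)
    present in the file.  Rows with inverted or non-finite frequencies are
    rejected with a logged count; ``unknown`` rows are retained but flagged.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SelectionTableError(f"{path}: missing columns {missing}")
    out = df.rename(columns={"Low Freq (Hz)": "f_min_hz",
                             "High Freq (Hz)": "f_max_hz"})
    ok = (np.isfinite(out["f_min_hz"]) & np.isfinite(out["f_max_hz"])
          & (out["f_min_hz"] >= 0) & (out["f_min_hz"] < out["f_max_hz"]))
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: rejected %d annotation rows with invalid frequencies",
                       path, n_bad)
    out = out.loc[ok].reset_index(drop=True)
    out["taxon"] = out["taxon"].astype(str)
    out["is_unknown"] = ~out["taxon"].isin(KNOWN_TAXA)
    return out


def write_selection_table(annotations: pd.DataFrame, path) -> None:
    """Write annotations back out as a Raven selection table (TSV)."""
    df = annotations.copy()
    df = df.rename(columns={"f_min_hz": "Low Freq (Hz)",
                            "f_max_hz": "High Freq (Hz)"})
    df = df.drop(columns=[c for c in ("is_unknown",) if c in df.columns])
    if "Selection" not in df.columns:
        df.insert(0, "Selection", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False)


def _range_quantiles(f_min, f_max, coverage):
    alpha = (1.0 - coverage) / 2.0
    lo = float(np.quantile(np.asarray(f_min, float), alpha))
    hi = float(np.quantile(np.asarray(f_max, float), 1.0 - alpha))
    return lo, hi


def taxon_frequency_ranges(annotations: pd.DataFrame,
                           coverage: float = 0.90,
                           method: str = "extents") -> pd.DataFrame:
    """Per-taxon frequency range bracketing ``coverage`` of call extents.

    ``method='extents'`` (default) takes the (1-coverage)/2 quantile of the
    minimum frequencies and the matching upper quantile of the maximum
    frequencies, so the central 90% of call extents fall inside the range.
    ``method='midpoint'`` applies the same quantile rule to call midpoints.
    Quantiles interpolate linearly between order statistics.  ``unknown``
    rows are excluded; empty taxa are omitted.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    known = annotations.loc[~annotations["is_unknown"]]
    rows = []
    for taxon, grp in known.groupby("taxon", sort=False):
        if len(grp) == 0:
            continue
        if method == "extents":
            lo, hi = _range_quantiles(grp["f_min_hz"], grp["f_max_hz"], coverage)
        elif method == "midpoint":
            mid = (grp["f_min_hz"] + grp["f_max_hz"]) / 2.0
            lo, hi = _range_quantiles(mid, mid, coverage)
        else:
            raise ValueError(f"unknown method: {method!r}")
        rows.append({"taxon": taxon, "lo_hz": lo, "hi_hz": hi,
                     "coverage": coverage, "n_annotations": len(grp)})
    return pd.DataFrame(rows)


def biophonic_range(annotations: pd.DataFrame,
                    coverage: float = 0.90) -> tuple[float, float]:
    """Pooled central-``coverage`` range of all biophony (non-human taxa)."""
    bio = annotations.loc[annotations["taxon"].isin(BIOPHONY_TAXA)]
    if len(bio) == 0:
        raise ValueError("no biophonic annotations (mammal/amphibian/bird/insect)")
    return _range_quantiles(bio["f_min_hz"], bio["f_max_hz"], coverage)


def frequency_partition_test(annotations: pd.DataFrame,
                             characteristic: str = "midpoint",
                             taxa=BIOPHONY_TAXA) -> dict:
    """One-way ANOVA + Bonferroni pairwise t-tests for frequency partitioning.

    Tests whether the chosen per-call frequency characteristic (``'min'``,
    ``'max'`` or ``'midpoint'``) differs between taxa — the Acoustic Niche
    Hypothesis expectation.  Returns a dict with the F statistic, its p
    value, group sizes, and a pairwise table of Bonferroni-adjusted p values.
    """
    char_fn = {"min": lambda g: g["f_min_hz"],
               "max": lambda g: g["f_max_hz"],
               "midpoint": lambda g: (g["f_min_hz"] + g["f_max_hz"]) / 2.0}
    if characteristic not in char_fn:
        raise ValueError(f"unknown characteristic: {characteristic!r}")
    groups, labels = [], []
    for taxon in taxa:
        vals = char_fn[characteristic](
            annotations.loc[annotations["taxon"] == taxon]).to_numpy(float)
        if vals.size >= 2:
            groups.append(vals)
            labels.append(taxon)
    if len(groups) < 2:
        raise ValueError("need at least two taxa with >= 2 annotations")
    f_stat, p = stats.f_oneway(*groups)
    pairs = []
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t_stat, p_raw = stats.ttest_ind(groups[i], groups[j])
            pairs.append({"taxon_a": labels[i], "taxon_b": labels[j],
                          "t": float(t_stat), "p_raw": float(p_raw),
                          "p_adjusted": min(1.0, float(p_raw) * n_pairs)})
    return {"characteristic": characteristic, "f_statistic": float(f_stat),
            "p_value": float(p), "groups": dict(zip(labels, map(len, groups))),
            "pairwise": pd.DataFrame(pairs)}


def occupancy_density(annotations: pd.DataFrame,
                      grid_hz: np.ndarray | None = None,
                      taxa=BIOPHONY_TAXA) -> pd.DataFrame:
    """Per-taxon band-occupancy density over a frequency grid.

    Each annotation contributes uniform mass over [f_min, f_max]; densities
    are normalized to integrate to one per taxon.  Intended for plots only,
    not statistics.
    """
    if grid_hz is None:
        grid_hz = np.linspace(0.0, 24000.0, 481)
    grid_hz = np.asarray(grid_hz, float)
    out = {"freq_hz": grid_hz}
    for taxon in taxa:
        grp = annotations.loc[annotations["taxon"] == taxon]
        dens = np.zeros_like(grid_hz)
        for lo, hi in zip(grp["f_min_hz"], grp["f_max_hz"]):
            dens += ((grid_hz >= lo) & (grid_hz <= hi)) / (hi - lo)
        if len(grp):
            area = np.trapezoid(dens, grid_hz)
            if area > 0:
                dens = dens / area
        out[taxon] = dens
    return pd.DataFrame(out)
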