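"""End-to-end orchestration: synth → indices → selection → similarity.

The pipeline is declarative: a :class:`PipelineConfig` fixes every stage
parameter (FFT size 512 at 48 kHz, similarity constant k = 0.00001, 90%
range coverage, strict-majority bin retention, the 1-9 kHz focal range and
the standard exclusion rules), and the run writes CSV/JSON outputs plus a
manifest with the config hash, seed, library versions and per-stage row
counts, so outputs from different configurations are never silently mixed.
Every table starts with a ``# config_hash=`` comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotations as ann
from . import index as idx
from . import selection as sel
from . import similarity as sim
from . import synth

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults reproduce the standard settings."""

    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    seed: int = 0
    # input paths (used when the synth stage is disabled)
    audio_dir: str | None = None
    metadata_csv: str | None = None
    annotation_tsv: str | None = None
    supplied_bins: list[int] | None = None
    # stage toggles
    run_synth: bool = True
    run_select: bool = True
    fast_mode: bool = True
    # stage parameters
    sample_rate: int = idx.SAMPLE_RATE
    fft_size: int = idx.FFT_SIZE
    smooth: bool = True
    clip_negative: bool = True
    edge_minutes: int = idx.DEFAULT_EDGE_MINUTES
    excluded_minutes: tuple = idx.DEFAULT_EXCLUDED_MINUTES
    focal_range: tuple = sim.FOCAL_RANGE
    retention_threshold: float = 0.5
    coverage: float = 0.90
    k: float = sim.DEFAULT_K
    n_annotations_per_taxon: int = 400

    def __post_init__(self):
        if isinstance(self.synth, dict):
            self.synth = synth.SynthConfig(**self.synth)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("excluded_minutes", "focal_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "synth" in raw and isinstance(raw["synth"], dict):
            for k in ("effect_sizes", "taxon_bands"):
                if k in raw["synth"] and raw["synth"][k] is not None:
                    raw["synth"][k] = {kk: tuple(v) if isinstance(v, list) else v
                                       for kk, v in raw["synth"][k].items()}
        return cls(**raw)


def write_table(df: pd.DataFrame, path, config_hash: str) -> None:
    """CSV with a leading config-hash comment, so provenance travels along."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def validate_inputs(config: PipelineConfig) -> dict:
    """Pre-flight checks; returns {'fatal': [...], 'warnings': [...]}."""
    fatal, warn = [], []
    required_meta = ["site_id", "land_use", "annual_precipitation", "evi",
                     "human_modification", "elevation", "canopy_height",
                     "hardware"]
    if not config.run_synth:
        if config.metadata_csv is None:
            fatal.append("metadata_csv required when the synth stage is disabled")
        else:
            meta = read_table(config.metadata_csv)
            missing = [c for c in required_meta if c not in meta.columns]
            if missing:
                fatal.append(f"metadata missing columns: {missing}")
        if config.annotation_tsv is not None:
            try:
                ann.read_selection_table(config.annotation_tsv)
            except ann.SelectionTableError as exc:
                fatal.append(str(exc))
    if config.audio_dir is not None and not config.fast_mode:
        wavs = sorted(Path(config.audio_dir).rglob("*.wav"))
        if not wavs:
            fatal.append(f"no WAV files under {config.audio_dir}")
        for p in wavs[:5]:
            try:
                _, rate = idx.read_wav(p)
            except Exception as exc:  # unreadable file is fatal
                fatal.append(f"{p}: {exc}")
                continue
            if rate != config.sample_rate:
                fatal.append(f"{p}: sample rate {rate} != {config.sample_rate}")
    if config.sample_rate != idx.SAMPLE_RATE:
        warn.append("non-standard sample rate; band geometry will differ")
    return {"fatal": fatal, "warnings": warn}


# ---------------------------------------------------------------------------
# stages

def stage_index_fast(sites: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Fast mode: synthesize dB spectrograms per site-day, reduce to indices.

    Per (site, day, minute) the 256-band ΣPMN vector is reduced on the fly
    to the stored aggregates: full-spectrum sum, the 1-kHz band sums and the
    mean BGNsp over the focal range.  (Whole-day spectrogram stacks are
    never materialized together.)
    """
    scfg = config.synth
    khz_bands = [(lo, lo + 1000.0) for lo in np.arange(0.0, 24000.0, 1000.0)]
    khz_idx = [idx.bands_in_range(lo, hi) for lo, hi in khz_bands]
    focal_idx = idx.bands_in_range(*config.focal_range)
    # fast-mode frames subsample the minute; rescale the frame sums to the
    # dB·frame units of a full 5625-frame minute so downstream quantities
    # (and the similarity constant k) live on the same scale in both modes
    frame_scale = idx.FRAMES_PER_MINUTE / scfg.fast_frames
    rows = []
    for _, site in sites.iterrows():
        for day in range(scfg.n_days):
            spec = synth.synth_spectrograms(site, day, scfg)
            sigma, _pmn, bgn = idx.sigma_pmn_batch(
                spec, smooth=config.smooth, clip_negative=config.clip_negative)
            sigma = sigma * np.float32(frame_scale)
            rec = {"site_id": site["site_id"], "day": day,
                   "minute_of_day": np.arange(sigma.shape[0]),
                   "sigma_full": sigma.sum(axis=1),
                   "sigma_pmn": sigma[:, focal_idx].sum(axis=1),
                   "bgn": bgn[:, focal_idx].mean(axis=1)}
            for (lo, _hi), bidx in zip(khz_bands, khz_idx):
                rec[f"band_{int(lo)}"] = sigma[:, bidx].sum(axis=1)
            rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


def stage_index_audio(audio_dir, config: PipelineConfig) -> pd.DataFrame:
    """Full-audio mode: compute indices from WAV minutes on disk.

    Expects files named ``<site_id>_d<day>_m<minute>.wav`` anywhere under
    ``audio_dir``.
    """
    khz_bands = [(lo, lo + 1000.0) for lo in np.arange(0.0, 24000.0, 1000.0)]
    khz_idx = [idx.bands_in_range(lo, hi) for lo, hi in khz_bands]
    focal_idx = idx.bands_in_range(*config.focal_range)
    rows = []
    for path in sorted(Path(audio_dir).rglob("*.wav")):
        stem = path.stem
        try:
            site_id, dpart, mpart = stem.rsplit("_", 2)
            day, minute = int(dpart[1:]), int(mpart[1:])
        except ValueError as exc:
            raise PipelineError(f"index: cannot parse WAV name {path.name}") from exc
        audio, rate = idx.read_wav(path)
        spec = idx.compute_spectrogram(audio, rate, config.fft_size,
                                       site_id=site_id, day=day,
                                       minute_of_day=minute)
        sigma, _pmn, bgn = idx.sigma_pmn_minute(
            spec.values, smooth=config.smooth, clip_negative=config.clip_negative)
        rec = {"site_id": site_id, "day": day, "minute_of_day": minute,
               "sigma_full": float(sigma.sum()),
               "sigma_pmn": float(sigma[focal_idx].sum()),
               "bgn": float(bgn[focal_idx].mean())}
        for (lo, _hi), bidx in zip(khz_bands, khz_idx):
            rec[f"band_{int(lo)}"] = float(sigma[bidx].sum())
        rows.append(rec)
    if not rows:
        raise PipelineError(f"index: no WAV files under {audio_dir}")
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {"config_hash": chash, "seed": config.seed,
                      "versions": _versions(), "stages": {}, "complete": False}
    config.to_yaml(outdir / "config.yaml")

    def _fail(stage, exc):
        manifest["stages"][stage] = {"error": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- synth -------------------------------------------------------------
    try:
        if config.run_synth:
            scfg = config.synth.with_seed(
                config.synth.seed if config.synth.seed else config.seed)
            sites = synth.generate_sites(scfg)
            annotations_raw = synth.generate_annotations(
                scfg, n_per_taxon=config.n_annotations_per_taxon, sites=sites)
            ann.write_selection_table(
                annotations_raw.rename(columns={"Low Freq (Hz)": "f_min_hz",
                                                "High Freq (Hz)": "f_max_hz"}),
                outdir / "annotations.tsv")
            config = _replace_synth(config, scfg)
        else:
            sites = read_table(config.metadata_csv)
        write_table(sites, outdir / "metadata.csv", chash)
        manifest["stages"]["synth"] = {"n_sites": len(sites)}
    except PipelineError:
        raise
    except Exception as exc:
        _fail("synth", exc)

    # --- indices + exclusions ---------------------------------------------
    try:
        if config.fast_mode:
            index_df = stage_index_fast(sites, config)
        else:
            index_df = stage_index_audio(config.audio_dir, config)
        n_raw = len(index_df)
        index_df = idx.apply_exclusions(index_df,
                                        edge_minutes=config.edge_minutes,
                                        excluded_minutes=config.excluded_minutes)
        response = idx.aggregate_time(index_df, scheme="minute_of_day")
        write_table(response, outdir / "response.csv", chash)
        manifest["stages"]["index"] = {"n_minutes_raw": n_raw,
                                       "n_minutes_kept": len(index_df),
                                       "n_response_rows": len(response)}
    except PipelineError:
        raise
    except Exception as exc:
        _fail("index", exc)

    # --- annotation ranges --------------------------------------------------
    try:
        ann_path = (outdir / "annotations.tsv" if config.run_synth
                    else config.annotation_tsv)
        if ann_path is not None:
            annotations = ann.read_selection_table(ann_path)
            ranges = ann.taxon_frequency_ranges(annotations, config.coverage)
            bio_lo, bio_hi = ann.biophonic_range(annotations, config.coverage)
            partition = ann.frequency_partition_test(annotations)
            write_table(ranges, outdir / "taxon_ranges.csv", chash)
            manifest["stages"]["annotation_ranges"] = {
                "n_annotations": len(annotations),
                "biophonic_range_hz": [bio_lo, bio_hi],
                "anova_f": partition["f_statistic"],
                "anova_p": partition["p_value"]}
    except PipelineError:
        raise
    except Exception as exc:
        _fail("annotation_ranges", exc)

    # --- acoustic-space selection -------------------------------------------
    try:
        if config.run_select:
            selections = sel.select_minutes(response, sites)
            bins = sel.retained_bins(selections, config.retention_threshold)
            write_table(selections, outdir / "selections.csv", chash)
            write_table(pd.DataFrame({"time_bin": bins}),
                        outdir / "retained_bins.csv", chash)
            ten_min = (index_df.assign(time_bin=index_df["minute_of_day"] // 10)
                       .groupby(["site_id", "time_bin"], as_index=False)
                       ["sigma_pmn"].mean()
                       .merge(sites, on="site_id"))
            importance = sel.variable_importance(ten_min, seed=config.seed)
            write_table(importance, outdir / "variable_importance.csv", chash)
            manifest["stages"]["selection"] = {
                "n_minutes_modeled": len(selections),
                "retained_fraction": float(np.mean(selections["landuse_retained"])),
                "n_retained_bins": len(bins)}
        else:
            if not config.supplied_bins:
                raise PipelineError("selection disabled but no supplied_bins given")
            bins = list(config.supplied_bins)
            manifest["stages"]["selection"] = {"supplied_bins": len(bins)}
    except PipelineError:
        raise
    except Exception as exc:
        _fail("selection", exc)

    # --- similarity ----------------------------------------------------------
    try:
        merged = response.merge(sites[["site_id", "land_use"]], on="site_id")
        inters = sim.build_intersections(bins, config.focal_range)
        distances = sim.distance_table(merged, inters, k=config.k)
        write_table(distances, outdir / "distances.csv", chash)

        _, per_bin_skew, grand_skew = sim.skew_ratios(distances)
        write_table(per_bin_skew, outdir / "skew.csv", chash)

        base = "reference_forest"
        others = ["natural_regeneration", "plantation", "pasture"]
        series = {}
        for cls in others:
            d = sim.pair_similarity(distances, cls, base)
            series[cls] = d.groupby("time_bin")["wasserstein"].mean()
        fried_table = pd.DataFrame(series).dropna()
        fried_stat, fried_p = sim.friedman_across_bins(fried_table)
        wilcoxon = sim.pairwise_wilcoxon(fried_table)
        write_table(wilcoxon, outdir / "wilcoxon.csv", chash)

        dawn_inters = sim.build_intersections(range(30, 39), config.focal_range)
        all_inters = sim.build_intersections(range(144), (1000.0, 24000.0))
        dawn_distances = sim.distance_table(merged, dawn_inters, k=config.k)
        full_distances = sim.distance_table(merged, all_inters, k=config.k)
        summaries = pd.concat([
            sim.similarity_summary(distances, "focal"),
            sim.similarity_summary(dawn_distances, "dawn_only"),
            sim.similarity_summary(full_distances, "full_spectrum"),
        ], ignore_index=True)
        write_table(summaries, outdir / "similarity_summary.csv", chash)

        manifest["stages"]["similarity"] = {
            "n_intersections": len(inters),
            "n_distance_rows": len(distances),
            "friedman_chi2": fried_stat, "friedman_p": fried_p,
            "grand_mean_skew": grand_skew}
        with open(outdir / "summary.json", "w") as fh:
            json.dump({
                "config_hash": chash,
                "retained_bins": [int(b) for b in bins],
                "grand_mean_skew": grand_skew,
                "friedman": {"chi2": fried_stat, "p": fried_p},
                "mean_similarity": {
                    f"{r.class_a}|{r.class_b}|{r.mode}": r.mean_similarity
                    for r in summaries.itertuples()},
            }, fh, indent=2)
    except PipelineError:
        raise
    except Exception as exc:
        _fail("similarity", exc)

    manifest["complete"] = True
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _replace_synth(config: PipelineConfig, scfg) -> PipelineConfig:
    from dataclasses import replace
    return replace(config, synth=scfg)


def _versions() -> dict:
    import scipy
    import xgboost

    from . import __version__
    return {"sonoscape": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "xgboost": xgboost.__version__}
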