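"""Synthetic multi-site, multi-day soundscapes with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: four land-use archetypes (reference forest, natural regeneration,
plantation, pasture) recorded continuously for several days at 48 kHz,
with dawn/dusk chorus peaks whose energy is ordered by land-use condition,
a constant insect drone band, intermittent stationary geophony (rain/wind),
low-frequency anthropophony weighted by human modification, and per-site
covariates and recorder hardware.

Two output modes share one statistical model:

* **audio mode** — 60-s float waveforms at 48 kHz per (site, day, minute),
  fed through the full spectrogram path;
* **fast mode** — per-minute dB spectrograms emitted directly, with the
  noise floor of each (site, minute, band) constant over frames and all
  signal expressed as transient pulses or stationary offsets above it.

Everything is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .index import BAND_WIDTH_HZ, N_BANDS, SAMPLE_RATE, bands_in_range

logger = logging.getLogger(__name__)

LAND_USES = ("reference_forest", "natural_regeneration", "plantation", "pasture")
TAXA = ("human_domestic", "mammal", "amphibian", "bird", "insect")
BIOPHONY_TAXA = ("mammal", "amphibian", "bird", "insect")
HARDWARE_VERSIONS = ("v1_1", "v1_2")

_SITE_PREFIX = {"reference_forest": "RF", "natural_regeneration": "NR",
                "plantation": "PL", "pasture": "PA"}

# rng stream tags, so the per-purpose substreams never collide
_TAG_SITES, _TAG_ANNOT, _TAG_SPEC, _TAG_AUDIO, _TAG_FLOOR = 11, 12, 13, 14, 15


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition knobs of the synthetic soundscape generator.

    Defaults mirror the recording design the analysis targets: six
    continuous days per site, dawn chorus centered 05:30 and dusk chorus
    centered 17:50, chorus energy ordered reference forest >= natural
    regeneration >= plantation >= pasture.
    """

    n_sites_per_class: int = 10
    n_days: int = 6
    seed: int = 0
    #: multiplier on chorus pulse amplitude per land-use class
    effect_sizes: Mapping[str, float] = field(default_factory=lambda: {
        "reference_forest": 1.0, "natural_regeneration": 0.85,
        "plantation": 0.7, "pasture": 0.25})
    dawn_center: int = 330          # minute of day, 05:30
    dawn_half_width: int = 50       # minutes
    dusk_center: int = 1070         # 17:50
    dusk_half_width: int = 50
    chorus_db: float = 12.0         # peak chorus pulse amplitude above floor
    chorus_pulse_fraction: float = 0.25
    ambient_db: float = 6.0         # class-independent background biophony
    ambient_pulse_fraction: float = 0.06
    insect_db: float = 8.0          # constant (stationary) insect drone
    rain_rate: float = 0.03         # per-minute probability of rain
    wind_rate: float = 0.02
    rain_db: float = 10.0
    wind_db: float = 6.0
    anthropophony_db: float = 10.0  # scaled by human_modification, < 1 kHz
    anthro_pulse_fraction: float = 0.15
    taxon_bands: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "human_domestic": (50.0, 950.0), "mammal": (300.0, 1040.0),
        "amphibian": (1100.0, 4900.0), "bird": (1260.0, 8000.0),
        "insect": (4830.0, 12320.0)})
    floor_db: float = -85.0         # sensor noise floor, dB
    floor_site_range: float = 4.0   # uniform spread of per-site floor offsets
    hardware_gain: float = 1.05     # pulse-amplitude multiplier of v1_2 units
    fast_frames: int = 64           # frames per minute in fast (spectrogram) mode
    background_amp: float = 1e-4    # waveform noise amplitude, audio mode

    def __post_init__(self):
        if self.n_sites_per_class < 1:
            raise ConfigError("n_sites_per_class must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        e = [self.effect_sizes[c] for c in LAND_USES]
        if not all(a >= b for a, b in zip(e, e[1:])):
            raise ConfigError(
                "effect sizes must be ordered reference_forest >= "
                "natural_regeneration >= plantation >= pasture")
        for taxon, (lo, hi) in self.taxon_bands.items():
            if not (0 <= lo < hi <= SAMPLE_RATE / 2):
                raise ConfigError(f"invalid band for {taxon}: ({lo}, {hi})")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# diel structure and ground truth

def diel_envelope(minutes, config: SynthConfig) -> np.ndarray:
    """Chorus activity envelope in [0, 1] over minutes of the day.

    Raised-cosine bumps at the dawn and dusk centers; exactly zero outside
    the chorus windows, so the land-use contrast is confined to them.
    """
    m = np.asarray(minutes, dtype=np.float64)
    env = np.zeros_like(m)
    for center, half in ((config.dawn_center, config.dawn_half_width),
                         (config.dusk_center, config.dusk_half_width)):
        d = np.abs(m - center)
        inside = d <= half
        env[inside] = np.maximum(env[inside],
                                 0.5 * (1 + np.cos(np.pi * d[inside] / half)))
    return env


def ground_truth_minutes(config: SynthConfig, threshold: float = 0.5) -> np.ndarray:
    """Minutes of day where the land-use contrast is at least half strength."""
    return np.nonzero(diel_envelope(np.arange(1440), config) >= threshold)[0]


def ground_truth_bins(config: SynthConfig, threshold: float = 0.5) -> list[int]:
    """10-min bins whose mean chorus envelope reaches ``threshold``.

    This is the ground-truth schedule the acoustic-space selection stage is
    expected to recover.
    """
    env = diel_envelope(np.arange(1440), config).reshape(144, 10).mean(axis=1)
    return [int(b) for b in np.nonzero(env >= threshold)[0]]


# ---------------------------------------------------------------------------
# sites

def generate_sites(config: SynthConfig) -> pd.DataFrame:
    """Site metadata table: 4 x n_sites_per_class sites with covariates.

    Precipitation, EVI and elevation are drawn from the same plausible
    uniform ranges for every class; only canopy height and human
    modification carry systematic class shifts (pastures low canopy / high
    modification), so model selection has to find the land-use signal in the
    audio rather than in a confounded covariate.
    """
    rng = np.random.default_rng([config.seed, _TAG_SITES])
    rows = []
    canopy_ranges = {"reference_forest": (18.0, 35.0), "natural_regeneration": (8.0, 20.0),
                     "plantation": (10.0, 25.0), "pasture": (0.3, 3.0)}
    hm_ranges = {"reference_forest": (0.0, 0.2), "natural_regeneration": (0.1, 0.4),
                 "plantation": (0.2, 0.5), "pasture": (0.5, 0.9)}
    idx = 0
    for land_use in LAND_USES:
        for k in range(config.n_sites_per_class):
            rows.append({
                "site_id": f"{_SITE_PREFIX[land_use]}{k:03d}",
                "site_index": idx,
                "land_use": land_use,
                "annual_precipitation": rng.uniform(1500.0, 2500.0),
                "evi": rng.uniform(0.4, 0.9),
                "human_modification": rng.uniform(*hm_ranges[land_use]),
                "elevation": rng.uniform(50.0, 1500.0),
                "canopy_height": rng.uniform(*canopy_ranges[land_use]),
                "hardware": HARDWARE_VERSIONS[int(rng.random() < 0.4)],
            })
            idx += 1
    return pd.DataFrame(rows)


def _site_floor_params(config: SynthConfig, site_index: int) -> tuple[float, float]:
    """Per-site noise-floor offset (dB) and ambient-activity multiplier."""
    rng = np.random.default_rng([config.seed, _TAG_FLOOR, int(site_index)])
    half = config.floor_site_range / 2.0
    offset = rng.uniform(-half, half)
    ambient_mult = rng.uniform(0.85, 1.15)
    return float(offset), float(ambient_mult)


# ---------------------------------------------------------------------------
# fast mode: dB spectrograms

def synth_spectrograms(site: Mapping, day: int, config: SynthConfig,
                       minutes=None, n_frames: int | None = None) -> np.ndarray:
    """Fast-mode dB spectrograms for one site-day: (minutes, 256, frames).

    The noise floor of each (minute, band) is a constant dB level (sensor
    self-noise plus any stationary component active that minute); transient
    activity is expressed as pulses above it:

    * chorus pulses in the bird band, amplitude scaled by the land-use
      effect size, the diel envelope and the hardware gain;
    * class-independent ambient biophony pulses across 1.1-9 kHz, all day;
    * anthropophony pulses below 1 kHz, scaled by human modification;
    * stationary offsets: constant insect drone band, and whole-spectrum
      rain / low-band wind on randomly rainy or windy minutes — these shift
      a band's mode and are removed by the background estimator.
    """
    if minutes is None:
        minutes = np.arange(1440)
    minutes = np.asarray(minutes, dtype=np.int64)
    if minutes.size and (minutes.min() < 0 or minutes.max() > 1439):
        raise ConfigError("minute_of_day must lie in [0, 1439]")
    t = int(n_frames if n_frames is not None else config.fast_frames)
    site_index = int(site["site_index"])
    rng = np.random.default_rng([config.seed, _TAG_SPEC, site_index, int(day)])
    floor_offset, ambient_mult = _site_floor_params(config, site_index)
    m = minutes.size
    floor = config.floor_db + floor_offset
    # float32 throughout: the fast path touches ~10^7 cells per site-day
    spec = np.full((m, N_BANDS, t), floor, dtype=np.float32)

    effect = config.effect_sizes[site["land_use"]]
    hw_gain = config.hardware_gain if site.get("hardware") == "v1_2" else 1.0
    env = diel_envelope(minutes, config)

    chorus_idx = bands_in_range(*config.taxon_bands["bird"])
    ambient_idx = bands_in_range(1100.0, 9000.0)
    insect_idx = bands_in_range(*config.taxon_bands["insect"])
    anthro_idx = bands_in_range(0.0, 1000.0)
    wind_idx = bands_in_range(0.0, 1500.0)

    # transient pulse components: amplitude 0 outside their schedule
    chorus_amp = config.chorus_db * effect * hw_gain * env
    _add_pulses(spec, rng, chorus_idx, config.chorus_pulse_fraction,
                chorus_amp, active=env > 0)
    ambient_amp = np.full(m, config.ambient_db * ambient_mult * hw_gain)
    _add_pulses(spec, rng, ambient_idx, config.ambient_pulse_fraction, ambient_amp)
    anthro_amp = np.full(m, config.anthropophony_db * float(site["human_modification"]))
    _add_pulses(spec, rng, anthro_idx, config.anthro_pulse_fraction, anthro_amp)

    # stationary components: flat over frames, absorbed into the band mode
    if config.insect_db > 0:
        spec[:, insect_idx, :] += config.insect_db
    rainy = rng.random(m) < config.rain_rate
    spec[rainy] += config.rain_db
    windy = rng.random(m) < config.wind_rate
    spec[np.ix_(np.nonzero(windy)[0], wind_idx)] += config.wind_db
    return spec


def _add_pulses(spec, rng, band_idx, fraction, amp_per_minute, active=None):
    """Add transient pulses: ``fraction`` of frames raised by ~amp dB."""
    m, _, t = spec.shape
    nb = band_idx.size
    if nb == 0 or fraction <= 0:
        return
    amp = np.asarray(amp_per_minute, dtype=np.float32)
    mask = rng.random((m, nb, t), dtype=np.float32) < fraction
    add = rng.standard_normal((m, nb, t), dtype=np.float32)
    add *= np.float32(0.5)  # +-0.5 dB amplitude jitter
    add += amp[:, None, None]
    np.maximum(add, np.float32(0.0), out=add)
    add *= mask
    if active is not None:
        add *= np.asarray(active, dtype=np.float32)[:, None, None]
    spec[:, band_idx, :] += add


# ---------------------------------------------------------------------------
# audio mode

def synth_minute(site: Mapping, minute_of_day: int, day: int,
                 config: SynthConfig) -> np.ndarray:
    """One 60-s mono waveform at 48 kHz for (site, day, minute).

    Same component structure as fast mode, rendered as audio: broadband
    noise background, gated narrowband chorus tones in the bird band,
    a constant insect tone, stationary rain noise and a gated low-frequency
    anthropophony tone.  Deterministic given (site, minute, day, seed).
    """
    if not 0 <= int(minute_of_day) <= 1439:
        raise ConfigError(f"minute_of_day out of range: {minute_of_day}")
    site_index = int(site["site_index"])
    rng = np.random.default_rng(
        [config.seed, _TAG_AUDIO, site_index, int(day), int(minute_of_day)])
    n = 60 * SAMPLE_RATE
    tt = np.arange(n) / SAMPLE_RATE
    audio = np.zeros(n)
    if config.background_amp > 0:
        audio += rng.normal(0.0, config.background_amp, size=n)

    effect = config.effect_sizes[site["land_use"]]
    hw_gain = config.hardware_gain if site.get("hardware") == "v1_2" else 1.0
    env = float(diel_envelope([minute_of_day], config)[0])

    def gated_tone(freq, amp, fraction):
        if amp <= 0 or fraction <= 0:
            return
        # on/off gate piecewise-constant over ~0.25 s segments
        n_seg = 240
        gate = (rng.random(n_seg) < fraction).astype(np.float64)
        gate = np.repeat(gate, n // n_seg)
        phase = rng.uniform(0, 2 * np.pi)
        audio[:] += amp * gate * np.sin(2 * np.pi * freq * tt + phase)

    chorus_amp = config.background_amp * 10 ** (config.chorus_db / 20.0) \
        * effect * hw_gain * env * 4.0
    lo, hi = config.taxon_bands["bird"]
    for _ in range(4):
        gated_tone(rng.uniform(lo, hi), chorus_amp, config.chorus_pulse_fraction)

    ambient_amp = config.background_amp * 10 ** (config.ambient_db / 20.0) * 2.0
    gated_tone(rng.uniform(1100.0, 9000.0), ambient_amp, config.ambient_pulse_fraction)

    if config.insect_db > 0 and config.background_amp > 0:
        ilo, ihi = config.taxon_bands["insect"]
        audio += (config.background_amp * 10 ** (config.insect_db / 20.0)
                  * np.sin(2 * np.pi * rng.uniform(ilo, ihi) * tt))

    anthro_amp = (config.background_amp * 10 ** (config.anthropophony_db / 20.0)
                  * float(site["human_modification"]) * 2.0)
    gated_tone(rng.uniform(100.0, 900.0), anthro_amp, config.anthro_pulse_fraction)

    if config.background_amp > 0 and rng.random() < config.rain_rate:
        audio += rng.normal(0.0, config.background_amp * 10 ** (config.rain_db / 20.0),
                            size=n)
    return audio


# ---------------------------------------------------------------------------
# annotations

def generate_annotations(config: SynthConfig, n_per_taxon: int = 400,
                         n_unknown: int = 40,
                         sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Synthetic sonotype annotation table in Raven selection-table shape.

    Per taxon, minimum frequencies are drawn uniformly from the lower 15%
    of the configured band and maximum frequencies from its upper 15%, so
    the central-90% quantile rule applied downstream recovers (slightly
    inside) the configured band.  Rows labeled ``unknown`` get arbitrary
    bands and are retained but flagged by the reader.
    """
    if not config.taxon_bands:
        raise ConfigError("taxon_bands must be configured")
    rng = np.random.default_rng([config.seed, _TAG_ANNOT])
    site_ids = (list(sites["site_id"]) if sites is not None
                else [f"{p}000" for p in _SITE_PREFIX.values()])
    rows = []
    sel = 1

    def _row(taxon, f_min, f_max):
        nonlocal sel
        minute = int(rng.integers(0, 1440))
        begin = float(rng.uniform(0.0, 57.0))
        rows.append({
            "Selection": sel, "View": "Spectrogram 1", "Channel": 1,
            "Begin Time (s)": begin,
            "End Time (s)": begin + float(rng.uniform(0.3, 3.0)),
            "Low Freq (Hz)": round(float(f_min), 1),
            "High Freq (Hz)": round(float(f_max), 1),
            "taxon": taxon,
            "site_id": site_ids[int(rng.integers(0, len(site_ids)))],
            "minute_of_day": minute,
            "diel_class": "diurnal" if 360 <= minute < 1080 else "nocturnal",
        })
        sel += 1

    for taxon in TAXA:
        lo, hi = config.taxon_bands[taxon]
        w = hi - lo
        for _ in range(n_per_taxon):
            _row(taxon, rng.uniform(lo, lo + 0.15 * w),
                 rng.uniform(hi - 0.15 * w, hi))
    for _ in range(n_unknown):
        f_lo = rng.uniform(100.0, 20000.0)
        _row("unknown", f_lo, f_lo + rng.uniform(100.0, 3000.0))
    return pd.DataFrame(rows)
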