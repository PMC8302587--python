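"""Synthetic feedback-locked EEG epochs with injected, feature-scaled components.

Each injected component is a Gaussian-windowed cosine burst (a Morlet-like
wavelet packet) with a fixed scalp topography, whose single-trial amplitude is
an affine function of a behavioral feature (RPE magnitude, outcome
probability, or a constant) and which is only present on a configurable
subset of trials (e.g. negative-valence outcomes). Summing components with
1/f-plus-white noise and per-participant offsets yields epochs whose ground
truth is known exactly, so every downstream analysis stage can be validated
by parameter recovery.

Default components encode the empirical picture this package is built
around: an early frontal theta burst on negative outcomes (FRN), a slower
centro-parietal delta burst on positive outcomes (RewP), and a late
fronto-central delta component whose amplitude falls with outcome
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

NEGATIVE_CONDITIONS = ("easy loss", "easy neutral", "hard loss")
POSITIVE_CONDITIONS = ("easy win", "hard win", "hard neutral")


def condition_labels(trials: pd.DataFrame) -> pd.Series:
    """Condition label per trial: "<difficulty> <outcome>" for Target Time
    events, or the ``condition`` column as-is for Oddball events."""
    if "condition" in trials.columns:
        return trials["condition"].astype(str)
    return trials["difficulty"].astype(str) + " " + trials["outcome"].astype(str)


@dataclass(frozen=True)
class ChannelLayout:
    """Channel names with 2D scalp positions normalized to unit head radius."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.names), 2):
            raise ValueError("positions must be (n_channels, 2)")

    @classmethod
    def biosemi64(cls) -> "ChannelLayout":
        """Standard 64-channel extended 10-20 (BioSemi) layout via mne."""
        import mne

        montage = mne.channels.make_standard_montage("biosemi64")
        pos3d = montage.get_positions()["ch_pos"]
        names = tuple(montage.ch_names)
        xy = np.array([pos3d[ch][:2] for ch in names])
        xy = xy / np.abs(xy).max()
        return cls(names=names, positions=xy)

    def subset(self, names: Sequence[str]) -> "ChannelLayout":
        idx = [self.names.index(n) for n in names]
        return ChannelLayout(tuple(names), self.positions[idx])

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class ComponentSpec:
    """One injected EEG component.

    The signal a trial receives is
    ``polarity * (gain_intercept + gain_slope * feature) * burst * topography``
    where the burst is ``cos(2 pi f (t - t0)) * GaussianEnvelope(t - t0)``
    with envelope FWHM ``envelope_fwhm`` seconds (default two cycles), and
    the topography is an isotropic Gaussian on the 2D layout around
    ``peak_channel`` (weight exactly 1 there). ``condition_mask`` is either
    "all", "negative_outcomes", "positive_outcomes", or an explicit tuple of
    condition labels.
    """

    label: str
    center_latency: float
    frequency: float
    peak_channel: str
    polarity: int = 1
    gain_intercept: float = 0.0
    gain_slope: float = 1.0
    driving_feature: str = "constant"
    condition_mask: str | tuple[str, ...] = "all"
    envelope_fwhm: float | None = None  # seconds; None -> 2 cycles
    topography_width: float = 0.4  # head radii

    @property
    def fwhm(self) -> float:
        return (self.envelope_fwhm if self.envelope_fwhm is not None
                else 2.0 / self.frequency)

    def envelope(self, times: np.ndarray) -> np.ndarray:
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((times - self.center_latency) / sigma) ** 2)

    def waveform(self, times: np.ndarray) -> np.ndarray:
        carrier = np.cos(2 * np.pi * self.frequency
                         * (times - self.center_latency))
        return carrier * self.envelope(times)

    def topography(self, layout: ChannelLayout) -> np.ndarray:
        # the peak channel anchors the Gaussian even when it is not among
        # the synthesized channels (subset layouts)
        if self.peak_channel in layout.names:
            peak = layout.positions[layout.index(self.peak_channel)]
        else:
            full = ChannelLayout.biosemi64()
            peak = full.positions[full.index(self.peak_channel)]
        d2 = ((layout.positions - peak) ** 2).sum(axis=1)
        return np.exp(-0.5 * d2 / self.topography_width ** 2)

    def trial_mask(self, conditions: pd.Series) -> np.ndarray:
        if self.condition_mask == "all":
            return np.ones(len(conditions), bool)
        if self.condition_mask == "negative_outcomes":
            wanted: tuple[str, ...] = NEGATIVE_CONDITIONS
        elif self.condition_mask == "positive_outcomes":
            wanted = POSITIVE_CONDITIONS
        else:
            wanted = tuple(self.condition_mask)
        return conditions.isin(wanted).to_numpy()


@dataclass(frozen=True)
class NoiseSpec:
    """Structured noise: spectrally shaped (1/f^a) plus white, per trial and
    channel, with a per-participant DC offset and an optional multiplicative
    per-participant amplitude factor applied to all components."""

    one_over_f_exponent: float = 1.0
    noise_sd: float = 10.0  # uV, RMS of the 1/f part
    white_sd: float = 2.0  # uV
    participant_intercept_sd: float = 1.0  # uV
    participant_gain_log_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.white_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def default_component_set(snr_scale: float = 1.0) -> list[ComponentSpec]:
    """FRN, RewP and a late frontal probability component.

    Gains are sized so single-trial amplitudes are roughly half the noise SD
    at the peak channel (group effects detectable with ~20 participants x
    600 trials, but not trivially). The probability component's amplitude
    *decreases* with outcome probability (negative slope, positive offset).
    """
    return [
        ComponentSpec(
            label="FRN", center_latency=0.216, frequency=6.0,
            peak_channel="Fz", polarity=-1,
            gain_intercept=0.0, gain_slope=5.0 * snr_scale,
            driving_feature="rpe_magnitude",
            condition_mask="negative_outcomes"),
        ComponentSpec(
            label="RewP", center_latency=0.310, frequency=3.0,
            peak_channel="Pz", polarity=1,
            gain_intercept=0.0, gain_slope=5.0 * snr_scale,
            driving_feature="rpe_magnitude",
            condition_mask="positive_outcomes"),
        ComponentSpec(
            label="LFP-prob", center_latency=0.380, frequency=4.0,
            peak_channel="FCz", polarity=1,
            gain_intercept=6.0 * snr_scale, gain_slope=-6.0 * snr_scale,
            driving_feature="outcome_probability",
            condition_mask="all"),
    ]


@dataclass
class EpochsContainer:
    """Trials x channels x time voltage array plus its trial metadata."""

    data: np.ndarray  # float32, (n_trials, n_channels, n_times), uV
    times: np.ndarray  # seconds relative to feedback
    channels: tuple[str, ...]
    sfreq: float
    events: pd.DataFrame

    def __post_init__(self) -> None:
        n_tr, n_ch, n_t = self.data.shape
        if len(self.events) != n_tr:
            raise ValueError(
                f"events table has {len(self.events)} rows for {n_tr} trials")
        if len(self.channels) != n_ch:
            raise ValueError("channel list does not match data")
        if len(self.times) != n_t:
            raise ValueError("time axis does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def select_trials(self, mask) -> "EpochsContainer":
        mask = np.asarray(mask)
        return EpochsContainer(
            self.data[mask], self.times, self.channels, self.sfreq,
            self.events.loc[mask].reset_index(drop=True))

    def select_channels(self, names: Sequence[str]) -> "EpochsContainer":
        idx = [self.channels.index(n) for n in names]
        return EpochsContainer(
            self.data[:, idx], self.times, tuple(names), self.sfreq,
            self.events)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_times: int, exponent: float) -> np.ndarray:
    """Unit-SD spectrally shaped noise along the last axis."""
    white = rng.standard_normal(shape + (n_times,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times)
    freqs[0] = freqs[1]
    spec *= freqs ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n=n_times, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def synthesize_epochs(trials: pd.DataFrame,
                      features: pd.DataFrame | None,
                      components: Sequence[ComponentSpec],
                      noise: NoiseSpec | None = None,
                      layout: ChannelLayout | None = None,
                      seed: int | None = None,
                      sfreq: float = 250.0,
                      tmin: float = -0.2,
                      tmax: float = 1.0,
                      participant_factors: Mapping[str, float] | None = None,
                      ) -> EpochsContainer:
    """Build one epoch per row of ``trials``.

    ``features`` must be row-aligned with ``trials`` (same order) and supply
    every component's driving feature; it may be None when all components are
    constant-driven. ``participant_factors`` optionally fixes each
    participant's multiplicative amplitude factor (shared across tasks, e.g.
    to induce inter-participant correlations between paradigms); otherwise
    factors are drawn from the noise spec. Deterministic given ``seed``.
    """
    noise = noise or NoiseSpec()
    layout = layout or ChannelLayout.biosemi64()
    rng = np.random.default_rng(seed)
    n_times = int(round((tmax - tmin) * sfreq)) + 1
    times = tmin + np.arange(n_times) / sfreq
    trials = trials.reset_index(drop=True)
    n_trials = len(trials)
    n_ch = len(layout.names)
    conditions = condition_labels(trials)

    data = np.zeros((n_trials, n_ch, n_times), np.float32)

    participants = list(dict.fromkeys(trials["participant_id"]))
    offsets, factors = {}, {}
    for pid in participants:
        offsets[pid] = rng.normal(0.0, noise.participant_intercept_sd)
        if participant_factors is not None and pid in participant_factors:
            factors[pid] = float(participant_factors[pid])
        else:
            factors[pid] = float(np.exp(
                rng.normal(0.0, noise.participant_gain_log_sd)))
    p_offset = trials["participant_id"].map(offsets).to_numpy(float)
    p_factor = trials["participant_id"].map(factors).to_numpy(float)

    for comp in components:
        if comp.driving_feature == "constant":
            feat = np.ones(n_trials)
        else:
            if features is None or comp.driving_feature not in features:
                raise ValueError(
                    f"feature {comp.driving_feature!r} required by component "
                    f"{comp.label!r} is missing")
            feat = features[comp.driving_feature].to_numpy(float)
        mask = comp.trial_mask(conditions)
        if not mask.any():
            continue
        amp = (comp.polarity
               * (comp.gain_intercept + comp.gain_slope * feat[mask])
               * p_factor[mask])
        wave = comp.waveform(times)
        topo = comp.topography(layout)
        data[mask] += (amp[:, None, None].astype(np.float32)
                       * topo[None, :, None].astype(np.float32)
                       * wave[None, None, :].astype(np.float32))

    data += p_offset[:, None, None].astype(np.float32)

    if noise.noise_sd > 0 or noise.white_sd > 0:
        chunk = max(1, int(2e7 // (n_ch * n_times)))
        for start in range(0, n_trials, chunk):
            stop = min(start + chunk, n_trials)
            if noise.noise_sd > 0:
                data[start:stop] += (noise.noise_sd * _pink_noise(
                    rng, (stop - start, n_ch), n_times,
                    noise.one_over_f_exponent)).astype(np.float32)
            if noise.white_sd > 0:
                data[start:stop] += (noise.white_sd * rng.standard_normal(
                    (stop - start, n_ch, n_times))).astype(np.float32)

    return EpochsContainer(data=data, times=times, channels=layout.names,
                           sfreq=sfreq, events=trials.copy())


def write_epochs(container: EpochsContainer, path) -> None:
    """Write epochs to HDF5 (schema: /data, /times, /channels, /sfreq,
    /events/<column>; attribute schema_version)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("data", data=container.data.astype(np.float32))
        f.create_dataset("times", data=container.times)
        f.create_dataset(
            "channels",
            data=np.array(container.channels, dtype=h5py.string_dtype()))
        f.create_dataset("sfreq", data=float(container.sfreq))
        ev = f.create_group("events")
        ev.attrs["columns"] = list(container.events.columns)
        for col in container.events.columns:
            vals = container.events[col].to_numpy()
            if vals.dtype == object or str(vals.dtype).startswith("str"):
                vals = np.array([str(v) for v in vals],
                                dtype=h5py.string_dtype())
            ev.create_dataset(col, data=vals)


def read_epochs(path) -> EpochsContainer:
    """Read an epochs HDF5 container; validates schema and trial linkage."""
    with h5py.File(path, "r") as f:
        for name in ("data", "times", "channels", "sfreq", "events"):
            if name not in f:
                raise ValueError(f"malformed epochs file: missing /{name}")
        data = f["data"][()]
        times = f["times"][()]
        channels = tuple(c.decode() if isinstance(c, bytes) else str(c)
                         for c in f["channels"][()])
        sfreq = float(f["sfreq"][()])
        ev = f["events"]
        cols = list(ev.attrs["columns"])
        table = {}
        for col in cols:
            vals = ev[col][()]
            if vals.dtype.kind in ("S", "O"):
                vals = np.array([v.decode() if isinstance(v, bytes) else v
                                 for v in vals])
            table[col] = vals
        events = pd.DataFrame(table)
    return EpochsContainer(data=data, times=times, channels=channels,
                           sfreq=sfreq, events=events)
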