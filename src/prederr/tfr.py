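"""Morlet-wavelet single-trial evoked power with decibel baseline correction.

Wavelets are complex sine waves tapered by a Gaussian with time-domain SD
``n_cycles / (2 pi f)`` (three cycles per frequency by default, frequencies
1-12 Hz in 1 Hz steps). Evoked power is the squared coefficient magnitude,
converted to dB relative to the mean power in the 200 ms pre-feedback
baseline, separately per trial, channel and frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .synth import EpochsContainer, SCHEMA_VERSION

POWER_EPS = 1e-20


@dataclass(frozen=True)
class MorletSpec:
    frequencies: tuple[float, ...] = tuple(float(f) for f in range(1, 13))
    n_cycles: float = 3.0
    pad_seconds: float = 2.0  # reflection padding before convolution

    def sigma_t(self, freq: float) -> float:
        """Gaussian time-domain SD of the wavelet at ``freq``."""
        return self.n_cycles / (2.0 * np.pi * freq)

    def fwhm(self, freq: float) -> float:
        return self.sigma_t(freq) * 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class TFRContainer:
    """Single-trial power in dB relative to the pre-feedback baseline."""

    power_db: np.ndarray  # (trials, channels, freqs, times), float32
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    sfreq: float
    events: pd.DataFrame
    baseline: tuple[float, float] = (-0.2, 0.0)
    edge_flagged_freqs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        n_tr, n_ch, n_f, n_t = self.power_db.shape
        if len(self.events) != n_tr:
            raise ValueError("events table does not match trial count")
        if len(self.channels) != n_ch or len(self.freqs) != n_f \
                or len(self.times) != n_t:
            raise ValueError("axis metadata does not match power array")

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def select_trials(self, mask) -> "TFRContainer":
        mask = np.asarray(mask)
        return TFRContainer(self.power_db[mask], self.freqs, self.times,
                            self.channels, self.sfreq,
                            self.events.loc[mask].reset_index(drop=True),
                            self.baseline, self.edge_flagged_freqs)


def _wavelet(freq: float, sigma: float, sfreq: float) -> np.ndarray:
    """Complex Morlet kernel, amplitude-normalized so a unit-amplitude
    sinusoid at the wavelet frequency yields |coefficient| = 1."""
    half = int(np.ceil(5.0 * sigma * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    envelope = np.exp(-0.5 * (t / sigma) ** 2)
    kernel = envelope * np.exp(2j * np.pi * freq * t)
    return kernel * (2.0 / envelope.sum())


def morlet_transform(epochs: EpochsContainer,
                     spec: MorletSpec | None = None) -> np.ndarray:
    """Complex wavelet coefficients, (trials, channels, freqs, times).

    The epoch is reflection-padded by ``spec.pad_seconds`` on both sides
    before convolution to limit edge effects; coefficients are cropped back
    to the original time axis. |coefficient| estimates the instantaneous
    amplitude of a matched sinusoid.
    """
    spec = spec or MorletSpec()
    nyquist = epochs.sfreq / 2.0
    for f in spec.frequencies:
        if f >= nyquist:
            raise ValueError(f"frequency {f} Hz is at or above Nyquist "
                             f"({nyquist} Hz)")
    data = epochs.data.astype(np.float64)
    n_t = data.shape[-1]
    pad = int(round(spec.pad_seconds * epochs.sfreq))
    padded = np.pad(data, [(0, 0), (0, 0), (pad, pad)], mode="reflect")
    out = np.empty(data.shape[:2] + (len(spec.frequencies), n_t), complex)
    for k, f in enumerate(spec.frequencies):
        kernel = _wavelet(f, spec.sigma_t(f), epochs.sfreq)
        conv = fftconvolve(padded, kernel[None, None, :], mode="same",
                           axes=-1)
        out[:, :, k, :] = conv[..., pad:pad + n_t]
    return out


def evoked_power_db(coefficients: np.ndarray, times: np.ndarray,
                    baseline: tuple[float, float] = (-0.2, 0.0),
                    eps: float = POWER_EPS) -> np.ndarray:
    """10*log10(power / baseline mean power) with per-trial, per-channel,
    per-frequency baselines; zero baselines are floored at ``eps`` with a
    warning."""
    b0, b1 = baseline
    bmask = (times >= b0) & (times < b1)
    if not bmask.any():
        raise ValueError("baseline window is outside the epoch")
    power = np.abs(coefficients) ** 2
    base = power[..., bmask].mean(axis=-1, keepdims=True)
    if (base <= eps).any():
        warnings.warn("zero baseline power floored at eps", RuntimeWarning)
        base = np.maximum(base, eps)
    return 10.0 * np.log10(np.maximum(power, eps) / base)


def tfr_transform(epochs: EpochsContainer,
                  spec: MorletSpec | None = None,
                  baseline: tuple[float, float] = (-0.2, 0.0)
                  ) -> TFRContainer:
    """Morlet transform + dB baseline correction in one step.

    Frequencies whose wavelet (10 sigma support) outlasts the epoch are kept
    but flagged as edge-contaminated in the container metadata.
    """
    spec = spec or MorletSpec()
    coefs = morlet_transform(epochs, spec)
    power = evoked_power_db(coefs, epochs.times, baseline)
    epoch_len = epochs.times[-1] - epochs.times[0]
    flagged = tuple(f for f in spec.frequencies
                    if 10.0 * spec.sigma_t(f) > epoch_len)
    return TFRContainer(
        power_db=power.astype(np.float32),
        freqs=np.asarray(spec.frequencies, float), times=epochs.times,
        channels=tuple(epochs.channels), sfreq=epochs.sfreq,
        events=epochs.events.copy(), baseline=baseline,
        edge_flagged_freqs=flagged)


def write_tfr(container: TFRContainer, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["edge_flagged_freqs"] = list(container.edge_flagged_freqs)
        f.create_dataset("power_db",
                         data=container.power_db.astype(np.float32))
        f.create_dataset("freqs", data=container.freqs)
        f.create_dataset("times", data=container.times)
        f.create_dataset("sfreq", data=float(container.sfreq))
        f.create_dataset(
            "channels",
            data=np.array(container.channels, dtype=h5py.string_dtype()))
        ev = f.create_group("events")
        ev.attrs["columns"] = list(container.events.columns)
        for col in container.events.columns:
            vals = container.events[col].to_numpy()
            if vals.dtype == object or str(vals.dtype).startswith("str"):
                vals = np.array([str(v) for v in vals],
                                dtype=h5py.string_dtype())
            ev.create_dataset(col, data=vals)


def read_tfr(path) -> TFRContainer:
    with h5py.File(path, "r") as f:
        for name in ("power_db", "freqs", "times", "channels", "events"):
            if name not in f:
                raise ValueError(f"malformed TFR file: missing /{name}")
        ev = f["events"]
        table = {}
        for col in ev.attrs["columns"]:
            vals = ev[col][()]
            if vals.dtype.kind in ("S", "O"):
                vals = np.array([v.decode() if isinstance(v, bytes) else v
                                 for v in vals])
            table[col] = vals
        return TFRContainer(
            power_db=f["power_db"][()], freqs=f["freqs"][()],
            times=f["times"][()],
            channels=tuple(c.decode() if isinstance(c, bytes) else str(c)
                           for c in f["channels"][()]),
            sfreq=float(f["sfreq"][()]), events=pd.DataFrame(table),
            edge_flagged_freqs=tuple(f.attrs.get("edge_flagged_freqs", ())))
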