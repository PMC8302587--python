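"""ERP preprocessing, condition averages, difference waves, and point
estimates (FRN mean-window / peak-to-peak / latency, P3 mean window)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .synth import EpochsContainer, condition_labels

CONDITIONS = ("easy win", "easy loss", "easy neutral",
              "hard win", "hard loss", "hard neutral")

#: peak-search intervals (s); the N2 window is reused to center the FRN mean
#: window because no separate interval is specified for it
P2_SEARCH = (0.100, 0.260)
N2_SEARCH = (0.180, 0.300)
P3_SEARCH = (0.250, 0.450)
MIN_TRIALS_PER_CONDITION = 20
RT_BOUNDS = (0.6, 1.4)


def preprocess_erp(epochs: EpochsContainer,
                   l_freq: float = 0.5, h_freq: float = 20.0,
                   baseline: tuple[float, float] = (-0.2, 0.0),
                   rt_bounds: tuple[float, float] | None = RT_BOUNDS,
                   ) -> EpochsContainer:
    """RT-screen trials, zero-phase band-pass, then baseline-correct.

    Trials with missing or out-of-bounds RTs are dropped first. A 4th-order
    Butterworth band-pass is applied forward-backward (zero phase) per trial
    and channel, then the mean of the pre-feedback baseline window is
    subtracted per trial and channel.
    """
    times = epochs.times
    b0, b1 = baseline
    bmask = (times >= b0) & (times < b1)
    if not bmask.any():
        raise ValueError("epoch does not cover the baseline window")

    if rt_bounds is not None and "rt_s" in epochs.events.columns:
        rt = epochs.events["rt_s"].to_numpy(float)
        keep = np.isfinite(rt) & (rt >= rt_bounds[0]) & (rt <= rt_bounds[1])
        epochs = epochs.select_trials(keep)

    sos = signal.butter(4, [l_freq, h_freq], btype="bandpass",
                        fs=epochs.sfreq, output="sos")
    data = signal.sosfiltfilt(
        sos, epochs.data.astype(np.float64), axis=-1,
        padtype="odd", padlen=epochs.data.shape[-1] - 1)
    data = data - data[..., bmask].mean(axis=-1, keepdims=True)
    return EpochsContainer(data.astype(np.float32), times, epochs.channels,
                           epochs.sfreq, epochs.events.copy())


@dataclass
class ERPSet:
    """Per participant x condition average waveforms."""

    data: np.ndarray  # (n_participants, n_conditions, n_channels, n_times)
    participants: tuple[str, ...]
    conditions: tuple[str, ...]
    channels: tuple[str, ...]
    times: np.ndarray
    sfreq: float
    trial_counts: pd.DataFrame  # participant_id, condition, n_trials
    flagged: tuple[str, ...]  # participants with a low-count condition

    def waveform(self, participant: str, condition: str,
                 channel: str) -> np.ndarray:
        return self.data[self.participants.index(participant),
                         self.conditions.index(condition),
                         self.channels.index(channel)]


def condition_average(epochs: EpochsContainer,
                      min_trials: int = MIN_TRIALS_PER_CONDITION) -> ERPSet:
    """Average epochs within participant and condition.

    Participants with fewer than ``min_trials`` in any condition are flagged
    (not dropped); dropping is left to pipeline policy.
    """
    conds = condition_labels(epochs.events)
    pids = tuple(dict.fromkeys(epochs.events["participant_id"]))
    present = tuple(c for c in CONDITIONS if (conds == c).any()) or \
        tuple(dict.fromkeys(conds))
    n_p, n_c = len(pids), len(present)
    data = np.full((n_p, n_c, len(epochs.channels), len(epochs.times)),
                   np.nan)
    counts = []
    flagged = []
    pid_arr = epochs.events["participant_id"].to_numpy()
    for i, pid in enumerate(pids):
        low = False
        for j, cond in enumerate(present):
            mask = (pid_arr == pid) & (conds == cond).to_numpy()
            n = int(mask.sum())
            counts.append(dict(participant_id=pid, condition=cond,
                               n_trials=n))
            if n:
                data[i, j] = epochs.data[mask].mean(axis=0)
            if n < min_trials:
                low = True
        if low:
            flagged.append(pid)
    return ERPSet(data=data, participants=pids, conditions=present,
                  channels=tuple(epochs.channels), times=epochs.times,
                  sfreq=epochs.sfreq, trial_counts=pd.DataFrame(counts),
                  flagged=tuple(flagged))


def grand_average(erps: ERPSet) -> np.ndarray:
    """Equal-weight mean of participant averages: (conditions, ch, time)."""
    return np.nanmean(erps.data, axis=0)


#: contrast -> (positive side, negative side); sides are condition tuples
DIFFERENCE_CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "rewp": (("easy win", "hard neutral", "hard win"),
             ("easy neutral", "easy loss", "hard loss")),
    "valence_hw_el": (("hard win",), ("easy loss",)),
    "valence_ew_hl": (("easy win",), ("hard loss",)),
    "valence_hn_en": (("hard neutral",), ("easy neutral",)),
    "magnitude_el_en": (("easy loss",), ("easy neutral",)),
    "magnitude_hw_hn": (("hard win",), ("hard neutral",)),
    "probability_en_hl": (("easy neutral",), ("hard loss",)),
    "probability_hn_ew": (("hard neutral",), ("easy win",)),
}


def difference_waves(erps: ERPSet,
                     channels: Sequence[str] = ("Fz", "Pz")
                     ) -> dict[str, np.ndarray]:
    """Labeled per-participant difference waveforms at the given channels.

    Includes the RewP contrast (positive-valence mean minus negative-valence
    mean) and the matched valence, magnitude and probability contrasts.
    Arrays are (n_participants, n_channels, n_times).
    """
    for cond in CONDITIONS:
        if cond not in erps.conditions:
            raise ValueError(f"missing condition: {cond!r}")
    ch_idx = [erps.channels.index(c) for c in channels]
    out = {}
    for name, (pos, neg) in DIFFERENCE_CONTRASTS.items():
        pos_idx = [erps.conditions.index(c) for c in pos]
        neg_idx = [erps.conditions.index(c) for c in neg]
        wave = (erps.data[:, pos_idx].mean(axis=1)
                - erps.data[:, neg_idx].mean(axis=1))
        out[name] = wave[:, ch_idx]
    return out


def _local_extrema(x: np.ndarray, kind: str) -> np.ndarray:
    """Indices of strict local minima/maxima; ties go to the earlier sample."""
    if kind == "min":
        hits = (x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])
    else:
        hits = (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])
    return np.flatnonzero(hits) + 1


def frn_peak_latency(waveform: np.ndarray, times: np.ndarray,
                     search: tuple[float, float] = N2_SEARCH) -> float:
    """Latency (s) of the most negative local minimum in the search window,
    or NaN when the window contains no local negative peak."""
    lo, hi = search
    sel = np.flatnonzero((times >= lo) & (times <= hi))
    idx = _local_extrema(waveform, "min")
    idx = idx[np.isin(idx, sel)]
    if idx.size == 0:
        return float("nan")
    best = idx[np.argmin(waveform[idx])]
    return float(times[best])


def _p3_peak_latency(waveform: np.ndarray, times: np.ndarray,
                     search: tuple[float, float] = P3_SEARCH) -> float:
    lo, hi = search
    sel = np.flatnonzero((times >= lo) & (times <= hi))
    idx = _local_extrema(waveform, "max")
    idx = idx[np.isin(idx, sel)]
    if idx.size == 0:
        return float("nan")
    best = idx[np.argmax(waveform[idx])]
    return float(times[best])


def _window_mean(waveform: np.ndarray, times: np.ndarray, center: float,
                 width: float = 0.100) -> float:
    lo, hi = center - width / 2, center + width / 2
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError("measurement window exceeds epoch bounds")
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    return float(waveform[mask].mean())


def frn_mean_window(erps: ERPSet, channel: str = "Fz") -> pd.DataFrame:
    """Mean amplitude in a 100 ms window centered on each participant's FRN
    peak latency from the all-condition average ERP (re-centered per
    participant, not per condition)."""
    rows = []
    ci = erps.channels.index(channel)
    for i, pid in enumerate(erps.participants):
        allcond = np.nanmean(erps.data[i, :, ci], axis=0)
        lat = frn_peak_latency(allcond, erps.times)
        for j, cond in enumerate(erps.conditions):
            val = (np.nan if np.isnan(lat) else
                   _window_mean(erps.data[i, j, ci], erps.times, lat))
            rows.append(dict(participant_id=pid, condition=cond,
                             frn_mean_uv=val))
    return pd.DataFrame(rows)


def frn_peak_to_peak(erps: ERPSet, channel: str = "Fz") -> pd.DataFrame:
    """P2-minus-N2 amplitude per participant and condition.

    Computed only when a positive local peak in 100-260 ms precedes a
    negative local peak in 180-300 ms; otherwise the value is missing. Also
    returns each condition's N2 latency and its within-participant
    normalization (mean latency across conditions subtracted).
    """
    rows = []
    ci = erps.channels.index(channel)
    for i, pid in enumerate(erps.participants):
        lats = {}
        for j, cond in enumerate(erps.conditions):
            wave = erps.data[i, j, ci]
            n2_lat = frn_peak_latency(wave, erps.times)
            lats[cond] = n2_lat
            p2p = np.nan
            if not np.isnan(n2_lat):
                lo, hi = P2_SEARCH
                sel = np.flatnonzero(
                    (erps.times >= lo) & (erps.times <= hi)
                    & (erps.times < n2_lat))
                idx = _local_extrema(wave, "max")
                idx = idx[np.isin(idx, sel)]
                if idx.size:
                    p2 = wave[idx].max()
                    n2 = wave[np.argmin(np.abs(erps.times - n2_lat))]
                    p2p = float(p2 - n2)
            rows.append(dict(participant_id=pid, condition=cond,
                             frn_p2p_uv=p2p, frn_latency_s=lats[cond]))
        vals = np.array(list(lats.values()))
        mean_lat = np.nan if np.isnan(vals).all() else np.nanmean(vals)
        for r in rows[-len(erps.conditions):]:
            r["frn_latency_norm_s"] = r["frn_latency_s"] - mean_lat
    return pd.DataFrame(rows)


def p3_mean_window(erps: ERPSet, channel: str = "Pz") -> pd.DataFrame:
    """Mean amplitude in a 100 ms window centered on each participant's P3
    positive-peak latency (search 250-450 ms) from the all-condition average
    at the posterior channel."""
    rows = []
    ci = erps.channels.index(channel)
    for i, pid in enumerate(erps.participants):
        allcond = np.nanmean(erps.data[i, :, ci], axis=0)
        lat = _p3_peak_latency(allcond, erps.times)
        for j, cond in enumerate(erps.conditions):
            val = (np.nan if np.isnan(lat) else
                   _window_mean(erps.data[i, j, ci], erps.times, lat))
            rows.append(dict(participant_id=pid, condition=cond,
                             p3_mean_uv=val))
    return pd.DataFrame(rows)


def point_estimates(erps: ERPSet) -> pd.DataFrame:
    """Combined point-estimate table (TSV schema: participant_id, condition,
    frn_mean_uv, frn_p2p_uv, frn_latency_norm_s, p3_mean_uv)."""
    mean = frn_mean_window(erps)
    p2p = frn_peak_to_peak(erps)
    p3 = p3_mean_window(erps)
    out = mean.merge(
        p2p[["participant_id", "condition", "frn_p2p_uv",
             "frn_latency_norm_s"]],
        on=["participant_id", "condition"]).merge(
        p3, on=["participant_id", "condition"])
    return out


def compare_neutral_latencies(point_est: pd.DataFrame) -> dict:
    """Paired two-sided t-test of easy- vs hard-neutral normalized FRN
    latencies across participants."""
    wide = point_est.pivot(index="participant_id", columns="condition",
                           values="frn_latency_norm_s")
    pairs = wide[["easy neutral", "hard neutral"]].dropna()
    if len(pairs) < 3:
        raise ValueError("need >= 3 participants with both neutral latencies")
    diff = (pairs["easy neutral"] - pairs["hard neutral"]).to_numpy()
    if np.allclose(diff, 0.0):
        return dict(t=0.0, p=1.0, dof=len(diff) - 1, mean_diff_s=0.0,
                    degenerate=False)
    if np.isclose(diff.std(ddof=1), 0.0):
        return dict(t=np.nan, p=np.nan, dof=len(diff) - 1,
                    mean_diff_s=float(diff.mean()), degenerate=True)
    t, p = stats.ttest_rel(pairs["easy neutral"], pairs["hard neutral"])
    return dict(t=float(t), p=float(p), dof=len(diff) - 1,
                mean_diff_s=float(diff.mean()), degenerate=False)


def write_point_estimates(point_est: pd.DataFrame, path) -> None:
    cols = ["participant_id", "condition", "frn_mean_uv", "frn_p2p_uv",
            "frn_latency_norm_s", "p3_mean_uv"]
    point_est[cols].to_csv(path, sep="\t", index=False)
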