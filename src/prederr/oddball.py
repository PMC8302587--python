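"""Canonical Oddball N2/P3 benchmarks and inter-participant correlations
with Target Time window amplitudes.

The Oddball task elicits textbook stimulus-locked components: frontal N2
negativities for target (N2c) and novel (N2b) stimuli, a fronto-central P3a
for novels and a posterior P3b for targets. Each participant's benchmark is
the mean amplitude in a 50 ms window centered on the grand-average peak, and
benchmarks are correlated across participants with Target Time amplitudes
measured in the windows showing maximal model-based effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .erp import (_local_extrema, condition_average, preprocess_erp,
                  grand_average)
from .regression import fdr_correct, window_average
from .synth import ComponentSpec, EpochsContainer

ODDBALL_RT_BOUNDS = (0.1, 1.3)
N2_SEARCH = (0.2, 0.3)
P3_SEARCH = (0.3, 0.45)
BENCHMARK_WINDOW = 0.05  # s

#: benchmark -> (condition, channel, search window, peak kind)
BENCHMARK_DEFS = {
    "n2b": ("novel", "Fz", N2_SEARCH, "min"),
    "n2c": ("target", "Fz", N2_SEARCH, "min"),
    "p3a": ("novel", "Cz", P3_SEARCH, "max"),
    "p3b": ("target", "Pz", P3_SEARCH, "max"),
}

#: Target Time windows showing maximal model-based effects:
#: (label, center s, channel)
TARGET_TIME_WINDOWS = (("rpe_value", 0.216, "Fz"),
                       ("rpe_magnitude", 0.308, "Pz"),
                       ("outcome_probability", 0.380, "Fz"))


def default_oddball_components(snr_scale: float = 1.0
                               ) -> list[ComponentSpec]:
    """Stimulus-locked N2/P3 components for synthetic Oddball epochs.

    Constant-driven; per-participant amplitude factors (shared with the
    Target Time synthesis via ``participant_factors``) are what make
    cross-task inter-participant correlations non-trivial.
    """
    return [
        ComponentSpec(label="N2b", center_latency=0.250, frequency=6.0,
                      peak_channel="Fz", polarity=-1,
                      gain_intercept=4.0 * snr_scale,
                      condition_mask=("novel",)),
        ComponentSpec(label="N2c", center_latency=0.250, frequency=6.0,
                      peak_channel="Fz", polarity=-1,
                      gain_intercept=5.0 * snr_scale,
                      condition_mask=("target",)),
        ComponentSpec(label="P3a", center_latency=0.350, frequency=3.0,
                      peak_channel="Cz", polarity=1,
                      gain_intercept=6.0 * snr_scale,
                      condition_mask=("novel",)),
        ComponentSpec(label="P3b", center_latency=0.350, frequency=3.0,
                      peak_channel="Pz", polarity=1,
                      gain_intercept=7.0 * snr_scale,
                      condition_mask=("target",)),
    ]


def preprocess_oddball(epochs: EpochsContainer) -> EpochsContainer:
    """Filter/baseline like Target Time epochs, but apply the Oddball RT
    screen to target trials only (standards and novels require no press)."""
    is_target = (epochs.events["condition"] == "target").to_numpy()
    rt = epochs.events["rt_s"].to_numpy(float)
    bad = is_target & (~np.isfinite(rt) | (rt < ODDBALL_RT_BOUNDS[0])
                       | (rt > ODDBALL_RT_BOUNDS[1]))
    return preprocess_erp(epochs.select_trials(~bad), rt_bounds=None)


def oddball_benchmarks(epochs: EpochsContainer,
                       preprocessed: bool = False) -> pd.DataFrame:
    """Per-participant N2b/N2c/P3a/P3b mean-window amplitudes.

    The 50 ms measurement window is centered on the grand-average peak
    (earliest extremum on ties) per benchmark definition and shared across
    participants. Raises when a grand-average search window has no peak.
    """
    if not preprocessed:
        epochs = preprocess_oddball(epochs)
    erps = condition_average(epochs, min_trials=1)
    grand = grand_average(erps)
    out = pd.DataFrame({"participant_id": list(erps.participants)})
    for name, (cond, channel, search, kind) in BENCHMARK_DEFS.items():
        cj = erps.conditions.index(cond)
        ci = erps.channels.index(channel)
        wave = grand[cj, ci]
        sel = np.flatnonzero((erps.times >= search[0])
                             & (erps.times <= search[1]))
        idx = _local_extrema(wave, kind)
        idx = idx[np.isin(idx, sel)]
        if idx.size == 0:
            raise ValueError(
                f"no {kind} peak for {name} in {search} at {channel}")
        best = idx[np.argmin(wave[idx])] if kind == "min" \
            else idx[np.argmax(wave[idx])]
        center = erps.times[best]
        wmask = (erps.times >= center - BENCHMARK_WINDOW / 2 - 1e-9) \
            & (erps.times <= center + BENCHMARK_WINDOW / 2 + 1e-9)
        out[name] = erps.data[:, cj, ci][:, wmask].mean(axis=1)
        out.attrs[f"{name}_latency_s"] = float(center)
    return out


def target_time_window_amplitudes(epochs: EpochsContainer,
                                  windows: Sequence[tuple[str, float, str]]
                                  = TARGET_TIME_WINDOWS,
                                  preprocessed: bool = False
                                  ) -> pd.DataFrame:
    """Per participant x condition mean amplitudes in the model-effect
    windows (long table: participant_id, condition, window, amplitude)."""
    if not preprocessed:
        epochs = preprocess_erp(epochs)
    erps = condition_average(epochs, min_trials=1)
    rows = []
    for label, center, channel in windows:
        ci = erps.channels.index(channel)
        wmask = (erps.times >= center - BENCHMARK_WINDOW / 2 - 1e-9) \
            & (erps.times <= center + BENCHMARK_WINDOW / 2 + 1e-9)
        amp = erps.data[:, :, ci][:, :, wmask].mean(axis=-1)
        for i, pid in enumerate(erps.participants):
            for j, cond in enumerate(erps.conditions):
                rows.append(dict(participant_id=pid, condition=cond,
                                 window=label, amplitude=amp[i, j]))
    return pd.DataFrame(rows)


def interparticipant_correlations(benchmarks: pd.DataFrame,
                                  target_amplitudes: pd.DataFrame,
                                  fdr_level: float = 0.05) -> pd.DataFrame:
    """Pearson r across participants for each (benchmark x Target Time
    condition) pair, per Target Time window; BH-FDR per window over the
    benchmarks x conditions family. Zero-variance vectors yield missing r
    (excluded from the family)."""
    bench_cols = [c for c in benchmarks.columns if c != "participant_id"]
    rows = []
    for window, wsub in target_amplitudes.groupby("window", sort=False):
        wide = wsub.pivot(index="participant_id", columns="condition",
                          values="amplitude")
        merged = benchmarks.set_index("participant_id").join(wide,
                                                             how="inner")
        if len(merged) < 4:
            raise ValueError("need >= 4 shared participants")
        for bench in bench_cols:
            for cond in wide.columns:
                x = merged[bench].to_numpy(float)
                y = merged[cond].to_numpy(float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 4 or x[ok].std() == 0 or y[ok].std() == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(x[ok], y[ok])
                rows.append(dict(window=window, benchmark=bench,
                                 condition=cond, r=r, p=p, q=np.nan,
                                 n=int(ok.sum())))
    table = pd.DataFrame(rows)
    for window, sub in table.groupby("window", sort=False):
        valid = sub.dropna(subset=["p"])
        if len(valid):
            table.loc[valid.index, "q"] = fdr_correct(
                valid["p"].to_numpy(), fdr_level)
    return table
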