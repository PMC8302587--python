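"""Mass-univariate linear mixed-effects regression across time, channels and
time-frequency points, with BH-FDR correction, relative-AIC model comparison,
valence splits, and point-estimate regressions.

At every analysis point a linear mixed model with participant random
intercepts is fit by maximum likelihood (ML, not REML, so AIC is comparable
across fixed-effect structures). Coefficients are tested with two-sided
t-tests on residual degrees of freedom, and p-values are corrected by
Benjamini-Hochberg FDR over the family declared by each analysis
(timepoints x predictors; channels x predictors x windows; or timepoints x
frequencies x predictors), separately per electrode analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .synth import (EpochsContainer, NEGATIVE_CONDITIONS,
                    POSITIVE_CONDITIONS, condition_labels)
from .tfr import TFRContainer

RESULT_COLUMNS = ["analysis", "channel", "time_s", "freq_hz", "predictor",
                  "beta", "se", "t", "p", "q", "aic", "logLik", "n_obs"]

#: default 50 ms topography windows: (center s, channel of the peak
#: coefficient it was derived from, predictor label)
DEFAULT_TOPO_WINDOWS = ((0.216, "rpe_value"), (0.308, "rpe_magnitude"),
                        (0.380, "outcome_probability"))

VALENCE_SPLIT_PREDICTORS = ["rpe_magnitude", "outcome_probability"]


class ConvergenceError(RuntimeError):
    """Raised when the mixed model cannot be fit at a point."""


@dataclass
class MixedModelResult:
    """One fitted mixed model: per-predictor inference plus fit metrics.

    ``params`` is indexed by predictor (including "intercept") with columns
    beta, se, t, p. AIC is 2k - 2 logLik with k counting fixed effects plus
    the two variance components.
    """

    params: pd.DataFrame
    sigma2_group: float
    sigma2_resid: float
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    dof_resid: int


def fit_lmm(response, design: pd.DataFrame | None,
            groups) -> MixedModelResult:
    """ML fit of ``response ~ 1 + design`` with participant random intercepts.

    ``design`` may be None/empty for the intercept-only baseline model.
    Raises ConvergenceError (with optimizer diagnostics) or ValueError
    naming collinear columns on a rank-deficient design.
    """
    y = np.asarray(response, float)
    groups = np.asarray(groups)
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2:
        raise ValueError("need >= 2 groups (participants)")
    if design is None or design.shape[1] == 0:
        X = pd.DataFrame({"intercept": np.ones(len(y))})
    else:
        X = design.copy()
        X.insert(0, "intercept", 1.0)
    Xmat = X.to_numpy(float)
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValueError(
            f"rank-deficient design; columns: {list(X.columns)}")

    model = MixedLM(y, Xmat, groups=codes)
    result = se = None
    diagnostics = []
    for method in ("lbfgs", "powell"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                res = model.fit(reml=False, method=method)
            except Exception as err:
                diagnostics.append(f"{method}: {err}")
                continue
            with np.errstate(invalid="ignore"):
                cand_se = np.asarray(res.bse_fe, float)
        if not res.converged:
            diagnostics.append(f"{method}: did not converge")
            continue
        if not (np.isfinite(cand_se).all() and (cand_se > 0).all()):
            # boundary variance estimates can make the Hessian singular
            diagnostics.append(f"{method}: singular covariance")
            continue
        if not np.isfinite(res.llf):
            # a variance component pinned at exactly zero can report an
            # infinite profiled likelihood; retry with the next optimizer
            diagnostics.append(f"{method}: non-finite log-likelihood")
            continue
        result, se = res, cand_se
        break
    if result is None:
        raise ConvergenceError(
            "mixed model failed to converge: " + "; ".join(diagnostics))

    k_fixed = Xmat.shape[1]
    n = len(y)
    n_groups = len(uniques)
    beta = np.asarray(result.fe_params, float)
    tval = beta / se
    dof = max(n - k_fixed - n_groups, 1)
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    loglik = float(result.llf)
    k = k_fixed + 2  # + random-intercept variance + residual variance
    params = pd.DataFrame(
        dict(beta=beta, se=se, t=tval, p=pval), index=list(X.columns))
    return MixedModelResult(
        params=params,
        sigma2_group=float(np.asarray(result.cov_re)[0, 0]),
        sigma2_resid=float(result.scale),
        loglik=loglik, aic=2.0 * k - 2.0 * loglik,
        n_obs=n, n_groups=n_groups, converged=True, dof_resid=dof)


def fdr_correct(p_values, level: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over one declared family."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, alpha=level, method="fdr_bh")[1]


@dataclass
class MassUnivariateResult:
    """Grid of mixed-model fits with per-family q-values.

    ``table`` has one row per grid point per predictor (TSV schema:
    analysis, channel, time_s, freq_hz, predictor, beta, se, t, p, q, aic,
    logLik, n_obs). The intercept is reported but excluded from the FDR
    family (q = NaN there).
    """

    table: pd.DataFrame
    family: str
    fdr_level: float = 0.05
    n_failed: int = 0

    def significant(self) -> pd.DataFrame:
        return self.table.loc[self.table["q"] < self.fdr_level]


def _result_rows(fit: MixedModelResult, analysis: str, channel: str,
                 time_s: float, freq_hz: float) -> list[dict]:
    rows = []
    for name, row in fit.params.iterrows():
        rows.append(dict(
            analysis=analysis, channel=channel, time_s=time_s,
            freq_hz=freq_hz, predictor=name, beta=row["beta"], se=row["se"],
            t=row["t"], p=row["p"], q=np.nan, aic=fit.aic, logLik=fit.loglik,
            n_obs=fit.n_obs))
    return rows


def _apply_fdr(table: pd.DataFrame, by_channel: bool,
               level: float) -> pd.DataFrame:
    """BH over non-intercept rows, separately per channel when requested."""
    mask = table["predictor"] != "intercept"
    groups = table.loc[mask].groupby("channel") if by_channel \
        else [(None, table.loc[mask])]
    for _, sub in groups:
        table.loc[sub.index, "q"] = fdr_correct(
            sub["p"].to_numpy(), level)
    return table


def _check_alignment(n_trials: int, design: pd.DataFrame) -> None:
    if len(design) != n_trials:
        raise ValueError(
            f"design has {len(design)} rows for {n_trials} epochs; align "
            "the design to the retained trials first")


def mass_univariate_time(epochs: EpochsContainer, design: pd.DataFrame,
                         channels: Sequence[str] = ("Fz", "Pz"),
                         window: tuple[float, float] = (0.05, 0.5),
                         stride: int = 1,
                         fdr_level: float = 0.05,
                         analysis: str = "erp_time") -> MassUnivariateResult:
    """One LMM per (channel, timepoint); FDR family = timepoints x
    predictors, applied separately per channel."""
    _check_alignment(epochs.n_trials, design)
    groups = epochs.events["participant_id"].to_numpy()
    tmask = np.flatnonzero((epochs.times >= window[0] - 1e-9)
                           & (epochs.times <= window[1] + 1e-9))[::stride]
    rows, n_failed = [], 0
    for ch in channels:
        ci = epochs.channel_index(ch)
        for ti in tmask:
            y = epochs.data[:, ci, ti]
            try:
                fit = fit_lmm(y, design, groups)
            except ConvergenceError:
                n_failed += 1
                continue
            rows += _result_rows(fit, analysis, ch,
                                 float(epochs.times[ti]), np.nan)
    table = _apply_fdr(pd.DataFrame(rows, columns=RESULT_COLUMNS), True,
                       fdr_level)
    return MassUnivariateResult(table, family="timepoints x predictors, "
                                "per channel", fdr_level=fdr_level,
                                n_failed=n_failed)


def window_average(epochs: EpochsContainer, center: float,
                   width: float = 0.05) -> np.ndarray:
    """Trial x channel amplitudes averaged in a window around ``center``."""
    lo, hi = center - width / 2, center + width / 2
    if lo < epochs.times[0] - 1e-9 or hi > epochs.times[-1] + 1e-9:
        raise ValueError("window exceeds epoch bounds")
    mask = (epochs.times >= lo - 1e-9) & (epochs.times <= hi + 1e-9)
    return epochs.data[:, :, mask].mean(axis=-1)


def topography_windows(epochs: EpochsContainer, design: pd.DataFrame,
                       windows: Sequence[tuple[float, str]]
                       = DEFAULT_TOPO_WINDOWS,
                       width: float = 0.05,
                       fdr_level: float = 0.05) -> MassUnivariateResult:
    """Per-channel LMMs on window-averaged amplitude; FDR family = all
    channels x predictors x windows (one family).

    ``windows`` are (center latency, label) pairs, normally centered on the
    peak coefficient latencies of a prior time-resolved result.
    """
    _check_alignment(epochs.n_trials, design)
    groups = epochs.events["participant_id"].to_numpy()
    rows, n_failed = [], 0
    for center, label in windows:
        amps = window_average(epochs, center, width)
        for ci, ch in enumerate(epochs.channels):
            try:
                fit = fit_lmm(amps[:, ci], design, groups)
            except ConvergenceError:
                n_failed += 1
                continue
            rows += _result_rows(fit, f"topo[{label}]", ch, center, np.nan)
    table = _apply_fdr(pd.DataFrame(rows, columns=RESULT_COLUMNS), False,
                       fdr_level)
    return MassUnivariateResult(table, family="channels x predictors x "
                                "windows", fdr_level=fdr_level,
                                n_failed=n_failed)


def mass_univariate_tfr(tfr: TFRContainer, design: pd.DataFrame,
                        channels: Sequence[str] = ("Fz", "Pz"),
                        window: tuple[float, float] = (0.0, 0.5),
                        stride: int = 1,
                        fdr_level: float = 0.05,
                        analysis: str = "tfr") -> MassUnivariateResult:
    """One LMM per (time, frequency) cell; FDR family = timepoints x
    frequencies x predictors, per channel. ``stride`` subsamples the time
    grid (recorded in the analysis label)."""
    _check_alignment(tfr.power_db.shape[0], design)
    groups = tfr.events["participant_id"].to_numpy()
    tmask = np.flatnonzero((tfr.times >= window[0] - 1e-9)
                           & (tfr.times <= window[1] + 1e-9))[::stride]
    label = f"{analysis}[stride={stride}]"
    rows, n_failed = [], 0
    for ch in channels:
        ci = tfr.channel_index(ch)
        for fi, f in enumerate(tfr.freqs):
            for ti in tmask:
                y = tfr.power_db[:, ci, fi, ti]
                try:
                    fit = fit_lmm(y, design, groups)
                except ConvergenceError:
                    n_failed += 1
                    continue
                rows += _result_rows(fit, label, ch, float(tfr.times[ti]),
                                     float(f))
    table = _apply_fdr(pd.DataFrame(rows, columns=RESULT_COLUMNS), True,
                       fdr_level)
    return MassUnivariateResult(table, family="timepoints x frequencies x "
                                "predictors, per channel",
                                fdr_level=fdr_level, n_failed=n_failed)


def compare_models(epochs: EpochsContainer,
                   designs: Mapping[str, pd.DataFrame],
                   channel: str,
                   times: Sequence[float]) -> pd.DataFrame:
    """Per-timepoint AIC of each model variant relative to the
    intercept-only (random intercepts only) baseline.

    All variants must be fit on identical observations; the baseline's
    relative AIC is identically 0. Lower is better.
    """
    items = list(designs.items())
    idx0 = items[0][1].index
    for name, d in items[1:]:
        if not d.index.equals(idx0) or len(d) != len(items[0][1]):
            raise ValueError(
                f"variant {name!r} is not aligned with the others")
    _check_alignment(epochs.n_trials, items[0][1])
    groups = epochs.events["participant_id"].to_numpy()
    ci = epochs.channel_index(channel)
    rows = []
    for t_s in times:
        ti = int(np.argmin(np.abs(epochs.times - t_s)))
        y = epochs.data[:, ci, ti]
        base = fit_lmm(y, None, groups)
        rows.append(dict(channel=channel, time_s=float(epochs.times[ti]),
                         variant="baseline", aic=base.aic, rel_aic=0.0))
        for name, d in items:
            fit = fit_lmm(y, d, groups)
            rows.append(dict(channel=channel,
                             time_s=float(epochs.times[ti]), variant=name,
                             aic=fit.aic, rel_aic=fit.aic - base.aic))
    return pd.DataFrame(rows)


def split_by_valence(events: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean masks for the negative (easy loss, easy neutral, hard loss)
    and positive (easy win, hard win, hard neutral) outcome groups."""
    conds = condition_labels(events)
    return {
        "negative": conds.isin(NEGATIVE_CONDITIONS).to_numpy(),
        "positive": conds.isin(POSITIVE_CONDITIONS).to_numpy(),
    }


def valence_split_regression(data: EpochsContainer | TFRContainer,
                             features: pd.DataFrame,
                             analysis: str = "time",
                             **kwargs) -> dict[str, MassUnivariateResult]:
    """Run a mass-univariate analysis separately on negative and positive
    outcomes with only RPE magnitude and probability as predictors (the
    two-predictor design avoids collinearity with valenced terms)."""
    events = data.events
    _check_alignment(data.power_db.shape[0]
                     if isinstance(data, TFRContainer) else data.n_trials,
                     features)
    masks = split_by_valence(events)
    out = {}
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"empty {name}-outcome subset")
        sub = data.select_trials(mask)
        design = (features.loc[mask, VALENCE_SPLIT_PREDICTORS]
                  .reset_index(drop=True))
        if isinstance(data, TFRContainer):
            out[name] = mass_univariate_tfr(
                sub, design, analysis=f"tfr_{name}", **kwargs)
        elif analysis == "time":
            out[name] = mass_univariate_time(
                sub, design, analysis=f"erp_time_{name}", **kwargs)
        else:
            out[name] = topography_windows(sub, design, **kwargs)
    return out


def condition_average_features(trials: pd.DataFrame,
                               features: pd.DataFrame,
                               predictors: Sequence[str] | None = None
                               ) -> pd.DataFrame:
    """Average model predictors within condition for each participant
    (the predictor table used by point-estimate regressions)."""
    predictors = list(predictors or
                      ["expected_value", "rpe_value", "rpe_magnitude",
                       "outcome_probability"])
    df = trials.loc[features.index].copy()
    df["condition"] = condition_labels(df)
    merged = pd.concat([df[["participant_id", "condition"]],
                        features[predictors]], axis=1)
    return (merged.groupby(["participant_id", "condition"], observed=True)
            [predictors].mean().reset_index())


def point_estimate_regression(point_estimates: pd.DataFrame,
                              features_by_condition: pd.DataFrame,
                              metric: str,
                              fdr_level: float = 0.05) -> MixedModelResult:
    """Regress a per-participant x condition point estimate on
    condition-averaged predictors.

    Amplitude metrics use the mixed model with participant random
    intercepts; the normalized FRN latency uses a plain fixed-effects
    regression (latencies are already normalized within participant). Rows
    with a missing metric are dropped listwise. q-values (BH over the model
    predictors) are appended to ``params``.
    """
    merged = point_estimates.merge(features_by_condition,
                                   on=["participant_id", "condition"])
    merged = merged.dropna(subset=[metric])
    if merged.empty:
        raise ValueError(f"metric {metric!r} is missing everywhere")
    predictors = [c for c in features_by_condition.columns
                  if c not in ("participant_id", "condition")]
    design = merged[predictors].reset_index(drop=True)
    y = merged[metric].to_numpy(float)
    if metric == "frn_latency_norm_s":
        X = np.column_stack([np.ones(len(y)), design.to_numpy(float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(y) - X.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tval = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tval), dof)
        loglik = float(-0.5 * len(y) * (np.log(2 * np.pi * sigma2
                                               * dof / len(y)) + 1))
        params = pd.DataFrame(dict(beta=beta, se=se, t=tval, p=pval),
                              index=["intercept"] + predictors)
        result = MixedModelResult(
            params=params, sigma2_group=0.0, sigma2_resid=float(sigma2),
            loglik=loglik, aic=2.0 * (X.shape[1] + 1) - 2.0 * loglik,
            n_obs=len(y), n_groups=merged["participant_id"].nunique(),
            converged=True, dof_resid=dof)
    else:
        result = fit_lmm(y, design,
                         merged["participant_id"].to_numpy())
    mask = result.params.index != "intercept"
    q = np.full(len(result.params), np.nan)
    q[mask] = fdr_correct(result.params.loc[mask, "p"].to_numpy(),
                          fdr_level)
    result.params["q"] = q
    return result


def write_result(result: MassUnivariateResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def write_model_comparison(comparison: pd.DataFrame, path) -> None:
    comparison.to_csv(path, sep="\t", index=False)
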