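"""Behavioral model: win-probability logistic fit and prediction-error features.

The model assumes a participant's probability of winning a trial depends only
on the tolerance in force on that trial,

    p_win = 1 / (1 + exp(-(b0 + b1 * t))),

with t the tolerance in milliseconds. Expected value linearly maps p_win onto
the reward range [-1, 1] (EV = 2 p - 1); the reward prediction error is the
obtained reward minus EV, its absolute value is the RPE magnitude, and the
outcome probability is the empirical frequency of the trial's outcome class
within its difficulty. Alternative design matrices (outcome-only models and
accuracy-based expected-value controls) are built here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

DESIGN_VARIANTS = ("RL", "RL_noMag", "RL_noProb", "OutcomeValue",
                   "OutcomeValence", "EV_block", "EV_roll5", "EV_roll10")

RL_PREDICTORS = ["expected_value", "rpe_value", "rpe_magnitude",
                 "outcome_probability"]


class FitError(RuntimeError):
    """Raised when the logistic win model cannot be estimated."""


@dataclass(frozen=True)
class LogisticWinModel:
    """Fitted logistic win-probability model (per participant).

    ``beta1`` is in log-odds per millisecond of tolerance.
    """

    beta0: float
    beta1: float
    converged: bool
    log_likelihood: float
    beta0_se: float = np.nan
    beta1_se: float = np.nan

    def predict(self, tolerance_ms) -> np.ndarray | float:
        return predict_win_probability(self, tolerance_ms)


def _model_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Non-training, non-neutral trials used for the logistic fit."""
    keep = ~trials["is_training"] & (trials["outcome"] != "neutral")
    return trials.loc[keep]


def fit_win_probability(trials: pd.DataFrame) -> LogisticWinModel:
    """ML logistic regression of win (1) vs loss (0) on tolerance (ms).

    Training trials are excluded; neutral trials are excluded because they
    are delivered at random and carry no performance information.
    """
    df = _model_trials(trials)
    y = (df["outcome"] == "win").to_numpy(float)
    t = df["tolerance_ms"].to_numpy(float)
    if y.size and (y.min() == y.max()):
        raise FitError("all outcomes are the same class; "
                       "win probability is not identified")
    if np.unique(t).size < 2:
        raise FitError("need >= 2 distinct tolerances to fit a slope")
    X = sm.add_constant(t)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as err:  # statsmodels raises on perfect separation
        raise FitError(f"logistic fit failed: {err}") from err
    if not res.converged:
        raise FitError("logistic fit did not converge")
    # Quasi-perfect separation escapes statsmodels' check but yields wild
    # coefficients; flag it explicitly.
    if abs(res.params[1]) > 1.0:  # > 1 log-odds per ms is non-physiological
        raise FitError("near-perfect separation: slope diverged")
    return LogisticWinModel(
        beta0=float(res.params[0]), beta1=float(res.params[1]),
        converged=bool(res.converged), log_likelihood=float(res.llf),
        beta0_se=float(res.bse[0]), beta1_se=float(res.bse[1]))


def predict_win_probability(model: LogisticWinModel, tolerance_ms):
    """Evaluate the fitted logistic at the given tolerance(s) in ms."""
    t = np.asarray(tolerance_ms, float)
    p = 1.0 / (1.0 + np.exp(-(model.beta0 + model.beta1 * t)))
    return float(p) if p.ndim == 0 else p


def expected_value(p_win):
    """Linearly scale a win probability onto the reward range [-1, 1]."""
    p = np.asarray(p_win, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_win must be in [0, 1]")
    ev = 2.0 * p - 1.0
    return float(ev) if ev.ndim == 0 else ev


def _outcome_probability(df: pd.DataFrame) -> pd.Series:
    """Empirical frequency of each trial's outcome class within difficulty."""
    out = pd.Series(np.nan, index=df.index)
    for _, sub in df.groupby("difficulty", observed=True):
        counts = sub["outcome"].value_counts(normalize=True)
        out.loc[sub.index] = sub["outcome"].map(counts).to_numpy()
    return out


def compute_pe_features(trials: pd.DataFrame,
                        model: LogisticWinModel) -> pd.DataFrame:
    """Single-trial PE features for one participant's non-training trials.

    Neutral trials are excluded from the logistic *fit* but do receive
    features here: their EV follows from the trial's tolerance, so their RPE
    is negative in easy blocks (EV > 0) and positive in hard blocks (EV < 0).
    """
    df = trials.loc[~trials["is_training"]].copy()
    p = predict_win_probability(model, df["tolerance_ms"].to_numpy())
    ev = expected_value(p)
    reward = df["reward_value"].to_numpy(float)
    rpe = reward - ev
    feats = pd.DataFrame({
        "participant_id": df["participant_id"].to_numpy(),
        "trial_index": df["trial_index"].to_numpy(),
        "p_win": p,
        "expected_value": ev,
        "rpe_value": rpe,
        "rpe_magnitude": np.abs(rpe),
        "outcome_probability": _outcome_probability(df).to_numpy(),
    }, index=df.index)
    return feats


def pe_feature_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Fit the win model and compute PE features per participant; concat."""
    pieces = []
    for _, sub in trials.groupby("participant_id", sort=True):
        model = fit_win_probability(sub)
        pieces.append(compute_pe_features(sub, model))
    return pd.concat(pieces).sort_index()


def _rolling_accuracy(df: pd.DataFrame, window: int | None) -> np.ndarray:
    """Trailing win rate over non-neutral outcomes, causal, within block.

    ``window=None`` uses the whole block (block-level accuracy). Early trials
    use whatever history exists; the very first scored trial of a block falls
    back to the block's overall accuracy so every trial has a value.
    """
    out = np.full(len(df), np.nan)
    pos = {idx: i for i, idx in enumerate(df.index)}
    for _, blk in df.groupby(["participant_id", "block_index"], sort=False):
        scored = blk["outcome"] != "neutral"
        wins = (blk["outcome"] == "win").to_numpy(float)
        block_acc = wins[scored.to_numpy()].mean()
        if window is None:
            for idx in blk.index:
                out[pos[idx]] = block_acc
            continue
        hist: list[float] = []
        for idx, is_scored, w in zip(blk.index, scored.to_numpy(), wins):
            out[pos[idx]] = np.mean(hist[-window:]) if hist else block_acc
            if is_scored:
                hist.append(w)
    return out


def build_design(trials: pd.DataFrame, features: pd.DataFrame,
                 variant: str = "RL") -> pd.DataFrame:
    """Predictor table for one model variant, aligned to ``features`` rows.

    RL uses the four model-based predictors. OutcomeValue swaps the RL
    value/magnitude for raw outcome codes (value -1/0/+1; magnitude 0 for
    neutral, 1 otherwise). OutcomeValence instead treats neutral feedback as
    a valenced omission: losses and easy neutrals code -1, wins and hard
    neutrals +1. EV_block / EV_roll5 / EV_roll10 rebuild the RL predictors
    after replacing the single-trial win probability with block-level or
    trailing-window accuracy.
    """
    if variant not in DESIGN_VARIANTS:
        raise ValueError(f"unknown design variant: {variant!r}")
    df = trials.loc[features.index]
    if variant in ("RL", "RL_noMag", "RL_noProb"):
        design = features[RL_PREDICTORS].copy()
        if variant == "RL_noMag":
            design = design.drop(columns="rpe_magnitude")
        elif variant == "RL_noProb":
            design = design.drop(columns="outcome_probability")
        return design
    if variant in ("OutcomeValue", "OutcomeValence"):
        magnitude = (df["outcome"] != "neutral").astype(float)
        if variant == "OutcomeValue":
            first = df["reward_value"].astype(float).rename("value")
        else:
            valence = np.where(
                (df["outcome"] == "win")
                | ((df["outcome"] == "neutral") & (df["difficulty"] == "hard")),
                1.0, -1.0)
            first = pd.Series(valence, index=df.index, name="valence")
        return pd.DataFrame({
            first.name: first,
            "magnitude": magnitude,
            "outcome_probability": features["outcome_probability"],
        })
    window = {"EV_block": None, "EV_roll5": 5, "EV_roll10": 10}[variant]
    p = np.clip(_rolling_accuracy(df, window), 1e-6, 1 - 1e-6)
    ev = 2.0 * p - 1.0
    rpe = df["reward_value"].to_numpy(float) - ev
    return pd.DataFrame({
        "expected_value": ev,
        "rpe_value": rpe,
        "rpe_magnitude": np.abs(rpe),
        "outcome_probability": features["outcome_probability"],
    }, index=features.index)


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from regressing predictor j (with intercept) on the others.
    """
    X = predictors.to_numpy(float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) \
            < X.shape[1] + 1:
        raise ValueError(
            f"rank-deficient predictor set: {list(predictors.columns)}")
    out = {}
    for j, name in enumerate(predictors.columns):
        y = X[:, j]
        others = np.column_stack(
            [np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        out[name] = 1.0 / max(ss_res / ss_tot, 1e-12)
    return pd.Series(out, name="vif")


def apply_subjective_bias(features: pd.DataFrame, bias_easy: float,
                          bias_hard: float,
                          trials: pd.DataFrame) -> pd.DataFrame:
    """Recompute EV/RPE features from biased win probabilities.

    Models a participant whose subjective win probability differs from the
    objective model by a constant per difficulty; probabilities are clipped
    to (0, 1) before the EV mapping.
    """
    if not (-1 < bias_easy < 1 and -1 < bias_hard < 1):
        raise ValueError("biases must be in (-1, 1)")
    df = trials.loc[features.index]
    bias = np.where(df["difficulty"] == "easy", bias_easy, bias_hard)
    p = np.clip(features["p_win"].to_numpy() + bias, 1e-9, 1 - 1e-9)
    ev = 2.0 * p - 1.0
    rpe = df["reward_value"].to_numpy(float) - ev
    out = features.copy()
    out["p_win"] = p
    out["expected_value"] = ev
    out["rpe_value"] = rpe
    out["rpe_magnitude"] = np.abs(rpe)
    return out


def quantify_subjective_bias(ratings: pd.DataFrame,
                             probs: pd.Series | np.ndarray
                             ) -> tuple[pd.DataFrame, dict]:
    """Mean rating-minus-model bias per participant and difficulty, plus a
    two-sided comparison of within-cell z-scored ratings before wins vs
    losses.

    ``probs`` are model-based win probabilities aligned to ``ratings`` rows.
    Returns (bias table, comparison dict with t, df, p and the z-scored
    group means).
    """
    from scipy import stats

    df = ratings.copy()
    df["p_model"] = np.asarray(probs, float)
    df["bias"] = df["rating"] - df["p_model"]
    cell = df.groupby(["participant_id", "difficulty"], observed=True)
    if (cell["rating"].count() < 2).any():
        raise ValueError("need >= 2 ratings per participant x difficulty")
    bias = cell["bias"].mean().rename("mean_bias").reset_index()

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    df["z_rating"] = cell["rating"].transform(_z)
    z_win = df.loc[df["upcoming_outcome"] == "win", "z_rating"]
    z_loss = df.loc[df["upcoming_outcome"] == "loss", "z_rating"]
    t, p = stats.ttest_ind(z_win, z_loss)
    comparison = dict(
        t=float(t), p=float(p), dof=float(len(z_win) + len(z_loss) - 2),
        mean_z_before_win=float(z_win.mean()),
        mean_z_before_loss=float(z_loss.mean()))
    return bias, comparison


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
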