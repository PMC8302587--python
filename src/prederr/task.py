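"""Synthetic sessions for an adaptive interval-timing ("Target Time") task.

A simulated participant tries to press a button exactly 1 s after trial onset.
A response counts as a win when it lands within an adaptive tolerance window
around the target; two independent up-down staircases (one per difficulty)
titrate that tolerance so easy blocks clamp near 80 % wins and hard blocks
near 20 %. On a random subset of trials the outcome is replaced by neutral
feedback. The module also simulates a three-tone Oddball session and pre-
feedback subjective win-probability ratings, and reads/writes trial events as
TSV tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

EVENT_COLUMNS = [
    "participant_id", "trial_index", "block_index", "difficulty",
    "is_training", "tolerance_ms", "rt_s", "outcome", "reward_value", "iti_s",
]
ODDBALL_COLUMNS = ["participant_id", "trial_index", "condition", "rt_s"]


@dataclass(frozen=True)
class TaskConfig:
    """Structure and staircase parameters of a Target Time session.

    Defaults encode the task design: 35 training trials (5 intro, then 15
    easy- and 15 hard-staircase trials), eight 75-trial blocks (four easy and
    four hard in randomized order), neutral feedback on a random 12 % of main
    trials, tolerance steps of -3/+12 ms (easy) and -12/+3 ms (hard) after
    wins/losses, and tolerance bounds of 15-400 ms around the 1 s target.
    """

    n_training_intro: int = 5
    n_training_staircase_per_difficulty: int = 15
    n_blocks: int = 8
    trials_per_block: int = 75
    neutral_rate: float = 0.12
    iti_choices: tuple[float, ...] = (0.7, 1.0)
    target_interval: float = 1.0
    step_win_easy: float = -3.0
    step_loss_easy: float = 12.0
    step_win_hard: float = -12.0
    step_loss_hard: float = 3.0
    tol_min: float = 15.0
    tol_max: float = 400.0
    reward_points: int = 100
    # Starting tolerances for the intro/staircase training trials. The easy
    # start is deliberately wide; training under-titrates it (slow -3 ms
    # steps) so easy blocks begin above their staircase equilibrium.
    init_tolerance_easy: float = 300.0
    init_tolerance_hard: float = 100.0
    # Neutral-feedback trials do not drive the staircase by default
    # (feedback-driven titration); flip to update on the hidden outcome.
    neutral_updates_staircase: bool = False
    # By default each block restarts its staircase from the training-
    # calibrated level ("initialize both staircases to individual performance
    # levels"); set True to carry tolerance continuously across blocks.
    staircase_continuous: bool = False

    def __post_init__(self) -> None:
        if not self.tol_min < self.tol_max:
            raise ValueError("tol_min must be < tol_max")
        if not 0.0 <= self.neutral_rate < 1.0:
            raise ValueError("neutral_rate must be in [0, 1)")
        if self.n_blocks % 2:
            raise ValueError("n_blocks must be even (half easy, half hard)")

    @property
    def n_training(self) -> int:
        return (self.n_training_intro
                + 2 * self.n_training_staircase_per_difficulty)

    @property
    def n_main(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class AgentSpec:
    """Stochastic response model standing in for a participant.

    RTs are Gaussian around ``rt_mean`` with per-trial time-on-task
    deterioration: the mean slows by ``drift_per_trial`` seconds per trial and
    the SD grows by the fraction ``sd_growth_per_trial`` per trial. On a
    ``lapse_rate`` fraction of trials the response is instead uniform over
    ``lapse_range`` (attentional lapse). No trial-level learning is modeled.
    """

    rt_mean: float = 1.0
    rt_sd: float = 0.115
    drift_per_trial: float = 5e-4
    sd_growth_per_trial: float = 4e-4
    lapse_rate: float = 0.02
    lapse_range: tuple[float, float] = (0.6, 1.4)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rt_sd <= 0:
            raise ValueError("rt_sd must be > 0")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must be in [0, 1)")


@dataclass(frozen=True)
class PopulationSpec:
    """Distributions from which a cohort's AgentSpecs are drawn.

    Timing noise spans typical human Weber fractions for a 1 s interval
    (8-15 %). Drift and SD-growth magnitudes were calibrated once so that the
    staircase dynamics reproduce the task's reported group accuracy clamps
    (~82.7 % easy, ~18.1 % hard); see the methods note.
    """

    rt_mean: float = 1.0
    rt_sd_range: tuple[float, float] = (0.08, 0.15)
    drift_mean: float = 5e-4
    drift_sd: float = 1e-4
    sd_growth: float = 4e-4
    lapse_rate: float = 0.02


@dataclass
class StaircaseState:
    tolerance: float
    difficulty: str


@dataclass(frozen=True)
class OddballConfig:
    """Three-tone Oddball session: 10 training trials, 3 x 130 main trials."""

    n_training: int = 10
    n_blocks: int = 3
    trials_per_block: int = 130
    p_standard: float = 0.755
    p_target: float = 0.1225
    p_novel: float = 0.1225
    rt_mean: float = 0.364
    rt_sd: float = 0.063

    def __post_init__(self) -> None:
        total = self.p_standard + self.p_target + self.p_novel
        if abs(total - 1.0) > 1e-9:
            raise ValueError("condition probabilities must sum to 1")

    @property
    def n_main(self) -> int:
        return self.n_blocks * self.trials_per_block


def step_tolerance(state: StaircaseState, outcome: str,
                   config: TaskConfig | None = None) -> StaircaseState:
    """Apply one staircase update and clamp to the configured bounds.

    Wins tighten and losses widen the tolerance by the difficulty-specific
    step; neutral feedback leaves the staircase untouched.
    """
    config = config or TaskConfig()
    if state.difficulty not in ("easy", "hard"):
        raise ValueError(f"unknown difficulty: {state.difficulty!r}")
    if outcome not in ("win", "loss", "neutral"):
        raise ValueError(f"unknown outcome: {outcome!r}")
    if outcome == "neutral":
        return StaircaseState(state.tolerance, state.difficulty)
    steps = {
        ("easy", "win"): config.step_win_easy,
        ("easy", "loss"): config.step_loss_easy,
        ("hard", "win"): config.step_win_hard,
        ("hard", "loss"): config.step_loss_hard,
    }
    tol = state.tolerance + steps[(state.difficulty, outcome)]
    tol = min(config.tol_max, max(config.tol_min, tol))
    return StaircaseState(tol, state.difficulty)


class _Agent:
    """Stateful sampler for one agent's RTs and analytic win probabilities."""

    def __init__(self, spec: AgentSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.t = 0

    def _moments(self) -> tuple[float, float]:
        s = self.spec
        mean = s.rt_mean + s.drift_per_trial * self.t
        sd = s.rt_sd * (1.0 + s.sd_growth_per_trial * self.t)
        return mean, sd

    def draw_rt(self) -> float:
        self.t += 1
        mean, sd = self._moments()
        if self.rng.random() < self.spec.lapse_rate:
            lo, hi = self.spec.lapse_range
            return float(self.rng.uniform(lo, hi))
        return float(self.rng.normal(mean, sd))

    def win_probability(self, tolerance_ms: float, target: float) -> float:
        """P(|RT - target| <= tolerance) for the *next* trial."""
        s = self.spec
        mean = s.rt_mean + s.drift_per_trial * (self.t + 1)
        sd = s.rt_sd * (1.0 + s.sd_growth_per_trial * (self.t + 1))
        tol = tolerance_ms / 1000.0
        lo, hi = target - tol, target + tol
        p_gauss = norm.cdf(hi, mean, sd) - norm.cdf(lo, mean, sd)
        llo, lhi = s.lapse_range
        overlap = max(0.0, min(hi, lhi) - max(lo, llo))
        p_lapse = overlap / (lhi - llo)
        return float((1 - s.lapse_rate) * p_gauss + s.lapse_rate * p_lapse)


def simulate_session(agent: AgentSpec | None = None,
                     config: TaskConfig | None = None,
                     seed: int | None = None,
                     participant_id: str = "p000") -> pd.DataFrame:
    """Simulate one full Target Time session.

    Returns one row per trial (35 training + n_blocks x trials_per_block main
    trials) with the canonical event columns plus ``p_win_true``, the agent's
    analytic win probability at that trial's tolerance (used by the ratings
    simulator; dropped when writing the events TSV).
    """
    agent = agent or AgentSpec()
    config = config or TaskConfig()
    if seed is None:
        seed = agent.seed
    rng = np.random.default_rng(seed)
    sampler = _Agent(agent, rng)
    target = config.target_interval

    stair = {
        "easy": StaircaseState(config.init_tolerance_easy, "easy"),
        "hard": StaircaseState(config.init_tolerance_hard, "hard"),
    }
    rows: list[dict] = []
    trial_index = 0

    def run_trial(difficulty: str, block_index: int, is_training: bool,
                  staircased: bool) -> None:
        nonlocal trial_index
        state = stair[difficulty]
        tol = state.tolerance
        p_true = sampler.win_probability(tol, target)
        rt = sampler.draw_rt()
        hidden_win = abs(rt - target) <= tol / 1000.0
        neutral = (not is_training) and rng.random() < config.neutral_rate
        if neutral:
            outcome, reward = "neutral", 0
        else:
            outcome = "win" if hidden_win else "loss"
            reward = 1 if hidden_win else -1
        iti = float(rng.choice(config.iti_choices))
        rows.append(dict(
            participant_id=participant_id, trial_index=trial_index,
            block_index=block_index, difficulty=difficulty,
            is_training=is_training, tolerance_ms=tol, rt_s=rt,
            outcome=outcome, reward_value=reward, iti_s=iti,
            p_win_true=p_true,
        ))
        trial_index += 1
        if staircased:
            if neutral and not config.neutral_updates_staircase:
                return
            stair[difficulty] = step_tolerance(
                state, "win" if hidden_win else "loss", config)

    for _ in range(config.n_training_intro):
        run_trial("easy", -1, True, staircased=False)
    for _ in range(config.n_training_staircase_per_difficulty):
        run_trial("easy", -1, True, staircased=True)
    for _ in range(config.n_training_staircase_per_difficulty):
        run_trial("hard", -1, True, staircased=True)

    init = {d: stair[d].tolerance for d in stair}
    half = config.n_blocks // 2
    blocks = np.array(["easy"] * half + ["hard"] * half)
    rng.shuffle(blocks)
    for b, difficulty in enumerate(blocks):
        if not config.staircase_continuous:
            stair[difficulty] = StaircaseState(init[difficulty], difficulty)
        for _ in range(config.trials_per_block):
            run_trial(difficulty, b, False, staircased=True)

    return pd.DataFrame(rows)


def simulate_cohort(n_participants: int,
                    population: PopulationSpec | None = None,
                    config: TaskConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate a cohort; one concatenated trial table.

    Seeding: ``SeedSequence(seed)`` is split into one population stream (agent
    parameter draws, in participant order) followed by one sub-stream per
    participant session; this stream order is part of the interface.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    population = population or PopulationSpec()
    config = config or TaskConfig()
    children = np.random.SeedSequence(seed).spawn(n_participants + 1)
    pop_rng = np.random.default_rng(children[0])
    sessions = []
    for i in range(n_participants):
        agent = AgentSpec(
            rt_mean=population.rt_mean,
            rt_sd=float(pop_rng.uniform(*population.rt_sd_range)),
            drift_per_trial=float(pop_rng.normal(population.drift_mean,
                                                 population.drift_sd)),
            sd_growth_per_trial=population.sd_growth,
            lapse_rate=population.lapse_rate,
        )
        sessions.append(simulate_session(
            agent, config, seed=children[i + 1],
            participant_id=f"p{i:03d}"))
    return pd.concat(sessions, ignore_index=True)


def simulate_oddball_session(config: OddballConfig | None = None,
                             seed: int | None = None,
                             participant_id: str = "p000") -> pd.DataFrame:
    """Simulate one Oddball session (training + main trials).

    Conditions are drawn i.i.d. with the configured probabilities; simulated
    button presses (Gaussian RTs) occur on target trials only.
    """
    config = config or OddballConfig()
    rng = np.random.default_rng(seed)
    n = config.n_training + config.n_main
    conds = rng.choice(["standard", "target", "novel"], size=n,
                       p=[config.p_standard, config.p_target, config.p_novel])
    rts = np.full(n, np.nan)
    is_target = conds == "target"
    rts[is_target] = np.maximum(
        rng.normal(config.rt_mean, config.rt_sd, is_target.sum()), 0.05)
    return pd.DataFrame(dict(
        participant_id=participant_id, trial_index=np.arange(n),
        condition=conds, rt_s=rts,
        is_training=np.arange(n) < config.n_training,
    ))


def simulate_ratings(session: pd.DataFrame,
                     bias_easy: float = -0.10,
                     bias_hard: float = 0.10,
                     noise_sd: float = 0.10,
                     every_k: int = 3,
                     seed: int | None = None) -> pd.DataFrame:
    """Subjective win-probability ratings on every k-th main trial.

    Each rating is the agent's true win probability for that trial plus a
    difficulty-specific bias and Gaussian noise, clipped to [0, 1]; it is
    emitted before feedback, so the paired ``upcoming_outcome`` is the win or
    loss implied by the response alone (neutral feedback notwithstanding).
    Defaults place the biases in the direction reported for this task:
    underestimation in easy and overestimation in hard blocks.
    """
    if not (-1 < bias_easy < 1 and -1 < bias_hard < 1):
        raise ValueError("biases must be in (-1, 1)")
    if every_k < 1:
        raise ValueError("every_k must be >= 1")
    rng = np.random.default_rng(seed)
    main = session.loc[~session["is_training"]].reset_index(drop=True)
    rows = []
    for i in range(every_k - 1, len(main), every_k):
        tr = main.iloc[i]
        bias = bias_easy if tr["difficulty"] == "easy" else bias_hard
        rating = tr["p_win_true"] + bias + rng.normal(0.0, noise_sd)
        won = abs(tr["rt_s"] - 1.0) <= tr["tolerance_ms"] / 1000.0
        rows.append(dict(
            participant_id=tr["participant_id"],
            trial_index=int(tr["trial_index"]),
            rating=float(np.clip(rating, 0.0, 1.0)),
            upcoming_outcome="win" if won else "loss",
            difficulty=tr["difficulty"],
        ))
    return pd.DataFrame(rows)


def block_accuracy(trials: pd.DataFrame,
                   rt_bounds: tuple[float, float] | None = None
                   ) -> pd.DataFrame:
    """Per-participant win rate over non-neutral main trials, by difficulty.

    ``rt_bounds`` optionally applies the behavioral RT screen before counting.
    """
    df = trials.loc[~trials["is_training"] & (trials["outcome"] != "neutral")]
    if rt_bounds is not None:
        lo, hi = rt_bounds
        df = df.loc[(df["rt_s"] >= lo) & (df["rt_s"] <= hi)]
    acc = (df.assign(win=(df["outcome"] == "win").astype(float))
             .groupby(["participant_id", "difficulty"], observed=True)["win"]
             .mean().rename("accuracy").reset_index())
    return acc


def write_events(trials: pd.DataFrame, path) -> None:
    """Write the canonical trial-event TSV (UTF-8, tab-separated, header)."""
    trials[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_training"] = df["is_training"].astype(bool)
    return df


def write_oddball_events(trials: pd.DataFrame, path) -> None:
    trials[ODDBALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_oddball_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
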