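"""Stop-signal task engine.

Implements the stop-signal paradigm used to measure response inhibition:
interleaved go and stop trials, a dual staircase that adapts the
stop-signal delay (SSD) in 50-ms steps so that stopping succeeds on about
half of the stop trials, a horse-race simulator for synthetic subjects,
and the median-method SSRT estimator

    SSRT = median(go RT) - median(SSD).

The horse-race model assumes an independent go process and stop process;
a response is emitted on a stop trial iff the go process finishes before
the stop process, i.e. iff go_finish_time <= SSD + SSRT_true.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

__all__ = [
    "TrialPlan",
    "StaircaseState",
    "RaceModelParams",
    "SubjectBehavior",
    "BehavioralSummary",
    "build_trial_sequence",
    "staircase_update",
    "simulate_subject",
    "estimate_ssrt",
    "behavior_to_frame",
]

ISI_RANGE_MS = (1300.0, 4800.0)


@dataclass(frozen=True)
class TrialPlan:
    """An ordered sequence of go/stop trials grouped into blocks."""

    blocks: int
    trials_per_block: int
    stop_per_block: int
    trial_types: np.ndarray  # array of "go" / "stop", length blocks*trials_per_block
    isi_ms: np.ndarray  # per-trial inter-stimulus interval, ms

    @property
    def n_trials(self) -> int:
        return self.blocks * self.trials_per_block

    @property
    def n_stop_trials(self) -> int:
        return self.blocks * self.stop_per_block


@dataclass(frozen=True)
class StaircaseState:
    """One up/down SSD staircase (50-ms steps, clamped to [0, 800] ms)."""

    ssd_ms: float
    step_ms: float = 50.0
    lower_ms: float = 0.0
    upper_ms: float = 800.0
    start_ms: float = 150.0

    def __post_init__(self) -> None:
        if not (self.lower_ms <= self.ssd_ms <= self.upper_ms):
            raise ValueError(
                f"ssd_ms={self.ssd_ms} outside clamp bounds "
                f"[{self.lower_ms}, {self.upper_ms}]"
            )


@dataclass(frozen=True)
class RaceModelParams:
    """Horse-race subject: ex-Gaussian go RT and a constant stop latency.

    The go-RT distribution is ex-Gaussian(mu, sigma, tau) in ms — the
    standard parametric family for response times (mean = mu + tau).
    Defaults approximate the behavioral profile of a healthy middle-aged
    adult: mean go RT ~675 ms, ~2% wrong-key presses, ~11% omissions.
    """

    mu_ms: float = 500.0
    sigma_ms: float = 50.0
    tau_ms: float = 175.0
    true_ssrt_ms: float = 300.0
    omission_rate: float = 0.1124
    choice_error_rate: float = 0.0207

    def __post_init__(self) -> None:
        for name in ("mu_ms", "sigma_ms", "tau_ms", "true_ssrt_ms"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite race-model parameter {name}={v}")
        if self.sigma_ms < 0 or self.tau_ms < 0:
            raise ValueError("sigma_ms and tau_ms must be non-negative")
        if self.true_ssrt_ms <= 0:
            raise ValueError("true_ssrt_ms must be positive")
        for name in ("omission_rate", "choice_error_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")

    def sample_go_rt(self, rng: np.random.Generator, size: int | None = None):
        """Ex-Gaussian draw(s): Normal(mu, sigma) + Exp(tau)."""
        return (
            rng.normal(self.mu_ms, self.sigma_ms, size)
            + rng.exponential(self.tau_ms, size)
            if self.tau_ms > 0
            else rng.normal(self.mu_ms, self.sigma_ms, size)
        )

    def go_finish_cdf(self, t_ms: np.ndarray | float) -> np.ndarray | float:
        """Analytic CDF of the go finishing time (ex-Gaussian)."""
        from scipy import stats

        return stats.exponnorm.cdf(
            t_ms, K=self.tau_ms / self.sigma_ms, loc=self.mu_ms, scale=self.sigma_ms
        )


@dataclass
class SubjectBehavior:
    """Per-trial records of one simulated (or observed) subject."""

    trial_index: np.ndarray
    block: np.ndarray
    trial_type: np.ndarray  # "go" | "stop"
    staircase: np.ndarray  # 0/1 for stop trials, -1 for go trials
    ssd_ms: np.ndarray  # NaN on go trials
    responded: np.ndarray  # bool
    rt_ms: np.ndarray  # NaN when no response
    correct: np.ndarray  # go: right key pressed; stop: successful inhibition

    def __len__(self) -> int:
        return len(self.trial_index)


@dataclass(frozen=True)
class BehavioralSummary:
    """Per-subject behavioral summary; ssrt_ms = median go RT − median SSD."""

    median_go_rt_ms: float
    median_ssd_ms: float
    stop_success_rate: float  # percent
    ssrt_ms: float
    go_accuracy_pct: float
    omission_pct: float


def build_trial_sequence(
    blocks: int, trials_per_block: int, stop_per_block: int, seed: int
) -> TrialPlan:
    """Build a trial plan with stop positions shuffled uniformly per block.

    Each block holds exactly ``stop_per_block`` stop trials among
    ``trials_per_block`` total; ISIs are drawn uniformly on [1300, 4800] ms.
    Deterministic given ``seed``.
    """
    if blocks < 1 or trials_per_block < 1:
        raise ValueError("blocks and trials_per_block must be >= 1")
    if stop_per_block < 0 or stop_per_block > trials_per_block:
        raise ValueError(
            f"stop_per_block={stop_per_block} exceeds trials_per_block={trials_per_block}"
        )
    rng = np.random.default_rng(seed)
    types = []
    for _ in range(blocks):
        block = np.array(
            ["go"] * (trials_per_block - stop_per_block) + ["stop"] * stop_per_block
        )
        types.append(rng.permutation(block))
    trial_types = np.concatenate(types)
    isi = rng.uniform(*ISI_RANGE_MS, size=trial_types.size)
    return TrialPlan(blocks, trials_per_block, stop_per_block, trial_types, isi)


def staircase_update(state: StaircaseState, stop_succeeded: bool) -> StaircaseState:
    """Step the SSD up after a successful stop, down after a failed one.

    Successful inhibition makes the next stop harder (+50 ms); a failure
    makes it easier (−50 ms). The SSD is clamped to [lower_ms, upper_ms].
    """
    delta = state.step_ms if stop_succeeded else -state.step_ms
    new_ssd = float(np.clip(state.ssd_ms + delta, state.lower_ms, state.upper_ms))
    return replace(state, ssd_ms=new_ssd)


def simulate_subject(
    params: RaceModelParams, plan: TrialPlan, seed: int
) -> SubjectBehavior:
    """Run one subject through a trial plan under the horse-race model.

    Stop trials alternate strictly between two staircases starting at 150
    and 350 ms. On a stop trial the sampled go finishing time races the
    stop process: a response is emitted iff it is not an omission and the
    go process finishes by SSD + true SSRT. Deterministic given ``seed``.
    """
    if plan.n_trials == 0:
        raise ValueError("empty trial plan")
    rng = np.random.default_rng(seed)
    n = plan.n_trials
    staircases = [
        StaircaseState(ssd_ms=150.0, start_ms=150.0),
        StaircaseState(ssd_ms=350.0, start_ms=350.0),
    ]
    sc_id = np.full(n, -1, dtype=int)
    ssd = np.full(n, np.nan)
    responded = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)
    correct = np.zeros(n, dtype=bool)
    block = np.repeat(np.arange(plan.blocks), plan.trials_per_block)

    stop_count = 0
    for i, ttype in enumerate(plan.trial_types):
        omitted = rng.random() < params.omission_rate
        go_time = params.sample_go_rt(rng)
        if ttype == "go":
            if not omitted:
                responded[i] = True
                rt[i] = go_time
                correct[i] = rng.random() >= params.choice_error_rate
        else:
            k = stop_count % 2  # strict alternation between the two staircases
            stop_count += 1
            sc_id[i] = k
            ssd[i] = staircases[k].ssd_ms
            go_wins = (not omitted) and go_time <= ssd[i] + params.true_ssrt_ms
            if go_wins:
                responded[i] = True
                rt[i] = go_time
            correct[i] = not go_wins  # successful inhibition
            staircases[k] = staircase_update(staircases[k], stop_succeeded=not go_wins)

    return SubjectBehavior(
        trial_index=np.arange(n),
        block=block,
        trial_type=plan.trial_types.copy(),
        staircase=sc_id,
        ssd_ms=ssd,
        responded=responded,
        rt_ms=rt,
        correct=correct,
    )


def estimate_ssrt(behavior: SubjectBehavior) -> BehavioralSummary:
    """Median-method SSRT: median go RT minus median SSD over stop trials.

    The go-RT median is taken over responded go trials (omissions carry no
    RT and are excluded; wrong-key presses carry an RT and are included);
    the SSD median over all stop trials.
    """
    is_go = behavior.trial_type == "go"
    is_stop = ~is_go
    go_rts = behavior.rt_ms[is_go & behavior.responded]
    ssds = behavior.ssd_ms[is_stop]
    if go_rts.size == 0 or ssds.size == 0:
        raise ValueError(
            "insufficient trials: need >=1 responded go trial and >=1 stop trial"
        )
    median_go = float(np.median(go_rts))
    median_ssd = float(np.median(ssds))
    n_go = int(is_go.sum())
    n_stop = int(is_stop.sum())
    return BehavioralSummary(
        median_go_rt_ms=median_go,
        median_ssd_ms=median_ssd,
        stop_success_rate=100.0 * float(behavior.correct[is_stop].mean()),
        ssrt_ms=median_go - median_ssd,
        go_accuracy_pct=100.0 * float(behavior.correct[is_go].sum() / n_go),
        omission_pct=100.0 * float((~behavior.responded[is_go]).sum() / n_go),
    )


def behavior_to_frame(behavior: SubjectBehavior) -> pd.DataFrame:
    """Tabular (TSV-ready) view of a subject's trial records."""
    return pd.DataFrame(
        {
            "trial_index": behavior.trial_index,
            "block": behavior.block,
            "type": behavior.trial_type,
            "staircase": behavior.staircase,
            "ssd_ms": behavior.ssd_ms,
            "responded": behavior.responded,
            "rt_ms": behavior.rt_ms,
            "correct": behavior.correct,
        }
    )
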