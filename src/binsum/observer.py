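"""Synthetic 2AFC observer, adaptive staircases and psychometric analysis.

The simulated listener implements the signal-detection link between the
combination model and percent-correct performance: each interval's model
response is perturbed by late additive Gaussian noise of standard
deviation ``sigma40``, and the listener picks the interval with the larger
noisy response.  Hence

    P(correct) = Phi(delta_resp / (sigma40 * sqrt(2)))

where ``delta_resp`` is the response difference between the signal and
standard intervals.  At ``delta_resp = sigma40`` this gives
Phi(1/sqrt 2) ~= 0.760, so the model-side threshold criterion (one
criterion step of response) and the psychophysical 75 percent-correct
threshold coincide to within a percentage point.

The experimental procedure mirrors the study design: pairs of 3-down-1-up
staircases with 3 dB steps (dB = 20*log10(percent depth)), terminating at
the lesser of 70 trials or 12 reversals, three repetitions per listener,
thresholds from a cumulative log-Gaussian (probit) fit to trials pooled
across repetitions, read off at 75 percent correct.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .model import interval_response, to_db, from_db, increment_threshold
from .params import ModelParams
from .stimuli import PSYCH_CONDITIONS, PsychCondition, psych_intervals

__all__ = [
    "StaircaseConfig",
    "TrialRecord",
    "PsychometricFit",
    "DipperDataset",
    "prob_correct_2afc",
    "run_staircase",
    "run_staircase_pair",
    "pool_fit_probit",
    "reversal_levels",
    "simulate_experiment",
    "PEDESTALS",
    "POOLED_DETECTION",
]

logger = logging.getLogger(__name__)

#: pedestal modulation depths of the study design (percent, 100*m)
PEDESTALS = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)

#: condition label under which mon/dich/half_bin detection data are pooled
POOLED_DETECTION = "detect_pooled"

_MAX_TARGET_PCT = 100.0  # physical ceiling: full modulation
_SQRT2 = math.sqrt(2.0)
_MAX_TARGET_DB = 40.0


@dataclass(frozen=True)
class StaircaseConfig:
    """3-down-1-up staircase settings (defaults follow the study design)."""

    step_db: float = 3.0
    max_trials: int = 70
    max_reversals: int = 12
    n_staircases: int = 2
    #: staircase starting level relative to the observer's analytic
    #: threshold (the published design does not state starting levels)
    start_above_db: float = 20.0

    def __post_init__(self) -> None:
        if self.step_db <= 0:
            raise ValueError("step_db must be > 0")
        if self.max_trials < 1 or self.max_reversals < 1:
            raise ValueError("termination limits must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    condition: str
    pedestal: float
    target: float
    target_db: float
    correct: bool
    repetition: int
    staircase_id: int


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative log-Gaussian (probit) fit, P(x) = 0.5 + 0.5*Phi((x-mu)/sd).

    ``x`` is the target level in dB; with the 2AFC guessing floor of 0.5
    the 75 percent-correct point is exactly ``mu``.
    """

    mu: float
    sd: float
    n_trials: int

    @property
    def threshold75(self) -> float:
        return self.mu

    def predict(self, x_db):
        return 0.5 + 0.5 * norm.cdf((np.asarray(x_db, float) - self.mu) / self.sd)


class DipperDataset:
    """Discrimination thresholds (dB) indexed by condition x pedestal.

    The mon/dich/half_bin detection cells are pooled into a single
    ``detect_pooled`` row, because at pedestal 0 those three arrangements
    are the identical stimulus.  ``df`` columns: condition, pedestal_pct,
    threshold_db, n_trials.
    """

    def __init__(self, df: pd.DataFrame, n_participants: int, seed: Optional[int] = None):
        required = {"condition", "pedestal_pct", "threshold_db", "n_trials"}
        if not required.issubset(df.columns):
            raise ValueError(f"dataset needs columns {sorted(required)}")
        self.df = df.reset_index(drop=True)
        self.n_participants = int(n_participants)
        self.seed = seed

    def threshold(self, condition: str, pedestal: float) -> float:
        cond = str(getattr(condition, "value", condition))
        if pedestal == 0 and cond in ("mon", "dich", "half_bin"):
            cond = POOLED_DETECTION
        sel = self.df[
            (self.df.condition == cond) & (self.df.pedestal_pct == pedestal)
        ]
        if sel.empty:
            raise KeyError(f"no threshold for {cond}@{pedestal}")
        return float(sel.threshold_db.iloc[0])

    @property
    def pedestals(self) -> np.ndarray:
        return np.sort(self.df.pedestal_pct.unique())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_participants: int = 1, seed=None) -> "DipperDataset":
        return cls(pd.read_csv(path), n_participants, seed)

    def __eq__(self, other) -> bool:
        return isinstance(other, DipperDataset) and self.df.equals(other.df)


def prob_correct_2afc(delta_resp, params: ModelParams) -> float | np.ndarray:
    """Probability of a correct 2AFC response given the response difference."""
    d = np.asarray(delta_resp, dtype=float)
    out = norm.cdf(d / (params.sigma40 * np.sqrt(2.0)))
    return out if out.ndim else float(out)


def _observer_p_correct(
    condition, pedestal: float, target_pct: float, params: ModelParams, model: str
) -> float:
    std, sig = psych_intervals(condition, pedestal, target_pct)
    delta = interval_response(*sig, params, model) - interval_response(*std, params, model)
    return prob_correct_2afc(delta, params)


def make_observer(condition, pedestal: float, params: ModelParams, model: str = "gain"):
    """Fast scalar observer for one cell: target percent -> P(correct).

    Equivalent to :func:`_observer_p_correct` but in plain float
    arithmetic, since the staircase loop calls it once per trial.
    """
    from .stimuli import psych_increment_spec

    (L0, R0), (aL, aR) = psych_increment_spec(condition, pedestal)
    p, q, Z = params.p, params.q, params.Z
    Zq = Z**q
    w = params.omega
    denom = params.sigma40 * math.sqrt(2.0)

    if model == "linear":
        s0 = L0 + R0
        base = s0**p / (Zq + s0**q)
        a = aL + aR

        def observer(t: float) -> float:
            s = s0 + a * t
            delta = s**p / (Zq + s**q) - base
            return 0.5 * (1.0 + math.erf(delta / denom / _SQRT2))

        return observer

    def resp(cl: float, cr: float) -> float:
        clq = cl**q
        crq = cr**q
        r = 0.0
        if cl > 0.0:
            r += cl**p / (Zq + clq + w * crq)
        if cr > 0.0:
            r += cr**p / (Zq + crq + w * clq)
        return r

    base = resp(L0, R0)

    def observer(t: float) -> float:
        delta = resp(L0 + aL * t, R0 + aR * t) - base
        return 0.5 * (1.0 + math.erf(delta / denom / _SQRT2))

    return observer


def run_staircase(
    condition: PsychCondition | str,
    pedestal: float,
    cfg: StaircaseConfig,
    observer,
    rng: np.random.Generator,
    start_db: float,
    repetition: int = 0,
    staircase_id: int = 0,
) -> list[TrialRecord]:
    """Run one 3-down-1-up staircase against a stochastic observer.

    ``observer(target_pct)`` returns the probability of a correct
    response at that target level.  The level drops one step after every
    third consecutive correct response and rises one step after every
    error; reversals are direction changes of the level track.  The run
    stops at whichever of ``max_trials`` / ``max_reversals`` comes first.
    Levels are clipped at 100 percent modulation (with a warning) and the
    clipped trials are retained in the log.
    """
    level_db = float(start_db)
    trials: list[TrialRecord] = []
    streak = 0
    reversals = 0
    clipped = 0
    last_direction = 0  # -1 down, +1 up
    while len(trials) < cfg.max_trials and reversals < cfg.max_reversals:
        if level_db > _MAX_TARGET_DB:
            clipped += 1
            level_db = _MAX_TARGET_DB
        target = float(from_db(level_db))
        p = observer(target)
        correct = bool(rng.random() < p)
        trials.append(
            TrialRecord(
                condition=str(getattr(condition, "value", condition)),
                pedestal=float(pedestal),
                target=target,
                target_db=level_db,
                correct=correct,
                repetition=repetition,
                staircase_id=staircase_id,
            )
        )
        if correct:
            streak += 1
            if streak == 3:
                streak = 0
                direction = -1
                if last_direction == +1:
                    reversals += 1
                last_direction = direction
                level_db -= cfg.step_db
        else:
            streak = 0
            direction = +1
            if last_direction == -1:
                reversals += 1
            last_direction = direction
            level_db += cfg.step_db
    if clipped:
        logger.warning(
            "staircase %s @ pedestal %g: level clipped to 100%% modulation "
            "on %d trial(s)",
            getattr(condition, "value", condition), pedestal, clipped,
        )
    return trials


def run_staircase_pair(
    condition,
    pedestal: float,
    cfg: StaircaseConfig,
    observer,
    rng: np.random.Generator,
    start_db: float,
    repetition: int = 0,
) -> list[TrialRecord]:
    """Run a pair of independent staircases for one condition/pedestal cell.

    Each staircase keeps its own level, streak and reversal count and
    terminates independently.  In the booth the pair is interleaved
    trial-by-trial; here each runs on a deterministically split random
    substream, which produces the same per-staircase trajectories and the
    same pooled trial log (the probit analysis is order-invariant).
    """
    children = rng.spawn(cfg.n_staircases)
    out: list[TrialRecord] = []
    for sc_id, child in enumerate(children):
        out.extend(
            run_staircase(
                condition, pedestal, cfg, observer, child, start_db, repetition, sc_id
            )
        )
    return out


def reversal_levels(trials: Sequence[TrialRecord], step_db: float = 3.0) -> list[float]:
    """Levels (dB) at which a single staircase's track changed direction.

    Replays the 3-down-1-up bookkeeping over one staircase's trial log
    (in presentation order); the reversal level is the level of the trial
    that triggered the direction change.
    """
    streak = 0
    last_direction = 0
    out: list[float] = []
    for t in trials:
        if t.correct:
            streak += 1
            if streak == 3:
                streak = 0
                if last_direction == +1:
                    out.append(t.target_db)
                last_direction = -1
        else:
            streak = 0
            if last_direction == -1:
                out.append(t.target_db)
            last_direction = +1
    return out


def pool_fit_probit(trials: Sequence[TrialRecord]) -> PsychometricFit:
    """Probit threshold from a pooled trial log.

    Groups trials by target level (dB), then fits
    ``P(x) = 0.5 + 0.5*Phi((x - mu)/sd)`` by maximum binomial likelihood.
    Raises ``ValueError`` on degenerate data (fewer than two distinct
    levels, or all responses identical) where the location is
    non-identifiable.
    """
    if not trials:
        raise ValueError("no trials to fit")
    x = np.array([round(t.target_db, 9) for t in trials])
    c = np.array([t.correct for t in trials], dtype=float)
    levels, inv = np.unique(x, return_inverse=True)
    n_per = np.bincount(inv)
    k_per = np.bincount(inv, weights=c)
    if levels.size < 2:
        raise ValueError("need >= 2 distinct target levels for a probit fit")
    if k_per.sum() == 0 or k_per.sum() == n_per.sum():
        raise ValueError(
            "degenerate trial log (all correct or all wrong): threshold non-identifiable"
        )

    def nll(theta):
        mu, log_sd = theta
        sd = np.exp(log_sd)
        pc = 0.5 + 0.5 * norm.cdf((levels - mu) / sd)
        pc = np.clip(pc, 1e-9, 1 - 1e-9)
        return -(k_per * np.log(pc) + (n_per - k_per) * np.log(1 - pc)).sum()

    # robust init: level closest to 75% correct observed proportion
    prop = k_per / n_per
    mu0 = levels[np.argmin(np.abs(prop - 0.75))]
    best = None
    for log_sd0 in (np.log(2.0), np.log(6.0)):
        res = minimize(
            nll, x0=[mu0, log_sd0], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sd = best.x
    return PsychometricFit(mu=float(mu), sd=float(np.exp(log_sd)), n_trials=len(trials))


def _start_level_db(condition, pedestal, params, model, cfg) -> float:
    """Staircase start: a fixed offset above the observer's analytic threshold."""
    t = increment_threshold(condition, pedestal, params, model)
    return min(float(to_db(t)) + cfg.start_above_db, _MAX_TARGET_DB)


def simulate_experiment(
    true_params: ModelParams,
    cfg: StaircaseConfig = StaircaseConfig(),
    n_reps: int = 3,
    n_participants: int = 6,
    rng_seed: int = 0,
    pedestals: Sequence[float] = PEDESTALS,
    model: str = "gain",
    return_trials: bool = False,
):
    """Simulate the full discrimination experiment and return a DipperDataset.

    Runs all four interaural arrangements at every pedestal for each
    synthetic listener (three staircase-pair repetitions each), pools the
    mon/dich/half_bin detection trials, fits a probit per cell per
    listener, and averages thresholds in dB across listeners.  Fully
    reproducible from ``rng_seed``.
    """
    ss = np.random.SeedSequence(rng_seed)
    part_rngs = [np.random.default_rng(s) for s in ss.spawn(n_participants)]

    start_cache = {
        (c, P): _start_level_db(c, P, true_params, model, cfg)
        for c in PSYCH_CONDITIONS
        for P in pedestals
    }
    obs_cache = {
        (c, P): make_observer(c, P, true_params, model)
        for c in PSYCH_CONDITIONS
        for P in pedestals
    }

    rows = []
    all_trials: list[TrialRecord] = []
    per_part: dict[tuple[str, float], list[list[TrialRecord]]] = {}
    for rng in part_rngs:
        cell_logs: dict[tuple[str, float], list[TrialRecord]] = {}
        for rep in range(n_reps):
            for P in pedestals:
                for cond in PSYCH_CONDITIONS:
                    observer = obs_cache[(cond, P)]
                    log = run_staircase_pair(
                        cond, P, cfg, observer, rng, start_cache[(cond, P)], rep
                    )
                    key = (cond.value, P)
                    cell_logs.setdefault(key, []).extend(log)
        # pool the identical detection stimuli across mon/dich/half_bin
        if 0.0 in pedestals:
            pooled = []
            for cond in ("mon", "dich", "half_bin"):
                pooled.extend(cell_logs.pop((cond, 0.0), []))
            cell_logs[(POOLED_DETECTION, 0.0)] = pooled
        for key, log in cell_logs.items():
            per_part.setdefault(key, []).append(log)
        all_trials.extend(t for log in cell_logs.values() for t in log)

    for (cond, P), logs in sorted(per_part.items()):
        ths = [pool_fit_probit(log).threshold75 for log in logs]
        rows.append(
            {
                "condition": cond,
                "pedestal_pct": P,
                "threshold_db": float(np.mean(ths)),
                "n_trials": int(sum(len(log) for log in logs)),
            }
        )
    df = pd.DataFrame(rows).sort_values(["condition", "pedestal_pct"]).reset_index(drop=True)
    ds = DipperDataset(df, n_participants=n_participants, seed=rng_seed)
    if return_trials:
        return ds, pd.DataFrame([t.__dict__ for t in all_trials])
    return ds
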