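"""Synthetic agents, cohorts, ROI activity and statistic volumes.

The human cohort is replaced by simulated judgment agents.  A *rule* agent
responds from the linear cue-abstraction model; an *exemplar* agent responds
from the exemplar model over its own stored pool.  Responses are the model
prediction plus additive Gaussian noise, clipped to the response scale and
(optionally) rounded to the integer scale steps the response device allowed.

Four conditions mirror the study's 2x2 between-subject design (learning mode
instructed/spontaneous x process rule/similarity).  Spontaneous agents run a
feedback training phase with the study's stopping rule (stop at the first
16-item block with RMSE < 2 against the criteria, cap 40 blocks = 640
trials), then a screening test phase, then the scanner test phase; instructed
agents go straight to the scanner phase with their instructed parameters.

Generators for per-subject ROI contrast values with a controlled population
correlation to model fit, and for subject-level statistic volumes with
planted active regions, provide ground-truthed inputs for the second-level
statistics in :mod:`cuejudge.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import CUE_COLUMNS, JudgmentDataset
from .models import CAMParams, EBMParams, ExemplarPool, ebm_predict_many
from .task import (
    INSTRUCTED_COUNTS,
    SPONTANEOUS_COUNTS,
    CueProfile,
    Item,
    Role,
    StudyDesign,
    TaskEnvironment,
    generate_design,
)

__all__ = [
    "AgentSpec",
    "CohortConfig",
    "CohortResult",
    "TrainingResult",
    "CONDITIONS",
    "simulate_judgments",
    "simulate_training_phase",
    "simulate_cohort",
    "simulate_roi_activity",
    "simulate_roi_activity_multi",
    "simulate_stat_volumes",
]

CONDITIONS = (
    "instructed_rule",
    "instructed_similarity",
    "spontaneous_rule",
    "spontaneous_similarity",
)


@dataclass(frozen=True)
class AgentSpec:
    """A stationary synthetic judge.

    ``noise_sd`` is the standard deviation (criterion units) of additive
    Gaussian response noise; the default 2.0 places trained agents at the
    study's learning criterion (block RMSE < 2).
    """

    strategy: Literal["rule", "exemplar"]
    true_params: CAMParams | EBMParams
    pool: ExemplarPool | None = None
    noise_sd: float = 2.0
    response_rounding: bool = True
    response_scale: tuple[int, int] = (0, 30)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.strategy == "exemplar":
            if self.pool is None or len(self.pool) == 0:
                raise ValueError("exemplar agents need a nonempty pool")
            if not isinstance(self.true_params, EBMParams):
                raise TypeError("exemplar agents take EBMParams")
        elif not isinstance(self.true_params, CAMParams):
            raise TypeError("rule agents take CAMParams")

    def predict(self, profiles: Sequence[CueProfile]) -> np.ndarray:
        if self.strategy == "rule":
            X = np.array([CueProfile(p) for p in profiles], dtype=float)
            return self.true_params.intercept + X @ np.asarray(self.true_params.weights)
        return ebm_predict_many(self.true_params, self.pool, profiles)


def simulate_judgments(
    agent: AgentSpec, items: Sequence[Item], seed: int | np.random.SeedSequence = 0
) -> np.ndarray:
    """One response per item: model prediction + noise, clipped, rounded."""
    rng = np.random.default_rng(seed)
    preds = agent.predict([it.profile for it in items])
    resp = preds + rng.normal(0.0, agent.noise_sd, size=len(items)) if agent.noise_sd > 0 else preds.copy()
    lo, hi = agent.response_scale
    resp = np.clip(resp, lo, hi)
    if agent.response_rounding:
        resp = np.round(resp)
    return resp


@dataclass
class TrainingResult:
    responses_by_block: list[np.ndarray]
    terminated_at_block: int
    total_trials: int


def simulate_training_phase(
    agent: AgentSpec,
    training_items: Sequence[Item],
    rmse_criterion: float = 2.0,
    max_blocks: int = 40,
    seed: int | np.random.SeedSequence = 0,
    min_blocks: int = 1,
) -> TrainingResult:
    """Run feedback training blocks until the stopping rule fires.

    Stops at the first block whose RMSE against the criteria is below
    ``rmse_criterion``, else after ``max_blocks`` blocks; with the default
    16-item blocks and cap 40 this is at most 640 trials.  ``min_blocks``
    lets callers guarantee enough blocks for late-training model estimation
    (stationary agents can otherwise satisfy the criterion immediately,
    which real learners cannot).
    """
    if len(training_items) == 0:
        raise ValueError("training items must be nonempty")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    crit = np.array([it.criterion for it in training_items], dtype=float)
    blocks: list[np.ndarray] = []
    block = 0
    for block_seed in ss.spawn(max_blocks):
        block += 1
        resp = simulate_judgments(agent, training_items, seed=block_seed)
        blocks.append(resp)
        rmse = float(np.sqrt(np.mean((resp - crit) ** 2)))
        if rmse < rmse_criterion and block >= min_blocks:
            break
    return TrainingResult(blocks, terminated_at_block=block, total_trials=block * len(training_items))


@dataclass(frozen=True)
class CohortConfig:
    """Sizes, environments and agent settings for the four conditions.

    Default sizes (19, 19, 16, 20) give the study's analyzed sample of 74.
    Exemplar agents draw each similarity parameter uniformly from
    ``exemplar_s_range``; rule agents use the environment's true intercept
    and weights (idealized trained learners).
    """

    n_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {
            "instructed_rule": 19,
            "instructed_similarity": 19,
            "spontaneous_rule": 16,
            "spontaneous_similarity": 20,
        }
    )
    noise_sd: float = 2.0
    response_rounding: bool = True
    exemplar_s_range: tuple[float, float] = (0.1, 0.5)
    fmri_repetitions: int = 3
    screening_repetitions: int = 2
    min_training_blocks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for cond in self.n_per_condition:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        if any(n < 1 for n in self.n_per_condition.values()):
            raise ValueError("each condition needs n >= 1")


def _condition_environment(condition: str) -> TaskEnvironment:
    if condition == "spontaneous_similarity":
        return TaskEnvironment(kind="multiplicative")
    return TaskEnvironment(kind="additive")


@dataclass
class CohortResult:
    """Simulated judgments plus the ground truth needed for recovery tests."""

    dataset: JudgmentDataset
    agents: dict[str, AgentSpec]
    conditions: dict[str, str]
    designs: dict[str, StudyDesign]
    fit_pools: dict[str, ExemplarPool]
    training_blocks: dict[str, int]


def _records_for(pid, condition, phase, block, items, responses):
    rows = []
    for it, r in zip(items, responses):
        rows.append(
            {
                "participant": pid,
                "phase": phase,
                "block": block,
                "role": it.role.value,
                **{c: v for c, v in zip(CUE_COLUMNS, it.profile)},
                "criterion": np.nan if it.criterion is None else it.criterion,
                "response": float(r),
            }
        )
    return rows


def simulate_cohort(config: CohortConfig | None = None) -> CohortResult:
    """Simulate the full four-condition cohort.

    Returns the pooled judgment dataset together with the agent registry
    (true generating parameters), the per-condition designs, and the
    exemplar pools the fitting stage should assume (the memorized items for
    instructed conditions, the training items for spontaneous ones).
    """
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(cfg.seed)
    design_ss, agent_ss = root.spawn(2)

    designs: dict[str, StudyDesign] = {}
    fit_pools: dict[str, ExemplarPool] = {}
    for cond, dss in zip(CONDITIONS, design_ss.spawn(len(CONDITIONS))):
        env = _condition_environment(cond)
        counts = INSTRUCTED_COUNTS if cond.startswith("instructed") else SPONTANEOUS_COUNTS
        designs[cond] = generate_design(counts, environment=env, seed=dss)
        pool_role = Role.MEMORIZED if cond.startswith("instructed") else Role.TRAINING
        fit_pools[cond] = ExemplarPool.from_items(designs[cond].item_sets[pool_role])

    rows: list[dict] = []
    agents: dict[str, AgentSpec] = {}
    conditions: dict[str, str] = {}
    training_blocks: dict[str, int] = {}
    prefixes = {
        "instructed_rule": "ir",
        "instructed_similarity": "is",
        "spontaneous_rule": "sr",
        "spontaneous_similarity": "ss",
    }

    for cond in CONDITIONS:
        n = cfg.n_per_condition.get(cond, 0)
        if n == 0:
            continue
        design = designs[cond]
        env = design.environment
        fmri_items = design.items(Role.FMRI_NEW, Role.EXTREME)
        cond_ss = np.random.SeedSequence((cfg.seed, CONDITIONS.index(cond)))
        for i, pss in enumerate(cond_ss.spawn(n)):
            pid = f"{prefixes[cond]}{i+1:02d}"
            param_rng = np.random.default_rng(pss.spawn(1)[0])
            if cond.endswith("rule"):
                agent = AgentSpec(
                    "rule",
                    CAMParams(env.intercept, env.weights),
                    noise_sd=cfg.noise_sd,
                    response_rounding=cfg.response_rounding,
                    response_scale=env.response_scale,
                )
            else:
                s = tuple(param_rng.uniform(*cfg.exemplar_s_range, size=5))
                agent = AgentSpec(
                    "exemplar",
                    EBMParams(s),
                    pool=fit_pools[cond],
                    noise_sd=cfg.noise_sd,
                    response_rounding=cfg.response_rounding,
                    response_scale=env.response_scale,
                )
            agents[pid] = agent
            conditions[pid] = cond

            phase_ss = pss.spawn(3)
            if cond.startswith("spontaneous"):
                t_items = design.item_sets[Role.TRAINING]
                training = simulate_training_phase(
                    agent, t_items, seed=phase_ss[0], min_blocks=cfg.min_training_blocks
                )
                training_blocks[pid] = training.terminated_at_block
                for b, resp in enumerate(training.responses_by_block, start=1):
                    rows.extend(_records_for(pid, cond, "training", b, t_items, resp))
                screen_items = design.items(Role.TRAINING, Role.SCREENING_NEW, Role.EXTREME)
                for rep, rss in enumerate(phase_ss[1].spawn(cfg.screening_repetitions), start=1):
                    resp = simulate_judgments(agent, screen_items, seed=rss)
                    rows.extend(_records_for(pid, cond, "screening", rep, screen_items, resp))
            for rep, rss in enumerate(phase_ss[2].spawn(cfg.fmri_repetitions), start=1):
                resp = simulate_judgments(agent, fmri_items, seed=rss)
                rows.extend(_records_for(pid, cond, "fmri", rep, fmri_items, resp))

    frame = pd.DataFrame(rows)
    dataset = JudgmentDataset(frame, response_scale=(0, 30))
    return CohortResult(dataset, agents, conditions, designs, fit_pools, training_blocks)


def simulate_roi_activity(
    fit_values: Sequence[float],
    target_r: float,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Per-subject ROI contrast values correlated with model fit.

    Uses the latent-correlation construction y = r * z(f) + sqrt(1-r^2) * e
    with standardized fit values z(f) and independent standard-normal noise
    e, so the *population* correlation with ``fit_values`` is exactly
    ``target_r`` (the sample correlation converges to it as n grows; at
    |target_r| = 1 the noise branch vanishes and the sample correlation is
    exactly +/-1).
    """
    f = np.asarray(fit_values, dtype=float)
    if len(f) < 3:
        raise ValueError("need at least 3 subjects")
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target correlation must lie in [-1, 1]")
    sd = f.std()
    if sd == 0:
        raise ValueError("fit values are constant; correlation undefined")
    z = (f - f.mean()) / sd
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(f))
    return target_r * z + np.sqrt(1.0 - target_r**2) * noise


def simulate_roi_activity_multi(
    covariates: np.ndarray,
    target_rs: Sequence[float],
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """ROI values with prescribed population correlations to several covariates.

    Generalizes :func:`simulate_roi_activity`: given an (n, k) covariate
    matrix (e.g., EBM and CAM fit values) and a k-vector of target
    correlations rho, the systematic part is Z @ (R^-1 rho) with Z the
    standardized covariates and R their sample correlation matrix, plus
    independent Gaussian noise scaled so the total variance is 1.  Requires
    rho' R^-1 rho <= 1 (an attainable correlation vector).
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    rho = np.asarray(target_rs, dtype=float)
    if X.shape[1] != len(rho):
        raise ValueError("one target correlation per covariate required")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("covariates must be nonconstant")
    Z = (X - X.mean(axis=0)) / sds
    R = np.corrcoef(Z, rowvar=False)
    R = np.atleast_2d(R)
    w = np.linalg.solve(R, rho)
    explained = float(rho @ w)
    if explained > 1.0 + 1e-9:
        raise ValueError("target correlation vector is not attainable for these covariates")
    rng = np.random.default_rng(seed)
    noise_sd = math.sqrt(max(1.0 - explained, 0.0))
    return Z @ w + noise_sd * rng.standard_normal(X.shape[0])


def simulate_stat_volumes(
    shape: tuple[int, int, int],
    active_masks: Sequence[np.ndarray],
    effect: float,
    n_subjects: int | Sequence[int],
    seed: int | np.random.SeedSequence = 0,
    noise_sd: float = 1.0,
) -> list[np.ndarray]:
    """Subject-level contrast volumes per group: noise plus a planted effect.

    ``active_masks`` holds one boolean grid per group; each subject volume is
    i.i.d. Gaussian noise with ``effect`` added inside the group's active
    region (so ``effect / noise_sd`` is the voxelwise Cohen's d).  Returns a
    list of (n_subjects, *shape) arrays, one per group.
    """
    masks = [np.asarray(m, dtype=bool) for m in active_masks]
    for m in masks:
        if m.shape != tuple(shape):
            raise ValueError("active region mask does not match the grid shape")
    ns = [int(n_subjects)] * len(masks) if np.isscalar(n_subjects) else [int(n) for n in n_subjects]
    if len(ns) != len(masks):
        raise ValueError("one subject count per group required")
    rng = np.random.default_rng(seed)
    out = []
    for m, n in zip(masks, ns):
        vols = rng.normal(0.0, noise_sd, size=(n, *shape))
        vols[:, m] += effect
        out.append(vols)
    return out
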