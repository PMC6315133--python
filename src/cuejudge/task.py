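"""Cue profiles, items and the additive/multiplicative judgment environments.

The judgment task asks for the toxicity of a stimulus ("bug") that varies on
five binary cues, each coded -1 or +1.  The toxicity criterion is a fixed
function of the cues: either a linear-additive rule

    c = 15 + 5*C1 + 4*C2 + 3*C3 + 2*C4 + 1*C5

spanning [0, 30] over the 32 possible profiles, or a multiplicative rule

    c = 2 + 3 * exp((5*C1 + 4*C2 + 3*C3 + 2*C4 + 1*C5) / 6)

which is a strictly monotone transform of the same weighted cue sum, so the
two environments rank all profiles identically while only the additive one is
linearly learnable cue by cue.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CueProfile",
    "Role",
    "Item",
    "TaskEnvironment",
    "StudyDesign",
    "DesignError",
    "additive_criterion",
    "multiplicative_criterion",
    "enumerate_profiles",
    "generate_design",
    "read_items",
    "write_items",
]

N_CUES = 5


class DesignError(ValueError):
    """Raised for infeasible or inconsistent study-design requests."""


class CueProfile(tuple):
    """An ordered 5-tuple of binary cue values, each -1 or +1.

    Subclasses ``tuple`` so profiles are hashable, comparable and usable as
    set/dict members.
    """

    def __new__(cls, values: Iterable[int]) -> "CueProfile":
        vals = tuple(int(v) for v in values)
        if len(vals) != N_CUES:
            raise ValueError(f"cue profile needs exactly {N_CUES} values, got {len(vals)}")
        if any(v not in (-1, 1) for v in vals):
            raise ValueError(f"cue values must be -1 or +1, got {vals}")
        return super().__new__(cls, vals)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CueProfile{tuple(self)}"


class Role(str, Enum):
    """Role of an item in the study design."""

    MEMORIZED = "M"
    TRAINING = "T"
    SCREENING_NEW = "S"
    EXTREME = "E"
    FMRI_NEW = "N"
    BASELINE = "B"


@dataclass(frozen=True)
class TaskEnvironment:
    """A judgment environment: a criterion function over cue profiles.

    Parameters
    ----------
    kind:
        ``"additive"`` or ``"multiplicative"``.
    intercept, weights:
        Constants of the linear cue combination.  Weights must be strictly
        decreasing and positive, mirroring the task's monotone cue
        importance.
    mult_offset, mult_scale, mult_divisor:
        Constants of the multiplicative (exponential) criterion.
    response_scale:
        Closed integer interval of admissible responses.
    """

    kind: str = "additive"
    intercept: float = 15.0
    weights: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0, 1.0)
    mult_offset: float = 2.0
    mult_scale: float = 3.0
    mult_divisor: float = 6.0
    response_scale: tuple[int, int] = (0, 30)

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if len(self.weights) != N_CUES:
            raise ValueError("exactly five cue weights required")
        w = self.weights
        if any(a <= b for a, b in zip(w, w[1:])) or any(x <= 0 for x in w):
            raise ValueError("weights must be strictly decreasing and positive")
        lo, hi = self.response_scale
        if not lo < hi:
            raise ValueError("response scale lower bound must be below upper bound")

    def weighted_sum(self, profile: CueProfile) -> float:
        return float(np.dot(self.weights, profile))

    def criterion(self, profile: CueProfile) -> float:
        """Criterion value of ``profile`` under this environment's rule."""
        if self.kind == "additive":
            return additive_criterion(profile, self)
        return multiplicative_criterion(profile, self)


def additive_criterion(profile: CueProfile, env: TaskEnvironment) -> float:
    """Linear-additive criterion: intercept + weighted cue sum."""
    if env.kind != "additive":
        raise ValueError("additive_criterion requires an additive environment")
    return env.intercept + env.weighted_sum(CueProfile(profile))


def multiplicative_criterion(profile: CueProfile, env: TaskEnvironment) -> float:
    """Multiplicative criterion: offset + scale * exp(weighted sum / divisor)."""
    if env.kind != "multiplicative":
        raise ValueError("multiplicative_criterion requires a multiplicative environment")
    s = env.weighted_sum(CueProfile(profile))
    return env.mult_offset + env.mult_scale * math.exp(s / env.mult_divisor)


@dataclass(frozen=True)
class Item:
    """A stimulus: a cue profile with a design role and its true criterion.

    Baseline items (the visual-detection comparison task) carry no criterion.
    """

    profile: CueProfile
    role: Role
    criterion: float | None

    def __post_init__(self) -> None:
        if self.role is Role.BASELINE:
            if self.criterion is not None:
                raise ValueError("baseline items carry no criterion")
        elif self.criterion is None or not math.isfinite(self.criterion):
            raise ValueError("non-baseline items need a finite criterion")

    @classmethod
    def from_env(cls, profile: CueProfile, role: Role, env: TaskEnvironment) -> "Item":
        if role is Role.BASELINE:
            return cls(CueProfile(profile), role, None)
        return cls(CueProfile(profile), role, env.criterion(CueProfile(profile)))


def enumerate_profiles() -> list[CueProfile]:
    """All 32 distinct cue profiles in a fixed lexicographic order."""
    return [CueProfile(p) for p in itertools.product((-1, 1), repeat=N_CUES)]


# Default per-role item counts for the two experiments.  Spontaneous roles
# partition the 32-profile space: 16 training + 6 screening-new + 2 extreme
# + 8 fMRI-new.
SPONTANEOUS_COUNTS: dict[Role, int] = {
    Role.TRAINING: 16,
    Role.SCREENING_NEW: 6,
    Role.EXTREME: 2,
    Role.FMRI_NEW: 8,
    Role.BASELINE: 8,
}
INSTRUCTED_COUNTS: dict[Role, int] = {
    Role.MEMORIZED: 6,
    Role.EXTREME: 2,
    Role.FMRI_NEW: 8,
    Role.BASELINE: 8,
}


@dataclass
class StudyDesign:
    """An environment together with per-role item sets."""

    environment: TaskEnvironment
    item_sets: dict[Role, list[Item]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role, items in self.item_sets.items():
            profs = [it.profile for it in items]
            if len(set(profs)) != len(profs):
                raise DesignError(f"duplicate profiles within role {role.value}")
        new = {it.profile for it in self.item_sets.get(Role.FMRI_NEW, [])}
        seen = {
            it.profile
            for r in (Role.MEMORIZED, Role.TRAINING)
            for it in self.item_sets.get(r, [])
        }
        if new & seen:
            raise DesignError("fMRI-new items overlap memorized/training items")

    @property
    def counts(self) -> dict[Role, int]:
        return {role: len(items) for role, items in self.item_sets.items()}

    def items(self, *roles: Role) -> list[Item]:
        out: list[Item] = []
        for role in roles:
            out.extend(self.item_sets.get(role, []))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        i = 0
        for role in Role:
            for it in self.item_sets.get(role, []):
                rows.append(
                    {
                        "item_id": i,
                        "role": role.value,
                        **{f"c{k+1}": it.profile[k] for k in range(N_CUES)},
                        "criterion": np.nan if it.criterion is None else it.criterion,
                    }
                )
                i += 1
        return pd.DataFrame(rows)


def _full_rank(profiles: Sequence[CueProfile]) -> bool:
    X = np.column_stack([np.ones(len(profiles)), np.array(profiles, dtype=float)])
    return np.linalg.matrix_rank(X) == N_CUES + 1


def _loo_identifiable(profiles: Sequence[CueProfile]) -> bool:
    if len(profiles) < N_CUES + 2:
        return False
    return all(
        _full_rank([p for j, p in enumerate(profiles) if j != i]) for i in range(len(profiles))
    )


def generate_design(
    counts: Mapping[Role, int] | None = None,
    environment: TaskEnvironment | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> StudyDesign:
    """Generate a study design with the requested per-role item counts.

    Non-baseline roles are drawn disjointly from the 32 cue profiles; the two
    extreme items are pinned to the all-low and all-high profiles (the
    extrapolation probes, whose criteria bracket the training range), and
    fMRI-phase new items never appear among memorized or training items.
    Pure in ``(counts, environment, seed)``.
    """
    env = environment or TaskEnvironment()
    if counts is None:
        counts = SPONTANEOUS_COUNTS
    counts = {Role(r): int(n) for r, n in counts.items()}
    if any(n < 0 for n in counts.values()):
        raise DesignError("negative item count")

    rng = np.random.default_rng(seed)
    all_profiles = enumerate_profiles()
    lo_profile = CueProfile((-1,) * N_CUES)
    hi_profile = CueProfile((1,) * N_CUES)

    n_extreme = counts.get(Role.EXTREME, 0)
    if n_extreme not in (0, 2):
        raise DesignError("extreme role holds exactly the all-low/all-high pair (count 0 or 2)")

    interior = [p for p in all_profiles if p not in (lo_profile, hi_profile)]
    draw_roles = [r for r in (Role.MEMORIZED, Role.TRAINING, Role.SCREENING_NEW, Role.FMRI_NEW) if counts.get(r, 0)]
    needed = sum(counts[r] for r in draw_roles)
    if needed > len(interior):
        raise DesignError(
            f"requested {needed} disjoint non-extreme items; only {len(interior)} profiles available"
        )

    # The scanner-phase item set must keep the linear model identifiable with
    # any single item held out (leave-one-out fitting), and the training set
    # must identify it outright; resample until both hold.
    extremes = [lo_profile, hi_profile] if n_extreme else []
    for _ in range(500):
        order = rng.permutation(len(interior))
        pool = [interior[i] for i in order]
        assignment: dict[Role, list[CueProfile]] = {}
        cursor = 0
        for role in draw_roles:
            assignment[role] = pool[cursor : cursor + counts[role]]
            cursor += counts[role]
        ok = True
        if counts.get(Role.FMRI_NEW, 0):
            ok &= _loo_identifiable(assignment[Role.FMRI_NEW] + extremes)
        if counts.get(Role.TRAINING, 0):
            ok &= _full_rank(assignment[Role.TRAINING])
        if ok:
            break
    else:
        raise DesignError("could not draw an identifiable item set for the requested counts")

    item_sets: dict[Role, list[Item]] = {}
    for role in draw_roles:
        item_sets[role] = [Item.from_env(p, role, env) for p in assignment[role]]
    if n_extreme:
        item_sets[Role.EXTREME] = [
            Item.from_env(lo_profile, Role.EXTREME, env),
            Item.from_env(hi_profile, Role.EXTREME, env),
        ]
    n_base = counts.get(Role.BASELINE, 0)
    if n_base:
        idx = rng.integers(0, len(all_profiles), size=n_base)
        # baseline bugs are perceptual fillers; profiles may repeat across the
        # stream but are stored as distinct events downstream
        seen: list[Item] = []
        used: set[CueProfile] = set()
        for i in idx:
            p = all_profiles[i]
            while p in used:
                p = all_profiles[(all_profiles.index(p) + 1) % len(all_profiles)]
            used.add(p)
            seen.append(Item(p, Role.BASELINE, None))
        item_sets[Role.BASELINE] = seen

    return StudyDesign(environment=env, item_sets=item_sets)


def write_items(design: StudyDesign, path) -> None:
    """Write the design's item table as CSV (item_id, role, c1..c5, criterion)."""
    design.to_frame().to_csv(path, index=False)


def read_items(path, environment: TaskEnvironment | None = None) -> StudyDesign:
    """Read an item table written by :func:`write_items`.

    If ``environment`` is given, non-baseline criteria are validated against
    it (so transcribed published item sets can be checked on load).
    """
    df = pd.read_csv(path)
    env = environment or TaskEnvironment()
    item_sets: dict[Role, list[Item]] = {}
    for _, row in df.iterrows():
        role = Role(row["role"])
        profile = CueProfile(tuple(int(row[f"c{k+1}"]) for k in range(N_CUES)))
        if role is Role.BASELINE:
            item = Item(profile, role, None)
        else:
            crit = float(row["criterion"])
            if environment is not None and abs(crit - env.criterion(profile)) > 1e-9:
                raise DesignError(
                    f"criterion {crit} inconsistent with environment for profile {tuple(profile)}"
                )
            item = Item(profile, role, crit)
        item_sets.setdefault(role, []).append(item)
    return StudyDesign(environment=env, item_sets=item_sets)
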