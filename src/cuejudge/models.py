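"""The two judgment models: cue abstraction (CAM) and exemplar-based (EBM).

CAM assumes abstracted knowledge of each cue-criterion relation and predicts
a linear-additive combination of the cues,

    c_CAM = k + sum_i w_i * C_i,

with intercept ``k`` and cue weights ``w_i`` free.  EBM assumes judgments are
similarity-weighted averages over stored exemplars,

    c_EBM = sum_n S_n * c_n / sum_n S_n,

with probe-exemplar similarity given by the original context model's
multiplicative rule: S = prod_i d_i, where d_i = 1 when the cue values on
dimension i coincide and d_i = s_i in [0, 1] when they deviate.  Small s_i
mean a mismatch on that cue strongly discounts an exemplar.

Model predictions are raw (not clipped to the response scale); clipping and
rounding belong to the response model in :mod:`cuejudge.simulate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .task import N_CUES, CueProfile, Item

__all__ = [
    "CAMParams",
    "EBMParams",
    "ExemplarPool",
    "DegeneratePredictionError",
    "cam_predict",
    "context_similarity",
    "ebm_predict",
]


class DegeneratePredictionError(ZeroDivisionError):
    """Probe has zero total similarity to every exemplar in the pool."""


@dataclass(frozen=True)
class CAMParams:
    """Intercept and five cue weights of the linear judgment model."""

    intercept: float
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != N_CUES:
            raise ValueError("exactly five cue weights required")
        if not np.all(np.isfinite([self.intercept, *self.weights])):
            raise ValueError("CAM parameters must be finite")

    def to_dict(self) -> dict:
        return {"k": self.intercept, **{f"w{i+1}": w for i, w in enumerate(self.weights)}}

    @classmethod
    def from_dict(cls, d: dict) -> "CAMParams":
        return cls(float(d["k"]), tuple(float(d[f"w{i+1}"]) for i in range(N_CUES)))


@dataclass(frozen=True)
class EBMParams:
    """Per-dimension mismatch similarities s_1..s_5, each in [0, 1].

    s_i = 0 makes a mismatch on cue i annihilating (exact-match retrieval on
    that cue); s_i = 1 makes cue i irrelevant to similarity.
    """

    similarities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.similarities) != N_CUES:
            raise ValueError("exactly five similarity parameters required")
        s = np.asarray(self.similarities, dtype=float)
        if not (np.all(np.isfinite(s)) and np.all(s >= 0.0) and np.all(s <= 1.0)):
            raise ValueError("similarity parameters must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {f"s{i+1}": s for i, s in enumerate(self.similarities)}

    @classmethod
    def from_dict(cls, d: dict) -> "EBMParams":
        return cls(tuple(float(d[f"s{i+1}"]) for i in range(N_CUES)))


@dataclass(frozen=True)
class ExemplarPool:
    """The stored (profile, criterion) pairs the EBM averages over."""

    exemplars: tuple[tuple[CueProfile, float], ...]

    def __post_init__(self) -> None:
        if len(self.exemplars) < 1:
            raise ValueError("exemplar pool must be nonempty")
        if not all(np.isfinite(c) for _, c in self.exemplars):
            raise ValueError("exemplar criteria must be finite")

    @classmethod
    def from_items(cls, items: Iterable[Item]) -> "ExemplarPool":
        ex = tuple((it.profile, float(it.criterion)) for it in items)
        return cls(ex)

    def __len__(self) -> int:
        return len(self.exemplars)

    @property
    def profiles(self) -> np.ndarray:
        return np.array([p for p, _ in self.exemplars], dtype=float)

    @property
    def criteria(self) -> np.ndarray:
        return np.array([c for _, c in self.exemplars], dtype=float)


def cam_predict(params: CAMParams, profile: CueProfile) -> float:
    """Linear-additive prediction k + sum_i w_i * C_i."""
    return float(params.intercept + np.dot(params.weights, CueProfile(profile)))


def context_similarity(probe: CueProfile, exemplar: CueProfile, params: EBMParams) -> float:
    """Multiplicative context-model similarity between two profiles."""
    probe = CueProfile(probe)
    exemplar = CueProfile(exemplar)
    sim = 1.0
    for p, e, s in zip(probe, exemplar, params.similarities):
        if p != e:
            sim *= s
    return sim


def _similarity_matrix(probes: np.ndarray, pool_profiles: np.ndarray, s: np.ndarray) -> np.ndarray:
    """(n_probes, n_pool) similarity matrix for vectorized EBM evaluation."""
    mism = probes[:, None, :] != pool_profiles[None, :, :]
    return np.prod(np.where(mism, s[None, None, :], 1.0), axis=2)


def ebm_predict(params: EBMParams, pool: ExemplarPool, probe: CueProfile) -> float:
    """Similarity-weighted mean of the pool criteria at ``probe``.

    Raises
    ------
    DegeneratePredictionError
        If the probe has zero similarity to every exemplar (possible only
        when some s_i = 0), rather than silently returning 0/0.
    """
    probe = CueProfile(probe)
    s = np.asarray(params.similarities)
    sims = _similarity_matrix(np.array([probe], dtype=float), pool.profiles, s)[0]
    total = sims.sum()
    if total <= 0.0:
        raise DegeneratePredictionError(
            "probe has zero similarity to every exemplar in the pool"
        )
    return float(sims @ pool.criteria / total)


def ebm_predict_many(
    params: EBMParams, pool: ExemplarPool, probes: Sequence[CueProfile]
) -> np.ndarray:
    """Vectorized :func:`ebm_predict` over several probes."""
    P = np.array([CueProfile(p) for p in probes], dtype=float)
    sims = _similarity_matrix(P, pool.profiles, np.asarray(params.similarities))
    totals = sims.sum(axis=1)
    if np.any(totals <= 0.0):
        raise DegeneratePredictionError(
            "some probe has zero similarity to every exemplar in the pool"
        )
    return sims @ pool.criteria / totals


def params_to_json(params: CAMParams | EBMParams) -> str:
    """Serialize a parameter set with explicit field names."""
    kind = "CAM" if isinstance(params, CAMParams) else "EBM"
    return json.dumps({"model": kind, **params.to_dict()})


def params_from_json(text: str) -> CAMParams | EBMParams:
    d = json.loads(text)
    if d.get("model") == "CAM":
        return CAMParams.from_dict(d)
    if d.get("model") == "EBM":
        return EBMParams.from_dict(d)
    raise ValueError("unknown model kind in parameter JSON")
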