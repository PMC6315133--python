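"""End-to-end study orchestration: simulate, fit, classify, test, report.

``run_study`` executes the full synthetic analogue of the study in order:

1. simulate the four-condition cohort of judgment agents;
2. fit CAM and EBM to each participant's scanner-phase judgments by
   leave-one-out cross-validation and classify each participant's strategy;
3. run the 2x2 mixed ANOVA (model fit within x condition between) per
   learning mode;
4. generate per-subject ROI contrast values with configured population
   correlations to the model fits, then run the ROI x model correlation
   table with Bonferroni control and the dependent-correlation z-tests;
5. generate per-condition subject volumes with a planted shared active
   region and run the max-p conjunction with FDR control plus a two-sample
   contrast between the instructed conditions.

A single study seed is fanned out into per-stage substreams, so each stage
is independently reproducible and stage-wise CLI runs compose to the same
numbers as the monolithic call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import (
    FitOptions,
    JudgmentDataset,
    classify_strategy,
    loocv_rmsd,
)
from .models import ExemplarPool
from .simulate import (
    CohortConfig,
    CohortResult,
    simulate_cohort,
    simulate_roi_activity_multi,
    simulate_stat_volumes,
)
from .stats import (
    bonferroni_threshold,
    conjunction_fdr,
    meng_dependent_z,
    mixed_anova_interaction,
    pearson_correlation,
    voxelwise_one_sample_t,
    voxelwise_two_sample_t,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "write_report",
    "validate_report",
    "fit_cohort",
    "fit_participants",
    "roi_analysis",
    "conjunction_analysis",
]

DEFAULT_ROIS: dict[str, dict[str, float]] = {
    # structural analogues of the two headline clusters: one region tied to
    # exemplar-model fit, one to cue-abstraction-model fit (RMSD is a badness
    # of fit, hence the negative signs)
    "precuneus": {"ebm": -0.4, "cam": 0.0},
    "superior_frontal": {"ebm": 0.0, "cam": -0.36},
}


@dataclass
class StudyConfig:
    """Every knob of a full study run, with the study's defaults."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit_options: FitOptions = field(default_factory=lambda: FitOptions(restarts=5))
    alpha: float = 0.05
    q: float = 0.05
    sphere_radius_mm: float = 5.0
    tails: str = "two"
    rois: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: dict(DEFAULT_ROIS))
    volume_shape: tuple[int, int, int] = (12, 12, 12)
    volume_effect: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.cohort, CohortConfig):
            self.cohort = CohortConfig(**self.cohort)
        if not isinstance(self.fit_options, FitOptions):
            self.fit_options = FitOptions(**self.fit_options)
        # the cohort always runs on the study seed so one seed governs a run
        if self.cohort.seed != self.seed:
            self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["n_per_condition"] = dict(self.cohort.n_per_condition)
        d["rois"] = {k: dict(v) for k, v in self.rois.items()}
        d["volume_shape"] = list(self.volume_shape)
        return d

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "volume_shape" in raw:
            raw["volume_shape"] = tuple(raw["volume_shape"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    names = ("cohort", "roi", "volumes")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return dict(zip(names, children))


def fit_participants(
    dataset: JudgmentDataset,
    conditions: Mapping[str, str],
    pools: Mapping[str, ExemplarPool],
    strategies: Mapping[str, str],
    options: FitOptions,
    phase: str = "fmri",
) -> pd.DataFrame:
    """LOOCV-fit both models to every participant and classify strategies."""
    rows = []
    for pid in dataset.participants():
        cond = conditions[pid]
        records = dataset.slice(participant=pid, phase=phase)
        fit_c = loocv_rmsd("CAM", records, options=options)
        fit_e = loocv_rmsd("EBM", records, pool=pools[cond], options=options)
        label = classify_strategy(fit_c, fit_e, tie_tol=options.tie_tol)
        rows.append(
            {
                "participant": pid,
                "condition": cond,
                "true_strategy": strategies.get(pid, ""),
                "rmsd_cam": fit_c.rmsd,
                "rmsd_ebm": fit_e.rmsd,
                "label": label.label,
                "margin": label.margin,
            }
        )
    return pd.DataFrame(rows)


def fit_cohort(
    cohort: CohortResult, options: FitOptions, phase: str = "fmri"
) -> pd.DataFrame:
    """:func:`fit_participants` applied to an in-memory simulated cohort."""
    strategies = {pid: agent.strategy for pid, agent in cohort.agents.items()}
    return fit_participants(
        cohort.dataset, cohort.conditions, cohort.fit_pools, strategies, options, phase
    )


def anova_tables(fits: pd.DataFrame) -> pd.DataFrame:
    """Model x condition mixed-ANOVA interaction, per learning mode."""
    rows = []
    for mode in ("instructed", "spontaneous"):
        sub = fits[fits["condition"].str.startswith(mode)]
        if sub["condition"].nunique() < 2:
            continue
        res = mixed_anova_interaction(
            sub[["rmsd_cam", "rmsd_ebm"]].to_numpy(), sub["condition"].to_numpy()
        )
        rows.append(
            {
                "learning_mode": mode,
                "effect": res.effect,
                "F": res.F,
                "df1": res.df[0],
                "df2": res.df[1],
                "MSE": res.MSE,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def roi_analysis(
    fits: pd.DataFrame,
    rois: Mapping[str, Mapping[str, float]],
    alpha: float,
    tails: str,
    seed: np.random.SeedSequence | int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ROI activity and run the correlation/comparison analyses.

    Returns (roi_table, correlations, comparisons).  Two hypotheses (CAM and
    EBM fit) are tested per ROI, so the Bonferroni threshold within each ROI
    family is alpha / 2.
    """
    ebm = fits["rmsd_ebm"].to_numpy()
    cam = fits["rmsd_cam"].to_numpy()
    X = np.column_stack([ebm, cam])
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    threshold = bonferroni_threshold(alpha, 2)

    roi_rows, corr_rows, comp_rows = [], [], []
    r_kh = float(np.corrcoef(ebm, cam)[0, 1])
    for (name, targets), roi_ss in zip(rois.items(), ss.spawn(len(rois))):
        activity = simulate_roi_activity_multi(
            X, [targets["ebm"], targets["cam"]], seed=roi_ss
        )
        for pid, a in zip(fits["participant"], activity):
            roi_rows.append({"participant": pid, "roi": name, "activity": a})
        res_e = pearson_correlation(activity, ebm, tails=tails)
        res_c = pearson_correlation(activity, cam, tails=tails)
        for model, res in (("EBM", res_e), ("CAM", res_c)):
            corr_rows.append(
                {
                    "roi": name,
                    "model": model,
                    "r": res.r,
                    "n": res.n,
                    "p": res.p,
                    "threshold": threshold,
                    "significant": res.p < threshold,
                }
            )
        comp = meng_dependent_z(res_e.r, res_c.r, r_kh, n=len(activity), tails=tails)
        comp_rows.append(
            {
                "roi": name,
                "r_ebm": res_e.r,
                "r_cam": res_c.r,
                "r_fits": r_kh,
                "z": comp.z,
                "p": comp.p,
                "significant": comp.p < alpha,
            }
        )
    return pd.DataFrame(roi_rows), pd.DataFrame(corr_rows), pd.DataFrame(comp_rows)


def conjunction_analysis(
    config: StudyConfig, n_per_condition: Mapping[str, int], seed
) -> dict:
    """Planted-region conjunction across the four conditions, plus a contrast.

    A central box is active in every condition (the shared-process analogue);
    the conjunction should recover it and little else.  Also runs the
    two-sample t contrast between the two instructed conditions.
    """
    shape = tuple(config.volume_shape)
    mask = np.zeros(shape, dtype=bool)
    c = [s // 2 for s in shape]
    w = max(1, min(shape) // 6)
    mask[c[0] - w : c[0] + w, c[1] - w : c[1] + w, c[2] - w : c[2] + w] = True

    conds = list(n_per_condition)
    groups = simulate_stat_volumes(
        shape,
        [mask] * len(conds),
        effect=config.volume_effect,
        n_subjects=[n_per_condition[c] for c in conds],
        seed=seed,
    )
    p_vols = [voxelwise_one_sample_t(g)[1] for g in groups]
    conj = conjunction_fdr(p_vols, q=config.q)
    frac = float(conj.mask[mask].mean()) if mask.any() else 0.0

    contrast = {}
    if "instructed_rule" in n_per_condition and "instructed_similarity" in n_per_condition:
        ia = groups[conds.index("instructed_rule")]
        ib = groups[conds.index("instructed_similarity")]
        _, p_two = voxelwise_two_sample_t(ia, ib)
        rej, crit = np.zeros(0), 0.0
        finite = np.isfinite(p_two.data)
        from .stats import bh_fdr

        rej, crit = bh_fdr(p_two.data[finite], config.q)
        contrast = {
            "n_significant": int(rej.sum()),
            "critical_p": crit,
        }

    return {
        "grid": list(shape),
        "planted_voxels": int(mask.sum()),
        "n_significant": conj.n_significant,
        "critical_p": conj.critical_p,
        "planted_recovery_fraction": frac,
        "instructed_contrast": contrast,
    }


@dataclass
class StudyReport:
    config: dict
    seed: int
    fits: pd.DataFrame
    anova: pd.DataFrame
    roi_table: pd.DataFrame
    correlations: pd.DataFrame
    comparisons: pd.DataFrame
    conjunction: dict
    provenance: dict

    def summary(self) -> dict:
        return {
            "n_participants": int(len(self.fits)),
            "n_correct_classifications": int(
                (
                    (self.fits["true_strategy"] == "rule") & (self.fits["label"] == "rule")
                    | (self.fits["true_strategy"] == "exemplar")
                    & (self.fits["label"] == "similarity")
                ).sum()
            ),
            "anova": self.anova.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
            "conjunction": self.conjunction,
            "provenance": self.provenance,
        }


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Execute the full pipeline; deterministic given ``config.seed``."""
    cfg = config or StudyConfig()
    seeds = _stage_seeds(cfg.seed)

    stage = "simulate"
    try:
        cohort = simulate_cohort(cfg.cohort)
        stage = "fit"
        fits = fit_cohort(cohort, cfg.fit_options)
        stage = "anova"
        anova = anova_tables(fits)
        stage = "roi"
        roi_table, correlations, comparisons = roi_analysis(
            fits, cfg.rois, cfg.alpha, cfg.tails, seeds["roi"]
        )
        stage = "conjunction"
        conjunction = conjunction_analysis(cfg, cfg.cohort.n_per_condition, seeds["volumes"])
    except Exception as err:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    cfg_dict = cfg.to_dict()
    provenance = {
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "cuejudge_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    return StudyReport(
        config=cfg_dict,
        seed=cfg.seed,
        fits=fits,
        anova=anova,
        roi_table=roi_table,
        correlations=correlations,
        comparisons=comparisons,
        conjunction=conjunction,
        provenance=provenance,
    )


REPORT_REQUIRED_KEYS = {
    "n_participants",
    "n_correct_classifications",
    "anova",
    "correlations",
    "comparisons",
    "conjunction",
    "provenance",
}


def validate_report(summary: dict) -> None:
    """Schema check for a report summary; raises ValueError on violations."""
    missing = REPORT_REQUIRED_KEYS - set(summary)
    if missing:
        raise ValueError(f"report missing key(s): {sorted(missing)}")
    for row in summary["correlations"]:
        for key in ("roi", "model", "r", "p", "significant"):
            if key not in row:
                raise ValueError(f"correlation row missing {key!r}")
        if not -1.0 <= row["r"] <= 1.0:
            raise ValueError("correlation outside [-1, 1]")
    prov = summary["provenance"]
    for key in ("seed", "config_sha256", "cuejudge_version"):
        if key not in prov:
            raise ValueError(f"provenance missing {key!r}")


def write_report(report: StudyReport, outdir) -> Path:
    """Persist all report tables and the JSON summary under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.fits.to_csv(out / "fits.csv", index=False)
    report.anova.to_csv(out / "anova.csv", index=False)
    report.roi_table.to_csv(out / "roi_activity.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.comparisons.to_csv(out / "comparisons.csv", index=False)
    payload = {"config": report.config, **report.summary()}
    path = out / "report.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    return path
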