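"""End-to-end orchestration: generate, segment, shell, and summarise.

Two entry points: a summary study that simulates per-subject biomarker
means directly (fast; statistical targets), and a volumetric study that
runs the full imaging path on a small number of phantoms.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults, io, segmentation, shells as shells_mod, stats as stats_mod
from .grids import LABEL_CSF, LABEL_NAWM, LABEL_STROKE, LABEL_WMH
from .phantom import (
    BiomarkerTable,
    PenumbraConfig,
    assign_vrf,
    make_cohort,
    make_label_phantom,
    synthesize_parametric,
    synthesize_structural,
)

logger = logging.getLogger("wmpipeline")

__all__ = ["PipelineConfig", "run_summary_study", "run_volumetric_study"]


@dataclass
class PipelineConfig:
    """All pipeline knobs with published-table defaults; round-trips via YAML."""

    seed: int = 0
    group_sizes: dict[int, int] = field(default_factory=lambda: dict(defaults.GROUP_SIZES))
    biomarker_table: dict = field(
        default_factory=lambda: {b: dict(t) for b, t in defaults.BIOMARKER_TABLE.items()}
    )
    rho: float = defaults.DEFAULT_RHO
    per_score_nawm: dict = field(
        default_factory=lambda: {s: dict(t) for s, t in defaults.PER_SCORE_NAWM.items()}
    )
    vrf_incidence: dict = field(default_factory=lambda: dict(defaults.VRF_INCIDENCE))
    penumbra_amplitude: float = defaults.PENUMBRA_AMPLITUDE
    penumbra_decay_mm: float = defaults.PENUMBRA_DECAY_MM
    quantize_levels: int = defaults.DEFAULT_QUANTIZE_LEVELS
    shell_step_mm: float = defaults.SHELL_STEP_MM
    shell_max_mm: float = defaults.SHELL_MAX_MM
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_scale: float = 1.0
    out_dir: str | None = None

    def validate(self) -> None:
        problems = []
        if any(n < 0 for n in self.group_sizes.values()):
            problems.append("group sizes must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            problems.append(f"rho {self.rho} outside [-1, 1]")
        if not 0.0 <= self.penumbra_amplitude <= 1.0:
            problems.append("penumbra amplitude outside [0, 1]")
        if self.penumbra_decay_mm <= 0:
            problems.append("penumbra decay must be positive")
        if self.quantize_levels < 2:
            problems.append("quantize_levels must be >= 2")
        if self.shell_step_mm <= 0 or self.shell_max_mm < self.shell_step_mm:
            problems.append("need 0 < shell_step_mm <= shell_max_mm")
        if self.noise_scale < 0:
            problems.append("noise_scale must be >= 0")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    # -- file form -------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(**raw)
        cfg.group_sizes = {int(k): int(v) for k, v in cfg.group_sizes.items()}
        cfg.biomarker_table = {
            b: {t: tuple(ms) for t, ms in tissues.items()}
            for b, tissues in cfg.biomarker_table.items()
        }
        cfg.per_score_nawm = {
            int(s): {b: tuple(ms) for b, ms in row.items()}
            for s, row in cfg.per_score_nawm.items()
        }
        cfg.vrf_incidence = {k: tuple(v) for k, v in cfg.vrf_incidence.items()}
        cfg.grid_shape = tuple(int(s) for s in cfg.grid_shape)
        cfg.voxel_dims = tuple(float(d) for d in cfg.voxel_dims)
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        raw = self.to_dict()
        # YAML has no tuple type; store as lists and restore on load
        path.write_text(yaml.safe_dump(_tuples_to_lists(raw), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _table(cfg: PipelineConfig) -> BiomarkerTable:
    return BiomarkerTable(values={b: dict(t) for b, t in cfg.biomarker_table.items()},
                          rho=cfg.rho)


def run_summary_study(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Simulate the cohort at the subject level and compute all result tables.

    Returns tables shaped like the published outputs: paired tissue
    comparison (``table2``), per-score trend ANCOVA (``table3``), ROC
    discrimination (``roc``) and risk-factor incidence (``vrf``).
    """
    config.validate()
    table = _table(config)
    records, summaries = make_cohort(config.group_sizes, table,
                                     config.per_score_nawm, seed=config.seed)
    records = assign_vrf(records, config.vrf_incidence, seed=config.seed + 1)
    cohort = io.cohort_to_frame(records)
    frame = summaries.merge(cohort[["id"] + list(defaults.VRF_FACTORS)], on="id")

    biomarkers = table.biomarkers
    # paired comparison + effect sizes
    rows = []
    for b in biomarkers:
        x = frame[f"nawm_{b}"].to_numpy()
        y = frame[f"wmh_{b}"].to_numpy()
        t, df, p = stats_mod.paired_t(x, y)
        d = stats_mod.cohen_d_pooled(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1))
        rows.append({"biomarker": b, "nawm_mean": x.mean(), "nawm_sd": x.std(ddof=1),
                     "wmh_mean": y.mean(), "wmh_sd": y.std(ddof=1),
                     "t": t, "df": df, "p": p, "cohen_d": d})
    table2 = pd.DataFrame(rows)

    # per-biomarker ROC over pooled labelled observations
    rows = []
    for b in biomarkers:
        values = np.concatenate([frame[f"nawm_{b}"], frame[f"wmh_{b}"]])
        labels = np.concatenate([np.zeros(len(frame)), np.ones(len(frame))])
        roc = stats_mod.roc_discrimination(values, labels)
        _, slope, dev, separated = stats_mod.logistic_univariate(values, labels)
        rows.append({"biomarker": b, "auc": roc.auc, "ci_low": roc.auc_ci[0],
                     "ci_high": roc.auc_ci[1], "threshold": roc.threshold,
                     "sensitivity": roc.sensitivity, "specificity": roc.specificity,
                     "accuracy": roc.accuracy, "direction": roc.direction,
                     "logit_slope": slope, "logit_deviance": dev,
                     "separated": separated})
    roc_table = pd.DataFrame(rows)

    # trend across severity groups, with and without the risk-factor block
    vrf_block = frame[list(defaults.VRF_FACTORS)]
    rows = []
    for b in biomarkers:
        outcome = frame[f"nawm_{b}"]
        base = stats_mod.ancova_trend(outcome, frame["fazekas_total"],
                                      age=frame["age_days"], gender=frame["gender"])
        full = stats_mod.ancova_trend(outcome, frame["fazekas_total"],
                                      age=frame["age_days"], gender=frame["gender"],
                                      vrf_block=vrf_block)
        f_nested, df1, df2, p_nested = stats_mod.nested_f(base.model, full.model)
        per_score = frame.groupby("fazekas_total")[f"nawm_{b}"].agg(["mean", "std", "size"])
        for score, row in per_score.iterrows():
            rows.append({"biomarker": b, "fazekas_total": int(score), "term": "group",
                         "mean": row["mean"], "sd": row["std"], "n": int(row["size"]),
                         "F": np.nan, "p": np.nan, "r_squared": np.nan})
        rows.append({"biomarker": b, "fazekas_total": np.nan, "term": "ancova_gender_age",
                     "mean": np.nan, "sd": np.nan, "n": len(frame),
                     "F": base.terms["score"][0], "p": base.terms["score"][1],
                     "r_squared": base.r_squared})
        rows.append({"biomarker": b, "fazekas_total": np.nan, "term": "ancova_gender_age_vrf",
                     "mean": np.nan, "sd": np.nan, "n": len(frame),
                     "F": full.terms["score"][0], "p": full.terms["score"][1],
                     "r_squared": full.r_squared})
        rows.append({"biomarker": b, "fazekas_total": np.nan, "term": "nested_f_vrf",
                     "mean": np.nan, "sd": np.nan, "n": len(frame),
                     "F": f_nested, "p": p_nested, "r_squared": np.nan})
    table3 = pd.DataFrame(rows)

    # gender incidence of each risk factor
    rows = []
    for factor in defaults.VRF_FACTORS:
        male = cohort[cohort["gender"] == "M"][factor]
        female = cohort[cohort["gender"] == "F"][factor]
        counts = [[int(male.sum()), int(len(male) - male.sum())],
                  [int(female.sum()), int(len(female) - female.sum())]]
        try:
            chi2, df, p = stats_mod.chi_square_incidence(counts)
        except ValueError:
            chi2, df, p = np.nan, 1, np.nan
        rows.append({"factor": factor, "n": int(cohort[factor].sum()),
                     "total_pct": 100.0 * cohort[factor].mean(),
                     "male_pct": 100.0 * male.mean(), "female_pct": 100.0 * female.mean(),
                     "chi2": chi2, "p": p})
    vrf_table = pd.DataFrame(rows)

    tables = {"table2": table2, "table3": table3, "roc": roc_table,
              "vrf": vrf_table, "cohort": cohort}
    if config.out_dir:
        io.save_results(tables, config.out_dir)
    return tables


def segment_subject(structural: dict, brain_mask: np.ndarray, n_levels: int):
    """Run the colour-fusion segmentation on one subject's structural volumes.

    Returns raw (unrefined) nawm/csf/wmh masks.
    """
    norm = {m: segmentation.normalize_channel(v, brain_mask) for m, v in structural.items()}
    fused_wm = segmentation.fuse_red_green(norm["T1W"], norm["T2W"])
    clusters_wm = segmentation.minimum_variance_quantize(fused_wm, brain_mask, n_levels)
    shape = brain_mask.shape
    nawm = segmentation.select_tissue_clusters(clusters_wm, "nawm", "T1W+T2W", shape)
    csf = segmentation.select_tissue_clusters(clusters_wm, "csf", "T1W+T2W", shape)
    fused_les = segmentation.fuse_red_green(norm["T2SW"], norm["FLAIR"])
    clusters_les = segmentation.minimum_variance_quantize(fused_les, brain_mask, n_levels)
    wmh = segmentation.select_tissue_clusters(clusters_les, "wmh", "T2SW+FLAIR", shape)
    # a "lesion" mask covering a large share of the brain means there were no
    # lesions to find (the adaptive cut then splits normal tissue instead)
    if wmh.sum() > 0.25 * brain_mask.sum():
        logger.info("lesion mask covers >25%% of brain; treating as lesion-free")
        wmh = np.zeros_like(wmh)
    return nawm, csf, wmh


def run_volumetric_study(
    config: PipelineConfig,
    n_subjects: int = 5,
    scores: list[int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Full imaging path on phantoms: generate, segment, refine, shell, average.

    Returns ``summaries`` (per-subject tissue means), ``shell_means``,
    ``dice`` (recovered vs ground-truth masks) and a paired-comparison
    ``table2`` over the recovered masks.
    """
    config.validate()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    scores = scores if scores is not None else [(i % 6) + 1 for i in range(n_subjects)]
    if len(scores) != n_subjects:
        raise ValueError("scores must match n_subjects")
    table = _table(config)
    penumbra = PenumbraConfig(config.penumbra_amplitude, config.penumbra_decay_mm)

    summary_rows, shell_rows, dice_rows = [], [], []
    skipped_no_lesion = 0
    for i, score in enumerate(scores):
        sid = f"V{i:03d}"
        seed_i = config.seed + 1000 * (i + 1)
        labels = make_label_phantom(config.grid_shape, config.voxel_dims, score, seed_i)
        structural = synthesize_structural(labels, seed=seed_i + 1,
                                           noise_scale=config.noise_scale)
        parametric = synthesize_parametric(labels, table, penumbra, seed=seed_i + 2,
                                           noise_scale=config.noise_scale)
        brain = labels.brain_mask
        nawm_raw, csf_raw, wmh_raw = segment_subject(structural, brain, config.quantize_levels)

        truth = {"nawm": labels.mask(LABEL_NAWM), "csf": labels.mask(LABEL_CSF),
                 "wmh": labels.mask(LABEL_WMH)}
        for name, raw in (("nawm", nawm_raw), ("csf", csf_raw), ("wmh", wmh_raw)):
            dice_rows.append({"subject": sid, "mask": name, "score": score,
                              "dice": segmentation.dice(raw, truth[name])})

        nawm, wmh = segmentation.refine_masks(nawm_raw, wmh_raw, csf_raw)
        stroke = labels.mask(LABEL_STROKE)
        nawm = segmentation.exclude_stroke(nawm, stroke)
        wmh = segmentation.exclude_stroke(wmh, stroke)

        for b, vol in parametric.items():
            for label, mask in (("nawm", nawm), ("wmh", wmh)):
                if not mask.any():
                    continue
                s = stats_mod.masked_mean(vol, mask, sid, label, b)
                summary_rows.append(dataclasses.asdict(s) | {"score": score})

        if not wmh.any():
            skipped_no_lesion += 1
            continue
        shell_set = shells_mod.build_shells(wmh, nawm, config.voxel_dims,
                                            config.shell_max_mm, config.shell_step_mm)
        for label, mask in shell_set.labelled_masks():
            if not mask.any():
                continue
            for b, vol in parametric.items():
                s = stats_mod.masked_mean(vol, mask, sid, label, b)
                shell_rows.append(dataclasses.asdict(s) | {"score": score})

    logger.info("volumetric study: %d subjects, %d skipped for shells (no lesions)",
                n_subjects, skipped_no_lesion)
    summaries = pd.DataFrame(summary_rows)
    shell_means = pd.DataFrame(shell_rows)
    dice_table = pd.DataFrame(dice_rows)

    rows = []
    if not summaries.empty:
        wide = summaries.pivot_table(index=["subject", "biomarker"], columns="label",
                                     values="mean").reset_index()
        for b in table.biomarkers:
            sub = wide[(wide["biomarker"] == b)].dropna(subset=["nawm", "wmh"])
            if len(sub) >= 3:
                x = sub["nawm"].to_numpy()
                y = sub["wmh"].to_numpy()
                t, df, p = stats_mod.paired_t(x, y)
                d = stats_mod.cohen_d_pooled(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1))
                rows.append({"biomarker": b, "nawm_mean": x.mean(), "wmh_mean": y.mean(),
                             "t": t, "df": df, "p": p, "cohen_d": d, "n": len(sub)})
    table2 = pd.DataFrame(rows)

    tables = {"summaries": summaries, "shell_means": shell_means,
              "dice": dice_table, "table2_volumetric": table2}
    if config.out_dir:
        io.save_results({k: v for k, v in tables.items() if not v.empty}, config.out_dir)
    return tables
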