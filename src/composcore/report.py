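"""Sign alignment, condition-effect testing, summaries and the pipeline.

A raw composite (bottleneck activation or PC1 score) has an arbitrary
sign.  It is aligned against the direction-adjusted mean z-score so that
"higher = healthier" always holds, then the two-condition crossover
effect is tested with a repeated-measures ANOVA.  With one within-subject
factor at two levels that ANOVA is exactly the paired t-test (F = t^2,
identical p), and it is implemented through that closed form.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .autoencoder import (
    AEArchitecture,
    TrainingConfig,
    encode,
    evaluate_cv,
    explained_variance,
    grid_search,
    reconstruct,
    train_ae,
)
from .cohort import (
    CohortDataset,
    StandardizedMatrix,
    load_cohort,
    standardize,
)
from .errors import (
    ConfigError,
    DegenerateStatisticError,
    InsufficientDataError,
    PairingError,
)
from .pca import fit_pca, pca_composite, stability_check
from .simulate import GeneratorConfig, generate_cohort, preset_config

__all__ = [
    "CompositeResult",
    "RMAnovaResult",
    "align_sign",
    "rm_anova",
    "per_measure_tests",
    "summarize",
    "arrow_plot_data",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("composcore")


@dataclass
class CompositeResult:
    """Aligned composite scores with provenance."""

    method: str                       # "ae" or "pca"
    raw: np.ndarray
    aligned: np.ndarray
    sign_factor: int
    explained_variance: float | None
    row_index: list[tuple]


@dataclass
class RMAnovaResult:
    """Two-level repeated-measures ANOVA (paired-t reduction)."""

    F: float
    df: tuple[int, int]
    p: float
    t: float
    mean_difference: float
    n_pairs: int


def align_sign(
    raw: np.ndarray,
    data: StandardizedMatrix,
    directions: np.ndarray,
    method: str = "ae",
    explained_var: float | None = None,
) -> CompositeResult:
    """Flip a raw composite so improvement raises the score.

    The alignment proxy for record i is p_i = mean_k(d_k * z_ik), the
    direction-adjusted mean z-score; the sign factor is +1 when the raw
    composite correlates non-negatively with the proxy, else -1.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] != data.matrix.shape[0]:
        raise InsufficientDataError("one score per record required")
    if np.std(raw) == 0:
        raise DegenerateStatisticError(
            "composite has zero variance; sign alignment undefined"
        )
    d = np.asarray(directions, dtype=float)
    proxy = (data.matrix * d).mean(axis=1)
    corr = float(np.corrcoef(raw, proxy)[0, 1]) if np.std(proxy) > 0 else 1.0
    sign = 1 if corr >= 0 else -1
    return CompositeResult(
        method=method,
        raw=raw,
        aligned=sign * raw,
        sign_factor=sign,
        explained_variance=explained_var,
        row_index=list(data.row_index),
    )


def _paired_scores(
    scores: CompositeResult, data: CohortDataset
) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-subject (first-level, second-level) aligned scores."""
    level_a, level_b = data.condition_levels
    by_key = dict(zip(scores.row_index, scores.aligned))
    a, b, subjects = [], [], []
    for subj in data.subjects:
        ka, kb = (subj, level_a), (subj, level_b)
        if ka not in by_key or kb not in by_key:
            raise PairingError(
                f"subject {subj!r} lacks a record under one condition"
            )
        a.append(by_key[ka])
        b.append(by_key[kb])
        subjects.append(subj)
    return np.array(a), np.array(b), subjects


def rm_anova(scores: CompositeResult, data: CohortDataset) -> RMAnovaResult:
    """Repeated-measures ANOVA of the condition effect (two levels).

    Computed through the exact paired-t reduction: with paired
    differences d_i (second condition level minus first),
    t = mean(d) / (sd(d)/sqrt(n)), F = t^2 on (1, n-1) df, and p equals
    the two-sided paired-t p-value.
    """
    a, b, _ = _paired_scores(scores, data)
    n = len(a)
    if n < 2:
        raise InsufficientDataError("repeated-measures test needs >= 2 pairs")
    diff = b - a
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateStatisticError(
            "all paired differences identical; F statistic undefined"
        )
    t = float(diff.mean() / (sd / math.sqrt(n)))
    F = t * t
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return RMAnovaResult(
        F=F,
        df=(1, n - 1),
        p=p,
        t=t,
        mean_difference=float(diff.mean()),
        n_pairs=n,
    )


def per_measure_tests(data: CohortDataset) -> pd.DataFrame:
    """Paired t-test of the condition effect for each raw measure.

    Two within-subject levels make the paired t the canonical per-measure
    test; significance is flagged at p < 0.05 with no multiple-testing
    correction (the aggregate composite test is the primary analysis).
    """
    level_a, level_b = data.condition_levels
    ta = data.table[data.table["condition"] == level_a].set_index("subject")
    tb = data.table[data.table["condition"] == level_b].set_index("subject")
    rows = []
    for m in data.battery:
        va = ta[m.name].reindex(data.subjects).to_numpy(dtype=float)
        vb = tb[m.name].reindex(data.subjects).to_numpy(dtype=float)
        res = stats.ttest_rel(vb, va)
        rows.append(
            {
                "measure": m.name,
                "direction": m.direction,
                "mean_difference": float(np.mean(vb - va)),
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "significant_0.05": bool(res.pvalue < 0.05),
            }
        )
    return pd.DataFrame(rows)


def summarize(
    scores: CompositeResult | None, data: CohortDataset
) -> pd.DataFrame:
    """Per-condition summaries: mean, sample SD, SE, n.

    One row per (variable, condition), covering every raw measure and —
    when scores are given — the aligned composite.  SD/SE are reported as
    missing when a condition has a single record.
    """
    rows = []

    def _summary(name: str, cond: str, values: np.ndarray) -> dict:
        n = len(values)
        sd = float(np.std(values, ddof=1)) if n > 1 else float("nan")
        return {
            "variable": name,
            "condition": cond,
            "mean": float(np.mean(values)),
            "sd": sd,
            "se": sd / math.sqrt(n) if n > 1 else float("nan"),
            "n": n,
        }

    for cond in data.condition_levels:
        mask = (data.table["condition"] == cond).to_numpy()
        for m in data.battery:
            rows.append(
                _summary(m.name, cond, data.values[mask][:, data.measure_names.index(m.name)])
            )
        if scores is not None:
            cond_scores = np.array(
                [s for (key, s) in zip(scores.row_index, scores.aligned)
                 if key[1] == cond]
            )
            rows.append(_summary(f"composite_{scores.method}", cond, cond_scores))
    return pd.DataFrame(rows)


def arrow_plot_data(
    scores: CompositeResult, data: CohortDataset
) -> pd.DataFrame:
    """Per-subject score movement between conditions, for arrow plots.

    One row per subject with the aligned score under each condition level
    (from = first level, to = second level) plus a final ``group_mean``
    row; serializable straight to CSV.
    """
    a, b, subjects = _paired_scores(scores, data)
    frame = pd.DataFrame(
        {
            "subject": subjects,
            "from_condition": data.condition_levels[0],
            "from_score": a,
            "to_condition": data.condition_levels[1],
            "to_score": b,
            "displacement": b - a,
        }
    )
    mean_row = pd.DataFrame(
        {
            "subject": ["group_mean"],
            "from_condition": data.condition_levels[0],
            "from_score": [float(a.mean())],
            "to_condition": data.condition_levels[1],
            "to_score": [float(b.mean())],
            "displacement": [float(b.mean() - a.mean())],
        }
    )
    return pd.concat([frame, mean_row], ignore_index=True)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end comparison run needs."""

    input_csv: str | Path | None = None
    preset: str | None = None
    n_subjects: int | None = None
    generator: GeneratorConfig | None = None
    methods: tuple[str, ...] = ("ae", "pca")
    seed: int = 0
    epochs: int = 2000
    run_grid_search: bool = False
    scaler_policy: str = "train"
    out_dir: str | Path | None = None


def _load_or_simulate(cfg: PipelineConfig) -> CohortDataset:
    if cfg.input_csv is not None:
        return load_cohort(cfg.input_csv)
    if cfg.generator is not None:
        return generate_cohort(cfg.generator)
    if cfg.preset is not None:
        gen = preset_config(cfg.preset, seed=cfg.seed, n_subjects=cfg.n_subjects)
        if not isinstance(gen, GeneratorConfig):
            raise ConfigError(
                f"preset {cfg.preset!r} yields a standardized matrix, not a "
                "cohort; use a cohort preset for the pipeline"
            )
        return generate_cohort(gen)
    raise ConfigError("specify an input CSV, a generator config, or a preset")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Load or simulate a cohort, score it with the requested methods,
    test the condition effect, and assemble a reproducible report.

    Returns the report dict; with ``out_dir`` set, also writes
    report.json, scores.csv, summary.csv, loadings.csv and arrows.csv.
    The report depends only on the inputs and the seed (no timestamps),
    so identical configurations produce byte-identical bundles.
    """
    t0 = time.perf_counter()
    data = _load_or_simulate(cfg)
    logger.info("cohort: %d records, %d subjects (%.2fs)",
                data.n_records, len(data.subjects), time.perf_counter() - t0)
    sm = standardize(data)
    d = data.directions

    report: dict = {
        "config": {
            "input_csv": str(cfg.input_csv) if cfg.input_csv else None,
            "preset": cfg.preset,
            "n_subjects": cfg.n_subjects,
            "methods": list(cfg.methods),
            "seed": cfg.seed,
            "epochs": cfg.epochs,
            "grid_search": cfg.run_grid_search,
            "scaler_policy": cfg.scaler_policy,
        },
        "cohort": {
            "n_records": data.n_records,
            "n_subjects": len(data.subjects),
            "condition_levels": list(data.condition_levels),
            "measures": data.measure_names,
        },
        "methods": {},
        "per_measure_tests": per_measure_tests(data).to_dict(orient="records"),
        "multiple_testing_correction": "none (composite test is primary)",
    }

    score_frames = []
    summaries = []
    arrows_frames = []
    loadings_frame = None

    train_cfg = TrainingConfig(
        epochs=cfg.epochs, seed=cfg.seed, scaler_policy=cfg.scaler_policy
    )

    for method in cfg.methods:
        t1 = time.perf_counter()
        if method == "ae":
            if cfg.run_grid_search:
                arch, cv, table = grid_search(sm, train_cfg)
                report["methods"]["ae_grid"] = table.to_dict(orient="records")
            else:
                arch = AEArchitecture()
                cv = evaluate_cv(sm, arch, train_cfg)
            model = train_ae(sm, arch, train_cfg)
            raw = encode(model, sm)
            train_ev = explained_variance(sm.matrix, reconstruct(model, sm))
            comp = align_sign(raw, sm, d, method="ae", explained_var=train_ev)
            method_report = {
                "architecture": {
                    "hidden_width": arch.hidden_width,
                    "hidden_activation": arch.hidden_activation,
                    "dropout_rate": arch.dropout_rate,
                },
                "train_explained_variance": train_ev,
                "cv_mean_test_explained_variance": cv.explained_variance_fraction,
                "cv_mean_test_reconstruction_error": cv.reconstruction_error,
                "cv_runs": cv.runs,
                "final_training_loss": model.final_loss,
                "n_epochs_run": int(len(model.loss_trace) - 1),
            }
        elif method == "pca":
            pca = fit_pca(sm, n_components=2, directions=d)
            raw = pca_composite(pca)
            ev = float(pca.variance_fractions[0])
            comp = align_sign(raw, sm, d, method="pca", explained_var=ev)
            stable, stab_report = stability_check(sm, directions=d)
            loadings_frame = pd.DataFrame(
                {
                    "measure": data.measure_names,
                    "load_factor": pca.loadings[:, 0],
                    "direction_of_improvement": [
                        "Higher" if m.direction > 0 else "Lower"
                        for m in data.battery
                    ],
                }
            )
            method_report = {
                "pc1_variance_fraction": ev,
                "pc2_variance_fraction": float(pca.variance_fractions[1]),
                "loadings_pc1": pca.loadings[:, 0].tolist(),
                "stability": {"stable": stable, **stab_report},
            }
        else:
            raise ConfigError(f"unknown method {method!r}")

        anova = rm_anova(comp, data)
        method_report.update(
            {
                "sign_factor": comp.sign_factor,
                "rm_anova": {
                    "F": anova.F,
                    "df": list(anova.df),
                    "p": anova.p,
                    "t": anova.t,
                    "mean_difference": anova.mean_difference,
                    "n_pairs": anova.n_pairs,
                },
                "group_means": {
                    cond: float(
                        np.mean([s for key, s in zip(comp.row_index, comp.aligned)
                                 if key[1] == cond])
                    )
                    for cond in data.condition_levels
                },
            }
        )
        report["methods"][method] = method_report

        score_frames.append(
            pd.DataFrame(
                {
                    "subject": [k[0] for k in comp.row_index],
                    "condition": [k[1] for k in comp.row_index],
                    "method": method,
                    "composite_raw": comp.raw,
                    "composite_aligned": comp.aligned,
                }
            )
        )
        summaries.append(summarize(comp, data))
        arrows = arrow_plot_data(comp, data)
        arrows.insert(0, "method", method)
        arrows_frames.append(arrows)
        logger.info("method %s done in %.2fs (p=%.3g)",
                    method, time.perf_counter() - t1, anova.p)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.concat(score_frames, ignore_index=True).to_csv(
            out / "scores.csv", index=False
        )
        # summary rows are identical across methods except the composite row
        pd.concat(summaries, ignore_index=True).drop_duplicates().to_csv(
            out / "summary.csv", index=False
        )
        pd.concat(arrows_frames, ignore_index=True).to_csv(
            out / "arrows.csv", index=False
        )
        if loadings_frame is not None:
            loadings_frame.to_csv(out / "loadings.csv", index=False)
    return report
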