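"""End-to-end orchestration of the TMA prognostic-profiling pipeline.

:func:`run_pipeline` sequences the stages on a fully synthetic study —
spot scoring → matrix preprocessing → survival-linked clustering →
biomarker selection → supervised validation → gene-expression validation —
and returns (and optionally writes) a single JSON-serializable summary.
All randomness flows from one root seed, expanded per stage.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import (
    biomarker_selection,
    expression_validation,
    ihc_scoring,
    preprocessing,
    prognostic_clustering,
    synthetic_data,
)

log = logging.getLogger("tmaprog")

SUMMARY_SCHEMA_VERSION = 1
_FLOAT_DECIMALS = 6


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic pipeline run."""

    seed: int = 0
    # cohort
    n_patients: int = 56
    n_features: int = 108
    n_planted: int = 10
    effect: float = 2.0
    group_sizes: tuple[int, int] = (19, 37)
    missing_rate: float = 0.05
    censor_rate: float = 0.2
    hazards: tuple[float, float] = synthetic_data.DEFAULT_HAZARDS
    # tumor-vs-normal stage
    n_normals: int = 26
    n_aberrant: int = 8          # features shifted per direction in tumor
    aberrant_effect: float = 2.5
    # spot-scoring demo
    n_spots: int = 6
    spot_nuclei: int = 60
    # analysis settings
    scoring_mode: str = "nucleus"
    q_cuts: tuple[float, ...] = (0.05, 0.01)
    models: tuple[str, ...] = ("svm", "rf", "glm")
    train_fraction: float = 2.0 / 3.0
    n_genes: int = 300
    out_dir: str | None = None

    def validate(self) -> None:
        for q in self.q_cuts:
            if not 0.0 < q < 1.0:
                raise ValueError("q tiers must lie in (0, 1)")
        if self.scoring_mode not in ("nucleus", "pixel"):
            raise ValueError("scoring_mode must be 'nucleus' or 'pixel'")
        for m in self.models:
            if m not in ("svm", "rf", "glm"):
                raise ValueError(f"unknown model kind {m!r}")


def config_from_yaml(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("group_sizes", "hazards", "q_cuts", "models"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, _FLOAT_DECIMALS)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), _FLOAT_DECIMALS)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute every stage on synthetic data; return the summary dict.

    Any stage failure is re-raised with the stage name attached.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    seeds = _stage_seeds(cfg.seed)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": cfg.seed}
    stage = "setup"
    try:
        # ---- spot scoring demo -------------------------------------------
        stage = "spot_scoring"
        _stage(stage)
        rng = np.random.default_rng(seeds[0])
        errors = []
        for i in range(cfg.n_spots):
            frac = rng.dirichlet(np.ones(4))
            img, truth = synthetic_data.generate_spot_image(
                cfg.spot_nuclei, tuple(frac), seed=int(rng.integers(2**31))
            )
            _, h = ihc_scoring.score_spot(img, mode=cfg.scoring_mode)
            errors.append(abs(h.value - truth.true_h_score))
        summary["spot_scoring"] = {
            "n_spots": cfg.n_spots,
            "mean_abs_h_error": float(np.mean(errors)),
            "max_abs_h_error": float(np.max(errors)),
        }

        # ---- synthetic cohort --------------------------------------------
        stage = "synthetic_cohort"
        _stage(stage)
        mu_rng = np.random.default_rng(seeds[1])
        baseline_mu = mu_rng.uniform(80.0, 200.0, size=cfg.n_features)
        matrix, truth = synthetic_data.generate_cohort_matrix(
            cfg.n_patients,
            cfg.n_features,
            cfg.n_planted,
            cfg.effect,
            cfg.group_sizes,
            cfg.missing_rate,
            seed=seeds[1],
            hazards=cfg.hazards,
            censor_rate=cfg.censor_rate,
            baseline_mu=baseline_mu,
        )
        clinical = synthetic_data.clinical_to_frame(
            synthetic_data.generate_survival(truth, seed=seeds[2])
        )

        # matched normal tissue: same baselines, no prognostic structure;
        # tumor-aberrant features are shifted in the normal matrix so the
        # tumor appears increased / decreased, including one mislocalized
        # protein (one compartment up, another down)
        normal_matrix, _ = synthetic_data.generate_cohort_matrix(
            cfg.n_normals,
            cfg.n_features,
            0,
            0.0,
            (cfg.n_normals // 2, cfg.n_normals - cfg.n_normals // 2),
            cfg.missing_rate,
            seed=seeds[3],
            baseline_mu=baseline_mu,
        )
        ab_rng = np.random.default_rng(seeds[3])
        cols = list(matrix.columns)
        by_protein: dict[str, list[str]] = {}
        for c in cols:
            by_protein.setdefault(c.rsplit("_", 1)[0], []).append(c)
        multi = next(p for p, fs in sorted(by_protein.items()) if len(fs) >= 2)
        up = {by_protein[multi][0]}
        down = {by_protein[multi][1]}
        rest = [c for c in cols if c not in up | down]
        extra = ab_rng.choice(len(rest), size=2 * cfg.n_aberrant - 2, replace=False)
        for j, idx in enumerate(extra):
            (up if j % 2 == 0 else down).add(rest[idx])
        normal_matrix[sorted(up)] -= cfg.aberrant_effect * 30.0
        normal_matrix[sorted(down)] += cfg.aberrant_effect * 30.0
        normal_matrix = normal_matrix.clip(0.0, 300.0)
        normal_matrix.index = [f"NB{i + 1:03d}" for i in range(cfg.n_normals)]
        truth_aberrant = {"increased": sorted(up), "decreased": sorted(down)}

        # ---- preprocessing -----------------------------------------------
        stage = "preprocessing"
        _stage(stage)
        matrix_kept, excl_report = preprocessing.apply_exclusions(matrix, clinical)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normed = preprocessing.quantile_normalize(matrix_kept)
            complete = preprocessing.impute_missing(normed)
        summary["preprocessing"] = {
            "exclusion_report": excl_report,
            "n_patients": int(complete.shape[0]),
            "n_features": int(complete.shape[1]),
        }

        # ---- clustering + survival ---------------------------------------
        stage = "clustering_survival"
        _stage(stage)
        assignment = prognostic_clustering.hierarchical_cluster(complete, k=2)
        clin = clinical.loc[complete.index]
        assignment = prognostic_clustering.assign_prognosis_labels(
            assignment, clin["time_months"], clin["event"]
        )
        comp = prognostic_clustering.compare_group_survival(
            clin["time_months"], clin["event"], assignment.labels
        )
        ari = adjusted_rand_score(
            truth.group_assignment.loc[complete.index], assignment.labels
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cox = prognostic_clustering.cox_multivariate(clin, assignment.labels)
            combined = pd.concat([matrix_kept, normal_matrix])
            combined_norm = preprocessing.impute_missing(
                preprocessing.quantile_normalize(combined)
            )
            tissue = pd.Series(
                ["tumor"] * matrix_kept.shape[0] + ["normal"] * normal_matrix.shape[0],
                index=combined.index,
            )
            fisher_p, _ = prognostic_clustering.tumor_normal_separation(
                combined_norm, tissue
            )
        summary["clustering"] = {
            "cluster_sizes": assignment.labels.value_counts().sort_index().to_dict(),
            "poor_prognosis_label": assignment.poor_prognosis_label,
            "ari_vs_truth": float(ari),
            "median_survival_months": {str(k): v for k, v in comp.median_survival.items()},
            "logrank_chi2": comp.logrank_chi2,
            "logrank_p": comp.p_value,
            "tumor_normal_fisher_p": fisher_p,
            "cox": {
                cov: {k: float(v) for k, v in row.items()}
                for cov, row in cox.iterrows()
            },
        }

        # ---- biomarker selection -----------------------------------------
        stage = "biomarker_selection"
        _stage(stage)
        poor = assignment.poor_prognosis_label
        ttest = biomarker_selection.t_test_per_feature(
            complete, assignment.labels, poor_label=poor
        )
        selection: dict[str, dict] = {}
        markers_by_tier: dict[float, list[str]] = {}
        for q_cut in cfg.q_cuts:
            chosen = biomarker_selection.select_biomarkers(ttest, q_cut)
            markers_by_tier[q_cut] = [r.feature for r in chosen]
            tp = len(set(markers_by_tier[q_cut]) & truth.planted_features)
            selection[str(q_cut)] = {
                "n_selected": len(chosen),
                "n_planted_recovered": tp,
                "n_false_positive": len(chosen) - tp,
                "markers": [
                    {"feature": r.feature, "q": r.q_value, "direction": r.direction}
                    for r in chosen
                ],
            }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inc, dec = biomarker_selection.tumor_vs_normal(
                complete, preprocessing.impute_missing(normal_matrix), cfg.q_cuts[0]
            )
        misloc = biomarker_selection.detect_mislocalized(inc, dec)
        summary["biomarker_selection"] = selection
        summary["tumor_vs_normal"] = {
            "n_increased": len(inc),
            "n_decreased": len(dec),
            "mislocalized_proteins": misloc,
            "planted_aberrant": {
                k: len(v) for k, v in truth_aberrant.items()
            },
        }

        # ---- supervised validation ---------------------------------------
        stage = "supervised_validation"
        _stage(stage)
        markers = markers_by_tier[cfg.q_cuts[0]]
        sup: dict = {}
        if len(markers) == 0:
            sup["note"] = "no markers selected; supervised stage skipped"
        else:
            good = 2 if poor == 1 else 1
            from .supervised_validation import rank_features, split_train_test, train_eval

            split = split_train_test(assignment.labels, cfg.train_fraction, seed=seeds[4])
            for kind in cfg.models:
                ev = train_eval(
                    kind, complete[markers], assignment.labels, split, good, seed=seeds[4]
                )
                sup[kind] = {
                    "accuracy": ev.accuracy,
                    "sensitivity": ev.sensitivity,
                    "specificity": ev.specificity,
                    "auc": ev.auc,
                }
                if kind == "glm":
                    sup[kind]["feature_ranking"] = rank_features(ev)
        summary["supervised_validation"] = sup

        # ---- gene-expression validation ----------------------------------
        stage = "expression_validation"
        _stage(stage)
        planted_markers = sorted(truth.planted_features)
        if not planted_markers:
            summary["expression_validation"] = {
                "note": "no planted markers; expression validation skipped"
            }
            summary = _round_floats(summary)
            if cfg.out_dir is not None:
                _write_artifacts(cfg, summary, complete, assignment, clin)
            return summary
        expr, gene_map = synthetic_data.generate_expression_dataset(
            truth, n_genes=cfg.n_genes, seed=seeds[5]
        )
        genes = expression_validation.map_markers_to_genes(planted_markers, gene_map)
        D = expression_validation.gene_distance_matrix(expr, genes)
        coords = expression_validation.classical_mds(D, dim=2)
        km_labels = expression_validation.kmeans_two(coords, seed=seeds[6])
        expr_clin = synthetic_data.clinical_to_frame(
            synthetic_data.generate_survival(truth, seed=seeds[7])
        )
        comp2 = expression_validation.validate_survival(
            km_labels, expr_clin["time_months"], expr_clin["event"]
        )
        ari2 = adjusted_rand_score(truth.group_assignment, km_labels)
        summary["expression_validation"] = {
            "n_marker_genes": len(genes),
            "ari_vs_truth": float(ari2),
            "logrank_p": comp2.p_value,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = _round_floats(summary)
    if cfg.out_dir is not None:
        _write_artifacts(cfg, summary, complete, assignment, clin)
    return summary


def _write_artifacts(cfg, summary, complete, assignment, clin) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    preprocessing.write_matrix_tsv(complete, out / "matrix_normalized.tsv")
    assignment.labels.to_frame().to_csv(out / "cluster_labels.tsv", sep="\t")
    clin.to_csv(out / "clinical.csv")
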