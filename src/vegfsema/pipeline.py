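"""End-to-end orchestration of the synthetic (or user-supplied) analysis.

A single :class:`PipelineConfig` drives five stages in dependency order —
cohort simulation, cross-dataset differential expression, PLS-DA outcome
modelling, survival stratification, consensus clustering, and the
per-sample binding simulation — writing TSV/JSON outputs plus a manifest
recording inputs, seed and per-stage status.  Each stage draws its
randomness from a child seed derived from (global seed, stage name), so
any stage reproduces in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding, cohort, consensus, diffexp, plsda, survival
from .panel import ExpressionMatrix, center_on_normals, default_vegf_sema_panel

ALL_STAGES = ("simulate", "de", "plsda", "survival", "cluster", "binding")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "vegfsema_out"
    stages: tuple[str, ...] = ALL_STAGES
    n_datasets: int = 4
    n_components: int = 2
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    n_resamples: int = 500
    expression_tsv: str | None = None   # user data instead of simulation
    metadata_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across platforms)."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class StageStatus:
    name: str
    status: str
    outputs: list[str] = field(default_factory=list)
    error: str | None = None


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "gene") -> str:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
    return str(path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    statuses: list[StageStatus] = []
    state: dict = {}
    failed = set()

    deps = {"simulate": (), "de": ("simulate",), "plsda": ("simulate",),
            "survival": ("plsda",), "cluster": ("simulate",),
            "binding": ("simulate",)}
    requested = [s for s in ALL_STAGES if s in cfg.stages]
    for s in requested:
        if s not in deps:
            raise ValueError(f"unknown stage {s!r}")

    done: set[str] = set()
    for stage in requested:
        unmet = [d for d in deps[stage] if d not in done]
        if unmet:
            failed.add(stage)
            statuses.append(StageStatus(
                stage, "skipped",
                error=f"unmet upstream stages: {unmet}"))
            continue
        try:
            outputs = _run_stage(stage, cfg, state, out)
            statuses.append(StageStatus(stage, "completed", outputs))
            done.add(stage)
        except Exception as exc:  # recorded per stage; dependents skipped
            failed.add(stage)
            statuses.append(StageStatus(stage, "failed", error=str(exc)))

    manifest = {
        "seed": cfg.seed,
        "stages": [{"name": s.name, "status": s.status, "outputs": s.outputs,
                    "error": s.error} for s in statuses],
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "n_failed": len(failed),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _simulate(cfg: PipelineConfig, state: dict, out: Path) -> list[str]:
    seed = stage_seed(cfg.seed, "simulate")
    rng = np.random.default_rng(seed)
    eff = cohort.default_effect_table()
    if cfg.expression_tsv is not None:
        from .panel import read_expression_tsv, subset_to_panel
        m = subset_to_panel(
            read_expression_tsv(cfg.expression_tsv, cfg.metadata_tsv),
            default_vegf_sema_panel(), on_missing="drop")
        state["main_cohort"] = m
        state["datasets"] = [m]
        state["met_cohort"] = m
        return []
    main_cfg = cohort.CohortConfig.gse35988_like()
    m, truth = cohort.simulate_cohort(main_cfg, eff, rng)
    state["main_cohort"] = m
    state["truth"] = truth
    bcr_cfg = cohort.CohortConfig.bcr_cohort()
    bm, btruth = cohort.simulate_cohort(bcr_cfg, eff, rng)
    state["bcr_cohort"] = cohort.attach_bcr_outcomes(bm, bcr_cfg, rng, btruth)
    state["datasets"] = cohort.simulate_multidataset(
        cohort.CohortConfig(), eff, n_datasets=cfg.n_datasets, seed=rng)
    met_m, _ = cohort.simulate_cohort(cohort.CohortConfig.multi_metastasis(), eff, rng)
    state["met_cohort"] = met_m
    expr = out / "cohort_expression.tsv"
    meta = out / "cohort_metadata.tsv"
    m.write_tsv(expr, meta)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, default=float)
    return [str(expr), str(meta), str(out / "truth.json")]


def _run_stage(stage: str, cfg: PipelineConfig, state: dict, out: Path) -> list[str]:
    if stage == "simulate":
        return _simulate(cfg, state, out)

    if stage == "de":
        tables = [diffexp.compare_groups(m, "normal", "primary")
                  for m in state["datasets"]]
        rec = diffexp.recurrence_summary(tables)
        paths = []
        for i, tab in enumerate(tables):
            paths.append(_write_tsv(tab, out / f"de_primary_vs_normal_ds{i + 1}.tsv"))
        paths.append(_write_tsv(rec, out / "recurrence_primary_vs_normal.tsv"))
        return paths

    if stage == "plsda":
        m = state.get("bcr_cohort", state["main_cohort"])
        sel = plsda.select_outcome_cohort(m)
        X, y, genes = plsda.outcome_design(sel)
        model = plsda.fit_plsda(X, y, n_components=cfg.n_components,
                                feature_names=genes)
        report = plsda.cv_accuracy(X, y, n_components=cfg.n_components,
                                   seed=stage_seed(cfg.seed, "plsda"))
        roc = plsda.loocv_roc(X, y, n_components=cfg.n_components)
        state["plsda_model"] = model
        state["outcome_cohort"] = sel
        paths = [_write_tsv(model.loadings_table(), out / "plsda_loadings.tsv")]
        with open(out / "plsda_cv.json", "w") as fh:
            json.dump({**report.to_json_dict(), "loocv_auc": roc.auc}, fh, indent=2)
        paths.append(str(out / "plsda_cv.json"))
        return paths

    if stage == "survival":
        curves, lr = survival.compare_survival_by_class(
            state["outcome_cohort"], state["plsda_model"])
        paths = []
        for name, c in curves.items():
            df = pd.DataFrame({"time": c.event_times, "at_risk": c.at_risk,
                               "events": c.n_events, "survival": c.survival})
            paths.append(_write_tsv(df, out / f"km_{name}.tsv", index_label="i"))
        with open(out / "logrank.json", "w") as fh:
            json.dump({"chi2": lr.chi2, "df": lr.df, "p": lr.p}, fh, indent=2)
        paths.append(str(out / "logrank.json"))
        return paths

    if stage == "cluster":
        met = state["met_cohort"]
        centered = center_on_normals(met)
        mets = centered.select_samples(
            list(centered.metadata.index[centered.tissue_mask("metastatic")]))
        model = consensus.ConsensusKMeans(
            k_range=cfg.k_range, n_resamples=cfg.n_resamples,
            random_state=stage_seed(cfg.seed, "cluster"))
        model.fit(mets.values.to_numpy())
        assoc = consensus.cluster_patient_association(
            model.labels_, mets.metadata["patient_id"].to_numpy(),
            seed=stage_seed(cfg.seed, "cluster") + 1)
        assign = pd.DataFrame({"cluster": model.labels_,
                               "patient_id": mets.metadata["patient_id"]},
                              index=mets.sample_ids)
        paths = [_write_tsv(assign, out / "cluster_assignments.tsv", "sample_id"),
                 _write_tsv(pd.DataFrame(model.consensus_[model.k_],
                                         index=mets.sample_ids,
                                         columns=mets.sample_ids),
                            out / "consensus_matrix.tsv", "sample_id")]
        with open(out / "cluster_association.json", "w") as fh:
            json.dump({"k": model.k_, "pac": model.pac_,
                       "low_confidence": model.low_confidence_,
                       "chi2": assoc["chi2"], "df": assoc["df"],
                       "p_asymptotic": assoc["p_asymptotic"],
                       "p_permutation": assoc["p_permutation"]}, fh, indent=2)
        paths.append(str(out / "cluster_association.json"))
        return paths

    if stage == "binding":
        m = state["main_cohort"]
        params = binding.default_parameters()
        results = binding.run_population(params, m)
        agg = binding.aggregates_frame(results, m)
        comp = binding.group_compare_complexes(results, m)
        fits = binding.variance_explained(results, m)
        quad = binding.quadrant_classify(results, m)
        paths = [
            _write_tsv(agg, out / "binding_aggregates.tsv", "sample_id"),
            _write_tsv(comp, out / "binding_group_tests.tsv", "i"),
            _write_tsv(fits, out / "binding_regressions.tsv", "i"),
            _write_tsv(quad, out / "binding_quadrants.tsv", "sample_id"),
        ]
        return paths

    raise ValueError(f"unknown stage {stage!r}")
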