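"""End-to-end orchestration of the writer-signature analysis.

Stages, in order: cohort ingest/generation, consensus-NMF subtyping,
differential expression between subtypes, VNLHHO gene selection over the
DEGs, prognostic screening, signature construction (screen intersected
with the selected genes), PCA score fitting with a maximally selected
rank-statistic cutpoint, and survival-based evaluation (KM, log-rank,
Cox, time-dependent AUC, concordance), with an optional second cohort
scored by the frozen model and an optional gene-subtype re-clustering of
the prognostic DEGs.

Every stage's random stream derives from the single global seed by a
fixed offset, so changing one stage's settings never perturbs another's
draws.  Outputs are plain TSV/JSON plus a manifest with content digests,
so two runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (CohortConfig, SyntheticCohort, generate_cohort,
                       read_expression, read_clinical, align_cohort,
                       ExpressionMatrix, write_tsv)
from .cnmf import consensus_cluster
from .de import moderated_t_test, filter_degs
from .vnlhho import VNLHHOConfig, select_features
from .survival import (km_curve, logrank, cox_fit, prognostic_screen,
                       max_rank_cutpoint, td_auc, c_index)
from .score import fit_score, apply_score, stratify
from .errors import PipelineError, InputError, WritersigError

log = logging.getLogger("writersig")

# fixed per-stage seed offsets (kept < 2**31 with any small global seed)
STAGE_SEED_OFFSETS = {
    "cohort": 0,
    "subtype": 101,
    "select": 202,
    "cutpoint": 303,
    "gene_subtype": 404,
}


@dataclass
class PipelineConfig:
    """Structured configuration mirroring the CLI flags."""

    expression_path: str | None = None
    clinical_path: str | None = None
    validation_expression_path: str | None = None
    validation_clinical_path: str | None = None
    synthetic: CohortConfig | None = None
    validation_synthetic: CohortConfig | None = None
    k_subtypes: int = 2
    n_consensus_runs: int = 30
    lfc_min: float = 0.5
    p_max: float = 0.05
    screen_alpha: float = 0.001
    vnlhho: VNLHHOConfig = field(default_factory=VNLHHOConfig)
    cutpoint_minprop: float = 0.1
    cutpoint_permutations: int = 0
    horizons: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    gene_subtypes: bool = True
    output_dir: str = "writersig_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_max < 1 and 0 < self.screen_alpha < 1):
            raise PipelineError("config", "p thresholds must lie in (0, 1)")
        if list(self.horizons) != sorted(self.horizons) or min(self.horizons) <= 0:
            raise PipelineError("config", "horizons must be positive and increasing")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            raw["synthetic"] = CohortConfig(**raw["synthetic"])
        if "validation_synthetic" in raw and isinstance(raw["validation_synthetic"], dict):
            raw["validation_synthetic"] = CohortConfig(**raw["validation_synthetic"])
        if "vnlhho" in raw and isinstance(raw["vnlhho"], dict):
            raw["vnlhho"] = VNLHHOConfig(**raw["vnlhho"])
        if "horizons" in raw:
            raw["horizons"] = tuple(raw["horizons"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return int(config.seed) + STAGE_SEED_OFFSETS[stage]


def _load_cohort(config: PipelineConfig, validation: bool):
    if validation:
        expr_path, clin_path = (config.validation_expression_path,
                                config.validation_clinical_path)
        synth = config.validation_synthetic
    else:
        expr_path, clin_path = config.expression_path, config.clinical_path
        synth = config.synthetic
    if expr_path is not None:
        if clin_path is None:
            raise PipelineError("cohort", "expression given without clinical table")
        expression = read_expression(expr_path)
        clinical = read_clinical(clin_path)
        return align_cohort(expression, clinical)
    if synth is not None:
        seed = synth.seed if synth.seed else _stage_seed(config, "cohort") + (7 if validation else 0)
        cohort = generate_cohort(dataclasses.replace(synth, seed=seed))
        return cohort.expression, cohort.clinical
    return None


def _evaluate(scores: pd.DataFrame, clinical: pd.DataFrame,
              config: PipelineConfig, label: str) -> dict:
    """KM / log-rank / Cox / AUC / C-index for a scored, stratified cohort."""
    merged = scores.merge(clinical, on="sample_id", validate="one_to_one")
    t = merged["os_years"].to_numpy(float)
    e = merged["os_event"].to_numpy(int)
    s = merged["pca_score"].to_numpy(float)
    high = (merged["stratum"] == "high").to_numpy()
    out: dict = {"cohort": label, "n": int(len(merged)),
                 "n_events": int(e.sum())}
    if 0 < high.sum() < high.size:
        chi2, p = logrank(t, e, high)
        km_low, km_high = km_curve(t[~high], e[~high]), km_curve(t[high], e[high])
        out["logrank_chi2"] = chi2
        out["logrank_p"] = p
        out["median_os_low"] = km_low.median
        out["median_os_high"] = km_high.median
    else:
        out["logrank_p"] = None

    cox_uni = cox_fit(t, e, s, names=["pca_score"])
    out["cox_univariate"] = _cox_dict(cox_uni)
    covs, names = [s], ["pca_score"]
    if "age" in merged:
        covs.append(merged["age"].to_numpy(float))
        names.append("age")
    for col in merged.columns:
        if col.endswith("_status") or col in ("gender", "grade"):
            codes = pd.factorize(merged[col])[0].astype(float)
            if codes.std() > 0:
                covs.append(codes)
                names.append(col)
    if len(covs) > 1:
        out["cox_multivariate"] = _cox_dict(cox_fit(t, e, np.column_stack(covs), names=names))
    aucs = {}
    for h in config.horizons:
        try:
            aucs[str(h)] = td_auc(s, t, e, h)
        except InputError:
            aucs[str(h)] = None
    out["td_auc"] = aucs
    out["c_index"] = c_index(s, t, e)
    return out


def _cox_dict(res) -> dict:
    return {
        "names": res.names,
        "coef": res.coef.tolist(),
        "hazard_ratio": res.hazard_ratio.tolist(),
        "ci_low": res.ci_low.tolist(),
        "ci_high": res.ci_high.tolist(),
        "p_value": res.p_value.tolist(),
        "converged": res.converged,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write artifacts and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": _config_echo(config), "stages": {}}
    t_start = time.perf_counter()

    def record(stage: str, files: dict[str, Path], **counts) -> None:
        manifest["stages"][stage] = {
            "outputs": {name: {"path": str(p.relative_to(out)), "sha256": _digest(p)}
                        for name, p in files.items()},
            **counts,
        }
        log.info("stage %-12s done at %6.1fs %s", stage,
                 time.perf_counter() - t_start, counts or "")

    # 1. cohort --------------------------------------------------------
    loaded = _load_cohort(config, validation=False)
    if loaded is None:
        raise PipelineError("cohort", "no input files and no synthetic config",
                            "set expression_path/clinical_path or synthetic")
    expression, clinical = loaded
    expr_path = out / "expression.tsv"
    frame = expression.to_frame()
    frame.index.name = "gene_id"
    write_tsv(frame, expr_path, index=True)
    clin_path = out / "clinical.tsv"
    write_tsv(clinical, clin_path)
    record("cohort", {"expression": expr_path, "clinical": clin_path},
           n_samples=len(expression.sample_ids), n_genes=len(expression.gene_ids))

    # 2. consensus subtyping ------------------------------------------
    sub = consensus_cluster(expression.values, k=config.k_subtypes,
                            n_runs=config.n_consensus_runs,
                            seed=_stage_seed(config, "subtype"))
    labels = pd.DataFrame({"sample_id": expression.sample_ids,
                           "subtype": sub.labels})
    labels_path = out / "subtypes.tsv"
    labels.to_csv(labels_path, sep="\t", index=False)
    cons_path = out / "consensus.tsv"
    write_tsv(pd.DataFrame(sub.consensus, index=expression.sample_ids,
                           columns=expression.sample_ids), cons_path, index=True)
    diag_path = out / "subtype_diagnostics.json"
    diag_path.write_text(json.dumps({
        "k": sub.k, "n_runs": sub.n_runs, "asw": sub.asw,
        "cophenetic": sub.cophenetic, "degenerate": sub.degenerate,
        "seed": _stage_seed(config, "subtype"),
    }, indent=1))
    record("subtype", {"labels": labels_path, "consensus": cons_path,
                       "diagnostics": diag_path},
           asw=sub.asw, sizes=np.bincount(sub.labels)[1:].tolist())
    if sub.degenerate:
        raise PipelineError("subtype", "consensus clustering degenerate "
                            "(all samples co-cluster)", "check input variation")

    # 3. differential expression --------------------------------------
    de_table = moderated_t_test(expression, sub.labels)
    de_path = out / "deg_table.tsv"
    de_table.to_csv(de_path, sep="\t", index=False, float_format="%.6g")
    degs = filter_degs(de_table, lfc_min=config.lfc_min, p_max=config.p_max)
    degs_path = out / "degs.txt"
    degs_path.write_text("\n".join(degs) + "\n")
    record("de", {"table": de_path, "degs": degs_path}, n_degs=len(degs))
    if not degs:
        raise PipelineError("de", "no genes pass the DEG filter",
                            "relax lfc_min/p_max or check subtyping")

    # 4. VNLHHO selection over DEGs -----------------------------------
    deg_matrix = expression.subset(degs)
    vcfg = dataclasses.replace(config.vnlhho, seed=_stage_seed(config, "select"))
    selection = select_features(deg_matrix, sub.labels, vcfg)
    sel_path = out / "selected_genes.txt"
    sel_path.write_text("\n".join(selection.selected_genes) + "\n")
    sel_json = out / "selection.json"
    sel_json.write_text(json.dumps({
        "selected_genes": selection.selected_genes,
        "best_fitness": selection.best_fitness,
        "fitness_history": selection.fitness_history,
        "n_evaluations": selection.n_evaluations,
        "config": asdict(selection.config_echo),
    }, indent=1))
    record("select", {"genes": sel_path, "result": sel_json},
           n_selected=len(selection.selected_genes))

    # 5. prognostic screen of DEGs ------------------------------------
    screened = prognostic_screen(expression, clinical, degs,
                                 alpha=config.screen_alpha)
    screen_path = out / "prognostic_genes.txt"
    screen_path.write_text("\n".join(screened) + ("\n" if screened else ""))
    record("screen", {"genes": screen_path}, n_prognostic=len(screened))

    # 6. signature = screen ∩ selected --------------------------------
    screen_set = set(screened)
    signature = [g for g in selection.selected_genes if g in screen_set]
    sig_path = out / "signature_genes.txt"
    sig_path.write_text("\n".join(signature) + ("\n" if signature else ""))
    record("signature", {"genes": sig_path}, n_signature=len(signature))
    if len(signature) < 2:
        raise PipelineError("signature",
                            f"empty or singleton signature ({len(signature)} genes)",
                            "lower screen_alpha stringency or raise effect size")

    # 7. score model ---------------------------------------------------
    model = fit_score(expression, signature)
    train_scores = apply_score(model, expression)
    merged = train_scores.merge(clinical, on="sample_id")
    cut = max_rank_cutpoint(merged["pca_score"].to_numpy(float),
                            merged["os_years"].to_numpy(float),
                            merged["os_event"].to_numpy(int),
                            minprop=config.cutpoint_minprop,
                            n_permutations=config.cutpoint_permutations,
                            seed=_stage_seed(config, "cutpoint"))
    model.cutpoint = cut.cutpoint
    train_scores = stratify(train_scores, model)
    merged = train_scores.merge(clinical, on="sample_id")
    high = (merged["stratum"] == "high").to_numpy()
    km_high = km_curve(merged.loc[high, "os_years"], merged.loc[high, "os_event"])
    km_low = km_curve(merged.loc[~high, "os_years"], merged.loc[~high, "os_event"])

    def _risk_key(c):  # prefer median OS; fall back to final survival level
        if c.median is not None:
            return c.median
        return 1e9 + (c.survival[-1] if c.survival.size else 1.0)

    model.risk_direction = ("high_score_high_risk"
                            if _risk_key(km_high) <= _risk_key(km_low)
                            else "high_score_low_risk")
    model_path = out / "score_model.json"
    model.to_json(model_path)
    scores_path = out / "scores.tsv"
    write_tsv(train_scores, scores_path)
    record("score", {"model": model_path, "scores": scores_path},
           cutpoint=cut.cutpoint, max_statistic=cut.max_statistic,
           risk_direction=model.risk_direction)

    # 8. evaluation (+ optional validation cohort, gene subtypes) ------
    evaluation = {"training": _evaluate(train_scores, clinical, config, "training")}
    val = _load_cohort(config, validation=True)
    if val is not None:
        v_expr, v_clin = val
        val_scores = stratify(apply_score(model, v_expr), model)
        val_scores_path = out / "scores_validation.tsv"
        write_tsv(val_scores, val_scores_path)
        evaluation["validation"] = _evaluate(val_scores, v_clin, config, "validation")
    if config.gene_subtypes and screened:
        gene_sub = consensus_cluster(expression.subset(screened).values,
                                     k=config.k_subtypes,
                                     n_runs=config.n_consensus_runs,
                                     seed=_stage_seed(config, "gene_subtype"))
        gs_path = out / "gene_subtypes.tsv"
        pd.DataFrame({"sample_id": expression.sample_ids,
                      "gene_subtype": gene_sub.labels}).to_csv(gs_path, sep="\t",
                                                               index=False)
        evaluation["gene_subtype"] = {"asw": gene_sub.asw,
                                      "cophenetic": gene_sub.cophenetic,
                                      "sizes": np.bincount(gene_sub.labels)[1:].tolist()}
        manifest["stages"]["gene_subtype"] = {
            "outputs": {"labels": {"path": str(gs_path.relative_to(out)),
                                   "sha256": _digest(gs_path)}},
            "asw": gene_sub.asw,
        }
    eval_path = out / "evaluation.json"
    eval_path.write_text(json.dumps(evaluation, indent=1))
    record("evaluate", {"evaluation": eval_path})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    return json.loads(json.dumps(echo, default=str))
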