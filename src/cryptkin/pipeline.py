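"""End-to-end orchestration: preprocess -> dichotomize -> deletion/NFS ->
associations -> regressions -> enrichment, with a JSON run manifest.

The pipeline consumes either directories written by
:func:`cryptkin.synthetic.write_cohort` (or equivalently formatted user
exports) or in-memory :class:`~cryptkin.synthetic.SyntheticCohort` objects.
Every stage logs its input/output row counts — the joined denominator of
each analysis is always explicit — and the manifest records seeds,
thresholds and SHA-256 checksums of every output file, so a re-run with the
same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna, enrichment as enr, preprocess as pp, stats as st
from .io_formats import read_gmt
from .registry import DEFAULT_REGISTRY
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort, read_cohort

logger = logging.getLogger(__name__)

CLINICAL_CATEGORICAL = [
    "sex", "location", "t_stage", "n_stage", "m_stage", "tnm_stage",
    "msi_status", "subtype", "braf_mut", "tp53_mut",
]
CLINICAL_CONTINUOUS = ["age", "fga", "tmb", "aneuploidy"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    output_dir: str | Path
    cohort_dirs: dict[str, str | Path] = dc_field(default_factory=dict)
    simulate: dict[str, CohortSpec] = dc_field(default_factory=dict)
    recipe: pp.NormalizationRecipe = dc_field(default_factory=pp.NormalizationRecipe)
    deletion_threshold: float = cna.DELETION_THRESHOLD
    five_prime_only: bool = False
    gene_sets_path: str | Path | None = None
    n_perm: int = 1000
    permutation_mode: str = "phenotype"
    seed: int = 0
    exclusion_list: list[str] = dc_field(default_factory=list)
    blocks: tuple[str, ...] = ("fusion", "associations", "regression", "enrichment")

    def validate(self) -> None:
        if not self.cohort_dirs and not self.simulate:
            raise ValueError("config must name cohort directories or simulation specs")
        for label, d in self.cohort_dirs.items():
            d = Path(d)
            for name in ("expression.gct", "segments.seg", "clinical.tsv"):
                if not (d / name).exists():
                    raise ValueError(f"cohort {label!r}: missing input file {d / name}")
        if self.gene_sets_path is not None and not Path(self.gene_sets_path).exists():
            raise ValueError(f"gene set file not found: {self.gene_sets_path}")
        if self.deletion_threshold >= 0:
            raise ValueError("deletion threshold must be negative")


def exclude_known_fusions(samples, exclusion_list) -> list[str]:
    """Drop samples on a known fusion-positive exclusion list (set difference).

    Ids on the list that are absent from the cohort are logged and ignored.
    """
    sample_set = list(samples)
    excluded = [s for s in exclusion_list if s in sample_set]
    missing = [s for s in exclusion_list if s not in sample_set]
    if missing:
        logger.warning("exclusion ids not present in cohort: %s", missing)
    kept = [s for s in sample_set if s not in set(excluded)]
    logger.info("excluded %d known fusion-positive samples, %d retained",
                len(excluded), len(kept))
    return kept


def run_pipeline(config: PipelineConfig, cohorts: dict[str, SyntheticCohort] | None = None) -> dict:
    """Execute the configured stages in order; returns the result bundle.

    ``cohorts`` may inject in-memory cohorts (e.g. from
    :func:`~cryptkin.synthetic.generate_cohort`); otherwise they are read
    from ``config.cohort_dirs`` or generated from ``config.simulate``.
    """
    if cohorts is None:
        config.validate()
        cohorts = {}
        for label, d in config.cohort_dirs.items():
            cohorts[label] = read_cohort(d)
        for label, spec in config.simulate.items():
            cohorts[label] = generate_cohort(spec)
    if not cohorts:
        raise ValueError("no cohorts to analyse")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "deletion_threshold": config.deletion_threshold,
        "n_perm": config.n_perm,
        "stages": {},
        "outputs": {},
    }
    results: dict = {}

    # --- stage: preprocess + pool -------------------------------------
    ntrk_tables = {}
    for label, cohort in cohorts.items():
        kept = exclude_known_fusions(cohort.expression.samples, config.exclusion_list)
        expr = cohort.expression.values[kept]
        ntrk = expr.loc[expr.index.intersection(["NTRK1", "NTRK2", "NTRK3"])]
        normalized = pp.winsorize_normalize(ntrk, config.recipe)
        profile = normalized.T
        profile = profile.join(cohort.clinical.loc[kept], how="left")
        ntrk_tables[label] = profile
    pooled, bias_report = pp.pool_cohorts(
        ntrk_tables, config.recipe,
        continuous=[c for c in ["NTRK1", "NTRK2", "NTRK3", *CLINICAL_CONTINUOUS]
                    if c in next(iter(ntrk_tables.values())).columns],
        categorical=[c for c in CLINICAL_CATEGORICAL
                     if c in next(iter(ntrk_tables.values())).columns],
    )
    manifest["stages"]["preprocess"] = {
        "cohorts": {k: len(v) for k, v in ntrk_tables.items()},
        "pooled_n": len(pooled),
    }
    results["pooled"] = pooled
    results["bias_report"] = bias_report
    _write_output(bias_report, outdir / "cohort_bias.tsv", manifest)

    # --- stage: dichotomize -------------------------------------------
    gene_cols = [g for g in ("NTRK1", "NTRK2", "NTRK3") if g in pooled.columns]
    expr_pooled = pooled[gene_cols].T
    labels = pp.dichotomize_matrix(expr_pooled, config.recipe)
    results["dichotomized"] = labels
    _write_output(labels.T, outdir / "expression_labels.tsv", manifest)

    # --- stage: deletions + fusion scores -----------------------------
    if "fusion" in config.blocks:
        all_segments = [s for cohort in cohorts.values() for s in cohort.segments]
        deletions = cna.call_deletions_cohort(
            all_segments, DEFAULT_REGISTRY, config.deletion_threshold,
            samples=list(pooled.index), five_prime_only=config.five_prime_only,
        )
        ntrk3_high = labels.loc["NTRK3"] == "high"
        scores = cna.score_cohort(deletions, ntrk3_high)
        summary = cna.summarize_fusion_cohort(scores)
        score_frame = cna.scores_to_frame(scores)
        results["deletions"] = deletions
        results["fusion_scores"] = score_frame
        results["fusion_summary"] = summary
        manifest["stages"]["fusion"] = {
            "joined_n": summary["n"],
            "nfs1_high": summary["nfs1_high"],
            "nfs2_high": summary["nfs2_high"],
        }
        _write_output(score_frame, outdir / "fusion_scores.tsv", manifest)
        (outdir / "fusion_summary.json").write_text(json.dumps(summary, indent=1))
        _record_file(outdir / "fusion_summary.json", manifest)
        pooled = pooled.join(score_frame[["nfs1", "nfs2", "nfs1_high", "nfs2_high"]], how="left")
        results["pooled"] = pooled

    # --- stage: clinicopathological associations ----------------------
    if "associations" in config.blocks:
        assoc_tables = {}
        outcomes = gene_cols + (
            ["nfs1_high", "nfs2_high"] if "nfs1_high" in pooled.columns else []
        )
        for outcome in outcomes:
            if outcome in gene_cols:
                out_labels = labels.loc[outcome]
            else:
                out_labels = pooled[outcome].map({True: "high", False: "low"})
            block = []
            for var in CLINICAL_CATEGORICAL:
                if var not in pooled.columns:
                    continue
                table = pd.crosstab(pooled[var], out_labels)
                try:
                    res = st.chi_square(table, predictor=var, outcome=outcome)
                except ValueError:
                    continue
                block.append(res)
            for var in CLINICAL_CONTINUOUS:
                if var not in pooled.columns:
                    continue
                mask = pooled[var].notna() & out_labels.notna()
                try:
                    res = st.group_difference(
                        pooled.loc[mask, var], out_labels[mask],
                        method="anova", predictor=var, outcome=outcome,
                    )
                except ValueError:
                    continue
                block.append(res)
            assoc_tables[outcome] = st.association_block(block)
        assoc = pd.concat(assoc_tables.values(), ignore_index=True) if assoc_tables else pd.DataFrame()
        results["associations"] = assoc
        manifest["stages"]["associations"] = {"n_tests": len(assoc)}
        _write_output(assoc, outdir / "associations.tsv", manifest)

    # --- stage: deregulation regressions ------------------------------
    if "regression" in config.blocks:
        fits = {}
        meth = pd.concat(
            [c.methylation.T for c in cohorts.values() if not c.methylation.empty]
        ) if any(not c.methylation.empty for c in cohorts.values()) else pd.DataFrame()
        cna_cats = pd.concat([c.gene_cna.T for c in cohorts.values()])
        cohort_indicator = (pooled[config.recipe.cohort_column]
                            == list(cohorts)[0]).astype(float)
        for gene in gene_cols:
            design = pd.DataFrame(index=pooled.index)
            if gene in meth.columns:
                design["methylation"] = meth[gene]
            if gene in cna_cats.columns:
                design["cna"] = cna_cats[gene].astype(float)
            if gene == "NTRK3" and "nfs2" in pooled.columns:
                design["nfs2"] = pooled["nfs2"].astype(float)
            if len(cohorts) > 1:
                design["cohort"] = cohort_indicator
            design = design.dropna(axis=1, how="all")
            if design.empty:
                continue
            mask = design.notna().all(axis=1) & pooled[gene].notna()
            if mask.sum() <= design.shape[1] + 2:
                continue
            fits[gene] = st.fit_linear(
                pooled.loc[mask, gene], design.loc[mask], outcome_name=gene
            )
        results["regressions"] = fits
        reg_rows = [
            {"outcome": f.outcome, "term": name, "B": coef, "p_value": p,
             "adjusted_r2": f.adjusted_r2, "f_statistic": f.f_statistic,
             "model_p": f.model_p, "n_used": f.n_used}
            for f in fits.values() for name, coef, p in f.terms
        ]
        reg_frame = pd.DataFrame(reg_rows)
        manifest["stages"]["regression"] = {"n_models": len(fits)}
        _write_output(reg_frame, outdir / "regressions.tsv", manifest)

    # --- stage: enrichment (per cohort, as gene panels differ) --------
    if "enrichment" in config.blocks and config.gene_sets_path is not None:
        collection = read_gmt(config.gene_sets_path)
        enr_frames = []
        for label, cohort in cohorts.items():
            cohort_samples = [s for s in cohort.expression.samples if s in labels.columns]
            phenotype = labels.loc["NTRK3", cohort_samples].tolist()
            if len(set(phenotype)) < 2:
                logger.warning("cohort %s: single phenotype class, skipping enrichment", label)
                continue
            res = enr.permutation_null(
                cohort.expression.values[cohort_samples], phenotype,
                collection, n_perm=config.n_perm, mode=config.permutation_mode,
                seed=config.seed, positive_class="high",
            )
            frame = pd.DataFrame(
                [{"cohort": label, "set_name": r.set_name, "es": r.es,
                  "nes": r.nes, "nominal_p": r.nominal_p, "fdr": r.fdr,
                  "size": r.size} for r in res]
            )
            enr_frames.append(frame)
        if enr_frames:
            enr_table = pd.concat(enr_frames, ignore_index=True)
            results["enrichment"] = enr_table
            manifest["stages"]["enrichment"] = {"n_rows": len(enr_table)}
            _write_output(enr_table, outdir / "enrichment.tsv", manifest)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    results["manifest_path"] = manifest_path
    return results


def _write_output(frame: pd.DataFrame, path: Path, manifest: dict) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g")
    _record_file(path, manifest)


def _record_file(path: Path, manifest: dict) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest["outputs"][path.name] = {"sha256": digest, "bytes": path.stat().st_size}
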