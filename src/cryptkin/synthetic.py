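"""Synthetic two-cohort colorectal-cancer data with planted structure.

The generator emulates the statistical skeleton the analysis assumes, so the
whole pipeline is testable without any data download:

* a configurable fraction of samples carries a planted "cryptic fusion":
  a copy-number segment deleting the 5' half of NTRK3 (segment mean drawn
  from Uniform(-1.2, -0.35)), a deletion of one random 5' partner gene, and
  an NTRK3 expression shift of +3 noise SDs;
* NTRK2 expression is coupled to its copy-number category with an additive
  dose effect per category step;
* methylation beta values are anti-correlated with expression for all three
  NTRK genes through a linear (negative) slope;
* clinical covariates are drawn conditional on a planted CIN/MSI/GS subtype
  (MSI status, tumour location, BRAF mutation, FGA, TMB, aneuploidy), and
  expression is subtype-structured (NTRK1 up-shifted in the hypermutated/MSI
  subtype, NTRK2/NTRK3 outside it), so categorical association tests have
  real signal to find;
* background copy-number segments have means inside (-0.25, 0.25) and thus
  never trip the -0.3 deletion threshold: every deletion call traces back to
  a planted event.

Everything is deterministic given the :class:`CohortSpec` seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import ExpressionMatrix, SegmentRecord
from .registry import DEFAULT_REGISTRY, PARTNER_GENES

NTRK_GENES = ("NTRK1", "NTRK2", "NTRK3")

#: GISTIC category probabilities used for genes without planted structure
_GISTIC_PROBS = {-2: 0.03, -1: 0.12, 0: 0.65, 1: 0.15, 2: 0.05}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``fusion_fraction`` is the per-sample probability of planting the
    deletion-plus-overexpression fusion surrogate; ``cna_dose_effect`` the
    additive expression shift per NTRK2 copy-number category step;
    ``methylation_slope`` the (negative) linear effect of the beta value on
    expression; ``subtype_proportions`` the CIN/MSI/GS mix.
    """

    n_samples: int
    cohort_label: str = "cohortA"
    fusion_fraction: float = 0.085
    cna_dose_effect: float = 0.5
    methylation_slope: float = -1.0
    noise_sd: float = 1.0
    subtype_expression_shift: float = 0.5
    subtype_proportions: tuple[float, float, float] = (0.65, 0.15, 0.20)
    n_background_genes: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.fusion_fraction <= 1.0:
            raise ValueError("fusion_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.methylation_slope > 0:
            raise ValueError("methylation_slope must be <= 0")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        if len(self.subtype_proportions) != 3:
            raise ValueError("subtype_proportions must be a 3-vector over CIN/MSI/GS")


@dataclass
class SyntheticCohort:
    """One generated cohort: five aligned data layers plus the planted truth."""

    spec: CohortSpec
    expression: ExpressionMatrix
    segments: list[SegmentRecord]
    gene_cna: pd.DataFrame  # gene x sample GISTIC codes
    methylation: pd.DataFrame  # gene x sample beta values
    clinical: pd.DataFrame  # sample-indexed annotation
    truth: pd.DataFrame  # sample-indexed planted labels

    @property
    def samples(self) -> list[str]:
        return self.expression.samples


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one synthetic cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"{spec.cohort_label}-{i:04d}" for i in range(n)]

    background = [f"GENE{i:04d}" for i in range(spec.n_background_genes)]
    genes = list(NTRK_GENES) + list(PARTNER_GENES) + background

    subtype = rng.choice(["CIN", "MSI", "GS"], size=n, p=list(spec.subtype_proportions))
    fusion = rng.random(n) < spec.fusion_fraction
    fusion_partner = np.where(
        fusion, rng.choice(PARTNER_GENES, size=n), ""
    )

    baseline = rng.uniform(4.0, 10.0, size=len(genes))
    expr = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(genes), n))
    expr_frame = pd.DataFrame(expr, index=genes, columns=samples)

    # methylation layer, anti-correlated with expression for the NTRK genes
    methylation = pd.DataFrame(
        rng.beta(2.0, 2.0, size=(len(NTRK_GENES), n)),
        index=list(NTRK_GENES), columns=samples,
    )
    for gene in NTRK_GENES:
        expr_frame.loc[gene] += spec.methylation_slope * methylation.loc[gene].to_numpy()

    # gene-level GISTIC categories; NTRK2 carries the dose-coupled signal
    codes = np.array(sorted(_GISTIC_PROBS))
    probs = np.array([_GISTIC_PROBS[c] for c in codes])
    cna_rows = {}
    for gene in list(NTRK_GENES) + list(PARTNER_GENES):
        cna_rows[gene] = rng.choice(codes, size=n, p=probs)
    cna_rows["NTRK3"] = np.where(fusion, -1, cna_rows["NTRK3"])
    gene_cna = pd.DataFrame(cna_rows, index=samples).T
    expr_frame.loc["NTRK2"] += spec.cna_dose_effect * gene_cna.loc["NTRK2"].to_numpy()

    # subtype-specific expression: NTRK1 higher in the hypermutated/MSI
    # subtype, NTRK2/NTRK3 higher outside it (in units of the noise SD)
    shift = spec.subtype_expression_shift * spec.noise_sd
    is_msi_subtype = subtype == "MSI"
    expr_frame.loc["NTRK1"] += shift * is_msi_subtype
    expr_frame.loc["NTRK2"] += shift * ~is_msi_subtype
    expr_frame.loc["NTRK3"] += shift * ~is_msi_subtype

    # planted fusion surrogate: 5' NTRK3 deletion + partner deletion + overexpression
    expr_frame.loc["NTRK3"] += 3.0 * spec.noise_sd * fusion

    segments = _generate_segments(rng, samples, fusion, fusion_partner)

    clinical = _generate_clinical(rng, samples, subtype)

    truth = pd.DataFrame(
        {
            "planted_fusion": fusion,
            "fusion_partner": fusion_partner,
            "subtype": subtype,
            "ntrk2_cna": gene_cna.loc["NTRK2"].to_numpy(),
        },
        index=pd.Index(samples, name="sample_id"),
    )

    expr_frame = expr_frame.clip(lower=0.0)
    return SyntheticCohort(
        spec=spec,
        expression=ExpressionMatrix(expr_frame, stage="raw"),
        segments=segments,
        gene_cna=gene_cna,
        methylation=methylation,
        clinical=clinical,
        truth=truth,
    )


def _generate_segments(rng, samples, fusion, fusion_partner) -> list[SegmentRecord]:
    """Background copy-neutral segments plus planted deletion segments."""
    segments: list[SegmentRecord] = []
    chroms = [str(c) for c in range(1, 23)]
    ntrk3 = DEFAULT_REGISTRY["NTRK3"]
    five_prime = ntrk3.five_prime_half()
    for i, sid in enumerate(samples):
        n_bg = int(rng.integers(2, 6))
        for _ in range(n_bg):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(1, 100_000_000))
            length = int(rng.integers(50_000, 5_000_000))
            mean = float(rng.uniform(-0.25, 0.25))
            segments.append(
                SegmentRecord(sid, chrom, start, start + length, int(rng.integers(10, 500)), mean)
            )
        if fusion[i]:
            mean = float(rng.uniform(-1.2, -0.35))
            segments.append(
                SegmentRecord(
                    sid, ntrk3.chromosome,
                    five_prime.start - 1_000, five_prime.end + 1_000,
                    int(rng.integers(50, 300)), mean,
                )
            )
            partner = DEFAULT_REGISTRY[fusion_partner[i]]
            pmean = float(rng.uniform(-1.2, -0.35))
            segments.append(
                SegmentRecord(
                    sid, partner.chromosome,
                    partner.start - 1_000, partner.end + 1_000,
                    int(rng.integers(50, 300)), pmean,
                )
            )
    return segments


def _generate_clinical(rng, samples, subtype) -> pd.DataFrame:
    """Clinical covariates conditioned on the planted molecular subtype."""
    n = len(samples)
    is_msi = subtype == "MSI"
    is_cin = subtype == "CIN"

    msi_status = np.where(
        rng.random(n) < np.where(is_msi, 0.90, 0.05), "MSI", "MSS"
    )
    location = np.where(
        rng.random(n) < np.where(is_msi, 0.80, 0.35), "right", "left"
    )
    braf = np.where(rng.random(n) < np.where(is_msi, 0.40, 0.08), "mut", "wt")
    tp53 = np.where(rng.random(n) < np.where(is_cin, 0.70, 0.40), "mut", "wt")

    t_stage = np.where(rng.random(n) < 0.70, "T3-4", "T1-2")
    n_stage = np.where(rng.random(n) < 0.45, "N+", "N0")
    m_stage = np.where(rng.random(n) < 0.15, "M1", "M0")
    tnm = np.where((n_stage == "N+") | (m_stage == "M1"), "III-IV", "I-II")

    fga = np.clip(
        rng.normal(np.where(is_cin, 0.45, np.where(is_msi, 0.15, 0.20)), 0.08), 0, 1
    )
    tmb = np.exp(rng.normal(np.where(is_msi, 3.0, 1.5), 0.5))
    aneuploidy = np.clip(rng.normal(np.where(is_cin, 12.0, 5.0), 3.0), 0, None)

    age = np.clip(rng.normal(68, 11, size=n), 25, 95)
    sex = np.where(rng.random(n) < 0.55, "male", "female")

    os_latent = rng.exponential(60.0, size=n)
    os_censor = rng.uniform(12.0, 120.0, size=n)
    dfs_latent = rng.exponential(45.0, size=n)
    dfs_censor = rng.uniform(6.0, 96.0, size=n)

    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "sex": sex,
            "location": location,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "m_stage": m_stage,
            "tnm_stage": tnm,
            "msi_status": msi_status,
            "subtype": subtype,
            "braf_mut": braf,
            "tp53_mut": tp53,
            "fga": np.round(fga, 4),
            "tmb": np.round(tmb, 3),
            "aneuploidy": np.round(aneuploidy, 2),
            "os_months": np.round(np.minimum(os_latent, os_censor), 2),
            "os_event": (os_latent <= os_censor).astype(int),
            "dfs_months": np.round(np.minimum(dfs_latent, dfs_censor), 2),
            "dfs_event": (dfs_latent <= dfs_censor).astype(int),
        },
        index=pd.Index(samples, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Persistence


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write all layers of a cohort to ``directory``; returns the file map.

    Formats: GCT (expression), SEG (segments), TSV (gene CNA, methylation,
    clinical) and a JSON truth sidecar.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.gct",
        "segments": directory / "segments.seg",
        "gene_cna": directory / "gene_cna.tsv",
        "methylation": directory / "methylation.tsv",
        "clinical": directory / "clinical.tsv",
        "truth": directory / "truth.json",
    }
    try:
        iof.write_gct(cohort.expression, paths["expression"])
        iof.write_seg(cohort.segments, paths["segments"])
        iof.write_matrix_tsv(cohort.gene_cna, paths["gene_cna"])
        iof.write_matrix_tsv(cohort.methylation, paths["methylation"])
        cohort.clinical.to_csv(paths["clinical"], sep="\t")
        paths["truth"].write_text(
            cohort.truth.reset_index().to_json(orient="records", indent=1)
        )
    except OSError as exc:
        raise OSError(f"failed writing cohort file: {exc.filename or directory}") from exc
    return paths


def read_cohort(directory, spec: CohortSpec | None = None) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    expression = iof.read_gct(directory / "expression.gct")
    segments = iof.read_seg(directory / "segments.seg")
    gene_cna = iof.read_matrix_tsv(directory / "gene_cna.tsv")
    methylation = iof.read_matrix_tsv(directory / "methylation.tsv")
    clinical = iof.read_clinical_tsv(directory / "clinical.tsv")
    truth = pd.read_json(directory / "truth.json", orient="records").set_index("sample_id")
    if spec is None:
        spec = CohortSpec(n_samples=len(expression.samples), cohort_label="loaded")
    return SyntheticCohort(
        spec=spec, expression=expression, segments=segments,
        gene_cna=gene_cna, methylation=methylation, clinical=clinical, truth=truth,
    )
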