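"""Deletion calling from copy-number segments and cryptic NTRK3-fusion scoring.

The cryptic-fusion inference rests on a simple genomic observation: a 3'
fusion partner that is overexpressed while carrying a (often 5'-partial)
deletion — especially alongside a deletion in a known 5' partner gene — is
likely participating in a gene fusion even when no structural-variant call
exists. The two composite scores are additive indicator sums:

* ``NFS1 = [NTRK3 deleted] + [any 5' partner deleted] + [NTRK3 expression high]``
  (range 0-3, "high" at 3),
* ``NFS2 = [NTRK3 deleted] + [NTRK3 expression high]`` (range 0-2, "high" at 2).

A gene counts as deleted when at least one copy-number segment overlaps its
locus (closed intervals) with a segment mean at or below the deletion
threshold, -0.3 log2 copy-ratio by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneLocus, SegmentRecord
from .registry import PARTNER_GENES

DELETION_THRESHOLD = -0.3

CNA_CATEGORIES = ("loss/deletion", "wild-type", "gain/amplification")


@dataclass(frozen=True)
class DeletionCall:
    """Outcome of interrogating one gene locus in one sample's segments."""

    gene: str
    sample_id: str
    deleted: bool
    supporting_segment_mean: float | None = None
    overlap_bp: int = 0

    def __post_init__(self):
        if self.deleted and (self.supporting_segment_mean is None or self.overlap_bp < 1):
            raise ValueError("a deletion call requires a supporting segment and overlap")


@dataclass(frozen=True)
class FusionScore:
    """Per-sample NFS1/NFS2 cryptic-fusion scores with their components."""

    sample_id: str
    nfs1: int
    nfs2: int
    nfs1_high: bool
    nfs2_high: bool
    ntrk3_deleted: bool = False
    ntrk3_high: bool = False
    partner_deleted: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0 <= self.nfs1 <= 3 and 0 <= self.nfs2 <= 2):
            raise ValueError("NFS1 in 0..3 and NFS2 in 0..2")
        if self.nfs1_high and not self.nfs2_high:
            raise ValueError("NFS1-high implies NFS2-high")


def _overlap_bp(seg: SegmentRecord, locus: GeneLocus) -> int:
    if seg.chromosome != locus.chromosome:
        return 0
    lo = max(seg.start, locus.start)
    hi = min(seg.end, locus.end)
    return max(0, hi - lo + 1)


def call_deletion(
    segments: Sequence[SegmentRecord],
    locus: GeneLocus,
    threshold: float = DELETION_THRESHOLD,
    sample_id: str | None = None,
    five_prime_only: bool = False,
) -> DeletionCall:
    """Call a gene deletion from one sample's copy-number segments.

    The gene is deleted iff at least one segment overlaps the locus (closed
    intervals; any partial overlap suffices) with segment mean <= ``threshold``.
    Among qualifying segments the minimum segment mean is reported as the
    supporting evidence. With ``five_prime_only`` the strand-aware 5' half of
    the gene is interrogated instead of the whole locus. An empty segment
    list yields a negative call (no-call is treated as not deleted).
    """
    if threshold >= 0:
        raise ValueError("deletion threshold must be negative")
    target = locus.five_prime_half() if five_prime_only else locus
    sid = sample_id if sample_id is not None else (segments[0].sample_id if segments else "")
    best_mean = None
    best_bp = 0
    for seg in segments:
        bp = _overlap_bp(seg, target)
        if bp >= 1 and seg.segment_mean <= threshold:
            if best_mean is None or seg.segment_mean < best_mean:
                best_mean = seg.segment_mean
                best_bp = bp
    if best_mean is None:
        return DeletionCall(locus.symbol, sid, False)
    return DeletionCall(locus.symbol, sid, True, best_mean, best_bp)


def call_deletions_cohort(
    segments: Iterable[SegmentRecord],
    loci: Mapping[str, GeneLocus],
    threshold: float = DELETION_THRESHOLD,
    samples: Sequence[str] | None = None,
    five_prime_only: bool = False,
) -> pd.DataFrame:
    """Boolean sample x gene deletion matrix over a whole cohort.

    ``samples`` fixes the row universe (samples without segments get
    all-False rows); by default the samples observed in ``segments`` are used.
    """
    by_sample: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    if samples is None:
        samples = sorted(by_sample)
    data = {
        gene: [
            call_deletion(by_sample.get(s, []), locus, threshold, s, five_prime_only).deleted
            for s in samples
        ]
        for gene, locus in loci.items()
    }
    return pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))


def categorize_cna(table: pd.DataFrame, dialect: str = "gistic_thresholded") -> pd.DataFrame:
    """Map a gene x sample copy-number table onto the three-level categories.

    ``gistic_thresholded``: codes {-2, -1} -> loss/deletion, {0} -> wild-type,
    {1, 2} -> gain/amplification. ``linear``: log2 copy-ratios thresholded at
    +/-0.3.
    """
    values = table.to_numpy(dtype=float)
    if dialect == "gistic_thresholded":
        known = np.isin(values, [-2, -1, 0, 1, 2]) | ~np.isfinite(values)
        if not known.all():
            bad = sorted(set(values[~known].tolist()))
            raise ValueError(f"unknown GISTIC codes: {bad}")
        cats = np.where(values < 0, CNA_CATEGORIES[0],
                        np.where(values > 0, CNA_CATEGORIES[2], CNA_CATEGORIES[1]))
    elif dialect == "linear":
        cats = np.where(values <= -0.3, CNA_CATEGORIES[0],
                        np.where(values >= 0.3, CNA_CATEGORIES[2], CNA_CATEGORIES[1]))
    else:
        raise ValueError(f"unknown CNA dialect {dialect!r}")
    out = pd.DataFrame(cats, index=table.index, columns=table.columns)
    out[~np.isfinite(values)] = np.nan
    return out


def compute_nfs(
    sample_id: str,
    ntrk3_deleted: bool,
    partner_deleted: Sequence[str],
    ntrk3_high: bool,
) -> FusionScore:
    """Assemble the additive NFS1/NFS2 fusion scores for one sample.

    ``partner_deleted`` lists the 5' partner genes called deleted; any
    non-empty list contributes one point to NFS1.
    """
    i_del = int(bool(ntrk3_deleted))
    i_partner = int(len(partner_deleted) > 0)
    i_high = int(bool(ntrk3_high))
    nfs1 = i_del + i_partner + i_high
    nfs2 = i_del + i_high
    return FusionScore(
        sample_id=sample_id,
        nfs1=nfs1,
        nfs2=nfs2,
        nfs1_high=nfs1 == 3,
        nfs2_high=nfs2 == 2,
        ntrk3_deleted=bool(ntrk3_deleted),
        ntrk3_high=bool(ntrk3_high),
        partner_deleted=tuple(partner_deleted),
    )


def score_cohort(
    deletions: pd.DataFrame,
    ntrk3_high: Mapping[str, bool] | pd.Series,
    gene: str = "NTRK3",
    partners: Sequence[str] = PARTNER_GENES,
) -> list[FusionScore]:
    """Compute fusion scores for every sample in a deletion matrix.

    ``deletions`` is the boolean sample x gene matrix from
    :func:`call_deletions_cohort`; ``ntrk3_high`` maps sample id to the
    dichotomized NTRK3 expression state. Samples missing from either input
    are dropped (the joined denominator is the caller's to report).
    """
    high = pd.Series(ntrk3_high)
    scores = []
    present_partners = [p for p in partners if p in deletions.columns]
    for sid in deletions.index:
        if sid not in high.index:
            continue
        row = deletions.loc[sid]
        deleted_partners = [p for p in present_partners if bool(row[p])]
        scores.append(
            compute_nfs(sid, bool(row[gene]), deleted_partners, bool(high[sid]))
        )
    return scores


def summarize_fusion_cohort(scores: Sequence[FusionScore]) -> dict:
    """Cohort-level counts and fractions of deletion and fusion-score states.

    Counts reported: NTRK3-plus-partner double deletion, NTRK3-or-partner
    deletion, NTRK3 deletion alone (no partner deleted), and the NFS1-high /
    NFS2-high rates. The denominator ``n`` is the joined sample count the
    scores were computed on.
    """
    n = len(scores)

    def frac(k: int) -> float:
        return k / n if n else 0.0

    double = sum(s.ntrk3_deleted and len(s.partner_deleted) > 0 for s in scores)
    either = sum(s.ntrk3_deleted or len(s.partner_deleted) > 0 for s in scores)
    alone = sum(s.ntrk3_deleted and len(s.partner_deleted) == 0 for s in scores)
    nfs1_high = sum(s.nfs1_high for s in scores)
    nfs2_high = sum(s.nfs2_high for s in scores)
    return {
        "n": n,
        "double_deletion": double,
        "double_deletion_fraction": frac(double),
        "either_deletion": either,
        "either_deletion_fraction": frac(either),
        "ntrk3_deletion_alone": alone,
        "ntrk3_deletion_alone_fraction": frac(alone),
        "nfs1_high": nfs1_high,
        "nfs1_high_fraction": frac(nfs1_high),
        "nfs2_high": nfs2_high,
        "nfs2_high_fraction": frac(nfs2_high),
    }


def scores_to_frame(scores: Sequence[FusionScore]) -> pd.DataFrame:
    """Tidy per-sample table of fusion-score components and totals."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "ntrk3_deleted": [s.ntrk3_deleted for s in scores],
            "partner_deleted": [";".join(s.partner_deleted) for s in scores],
            "ntrk3_high": [s.ntrk3_high for s in scores],
            "nfs1": [s.nfs1 for s in scores],
            "nfs2": [s.nfs2 for s in scores],
            "nfs1_high": [s.nfs1_high for s in scores],
            "nfs2_high": [s.nfs2_high for s in scores],
        }
    ).set_index("sample_id")
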