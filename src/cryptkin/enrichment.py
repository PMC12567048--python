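"""Gene-set enrichment: weighted-KS running-sum scores with a permutation
null, and Fisher over-representation with volcano export.

The enrichment score (ES) of a gene set against a ranked gene list is the
signed maximum deviation of a running sum that increments by
``|score|^p / sum(|score|^p over hits)`` at set members and decrements by
``1 / (N - Nh)`` at non-members. ``p = 1`` is the canonical weighted
statistic; ``p = 0`` reduces to the classic Kolmogorov-Smirnov deviation
between hit and miss positional CDFs.

Significance comes from permutations: phenotype permutation (labels are
reshuffled and the whole ranking recomputed; preferred, requires enough
samples per class) or gene-set permutation (random sets of matched size
against the fixed observed ranking). The normalized ES (NES) divides the
observed ES by the mean |ES| of same-sign permutations of the same set, and
the FDR uses the canonical sign-pooled ratio-of-tails estimate:

    FDR(NES*) = [#{permuted NES >= NES*} / #{permuted NES >= 0}]
              / [#{observed NES >= NES*} / #{observed NES >= 0}]

(capped at 1; mirrored for negative NES*).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

SD_FLOOR = 0.2  # per-class SD floored at max(0.2 * |mean|, 0.2), GSEA convention


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, scores non-increasing."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr: float
    leading_edge: list[str]
    size: int


@dataclass
class OraResult:
    set_name: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    adjusted_p: float | None = None

    @property
    def log2_or(self) -> float:
        return float(np.log2(self.odds_ratio))

    @property
    def neg_log10_adj_p(self) -> float:
        if self.adjusted_p is None:
            raise ValueError("adjusted p not yet computed")
        return float(-np.log10(max(self.adjusted_p, 1e-300)))


# ---------------------------------------------------------------------------
# Ranking metrics


def _class_stats(X: np.ndarray, member: np.ndarray):
    """Per-gene mean and sample SD for a boolean class-membership matrix.

    ``X`` is genes x samples; ``member`` is samples x k (k label
    assignments, e.g. permutations). Returns mean and SD arrays of shape
    genes x k.
    """
    member = member.astype(float)
    n = member.sum(axis=0)
    s1 = X @ member
    s2 = (X * X) @ member
    mean = s1 / n
    var = (s2 - n * mean**2) / (n - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return mean, sd, n


def _metric_scores(X: np.ndarray, pos: np.ndarray, metric: str) -> np.ndarray:
    """Ranking scores for one or many label assignments.

    ``pos`` is samples x k boolean (True = positive class). Output is
    genes x k.
    """
    neg = ~pos
    mA, sA, nA = _class_stats(X, pos)
    mB, sB, nB = _class_stats(X, neg)
    if metric == "signal_to_noise":
        sA = np.maximum(sA, np.maximum(SD_FLOOR * np.abs(mA), SD_FLOOR))
        sB = np.maximum(sB, np.maximum(SD_FLOOR * np.abs(mB), SD_FLOOR))
        return (mA - mB) / (sA + sB)
    if metric == "t_stat":
        se = np.sqrt(sA**2 / nA + sB**2 / nB)
        se = np.maximum(se, 1e-12)
        return (mA - mB) / se
    if metric == "log2_ratio":
        eps = 1e-9
        return np.log2(np.maximum(mA, eps) / np.maximum(mB, eps))
    raise ValueError(f"unknown ranking metric {metric!r}")


def rank_genes(
    expression: ExpressionMatrix | pd.DataFrame,
    phenotype: Sequence[str],
    metric: str = "signal_to_noise",
    positive_class: str | None = None,
) -> RankedList:
    """Rank genes by differential expression between two phenotype classes.

    The score is positive when expression is higher in the positive class
    (by default the first label encountered). Genes are ordered by
    decreasing score with ties broken lexicographically by symbol.
    """
    frame = expression.values if isinstance(expression, ExpressionMatrix) else expression
    labels = np.asarray(list(phenotype))
    if labels.size != frame.shape[1]:
        raise ValueError("phenotype length must equal sample count")
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("phenotype must have exactly two classes")
    if positive_class is None:
        positive_class = classes[0]
    pos = labels == positive_class
    if pos.sum() < 3 or (~pos).sum() < 3:
        raise ValueError("each phenotype class needs at least 3 samples")

    # pre-sort genes lexicographically so a stable sort breaks score ties
    # by symbol, making rankings reproducible bit-for-bit
    frame = frame.sort_index(kind="stable")
    X = frame.to_numpy(dtype=float)
    scores = _metric_scores(X, pos[:, None], metric)[:, 0]
    order = np.argsort(-scores, kind="stable")
    return RankedList([frame.index[i] for i in order], scores[order])


# ---------------------------------------------------------------------------
# Enrichment score


def enrichment_score(
    ranked: RankedList, gene_set: Sequence[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score of ``gene_set`` against ``ranked``.

    Returns ``(es, running_sum, leading_edge)``. The leading edge contains
    the set members at or before the running-sum extremum for a positive ES,
    or at or after it for a negative ES.
    """
    members = set(gene_set)
    hits = np.array([g in members for g in ranked.genes])
    n = hits.size
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == n:
        raise ValueError("gene set equals the whole ranked universe")
    running = _running_sum(ranked.scores, hits, weight_p)
    # positive extremum preferred on a magnitude tie (deterministic rule)
    if running.max() >= -running.min() - 1e-12:
        idx = int(np.argmax(running))
    else:
        idx = int(np.argmin(running))
    es = float(running[idx])
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.genes) if hits[i] and i <= idx]
    else:
        leading = [g for i, g in enumerate(ranked.genes) if hits[i] and i >= idx]
    return es, running, leading


def _running_sum(scores: np.ndarray, hits: np.ndarray, weight_p: float) -> np.ndarray:
    n = hits.size
    nh = int(hits.sum())
    w = np.abs(scores) ** weight_p
    hit_w = np.where(hits, w, 0.0)
    nr = hit_w.sum()
    if nr == 0:  # all member scores zero: fall back to unweighted increments
        hit_w = hits.astype(float)
        nr = float(nh)
    steps = hit_w / nr - (~hits) / (n - nh)
    return np.cumsum(steps)


# ---------------------------------------------------------------------------
# Permutation null


def permutation_null(
    expression: ExpressionMatrix | pd.DataFrame,
    phenotype: Sequence[str],
    gene_sets: GeneSetCollection | Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    mode: str = "phenotype",
    seed: int | None = None,
    metric: str = "signal_to_noise",
    weight_p: float = 1.0,
    positive_class: str | None = None,
) -> list[EnrichmentResult]:
    """GSEA-style enrichment with an empirical permutation null.

    ``mode='phenotype'`` reshuffles class labels and recomputes the whole
    ranking per permutation (requires >= 7 samples per class, otherwise the
    engine falls back to ``'gene_set'`` mode and logs the switch);
    ``mode='gene_set'`` scores random same-size gene sets against the fixed
    observed ranking. Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    frame = expression.values if isinstance(expression, ExpressionMatrix) else expression
    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else dict(gene_sets)
    sets = {
        name: [g for g in genes if g in frame.index]
        for name, genes in sets.items()
    }
    sets = {name: genes for name, genes in sets.items() if genes}
    if not sets:
        raise ValueError("no gene set intersects the expression universe")

    labels = np.asarray(list(phenotype))
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("phenotype must have exactly two classes")
    if positive_class is None:
        positive_class = classes[0]
    pos = labels == positive_class

    if mode == "phenotype" and (pos.sum() < 7 or (~pos).sum() < 7):
        logger.warning(
            "phenotype permutation needs >=7 samples per class "
            "(have %d/%d); switching to gene_set mode", pos.sum(), (~pos).sum()
        )
        mode = "gene_set"
    if mode not in {"phenotype", "gene_set"}:
        raise ValueError(f"unknown permutation mode {mode!r}")

    rng = np.random.default_rng(seed)
    frame = frame.sort_index(kind="stable")
    X = frame.to_numpy(dtype=float)
    genes = list(frame.index)
    n_genes = len(genes)

    obs_scores = _metric_scores(X, pos[:, None], metric)[:, 0]
    obs_order = np.argsort(-obs_scores, kind="stable")
    obs_ranked = RankedList([genes[i] for i in obs_order], obs_scores[obs_order])

    set_names = list(sets)
    memb = np.zeros((n_genes, len(set_names)), dtype=bool)
    gene_index = {g: i for i, g in enumerate(genes)}
    for j, name in enumerate(set_names):
        for g in sets[name]:
            memb[gene_index[g], j] = True

    obs_es = np.empty(len(set_names))
    leading_edges = []
    for j, name in enumerate(set_names):
        es, _, leading = enrichment_score(obs_ranked, sets[name], weight_p)
        obs_es[j] = es
        leading_edges.append(leading)

    # null ES matrix: sets x permutations
    if mode == "phenotype":
        perm_pos = np.empty((labels.size, n_perm), dtype=bool)
        for k in range(n_perm):
            perm_pos[:, k] = pos[rng.permutation(labels.size)]
        perm_scores = _metric_scores(X, perm_pos, metric)  # genes x perms
        perm_order = np.argsort(-perm_scores, axis=0, kind="stable")
        ordered_scores = np.take_along_axis(perm_scores, perm_order, axis=0)
        null_es = np.empty((len(set_names), n_perm))
        for j in range(len(set_names)):
            ordered_memb = memb[:, j][perm_order]  # genes x perms
            null_es[j] = _es_columns(ordered_scores, ordered_memb, weight_p)
    else:
        null_es = np.empty((len(set_names), n_perm))
        for j, name in enumerate(set_names):
            k = len(sets[name])
            draws = rng.random((n_genes, n_perm)).argpartition(k - 1, axis=0)[:k]
            ordered_memb = np.zeros((n_genes, n_perm), dtype=bool)
            np.put_along_axis(ordered_memb, draws, True, axis=0)
            # random sets are drawn in ranked-position space directly
            null_es[j] = _es_columns(
                np.broadcast_to(obs_scores[obs_order][:, None], (n_genes, n_perm)),
                ordered_memb,
                weight_p,
            )

    return _assemble_results(
        set_names, sets, obs_es, null_es, leading_edges, n_perm
    )


def _es_columns(ordered_scores: np.ndarray, ordered_memb: np.ndarray, weight_p: float) -> np.ndarray:
    """ES for each column of an already-ordered score/membership matrix."""
    n = ordered_memb.shape[0]
    nh = ordered_memb.sum(axis=0)
    w = np.abs(ordered_scores) ** weight_p
    hit_w = np.where(ordered_memb, w, 0.0)
    nr = hit_w.sum(axis=0)
    fallback = nr == 0
    if fallback.any():
        hit_w[:, fallback] = ordered_memb[:, fallback].astype(float)
        nr = np.where(fallback, nh, nr)
    steps = hit_w / nr - (~ordered_memb) / (n - nh)
    running = np.cumsum(steps, axis=0)
    hi = running.max(axis=0)
    lo = running.min(axis=0)
    return np.where(hi >= -lo - 1e-12, hi, lo)


def _assemble_results(set_names, sets, obs_es, null_es, leading_edges, n_perm):
    n_sets = len(set_names)
    nes = np.full(n_sets, np.nan)
    nominal_p = np.full(n_sets, np.nan)
    null_nes = np.full_like(null_es, np.nan)

    for j in range(n_sets):
        row = null_es[j]
        pos_mask, neg_mask = row >= 0, row < 0
        mean_pos = row[pos_mask].mean() if pos_mask.any() else np.nan
        mean_neg = np.abs(row[neg_mask]).mean() if neg_mask.any() else np.nan
        if pos_mask.any():
            null_nes[j, pos_mask] = row[pos_mask] / mean_pos
        if neg_mask.any():
            null_nes[j, neg_mask] = row[neg_mask] / mean_neg
        es = obs_es[j]
        if es >= 0:
            if pos_mask.any():
                nominal_p[j] = (row[pos_mask] >= es).sum() / pos_mask.sum()
                nes[j] = es / mean_pos
            else:
                nominal_p[j] = 1.0 / (n_perm + 1)  # no same-sign permutations
        else:
            if neg_mask.any():
                nominal_p[j] = (row[neg_mask] <= es).sum() / neg_mask.sum()
                nes[j] = es / mean_neg
            else:
                nominal_p[j] = 1.0 / (n_perm + 1)

    pooled = null_nes[np.isfinite(null_nes)]
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled < 0]
    obs_pos = nes[np.isfinite(nes) & (nes >= 0)]
    obs_neg = nes[np.isfinite(nes) & (nes < 0)]

    fdr = np.full(n_sets, np.nan)
    for j in range(n_sets):
        v = nes[j]
        if not np.isfinite(v):
            fdr[j] = np.nan
            continue
        if v >= 0:
            num = (pooled_pos >= v).mean() if pooled_pos.size else 0.0
            den = (obs_pos >= v).sum() / max(obs_pos.size, 1)
        else:
            num = (pooled_neg <= v).mean() if pooled_neg.size else 0.0
            den = (obs_neg <= v).sum() / max(obs_neg.size, 1)
        fdr[j] = min(1.0, num / den) if den > 0 else np.nan

    # q-value-style monotone smoothing within each sign class: a set's FDR
    # is the minimum ratio-of-tails estimate over all thresholds that reject
    # it, so FDR is non-increasing in |NES|
    for sign_mask in (np.isfinite(nes) & (nes >= 0), np.isfinite(nes) & (nes < 0)):
        idx = np.where(sign_mask)[0]
        if idx.size < 2:
            continue
        order = idx[np.argsort(np.abs(nes[idx]), kind="stable")]  # weakest first
        fdr[order] = np.fmin.accumulate(fdr[order])

    return [
        EnrichmentResult(
            set_name=set_names[j],
            es=float(obs_es[j]),
            nes=float(nes[j]),
            nominal_p=float(nominal_p[j]),
            fdr=float(fdr[j]),
            leading_edge=leading_edges[j],
            size=len(sets[set_names[j]]),
        )
        for j in range(n_sets)
    ]


# ---------------------------------------------------------------------------
# Over-representation


def ora_fisher(
    hit_genes: Sequence[str], gene_set: Sequence[str], universe: Sequence[str]
) -> OraResult:
    """One-sided (enrichment) Fisher exact test of set membership among hits.

    The odds ratio uses the Haldane-Anscombe +0.5 continuity correction when
    any cell of the 2x2 table is zero, so it is always finite.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hits = set(hit_genes) & uni
    members = set(gene_set) & uni
    a = len(hits & members)
    b = len(members - hits)
    c = len(hits - members)
    d = len(uni) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = sps.fisher_exact(table, alternative="greater")
    if (table == 0).any():
        oa, ob, oc, od = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        oa, ob, oc, od = a, b, c, d
    odds = (oa * od) / (ob * oc)
    return OraResult(set_name="", table=((a, b), (c, d)), odds_ratio=float(odds), p=float(p))


def ora_analysis(
    hit_genes: Sequence[str],
    gene_sets: GeneSetCollection | Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> list[OraResult]:
    """Fisher over-representation across a collection, BH-adjusted."""
    from .stats import bh_adjust

    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else dict(gene_sets)
    results = []
    for name, genes in sets.items():
        res = ora_fisher(hit_genes, genes, universe)
        res.set_name = name
        results.append(res)
    adj = bh_adjust([r.p for r in results])
    for r, q in zip(results, adj):
        r.adjusted_p = float(q)
    return results


def volcano_table(results: Sequence[OraResult]) -> pd.DataFrame:
    """Tidy (set, log2 OR, -log10 adjusted p) table, sorted by adjusted p."""
    rows = [
        {
            "set_name": r.set_name,
            "log2_or": r.log2_or,
            "neg_log10_adj_p": r.neg_log10_adj_p,
            "odds_ratio": r.odds_ratio,
            "p": r.p,
            "adjusted_p": r.adjusted_p,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    return frame.sort_values("adjusted_p", kind="stable").reset_index(drop=True)
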