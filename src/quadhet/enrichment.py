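"""Expression-side comparisons: thresholded differential-expression
selection, quartile sample grouping and hypergeometric over-representation
with Benjamini-Hochberg adjustment.

The DE test is a deliberate lightweight stand-in for a negative-binomial
model fit: total-count normalization, log2 fold change with a +1
pseudocount, and a two-sample rank-sum p-value per gene.  The selection
thresholds (fold change > 2, FDR < 0.05) are the contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, InputFormatError, StageError
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


def library_size_normalize(counts: np.ndarray) -> np.ndarray:
    """Scale each sample (column) to the mean library size."""
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise StageError("sample with zero total count")
    return counts * (lib.mean() / lib)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min_{j >= rank(i)} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise StageError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


# ---------------------------------------------------------------------------
# differential expression


@dataclass
class DEResult:
    gene: str
    log2_fc: float
    p_value: float
    fdr: float
    selected: bool


def select_de_genes(counts: ExpressionMatrix,
                    group_a_ids: Sequence[str],
                    group_b_ids: Sequence[str],
                    fc_threshold: float = 2.0,
                    fdr_threshold: float = 0.05) -> list[DEResult]:
    """Per-gene rank-sum test between two sample groups, BH-adjusted.

    A gene is selected iff |fold change| > fc_threshold (fold change on
    pseudocounted normalized means, either direction) and fdr < fdr_threshold.
    """
    if len(group_a_ids) < 2 or len(group_b_ids) < 2:
        raise StageError("each group needs at least 2 samples")
    try:
        ia = [counts.samples.index(s) for s in group_a_ids]
        ib = [counts.samples.index(s) for s in group_b_ids]
    except ValueError as exc:
        raise InputFormatError(f"group sample missing from count matrix: {exc}") from exc

    norm = library_size_normalize(np.asarray(counts.counts, dtype=float))
    a, b = norm[:, ia], norm[:, ib]
    log2_fc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))

    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                                 method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # constant genes: no evidence
    fdr = bh_adjust(p)

    min_log2 = np.log2(fc_threshold)
    selected = (np.abs(log2_fc) > min_log2) & (fdr < fdr_threshold)
    return [DEResult(g, float(log2_fc[i]), float(p[i]), float(fdr[i]),
                     bool(selected[i]))
            for i, g in enumerate(counts.genes)]


# ---------------------------------------------------------------------------
# quartile grouping


@dataclass
class GroupAssignment:
    group_name: str
    sample_ids: list[str]
    rule: str


def quartile_groups(counts: ExpressionMatrix,
                    genes: str | Sequence[str],
                    quartile: float = 0.25,
                    ) -> tuple[GroupAssignment, GroupAssignment]:
    """High/low sample groups by normalized expression quartile.

    Single gene: the top and bottom ``floor(quartile * n_samples)`` samples
    ranked by that gene.  Two genes (joint rule): the intersections of the
    per-gene top sets and of the per-gene bottom sets; an empty
    intersection is reported, not fatal.  Boundary ties resolve by stable
    sample order.
    """
    if isinstance(genes, str):
        genes = [genes]
    genes = list(genes)
    if len(genes) not in (1, 2):
        raise ConfigError("quartile grouping takes one or two gene symbols")
    if not (0.0 < quartile < 0.5):
        raise ConfigError(f"quartile must be in (0, 0.5), got {quartile}")

    norm = library_size_normalize(np.asarray(counts.counts, dtype=float))
    n = len(counts.samples)
    k = int(np.floor(quartile * n))
    if k < 1:
        raise StageError(f"quartile group would be empty for n={n}")

    tops, bottoms = [], []
    for g in genes:
        expr = norm[counts.gene_index(g)]
        order = np.argsort(expr, kind="stable")  # ascending, stable on ties
        bottoms.append([counts.samples[i] for i in order[:k]])
        tops.append([counts.samples[i] for i in order[n - k:]])

    if len(genes) == 1:
        high, low = tops[0], bottoms[0]
        rule_hi, rule_lo = "single_gene_top25", "single_gene_bottom25"
        name = genes[0]
    else:
        high = [s for s in counts.samples if all(s in t for t in map(set, tops))]
        low = [s for s in counts.samples if all(s in b for b in map(set, bottoms))]
        rule_hi, rule_lo = "joint_top25", "joint_bottom25"
        name = "+".join(genes)
        if not high or not low:
            logger.warning("joint quartile intersection empty (high=%d, low=%d)",
                           len(high), len(low))
    return (GroupAssignment(f"{name}_high", high, rule_hi),
            GroupAssignment(f"{name}_low", low, rule_lo))


# ---------------------------------------------------------------------------
# over-representation


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # overlap of query and set within universe
    K: int  # set size within universe
    n: int  # query size within universe
    N: int  # universe size
    p_value: float
    adjusted_p: float
    significant: bool


def hypergeometric_enrichment(query_genes: Iterable[str],
                              sets: GeneSetCollection,
                              universe: Iterable[str] | None = None,
                              alpha: float = 0.05) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per gene set.

    p = P(X >= k) for X ~ Hypergeom(N, K, n); BH adjustment across all
    tested sets; sorted by (adjusted_p, set name).  Query genes outside the
    universe are dropped with a warning.
    """
    uni = list(universe) if universe is not None else (sets.universe or [])
    if not uni:
        raise StageError("empty gene universe")
    uni_set = set(uni)
    query = list(dict.fromkeys(query_genes))  # dedupe, keep order
    dropped = [g for g in query if g not in uni_set]
    if dropped:
        logger.warning("%d query genes outside universe dropped", len(dropped))
    query_set = {g for g in query if g in uni_set}

    N, n = len(uni_set), len(query_set)
    names = sorted(sets.sets)
    rows = []
    for name in names:
        members = set(sets.sets[name]) & uni_set
        K = len(members)
        k = len(members & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    adj = bh_adjust([p for _, _, _, p in rows])
    results = [EnrichmentResult(name, k, K, n, N, p, float(a), bool(a < alpha))
               for (name, k, K, p), a in zip(rows, adj)]
    results.sort(key=lambda r: (r.adjusted_p, r.set_name))
    return results
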