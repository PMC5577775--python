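"""Descriptive and inferential statistics for GLCP-derived candidate genes.

Tissue-specificity index tau, expression summaries, transposable-element
overlap fractions, breakpoint-interval enrichment (hypergeometric plus two
permutation nulls), and cross-species expression correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import (
    ExpressionMatrix,
    Gene,
    Interval,
    merge_intervals,
    overlap_length,
)
from .null_models import Bundle, cluster_bundles, place_random_bundles

MIN_TISSUES_FOR_TAU = 5


def tissue_specificity_tau(expr_row) -> float:
    """Tissue-specificity index tau = sum_i(1 - x_i / x_max) / (N - 1).

    0 for uniform expression, 1 for single-tissue expression; scale-invariant.
    Requires at least five tissues; an all-zero row yields NaN.
    """
    x = np.asarray(expr_row, dtype=float)
    if x.ndim != 1 or len(x) < MIN_TISSUES_FOR_TAU:
        raise ValueError(f"tau needs >= {MIN_TISSUES_FOR_TAU} tissues")
    if (x < 0).any():
        raise ValueError("negative expression value")
    xmax = x.max()
    if xmax == 0:
        return float("nan")
    return float((1 - x / xmax).sum() / (len(x) - 1))


def tau_table(matrix: ExpressionMatrix, gene_set: list[str] | None = None) -> dict[str, float]:
    """Tau per gene; genes with fewer than five tissues are excluded with a warning."""
    if len(matrix.tissues) < MIN_TISSUES_FOR_TAU:
        warnings.warn(
            f"matrix has {len(matrix.tissues)} tissues; tau needs "
            f">= {MIN_TISSUES_FOR_TAU}; all genes excluded"
        )
        return {}
    genes = matrix.genes if gene_set is None else [g for g in gene_set if g in matrix]
    return {g: tissue_specificity_tau(matrix.row(g)) for g in genes}


def expression_summaries(
    matrix: ExpressionMatrix,
    gene_set: list[str],
    expressed_threshold: float = 1.0,
):
    """Per-gene mean, max, breadth (tissues >= threshold) and expressed flag.

    A gene is expressed when its maximum RPKM across tissues reaches the
    threshold (default 1.0).  Genes missing from the matrix get NA rows.
    """
    import pandas as pd

    rows = []
    for g in gene_set:
        if g in matrix:
            x = matrix.row(g)
            breadth = int((x >= expressed_threshold).sum())
            rows.append((g, float(x.mean()), float(x.max()), breadth, bool(x.max() >= expressed_threshold)))
        else:
            rows.append((g, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["gene_id", "mean", "max", "breadth", "expressed"]).set_index(
        "gene_id"
    )


def interval_overlap_fraction(exons: list[Interval], feature_intervals: list[Interval]) -> float:
    """Fraction of exonic bases covered by the (merged) feature intervals."""
    exonic = sum(e - s for s, e in exons)
    if exonic == 0:
        return 0.0
    merged = merge_intervals(feature_intervals)
    covered = sum(overlap_length(exon, f) for exon in exons for f in merged)
    return covered / exonic


def tss_feature_overlap(
    genes_a: list[Gene],
    genes_b: list[Gene],
    feature_intervals: dict[str, list[Interval]],
    use_fisher: bool = False,
) -> dict:
    """Fraction of genes with an isoform TSS inside a feature, compared between sets.

    The TSS is the strand-dependent first base of the transcript.  The
    two-proportion comparison uses Pearson chi-squared (Fisher via flag).
    """
    merged = {c: merge_intervals(v) for c, v in feature_intervals.items()}

    def hit(gene: Gene) -> bool:
        for t in gene.transcripts:
            tss = t.tss
            for s, e in merged.get(t.chrom, ()):
                if s <= tss < e:
                    return True
        return False

    na = sum(1 for g in genes_a if hit(g))
    nb = sum(1 for g in genes_b if hit(g))
    table = np.array([[na, len(genes_a) - na], [nb, len(genes_b) - nb]], dtype=float)
    if use_fisher:
        _, p = stats.fisher_exact(table)
        stat = float("nan")
    elif table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "fraction_a": na / len(genes_a) if genes_a else float("nan"),
        "fraction_b": nb / len(genes_b) if genes_b else float("nan"),
        "statistic": float(stat),
        "p_value": float(p),
        "table": table,
    }


@dataclass
class EnrichmentResult:
    observed: int
    fraction_a: float
    fraction_b: float
    p_hypergeom: float
    p_perm_intervals: float
    p_perm_features: float
    expected_perm_intervals: float
    expected_perm_features: float


def _gene_overlaps_intervals(gene: Gene, merged: dict[str, list[Interval]]) -> bool:
    """Exonic overlap between any isoform and any feature interval."""
    ivs = merged.get(gene.chrom, ())
    for t in gene.transcripts:
        for exon in t.exons:
            for f in ivs:
                if f[0] >= exon[1]:
                    break
                if overlap_length(exon, f) > 0:
                    return True
    return False


def breakpoint_enrichment(
    set_a: list[Gene],
    set_b: list[Gene],
    intervals: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of set A genes overlapping breakpoint intervals relative to set B.

    Three tests are reported: a hypergeometric tail on the 2x2 overlap table,
    a permutation re-placing the intervals uniformly on their chromosomes
    (length preserved), and a permutation re-placing set A's transcripts via
    the bundle shuffler.  Permutation p-values use the add-one estimator.
    """
    if not set_a:
        raise ValueError("set A must be non-empty")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    ids_a = {g.gene_id for g in set_a}
    if ids_a & {g.gene_id for g in set_b}:
        raise ValueError("gene sets must be disjoint")
    rng = np.random.default_rng(seed)

    by_chrom: dict[str, list[Interval]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = {c: merge_intervals(v) for c, v in by_chrom.items()}

    obs_a = sum(1 for g in set_a if _gene_overlaps_intervals(g, merged))
    obs_b = sum(1 for g in set_b if _gene_overlaps_intervals(g, merged))

    # hypergeometric: population = A u B, successes = all overlapping, draws = |A|
    N = len(set_a) + len(set_b)
    K = obs_a + obs_b
    n = len(set_a)
    p_hyper = float(stats.hypergeom.sf(obs_a - 1, N, K, n))

    # permutation 1: shuffle interval locations, length preserved
    hits = 0
    total = 0.0
    for _ in range(n_perm):
        perm: dict[str, list[Interval]] = {}
        for chrom, ivs in by_chrom.items():
            L = chrom_lengths[chrom]
            out = []
            for s, e in ivs:
                span = e - s
                start = int(rng.integers(0, max(1, L - span)))
                out.append((start, start + span))
            perm[chrom] = merge_intervals(out)
        count = sum(1 for g in set_a if _gene_overlaps_intervals(g, perm))
        total += count
        if count >= obs_a:
            hits += 1
    p_perm_intervals = (hits + 1) / (n_perm + 1)
    expected_intervals = total / n_perm

    # permutation 2: shuffle set A locations via the bundle placer
    bundles_by_chrom: dict[str, list[Bundle]] = {}
    for chrom in {g.chrom for g in set_a}:
        ts = [t for g in set_a if g.chrom == chrom for t in g.transcripts]
        bundles_by_chrom[chrom] = cluster_bundles(ts)
    exclusions: dict[str, list[Interval]] = {}
    for g in list(set_a) + list(set_b):
        exclusions.setdefault(g.chrom, []).append(g.span)
    hits = 0
    total = 0.0
    for _ in range(n_perm):
        count = 0
        for chrom, bundles in bundles_by_chrom.items():
            res = place_random_bundles(
                bundles, chrom_lengths[chrom], exclusions.get(chrom, []), rng
            )
            by_gene: dict[str, list] = {}
            for t in res.transcripts:
                by_gene.setdefault(t.gene_id, []).append(t)
            for gid, ts in by_gene.items():
                fake = Gene(
                    gene_id=gid,
                    chrom=chrom,
                    strand=ts[0].strand,
                    start=min(t.start for t in ts),
                    end=max(t.end for t in ts),
                    biotype=ts[0].biotype,
                    transcripts=ts,
                )
                if _gene_overlaps_intervals(fake, merged):
                    count += 1
        total += count
        if count >= obs_a:
            hits += 1
    p_perm_features = (hits + 1) / (n_perm + 1)
    expected_features = total / n_perm

    return EnrichmentResult(
        observed=obs_a,
        fraction_a=obs_a / len(set_a),
        fraction_b=obs_b / len(set_b) if set_b else float("nan"),
        p_hypergeom=p_hyper,
        p_perm_intervals=p_perm_intervals,
        p_perm_features=p_perm_features,
        expected_perm_intervals=expected_intervals,
        expected_perm_features=expected_features,
    )


def expression_correlation(
    pairs: list[tuple[str, str]],
    expr_ref: ExpressionMatrix,
    expr_target: ExpressionMatrix,
    summary: str = "mean",
    method: str = "spearman",
) -> tuple[float, float]:
    """Rank correlation of summary expression across (GLCP, candidate) pairs.

    Summary per gene is the mean (default) or max RPKM across tissues.
    Returns (rho, p); NA with fewer than three complete pairs.
    """
    fn = {"mean": np.mean, "max": np.max}[summary]
    xs, ys = [], []
    for q, t in pairs:
        if q in expr_ref and t in expr_target:
            xs.append(float(fn(expr_ref.row(q))))
            ys.append(float(fn(expr_target.row(t))))
    if len(xs) < 3:
        return (float("nan"), float("nan"))
    if method == "spearman":
        rho, p = stats.spearmanr(xs, ys)
    elif method == "pearson":
        rho, p = stats.pearsonr(xs, ys)
    else:
        raise ValueError(f"unknown method {method!r}")
    return (float(rho), float(p))
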