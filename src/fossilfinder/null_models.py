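"""Randomization null models for the synteny counts and empirical FDR.

Three schemes estimate how many syntenic GLCP-candidate pairs arise by
chance: re-placing the candidate transcripts at random genomic positions
('placement'), swapping the GLCPs for random protein-coding genes
('geneset'), or both at once ('both').  Isoforms are clustered into bundles
that move as a unit, preserving internal exon structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeAnnotation, Interval, TranscriptModel, merge_intervals

SCHEMES = ("placement", "geneset", "both")
DEFAULT_ITERATIONS = {"placement": 1000, "geneset": 1000, "both": 10_000}


@dataclass
class Bundle:
    """Overlapping transcript isoforms moved as one unit during placement."""

    chrom: str
    start: int
    end: int
    members: list[TranscriptModel]

    @property
    def span_length(self) -> int:
        return self.end - self.start


def cluster_bundles(transcripts: list[TranscriptModel]) -> list[Bundle]:
    """Connected components of the span-overlap graph on one chromosome.

    Because components of interval overlap are contiguous runs after sorting
    by start, a single sweep suffices.
    """
    if not transcripts:
        return []
    chroms = {t.chrom for t in transcripts}
    if len(chroms) > 1:
        raise ValueError("cluster_bundles operates on one chromosome at a time")
    ts = sorted(transcripts, key=lambda t: (t.start, t.end, t.transcript_id))
    bundles: list[Bundle] = []
    cur = Bundle(ts[0].chrom, ts[0].start, ts[0].end, [ts[0]])
    for t in ts[1:]:
        if t.start < cur.end:
            cur.members.append(t)
            cur.end = max(cur.end, t.end)
        else:
            bundles.append(cur)
            cur = Bundle(t.chrom, t.start, t.end, [t])
    bundles.append(cur)
    return bundles


@dataclass
class PlacementResult:
    transcripts: list[TranscriptModel]
    placed: int
    skipped: int


def place_random_bundles(
    bundles: list[Bundle],
    chrom_length: int,
    exclusion_intervals: list[Interval],
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> PlacementResult:
    """Place each bundle uniformly on its chromosome, avoiding exclusions.

    Placed bundles keep their internal structure (exon offsets, strands) and
    may not overlap an exclusion interval or a previously placed bundle.
    Bundles that cannot be placed within ``max_attempts`` draws are skipped.
    """
    exclusions = merge_intervals(exclusion_intervals)
    occupied: list[Interval] = list(exclusions)
    out: list[TranscriptModel] = []
    placed = skipped = 0
    for bundle in bundles:
        span = bundle.span_length
        if span > chrom_length:
            raise ValueError("bundle longer than chromosome")
        ok = False
        for _ in range(max_attempts):
            start = int(rng.integers(0, chrom_length - span + 1))
            candidate = (start, start + span)
            if any(candidate[0] < e and s < candidate[1] for s, e in occupied):
                continue
            ok = True
            break
        if not ok:
            skipped += 1
            continue
        placed += 1
        occupied.append(candidate)
        shift = start - bundle.start
        for t in bundle.members:
            out.append(
                TranscriptModel(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    chrom=t.chrom,
                    strand=t.strand,
                    exons=tuple((s + shift, e + shift) for s, e in t.exons),
                    biotype=t.biotype,
                )
            )
    return PlacementResult(transcripts=out, placed=placed, skipped=skipped)


def random_gene_sets(
    gene_universe: list[str],
    n_per_set: int,
    iterations: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Independent samples of genes without replacement within each set."""
    universe = sorted(gene_universe)
    if n_per_set > len(universe):
        raise ValueError("n_per_set exceeds the gene universe")
    return [
        rng.choice(universe, size=n_per_set, replace=False).tolist()
        for _ in range(iterations)
    ]


@dataclass
class NullResult:
    observed: int
    null_values: list[int]
    scheme: str
    seed: int
    null_mean: float = field(init=False)
    ci90: tuple[float, float] = field(init=False)
    empirical_p: float = field(init=False)
    excess: float = field(init=False)
    fdr: float = field(init=False)

    def __post_init__(self) -> None:
        nulls = np.asarray(self.null_values, dtype=float)
        self.null_mean = float(nulls.mean())
        self.ci90 = (
            float(np.percentile(nulls, 5)),
            float(np.percentile(nulls, 95)),
        )
        n = len(nulls)
        self.empirical_p = (int((nulls >= self.observed).sum()) + 1) / (n + 1)
        self.excess = self.observed - self.null_mean
        self.fdr = self.null_mean / self.observed if self.observed > 0 else float("nan")


def empirical_null(count_fn, scheme: str, iterations: int, seed: int) -> NullResult:
    """Empirical null of a synteny count under one randomization scheme.

    ``count_fn(rng)`` must return the syntenic-pair count computed on inputs
    perturbed with ``rng``; ``count_fn(None)`` returns the observed count on
    unperturbed inputs.  The add-one estimator (r+1)/(n+1) gives a one-sided
    (enrichment) p; the 90% CI is the empirical 5th-95th percentile band.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if iterations < 20:
        raise ValueError("need at least 20 iterations for a meaningful CI")
    master = np.random.default_rng(seed)
    observed = int(count_fn(None))
    nulls = [int(count_fn(np.random.default_rng(master.integers(2**31)))) for _ in range(iterations)]
    return NullResult(observed=observed, null_values=nulls, scheme=scheme, seed=seed)


def estimate_fdr(result: NullResult, cap: bool = True) -> float:
    """FDR of the synteny screen: expected chance pairs over observed pairs."""
    if result.observed == 0:
        return float("nan")
    raw = result.null_mean / result.observed
    return min(1.0, raw) if cap else raw


# ---------------------------------------------------------------------------
# scheme plumbing for the synteny count
# ---------------------------------------------------------------------------

def make_synteny_count_fn(
    glcp_ids: list[str],
    candidate_ids: list[str],
    anno_q: GenomeAnnotation,
    anno_t: GenomeAnnotation,
    homology,
    chains,
    params,
    scheme: str,
    coding_universe: list[str] | None = None,
):
    """Build ``count_fn(rng)`` for :func:`empirical_null` on the full pipeline.

    placement: candidate transcripts are clustered into bundles and re-placed
    on their chromosomes, avoiding protein-coding genes and the original
    candidate loci.  geneset: the GLCP set is replaced by an equally sized
    random draw from the reference species' conserved coding genes.  both:
    fresh placement and a fresh gene set every iteration.
    """
    from .synteny import AnnotationIndex, ChainIndex, call_syntenic_pairs

    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    index_q = AnnotationIndex(anno_q)
    chain_index = ChainIndex(chains, params.gap_split, params.chain_q_side)
    candidate_set = set(candidate_ids)
    cand_transcripts = [t for t in anno_t.transcripts if t.gene_id in candidate_set]
    other_transcripts = [t for t in anno_t.transcripts if t.gene_id not in candidate_set]
    if coding_universe is None:
        coding_universe = sorted(
            g.gene_id for g in anno_q.coding_genes() if g.gene_id not in set(glcp_ids)
        )

    exclusions_by_chrom: dict[str, list[Interval]] = {}
    for t in anno_t.transcripts:
        exclusions_by_chrom.setdefault(t.chrom, []).append(
            (t.start, t.end)
        )  # coding genes, lncRNAs and original candidate loci all excluded

    bundles_by_chrom: dict[str, list[Bundle]] = {}
    for chrom in {t.chrom for t in cand_transcripts}:
        bundles_by_chrom[chrom] = cluster_bundles(
            [t for t in cand_transcripts if t.chrom == chrom]
        )

    def count_fn(rng: np.random.Generator | None) -> int:
        queries = list(glcp_ids)
        anno_t_run = anno_t
        index_t_run = None
        if rng is not None and scheme in ("geneset", "both"):
            queries = rng.choice(sorted(coding_universe), size=min(len(glcp_ids), len(coding_universe)),
                                 replace=False).tolist()
        if rng is not None and scheme in ("placement", "both"):
            moved: list[TranscriptModel] = []
            for chrom in sorted(bundles_by_chrom):
                res = place_random_bundles(
                    bundles_by_chrom[chrom],
                    anno_t.chrom_lengths[chrom],
                    exclusions_by_chrom.get(chrom, []),
                    rng,
                )
                moved.extend(res.transcripts)
            anno_t_run = GenomeAnnotation(
                species=anno_t.species,
                chrom_lengths=dict(anno_t.chrom_lengths),
                transcripts=other_transcripts + moved,
                unbridged_gaps={k: list(v) for k, v in anno_t.unbridged_gaps.items()},
                genome_size=anno_t.genome_size,
            )
        pairs = call_syntenic_pairs(
            queries,
            sorted(candidate_set & set(anno_t_run.genes)),
            anno_q,
            anno_t_run,
            homology,
            chains,
            params,
            index_q=index_q,
            index_t=index_t_run,
            chain_index=chain_index,
        )
        return sum(1 for p in pairs if p.verdict == "syntenic")

    return count_fn


def write_null_table(results: list[NullResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("scheme\tobserved\tnull_mean\tci90_lo\tci90_hi\tempirical_p\texcess\tfdr\n")
        for r in results:
            fh.write(
                f"{r.scheme}\t{r.observed}\t{r.null_mean:.4f}\t{r.ci90[0]:.4f}\t"
                f"{r.ci90[1]:.4f}\t{r.empirical_p:.6g}\t{r.excess:.4f}\t"
                f"{estimate_fdr(r):.4f}\n"
            )
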