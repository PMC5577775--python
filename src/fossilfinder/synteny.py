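"""Two-phase synteny matching between lost-gene loci and candidate lncRNAs.

Phase 1 (anchor matching): a query gene G_Q (a GLCP in the reference species)
and a target gene G_T (a candidate lncRNA or pseudogene in a mammal) are
*potentially syntenic* when an orthologous pair of protein-coding genes flanks
or overlaps both, on matching sides and with the same relative orientation.

Phase 2 (disruptor filtering): whole-genome alignment chains around both loci
are classified as upstream / overlapping / downstream of each gene; a chain
whose placement is contradictory between the two genomes (e.g. upstream of
G_Q but downstream of G_T) is a *disruptor* and rejects the pair.

Upstream/downstream are strand-relative to the focal gene; disruptor
contradiction is tested after normalizing the target-side label by the parity
of chain strands and gene strands, so a cleanly inverted locus never
self-disrupts.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    AlignmentChain,
    Gene,
    GenomeAnnotation,
    Interval,
    intervals_overlap,
)

HUMAN_GENOME_SIZE = 3_137_161_264  # hg19 golden-path length
DEFAULT_MAX_DIST_HUMAN = 500_000
DEFAULT_GAP_SPLIT = 10_000
DEFAULT_FLANK = 100_000

_DISRUPTOR_CASES = {
    ("up", "down"),
    ("down", "up"),
    ("up", "overlap"),
    ("down", "overlap"),
    ("overlap", "up"),
    ("overlap", "down"),
}


def scaled_max_distance(species_genome_size: int, human_genome_size: int = HUMAN_GENOME_SIZE,
                        human_max_dist: int = DEFAULT_MAX_DIST_HUMAN) -> int:
    """Neighbor-search radius: 500 kb in human, scaled by relative genome size."""
    if species_genome_size <= 0 or human_genome_size <= 0:
        raise ValueError("genome sizes must be positive")
    return int(round(human_max_dist * species_genome_size / human_genome_size))


# ---------------------------------------------------------------------------
# neighborhood contexts
# ---------------------------------------------------------------------------

@dataclass
class NeighborContext:
    """Focal gene with its conserved coding neighborhood."""

    gene: Gene
    upstream: Gene | None
    downstream: Gene | None
    overlapping: tuple[Gene, ...]
    window: Interval

    def context_genes(self) -> list[Gene]:
        out = list(self.overlapping)
        if self.upstream is not None:
            out.append(self.upstream)
        if self.downstream is not None:
            out.append(self.downstream)
        return out


class AnnotationIndex:
    """Per-chromosome sorted gene arrays for fast neighborhood queries."""

    def __init__(self, annotation: GenomeAnnotation):
        self.annotation = annotation
        self._chrom: dict[str, tuple[list[Gene], np.ndarray, np.ndarray, int]] = {}
        for chrom in annotation.chrom_lengths:
            genes = annotation.genes_on(chrom)
            starts = np.array([g.start for g in genes], dtype=np.int64)
            ends = np.array([g.end for g in genes], dtype=np.int64)
            maxlen = int((ends - starts).max()) if genes else 0
            self._chrom[chrom] = (genes, starts, ends, maxlen)
        self._gaps = {
            chrom: sorted(ivs) for chrom, ivs in annotation.unbridged_gaps.items()
        }

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._chrom[chrom][0]

    def _blocked(self, chrom: str, left: int, right: int) -> bool:
        """True if an unbridged assembly gap overlaps the open interval (left, right)."""
        if right <= left:
            return False
        for gs, ge in self._gaps.get(chrom, ()):
            if gs >= right:
                break
            if ge > left:
                return True
        return False


def neighbor_context(
    gene: Gene,
    index: AnnotationIndex,
    conserved: set[str],
    max_dist: int,
    exclude: frozenset[str] = frozenset(),
) -> NeighborContext:
    """Build the Upstream/Overlapping/Downstream context of a focal gene.

    Overlapping: conserved coding genes whose spans intersect the focal span.
    Upstream/Downstream: the single closest non-overlapping conserved coding
    gene on each strand-relative side, within ``max_dist`` of the focal gene's
    edge and not separated from it by an unbridged assembly gap.  Equidistant
    ties break toward the smaller gene start, then gene id.
    """
    genes, starts, ends, maxlen = index._chrom[gene.chrom]

    def eligible(g: Gene) -> bool:
        return (
            g.gene_id != gene.gene_id
            and g.gene_id in conserved
            and g.gene_id not in exclude
        )

    # overlapping genes: start < gene.end and end > gene.start
    lo = bisect_left(starts, gene.start - maxlen) if maxlen else bisect_left(starts, gene.start)
    hi = bisect_right(starts, gene.end)
    overlapping = tuple(
        g
        for g in genes[lo:hi]
        if eligible(g) and intervals_overlap(g.span, gene.span)
    )

    # left neighbor: max end among eligible genes with end <= gene.start
    left: Gene | None = None
    i = bisect_left(starts, gene.start) - 1
    floor = gene.start - max_dist - maxlen
    while i >= 0 and starts[i] >= floor:
        g = genes[i]
        if g.end <= gene.start and eligible(g) and gene.start - g.end <= max_dist:
            if left is None or g.end > left.end or (
                g.end == left.end and (g.start, g.gene_id) < (left.start, left.gene_id)
            ):
                left = g
        i -= 1
    if left is not None and index._blocked(gene.chrom, left.end, gene.start):
        left = None

    # right neighbor: min start among eligible genes with start >= gene.end
    right: Gene | None = None
    j = bisect_left(starts, gene.end)
    while j < len(genes) and starts[j] - gene.end <= max_dist:
        g = genes[j]
        if g.start >= gene.end and eligible(g):
            right = g
            break
        j += 1
    if right is not None and index._blocked(gene.chrom, gene.end, right.start):
        right = None

    if gene.strand == "+":
        upstream, downstream = left, right
    else:
        upstream, downstream = right, left

    members = [gene] + list(overlapping) + [g for g in (upstream, downstream) if g]
    window = (min(g.start for g in members), max(g.end for g in members))
    return NeighborContext(gene, upstream, downstream, overlapping, window)


# ---------------------------------------------------------------------------
# phase 1: anchors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    gene_q: str
    gene_t: str
    side: str  # 'up' or 'down' (the clause that matched; overlap genes join both)
    same_orientation: bool  # relative orientation of focal gene to this anchor


def _relative_orientation(focal: Gene, anchor: Gene) -> bool:
    return focal.strand == anchor.strand


def potentially_syntenic(ctx_q: NeighborContext, ctx_t: NeighborContext, homology) -> list[Anchor]:
    """All ortholog anchor pairs matching between the two contexts.

    Clause 'up': homologs between Upstream v Overlapping of both genes;
    clause 'down': likewise for Downstream v Overlapping.  A matching pair
    must have the same relative orientation to the two focal genes.
    """
    up_q = list(ctx_q.overlapping) + ([ctx_q.upstream] if ctx_q.upstream else [])
    down_q = list(ctx_q.overlapping) + ([ctx_q.downstream] if ctx_q.downstream else [])
    up_t = list(ctx_t.overlapping) + ([ctx_t.upstream] if ctx_t.upstream else [])
    down_t = list(ctx_t.overlapping) + ([ctx_t.downstream] if ctx_t.downstream else [])

    anchors: dict[tuple[str, str], Anchor] = {}
    for side, qs, ts in (("up", up_q, up_t), ("down", down_q, down_t)):
        for x in qs:
            for y in ts:
                if not homology.are_orthologs(x.gene_id, y.gene_id):
                    continue
                rq = _relative_orientation(ctx_q.gene, x)
                rt = _relative_orientation(ctx_t.gene, y)
                if rq != rt:
                    continue
                anchors.setdefault((x.gene_id, y.gene_id), Anchor(x.gene_id, y.gene_id, side, rq))
    return [anchors[k] for k in sorted(anchors)]


# ---------------------------------------------------------------------------
# phase 2: chains and disruptors
# ---------------------------------------------------------------------------

def split_chains(chains: list[AlignmentChain], gap_threshold: int = DEFAULT_GAP_SPLIT) -> list[AlignmentChain]:
    """Split chains wherever the inter-block gap in either genome exceeds the threshold.

    The multiset of aligned blocks is preserved exactly.
    """
    out: list[AlignmentChain] = []
    for chain in chains:
        pieces: list[list[tuple[int, int, int, int]]] = [[chain.blocks[0]]]
        for prev, cur in zip(chain.blocks, chain.blocks[1:]):
            gap_t = cur[0] - prev[1]
            if chain.q_strand == "-":
                gap_q = prev[2] - cur[3]
            else:
                gap_q = cur[2] - prev[3]
            if gap_t > gap_threshold or gap_q > gap_threshold:
                pieces.append([cur])
            else:
                pieces[-1].append(cur)
        if len(pieces) == 1:
            out.append(chain)
        else:
            for k, piece in enumerate(pieces, start=1):
                out.append(
                    AlignmentChain(
                        chain_id=f"{chain.chain_id}.{k}",
                        score=chain.score,
                        t_chrom=chain.t_chrom,
                        t_size=chain.t_size,
                        t_strand=chain.t_strand,
                        q_chrom=chain.q_chrom,
                        q_size=chain.q_size,
                        q_strand=chain.q_strand,
                        blocks=tuple(piece),
                    )
                )
    return out


def classify_chain(
    chain: AlignmentChain,
    side: str,
    ctx: NeighborContext,
    flank: int = DEFAULT_FLANK,
) -> str:
    """Place a chain relative to a focal gene: 'up', 'overlap', 'down' or 'outside'.

    Chains whose footprint misses the window spanning Upstream..Downstream of
    the gene plus ``flank`` on each side are 'outside'.  Any block (or a
    footprint straddling the gene) intersecting the gene span counts as
    overlap; otherwise the side is strand-relative to the gene.
    """
    chrom, _, span, blocks = chain.side(side)
    gene = ctx.gene
    if chrom != gene.chrom:
        return "outside"
    window = (ctx.window[0] - flank, ctx.window[1] + flank)
    if not intervals_overlap(span, window):
        return "outside"
    if intervals_overlap(span, gene.span):
        if any(intervals_overlap(b, gene.span) for b in blocks):
            return "overlap"
        # footprint straddles the gene with no block inside: still overlap
        return "overlap"
    left = span[1] <= gene.start
    if gene.strand == "+":
        return "up" if left else "down"
    return "down" if left else "up"


def find_disruptors(
    ctx_q: NeighborContext,
    ctx_t: NeighborContext,
    chains: list[AlignmentChain],
    flank: int = DEFAULT_FLANK,
    q_side: str = "q",
) -> list[str]:
    """Chains whose placement is contradictory between the two loci.

    Contradiction cases: up/down, down/up, up-or-down/overlap and
    overlap/up-or-down, after flipping the target-side up/down label when the
    chain's strand parity disagrees with the gene pair's strand parity.
    """
    t_side = "t" if q_side == "q" else "q"
    gene_parity = ctx_q.gene.strand == ctx_t.gene.strand
    disruptors: list[str] = []
    for chain in chains:
        label_q = classify_chain(chain, q_side, ctx_q, flank)
        if label_q == "outside":
            continue
        label_t = classify_chain(chain, t_side, ctx_t, flank)
        if label_t == "outside":
            continue
        chain_parity = chain.q_strand == chain.t_strand
        if chain_parity != gene_parity and label_t in ("up", "down"):
            label_t = "down" if label_t == "up" else "up"
        if (label_q, label_t) in _DISRUPTOR_CASES:
            disruptors.append(chain.chain_id)
    return disruptors


# ---------------------------------------------------------------------------
# pair calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntenyPair:
    query_gene: str
    query_species: str
    target_gene: str
    target_species: str
    anchors: tuple[Anchor, ...]
    disruptors: tuple[str, ...]
    verdict: str  # 'syntenic' or 'rejected'


@dataclass
class SyntenyParams:
    max_dist_q: int
    max_dist_t: int
    gap_split: int = DEFAULT_GAP_SPLIT
    flank: int = DEFAULT_FLANK
    chain_q_side: str = "q"  # which chain side lives in the query genome


class ChainIndex:
    """Chains grouped by query-side chromosome, pre-split."""

    def __init__(self, chains: list[AlignmentChain], gap_split: int, q_side: str = "q"):
        self.q_side = q_side
        self.by_q_chrom: dict[str, list[AlignmentChain]] = {}
        for c in split_chains(chains, gap_split):
            chrom = c.side(q_side)[0]
            self.by_q_chrom.setdefault(chrom, []).append(c)

    def near(self, q_chrom: str) -> list[AlignmentChain]:
        return self.by_q_chrom.get(q_chrom, [])


def conserved_gene_ids(annotation: GenomeAnnotation, other: GenomeAnnotation, homology) -> set[str]:
    """Coding genes with at least one ortholog annotated in the other genome."""
    other_genes = set(other.genes)
    return {
        g.gene_id
        for g in annotation.coding_genes()
        if homology.orthologs_of(g.gene_id) & other_genes
    }


def call_syntenic_pairs(
    glcp_ids: list[str],
    candidate_ids: list[str],
    anno_q: GenomeAnnotation,
    anno_t: GenomeAnnotation,
    homology,
    chains: list[AlignmentChain],
    params: SyntenyParams,
    *,
    index_q: AnnotationIndex | None = None,
    index_t: AnnotationIndex | None = None,
    chain_index: ChainIndex | None = None,
) -> list[SyntenyPair]:
    """Run both phases over every (GLCP, candidate) combination.

    Only pairs with at least one anchor are returned; the verdict is
    'syntenic' when no disruptor chain exists, 'rejected' otherwise.
    Deterministic: output sorted by (query, target).
    """
    collisions = set(anno_q.genes) & set(anno_t.genes)
    if collisions:
        raise ValueError(f"gene ids present in both genomes: {sorted(collisions)[:5]}")

    index_q = index_q or AnnotationIndex(anno_q)
    index_t = index_t or AnnotationIndex(anno_t)
    chain_index = chain_index or ChainIndex(chains, params.gap_split, params.chain_q_side)

    conserved_q = conserved_gene_ids(anno_q, anno_t, homology)
    conserved_t = conserved_gene_ids(anno_t, anno_q, homology)

    ctx_t_cache: dict[str, NeighborContext] = {}
    t_context_index: dict[str, set[str]] = {}
    for cid in candidate_ids:
        gene = anno_t.genes.get(cid)
        if gene is None:
            continue
        ctx = neighbor_context(gene, index_t, conserved_t, params.max_dist_t)
        ctx_t_cache[cid] = ctx
        for g in ctx.context_genes():
            t_context_index.setdefault(g.gene_id, set()).add(cid)

    pairs: list[SyntenyPair] = []
    for qid in sorted(set(glcp_ids)):
        gq = anno_q.genes.get(qid)
        if gq is None:
            continue
        ctx_q = neighbor_context(gq, index_q, conserved_q, params.max_dist_q)
        hits: set[str] = set()
        for x in ctx_q.context_genes():
            for y in homology.orthologs_of(x.gene_id):
                hits |= t_context_index.get(y, set())
        chains_near = chain_index.near(gq.chrom)
        for cid in sorted(hits):
            ctx_t = ctx_t_cache[cid]
            anchors = potentially_syntenic(ctx_q, ctx_t, homology)
            if not anchors:
                continue
            disruptors = find_disruptors(
                ctx_q, ctx_t, chains_near, params.flank, params.chain_q_side
            )
            pairs.append(
                SyntenyPair(
                    query_gene=qid,
                    query_species=anno_q.species,
                    target_gene=cid,
                    target_species=anno_t.species,
                    anchors=tuple(anchors),
                    disruptors=tuple(disruptors),
                    verdict="syntenic" if not disruptors else "rejected",
                )
            )
    return pairs


@dataclass
class RecoveryResult:
    recovered: int
    tested: int

    @property
    def fraction(self) -> float:
        return self.recovered / self.tested if self.tested else float("nan")


def ortholog_recovery(
    anno_q: GenomeAnnotation,
    anno_t: GenomeAnnotation,
    homology,
    chains: list[AlignmentChain],
    params: SyntenyParams,
    max_pairs: int | None = None,
    seed: int = 0,
) -> RecoveryResult:
    """Leave-one-out sensitivity check on orthologous coding pairs.

    Each orthologous coding pair is removed from the anchor-eligible set and
    the two-phase caller is run with its members as query and target; the
    fraction of pairs called syntenic measures the method's sensitivity.
    """
    index_q = AnnotationIndex(anno_q)
    index_t = AnnotationIndex(anno_t)
    chain_index = ChainIndex(chains, params.gap_split, params.chain_q_side)
    conserved_q = conserved_gene_ids(anno_q, anno_t, homology)
    conserved_t = conserved_gene_ids(anno_t, anno_q, homology)

    pairs: list[tuple[str, str]] = []
    for a in sorted(conserved_q):
        targets = sorted(homology.orthologs_of(a) & set(anno_t.genes))
        if targets:
            pairs.append((a, targets[0]))
    if len(pairs) < 2:
        raise ValueError("need at least two orthologous coding pairs")
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]

    recovered = 0
    for a, b in pairs:
        exclude = frozenset((a, b))
        ga, gb = anno_q.genes[a], anno_t.genes[b]
        ctx_q = neighbor_context(ga, index_q, conserved_q, params.max_dist_q, exclude)
        ctx_t = neighbor_context(gb, index_t, conserved_t, params.max_dist_t, exclude)
        anchors = potentially_syntenic(ctx_q, ctx_t, homology)
        if not anchors:
            continue
        if find_disruptors(ctx_q, ctx_t, chain_index.near(ga.chrom), params.flank,
                           params.chain_q_side):
            continue
        recovered += 1
    return RecoveryResult(recovered=recovered, tested=len(pairs))


def write_pair_table(pairs: list[SyntenyPair], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "query_gene\tquery_species\ttarget_gene\ttarget_species\t"
            "n_anchors\tanchors\tn_disruptors\tverdict\n"
        )
        for p in pairs:
            anchor_str = ";".join(f"{a.gene_q}:{a.gene_t}:{a.side}" for a in p.anchors)
            fh.write(
                f"{p.query_gene}\t{p.query_species}\t{p.target_gene}\t{p.target_species}\t"
                f"{len(p.anchors)}\t{anchor_str}\t{len(p.disruptors)}\t{p.verdict}\n"
            )
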