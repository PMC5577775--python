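"""Synteny caller tests, including brute-force oracle equivalence on random loci."""

import numpy as np
import pytest

from fossilfinder.genome_io import AlignmentChain
from fossilfinder.glcp_caller import HomologyMap, SpeciesRoster
from fossilfinder.synteny import (
    AnnotationIndex,
    ChainIndex,
    SyntenyParams,
    call_syntenic_pairs,
    classify_chain,
    find_disruptors,
    neighbor_context,
    potentially_syntenic,
    scaled_max_distance,
    split_chains,
)
from conftest import make_annotation, make_transcript


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain scans, no indexes)
# ---------------------------------------------------------------------------

def brute_context(gene, all_genes, conserved, max_dist, gaps):
    def eligible(g):
        return g.gene_id != gene.gene_id and g.gene_id in conserved

    def blocked(lo, hi):
        return any(gs < hi and ge > lo for gs, ge in gaps if hi > lo)

    over = [
        g for g in all_genes
        if g.chrom == gene.chrom and eligible(g) and g.start < gene.end and g.end > gene.start
    ]
    lefts = [
        g for g in all_genes
        if g.chrom == gene.chrom and eligible(g) and g.end <= gene.start
        and gene.start - g.end <= max_dist
    ]
    left = None
    if lefts:
        left = sorted(lefts, key=lambda g: (-g.end, g.start, g.gene_id))[0]
        if blocked(left.end, gene.start):
            left = None
    rights = [
        g for g in all_genes
        if g.chrom == gene.chrom and eligible(g) and g.start >= gene.end
        and g.start - gene.end <= max_dist
    ]
    right = None
    if rights:
        right = sorted(rights, key=lambda g: (g.start, g.gene_id))[0]
        if blocked(gene.end, right.start):
            right = None
    if gene.strand == "+":
        up, down = left, right
    else:
        up, down = right, left
    return up, down, over


def brute_anchors(gq, ctx_q, gt, ctx_t, orth):
    up_q, down_q, over_q = ctx_q
    up_t, down_t, over_t = ctx_t
    anchors = set()
    for q_set, t_set in (
        (over_q + ([up_q] if up_q else []), over_t + ([up_t] if up_t else [])),
        (over_q + ([down_q] if down_q else []), over_t + ([down_t] if down_t else [])),
    ):
        for x in q_set:
            for y in t_set:
                if (x.gene_id, y.gene_id) in orth and (gq.strand == x.strand) == (
                    gt.strand == y.strand
                ):
                    anchors.add((x.gene_id, y.gene_id))
    return anchors


def brute_chain_label(span, blocks, gene, window_lo, window_hi):
    if span[1] <= window_lo or span[0] >= window_hi:
        return "outside"
    if span[0] < gene.end and span[1] > gene.start:
        return "overlap"
    left = span[1] <= gene.start
    if gene.strand == "+":
        return "up" if left else "down"
    return "down" if left else "up"


def brute_disruptors(gq, win_q, gt, win_t, chains, flank):
    bad = {("up", "down"), ("down", "up"), ("up", "overlap"), ("down", "overlap"),
           ("overlap", "up"), ("overlap", "down")}
    out = []
    for c in chains:
        if c.q_chrom != gq.chrom or c.t_chrom != gt.chrom:
            continue
        lq = brute_chain_label(c.q_span, c.q_blocks, gq, win_q[0] - flank, win_q[1] + flank)
        lt = brute_chain_label(c.t_span, c.t_blocks, gt, win_t[0] - flank, win_t[1] + flank)
        if lq == "outside" or lt == "outside":
            continue
        if (c.q_strand == c.t_strand) != (gq.strand == gt.strand) and lt in ("up", "down"):
            lt = {"up": "down", "down": "up"}[lt]
        if (lq, lt) in bad:
            out.append(c.chain_id)
    return out


def random_locus(rng, n_genes_q=12, n_genes_t=12, n_chains=8):
    """Random single-chromosome two-genome locus with random orthology and chains."""

    def genes(prefix, n):
        ts = []
        pos = rng.integers(0, 5_000)
        for k in range(n):
            length = int(rng.integers(1_000, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            ts.append(
                make_transcript(f"{prefix}{k}_t", f"{prefix}{k}", "chr1", strand,
                                [(int(pos), int(pos + length))])
            )
            pos += length + int(rng.integers(-500, 30_000))  # occasional overlaps
            pos = max(pos, ts[-1].exons[0][0] + 100)
        return ts

    anno_q = make_annotation(genes("Q", n_genes_q), species="qsp")
    anno_t = make_annotation(genes("T", n_genes_t), species="tsp")
    species_of = {g: "qsp" for g in anno_q.genes} | {g: "tsp" for g in anno_t.genes}
    hm = HomologyMap(species_of=species_of, family_of={g: g for g in species_of},
                     roster=SpeciesRoster())
    q_ids, t_ids = sorted(anno_q.genes), sorted(anno_t.genes)
    for q in q_ids:
        if rng.random() < 0.7:
            hm.add_orthologs(q, t_ids[rng.integers(0, len(t_ids))])
    chains = []
    for k in range(n_chains):
        size = int(rng.integers(500, 8_000))
        n_blocks = int(rng.integers(1, 4))
        t0 = int(rng.integers(0, 150_000))
        q0 = int(rng.integers(0, 150_000))
        blocks = []
        for b in range(n_blocks):
            blocks.append((t0, t0 + size, q0, q0 + size))
            t0 += size + int(rng.integers(0, 3_000))
            q0 += size + int(rng.integers(0, 3_000))
        q_strand = "+" if rng.random() < 0.5 else "-"
        if q_strand == "-":
            qb = sorted((qs, qe) for _, _, qs, qe in blocks)[::-1]
            blocks = [(ts, te, s, e) for (ts, te, _, _), (s, e) in zip(blocks, qb)]
        chains.append(
            AlignmentChain(f"c{k}", 1.0, "chr1", 1_000_000, "+", "chr1", 1_000_000,
                           q_strand, tuple(blocks))
        )
    return anno_q, anno_t, hm, chains


class TestScaledMaxDistance:
    @pytest.mark.parametrize(
        "species,human,expected",
        [(3_000_000, 3_000_000, 500_000), (1_500_000, 3_000_000, 250_000),
         (3_750_000, 3_000_000, 625_000)],
    )
    def test_linear_scaling(self, species, human, expected):
        assert scaled_max_distance(species, human) == expected

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            scaled_max_distance(0, 100)


class TestNeighborContext:
    def test_lone_gene_has_empty_context(self):
        anno = make_annotation([make_transcript("t", "g", "chr1", "+", [(1000, 2000)])])
        ctx = neighbor_context(anno.genes["g"], AnnotationIndex(anno), {"g"}, 500_000)
        assert ctx.upstream is None and ctx.downstream is None and ctx.overlapping == ()

    def test_contained_gene_is_overlapping(self):
        anno = make_annotation(
            [
                make_transcript("t", "g", "chr1", "+", [(1000, 9000)]),
                make_transcript("t2", "inner", "chr1", "+", [(3000, 4000)]),
            ]
        )
        ctx = neighbor_context(anno.genes["g"], AnnotationIndex(anno), {"inner"}, 500_000)
        assert [g.gene_id for g in ctx.overlapping] == ["inner"]

    def test_max_dist_and_gap_rules(self):
        # five candidates at known offsets: one beyond max_dist, one across a gap
        anno = make_annotation(
            [
                make_transcript("t", "g", "chr1", "+", [(100_000, 110_000)]),
                make_transcript("a_t", "a", "chr1", "+", [(95_000, 98_000)]),      # closest left
                make_transcript("b_t", "b", "chr1", "+", [(80_000, 85_000)]),      # further left
                make_transcript("c_t", "c", "chr1", "+", [(112_000, 113_000)]),    # right, across gap
                make_transcript("d_t", "d", "chr1", "+", [(150_000, 151_000)]),    # right, further
                make_transcript("e_t", "e", "chr1", "+", [(700_000, 701_000)]),    # beyond max_dist
            ],
            gaps={"chr1": [(110_500, 111_000)]},
        )
        conserved = {"a", "b", "c", "d", "e"}
        ctx = neighbor_context(anno.genes["g"], AnnotationIndex(anno), conserved, 500_000)
        assert ctx.upstream.gene_id == "a"
        # 'c' is blocked by the unbridged gap, so there is no downstream neighbor
        assert ctx.downstream is None

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        for rep in range(30):
            anno_q, _, _, _ = random_locus(rng)
            index = AnnotationIndex(anno_q)
            genes = list(anno_q.genes.values())
            conserved = {g.gene_id for g in genes if rng.random() < 0.8}
            for gene in genes:
                ctx = neighbor_context(gene, index, conserved, 50_000)
                up, down, over = brute_context(
                    gene, genes, conserved, 50_000, anno_q.unbridged_gaps.get("chr1", [])
                )
                assert (ctx.upstream.gene_id if ctx.upstream else None) == (
                    up.gene_id if up else None
                )
                assert (ctx.downstream.gene_id if ctx.downstream else None) == (
                    down.gene_id if down else None
                )
                assert {g.gene_id for g in ctx.overlapping} == {g.gene_id for g in over}


class TestAnchors:
    def _pair(self, strand_q="+", strand_t="+", anchor_strand_q="+", anchor_strand_t="+"):
        anno_q = make_annotation(
            [
                make_transcript("xq_t", "xq", "chr1", anchor_strand_q, [(1000, 2000)]),
                make_transcript("gq_t", "gq", "chr1", strand_q, [(10_000, 12_000)]),
            ],
            species="qsp",
        )
        anno_t = make_annotation(
            [
                make_transcript("xt_t", "xt", "chr1", anchor_strand_t, [(1000, 2000)]),
                make_transcript("gt_t", "gt", "chr1", strand_t, [(10_000, 12_000)]),
            ],
            species="tsp",
        )
        hm = HomologyMap(
            species_of={"xq": "qsp", "gq": "qsp", "xt": "tsp", "gt": "tsp"},
            family_of={g: g for g in ("xq", "gq", "xt", "gt")},
            roster=SpeciesRoster(),
        )
        hm.add_orthologs("xq", "xt")
        ctx_q = neighbor_context(anno_q.genes["gq"], AnnotationIndex(anno_q), {"xq"}, 500_000)
        ctx_t = neighbor_context(anno_t.genes["gt"], AnnotationIndex(anno_t), {"xt"}, 500_000)
        return potentially_syntenic(ctx_q, ctx_t, hm)

    def test_single_upstream_anchor(self):
        anchors = self._pair()
        assert len(anchors) == 1 and anchors[0].gene_q == "xq"

    def test_flipped_orientation_kills_anchor(self):
        assert self._pair(anchor_strand_t="-") == []

    def test_whole_locus_inversion_keeps_anchor(self):
        # mirrored target locus: gene and anchor flipped AND on swapped sides
        anno_q = make_annotation(
            [
                make_transcript("xq_t", "xq", "chr1", "+", [(1000, 2000)]),
                make_transcript("gq_t", "gq", "chr1", "+", [(10_000, 12_000)]),
            ],
            species="qsp",
        )
        anno_t = make_annotation(
            [
                make_transcript("gt_t", "gt", "chr1", "-", [(10_000, 12_000)]),
                make_transcript("xt_t", "xt", "chr1", "-", [(20_000, 21_000)]),
            ],
            species="tsp",
        )
        hm = HomologyMap(
            species_of={"xq": "qsp", "gq": "qsp", "xt": "tsp", "gt": "tsp"},
            family_of={g: g for g in ("xq", "gq", "xt", "gt")},
            roster=SpeciesRoster(),
        )
        hm.add_orthologs("xq", "xt")
        ctx_q = neighbor_context(anno_q.genes["gq"], AnnotationIndex(anno_q), {"xq"}, 500_000)
        ctx_t = neighbor_context(anno_t.genes["gt"], AnnotationIndex(anno_t), {"xt"}, 500_000)
        assert len(potentially_syntenic(ctx_q, ctx_t, hm)) == 1

    def test_matches_cross_product_oracle(self):
        rng = np.random.default_rng(17)
        for rep in range(50):
            anno_q, anno_t, hm, _ = random_locus(rng)
            orth = {
                (a, b) for a, bs in hm.orthologs.items() for b in bs
            }
            index_q, index_t = AnnotationIndex(anno_q), AnnotationIndex(anno_t)
            conserved_q = {a for a, b in orth if a in anno_q.genes}
            conserved_t = {b for a, b in orth if b in anno_t.genes}
            gq = list(anno_q.genes.values())[rng.integers(0, len(anno_q.genes))]
            gt = list(anno_t.genes.values())[rng.integers(0, len(anno_t.genes))]
            ctx_q = neighbor_context(gq, index_q, conserved_q - {gq.gene_id}, 80_000)
            ctx_t = neighbor_context(gt, index_t, conserved_t - {gt.gene_id}, 80_000)
            got = {(a.gene_q, a.gene_t) for a in potentially_syntenic(ctx_q, ctx_t, hm)}
            expected = brute_anchors(
                gq,
                brute_context(gq, list(anno_q.genes.values()), conserved_q - {gq.gene_id},
                              80_000, []),
                gt,
                brute_context(gt, list(anno_t.genes.values()), conserved_t - {gt.gene_id},
                              80_000, []),
                orth,
            )
            assert got == expected


class TestSplitChains:
    def _chain(self, gaps_q, gaps_t=None):
        gaps_t = gaps_t if gaps_t is not None else [0] * len(gaps_q)
        blocks = []
        t = q = 0
        size = 1000
        for gq, gt in zip([0] + list(gaps_q), [0] + list(gaps_t)):
            t += gt
            q += gq
            blocks.append((t, t + size, q, q + size))
            t += size
            q += size
        return AlignmentChain("c", 1.0, "chrT", 10**7, "+", "chrQ", 10**7, "+", tuple(blocks))

    def test_single_large_gap_cuts_once(self):
        out = split_chains([self._chain([15_000])])
        assert len(out) == 2

    def test_small_gaps_left_untouched(self):
        chain = self._chain([5_000, 9_999])
        assert split_chains([chain]) == [chain]

    def test_cut_point_enumeration_and_block_conservation(self):
        chain = self._chain([5_000, 12_000, 3_000, 20_000])
        out = split_chains([chain])
        assert len(out) == 3
        merged = sorted(b for c in out for b in c.blocks)
        assert merged == sorted(chain.blocks)

    def test_gap_on_either_side_triggers_split(self):
        chain = self._chain([0], gaps_t=[11_000])
        assert len(split_chains([chain])) == 2

    def test_scenario_chains_conserve_block_multiset(self, scenario):
        split = split_chains(scenario.chains)
        assert sorted(b for c in split for b in c.blocks) == sorted(
            b for c in scenario.chains for b in c.blocks
        )


class TestClassifyAndDisruptors:
    def _ctx(self, strand="+"):
        anno = make_annotation(
            [
                make_transcript("u_t", "u", "chr1", "+", [(50_000, 60_000)]),
                make_transcript("g_t", "g", "chr1", strand, [(200_000, 220_000)]),
                make_transcript("d_t", "d", "chr1", "+", [(400_000, 410_000)]),
            ]
        )
        return neighbor_context(anno.genes["g"], AnnotationIndex(anno), {"u", "d"}, 500_000)

    def _chain_at(self, q_iv, t_iv, q_strand="+"):
        size = min(q_iv[1] - q_iv[0], t_iv[1] - t_iv[0])
        return AlignmentChain(
            "c", 1.0, "chr1", 10**7, "+", "chr1", 10**7, q_strand,
            ((t_iv[0], t_iv[0] + size, q_iv[0], q_iv[0] + size),),
        )

    def test_footprint_inside_gene_is_overlap(self):
        chain = self._chain_at((205_000, 210_000), (0, 5_000))
        assert classify_chain(chain, "q", self._ctx()) == "overlap"

    def test_past_neighbor_but_within_flank_is_downstream(self):
        chain = self._chain_at((460_000, 470_000), (0, 10_000))
        assert classify_chain(chain, "q", self._ctx()) == "down"
        assert classify_chain(chain, "q", self._ctx(strand="-")) == "up"

    def test_outside_flanked_window(self):
        chain = self._chain_at((600_000, 610_000), (0, 10_000))
        assert classify_chain(chain, "q", self._ctx()) == "outside"

    def test_straddling_gene_start_is_overlap(self):
        chain = self._chain_at((195_000, 205_000), (0, 10_000))
        assert classify_chain(chain, "q", self._ctx()) == "overlap"

    def test_collinear_chain_is_not_a_disruptor(self):
        ctx_q, ctx_t = self._ctx(), self._ctx()
        chain = self._chain_at((40_000, 440_000), (40_000, 440_000))
        assert find_disruptors(ctx_q, ctx_t, [chain]) == []

    def test_case_i_upstream_to_downstream_disrupts(self):
        ctx_q, ctx_t = self._ctx(), self._ctx()
        chain = self._chain_at((100_000, 120_000), (300_000, 320_000))
        assert find_disruptors(ctx_q, ctx_t, [chain]) == ["c"]

    def test_whole_locus_inversion_does_not_self_disrupt(self):
        ctx_q = self._ctx()
        # mirror-image locus: gene on '-', neighborhood reversed
        anno_t = make_annotation(
            [
                make_transcript("u2_t", "u2", "chr1", "-", [(400_000, 410_000)]),
                make_transcript("g2_t", "g2", "chr1", "-", [(200_000, 220_000)]),
                make_transcript("d2_t", "d2", "chr1", "-", [(50_000, 60_000)]),
            ]
        )
        ctx_t = neighbor_context(anno_t.genes["g2"], AnnotationIndex(anno_t), {"u2", "d2"}, 500_000)
        # inverted chain maps the region upstream of G_Q (80-120 kb) to its
        # mirror image (360-400 kb), which is strand-relative upstream of the
        # '-' target gene: consistent, not a disruptor
        chain = AlignmentChain(
            "inv", 1.0, "chr1", 10**7, "+", "chr1", 10**7, "-",
            ((360_000, 400_000, 80_000, 120_000),),
        )
        assert find_disruptors(ctx_q, ctx_t, [chain]) == []
        # same placement but without the strand flip: contradictory (case i)
        chain2 = AlignmentChain(
            "noflip", 1.0, "chr1", 10**7, "+", "chr1", 10**7, "+",
            ((360_000, 400_000, 80_000, 120_000),),
        )
        assert find_disruptors(ctx_q, ctx_t, [chain2]) == ["noflip"]


class TestPipelineComposition:
    def test_verdicts_match_brute_force_on_random_loci(self):
        """Full two-phase verdicts equal the naive oracle on >=100 random toy loci."""
        rng = np.random.default_rng(23)
        params = SyntenyParams(max_dist_q=80_000, max_dist_t=80_000, gap_split=10**9)
        n_checked = 0
        for rep in range(150):
            anno_q, anno_t, hm, chains = random_locus(rng)
            conserved_q = {
                g for g in anno_q.genes
                if hm.orthologs.get(g, set()) & set(anno_t.genes)
            }
            conserved_t = {
                g for g in anno_t.genes
                if hm.orthologs.get(g, set()) & set(anno_q.genes)
            }
            queries = sorted(set(anno_q.genes) - conserved_q)[:3]
            candidates = sorted(set(anno_t.genes) - conserved_t)[:3]
            pairs = call_syntenic_pairs(
                queries, candidates, anno_q, anno_t, hm, chains, params
            )
            got = {(p.query_gene, p.target_gene): p.verdict for p in pairs}
            genes_q, genes_t = list(anno_q.genes.values()), list(anno_t.genes.values())
            orth = {(a, b) for a, bs in hm.orthologs.items() for b in bs}
            expected = {}
            for qid in queries:
                gq = anno_q.genes[qid]
                bq = brute_context(gq, genes_q, conserved_q, 80_000, [])
                for cid in candidates:
                    gt = anno_t.genes[cid]
                    bt = brute_context(gt, genes_t, conserved_t, 80_000, [])
                    anchors = brute_anchors(gq, bq, gt, bt, orth)
                    if not anchors:
                        continue
                    members_q = [gq] + [g for g in bq if g and not isinstance(g, list)]
                    win_q = (min(g.start for g in members_q + bq[2]),
                             max(g.end for g in members_q + bq[2]))
                    members_t = [gt] + [g for g in bt if g and not isinstance(g, list)]
                    win_t = (min(g.start for g in members_t + bt[2]),
                             max(g.end for g in members_t + bt[2]))
                    disr = brute_disruptors(gq, win_q, gt, win_t, chains, 100_000)
                    expected[(qid, cid)] = "syntenic" if not disr else "rejected"
                    n_checked += 1
            assert got == expected
        assert n_checked >= 100

    def test_no_chains_means_no_disruptors(self, clean_scenario):
        sc = clean_scenario
        from fossilfinder.pipeline import candidate_gene_ids, synteny_params_for

        params = synteny_params_for(sc.anno_ref, sc.anno_target)
        with_chains = call_syntenic_pairs(
            sc.glcps, candidate_gene_ids(sc.anno_target), sc.anno_ref, sc.anno_target,
            sc.homology, sc.chains, params,
        )
        without = call_syntenic_pairs(
            sc.glcps, candidate_gene_ids(sc.anno_target), sc.anno_ref, sc.anno_target,
            sc.homology, [], params,
        )
        assert {(p.query_gene, p.target_gene) for p in without} == {
            (p.query_gene, p.target_gene) for p in with_chains
        }
        assert all(p.verdict == "syntenic" for p in without)

    def test_phase_two_only_removes_pairs(self, scenario):
        from fossilfinder.pipeline import candidate_gene_ids, synteny_params_for

        sc = scenario
        params = synteny_params_for(sc.anno_ref, sc.anno_target)
        pairs = call_syntenic_pairs(
            sc.glcps, candidate_gene_ids(sc.anno_target), sc.anno_ref, sc.anno_target,
            sc.homology, sc.chains, params,
        )
        syntenic = {(p.query_gene, p.target_gene) for p in pairs if p.verdict == "syntenic"}
        potential = {(p.query_gene, p.target_gene) for p in pairs}
        assert syntenic <= potential

    def test_deterministic_output(self, scenario):
        from fossilfinder.pipeline import candidate_gene_ids, synteny_params_for

        sc = scenario
        params = synteny_params_for(sc.anno_ref, sc.anno_target)
        args = (sc.glcps, candidate_gene_ids(sc.anno_target), sc.anno_ref,
                sc.anno_target, sc.homology, sc.chains, params)
        assert call_syntenic_pairs(*args) == call_syntenic_pairs(*args)

    def test_cross_species_id_collision_rejected(self):
        anno = make_annotation([make_transcript("t", "g", "chr1", "+", [(0, 100)])])
        hm = HomologyMap(species_of={"g": "s"}, family_of={"g": "g"}, roster=SpeciesRoster())
        with pytest.raises(ValueError, match="both genomes"):
            call_syntenic_pairs(["g"], ["g"], anno, anno, hm, [],
                                SyntenyParams(max_dist_q=1, max_dist_t=1))
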