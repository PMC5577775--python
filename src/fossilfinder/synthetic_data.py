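"""Two-genome synthetic scenarios with planted lost genes and derived lncRNAs.

The generator lays out a reference-species genome (chicken-like) and a
mammalian genome (human-like) with shared gene order, deletes a configurable
fraction of the mammalian orthologs (the planted GLCPs), plants derived
lncRNAs or unprocessed pseudogenes at a fraction of the emptied loci, adds
background lncRNAs, applies relocations and inversions to the mammalian
genome, and synthesizes alignment chains from the resulting collinearity
map.  Everything downstream of the generator — annotations, homology tables,
chains, expression matrices, sequences, repeats, assembly gaps, breakpoint
intervals and the truth table of planted pairs — is reproducible from the
seed alone.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    AlignmentChain,
    GenomeAnnotation,
    Interval,
    TranscriptModel,
    merge_intervals,
)
from .glcp_caller import (
    CORE_MAMMALS,
    HomologyMap,
    SpeciesRoster,
)

VERTEBRATE_OUTGROUPS = ("opossum", "chicken", "lizard", "xenopus", "coelacanth")


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic two-genome scenario.

    Defaults emulate the study conditions: genes with log-normal lengths
    (median ~20 kb), geometric intergenic spacing (mean ~60 kb), 5% of genes
    ancestrally lost in the mammal, 40% of lost loci spawning a derived
    lncRNA (15% a pseudogene), 30% sequence divergence between a derived
    lncRNA and its ancestor, and tissue-structured expression where lost
    genes are more tissue-specific than their family members.
    """

    seed: int
    n_chromosomes: int = 4
    genes_per_chromosome: int = 50
    gene_length_median: float = 20_000.0
    gene_length_sigma: float = 0.6
    intergenic_mean: float = 60_000.0
    glcp_fraction: float = 0.05
    derived_lncrna_fraction: float = 0.4
    derived_pseudogene_fraction: float = 0.15
    n_background_lncrnas: int = 30
    n_inversions: int = 2
    relocation_fraction: float = 0.02
    divergence: float = 0.3
    indel_rate: float = 0.02
    seq_length_range: tuple[int, int] = (200, 500)
    n_tissues: int = 6
    expr_scale_mean: float = 10.0
    alpha_glcp: float = 0.3
    alpha_coding: float = 3.0
    alpha_derived_lnc: float = 2.0
    alpha_background_lnc: float = 0.5
    repeat_density: float = 0.05
    n_unbridged_gaps_per_chrom: int = 1
    second_isoform_fraction: float = 0.3
    mammal_presence_fraction: float = 0.15
    vertebrate_omission_rate: float = 0.2
    ref_species: str = "chicken"
    target_species: str = "human"

    def __post_init__(self) -> None:
        for name in (
            "glcp_fraction",
            "derived_lncrna_fraction",
            "derived_pseudogene_fraction",
            "divergence",
            "indel_rate",
            "relocation_fraction",
            "repeat_density",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.derived_lncrna_fraction + self.derived_pseudogene_fraction > 1:
            raise ValueError("derived fractions sum above 1")
        if self.n_tissues < 5:
            raise ValueError("need at least 5 tissues")


@dataclass(frozen=True)
class TruthPair:
    glcp_gene: str
    derived_gene: str
    kind: str  # 'lncRNA' or 'unprocessed_pseudogene'


@dataclass
class Segment:
    """One maximal collinear piece of the two-genome map (equal lengths)."""

    a_chrom: str
    a_start: int
    a_end: int
    b_chrom: str
    b_start: int
    b_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


@dataclass
class SyntheticScenario:
    config: ScenarioConfig
    anno_ref: GenomeAnnotation
    anno_target: GenomeAnnotation
    homology: HomologyMap
    chains: list[AlignmentChain]
    sequences: dict[str, str]
    expr_ref: "object"
    expr_target: "object"
    repeats: dict[str, list[Interval]]
    breakpoints: list[tuple[str, int, int]]
    truth: list[TruthPair]
    glcps: list[str] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate_sequence(seq: str, substitution_rate: float, indel_rate: float,
                    rng: np.random.Generator) -> str:
    """Apply per-base substitutions and small indels to a sequence."""
    bases = "ACGT"
    out: list[str] = []
    for c in seq:
        u = rng.random()
        if u < indel_rate / 2:
            continue  # deletion
        if u < indel_rate:
            out.append(bases[rng.integers(0, 4)])  # insertion before base
        if rng.random() < substitution_rate:
            alt = [b for b in bases if b != c]
            out.append(alt[rng.integers(0, 3)])
        else:
            out.append(c)
    return "".join(out)


def _make_exons(start: int, length: int, n_exons: int, rng: np.random.Generator) -> tuple[Interval, ...]:
    """Partition [start, start+length) into alternating exons/introns (>=50 bp each)."""
    n_parts = 2 * n_exons - 1
    min_part = 50
    if length < n_parts * min_part:
        n_exons = max(1, length // (2 * min_part))
        n_parts = 2 * n_exons - 1
    extra = length - n_parts * min_part
    weights = rng.dirichlet(np.ones(n_parts))
    sizes = (weights * extra).astype(int) + min_part
    sizes[-1] += length - sizes.sum()
    exons = []
    pos = start
    for k, size in enumerate(sizes):
        if k % 2 == 0:
            exons.append((pos, pos + int(size)))
        pos += int(size)
    return tuple(exons)


def _flip_exons(exons: tuple[Interval, ...], s: int, e: int) -> tuple[Interval, ...]:
    return tuple(sorted((s + e - e0, s + e - s0) for s0, e0 in exons))


def _free_intervals(occupied: list[Interval], length: int, margin: int = 1000) -> list[Interval]:
    merged = merge_intervals([(max(0, s - margin), min(length, e + margin)) for s, e in occupied])
    free = []
    prev = 0
    for s, e in merged:
        if s > prev:
            free.append((prev, s))
        prev = e
    if prev < length:
        free.append((prev, length))
    return free


def _pick_free_position(free: list[Interval], span: int, rng: np.random.Generator) -> int | None:
    fits = [(s, e) for s, e in free if e - s >= span]
    if not fits:
        return None
    weights = np.array([e - s - span + 1 for s, e in fits], dtype=float)
    k = rng.choice(len(fits), p=weights / weights.sum())
    s, e = fits[k]
    return int(rng.integers(s, e - span + 1))


def generate_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Generate a full scenario; see the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    ref, tgt = config.ref_species, config.target_species
    roster = SpeciesRoster()

    # ----- shared ancestral layout ------------------------------------------------
    chrom_lengths: dict[str, int] = {}
    ref_transcripts: list[TranscriptModel] = []
    gene_layout: list[dict] = []  # one entry per ancestral gene
    counter = 0
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        pos = 10_000
        for _ in range(config.genes_per_chromosome):
            length = int(
                np.clip(
                    rng.lognormal(np.log(config.gene_length_median), config.gene_length_sigma),
                    2_000,
                    200_000,
                )
            )
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 7))
            exons = _make_exons(pos, length, n_ex, rng)
            gid = f"{ref}_g{counter:05d}"
            ref_transcripts.append(
                TranscriptModel(f"{gid}_t1", gid, chrom, strand, exons, "protein_coding")
            )
            gene_layout.append(
                {
                    "idx": counter,
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + length,
                    "strand": strand,
                    "exons": exons,
                    "ref_gene": gid,
                    "tgt_gene": f"{tgt}_g{counter:05d}",
                }
            )
            counter += 1
            spacing = int(rng.geometric(1.0 / config.intergenic_mean)) + 2_000
            pos += length + spacing
        chrom_lengths[chrom] = pos + 50_000

    n_genes = counter

    # ----- families ---------------------------------------------------------------
    family_of: dict[str, str] = {}
    order = rng.permutation(n_genes)
    fam_n = 0
    i = 0
    while i < len(order):
        size = 1 if rng.random() < 0.7 else int(rng.integers(2, 5))
        members = order[i : i + size]
        fam = f"fam{fam_n:05d}"
        fam_n += 1
        for m in members:
            family_of[gene_layout[m]["ref_gene"]] = fam
            family_of[gene_layout[m]["tgt_gene"]] = fam
        i += size

    # ----- planted losses ---------------------------------------------------------
    n_glcp = max(1, int(round(config.glcp_fraction * n_genes)))
    # bias losses toward multi-member families (compensation by paralogs)
    fam_sizes: dict[str, int] = {}
    for g in gene_layout:
        fam_sizes[family_of[g["ref_gene"]]] = fam_sizes.get(family_of[g["ref_gene"]], 0) + 1
    weights = np.array(
        [2.0 if fam_sizes[family_of[g["ref_gene"]]] > 1 else 1.0 for g in gene_layout]
    )
    glcp_idx = set(
        rng.choice(n_genes, size=n_glcp, replace=False, p=weights / weights.sum()).tolist()
    )
    for i in glcp_idx:  # the mammalian copy no longer exists
        family_of.pop(gene_layout[i]["tgt_gene"], None)

    # ----- cross-roster homology ---------------------------------------------------
    species_of: dict[str, str] = {}
    hm_pairs: list[tuple[str, str]] = []
    other_mammals = [s for s in CORE_MAMMALS if s != tgt]
    vertebrates = [s for s in VERTEBRATE_OUTGROUPS if s != ref]
    for g in gene_layout:
        rg = g["ref_gene"]
        species_of[rg] = ref
        lost = g["idx"] in glcp_idx
        if not lost:
            species_of[g["tgt_gene"]] = tgt
            hm_pairs.append((rg, g["tgt_gene"]))
        # other mammals
        if lost:
            if rng.random() < config.mammal_presence_fraction:
                sp = other_mammals[rng.integers(0, len(other_mammals))]
                hid = f"{sp}_h{g['idx']:05d}"
                species_of[hid] = sp
                family_of[hid] = family_of[rg]
                hm_pairs.append((rg, hid))
        else:
            for sp in other_mammals:
                if rng.random() < config.vertebrate_omission_rate:
                    continue
                hid = f"{sp}_h{g['idx']:05d}"
                species_of[hid] = sp
                family_of[hid] = family_of[rg]
                hm_pairs.append((rg, hid))
        # non-mammalian vertebrates: support for everyone (with omissions)
        kept = [sp for sp in vertebrates if rng.random() >= config.vertebrate_omission_rate]
        while lost and len(kept) < 2:  # planted GLCPs always retain vertebrate support
            extra = vertebrates[rng.integers(0, len(vertebrates))]
            if extra not in kept:
                kept.append(extra)
        for sp in kept:
            hid = f"{sp}_h{g['idx']:05d}"
            species_of[hid] = sp
            family_of[hid] = family_of[rg]
            hm_pairs.append((rg, hid))

    # ----- mammalian genome: copy, delete, plant ----------------------------------
    tgt_transcripts: list[TranscriptModel] = []
    truth: list[TruthPair] = []
    lnc_n = pseudo_n = 0
    for g in gene_layout:
        if g["idx"] not in glcp_idx:
            tgt_transcripts.append(
                TranscriptModel(
                    f"{g['tgt_gene']}_t1", g["tgt_gene"], g["chrom"], g["strand"],
                    g["exons"], "protein_coding",
                )
            )
            continue
        u = rng.random()
        if u < config.derived_lncrna_fraction:
            gid = f"{tgt}_lnc{lnc_n:04d}"
            lnc_n += 1
            n_keep = min(len(g["exons"]), int(rng.integers(1, 4)))
            first = int(rng.integers(0, len(g["exons"]) - n_keep + 1))
            exons = g["exons"][first : first + n_keep]
            tgt_transcripts.append(
                TranscriptModel(f"{gid}_t1", gid, g["chrom"], g["strand"], exons, "lncRNA")
            )
            if len(exons) > 1 and rng.random() < config.second_isoform_fraction:
                tgt_transcripts.append(
                    TranscriptModel(f"{gid}_t2", gid, g["chrom"], g["strand"], exons[:-1], "lncRNA")
                )
            truth.append(TruthPair(g["ref_gene"], gid, "lncRNA"))
        elif u < config.derived_lncrna_fraction + config.derived_pseudogene_fraction:
            gid = f"{tgt}_ups{pseudo_n:04d}"
            pseudo_n += 1
            tgt_transcripts.append(
                TranscriptModel(
                    f"{gid}_t1", gid, g["chrom"], g["strand"], g["exons"],
                    "unprocessed_pseudogene",
                )
            )
            truth.append(TruthPair(g["ref_gene"], gid, "unprocessed_pseudogene"))

    # ----- background lncRNAs ------------------------------------------------------
    occupied: dict[str, list[Interval]] = {c: [] for c in chrom_lengths}
    for t in tgt_transcripts:
        occupied[t.chrom].append(t.span)
    for b in range(config.n_background_lncrnas):
        chrom = f"chr{1 + b % config.n_chromosomes}"
        span = int(np.clip(rng.lognormal(np.log(4_000), 0.5), 1_000, 30_000))
        free = _free_intervals(occupied[chrom], chrom_lengths[chrom])
        start = _pick_free_position(free, span, rng)
        if start is None:
            raise ValueError(
                f"cannot place background lncRNA {b}: n_background_lncrnas="
                f"{config.n_background_lncrnas} does not fit intergenic space"
            )
        gid = f"{tgt}_lnc{lnc_n:04d}"
        lnc_n += 1
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _make_exons(start, span, int(rng.integers(1, 4)), rng)
        tgt_transcripts.append(TranscriptModel(f"{gid}_t1", gid, chrom, strand, exons, "lncRNA"))
        occupied[chrom].append((start, start + span))

    # ----- rearrangements -----------------------------------------------------------
    segments: list[Segment] = [
        Segment(c, 0, L, c, 0, L, "+") for c, L in chrom_lengths.items()
    ]
    events: list[dict] = []
    breakpoints: list[tuple[str, int, int]] = []

    # relocations: move coding genes to random intergenic positions
    coding_idx = [g["idx"] for g in gene_layout if g["idx"] not in glcp_idx]
    n_reloc = int(round(config.relocation_fraction * len(coding_idx)))
    reloc = set(
        rng.choice(coding_idx, size=n_reloc, replace=False).tolist() if n_reloc else []
    )
    by_gene: dict[str, list[int]] = {}
    for k, t in enumerate(tgt_transcripts):
        by_gene.setdefault(t.gene_id, []).append(k)
    for g in gene_layout:
        if g["idx"] not in reloc:
            continue
        gid = g["tgt_gene"]
        span = g["end"] - g["start"]
        # pick a destination anywhere in the mammal genome
        dest = None
        for _ in range(100):
            chrom = f"chr{1 + rng.integers(0, config.n_chromosomes)}"
            free = _free_intervals(occupied[chrom], chrom_lengths[chrom], margin=2_000)
            start = _pick_free_position(free, span, rng)
            if start is not None:
                dest = (chrom, start)
                break
        if dest is None:
            continue
        chrom_new, start_new = dest
        shift = start_new - g["start"]
        for k in by_gene[gid]:
            t = tgt_transcripts[k]
            tgt_transcripts[k] = TranscriptModel(
                t.transcript_id, t.gene_id, chrom_new, t.strand,
                tuple((s + shift, e + shift) for s, e in t.exons), t.biotype,
            )
        occupied[g["chrom"]] = [iv for iv in occupied[g["chrom"]] if iv != (g["start"], g["end"])]
        occupied[chrom_new].append((start_new, start_new + span))
        # cut the hole out of the segment containing the ancestral locus
        new_segments = []
        for seg in segments:
            if seg.a_chrom != g["chrom"] or seg.a_end <= g["start"] or seg.a_start >= g["end"]:
                new_segments.append(seg)
                continue
            if seg.a_start < g["start"]:
                new_segments.append(
                    Segment(seg.a_chrom, seg.a_start, g["start"], seg.b_chrom,
                            seg.b_start, seg.b_start + (g["start"] - seg.a_start), "+")
                )
            if g["end"] < seg.a_end:
                new_segments.append(
                    Segment(seg.a_chrom, g["end"], seg.a_end, seg.b_chrom,
                            seg.b_start + (g["end"] - seg.a_start), seg.b_end, "+")
                )
            new_segments.append(
                Segment(g["chrom"], g["start"], g["end"], chrom_new,
                        start_new, start_new + span, "+")
            )
        segments = new_segments
        events.append(
            {"type": "relocation", "gene": gid,
             "old": (g["chrom"], g["start"], g["end"]),
             "new": (chrom_new, start_new, start_new + span)}
        )
        breakpoints.append((g["chrom"], g["start"], g["end"]))  # excision scar
        breakpoints.append((chrom_new, start_new, start_new + span))  # insertion scar

    # inversions: disjoint intervals with boundaries in feature-free space
    def feature_free(chrom: str) -> list[Interval]:
        occ = [t.span for t in tgt_transcripts if t.chrom == chrom]
        return _free_intervals(occ, chrom_lengths[chrom], margin=200)

    used_inv: dict[str, list[Interval]] = {}
    n_done = 0
    attempts = 0
    while n_done < config.n_inversions and attempts < 200 * max(1, config.n_inversions):
        attempts += 1
        chrom = f"chr{1 + rng.integers(0, config.n_chromosomes)}"
        L = chrom_lengths[chrom]
        free = feature_free(chrom)
        s = _pick_free_position(free, 1, rng)
        if s is None:
            continue
        lo, hi = int(0.05 * L), int(0.5 * L)
        span = int(rng.integers(lo, hi))
        e = s + span
        if e >= L:
            continue
        in_free = any(fs <= e < fe for fs, fe in feature_free(chrom))
        if not in_free:
            continue
        if any(s < ue and us < e for us, ue in used_inv.get(chrom, [])):
            continue
        used_inv.setdefault(chrom, []).append((s, e))
        # transform features inside [s, e)
        for k, t in enumerate(tgt_transcripts):
            if t.chrom != chrom or t.end <= s or t.start >= e:
                continue
            if t.start < s or t.end > e:
                raise AssertionError("feature straddles inversion boundary")
            tgt_transcripts[k] = TranscriptModel(
                t.transcript_id, t.gene_id, chrom,
                "-" if t.strand == "+" else "+",
                _flip_exons(t.exons, s, e), t.biotype,
            )
        # transform segments
        new_segments = []
        for seg in segments:
            if seg.b_chrom != chrom or seg.b_end <= s or seg.b_start >= e:
                new_segments.append(seg)
                continue
            assert seg.strand == "+", "inversions must be disjoint"
            pieces = []
            cuts = [seg.b_start, seg.b_end]
            for pos in (s, e):
                if seg.b_start < pos < seg.b_end:
                    cuts.append(pos)
            cuts = sorted(set(cuts))
            for b0, b1 in zip(cuts, cuts[1:]):
                a0 = seg.a_start + (b0 - seg.b_start)
                a1 = seg.a_start + (b1 - seg.b_start)
                if s <= b0 and b1 <= e:
                    pieces.append(
                        Segment(seg.a_chrom, a0, a1, chrom, s + e - b1, s + e - b0, "-")
                    )
                else:
                    pieces.append(Segment(seg.a_chrom, a0, a1, chrom, b0, b1, "+"))
            new_segments.extend(pieces)
        segments = new_segments
        # transform earlier breakpoint scars caught inside the inversion
        moved = []
        for bc, bs, be in breakpoints:
            if bc == chrom and bs >= s and be <= e:
                moved.append((bc, s + e - be, s + e - bs))
            else:
                moved.append((bc, bs, be))
        breakpoints = moved
        events.append({"type": "inversion", "chrom": chrom, "start": s, "end": e})
        breakpoints.append((chrom, max(0, s - 500), s + 500))
        breakpoints.append((chrom, max(0, e - 500), e + 500))
        n_done += 1
    if n_done < config.n_inversions:
        raise ValueError(
            f"could only place {n_done}/{config.n_inversions} inversions; "
            f"genome too small (n_chromosomes={config.n_chromosomes}, "
            f"genes_per_chromosome={config.genes_per_chromosome})"
        )

    # ----- chains from the collinearity map -----------------------------------------
    chains: list[AlignmentChain] = []
    chain_n = 0
    for seg in sorted(segments, key=lambda s: (s.a_chrom, s.a_start)):
        if seg.length < 500:
            continue
        blocks: list[tuple[int, int, int, int]] = []
        off = 0
        while off < seg.length:
            size = int(min(seg.length - off, rng.integers(3_000, 15_000)))
            a0 = seg.a_start + off
            if seg.strand == "+":
                b0 = seg.b_start + off
                blocks.append((b0, b0 + size, a0, a0 + size))
            else:
                b1 = seg.b_end - off
                blocks.append((b1 - size, b1, a0, a0 + size))
            off += size
            gap = int(rng.integers(12_000, 25_000)) if rng.random() < 0.08 else int(rng.integers(0, 600))
            off += gap
        blocks.sort(key=lambda b: b[0])
        chain_n += 1
        chains.append(
            AlignmentChain(
                chain_id=f"chain{chain_n}",
                score=float(seg.length),
                t_chrom=seg.b_chrom,
                t_size=chrom_lengths[seg.b_chrom],
                t_strand="+",
                q_chrom=seg.a_chrom,
                q_size=chrom_lengths[seg.a_chrom],
                q_strand=seg.strand,
                blocks=tuple(blocks),
            )
        )

    # ----- unbridged gaps, repeats ---------------------------------------------------
    ref_occupied: dict[str, list[Interval]] = {c: [] for c in chrom_lengths}
    for t in ref_transcripts:
        ref_occupied[t.chrom].append(t.span)

    def place_gaps(occ: dict[str, list[Interval]]) -> dict[str, list[Interval]]:
        gaps: dict[str, list[Interval]] = {}
        for chrom in sorted(chrom_lengths):
            for _ in range(config.n_unbridged_gaps_per_chrom):
                free = _free_intervals(occ[chrom], chrom_lengths[chrom], margin=500)
                start = _pick_free_position(free, 200, rng)
                if start is None:
                    continue
                gaps.setdefault(chrom, []).append((start, start + 200))
                occ[chrom].append((start, start + 200))
        return gaps

    ref_gaps = place_gaps(ref_occupied)
    tgt_gaps = place_gaps(occupied)

    repeats: dict[str, list[Interval]] = {}
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        target_bp = int(config.repeat_density * L)
        covered = 0
        ivs: list[Interval] = []
        while covered < target_bp:
            span = int(rng.exponential(500)) + 50
            start = int(rng.integers(0, max(1, L - span)))
            ivs.append((start, start + span))
            covered += span
        repeats[chrom] = merge_intervals(ivs)

    # ----- expression -----------------------------------------------------------------
    tissues = [f"tissue{k + 1}" for k in range(config.n_tissues)]
    derived_parent = {t.derived_gene: t.glcp_gene for t in truth}

    def expr_value(scale: float, alpha: float) -> np.ndarray:
        profile = rng.dirichlet(np.full(config.n_tissues, alpha))
        return scale * profile * config.n_tissues

    ref_gene_ids = sorted({t.gene_id for t in ref_transcripts})
    scale_of: dict[str, float] = {}
    ref_rows = []
    glcp_ref_ids = {gene_layout[i]["ref_gene"] for i in glcp_idx}
    for g in ref_gene_ids:
        scale = rng.gamma(2.0, config.expr_scale_mean / 2.0)
        scale_of[g] = scale
        alpha = config.alpha_glcp if g in glcp_ref_ids else config.alpha_coding
        ref_rows.append(expr_value(scale, alpha))

    tgt_gene_ids = sorted({t.gene_id for t in tgt_transcripts})
    biotype_of = {t.gene_id: t.biotype for t in tgt_transcripts}
    tgt_rows = []
    for g in tgt_gene_ids:
        bt = biotype_of[g]
        if bt == "protein_coding":
            scale = rng.gamma(2.0, config.expr_scale_mean / 2.0)
            alpha = config.alpha_coding
        elif g in derived_parent:
            parent_scale = scale_of[derived_parent[g]]
            scale = parent_scale * float(np.exp(rng.normal(0, 0.3)))
            alpha = config.alpha_derived_lnc
            if bt == "unprocessed_pseudogene" and rng.random() < 0.5:
                scale *= 0.02  # unexpressed pseudogene
        else:
            scale = rng.gamma(2.0, 1.0)
            alpha = config.alpha_background_lnc
        tgt_rows.append(expr_value(scale, alpha))

    from .genome_io import ExpressionMatrix

    expr_ref = ExpressionMatrix(ref_gene_ids, list(tissues), np.array(ref_rows))
    expr_target = ExpressionMatrix(tgt_gene_ids, list(tissues), np.array(tgt_rows))

    # ----- sequences ------------------------------------------------------------------
    sequences: dict[str, str] = {}
    lo, hi = config.seq_length_range
    for i in sorted(glcp_idx):
        g = gene_layout[i]
        sequences[g["ref_gene"]] = _random_dna(rng, int(rng.integers(lo, hi + 1)))
    for pair in truth:
        sequences[pair.derived_gene] = mutate_sequence(
            sequences[pair.glcp_gene], config.divergence, config.indel_rate, rng
        )
    for g in tgt_gene_ids:
        if g not in sequences and biotype_of[g] != "protein_coding":
            sequences[g] = _random_dna(rng, int(rng.integers(lo, hi + 1)))

    # ----- assemble -------------------------------------------------------------------
    anno_ref = GenomeAnnotation(
        species=ref,
        chrom_lengths=dict(chrom_lengths),
        transcripts=ref_transcripts,
        unbridged_gaps=ref_gaps,
    )
    anno_target = GenomeAnnotation(
        species=tgt,
        chrom_lengths=dict(chrom_lengths),
        transcripts=tgt_transcripts,
        unbridged_gaps=tgt_gaps,
    )
    homology = HomologyMap(species_of=species_of, family_of=dict(family_of), roster=roster)
    for a, b in hm_pairs:
        homology.add_orthologs(a, b)

    return SyntheticScenario(
        config=config,
        anno_ref=anno_ref,
        anno_target=anno_target,
        homology=homology,
        chains=chains,
        sequences=sequences,
        expr_ref=expr_ref,
        expr_target=expr_target,
        repeats=repeats,
        breakpoints=sorted(breakpoints),
        truth=sorted(truth, key=lambda t: t.glcp_gene),
        glcps=sorted(glcp_ref_ids),
        events=events,
    )


def standard_recovery_config(seed: int = 42) -> ScenarioConfig:
    """Scenario for the ortholog-recovery sensitivity benchmark.

    20 chromosomes x 100 orthologous coding genes with mild rearrangement
    noise: 5% of genes relocated to random positions in the mammal and five
    chromosome-scale inversions, chains synthesized from the collinearity map.
    """
    return ScenarioConfig(
        seed=seed,
        n_chromosomes=20,
        genes_per_chromosome=100,
        relocation_fraction=0.05,
        n_inversions=5,
        glcp_fraction=0.02,
        n_background_lncrnas=100,
    )


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

SCENARIO_FILES = (
    "ref.bed", "target.bed", "ref.chroms.tsv", "target.chroms.tsv",
    "ref.gaps.bed", "target.gaps.bed", "orthologs.tsv", "families.tsv",
    "alignments.chain", "sequences.fasta", "expr_ref.tsv", "expr_target.tsv",
    "repeats.bed", "breakpoints.bed", "truth.tsv",
)


def write_scenario(scenario: SyntheticScenario, out_dir, force: bool = False) -> dict[str, str]:
    """Write every scenario component in standard text formats; returns a manifest.

    The manifest maps filename to sha256 and is also written as manifest.tsv.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from . import genome_io as gio

    os.makedirs(out_dir, exist_ok=True)
    existing = [f for f in os.listdir(out_dir) if not f.startswith(".")]
    if existing and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True)")

    p = lambda name: os.path.join(out_dir, name)
    gio.write_annotation_bed12(scenario.anno_ref, p("ref.bed"))
    gio.write_annotation_bed12(scenario.anno_target, p("target.bed"))
    for anno, name in ((scenario.anno_ref, "ref"), (scenario.anno_target, "target")):
        with open(p(f"{name}.chroms.tsv"), "w") as fh:
            fh.write(f"#species={anno.species}\n")
            fh.write("chrom\tlength\n")
            for c in sorted(anno.chrom_lengths):
                fh.write(f"{c}\t{anno.chrom_lengths[c]}\n")
        gio.write_bed(
            sorted(
                (c, s, e) for c, ivs in anno.unbridged_gaps.items() for s, e in ivs
            ),
            p(f"{name}.gaps.bed"),
        )
    gio.write_homology(scenario.homology, p("orthologs.tsv"), p("families.tsv"))
    gio.write_chains(scenario.chains, p("alignments.chain"))
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(scenario.sequences.items())
    ]
    SeqIO.write(records, p("sequences.fasta"), "fasta")
    gio.write_expression(scenario.expr_ref, p("expr_ref.tsv"))
    gio.write_expression(scenario.expr_target, p("expr_target.tsv"))
    gio.write_bed(
        sorted((c, s, e) for c, ivs in scenario.repeats.items() for s, e in ivs),
        p("repeats.bed"),
    )
    gio.write_bed(sorted(scenario.breakpoints), p("breakpoints.bed"))
    with open(p("truth.tsv"), "w") as fh:
        fh.write("glcp_gene\tderived_gene\tkind\n")
        for t in scenario.truth:
            fh.write(f"{t.glcp_gene}\t{t.derived_gene}\t{t.kind}\n")

    manifest: dict[str, str] = {}
    for name in SCENARIO_FILES:
        with open(p(name), "rb") as fh:
            manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    with open(p("manifest.tsv"), "w") as fh:
        fh.write("file\tsha256\n")
        for name in SCENARIO_FILES:
            fh.write(f"{name}\t{manifest[name]}\n")
    return manifest


def verify_manifest(out_dir) -> bool:
    """Re-hash every file listed in manifest.tsv; True iff all checksums match."""
    path = os.path.join(out_dir, "manifest.tsv")
    with open(path) as fh:
        next(fh)
        entries = [line.strip().split("\t") for line in fh if line.strip()]
    for name, digest in entries:
        with open(os.path.join(out_dir, name), "rb") as f:
            if hashlib.sha256(f.read()).hexdigest() != digest:
                return False
    return True


def read_scenario_annotations(out_dir) -> tuple[GenomeAnnotation, GenomeAnnotation]:
    """Read back the two annotations written by :func:`write_scenario`."""
    from . import genome_io as gio

    out = []
    for name in ("ref", "target"):
        chroms_path = os.path.join(out_dir, f"{name}.chroms.tsv")
        meta = gio.read_assembly_metadata(
            chroms_path, os.path.join(out_dir, f"{name}.gaps.bed")
        )
        species = name
        with open(chroms_path) as fh:
            first = fh.readline().strip()
            if first.startswith("#species="):
                species = first.split("=", 1)[1]
        meta["species"] = species
        out.append(gio.read_annotation(os.path.join(out_dir, f"{name}.bed"), "BED12", meta))
    return out[0], out[1]
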