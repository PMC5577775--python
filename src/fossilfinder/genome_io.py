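"""Readers, writers and validated in-memory models for the pipeline's file formats.

All coordinates are 0-based half-open internally.  BED is read natively;
GTF-lite (1-based closed) is converted on read.  UCSC chain files are parsed
bit-exactly per the UCSC definition, with minus-strand query coordinates
normalized to the forward strand at parse time (the strand flag is retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

Interval = tuple[int, int]

BIOTYPES = ("protein_coding", "lncRNA", "unprocessed_pseudogene")


class ParseError(ValueError):
    """Raised when a file does not conform to its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a model invariant."""


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals into a sorted disjoint list."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: an ordered set of exons on a chromosome."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"{self.transcript_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise ValidationError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site: first base of the transcript on its strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Gene:
    """Gene-level span derived from the union of its isoforms."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


@dataclass
class GenomeAnnotation:
    """Per-species transcript catalog plus assembly metadata."""

    species: str
    chrom_lengths: dict[str, int]
    transcripts: list[TranscriptModel]
    unbridged_gaps: dict[str, list[Interval]] = field(default_factory=dict)
    genome_size: int = 0

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            self.genome_size = sum(self.chrom_lengths.values())
        self._build_genes()
        self._validate()

    def _build_genes(self) -> None:
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        self.genes: dict[str, Gene] = {}
        for gid, ts in by_gene.items():
            chroms = {t.chrom for t in ts}
            strands = {t.strand for t in ts}
            if len(chroms) > 1:
                raise ValidationError(f"gene {gid}: isoforms on multiple chromosomes")
            if len(strands) > 1:
                raise ValidationError(f"gene {gid}: mixed-strand isoforms")
            biotypes = {t.biotype for t in ts}
            if len(biotypes) > 1:
                raise ValidationError(f"gene {gid}: mixed biotypes {biotypes}")
            self.genes[gid] = Gene(
                gene_id=gid,
                chrom=ts[0].chrom,
                strand=ts[0].strand,
                start=min(t.start for t in ts),
                end=max(t.end for t in ts),
                biotype=ts[0].biotype,
                transcripts=sorted(ts, key=lambda t: (t.start, t.transcript_id)),
            )

    def _validate(self) -> None:
        for t in self.transcripts:
            if t.chrom not in self.chrom_lengths:
                raise ValidationError(f"{t.transcript_id}: chrom {t.chrom} not in assembly metadata")
            if t.end > self.chrom_lengths[t.chrom]:
                raise ValidationError(
                    f"{t.transcript_id}: end {t.end} beyond {t.chrom} length "
                    f"{self.chrom_lengths[t.chrom]}"
                )

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes.values() if g.chrom == chrom),
            key=lambda g: (g.start, g.gene_id),
        )

    def coding_genes(self) -> list[Gene]:
        return [g for g in self.genes.values() if g.biotype == "protein_coding"]


@dataclass
class AlignmentChain:
    """One UCSC alignment chain between a target (t) and a query (q) genome.

    ``blocks`` holds (t_start, t_end, q_start, q_end) tuples in alignment
    order (ascending in t); all coordinates are forward-strand 0-based
    half-open.  For a minus-strand query the q coordinates descend in
    alignment order.
    """

    chain_id: str
    score: float
    t_chrom: str
    t_size: int
    t_strand: str
    q_chrom: str
    q_size: int
    q_strand: str
    blocks: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError(f"chain {self.chain_id}: no blocks")
        for ts, te, qs, qe in self.blocks:
            if te - ts != qe - qs or te <= ts:
                raise ValidationError(f"chain {self.chain_id}: inconsistent block sizes")

    @property
    def t_blocks(self) -> list[Interval]:
        return sorted((ts, te) for ts, te, _, _ in self.blocks)

    @property
    def q_blocks(self) -> list[Interval]:
        return sorted((qs, qe) for _, _, qs, qe in self.blocks)

    @property
    def t_span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def q_span(self) -> Interval:
        qb = self.q_blocks
        return (qb[0][0], qb[-1][1])

    def side(self, which: str) -> tuple[str, str, Interval, list[Interval]]:
        """(chrom, strand, footprint span, blocks) for side 'q' or 't'."""
        if which == "t":
            return self.t_chrom, self.t_strand, self.t_span, self.t_blocks
        if which == "q":
            return self.q_chrom, self.q_strand, self.q_span, self.q_blocks
        raise ValueError(f"side must be 'q' or 't', got {which!r}")


@dataclass
class ExpressionMatrix:
    """Non-negative RPKM values, genes x tissues."""

    genes: list[str]
    tissues: list[str]
    values: "object"  # numpy array, shape (n_genes, n_tissues)

    def __post_init__(self) -> None:
        import numpy as np

        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.tissues)):
            raise ValidationError("expression matrix shape does not match labels")
        if (self.values < 0).any():
            raise ValidationError("negative expression value")
        if not self.tissues:
            raise ValidationError("expression matrix needs at least one tissue")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene_id: str):
        return self.values[self._index[gene_id]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index


# ---------------------------------------------------------------------------
# BED12 / GTF-lite annotation I/O
# ---------------------------------------------------------------------------

def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ParseError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    try:
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ParseError(f"line {lineno}: blockCount disagrees with block lists")
    parts = name.split("|")
    transcript_id = parts[0]
    gene_id = parts[1] if len(parts) > 1 else transcript_id
    biotype = parts[2] if len(parts) > 2 else "protein_coding"
    exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
    if exons[-1][1] != end:
        raise ParseError(f"line {lineno}: blocks do not end at chromEnd")
    return TranscriptModel(transcript_id, gene_id, chrom, strand, exons, biotype)


def _parse_gtf_lite(lines: Iterable[str]) -> list[TranscriptModel]:
    exons: dict[str, dict] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 9:
            raise ParseError(f"line {lineno}: GTF needs 9 fields, got {len(f)}")
        if f[2] != "exon":
            continue
        try:
            start, end = int(f[3]) - 1, int(f[4])  # 1-based closed -> half-open
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        attrs = {}
        for item in f[8].rstrip(";").split(";"):
            item = item.strip()
            if not item:
                continue
            key, _, val = item.partition(" ")
            attrs[key] = val.strip().strip('"')
        try:
            tid = attrs["transcript_id"]
        except KeyError:
            raise ParseError(f"line {lineno}: missing transcript_id attribute")
        rec = exons.setdefault(
            tid,
            {
                "gene_id": attrs.get("gene_id", tid),
                "chrom": f[0],
                "strand": f[6],
                "biotype": attrs.get("gene_biotype", "protein_coding"),
                "exons": [],
            },
        )
        rec["exons"].append((start, end))
    out = []
    for tid, rec in exons.items():
        out.append(
            TranscriptModel(
                tid,
                rec["gene_id"],
                rec["chrom"],
                rec["strand"],
                tuple(sorted(rec["exons"])),
                rec["biotype"],
            )
        )
    return out


def read_annotation(path, fmt: str, metadata: dict) -> GenomeAnnotation:
    """Read a transcript catalog in BED12 or GTF-lite format.

    ``metadata`` supplies ``species``, ``chrom_lengths`` and optionally
    ``unbridged_gaps`` (dict chrom -> interval list).
    """
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith(("#", "track"))]
    if fmt == "BED12":
        transcripts = [_parse_bed12_line(ln, i) for i, ln in enumerate(lines, start=1)]
    elif fmt == "GTF-lite":
        transcripts = _parse_gtf_lite(lines)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return GenomeAnnotation(
        species=metadata["species"],
        chrom_lengths=dict(metadata["chrom_lengths"]),
        transcripts=transcripts,
        unbridged_gaps={k: list(v) for k, v in metadata.get("unbridged_gaps", {}).items()},
        genome_size=metadata.get("genome_size", 0),
    )


def write_annotation_bed12(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        for t in sorted(annotation.transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.start) for s, _ in t.exons)
            name = f"{t.transcript_id}|{t.gene_id}|{t.biotype}"
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        name,
                        "0",
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain I/O
# ---------------------------------------------------------------------------

def reverse_interval(iv: Interval, size: int) -> Interval:
    """Map an interval between forward and reverse strand coordinates (involution)."""
    return (size - iv[1], size - iv[0])


def read_chains(path) -> list[AlignmentChain]:
    """Parse a UCSC chain file, normalizing minus-strand coordinates to forward."""
    chains: list[AlignmentChain] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("chain"):
            raise ParseError(f"line {i + 1}: expected chain header, got {line[:40]!r}")
        f = line.split()
        if len(f) != 13:
            raise ParseError(f"line {i + 1}: chain header needs 13 fields, got {len(f)}")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = f
        t_size, t_start, t_end = int(t_size), int(t_start), int(t_end)
        q_size, q_start, q_end = int(q_size), int(q_start), int(q_end)
        if t_strand != "+":
            raise ParseError(f"line {i + 1}: target strand must be '+' in UCSC chains")
        i += 1
        triples: list[tuple[int, int, int]] = []
        closed = False
        while i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                break
            parts = row.split()
            if len(parts) == 3:
                triples.append((int(parts[0]), int(parts[1]), int(parts[2])))
            elif len(parts) == 1:
                triples.append((int(parts[0]), 0, 0))
                closed = True
                break
            else:
                raise ParseError(f"line {i}: malformed chain data row {row!r}")
        if not closed:
            raise ParseError(f"chain {chain_id}: truncated block list (no terminal size row)")
        t_cursor, q_cursor = t_start, q_start
        blocks = []
        for size, dt, dq in triples:
            t_b = (t_cursor, t_cursor + size)
            q_b_strand = (q_cursor, q_cursor + size)
            if q_strand == "-":
                q_b = reverse_interval(q_b_strand, q_size)
            else:
                q_b = q_b_strand
            blocks.append((t_b[0], t_b[1], q_b[0], q_b[1]))
            t_cursor += size + dt
            q_cursor += size + dq
        if t_cursor - triples[-1][1] != t_end or q_cursor - triples[-1][2] != q_end:
            raise ParseError(
                f"chain {chain_id}: cumulative block sizes disagree with header span"
            )
        chains.append(
            AlignmentChain(
                chain_id=chain_id,
                score=float(score),
                t_chrom=t_name,
                t_size=t_size,
                t_strand=t_strand,
                q_chrom=q_name,
                q_size=q_size,
                q_strand=q_strand,
                blocks=tuple(blocks),
            )
        )
    return chains


def write_chains(chains: Sequence[AlignmentChain], path) -> None:
    """Write chains in UCSC chain format (inverse of :func:`read_chains`)."""
    with open(path, "w") as fh:
        for c in chains:
            t_start, t_end = c.blocks[0][0], c.blocks[-1][1]
            if c.q_strand == "-":
                # header q coordinates are on the reversed strand
                q_first = reverse_interval((c.blocks[0][2], c.blocks[0][3]), c.q_size)
                q_last = reverse_interval((c.blocks[-1][2], c.blocks[-1][3]), c.q_size)
                q_start, q_end = q_first[0], q_last[1]
            else:
                q_start, q_end = c.blocks[0][2], c.blocks[-1][3]
            fh.write(
                f"chain {c.score:g} {c.t_chrom} {c.t_size} {c.t_strand} {t_start} {t_end} "
                f"{c.q_chrom} {c.q_size} {c.q_strand} {q_start} {q_end} {c.chain_id}\n"
            )
            for k, (ts, te, qs, qe) in enumerate(c.blocks):
                size = te - ts
                if k == len(c.blocks) - 1:
                    fh.write(f"{size}\n\n")
                else:
                    nts = c.blocks[k + 1][0]
                    dt = nts - te
                    if c.q_strand == "-":
                        dq = qs - c.blocks[k + 1][3]
                    else:
                        dq = c.blocks[k + 1][2] - qe
                    fh.write(f"{size} {dt} {dq}\n")


# ---------------------------------------------------------------------------
# homology / expression / metadata TSVs
# ---------------------------------------------------------------------------

def read_homology(orthologs_path, families_path, roster=None):
    """Read ortholog-pair and family TSVs into a HomologyMap.

    orthologs TSV columns: gene_a, species_a, gene_b, species_b, homology_type.
    families TSV columns: gene_id, species, family_id.
    Genes in the ortholog table missing from the family table get singleton
    families (with a warning).
    """
    import pandas as pd

    from .glcp_caller import HomologyMap

    fam = pd.read_csv(families_path, sep="\t", dtype=str)
    for col in ("gene_id", "species", "family_id"):
        if col not in fam.columns:
            raise ParseError(f"families table missing column {col!r}")
    dup = fam.groupby("gene_id")["family_id"].nunique()
    bad = dup[dup > 1]
    if len(bad):
        raise ValidationError(f"contradictory family rows for genes: {list(bad.index)[:5]}")
    fam = fam.drop_duplicates()

    ort = pd.read_csv(orthologs_path, sep="\t", dtype=str)
    for col in ("gene_a", "species_a", "gene_b", "species_b"):
        if col not in ort.columns:
            raise ParseError(f"orthologs table missing column {col!r}")

    species_of = dict(zip(fam["gene_id"], fam["species"]))
    family_of = dict(zip(fam["gene_id"], fam["family_id"]))
    missing = []
    for _, row in ort.iterrows():
        for g, sp in ((row["gene_a"], row["species_a"]), (row["gene_b"], row["species_b"])):
            if g not in species_of:
                species_of[g] = sp
                family_of[g] = f"singleton:{g}"
                missing.append(g)
    if missing:
        warnings.warn(
            f"{len(missing)} genes in ortholog table absent from family table; "
            "assigned singleton families"
        )
    hm = HomologyMap(species_of=species_of, family_of=family_of, roster=roster)
    for _, row in ort.iterrows():
        hm.add_orthologs(row["gene_a"], row["gene_b"])
    return hm


def write_homology(homology, orthologs_path, families_path) -> None:
    with open(families_path, "w") as fh:
        fh.write("gene_id\tspecies\tfamily_id\n")
        for g in sorted(homology.species_of):
            fh.write(f"{g}\t{homology.species_of[g]}\t{homology.family_of[g]}\n")
    with open(orthologs_path, "w") as fh:
        fh.write("gene_a\tspecies_a\tgene_b\tspecies_b\thomology_type\n")
        seen = set()
        for a in sorted(homology.orthologs):
            for b in sorted(homology.orthologs[a]):
                key = tuple(sorted((a, b)))
                if key in seen:
                    continue
                seen.add(key)
                fh.write(
                    f"{key[0]}\t{homology.species_of[key[0]]}\t{key[1]}\t"
                    f"{homology.species_of[key[1]]}\tortholog_one2one\n"
                )


def read_expression(path) -> ExpressionMatrix:
    """Read a gene_id + one-column-per-tissue TSV of RPKM values."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ParseError("expression table must start with a gene_id column")
    tissues = list(df.columns[1:])
    values = df[tissues].to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("negative expression value")
    return ExpressionMatrix(genes=list(df["gene_id"].astype(str)), tissues=tissues, values=values)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.tissues) + "\n")
        for g, row in zip(matrix.genes, matrix.values):
            fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_assembly_metadata(chroms_path, gaps_path=None) -> dict:
    """Read chromosome-length TSV (chrom, length) and optional gaps BED."""
    chrom_lengths: dict[str, int] = {}
    with open(chroms_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("chrom\t", "#")):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ParseError(f"line {lineno}: assembly metadata needs chrom and length")
            chrom_lengths[f[0]] = int(f[1])
    gaps: dict[str, list[Interval]] = {}
    if gaps_path is not None:
        for chrom, s, e, *_ in read_bed(gaps_path):
            gaps.setdefault(chrom, []).append((s, e))
    return {"chrom_lengths": chrom_lengths, "unbridged_gaps": gaps}


def read_bed(path) -> list[tuple]:
    """Read a BED3+ file into (chrom, start, end, *rest) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"line {lineno}: BED needs >=3 fields")
            out.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return out


def write_bed(records: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


# ---------------------------------------------------------------------------
# catalog filters
# ---------------------------------------------------------------------------

@dataclass
class FilterRules:
    """Catalog-cleaning rules applied before the synteny analysis.

    min_single_exon_length drops single-exon transcripts shorter than the
    threshold (applied to pseudogene catalogs).  max_tandem_repeat_fraction
    drops transcripts whose exonic bases are covered by simple/tandem repeats
    beyond the threshold (applied to lncRNA catalogs).  exclude_antisense
    drops transcripts with exonic overlap on the opposite strand of any
    protein-coding gene.
    """

    min_single_exon_length: int | None = 500
    max_tandem_repeat_fraction: float | None = 0.5
    exclude_antisense: bool = True
    apply_to_biotypes: tuple[str, ...] = ("lncRNA", "unprocessed_pseudogene")


@dataclass
class FilterReport:
    removed_short_single_exon: int = 0
    removed_repeat_fraction: int = 0
    removed_antisense: int = 0
    kept: int = 0


def filter_catalog(
    annotation: GenomeAnnotation,
    rules: FilterRules,
    repeat_intervals: dict[str, list[Interval]] | None = None,
) -> tuple[GenomeAnnotation, FilterReport]:
    """Apply catalog filters; returns the filtered annotation and a report.

    Idempotent: filtering a filtered catalog removes nothing further.
    """
    if rules.max_tandem_repeat_fraction is not None and repeat_intervals is None:
        raise ValueError("repeat-fraction rule active but no repeat intervals supplied")

    merged_repeats = {
        chrom: merge_intervals(ivs) for chrom, ivs in (repeat_intervals or {}).items()
    }
    coding_exons: dict[tuple[str, str], list[Interval]] = {}
    if rules.exclude_antisense:
        for t in annotation.transcripts:
            if t.biotype == "protein_coding":
                key = (t.chrom, t.strand)
                coding_exons.setdefault(key, []).extend(t.exons)
        coding_exons = {k: merge_intervals(v) for k, v in coding_exons.items()}

    report = FilterReport()
    kept: list[TranscriptModel] = []
    for t in annotation.transcripts:
        if t.biotype not in rules.apply_to_biotypes:
            kept.append(t)
            continue
        if (
            rules.min_single_exon_length is not None
            and len(t.exons) == 1
            and t.exonic_length < rules.min_single_exon_length
        ):
            report.removed_short_single_exon += 1
            continue
        if rules.max_tandem_repeat_fraction is not None:
            reps = merged_repeats.get(t.chrom, [])
            covered = sum(
                overlap_length(exon, r) for exon in t.exons for r in reps
            )
            if covered / t.exonic_length > rules.max_tandem_repeat_fraction:
                report.removed_repeat_fraction += 1
                continue
        if rules.exclude_antisense:
            other = "-" if t.strand == "+" else "+"
            opp = coding_exons.get((t.chrom, other), [])
            if any(overlap_length(exon, r) > 0 for exon in t.exons for r in opp):
                report.removed_antisense += 1
                continue
        kept.append(t)
    report.kept = len(kept)
    filtered = GenomeAnnotation(
        species=annotation.species,
        chrom_lengths=dict(annotation.chrom_lengths),
        transcripts=kept,
        unbridged_gaps={k: list(v) for k, v in annotation.unbridged_gaps.items()},
        genome_size=annotation.genome_size,
    )
    return filtered, report
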