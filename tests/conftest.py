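import pytest

from fossilfinder.genome_io import GenomeAnnotation, TranscriptModel
from fossilfinder.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default-sized scenario with mild rearrangement noise."""
    return generate_scenario(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def clean_scenario():
    """Zero-rearrangement scenario (the noiseless limit)."""
    return generate_scenario(
        ScenarioConfig(seed=3, n_inversions=0, relocation_fraction=0.0)
    )


def make_transcript(tid, gene, chrom, strand, exons, biotype="protein_coding"):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons), biotype)


def make_annotation(transcripts, chrom_lengths=None, species="testspecies", gaps=None):
    if chrom_lengths is None:
        chrom_lengths = {}
        for t in transcripts:
            chrom_lengths[t.chrom] = max(chrom_lengths.get(t.chrom, 0), t.end + 10_000)
    return GenomeAnnotation(
        species=species,
        chrom_lengths=chrom_lengths,
        transcripts=list(transcripts),
        unbridged_gaps=gaps or {},
    )
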