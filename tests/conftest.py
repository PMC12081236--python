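import numpy as np
import pytest

from heurosplice.synthetic import (
    GeneratorConfig,
    designed_fixture,
    generate_genome,
)
from heurosplice.transcript_model import (
    RelativePosition,
    TranscriptModel,
    VariantRecord,
)


@pytest.fixture(scope="session")
def fixture_data():
    """(genome dict, transcript, info) for the designed six-exon fixture."""
    return designed_fixture()


@pytest.fixture(scope="session")
def genome(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def transcript(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def sampled_data():
    """A batch of checklist-compliant sampled transcripts."""
    return generate_genome(GeneratorConfig(seed=11, n_transcripts=10,
                                           exon_count=(4, 6)))


def make_variant(transcript: TranscriptModel, genome, intron_index: int,
                 relstr: str, alt_sense: str) -> VariantRecord:
    """SNV at a relative position of one intron, alt given on sense strand."""
    from dataclasses import replace

    from heurosplice.transcript_model import fetch_sequence

    rel = RelativePosition.parse(relstr)
    if rel.kind in ("+", "-"):
        g0 = transcript.rel_to_genomic(rel, intron_index=intron_index)
    elif rel.kind == "E-":
        g0 = transcript.rel_to_genomic(replace(rel, exon_index=intron_index))
    else:
        g0 = transcript.rel_to_genomic(
            replace(rel, exon_index=intron_index + 1))
    ref = fetch_sequence(genome, transcript.chrom, g0, g0 + 1)
    if transcript.strand == "-":
        alt = alt_sense.translate(str.maketrans("ACGT", "TGCA"))
    else:
        alt = alt_sense
    return VariantRecord(chrom=transcript.chrom, pos=g0 + 1, ref=ref, alt=alt)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
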