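import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from isoqc.annotation import Annotation, GenomicInterval, TranscriptModel
from isoqc.coding import train_coding_model
from isoqc.simulate import (
    SimConfig,
    inject_novel_features,
    make_reference,
    make_training_sequences,
)


def tx(tid, exons, strand="+", chrom="chr1", gene="G1", cds=None, source="reference"):
    """Terse transcript builder for tests."""
    return TranscriptModel(
        tid,
        gene,
        chrom,
        strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds=GenomicInterval(chrom, *cds, strand) if cds else None,
        source=source,
    )


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_reference(sim_cfg):
    return make_reference(sim_cfg)


@pytest.fixture(scope="session")
def sim_novel(sim_cfg, sim_reference):
    _, reference, _ = sim_reference
    return inject_novel_features(reference, sim_cfg)


@pytest.fixture(scope="session")
def coding_model():
    coding_seqs, noncoding_seqs = make_training_sequences(5)
    return train_coding_model(coding_seqs, noncoding_seqs)


@pytest.fixture()
def three_exon_reference():
    t = tx("R1", [(100, 200), (300, 400), (500, 600)])
    return Annotation({"R1": t})
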