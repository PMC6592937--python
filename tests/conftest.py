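import dataclasses

import pytest

import meripscan as ms
from meripscan.pipeline import PRESETS


@pytest.fixture
def plus_model():
    """Single-exon coding transcript on +: genomic [1000, 2000), 1000 nt."""
    return ms.TranscriptModel(
        gene_id="gplus", transcript_id="tplus", chrom="chr1", strand="+",
        exons=((1000, 2000),), cds_start=100, cds_end=700,
    )


@pytest.fixture
def minus_model():
    """Single-exon coding transcript on -: genomic [1000, 2000), 1000 nt."""
    return ms.TranscriptModel(
        gene_id="gminus", transcript_id="tminus", chrom="chr1", strand="-",
        exons=((1000, 2000),), cds_start=100, cds_end=700,
    )


@pytest.fixture
def two_exon_plus():
    """2-exon + transcript: exons of 100 nt and 200 nt, intron [1100, 1500)."""
    return ms.TranscriptModel(
        gene_id="g2", transcript_id="t2", chrom="chr1", strand="+",
        exons=((1000, 1100), (1500, 1700)), cds_start=50, cds_end=250,
    )


@pytest.fixture
def two_exon_minus():
    return ms.TranscriptModel(
        gene_id="g2m", transcript_id="t2m", chrom="chr1", strand="-",
        exons=((1000, 1100), (1500, 1700)), cds_start=50, cds_end=250,
    )


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The standard recovery benchmark: 300 genes, one 8-fold site each,
    30x coverage, half the sites responding 4-fold to knockdown, seed 1."""
    params = dataclasses.replace(PRESETS["benchmark"], seed=1)
    return ms.simulate_dataset(params)


@pytest.fixture(scope="session")
def benchmark_peaks(benchmark_dataset):
    """Peak-calling results for both benchmark conditions."""
    ds = benchmark_dataset
    return {
        cond: ms.call_peaks(ds.models, *ds.reads[cond])
        for cond in ds.params.conditions
    }
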