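import numpy as np
import pandas as pd
import pytest

from admixcnv import (
    FilterPolicy,
    GenomeTable,
    ManifestEntry,
    SampleManifest,
    SegmentRecord,
    SimConfig,
    filter_segments,
    simulate_dataset,
)
from admixcnv.synthetic_data import NoiseRates


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeTable:
    return GenomeTable(
        {"chr1": 3_000_000, "chr2": 2_000_000, "chrX": 1_000_000},
        autosomes={"chr1", "chr2"},
    )


@pytest.fixture(scope="session")
def tiny_manifest() -> SampleManifest:
    return SampleManifest(
        [
            ManifestEntry("S1", "POP_A", "ancestral_indian"),
            ManifestEntry("S2", "POP_A", "ancestral_indian"),
            ManifestEntry("S3", "POP_B", "ancestral_african"),
            ManifestEntry("S4", "POP_B", "ancestral_african"),
            ManifestEntry("S5", "OG", "admixed"),
        ]
    )


def make_segment(**kwargs) -> SegmentRecord:
    base = dict(
        sample_id="S1",
        chrom="chr1",
        start=10_000,
        end=60_000,
        cn_state=1,
        n_probes=10,
        max_gap=3_000,
        lod=25.0,
        confidence=0.01,
    )
    base.update(kwargs)
    return SegmentRecord(**base)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """200-locus, 60-sample cohort with no decoys (exact CNVR recovery)."""
    cfg = SimConfig(
        n_loci=200,
        populations=(
            ("IND", "ancestral_indian", 20),
            ("AFR", "ancestral_african", 20),
            ("OG", "admixed", 20),
        ),
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Cohort with labeled decoy segments violating one filter rule each."""
    cfg = SimConfig(
        n_loci=120,
        populations=(
            ("IND", "ancestral_indian", 15),
            ("AFR", "ancestral_african", 15),
            ("OG", "admixed", 15),
        ),
        noise_rates=NoiseRates(
            non_autosomal=0.02, low_probe=0.02, gapped=0.02,
            low_lod=0.02, oversized=0.01,
        ),
        seed=23,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def kept_segments(noisefree_dataset):
    rep = filter_segments(
        noisefree_dataset.segments, FilterPolicy(), noisefree_dataset.genome
    )
    assert not rep.rejected
    return rep.kept
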