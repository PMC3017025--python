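"""Shared fixtures: simulated toy worlds and small hand-written inputs."""

import pytest

from stace.genome import AnnotationIndex, build_virtual_transcriptome
from stace.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim_clean():
    """Noise-free toy world: 8 annotated genes (one pseudogene, one ncRNA),
    3 planted novel genes, no tag sequencing errors."""
    return simulate(SimulationConfig(seed=1, tag_error_rate=0.0))


@pytest.fixture(scope="session")
def sim_noisy():
    """Toy world with substitution errors injected into the tag library."""
    return simulate(SimulationConfig(seed=2, tag_error_rate=0.1))


@pytest.fixture(scope="session")
def clean_index(sim_clean):
    return AnnotationIndex.build(sim_clean.annotated_models, sim_clean.genome.chrom_names)


@pytest.fixture(scope="session")
def clean_vt(sim_clean):
    return build_virtual_transcriptome(sim_clean.genome, sim_clean.annotated_models)


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">chr1\nACGTACGTACGTACGTACGT\n>chr2\nGGGGCCCCAAAATTTT\n")
    return path


@pytest.fixture
def two_exon_gff(tmp_path):
    """One plus-strand gene, exons [1,100] and [201,300] (1-based)."""
    gff = tmp_path / "two_exon.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t1\t300\t.\t+\t.\tID=g1\n"
        "chr1\ttest\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
        "chr1\ttest\texon\t1\t100\t.\t+\t.\tID=t1.e1;Parent=t1\n"
        "chr1\ttest\texon\t201\t300\t.\t+\t.\tID=t1.e2;Parent=t1\n"
    )
    return gff


@pytest.fixture
def long_chrom_fasta(tmp_path):
    import numpy as np

    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    path = tmp_path / "long.fasta"
    path.write_text(">chr1\n" + seq + "\n")
    return path
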