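import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def small_sim_config():
    """A fast planted dataset: 30 shared (6 DE), 3 exclusive, 5 novel loci."""
    from excluseq import SimulationConfig

    return SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=60_000,
        b_chrom_length=20_000,
        n_shared_transcripts=30,
        n_exclusive_transcripts=3,
        n_novel_loci=5,
        n_de_genes=6,
        transcript_length_range=(500, 1200),
        n_read_pairs=12_000,
        exclusive_min_expected_pairs=120,
    )


@pytest.fixture
def small_dataset(small_sim_config):
    from excluseq import simulate_genome, simulate_reads

    genome, annotation, truth = simulate_genome(small_sim_config)
    reads = {
        cond: simulate_reads(genome, truth, cond, small_sim_config)
        for cond in ("wt", "carrier")
    }
    return small_sim_config, genome, annotation, truth, reads


def transcript_seq(genome, truth, transcript_id: str) -> str:
    """Spliced transcript sequence from the simulated genome."""
    from excluseq._kmers import decode_seq, encode_seq

    codes = {r.id: encode_seq(r.seq) for r in genome}
    return decode_seq(truth.models[transcript_id].extract_codes(codes))


def matches_transcript(contig_seq: str, tseq: str) -> bool:
    """Containment up to strand — the contig/transcript matching convention."""
    from excluseq._kmers import revcomp_str

    rc = revcomp_str(contig_seq)
    return (
        contig_seq in tseq or rc in tseq or tseq in contig_seq or tseq in rc
    )
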