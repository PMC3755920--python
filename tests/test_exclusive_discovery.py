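"""The discovery funnel on planted data: subtraction, verification cascade,
reciprocal control, audit completeness."""

import numpy as np
import pytest

from excluseq import (
    DiscoveryConfig,
    FilterThresholds,
    MappingPolicy,
    ScoringScheme,
    run_discovery,
)
from excluseq.assembly import Contig, multi_k_assemble
from excluseq.exclusive_discovery import (
    DiscoveryError,
    check_reciprocal,
    subtract_assemblies,
    verify_by_mapping,
)
from excluseq.io_formats import SequenceRecord
from excluseq.synthetic_data import tile_reads

from conftest import matches_transcript, random_dna, transcript_seq


def contig(i, seq):
    return Contig(f"c{i}", seq, 30.0, 21)


class TestSubtraction:
    def test_self_subtraction_is_empty(self, rng):
        cs = [contig(i, random_dna(rng, 500)) for i in range(5)]
        assert subtract_assemblies(cs, cs) == []

    def test_empty_wt_passes_everything(self, rng):
        cs = [contig(i, random_dna(rng, 500)) for i in range(4)]
        assert subtract_assemblies(cs, []) == cs

    def test_only_novel_contigs_survive(self, rng):
        shared = [random_dna(rng, 600) for _ in range(5)]
        extra = random_dna(rng, 600)
        carrier = [contig(i, s) for i, s in enumerate(shared + [extra])]
        wt = [contig(100 + i, s) for i, s in enumerate(shared)]
        out = subtract_assemblies(carrier, wt)
        assert [c.seq for c in out] == [extra]


class TestVerifyCascade:
    def _setup(self, rng, carrier_copies, wt_copies):
        """One candidate, N reads from it per condition, plus background reads
        that map nowhere (they keep the mapped totals realistic)."""
        from excluseq._kmers import encode_seq

        cand = contig(0, random_dna(rng, 600))
        creads = tile_reads([SequenceRecord("c", cand.seq)], 100, 1).codes
        filler = np.vstack([encode_seq(random_dna(rng, 100)) for _ in range(50)])

        def sample(n):
            picks = [creads[rng.integers(len(creads))] for _ in range(n)]
            return np.vstack(picks + [filler]) if picks else filler

        return cand, [sample(carrier_copies)], [sample(wt_copies)]

    def test_any_wt_read_excludes(self, rng):
        cand, carrier, wt = self._setup(rng, carrier_copies=200, wt_copies=1)
        (call,) = verify_by_mapping([cand], carrier, wt)
        assert call.verdict == "excluded_opposite_reads"
        assert call.wt_count == 1

    def test_low_count_excluded(self, rng):
        cand, carrier, wt = self._setup(rng, carrier_copies=49, wt_copies=0)
        (call,) = verify_by_mapping([cand], carrier, wt)
        assert call.verdict == "excluded_low_count"
        assert call.carrier_count == 49

    def test_abundant_candidate_called_exclusive(self, rng):
        cand, carrier, wt = self._setup(rng, carrier_copies=200, wt_copies=0)
        (call,) = verify_by_mapping([cand], carrier, wt)
        assert call.verdict == "exclusive"
        assert call.carrier_count >= 50 and call.carrier_rpm >= 10
        assert [name for name, *_ in call.filter_trail] == [
            "subtraction", "opposite_reads", "min_reads", "min_rpm",
        ]

    def test_zero_mapped_carrier_reads_is_pipeline_error(self, rng):
        cand = contig(0, random_dna(rng, 600))
        from excluseq._kmers import encode_seq

        bg = [np.vstack([encode_seq(random_dna(rng, 100)) for _ in range(20)])]
        with pytest.raises(DiscoveryError):
            verify_by_mapping([cand], bg, bg)

    def test_threshold_monotonicity(self, rng):
        cand, carrier, wt = self._setup(rng, carrier_copies=60, wt_copies=0)
        n_excl = []
        for min_reads in (10, 50, 61, 1000):
            calls = verify_by_mapping(
                [cand], carrier, wt, thresholds=FilterThresholds(min_reads=min_reads)
            )
            n_excl.append(sum(c.verdict == "exclusive" for c in calls))
        assert n_excl == sorted(n_excl, reverse=True)


class TestEndToEnd:
    def test_planted_dataset_recovers_exclusives(self, small_dataset):
        cfg, genome, annotation, truth, reads = small_dataset
        report = run_discovery(list(reads["carrier"]), list(reads["wt"]))
        excl_truth = truth.by_label("exclusive")
        tseqs = {t.transcript_id: transcript_seq(genome, truth, t.transcript_id)
                 for t in excl_truth}
        matched = set()
        for c in report.exclusive:
            hits = [tid for tid, ts in tseqs.items() if matches_transcript(c.seq, ts)]
            assert hits, f"false positive exclusive call {c.id}"
            matched.update(hits)
        assert matched == set(tseqs)
        assert report.summary["exclusive"] == len(excl_truth)
        assert report.reciprocal == []
        # no shared/novel/DE transcript is ever called exclusive
        other = [transcript_seq(genome, truth, t.transcript_id)
                 for t in truth.transcripts if t.label != "exclusive"]
        for c in report.exclusive:
            assert not any(matches_transcript(c.seq, ts) for ts in other)

    def test_audit_covers_every_carrier_contig(self, small_dataset, tmp_path):
        cfg, genome, annotation, truth, reads = small_dataset
        report = run_discovery(
            list(reads["carrier"]), list(reads["wt"]), outdir=tmp_path
        )
        carrier_contigs = multi_k_assemble(list(reads["carrier"]), condition="carrier")
        audit_ids = [c.contig.id for c in report.calls]
        assert sorted(audit_ids) == sorted(c.id for c in carrier_contigs)
        assert len(set(audit_ids)) == len(audit_ids)
        lines = (tmp_path / "audit.tsv").read_text().splitlines()
        assert len(lines) == len(audit_ids) + 1
        assert (tmp_path / "exclusive.fa").exists()
        assert (tmp_path / "summary.json").exists()

    def test_identical_inputs_give_zero_exclusive(self, small_dataset):
        cfg, genome, annotation, truth, reads = small_dataset
        same = list(reads["carrier"])
        report = run_discovery(same, same)
        assert report.summary["candidates_after_subtraction"] == 0
        assert report.exclusive == []
        assert report.reciprocal == []

    def test_no_exclusive_dataset(self):
        from excluseq import SimulationConfig, simulate_genome, simulate_reads

        cfg = SimulationConfig(
            seed=11, n_shared_transcripts=20, n_exclusive_transcripts=0,
            n_novel_loci=3, n_de_genes=4, chrom_length=50_000, n_read_pairs=8000,
        )
        genome, _, truth = simulate_genome(cfg)
        wt = simulate_reads(genome, truth, "wt", cfg)
        carrier = simulate_reads(genome, truth, "carrier", cfg)
        report = run_discovery(list(carrier), list(wt))
        assert report.summary["exclusive"] == 0
        assert report.reciprocal == []


class TestReciprocal:
    def test_planted_wt_only_transcript_returned(self, small_dataset, rng):
        cfg, genome, annotation, truth, reads = small_dataset
        wt_only = random_dna(rng, 800)
        extra = tile_reads([SequenceRecord("wtx", wt_only)], 100, 2)
        wt_aug = list(reads["wt"]) + [extra]
        carrier = list(reads["carrier"])
        config = DiscoveryConfig()
        carrier_contigs = multi_k_assemble(carrier, config.k_values, condition="carrier")
        wt_contigs = multi_k_assemble(wt_aug, config.k_values, condition="wt")
        found = check_reciprocal(
            wt_contigs, carrier_contigs, carrier, wt_aug,
            config.scheme, config.policy, config.thresholds,
        )
        assert len(found) == 1
        assert matches_transcript(found[0].contig.seq, wt_only)
        assert found[0].verdict == "wt_exclusive"

    def test_zero_thresholds_return_any_expressed_nohit_contig(self, small_dataset, rng):
        cfg, genome, annotation, truth, reads = small_dataset
        wt_only = random_dna(rng, 600)
        extra = tile_reads([SequenceRecord("wtx", wt_only)], 100, 8)
        wt_aug = list(reads["wt"]) + [extra]
        carrier = list(reads["carrier"])
        config = DiscoveryConfig()
        carrier_contigs = multi_k_assemble(carrier, config.k_values, condition="carrier")
        wt_contigs = multi_k_assemble(wt_aug, config.k_values, condition="wt")
        zero = FilterThresholds(background_min_reads=0, background_min_rpm=0.0)
        found = check_reciprocal(
            wt_contigs, carrier_contigs, carrier, wt_aug,
            config.scheme, config.policy, zero,
        )
        assert any(matches_transcript(c.contig.seq, wt_only) for c in found)
        assert all(c.wt_count >= 1 for c in found)
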