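"""The condition-exclusive transcript discovery pipeline.

Orchestrates the full funnel: per-condition de novo assembly, cross-assembly
homology subtraction (carrier contigs with no hit in the wild-type assembly
at E <= 0.1), exact-mapping verification of both read sets against the
candidate contigs, and the exclusion cascade — any opposite-condition read
excludes a candidate, then minimum read count (50) and minimum RPM (10) are
enforced. A reciprocal check confirms that no wild-type contig is expressed
above background (more than 10 reads or more than 2 RPM) while absent from
the carrier assembly.

Every assembled carrier contig receives exactly one verdict with a complete
filter trail, so the audit table reconstructs the funnel end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .assembly import Contig, multi_k_assemble
from .homology import ScoringScheme, SubjectIndex, has_hit
from .io_formats import SequenceRecord, write_fasta
from .mapping_quant import ExactIndex, MappingPolicy, map_reads

logger = logging.getLogger(__name__)


class DiscoveryError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class FilterThresholds:
    """The exclusion-cascade constants."""

    subtraction_max_evalue: float = 0.1
    min_reads: int = 50
    min_rpm: float = 10.0
    opposite_condition_max_reads: int = 0
    background_min_reads: int = 10
    background_min_rpm: float = 2.0

    def __post_init__(self):
        vals = (
            self.subtraction_max_evalue,
            self.min_reads,
            self.min_rpm,
            self.opposite_condition_max_reads,
            self.background_min_reads,
            self.background_min_rpm,
        )
        if any(v < 0 for v in vals):
            raise ValueError("thresholds must be >= 0")


@dataclass
class CandidateCall:
    """One carrier contig with its filter trail and final verdict."""

    contig: Contig
    subtraction_pass: bool
    carrier_count: int = 0
    wt_count: int = 0
    carrier_rpm: float = 0.0
    wt_rpm: float = 0.0
    verdict: str = "excluded_subtraction"
    filter_trail: list[tuple] = field(default_factory=list)


@dataclass
class DiscoveryConfig:
    """Everything run_discovery needs besides the two read sets."""

    k_values: tuple[int, ...] = (21, 31, 41)
    min_coverage: int = 3
    min_length: int = 200
    scheme: ScoringScheme = field(default_factory=ScoringScheme.nucleotide_default)
    policy: MappingPolicy = field(default_factory=MappingPolicy)  # -v 0 -k 50 -m 50
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    k_index: int = 20


def _contig_records(contigs) -> list[SequenceRecord]:
    return [
        SequenceRecord(c.id, c.seq, description=f"cov={c.mean_coverage:.1f}")
        for c in contigs
    ]


def subtract_assemblies(
    carrier_contigs,
    wt_contigs,
    scheme: ScoringScheme | None = None,
    thresholds: FilterThresholds | None = None,
) -> list[Contig]:
    """Carrier contigs with no homology hit in the wild-type assembly.

    An empty wild-type set passes everything through; order is preserved.
    """
    scheme = scheme or ScoringScheme.nucleotide_default()
    thresholds = thresholds or FilterThresholds()
    carrier_contigs = list(carrier_contigs)
    if not wt_contigs:
        return carrier_contigs
    index = SubjectIndex(_contig_records(wt_contigs), scheme)
    return [
        c
        for c in carrier_contigs
        if not has_hit(
            SequenceRecord(c.id, c.seq), index, scheme, thresholds.subtraction_max_evalue
        )
    ]


def _rpm(count: int, total: int) -> float:
    return count / total * 1e6 if total > 0 else 0.0


def verify_by_mapping(
    candidates,
    carrier_reads,
    wt_reads,
    policy: MappingPolicy | None = None,
    thresholds: FilterThresholds | None = None,
    k_index: int = 20,
) -> list[CandidateCall]:
    """Map both read sets onto the candidate contigs and apply the cascade.

    Verdicts are assigned in fixed order (opposite-condition reads, minimum
    count, minimum RPM) so each exclusion names the first failing filter; the
    trail records every filter for every candidate. RPM denominators are each
    sample's reads mapped to the candidate index.
    """
    policy = policy or MappingPolicy()
    thresholds = thresholds or FilterThresholds()
    candidates = list(candidates)
    if not candidates:
        return []
    index = ExactIndex(_contig_records(candidates), k_index)
    res_c = map_reads(carrier_reads, index, policy)
    res_w = map_reads(wt_reads, index, policy)
    if res_c.total_mapped == 0:
        raise DiscoveryError("verification: zero carrier reads map to the candidates")
    calls = []
    for i, contig in enumerate(candidates):
        cc = int(res_c.counts[i])
        wc = int(res_w.counts[i])
        crpm = _rpm(cc, res_c.total_mapped)
        wrpm = _rpm(wc, res_w.total_mapped)
        t = thresholds
        checks = [
            ("subtraction", 0.0, t.subtraction_max_evalue, True),
            ("opposite_reads", wc, t.opposite_condition_max_reads, wc <= t.opposite_condition_max_reads),
            ("min_reads", cc, t.min_reads, cc >= t.min_reads),
            ("min_rpm", crpm, t.min_rpm, crpm >= t.min_rpm),
        ]
        if not checks[1][3]:
            verdict = "excluded_opposite_reads"
        elif not checks[2][3]:
            verdict = "excluded_low_count"
        elif not checks[3][3]:
            verdict = "excluded_low_rpm"
        else:
            verdict = "exclusive"
        calls.append(
            CandidateCall(
                contig=contig,
                subtraction_pass=True,
                carrier_count=cc,
                wt_count=wc,
                carrier_rpm=crpm,
                wt_rpm=wrpm,
                verdict=verdict,
                filter_trail=checks,
            )
        )
    return calls


def check_reciprocal(
    wt_contigs,
    carrier_contigs,
    carrier_reads,
    wt_reads,
    scheme: ScoringScheme | None = None,
    policy: MappingPolicy | None = None,
    thresholds: FilterThresholds | None = None,
    k_index: int = 20,
) -> list[CandidateCall]:
    """Wild-type contigs specific to the wild-type sample and expressed above
    background — the mirror of the forward verification with the roles
    swapped.

    Specific means no homology hit in the carrier assembly and no more than
    ``opposite_condition_max_reads`` carrier reads; above background means
    strictly more than ``background_min_reads`` wild-type reads or strictly
    more than ``background_min_rpm`` RPM. The negative control of the design:
    with conditions differing only by added carrier loci this list is
    expected to be empty.
    """
    scheme = scheme or ScoringScheme.nucleotide_default()
    policy = policy or MappingPolicy()
    thresholds = thresholds or FilterThresholds()
    candidates = subtract_assemblies(wt_contigs, carrier_contigs, scheme, thresholds)
    if not candidates:
        return []
    index = ExactIndex(_contig_records(candidates), k_index)
    res_w = map_reads(wt_reads, index, policy)
    res_c = map_reads(carrier_reads, index, policy)
    out = []
    for i, contig in enumerate(candidates):
        wc = int(res_w.counts[i])
        cc = int(res_c.counts[i])
        wrpm = _rpm(wc, res_w.total_mapped)
        specific = cc <= thresholds.opposite_condition_max_reads
        above = wc > thresholds.background_min_reads or wrpm > thresholds.background_min_rpm
        if specific and above:
            out.append(
                CandidateCall(
                    contig=contig,
                    subtraction_pass=True,
                    carrier_count=cc,
                    wt_count=wc,
                    carrier_rpm=_rpm(cc, res_c.total_mapped),
                    wt_rpm=wrpm,
                    verdict="wt_exclusive",
                    filter_trail=[
                        ("opposite_reads", cc, thresholds.opposite_condition_max_reads, specific),
                        ("background_reads", wc, thresholds.background_min_reads, wc > thresholds.background_min_reads),
                        ("background_rpm", wrpm, thresholds.background_min_rpm, wrpm > thresholds.background_min_rpm),
                    ],
                )
            )
    return out


@dataclass
class DiscoveryReport:
    calls: list[CandidateCall]
    reciprocal: list[CandidateCall]
    summary: dict

    @property
    def exclusive(self) -> list[Contig]:
        return [c.contig for c in self.calls if c.verdict == "exclusive"]


def run_discovery(
    carrier_reads,
    wt_reads,
    config: DiscoveryConfig | None = None,
    outdir=None,
) -> DiscoveryReport:
    """End-to-end discovery: assemble, subtract, verify, reciprocal-check.

    ``carrier_reads``/``wt_reads`` accept a ReadSet, an iterable of records,
    a FASTQ path, or a list of either (mates are pooled — assembly and exact
    verification are pairing-agnostic). With ``outdir`` set, writes
    exclusive.fa, audit.tsv and summary.json.
    """
    config = config or DiscoveryConfig()
    try:
        carrier_contigs = multi_k_assemble(
            carrier_reads, config.k_values, config.min_coverage, config.min_length, "carrier"
        )
        wt_contigs = multi_k_assemble(
            wt_reads, config.k_values, config.min_coverage, config.min_length, "wt"
        )
    except Exception as exc:
        raise DiscoveryError(f"assembly: {exc}") from exc
    candidates = subtract_assemblies(
        carrier_contigs, wt_contigs, config.scheme, config.thresholds
    )
    candidate_ids = {c.id for c in candidates}
    calls = verify_by_mapping(
        candidates, carrier_reads, wt_reads, config.policy, config.thresholds, config.k_index
    )
    t = config.thresholds
    for contig in carrier_contigs:
        if contig.id not in candidate_ids:
            calls.append(
                CandidateCall(
                    contig=contig,
                    subtraction_pass=False,
                    verdict="excluded_subtraction",
                    filter_trail=[("subtraction", 1.0, t.subtraction_max_evalue, False)],
                )
            )
    order = {c.id: i for i, c in enumerate(carrier_contigs)}
    calls.sort(key=lambda c: order[c.contig.id])
    reciprocal = check_reciprocal(
        wt_contigs, carrier_contigs, carrier_reads, wt_reads,
        config.scheme, config.policy, config.thresholds, config.k_index,
    )
    exclusive = [c for c in calls if c.verdict == "exclusive"]
    summary = {
        "carrier_contigs": len(carrier_contigs),
        "wt_contigs": len(wt_contigs),
        "candidates_after_subtraction": len(candidates),
        "exclusive": len(exclusive),
        "reciprocal_wt_exclusive": len(reciprocal),
    }
    report = DiscoveryReport(calls=calls, reciprocal=reciprocal, summary=summary)
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: DiscoveryReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(_contig_records(report.exclusive), outdir / "exclusive.fa")
    with open(outdir / "audit.tsv", "w") as fh:
        fh.write(
            "contig_id\tlength\tcarrier_count\twt_count\tcarrier_rpm\twt_rpm\t"
            "verdict\ttrail\n"
        )
        for c in report.calls:
            trail = ";".join(
                f"{name}:{value}/{thr}:{'pass' if ok else 'fail'}"
                for name, value, thr, ok in c.filter_trail
            )
            fh.write(
                f"{c.contig.id}\t{len(c.contig.seq)}\t{c.carrier_count}\t{c.wt_count}\t"
                f"{c.carrier_rpm:.4f}\t{c.wt_rpm:.4f}\t{c.verdict}\t{trail}\n"
            )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
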