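"""Read simulator: references, error injection, truth, concordance scoring."""

import math

import numpy as np
import pytest

from strlnr import (ConfigurationError, ErrorAudit, ErrorProfile, SimLocusSpec,
                    SimTruth, ValidationError, build_reference, make_panel,
                    revcomp, score_concordance, simulate_reads)
from strlnr.genotyper import GenotypeCall
from strlnr.simulate import _corrupt


def _spec(design="data1", motif="ATC", reps=10, flank=1000):
    return SimLocusSpec.from_design("SIM", motif, reps, design, flank)


class TestBuildReference:
    def test_layout_and_coordinates(self):
        ref, locus = build_reference(_spec(), seed=1)
        assert len(ref) == 2030
        assert (locus.start, locus.end) == (1000, 1030)
        assert ref[1000:1030] == "ATC" * 10

    def test_flanks_screened_for_motif_runs_and_boundary_extension(self):
        for seed in range(5):
            ref, locus = build_reference(_spec(), seed=seed)
            left, right = ref[:locus.start], ref[locus.end:]
            assert "ATC" * 3 not in left and "ATC" * 3 not in right
            # the tract cannot be extended into the flanks
            assert left[-1] != "C" and right[0] != "A"

    def test_seeded_determinism(self):
        assert build_reference(_spec(), seed=9)[0] == build_reference(_spec(), seed=9)[0]

    def test_small_flank_rejected(self):
        with pytest.raises(ConfigurationError):
            SimLocusSpec.from_design("X", "ATC", 10, "data1", flank_len=50)

    def test_design_offsets(self):
        assert _spec("data1").allele_b_repeats == 10
        assert _spec("data2").allele_b_repeats == 14
        assert _spec("data3").allele_b_repeats == 6
        assert _spec("data2").truth_repeats == frozenset({10, 14})


class TestSimulateReads:
    def test_zero_error_reads_are_exact_haplotype_substrings(self):
        spec = _spec("data2")
        ref, locus = build_reference(spec, seed=2)
        reads, truth, audit = simulate_reads(ref, locus, spec, ErrorProfile(),
                                             200, seed=3)
        haps = [ref[:1000] + "ATC" * r + ref[1030:] for r in (10, 14)]
        for r in reads:
            assert any(r.sequence in h or revcomp(r.sequence) in h for h in haps)
        assert audit.mismatch_bases == audit.inserted_bases == audit.deleted_bases == 0
        assert sum(truth.reads_per_allele) == 200

    def test_allele_balance_within_binomial_99_interval(self):
        spec = _spec("data2")
        ref, locus = build_reference(spec, seed=4)
        _, truth, _ = simulate_reads(ref, locus, spec, ErrorProfile(), 10000, seed=5)
        # Binomial(10000, 0.5): 99% interval is 5000 +/- 2.576*sqrt(2500)
        half = 2.576 * math.sqrt(10000 * 0.25)
        assert abs(truth.reads_per_allele[0] - 5000) <= half

    def test_error_rates_realized_within_ten_percent(self):
        profile = ErrorProfile(2.0, 1.0, 1.0)
        rng = np.random.default_rng(6)
        audit = ErrorAudit()
        template = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        for _ in range(120):  # 120 kb of simulated sequence
            _corrupt(template, profile, rng, audit)
        mm, ins, dele = audit.realized_rates()
        assert abs(mm - 2.0) <= 0.2
        assert abs(ins - 1.0) <= 0.1
        assert abs(dele - 1.0) <= 0.1

    def test_seeded_fastq_determinism(self):
        spec = _spec()
        ref, locus = build_reference(spec, seed=7)
        profile = ErrorProfile(2.0, 1.0, 1.0)
        a, _, _ = simulate_reads(ref, locus, spec, profile, 100, seed=8)
        b, _, _ = simulate_reads(ref, locus, spec, profile, 100, seed=8)
        assert "".join(r.to_fastq() for r in a) == "".join(r.to_fastq() for r in b)

    def test_nonpositive_read_count_rejected(self):
        spec = _spec()
        ref, locus = build_reference(spec, seed=1)
        with pytest.raises(ConfigurationError):
            simulate_reads(ref, locus, spec, ErrorProfile(), 0)


class TestScoreConcordance:
    @staticmethod
    def _truth(name, repeats, design="data1"):
        reps = tuple(sorted(repeats)) if len(repeats) > 1 else (repeats[0],) * 2
        return SimTruth(name, design, "ATC", 10, reps,
                        tuple(3 * r for r in reps), (100, 100))

    @staticmethod
    def _call(name, repeats):
        return GenotypeCall(name, [3 * r for r in repeats],
                            "homozygous" if len(repeats) == 1 else "heterozygous",
                            [100] * len(repeats), allele_repeats=list(repeats))

    def test_all_matching_is_100(self):
        truths = [self._truth(f"L{i}", [10]) for i in range(4)]
        calls = [self._call(f"L{i}", [10]) for i in range(4)]
        assert score_concordance(calls, truths).overall == 100.0

    def test_three_of_four_is_75(self):
        truths = [self._truth(f"L{i}", [10]) for i in range(4)]
        calls = [self._call(f"L{i}", [10]) for i in range(3)]
        calls.append(self._call("L3", [9]))  # one allele one unit short
        report = score_concordance(calls, truths)
        assert report.overall == 75.0
        assert list(report.frame["reason"]) == ["", "", "", "wrong allele"]

    def test_two_of_four_is_50(self):
        truths = [self._truth(f"L{i}", [10]) for i in range(4)]
        calls = [self._call(f"L{i}", [10]) for i in range(2)]
        calls += [self._call("L2", [9]), self._call("L3", [11])]
        assert score_concordance(calls, truths).overall == 50.0

    def test_missing_and_no_call_loci_are_discordant(self):
        truths = [self._truth("A", [10]), self._truth("B", [10, 14], "data2")]
        nc = GenotypeCall("B", [], "no-call", [], reason="x")
        report = score_concordance([nc], truths)
        assert report.overall == 0.0
        assert set(report.frame["reason"]) == {"no-call"}

    def test_unknown_locus_in_calls_is_an_error(self):
        with pytest.raises(ValidationError):
            score_concordance([self._call("ghost", [10])], [self._truth("A", [10])])

    def test_partial_allele_set_categorized(self):
        truths = [self._truth("A", [10, 14], "data2")]
        report = score_concordance([self._call("A", [10])], truths)
        assert list(report.frame["reason"]) == ["missed allele"]


class TestMakePanel:
    def test_designs_cycle_and_motif_lengths(self):
        panel = make_panel(6, ("data1", "data2", "data3"), seed=1)
        assert [s.design for s in panel] == ["data1", "data2", "data3"] * 2
        assert all(len(s.motif) in (3, 4) for s in panel)
        assert all(s.allele_b_repeats >= 1 for s in panel)
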