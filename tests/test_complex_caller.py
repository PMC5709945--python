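import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapsv import (
    DigestionParams,
    ErrorModelParams,
    HaplotypeMap,
    VariantPlan,
    digest,
    inject_variants,
    simulate_molecules,
)
from mapsv.aligner import AlignerParams, align_molecules, filter_by_confidence
from mapsv.complex_caller import (
    CnvParams,
    InversionParams,
    detect_cnvs,
    detect_medium_inversions,
    detect_split_svs,
    distances_match,
    is_reverse_palindromic,
    reverse_complement_cigar,
)
from mapsv.core import AlignmentRecord, SplitAlignment
from mapsv.simulator import random_genome


class TestCigarAlgebra:
    @pytest.mark.parametrize("cigar,expected", [
        ("MDDI", "DIIM"),
        ("M", "M"),
        ("DIDIDI", "DIDIDI"),
        ("MMDMM", "MMIMM"),
    ])
    def test_reverse_complement(self, cigar, expected):
        assert reverse_complement_cigar(cigar) == expected

    @pytest.mark.parametrize("cigar,palindromic", [
        ("DIDIDI", True),
        ("M", True),
        ("DDII", True),
        ("MDDI", False),
        ("MD", False),
    ])
    def test_reverse_palindromic_predicate(self, cigar, palindromic):
        assert is_reverse_palindromic(cigar) is palindromic

    @given(st.text(alphabet="MDI", min_size=0, max_size=20))
    @settings(max_examples=200, derandomize=True)
    def test_reverse_complement_is_involution(self, cigar):
        assert reverse_complement_cigar(reverse_complement_cigar(cigar)) == cigar
        assert is_reverse_palindromic(cigar) == (
            cigar == reverse_complement_cigar(cigar))

    def test_bad_character_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement_cigar("MXD")


class TestDistancesMatch:
    def test_lower_boundary_inclusive(self):
        assert distances_match(10_000, 8_500, 0.1, 500)

    def test_upper_boundary(self):
        assert distances_match(10_000, 11_500, 0.1, 500)
        assert not distances_match(10_000, 11_501, 0.1, 500)

    def test_exact_match_zero_tolerance(self):
        assert distances_match(5_000, 5_000, 0.0, 0.0)

    @given(d=st.floats(100, 1e6), dp=st.floats(100, 1e6),
           e_t=st.floats(0, 0.5), e_m=st.floats(0, 5000), extra=st.floats(0, 0.3))
    @settings(max_examples=200, derandomize=True)
    def test_widening_tolerance_never_flips_true_to_false(self, d, dp, e_t, e_m, extra):
        if distances_match(d, dp, e_t, e_m):
            assert distances_match(d, dp, e_t + extra, e_m + extra * 1000)


@pytest.fixture(scope="module")
def inversion_run():
    """100x simulation of a genome with two medium inversions."""
    seq = random_genome(4_000_000, seed=51)
    # below ~50 kbp an inversion rarely contains the four interior sites the
    # detector requires, so use sizes where detection is feasible
    plan = VariantPlan(n_inversions=2, inversion_size_range=(60_000, 95_000))
    mutated, truth = inject_variants(seq, plan, seed=52)
    refmap = digest({"chr1": seq})
    hap = HaplotypeMap.from_sequences(1, {"chr1": mutated})
    mols = simulate_molecules([hap], ErrorModelParams(coverage=100), seed=53)
    alns = filter_by_confidence(
        align_molecules(mols, refmap, AlignerParams(gamma_align=0.012)), 9.0)
    return truth, refmap, mols, alns


class TestMediumInversions:
    def test_simulated_inversions_recovered(self, inversion_run):
        truth, refmap, mols, alns = inversion_run
        calls = detect_medium_inversions(alns, mols, refmap)
        sites = np.asarray(refmap["chr1"].sites)
        for v in truth:
            n_inside = int(np.sum((sites > v.start) & (sites < v.end)))
            if n_inside < 4:
                continue  # intrinsically infeasible for this detector
            assert any(c.start < v.end and v.start < c.end for c in calls), v

    def test_no_calls_on_inversion_free_data(self, small_refmap, noisy_molecules):
        alns = filter_by_confidence(
            align_molecules(noisy_molecules, small_refmap,
                            AlignerParams(gamma_align=0.012)), 9.0)
        calls = detect_medium_inversions(alns, noisy_molecules, small_refmap)
        assert calls == []

    def test_support_threshold_boundary(self, inversion_run):
        truth, refmap, mols, alns = inversion_run
        strict = InversionParams(min_molecules=10)
        impossible = InversionParams(min_molecules=10_000)
        assert detect_medium_inversions(alns, mols, refmap, impossible) == []
        assert len(detect_medium_inversions(alns, mols, refmap, strict)) >= 1


def _segment(mol_id, chrom, start, end, orientation, lo_label, n=6):
    pairs = [(lo_label + k, k) for k in range(n)]
    if orientation == "-":
        pairs = [(lo_label + n - 1 - k, k) for k in range(n)]
    return AlignmentRecord(mol_id, chrom, start, end, orientation,
                           sorted(pairs, key=lambda p: p[1]), "M" * n, 30.0)


class TestSplitSvs:
    def test_interchromosomal_junction_needs_two_molecules(self):
        def split(mol_id):
            return SplitAlignment(mol_id, [
                _segment(mol_id, "chr1", 100_000, 200_000, "+", 0),
                _segment(mol_id, "chr2", 500_000, 600_000, "+", 6),
            ])
        assert detect_split_svs([split(1)]) == []
        calls = detect_split_svs([split(1), split(2)])
        assert len(calls) == 1
        assert calls[0].sv_type == "translocation_inter"
        assert calls[0].support == 2

    def test_opposite_orientation_pair_is_large_inversion(self):
        splits = [SplitAlignment(i, [
            _segment(i, "chr1", 100_000, 200_000, "+", 0),
            _segment(i, "chr1", 200_500, 320_000, "-", 6),
        ]) for i in (1, 2, 3)]
        (call,) = detect_split_svs(splits)
        assert call.sv_type == "inversion_large"

    def test_noncolinear_same_orientation_is_intra_translocation(self):
        splits = [SplitAlignment(i, [
            _segment(i, "chr1", 100_000, 200_000, "+", 0),
            _segment(i, "chr1", 900_000, 1_000_000, "+", 6),
        ]) for i in (1, 2)]
        (call,) = detect_split_svs(splits)
        assert call.sv_type == "translocation_intra"
        assert call.info["mate_position"] == pytest.approx(900_000.0)

    def test_colinear_continuation_is_not_an_sv(self):
        splits = [SplitAlignment(i, [
            _segment(i, "chr1", 100_000, 200_000, "+", 0),
            _segment(i, "chr1", 205_000, 300_000, "+", 6),
        ]) for i in (1, 2)]
        assert detect_split_svs(splits) == []


class TestCnv:
    def test_uniform_coverage_yields_no_calls(self, small_refmap, noisy_molecules):
        alns = filter_by_confidence(
            align_molecules(noisy_molecules, small_refmap,
                            AlignerParams(gamma_align=0.012)), 9.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert detect_cnvs(alns, small_refmap) == []

    def test_three_copy_segment_called_as_gain(self):
        seq = random_genome(2_500_000, seed=61)
        plan = VariantPlan(n_cnvs=1, cnv_size_range=(200_000, 200_001), cnv_copies=3)
        mutated, truth = inject_variants(seq, plan, seed=62)
        refmap = digest({"chr1": seq})
        hap = HaplotypeMap.from_sequences(1, {"chr1": mutated})
        mols = simulate_molecules([hap], ErrorModelParams(coverage=100), seed=63)
        alns = filter_by_confidence(
            align_molecules(mols, refmap, AlignerParams(gamma_align=0.012)), 9.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls = detect_cnvs(alns, refmap)
        v = truth[0]
        gains = [c for c in calls if c.sv_type == "cnv_gain"]
        assert any(c.start < v.end and v.start < c.end for c in gains)
        assert not [c for c in calls if c.sv_type == "cnv_loss"]

    def test_single_marginal_window_removed_by_fdr(self):
        # direct Benjamini-Hochberg arithmetic: one p=0.04 block among many
        # null blocks cannot survive FDR 0.05 when 0.04 > 0.05 * 1 / n_blocks
        p_values = np.concatenate([[0.04], np.linspace(0.2, 1.0, 9999)])
        order = np.argsort(p_values)
        n = len(p_values)
        passed = [p_values[i] <= 0.05 * (rank + 1) / n
                  for rank, i in enumerate(order)]
        assert not any(passed)
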