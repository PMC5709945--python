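from itertools import combinations

import numpy as np
import pytest

from mapsv.simulator import ErrorModelParams, generate_ratio_dataset
from mapsv.size_caller import (
    SizeCallerParams,
    SizeEvidence,
    call_size_sv,
    cauchy_density,
    size_likelihoods,
)


def cauchy(r, loc, g):
    return g / (np.pi * ((r - loc) ** 2 + g**2))


def restricted_topk_oracle(ratios, r0, g, k_min, side):
    """Direct evaluation of the simplified mixture sum: one term per split
    point k, the variant component being the k rank-extreme ratios with its
    own sample median as location (terms violating the location expectation
    are dropped)."""
    r = np.sort(ratios)
    M = len(r)
    total = 0.0
    for k in range(k_min, M - k_min + 1):
        if side == "ins":
            var, null = r[M - k:], r[:M - k]
            mu = np.median(var)
            if not mu > r0:
                continue
        else:
            var, null = r[:k], r[k:]
            mu = np.median(var)
            if not mu < r0:
                continue
        total += np.prod(cauchy(null, r0, g)) * np.prod(cauchy(var, mu, g))
    return total / 2**M


def unrestricted_subset_oracle(ratios, r0, g, k_min, side):
    """Full mixture sum over every admissible subset (not only rank-extreme
    ones), each with its own sample-median location."""
    r = np.sort(ratios)
    M = len(r)
    total = 0.0
    for k in range(k_min, M - k_min + 1):
        for subset in combinations(range(M), k):
            var = r[list(subset)]
            null = np.delete(r, list(subset))
            mu = np.median(var)
            if side == "ins" and not mu > r0:
                continue
            if side == "del" and not mu < r0:
                continue
            total += np.prod(cauchy(null, r0, g)) * np.prod(cauchy(var, mu, g))
    return total / 2**M


class TestCauchyDensity:
    def test_peak_value(self):
        assert cauchy_density(1.0, 1.0, 0.05) == pytest.approx(1 / (np.pi * 0.05))

    def test_half_peak_at_one_scale(self):
        assert cauchy_density(1.05, 1.0, 0.05) == pytest.approx(1 / (2 * np.pi * 0.05))

    def test_integrates_to_one(self):
        grid = np.linspace(-5000, 5000, 4_000_001)
        total = np.trapezoid(cauchy_density(grid, 1.0, 0.05), grid)
        assert total == pytest.approx(1.0, abs=1e-4)


class TestSizeLikelihoods:
    PARAMS = SizeCallerParams(gamma=0.05, k_min=1, M_min=4)

    def _evidence(self, ratios, d0=10000.0):
        return SizeEvidence("chr1", 0.0, d0, d0, np.asarray(ratios) * d0)

    def test_degenerate_null_hom_equals_h0(self):
        ev = self._evidence([1.0] * 6)
        lik = size_likelihoods(ev, self.PARAMS)
        assert lik.log_h0 == pytest.approx(6 * np.log(1 / (np.pi * 0.05)))
        assert lik.log_hom == pytest.approx(lik.log_h0)

    def test_het_ins_matches_topk_oracle_and_k2_dominates(self):
        ratios = [1.0, 1.0, 2.0, 2.0]
        ev = self._evidence(ratios)
        lik = size_likelihoods(ev, self.PARAMS)
        oracle = restricted_topk_oracle(ratios, 1.0, 0.05, 1, "ins")
        assert np.exp(lik.log_het_ins) == pytest.approx(oracle, rel=1e-9)
        assert lik.het_ins_k == 2

    @pytest.mark.parametrize("gamma,k_min", [(0.05, 1), (0.02, 2), (0.1, 3)])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_simplified_sums_match_oracle_across_grid(self, gamma, k_min, seed):
        rng = np.random.default_rng(seed)
        M = 10
        ratios = np.concatenate([1 + 0.02 * rng.standard_normal(M // 2),
                                 1.6 + 0.02 * rng.standard_normal(M // 2)])
        ev = self._evidence(ratios)
        params = SizeCallerParams(gamma=gamma, k_min=k_min)
        lik = size_likelihoods(ev, params)
        for side, log_val in (("ins", lik.log_het_ins), ("del", lik.log_het_del)):
            oracle = restricted_topk_oracle(ratios, 1.0, gamma, k_min, side)
            if oracle == 0.0:
                assert log_val == -np.inf
            else:
                assert np.exp(log_val) == pytest.approx(oracle, rel=1e-9)

    def test_simplified_no_greater_than_full_subset_sum(self):
        rng = np.random.default_rng(3)
        ratios = np.concatenate([1 + 0.03 * rng.standard_normal(3),
                                 1.5 + 0.03 * rng.standard_normal(3)])
        ev = self._evidence(ratios)
        lik = size_likelihoods(ev, SizeCallerParams(gamma=0.05, k_min=1))
        full = unrestricted_subset_oracle(ratios, 1.0, 0.05, 1, "ins")
        assert np.exp(lik.log_het_ins) <= full * (1 + 1e-12)

    def test_tri_matches_direct_sum(self):
        ratios = np.array([0.6, 0.6, 0.62, 1.4, 1.4, 1.42])
        ev = self._evidence(ratios)
        lik = size_likelihoods(ev, SizeCallerParams(gamma=0.05, k_min=1))
        r = np.sort(ratios)
        M = len(r)
        expected = sum(
            np.prod(cauchy(r[:k], np.median(r[:k]), 0.05))
            * np.prod(cauchy(r[k:], np.median(r[k:]), 0.05))
            for k in range(1, M)
        ) / 2**M
        assert np.exp(lik.log_tri) == pytest.approx(expected, rel=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        ratios = 1 + 0.3 * rng.standard_normal(12)
        ev1 = self._evidence(ratios, d0=10000.0)
        ev2 = SizeEvidence("chr1", 0.0, 70000.0, 70000.0, ratios * 70000.0)
        l1 = size_likelihoods(ev1, self.PARAMS)
        l2 = size_likelihoods(ev2, self.PARAMS)
        assert l1.log_h0 == pytest.approx(l2.log_h0)
        assert l1.log_hom == pytest.approx(l2.log_hom)
        assert l1.log_het_ins == pytest.approx(l2.log_het_ins)

    def test_lr_monotone_in_hom_shift(self):
        params = self.PARAMS
        lrs = []
        for shift in (0.0, 0.2, 0.5, 1.0):
            ev = self._evidence([1.0 + shift] * 8)
            lik = size_likelihoods(ev, params)
            lrs.append(lik.log_h0 - lik.log_hom)
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


class TestCallDecisions:
    PARAMS = SizeCallerParams(gamma=0.05, k_min=3, M_min=10, delta=2000.0)

    def _evidence(self, ratios, d0=10000.0):
        return SizeEvidence("chr1", 0.0, d0, d0, np.asarray(ratios) * d0)

    def test_pure_null_is_no_call(self):
        assert call_size_sv(self._evidence([1.0] * 20), self.PARAMS) == []

    def test_uniform_shift_called_homozygous_insertion(self):
        (call,) = call_size_sv(self._evidence([1.5] * 20), self.PARAMS)
        assert (call.sv_type, call.zygosity) == ("insertion", "hom")
        assert call.size == pytest.approx(5000.0)

    def test_uniform_shrink_called_homozygous_deletion(self):
        (call,) = call_size_sv(self._evidence([0.55] * 20), self.PARAMS)
        assert (call.sv_type, call.zygosity) == ("deletion", "hom")
        assert call.size == pytest.approx(-4500.0)

    def test_balanced_split_called_triallelic_pair(self):
        rng = np.random.default_rng(5)
        ratios = np.concatenate([0.6 + 0.01 * rng.standard_normal(10),
                                 1.4 + 0.01 * rng.standard_normal(10)])
        calls = call_size_sv(self._evidence(ratios), self.PARAMS)
        assert sorted(c.sv_type for c in calls) == ["deletion", "insertion"]
        assert all(c.info.get("multi_allele") for c in calls)
        sizes = sorted(c.size for c in calls)
        assert sizes[0] == pytest.approx(-4000.0, abs=300)
        assert sizes[1] == pytest.approx(4000.0, abs=300)

    def test_half_shifted_called_heterozygous_insertion(self):
        rng = np.random.default_rng(6)
        ratios = np.concatenate([1 + 0.01 * rng.standard_normal(10),
                                 1.5 + 0.01 * rng.standard_normal(10)])
        (call,) = call_size_sv(self._evidence(ratios), self.PARAMS)
        assert (call.sv_type, call.zygosity) == ("insertion", "het")

    def test_below_coverage_floor_is_no_call(self):
        assert call_size_sv(self._evidence([1.5] * 5), self.PARAMS) == []

    def test_distance_change_filter_blocks_small_events(self):
        # 15% shift of a 10 kbp gap = 1.5 kbp < delta
        assert call_size_sv(self._evidence([1.15] * 20), self.PARAMS) == []


class TestRatioDatasetRecovery:
    def test_type_and_zygosity_recovered_on_ideal_input(self):
        from mapsv import DiploidParams, VariantPlan, build_diploid, digest, inject_variants
        from mapsv.simulator import random_genome

        reference = random_genome(4_000_000, seed=31)
        plan = VariantPlan(n_insertions=12, n_deletions=12)
        _, truth_hap = inject_variants(reference, plan, seed=32)
        _, _, truth = build_diploid(truth_hap, reference, DiploidParams(), seed=33)
        refmap = digest({"chr1": reference})
        loci = generate_ratio_dataset(truth, refmap, 40.0, ErrorModelParams(), 34)
        params = SizeCallerParams(gamma=0.02, M_min=20)
        n_ok = n_sv = n_false_null = 0
        for locus in loci:
            ev = SizeEvidence(locus.chromosome, locus.left_site, locus.right_site,
                              locus.d0, locus.ratios * locus.d0)
            calls = call_size_sv(ev, params)
            if locus.truth_kind == "none":
                n_false_null += bool(calls)
            elif ev.M >= 20:
                n_sv += 1
                n_ok += bool(calls) and calls[0].sv_type == locus.truth_kind \
                    and calls[0].zygosity == locus.truth_zygosity
        assert n_sv >= 15
        assert n_ok / n_sv >= 0.95
        assert n_false_null == 0
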