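import numpy as np
import pytest
from scipy import stats

from mapsv import (
    DigestionParams,
    DiploidParams,
    ErrorModelParams,
    HaplotypeMap,
    VariantPlan,
    build_diploid,
    digest,
    inject_variants,
    simulate_molecules,
)
from mapsv import om_io
from mapsv.digestion import find_nick_sites, reverse_complement
from mapsv.simulator import (
    _draw_alpha,
    _stochastic_merge,
    apply_variants,
    estimate_error_params,
    generate_ratio_dataset,
    oracle_alignments,
    random_genome,
)


class TestInjectVariants:
    def test_empty_plan_is_identity(self, small_genome):
        mutated, truth = inject_variants(small_genome, VariantPlan(), seed=1)
        assert mutated == small_genome and truth == []

    def test_deletion_shortens_sequence(self, small_genome):
        plan = VariantPlan(n_deletions=1, indel_size_range=(5000, 5001))
        mutated, truth = inject_variants(small_genome, plan, seed=2)
        assert len(small_genome) - len(mutated) == int(truth[0].size)

    def test_inversion_segment_is_reverse_complement(self, small_genome):
        plan = VariantPlan(n_inversions=1, inversion_size_range=(8000, 8001))
        mutated, truth = inject_variants(small_genome, plan, seed=3)
        v = truth[0]
        s, e = int(v.start), int(v.end)
        assert mutated[s:e] == reverse_complement(small_genome[s:e])

    def test_truth_list_replays_to_mutated_sequence(self, mutated_small, small_genome):
        mutated, truth = mutated_small
        assert apply_variants(small_genome, truth) == mutated

    def test_infeasible_plan_raises(self):
        seq = random_genome(50_000, seed=4)
        plan = VariantPlan(n_deletions=50, edge_margin=1000.0)
        with pytest.raises(RuntimeError, match="infeasible"):
            inject_variants(seq, plan, seed=5)


class TestBuildDiploid:
    def test_phom_one_makes_all_homozygous(self, mutated_small, small_genome):
        _, truth = mutated_small
        s1, s2, annotated = build_diploid(truth, small_genome, DiploidParams(1.0, 0.5), 1)
        assert all(v.zygosity == "hom" for v in annotated)
        assert s1 == s2

    def test_phom_zero_phet_zero_all_het_on_hap1(self, mutated_small, small_genome):
        _, truth = mutated_small
        s1, s2, annotated = build_diploid(truth, small_genome, DiploidParams(0.0, 0.0), 1)
        assert all(v.zygosity == "het" and v.haplotypes == (1,) for v in annotated)
        assert s2 == small_genome

    def test_hom_fraction_tracks_phom(self, small_genome):
        rng = np.random.default_rng(6)
        variants = inject_variants(small_genome, VariantPlan(n_snvs=1000, edge_margin=1000.0), rng)[1]
        _, _, annotated = build_diploid(variants, small_genome, DiploidParams(0.5, 0.5), 7)
        n_hom = sum(v.zygosity == "hom" for v in annotated)
        lo, hi = stats.binom.interval(0.99, len(annotated), 0.5)
        assert lo <= n_hom <= hi

    def test_locus_count_preserved(self, mutated_small, small_genome):
        _, truth = mutated_small
        _, _, annotated = build_diploid(truth, small_genome, DiploidParams(), 8)
        assert len(annotated) == len(truth)


class TestErrorModelStages:
    def test_noiseless_limit_reproduces_digestion(self, small_genome):
        seq = small_genome[:400_000]
        hap = HaplotypeMap.from_sequences(1, {"chr1": seq})
        params = ErrorModelParams(f_minus=0.0, f_plus=0.0, s_alpha=0.0,
                                  e=0.0, d_half=0.0)
        mols = simulate_molecules([hap], params, seed=1, n_molecules=20)
        sites = np.asarray(find_nick_sites(seq, DigestionParams()))
        for mol in mols:
            t = mol.truth
            labels = np.asarray(mol.labels)
            if t.orientation == "-":
                labels = (mol.length - labels)[::-1]
            expected = sites[(sites >= t.start) & (sites < t.end)] - t.start
            assert np.allclose(labels, expected, atol=1e-6)

    def test_false_positive_counts_are_poisson(self):
        # motif-free genome: every label is a false positive; one molecule = one gap
        seq = "A" * 200_000
        hap = HaplotypeMap.from_sequences(1, {"chr1": seq})
        f_plus = 1.2e-5
        params = ErrorModelParams(l0=100_000.0, mu_l=1.0, f_minus=0.0,
                                  f_plus=f_plus, s_alpha=0.0, e=0.0, d_half=0.0)
        mols = simulate_molecules([hap], params, seed=2, n_molecules=10_000)
        counts = np.array([m.n_labels for m in mols
                           if m.truth.end - m.truth.start > 100_000.0 - 1])
        lam = counts.mean()
        kmax = int(counts.max())
        observed = np.bincount(counts, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), lam) * len(counts)
        # pool the sparse tail so expected counts stay >= 5
        cut = int(np.searchsorted(np.cumsum(expected[::-1]), 5.0))
        k = kmax + 1 - cut
        obs = np.append(observed[:k], observed[k:].sum())
        exp = np.append(expected[:k], expected[k:].sum())
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, len(obs) - 2)
        assert p > 0.01
        # mean consistent with d * f_plus over many draws
        assert abs(lam - 100_000.0 * f_plus) < 0.05

    def test_fp_mean_about_one_per_100kbp_gap(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(100_000 * 1e-5, size=20_000)
        assert abs(counts.mean() - 1.0) < 0.05

    def test_merge_probability_half_at_dhalf(self):
        rng = np.random.default_rng(4)
        d_half, n = 1500.0, 10_000
        merged = sum(
            len(_stochastic_merge(np.array([0.0, d_half]), d_half, rng)) == 1
            for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(merged / n - 0.5) <= 3 * se

    @pytest.mark.parametrize("d", [500.0, 1200.0, 1800.0, 2500.0])
    def test_merge_rate_follows_logistic(self, d):
        rng = np.random.default_rng(5)
        d_half, n = 1500.0, 4000
        expect = 1.0 - 1.0 / (1.0 + np.exp(-0.01 * (d - d_half)))
        merged = sum(
            len(_stochastic_merge(np.array([0.0, d]), d_half, rng)) == 1
            for _ in range(n)
        )
        se = np.sqrt(max(expect * (1 - expect), 1e-6) / n)
        assert abs(merged / n - expect) <= max(3 * se, 0.005)

    def test_stretch_factor_is_cauchy(self):
        rng = np.random.default_rng(6)
        draws = np.array([_draw_alpha(rng, 1.0, 0.015) for _ in range(20_000)])
        q1, med, q3 = np.percentile(draws, [25, 50, 75])
        assert abs(med - 1.0) < 1e-3
        assert abs((q3 - q1) / 2 - 0.015) < 1.5e-3

    def test_same_seed_gives_byte_identical_bnx(self, mutated_small, tmp_path):
        mutated, _ = mutated_small
        hap = HaplotypeMap.from_sequences(1, {"chr1": mutated})
        out = []
        for _ in range(2):
            mols = simulate_molecules([hap], ErrorModelParams(coverage=5), seed=99)
            p = tmp_path / "x.bnx"
            om_io.write_molecules(mols, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_all_fn_no_fp_warns_and_yields_bare_molecules(self, small_genome):
        hap = HaplotypeMap.from_sequences(1, {"chr1": small_genome[:300_000]})
        params = ErrorModelParams(f_minus=1.0, f_plus=0.0)
        with pytest.warns(UserWarning, match="no internal labels"):
            mols = simulate_molecules([hap], params, seed=1, n_molecules=5)
        assert all(m.n_labels == 0 for m in mols)


class TestRatioDataset:
    def _loci(self, seed=11, depth=40.0):
        reference = random_genome(1_500_000, seed=9)
        plan = VariantPlan(n_insertions=5, n_deletions=5)
        _, truth = inject_variants(reference, plan, seed=10)
        refmap = digest({"chr1": reference})
        return generate_ratio_dataset(truth, refmap, depth, ErrorModelParams(), seed)

    def test_null_locus_without_noise_has_unit_ratios(self):
        reference = random_genome(500_000, seed=12)
        refmap = digest({"chr1": reference})
        em = ErrorModelParams(s_alpha=0.0)
        loci = generate_ratio_dataset([], refmap, 20.0, em, 13, n_null_per_sv=0.0)
        assert loci == []

    def test_hom_insertion_doubles_ratio_without_noise(self):
        reference = random_genome(1_500_000, seed=9)
        refmap = digest({"chr1": reference})
        sites = np.asarray(refmap["chr1"].sites)
        gap = float(sites[11] - sites[10])
        from mapsv.simulator import TruthVariant
        v = TruthVariant("insertion", "chr1", sites[10] + gap / 2, sites[10] + gap / 2,
                         gap, "hom", (1, 2))
        em = ErrorModelParams(s_alpha=0.0)
        loci = generate_ratio_dataset([v], refmap, 30.0, em, 14, n_null_per_sv=0.0)
        assert np.allclose(loci[0].ratios, 2.0)

    def test_het_locus_draws_each_allele_half_the_time(self):
        reference = random_genome(1_500_000, seed=9)
        refmap = digest({"chr1": reference})
        sites = np.asarray(refmap["chr1"].sites)
        from mapsv.simulator import TruthVariant
        v = TruthVariant("insertion", "chr1", sites[10] + 1, sites[10] + 1,
                         float(sites[11] - sites[10]), "het", (1,))
        em = ErrorModelParams(s_alpha=0.0)
        loci = generate_ratio_dataset([v], refmap, 10_000.0, em, 15, n_null_per_sv=0.0)
        frac_ins = np.mean(loci[0].ratios > 1.5)
        lo, hi = stats.binom.interval(0.999, len(loci[0].ratios), 0.5)
        assert lo / len(loci[0].ratios) <= frac_ins <= hi / len(loci[0].ratios)


class TestParameterEstimation:
    def test_recovery_within_20_percent_on_perfect_alignments(self, small_genome):
        refmap = digest({"chr1": small_genome})
        truth = {"f_minus": 0.10, "f_plus": 1e-5, "o_alpha": 1.0, "s_alpha": 0.015}
        params = ErrorModelParams(f_minus=0.10, f_plus=1e-5)
        hap = HaplotypeMap.from_sequences(1, {"chr1": small_genome})
        mols = simulate_molecules([hap], params, seed=21, n_molecules=400)
        est = estimate_error_params(oracle_alignments(mols, refmap), mols, refmap)
        for key, val in truth.items():
            assert abs(est[key] - val) / val < 0.20, key

    def test_error_free_data_estimates_zero_rates(self, small_genome):
        # molecules carry no resolution merging, so digest the reference
        # unmerged as well for an exactly matching site universe
        refmap = digest({"chr1": small_genome}, DigestionParams(d_half=1e-9))
        params = ErrorModelParams(f_minus=0.0, f_plus=0.0, s_alpha=0.0, e=0.0,
                                  d_half=0.0)
        hap = HaplotypeMap.from_sequences(1, {"chr1": small_genome})
        mols = simulate_molecules([hap], params, seed=22, n_molecules=100)
        est = estimate_error_params(oracle_alignments(mols, refmap), mols, refmap)
        assert est["f_minus"] < 0.01 and est["f_plus"] < 1e-7

    def test_cauchy_iqr_half_matches_scale(self):
        rng = np.random.default_rng(23)
        for n in (500, 5000):
            sample = rng.standard_cauchy(n) * 0.015 + 1.0
            q1, q3 = np.percentile(sample, [25, 75])
            assert abs((q3 - q1) / 2 - 0.015) < 0.003

    def test_no_alignments_is_error(self, small_refmap):
        with pytest.raises(ValueError):
            estimate_error_params([], [], small_refmap)
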