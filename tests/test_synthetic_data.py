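"""Generator distributions against analytic coalescent and substitution
expectations, plus an independent simulator cross-check (msprime)."""

import numpy as np
import pytest
from scipy import stats

from tipdating.clock_model import (
    ClockModel,
    DemographicModel,
    SubstitutionParams,
    partition_log_likelihood,
)
from tipdating.io_formats import AgeStatus, AnnotationRow, AnnotationTable
from tipdating.synthetic_data import (
    StudyConfig,
    compact_annotation,
    make_study_dataset,
    mammoth_annotation,
    simulate_alignment,
    simulate_genealogy,
    simulate_pileup,
)
from tipdating.consensus import DEFAULT_POLICY, call_consensus


class TestSimulateGenealogy:
    def test_two_tip_tmrca_mean_matches_Ne(self, rng):
        ne = 1000.0
        demog = DemographicModel(mode="constant", Ne=ne)
        tmrca = np.array([
            simulate_genealogy([0.0, 0.0], demog, rng).age[-1] for _ in range(2000)
        ])
        se = tmrca.std(ddof=1) / np.sqrt(len(tmrca))
        assert abs(tmrca.mean() - ne) < 3 * se

    def test_ten_tip_tmrca_matches_coalescent_expectation(self, rng):
        ne = 500.0
        demog = DemographicModel(mode="constant", Ne=ne)
        expected = 2 * ne * (1 - 1 / 10)
        tmrca = np.array([
            simulate_genealogy([0.0] * 10, demog, rng).age[-1] for _ in range(2000)
        ])
        se = tmrca.std(ddof=1) / np.sqrt(len(tmrca))
        assert abs(tmrca.mean() - expected) < 3 * se

    def test_root_always_older_than_oldest_tip(self, rng):
        demog = DemographicModel(mode="constant", Ne=200.0)
        for _ in range(50):
            tree = simulate_genealogy([0.0, 5000.0], demog, rng)
            assert tree.age[tree.root] >= 5000.0
            tree.validate()

    def test_two_tip_tmrca_is_exponential(self, rng):
        """KS against Exponential(1/Ne) on 5000 isochronous draws."""
        ne = 1.0
        demog = DemographicModel(mode="constant", Ne=ne)
        draws = np.array([
            simulate_genealogy([0.0, 0.0], demog, rng).age[-1] for _ in range(5000)
        ])
        assert stats.kstest(draws, stats.expon(scale=ne).cdf).pvalue > 0.01

    def test_heterochronous_tmrca_matches_msprime(self, rng):
        """Cross-check the serial sampler against an independent coalescent
        simulator on 3 tips with staggered sampling times."""
        msprime = pytest.importorskip("msprime")
        ne = 1000.0
        ages = [0.0, 300.0, 900.0]
        ours = np.array([
            simulate_genealogy(ages, DemographicModel(mode="constant", Ne=ne),
                               rng).age[-1]
            for _ in range(3000)
        ])
        theirs = []
        for i in range(3000):
            ts = msprime.sim_ancestry(
                samples=[msprime.SampleSet(1, time=t, ploidy=1) for t in ages],
                population_size=ne, ploidy=1, random_seed=i + 1)
            theirs.append(ts.max_root_time)
        assert stats.ks_2samp(ours, np.array(theirs)).pvalue > 0.01

    def test_grid_demography_first_epoch_behaves_like_constant(self, rng):
        grid = DemographicModel(mode="grid", boundaries=[1e7],
                                sizes=[800.0, 800.0], gmrf_precision=1.0)
        draws = np.array([
            simulate_genealogy([0.0, 0.0], grid, rng).age[-1] for _ in range(2000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 800.0) < 3 * se

    def test_fewer_than_two_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_genealogy([0.0], DemographicModel(mode="constant", Ne=1.0), 0)


class TestSimulateAlignment:
    def setup_method(self):
        self.ann = AnnotationTable([AnnotationRow("control_region", 1, 1000)])
        self.params = {"control_region": SubstitutionParams(
            kappa=1.0, freqs=[0.25] * 4)}

    def test_zero_clock_rate_gives_identical_sequences(self, rng):
        demog = DemographicModel(mode="constant", Ne=100.0)
        tree = simulate_genealogy([0.0, 0.0, 50.0], demog, rng)
        aln = simulate_alignment(tree, self.ann, 1000, self.params, 0.0, rng)
        seqs = {seq for _, seq in aln.records}
        assert len(seqs) == 1

    def test_pairwise_difference_matches_jukes_cantor(self, rng):
        """Two tips at total path 0.1 subs/site under kappa=1, equal
        frequencies: p-distance follows the Jukes-Cantor closed form."""
        from tipdating.trees import parse_newick

        tree = parse_newick("(a:50,b:50);")  # years; clock 1e-3 -> d = 0.1
        ann = AnnotationTable([AnnotationRow("control_region", 1, 100_000)])
        aln = simulate_alignment(tree, ann, 100_000, self.params, 1e-3, rng)
        a, b = aln.records[0][1], aln.records[1][1]
        diff = np.mean([x != y for x, y in zip(a, b)])
        p = 0.75 * (1 - np.exp(-4 * 0.1 / 3))
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(diff - p) < 3 * se

    def test_base_composition_matches_stationary_frequencies(self, rng):
        from tipdating.trees import parse_newick

        freqs = np.array([0.35, 0.25, 0.15, 0.25])
        params = {"control_region": SubstitutionParams(kappa=5.0, freqs=freqs)}
        tree = parse_newick("(a:1000,b:1000);")
        ann = AnnotationTable([AnnotationRow("control_region", 1, 50_000)])
        aln = simulate_alignment(tree, ann, 50_000, params, 1e-4, rng)
        seq = aln.records[0][1]
        for b, f in zip("ACGT", freqs):
            obs = seq.count(b) / len(seq)
            se = np.sqrt(f * (1 - f) / len(seq))
            assert abs(obs - f) < 4 * se

    def test_site_patterns_match_pruning_probabilities(self, rng):
        """Chi-square goodness of fit of simulated 3-tip site patterns
        against likelihood-computed pattern probabilities (100 kb)."""
        from tipdating.trees import parse_newick
        from itertools import product

        tree = parse_newick("((a:30,b:30):20,c:50);")
        params = SubstitutionParams(kappa=4.0, freqs=[0.3, 0.2, 0.2, 0.3],
                                    gamma_shape=0.7, p_inv=0.2)
        clock = ClockModel(2e-3)
        ann = AnnotationTable([AnnotationRow("control_region", 1, 100_000)])
        aln = simulate_alignment(tree, ann, 100_000,
                                 {"control_region": params}, 2e-3, rng)
        seqs = dict(aln.records)
        observed = {}
        for triple in zip(seqs["a"], seqs["b"], seqs["c"]):
            observed[triple] = observed.get(triple, 0) + 1
        expected = {}
        for triple in product("ACGT", repeat=3):
            records = [("a", triple[0]), ("b", triple[1]), ("c", triple[2])]
            expected[triple] = np.exp(
                partition_log_likelihood(tree, records, params, clock)) * 100_000
        obs = np.array([observed.get(t, 0) for t in sorted(expected)])
        exp = np.array([expected[t] for t in sorted(expected)])
        keep = exp >= 5  # standard chi-square validity threshold
        chi2 = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
        chi2 += float(exp[~keep].sum())  # lump rare cells conservatively
        dof = int(keep.sum()) - 1
        assert stats.chi2.sf(chi2, dof) > 0.01

    def test_negative_clock_rejected(self, rng):
        demog = DemographicModel(mode="constant", Ne=100.0)
        tree = simulate_genealogy([0.0, 0.0], demog, rng)
        with pytest.raises(ValueError):
            simulate_alignment(tree, self.ann, 1000, self.params, -1.0, rng)


class TestSimulatePileup:
    def test_error_free_high_depth_reproduces_truth(self, rng):
        truth = "".join(rng.choice(list("ACGT"), size=500))
        counts = simulate_pileup(truth, mean_depth=30, error_rate=0.0, seed=rng)
        consensus = call_consensus(counts, DEFAULT_POLICY)
        # positions under 3x are masked; every called base must match truth
        assert all(c in ("N", t) for c, t in zip(consensus, truth))
        assert sum(c == "N" for c in consensus) < 25

    def test_low_depth_forces_mostly_missing_consensus(self, rng):
        truth = "A" * 2000
        counts = simulate_pileup(truth, mean_depth=0.5, error_rate=0.0, seed=rng)
        consensus = call_consensus(counts, DEFAULT_POLICY)
        assert sum(c == "N" for c in consensus) / 2000 > 0.8

    def test_observed_mean_depth_matches_request(self, rng):
        truth = "C" * 16_000
        mean, disp = 12.0, 4.0
        counts = simulate_pileup(truth, mean_depth=mean, depth_dispersion=disp,
                                 error_rate=0.01, seed=rng)
        depths = counts.sum(axis=1)
        se = np.sqrt((mean + mean**2 / disp) / 16_000)
        assert abs(depths.mean() - mean) < 3 * se

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_pileup("ACGT", mean_depth=0.0)
        with pytest.raises(ValueError):
            simulate_pileup("ACGT", mean_depth=5, error_rate=0.3)


class TestMakeStudyDataset:
    def test_bookkeeping_counts(self, small_annotation):
        cfg = StudyConfig(n_calibrated=20, n_undated=1, n_outgroup=2,
                          seq_length=400, annotation=small_annotation)
        aln, table, tree, truth = make_study_dataset(cfg, 7)
        assert len(aln.records) == 23
        undated = [r for r in table if r.age_status is AgeStatus.UNDATED]
        assert len(undated) == 1
        assert (undated[0].prior_lo, undated[0].prior_hi) == (1_000.0, 2_000_000.0)

    def test_calibrated_ages_equal_generating_ages(self, small_dataset):
        aln, table, tree, truth = small_dataset
        for rec in table:
            if rec.age_status is AgeStatus.CALIBRATED_FIXED:
                assert rec.fixed_age == pytest.approx(truth.tip_ages[rec.sample_id])

    def test_deterministic_given_seed(self, small_annotation):
        cfg = StudyConfig(n_calibrated=5, n_undated=1, n_outgroup=2,
                          seq_length=400, annotation=small_annotation)
        a1 = make_study_dataset(cfg, 99)
        a2 = make_study_dataset(cfg, 99)
        assert a1[0].records == a2[0].records
        np.testing.assert_array_equal(a1[2].age, a2[2].age)

    def test_outgroup_split_near_calibration_and_monophyletic(self):
        cfg = StudyConfig(n_calibrated=6, n_undated=1, n_outgroup=2, seq_length=400,
                          annotation=compact_annotation(400))
        _, _, tree, truth = make_study_dataset(cfg, 5)
        assert truth.root_age == pytest.approx(tree.age[tree.root])
        assert 0.75 * 5.3e6 < truth.root_age < 1.4 * 5.3e6
        # the outgroup pair must form one of the root's child clades
        masks = tree.clade_bitmask()
        out_idx = [i for i, lab in enumerate(tree.labels) if lab.startswith("out")]
        want = sum(1 << i for i in out_idx)
        children = [masks[c] for c in tree.children(tree.root)]
        assert want in children

    def test_mammoth_layout_dimensions(self):
        ann = mammoth_annotation()
        assert ann.vntr().start == 16_157 and ann.vntr().end == 16_476
        cfg = StudyConfig(n_calibrated=4, n_undated=1, n_outgroup=2)
        aln, *_ = make_study_dataset(cfg, 1)
        assert aln.n_columns == 16_770
        assert len(aln.partition_columns("masked")) == 320
        for name in ("tRNA", "rRNA", "codon1", "codon2", "codon3", "control_region"):
            assert len(aln.partition_columns(name)) > 0
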