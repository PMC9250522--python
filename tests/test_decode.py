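import numpy as np
import pytest

from odorbarrel import decode as dec
from odorbarrel.preprocess import compute_dff, neuropil_correct
from odorbarrel.protocol import make_protocol, multi_odor_conditions
from odorbarrel.synth import (
    PopulationParams,
    simulate_facial_motion,
    simulate_population,
)


@pytest.fixture(scope="module")
def tuned_pv(protocol):
    """Features from a session with strong orientation tuning and a weak,
    orthogonal odor-identity subspace."""
    params = PopulationParams(
        n_cells=100, frac_modulated=0.0, orientation_coef=0.4,
        odor_identity_coef=0.08, subspace_angle_deg=90.0,
    )
    fluor, gt = simulate_population(protocol, params, seed=31)
    dff = compute_dff(neuropil_correct(fluor.F, fluor.F_n), protocol)
    return dec.build_features(dff), gt


class TestBuildFeatures:
    def test_eleven_second_trial_gives_eleven_bins(self, tuned_pv, protocol):
        pv, _ = tuned_pv
        assert pv.n_bins == 11
        assert pv.X.shape == (protocol.n_trials, 100, 11)

    def test_z_score_standardizes_features(self, protocol):
        fluor, _ = simulate_population(protocol, PopulationParams(n_cells=6), seed=1)
        dff = compute_dff(neuropil_correct(fluor.F, fluor.F_n), protocol)
        z = dec.build_features(dff, z_score=True)
        assert np.allclose(z.X.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.X.std(axis=0), 1.0, atol=1e-10)

    def test_pooling_concatenates_cells(self, protocol):
        mats = []
        for seed in (1, 2):
            proto = protocol.with_seed(seed)
            fluor, _ = simulate_population(proto, PopulationParams(n_cells=20), seed=seed)
            mats.append(compute_dff(neuropil_correct(fluor.F, fluor.F_n), proto))
        pooled = dec.build_features(mats)
        assert pooled.X.shape[1] == 40
        assert pooled.pooled
        # pooled rows are condition-matched: labels sorted by condition
        assert (np.diff(pooled.y) >= 0).all()

    def test_mismatched_protocols_rejected(self, protocol):
        conds, reps = multi_odor_conditions()
        other = make_protocol(conds, reps, seed=0)
        fl1, _ = simulate_population(protocol, PopulationParams(n_cells=5), seed=0)
        fl2, _ = simulate_population(other, PopulationParams(n_cells=5), seed=0)
        d1 = compute_dff(neuropil_correct(fl1.F, fl1.F_n), protocol)
        d2 = compute_dff(neuropil_correct(fl2.F, fl2.F_n), other)
        with pytest.raises(ValueError, match="condition"):
            dec.build_features([d1, d2])


class TestCentroidCV:
    def test_separable_classes_decode_perfectly(self, tuned_pv, protocol):
        pv, _ = tuned_pv
        conds = protocol.trial_conditions()
        grat = np.array([c.grating or "" for c in conds], dtype=object)
        tact = np.flatnonzero(grat != "")
        sub = pv.restrict(trials=tact, y=grat[tact])
        res = dec.centroid_cv(sub, k=10, seed=0)
        assert res.accuracy[sub.stim_bins].min() > 95.0

    def test_hand_computed_two_fold_toy_problem(self):
        """X = {0,0,1,1}: fold centroids are 0 and 1, every test trial is
        closer to its own class centroid -> accuracy 100%."""
        proto = make_protocol(seed=0)
        X = np.array([0.0, 0.0, 1.0, 1.0])[:, None, None]
        pv = dec.PopulationVectors(
            X=X, y=np.array(["a", "a", "b", "b"]), bin_edges_s=np.array([0.0, 1.0]),
            protocol=proto,
        )
        res = dec.centroid_cv(pv, k=2, seed=0)
        assert res.accuracy[0] == pytest.approx(100.0)

    def test_chance_level_on_label_independent_data(self):
        proto = make_protocol(seed=0)
        rng = np.random.default_rng(0)
        accs = []
        for rep in range(120):
            X = rng.standard_normal((80, 10, 1))
            y = np.repeat(["a", "b"], 40)
            pv = dec.PopulationVectors(
                X=X, y=y, bin_edges_s=np.array([0.0, 1.0]), protocol=proto
            )
            accs.append(dec.centroid_cv(pv, k=10, seed=rep).accuracy[0])
        assert np.mean(accs) == pytest.approx(50.0, abs=3.0)

    def test_too_few_trials_per_class_suggests_smaller_k(self):
        proto = make_protocol(seed=0)
        pv = dec.PopulationVectors(
            X=np.zeros((6, 2, 1)), y=np.repeat(["a", "b"], 3),
            bin_edges_s=np.array([0.0, 1.0]), protocol=proto,
        )
        with pytest.raises(ValueError, match="smaller k"):
            dec.centroid_cv(pv, k=5)


class TestPermutationPvalue:
    def test_strong_signal_hits_pvalue_floor(self, tuned_pv, protocol):
        pv, _ = tuned_pv
        conds = protocol.trial_conditions()
        grat = np.array([c.grating or "" for c in conds], dtype=object)
        tact = np.flatnonzero(grat != "")
        sub = pv.restrict(trials=tact, y=grat[tact]).restrict(bins=pv.stim_bins[:1])
        res = dec.permutation_pvalue(sub, n_shuffles=25, seed=0)
        assert res.pvalues[0] == pytest.approx(1 / 25)

    def test_two_sided_option_also_flags_strong_signal(self, tuned_pv, protocol):
        pv, _ = tuned_pv
        conds = protocol.trial_conditions()
        grat = np.array([c.grating or "" for c in conds], dtype=object)
        tact = np.flatnonzero(grat != "")
        sub = pv.restrict(trials=tact, y=grat[tact]).restrict(bins=pv.stim_bins[:1])
        res = dec.permutation_pvalue(sub, n_shuffles=20, seed=0, alternative="two-sided")
        assert res.pvalues[0] == pytest.approx(1 / 20)
        with pytest.raises(ValueError, match="alternative"):
            dec.permutation_pvalue(sub, n_shuffles=5, alternative="less")

    def test_seed_determinism(self):
        proto = make_protocol(seed=0)
        rng = np.random.default_rng(1)
        pv = dec.PopulationVectors(
            X=rng.standard_normal((40, 5, 1)), y=np.repeat(["a", "b"], 20),
            bin_edges_s=np.array([0.0, 1.0]), protocol=proto,
        )
        r1 = dec.permutation_pvalue(pv, n_shuffles=15, seed=3, k=5)
        r2 = dec.permutation_pvalue(pv, n_shuffles=15, seed=3, k=5)
        assert np.array_equal(r1.shuffle_accuracies, r2.shuffle_accuracies)
        assert np.array_equal(r1.pvalues, r2.pvalues)


class TestTransferTest:
    def test_orthogonal_subspace_keeps_tactile_decoding(self, tuned_pv, protocol):
        """Orientation decoder trained without odors transfers to odor trials."""
        pv, _ = tuned_pv
        conds = protocol.trial_conditions()
        grat = np.array([c.grating or "" for c in conds], dtype=object)
        has_odor = np.array([c.odor is not None for c in conds])
        train = np.flatnonzero((grat != "") & ~has_odor)
        test = np.flatnonzero((grat != "") & has_odor)
        tr = dec.transfer_test(pv, grat, train, test, k=10, seed=0)
        assert tr.out_domain_accuracy >= tr.in_domain_accuracy - 5.0

    def test_weak_odor_decoder_collapses_with_touch(self, tuned_pv, protocol):
        """Odor decoder trained on odor-only trials falls to chance when the
        dominant tactile signal is added."""
        pv, _ = tuned_pv
        conds = protocol.trial_conditions()
        odor = np.array([c.odor or "" for c in conds], dtype=object)
        grat = np.array([c.grating or "" for c in conds], dtype=object)
        train = np.flatnonzero((odor != "") & (grat == ""))
        test = np.flatnonzero((odor != "") & (grat != ""))
        tr = dec.transfer_test(pv, odor, train, test, k=10, seed=0)
        assert tr.in_domain_accuracy > 75.0
        # chance = 50% for two odors; binomial 95% band for n = 40 test trials
        assert abs(tr.out_domain_accuracy - 50.0) < 2 * 100 * np.sqrt(0.25 / 40) + 5.0

    def test_overlapping_train_test_rejected(self, tuned_pv):
        pv, _ = tuned_pv
        y = pv.y.astype(str)
        with pytest.raises(ValueError, match="disjoint"):
            dec.transfer_test(pv, y, np.arange(10), np.arange(5, 15))


@pytest.fixture(scope="module")
def odor5_pv():
    conds, reps = multi_odor_conditions(mixtures=(), reps_per_odor=20, n_blank=10)
    proto = make_protocol(conds, reps, seed=7)
    params = PopulationParams(
        n_cells=60, frac_tactile=0.0, frac_modulated=0.0,
        odor_identity_coef=0.3, noise_sigma=3.0,
    )
    fluor, _ = simulate_population(proto, params, seed=7)
    dff = compute_dff(neuropil_correct(fluor.F, fluor.F_n), proto)
    pv = dec.build_features(dff)
    odors = np.array([c.odor or "" for c in proto.trial_conditions()], dtype=object)
    keep = np.flatnonzero(odors != "")
    return pv.restrict(trials=keep, y=odors[keep])


class TestSvmDecode:
    def test_separated_classes_give_diagonal_confusion(self, odor5_pv):
        res = dec.svm_decode(odor5_pv, k=5, C=1.0, seed=0)
        assert res.accuracy[odor5_pv.stim_bins].max() > 95.0
        cm = res.confusion
        assert cm.sum() == odor5_pv.y.size
        assert np.trace(cm) / cm.sum() > 0.95
        # confusion rows sum to class trial counts
        assert (cm.sum(axis=1) == 20).all()

    def test_shuffled_labels_give_chance(self, odor5_pv):
        rng = np.random.default_rng(0)
        accs = []
        for rep in range(8):
            ys = rng.permutation(odor5_pv.y)
            sub = odor5_pv.restrict(y=ys).restrict(bins=odor5_pv.stim_bins[:1])
            accs.append(dec.svm_decode(sub, k=5, C=1.0, seed=rep).accuracy[0])
        assert np.mean(accs) == pytest.approx(20.0, abs=6.0)

    def test_c_selection_keeps_baseline_at_chance(self, odor5_pv):
        res = dec.svm_decode(odor5_pv, k=5, seed=0, C_grid=np.array([0.01, 1.0]))
        base = res.accuracy[odor5_pv.baseline_bins]
        chance = res.chance
        half = 100 * 1.96 * np.sqrt((chance / 100) * (1 - chance / 100) / odor5_pv.y.size)
        assert np.all(np.abs(base - chance) <= half + 10.0)


@pytest.fixture(scope="module")
def mixture_pv():
    conds, reps = multi_odor_conditions(odors=("AA", "EB"), reps_per_odor=25,
                                        reps_per_mixture=12, n_blank=10)
    proto = make_protocol(conds, reps, seed=9)
    params = PopulationParams(
        n_cells=60, frac_tactile=0.0, frac_modulated=0.0,
        odor_identity_coef=0.3, noise_sigma=3.0,
    )
    fluor, _ = simulate_population(proto, params, seed=9)
    dff = compute_dff(neuropil_correct(fluor.F, fluor.F_n), proto)
    return dec.build_features(dff)


class TestMixtureCategorize:
    def test_dominant_component_wins(self, mixture_pv):
        scores = dec.mixture_categorize(mixture_pv)
        assert scores["AA80:EB20"]["AA"] > 0.5
        assert scores["AA20:EB80"]["EB"] > 0.5

    def test_missing_pure_class_rejected(self, mixture_pv):
        with pytest.raises(ValueError, match="pure-odor"):
            dec.mixture_categorize(mixture_pv, pure=("AA", "Hex"))


class TestFacialDecode:
    def test_uninformative_motion_decodes_at_chance(self, protocol):
        fm = simulate_facial_motion(protocol, rank=4, odor_informative=False,
                                    seed=0, noise_sigma=0.1)
        odor_trials = protocol.trials_where(category="odor_only")
        res = dec.facial_decode(fm, protocol, n_pcs=20, trials=odor_trials, k=5, seed=0)
        stim = res.accuracy[dec.PopulationVectors(
            X=np.zeros((1, 1, res.accuracy.size)), y=np.array([0]),
            bin_edges_s=res.bin_edges_s, protocol=protocol,
        ).stim_bins]
        # two odors: chance 50%, binomial band for 40 trials
        assert abs(stim.mean() - 50.0) < 2 * 100 * np.sqrt(0.25 / 40) + 8.0

    def test_informative_motion_decodes_above_chance(self, protocol):
        fm = simulate_facial_motion(protocol, rank=4, odor_informative=True,
                                    seed=1, noise_sigma=0.05, odor_effect=5.0)
        odor_trials = protocol.trials_where(category="odor_only")
        res = dec.facial_decode(fm, protocol, n_pcs=20, trials=odor_trials, k=5, seed=0)
        assert res.accuracy.max() > 80.0

    def test_npcs_truncated_to_rank_with_warning(self, short_protocol):
        fm = simulate_facial_motion(short_protocol, rank=2, seed=0, n_pixels=30)
        with pytest.warns(UserWarning, match="rank"):
            dec.facial_decode(fm, short_protocol, n_pcs=500, k=2, seed=0)
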