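from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

from holdoutsampler import (
    ContractError,
    FeatureMatrix,
    GeneratorConfig,
    Holdout,
    HyperRanges,
    SamplerConfig,
    accuracy_cdf,
    accuracy_summary,
    generate_dataset,
    kfold_validate,
    load_consensus,
    make_holdouts,
    save_consensus,
    select_holdouts,
    fit_holdout,
)
from holdoutsampler.classifiers import ClassifierSpec
from holdoutsampler.sampler import ConsensusModel


def stub_holdout(index, acc_test, vote, groups=("structural",), columns=("structural.asa",)):
    """A fitted-looking holdout whose model always votes *vote*."""
    model = SimpleNamespace(
        predict=lambda X: (np.full(len(X), float(vote)), np.full(len(X), vote, dtype=int))
    )
    return Holdout(
        index=index,
        train_idx=np.arange(3),
        test_idx=np.arange(3, 4),
        groups=groups,
        spec=ClassifierSpec("rf", 10, "sigmoid", 10, 0),
        fit_seed=0,
        columns=columns,
        model=model,
        acc_train=1.0,
        acc_test=acc_test,
    )


class TestMakeHoldouts:
    def test_split_sizes_75_25(self):
        cfg = SamplerConfig(n_holdouts=100, train_frac=0.75, seed=0)
        hs = make_holdouts(1000, cfg)
        assert len(hs) == 100
        for h in hs:
            assert len(h.train_idx) == 750
            assert len(h.test_idx) == 250
            assert len(np.intersect1d(h.train_idx, h.test_idx)) == 0

    def test_same_seed_identical(self):
        cfg = SamplerConfig(n_holdouts=10, seed=4)
        h1, h2 = make_holdouts(100, cfg), make_holdouts(100, cfg)
        for a, b in zip(h1, h2):
            np.testing.assert_array_equal(a.train_idx, b.train_idx)
            assert a.groups == b.groups and a.spec == b.spec

    def test_counter_seeding_stable_under_n_holdouts(self):
        """Enlarging n_holdouts never perturbs the earlier holdouts."""
        cfg10 = SamplerConfig(n_holdouts=10, seed=4)
        cfg30 = replace(cfg10, n_holdouts=30)
        h10, h30 = make_holdouts(100, cfg10), make_holdouts(100, cfg30)
        for a, b in zip(h10, h30):
            np.testing.assert_array_equal(a.train_idx, b.train_idx)
            assert a.spec == b.spec

    def test_group_inclusion_frequency(self):
        """Each of the 6 groups lands in a subset with marginal probability
        0.5 / (1 - 2^-6) ~ 0.508 after the empty-redraw correction."""
        cfg = SamplerConfig(n_holdouts=4000, seed=1)
        hs = make_holdouts(10, cfg)
        for g in ("mutation", "stability"):
            freq = np.mean([g in h.groups for h in hs])
            assert 0.47 <= freq <= 0.55
        assert all(h.groups for h in hs)

    def test_no_groups_rejected(self):
        with pytest.raises(ContractError):
            make_holdouts(100, SamplerConfig(), attribute_groups=())


class TestFitHoldout:
    def test_separable_attribute_perfect_accuracy(self, small_matrix, fast_config):
        h = make_holdouts(small_matrix.n_samples, fast_config, ("structural",))[0]
        h = replace_spec(h, kind="rf")
        fit_holdout(h, small_matrix)
        assert h.acc_test == 1.0
        assert h.columns == ("structural.asa",)

    def test_permuted_labels_near_chance(self, fast_config):
        rng = np.random.default_rng(0)
        n = 1000
        fm = FeatureMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            X=rng.standard_normal((n, 3)),
            attribute_names=["structural.a", "structural.b", "structural.c"],
            attribute_groups={f"structural.{c}": "structural" for c in "abc"},
            labels=rng.integers(0, 2, n),
        )
        h = make_holdouts(n, fast_config, ("structural",))[0]
        h = replace_spec(h, kind="rf")
        fit_holdout(h, fm)
        assert 0.4 <= h.acc_test <= 0.6

    def test_refit_deterministic(self, small_matrix, fast_config):
        h1 = make_holdouts(small_matrix.n_samples, fast_config, small_matrix.groups_present)[0]
        h2 = make_holdouts(small_matrix.n_samples, fast_config, small_matrix.groups_present)[0]
        fit_holdout(h1, small_matrix)
        fit_holdout(h2, small_matrix)
        assert h1.acc_train == h2.acc_train
        assert h1.acc_test == h2.acc_test

    def test_single_class_bag_flagged(self, fast_config):
        n = 40
        fm = FeatureMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            X=np.random.default_rng(0).standard_normal((n, 1)),
            attribute_names=["structural.a"],
            attribute_groups={"structural.a": "structural"},
            labels=np.zeros(n, dtype=int),  # degenerate everywhere
        )
        h = make_holdouts(n, fast_config, ("structural",))[0]
        fit_holdout(h, fm)
        assert h.flagged and not h.fitted


def replace_spec(h, **kw):
    h.spec = replace(h.spec, **kw)
    return h


class TestSelection:
    def test_worked_example(self):
        hs = [stub_holdout(i, a, 1) for i, a in enumerate([0.50, 0.80, 0.95, 1.00])]
        cm = select_holdouts(hs, 0.90)
        assert sorted(h.acc_test for h in cm.selected) == [0.95, 1.00]

    def test_all_equal_all_selected(self):
        hs = [stub_holdout(i, 0.7, 1) for i in range(5)]
        assert len(select_holdouts(hs, 0.95).selected) == 5

    def test_strict_inequality_edge(self):
        hs = [stub_holdout(0, 0.90, 1), stub_holdout(1, 1.00, 1)]
        cm = select_holdouts(hs, 0.90)
        assert [h.acc_test for h in cm.selected] == [1.00]

    def test_brute_force_enumeration(self):
        """Selection reproduces {i : acc_i > tau*max} on random vectors,
        including exact-tie accuracies planted at tau*max."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            accs = np.round(rng.random(20), 3)
            tau = rng.choice([0.5, 0.9, 0.99])
            accs[0] = np.max(accs)
            accs[1] = tau * accs[0]  # exact boundary: must be excluded
            hs = [stub_holdout(i, float(a), 1) for i, a in enumerate(accs)]
            cm = select_holdouts(hs, tau)
            expected = {i for i, a in enumerate(accs) if a > tau * accs.max()}
            assert {h.index for h in cm.selected} == expected

    def test_tau_monotonicity(self):
        rng = np.random.default_rng(5)
        accs = rng.random(30)
        hs = [stub_holdout(i, float(a), 1) for i, a in enumerate(accs)]
        sizes = [len(select_holdouts(hs, t).selected) for t in (0.5, 0.7, 0.9, 0.99)]
        assert sizes == sorted(sizes, reverse=True)

    def test_all_flagged_rejected(self):
        h = stub_holdout(0, 0.5, 1)
        h.flagged = True
        with pytest.raises(ContractError, match="no valid holdouts"):
            select_holdouts([h], 0.9)


class TestConsensus:
    def data(self, n=6):
        return FeatureMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            X=np.zeros((n, 1)),
            attribute_names=["structural.asa"],
            attribute_groups={"structural.asa": "structural"},
            labels=np.zeros(n, dtype=int),
        )

    def test_single_holdout_passthrough(self):
        cm = ConsensusModel([stub_holdout(0, 0.9, 1)], 0.9)
        scores, classes = cm.predict(self.data())
        np.testing.assert_array_equal(classes, 1)

    def test_majority_arithmetic(self):
        hs = [stub_holdout(i, 0.8, v) for i, v in enumerate([1, 1, 0])]
        cm = ConsensusModel(hs, 0.9, vote_rule="majority")
        scores, classes = cm.predict(self.data())
        np.testing.assert_allclose(scores, 2 / 3)
        np.testing.assert_array_equal(classes, 1)

    def test_accuracy_weighting(self):
        hs = [stub_holdout(0, 0.9, 1), stub_holdout(1, 0.6, 0)]
        cm = ConsensusModel(hs, 0.9, vote_rule="accuracy_weighted")
        scores, _ = cm.predict(self.data())
        np.testing.assert_allclose(scores, 0.9 / 1.5)

    def test_missing_column_named(self):
        cm = ConsensusModel([stub_holdout(0, 0.9, 1, columns=("structural.gone",))], 0.9)
        with pytest.raises(ContractError, match="structural.gone"):
            cm.predict(self.data())

    def test_tie_at_threshold_is_deleterious(self):
        hs = [stub_holdout(0, 0.8, 1), stub_holdout(1, 0.8, 0)]
        cm = ConsensusModel(hs, 0.9, vote_rule="majority")
        scores, classes = cm.predict(self.data())
        np.testing.assert_allclose(scores, 0.5)
        np.testing.assert_array_equal(classes, 1)

    def test_serialization_round_trip(self, tmp_path, small_matrix, fast_config):
        hs = make_holdouts(small_matrix.n_samples, fast_config, small_matrix.groups_present)
        for h in hs:
            fit_holdout(h, small_matrix)
        cm = select_holdouts(hs, 0.9)
        s1, c1 = cm.predict(small_matrix)
        path = tmp_path / "model.joblib"
        save_consensus(cm, path)
        cm2 = load_consensus(path)
        s2, c2 = cm2.predict(small_matrix)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(c1, c2)


@pytest.fixture(scope="module")
def report_and_data():
    data, _ = generate_dataset(GeneratorConfig(n_samples=300, seed=8))
    cfg = SamplerConfig(
        n_holdouts=6, k_folds=3, seed=8,
        ranges=HyperRanges(elm_hidden=(5, 30), rf_trees=(10, 10)),
    )
    return kfold_validate(data, cfg), data, cfg


class TestKFold:

    def test_folds_partition_samples(self, report_and_data):
        report, data, _ = report_and_data
        all_blind = np.concatenate([f.blind_idx for f in report.folds])
        assert sorted(all_blind) == list(range(data.n_samples))

    def test_no_leakage_into_holdouts(self, report_and_data):
        report, _, _ = report_and_data
        for f in report.folds:
            blind = set(f.blind_idx.tolist())
            for tr, te in zip(f.holdout_train_idx, f.holdout_test_idx):
                assert blind.isdisjoint(tr.tolist())
                assert blind.isdisjoint(te.tolist())

    def test_deterministic_given_seed(self, report_and_data):
        report, data, cfg = report_and_data
        again = kfold_validate(data, cfg)
        assert report.to_dict() == again.to_dict()

    def test_class_smaller_than_k_rejected(self):
        data, _ = generate_dataset(GeneratorConfig(n_samples=30, seed=0))
        with pytest.raises(ContractError):
            kfold_validate(data, SamplerConfig(k_folds=25, n_holdouts=2))


class TestAccuracyReporting:
    def test_cdf_values(self):
        hs = [stub_holdout(0, 0.5, 1), stub_holdout(1, 1.0, 1)]
        cdf = accuracy_cdf(hs)
        vals, fracs = cdf["all"]
        np.testing.assert_array_equal(vals, [0.5, 1.0])
        np.testing.assert_array_equal(fracs, [0.5, 1.0])

    def test_cdf_monotone_ends_at_one(self):
        rng = np.random.default_rng(0)
        hs = [stub_holdout(i, float(a), 1) for i, a in enumerate(rng.random(25))]
        vals, fracs = accuracy_cdf(hs)["all"]
        assert np.all(np.diff(vals) >= 0)
        assert np.all(np.diff(fracs) > 0)
        assert fracs[-1] == 1.0

    def test_summary_quartiles_linear_interpolation(self):
        accs = [0.1, 0.2, 0.3, 0.4]
        s = accuracy_summary(accs)
        assert s["iqr"] == pytest.approx(
            np.percentile(accs, 75) - np.percentile(accs, 25)
        )
        assert s["median"] == pytest.approx(0.25)
        assert s["n"] == 4
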