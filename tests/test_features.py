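"""Conv-1 feature extraction, pooling, and detector classification."""

import numpy as np
import pytest

from epidmr import (
    ConvNetClassifier,
    classify_detectors,
    one_hot,
    one_hot_batch,
    pool_features,
    reexpress,
)
from epidmr._nnet import BatchNorm1D
from epidmr.network import NetworkSpec, build_network


def make_indicator_net(pattern: str, input_length: int, n_kernels: int = 1):
    """A fitted-looking 1-block network whose kernel 0 is an exact indicator
    of ``pattern``: activation k at a position means k matching bases."""
    spec = NetworkSpec(n_blocks=1, block1_filters=n_kernels,
                       kernel_size=len(pattern), dropout_rate=0.0,
                       dense_sizes=(4,))
    est = ConvNetClassifier(
        n_blocks=1, block1_filters=n_kernels, kernel_size=len(pattern),
        dropout_rate=0.0, dense_sizes=(4,),
    )
    est.net_ = build_network(spec, input_length, np.random.default_rng(0))
    est.input_length_ = input_length
    est.classes_ = np.array([0, 1])
    kernels = np.zeros((n_kernels, 5, len(pattern)), dtype=np.float32)
    kernels[0] = one_hot(pattern)
    est.net_.layers[0].set_kernels(kernels, np.zeros(n_kernels, dtype=np.float32))
    bn = est.net_.layers[1]
    assert isinstance(bn, BatchNorm1D)
    bn.running_mean[...] = 0.0
    bn.running_var[...] = 1.0 - bn.eps  # so the normalization is identity
    est.conv1_kernels_ = kernels
    est.n_features_ = n_kernels
    return est


class TestConv1Activations:
    def test_shape_and_nonnegativity(self, trained_net, small_Xy):
        X, _ = small_Xy
        act = trained_net.conv1_activations(X[:10])
        assert act.shape == (10, 32, X.shape[2] - 20 + 1)
        assert act.min() >= 0.0

    def test_indicator_kernel_matches_sliding_oracle(self):
        pattern = "ACGT"
        seqs = ["AAACGTAAAACGTAAAAAAACGTAa".upper()[:25]]
        net = make_indicator_net(pattern, 25)
        act = net.conv1_activations(one_hot_batch(seqs))[0, 0]
        # brute-force oracle: count of matching bases at each offset
        oracle = np.array([
            sum(seqs[0][p + j] == pattern[j] for j in range(4))
            for p in range(22)
        ])
        np.testing.assert_allclose(act, oracle, atol=1e-4)
        assert act.argmax() == seqs[0].find(pattern)


class TestPoolFeatures:
    def test_single_nonzero_entry_max(self):
        m = np.zeros((1, 8, 30))
        m[0, 7, 13] = 3.0
        v = pool_features(m, "max")
        assert v.shape == (1, 8)
        assert v[0, 7] == 3.0 and v.sum() == 3.0

    def test_constant_map_max_equals_mean(self):
        m = np.full((2, 4, 9), 1.7)
        np.testing.assert_array_equal(pool_features(m, "max"),
                                      pool_features(m, "mean"))

    def test_random_map_against_row_scan(self, rng):
        m = rng.random((1, 3, 5))
        got = pool_features(m, "max")[0]
        oracle = [max(m[0, r, c] for c in range(5)) for r in range(3)]
        np.testing.assert_allclose(got, oracle)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown pooling"):
            pool_features(np.zeros((1, 2, 3)), "median")

    def test_max_invariant_to_motif_position(self):
        # translation property: a planted pattern pools identically anywhere
        pattern = "ACGT"
        net = make_indicator_net(pattern, 30)
        vals = []
        for start in (0, 11, 26):
            seq = "T" * start + pattern + "T" * (30 - 4 - start)
            vals.append(pool_features(
                net.conv1_activations(one_hot_batch([seq])), "max")[0, 0])
        assert vals[0] == vals[1] == vals[2] == 4.0


class TestReexpress:
    def test_shape_and_order(self, trained_net, small_Xy):
        X, _ = small_Xy
        feats = reexpress(trained_net, X[:12])
        assert feats.shape == (12, 32)

    def test_duplicate_windows_identical_rows(self, trained_net, small_Xy):
        X, _ = small_Xy
        dup = np.concatenate([X[:1], X[:1]])
        feats = reexpress(trained_net, dup)
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_deterministic_across_calls(self, trained_net, small_Xy):
        X, _ = small_Xy
        np.testing.assert_array_equal(
            reexpress(trained_net, X[:6]), reexpress(trained_net, X[:6])
        )

    def test_indicator_kernel_separates_planted_motif(self):
        pattern = "ACGTA"
        net = make_indicator_net(pattern, 40)
        pos = ["T" * 10 + pattern + "T" * 25, pattern + "T" * 35]
        neg = ["C" * 40, "T" * 40]
        feats = reexpress(net, one_hot_batch(pos + neg), pooling="max")
        assert feats[:2, 0].min() > feats[2:, 0].max()


class TestClassifyDetectors:
    def test_indicator_kernel_is_dmr_detector(self):
        pattern = "ACGTA"
        net = make_indicator_net(pattern, 40, n_kernels=2)
        seqs = ["T" * 10 + pattern + "T" * 25, pattern + "T" * 35,
                "C" * 40, "G" * 40]
        X = one_hot_batch(seqs)
        y = np.array([1, 1, 0, 0])
        assignments = classify_detectors(net, X, y, pooling="max")
        by_id = {a.feature_id: a for a in assignments}
        assert by_id[0].detector_class == "DMR"
        assert by_id[0].activation_difference > 0

    def test_label_negation_flips_every_detector(self, trained_net, small_Xy):
        X, y = small_Xy
        sel = np.r_[0:30, 100:130]  # both classes (positives come first)
        a = classify_detectors(trained_net, X[sel], y[sel])
        b = classify_detectors(trained_net, X[sel], 1 - y[sel])
        flip = {"DMR": "nonDMR", "nonDMR": "DMR"}
        by_id_b = {x.feature_id: x for x in b}
        for x in a:
            other = by_id_b[x.feature_id]
            assert other.activation_difference == pytest.approx(
                -x.activation_difference, abs=1e-9
            )
            if x.activation_difference != 0:
                assert other.detector_class == flip[x.detector_class]

    def test_matches_group_mean_oracle(self, trained_net, small_Xy):
        X, y = small_Xy
        sel = np.r_[0:25, 100:125]
        Xs, ys = X[sel], y[sel]
        feats = reexpress(trained_net, Xs, pooling="mean")
        got = {a.feature_id: a.activation_difference
               for a in classify_detectors(trained_net, Xs, ys,
                                           pooling="mean")}
        for k in range(feats.shape[1]):
            oracle = feats[ys == 1, k].mean() - feats[ys == 0, k].mean()
            # float32 reduction order differs between axis-wise and
            # column-wise means
            assert got[k] == pytest.approx(oracle, abs=1e-6)

    def test_partition_covers_all_kernels(self, trained_net, small_Xy):
        X, y = small_Xy
        sel = np.r_[0:20, 100:120]
        assignments = classify_detectors(trained_net, X[sel], y[sel])
        assert sorted(a.feature_id for a in assignments) == list(range(32))
        diffs = [a.activation_difference for a in assignments]
        assert diffs == sorted(diffs, reverse=True)

    def test_single_class_rejected(self, trained_net, small_Xy):
        X, y = small_Xy
        with pytest.raises(ValueError, match="both classes"):
            classify_detectors(trained_net, X[y == 1], y[y == 1])
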