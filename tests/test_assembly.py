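import numpy as np
import pandas as pd
import pytest
from lxml import etree

from scgrn import (
    GoldStandard,
    PriorMatrix,
    RankedNetwork,
    bootstrap_indices,
    build_ranked_network,
    combine_ranks,
    combine_tasks,
    read_network,
    threshold_by_precision,
    write_network,
)


def _df(values, genes=None, tfs=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    tfs = tfs or [f"t{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=tfs)


def _net_from_list(pairs_with_conf):
    rows = [
        {"regulator": tf, "target": g, "combined_confidence": c, "sign": 1,
         "in_prior": False}
        for tf, g, c in pairs_with_conf
    ]
    return RankedNetwork(pd.DataFrame(rows))


class TestBootstrap:
    def test_vectors_have_length_n(self):
        idx = bootstrap_indices(17, 4, seed=0)
        assert len(idx) == 4
        assert all(len(v) == 17 for v in idx)

    def test_deterministic_per_seed(self):
        a = bootstrap_indices(30, 3, seed=5)
        b = bootstrap_indices(30, 3, seed=5)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_distinct_fraction_near_632(self):
        # closed-form bootstrap coverage: 1 - (1 - 1/n)^n
        n = 500
        idx = bootstrap_indices(n, 40, seed=1)
        fractions = [len(np.unique(v)) / n for v in idx]
        expected = 1 - (1 - 1 / n) ** n
        assert abs(np.mean(fractions) - expected) < 0.01


class TestCombineRanks:
    def test_single_input_preserves_order(self, rng):
        m = _df(rng.random((5, 3)))
        conf = combine_ranks([m])
        orig = m.to_numpy().ravel()
        comb = conf.to_numpy().ravel()
        assert (np.argsort(orig) == np.argsort(comb)).all()
        assert comb.min() == 0.0 and comb.max() == 1.0

    def test_reversed_orderings_cancel(self):
        # 4 edges ranked 1..4 one way and 4..1 the other: all rank sums equal
        m1 = _df([[0.1, 0.2, 0.3, 0.4]], genes=["g"], tfs=list("abcd"))
        m2 = _df([[0.4, 0.3, 0.2, 0.1]], genes=["g"], tfs=list("abcd"))
        conf = combine_ranks([m1, m2])
        assert np.allclose(conf.to_numpy(), 0.5)

    def test_invariant_under_monotone_transform(self, rng):
        m1 = _df(rng.random((6, 4)))
        m2 = _df(rng.random((6, 4)), genes=m1.index.tolist(), tfs=m1.columns.tolist())
        ref = combine_ranks([m1, m2])
        warped = combine_ranks([np.exp(3 * m1) - 0.5, m2])
        pd.testing.assert_frame_equal(ref, warped)

    def test_symmetric_in_input_order(self, rng):
        m1, m2 = _df(rng.random((4, 4))), _df(rng.random((4, 4)))
        pd.testing.assert_frame_equal(combine_ranks([m1, m2]), combine_ranks([m2, m1]))

    def test_axis_mismatch_errors(self, rng):
        m1 = _df(rng.random((3, 2)))
        m2 = _df(rng.random((2, 2)))
        with pytest.raises(ValueError, match="mismatched axes"):
            combine_ranks([m1, m2])


class TestCombineTasks:
    def test_identical_tasks_preserve_ordering(self, rng):
        m = _df(rng.random((5, 4)))
        conf = combine_tasks([m] * 11)
        assert (np.argsort(conf.to_numpy().ravel()) == np.argsort(m.to_numpy().ravel())).all()

    def test_consistently_confident_edge_outranks(self):
        # edge "a" confident in both tasks beats edge "b" confident in one
        m1 = _df([[0.9, 0.5, 0.1]], genes=["g"], tfs=list("abc"))
        m2 = _df([[0.9, 0.1, 0.5]], genes=["g"], tfs=list("abc"))
        conf = combine_tasks([m1, m2])
        assert conf.loc["g", "a"] > conf.loc["g", "b"]

    def test_output_in_unit_interval(self, rng):
        conf = combine_tasks([_df(rng.random((6, 3))) for _ in range(3)])
        v = conf.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0


class TestThresholdByPrecision:
    def _standard(self):
        return PriorMatrix(_df([[1, 0], [1, 0], [0, 0], [0, 0]],
                               genes=["g1", "g2", "g3", "g4"], tfs=["t1", "t2"]))

    def test_hit_hit_miss_miss_keeps_boundary(self):
        net = _net_from_list([
            ("t1", "g1", 0.9), ("t1", "g2", 0.8), ("t1", "g3", 0.7), ("t1", "g4", 0.6),
        ])
        kept = threshold_by_precision(net, self._standard(), 0.5)
        # terminal precision at rank 4 is exactly 0.5, so the whole list stays
        assert len(kept) == 4
        kept_strict = threshold_by_precision(net, self._standard(), 0.75)
        assert len(kept_strict) == 2

    def test_all_hits_keep_everything(self):
        net = _net_from_list([("t1", "g1", 0.9), ("t1", "g2", 0.8)])
        assert len(threshold_by_precision(net, self._standard(), 0.5)) == 2

    def test_no_hits_gives_empty_network(self):
        net = _net_from_list([("t1", "g3", 0.9), ("t1", "g4", 0.8)])
        assert len(threshold_by_precision(net, self._standard(), 0.5)) == 0

    def test_out_of_universe_edges_ride_above_cutoff(self):
        net = _net_from_list([
            ("t1", "g1", 0.9), ("tX", "gX", 0.85), ("t1", "g2", 0.8), ("t1", "g3", 0.1),
        ])
        kept = threshold_by_precision(net, self._standard(), 0.9)
        assert ("tX", "gX") in set(zip(kept.edges["regulator"], kept.edges["target"]))
        assert len(kept) == 3

    def test_entirely_outside_universe_errors(self):
        net = _net_from_list([("tX", "gX", 0.9)])
        with pytest.raises(ValueError, match="universe"):
            threshold_by_precision(net, self._standard(), 0.5)


class TestNetworkIO:
    def test_tsv_round_trip(self, tmp_path):
        net = _net_from_list([("t1", "g1", 0.9), ("t2", "g2", 0.4)])
        write_network(net, tmp_path / "net.tsv")
        back = read_network(tmp_path / "net.tsv")
        pd.testing.assert_frame_equal(back.edges, net.edges)

    def test_empty_network_writes_header_only(self, tmp_path):
        net = _net_from_list([("t1", "g1", 0.9)])
        empty = RankedNetwork(net.edges.iloc[0:0])
        write_network(empty, tmp_path / "empty.tsv")
        lines = (tmp_path / "empty.tsv").read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("regulator\ttarget")

    def test_gexf_is_well_formed_xml(self, tmp_path):
        net = _net_from_list([("t1", "g1", 0.9), ("t1", "g2", 0.5)])
        write_network(net, tmp_path / "net.gexf", fmt="gexf")
        tree = etree.parse(str(tmp_path / "net.gexf"))
        assert tree.getroot().tag.endswith("gexf")

    def test_unknown_format_errors(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_network(_net_from_list([("t", "g", 0.1)]), tmp_path / "x", fmt="dot")


class TestRankedNetworkConstruction:
    def test_zero_score_edges_excluded(self):
        conf = _df([[0.9, 0.1], [0.5, 0.2]])
        signs = _df([[1, 0], [-1, 0]])
        keep = _df([[True, False], [True, False]]).astype(bool)
        net = build_ranked_network(conf, signs, keep_mask=keep)
        assert len(net) == 2
        assert set(net.edges["regulator"]) == {"t0"}

    def test_ordering_and_tie_breaks(self):
        conf = _df([[0.5, 0.5], [0.9, 0.1]])
        signs = _df(np.ones((2, 2)))
        net = build_ranked_network(conf, signs)
        pairs = list(zip(net.edges["regulator"], net.edges["target"]))
        assert pairs[0] == ("t0", "g1")
        assert pairs[1:3] == [("t0", "g0"), ("t1", "g0")]  # tie: lexicographic

    def test_sign_never_contradicts_unanimous_coefficients(self, rng):
        from scgrn.assembly import mean_sign

        betas = [_df(rng.random((4, 3)) + 0.1) for _ in range(5)]  # all positive
        signs = mean_sign(betas)
        assert (signs.to_numpy() == 1).all()
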