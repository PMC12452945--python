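import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trufflenet.network import (
    CorrelationRecord,
    build_network,
    drop_undefined,
    fdr_adjust,
    pairwise_correlations,
)
from trufflenet.preprocess import ClrMatrix


def _clr(columns: dict) -> ClrMatrix:
    df = pd.DataFrame(columns, dtype=float)
    df.index = [f"s{i}" for i in range(len(df))]
    return ClrMatrix(df, centered=False)


def _bh_reference(pvals):
    """Independent BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, clipped."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, pvals[idx] * m / (rank + 1))
        q[idx] = running
    return q


class TestPairwiseCorrelations:
    def test_collinear(self):
        (rec,) = pairwise_correlations(_clr({"x": [1, 2, 3], "y": [2, 4, 6]}))
        assert rec.r == pytest.approx(1.0)
        assert rec.p == pytest.approx(0.0, abs=1e-12)

    def test_anti_collinear(self):
        (rec,) = pairwise_correlations(_clr({"x": [1, 2, 3], "y": [3, 2, 1]}))
        assert rec.r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        (rec,) = pairwise_correlations(_clr({"x": [1, 2, 3, 4],
                                             "y": [2, 1, 4, 3]}))
        assert rec.r == pytest.approx(0.6)

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pairwise_correlations(_clr({"x": [1, 2], "y": [2, 1]}))

    def test_zero_variance_pair_marked_undefined(self):
        recs = pairwise_correlations(
            _clr({"a": [1, 1, 1], "b": [1, 2, 3], "c": [3, 1, 2]}))
        by_pair = {(r.taxon_a, r.taxon_b): r for r in recs}
        assert not by_pair[("a", "b")].defined
        assert not by_pair[("a", "c")].defined
        assert by_pair[("b", "c")].defined
        assert len(drop_undefined(recs)) == 1

    def test_oracle_equivalence_small_matrices(self, rng):
        """r and p match the direct product-moment formula + t CDF to 1e-10
        on small random CLR matrices."""
        for n, k in [(4, 3), (6, 5), (10, 6), (5, 2)]:
            X = rng.normal(size=(n, k))
            clr = ClrMatrix(
                pd.DataFrame(X, columns=[f"t{j}" for j in range(k)],
                             index=[f"s{i}" for i in range(n)]),
                centered=False,
            )
            recs = {(r.taxon_a, r.taxon_b): r for r in pairwise_correlations(clr)}
            taxa = sorted(clr.taxa)
            for i in range(k):
                for j in range(i + 1, k):
                    x, y = clr.data[taxa[i]], clr.data[taxa[j]]
                    dx, dy = x - x.mean(), y - y.mean()
                    r_ref = (dx * dy).sum() / math.sqrt(
                        (dx**2).sum() * (dy**2).sum())
                    t_ref = r_ref * math.sqrt((n - 2) / (1 - r_ref**2))
                    p_ref = 2 * stats.t.cdf(-abs(t_ref), n - 2)
                    rec = recs[(taxa[i], taxa[j])]
                    assert rec.r == pytest.approx(r_ref, abs=1e-10)
                    assert rec.p == pytest.approx(p_ref, abs=1e-10)

    def test_implied_matrix_symmetry_and_pair_count(self, rng):
        X = rng.normal(size=(8, 6))
        clr = ClrMatrix(pd.DataFrame(X, columns=list("abcdef")),
                        centered=False)
        recs = pairwise_correlations(clr)
        assert len(recs) == 15
        assert all(r.taxon_a < r.taxon_b for r in recs)


class TestFdrAdjust:
    def _records(self, pvals):
        return [CorrelationRecord(f"a{i}", f"b{i}", 0.5, p)
                for i, p in enumerate(pvals)]

    def test_equal_spacing_vector(self):
        out = fdr_adjust(self._records([0.01, 0.02, 0.03, 0.04]))
        assert [r.q for r in out] == pytest.approx([0.04] * 4)

    def test_single_p(self):
        (out,) = fdr_adjust(self._records([0.2]))
        assert out.q == pytest.approx(0.2)

    def test_two_p_vector(self):
        out = fdr_adjust(self._records([0.005, 0.5]))
        assert [r.q for r in out] == pytest.approx([0.01, 0.5])

    def test_empty_input(self):
        assert fdr_adjust([]) == []

    def test_monotone_and_matches_reference(self, rng):
        pvals = rng.uniform(size=60)
        out = fdr_adjust(self._records(pvals))
        qs = np.array([r.q for r in out])
        np.testing.assert_allclose(qs, _bh_reference(pvals), atol=1e-12)
        order = np.argsort(pvals)
        assert (np.diff(qs[order]) >= -1e-12).all()

    def test_permutation_invariance(self, rng):
        pvals = list(rng.uniform(size=20))
        recs = self._records(pvals)
        q1 = {(r.taxon_a, r.taxon_b): r.q for r in fdr_adjust(recs)}
        perm = [recs[i] for i in rng.permutation(20)]
        q2 = {(r.taxon_a, r.taxon_b): r.q for r in fdr_adjust(perm)}
        assert q1 == pytest.approx(q2)

    def test_rejects_undefined_p(self):
        recs = self._records([0.1]) + [
            CorrelationRecord("x", "y", float("nan"), float("nan"))]
        with pytest.raises(ValueError):
            fdr_adjust(recs)


class TestBuildNetwork:
    def test_weak_r_excluded_despite_significance(self):
        net = build_network([CorrelationRecord("a", "b", 0.09, 1e-4, q=0.001)])
        assert net.n_edges == 0
        assert net.n_nodes == 2  # isolated nodes retained

    def test_negative_edge_sign(self):
        net = build_network([CorrelationRecord("a", "b", -0.5, 1e-3, q=0.01)])
        ((_, _, data),) = net.edge_records()
        assert data["sign"] == -1
        assert net.n_negative == 1

    def test_non_significant_q_excluded(self):
        net = build_network([CorrelationRecord("a", "b", 0.95, 0.1, q=0.20)])
        assert net.n_edges == 0

    def test_raw_p_flag(self):
        rec = CorrelationRecord("a", "b", 0.95, 0.01, q=0.20)
        assert build_network([rec], use_raw_p=True).n_edges == 1
        assert build_network([rec]).n_edges == 0

    def test_isolated_taxa_from_explicit_universe(self):
        net = build_network(
            [CorrelationRecord("a", "b", 0.9, 1e-5, q=1e-4)],
            taxa=["a", "b", "c", "d"],
        )
        assert net.n_nodes == 4
        assert net.n_edges == 1

    def test_unadjusted_records_rejected(self):
        with pytest.raises(ValueError, match="FDR"):
            build_network([CorrelationRecord("a", "b", 0.9, 1e-5)])
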