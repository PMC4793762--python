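import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from influnet import (
    CoexpressionEdge,
    DirectedInvestment,
    build_coexpression_network,
    build_influence_network,
    compute_influence_network,
    orient_investments,
    regression_slopes,
)
from .conftest import make_matrix, random_matrix


def vectors_with_moments(var_x, var_y, cov, n=40, seed=0):
    """Construct x, y with exact sample variance/covariance targets."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    u = rng.normal(size=n)
    x = x - x.mean()
    u = u - u.mean()
    u = u - (u @ x) / (x @ x) * x  # orthogonal to x
    x = x / np.sqrt(x @ x / (n - 1)) * np.sqrt(var_x)
    u = u / np.sqrt(u @ u / (n - 1))
    a = cov / var_x
    resid_var = var_y - a**2 * var_x
    y = a * x + np.sqrt(resid_var) * u
    return x, y


class TestRegressionSlopes:
    def test_hand_computed_slopes_and_sr(self):
        x, y = vectors_with_moments(var_x=1.0, var_y=4.0, cov=1.0)
        sp = regression_slopes(x, y)
        assert sp.b_yx == pytest.approx(1.0, abs=1e-10)
        assert sp.b_xy == pytest.approx(0.25, abs=1e-10)
        assert sp.sr == pytest.approx(0.25, abs=1e-10)

    def test_identical_vectors(self, rng):
        x = rng.normal(size=30)
        sp = regression_slopes(x, x.copy())
        assert sp.b_yx == pytest.approx(1.0) and sp.b_xy == pytest.approx(1.0)
        assert sp.sr == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_sr_in_unit_interval_and_slopes_share_sign(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        sp = regression_slopes(x, y)
        assert 0 < sp.sr <= 1
        assert np.sign(sp.b_yx) == np.sign(sp.b_xy)

    def test_zero_variance_and_zero_covariance_errors(self, rng):
        with pytest.raises(ValueError, match="variance"):
            regression_slopes(np.ones(10), rng.normal(size=10))
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])  # exactly uncorrelated
        with pytest.raises(ValueError, match="covariance"):
            regression_slopes(x, y)


def _edge(a="GA", b="GB", r_zero=0.6, r_direct=0.45):
    return CoexpressionEdge(
        gene_a=a, gene_b=b, r_zero=r_zero, r_direct=r_direct,
        r_indirect=r_zero - r_direct, p_value=0.001, conditioning_pair=("GX", "GY"),
    )


class TestOrientation:
    def test_direct_flows_from_smaller_to_larger_variance(self):
        x, y = vectors_with_moments(var_x=2.0, var_y=3.0, cov=1.0)
        oriented = orient_investments(_edge(), regression_slopes(x, y))
        assert (oriented.direct.investor, oriented.direct.target) == ("GA", "GB")
        assert oriented.direct.weight == pytest.approx(0.45)
        assert (oriented.indirect.investor, oriented.indirect.target) == ("GB", "GA")
        assert oriented.indirect.weight == pytest.approx(0.15)
        assert not oriented.tied

    def test_label_swap_swaps_directions_but_not_weights(self):
        x, y = vectors_with_moments(var_x=2.0, var_y=3.0, cov=1.0)
        fwd = orient_investments(_edge(), regression_slopes(x, y))
        # relabel so the larger-variance vector is gene_a
        rev = orient_investments(_edge(), regression_slopes(y, x))
        assert (rev.direct.investor, rev.direct.target) == ("GB", "GA")
        assert rev.direct.weight == fwd.direct.weight
        assert rev.indirect.weight == fwd.indirect.weight

    def test_exact_variance_tie_breaks_lexicographically_and_flags(self, rng):
        x = rng.normal(size=30)
        y = -x  # equal variances, |b_yx| == |b_xy| == 1
        oriented = orient_investments(_edge(), regression_slopes(x, y))
        assert oriented.tied
        assert oriented.direct.investor == "GA"  # lexicographically smaller

    def test_direct_investments_point_up_the_variance_order(self):
        # property over random structured matrices
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=(6, 120))
            base[1] += 0.7 * base[0]
            base[3] += 0.5 * base[2]
            matrix = make_matrix(np.abs(base) + 50.0)
            net = build_coexpression_network(matrix, alpha=0.9)
            if not net.edges:
                continue
            variances = dict(zip(matrix.gene_ids, matrix.values.var(axis=1, ddof=1)))
            rows = {g: matrix.values[i] for i, g in enumerate(matrix.gene_ids)}
            for e in net.edges:
                oriented = orient_investments(
                    e, regression_slopes(rows[e.gene_a], rows[e.gene_b])
                )
                if not oriented.tied:
                    assert (
                        variances[oriented.direct.investor]
                        < variances[oriented.direct.target]
                    )


class TestInfluenceNormalization:
    def test_star_graph_hand_enumeration(self):
        # A, B, C each invest only in hub D (weights 3, 2, 5); D invests back
        inv = [
            DirectedInvestment("A", "D", 3.0, "direct"),
            DirectedInvestment("B", "D", 2.0, "direct"),
            DirectedInvestment("C", "D", 5.0, "direct"),
            DirectedInvestment("D", "A", 3.0, "indirect"),
            DirectedInvestment("D", "B", 2.0, "indirect"),
            DirectedInvestment("D", "C", 5.0, "indirect"),
        ]
        net = compute_influence_network(inv)
        assert net.influences[("D", "A")] == pytest.approx(1.0)  # A's only investment
        assert net.influences[("A", "D")] == pytest.approx(0.3)  # 3 / (3 + 2 + 5)
        assert net.influences[("B", "D")] == pytest.approx(0.2)
        assert net.influences[("C", "D")] == pytest.approx(0.5)

    def test_single_investment_confers_influence_one(self):
        net = compute_influence_network([DirectedInvestment("B", "A", 0.37, "direct")])
        assert net.influences[("A", "B")] == pytest.approx(1.0)

    def test_conferred_influences_sum_to_one_per_investor_and_sign(self, rng):
        investments = []
        for k in range(40):
            investor = f"G{rng.integers(0, 8)}"
            target = f"T{k}"
            w = float(rng.normal())
            if w != 0:
                investments.append(DirectedInvestment(investor, target, w, "direct"))
        net = compute_influence_network(investments, sign_split=True)
        sums: dict = {}
        for inv in investments:
            cls = "positive" if inv.weight > 0 else "negative"
            key = (inv.investor, cls)
            sums[key] = sums.get(key, 0.0) + net.influences[(inv.target, inv.investor)]
        for total in sums.values():
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_sign_classes_normalized_separately(self):
        inv = [
            DirectedInvestment("B", "A", 0.6, "direct"),
            DirectedInvestment("B", "C", -0.2, "indirect"),
            DirectedInvestment("B", "D", 0.2, "indirect"),
        ]
        net = compute_influence_network(inv, sign_split=True)
        assert net.influences[("A", "B")] == pytest.approx(0.75)  # 0.6 / 0.8
        assert net.influences[("C", "B")] == pytest.approx(1.0)  # only negative
        assert net.sign_class[("C", "B")] == "negative"
        pooled = compute_influence_network(inv, sign_split=False)
        assert pooled.influences[("A", "B")] == pytest.approx(0.6)  # /(0.6+0.2+0.2)
        assert pooled.influences[("C", "B")] == pytest.approx(-0.2)

    def test_zero_weight_confers_zero_influence(self):
        net = compute_influence_network(
            [
                DirectedInvestment("B", "A", 0.0, "indirect"),
                DirectedInvestment("B", "C", 0.5, "direct"),
            ]
        )
        assert net.influences[("A", "B")] == 0.0
        assert net.sign_class[("A", "B")] == "zero"


class TestBuildInfluenceNetwork:
    def test_every_coexpression_pair_gets_both_orientations(self):
        matrix = random_matrix(8, 300, seed=21)
        net = build_coexpression_network(matrix, alpha=0.9)
        infl = build_influence_network(matrix, net)
        for e in net.edges:
            assert (e.gene_a, e.gene_b) in infl.influences
            assert (e.gene_b, e.gene_a) in infl.influences
        assert set(infl.pairs()) == {e.pair for e in net.edges}

    def test_sr_max_filter_drops_near_symmetric_edges(self):
        matrix = random_matrix(8, 300, seed=21)
        net = build_coexpression_network(matrix, alpha=0.9)
        full = build_influence_network(matrix, net)
        filtered = build_influence_network(matrix, net, sr_max=0.5)
        assert len(filtered.pairs()) <= len(full.pairs())
        for key in filtered.annotations:
            assert filtered.annotations[key]["sr"] <= 0.5

    def test_deterministic(self):
        matrix = random_matrix(7, 200, seed=2)
        net = build_coexpression_network(matrix, alpha=0.9)
        a = build_influence_network(matrix, net).to_frame()
        b = build_influence_network(matrix, net).to_frame()
        assert a.equals(b)

    def test_investments_local_to_their_edge(self):
        # dropping a gene outside a pair's conditioning set leaves that
        # pair's investments untouched
        matrix = random_matrix(9, 250, seed=33)
        net = build_coexpression_network(matrix, alpha=0.9)
        infl = build_influence_network(matrix, net)
        target_edge = net.edges[0]
        involved = set(target_edge.pair) | set(target_edge.conditioning_pair)
        removable = [g for g in matrix.gene_ids if g not in involved]
        drop = removable[-1]
        keep = [i for i, g in enumerate(matrix.gene_ids) if g != drop]
        from influnet import ExpressionMatrix

        sub = ExpressionMatrix(
            gene_ids=[matrix.gene_ids[i] for i in keep],
            sample_ids=list(matrix.sample_ids),
            values=matrix.values[keep],
        )
        sub_net = build_coexpression_network(sub, alpha=0.9)
        sub_edge = {e.pair: e for e in sub_net.edges}.get(target_edge.pair)
        assert sub_edge is not None
        if sub_edge.conditioning_pair == target_edge.conditioning_pair:
            assert sub_edge.r_direct == target_edge.r_direct
            rows = {g: sub.values[i] for i, g in enumerate(sub.gene_ids)}
            oriented = orient_investments(
                sub_edge, regression_slopes(rows[sub_edge.gene_a], rows[sub_edge.gene_b])
            )
            full_rows = {g: matrix.values[i] for i, g in enumerate(matrix.gene_ids)}
            oriented_full = orient_investments(
                target_edge,
                regression_slopes(full_rows[target_edge.gene_a], full_rows[target_edge.gene_b]),
            )
            assert oriented.direct == oriented_full.direct
            assert oriented.indirect == oriented_full.indirect
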