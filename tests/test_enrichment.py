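import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from migessent import (
    ContingencyTable,
    GeneList,
    SyntheticConfig,
    build_table,
    control_battery,
    enrichment_test,
    fisher_two_sided,
    fold_enrichment,
    fold_from_fractions,
    generate_essentiality,
    generate_universe,
    odds_ratio,
    per_line_essentialomes,
    test_enrichment,
    total_essentialome,
)

from _oracles import fisher_oracle
from conftest import make_universe


@st.composite
def tables(draw, max_n=200):
    N = draw(st.integers(2, max_n))
    K = draw(st.integers(0, N))
    n = draw(st.integers(0, N))
    k = draw(st.integers(max(0, n + K - N), min(n, K)))
    return ContingencyTable(N=N, K=K, n=n, k=k)


class TestContingencyTable:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ContingencyTable(N=10, K=4, n=5, k=5)
        with pytest.raises(ValueError):
            ContingencyTable(N=10, K=12, n=5, k=3)

    def test_build_table_counts_on_intersections(self, small_universe):
        # universe has 6 genes, 2 MIGs (A, C)
        query = GeneList(name="q", members=("A", "B", "D", "Z"))  # Z falls out
        t = build_table(query, small_universe.migs, small_universe)
        assert (t.N, t.K, t.n, t.k) == (6, 2, 3, 1)

    def test_feature_equal_universe_saturates(self, small_universe):
        query = GeneList(name="q", members=("A", "B"))
        feature = GeneList(name="all", members=tuple(small_universe.interrogated))
        t = build_table(query, feature, small_universe)
        assert t.k == t.n and t.K == t.N


class TestFisherTwoSided:
    def test_printed_cdg_tables_reproduce(self):
        # fully printed worked examples: 33/742 and 62/1386 MIGs vs 648/20,444
        p_human = fisher_two_sided(ContingencyTable(N=20444, K=648, n=742, k=33))
        assert p_human == pytest.approx(0.0535, abs=5e-4)
        p_all = fisher_two_sided(ContingencyTable(N=20444, K=648, n=1386, k=62))
        assert round(p_all, 4) == 0.0067

    def test_balanced_table_p_is_one(self):
        assert fisher_two_sided(ContingencyTable(N=4, K=2, n=2, k=1)) == 1.0

    def test_enumerated_small_table(self):
        # N=6, K=3, n=3: C(6,3)=20 arrangements; P(k=3)=P(k=0)=1/20 -> p = 2/20
        assert fisher_two_sided(ContingencyTable(N=6, K=3, n=3, k=3)) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("N,K,n,k", [(10, 0, 4, 0), (10, 5, 0, 0), (10, 10, 4, 4), (10, 4, 10, 4)])
    def test_degenerate_tables_return_one(self, N, K, n, k):
        assert fisher_two_sided(ContingencyTable(N=N, K=K, n=n, k=k)) == 1.0

    @given(tables())
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_scipy_and_oracle(self, t):
        """Independent cross-checks: scipy's Fisher test and integer enumeration."""
        p = fisher_two_sided(t)
        assert 0 <= p <= 1
        assert p == pytest.approx(fisher_oracle(t.N, t.K, t.n, t.k), abs=1e-10)
        assert p == pytest.approx(fisher_exact(t.as_array())[1], rel=1e-8, abs=1e-12)

    @given(tables())
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_transposition_symmetry(self, t):
        """Swapping the roles of query and feature leaves p unchanged."""
        swapped = ContingencyTable(N=t.N, K=t.n, n=t.K, k=t.k)
        assert fisher_two_sided(t) == pytest.approx(fisher_two_sided(swapped), rel=1e-12)

    def test_p_is_one_at_the_hypergeometric_mode(self):
        # mode of hypergeom(N=20, K=8, n=10) is floor((n+1)(K+1)/(N+2)) = 4
        assert fisher_two_sided(ContingencyTable(N=20, K=8, n=10, k=4)) == pytest.approx(1.0)


class TestFoldAndOddsRatio:
    def test_derived_fold(self):
        t = ContingencyTable(N=20, K=5, n=4, k=3)
        assert fold_enrichment(t) == pytest.approx(3.0)

    def test_query_equals_universe_fold_is_one(self):
        t = ContingencyTable(N=20, K=5, n=20, k=5)
        assert fold_enrichment(t) == pytest.approx(1.0)

    def test_fold_undefined_for_empty_margins(self):
        with pytest.raises(ValueError):
            fold_enrichment(ContingencyTable(N=10, K=0, n=4, k=0))

    @pytest.mark.parametrize(
        "qf,uf,expected", [(8.1, 3.4, 2.4), (9.3, 3.4, 2.7), (31.7, 9.8, 3.2), (27.5, 9.8, 2.8)]
    )
    def test_paper_style_one_decimal_folds(self, qf, uf, expected):
        assert fold_from_fractions(qf, uf) == expected

    def test_odds_ratio_matches_scipy(self):
        t = ContingencyTable(N=100, K=20, n=30, k=10)
        assert odds_ratio(t) == pytest.approx(fisher_exact(t.as_array())[0])

    def test_direction_labels(self, small_universe):
        enriched = enrichment_test(ContingencyTable(N=100, K=10, n=10, k=5))
        depleted = enrichment_test(ContingencyTable(N=100, K=50, n=10, k=1))
        assert enriched.direction == "enriched" and depleted.direction == "depleted"


class TestConventions:
    def test_excludes_query_changes_reported_background_only(self, small_universe):
        query = GeneList(name="q", members=("A", "B"))
        inc = test_enrichment(query, small_universe.migs, small_universe, "universe_includes_query")
        exc = test_enrichment(query, small_universe.migs, small_universe, "universe_excludes_query")
        assert inc.p_two_sided == exc.p_two_sided
        assert inc.universe_fraction == pytest.approx(2 / 6)
        assert exc.universe_fraction == pytest.approx(1 / 4)


class TestControlBattery:
    def test_single_feature_matches_direct_call(self, small_universe):
        query = GeneList(name="q", members=("A", "B"))
        [res] = control_battery(query, [small_universe.migs], small_universe)
        direct = test_enrichment(query, small_universe.migs, small_universe)
        assert res.p_two_sided == direct.p_two_sided and res.table == direct.table

    def test_empty_battery(self, small_universe):
        assert control_battery(GeneList(name="q", members=("A",)), [], small_universe) == []

    def test_bh_adjustment_monotone_and_bounded(self, small_universe):
        query = GeneList(name="q", members=("A", "B", "C"))
        feats = [
            small_universe.migs,
            GeneList(name="f2", members=("B", "D")),
            GeneList(name="f3", members=("E", "F")),
        ]
        results = control_battery(query, feats, small_universe, adjust=True)
        for r in results:
            assert r.p_adjusted is not None and r.p_adjusted >= r.p_two_sided - 1e-15

    def test_planted_mig_signal_detected_and_null_controls_calibrated(self):
        """Monte Carlo: the planted MIG enrichment is detected in >=95% of
        simulations while null control lists reject at no more than alpha
        (plus binomial noise)."""
        n_sims = 200
        cfg = SyntheticConfig()  # default scale: 17,000 genes, 50 lines, OR 2.5
        universe = generate_universe(cfg, seed=101)
        rng = np.random.default_rng(202)
        genes = list(universe.interrogated)
        mig_hits = 0
        control_rejections = np.zeros(4)
        control_sizes = (685, 482, 1713, 1724)  # miRNA-host/kinome/TF/cell-cycle list sizes
        for i in range(n_sims):
            matrix, _ = generate_essentiality(universe, cfg, seed=1000 + i)
            total = total_essentialome(per_line_essentialomes(matrix))
            query = GeneList(name="total", members=tuple(sorted(total.members)))
            controls = [
                GeneList(name=f"ctrl{j}", members=tuple(rng.choice(genes, size=s, replace=False)))
                for j, s in enumerate(control_sizes)
            ]
            results = control_battery(query, [universe.migs, *controls], universe)
            if results[0].p_two_sided < 0.05:
                mig_hits += 1
            control_rejections += [r.p_two_sided < 0.05 for r in results[1:]]
        assert mig_hits / n_sims >= 0.95
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert (control_rejections / n_sims <= 0.05 + 2 * se).all()
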