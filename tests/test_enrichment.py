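import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from darffc import (
    GOAnnotationTable,
    background_frequencies,
    binomial_tail_p,
    combine_targets,
    enrich_global,
    enrich_per_connection,
    target_frequencies,
)

from oracles import binom_upper_tail

MF = "molecular_function"


def table(pairs, namespace=MF):
    return GOAnnotationTable(records=[(g, t, namespace) for g, t in pairs])


class TestBackground:
    def test_redundant_counts(self):
        t = table([("g1", "GO:0000001"), ("g2", "GO:0000001"), ("g3", "GO:0000002")])
        bg = background_frequencies(t, ["g1", "g2", "g3"], MF)
        assert bg.E == 3
        assert bg.N == 2
        assert bg.F_g["GO:0000001"] == 2
        assert bg.r("GO:0000001") == pytest.approx(2 / 3)

    def test_terms_outside_effecters_excluded(self):
        t = table([("g1", "GO:0000001"), ("tf", "GO:0000009")])
        bg = background_frequencies(t, ["g1"], MF)
        assert "GO:0000009" not in bg.F_g
        assert bg.N == 1

    def test_single_shared_term(self):
        t = table([("g1", "GO:0000003")] * 4)
        bg = background_frequencies(t, ["g1"], MF)
        assert (bg.E, bg.N, bg.r("GO:0000003")) == (4, 1, 1.0)

    def test_empty_intersection_errors(self):
        t = table([("g1", "GO:0000001")])
        with pytest.raises(ValueError):
            background_frequencies(t, ["other"], MF)
        with pytest.raises(ValueError):
            background_frequencies(t, [], MF)


class TestBinomialTail:
    def test_inclusive_edge_cases(self):
        assert binomial_tail_p(0, 10, 0.3) == 1.0
        assert binomial_tail_p(10, 10, 0.3) == pytest.approx(0.3**10)

    def test_worked_example(self):
        # 1 - (0.8)^5 - 5(0.2)(0.8)^4
        assert binomial_tail_p(2, 5, 0.2) == pytest.approx(0.26272)

    def test_exclusive_flag(self):
        incl = binomial_tail_p(2, 5, 0.2, inclusive=True)
        excl = binomial_tail_p(2, 5, 0.2, inclusive=False)
        assert excl < incl
        assert excl == pytest.approx(incl - 10 * 0.2**2 * 0.8**3)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            binomial_tail_p(6, 5, 0.2)
        with pytest.raises(ValueError):
            binomial_tail_p(1, 5, 0.0)
        with pytest.raises(ValueError):
            binomial_tail_p(1, 5, 1.5)

    def test_deep_tail_stays_positive(self):
        p = binomial_tail_p(150, 2000, 0.01)
        assert 0 < p < 1e-40

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        D=st.integers(1, 50),
        f_frac=st.floats(0, 1),
        r=st.sampled_from([0.01, 0.1, 0.25, 0.5, 0.9, 1.0]),
    )
    def test_matches_direct_summation(self, D, f_frac, r):
        f = round(f_frac * D)
        assert binomial_tail_p(f, D, r) == pytest.approx(
            binom_upper_tail(f, D, r), abs=1e-12
        )

    def test_monotone_in_f_and_r(self):
        D = 30
        ps = [binomial_tail_p(f, D, 0.3) for f in range(D + 1)]
        assert all(b <= a for a, b in zip(ps, ps[1:]))
        rs = [binomial_tail_p(10, D, r) for r in (0.05, 0.1, 0.3, 0.6, 0.9)]
        assert all(b >= a for a, b in zip(rs, rs[1:]))


class TestEnrichTables:
    def _setup(self, seed=0, multiplier=6.0):
        from darffc import generate_annotations

        rng_genes = [f"g{i}" for i in range(300)]
        targets = rng_genes[:40]
        annotations, truth = generate_annotations(
            rng_genes,
            vocabulary_size=120,
            planted_terms=["GO:0000005", "GO:0000012"],
            target_genes=targets,
            multiplier=multiplier,
            seed=seed,
        )
        bg = background_frequencies(annotations, rng_genes, MF)
        tf = target_frequencies(annotations, targets, MF)
        return annotations, bg, tf, truth

    def test_planted_terms_rank_first(self):
        _, bg, tf, truth = self._setup()
        result = enrich_global(bg, tf)
        top = list(result.surviving["term"].head(4))
        for term in truth.planted_enriched_terms:
            assert term in top

    def test_low_frequency_filter_boundary(self):
        # E = 2000 via one gene with 2000 records; cutoff F_g <= 2
        pairs = [("g0", "GO:0000001")] * 1996 + [("g0", "GO:0000002")] * 2 + [
            ("g0", "GO:0000003")
        ] * 2
        t = table(pairs)
        bg = background_frequencies(t, ["g0"], MF)
        tf = target_frequencies(t, ["g0"], MF)
        result = enrich_global(bg, tf)
        flagged = result.table.set_index("term")["low_frequency"]
        assert flagged["GO:0000002"]
        assert not flagged["GO:0000001"]
        assert "GO:0000002" not in set(result.surviving["term"])

    def test_ranking_orders_by_p(self):
        _, bg, tf, _ = self._setup()
        p = enrich_global(bg, tf).surviving["P_g"].to_numpy()
        assert (np.diff(p) >= 0).all()

    def test_multiplicity_doubles_contribution(self):
        t = table([("g1", "GO:0000001"), ("g2", "GO:0000002")])
        single = target_frequencies(t, ["g1"], MF)
        double = target_frequencies(t, ["g1", "g1"], MF)
        assert double.D == 2 * single.D
        assert double.f_g["GO:0000001"] == 2 * single.f_g["GO:0000001"]

    def test_combine_targets_pools_counts(self):
        t = table([("g1", "GO:0000001"), ("g2", "GO:0000001")])
        a = target_frequencies(t, ["g1"], MF)
        b = target_frequencies(t, ["g1", "g2"], MF)
        pooled = combine_targets([a, b])
        assert pooled.D == 3
        assert pooled.f_g["GO:0000001"] == 3

    def test_per_connection_filters_and_identity(self):
        annotations, bg, _, truth = self._setup()
        genes = [f"g{i}" for i in range(40)]
        t1 = target_frequencies(annotations, genes, MF, label="c1")
        t2 = target_frequencies(annotations, genes, MF, label="c2")
        empty = target_frequencies(annotations, ["absent"], MF, label="c3")
        r1, r2, r3 = enrich_per_connection(bg, [t1, t2, empty])
        # identical target sets give identical tables
        assert r1.surviving.drop(columns=[]).equals(r2.surviving)
        # no annotated targets -> nothing survives the P filter
        assert r3.surviving.empty
        # per-connection P filter enforced
        assert (r1.surviving["P_g"] < 0.01).all()

    def test_planted_connection_only(self):
        annotations, bg, _, truth = self._setup(multiplier=10.0)
        enriched = target_frequencies(annotations, [f"g{i}" for i in range(40)], MF)
        background_only = target_frequencies(
            annotations, [f"g{i}" for i in range(200, 240)], MF
        )
        r1, r2 = enrich_per_connection(bg, [enriched, background_only])
        planted = set(truth.planted_enriched_terms)
        assert planted <= set(r1.surviving["term"])
        assert not planted & set(r2.surviving["term"])

    def test_namespace_mismatch_rejected(self):
        t = table([("g1", "GO:0000001")])
        bg = background_frequencies(t, ["g1"], MF)
        bp = target_frequencies(
            GOAnnotationTable(records=[("g1", "GO:0000001", "biological_process")]),
            ["g1"],
            "biological_process",
        )
        with pytest.raises(ValueError):
            enrich_global(bg, bp)

    def test_unplanted_terms_not_spuriously_top(self):
        """With multiplier 1 the planted terms behave like background: their
        P values are not extreme (median over seeds well above 0.1)."""
        ps = []
        for seed in range(7):
            _, bg, tf, truth = self._setup(seed=seed, multiplier=1.0)
            result = enrich_global(bg, tf)
            tab = result.table.set_index("term")
            for term in truth.planted_enriched_terms:
                if term in tab.index:
                    ps.append(tab.loc[term, "P_g"])
        assert np.median(ps) > 0.1
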