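from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from compseq import (
    ConcordanceTable,
    DEConfig,
    DifferentialExpression,
    DilutionRatioSet,
    ValidationError,
    classify_cross_extraction,
    compare_focal_tissues,
    compute_rpkm,
    dilution_ratios,
    fisher_exact_2x2,
    presence_absence_table,
    subset_analysis,
)
from compseq.quantify import RpkmMatrix
from conftest import make_model
from compseq.simulate import simulate_experiment
import oracles


def _fake_results(method, extraction, table_rows):
    """Minimal DEResults stand-in built from (gene, call, direction) rows."""
    from compseq.detest import DEResults

    class _Cfg:
        pass

    class _Model:
        pass

    model = _Model()
    model.extraction = extraction
    cfg = _Cfg()
    cfg.method = method
    model.config = cfg
    table = pd.DataFrame(
        table_rows, columns=["gene_id", "call", "direction"]
    ).set_index("gene_id")
    table["M"] = np.where(table["direction"] == "up_in_condition1", 1.0,
                          np.where(table["direction"] == "up_in_condition2", -1.0, 0.0))
    return DEResults(model, table)


class TestClassifyCrossExtraction:
    def test_categories(self):
        focal = _fake_results(
            "noiseq_like", "gland",
            [
                ("g1", "DE", "up_in_condition1"),
                ("g2", "DE", "up_in_condition1"),
                ("g3", "DE", "up_in_condition2"),
                ("g4", "not_DE", "none"),
            ],
        )
        comp = _fake_results(
            "noiseq_like", "composite",
            [
                ("g1", "not_DE", "none"),            # false-negative candidate
                ("g2", "DE", "up_in_condition2"),    # contradicted
                ("g3", "DE", "up_in_condition2"),    # concordant
            ],
        )
        tab = classify_cross_extraction(focal, comp)
        assert tab.categories == {
            "g1": "not_sig", "g2": "opposite_direction", "g3": "same_direction"
        }
        assert tab.n_focal_de == tab.n_not_sig + tab.n_same_direction + tab.n_opposite_direction

    def test_absent_gene_counts_as_not_sig(self):
        focal = _fake_results("noiseq_like", "gland", [("gX", "DE", "up_in_condition1")])
        comp = _fake_results("noiseq_like", "composite", [("gY", "not_DE", "none")])
        tab = classify_cross_extraction(focal, comp)
        assert tab.categories == {"gX": "not_sig"}

    def test_method_mismatch_rejected(self):
        focal = _fake_results("noiseq_like", "gland", [("g1", "DE", "up_in_condition1")])
        comp = _fake_results("nb_exact", "composite", [("g1", "not_DE", "none")])
        with pytest.raises(ValidationError, match="method"):
            classify_cross_extraction(focal, comp)

    def test_small_mass_fraction_yields_majority_not_sig(self):
        # 50 gland-exclusive DE genes at w=0.02: most focal-DE calls should
        # vanish in the composite (the false-negative phenomenon)
        rng = np.random.default_rng(17)
        G = 800
        lam = np.zeros((G, 2, 2))
        lam[:, 0, :] = rng.lognormal(2.5, 0.8, size=G)[:, None]
        lam[:, 1, :] = rng.lognormal(2.5, 0.8, size=G)[:, None]
        de = rng.choice(G, size=50, replace=False)
        lam[de, 1, :] = 0.0                       # gland-exclusive
        signs = rng.choice([-1.0, 1.0], size=50)
        lam[de, 0, 0] *= 2.0 ** (signs * 1.0)
        lam[de, 0, 1] *= 2.0 ** (-signs * 1.0)
        model = make_model(lam, tissues=("gland", "rest"), w=(0.02, 0.98), phi=(0.05, 0.05))
        cm = simulate_experiment(
            model, extractions=["gland", "composite"], n_replicates=2,
            depth=2_000_000, seed=17,
        )
        cfg = DEConfig(method="noiseq_like")
        focal = DifferentialExpression(cm, "gland", config=cfg).fit()
        comp = DifferentialExpression(cm, "composite", config=cfg).fit()
        tab = classify_cross_extraction(focal, comp)
        assert tab.n_focal_de > 20
        assert tab.n_not_sig / tab.n_focal_de > 0.5


class TestPresenceAbsence:
    def _rpkm(self, gland, composite):
        genes = [f"g{i}" for i in range(len(gland))]
        vals = pd.DataFrame(
            {
                "f1": gland, "f2": gland,
                "c1": composite, "c2": composite,
            },
            index=genes, dtype=float,
        )
        meta = pd.DataFrame(
            {
                "extraction": ["gland", "gland", "composite", "composite"],
                "condition": "condition1",
                "replicate": [1, 2, 1, 2],
            },
            index=vals.columns,
        )
        return RpkmMatrix(vals, meta)

    def test_sets_and_bins(self):
        rpkm = self._rpkm([15.0, 50.0, 5.0, 150.0], [5.0, 60.0, 45.0, 2.0])
        pa = presence_absence_table(rpkm, "gland", "composite", "condition1", 10.0)
        assert set(pa.focal_only) == {"g0", "g3"}
        assert set(pa.composite_only) == {"g2"}
        # g0 at 15 -> (10, 30]; g3 at 150 -> (100, 300]
        assert pa.bins_focal_only[pd.Interval(10.0, 30.0)] == 1
        assert pa.bins_focal_only[pd.Interval(100.0, 300.0)] == 1
        assert int(pa.bins_focal_only.sum()) == len(pa.focal_only)
        assert int(pa.bins_composite_only.sum()) == len(pa.composite_only)

    def test_shared_gene_in_neither_set(self):
        rpkm = self._rpkm([20.0], [30.0])
        pa = presence_absence_table(rpkm, "gland", "composite", "condition1", 10.0)
        assert not pa.focal_only and not pa.composite_only

    def test_invalid_threshold(self):
        rpkm = self._rpkm([20.0], [30.0])
        with pytest.raises(ValidationError):
            presence_absence_table(rpkm, "gland", "composite", "condition1", 0.0)

    def test_high_expression_focal_gene_can_vanish(self):
        # a highly expressed gland-exclusive gene lands in the (+,-) set with
        # focal RPKM above 100 when the composite is shallow and coarse-grained
        lam = np.full((500, 2, 2), 10.0)
        lam[0, 0, :] = 300.0
        lam[0, 1, :] = 0.0
        model = make_model(lam, w=(0.02, 0.98), phi=(0.05, 0.05))
        from compseq.simulate import HomogenizationSpec

        cm = simulate_experiment(
            model, extractions=["gland", "composite"], n_replicates=2, depth=50_000,
            homogenization=HomogenizationSpec(50), seed=0,
        )
        rpkm = compute_rpkm(cm)
        pa = presence_absence_table(rpkm, "gland", "composite", "condition1", 10.0)
        assert "g000" in pa.focal_only
        assert pa.focal_only["g000"] > 100.0


class TestDilutionRatios:
    def _rpkm(self, gland, composite):
        return TestPresenceAbsence._rpkm(self, gland, composite)

    def test_equal_expression_counts_at_or_below(self):
        rpkm = self._rpkm([50.0, 80.0], [50.0, 40.0])
        d = dilution_ratios(rpkm, "gland", "composite", "condition1", ["g0", "g1"])
        assert d.ratios["g0"] == pytest.approx(1.0)
        assert d.n_above_1 == 1 and d.n_at_or_below_1 == 1

    def test_zero_composite_is_undefined(self):
        rpkm = self._rpkm([100.0, 30.0], [0.0, 15.0])
        d = dilution_ratios(rpkm, "gland", "composite", "condition1", ["g0", "g1"])
        assert d.undefined == ("g0",)
        assert d.n_above_1 == 1 and d.n_undefined == 1
        assert d.n_above_1 + d.n_at_or_below_1 + d.n_undefined == 2

    def test_empty_gene_set_rejected(self):
        rpkm = self._rpkm([1.0], [1.0])
        with pytest.raises(ValidationError):
            dilution_ratios(rpkm, "gland", "composite", "condition1", [])

    def test_exclusive_gene_ratio_near_one_over_w(self):
        # deep sequencing, low dispersion: mean ratio ~ 1/w = 50 for a gene
        # exclusive to a w = 0.02 tissue
        lam = np.full((200, 2, 2), 10.0)
        lam[0, 0, :] = 40.0
        lam[0, 1, :] = 0.0
        model = make_model(lam, w=(0.02, 0.98), phi=(0.005, 0.005))
        ratios = []
        for seed in range(60):
            cm = simulate_experiment(
                model, extractions=["gland", "composite"], n_replicates=2,
                depth=500_000, seed=seed,
            )
            rpkm = compute_rpkm(cm)
            d = dilution_ratios(rpkm, "gland", "composite", "condition1", ["g000"])
            ratios.append(d.ratios["g000"])
        assert np.mean(ratios) == pytest.approx(50.0, rel=0.15)


class TestFisher:
    def test_maximally_null_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_enumeration_value(self):
        res = fisher_exact_2x2([[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(34 / 70, rel=1e-12)
        assert res.odds_ratio == pytest.approx(9.0)

    def test_odds_ratio_conventions(self):
        assert np.isinf(fisher_exact_2x2([[5, 0], [2, 3]]).odds_ratio)
        assert np.isnan(fisher_exact_2x2([[0, 0], [2, 3]]).odds_ratio)

    def test_exhaustive_small_margins_vs_rational_oracle(self):
        # every 2x2 table with both margins <= 12, against exact rational
        # enumeration and scipy's implementation
        for r1 in range(0, 13):
            for c1 in range(0, 13):
                n = 12
                for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                    b, c = r1 - a, c1 - a
                    d = n - r1 - c1 + a
                    if min(b, c, d) < 0 or a + b + c + d == 0:
                        continue
                    got = fisher_exact_2x2([[a, b], [c, d]]).p_value
                    want = float(oracles.fisher_p_exact(a, b, c, d))
                    assert got == pytest.approx(want, rel=1e-10), (a, b, c, d)
                    assert got == pytest.approx(
                        scipy_fisher([[a, b], [c, d]])[1], rel=1e-7, abs=1e-12
                    )

    def test_rejects_negative_cells(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @settings(deadline=None, max_examples=60)
    @given(st.tuples(*[st.integers(min_value=0, max_value=40)] * 4))
    def test_transpose_symmetry(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p1 = fisher_exact_2x2([[a, b], [c, d]]).p_value
        p2 = fisher_exact_2x2([[d, c], [b, a]]).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestCompareFocalTissues:
    def test_proportional_tables_near_null(self):
        a = ConcordanceTable.from_counts("gland", "abdomen", 40, 8, 2)
        b = ConcordanceTable.from_counts("gut", "abdomen", 80, 16, 4)
        res = compare_focal_tissues(a, b)
        assert res.p_value >= 0.99

    def test_type_mismatch_rejected(self):
        a = ConcordanceTable.from_counts("gland", "abdomen", 10, 5, 1)
        b = DilutionRatioSet.from_counts("gut", "abdomen", 10, 5)
        with pytest.raises(ValidationError):
            compare_focal_tissues(a, b)

    def test_dilution_comparison_builds_above1_table(self):
        a = DilutionRatioSet.from_counts("gland", "abdomen", 30, 10)
        b = DilutionRatioSet.from_counts("gut", "abdomen", 10, 30)
        res = compare_focal_tissues(a, b)
        assert res.table == ((30, 10), (10, 30))
        assert res.p_value < 0.001


class TestSubsetAnalysis:
    def _pair(self):
        focal = _fake_results(
            "noiseq_like", "gland",
            [
                ("g1", "DE", "up_in_condition1"),
                ("g2", "DE", "up_in_condition2"),
                ("g3", "DE", "up_in_condition1"),
            ],
        )
        comp = _fake_results(
            "noiseq_like", "composite",
            [
                ("g1", "not_DE", "none"),
                ("g2", "DE", "up_in_condition1"),
                ("g3", "DE", "up_in_condition1"),
            ],
        )
        return focal, comp

    def test_full_universe_matches_unrestricted(self):
        focal, comp = self._pair()
        full = classify_cross_extraction(focal, comp)
        sub = subset_analysis(focal, comp, ["g1", "g2", "g3"])
        assert sub.categories == full.categories

    def test_disjoint_list_gives_zero_counts(self):
        focal, comp = self._pair()
        sub = subset_analysis(focal, comp, ["g9"])
        assert sub.n_focal_de == 0 and sub.unresolved == ("g9",)

    def test_restriction_and_unresolved(self):
        focal, comp = self._pair()
        sub = subset_analysis(focal, comp, ["g2", "nope"])
        assert sub.categories == {"g2": "opposite_direction"}
        assert sub.unresolved == ("nope",)

    def test_empty_list_rejected(self):
        focal, comp = self._pair()
        with pytest.raises(ValidationError):
            subset_analysis(focal, comp, [])


class TestOppositeDirectionMechanism:
    def test_composite_follows_mass_weighted_net_effect(self):
        # up in a small tissue, down in a large one: the composite call must
        # follow the larger mass contribution (down, i.e. up_in_condition2)
        G = 300
        lam = np.full((G, 2, 2), 20.0)
        lam[0, 0, 0] = 80.0    # small tissue: up in condition1
        lam[0, 0, 1] = 20.0
        lam[0, 1, 0] = 20.0    # large tissue: down in condition1
        lam[0, 1, 1] = 80.0
        model = make_model(lam, tissues=("small", "large"), w=(0.1, 0.9), phi=(0.02, 0.02))
        cm = simulate_experiment(
            model, extractions=["small", "composite"], n_replicates=3,
            depth=1_000_000, seed=2,
        )
        cfg = DEConfig(method="noiseq_like")
        focal = DifferentialExpression(cm, "small", config=cfg).fit()
        comp = DifferentialExpression(cm, "composite", config=cfg).fit()
        assert focal.direction_of("g000") == "up_in_condition1"
        assert comp.table.at["g000", "call"] == "DE"
        assert comp.direction_of("g000") == "up_in_condition2"
        tab = classify_cross_extraction(focal, comp)
        assert tab.categories["g000"] == "opposite_direction"
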