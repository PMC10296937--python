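"""Chi-square over-introgression scan, trait-extreme selection and QTL naming."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import selintro as si
from selintro.qtlscan import (
    ScanConfig,
    assign_bin,
    chi2_overintrogression_test,
    chi2_threeclass_test,
    scan_selected_lines,
)
from selintro.simpop import (
    PedigreeConfig,
    Population,
    QtlEffect,
    TraitModel,
    simulate_bc_population,
    simulate_phenotypes,
)


class TestChi2Test:
    def test_observed_equal_expected_gives_p_one(self):
        chi2, p = chi2_overintrogression_test(2, 10, 0.2)
        assert chi2 == 0.0
        assert p == 1.0

    def test_arithmetic_oracle(self):
        # (8-1.09)^2/1.09 + (2-8.91)^2/8.91
        chi2, p = chi2_overintrogression_test(8, 10, 0.109)
        expected = (8 - 1.09) ** 2 / 1.09 + (2 - 8.91) ** 2 / 8.91
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert chi2 == pytest.approx(49.17, abs=0.01)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)

    def test_exact_binomial_option(self):
        _, p = chi2_overintrogression_test(8, 10, 0.109, exact=True)
        assert p == pytest.approx(stats.binomtest(8, 10, 0.109).pvalue, rel=1e-12)

    def test_degenerate_background_rejected(self):
        for p_bar in (0.0, 1.0):
            with pytest.raises(ValueError, match="degenerate"):
                chi2_overintrogression_test(1, 2, p_bar)

    @given(st.integers(0, 40), st.integers(0, 40))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_p_decreases_away_from_expectation(self, m1, m2):
        n, p_bar = 40, 0.3
        e = n * p_bar
        _, p1 = chi2_overintrogression_test(m1, n, p_bar)
        _, p2 = chi2_overintrogression_test(m2, n, p_bar)
        if abs(m1 - e) < abs(m2 - e):
            assert p1 >= p2

    def test_three_class_matches_scipy(self):
        counts, props = [10, 4, 6], [0.7, 0.1, 0.2]
        chi2, p = chi2_threeclass_test(counts, props)
        ref = stats.chisquare(counts, f_exp=[14, 2, 4])
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestBinNaming:
    @pytest.fixture()
    def chr12_map(self):
        return si.GeneticMap(
            ("a", "b", "c"), np.array([12, 12, 12]), np.array([0.0, 15.0, 18.0])
        )

    def test_marker_at_zero_is_bin_one(self, chr12_map):
        assert assign_bin("a", chr12_map, 10.0) == 1
        assert si.assign_bin_and_name("a", chr12_map, "ST", "ST") == "qST12.1"

    def test_paper_style_name(self, chr12_map):
        assert si.assign_bin_and_name("b", chr12_map, "GYP", "P") == "qGY12.2^P"
        assert si.assign_bin_and_name("b", chr12_map, "TGW", "N") == "qGW12.2^N"

    def test_markers_in_one_window_share_bin(self, chr12_map):
        assert assign_bin("b", chr12_map) == assign_bin("c", chr12_map) == 2

    def test_unknown_marker_rejected(self, chr12_map):
        with pytest.raises(KeyError):
            si.assign_bin_and_name("zz", chr12_map, "ST", "ST")


class TestScan:
    def test_null_rejection_rate_near_alpha(self, bc2f4_large):
        """Random selection: per-marker two-sided rejection rate ~ alpha."""
        bg = si.genome_background(bc2f4_large)
        p_bar = bg.carrier_freq
        carriers = bc2f4_large.genotypes >= 1
        rng = np.random.default_rng(17)
        n, alpha, reps = 78, 0.001, 200
        rejections, total = 0, 0
        for _ in range(reps):
            sel = rng.choice(bc2f4_large.n_lines, size=n, replace=False)
            m = carriers[sel].sum(axis=0)
            e1, e0 = n * p_bar, n * (1 - p_bar)
            chi2 = (m - e1) ** 2 / e1 + ((n - m) - e0) ** 2 / e0
            rejections += (stats.chi2.sf(chi2, 1) < alpha).sum()
            total += bc2f4_large.map.n_markers
        rate = rejections / total
        # coarse check at module level (the tight binomial-error band over
        # >= 1e5 pooled tests lives in the acceptance suite)
        assert alpha / 3 < rate < 3 * alpha

    def test_planted_qtl_detected_by_truncation_selection(self, gmap_default):
        marker = "M05_09"
        jm = gmap_default.index_of(marker)
        detected = 0
        reps = 20
        for r in range(reps):
            pop = simulate_bc_population(
                PedigreeConfig(n_lines=500, seed=5000 + r), gmap_default
            )
            model = TraitModel(
                qtl_effects=[QtlEffect("GYP", marker, 3.0, {"normal": 0.0})]
            )
            ph = simulate_phenotypes(pop, model, rng=6000 + r, check_id=None)
            means = ph[ph.treatment == "salt"].groupby("line_id")["GYP"].mean()
            top = means.nlargest(20).index.tolist()
            bg = si.genome_background(pop)
            hits = scan_selected_lines(pop, top, bg, ScanConfig())
            for h in hits:
                jh = gmap_default.index_of(h.marker_id)
                if h.chrom == 5 and abs(
                    gmap_default.pos_cM[jh] - gmap_default.pos_cM[jm]
                ) <= 10.0:
                    detected += 1
                    break
        assert detected >= 0.8 * reps

    def test_scan_invariant_to_line_order(self, bc2f4_large):
        rng = np.random.default_rng(4)
        sel = list(rng.choice(bc2f4_large.line_ids, size=40, replace=False))
        bg = si.genome_background(bc2f4_large)
        cfg = ScanConfig(alpha_scan=0.05)
        a = scan_selected_lines(bc2f4_large, sel, bg, cfg)
        b = scan_selected_lines(bc2f4_large, sel[::-1], bg, cfg)
        assert a == b

    def test_fold_enrichment_reported(self):
        gmap = si.GeneticMap(("m",), np.array([1]), np.array([0.0]))
        geno = np.array([[1]] * 8 + [[0]] * 2, dtype=np.int8)
        pop = Population(geno, gmap, tuple(f"l{i}" for i in range(10)))
        bg = si.GenomeBackground(mean_introgression=0.1, mean_het=0.008)
        hits = scan_selected_lines(pop, list(pop.line_ids), bg, ScanConfig())
        assert len(hits) == 1
        assert hits[0].fold_enrichment == pytest.approx(0.8 / 0.108)

    def test_empty_selection_rejected(self, bc2f4_large):
        bg = si.genome_background(bc2f4_large)
        with pytest.raises(ValueError, match="empty"):
            scan_selected_lines(bc2f4_large, [], bg, ScanConfig())

    def test_planted_qtls_rank_top(self, gmap_default):
        """k planted equal large-effect QTLs occupy the top-k bins by chi2."""
        markers = ["M02_05", "M06_10", "M09_03"]
        wins = 0
        reps = 10
        for r in range(reps):
            pop = simulate_bc_population(
                PedigreeConfig(n_lines=500, seed=7000 + r), gmap_default
            )
            effects = [
                QtlEffect("GYP", m, 3.0, {"normal": 0.0}) for m in markers
            ]
            ph = simulate_phenotypes(
                pop, TraitModel(qtl_effects=effects), rng=8000 + r, check_id=None
            )
            means = ph[ph.treatment == "salt"].groupby("line_id")["GYP"].mean()
            top = means.nlargest(30).index.tolist()
            bg = si.genome_background(pop)
            hits = scan_selected_lines(
                pop, top, bg, ScanConfig(alpha_scan=0.05)
            )
            # linked neighbours hitchhike, so recovery is judged at the
            # QTL-region level: walking down the chi2 ranking, the first
            # three distinct regions encountered must be the three planted
            # ones (a region = within 15 cM of a causal marker)
            def region(h):
                jh = gmap_default.index_of(h.marker_id)
                for m in markers:
                    jm = gmap_default.index_of(m)
                    if h.chrom == gmap_default.chrom[jm] and abs(
                        gmap_default.pos_cM[jh] - gmap_default.pos_cM[jm]
                    ) <= 15.0:
                        return m
                return "other"

            seen = []
            for h in sorted(hits, key=lambda x: -x.chi2):
                reg = region(h)
                if reg not in seen:
                    seen.append(reg)
                if len(seen) == 3:
                    break
            wins += set(seen) == set(markers)
        assert wins > reps / 2


class TestTraitExtremes:
    @pytest.fixture()
    def phenos(self, two_marker_map):
        pop = si.simulate_bc2f4_population(n_lines=30, gmap=two_marker_map, seed=6)
        return simulate_phenotypes(pop, TraitModel(), rng=7, check_id="CY1")

    def test_line_identical_to_check_not_selected(self):
        import pandas as pd

        rows = []
        for rep in range(1, 5):
            rows.append({"line_id": "CY1", "treatment": "normal", "rep": rep, "GYP": 20.0 + rep * 0.1})
        for rep in range(1, 3):
            rows.append({"line_id": "L1", "treatment": "normal", "rep": rep, "GYP": 20.0 + rep * 0.1})
        ph = pd.DataFrame(rows)
        assert si.select_trait_extremes(ph, "CY1", "GYP", "P") == []

    def test_strong_shift_selected(self):
        import pandas as pd

        # 10 residual sd above the check with 2 reps vs 4 check plots
        rows = [
            {"line_id": "CY1", "treatment": "normal", "rep": r, "GYP": v}
            for r, v in enumerate([19.8, 20.1, 20.0, 20.1], 1)
        ] + [
            {"line_id": "L1", "treatment": "normal", "rep": r, "GYP": v}
            for r, v in enumerate([21.5, 21.6], 1)
        ]
        ph = pd.DataFrame(rows)
        assert si.select_trait_extremes(ph, "CY1", "GYP", "P", alpha=0.01) == ["L1"]
        assert si.select_trait_extremes(ph, "CY1", "GYP", "N", alpha=0.01) == []

    def test_welch_p_matches_scipy(self, phenos):
        sub = phenos[phenos.treatment == "normal"]
        check = sub[sub.line_id == "CY1"]["GYP"].to_numpy()
        alpha = 0.01
        selected = si.select_trait_extremes(phenos, "CY1", "GYP", "P", alpha=alpha)
        for lid in selected:
            vals = sub[sub.line_id == lid]["GYP"].to_numpy()
            t, p = stats.ttest_ind(vals, check, equal_var=False)
            assert p < alpha and t > 0

    def test_direction_validation(self, phenos):
        with pytest.raises(ValueError, match="direction"):
            si.select_trait_extremes(phenos, "CY1", "GYP", "X")
        with pytest.raises(KeyError):
            si.select_trait_extremes(phenos, "CY1", "nope", "P")
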