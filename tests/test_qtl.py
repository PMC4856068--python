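import warnings

import numpy as np
import pytest

from bacumorph.qtl import (
    Marker,
    RILPanel,
    haldane_r,
    hk_lod,
    impute_genotype_probs,
    lod_support_interval,
    panel_from_csv,
    permutation_threshold,
    qtl_ld_test,
    read_genotype_csv,
    ril_expansion,
    scan,
    write_genotype_csv,
)
from bacumorph.synthetic import (
    PanelSimParams,
    PlantedQTL,
    effect_for_h2,
    generate_panel,
)


def _tiny_panel(geno, positions=None, phen=None, chrom="chr1"):
    geno = np.asarray(geno, dtype=float)
    if geno.shape[0] == 1:  # panels need >= 2 strains; pad a fully observed one
        geno = np.vstack([geno, np.zeros_like(geno[0])])
    m = geno.shape[1]
    positions = positions if positions is not None else np.arange(m) * 10.0
    markers = [Marker(f"m{j}", chrom, float(positions[j])) for j in range(m)]
    strains = [f"s{i}" for i in range(geno.shape[0])]
    phen = {"CS": np.asarray(phen, dtype=float)} if phen is not None else {}
    return RILPanel(strains=strains, markers=markers, genotypes=geno, phenotypes=phen)


class TestImputation:
    def test_observed_genotypes_stay_exact(self):
        panel = _tiny_panel([[0, 1, 0], [1, 1, 0]])
        probs = impute_genotype_probs(panel)
        assert set(np.unique(probs)) <= {0.0, 1.0}
        np.testing.assert_array_equal(probs, panel.genotypes)

    def test_midpoint_between_discordant_flanks_is_half(self):
        panel = _tiny_panel([[0, np.nan, 1]])
        probs = impute_genotype_probs(panel)
        assert probs[0, 1] == pytest.approx(0.5)

    def test_chromosome_end_copies_nearest(self):
        panel = _tiny_panel([[np.nan, 1, 0, np.nan]])
        probs = impute_genotype_probs(panel)
        assert probs[0, 0] == 1.0 and probs[0, 3] == 0.0

    def test_fully_missing_chromosome_is_half_with_warning(self):
        panel = _tiny_panel([[np.nan, np.nan, np.nan]])
        with pytest.warns(UserWarning, match="fully missing"):
            probs = impute_genotype_probs(panel)
        np.testing.assert_array_equal(probs[0], 0.5)

    def test_matches_hidden_state_enumeration(self, rng):
        """Oracle: enumerate all 2^5 homozygous state paths of the RIL chain
        and condition on the observed markers."""
        positions = np.array([0.0, 7.0, 19.0, 40.0, 55.0])
        r_star = ril_expansion(haldane_r(np.diff(positions)))
        for _ in range(20):
            geno = rng.integers(0, 2, 5).astype(float)
            missing = rng.random(5) < 0.5
            if missing.all():
                continue
            observed = geno.copy()
            observed[missing] = np.nan

            # brute-force posterior over paths
            post = np.zeros(5)
            total = 0.0
            for state in range(32):
                path = [(state >> j) & 1 for j in range(5)]
                if any(
                    not np.isnan(observed[j]) and path[j] != observed[j]
                    for j in range(5)
                ):
                    continue
                p = 0.5
                for j in range(4):
                    p *= r_star[j] if path[j] != path[j + 1] else 1 - r_star[j]
                post += p * np.array(path)
                total += p
            expected = post / total

            panel = _tiny_panel([observed], positions=positions)
            got = impute_genotype_probs(panel)[0]
            obs_idx = ~np.isnan(observed)
            np.testing.assert_allclose(got[obs_idx], expected[obs_idx], atol=1e-12)
            # interior missing markers (with flanks on both sides) match the
            # exact conditional; end runs use the nearest-value convention
            interior = np.isnan(observed)
            first, last = np.flatnonzero(obs_idx)[[0, -1]]
            interior[: first + 1] = False
            interior[last:] = False
            np.testing.assert_allclose(got[interior], expected[interior], atol=1e-9)


class TestHKLod:
    def test_constant_phenotype_gives_zero(self):
        res = hk_lod(np.array([0.0, 0, 1, 1]), np.array([2.0, 2, 2, 2]))
        assert res.lod == 0.0

    def test_worked_example(self):
        res = hk_lod(np.array([0.0, 0, 1, 1]), np.array([1.0, 1.1, 2.0, 2.1]))
        assert res.lod == pytest.approx(2 * np.log10(101), abs=1e-12)
        assert res.effect == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0 - 0.01 / 1.01)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(5, 40)
            x = rng.random(n)
            y = rng.normal(size=n)
            res = hk_lod(x, y)
            X0 = np.ones((n, 1))
            X1 = np.column_stack([np.ones(n), x])
            rss0 = np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2)
            rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2)
            assert res.lod == pytest.approx((n / 2) * np.log10(rss0 / rss1), abs=1e-9)

    def test_perfect_fit_capped(self):
        res = hk_lod(np.array([0.0, 0, 1, 1]), np.array([1.0, 1, 2, 2]))
        assert res.capped and res.lod == 300.0

    def test_monomorphic_marker_gives_zero(self):
        res = hk_lod(np.zeros(6), np.arange(6.0))
        assert res.lod == 0.0


class TestScan:
    def test_single_marker_genome_reduces_to_hk(self, rng):
        geno = rng.integers(0, 2, (20, 1)).astype(float)
        y = rng.normal(size=20)
        panel = _tiny_panel(geno, phen=y)
        res = scan(panel, "CS")
        assert res.table["lod"].iloc[0] == pytest.approx(
            hk_lod(geno[:, 0], y).lod, abs=1e-12
        )

    def test_planted_qtl_found_on_correct_chromosome(self):
        hits = 0
        for seed in range(20):
            params = PanelSimParams(
                qtl=(PlantedQTL("m3_10", effect_for_h2(0.5)),), seed=seed
            )
            panel, truth = generate_panel(params)
            res = scan(panel, "CS")
            if str(res.peak["chromosome"]) == "chr3":
                hits += 1
        assert hits >= 19

    def test_null_panel_max_lod_moderate(self):
        maxima = []
        for seed in range(10):
            panel, _ = generate_panel(PanelSimParams(seed=100 + seed))
            maxima.append(scan(panel, "CS").max_lod)
        assert all(m >= 0 for m in maxima)
        assert np.median(maxima) < 4.0

    def test_invariant_to_strain_ordering(self, rng):
        panel, _ = generate_panel(PanelSimParams(seed=9, n_strains=30))
        perm = rng.permutation(30)
        shuffled = RILPanel(
            strains=[panel.strains[i] for i in perm],
            markers=panel.markers,
            genotypes=panel.genotypes[perm],
            phenotypes={t: v[perm] for t, v in panel.phenotypes.items()},
        )
        np.testing.assert_allclose(
            scan(panel, "CS").table["lod"], scan(shuffled, "CS").table["lod"], atol=1e-9
        )

    def test_r2_lod_identity_at_peak(self):
        panel, _ = generate_panel(
            PanelSimParams(qtl=(PlantedQTL("m1_5", 1.0),), seed=2)
        )
        res = scan(panel, "CS")
        peak = res.peak
        assert peak["r_squared"] == pytest.approx(
            1 - 10 ** (-2 * peak["lod"] / res.n_strains), abs=1e-12
        )

    def test_excluding_parental_strains_drops_them(self):
        panel, _ = generate_panel(PanelSimParams(seed=3, n_strains=10))
        res = scan(panel, "CS", exclude_strains=["BXD001", "BXD002"])
        assert res.n_strains == 8

    def test_effect_estimate_unbiased(self):
        effects = []
        true_effect = effect_for_h2(0.5)
        for seed in range(200):
            params = PanelSimParams(
                qtl=(PlantedQTL("m2_10", true_effect),),
                seed=seed,
                n_strains=50,
                n_chromosomes=2,
            )
            panel, _ = generate_panel(params)
            res = scan(panel, "CS")
            row = res.table[res.table["marker"] == "m2_10"].iloc[0]
            effects.append(row["effect"] / 2.0)  # slope on P(D) = 2a
        assert abs(np.mean(effects) - true_effect) < 0.05 * true_effect


class TestPermutationThreshold:
    def test_deterministic_given_seed(self):
        panel, _ = generate_panel(PanelSimParams(seed=1))
        a = permutation_threshold(panel, "CS", n_perm=50, seed=7)
        b = permutation_threshold(panel, "CS", n_perm=50, seed=7)
        assert a.threshold == b.threshold
        np.testing.assert_array_equal(a.max_lods, b.max_lods)

    def test_lod_above_all_permutations_reports_below_one_over_n(self):
        panel, _ = generate_panel(
            PanelSimParams(qtl=(PlantedQTL("m1_10", effect_for_h2(0.6)),), seed=4)
        )
        res = scan(panel, "CS")
        perm = permutation_threshold(panel, "CS", n_perm=100, seed=0)
        assert res.max_lod > perm.max_lods.max()
        assert perm.empirical_p(res.max_lod) < 1.0 / 100
        assert perm.empirical_p(0.0) == 1.0

    def test_threshold_monotone_in_quantile(self):
        panel, _ = generate_panel(PanelSimParams(seed=5))
        th = [
            permutation_threshold(panel, "CS", n_perm=100, quantile=q, seed=3).threshold
            for q in (0.80, 0.90, 0.95, 0.99)
        ]
        assert th == sorted(th)

    def test_small_n_perm_warns(self):
        panel, _ = generate_panel(PanelSimParams(seed=6, n_strains=20))
        with pytest.warns(UserWarning, match="unstable"):
            permutation_threshold(panel, "CS", n_perm=10, seed=0)


class TestSupportInterval:
    def _scan_result(self, lods, positions=None):
        from bacumorph.qtl import ScanResult
        import pandas as pd

        positions = positions if positions is not None else np.arange(len(lods)) * 10.0
        table = pd.DataFrame(
            {
                "marker": [f"m{j}" for j in range(len(lods))],
                "chromosome": "chr1",
                "position_cm": positions,
                "lod": lods,
                "effect": 0.0,
                "r_squared": 0.0,
            }
        )
        return ScanResult(table=table, n_strains=20)

    def test_direct_reading_with_one_marker_extension(self):
        res = self._scan_result([1.0, 3.5, 5.0, 3.5, 1.0])
        lo, hi = lod_support_interval(res, "chr1")
        assert (lo, hi) == (10.0, 30.0)  # markers 2-4 (1-based)

    def test_monotone_curve_extends_to_chromosome_end(self):
        res = self._scan_result([0.0, 1.0, 2.0, 3.0, 4.0])
        lo, hi = lod_support_interval(res, "chr1")
        assert hi == 40.0

    def test_flat_curve_returns_whole_chromosome_with_warning(self):
        res = self._scan_result([2.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="flat"):
            lo, hi = lod_support_interval(res, "chr1")
        assert (lo, hi) == (0.0, 20.0)

    def test_planted_qtl_interval_covers_true_marker(self):
        covered = 0
        for seed in range(20):
            params = PanelSimParams(
                qtl=(PlantedQTL("m2_10", effect_for_h2(0.5)),), seed=300 + seed
            )
            panel, _ = generate_panel(params)
            res = scan(panel, "CS")
            true_pos = panel.markers[panel.marker_index("m2_10")].position_cm
            lo, hi = lod_support_interval(res, "chr2")
            if lo <= true_pos <= hi:
                covered += 1
        assert covered >= 18

    def test_unknown_chromosome_rejected(self):
        res = self._scan_result([1.0, 2.0, 1.0])
        with pytest.raises(KeyError):
            lod_support_interval(res, "chrX")


class TestLDTest:
    def test_perfectly_correlated_markers(self):
        geno = np.zeros((40, 2))
        geno[20:, :] = 1.0
        panel = _tiny_panel(geno)
        chi2, df, p = qtl_ld_test(panel, "m0", "m1")
        assert chi2 == pytest.approx(40.0)
        assert df == 1
        assert p == pytest.approx(2.54e-10, rel=0.05)

    def test_balanced_table_gives_zero(self):
        geno = np.array([[0, 0]] * 10 + [[0, 1]] * 10 + [[1, 0]] * 10 + [[1, 1]] * 10)
        panel = _tiny_panel(geno.astype(float))
        chi2, df, p = qtl_ld_test(panel, "m0", "m1")
        assert chi2 == 0.0 and p == 1.0

    def test_independent_markers_null(self):
        chis = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            geno = rng.integers(0, 2, (60, 2)).astype(float)
            if len(np.unique(geno[:, 0])) < 2 or len(np.unique(geno[:, 1])) < 2:
                continue
            chi2, _, _ = qtl_ld_test(_tiny_panel(geno), "m0", "m1")
            chis.append(chi2)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.5)  # chi2_1 mean = 1

    def test_monomorphic_marker_rejected(self):
        geno = np.column_stack([np.zeros(10), np.arange(10) % 2]).astype(float)
        with pytest.raises(ValueError):
            qtl_ld_test(_tiny_panel(geno), "m0", "m1")


class TestGenotypeCSV:
    def test_round_trip(self, tmp_path):
        panel, _ = generate_panel(PanelSimParams(seed=8, n_strains=6))
        write_genotype_csv(panel, tmp_path / "g.csv")
        markers, strains, geno = read_genotype_csv(tmp_path / "g.csv")
        assert strains == panel.strains
        assert [m.name for m in markers] == [m.name for m in panel.markers]
        np.testing.assert_array_equal(np.isnan(geno), np.isnan(panel.genotypes))
        ok = ~np.isnan(geno)
        np.testing.assert_array_equal(geno[ok], panel.genotypes[ok])

    def test_panel_from_csv_aligns_phenotypes(self, tmp_path):
        import pandas as pd

        panel, _ = generate_panel(PanelSimParams(seed=8, n_strains=6))
        write_genotype_csv(panel, tmp_path / "g.csv")
        pd.DataFrame(
            {"strain": panel.strains[::-1], "CS": np.arange(6.0)[::-1]}
        ).to_csv(tmp_path / "p.csv", index=False)
        loaded = panel_from_csv(tmp_path / "g.csv", tmp_path / "p.csv")
        np.testing.assert_array_equal(loaded.phenotypes["CS"], np.arange(6.0))
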