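"""Spearman scan, mixed-model association and PBS scan behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from altiscan import selection, sim
from altiscan.panel import PopulationPanel
from altiscan.stats import FrequencyTable, allele_frequencies, kinship_grm

from test_io import make_panel


def freq_table(freqs, codes):
    freqs = np.asarray(freqs, dtype=float)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(freqs.shape[0]) + 1,
            "vid": [f"v{i}" for i in range(freqs.shape[0])],
            "allele_a": "A",
            "allele_b": "G",
            "ancestral": "a",
            "cm": np.nan,
        }
    )
    return FrequencyTable(
        freqs,
        freqs * 10,
        np.full_like(freqs, 10.0),
        list(codes),
        variants,
    )


def pop_panel(codes, altitudes):
    return PopulationPanel(
        pd.DataFrame({"code": codes, "altitude_m": altitudes, "n_samples": 10})
    )


class TestSpearmanScan:
    def test_perfect_monotone_gives_rho_one(self):
        codes = [f"P{i:02d}" for i in range(10)]
        alts = np.linspace(100, 4000, 10)
        f = np.linspace(0.1, 0.9, 10)[None, :]
        out = selection.spearman_altitude_scan(freq_table(f, codes), pop_panel(codes, alts))
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert out["p_spearman"].iloc[0] == 0.0

    def test_constant_frequency_excluded(self):
        codes = [f"P{i}" for i in range(6)]
        alts = np.linspace(100, 4000, 6)
        f = np.vstack([np.full(6, 0.5), np.linspace(0.1, 0.6, 6)])
        out = selection.spearman_altitude_scan(freq_table(f, codes), pop_panel(codes, alts))
        assert np.isnan(out["rho"].iloc[0]) and np.isnan(out["p_spearman"].iloc[0])
        assert np.isfinite(out["p_spearman"].iloc[1])

    def test_t_approximation_within_2x_of_exact_permutation(self):
        """n=6 populations: t-approximate p within 2x of full 720-permutation p."""
        codes = [f"P{i}" for i in range(6)]
        alts = np.array([100.0, 500.0, 1200.0, 2100.0, 3200.0, 4400.0])
        f = np.array([[0.12, 0.31, 0.25, 0.44, 0.38, 0.61]])
        ft = freq_table(f, codes)
        pops = pop_panel(codes, alts)
        approx = selection.spearman_altitude_scan(ft, pops)["p_spearman"].iloc[0]
        exact = selection.spearman_altitude_scan(ft, pops, exact=True)["p_spearman"].iloc[0]
        # independent oracle: enumerate all 720 rank permutations
        rf = sps.rankdata(f[0])
        obs = abs(np.corrcoef(rf, sps.rankdata(alts))[0, 1])
        hits = sum(
            abs(np.corrcoef(rf, perm)[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(sps.rankdata(alts))
        )
        assert exact == pytest.approx(hits / 720)
        assert 0.5 < approx / exact < 2.0

    def test_invariant_under_monotone_altitude_transform(self):
        codes = [f"P{i:02d}" for i in range(12)]
        rng = np.random.default_rng(0)
        alts = rng.uniform(100, 4500, 12)
        f = rng.uniform(0.05, 0.95, size=(50, 12))
        ft = freq_table(f, codes)
        a = selection.spearman_altitude_scan(ft, pop_panel(codes, alts))
        b = selection.spearman_altitude_scan(ft, pop_panel(codes, np.exp(alts / 1000)))
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-12)
        np.testing.assert_allclose(a["p_spearman"], b["p_spearman"], atol=1e-12)

    def test_bonferroni_conservatism_under_null(self, null_profile):
        """Expected count of Bonferroni hits on a null panel stays at the null rate."""
        panel, truth = null_profile
        pops = truth.populations
        scan = [c for c in pops.codes if not c.startswith("EX")]
        ft = allele_frequencies(panel, scan)
        out = selection.spearman_altitude_scan(ft, pops)
        assert int(out["spearman_sig"].sum()) <= 3


class TestLmm:
    def test_identity_kinship_reproduces_ols(self):
        """With K = c·I the mixed model matches ordinary regression p-values."""
        rng = np.random.default_rng(1)
        n = 80
        panel = make_panel(rng.binomial(2, 0.4, size=(n, 200)).astype(np.int8))
        y = rng.normal(1000.0, 300.0, n)
        for c in (1.0, 3.5):
            # with K = c·I only sigma_g2*(c+delta) is identified; the fit must
            # still reproduce plain regression inference exactly
            fit = selection.lmm_fit_null(y, c * np.eye(n))
            lmm = selection.lmm_assoc_scan(panel, fit)
            ols = selection.ols_altitude_scan(panel, y)
            ok = np.isfinite(lmm["p_lmm"]) & np.isfinite(ols["p_ols"])
            dlog = np.abs(
                np.log10(lmm.loc[ok, "p_lmm"]) - np.log10(ols.loc[ok, "p_ols"])
            )
            assert dlog.max() < 0.1

    def test_generative_heritability_recovery(self, small_structured):
        """A structure-loaded phenotype is assigned > 0.9 variance; noise < 0.2."""
        panel, truth = small_structured
        k = kinship_grm(panel)
        rng = np.random.default_rng(3)
        # pure genetic effect: phenotype follows population structure (the
        # use-case: residence altitude assigned by population)
        y_gen = truth.populations.sample_altitudes(panel)
        fit = selection.lmm_fit_null(y_gen, k)
        assert fit.heritability > 0.9
        y_noise = rng.normal(size=panel.n_samples)
        fit2 = selection.lmm_fit_null(y_noise, k)
        assert fit2.heritability < 0.2

    def test_genomic_control_calibration(self, null_lmm):
        """LMM lambda_GC in [0.85, 1.15] on the null profile; naive OLS > 1.5."""
        lam = selection.genomic_inflation(null_lmm["p_lmm"])
        lam_ols = selection.genomic_inflation(null_lmm["p_ols"])
        assert 0.85 <= lam <= 1.15
        assert lam_ols > 1.5

    def test_null_pvalues_uniform_in_identity_limit(self):
        rng = np.random.default_rng(5)
        n = 60
        panel = make_panel(rng.binomial(2, 0.5, size=(n, 2_000)).astype(np.int8))
        y = rng.normal(0.0, 1.0, n)
        fit = selection.lmm_fit_null(y, np.eye(n))
        p = selection.lmm_assoc_scan(panel, fit)["p_lmm"].dropna()
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_strongly_coupled_locus_reaches_genome_wide_significance(self):
        """A locus with strong altitude coupling passes 5e-8 in >= 50% of replicates."""
        hits, total = 0, 0
        for seed in (42, 43, 44):
            cfg = sim.SimConfig(seed=seed, fraction_selected=0.0005,
                                selection_slope=0.25, n_variants=10_000)
            panel, truth = sim.simulate_balding_nichols(cfg)
            pops = truth.populations
            scan = [c for c in pops.codes if not c.startswith("EX")]
            idx = np.concatenate([panel.population_indices(c) for c in scan])
            sub = panel.subset(sample_idx=idx)
            fit = selection.lmm_fit_null(
                pops.sample_altitudes(sub), kinship_grm(sub)
            )
            lmm = selection.lmm_assoc_scan(sub, fit)
            vid = dict(zip(sub.variants["vid"], lmm["p_lmm"]))
            for v in truth.selected:
                hits += vid[v] < 5e-8
                total += 1
        assert hits / total >= 0.5


class TestPbsScan:
    def test_empirical_threshold_order_statistics(self, null_profile):
        """20,000 variants -> ceil(20,000 x 1e-4) = 2 variants flagged (ties kept)."""
        panel, truth = null_profile
        h = np.concatenate(
            [panel.population_indices(c) for c in truth.populations.high_altitude_codes()]
        )
        out = selection.pbs_scan(
            panel, h, panel.population_indices("EXC"), panel.population_indices("EXO")
        )
        n_finite = int(np.isfinite(out["pbs"]).sum())
        expected = int(np.ceil(n_finite * 1e-4))
        assert int(out["pbs_sig"].sum()) >= expected
        # the empirical threshold is positive, so zero-PBS variants
        # (e.g. identical frequencies in H, C and O) are never flagged
        assert out["pbs_threshold"].iloc[0] > 0
        # without ties at the threshold, exactly the top-k are flagged
        vals = np.sort(out.loc[np.isfinite(out["pbs"]), "pbs"].to_numpy())
        if vals[-expected] > vals[-expected - 1]:
            assert int(out["pbs_sig"].sum()) == expected

    def test_threshold_monotone_in_percentile(self, null_profile):
        panel, truth = null_profile
        h = np.concatenate(
            [panel.population_indices(c) for c in truth.populations.high_altitude_codes()]
        )
        c = panel.population_indices("EXC")
        o = panel.population_indices("EXO")
        thr = [
            selection.pbs_scan(panel, h, c, o, percentile=p)["pbs_threshold"].iloc[0]
            for p in (99.0, 99.9, 99.99)
        ]
        assert thr[0] <= thr[1] <= thr[2]

    def test_identical_groups_give_zero_pbs(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.5, size=(30, 50)).astype(np.int8)
        panel = make_panel(np.vstack([g, g, g]), pops=["H"] * 30 + ["C"] * 30 + ["O"] * 30)
        with pytest.warns(UserWarning, match="unstable"):
            out = selection.pbs_scan(
                panel,
                panel.population_indices("H"),
                panel.population_indices("C"),
                panel.population_indices("O"),
            )
        # identical genotype vectors in all groups: FSTs <= 0, PBS clamps to 0
        assert np.nanmax(np.abs(out["pbs"])) == pytest.approx(0.0, abs=1e-12)

    def test_overlapping_groups_rejected(self, null_profile):
        panel, _ = null_profile
        idx = panel.population_indices("EXC")
        with pytest.raises(ValueError, match="disjoint"):
            selection.pbs_scan(panel, idx, idx, panel.population_indices("EXO"))
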