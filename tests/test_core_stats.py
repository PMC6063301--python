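"""Frequency, FST, PBS, kinship and r² primitives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from altiscan import sim
from altiscan.panel import MISSING, GenotypePanel
from altiscan.stats import (
    allele_frequencies,
    genotype_counts,
    genotype_r2,
    kinship_grm,
    pairwise_r2,
    pbs,
    weir_cockerham_fst,
)

from test_io import make_panel


# --------------------------------------------------------------------------
# allele frequencies
# --------------------------------------------------------------------------
class TestAlleleFrequencies:
    def test_counting_and_polarization(self):
        geno = np.array([[0], [0], [1], [2]], dtype=np.int8)
        panel = make_panel(geno)
        ft = allele_frequencies(panel, ["POP"])
        assert ft.freq[0, 0] == pytest.approx(3 / 8)
        # ancestral = allele_b flips the derived orientation
        flipped = make_panel(geno)
        flipped.variants["ancestral"] = "b"
        ft2 = allele_frequencies(flipped, ["POP"])
        assert ft2.freq[0, 0] == pytest.approx(1 - 3 / 8)
        # unknown ancestral state -> NaN in polarized mode
        unk = make_panel(geno)
        unk.variants["ancestral"] = "unknown"
        assert np.isnan(allele_frequencies(unk, ["POP"]).freq[0, 0])

    def test_all_missing_population_yields_nan(self):
        geno = np.array([[0, MISSING], [1, MISSING], [MISSING, 0], [2, 1]], dtype=np.int8)
        panel = make_panel(geno, pops=["A", "A", "B", "B"])
        ft = allele_frequencies(panel, ["A", "B"])
        assert np.isnan(ft.freq[1, 0])
        assert ft.freq[1, 1] == pytest.approx(1 / 4)
        assert ft.freq[0, 0] == pytest.approx(1 / 4)


# --------------------------------------------------------------------------
# Weir & Cockerham FST
# --------------------------------------------------------------------------
def wc_component_oracle(c1, c2):
    """Spreadsheet-style scalar evaluation of the W&C (1984) components a, b, c."""
    n1, n2 = sum(c1), sum(c2)
    p1 = (2 * c1[2] + c1[1]) / (2 * n1)
    p2 = (2 * c2[2] + c2[1]) / (2 * n2)
    h1, h2 = c1[1] / n1, c2[1] / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


class TestWeirCockerham:
    def test_matches_componentwise_oracle_on_random_counts(self):
        """100 random genotype-count configurations agree with the oracle to 1e-10."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            c1 = rng.integers(0, 30, 3)
            c2 = rng.integers(0, 30, 3)
            if c1.sum() < 2 or c2.sum() < 2:
                continue
            got = weir_cockerham_fst(c1[None, :], c2[None, :]).fst[0]
            want = wc_component_oracle(c1, c2)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)
            checked += 1

    def test_fixed_difference_approaches_one(self):
        c1 = np.array([[0, 0, 50]])
        c2 = np.array([[50, 0, 0]])
        assert weir_cockerham_fst(c1, c2).fst[0] > 0.98

    def test_identical_counts_nonpositive(self):
        c = np.array([[10, 20, 10]])
        assert weir_cockerham_fst(c, c).fst[0] <= 0

    def test_monomorphic_pair_is_nan_not_zero(self):
        c = np.array([[10, 0, 0]])
        assert np.isnan(weir_cockerham_fst(c, c).fst[0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 40)] * 6))
    def test_symmetric_in_population_order(self, counts):
        c1 = np.array([counts[:3]])
        c2 = np.array([counts[3:]])
        if c1.sum() < 2 or c2.sum() < 2:
            return
        f12 = weir_cockerham_fst(c1, c2).fst[0]
        f21 = weir_cockerham_fst(c2, c1).fst[0]
        assert (np.isnan(f12) and np.isnan(f21)) or f12 == pytest.approx(f21, abs=1e-12)

    def test_mean_fst_tracks_drift_expectation(self, small_structured):
        """Mean per-variant FST within 15% of the Balding–Nichols expectation."""
        panel, truth = small_structured
        g1 = genotype_counts(panel, panel.population_indices("P01"))
        g2 = genotype_counts(panel, panel.population_indices("P02"))
        pf = weir_cockerham_fst(g1, g2)
        # two populations each drifted with F: the W&C theta estimates F;
        # the multi-locus estimate is the variance-component ratio of sums
        multi_locus = np.nansum(pf.a) / np.nansum(pf.denom)
        assert multi_locus == pytest.approx(0.15, rel=0.15)


# --------------------------------------------------------------------------
# PBS
# --------------------------------------------------------------------------
class TestPbs:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.0, 0.0, 0.0), 0.0),
            ((0.1, 0.1, 0.1), -np.log(0.9) / 2),
            ((0.15, 0.20, 0.10), (0.162519 + 0.223144 - 0.105361) / 2),
        ],
    )
    def test_closed_forms(self, triple, expected):
        got = pbs(*[np.array([v]) for v in triple]).pbs[0]
        assert got == pytest.approx(expected, abs=1e-6)

    def test_missing_fst_propagates(self):
        out = pbs(np.array([np.nan]), np.array([0.1]), np.array([0.1]))
        assert np.isnan(out.pbs[0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(0.0, 0.95)] * 3))
    def test_role_rotation_reconstructs_branches(self, fsts):
        """Rotating the focal role recovers all three branch lengths exactly."""
        f_hc, f_ho, f_co = fsts
        t = lambda f: -np.log1p(-min(f, 1 - 1e-12))
        b_h = pbs(np.r_[f_hc], np.r_[f_ho], np.r_[f_co]).pbs[0]
        b_c = pbs(np.r_[f_hc], np.r_[f_co], np.r_[f_ho]).pbs[0]
        b_o = pbs(np.r_[f_ho], np.r_[f_co], np.r_[f_hc]).pbs[0]
        assert b_h + b_c == pytest.approx(t(f_hc), abs=1e-9)
        assert b_h + b_o == pytest.approx(t(f_ho), abs=1e-9)
        assert b_c + b_o == pytest.approx(t(f_co), abs=1e-9)


# --------------------------------------------------------------------------
# kinship
# --------------------------------------------------------------------------
class TestKinship:
    def test_duplicate_sample_matches_diagonal(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, rng.uniform(0.1, 0.9, 2_000), size=(10, 2_000)).astype(np.int8)
        g = np.vstack([g, g[0:1]])
        panel = make_panel(g)
        k = kinship_grm(panel)
        assert k[0, -1] / k[0, 0] > 0.95

    def test_panmictic_panel_properties(self):
        # off-diagonal bias from sample-frequency centring is -1/(n-1),
        # so n must be large enough for the near-zero check
        cfg = sim.SimConfig(n_populations=1, n_samples=150, drift_f=0.01,
                            n_variants=5_000, fraction_selected=0.0,
                            external_references=False, seed=4)
        panel, _ = sim.simulate_balding_nichols(cfg)
        k = kinship_grm(panel)
        off = k[np.triu_indices_from(k, k=1)]
        assert abs(off.mean()) < 0.01
        assert np.diag(k).mean() == pytest.approx(1.0, abs=0.05)

    def test_structured_panel_within_exceeds_between(self, small_structured):
        panel, _ = small_structured
        k = kinship_grm(panel)
        i1 = panel.population_indices("P01")
        i2 = panel.population_indices("P02")
        within = np.concatenate(
            [k[np.ix_(i1, i1)][np.triu_indices(i1.size, 1)],
             k[np.ix_(i2, i2)][np.triu_indices(i2.size, 1)]]
        ).mean()
        between = k[np.ix_(i1, i2)].mean()
        assert within > between


# --------------------------------------------------------------------------
# genotype r²
# --------------------------------------------------------------------------
class TestGenotypeR2:
    def test_identity_and_sign_invariance(self):
        g = np.array([0, 1, 2, 0, 1, 2])
        assert genotype_r2(g, g) == pytest.approx(1.0)
        assert genotype_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_computed_pearson_squared(self):
        g1 = np.array([0, 1, 2, 0])
        g2 = np.array([0, 1, 1, 1])
        # by hand: cov=0.1875, var1=0.6875, var2=0.1875 -> r2 = 0.1875/0.6875
        expected = 0.1875**2 / (0.6875 * 0.1875)
        assert genotype_r2(g1, g2) == pytest.approx(expected)

    def test_constant_vector_undefined(self):
        assert np.isnan(genotype_r2(np.array([1, 1, 1]), np.array([0, 1, 2])))

    def test_pairwise_matrix_matches_scalar_with_missing(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        g[rng.random(g.shape) < 0.15] = MISSING
        mat = pairwise_r2(g)
        for i in range(6):
            for j in range(i + 1, 6):
                want = genotype_r2(g[:, i], g[:, j])
                if np.isnan(want):
                    assert np.isnan(mat[i, j])
                else:
                    assert mat[i, j] == pytest.approx(want, abs=1e-12)
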