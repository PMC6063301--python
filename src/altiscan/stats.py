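"""Frequency, FST, PBS, kinship and LD primitives.

These are the shared building blocks of the selection scan and the
demographic analyses: per-population derived-allele frequencies, the
Weir & Cockerham (1984) two-population FST estimator computed from genotype
counts, the Population Branch Statistic, the genomic relationship (kinship)
matrix, and genotype-dosage r².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from altiscan.panel import MISSING, GenotypePanel, PopulationPanel

__all__ = [
    "FrequencyTable",
    "PairwiseFst",
    "PbsValue",
    "allele_frequencies",
    "genotype_counts",
    "weir_cockerham_fst",
    "pbs",
    "kinship_grm",
    "genotype_r2",
    "pairwise_r2",
]


# --------------------------------------------------------------------------
# allele frequencies
# --------------------------------------------------------------------------
@dataclass
class FrequencyTable:
    """Per-variant × per-population derived (or allele-b) frequencies.

    Attributes
    ----------
    freq : ndarray, shape (n_variants, n_populations)
        Allele frequency; NaN where undefined (no genotyped samples, or
        unknown ancestral state in polarized mode).
    derived_count : ndarray
        Derived (or allele-b) allele counts.
    total_count : ndarray
        Total called allele counts (2 × genotyped samples).
    populations : list of str
    variants : DataFrame
        The variant table the rows refer to.
    polarized : bool
        True when frequencies refer to the derived allele.
    """

    freq: np.ndarray
    derived_count: np.ndarray
    total_count: np.ndarray
    populations: list[str]
    variants: pd.DataFrame = field(repr=False)
    polarized: bool = True

    @property
    def n_variants(self) -> int:
        return self.freq.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table with columns ``chrom pos vid pop freq``."""
        v = self.variants
        frames = []
        for j, pop in enumerate(self.populations):
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": v["chrom"],
                        "pos": v["pos"],
                        "vid": v["vid"],
                        "pop": pop,
                        "freq": self.freq[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def allele_frequencies(
    panel: GenotypePanel,
    populations: PopulationPanel | Sequence[str],
    polarized: bool = True,
) -> FrequencyTable:
    """Per-population allele frequencies, optionally polarized to the derived allele.

    Frequency = derived allele count / (2 × non-missing genotyped samples).
    With ``polarized=True``, variants whose ancestral allele is unknown get
    NaN frequencies everywhere; where the ancestral allele is ``allele_b``
    the count orientation is flipped.
    """
    codes = list(populations.codes) if isinstance(populations, PopulationPanel) else list(populations)
    if not codes:
        raise ValueError("at least one population required")
    g = panel.genotypes
    miss = g == MISSING
    n_var = panel.n_variants
    freq = np.full((n_var, len(codes)), np.nan)
    dcount = np.zeros((n_var, len(codes)))
    total = np.zeros((n_var, len(codes)))
    anc = panel.variants["ancestral"].to_numpy()
    for j, code in enumerate(codes):
        idx = panel.population_indices(code)
        if idx.size == 0:
            raise ValueError(f"population {code!r} has no samples in panel")
        sub = g[idx]
        called = ~miss[idx]
        tot = 2.0 * called.sum(axis=0)
        b_count = np.where(called, sub, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, b_count / np.maximum(tot, 1), np.nan)
        f = np.where(tot > 0, f, np.nan)
        if polarized:
            flip = anc == "b"
            f = np.where(flip, 1.0 - f, f)
            b_count = np.where(flip, tot - b_count, b_count)
            f = np.where(anc == "unknown", np.nan, f)
        freq[:, j] = f
        dcount[:, j] = b_count
        total[:, j] = tot
    return FrequencyTable(freq, dcount, total, codes, panel.variants, polarized)


def genotype_counts(panel: GenotypePanel, sample_idx: np.ndarray) -> np.ndarray:
    """Genotype counts (n_aa, n_ab, n_bb) per variant for a sample subset."""
    g = panel.genotypes[np.asarray(sample_idx)]
    return np.stack([(g == 0).sum(axis=0), (g == 1).sum(axis=0), (g == 2).sum(axis=0)], axis=1)


# --------------------------------------------------------------------------
# Weir & Cockerham FST
# --------------------------------------------------------------------------
@dataclass
class PairwiseFst:
    """Per-variant Weir & Cockerham (1984) FST components for one population pair.

    ``a`` is the among-population variance component (the numerator) and
    ``denom = a + b + c``; ``fst = a / denom``, NaN where the denominator is
    zero (monomorphic in both populations) or sample sizes are too small.
    """

    a: np.ndarray
    denom: np.ndarray
    fst: np.ndarray
    pair: tuple[str, str] = ("pop1", "pop2")


def weir_cockerham_fst(
    counts_pop1: np.ndarray,
    counts_pop2: np.ndarray,
    pair: tuple[str, str] = ("pop1", "pop2"),
) -> PairwiseFst:
    """Per-variant two-population Weir & Cockerham (1984) FST from genotype counts.

    Parameters
    ----------
    counts_pop1, counts_pop2 : ndarray, shape (n_variants, 3)
        Genotype counts ``(n_aa, n_ab, n_bb)`` per variant.

    Notes
    -----
    The estimator uses the observed heterozygote proportion (no HWE
    assumption). FST is the ratio ``a / (a + b + c)`` of the variance
    components; it is undefined (NaN) where both populations are
    monomorphic for the same allele or either has fewer than two genotyped
    samples, and may be negative for undifferentiated pairs (estimator
    noise) — negative values are preserved here and clamped only inside
    :func:`pbs`.
    """
    c1 = np.atleast_2d(np.asarray(counts_pop1, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts_pop2, dtype=float))
    if c1.shape != c2.shape or c1.shape[1] != 3:
        raise ValueError("counts must be (n_variants, 3) arrays of equal shape")
    n1 = c1.sum(axis=1)
    n2 = c2.sum(axis=1)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (2 * c1[:, 2] + c1[:, 1]) / (2 * n1)
        p2 = (2 * c2[:, 2] + c2[:, 1]) / (2 * n2)
        h1 = c1[:, 1] / n1
        h2 = c2[:, 1] / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where((denom != 0) & ok, a / np.where(denom == 0, np.nan, denom), np.nan)
    a = np.where(ok, a, np.nan)
    denom = np.where(ok, denom, np.nan)
    fst = np.where(denom == 0, np.nan, fst)
    return PairwiseFst(a=a, denom=denom, fst=fst, pair=pair)


# --------------------------------------------------------------------------
# Population Branch Statistic
# --------------------------------------------------------------------------
@dataclass
class PbsValue:
    """Per-variant PBS and the branch-transformed FST values it is built from.

    ``t_* = -ln(1 - FST)`` for the (H,C), (H,O), (C,O) pairs and
    ``pbs = (t_hc + t_ho - t_co) / 2``; H is the high-altitude focal group,
    C the closest lowland reference, O the outgroup reference.
    """

    t_hc: np.ndarray
    t_ho: np.ndarray
    t_co: np.ndarray
    pbs: np.ndarray


_FST_CEIL = 1.0 - 1e-12


def pbs(fst_hc: np.ndarray, fst_ho: np.ndarray, fst_co: np.ndarray) -> PbsValue:
    """Population Branch Statistic per variant from three pairwise FSTs.

    FST values are clamped into [0, 1 - 1e-12] before the log transform;
    any missing (NaN) FST propagates to a missing PBS.
    """
    ts = []
    for f in (fst_hc, fst_ho, fst_co):
        f = np.asarray(f, dtype=float)
        t = -np.log1p(-np.clip(f, 0.0, _FST_CEIL))
        t = np.where(np.isnan(f), np.nan, t)
        ts.append(t)
    t_hc, t_ho, t_co = ts
    value = (t_hc + t_ho - t_co) / 2.0
    return PbsValue(t_hc=t_hc, t_ho=t_ho, t_co=t_co, pbs=value)


# --------------------------------------------------------------------------
# kinship
# --------------------------------------------------------------------------
def kinship_grm(panel: GenotypePanel) -> np.ndarray:
    """Genomic relationship matrix K = Z Zᵀ / m from standardized genotypes.

    Genotypes are centred by 2p̂ and scaled by sqrt(2p̂(1-p̂)) per variant
    (p̂ = sample allele-b frequency); missing genotypes are mean-imputed
    before standardization; monomorphic variants are excluded.
    """
    if panel.n_samples < 2:
        raise ValueError("kinship requires at least two samples")
    g = panel.genotypes.astype(float)
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("no polymorphic variants for kinship estimation")
    g = g[:, keep]
    p = p[keep]
    mean = 2.0 * p
    g = np.where(np.isnan(g), mean, g)
    z = (g - mean) / np.sqrt(2.0 * p * (1.0 - p))
    return (z @ z.T) / z.shape[1]


# --------------------------------------------------------------------------
# LD r²
# --------------------------------------------------------------------------
def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype-dosage vectors.

    Computed over samples with complete calls for both variants; NaN when
    fewer than two complete pairs remain or either vector is constant.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING) & np.isfinite(g1) & np.isfinite(g2)
    x, y = g1[ok], g2[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pairwise_r2(genotypes: np.ndarray) -> np.ndarray:
    """All-pairs genotype r² matrix (variants × variants), missing-aware.

    ``genotypes`` is (samples × variants) with :data:`MISSING` for no-calls.
    Each entry uses samples complete for both variants; entries with < 2
    complete pairs or zero variance are NaN.
    """
    g = np.asarray(genotypes, dtype=float)
    m = (g != MISSING).astype(float)
    a = np.where(m > 0, g, 0.0)
    n = m.T @ m
    sx = a.T @ m
    sxy = a.T @ a
    sxx = (a * a).T @ m
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        r2 = cov**2 / (varx * varx.T)
        r2 = np.where((n >= 2) & (varx > 0) & (varx.T > 0), r2, np.nan)
    return r2
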