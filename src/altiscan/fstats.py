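"""f3 and D statistics with block jackknife, and the Mantel test.

Frequency-based estimators on diploid panels:

* admixture f3(C; A, B) = mean over SNPs of (c-a)(c-b) minus the target's
  finite-sample heterozygosity correction c(1-c)/(2n_c - 1); significantly
  negative values (Z <= -3) indicate the target is admixed between sources
  related to A and B;
* outgroup f3(O; X, Ref) = mean (o-x)(o-ref), measuring shared drift;
* D(W, X; Y, Z) = Σ(w-x)(y-z) / Σ(w+x-2wx)(y+z-2yz), a four-population
  treeness test; |Z| >= 4 counts as significant gene flow.

Standard errors come from a weighted delete-one block jackknife over
contiguous 500-SNP blocks in genome order. The Mantel test permutes the
rows/columns of one distance matrix jointly and reports a two-sided
permutation p with the +1 correction.

By convention, only populations with at least six samples should enter
these statistics (:data:`MIN_SAMPLES_FSTATS`).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FStatResult",
    "DEFAULT_BLOCK_SNPS",
    "MIN_SAMPLES_FSTATS",
    "assign_blocks",
    "block_jackknife",
    "f3_admixture",
    "f3_outgroup",
    "d_statistic",
    "mantel_test",
]

#: Contiguous SNPs per jackknife block.
DEFAULT_BLOCK_SNPS = 500
#: Minimum population sample size for f3/D statistics.
MIN_SAMPLES_FSTATS = 6
#: |Z| at or above which a D statistic counts as significant gene flow.
D_SIG_Z = 4.0
#: Z at or below which an admixture f3 counts as an admixture signal.
F3_ADMIXTURE_Z = -3.0


@dataclass
class FStatResult:
    """An f3/D estimate with its block-jackknife uncertainty."""

    value: float
    se: float
    z: float
    n_blocks: int
    n_snps_used: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FStatResult(value={self.value:.6g}, se={self.se:.3g}, "
            f"z={self.z:.2f}, blocks={self.n_blocks}, snps={self.n_snps_used})"
        )


def assign_blocks(n_snps: int, block_snps: int = DEFAULT_BLOCK_SNPS) -> np.ndarray:
    """Block index per SNP: contiguous runs of *block_snps* in genome order."""
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    return np.arange(n_snps) // block_snps


def _jackknife_from_loo(
    theta_hat: float, theta_loo: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Weighted delete-one jackknife estimate and SE (Busing et al. 1999)."""
    w = np.asarray(weights, dtype=float)
    loo = np.asarray(theta_loo, dtype=float)
    g = w.size
    if g < 2:
        raise ValueError("jackknife needs at least two blocks")
    n = w.sum()
    h = n / w
    theta_j = g * theta_hat - ((1.0 - w / n) * loo).sum()
    pseudo = h * theta_hat - (h - 1.0) * loo
    var = ((pseudo - theta_j) ** 2 / (h - 1.0)).sum() / g
    return float(theta_j), float(math.sqrt(max(var, 0.0)))


def block_jackknife(
    per_block_values: np.ndarray, per_block_weights: np.ndarray
) -> tuple[float, float]:
    """Weighted block-jackknife mean and standard error.

    *per_block_values* are block-level values of the statistic (block
    means), *per_block_weights* the SNP counts per block. The estimate is
    the weighted mean; the SE comes from delete-one-block resampling. For
    two equal-weight blocks with values a, b the SE reduces to |a - b| / 2.
    """
    v = np.asarray(per_block_values, dtype=float)
    w = np.asarray(per_block_weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same shape")
    if v.size < 2:
        raise ValueError("jackknife SE undefined with a single block")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    total_w = w.sum()
    total = (w * v).sum()
    theta_hat = total / total_w
    loo = (total - w * v) / (total_w - w)
    _, se = _jackknife_from_loo(theta_hat, loo, w)
    return float(theta_hat), se


def _per_snp_jackknife(
    terms: np.ndarray, block_snps: int
) -> tuple[float, float, int, int]:
    """Mean-type statistic: estimate, SE, n_blocks, n_snps from per-SNP terms."""
    terms = np.asarray(terms, dtype=float)
    ok = np.isfinite(terms)
    terms = terms[ok]
    n = terms.size
    if n < 2 * 1:
        raise ValueError("too few usable SNPs")
    blocks = assign_blocks(n, block_snps)
    n_blocks = int(blocks[-1]) + 1
    if n_blocks < 2:
        raise ValueError(
            f"only {n} usable SNPs -> a single {block_snps}-SNP jackknife block; "
            "SE undefined"
        )
    sums = np.bincount(blocks, weights=terms)
    counts = np.bincount(blocks).astype(float)
    est, se = block_jackknife(sums / counts, counts)
    return est, se, n_blocks, n

def f3_admixture(
    freq_target: np.ndarray,
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    n_target: int,
    blocks: int = DEFAULT_BLOCK_SNPS,
) -> FStatResult:
    """Admixture f3(target; A, B) with target heterozygosity bias correction.

    Per SNP: ``(c-a)(c-b) - c(1-c)/(2*n_target - 1)`` where c, a, b are the
    allele frequencies and *n_target* the target's diploid sample count.
    SNPs with any missing frequency, or monomorphic in all three
    populations, are dropped. A warning is issued below 1,000 usable SNPs.
    """
    c = np.asarray(freq_target, dtype=float)
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if n_target < 2:
        raise ValueError("target sample count must be >= 2 for the bias correction")
    ok = np.isfinite(c) & np.isfinite(a) & np.isfinite(b)
    mono = (c == a) & (a == b) & ((c == 0) | (c == 1))
    ok &= ~mono
    terms = (c - a) * (c - b) - c * (1.0 - c) / (2.0 * n_target - 1.0)
    terms = np.where(ok, terms, np.nan)
    n_ok = int(ok.sum())
    if n_ok < 1_000:
        warnings.warn(f"only {n_ok} usable SNPs for f3; estimate is noisy", stacklevel=2)
    est, se, n_blocks, n_used = _per_snp_jackknife(terms, blocks)
    z = est / se if se > 0 else float("nan")
    return FStatResult(est, se, z, n_blocks, n_used)


def f3_outgroup(
    freq_outgroup: np.ndarray,
    freq_x: np.ndarray,
    freq_ref: np.ndarray,
    blocks: int = DEFAULT_BLOCK_SNPS,
) -> FStatResult:
    """Outgroup f3(outgroup; X, Ref) = mean (o-x)(o-ref): shared drift of X and Ref.

    No bias correction is applied (the outgroup is held fixed). Warns when
    the outgroup frequencies correlate > 0.9 with X — a sign the "outgroup"
    is not actually external to the pair.
    """
    o = np.asarray(freq_outgroup, dtype=float)
    x = np.asarray(freq_x, dtype=float)
    ref = np.asarray(freq_ref, dtype=float)
    ok = np.isfinite(o) & np.isfinite(x) & np.isfinite(ref)
    mono = (o == x) & (x == ref) & ((o == 0) | (o == 1))
    ok &= ~mono
    if ok.sum() > 2 and np.std(o[ok]) > 0 and np.std(x[ok]) > 0:
        if np.corrcoef(o[ok], x[ok])[0, 1] > 0.9:
            warnings.warn(
                "outgroup frequencies correlate > 0.9 with X; outgroup f3 "
                "is not meaningful for a non-external outgroup",
                stacklevel=2,
            )
    terms = np.where(ok, (o - x) * (o - ref), np.nan)
    est, se, n_blocks, n_used = _per_snp_jackknife(terms, blocks)
    z = est / se if se > 0 else float("nan")
    return FStatResult(est, se, z, n_blocks, n_used)


def d_statistic(
    freq_w: np.ndarray,
    freq_x: np.ndarray,
    freq_y: np.ndarray,
    freq_z: np.ndarray,
    blocks: int = DEFAULT_BLOCK_SNPS,
) -> FStatResult:
    """Four-population D(W, X; Y, Z) with block-jackknife Z score.

    ``D = Σ(w-x)(y-z) / Σ(w+x-2wx)(y+z-2yz)`` over SNPs with all four
    frequencies defined. Exactly antisymmetric under swapping Y/Z or W/X.
    The SE comes from delete-one-block resampling of the ratio.
    """
    w = np.asarray(freq_w, dtype=float)
    x = np.asarray(freq_x, dtype=float)
    y = np.asarray(freq_y, dtype=float)
    z = np.asarray(freq_z, dtype=float)
    ok = np.isfinite(w) & np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    num = ((w - x) * (y - z))[ok]
    den = ((w + x - 2 * w * x) * (y + z - 2 * y * z))[ok]
    n = num.size
    if n < 2:
        raise ValueError("too few usable SNPs for D")
    total_den = den.sum()
    if total_den == 0:
        raise ValueError("D denominator is zero: no informative SNPs")
    block_ids = assign_blocks(n, blocks)
    n_blocks = int(block_ids[-1]) + 1
    if n_blocks < 2:
        raise ValueError("need at least two jackknife blocks for D")
    num_b = np.bincount(block_ids, weights=num)
    den_b = np.bincount(block_ids, weights=den)
    counts = np.bincount(block_ids).astype(float)
    theta_hat = num.sum() / total_den
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (num.sum() - num_b) / (total_den - den_b)
    if not np.isfinite(loo).all():
        raise ValueError("a delete-one block empties the D denominator")
    _, se = _jackknife_from_loo(theta_hat, loo, counts)
    zscore = theta_hat / se if se > 0 else float("nan")
    return FStatResult(float(theta_hat), se, zscore, n_blocks, n)


def mantel_test(
    matrix1: np.ndarray,
    matrix2: np.ndarray,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel permutation test of correlation between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; p is the
    two-sided permutation probability of |r_perm| >= |r_obs| under joint
    row/column permutations of *matrix2*, with the identity included
    (+1 correction). When every permutation can be enumerated within the
    budget (n! <= n_perm + 1) the test is exact and p = #(|r_perm| >=
    |r_obs|) / n!; otherwise permutations are sampled with the given seed.
    """
    m1 = np.asarray(matrix1, dtype=float)
    m2 = np.asarray(matrix2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = m1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least four populations")
    if not (np.allclose(m1, m1.T) and np.allclose(m2, m2.T)):
        raise ValueError("matrices must be symmetric")
    iu = np.triu_indices(n, k=1)
    x = m1[iu]
    if np.ptp(x) == 0 or np.ptp(m2[iu]) == 0:
        raise ValueError("constant distance matrix: r undefined")

    def corr(perm: np.ndarray) -> float:
        return float(np.corrcoef(x, m2[np.ix_(perm, perm)][iu])[0, 1])

    r_obs = corr(np.arange(n))
    tol = 1e-12
    if math.factorial(n) <= n_perm + 1:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            if abs(corr(np.array(perm))) >= abs(r_obs) - tol:
                hits += 1
            total += 1
        return r_obs, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(corr(rng.permutation(n))) >= abs(r_obs) - tol:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)
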