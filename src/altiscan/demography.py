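"""Runs of homozygosity, inbreeding, LD-decay Ne and divergence times.

The ROH scanner reproduces the PLINK sliding-window algorithm with strict
defaults: minimum 100 SNPs per run, zero heterozygote allowance, up to 5
missing calls per 50-SNP window, and a window-hit threshold of 0.05; the
input is expected to be LD-pruned (r² > 0.5) and restricted to common
variants (MAF > 0.05).

Effective population size is estimated from LD decay: for variant pairs at
recombination distance c (Morgans), the sample-size-adjusted r²
(y = r² - 1/n, n = 2 × samples) is binned by c and the hyperbola
y = 1/(α + βc) fitted by nonlinear least squares. Long-term Ne = β/4; each
bin also yields a time-resolved estimate Ne_t = (1/y - α̂)/(4c) referring to
roughly t = 1/(2c) generations ago, summarized by their harmonic mean.
Generations convert to years at 29 years per generation. Divergence time
between two populations uses the pure-drift clean-split relation
t = -2·Ne·ln(1 - FST) — approximate, and biased downward under migration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from altiscan.panel import MISSING, GenotypePanel, PopulationPanel
from altiscan.stats import pairwise_r2

logger = logging.getLogger(__name__)

__all__ = [
    "ROHSegment",
    "NeTrajectory",
    "SplitTime",
    "roh_scan",
    "inbreeding_f",
    "fit_ld_decay",
    "LdNeModel",
    "ne_from_ld",
    "divergence_time",
]

#: Years per human generation.
GENERATION_YEARS = 29.0


# --------------------------------------------------------------------------
# runs of homozygosity
# --------------------------------------------------------------------------
@dataclass
class ROHSegment:
    """One run of homozygosity (1-based inclusive bp coordinates)."""

    sample_id: str
    chrom: str
    start_pos: int
    end_pos: int
    n_snps: int
    length_bp: int
    n_missing: int = 0


def _window_counts(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window sums of a 0/1 vector (length m - w + 1)."""
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def roh_scan(
    panel: GenotypePanel,
    min_snps: int = 100,
    het_allow: int = 0,
    miss_allow: int = 5,
    window_snps: int = 50,
    window_threshold: float = 0.05,
) -> list[ROHSegment]:
    """PLINK-style sliding-window ROH detection for every sample.

    A window of *window_snps* consecutive SNPs is "homozygous" when it
    contains at most *het_allow* heterozygous and at most *miss_allow*
    missing calls. Per SNP, the fraction of overlapping homozygous windows
    is computed; SNPs at or above *window_threshold* are ROH-eligible.
    Maximal runs of eligible SNPs — broken at heterozygous calls (zero
    internal heterozygotes with the default allowance) and at missing calls
    beyond the segment missing budget — are reported when they span at
    least *min_snps* SNPs, with bp bounds at the first/last SNP positions.

    The panel should already be MAF-filtered and LD-pruned (the printed
    defaults assume MAF > 0.05 and r² <= 0.5).
    """
    segments: list[ROHSegment] = []
    chroms = panel.variants["chrom"].to_numpy()
    pos_all = panel.variants["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        m = cols.size
        if m < window_snps:
            warnings.warn(
                f"chromosome {chrom}: {m} variants < window of {window_snps}; skipped",
                stacklevel=2,
            )
            continue
        pos = pos_all[cols]
        for row in range(panel.n_samples):
            g = panel.genotypes[row, cols]
            het = (g == 1).astype(np.int64)
            mis = (g == MISSING).astype(np.int64)
            win_ok = (
                (_window_counts(het, window_snps) <= het_allow)
                & (_window_counts(mis, window_snps) <= miss_allow)
            ).astype(np.int64)
            # per-SNP: number of the m - w + 1 windows overlapping SNP i that
            # are homozygous, and how many windows overlap SNP i at all
            c = np.concatenate([[0], np.cumsum(win_ok)])
            n_win = win_ok.size
            starts = np.clip(np.arange(m) - window_snps + 1, 0, None)
            stops = np.minimum(np.arange(m), n_win - 1)
            hom_overlap = c[stops + 1] - c[starts]
            total_overlap = stops - starts + 1
            eligible = hom_overlap / total_overlap >= window_threshold
            runnable = eligible & (het == 0)

            i = 0
            while i < m:
                if not runnable[i] or mis[i]:
                    i += 1
                    continue
                j = i
                n_miss = 0
                last_good = i
                while j < m and runnable[j]:
                    if mis[j]:
                        if n_miss + 1 > miss_allow:
                            break
                        n_miss += 1
                    else:
                        last_good = j
                    j += 1
                # trim trailing missing calls
                end = last_good
                n_run = end - i + 1
                if n_run >= min_snps:
                    n_miss_in = int(mis[i : end + 1].sum())
                    segments.append(
                        ROHSegment(
                            sample_id=panel.sample_ids[row],
                            chrom=str(chrom),
                            start_pos=int(pos[i]),
                            end_pos=int(pos[end]),
                            n_snps=n_run,
                            length_bp=int(pos[end] - pos[i] + 1),
                            n_missing=n_miss_in,
                        )
                    )
                i = max(j, end + 1)
    return segments


def roh_table(segments: list[ROHSegment]) -> pd.DataFrame:
    """ROH segments as a DataFrame (one row per segment)."""
    return pd.DataFrame(
        [s.__dict__ for s in segments],
        columns=[
            "sample_id", "chrom", "start_pos", "end_pos",
            "n_snps", "length_bp", "n_missing",
        ],
    )


# --------------------------------------------------------------------------
# inbreeding
# --------------------------------------------------------------------------
def inbreeding_f(panel: GenotypePanel) -> pd.Series:
    """Per-sample inbreeding coefficient F from observed vs expected homozygosity.

    ``F = (O_hom - E_hom) / (N - E_hom)`` where the expected homozygous
    count sums 1 - 2p(1-p) over the sample's non-missing variants
    (p = panel allele frequency); monomorphic variants are excluded. NaN
    when the expectation saturates (all informative genotypes fixed).
    """
    g = panel.genotypes.astype(float)
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    g = g[:, keep]
    exp_hom_v = 1.0 - 2.0 * p[keep] * (1.0 - p[keep])
    called = np.isfinite(g)
    obs_hom = ((g == 0) | (g == 2)).sum(axis=1).astype(float)
    n_called = called.sum(axis=1).astype(float)
    exp_hom = np.where(called, exp_hom_v[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (obs_hom - exp_hom) / (n_called - exp_hom)
    f = np.where(np.isclose(n_called, exp_hom), np.nan, f)
    return pd.Series(f, index=panel.sample_ids, name="F")


# --------------------------------------------------------------------------
# LD-decay Ne
# --------------------------------------------------------------------------
@dataclass
class NeTrajectory:
    """Fitted LD-decay model and the Ne trajectory it implies.

    ``alpha``/``beta`` parameterize y = 1/(alpha + beta*c); long-term
    ``ne = beta / 4``. ``bins`` has one row per recombination-distance bin:
    midpoint c (Morgans), mean adjusted r², pair count, time t = 1/(2c)
    in generations (and years at 29 y/generation) and the per-bin Ne_t.
    ``ne_harmonic`` is the harmonic mean of the positive per-bin estimates.
    Divergence-time outputs built on these Ne values are approximate and
    downward-biased under migration.
    """

    alpha: float
    beta: float
    ne: float
    bins: pd.DataFrame = field(repr=False)
    ne_harmonic: float = float("nan")
    population: str = ""
    residual_ss: float = float("nan")
    generation_years: float = GENERATION_YEARS

    def summary(self) -> str:
        lines = [
            f"LD-decay Ne fit{' for ' + self.population if self.population else ''}",
            f"  model: y = 1/(alpha + beta*c)",
            f"  alpha = {self.alpha:.4g}   beta = {self.beta:.6g}",
            f"  long-term Ne = beta/4 = {self.ne:.1f}",
            f"  harmonic-mean Ne over bins = {self.ne_harmonic:.1f}",
            f"  bins: {len(self.bins)}   residual SS = {self.residual_ss:.3g}",
        ]
        return "\n".join(lines)


def fit_ld_decay(c: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Fit y = 1/(α + βc) to binned adjusted r²; returns (α, β, residual SS)."""
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(c) & np.isfinite(y) & (y > 0)
    if ok.sum() < 3:
        raise ValueError("need at least three positive bins to fit the decay curve")
    c, y = c[ok], y[ok]
    # 1/y = α + βc is linear: use its least squares as the starting point
    slope, intercept = np.polyfit(c, 1.0 / y, 1)
    p0 = (max(intercept, 1e-3), max(slope, 1.0))

    def model(ci, alpha, beta):
        return 1.0 / (alpha + beta * ci)

    try:
        popt, _ = curve_fit(
            model, c, y, p0=p0, bounds=((0.0, 0.0), (np.inf, np.inf)), maxfev=10_000
        )
    except RuntimeError as e:
        resid = y - model(c, *p0)
        raise RuntimeError(
            f"LD-decay fit failed to converge (start {p0}, residual SS "
            f"{float(resid @ resid):.3g})"
        ) from e
    alpha, beta = float(popt[0]), float(popt[1])
    resid = y - model(c, alpha, beta)
    return alpha, beta, float(resid @ resid)


def _trajectory_from_bins(
    c: np.ndarray, y: np.ndarray, n_pairs: np.ndarray, alpha: float, beta: float,
    population: str, residual_ss: float,
) -> NeTrajectory:
    with np.errstate(invalid="ignore", divide="ignore"):
        ne_t = np.where(y > 0, np.clip((1.0 / y - alpha), 0.0, None) / (4.0 * c), np.nan)
    t_gen = 1.0 / (2.0 * c)
    bins = pd.DataFrame(
        {
            "c_morgan": c,
            "r2_adj": y,
            "n_pairs": n_pairs,
            "t_generations": t_gen,
            "t_years": t_gen * GENERATION_YEARS,
            "ne_t": ne_t,
        }
    )
    pos = ne_t[np.isfinite(ne_t) & (ne_t > 0)]
    harmonic = float(pos.size / (1.0 / pos).sum()) if pos.size else float("nan")
    return NeTrajectory(
        alpha=alpha,
        beta=beta,
        ne=beta / 4.0,
        bins=bins,
        ne_harmonic=harmonic,
        population=population,
        residual_ss=residual_ss,
    )


class LdNeModel:
    """LD-decay effective-population-size model for one population.

    Statsmodels-style: construct from the data, call :meth:`fit` to obtain
    a :class:`NeTrajectory` results object.

    Parameters
    ----------
    panel : GenotypePanel
        Genotypes; variants need cM positions (``cm`` column) or a
        *genetic_map* / constant-rate fallback.
    population : str
        Population code; needs at least *min_n* samples.
    c_bins : ndarray
        Ascending recombination-distance bin edges in Morgans.
    genetic_map : DataFrame, optional
        Columns ``chrom pos cm``; overrides the panel's cM positions.
    cm_per_mb : float
        Constant-rate fallback when no map is available.
    """

    def __init__(
        self,
        panel: GenotypePanel,
        population: str,
        c_bins: np.ndarray,
        genetic_map: pd.DataFrame | None = None,
        min_n: int = 10,
        cm_per_mb: float = 1.0,
    ) -> None:
        idx = panel.population_indices(population)
        if idx.size < min_n:
            raise ValueError(
                f"population {population!r} has {idx.size} samples; "
                f"need >= {min_n} for LD-based Ne"
            )
        self.panel = panel
        self.population = population
        self.sample_idx = idx
        self.c_bins = np.asarray(c_bins, dtype=float)
        if (np.diff(self.c_bins) <= 0).any():
            raise ValueError("c_bins must be ascending")
        self.genetic_map = genetic_map
        self.cm_per_mb = cm_per_mb

    def _cm_positions(self) -> np.ndarray:
        v = self.panel.variants
        if self.genetic_map is not None:
            key = {(c, p): m for c, p, m in zip(
                self.genetic_map["chrom"].astype(str),
                self.genetic_map["pos"],
                self.genetic_map["cm"],
            )}
            cm = np.array([key.get((c, p), np.nan) for c, p in zip(v["chrom"], v["pos"])])
        else:
            cm = v["cm"].to_numpy(dtype=float)
        fallback = ~np.isfinite(cm)
        if fallback.any():
            cm = np.where(fallback, v["pos"].to_numpy() * 1e-6 * self.cm_per_mb, cm)
        return cm

    def fit(self) -> NeTrajectory:
        """Bin intra-chromosomal pair r², adjust for sample size, fit the hyperbola."""
        panel = self.panel
        n_chrom_samples = 2 * self.sample_idx.size
        cm = self._cm_positions()
        chroms = panel.variants["chrom"].to_numpy()
        edges = self.c_bins
        sums = np.zeros(edges.size - 1)
        counts = np.zeros(edges.size - 1, dtype=np.int64)
        g = panel.genotypes[self.sample_idx]
        for chrom in pd.unique(chroms):
            cols = np.flatnonzero(chroms == chrom)
            if cols.size < 2:
                continue
            r2 = pairwise_r2(g[:, cols])
            d = np.abs(cm[cols][:, None] - cm[cols][None, :]) / 100.0  # Morgans
            iu = np.triu_indices(cols.size, k=1)
            dist = d[iu]
            vals = r2[iu]
            ok = np.isfinite(vals)
            which = np.digitize(dist[ok], edges) - 1
            inside = (which >= 0) & (which < edges.size - 1)
            np.add.at(sums, which[inside], vals[ok][inside])
            np.add.at(counts, which[inside], 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        y = mean_r2 - 1.0 / n_chrom_samples
        mid = (edges[:-1] + edges[1:]) / 2.0
        keep = counts > 0
        alpha, beta, rss = fit_ld_decay(mid[keep], y[keep])
        return _trajectory_from_bins(
            mid[keep], y[keep], counts[keep], alpha, beta, self.population, rss
        )


def ne_from_ld(
    panel: GenotypePanel,
    population: str,
    c_bins: np.ndarray,
    genetic_map: pd.DataFrame | None = None,
    min_n: int = 10,
) -> NeTrajectory:
    """Functional wrapper around :class:`LdNeModel` (construct + fit)."""
    return LdNeModel(
        panel, population, c_bins, genetic_map=genetic_map, min_n=min_n
    ).fit()


# --------------------------------------------------------------------------
# divergence time
# --------------------------------------------------------------------------
@dataclass
class SplitTime:
    """Approximate divergence time of a population pair from mean FST.

    Pure-drift clean-split expectation t = -2·Ne·ln(1 - FST) (reducing to
    2·Ne·FST for small FST). Migration makes the estimate downward-biased;
    treat it as an order-of-magnitude indication, not a date.
    """

    pair: tuple[str, str]
    fst_mean: float
    ne: float
    t_generations: float
    t_years: float
    note: str = "approximate, downward-biased under migration"


def divergence_time(
    fst_mean: float, ne_harmonic: float, pair: tuple[str, str] = ("pop1", "pop2")
) -> SplitTime:
    """Divergence time from mean pairwise FST and a harmonic-mean Ne."""
    if not 0.0 <= fst_mean < 1.0:
        raise ValueError(f"mean FST must be in [0, 1), got {fst_mean}")
    if ne_harmonic <= 0:
        raise ValueError("Ne must be positive")
    t_gen = -2.0 * ne_harmonic * np.log1p(-fst_mean)
    return SplitTime(
        pair=pair,
        fst_mean=float(fst_mean),
        ne=float(ne_harmonic),
        t_generations=float(t_gen),
        t_years=float(t_gen * GENERATION_YEARS),
    )
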