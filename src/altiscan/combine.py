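"""Combining the three selection statistics and collating candidate regions.

The PBS value is converted to an empirical rank p-value (rank in decreasing
order divided by the number of SNPs, mean rank for ties), combined with the
Spearman and mixed-model p-values by Fisher's method (chi² = -2 Σ ln p, 2k
df), Bonferroni-controlled at 0.01/N, and the surviving variants are chained
into candidate genomic regions. The three tests are not independent, so the
combined p is an evidence ranking, not a calibrated type-1 error rate; no
dependence correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CandidateRegion",
    "pbs_rank_p",
    "fisher_combine",
    "bonferroni_flag",
    "collate_overlap",
    "cluster_regions",
]

#: Family-wise alpha for the combined statistic.
COMBINED_ALPHA = 0.01
#: Floor applied to zero p-values before taking logs.
P_FLOOR = 1e-300


def pbs_rank_p(pbs_values: np.ndarray) -> np.ndarray:
    """Empirical rank p-value of PBS: rank in decreasing order / N.

    Rank 1 is the largest PBS; tied values share the mean rank of their tied
    block; missing (NaN) PBS yields missing p. The result lies in (0, 1].
    """
    v = np.asarray(pbs_values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("need at least one finite PBS value")
    out = np.full(v.size, np.nan)
    ranks = sps.rankdata(-v[finite], method="average")
    out[finite] = ranks / finite.sum()
    return out


def fisher_combine(p_matrix: np.ndarray) -> pd.DataFrame:
    """Fisher's method across the columns of a (variants × tests) p-value matrix.

    chi² = -2 Σ ln p with 2k degrees of freedom and an upper-tail chi-square
    combined p. Zero p-values are clamped to 1e-300 (with a warning); any
    missing input p makes the combined p missing for that variant.

    Returns a DataFrame with columns ``chi2_fisher df p_combined``.
    """
    p = np.atleast_2d(np.asarray(p_matrix, dtype=float))
    if p.ndim != 2:
        raise ValueError("p_matrix must be 2-D (variants x tests)")
    k = p.shape[1]
    if ((p > 1.0) & np.isfinite(p)).any() or ((p < 0.0) & np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n_zero = int((p == 0.0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero p-value(s) clamped to {P_FLOOR}", stacklevel=2)
        p = np.where(p == 0.0, P_FLOOR, p)
    complete = np.isfinite(p).all(axis=1)
    chi2 = np.full(p.shape[0], np.nan)
    p_comb = np.full(p.shape[0], np.nan)
    chi2[complete] = -2.0 * np.log(p[complete]).sum(axis=1)
    p_comb[complete] = sps.chi2.sf(chi2[complete], df=2 * k)
    return pd.DataFrame({"chi2_fisher": chi2, "df": 2 * k, "p_combined": p_comb})


def bonferroni_flag(
    p_combined: np.ndarray, alpha: float = COMBINED_ALPHA, n_tests: int | None = None
) -> np.ndarray:
    """Strict Bonferroni significance: p < alpha / n_tests.

    *n_tests* defaults to the count of defined combined p-values. The
    inequality is strict, so p exactly at the threshold is not flagged.
    """
    p = np.asarray(p_combined, dtype=float)
    if n_tests is None:
        n_tests = int(np.isfinite(p).sum())
    if n_tests == 0:
        raise ValueError("no defined p-values to correct over")
    return np.where(np.isfinite(p), p < alpha / n_tests, False)


def collate_overlap(sig_sets: dict[str, set]) -> pd.DataFrame:
    """Membership table of significant variant ids across named methods.

    Returns one row per variant in the union, one boolean column per method,
    plus ``n_methods`` and ``in_all``; rows sorted by descending
    ``n_methods`` then id. Pairwise intersection counts are attached as the
    ``pairwise_counts`` DataFrame attribute.
    """
    if len(sig_sets) < 2:
        raise ValueError("need at least two sets to collate")
    names = list(sig_sets)
    union = sorted(set().union(*sig_sets.values()))
    table = pd.DataFrame(
        {name: [v in sig_sets[name] for v in union] for name in names},
        index=pd.Index(union, name="vid"),
    )
    table["n_methods"] = table[names].sum(axis=1)
    table["in_all"] = table[names].all(axis=1)
    table = table.sort_values(["n_methods", "vid"], ascending=[False, True])
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairs.append((a, b, len(sig_sets[a] & sig_sets[b])))
    table.attrs["pairwise_counts"] = pd.DataFrame(
        pairs, columns=["method_a", "method_b", "n_shared"]
    )
    return table


@dataclass
class CandidateRegion:
    """A cluster of significant SNPs on one chromosome.

    Coordinates are 1-based inclusive: ``start``/``end`` are the min/max
    positions of the member SNPs. ``top_vid`` is the member with the
    smallest combined p (ties: smaller position).
    """

    chrom: str
    start: int
    end: int
    vids: list[str]
    n_snps: int
    top_vid: str
    top_p: float

    def to_row(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "n_snps": self.n_snps,
            "top_vid": self.top_vid,
            "top_p": self.top_p,
        }


def cluster_regions(
    sig_variants: pd.DataFrame,
    max_gap_bp: int = 500_000,
    min_snps: int = 2,
) -> list[CandidateRegion]:
    """Chain significant SNPs into candidate regions by single linkage.

    Consecutive significant SNPs on one chromosome at most *max_gap_bp*
    apart join one region; clusters with fewer than *min_snps* members
    (singletons when ``min_snps=2``) are excluded — pass ``min_snps=1`` to
    see them. *sig_variants* needs columns ``chrom pos vid p_combined``.
    """
    req = {"chrom", "pos", "vid", "p_combined"}
    missing = req - set(sig_variants.columns)
    if missing:
        raise ValueError(f"sig_variants missing columns: {sorted(missing)}")
    df = sig_variants.sort_values(["chrom", "pos"], kind="stable")
    regions: list[CandidateRegion] = []
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp) + 1
        for part in np.split(np.arange(len(grp)), breaks):
            members = grp.iloc[part]
            if len(members) < min_snps:
                continue
            order = members.sort_values(["p_combined", "pos"], kind="stable")
            regions.append(
                CandidateRegion(
                    chrom=str(chrom),
                    start=int(members["pos"].min()),
                    end=int(members["pos"].max()),
                    vids=list(members["vid"]),
                    n_snps=len(members),
                    top_vid=str(order["vid"].iloc[0]),
                    top_p=float(order["p_combined"].iloc[0]),
                )
            )
    return regions


def regions_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Candidate regions as a BED-like (1-based inclusive) DataFrame."""
    return pd.DataFrame(
        [r.to_row() for r in regions],
        columns=["chrom", "start", "end", "n_snps", "top_vid", "top_p"],
    )
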