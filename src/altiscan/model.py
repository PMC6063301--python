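"""High-level fitted-model interface to the altitude-adaptation scan.

:class:`AltitudeSelectionScan` bundles the three per-SNP selection
statistics (Spearman altitude correlation, kinship-corrected mixed-model
association, PBS), their Fisher combination, Bonferroni control and
candidate-region clustering behind a statsmodels-style Model/Results pair:
build the model from a genotype panel plus population metadata, call
``fit()``, and read the per-variant evidence table, candidate regions,
diagnostics and ``summary()`` off the results object.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from altiscan import combine, selection
from altiscan.panel import GenotypePanel, PopulationPanel, HIGH_ALTITUDE_M
from altiscan.stats import allele_frequencies, kinship_grm

logger = logging.getLogger(__name__)

__all__ = ["AltitudeSelectionScan", "SelectionScanResults"]


class SelectionScanResults:
    """Results of a fitted :class:`AltitudeSelectionScan`.

    Attributes
    ----------
    variants : DataFrame
        Per-variant table: ``chrom pos vid rho p_spearman beta_lmm se_lmm
        p_lmm fst_hc fst_ho fst_co pbs p_rank_pbs chi2_fisher p_combined``
        plus the significance flags ``spearman_sig lmm_sig pbs_sig
        combined_sig``.
    regions : list of CandidateRegion
        Bonferroni-significant SNPs chained into candidate regions.
    null_fit : NullModelFit
        Variance components of the mixed-model null.
    n_tests : int
        Variants entering the Fisher combination (all three p-values
        defined) — the Bonferroni denominator.
    """

    def __init__(
        self,
        model: "AltitudeSelectionScan",
        variants: pd.DataFrame,
        regions: list[combine.CandidateRegion],
        null_fit,
        n_tests: int,
    ) -> None:
        self.model = model
        self.variants = variants
        self.regions = regions
        self.null_fit = null_fit
        self.n_tests = n_tests

    @property
    def regions_table(self) -> pd.DataFrame:
        return combine.regions_frame(self.regions)

    def significant(self) -> pd.DataFrame:
        """Variants passing the combined Bonferroni threshold."""
        return self.variants[self.variants["combined_sig"]]

    def overlap(self) -> pd.DataFrame:
        """Membership of significant variant ids across the three methods."""
        v = self.variants
        sets = {
            "spearman": set(v.loc[v["spearman_sig"], "vid"]),
            "lmm": set(v.loc[v["lmm_sig"], "vid"]),
            "pbs": set(v.loc[v["pbs_sig"], "vid"]),
        }
        return combine.collate_overlap(sets)

    def summary(self) -> str:
        v = self.variants
        m = self.model
        alpha = m.combined_alpha
        thr = alpha / self.n_tests if self.n_tests else float("nan")
        lines = [
            "Altitude selection scan",
            "=" * 60,
            f"variants scanned:            {len(v)}",
            f"populations (freq scan):     {len(m.scan_populations)}",
            f"high-altitude group H:       {len(m.group_h)} samples "
            f"({', '.join(m.high_pops)})",
            f"close reference C / outgroup O: {m.ref_c} / {m.ref_o}",
            f"kinship heritability ratio:  {self.null_fit.heritability:.3f}",
            f"Spearman Bonferroni hits:    {int(v['spearman_sig'].sum())}",
            f"LMM hits (p < {selection.LMM_ALPHA:g}):    {int(v['lmm_sig'].sum())}",
            f"PBS hits (>= {selection.PBS_PERCENTILE}th pct):  {int(v['pbs_sig'].sum())}",
            f"Fisher-combined tests:       {self.n_tests}",
            f"combined Bonferroni (p < {alpha:g}/{self.n_tests} = {thr:.3g}): "
            f"{int(v['combined_sig'].sum())} variants",
            f"candidate regions (>= {m.min_region_snps} SNPs, gap <= "
            f"{m.max_gap_bp/1000:.0f} kb): {len(self.regions)}",
        ]
        top = self.regions_table.sort_values("top_p").head(10)
        if len(top):
            lines.append("-" * 60)
            lines.append("top candidate regions (chrom start-end n_snps top_vid top_p):")
            for _, r in top.iterrows():
                lines.append(
                    f"  {r['chrom']:>3} {int(r['start'])}-{int(r['end'])} "
                    f"n={int(r['n_snps'])} {r['top_vid']} p={r['top_p']:.3g}"
                )
        return "\n".join(lines)

    def plot_manhattan(self, ax=None, statistic: str = "p_combined"):
        """Manhattan plot of -log10 of the chosen statistic along the genome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        v = self.variants
        offset = 0
        for i, (chrom, grp) in enumerate(v.groupby("chrom", sort=False)):
            with np.errstate(divide="ignore"):
                y = -np.log10(grp[statistic].to_numpy(dtype=float))
            ax.scatter(grp["pos"] + offset, y, s=4,
                       color="C0" if i % 2 == 0 else "C1", rasterized=True)
            offset += grp["pos"].max() + 1
        if self.n_tests:
            ax.axhline(
                -np.log10(self.model.combined_alpha / self.n_tests),
                color="red", lw=0.8, ls="--",
            )
        ax.set_xlabel("genome position")
        ax.set_ylabel(f"-log10 {statistic}")
        return ax

    def to_tsv(self, path) -> None:
        self.variants.to_csv(path, sep="\t", index=False, na_rep="NA")


class AltitudeSelectionScan:
    """Genome-wide scan for altitude adaptation on a genotype panel.

    Parameters
    ----------
    panel : GenotypePanel
        QC-filtered genotypes with ancestral-allele annotation.
    populations : PopulationPanel
        Altitude and region metadata for every population in the panel.
    ref_c : str
        Code of the closest lowland reference population (East-Asian-like
        role) used as the C branch of PBS.
    ref_o : str
        Code of the outgroup reference population (European-like role), the
        O branch of PBS.
    high_pops : sequence of str, optional
        Populations pooled into the high-altitude focal group H. Default:
        every population at or above *high_altitude_m* (excluding the two
        references).
    high_altitude_m : float
        High-altitude threshold in metres (default 2,500).
    scan_populations : sequence of str, optional
        Populations entering the Spearman frequency-altitude scan.
        Default: all non-reference populations.
    """

    def __init__(
        self,
        panel: GenotypePanel,
        populations: PopulationPanel,
        ref_c: str,
        ref_o: str,
        high_pops: Sequence[str] | None = None,
        high_altitude_m: float = HIGH_ALTITUDE_M,
        scan_populations: Sequence[str] | None = None,
        spearman_alpha: float = selection.SPEARMAN_ALPHA,
        lmm_alpha: float = selection.LMM_ALPHA,
        pbs_percentile: float = selection.PBS_PERCENTILE,
        combined_alpha: float = combine.COMBINED_ALPHA,
        max_gap_bp: int = 500_000,
        min_region_snps: int = 1,
    ) -> None:
        for ref in (ref_c, ref_o):
            populations.altitude_of(ref)  # raises on unknown code
        if ref_c == ref_o:
            raise ValueError("ref_c and ref_o must differ")
        self.panel = panel
        self.populations = populations
        self.ref_c = ref_c
        self.ref_o = ref_o
        non_ref = [c for c in populations.codes if c not in (ref_c, ref_o)]
        self.scan_populations = list(scan_populations) if scan_populations else non_ref
        if high_pops is None:
            high_pops = [
                c
                for c in non_ref
                if populations.is_high_altitude(c, high_altitude_m)
            ]
        if not high_pops:
            raise ValueError("no high-altitude populations for the PBS focal group")
        self.high_pops = list(high_pops)
        self.group_h = np.concatenate(
            [panel.population_indices(c) for c in self.high_pops]
        )
        self.group_c = panel.population_indices(ref_c)
        self.group_o = panel.population_indices(ref_o)
        self.spearman_alpha = spearman_alpha
        self.lmm_alpha = lmm_alpha
        self.pbs_percentile = pbs_percentile
        self.combined_alpha = combined_alpha
        self.max_gap_bp = max_gap_bp
        self.min_region_snps = min_region_snps

    @classmethod
    def from_files(cls, bed_prefix, metadata_tsv, ref_c: str, ref_o: str, **kwargs):
        """Build the model from PLINK files plus a metadata TSV."""
        from altiscan import io

        panel = io.read_plink(str(bed_prefix) + ".bed")
        pops = io.read_metadata(metadata_tsv, panel=panel)
        return cls(panel, pops, ref_c=ref_c, ref_o=ref_o, **kwargs)

    def fit(self) -> SelectionScanResults:
        """Run the three statistics, combine them, and collate candidate regions."""
        panel = self.panel
        logger.info("scan: derived allele frequencies (%d populations)",
                    len(self.scan_populations))
        polarized = (panel.variants["ancestral"] != "unknown").any()
        if not polarized:
            # every scan p-value is two-sided and therefore invariant to the
            # allele orientation; only the SIGN of rho / beta depends on it
            warnings.warn(
                "no ancestral-allele annotation: frequencies refer to allele_b; "
                "rho and beta signs are orientation-dependent, p-values are not",
                stacklevel=2,
            )
        freq = allele_frequencies(panel, self.scan_populations, polarized=polarized)
        spearman = selection.spearman_altitude_scan(
            freq, self.populations, alpha=self.spearman_alpha
        )

        logger.info("scan: kinship + mixed-model association")
        scan_idx = np.concatenate(
            [panel.population_indices(c) for c in self.scan_populations]
        )
        sub = panel.subset(sample_idx=scan_idx)
        kin = kinship_grm(sub)
        y = self.populations.sample_altitudes(sub)
        null_fit = selection.lmm_fit_null(y, kin)
        lmm = selection.lmm_assoc_scan(sub, null_fit, alpha=self.lmm_alpha)

        logger.info("scan: PBS (H=%d, C=%d, O=%d samples)",
                    self.group_h.size, self.group_c.size, self.group_o.size)
        pbs_df = selection.pbs_scan(
            panel, self.group_h, self.group_c, self.group_o,
            percentile=self.pbs_percentile,
        )

        variants = pd.concat(
            [panel.variants[["chrom", "pos", "vid"]], spearman, lmm, pbs_df],
            axis=1,
        )
        variants["p_rank_pbs"] = combine.pbs_rank_p(variants["pbs"].to_numpy())
        fisher = combine.fisher_combine(
            variants[["p_spearman", "p_lmm", "p_rank_pbs"]].to_numpy()
        )
        variants = pd.concat([variants, fisher], axis=1)
        n_tests = int(np.isfinite(variants["p_combined"]).sum())
        variants["combined_sig"] = combine.bonferroni_flag(
            variants["p_combined"].to_numpy(),
            alpha=self.combined_alpha,
            n_tests=n_tests,
        )
        regions = combine.cluster_regions(
            variants.loc[variants["combined_sig"],
                         ["chrom", "pos", "vid", "p_combined"]],
            max_gap_bp=self.max_gap_bp,
            min_snps=self.min_region_snps,
        )
        return SelectionScanResults(self, variants, regions, null_fit, n_tests)
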