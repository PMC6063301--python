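"""Genotype I/O, panel merging and quality control.

Readers/writers for PLINK bed/bim/fam (SNP-major, magic ``6C 1B 01``),
VCF v4.2 (GT only, via cyvcf2 for reading) and the sample metadata TSV
(``sample_id population altitude_m region language``), plus the QC chain:
variant call rate → sample missingness → Hardy–Weinberg exact test → MAF,
method-of-moments relatedness (PI_HAT) and greedy windowed LD pruning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from altiscan.panel import MISSING, GenotypePanel, PopulationPanel, normalize_chrom
from altiscan.stats import pairwise_r2

logger = logging.getLogger(__name__)

__all__ = [
    "PlinkFormatError",
    "RelatednessPair",
    "read_plink",
    "write_plink",
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "write_metadata",
    "merge_panels",
    "hwe_exact_test",
    "filter_qc",
    "estimate_pi_hat",
    "remove_related",
    "ld_prune",
]


class PlinkFormatError(ValueError):
    """Malformed PLINK binary file."""


# --------------------------------------------------------------------------
# PLINK bed/bim/fam
# --------------------------------------------------------------------------
_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit bed code -> allele-b dosage (00 hom-a1, 01 missing, 10 het, 11 hom-a2)
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypePanel:
    """Read a PLINK bed/bim/fam fileset into a :class:`GenotypePanel`.

    ``bim_path``/``fam_path`` default to the bed path with swapped suffix.
    The fam FID column is stored as the sample's population code. Genotypes
    count the bim A2 allele (stored as ``allele_b``).
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "vid": str, "a1": str, "a2": str},
    ) if bim_path.stat().st_size else pd.DataFrame(
        columns=["chrom", "vid", "cm", "pos", "a1", "a2"]
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n_samples, n_variants = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC[:2]:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes at offset 0 "
            f"(expected 6C 1B, got {raw[:2].hex() if raw else 'EOF'})"
        )
    if raw[2] != 0x01:
        raise PlinkFormatError(f"{bed_path}: not SNP-major (mode byte at offset 2 is {raw[2]:#x})")
    bytes_per_variant = (n_samples + 3) // 4
    expected = 3 + bytes_per_variant * n_variants
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: expected {expected} bytes for {n_samples} samples x "
            f"{n_variants} variants, found {len(raw)} (truncated at offset {len(raw)})"
        )
    if n_variants == 0 or n_samples == 0:
        geno = np.zeros((n_samples, n_variants), dtype=np.int8)
    else:
        data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(
            n_variants, bytes_per_variant
        )
        shifts = np.arange(4, dtype=np.uint8) * 2
        codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
        codes = codes.reshape(n_variants, -1)[:, :n_samples]
        geno = _BED_DECODE[codes].T  # samples x variants

    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"].map(normalize_chrom),
            "pos": bim["pos"].astype(int) if len(bim) else bim["pos"],
            "vid": bim["vid"],
            "allele_a": bim["a1"],
            "allele_b": bim["a2"],
            "ancestral": "unknown",
            "cm": bim["cm"].astype(float) if len(bim) else bim["cm"],
        }
    )
    samples = pd.DataFrame({"sample_id": fam["iid"], "population": fam["fid"]})
    return GenotypePanel(variants, samples, geno)


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a panel as PLINK bed/bim/fam under ``prefix``."""
    prefix = Path(prefix)
    v = panel.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "vid": v["vid"],
            "cm": v["cm"].fillna(0.0),
            "pos": v["pos"],
            "a1": v["allele_a"],
            "a2": v["allele_b"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.samples["population"],
            "iid": panel.samples["sample_id"],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n_samples = panel.n_samples
    bytes_per_variant = (n_samples + 3) // 4
    code_lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        code_lut[dosage % 4] = code  # MISSING=-1 -> index 3
    codes = code_lut[panel.genotypes.T % 4].astype(np.uint8)  # variants x samples
    padded = np.zeros((panel.n_variants, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n_samples] = codes
    packed = (
        padded.reshape(panel.n_variants, bytes_per_variant, 4)
        * (1 << (np.arange(4, dtype=np.uint8) * 2))[None, None, :]
    ).sum(axis=2, dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------
def read_vcf(vcf_path) -> GenotypePanel:
    """Read biallelic SNPs from a VCF (GT field) into a panel.

    Non-biallelic or non-SNP records are skipped (count logged); phase is
    ignored (dosage only). The INFO ``AA`` tag, when present and matching
    REF or ALT, sets the ancestral allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, columns = [], []
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        aa = rec.INFO.get("AA")
        if aa:
            aa = str(aa).upper()
        ancestral = "a" if aa == rec.REF else ("b" if aa == alts[0] else "unknown")
        rows.append((normalize_chrom(rec.CHROM), rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}",
                     rec.REF, alts[0], ancestral, np.nan))
        gt = rec.gt_types.copy()  # gts012: 0,1,2 dosage; 3 unknown
        gt[gt == 3] = MISSING
        columns.append(gt.astype(np.int8))
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "vid", "allele_a", "allele_b", "ancestral", "cm"]
    )
    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population": ""})
    panel = GenotypePanel(variants, samples, geno)
    panel.n_skipped_records = n_skipped
    return panel


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a panel as an uncompressed VCF v4.2 with GT-only genotypes."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["sample_id"])
            + "\n"
        )
        v = panel.variants
        for j in range(panel.n_variants):
            anc = v.at[j, "ancestral"]
            info = (
                f"AA={v.at[j, 'allele_a'] if anc == 'a' else v.at[j, 'allele_b']}"
                if anc in ("a", "b")
                else "."
            )
            gts = "\t".join(gt_str[int(g)] for g in panel.genotypes[:, j])
            fh.write(
                f"{v.at[j, 'chrom']}\t{v.at[j, 'pos']}\t{v.at[j, 'vid']}\t"
                f"{v.at[j, 'allele_a']}\t{v.at[j, 'allele_b']}\t.\t.\t{info}\tGT\t{gts}\n"
            )


# --------------------------------------------------------------------------
# metadata
# --------------------------------------------------------------------------
def read_metadata(tsv_path, panel: GenotypePanel | None = None) -> PopulationPanel:
    """Read the sample metadata TSV and aggregate it into a PopulationPanel.

    Required columns: ``sample_id population altitude_m``; ``region`` and
    ``language`` are optional. Altitude must be constant within a
    population. When *panel* is given, its samples must all be present in
    the metadata (error lists missing ids) and their population codes are
    assigned in place.
    """
    meta = pd.read_csv(tsv_path, sep="\t", dtype={"sample_id": str, "population": str})
    required = {"sample_id", "population", "altitude_m"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    for col in ("region", "language"):
        if col not in meta:
            meta[col] = ""
    alt_check = meta.groupby("population")["altitude_m"].nunique()
    bad = alt_check[alt_check > 1]
    if len(bad):
        raise ValueError(
            f"conflicting altitudes within populations: {sorted(bad.index)}"
        )
    agg = (
        meta.groupby("population", sort=False)
        .agg(
            altitude_m=("altitude_m", "first"),
            region=("region", "first"),
            language=("language", "first"),
            n_samples=("sample_id", "size"),
        )
        .reset_index()
        .rename(columns={"population": "code"})
    )
    pops = PopulationPanel(agg)
    if panel is not None:
        lookup = dict(zip(meta["sample_id"], meta["population"]))
        absent = [s for s in panel.sample_ids if s not in lookup]
        if absent:
            raise ValueError(f"samples missing from metadata: {absent}")
        panel.samples["population"] = [lookup[s] for s in panel.sample_ids]
    return pops


def write_metadata(panel: GenotypePanel, populations: PopulationPanel, path) -> None:
    """Write the per-sample metadata TSV for a panel."""
    t = populations.table.set_index("code")
    meta = pd.DataFrame(
        {
            "sample_id": panel.samples["sample_id"],
            "population": panel.samples["population"],
        }
    )
    meta["altitude_m"] = meta["population"].map(t["altitude_m"])
    meta["region"] = meta["population"].map(t["region"])
    meta["language"] = meta["population"].map(t["language"])
    meta.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# merging
# --------------------------------------------------------------------------
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a: str, b: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) SNPs."""
    return _COMPLEMENT.get(a.upper()) == b.upper()


def merge_panels(panel1: GenotypePanel, panel2: GenotypePanel) -> GenotypePanel:
    """Merge two panels on shared (chrom, pos) variants, concatenating samples.

    Alleles are reconciled allowing REF/ALT swaps (genotypes recoded
    ``2 - g``) and strand flips; strand-ambiguous A/T and C/G SNPs are
    always dropped, as are variants whose alleles cannot be reconciled.
    Variant metadata (ancestral state, cM) comes from *panel1*.
    """
    shared_ids = set(panel1.samples["sample_id"]) & set(panel2.samples["sample_id"])
    if shared_ids:
        raise ValueError(f"duplicate sample ids across panels: {sorted(shared_ids)}")

    v1 = panel1.variants
    v2 = panel2.variants
    key2 = {(c, p): j for j, (c, p) in enumerate(zip(v2["chrom"], v2["pos"]))}
    keep1, keep2, flip2 = [], [], []
    n_ambiguous = n_mismatch = 0
    for i, (c, p, a1, b1) in enumerate(
        zip(v1["chrom"], v1["pos"], v1["allele_a"], v1["allele_b"])
    ):
        j = key2.get((c, p))
        if j is None:
            continue
        if _is_ambiguous(a1, b1):
            n_ambiguous += 1
            continue
        a2, b2 = v2.at[j, "allele_a"], v2.at[j, "allele_b"]
        pairs = {
            (a2, b2): False,
            (b2, a2): True,
            (_COMPLEMENT.get(a2, "?"), _COMPLEMENT.get(b2, "?")): False,
            (_COMPLEMENT.get(b2, "?"), _COMPLEMENT.get(a2, "?")): True,
        }
        if (a1, b1) not in pairs:
            n_mismatch += 1
            continue
        keep1.append(i)
        keep2.append(j)
        flip2.append(pairs[(a1, b1)])
    if n_ambiguous:
        logger.info("merge_panels: dropped %d strand-ambiguous (A/T, C/G) SNPs", n_ambiguous)
    if n_mismatch:
        logger.info("merge_panels: dropped %d variants with irreconcilable alleles", n_mismatch)

    keep1 = np.array(keep1, dtype=int)
    keep2 = np.array(keep2, dtype=int)
    flip2 = np.array(flip2, dtype=bool)
    g1 = panel1.genotypes[:, keep1]
    g2 = panel2.genotypes[:, keep2].copy()
    if flip2.any():
        cols = g2[:, flip2]
        swapped = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
        g2[:, flip2] = swapped
    merged = GenotypePanel(
        v1.iloc[keep1].reset_index(drop=True),
        pd.concat([panel1.samples, panel2.samples], ignore_index=True),
        np.vstack([g1, g2]),
    )
    merged.n_ambiguous_dropped = n_ambiguous
    merged.n_mismatch_dropped = n_mismatch
    return merged


# --------------------------------------------------------------------------
# Hardy–Weinberg exact test
# --------------------------------------------------------------------------
def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value from genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the
    observed heterozygote count (Levene/Haldane conditional distribution;
    the PLINK/Wigginton convention, without mid-p).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(h) ∝ h ln2 - ln(hom_r!) - ln(h!) - ln(hom_c!)
    logp = hets * np.log(2.0) - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_ab]
    if p_obs.size == 0:  # parity mismatch cannot happen with valid counts
        raise ValueError("heterozygote count incompatible with allele counts")
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))


# --------------------------------------------------------------------------
# QC chain
# --------------------------------------------------------------------------
def filter_qc(
    panel: GenotypePanel,
    variant_call_rate: float = 0.99,
    sample_missing: float = 0.10,
    hwe_p: float = 1e-7,
    maf: float | None = None,
) -> GenotypePanel:
    """Apply the QC chain in fixed order and return the filtered panel.

    Order: (1) drop variants with call rate < *variant_call_rate*;
    (2) drop samples with missingness > *sample_missing*; (3) drop variants
    with HWE exact p < *hwe_p* (computed across all retained samples);
    (4) drop variants with MAF < *maf* if set. Removal counts are logged
    and attached as ``panel.qc_log``.
    """
    for name, thr in (("variant_call_rate", variant_call_rate),
                      ("sample_missing", sample_missing), ("hwe_p", hwe_p)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    log: dict[str, int] = {}

    keep_v = panel.variant_call_rate() >= variant_call_rate
    log["variants_call_rate"] = int((~keep_v).sum())
    panel = panel.subset(variant_idx=np.flatnonzero(keep_v))

    keep_s = panel.sample_missing_rate() <= sample_missing
    log["samples_missingness"] = int((~keep_s).sum())
    panel = panel.subset(sample_idx=np.flatnonzero(keep_s))

    g = panel.genotypes
    n_aa = (g == 0).sum(axis=0)
    n_ab = (g == 1).sum(axis=0)
    n_bb = (g == 2).sum(axis=0)
    hwe = np.array(
        [
            hwe_exact_test(int(a), int(h), int(b)) if a + h + b > 0 else 1.0
            for a, h, b in zip(n_aa, n_ab, n_bb)
        ]
    )
    keep_v = hwe >= hwe_p
    log["variants_hwe"] = int((~keep_v).sum())
    panel = panel.subset(variant_idx=np.flatnonzero(keep_v))

    if maf is not None:
        g = panel.genotypes.astype(float)
        g[g == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            p = np.nanmean(g, axis=0) / 2.0
        m = np.minimum(p, 1 - p)
        keep_v = np.isfinite(m) & (m >= maf)
        log["variants_maf"] = int((~keep_v).sum())
        panel = panel.subset(variant_idx=np.flatnonzero(keep_v))

    if panel.n_variants == 0:
        raise ValueError(
            "QC removed every variant; review thresholds "
            f"(removal counts: {log})"
        )
    logger.info("filter_qc removal counts: %s", log)
    panel.qc_log = log
    return panel


# --------------------------------------------------------------------------
# relatedness
# --------------------------------------------------------------------------
@dataclass
class RelatednessPair:
    """Method-of-moments IBD estimate for one sample pair."""

    sample_i: str
    sample_j: str
    pi_hat: float
    ibd0: float
    ibd1: float
    ibd2: float
    n_informative: int
    low_confidence: bool = False


def estimate_pi_hat(panel: GenotypePanel, min_informative: int = 50) -> list[RelatednessPair]:
    """PI_HAT (proportion IBD) for every sample pair, PLINK-style.

    Method-of-moments on identity-by-state counts against their HWE
    expectations under the panel's sample allele frequencies:
    ``PI_HAT = P(IBD=1)/2 + P(IBD=2)``, truncated into [0, 1]. Pairs with
    fewer than *min_informative* complete polymorphic variants are flagged
    low-confidence.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    g = panel.genotypes.astype(float)
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    informative = np.isfinite(p) & (p > 0) & (p < 1)
    q = 1.0 - p
    # per-variant IBS-class probabilities conditional on IBD state (HWE)
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e1_ibs1 = 2 * p * q
    e1_ibs2 = p**2 + q**2

    pairs: list[RelatednessPair] = []
    ids = panel.sample_ids
    for i in range(panel.n_samples):
        for j in range(i + 1, panel.n_samples):
            gi, gj = g[i], g[j]
            ok = np.isfinite(gi) & np.isfinite(gj) & informative
            n_inf = int(ok.sum())
            diff = np.abs(gi[ok] - gj[ok])
            n_ibs0 = float((diff == 2).sum())
            n_ibs1 = float((diff == 1).sum())
            n_ibs2 = float((diff == 0).sum())
            s0, s1a = e0_ibs0[ok].sum(), e0_ibs1[ok].sum()
            s1b, s2b = e1_ibs1[ok].sum(), e1_ibs2[ok].sum()
            if n_inf == 0 or s0 == 0 or s1b == 0:
                pairs.append(RelatednessPair(ids[i], ids[j], float("nan"),
                                             np.nan, np.nan, np.nan, n_inf, True))
                continue
            p0 = n_ibs0 / s0
            p1 = (n_ibs1 - p0 * s1a) / s1b
            p2 = (n_ibs2 - p0 * (n_inf - s0 - s1a) - p1 * s2b) / n_inf
            probs = np.clip([p0, p1, p2], 0.0, 1.0)
            total = probs.sum()
            if total > 0:
                probs = probs / total
            pi = float(np.clip(probs[1] / 2.0 + probs[2], 0.0, 1.0))
            pairs.append(
                RelatednessPair(ids[i], ids[j], pi, *probs, n_inf,
                                low_confidence=n_inf < min_informative)
            )
    return pairs


def remove_related(panel: GenotypePanel, pi_hat_max: float = 0.35) -> GenotypePanel:
    """Drop one member (the higher-missingness one) of each pair with PI_HAT > threshold."""
    pairs = estimate_pi_hat(panel)
    miss = dict(zip(panel.sample_ids, panel.sample_missing_rate()))
    drop: set[str] = set()
    for pr in sorted(pairs, key=lambda x: -(x.pi_hat if np.isfinite(x.pi_hat) else -1)):
        if not np.isfinite(pr.pi_hat) or pr.pi_hat <= pi_hat_max:
            continue
        if pr.sample_i in drop or pr.sample_j in drop:
            continue
        worse = pr.sample_i if miss[pr.sample_i] >= miss[pr.sample_j] else pr.sample_j
        drop.add(worse)
    keep = [i for i, s in enumerate(panel.sample_ids) if s not in drop]
    return panel.subset(sample_idx=keep)


# --------------------------------------------------------------------------
# LD pruning
# --------------------------------------------------------------------------
def ld_prune(
    panel: GenotypePanel,
    r2_max: float = 0.5,
    window_snps: int = 50,
    step_snps: int = 5,
) -> list[str]:
    """Greedy windowed LD pruning; returns retained variant ids in input order.

    Within each sliding window (per chromosome), while any retained pair has
    genotype r² > *r2_max*, the member with the lower call rate is removed
    (tie: the later one in map order).
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError(f"r2_max must be in (0, 1], got {r2_max}")
    call_rate = panel.variant_call_rate()
    chroms = panel.variants["chrom"].to_numpy()
    keep = np.ones(panel.n_variants, dtype=bool)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        m = idx.size
        for start in range(0, max(1, m - window_snps + 1), step_snps):
            win = idx[start : start + window_snps]
            win = win[keep[win]]
            if win.size < 2:
                continue
            r2 = pairwise_r2(panel.genotypes[:, win])
            active = np.ones(win.size, dtype=bool)
            while True:
                sub = np.where(active[:, None] & active[None, :], r2, np.nan)
                np.fill_diagonal(sub, np.nan)
                with np.errstate(invalid="ignore"):
                    offenders = np.argwhere(sub > r2_max)
                if offenders.size == 0:
                    break
                i, j = offenders[0]
                vi, vj = win[i], win[j]
                # remove lower call rate; tie -> later map order
                if call_rate[vi] < call_rate[vj]:
                    victim = i
                elif call_rate[vj] < call_rate[vi]:
                    victim = j
                else:
                    victim = max(i, j)
                active[victim] = False
            keep[win[~active]] = False
    vids = panel.variants["vid"].to_numpy()
    return [vids[i] for i in np.flatnonzero(keep)]
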