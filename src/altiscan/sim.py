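"""Synthetic genotype panels with planted ground truth.

The generator emulates the structure of a genotyped highland/lowland cohort:
many small populations with population-specific drift (Balding–Nichols
model), an altitude covariate spanning roughly 100–4,500 m, a minority of
loci whose derived-allele frequency increases with altitude, haplotype-block
LD from a founder-mosaic model, plantable autozygous segments, optional
admixed populations, and two external lowland reference populations standing
in for an East-Asian-like and a European-like panel.

Every generator is seed-deterministic: identical configuration plus seed
yields a bit-identical panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from altiscan.panel import MISSING, GenotypePanel, PopulationPanel

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_balding_nichols",
    "plant_altitude_selection",
    "simulate_admixed_population",
    "simulate_haplotype_mosaic",
    "plant_roh",
    "simulate_ld_decay_bins",
]


@dataclass
class SimConfig:
    """Configuration of the Balding–Nichols panel generator.

    Defaults define the standard study profile: 20 populations of 10–20
    samples with drift F in [0.01, 0.2], altitudes uniform on 100–4,500 m,
    20,000 variants on 4 chromosomes, 0.5% of loci altitude-selected with a
    frequency shift of 0.15 per km of altitude, ancestral frequencies
    uniform on [0.05, 0.95], plus two external lowland reference
    populations (an East-Asian-like close reference, ``EXC``, and a
    European-like outgroup, ``EXO``).
    """

    n_populations: int = 20
    n_samples: int | Sequence[int] | tuple[int, int] = (10, 20)
    drift_f: float | Sequence[float] | tuple[float, float] = (0.01, 0.2)
    altitude_m: Sequence[float] | tuple[float, float] = (100.0, 4500.0)
    n_variants: int = 20_000
    fraction_selected: float = 0.005
    selection_slope: float = 0.15  # derived-frequency shift per km of altitude
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    # selected loci are drawn from standing variation in this ancestral
    # frequency band: a derived allele already near fixation cannot express
    # an altitude cline (the additive shift saturates at the 0.99 clamp)
    selected_anc_freq_range: tuple[float, float] = (0.05, 0.3)
    n_chrom: int = 4
    bp_spacing: int = 5_000
    cm_per_mb: float = 1.0
    external_references: bool = True
    ref_n_samples: int = 30
    ref_drift_f: tuple[float, float] = (0.02, 0.05)  # (close reference, outgroup)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_selected < 1.0:
            raise ValueError("fraction_selected must be in [0, 1)")
        fs = np.atleast_1d(np.asarray(self.drift_f, dtype=float))
        if ((fs <= 0) | (fs >= 1)).any():
            raise ValueError("drift F must be in (0, 1)")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated panel."""

    selected: dict[str, float] = field(default_factory=dict)  # vid -> slope
    pop_freqs: pd.DataFrame | None = None  # variants (vid index) x population codes
    roh: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    admixture: dict[str, float] = field(default_factory=dict)  # pop code -> lambda
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)
    populations: PopulationPanel | None = None

    def validate_against(self, panel: GenotypePanel) -> None:
        vids = set(panel.variants["vid"])
        missing = set(self.selected) - vids
        if missing:
            raise ValueError(f"selected ids absent from panel: {sorted(missing)}")


def _variant_table(n_variants: int, n_chrom: int, bp_spacing: int, cm_per_mb: float) -> pd.DataFrame:
    per_chrom = int(np.ceil(n_variants / n_chrom))
    chroms, positions = [], []
    for c in range(n_chrom):
        k = min(per_chrom, n_variants - c * per_chrom)
        if k <= 0:
            break
        chroms.extend([str(c + 1)] * k)
        positions.extend((np.arange(k) + 1) * bp_spacing)
    pos = np.asarray(positions)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "vid": [f"v{i:06d}" for i in range(len(pos))],
            "allele_a": "A",
            "allele_b": "G",
            "ancestral": "a",  # allele_b is the derived allele by construction
            "cm": pos * 1e-6 * cm_per_mb,
        }
    )


def _resolve_per_pop(value, n_pops: int, rng: np.random.Generator, integer: bool) -> np.ndarray:
    """Expand a scalar, (lo, hi) range, or explicit sequence to one value per population."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == n_pops and n_pops != 2:
        out = arr
    elif arr.size == 2 and n_pops != 2:
        lo, hi = arr
        out = rng.integers(int(lo), int(hi) + 1, n_pops).astype(float) if integer else rng.uniform(lo, hi, n_pops)
    elif arr.size == n_pops:
        out = arr
    elif arr.size == 1:
        out = np.full(n_pops, arr[0])
    elif arr.size == 2:
        lo, hi = arr
        out = rng.integers(int(lo), int(hi) + 1, n_pops).astype(float) if integer else rng.uniform(lo, hi, n_pops)
    else:
        raise ValueError(f"cannot broadcast {arr.size} values to {n_pops} populations")
    return out


def simulate_balding_nichols(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Simulate a structured multi-population panel under the Balding–Nichols model.

    For each variant an ancestral derived-allele frequency ``p`` is drawn,
    each population's frequency is drawn from
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` (mean ``p``, variance ``p(1-p)F``),
    and diploid genotypes are Binomial(2, p_pop). The ancestral allele is
    recorded so the derived-allele frequency is known. If the configuration
    requests selected loci they are planted via
    :func:`plant_altitude_selection`; external reference populations (codes
    ``EXC``, ``EXO``, altitude 0, never selected) are appended last.

    Returns the panel and a :class:`SimTruth` carrying the planted truth and
    the :class:`PopulationPanel` (also on ``truth.populations``).
    """
    rng = np.random.default_rng(config.seed)
    n_pops = config.n_populations
    n_samp = _resolve_per_pop(config.n_samples, n_pops, rng, integer=True).astype(int)
    drift = _resolve_per_pop(config.drift_f, n_pops, rng, integer=False)
    alts = _resolve_per_pop(config.altitude_m, n_pops, rng, integer=False)

    codes = [f"P{k:02d}" for k in range(1, n_pops + 1)]
    regions = ["highland" if a >= 2500 else "lowland" for a in alts]
    if config.external_references:
        codes += ["EXC", "EXO"]
        n_samp = np.append(n_samp, [config.ref_n_samples, config.ref_n_samples])
        drift = np.append(drift, list(config.ref_drift_f))
        alts = np.append(alts, [0.0, 0.0])
        regions += ["external", "external"]

    variants = _variant_table(
        config.n_variants, config.n_chrom, config.bp_spacing, config.cm_per_mb
    )
    m = len(variants)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, m)

    pop_freqs = np.empty((m, len(codes)))
    geno_blocks = []
    sample_rows = []
    for k, code in enumerate(codes):
        f = drift[k]
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        pk = rng.beta(a, b)
        pop_freqs[:, k] = pk
        geno_blocks.append(rng.binomial(2, pk, size=(n_samp[k], m)).astype(np.int8))
        sample_rows.extend((f"{code}_{i:03d}", code) for i in range(n_samp[k]))

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])
    panel = GenotypePanel(variants, samples, np.vstack(geno_blocks))
    pops = PopulationPanel(
        pd.DataFrame(
            {
                "code": codes,
                "altitude_m": alts,
                "region": regions,
                "language": "",
                "n_samples": n_samp,
            }
        )
    )
    truth = SimTruth(
        pop_freqs=pd.DataFrame(pop_freqs, index=variants["vid"], columns=codes),
        populations=pops,
    )
    if config.fraction_selected > 0:
        n_sel = int(round(config.fraction_selected * m))
        lo_s, hi_s = config.selected_anc_freq_range
        eligible = np.flatnonzero((p_anc >= lo_s) & (p_anc <= hi_s))
        if eligible.size < n_sel:
            eligible = np.arange(m)
        loci = np.sort(rng.choice(eligible, size=n_sel, replace=False))
        panel, truth = plant_altitude_selection(
            panel,
            truth,
            list(variants["vid"].iloc[loci]),
            config.selection_slope,
            seed=rng.integers(0, 2**31 - 1),
        )
    return panel, truth


def plant_altitude_selection(
    panel: GenotypePanel,
    truth: SimTruth,
    loci: Sequence[str],
    slope_s: float,
    seed: int | None = None,
) -> tuple[GenotypePanel, SimTruth]:
    """Plant altitude-coupled selection at the given loci.

    For each chosen locus, every population's derived frequency is shifted
    to ``clip(p + slope_s * altitude_km, 0.01, 0.99)`` and that population's
    genotypes at the locus are redrawn; external reference populations
    (altitude 0) are shifted by 0, i.e. only redrawn. All other loci are
    untouched (bit-exact). Truth gains the locus -> slope map and the
    updated population frequencies.
    """
    if truth.pop_freqs is None or truth.populations is None:
        raise ValueError("truth must carry pop_freqs and populations")
    vid_index = {v: i for i, v in enumerate(panel.variants["vid"])}
    missing = [v for v in loci if v not in vid_index]
    if missing:
        raise KeyError(f"loci not in panel: {missing}")
    rng = np.random.default_rng(seed)
    panel = panel.copy()
    truth = SimTruth(
        selected=dict(truth.selected),
        pop_freqs=truth.pop_freqs.copy(),
        roh={k: list(v) for k, v in truth.roh.items()},
        admixture=dict(truth.admixture),
        pedigree=dict(truth.pedigree),
        populations=truth.populations,
    )
    pops = truth.populations
    alt_km = pops.table.set_index("code")["altitude_m"] / 1000.0
    anc = panel.variants["ancestral"].to_numpy()
    n_all_fixed = 0
    for vid in loci:
        i = vid_index[vid]
        shifted_all = []
        for code in truth.pop_freqs.columns:
            p_old = truth.pop_freqs.at[vid, code]
            p_new = float(np.clip(p_old + slope_s * alt_km[code], 0.01, 0.99))
            shifted_all.append(p_new)
            truth.pop_freqs.at[vid, code] = p_new
            idx = panel.population_indices(code)
            # pop_freqs are derived-allele frequencies; genotypes count allele_b
            p_b = 1.0 - p_new if anc[i] == "b" else p_new
            panel.genotypes[idx, i] = rng.binomial(2, p_b, size=idx.size).astype(np.int8)
        if all(p in (0.01, 0.99) for p in shifted_all):
            n_all_fixed += 1
        truth.selected[vid] = slope_s
    if n_all_fixed:
        warnings.warn(
            f"slope {slope_s} drove {n_all_fixed} locus/loci to the clamping "
            "bounds in every population",
            stacklevel=2,
        )
    return panel, truth


def simulate_admixed_population(
    freqs_a: np.ndarray,
    freqs_b: np.ndarray,
    lam: float,
    n_samples: int,
    seed: int | None = None,
) -> np.ndarray:
    """Genotypes of a population admixed as λ·A + (1-λ)·B at the frequency level."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    freqs_a = np.asarray(freqs_a, dtype=float)
    freqs_b = np.asarray(freqs_b, dtype=float)
    rng = np.random.default_rng(seed)
    p = lam * freqs_a + (1 - lam) * freqs_b
    return rng.binomial(2, p, size=(n_samples, p.size)).astype(np.int8)


def simulate_haplotype_mosaic(
    n_samples: int,
    n_variants: int = 2_000,
    n_founders: int = 20,
    n_chrom: int = 1,
    bp_spacing: int = 10_000,
    cm_per_mb: float = 1.0,
    founder_freq_range: tuple[float, float] = (0.1, 0.9),
    seed: int | None = None,
) -> tuple[GenotypePanel, np.ndarray]:
    """Diploid panel whose haplotypes are mosaics of a founder pool.

    Each of the 2·n_samples haplotypes walks along the chromosome copying
    one of *n_founders* founder haplotypes, switching to a uniformly chosen
    founder with probability equal to the inter-variant genetic distance in
    Morgans (constant *cm_per_mb* map). Small founder pools produce strong
    haplotype-block LD that decays with genetic distance — the structure the
    LD-based Ne estimator consumes.

    Returns the panel (samples are population ``MOS``) and the phased
    haplotype matrix of shape (2·n_samples, n_variants).
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    variants = _variant_table(n_variants, n_chrom, bp_spacing, cm_per_mb)
    m = len(variants)
    lo, hi = founder_freq_range
    founder_p = rng.uniform(lo, hi, m)
    founders = (rng.random((n_founders, m)) < founder_p).astype(np.int8)

    cm = variants["cm"].to_numpy()
    new_chrom = variants["chrom"].to_numpy()
    d_morgan = np.zeros(m)
    d_morgan[1:] = np.diff(cm) / 100.0
    d_morgan[1:][new_chrom[1:] != new_chrom[:-1]] = 1.0  # chromosome break
    switch_p = np.clip(d_morgan, 0.0, 1.0)
    switch_p[0] = 1.0  # initial founder draw

    n_hap = 2 * n_samples
    switches = rng.random((n_hap, m)) < switch_p[None, :]
    choices = rng.integers(0, n_founders, size=(n_hap, m))
    seg = np.cumsum(switches, axis=1) - 1  # segment index per site
    founder_idx = np.take_along_axis(choices, seg, axis=1)
    haplotypes = founders[founder_idx, np.arange(m)[None, :]]

    geno = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    samples = pd.DataFrame(
        {"sample_id": [f"MOS_{i:03d}" for i in range(n_samples)], "population": "MOS"}
    )
    return GenotypePanel(variants, samples, geno), haplotypes


def plant_roh(
    panel: GenotypePanel,
    sample: str,
    chrom: str,
    start_idx: int,
    n_snps: int,
    truth: SimTruth | None = None,
    seed: int | None = None,
) -> GenotypePanel:
    """Plant an autozygous segment: make *n_snps* consecutive genotypes homozygous.

    ``start_idx`` indexes the variants of *chrom* (0-based). Within the
    interval each heterozygous call is collapsed to one of its alleles
    (copying a single haplotype, chosen at random per site); homozygous and
    missing calls are unchanged, as is everything outside the interval.
    Overlapping planted intervals for one sample raise an error. The truth
    object, when given, records ``(chrom, start_idx, n_snps)``.
    """
    panel = panel.copy()
    if n_snps == 0:
        return panel
    chrom_idx = np.flatnonzero(panel.variants["chrom"].to_numpy() == str(chrom))
    if start_idx < 0 or start_idx + n_snps > chrom_idx.size:
        raise ValueError(
            f"interval [{start_idx}, {start_idx + n_snps}) outside chromosome "
            f"{chrom} ({chrom_idx.size} variants)"
        )
    if truth is not None:
        for c, s, n in truth.roh.get(sample, []):
            if c == str(chrom) and s < start_idx + n_snps and start_idx < s + n:
                raise ValueError(
                    f"planted ROH overlaps existing interval ({c}, {s}, {n}) "
                    f"for sample {sample}"
                )
        truth.roh.setdefault(sample, []).append((str(chrom), start_idx, n_snps))
    rng = np.random.default_rng(seed)
    row = int(panel.sample_indices([sample])[0])
    cols = chrom_idx[start_idx : start_idx + n_snps]
    g = panel.genotypes[row, cols]
    het = g == 1
    g[het] = (2 * rng.integers(0, 2, size=int(het.sum()))).astype(np.int8)
    panel.genotypes[row, cols] = g
    return panel


def simulate_ld_decay_bins(
    ne: float,
    alpha: float,
    c_bins: Sequence[float],
    n_chrom: int = 1,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Synthetic adjusted-r² LD-decay bins following 1/(α + 4·Ne·c).

    Per bin, *n_chrom* replicate values with Gaussian noise are averaged and
    the result truncated at 0. With ``noise_sd=0`` the bins are exactly on
    the curve, which makes them a closed-form oracle for the Ne fit.
    """
    if ne <= 0:
        raise ValueError("Ne must be positive")
    c = np.asarray(c_bins, dtype=float)
    if (np.diff(c) <= 0).any() or (c <= 0).any():
        raise ValueError("c_bins must be positive and ascending")
    rng = np.random.default_rng(seed)
    out = []
    for ci in c:
        base = 1.0 / (alpha + 4.0 * ne * ci)
        vals = base + rng.normal(0.0, noise_sd, size=n_chrom)
        out.append((float(ci), float(max(0.0, vals.mean()))))
    return out
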