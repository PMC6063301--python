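"""Core containers: variants, genotype panels and population metadata.

Genotypes are stored as an ``int8`` matrix of shape (samples, variants)
counting copies of ``allele_b`` (0, 1, 2), with :data:`MISSING` (= -1) for
no-calls. Coordinates are 1-based inclusive and chromosome labels are
normalised without a ``chr`` prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Genotype code for a missing call.
MISSING: int = -1

#: Altitude (metres) at or above which a population counts as high-altitude.
HIGH_ALTITUDE_M: float = 2500.0

VALID_ANCESTRAL = ("a", "b", "unknown")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix from a chromosome label."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP.

    Parameters
    ----------
    chrom : str
        Chromosome label (no ``chr`` prefix).
    pos : int
        1-based base-pair position.
    vid : str
        Variant identifier.
    allele_a, allele_b : str
        The two alleles; genotypes count copies of ``allele_b``.
    ancestral : str
        Which allele is ancestral: ``"a"``, ``"b"`` or ``"unknown"``.
    cm : float or None
        Optional genetic-map position in centimorgans.
    """

    chrom: str
    pos: int
    vid: str
    allele_a: str
    allele_b: str
    ancestral: str = "unknown"
    cm: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.vid}: pos must be >= 1, got {self.pos}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"variant {self.vid}: alleles must differ")
        if self.ancestral not in VALID_ANCESTRAL:
            raise ValueError(
                f"variant {self.vid}: ancestral must be one of {VALID_ANCESTRAL}"
            )


def _variants_frame(variants: Iterable[Variant]) -> pd.DataFrame:
    rows = [
        (v.chrom, v.pos, v.vid, v.allele_a, v.allele_b, v.ancestral, v.cm)
        for v in variants
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "vid", "allele_a", "allele_b", "ancestral", "cm"]
    )


class GenotypePanel:
    """Diploid genotype matrix with linked variant and sample tables.

    Parameters
    ----------
    variants : DataFrame or sequence of Variant
        Columns ``chrom pos vid allele_a allele_b ancestral cm`` (the last
        two optional; defaults ``unknown`` / ``NaN``).
    samples : DataFrame
        Columns ``sample_id`` and ``population``.
    genotypes : ndarray, shape (n_samples, n_variants)
        Counts of ``allele_b`` in {0, 1, 2}, or :data:`MISSING`.
    """

    def __init__(
        self,
        variants: pd.DataFrame | Sequence[Variant],
        samples: pd.DataFrame,
        genotypes: np.ndarray,
    ) -> None:
        if not isinstance(variants, pd.DataFrame):
            variants = _variants_frame(variants)
        else:
            variants = variants.copy()
        if "ancestral" not in variants:
            variants["ancestral"] = "unknown"
        if "cm" not in variants:
            variants["cm"] = np.nan
        variants["chrom"] = variants["chrom"].map(normalize_chrom)
        samples = samples.copy().reset_index(drop=True)
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(samples), len(variants)):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")
        if samples["sample_id"].duplicated().any():
            dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        self.variants = variants.reset_index(drop=True)
        self.samples = samples
        self.genotypes = genotypes

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GenotypePanel {self.n_samples} samples x {self.n_variants} variants>"
        )

    # --------------------------------------------------------------- missing
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where genotype is missing."""
        return self.genotypes == MISSING

    def variant_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per variant."""
        if self.n_samples == 0:
            return np.ones(self.n_variants)
        return 1.0 - self.missing_mask().mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per sample."""
        if self.n_variants == 0:
            return np.zeros(self.n_samples)
        return self.missing_mask().mean(axis=1)

    # --------------------------------------------------------------- subsets
    def subset(
        self,
        sample_idx: np.ndarray | Sequence[int] | None = None,
        variant_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypePanel":
        """Return a panel restricted to the given sample/variant indices."""
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypePanel(
            self.variants.iloc[v].reset_index(drop=True),
            self.samples.iloc[s].reset_index(drop=True),
            self.genotypes[np.ix_(s, v)],
        )

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {sid: i for i, sid in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample id not in panel: {e.args[0]}") from None

    def population_indices(self, code: str) -> np.ndarray:
        """Row indices of all samples belonging to population *code*."""
        return np.flatnonzero(self.samples["population"].to_numpy() == code)

    # ------------------------------------------------------------ polarization
    def derived_dosage(self) -> np.ndarray:
        """Genotypes recoded to count the derived allele (float, NaN-masked).

        Variants with unknown ancestral state yield all-NaN columns; where the
        ancestral allele is ``allele_b`` the dosage is flipped to ``2 - g``.
        """
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        anc = self.variants["ancestral"].to_numpy()
        flip = anc == "b"
        g[:, flip] = 2.0 - g[:, flip]
        g[:, anc == "unknown"] = np.nan
        return g

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            self.variants.copy(), self.samples.copy(), self.genotypes.copy()
        )


@dataclass
class PopulationPanel:
    """Population-level metadata: altitude, region, language, sample counts.

    The table has one row per population with columns
    ``code altitude_m region language n_samples``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        required = {"code", "altitude_m", "n_samples"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"population table missing columns: {sorted(missing)}")
        if "region" not in t:
            t["region"] = ""
        if "language" not in t:
            t["language"] = ""
        if t["code"].duplicated().any():
            raise ValueError("population codes must be unique")
        if (t["altitude_m"] < 0).any():
            raise ValueError("altitude_m must be >= 0")
        if (t["n_samples"] < 1).any():
            raise ValueError("every population needs n_samples >= 1")
        self.table = t

    @property
    def codes(self) -> np.ndarray:
        return self.table["code"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def altitude_of(self, code: str) -> float:
        row = self.table.loc[self.table["code"] == code, "altitude_m"]
        if row.empty:
            raise KeyError(f"unknown population code {code!r}")
        return float(row.iloc[0])

    def altitudes(self, codes: Iterable[str] | None = None) -> np.ndarray:
        """Altitudes (m) for the given codes, in order (default: all)."""
        if codes is None:
            return self.table["altitude_m"].to_numpy(dtype=float)
        return np.array([self.altitude_of(c) for c in codes], dtype=float)

    def is_high_altitude(self, code: str, threshold_m: float = HIGH_ALTITUDE_M) -> bool:
        """True if the population resides at or above *threshold_m* metres."""
        return self.altitude_of(code) >= threshold_m

    def high_altitude_codes(self, threshold_m: float = HIGH_ALTITUDE_M) -> list[str]:
        t = self.table
        return list(t.loc[t["altitude_m"] >= threshold_m, "code"])

    def sample_altitudes(self, panel: GenotypePanel) -> np.ndarray:
        """Per-sample altitude: each sample inherits its population's altitude."""
        alt = dict(zip(self.table["code"], self.table["altitude_m"]))
        pops = panel.samples["population"]
        unknown = sorted(set(pops) - set(alt))
        if unknown:
            raise KeyError(f"samples from populations without metadata: {unknown}")
        return pops.map(alt).to_numpy(dtype=float)
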