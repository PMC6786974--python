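"""Core in-memory containers: genotype dosages and phenotype tables.

Genotypes are held as an N x M dosage matrix (expected non-reference allele
count in [0, 2]) with a per-variant metadata frame; phenotypes as an N x P
matrix with NaN missingness and a group label per phenotype.  Phenotype
groups model the situation where phenotypes derived from the same modality
share one missing-sample pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

#: columns every variant metadata frame carries, in canonical order
VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "cm", "info", "maf"]


def dosage_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per variant from mean dosage: min(f, 1-f) with
    f = mean(dosage)/2."""
    f = np.asarray(dosages, dtype=float).mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


@dataclass
class GenotypeSet:
    """Dosage matrix plus per-variant metadata.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, one per dosage row.
    dosages : ndarray, shape (N, M)
        Expected non-reference allele counts in [0, 2].
    variants : DataFrame
        One row per variant with columns ``id, chrom, pos, ref, alt, cm,
        info, maf`` (``cm`` is the genetic-map position in centimorgans,
        ``info`` the imputation-quality score).
    hard_calls : ndarray or None, shape (N, M)
        Latent integer genotypes when known (simulation) — used for the
        Hardy-Weinberg filter; otherwise dosages are rounded on demand.
    """

    samples: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame
    hard_calls: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ParameterError(f"{len(self.samples)} samples but {n} dosage rows")
        if len(self.variants) != m:
            raise ParameterError(f"{len(self.variants)} variant records but {m} dosage columns")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ParameterError("dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        if "maf" not in self.variants.columns:
            self.variants["maf"] = dosage_maf(self.dosages)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def get_hard_calls(self) -> np.ndarray:
        """Integer genotypes: recorded ones if present, else rounded dosages."""
        if self.hard_calls is not None:
            return self.hard_calls
        return np.clip(np.rint(self.dosages), 0, 2).astype(np.int8)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeSet(
            samples=list(self.samples),
            dosages=self.dosages[:, keep],
            variants=self.variants.iloc[keep].reset_index(drop=True),
            hard_calls=None if self.hard_calls is None else self.hard_calls[:, keep],
        )


@dataclass
class PhenotypeTable:
    """N x P phenotype matrix with NaN missingness and per-phenotype groups."""

    samples: list[str]
    values: np.ndarray
    names: list[str]
    groups: list[str] = field(default_factory=list)
    prepared: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.samples) != n:
            raise ParameterError(f"{len(self.samples)} samples but {n} phenotype rows")
        if len(self.names) != p:
            raise ParameterError(f"{len(self.names)} names but {p} phenotype columns")
        if not self.groups:
            self.groups = ["all"] * p
        if len(self.groups) != p:
            raise ParameterError("one group label per phenotype required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean sample mask of non-missing rows shared by a group."""
        cols = [i for i, g in enumerate(self.groups) if g == group]
        return ~np.isnan(self.values[:, cols]).any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "sample_id", self.samples)
        return df
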