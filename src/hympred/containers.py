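"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in integer-coded matrices.
MISSING: int = -1

#: Columns every variant table carries (``depth`` is the per-site mean read depth).
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "depth")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of alternate-allele counts.

    Genotypes are coded 0/1/2 (count of the alternate allele in a diploid
    female) with :data:`MISSING` (-1) for no-calls.  ``variants`` holds one
    row per SNP with 1-based positions; ``geno_depth`` optionally carries
    per-genotype read depths with the same shape as ``codes``.
    """

    codes: np.ndarray
    ids: list[str]
    variants: pd.DataFrame
    geno_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D individuals x SNPs array")
        if self.codes.shape[0] != len(self.ids):
            raise ValueError(
                f"{self.codes.shape[0]} genotype rows but {len(self.ids)} ids"
            )
        if self.codes.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.codes.shape[1]} genotype columns but "
                f"{len(self.variants)} variant records"
            )
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns: {missing_cols}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the genotype call is missing."""
        return self.codes == MISSING

    def dosages(self) -> np.ndarray:
        """Float copy of the codes with missing calls as NaN."""
        out = self.codes.astype(float)
        out[self.codes == MISSING] = np.nan
        return out

    def subset(
        self,
        individuals: np.ndarray | None = None,
        variants: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        var = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        depth = None
        if self.geno_depth is not None:
            depth = self.geno_depth[np.ix_(ind, var)]
        return GenotypeMatrix(
            codes=self.codes[np.ix_(ind, var)],
            ids=[self.ids[i] for i in ind],
            variants=self.variants.iloc[var].reset_index(drop=True),
            geno_depth=depth,
        )


@dataclass
class SampleTable:
    """Per-individual metadata: generation label, optional host id, traits.

    Thin wrapper over a DataFrame with reserved columns ``id``,
    ``generation`` and ``host``; every other column is a trait.
    """

    frame: pd.DataFrame
    trait_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("id", "generation"):
            if col not in self.frame.columns:
                raise ValueError(f"sample table needs an '{col}' column")
        if "host" not in self.frame.columns:
            self.frame = self.frame.assign(host=pd.NA)
        if not self.trait_columns:
            reserved = {"id", "generation", "host"}
            self.trait_columns = [c for c in self.frame.columns if c not in reserved]

    def __len__(self) -> int:
        return len(self.frame)
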