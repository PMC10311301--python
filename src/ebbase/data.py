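"""In-memory container for gene-level allelic count tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CountsTable"]

# chromosome labels treated as non-autosomal when autosome filtering is on
_NON_AUTOSOMES = {"X", "Y", "M", "MT", "W", "Z"}


def is_autosome(label: str) -> bool:
    """Heuristic autosome check: numeric label (optionally 'chr'-prefixed)."""
    name = str(label)
    if name.lower().startswith("chr"):
        name = name[3:]
    return name.upper() not in _NON_AUTOSOMES


@dataclass
class CountsTable:
    """genes x libraries maternal/paternal allelic counts.

    ``m`` and ``p`` are integer DataFrames indexed by gene_id with one
    column per library; ``chromosome`` is an optional per-gene Series
    aligned to the same index.
    """

    m: pd.DataFrame
    p: pd.DataFrame
    chromosome: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.m.index.equals(self.p.index) or list(self.m.columns) != list(
            self.p.columns
        ):
            raise ValueError("maternal and paternal tables must share genes and samples")
        if self.m.index.has_duplicates:
            dupes = self.m.index[self.m.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        for df, name in ((self.m, "maternal"), (self.p, "paternal")):
            vals = df.to_numpy()
            if not np.issubdtype(vals.dtype, np.integer):
                raise ValueError(f"{name} counts must be integers")
            if (vals < 0).any():
                raise ValueError(f"negative {name} counts present")
        if self.chromosome is not None and not self.chromosome.index.equals(self.m.index):
            raise ValueError("chromosome labels must align with the gene index")

    @property
    def gene_ids(self) -> pd.Index:
        return self.m.index

    @property
    def samples(self) -> list[str]:
        return list(self.m.columns)

    @property
    def n_genes(self) -> int:
        return self.m.shape[0]

    @property
    def n_samples(self) -> int:
        return self.m.shape[1]

    def totals(self) -> pd.DataFrame:
        """Per-gene, per-library total allelic coverage n = m + p."""
        return self.m + self.p

    def total_counts_per_sample(self) -> pd.Series:
        return self.totals().sum(axis=0)

    def autosomal_mask(self) -> np.ndarray:
        """Boolean gene mask; all-True when no chromosome labels are present."""
        if self.chromosome is None:
            return np.ones(self.n_genes, dtype=bool)
        return self.chromosome.map(is_autosome).to_numpy(dtype=bool)

    def select_samples(self, samples: list[str]) -> "CountsTable":
        chrom = self.chromosome
        return CountsTable(self.m[samples].copy(), self.p[samples].copy(), chrom)

    def subset_genes(self, mask_or_index) -> "CountsTable":
        m = self.m.loc[mask_or_index] if not isinstance(mask_or_index, np.ndarray) else self.m[mask_or_index]
        p = self.p.loc[m.index]
        chrom = self.chromosome.loc[m.index] if self.chromosome is not None else None
        return CountsTable(m.copy(), p.copy(), chrom)

    @classmethod
    def from_arrays(
        cls,
        gene_ids,
        samples,
        m: np.ndarray,
        p: np.ndarray,
        chromosome=None,
    ) -> "CountsTable":
        idx = pd.Index(gene_ids, name="gene_id")
        mdf = pd.DataFrame(np.asarray(m, dtype=np.int64), index=idx, columns=samples)
        pdf = pd.DataFrame(np.asarray(p, dtype=np.int64), index=idx, columns=samples)
        chrom = pd.Series(chromosome, index=idx, name="chromosome") if chromosome is not None else None
        return cls(mdf, pdf, chrom)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountsTable):
            return NotImplemented
        same_chrom = (
            self.chromosome is None
            and other.chromosome is None
            or (
                self.chromosome is not None
                and other.chromosome is not None
                and self.chromosome.equals(other.chromosome)
            )
        )
        return self.m.equals(other.m) and self.p.equals(other.p) and same_chrom
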