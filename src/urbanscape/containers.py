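"""Core in-memory containers shared across the pipeline.

Genotypes are held as an individuals x loci dosage matrix (0/1/2 copies of
the alternate allele, ``nan`` for missing) together with per-genotype read
depths and locus/individual metadata tables.  Pairwise quantities
(differentiation, geographic distance, effective resistance) travel as
labelled symmetric matrices with a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt", "locus_id"]
INDIVIDUAL_COLUMNS = ["id", "colony_id"]

MATRIX_KINDS = {"fst", "linearised_fst", "geo_km", "resistance", "other"}


@dataclass
class GenotypeTable:
    """Bi-allelic SNP genotypes for a set of individuals.

    Parameters
    ----------
    dosages : ndarray, shape (n_individuals, n_loci)
        Count of alternate alleles in {0, 1, 2}; ``nan`` marks a missing
        genotype.
    depths : ndarray, same shape
        Per-genotype sequencing depth; ``nan`` where unknown.
    loci : DataFrame with columns chrom, pos (1-based), ref, alt, locus_id
    individuals : DataFrame with columns id, colony_id (and optionally sex)
    """

    dosages: np.ndarray
    depths: np.ndarray
    loci: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.dosages.shape != self.depths.shape:
            raise ValueError("dosages and depths must have the same shape")
        if self.dosages.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        missing = set(LOCUS_COLUMNS) - set(self.loci.columns)
        if missing:
            raise ValueError(f"loci table missing columns {sorted(missing)}")
        missing = set(INDIVIDUAL_COLUMNS) - set(self.individuals.columns)
        if missing:
            raise ValueError(f"individuals table missing columns {sorted(missing)}")
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("duplicate locus_id")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or nan")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def colony_ids(self) -> np.ndarray:
        return self.individuals["colony_id"].to_numpy()

    def subset_loci(self, keep: np.ndarray) -> "GenotypeTable":
        """Return a new table restricted to loci selected by boolean or index array."""
        keep = np.asarray(keep)
        return GenotypeTable(
            dosages=self.dosages[:, keep].copy(),
            depths=self.depths[:, keep].copy(),
            loci=self.loci.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep]
            .reset_index(drop=True),
            individuals=self.individuals.reset_index(drop=True),
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            self.dosages.copy(),
            self.depths.copy(),
            self.loci.copy(),
            self.individuals.copy(),
        )


@dataclass
class SymmetricMatrix:
    """Labelled symmetric pairwise matrix with zero diagonal."""

    labels: list
    values: np.ndarray
    kind: str = "other"

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle vectorisation (excluding the diagonal), row-major."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def pair_labels(self) -> list[tuple]:
        i, j = np.tril_indices(self.n, k=-1)
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]

    def reindex(self, labels: list) -> "SymmetricMatrix":
        """Reorder rows/columns to the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return SymmetricMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="label")

    @classmethod
    def from_tsv(cls, path, kind: str = "other") -> "SymmetricMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), kind)

    @classmethod
    def from_condensed(
        cls, labels: list, condensed: np.ndarray, kind: str = "other"
    ) -> "SymmetricMatrix":
        n = len(labels)
        values = np.zeros((n, n))
        i, j = np.tril_indices(n, k=-1)
        values[i, j] = condensed
        values[j, i] = condensed
        return cls(labels, values, kind)


def check_shared_labels(*matrices: SymmetricMatrix) -> list:
    """Assert all matrices carry the same label set; return the first's order."""
    ref = matrices[0].labels
    for m in matrices[1:]:
        if set(m.labels) != set(ref):
            raise ValueError("matrices do not share labels")
    return ref
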