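"""Core data containers shared across the package.

Genotypes are held as an animals x markers matrix of allele counts
(0/1/2 copies of the counted allele A), phenotypes as a tidy table of
repeated records.  Both round-trip through plain-text formats: a simple
TSV dialect and, for genotypes, the PLINK ``.raw`` additive dosage layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "PhenotypeRecords",
    "read_genotypes_tsv",
    "read_genotypes_plink_raw",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
]

PHENOTYPE_COLUMNS = ["animal_id", "sire_id", "trait", "value"]


@dataclass
class GenotypeTable:
    """Animals x SNPs allele-count matrix with id metadata.

    Parameters
    ----------
    counts
        Integer matrix of shape (n_animals, n_snps) with entries in {0,1,2}
        counting copies of the designated A allele.
    animal_ids
        One id per row.
    marker_ids
        One id per column.
    sires
        Optional sire id per animal (paternal half-sib structure); aligned
        to ``animal_ids``.
    """

    counts: np.ndarray
    animal_ids: list[str]
    marker_ids: list[str]
    sires: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("genotype counts must be a 2-D matrix")
        n, m = self.counts.shape
        if len(self.animal_ids) != n:
            raise ValueError(f"{len(self.animal_ids)} animal ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if self.sires is not None and len(self.sires) != n:
            raise ValueError("sire list must align with animal ids")
        bad = ~np.isin(self.counts, (0, 1, 2))
        if bad.any():
            raise ValueError("genotype entries must be allele counts in {0,1,2}")

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.animal_ids, name="animal_id"),
            columns=self.marker_ids,
        )

    def subset(self, animal_ids: Sequence[str]) -> "GenotypeTable":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = [pos[a] for a in animal_ids]
        sires = [self.sires[i] for i in idx] if self.sires is not None else None
        return GenotypeTable(
            self.counts[idx], list(animal_ids), list(self.marker_ids), sires
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        """Write rows=animals, columns=SNPs, first column ``animal_id``."""
        self.to_frame().to_csv(path, sep="\t")

    def to_plink_raw(self, path: str | Path) -> None:
        """Write the PLINK ``--recode A`` dialect.

        Columns FID IID PAT MAT SEX PHENOTYPE then one dosage column per
        SNP named ``<marker>_A``.  The PAT column carries the sire id.
        """
        sires = self.sires if self.sires is not None else ["0"] * self.n_animals
        meta = pd.DataFrame(
            {
                "FID": self.animal_ids,
                "IID": self.animal_ids,
                "PAT": sires,
                "MAT": ["0"] * self.n_animals,
                "SEX": [0] * self.n_animals,
                "PHENOTYPE": [-9] * self.n_animals,
            }
        )
        dosages = pd.DataFrame(
            self.counts, columns=[f"{m}_A" for m in self.marker_ids]
        )
        pd.concat([meta, dosages], axis=1).to_csv(path, sep=" ", index=False)


def read_genotypes_tsv(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeTable(
        df.to_numpy(dtype=np.int8),
        [str(a) for a in df.index],
        [str(m) for m in df.columns],
    )


def read_genotypes_plink_raw(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"not a PLINK RAW file; missing columns {missing}")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    markers = [c[:-2] if c.endswith("_A") else c for c in snp_cols]
    sires = [str(s) for s in df["PAT"]]
    return GenotypeTable(
        df[snp_cols].to_numpy(dtype=np.int8),
        [str(a) for a in df["IID"]],
        markers,
        sires=None if all(s == "0" for s in sires) else sires,
    )


@dataclass
class PhenotypeRecords:
    """Repeated phenotype records, one row per record.

    Thin wrapper over a tidy DataFrame with columns
    (animal_id, sire_id, trait, value); one animal may contribute many rows.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PHENOTYPE_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        self.data = self.data[PHENOTYPE_COLUMNS].reset_index(drop=True)
        if len(self.data) and not np.isfinite(self.data["value"].to_numpy(float)).all():
            raise ValueError("phenotype record values must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def animal_ids(self) -> list[str]:
        return [str(a) for a in self.data["animal_id"]]

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    def with_values(self, values: Iterable[float]) -> "PhenotypeRecords":
        out = self.data.copy()
        out["value"] = np.asarray(list(values), dtype=float)
        return PhenotypeRecords(out)

    def animal_means(self) -> pd.Series:
        """Per-animal mean of record values (the animal-level phenotype)."""
        return self.data.groupby("animal_id", sort=False)["value"].mean()

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> PhenotypeRecords:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "sire_id": str})
    return PhenotypeRecords(df)


def write_phenotypes_tsv(records: PhenotypeRecords, path: str | Path) -> None:
    records.to_tsv(path)
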