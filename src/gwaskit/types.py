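"""Core in-memory containers for summary statistics and reference data.

The atomic record is one SNP-trait association; a study is a
:class:`SumstatsTable` (metadata + one pandas DataFrame in the canonical
column layout).  The harmonization/QC reference is a :class:`ReferencePanel`
carrying a SNP map and a phased 0/1 haplotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

#: Canonical column order of the universal summary-statistics format.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "Z", "N"]

#: Study domains recognised by the registry.
DOMAINS = ("complex_trait", "mQTL", "pQTL", "glycan", "eQTL")

VALID_ALLELES = frozenset("ACGT")

_FLOAT_COLS = ("EAF", "BETA", "SE", "P", "Z", "N")
_STR_COLS = ("SNP", "CHR", "EA", "OA")


@dataclass
class StudyMetadata:
    """Descriptive metadata attached to one set of summary statistics."""

    study_id: str
    trait_name: str
    domain: str
    collection: str = ""
    sample_size: int | None = None
    ancestry: str = ""
    genome_build: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(
                f"domain {self.domain!r} not in {DOMAINS}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyMetadata":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class ParseReport:
    """Row-level accounting from reading one source file."""

    n_input: int = 0
    n_kept: int = 0
    n_bad_coords: int = 0
    n_bad_alleles: int = 0
    n_duplicate_ids: int = 0


def empty_frame() -> pd.DataFrame:
    """An empty DataFrame in the canonical layout."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in CANONICAL_COLUMNS})
    return _coerce_dtypes(df)


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in _STR_COLS:
        out[c] = out[c].astype("string").astype(object)
    out["POS"] = pd.to_numeric(out["POS"], errors="coerce").astype("int64")
    for c in _FLOAT_COLS:
        out[c] = pd.to_numeric(out[c], errors="coerce").astype(float)
    return out


@dataclass
class SumstatsTable:
    """One study's summary statistics: metadata plus canonical records.

    ``df`` holds columns ``SNP CHR POS EA OA EAF BETA SE P Z N``; missing
    values are NaN.  Record order is meaningful (sorted by chromosome and
    position after harmonization).
    """

    metadata: StudyMetadata
    df: pd.DataFrame
    parse_report: ParseReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing canonical columns: {missing}")
        self.df = _coerce_dtypes(self.df[CANONICAL_COLUMNS]).reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def copy(self) -> "SumstatsTable":
        return SumstatsTable(self.metadata, self.df.copy(), self.parse_report)

    def sort(self) -> "SumstatsTable":
        """Return a copy sorted by (CHR, POS)."""
        key = _chrom_sort_key(self.df["CHR"])
        df = (
            self.df.assign(_ck=key)
            .sort_values(["_ck", "POS"], kind="mergesort")
            .drop(columns="_ck")
            .reset_index(drop=True)
        )
        return SumstatsTable(self.metadata, df, self.parse_report)

    def zscores(self) -> pd.Series:
        """Z per record: the Z column where present, else BETA/SE."""
        z = self.df["Z"].copy()
        fallback = self.df["BETA"] / self.df["SE"]
        return z.where(z.notna(), fallback)


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering (1..22 < X < Y < MT < other)."""
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}

    def one(c: str) -> tuple:
        c = str(c).removeprefix("chr")
        if c.isdigit():
            return (0, int(c), "")
        if c.upper() in special:
            return (0, special[c.upper()], "")
        return (1, 0, c)

    return chrom.map(one)


@dataclass
class ReferencePanel:
    """Reference SNP map plus phased haplotypes for LD computation.

    ``snp_map`` columns: ``SNP CHR POS REF ALT AF`` where AF is the ALT
    allele frequency; ``haplotypes`` is a (2*n_individuals, n_snps) 0/1
    matrix whose column means equal AF.
    """

    snp_map: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.snp_map):
            raise ValueError("haplotype columns must match snp_map rows")
        if self.snp_map["SNP"].duplicated().any():
            raise ValueError("duplicate SNP ids in reference panel")
        af = self.haplotypes.mean(axis=0)
        if not np.allclose(af, self.snp_map["AF"].to_numpy(), atol=1e-12):
            raise ValueError("snp_map AF inconsistent with haplotype column means")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self) -> np.ndarray:
        """Diploid allele dosages (n_individuals, n_snps) in {0,1,2}."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int16)

    def subset(self, snp_ids: Iterable[str]) -> "ReferencePanel":
        """Panel restricted to the given SNP ids (panel order preserved)."""
        wanted = set(snp_ids)
        mask = self.snp_map["SNP"].isin(wanted).to_numpy()
        return ReferencePanel(
            self.snp_map.loc[mask].reset_index(drop=True),
            self.haplotypes[:, mask],
        )
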