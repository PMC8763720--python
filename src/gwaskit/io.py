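"""Reading and writing summary statistics and the reference panel.

Source files come in many column dialects; a :class:`DialectSpec` maps a
source header vocabulary onto the canonical fields.  The canonical on-disk
form is a TSV with columns ``SNP CHR POS EA OA EAF BETA SE P Z N`` ("NA"
for missing), transparently gzip-compressed when the path ends in ``.gz``.
The reference panel is a standard VCF with phased GT fields.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .types import (
    CANONICAL_COLUMNS,
    VALID_ALLELES,
    ParseReport,
    ReferencePanel,
    StudyMetadata,
    SumstatsTable,
    _coerce_dtypes,
)

DEFAULT_MISSING_CODES = frozenset({"NA", ".", "", "NaN"})

#: canonical field names a column_map may target
_CANONICAL_FIELDS = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "zscore": "Z",
    "n": "N",
}
_STAT_FIELDS = {"EAF", "BETA", "SE", "P", "Z", "N"}


@dataclass
class DialectSpec:
    """How to interpret one source file's columns.

    ``column_map`` maps source header names to canonical field names (either
    the lowercase names such as ``pvalue`` or the canonical column codes such
    as ``P``).  ``p_is_log10`` marks dialects whose p column holds -log10(p).
    """

    column_map: dict[str, str]
    delimiter: str = "\t"
    missing_codes: frozenset[str] = field(default_factory=lambda: DEFAULT_MISSING_CODES)
    p_is_log10: bool = False

    def __post_init__(self) -> None:
        self.missing_codes = frozenset(self.missing_codes)
        norm = {}
        for src, tgt in self.column_map.items():
            canon = _CANONICAL_FIELDS.get(tgt, tgt)
            if canon not in CANONICAL_COLUMNS:
                raise ValueError(f"unknown canonical field {tgt!r} for column {src!r}")
            norm[src] = canon
        self.column_map = norm
        targets = set(self.column_map.values())
        if "SNP" not in targets or not (targets & _STAT_FIELDS):
            raise ValueError(
                "column_map must cover snp_id plus at least one association statistic"
            )

    @classmethod
    def canonical(cls) -> "DialectSpec":
        """The identity dialect for canonical TSV files."""
        return cls(column_map={c: c for c in CANONICAL_COLUMNS})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DialectSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            column_map=raw["column_map"],
            delimiter=raw.get("delimiter", "\t"),
            missing_codes=frozenset(raw.get("missing_codes", DEFAULT_MISSING_CODES)),
            p_is_log10=bool(raw.get("p_is_log10", False)),
        )


def read_sumstats(
    path: str | Path,
    dialect: DialectSpec | None = None,
    metadata: StudyMetadata | None = None,
) -> SumstatsTable:
    """Read one summary-statistics file into the canonical table.

    Rows with unparseable chromosome/position, invalid alleles or duplicated
    SNP ids are dropped and counted in the attached ``parse_report``.
    """
    dialect = dialect or DialectSpec.canonical()
    if metadata is None:
        metadata = StudyMetadata(
            study_id=Path(path).stem, trait_name=Path(path).stem, domain="complex_trait"
        )
    raw = pd.read_csv(
        path,
        sep=dialect.delimiter,
        dtype=str,
        na_values=list(dialect.missing_codes),
        keep_default_na=False,
        compression="infer",
    )
    if raw.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    missing_cols = [c for c in dialect.column_map if c not in raw.columns]
    if missing_cols:
        raise KeyError(f"mapped columns absent from {path}: {missing_cols}")

    df = raw[list(dialect.column_map)].rename(columns=dialect.column_map)
    for c in CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    report = ParseReport(n_input=len(df))

    pos = pd.to_numeric(df["POS"], errors="coerce")
    ok_coords = pos.notna() & df["CHR"].notna()
    report.n_bad_coords = int((~ok_coords).sum())
    df = df.loc[ok_coords].copy()
    df["POS"] = pos.loc[ok_coords].astype("int64")

    for c in ("EA", "OA"):
        df[c] = df[c].astype(str).str.upper()
    ok_alleles = (
        df["EA"].isin(VALID_ALLELES)
        & df["OA"].isin(VALID_ALLELES)
        & (df["EA"] != df["OA"])
    )
    report.n_bad_alleles = int((~ok_alleles).sum())
    df = df.loc[ok_alleles].copy()

    for c in ("EAF", "BETA", "SE", "P", "Z", "N"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if dialect.p_is_log10:
        df["P"] = np.power(10.0, -df["P"])

    dup = df["SNP"].duplicated(keep="first")
    report.n_duplicate_ids = int(dup.sum())
    df = df.loc[~dup].reset_index(drop=True)
    report.n_kept = len(df)

    table = SumstatsTable(metadata, _coerce_dtypes(df[CANONICAL_COLUMNS]))
    table.parse_report = report
    return table


def write_sumstats(table: SumstatsTable, path: str | Path) -> Path:
    """Write a table as canonical TSV ("NA" for missing, 12 significant digits)."""
    path = Path(path)
    df = table.df.copy()

    def fmt(x: float) -> str:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return "NA"
        if float(x).is_integer() and abs(x) < 1e15:
            return str(int(x))
        return format(float(x), ".12g")

    lines = ["\t".join(CANONICAL_COLUMNS)]
    for row in df.itertuples(index=False):
        rec = dict(zip(CANONICAL_COLUMNS, row))
        lines.append(
            "\t".join(
                [
                    str(rec["SNP"]),
                    str(rec["CHR"]),
                    str(int(rec["POS"])),
                    str(rec["EA"]),
                    str(rec["OA"]),
                    fmt(rec["EAF"]),
                    fmt(rec["BETA"]),
                    fmt(rec["SE"]),
                    fmt(rec["P"]),
                    fmt(rec["Z"]),
                    fmt(rec["N"]),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if str(path).endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)
    return path


def load_reference(vcf_path: str | Path) -> ReferencePanel:
    """Load a phased VCF as the harmonization/QC reference panel.

    Only biallelic SNP records are kept; indels and multiallelic sites are
    skipped and counted on the returned panel's ``n_skipped`` attribute.
    Unphased genotypes raise, naming the first offending record.
    """
    vcf = VCF(str(vcf_path))
    rows = []
    haps = []
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        if (
            len(alts) != 1
            or var.REF not in VALID_ALLELES
            or alts[0] not in VALID_ALLELES
        ):
            n_skipped += 1
            continue
        gts = var.genotypes  # [a, b, phased] per sample
        col = []
        for g in gts:
            if len(g) != 3 or not g[2]:
                raise ValueError(
                    f"unphased genotype at {var.CHROM}:{var.POS} ({var.ID})"
                )
            col.extend((g[0], g[1]))
        rows.append(
            {
                "SNP": var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{alts[0]}",
                "CHR": str(var.CHROM),
                "POS": int(var.POS),
                "REF": var.REF,
                "ALT": alts[0],
            }
        )
        haps.append(col)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {vcf_path}")
    snp_map = pd.DataFrame(rows)
    H = np.array(haps, dtype=np.int8).T  # (2n, m)
    order = np.lexsort((snp_map["POS"].to_numpy(), snp_map["CHR"].to_numpy()))
    snp_map = snp_map.iloc[order].reset_index(drop=True)
    H = H[:, order]
    snp_map["AF"] = H.mean(axis=0)
    panel = ReferencePanel(snp_map, H)
    panel.n_skipped = n_skipped
    return panel


def write_reference_vcf(panel: ReferencePanel, path: str | Path) -> Path:
    """Serialize a panel as a minimal phased VCF (round-trips through
    :func:`load_reference`)."""
    path = Path(path)
    n = panel.n_individuals
    samples = [f"S{i + 1}" for i in range(n)]
    contigs = [f"##contig=<ID={c}>" for c in panel.snp_map["CHR"].unique()]
    header = [
        "##fileformat=VCFv4.2",
        *contigs,
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines = header
    H = panel.haplotypes
    for j, rec in enumerate(panel.snp_map.itertuples(index=False)):
        gts = "\t".join(f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(n))
        lines.append(
            f"{rec.CHR}\t{rec.POS}\t{rec.SNP}\t{rec.REF}\t{rec.ALT}\t.\t.\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
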