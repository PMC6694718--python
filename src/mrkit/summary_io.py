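"""Reading, validating and writing GWAS summary-statistic tables.

The on-disk format is plain delimited text (TSV by default) with a header
row.  Canonical column names follow the common upload-form vocabulary:

    SNP, effect_allele, other_allele, beta, se, eaf, pval, samplesize,
    Phenotype, units

Arbitrary source column names are supported through :class:`ColumnMapping`.
Rows violating the per-record invariants (identical alleles, non-positive
standard error, frequencies or p-values outside [0, 1], ...) are dropped and
recorded in an audit log rather than raised, so that a single malformed row
never aborts an analysis.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GwasRecord",
    "GwasSummaryTable",
    "ColumnMapping",
    "ValidationReport",
    "read_gwas_table",
    "write_table",
    "validate_table",
    "results_frame",
    "LOG_ODDS_UNITS",
]

#: Units string that flags a binary outcome reported on the log-odds scale.
LOG_ODDS_UNITS = "log odds"

#: Tokens treated as missing values (case-insensitive).
MISSING_TOKENS = {"", "na", "nan"}

#: Canonical field order of a record.
CANONICAL_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se",
                    "eaf", "pval", "n")

#: Fields that must be mapped when reading a file.
REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se")

#: Canonical on-disk column name for each field.
CANONICAL_COLUMNS = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "eaf": "eaf",
    "pval": "pval",
    "n": "samplesize",
    "phenotype": "Phenotype",
    "units": "units",
}

_ALLELE_RE = re.compile(r"^[ACGT]+$")

# float format giving enough digits for a lossless (<=1e-9 relative) round trip
_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class GwasRecord:
    """One SNP-trait association from a GWAS summary-statistics table.

    ``beta`` is the per-allele effect of ``effect_allele`` in phenotype
    units (log odds for binary traits); ``eaf`` is the effect-allele
    frequency.  Optional fields (``eaf``, ``pval``, ``n``) are ``None``
    when absent from the source.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: Optional[float] = None
    pval: Optional[float] = None
    n: Optional[int] = None

    def invalid_reason(self) -> Optional[str]:
        """Return the first violated invariant, or None if the record is valid."""
        if not self.snp_id:
            return "missing snp id"
        ea, oa = str(self.effect_allele).upper(), str(self.other_allele).upper()
        if not _ALLELE_RE.match(ea) or not _ALLELE_RE.match(oa):
            return "invalid allele"
        if ea == oa:
            return "identical alleles"
        if self.beta is None or (isinstance(self.beta, float) and math.isnan(self.beta)):
            return "missing beta"
        if self.se is None or (isinstance(self.se, float) and math.isnan(self.se)):
            return "missing se"
        if self.se <= 0:
            return "nonpositive se"
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return "eaf out of range"
        if self.pval is not None and not (0.0 <= self.pval <= 1.0):
            return "pval out of range"
        if self.n is not None and self.n <= 0:
            return "nonpositive sample size"
        return None


@dataclass
class ColumnMapping:
    """Map canonical field names to source column names.

    ``columns`` maps each canonical field (see :data:`CANONICAL_FIELDS`) to
    the column name used in the file; optional fields (``eaf``, ``pval``,
    ``n``) may be omitted or mapped to ``None``, in which case the values
    are missing.  ``delimiter`` must be a single character.
    """

    columns: dict = field(default_factory=lambda: dict(
        snp_id="SNP", effect_allele="effect_allele", other_allele="other_allele",
        beta="beta", se="se", eaf="eaf", pval="pval", n="samplesize",
        phenotype="Phenotype", units="units",
    ))
    delimiter: str = "\t"

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")
        for fieldname in REQUIRED_FIELDS:
            if not self.columns.get(fieldname):
                raise ValueError(f"required field not mapped: {fieldname}")

    @classmethod
    def default(cls, delimiter: str = "\t") -> "ColumnMapping":
        return cls(delimiter=delimiter)


@dataclass
class GwasSummaryTable:
    """An ordered collection of :class:`GwasRecord` plus study metadata.

    ``df`` holds one row per record with canonical column names
    (``snp_id``, ``effect_allele``, ``other_allele``, ``beta``, ``se``,
    ``eaf``, ``pval``, ``n``).  ``units`` is stored verbatim; the value
    ``"log odds"`` flags a binary trait whose estimates live on the
    log-odds scale.  ``audit`` records every dropped source row as
    ``(snp_id_or_row_label, reason)``.
    """

    df: pd.DataFrame
    phenotype_name: str = ""
    phenotype_id: str = ""
    units: str = ""
    sample_type: str = "continuous"
    audit: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_FIELDS if c not in self.df.columns]
        if missing:
            raise ValueError(f"table frame missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_binary(self) -> bool:
        return self.units.strip().lower() == LOG_ODDS_UNITS or self.sample_type == "binary"

    def records(self) -> Iterator[GwasRecord]:
        for row in self.df.itertuples(index=False):
            yield GwasRecord(
                snp_id=row.snp_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=row.beta,
                se=row.se,
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                pval=None if pd.isna(row.pval) else float(row.pval),
                n=None if pd.isna(row.n) else int(row.n),
            )

    def record_map(self) -> dict:
        return {r.snp_id: r for r in self.records()}

    @classmethod
    def from_records(cls, records: Sequence[GwasRecord], **meta) -> "GwasSummaryTable":
        df = pd.DataFrame(
            [(r.snp_id, r.effect_allele, r.other_allele, r.beta, r.se,
              np.nan if r.eaf is None else r.eaf,
              np.nan if r.pval is None else r.pval,
              np.nan if r.n is None else r.n) for r in records],
            columns=list(CANONICAL_FIELDS),
        )
        return cls(df=df, **meta)


@dataclass
class ValidationReport:
    """Per-invariant violation counts for a table (reporting only)."""

    counts: dict

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def is_clean(self) -> bool:
        return self.total == 0


def _coerce_numeric(raw: pd.Series, label: str, audit_rows: dict) -> pd.Series:
    """Parse a string column to float; flag non-missing unparseable cells."""
    stripped = raw.fillna("").astype(str).str.strip()
    is_missing = stripped.str.lower().isin(MISSING_TOKENS)
    parsed = pd.to_numeric(stripped.where(~is_missing, other=np.nan), errors="coerce")
    bad = (~is_missing) & parsed.isna()
    for idx in raw.index[bad]:
        audit_rows.setdefault(idx, f"unparseable numeric ({label})")
    return parsed


def read_gwas_table(
    path,
    mapping: Optional[ColumnMapping] = None,
    *,
    phenotype_name: str = "",
    phenotype_id: str = "",
    units: str = "",
    sample_type: str = "continuous",
) -> GwasSummaryTable:
    """Read a delimited summary-statistics file into a validated table.

    Rows failing record invariants are dropped and listed in the returned
    table's ``audit``.  Duplicate SNP ids keep the record with the smallest
    p-value (missing p-values sort last, ties keep the earliest row).

    Raises ``ValueError`` if the file is empty or a mapped required column
    is absent from the header.
    """
    mapping = mapping or ColumnMapping.default()
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=mapping.delimiter, dtype=str,
                          keep_default_na=False, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty file: {path}") from None
    if raw.empty and len(raw.columns) == 0:
        raise ValueError(f"empty file: {path}")

    for fieldname in REQUIRED_FIELDS:
        col = mapping.columns.get(fieldname)
        if col not in raw.columns:
            raise ValueError(f"required column missing from header: {col!r} (field {fieldname})")

    audit_rows: dict = {}
    out = pd.DataFrame(index=raw.index)
    snp_col = mapping.columns["snp_id"]
    out["snp_id"] = raw[snp_col].astype(str).str.strip()
    out["effect_allele"] = raw[mapping.columns["effect_allele"]].astype(str).str.strip().str.upper()
    out["other_allele"] = raw[mapping.columns["other_allele"]].astype(str).str.strip().str.upper()
    for fieldname in ("beta", "se", "eaf", "pval", "n"):
        col = mapping.columns.get(fieldname)
        if col and col in raw.columns:
            out[fieldname] = _coerce_numeric(raw[col], fieldname, audit_rows)
        else:
            out[fieldname] = np.nan

    # metadata may be carried as columns (first value wins) unless given
    for metafield, attr in (("phenotype", "phenotype_name"), ("units", "units")):
        col = mapping.columns.get(metafield)
        if col and col in raw.columns and len(raw):
            value = str(raw[col].iloc[0])
            if metafield == "phenotype" and not phenotype_name:
                phenotype_name = value
            if metafield == "units" and not units:
                units = value

    audit: list = []
    keep = np.ones(len(out), dtype=bool)
    for idx, reason in audit_rows.items():
        keep[out.index.get_loc(idx)] = False
        audit.append((out.at[idx, "snp_id"] or f"row {idx + 2}", reason))

    for pos, row in enumerate(out.itertuples(index=False)):
        if not keep[pos]:
            continue
        rec = GwasRecord(
            snp_id=row.snp_id, effect_allele=row.effect_allele,
            other_allele=row.other_allele, beta=row.beta, se=row.se,
            eaf=None if pd.isna(row.eaf) else float(row.eaf),
            pval=None if pd.isna(row.pval) else float(row.pval),
            n=None if pd.isna(row.n) else float(row.n),
        )
        reason = rec.invalid_reason()
        if reason is not None:
            keep[pos] = False
            audit.append((row.snp_id or f"row {pos + 2}", reason))

    out = out[keep].reset_index(drop=True)

    # duplicate snp ids: keep strongest evidence (smallest pval, missing last)
    if out["snp_id"].duplicated().any():
        order_key = out["pval"].fillna(np.inf)
        best = (
            pd.DataFrame({"snp_id": out["snp_id"], "key": order_key, "pos": np.arange(len(out))})
            .sort_values(["snp_id", "key", "pos"], kind="stable")
            .drop_duplicates("snp_id", keep="first")["pos"]
        )
        dropped = sorted(set(range(len(out))) - set(best))
        for pos in dropped:
            audit.append((out.at[pos, "snp_id"], "duplicate snp id"))
        out = out.iloc[sorted(best)].reset_index(drop=True)

    return GwasSummaryTable(
        df=out, phenotype_name=phenotype_name, phenotype_id=phenotype_id,
        units=units, sample_type=sample_type, audit=audit,
    )


def validate_table(table: GwasSummaryTable) -> ValidationReport:
    """Count invariant violations in a table without modifying it.

    An independent row scan; a table built through :func:`read_gwas_table`
    should always come back clean.
    """
    df = table.df
    counts = {
        "identical alleles": int((df["effect_allele"].str.upper() == df["other_allele"].str.upper()).sum()),
        "invalid allele": int(sum(
            not _ALLELE_RE.match(str(a).upper()) or not _ALLELE_RE.match(str(b).upper())
            for a, b in zip(df["effect_allele"], df["other_allele"])
        )),
        "nonpositive se": int(((df["se"] <= 0) | df["se"].isna()).sum()),
        "missing beta": int(df["beta"].isna().sum()),
        "eaf out of range": int(((df["eaf"] < 0) | (df["eaf"] > 1)).sum()),
        "pval out of range": int(((df["pval"] < 0) | (df["pval"] > 1)).sum()),
        "nonpositive sample size": int((df["n"] <= 0).sum()),
        "duplicate snp id": int(df["snp_id"].duplicated().sum()),
    }
    return ValidationReport(counts=counts)


def write_table(obj, path, fmt: str = "tsv", *, allow_empty: bool = False) -> Path:
    """Write a table (GwasSummaryTable, DataFrame) as delimited text.

    Floats carry 12 significant digits so ``read(write(x))`` round-trips a
    :class:`GwasSummaryTable` to better than 1e-9 relative error.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}[fmt]
    if isinstance(obj, GwasSummaryTable):
        frame = obj.df.rename(columns={k: CANONICAL_COLUMNS[k] for k in CANONICAL_FIELDS})
        frame = frame.copy()
        frame["Phenotype"] = obj.phenotype_name
        frame["units"] = obj.units
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    if frame.empty and not allow_empty:
        raise ValueError("refusing to write an empty table (pass allow_empty=True)")
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    return path


def results_frame(results, *, exposure: str = "", outcome: str = "",
                  id_exposure: str = "", id_outcome: str = "") -> pd.DataFrame:
    """Arrange MR results in the standard results-table layout.

    Columns: id.exposure, id.outcome, outcome, exposure, method, nsnp, b,
    se, pval.
    """
    from .estimators import method_display_name  # local import avoids cycle

    rows = [
        {
            "id.exposure": id_exposure, "id.outcome": id_outcome,
            "outcome": outcome, "exposure": exposure,
            "method": method_display_name(res.method), "nsnp": res.nsnp,
            "b": res.b, "se": res.se, "pval": res.pval,
        }
        for res in results
    ]
    return pd.DataFrame(rows, columns=["id.exposure", "id.outcome", "outcome",
                                       "exposure", "method", "nsnp", "b", "se", "pval"])
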