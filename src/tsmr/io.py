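"""Reading and writing GWAS summary statistics and analysis tables.

Summary statistics arrive as delimited text in one of several common
layouts (IEU "flat" exports, GWAS-SSF, FinnGen release files, or a
generic table with a user-supplied column map).  Everything is
normalised into a :class:`SummaryTable`: one row per variant with a
canonical column set (variant_id, chrom, pos, effect_allele,
other_allele, eaf, beta, se, pval, n).

Coordinates are 1-based (GWAS convention); genome build is metadata
only.  Rows that violate basic invariants (se <= 0, p outside (0, 1],
non-ACGT alleles, identical alleles) are dropped and counted in the
parse report rather than raising.  P-values of exactly zero are clamped
to the smallest positive normal float, with a warning count.
"""

from __future__ import annotations

import csv
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryTable",
    "CANONICAL_COLUMNS",
    "DIALECTS",
    "read_summary_stats",
    "write_summary_stats",
    "write_table",
    "ConfigurationError",
    "InputError",
]

#: canonical column order of a SummaryTable frame
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_TINY_P = sys.float_info.min  # clamp for p == 0

_VALID_ALLELES = frozenset("ACGT")


class ConfigurationError(ValueError):
    """A required column or setting could not be resolved."""


class InputError(ValueError):
    """The input file content is unusable (e.g. zero parsable rows)."""


# Column-synonym tables per dialect: canonical name -> source column.
# The generic dialect carries no synonyms and requires an explicit map.
DIALECTS: dict[str, dict[str, str]] = {
    "ieu_flat": {
        "variant_id": "SNP", "chrom": "chr", "pos": "pos",
        "effect_allele": "effect_allele", "other_allele": "other_allele",
        "eaf": "eaf", "beta": "beta", "se": "se", "pval": "pval",
        "n": "samplesize",
    },
    "gwas_ssf": {
        "variant_id": "rsid", "chrom": "chromosome",
        "pos": "base_pair_location", "effect_allele": "effect_allele",
        "other_allele": "other_allele", "eaf": "effect_allele_frequency",
        "beta": "beta", "se": "standard_error", "pval": "p_value",
        "n": "n",
    },
    "finngen": {
        "variant_id": "rsids", "chrom": "#chrom", "pos": "pos",
        "effect_allele": "alt", "other_allele": "ref",
        "eaf": "af_alt", "beta": "beta", "se": "sebeta", "pval": "pval",
        "n": "n",
    },
    "generic": {},
}

#: columns that may legitimately be absent (filled from keyword args)
_OPTIONAL = {"eaf", "n", "chrom", "pos"}


@dataclass
class SummaryTable:
    """Per-variant GWAS association records for one trait.

    ``frame`` holds the canonical columns; ``parse_report`` counts rows
    dropped or adjusted at read time; ``metadata`` records provenance
    such as the sample-size convention of the source.
    """

    trait_label: str
    ancestry_label: str = ""
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    parse_report: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> pd.DataFrame:
        return self.frame

    def validate(self) -> None:
        f = self.frame
        if f["variant_id"].duplicated().any():
            dupes = f.loc[f["variant_id"].duplicated(), "variant_id"].tolist()
            raise InputError(f"duplicate variant_id in {self.trait_label!r}: {dupes[:5]}")


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_summary_stats(
    path,
    dialect: str = "generic",
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
    ancestry_label: str = "",
    n_default: int | None = None,
) -> SummaryTable:
    """Read one GWAS summary-statistics file into a :class:`SummaryTable`.

    Parameters
    ----------
    path
        Delimited text file with a header row (tab, comma or semicolon).
    dialect
        One of ``ieu_flat``, ``gwas_ssf``, ``finngen``, ``generic``.
        ``generic`` requires an explicit ``column_map``.
    column_map
        Mapping from canonical column name to the file's column name;
        overrides the dialect's synonym table entry-by-entry.
    n_default
        Study-level sample size used when the file has no N column
        (recorded as convention "study_level" in the metadata).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistics file not found: {path}")
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    if dialect == "generic" and not column_map:
        raise ConfigurationError("generic dialect requires an explicit column_map")

    mapping = dict(DIALECTS[dialect])
    if column_map:
        mapping.update(column_map)

    raw = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    if raw.empty:
        raise InputError(f"no data rows in {path}")

    report: dict[str, int] = {"n_input": len(raw)}
    cols = {}
    neg_log10 = False
    for canon in CANONICAL_COLUMNS:
        src = mapping.get(canon, canon)
        if src in raw.columns:
            cols[canon] = raw[src]
        elif canon == "pval" and "neg_log_10_p_value" in raw.columns:
            cols[canon] = raw["neg_log_10_p_value"]
            neg_log10 = True
        elif canon in _OPTIONAL:
            cols[canon] = pd.Series([""] * len(raw))
        else:
            raise ConfigurationError(
                f"required column {canon!r} (source name {src!r}) missing from {path.name}"
            )

    df = pd.DataFrame({k: v.reset_index(drop=True) for k, v in cols.items()})

    # type coercion; failures become NaN and are dropped with counts
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    if df["n"].isna().all() and n_default is not None:
        df["n"] = float(n_default)
    df["n"] = df["n"].round().astype("Int64")

    if neg_log10:
        df["pval"] = np.power(10.0, -df["pval"])

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.strip().str.upper()
    df["chrom"] = df["chrom"].astype(str).str.strip()
    df["variant_id"] = df["variant_id"].astype(str).str.strip()

    n_zero_p = int((df["pval"] == 0).sum())
    if n_zero_p:
        df.loc[df["pval"] == 0, "pval"] = _TINY_P
    report["pval_clamped_to_min_float"] = n_zero_p

    bad = pd.DataFrame(index=df.index)
    bad["missing_core"] = df["beta"].isna() | df["se"].isna() | df["pval"].isna() | (df["variant_id"] == "")
    bad["nonpositive_se"] = df["se"] <= 0
    bad["pval_out_of_range"] = (df["pval"] <= 0) | (df["pval"] > 1)
    bad["bad_alleles"] = ~(
        df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
    ) | (df["effect_allele"] == df["other_allele"])
    drop = bad.any(axis=1)
    for reason in bad.columns:
        report[f"dropped_{reason}"] = int((bad[reason] & drop).sum())

    # EAF out of (0,1) is treated as missing, not a row drop (EAF optional)
    eaf_invalid = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
    df.loc[eaf_invalid, "eaf"] = np.nan
    report["eaf_set_missing"] = int(eaf_invalid.sum())

    df = df.loc[~drop].reset_index(drop=True)
    report["n_parsed"] = len(df)
    if df.empty:
        raise InputError(f"zero parsable rows in {path}")

    meta = {
        "source": str(path),
        "dialect": dialect,
        "n_convention": "study_level" if n_default is not None else "as_provided",
    }
    return SummaryTable(
        trait_label=trait_label or path.stem,
        ancestry_label=ancestry_label,
        frame=df[CANONICAL_COLUMNS],
        parse_report=report,
        metadata=meta,
    )


def write_summary_stats(table: SummaryTable, path) -> None:
    """Write a SummaryTable in the IEU-flat layout (re-readable as
    ``dialect='ieu_flat'``); floats carry 12 significant digits so a
    write/read round trip is the identity to well past 10 digits."""
    inv = {v: k for k, v in DIALECTS["ieu_flat"].items()}
    out = table.frame.rename(columns={k: v for v, k in inv.items()})
    write_table(out, path)


def write_table(table, path) -> None:
    """Write any tabular result as TSV with a header.

    Accepts a DataFrame, a sequence of dataclass-like records (anything
    with ``to_dict``/``__dict__``), or a mapping of columns.  Floats are
    rendered with 12 significant digits; row order is preserved.
    """
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"parent directory does not exist: {path.parent}")
    df = _as_frame(table)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    if isinstance(table, SummaryTable):
        return table.frame
    if hasattr(table, "to_frame") and callable(table.to_frame):
        out = table.to_frame()
        if isinstance(out, pd.DataFrame):
            return out
    if isinstance(table, Mapping):
        return pd.DataFrame(table)
    if isinstance(table, Sequence):
        rows = []
        for rec in table:
            if hasattr(rec, "to_dict"):
                rows.append(rec.to_dict())
            elif hasattr(rec, "__dict__"):
                rows.append(vars(rec))
            else:
                rows.append(dict(rec))
        return pd.DataFrame(rows)
    raise TypeError(f"cannot render {type(table).__name__} as a table")
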