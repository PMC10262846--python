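"""Instrument selection and exposure/outcome harmonization.

Instruments are exposure-GWAS variants passing the genome-wide
significance filter (p < 5e-8), pruned to approximate independence by
greedy LD clumping (r^2 > 0.01 within a +/-5,000 kb window), and kept
only when individually strong (F > 10, with F = R^2 (N-2) / (1 - R^2)
and R^2 the variance in the exposure explained by the variant).

Harmonization aligns outcome effects onto the exposure's effect allele:
matching alleles are kept, swapped alleles flip the outcome beta and
EAF, strand flips are complemented first, and palindromic (A/T, C/G)
variants — whose strand cannot be resolved from alleles — are retained
only when both studies' allele frequencies point the same way (same
side of 0.5) and the variant is clearly non-ambiguous (MAF < 0.3 in
both); otherwise they are dropped as ambiguous.  Instruments absent
from the outcome may be recovered through an LD proxy (r^2 >= 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import InputError, SummaryTable

__all__ = [
    "LDMatrix",
    "HarmonizedSet",
    "filter_genome_wide",
    "clump",
    "explained_variance",
    "f_statistic",
    "strength_filter",
    "harmonize",
    "COMPLEMENT",
    "is_palindromic",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = [
    "variant_id", "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "palindromic", "proxy_of",
]


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T or C/G allele pair: strand is unresolvable from alleles."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class LDMatrix:
    """Pairwise r^2 among named variants (symmetric, unit diagonal)."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise InputError(
                f"LD matrix shape {self.r2.shape} does not match {n} variant ids"
            )
        if not np.allclose(self.r2, self.r2.T):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise InputError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise InputError("LD r^2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, id1: str, id2: str) -> float | None:
        """r^2 between two variants; None if either is absent."""
        i = self._index.get(id1)
        j = self._index.get(id2)
        if i is None or j is None:
            return None
        return float(self.r2[i, j])

    @classmethod
    def from_square_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    @classmethod
    def from_long_tsv(cls, path) -> "LDMatrix":
        """Long format: columns id1, id2, r2; unlisted pairs are 0."""
        df = pd.read_csv(path, sep="\t")
        ids = sorted(set(df["id1"]) | set(df["id2"]))
        idx = {v: i for i, v in enumerate(ids)}
        m = np.eye(len(ids))
        for a, b, r in zip(df["id1"], df["id2"], df["r2"]):
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = float(r)
        return cls(ids, m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a common effect allele.

    The substrate of every MR estimator.  ``audit`` tallies what
    happened to each input instrument so that
    retained + dropped = input always balances.
    """

    exposure_label: str
    outcome_label: str
    frame: pd.DataFrame
    audit: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    variant_ids=None, exposure_label="exposure",
                    outcome_label="outcome", eaf_exp=None, eaf_out=None):
        beta_exp = np.asarray(beta_exp, dtype=float)
        n = beta_exp.size
        if variant_ids is None:
            variant_ids = [f"v{i + 1}" for i in range(n)]
        frame = pd.DataFrame({
            "variant_id": list(variant_ids),
            "beta_exp": beta_exp,
            "se_exp": np.asarray(se_exp, dtype=float),
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.asarray(se_out, dtype=float),
            "eaf_exp": np.full(n, np.nan) if eaf_exp is None else np.asarray(eaf_exp, float),
            "eaf_out": np.full(n, np.nan) if eaf_out is None else np.asarray(eaf_out, float),
            "palindromic": False,
            "proxy_of": None,
        })
        return cls(exposure_label, outcome_label, frame)


def filter_genome_wide(table: SummaryTable, p_threshold: float = 5e-8) -> SummaryTable:
    """Keep variants with p strictly below the genome-wide threshold."""
    kept = table.frame.loc[table.frame["pval"] < p_threshold].reset_index(drop=True)
    return SummaryTable(
        trait_label=table.trait_label,
        ancestry_label=table.ancestry_label,
        frame=kept,
        parse_report=dict(table.parse_report),
        metadata={**table.metadata, "p_threshold": p_threshold},
    )


def _chrom_key(c: str):
    c = str(c)
    return (0, int(c)) if c.isdigit() else (1, c)


def clump(
    table: SummaryTable,
    ld: LDMatrix,
    window_kb: int = 5000,
    r2_threshold: float = 0.01,
) -> SummaryTable:
    """Greedy LD clumping: repeatedly keep the most significant
    remaining variant and discard same-chromosome variants within
    +/- window_kb whose r^2 with it exceeds r2_threshold.

    Variants absent from the LD matrix are treated as unlinked and
    counted in the report.  Ties at equal p break by chromosome, then
    position, then variant_id, so output is invariant to row order.
    """
    df = table.frame.copy()
    if df["pos"].isna().any() or (df["chrom"] == "").any():
        raise InputError("clumping requires chrom and pos for every variant")

    order = sorted(
        range(len(df)),
        key=lambda i: (
            df["pval"].iat[i],
            _chrom_key(df["chrom"].iat[i]),
            int(df["pos"].iat[i]),
            df["variant_id"].iat[i],
        ),
    )
    window = window_kb * 1000
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    missing_ld: set[str] = set()
    ids = df["variant_id"].tolist()
    chroms = df["chrom"].tolist()
    poss = df["pos"].tolist()
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        for j in order:
            if not alive[j] or chroms[j] != chroms[i]:
                continue
            if abs(int(poss[j]) - int(poss[i])) > window:
                continue
            r2 = ld.lookup(ids[i], ids[j])
            if r2 is None:
                if ids[i] not in ld._index:
                    missing_ld.add(ids[i])
                if ids[j] not in ld._index:
                    missing_ld.add(ids[j])
                continue  # unlinked by assumption
            if r2 > r2_threshold:
                alive[j] = False

    out = df.iloc[kept].reset_index(drop=True)
    return SummaryTable(
        trait_label=table.trait_label,
        ancestry_label=table.ancestry_label,
        frame=out,
        parse_report=dict(table.parse_report),
        metadata={
            **table.metadata,
            "clump_report": {
                "n_input": len(df),
                "n_index": len(out),
                "n_removed": len(df) - len(out),
                "n_missing_ld": len(missing_ld),
            },
        },
    )


def explained_variance(record) -> float:
    """Variance in the exposure explained by one variant.

    R^2 = (2 EAF (1-EAF) beta^2) /
          [2 EAF (1-EAF) beta^2 + 2 EAF (1-EAF) N SE(beta)^2]

    ``record`` is any mapping/row with eaf, beta, se, n fields.
    """
    eaf = record["eaf"]
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        raise ValueError(
            "explained_variance requires EAF; drop the record or supply EAF explicitly"
        )
    eaf = float(eaf)
    if not 0 < eaf < 1:
        raise ValueError(f"EAF must lie in (0,1), got {eaf}")
    beta = float(record["beta"])
    se = float(record["se"])
    n = float(record["n"])
    if n <= 2:
        raise ValueError("sample size must exceed 2")
    num = 2.0 * eaf * (1.0 - eaf) * beta ** 2
    den = num + 2.0 * eaf * (1.0 - eaf) * n * se ** 2
    return num / den


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F statistic: R^2 (N - 2) / (1 - R^2)."""
    r2 = float(r2)
    if not 0 <= r2 < 1:
        raise ValueError(f"R^2 must lie in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError("sample size must exceed 2")
    return r2 * (n - 2) / (1.0 - r2)


def strength_filter(table: SummaryTable, f_min: float = 10.0,
                    on_missing_eaf: str = "error") -> SummaryTable:
    """Retain variants with per-variant F strictly above ``f_min``.

    ``on_missing_eaf``: 'error' (default) or 'drop' — records without
    EAF cannot be scored and are never silently imputed.
    """
    df = table.frame
    keep = []
    fs = []
    n_missing = 0
    for i in range(len(df)):
        row = df.iloc[i]
        if pd.isna(row["eaf"]):
            if on_missing_eaf == "drop":
                n_missing += 1
                continue
            raise ValueError(
                f"variant {row['variant_id']} has no EAF; cannot compute R^2/F "
                "(pass on_missing_eaf='drop' to exclude such records)"
            )
        f = f_statistic(explained_variance(row), int(row["n"]))
        if f > f_min:
            keep.append(i)
            fs.append(f)
    out = df.iloc[keep].reset_index(drop=True)
    out = out.assign(f_stat=fs)
    return SummaryTable(
        trait_label=table.trait_label,
        ancestry_label=table.ancestry_label,
        frame=out,
        parse_report=dict(table.parse_report),
        metadata={
            **table.metadata,
            "strength_report": {
                "n_input": len(df),
                "n_strong": len(out),
                "n_missing_eaf": n_missing,
                "f_min": f_min,
            },
        },
    )


def cumulative_f(table: SummaryTable) -> tuple[float, float]:
    """(sum of per-variant R^2, F of the cumulative R^2) over the IV set."""
    r2 = sum(explained_variance(table.frame.iloc[i]) for i in range(len(table.frame)))
    n = int(table.frame["n"].max())
    return r2, f_statistic(r2, n)


def _mafs_agree(eaf_exp: float, eaf_out: float, maf_threshold: float) -> bool:
    if np.isnan(eaf_exp) or np.isnan(eaf_out):
        return False
    same_side = (eaf_exp - 0.5) * (eaf_out - 0.5) > 0
    maf_exp = min(eaf_exp, 1 - eaf_exp)
    maf_out = min(eaf_out, 1 - eaf_out)
    return same_side and maf_exp < maf_threshold and maf_out < maf_threshold


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    maf_threshold: float = 0.3,
    proxy_table: pd.DataFrame | None = None,
    proxy_r2_min: float = 0.8,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per variant.

    Rules, in order, per exposure instrument:

    * missing from outcome: look up an LD proxy (``proxy_table`` columns
      iv_id, proxy_id, r2, ea_map, oa_map) with r^2 >= ``proxy_r2_min``;
      no eligible proxy -> drop (missing).
    * palindromic (A/T, C/G): strand flips are undetectable, so orient
      by allele frequency only — keep as-is iff both EAFs are on the
      same side of 0.5 and both MAFs < ``maf_threshold``; else drop.
    * same alleles -> keep; swapped -> negate outcome beta and
      complement its EAF; strand-complement -> complement alleles first
      then apply the same two cases; anything else -> drop (mismatch).
    """
    exposure.validate()
    outcome.validate()
    out_idx = {v: i for i, v in enumerate(outcome.frame["variant_id"])}

    proxies: dict[str, tuple[str, float, dict, dict]] = {}
    if proxy_table is not None:
        for _, r in proxy_table.iterrows():
            ea_map = _parse_allele_map(r.get("ea_map"))
            oa_map = _parse_allele_map(r.get("oa_map"))
            proxies[str(r["iv_id"])] = (str(r["proxy_id"]), float(r["r2"]), ea_map, oa_map)

    rows = []
    audit = {
        "n_input": len(exposure.frame), "retained": 0, "flipped": 0,
        "dropped_ambiguous": 0, "dropped_missing": 0,
        "dropped_mismatch": 0, "proxied": 0,
    }

    for _, ex in exposure.frame.iterrows():
        vid = ex["variant_id"]
        proxy_of = None
        if vid in out_idx:
            ou = outcome.frame.iloc[out_idx[vid]]
            ea_o, oa_o = ou["effect_allele"], ou["other_allele"]
        elif vid in proxies:
            proxy_id, r2, ea_map, oa_map = proxies[vid]
            if r2 < proxy_r2_min or proxy_id not in out_idx:
                audit["dropped_missing"] += 1
                continue
            ou = outcome.frame.iloc[out_idx[proxy_id]]
            # translate the proxy's alleles back into IV allele space
            ea_o = ea_map.get(ou["effect_allele"], ou["effect_allele"])
            oa_o = oa_map.get(ou["other_allele"], ou["other_allele"])
            proxy_of = proxy_id
        else:
            audit["dropped_missing"] += 1
            continue

        ea_e, oa_e = ex["effect_allele"], ex["other_allele"]
        beta_out = float(ou["beta"])
        eaf_out = float(ou["eaf"]) if pd.notna(ou["eaf"]) else np.nan
        eaf_exp = float(ex["eaf"]) if pd.notna(ex["eaf"]) else np.nan
        palin = is_palindromic(ea_e, oa_e)

        if palin:
            if not _mafs_agree(eaf_exp, eaf_out, maf_threshold):
                audit["dropped_ambiguous"] += 1
                continue
            flipped = False  # frequency-oriented: effects taken as aligned
        else:
            if (ea_o, oa_o) == (ea_e, oa_e):
                flipped = False
            elif (ea_o, oa_o) == (oa_e, ea_e):
                flipped = True
            else:
                cea = COMPLEMENT.get(ea_o, "?")
                coa = COMPLEMENT.get(oa_o, "?")
                if (cea, coa) == (ea_e, oa_e):
                    flipped = False
                elif (cea, coa) == (oa_e, ea_e):
                    flipped = True
                else:
                    audit["dropped_mismatch"] += 1
                    continue
        if flipped:
            beta_out = -beta_out
            if not np.isnan(eaf_out):
                eaf_out = 1.0 - eaf_out
            audit["flipped"] += 1
        if proxy_of is not None:
            audit["proxied"] += 1
        audit["retained"] += 1
        rows.append({
            "variant_id": vid,
            "beta_exp": float(ex["beta"]), "se_exp": float(ex["se"]),
            "beta_out": beta_out, "se_out": float(ou["se"]),
            "eaf_exp": eaf_exp, "eaf_out": eaf_out,
            "palindromic": palin, "proxy_of": proxy_of,
        })

    frame = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return HarmonizedSet(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        frame=frame,
        audit=audit,
    )


def _parse_allele_map(spec) -> dict:
    """'G:A,C:T' -> {'G': 'A', 'C': 'T'} (proxy allele -> IV allele)."""
    if spec is None or (isinstance(spec, float) and np.isnan(spec)) or spec == "":
        return {}
    out = {}
    for part in str(spec).split(","):
        k, v = part.split(":")
        out[k.strip().upper()] = v.strip().upper()
    return out
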