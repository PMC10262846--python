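"""Functional prioritization of instrument variants.

Instrument sets from several MR experiments are merged (with
provenance), each variant gets a "b score" — its single-SNP Wald-ratio
effect, taking the largest-|b| value when a variant instruments more
than one experiment — and a sequence-class perturbation score: the
maximum absolute entry of a 40-component chromatin sequence-class
vector (precomputed elsewhere and consumed here as a table).
Candidates pass when the sequence-class score exceeds 1 and |b|
exceeds 0.5; ranking is by sequence-class score, then |b|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import InputError

__all__ = [
    "VariantScore",
    "N_SEQ_CLASSES",
    "merge_iv_sets",
    "load_seq_class_table",
    "attach_scores",
    "select_functional",
    "heatmap_table",
]

N_SEQ_CLASSES = 40


@dataclass
class VariantScore:
    variant_id: str
    b_score: float
    seq_class_scores: np.ndarray
    class_labels: list[str]
    sei_score: float
    top_class_label: str
    source_experiments: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "b_score": self.b_score,
            "sei_score": self.sei_score,
            "top_class": self.top_class_label,
            "sources": ",".join(sorted(self.source_experiments)),
        }


def merge_iv_sets(sets) -> pd.DataFrame:
    """Union of per-experiment instrument lists with provenance.

    ``sets``: sequence of (label, variant-id list).  Returns a frame
    with one row per distinct variant and the sorted set of
    contributing experiment labels.
    """
    if not sets:
        raise ValueError("at least one instrument set is required")
    prov: dict[str, set] = {}
    order: list[str] = []
    for label, ids in sets:
        for vid in ids:
            if vid not in prov:
                prov[vid] = set()
                order.append(vid)
            prov[vid].add(label)
    return pd.DataFrame({
        "variant_id": order,
        "sources": [sorted(prov[v]) for v in order],
    })


def load_seq_class_table(path) -> pd.DataFrame:
    """Read a sequence-class score table: variant_id + exactly 40
    numeric columns.  Malformed rows raise with their row number."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != N_SEQ_CLASSES + 1:
        raise InputError(
            f"sequence-class table must have variant_id + {N_SEQ_CLASSES} "
            f"score columns, found {df.shape[1] - 1} score columns"
        )
    score_cols = df.columns[1:]
    for col in score_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0]) + 2  # header is row 1
            raise InputError(f"non-numeric score in column {col!r} at file row {row}")
        df[col] = coerced
    return df.rename(columns={df.columns[0]: "variant_id"})


def attach_scores(
    merged: pd.DataFrame,
    single_snp_betas: dict,
    seq_class_table: pd.DataFrame,
) -> tuple[list[VariantScore], list[str]]:
    """Combine b scores and sequence-class scores per merged variant.

    Parameters
    ----------
    merged
        Output of :func:`merge_iv_sets`.
    single_snp_betas
        Mapping experiment label -> {variant_id: single-SNP Wald beta}.
    seq_class_table
        Frame from :func:`load_seq_class_table`.

    Returns the scored variants plus the ids missing from the score
    table (flagged, not scored).
    """
    class_labels = list(seq_class_table.columns[1:])
    if len(class_labels) != N_SEQ_CLASSES:
        raise InputError(
            f"expected {N_SEQ_CLASSES} sequence classes, got {len(class_labels)}"
        )
    score_idx = {v: i for i, v in enumerate(seq_class_table["variant_id"])}
    mat = seq_class_table[class_labels].to_numpy(dtype=float)

    scored: list[VariantScore] = []
    missing: list[str] = []
    for _, row in merged.iterrows():
        vid = row["variant_id"]
        sources = set(row["sources"])
        bs = [
            single_snp_betas[lab][vid]
            for lab in sources
            if lab in single_snp_betas and vid in single_snp_betas[lab]
        ]
        if not bs:
            missing.append(vid)
            continue
        b_score = float(max(bs, key=abs))  # largest |b|, sign preserved
        if vid not in score_idx:
            missing.append(vid)
            continue
        vec = mat[score_idx[vid]]
        k = int(np.argmax(np.abs(vec)))
        scored.append(VariantScore(
            variant_id=vid,
            b_score=b_score,
            seq_class_scores=vec,
            class_labels=class_labels,
            sei_score=float(np.abs(vec).max()),
            top_class_label=class_labels[k],
            source_experiments=sources,
        ))
    return scored, missing


def select_functional(
    scores,
    sei_min: float = 1.0,
    b_min: float = 0.5,
    top_k: int | None = None,
) -> list[VariantScore]:
    """Threshold and rank candidates: sequence-class score > sei_min
    and |b| > b_min (both strict); rank by sequence-class score
    descending, then |b| descending, then variant_id; optionally
    truncate to ``top_k``."""
    kept = [s for s in scores if s.sei_score > sei_min and abs(s.b_score) > b_min]
    kept.sort(key=lambda s: (-s.sei_score, -abs(s.b_score), s.variant_id))
    return kept[:top_k] if top_k is not None else kept


def heatmap_table(scores) -> pd.DataFrame:
    """Long-format variant x sequence-class table for heatmap display."""
    rows = []
    for s in scores:
        for lab, val in zip(s.class_labels, s.seq_class_scores):
            rows.append({
                "variant_id": s.variant_id,
                "seq_class": lab,
                "score": float(val),
                "b_score": s.b_score,
            })
    return pd.DataFrame(rows, columns=["variant_id", "seq_class", "score", "b_score"])
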