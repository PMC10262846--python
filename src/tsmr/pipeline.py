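"""End-to-end orchestration of one MR experiment.

Mirrors the per-experiment workflow: genome-wide filter -> LD clumping
-> instrument-strength filter (F > 10) -> harmonization -> five-method
estimator suite -> heterogeneity (Cochran's Q, IVW and Egger forms) ->
Egger-intercept pleiotropy test -> MR-PRESSO (when the intercept test
is significant, or always when forced) -> single-SNP and leave-one-out
sensitivity analyses -> plot tables.  Every stage's variant counts,
thresholds, and seeds land in a deterministic JSON manifest so a run
can be reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import cochran_q, leave_one_out, plot_data, single_snp
from .instruments import (
    LDMatrix, clump, filter_genome_wide, harmonize, strength_filter,
)
from .io import InputError, read_summary_stats, write_table
from .model import EstimationError, MRModel
from .presso import presso as run_presso
from .prioritize import (
    attach_scores, heatmap_table, load_seq_class_table, merge_iv_sets,
    select_functional,
)

logger = logging.getLogger("tsmr")

__all__ = ["RunConfig", "EmptyInstrumentSetError", "run_mr_experiment",
           "run_prioritization"]


class EmptyInstrumentSetError(RuntimeError):
    """No instruments survive the selection/harmonization filters."""


@dataclass
class RunConfig:
    """All inputs and thresholds of one MR experiment."""

    exposure_path: str = ""
    outcome_path: str = ""
    exposure_dialect: str = "ieu_flat"
    outcome_dialect: str = "ieu_flat"
    exposure_column_map: dict | None = None
    outcome_column_map: dict | None = None
    exposure_label: str | None = None
    outcome_label: str | None = None
    ld_path: str | None = None
    ld_format: str = "square"  # or "long"
    proxy_path: str | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    window_kb: int = 5000
    maf_threshold: float = 0.3
    proxy_r2_min: float = 0.8
    f_min: float = 10.0
    alpha: float = 0.05
    presso_n_sim: int = 1000
    force_presso: bool = False
    n_boot: int = 1000
    seed: int = 0
    outdir: str = "tsmr_run"

    def __post_init__(self):
        for name in ("p_threshold", "clump_r2", "maf_threshold",
                     "proxy_r2_min", "f_min", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _read_ld(config: RunConfig) -> LDMatrix:
    if config.ld_path is None:
        return LDMatrix([], np.zeros((0, 0)))
    if config.ld_format == "long":
        return LDMatrix.from_long_tsv(config.ld_path)
    return LDMatrix.from_square_tsv(config.ld_path)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_mr_experiment(config: RunConfig) -> dict:
    """Execute the full per-experiment workflow; returns the manifest.

    Raises :class:`EmptyInstrumentSetError` when no instruments remain
    after selection and harmonization; other stage failures propagate
    with the stage named in the message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "read_inputs"
    try:
        exposure = read_summary_stats(
            config.exposure_path, dialect=config.exposure_dialect,
            column_map=config.exposure_column_map,
            trait_label=config.exposure_label,
        )
        outcome = read_summary_stats(
            config.outcome_path, dialect=config.outcome_dialect,
            column_map=config.outcome_column_map,
            trait_label=config.outcome_label,
        )
        counts["exposure_parsed"] = len(exposure)
        counts["outcome_parsed"] = len(outcome)

        stage = "filter_genome_wide"
        sig = filter_genome_wide(exposure, config.p_threshold)
        counts["genome_wide"] = len(sig)
        logger.info("%d variants at p < %g", len(sig), config.p_threshold)

        stage = "clump"
        ld = _read_ld(config)
        clumped = clump(sig, ld, window_kb=config.window_kb,
                        r2_threshold=config.clump_r2)
        counts["clumped"] = len(clumped)

        stage = "strength_filter"
        strong = strength_filter(clumped, f_min=config.f_min,
                                 on_missing_eaf="drop")
        counts["strong"] = len(strong)
        write_table(strong.frame, outdir / "ivs.tsv")

        stage = "harmonize"
        proxy_table = (
            pd.read_csv(config.proxy_path, sep="\t")
            if config.proxy_path else None
        )
        hset = harmonize(
            strong, outcome, maf_threshold=config.maf_threshold,
            proxy_table=proxy_table, proxy_r2_min=config.proxy_r2_min,
        )
        counts["harmonized"] = len(hset)
        write_table(hset.frame, outdir / "harmonized.tsv")
        if len(hset) == 0:
            raise EmptyInstrumentSetError(
                "no instruments remain after harmonization"
            )

        stage = "estimators"
        model = MRModel(hset)
        suite = model.fit_all(seed=config.seed, n_boot=config.n_boot,
                              alpha=config.alpha)
        write_table(suite.to_frame(), outdir / "mr_results.tsv")

        stage = "heterogeneity"
        het = [cochran_q(model, "ivw")]
        if len(hset) >= 3:
            het.append(cochran_q(model, "egger"))
        write_table([h.to_dict() for h in het], outdir / "heterogeneity.tsv")

        stage = "pleiotropy"
        pleio = suite.pleiotropy
        write_table([pleio.to_dict()], outdir / "pleiotropy.tsv")

        stage = "presso"
        presso_result = None
        presso_triggered = bool(pleio.pval < config.alpha)
        if (presso_triggered or config.force_presso) and len(hset) >= 4:
            presso_result = run_presso(
                model, n_sim=config.presso_n_sim, seed=config.seed,
                alpha=config.alpha,
            )
            presso_result.to_json(outdir / "presso.json")
            counts["presso_outliers"] = len(presso_result.outliers)

        stage = "sensitivity"
        singles = single_snp(model)
        single_frame = pd.DataFrame([
            {"variant_id": vid, **{k: v for k, v in r.to_dict().items()
                                   if k != "label"}}
            for vid, r in zip(model.variant_ids, singles)
        ])
        write_table(single_frame, outdir / "single_snp.tsv")
        loo = leave_one_out(model) if len(hset) >= 3 else pd.DataFrame()
        write_table(loo, outdir / "loo.tsv")

        stage = "plot_data"
        tables = plot_data(model, suite=suite, loo=loo)
        write_table(tables["scatter"], outdir / "scatter.tsv")
        write_table(tables["funnel"], outdir / "funnel.tsv")
    except EmptyInstrumentSetError:
        raise
    except (InputError, EstimationError, ValueError, OSError) as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    manifest = {
        "tool": "tsmr",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_counts": counts,
        "audit": hset.audit,
        "consistent": suite.consistent,
        "significant": suite.significant,
        "q_ivw": suite.q_ivw,
        "q_ivw_pval": suite.q_ivw_pval,
        "egger_intercept": pleio.to_dict(),
        "presso_triggered": presso_triggered,
        "presso": presso_result.to_dict() if presso_result else None,
        "results": {k: r.to_dict() for k, r in suite.results.items()},
        "outputs_sha256": _digest_outputs(outdir),
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _digest_outputs(outdir: Path) -> dict:
    digests = {}
    for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("presso.json")):
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return digests


def run_prioritization(
    runs,
    score_path,
    sei_min: float = 1.0,
    b_min: float = 0.5,
    top_k: int | None = None,
    outdir=None,
) -> dict:
    """Merge instrument sets across completed runs and rank candidates.

    ``runs``: sequence of (label, single_snp.tsv path).  Writes
    prioritized.tsv and heatmap.tsv when ``outdir`` is given; returns a
    report with both the merged and the scored variant counts plus the
    ranked selection.
    """
    betas: dict[str, dict[str, float]] = {}
    id_sets = []
    for label, path in runs:
        path = Path(path)
        if not path.exists():
            raise InputError(f"single-SNP table for run {label!r} not found: {path}")
        df = pd.read_csv(path, sep="\t")
        betas[label] = dict(zip(df["variant_id"].astype(str), df["beta"]))
        id_sets.append((label, df["variant_id"].astype(str).tolist()))

    merged = merge_iv_sets(id_sets)
    scores_table = load_seq_class_table(score_path)
    scored, unscored = attach_scores(merged, betas, scores_table)
    selected = select_functional(scored, sei_min=sei_min, b_min=b_min, top_k=top_k)

    ranked = pd.DataFrame([s.to_dict() for s in selected])
    heat = heatmap_table(selected)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(ranked, outdir / "prioritized.tsv")
        write_table(heat, outdir / "heatmap.tsv")

    return {
        "n_merged": len(merged),
        "n_scored": len(scored),
        "n_unscored": len(unscored),
        "unscored_ids": unscored,
        "n_selected": len(selected),
        "selected": [s.to_dict() for s in selected],
    }
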