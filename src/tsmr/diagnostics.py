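"""Heterogeneity, pleiotropy, and sensitivity diagnostics.

Cochran's Q tests whether the per-variant ratio estimates are mutually
consistent (IVW form) or whether residual spread remains around the
Egger line.  Single-SNP Wald ratios and leave-one-out IVW re-fits
reveal whether any one instrument drives the pooled estimate.
``plot_data`` emits the scatter/funnel/forest tables behind the
standard MR figures; rendering is optional and kept out of the
analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    EstimationError,
    MRModel,
    MRResult,
    MRSuite,
    PleiotropyResult,
    _as_model,
    _egger_fit,
    egger,
    ivw,
    wald_ratio,
)

__all__ = [
    "HeterogeneityResult",
    "cochran_q",
    "egger_intercept_test",
    "single_snp",
    "leave_one_out",
    "plot_data",
]


@dataclass
class HeterogeneityResult:
    method: str
    Q: float
    df: int
    pval: float

    def to_dict(self) -> dict:
        return {"method": self.method, "Q": self.Q, "df": self.df, "pval": self.pval}


def cochran_q(data, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic.

    IVW form: Q = sum w_j (ratio_j - beta_ivw)^2 with df = J-1.
    Egger form: weighted residual sum around the Egger line, df = J-2.
    P-value from the upper tail of chi-square(df).
    """
    m = _as_model(data)
    if method == "ivw":
        if m.n_snp < 2:
            raise EstimationError("Q (IVW) requires at least 2 pairs")
        w = m.weights
        ratios = m.ratios
        beta = float((w * ratios).sum() / w.sum())
        q = float((w * (ratios - beta) ** 2).sum())
        dof = m.n_snp - 1
    elif method == "egger":
        _, _, _, _, q, dof = _egger_fit(m)
    else:
        raise ValueError(f"unknown heterogeneity method {method!r}")
    pval = float(stats.chi2.sf(q, dof))
    return HeterogeneityResult(method=method, Q=q, df=dof, pval=max(pval, np.finfo(float).tiny))


def egger_intercept_test(data) -> PleiotropyResult:
    """Directional-pleiotropy test: the MR-Egger intercept.

    Exposed separately because the pipeline branches on its p-value
    (p < 0.05 triggers MR-PRESSO outlier handling)."""
    _, pleio = egger(data)
    return pleio


def single_snp(data) -> list[MRResult]:
    """Per-variant Wald ratios, in instrument order.

    These betas are the "b scores" consumed by functional variant
    prioritization."""
    m = _as_model(data)
    return [wald_ratio(m.frame.iloc[j]) for j in range(m.n_snp)]


def leave_one_out(data) -> pd.DataFrame:
    """Fixed-effect IVW re-fit excluding each variant in turn.

    The ``drives_result`` flag marks any exclusion that changes the
    estimate's sign or moves its p-value across the 0.05 boundary
    relative to the all-variant fit.
    """
    m = _as_model(data)
    if m.n_snp < 3:
        raise EstimationError("leave-one-out requires at least 3 pairs")
    full = ivw(m, model="fixed")
    rows = []
    mask = np.ones(m.n_snp, dtype=bool)
    for j in range(m.n_snp):
        mask[j] = False
        res = ivw(m.subset(mask), model="fixed")
        mask[j] = True
        drives = (np.sign(res.beta) != np.sign(full.beta)) or (
            (res.pval < 0.05) != (full.pval < 0.05)
        )
        rows.append({
            "excluded_id": m.variant_ids[j],
            "n_snp": res.n_snp,
            "beta": res.beta, "se": res.se,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "pval": res.pval,
            "drives_result": bool(drives),
        })
    return pd.DataFrame(rows)


def plot_data(data, suite: MRSuite | None = None,
              loo: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Data tables behind the scatter, funnel, and forest plots.

    Returns a dict with keys ``scatter`` (per-variant effects plus one
    fitted line per method), ``funnel`` (Wald ratio vs precision, with
    method verticals), ``forest_single`` and ``forest_loo``.
    """
    m = _as_model(data)
    singles = single_snp(m)
    ratios = np.array([r.beta for r in singles])
    ses = np.array([r.se for r in singles])

    scatter = pd.DataFrame({
        "variant_id": m.variant_ids,
        "beta_exp": m.x, "se_exp": m.sx,
        "beta_out": m.y, "se_out": m.sy,
    })
    lines = []
    if suite is not None:
        for name, res in suite.results.items():
            intercept = 0.0
            if name == "egger" and suite.pleiotropy is not None:
                intercept = suite.pleiotropy.intercept
            lines.append({"method": name, "intercept": intercept, "slope": res.beta})
    scatter_lines = pd.DataFrame(lines, columns=["method", "intercept", "slope"])

    funnel = pd.DataFrame({
        "variant_id": m.variant_ids,
        "ratio": ratios,
        "precision": 1.0 / ses,
    })
    forest_single = pd.DataFrame([
        {"variant_id": vid, **{k: v for k, v in r.to_dict().items() if k != "label"}}
        for vid, r in zip(m.variant_ids, singles)
    ])
    return {
        "scatter": scatter,
        "scatter_lines": scatter_lines,
        "funnel": funnel,
        "funnel_lines": scatter_lines.loc[
            scatter_lines["method"].isin(["ivw_fixed", "ivw_mre", "egger"]),
            ["method", "slope"],
        ].reset_index(drop=True),
        "forest_single": forest_single,
        "forest_loo": loo if loo is not None else pd.DataFrame(),
    }


def render_plots(tables: dict[str, pd.DataFrame], outdir) -> list[str]:
    """Optional matplotlib rendering of the plot tables (PNG files)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    sc = tables["scatter"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(sc["beta_exp"], sc["beta_out"], xerr=sc["se_exp"],
                yerr=sc["se_out"], fmt="o", ms=3, lw=0.8, alpha=0.7)
    xs = np.linspace(0, sc["beta_exp"].max() * 1.05, 50)
    for _, line in tables["scatter_lines"].iterrows():
        ax.plot(xs, line["intercept"] + line["slope"] * xs, label=line["method"], lw=1)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    p = outdir / "scatter.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(str(p))

    fn = tables["funnel"]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(fn["ratio"], fn["precision"], "o", ms=3, alpha=0.7)
    for _, line in tables["funnel_lines"].iterrows():
        ax.axvline(line["slope"], lw=1, label=line["method"])
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("1 / SE")
    ax.legend(fontsize=7)
    p = outdir / "funnel.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(str(p))
    return written
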