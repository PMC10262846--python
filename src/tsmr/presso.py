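"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

Three stages, all driven by the observed residual sum of squares (RSS)
of the per-variant outcome effects around leave-one-out IVW fits:

* global test — is there more residual pleiotropy than expected under
  the no-pleiotropy model?  The null distribution of the RSS is built
  by parametric simulation (outcome effects redrawn around the
  leave-one-out fitted values, exposure effects around their
  observations).
* outlier test — per-variant empirical p-value of each observed
  residual against its simulated null, Bonferroni-adjusted.
* distortion test — does removing the flagged outliers change the
  causal estimate more than removing an equally sized random subset?

Empirical p-values use add-one smoothing, (1 + #{sim >= obs})/(n_sim + 1),
so they are never exactly zero.  A seed is mandatory: identical seeds
reproduce the result bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import EstimationError, MRModel, MRResult, _as_model, ivw

__all__ = ["PressoResult", "presso"]


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    per_snp_p: dict = field(default_factory=dict)
    outliers: list = field(default_factory=list)
    distortion_p: float | None = None
    corrected: MRResult | None = None
    n_sim: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_p": self.global_p,
            "per_snp_p": self.per_snp_p,
            "outliers": list(self.outliers),
            "distortion_p": self.distortion_p,
            "corrected": self.corrected.to_dict() if self.corrected else None,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        """Per-variant residual p-values and outlier flags."""
        return pd.DataFrame({
            "variant_id": list(self.per_snp_p),
            "p_adjusted": list(self.per_snp_p.values()),
            "outlier": [v in set(self.outliers) for v in self.per_snp_p],
        })


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted through-origin slopes, one per variant.

    Vectorized: slope_{-j} = (S_xy - w_j x_j y_j) / (S_xx - w_j x_j^2).
    Works row-wise on 2-D inputs (simulations x variants).
    """
    sxy = (w * x * y).sum(axis=-1, keepdims=True)
    sxx = (w * x * x).sum(axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def presso(data, n_sim: int = 1000, seed: int | None = None,
           alpha: float = 0.05) -> PressoResult:
    """Run the MR-PRESSO global, outlier, and distortion tests.

    Parameters
    ----------
    data
        HarmonizedSet / MRModel / harmonized DataFrame with >= 4 pairs.
    n_sim
        Simulation count for the empirical null distributions.
    seed
        Mandatory RNG seed (reproducibility contract).
    alpha
        Threshold on the Bonferroni-adjusted per-variant p-values.
    """
    m = _as_model(data)
    if m.n_snp < 4:
        raise EstimationError("MR-PRESSO requires at least 4 harmonized pairs")
    if seed is None:
        raise ValueError("MR-PRESSO requires an explicit seed")
    rng = np.random.default_rng(seed)
    j = m.n_snp
    x, y, sx, sy = m.x, m.y, m.sx, m.sy
    w = 1.0 / sy ** 2

    slopes = _loo_slopes(x, y, w)
    resid_obs = w * (y - slopes * x) ** 2
    rss_obs = float(resid_obs.sum())

    # parametric null: redraw effects around the leave-one-out fit
    y_star = rng.normal(slopes[None, :] * x[None, :], sy[None, :], size=(n_sim, j))
    x_star = rng.normal(x[None, :], sx[None, :], size=(n_sim, j))
    slopes_star = _loo_slopes(x_star, y_star, w[None, :])
    resid_star = w[None, :] * (y_star - slopes_star * x_star) ** 2
    rss_star = resid_star.sum(axis=1)

    global_p = float((1 + (rss_star >= rss_obs).sum()) / (n_sim + 1))
    p_raw = (1 + (resid_star >= resid_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    p_adj = np.minimum(p_raw * j, 1.0)
    per_snp_p = {vid: float(p) for vid, p in zip(m.variant_ids, p_adj)}
    out_mask = p_adj < alpha
    outliers = [m.variant_ids[i] for i in np.flatnonzero(out_mask)]

    if out_mask.all():
        raise EstimationError("all variants flagged as outliers; no instruments remain")

    corrected = ivw(m.subset(~out_mask), model="fixed")

    distortion_p = None
    if outliers:
        beta_all = ivw(m, model="fixed").beta
        stat_obs = (beta_all - corrected.beta) / abs(corrected.beta)
        k = len(outliers)
        stats_null = np.empty(n_sim)
        idx = np.arange(j)
        for s in range(n_sim):
            drop = rng.choice(idx, size=k, replace=False)
            keep = np.ones(j, dtype=bool)
            keep[drop] = False
            b_sub = float((w[keep] * x[keep] * y[keep]).sum()
                          / (w[keep] * x[keep] ** 2).sum())
            stats_null[s] = (beta_all - b_sub) / abs(b_sub)
        distortion_p = float(
            (1 + (np.abs(stats_null) >= abs(stat_obs)).sum()) / (n_sim + 1)
        )

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        per_snp_p=per_snp_p,
        outliers=outliers,
        distortion_p=distortion_p,
        corrected=corrected,
        n_sim=n_sim,
        seed=int(seed),
    )
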