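"""Two-sample MR causal-effect estimators.

The working object is :class:`MRModel`, built from a
:class:`~tsmr.instruments.HarmonizedSet` (or a plain DataFrame of
harmonized exposure/outcome effect pairs).  ``fit(method=...)`` returns
an :class:`MRResult`; ``fit_all(seed=...)`` runs the five-method suite
(IVW, MR-Egger, weighted median, simple mode, weighted mode) and the
direction-consistency / significance rule used to call a causal effect.

All methods work on per-variant Wald ratios beta_out_j / beta_exp_j
with inverse-variance weights w_j = beta_exp_j^2 / se_out_j^2 (the
first-order ratio variance; exposure-side uncertainty is ignored by
convention — a second-order option exists on ``wald_ratio``).

* IVW: weighted mean of ratios = weighted regression through the
  origin; fixed-effect SE (Sum w)^(-1/2), or multiplicative
  random-effects SE inflated by max(1, sqrt(Q/(J-1))).
* MR-Egger: weighted regression of outcome on exposure effects with a
  free intercept after orienting all exposure effects positive; the
  intercept estimates the average directional pleiotropy (valid under
  InSIDE); t(J-2) inference with residual SE floored at 1.
* Weighted median: consistent when valid instruments carry >= 50% of
  the weight; SE by parametric bootstrap.
* Mode-based (simple/weighted): argmax of a Gaussian kernel density of
  the ratios; consistent when the largest homogeneous cluster of
  instruments is valid; SE by parametric bootstrap.

Results carry both the log-odds-scale estimate and its odds-ratio
transform, since binary-trait GWAS report log-OR per effect allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonizedSet

__all__ = [
    "MRModel", "MRResult", "PleiotropyResult", "MRSuite", "EstimationError",
    "wald_ratio", "ivw", "egger", "weighted_median", "mode_estimate", "run_all",
]

Z95 = float(stats.norm.ppf(0.975))

METHOD_LABELS = {
    "wald_ratio": "Wald ratio",
    "ivw_fixed": "Inverse variance weighted (fixed effects)",
    "ivw_mre": "Inverse variance weighted (multiplicative random effects)",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
}


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass
class MRResult:
    """One estimator's causal estimate on the log-OR (beta) scale."""

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    label: str = ""

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        lo, hi = self.or_ci
        return {
            "method": self.method, "label": self.label, "n_snp": self.n_snp,
            "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "pval": self.pval,
            "odds_ratio": self.or_, "or_ci_low": lo, "or_ci_high": hi,
        }

    def summary(self) -> str:
        lo, hi = self.or_ci
        return (
            f"{METHOD_LABELS.get(self.method, self.method)} "
            f"(nSNP={self.n_snp}): beta={self.beta:.4f} (SE {self.se:.4f}), "
            f"OR={self.or_:.3f} [95% CI {lo:.3f}, {hi:.3f}], p={self.pval:.3g}"
        )


@dataclass
class PleiotropyResult:
    """MR-Egger intercept: the average directional pleiotropic effect."""

    intercept: float
    se: float
    pval: float

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "se": self.se, "pval": self.pval}


@dataclass
class EggerResult(MRResult):
    """MR-Egger slope with the pleiotropy-intercept test attached."""

    pleiotropy: PleiotropyResult | None = None


@dataclass
class MRSuite:
    """Results of the five-method suite plus the decision rule.

    ``consistent`` — all five point estimates share a sign;
    ``significant`` — consistent AND all five p-values < 0.05.
    """

    results: dict = field(default_factory=dict)
    pleiotropy: PleiotropyResult | None = None
    q_ivw: float = np.nan
    q_ivw_pval: float = np.nan
    consistent: bool = False
    significant: bool = False

    CORE = ("ivw_fixed", "egger", "weighted_median", "simple_mode", "weighted_mode")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results.values()])

    def summary(self) -> str:
        lines = [r.summary() for r in self.results.values()]
        lines.append(
            f"Directions consistent across five methods: {self.consistent}; "
            f"all five p < 0.05: {self.significant}"
        )
        if self.pleiotropy is not None:
            p = self.pleiotropy
            lines.append(
                f"Egger intercept {p.intercept:.4f} (SE {p.se:.4f}), p={p.pval:.3g}"
            )
        return "\n".join(lines)


def _coerce(data) -> pd.DataFrame:
    if isinstance(data, HarmonizedSet):
        return data.frame
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError("expected a HarmonizedSet or DataFrame of harmonized pairs")


class MRModel:
    """Two-sample MR model over a set of harmonized instrument pairs.

    Parameters
    ----------
    data
        HarmonizedSet or DataFrame with columns beta_exp, se_exp,
        beta_out, se_out (and optionally variant_id).
    """

    def __init__(self, data, exposure_label: str | None = None,
                 outcome_label: str | None = None):
        frame = _coerce(data)
        if isinstance(data, HarmonizedSet):
            exposure_label = exposure_label or data.exposure_label
            outcome_label = outcome_label or data.outcome_label
        self.exposure_label = exposure_label or "exposure"
        self.outcome_label = outcome_label or "outcome"
        self.frame = frame.reset_index(drop=True)
        self.variant_ids = (
            self.frame["variant_id"].astype(str).tolist()
            if "variant_id" in self.frame
            else [f"v{i + 1}" for i in range(len(self.frame))]
        )
        self.x = self.frame["beta_exp"].to_numpy(dtype=float)
        self.sx = self.frame["se_exp"].to_numpy(dtype=float)
        self.y = self.frame["beta_out"].to_numpy(dtype=float)
        self.sy = self.frame["se_out"].to_numpy(dtype=float)
        if np.any(self.sy <= 0) or np.any(self.sx <= 0):
            raise EstimationError("all standard errors must be positive")

    @classmethod
    def from_harmonized(cls, hset: HarmonizedSet) -> "MRModel":
        return cls(hset)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "MRModel":
        return cls(df, **kw)

    # -- basic quantities -------------------------------------------------

    @property
    def n_snp(self) -> int:
        return self.x.size

    @property
    def ratios(self) -> np.ndarray:
        self._require_nonzero_exposure()
        return self.y / self.x

    @property
    def weights(self) -> np.ndarray:
        """First-order inverse-variance weights beta_exp^2 / se_out^2."""
        return self.x ** 2 / self.sy ** 2

    def _require_nonzero_exposure(self):
        zero = np.flatnonzero(self.x == 0)
        if zero.size:
            raise EstimationError(
                f"zero exposure effect for variant(s) "
                f"{[self.variant_ids[i] for i in zero]}"
            )

    # -- fitting ----------------------------------------------------------

    def fit(self, method: str = "ivw", **kw) -> MRResult:
        """Fit one estimator; see module functions for the math."""
        if method in ("ivw", "ivw_fixed"):
            return ivw(self, model="fixed", **kw)
        if method == "ivw_mre":
            return ivw(self, model="mre", **kw)
        if method == "egger":
            res, pleio = egger(self)
            return res
        if method == "weighted_median":
            return weighted_median(self, **kw)
        if method == "simple_mode":
            return mode_estimate(self, weighted=False, **kw)
        if method == "weighted_mode":
            return mode_estimate(self, weighted=True, **kw)
        if method == "wald_ratio":
            if self.n_snp != 1:
                raise EstimationError("wald_ratio applies to a single pair")
            return wald_ratio(self.frame.iloc[0], **kw)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, seed: int, n_boot: int = 1000, alpha: float = 0.05) -> MRSuite:
        return run_all(self, seed=seed, n_boot=n_boot, alpha=alpha)

    # -- diagnostics (delegation keeps one import direction) ---------------

    def cochran_q(self, method: str = "ivw"):
        from .diagnostics import cochran_q
        return cochran_q(self, method=method)

    def egger_intercept_test(self) -> PleiotropyResult:
        from .diagnostics import egger_intercept_test
        return egger_intercept_test(self)

    def single_snp(self):
        from .diagnostics import single_snp
        return single_snp(self)

    def leave_one_out(self):
        from .diagnostics import leave_one_out
        return leave_one_out(self)

    def presso(self, n_sim: int = 1000, seed: int | None = None, alpha: float = 0.05):
        from .presso import presso
        return presso(self, n_sim=n_sim, seed=seed, alpha=alpha)

    def subset(self, keep_mask) -> "MRModel":
        keep_mask = np.asarray(keep_mask)
        return MRModel(
            self.frame.loc[keep_mask].reset_index(drop=True),
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )


def _as_model(data) -> MRModel:
    return data if isinstance(data, MRModel) else MRModel(data)


def _normal_result(method: str, n_snp: int, beta: float, se: float,
                   label: str = "") -> MRResult:
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    pval = float(np.clip(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return MRResult(
        method=method, n_snp=n_snp, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        pval=pval, label=label,
    )


def wald_ratio(pair, second_order: bool = False) -> MRResult:
    """Single-variant causal estimate beta_out / beta_exp.

    SE by the delta method: first-order se_out/|beta_exp| (default) or
    second-order adding the exposure-side term
    beta_out^2 se_exp^2 / beta_exp^4.
    """
    bx = float(pair["beta_exp"])
    by = float(pair["beta_out"])
    sx = float(pair["se_exp"])
    sy = float(pair["se_out"])
    if bx == 0:
        raise EstimationError("wald ratio undefined for zero exposure effect")
    beta = by / bx
    var = sy ** 2 / bx ** 2
    if second_order:
        var = var + by ** 2 * sx ** 2 / bx ** 4
    label = str(pair["variant_id"]) if "variant_id" in pair else ""
    return _normal_result("wald_ratio", 1, beta, float(np.sqrt(var)), label=label)


def ivw(data, model: str = "fixed") -> MRResult:
    """Inverse-variance-weighted estimate: a fixed-effect meta-analysis
    of per-variant Wald ratios (equivalently, weighted least squares of
    beta_out on beta_exp through the origin).

    ``model='mre'`` inflates the SE by max(1, sqrt(Q/(J-1))) —
    multiplicative random effects; never below the fixed-effect SE.
    """
    m = _as_model(data)
    if m.n_snp < 2:
        if m.n_snp == 1 and model == "fixed":
            res = wald_ratio(m.frame.iloc[0])
            return _normal_result("ivw_fixed", 1, res.beta, res.se)
        raise EstimationError("IVW requires at least 2 harmonized pairs")
    ratios = m.ratios
    w = m.weights
    sw = w.sum()
    beta = float((w * ratios).sum() / sw)
    se = float(1.0 / np.sqrt(sw))
    method = "ivw_fixed"
    if model == "mre":
        q = float((w * (ratios - beta) ** 2).sum())
        se *= max(1.0, np.sqrt(q / (m.n_snp - 1)))
        method = "ivw_mre"
    elif model != "fixed":
        raise ValueError(f"unknown IVW model {model!r}")
    return _normal_result(method, m.n_snp, beta, se)


def _egger_fit(m: MRModel):
    """Weighted normal equations for MR-Egger, after orienting x >= 0."""
    if m.n_snp < 3:
        raise EstimationError("MR-Egger requires at least 3 harmonized pairs")
    sign = np.where(m.x < 0, -1.0, 1.0)
    x = m.x * sign
    y = m.y * sign
    w = 1.0 / m.sy ** 2
    s0, sx_ = w.sum(), (w * x).sum()
    sxx, sy_, sxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
    det = s0 * sxx - sx_ ** 2
    if det <= 0 or np.isclose(det / (s0 * sxx), 0.0):
        raise EstimationError(
            "degenerate MR-Egger design: no spread in exposure effects"
        )
    slope = (s0 * sxy - sx_ * sy_) / det
    intercept = (sxx * sy_ - sx_ * sxy) / det
    resid = y - intercept - slope * x
    q = float((w * resid ** 2).sum())
    dof = m.n_snp - 2
    scale = max(1.0, np.sqrt(q / dof))
    se_slope = float(np.sqrt(s0 / det)) * scale
    se_int = float(np.sqrt(sxx / det)) * scale
    return float(slope), se_slope, float(intercept), se_int, q, dof


def egger(data) -> tuple[EggerResult, PleiotropyResult]:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy; t(J-2) inference."""
    m = _as_model(data)
    slope, se_slope, intercept, se_int, q, dof = _egger_fit(m)
    tcrit = float(stats.t.ppf(0.975, dof))
    p_slope = float(np.clip(2 * stats.t.sf(abs(slope / se_slope), dof),
                            np.finfo(float).tiny, 1.0))
    p_int = float(np.clip(2 * stats.t.sf(abs(intercept / se_int), dof),
                          np.finfo(float).tiny, 1.0))
    pleio = PleiotropyResult(intercept=intercept, se=se_int, pval=p_int)
    res = EggerResult(
        method="egger", n_snp=m.n_snp, beta=slope, se=se_slope,
        ci_low=slope - tcrit * se_slope, ci_high=slope + tcrit * se_slope,
        pval=p_slope, pleiotropy=pleio,
    )
    return res, pleio


def _weighted_median(ratios: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: cumulative weight midpoints s_j =
    sum_{k<j} w_k + w_j/2 (weights normalized), linear interpolation of
    the sorted ratios over s at 0.5."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    wn = w[order] / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r))


def _boot_draws(m: MRModel, n_boot: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    bx = rng.normal(m.x, m.sx, size=(n_boot, m.n_snp))
    by = rng.normal(m.y, m.sy, size=(n_boot, m.n_snp))
    return bx, by


def weighted_median(data, n_boot: int = 1000, seed: int | None = None) -> MRResult:
    """Weighted-median estimator; parametric-bootstrap SE.

    Consistent when valid instruments contribute at least half the
    total weight.  ``n_boot=0`` returns the point estimate with NaN SE.
    """
    m = _as_model(data)
    if m.n_snp < 3:
        raise EstimationError("weighted median requires at least 3 pairs")
    if n_boot > 0 and seed is None:
        raise ValueError("a seed is required for the bootstrap SE (reproducibility)")
    ratios = m.ratios
    w = m.weights
    beta = _weighted_median(ratios, w)
    if n_boot == 0:
        return MRResult("weighted_median", m.n_snp, beta, np.nan,
                        np.nan, np.nan, np.nan)
    bx, by = _boot_draws(m, n_boot, seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        est[b] = _weighted_median(by[b] / bx[b], w)
    se = float(np.std(est, ddof=1))
    return _normal_result("weighted_median", m.n_snp, beta, se)


def _mode_point(ratios: np.ndarray, w: np.ndarray | None, phi: float) -> float:
    """Mode of the Gaussian-KDE of the ratios on a 512-point grid.

    Bandwidth: modified Silverman rule
    h = phi * 0.9 * min(sd, 1.4826*MAD) * J^(-1/5).
    """
    j = ratios.size
    sd = float(np.std(ratios, ddof=1))
    mad = float(1.4826 * np.median(np.abs(ratios - np.median(ratios))))
    h = phi * 0.9 * min(sd, mad) * j ** (-0.2)
    if h <= 0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - h, ratios.max() + h, 512)
    if w is None:
        wn = np.full(j, 1.0 / j)
    else:
        wn = w / w.sum()
    dens = (wn[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(data, weighted: bool = False, phi: float = 1.0,
                  n_boot: int = 1000, seed: int | None = None) -> MRResult:
    """Mode-based estimate (simple or weighted): the causal effect is
    taken at the densest cluster of per-variant ratios.  SE by
    parametric bootstrap (bandwidth recomputed per replicate)."""
    m = _as_model(data)
    if m.n_snp < 3:
        raise EstimationError("mode estimators require at least 3 pairs")
    if n_boot > 0 and seed is None:
        raise ValueError("a seed is required for the bootstrap SE (reproducibility)")
    ratios = m.ratios
    w = m.weights if weighted else None
    beta = _mode_point(ratios, w, phi)
    method = "weighted_mode" if weighted else "simple_mode"
    if n_boot == 0:
        return MRResult(method, m.n_snp, beta, np.nan, np.nan, np.nan, np.nan)
    bx, by = _boot_draws(m, n_boot, seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        est[b] = _mode_point(by[b] / bx[b], w, phi)
    se = float(np.std(est, ddof=1))
    return _normal_result(method, m.n_snp, beta, se)


def run_all(data, seed: int, n_boot: int = 1000, alpha: float = 0.05) -> MRSuite:
    """Five-method suite with the direction-consistency rule.

    Runs IVW (fixed effects; the multiplicative-random-effects variant
    is added when Cochran's Q is significant at ``alpha``), MR-Egger,
    weighted median, and the two mode estimators.  The causal call
    requires all five estimates to share a sign and all five p-values
    to be below 0.05.
    """
    m = _as_model(data)
    if m.n_snp < 3:
        raise EstimationError("the five-method suite requires at least 3 pairs")
    from .diagnostics import cochran_q  # local import avoids a cycle

    ss = np.random.SeedSequence(int(seed))
    s_med, s_smode, s_wmode = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]

    het = cochran_q(m, method="ivw")
    results: dict[str, MRResult] = {}
    results["ivw_fixed"] = ivw(m, model="fixed")
    if het.pval < alpha:
        results["ivw_mre"] = ivw(m, model="mre")
    egger_res, pleio = egger(m)
    results["egger"] = egger_res
    results["weighted_median"] = weighted_median(m, n_boot=n_boot, seed=s_med)
    results["simple_mode"] = mode_estimate(m, weighted=False, n_boot=n_boot, seed=s_smode)
    results["weighted_mode"] = mode_estimate(m, weighted=True, n_boot=n_boot, seed=s_wmode)

    core = [results[k] for k in MRSuite.CORE]
    signs = {np.sign(r.beta) for r in core}
    consistent = len(signs) == 1 and 0.0 not in signs
    significant = consistent and all(r.pval < 0.05 for r in core)
    return MRSuite(
        results=results, pleiotropy=pleio,
        q_ivw=het.Q, q_ivw_pval=het.pval,
        consistent=consistent, significant=significant,
    )
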