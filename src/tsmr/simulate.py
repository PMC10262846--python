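"""Synthetic GWAS summary-data generator with known ground truth.

Emulates the statistical structure a two-sample MR analysis assumes:
per-variant true exposure effects gamma_j, a global causal effect theta
carrying them into the outcome, optional direct (pleiotropic) effects
alpha_j, sampling noise scaled by GWAS sample size and allele frequency
via se ~ 1/sqrt(2 N EAF (1-EAF)), LD blocks of correlated variants,
palindromic alleles, outcome-trait-specific instruments (so
reverse-direction analyses have something to select), and planted
outliers (outcome effects displaced by 10 SE).

Pleiotropy modes
----------------
``none``           alpha = 0 everywhere.
``balanced``       alpha ~ N(0, pleio_sd) — mean-zero direct effects.
``directional``    alpha ~ N(pleio_mean, pleio_sd).
``inside_violated``directional plus corr(gamma, alpha) = 0.5, breaking
                   the InSIDE assumption MR-Egger relies on.
``pleio_fraction`` limits pleiotropy to the first fraction of
instruments; the rest stay valid.

Identical seed + config give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonizedSet, LDMatrix
from .io import SummaryTable, CANONICAL_COLUMNS

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_pair",
    "simulate_harmonized",
    "simulate_seq_class_table",
    "SEQ_CLASS_LABELS",
]

_TINY = np.finfo(float).tiny

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violated")

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

#: 40 chromatin sequence-class labels used for synthetic score tables
SEQ_CLASS_LABELS = (
    ["CTCF", "CTCF-cohesin"]
    + [f"TF{i}" for i in range(1, 5)]
    + [f"E{i}" for i in range(1, 13)]
    + [f"P{i}" for i in range(1, 5)]
    + [f"HET{i}" for i in range(1, 7)]
    + [f"TN{i}" for i in range(1, 5)]
    + [f"L{i}" for i in range(1, 9)]
)
assert len(SEQ_CLASS_LABELS) == 40


@dataclass
class SimulationConfig:
    """Conditions of one synthetic two-sample MR study.

    Defaults describe the reference scenario: 50 genuine instruments
    with realistic log-OR effects (gamma ~ N(0.06, 0.03) truncated to
    keep every instrument genome-wide detectable, z around 20 on a
    300k-sample exposure GWAS with F >> 10; the spread is sized so
    MR-Egger has adequate power at this J), a causal effect theta = 0.7
    on the log-odds scale, an outcome GWAS of effective sample size 4k
    (the scale of a small case-control GWAS), and no pleiotropy unless
    asked for.
    """

    n_variants: int = 300
    n_instruments: int = 50
    theta: float = 0.7
    pleiotropy_mode: str = "none"
    pleio_mean: float = 0.1
    pleio_sd: float = 0.05
    pleio_fraction: float = 1.0
    gamma_dist: tuple = (0.06, 0.03)
    n_exp: int = 300_000
    n_out: int = 4_000
    maf_range: tuple = (0.05, 0.5)
    ld_blocks: tuple = ((4, 0.9), (4, 0.9), (4, 0.64))
    palindromic_fraction: float = 0.1
    outlier_ids: tuple = ()
    n_outcome_instruments: int = 10
    delta_dist: tuple = (0.25, 0.05)
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimulationConfig requires an explicit seed")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}, "
                f"got {self.pleiotropy_mode!r}"
            )
        n_block = sum(s for s, _ in self.ld_blocks)
        n_tags = sum(s - 1 for s, _ in self.ld_blocks)
        needed = self.n_instruments + n_tags + self.n_outcome_instruments
        if self.n_instruments > self.n_variants:
            raise ValueError("n_instruments cannot exceed n_variants")
        if needed > self.n_variants:
            raise ValueError(
                f"n_variants={self.n_variants} too small for "
                f"{self.n_instruments} instruments + {n_tags} LD tags + "
                f"{self.n_outcome_instruments} outcome instruments"
            )
        if len(self.ld_blocks) > self.n_instruments:
            raise ValueError("more LD blocks than instruments")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthRecord:
    """Per-variant ground truth plus the global causal effect."""

    theta: float
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def instruments(self) -> pd.DataFrame:
        return self.frame.loc[self.frame["is_instrument"]]

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["theta"] = self.theta
        return out


def _se_model(n: int, eaf: np.ndarray) -> np.ndarray:
    """Standard GWAS sampling-error approximation 1/sqrt(2 N f (1-f))."""
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


#: minimum true instrument z-score; keeps every instrument detectable at
#: genome-wide significance (|z| 5.45), mirroring that real instrument
#: selection conditions on significance
_MIN_INSTRUMENT_Z = 6.0


def _draw_gamma(rng, cfg: SimulationConfig, se_exp: np.ndarray) -> np.ndarray:
    """True instrument effects: N(mean, sd) truncated below so that
    gamma / se_exp >= _MIN_INSTRUMENT_Z for every instrument."""
    mu, sd = cfg.gamma_dist
    lo = _MIN_INSTRUMENT_Z * se_exp
    a = (lo - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd,
                               size=se_exp.size, random_state=rng)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), _TINY, 1.0)


def _draw_alpha(rng, cfg: SimulationConfig, gamma: np.ndarray) -> np.ndarray:
    """Direct (pleiotropic) outcome effects for the instruments."""
    j = gamma.size
    alpha = np.zeros(j)
    k = int(round(cfg.pleio_fraction * j))
    if cfg.pleiotropy_mode == "none" or k == 0:
        return alpha
    if cfg.pleiotropy_mode == "balanced":
        alpha[:k] = rng.normal(0.0, cfg.pleio_sd, size=k)
    elif cfg.pleiotropy_mode == "directional":
        alpha[:k] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=k)
    else:  # inside_violated: corr(gamma, alpha) = 0.5
        mu, sd = cfg.gamma_dist
        zg = (gamma[:k] - mu) / sd
        eps = rng.normal(size=k)
        alpha[:k] = cfg.pleio_mean + cfg.pleio_sd * (0.5 * zg + np.sqrt(0.75) * eps)
    return alpha


def simulate_pair(
    config: SimulationConfig,
) -> tuple[SummaryTable, SummaryTable, TruthRecord, LDMatrix]:
    """Generate paired exposure/outcome summary tables, ground truth,
    and the LD matrix of all simulated variants.

    Variant roles, in id order: LD-block index instruments with their
    correlated tag variants, standalone instruments, outcome-trait-only
    instruments (null for the exposure), then null filler variants.
    Blocks are laid out contiguously; distinct loci sit 15 Mb apart on
    two chromosomes, so the 5,000-kb clumping window separates them.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_tags = sum(s - 1 for s, _ in cfg.ld_blocks)
    n = cfg.n_variants
    j = cfg.n_instruments

    # --- roles and layout -------------------------------------------------
    roles = []  # (role, block_id, r2) per variant
    for b, (size, r2) in enumerate(cfg.ld_blocks):
        roles.append(("instrument", b, r2))
        roles.extend([("tag", b, r2)] * (size - 1))
    roles.extend([("instrument", -1, 0.0)] * (j - len(cfg.ld_blocks)))
    roles.extend([("outcome_instrument", -1, 0.0)] * cfg.n_outcome_instruments)
    roles.extend([("null", -1, 0.0)] * (n - len(roles)))

    ids = [f"rs{100001 + i}" for i in range(n)]
    chroms = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    locus = 0
    i = 0
    while i < n:
        role, block, _ = roles[i]
        span = 1
        if role == "instrument" and block >= 0:
            span = cfg.ld_blocks[block][0]
        chrom = str(1 + locus % 2)
        base = 10_000_000 + (locus // 2) * 15_000_000
        for k in range(span):
            chroms[i + k] = chrom
            pos[i + k] = base + k * 50_000
        locus += 1
        i += span

    # --- allele frequencies and alleles -----------------------------------
    maf = rng.uniform(*cfg.maf_range, size=n)
    flip = rng.random(n) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    palin = rng.random(n) < cfg.palindromic_fraction
    alleles = np.empty((n, 2), dtype=object)
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    non_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    for i in range(n):
        alleles[i] = (
            _PALINDROMIC_PAIRS[pal_choice[i]] if palin[i]
            else _NONPALINDROMIC_PAIRS[non_choice[i]]
        )

    se_exp = _se_model(cfg.n_exp, eaf)
    eaf_out = np.clip(eaf + rng.normal(0.0, 0.01, size=n), 0.001, 0.999)
    se_out = _se_model(cfg.n_out, eaf_out)

    # --- true effects -----------------------------------------------------
    gamma = np.zeros(n)
    alpha = np.zeros(n)
    delta = np.zeros(n)
    is_instr = np.array([r[0] == "instrument" for r in roles])
    is_tag = np.array([r[0] == "tag" for r in roles])
    is_out_instr = np.array([r[0] == "outcome_instrument" for r in roles])

    gamma[is_instr] = _draw_gamma(rng, cfg, se_exp[is_instr])
    alpha[is_instr] = _draw_alpha(rng, cfg, gamma[is_instr])
    mu_d, sd_d = cfg.delta_dist
    delta[is_out_instr] = rng.normal(mu_d, sd_d, size=cfg.n_outcome_instruments)
    # tags inherit an attenuated signal from their block's index variant
    for idx in np.flatnonzero(is_tag):
        block = roles[idx][1]
        block_index = next(
            k for k in range(n) if roles[k] == ("instrument", block, roles[idx][2])
        )
        r = np.sqrt(roles[idx][2])
        gamma[idx] = r * gamma[block_index]
        alpha[idx] = r * alpha[block_index]

    # --- observed effects with LD-correlated noise ------------------------
    z_exp = rng.normal(size=n)
    z_out = rng.normal(size=n)
    for idx in np.flatnonzero(is_tag):
        block = roles[idx][1]
        block_index = next(
            k for k in range(n) if roles[k] == ("instrument", block, roles[idx][2])
        )
        r = np.sqrt(roles[idx][2])
        z_exp[idx] = r * z_exp[block_index] + np.sqrt(1 - r ** 2) * rng.normal()
        z_out[idx] = r * z_out[block_index] + np.sqrt(1 - r ** 2) * rng.normal()

    beta_exp = gamma + se_exp * z_exp
    mean_out = cfg.theta * gamma + alpha + delta
    beta_out = mean_out + se_out * z_out

    is_outlier = np.isin(ids, list(cfg.outlier_ids))
    beta_out = beta_out + np.where(is_outlier, 10.0 * se_out, 0.0)

    # --- assemble ----------------------------------------------------------
    def _table(label, beta, se, eaf_col, n_samp):
        frame = pd.DataFrame({
            "variant_id": ids,
            "chrom": chroms,
            "pos": pos,
            "effect_allele": alleles[:, 0],
            "other_allele": alleles[:, 1],
            "eaf": eaf_col,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": n_samp,
        })
        return SummaryTable(
            trait_label=label,
            ancestry_label="synthetic",
            frame=frame[CANONICAL_COLUMNS],
            metadata={"seed": cfg.seed, "synthetic": True},
        )

    exposure = _table("sim_exposure", beta_exp, se_exp, eaf, cfg.n_exp)
    outcome = _table("sim_outcome", beta_out, se_out, eaf_out, cfg.n_out)

    truth = TruthRecord(
        theta=cfg.theta,
        frame=pd.DataFrame({
            "variant_id": ids,
            "chrom": chroms,
            "pos": pos,
            "gamma": gamma,
            "alpha": alpha,
            "delta": delta,
            "is_instrument": is_instr,
            "is_tag": is_tag,
            "is_outcome_instrument": is_out_instr,
            "is_outlier": is_outlier,
        }),
    )

    r2 = np.eye(n)
    start = 0
    for size, block_r2 in cfg.ld_blocks:
        sl = slice(start, start + size)
        r2[sl, sl] = block_r2
        start += size
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(ids, r2)
    return exposure, outcome, truth, ld


def simulate_harmonized(config: SimulationConfig) -> tuple[HarmonizedSet, TruthRecord]:
    """Fast path: draw the instruments' harmonized effect pairs directly,
    skipping table plumbing, selection, and harmonization.

    Produces exactly ``n_instruments`` pairs with the same effect model
    as :func:`simulate_pair` (no LD tags, no palindromes, no missing
    variants).  Intended for estimator calibration studies.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_instruments
    ids = [f"iv{k + 1}" for k in range(j)]

    maf = rng.uniform(*cfg.maf_range, size=j)
    se_exp = _se_model(cfg.n_exp, maf)
    se_out = _se_model(cfg.n_out, maf)
    gamma = _draw_gamma(rng, cfg, se_exp)
    alpha = _draw_alpha(rng, cfg, gamma)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(cfg.theta * gamma + alpha, se_out)
    is_outlier = np.isin(ids, list(cfg.outlier_ids))
    beta_out = beta_out + np.where(is_outlier, 10.0 * se_out, 0.0)

    hset = HarmonizedSet.from_arrays(
        beta_exp, se_exp, beta_out, se_out,
        variant_ids=ids,
        exposure_label="sim_exposure", outcome_label="sim_outcome",
        eaf_exp=maf, eaf_out=maf,
    )
    truth = TruthRecord(
        theta=cfg.theta,
        frame=pd.DataFrame({
            "variant_id": ids,
            "gamma": gamma,
            "alpha": alpha,
            "delta": 0.0,
            "is_instrument": True,
            "is_tag": False,
            "is_outcome_instrument": False,
            "is_outlier": is_outlier,
        }),
    )
    return hset, truth


def simulate_seq_class_table(
    variant_ids,
    n_classes: int = 40,
    spike_spec: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fabricate a per-variant sequence-class score table.

    Background scores ~ N(0, 0.1); ``spike_spec`` maps variant_id ->
    (class_label, value) entries that are set exactly, so downstream
    max-|score| selection has a known answer.
    """
    if seed is None:
        raise ValueError("simulate_seq_class_table requires a seed")
    labels = list(SEQ_CLASS_LABELS[:n_classes])
    if n_classes > len(SEQ_CLASS_LABELS):
        labels += [f"X{i}" for i in range(n_classes - len(SEQ_CLASS_LABELS))]
    rng = np.random.default_rng(seed)
    ids = list(variant_ids)
    mat = rng.normal(0.0, 0.1, size=(len(ids), n_classes))
    if spike_spec:
        col = {lab: k for k, lab in enumerate(labels)}
        row = {vid: i for i, vid in enumerate(ids)}
        for vid, (lab, value) in spike_spec.items():
            if lab not in col:
                raise ValueError(f"unknown sequence class {lab!r}")
            if vid in row:
                mat[row[vid], col[lab]] = value
    out = pd.DataFrame(mat, columns=labels)
    out.insert(0, "variant_id", ids)
    return out
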