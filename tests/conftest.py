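import numpy as np
import pandas as pd
import pytest

from tsmr.instruments import HarmonizedSet
from tsmr.io import SummaryTable


def make_random_hset(n: int, seed: int, theta: float = 0.5) -> HarmonizedSet:
    """Random but well-conditioned harmonized pairs for oracle checks."""
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.05, 0.3, size=n) * rng.choice([-1, 1], size=n)
    se_exp = rng.uniform(0.005, 0.02, size=n)
    se_out = rng.uniform(0.02, 0.1, size=n)
    beta_exp = gamma + rng.normal(0, se_exp)
    beta_out = theta * gamma + rng.normal(0, se_out)
    return HarmonizedSet.from_arrays(beta_exp, se_exp, beta_out, se_out)


@pytest.fixture
def exact_line_hset() -> HarmonizedSet:
    """Outcome effects exactly on the line y = 0.1 + 0.2 x, equal SE."""
    return HarmonizedSet.from_arrays(
        beta_exp=[1.0, 2.0, 3.0],
        se_exp=[0.1, 0.1, 0.1],
        beta_out=[0.3, 0.5, 0.7],
        se_out=[0.1, 0.1, 0.1],
    )


def make_summary_table(rows, trait="trait") -> SummaryTable:
    """Build a SummaryTable from a list of dicts with canonical keys."""
    defaults = {
        "chrom": "1", "pos": 1000, "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.01, "pval": 1e-10, "n": 10_000,
    }
    recs = []
    for i, row in enumerate(rows):
        rec = {**defaults, "variant_id": f"rs{i + 1}", "pos": 1000 + i}
        rec.update(row)
        recs.append(rec)
    frame = pd.DataFrame(recs)
    return SummaryTable(trait_label=trait, frame=frame)
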