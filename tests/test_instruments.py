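import numpy as np
import pandas as pd
import pytest

from conftest import make_summary_table
from tsmr.instruments import (
    LDMatrix,
    clump,
    explained_variance,
    f_statistic,
    filter_genome_wide,
    harmonize,
    strength_filter,
)
from tsmr.io import InputError, SummaryTable
from tsmr.model import ivw


# ---------------------------------------------------------------- selection

def test_genome_wide_filter_is_strict():
    t = make_summary_table([{"pval": 1e-9}, {"pval": 5e-8}, {"pval": 1e-7}])
    kept = filter_genome_wide(t)
    assert len(kept) == 1
    assert kept.frame.loc[0, "variant_id"] == "rs1"


def test_threshold_one_keeps_everything():
    t = make_summary_table([{"pval": p} for p in (0.9, 0.5, 1e-4)])
    assert len(filter_genome_wide(t, p_threshold=1.0)) == 3


def test_filter_count_matches_construction():
    rng = np.random.default_rng(7)
    rows = [{"pval": float(p)} for p in rng.uniform(1e-7, 1, size=988)]
    rows += [{"pval": float(p)} for p in rng.uniform(1e-12, 1e-9, size=12)]
    t = make_summary_table(rows)
    assert len(filter_genome_wide(t)) == 12


# ---------------------------------------------------------------- clumping

def block_ld(ids, r2):
    n = len(ids)
    m = np.full((n, n), r2, dtype=float)
    np.fill_diagonal(m, 1.0)
    return LDMatrix(ids, m)


def test_single_block_keeps_smallest_p():
    t = make_summary_table([
        {"pval": 1e-10, "pos": 1000},
        {"pval": 1e-9, "pos": 2000},
        {"pval": 1e-8, "pos": 3000},
    ])
    ld = block_ld(["rs1", "rs2", "rs3"], 0.9)
    kept = clump(t, ld)
    assert kept.frame["variant_id"].tolist() == ["rs1"]


def test_different_chromosomes_both_kept():
    t = make_summary_table([
        {"pval": 1e-10, "chrom": "1"},
        {"pval": 1e-9, "chrom": "2"},
    ])
    ld = block_ld(["rs1", "rs2"], 0.99)
    assert len(clump(t, ld)) == 2


def brute_force_clump(frame, ld, window_kb=5000, r2_threshold=0.01):
    """Independent re-statement of the greedy rule for cross-checking."""
    remaining = frame.to_dict("records")
    kept = []
    while remaining:
        remaining.sort(key=lambda r: (r["pval"], str(r["chrom"]), r["pos"],
                                      r["variant_id"]))
        index = remaining.pop(0)
        kept.append(index["variant_id"])
        survivors = []
        for r in remaining:
            linked = False
            if r["chrom"] == index["chrom"] and \
                    abs(r["pos"] - index["pos"]) <= window_kb * 1000:
                r2 = ld.lookup(index["variant_id"], r["variant_id"])
                linked = r2 is not None and r2 > r2_threshold
            if not linked:
                survivors.append(r)
        remaining = survivors
    return kept


def mixed_example():
    # two blocks (rs1-3 at ~1 Mb, rs4-5 at ~2 Mb) + one unlinked (rs6)
    t = make_summary_table([
        {"pval": 1e-9, "pos": 1_000_000},
        {"pval": 1e-12, "pos": 1_050_000},
        {"pval": 1e-8, "pos": 1_100_000},
        {"pval": 1e-10, "pos": 9_000_000},
        {"pval": 1e-11, "pos": 9_050_000},
        {"pval": 1e-8, "pos": 60_000_000},
    ])
    ids = [f"rs{i}" for i in range(1, 7)]
    m = np.eye(6)
    for i, j_ in [(0, 1), (0, 2), (1, 2)]:
        m[i, j_] = m[j_, i] = 0.8
    m[3, 4] = m[4, 3] = 0.5
    return t, LDMatrix(ids, m)


def test_mixed_example_matches_brute_force():
    t, ld = mixed_example()
    kept = clump(t, ld).frame["variant_id"].tolist()
    assert kept == brute_force_clump(t.frame, ld)
    assert set(kept) == {"rs2", "rs5", "rs6"}


def test_clump_invariant_to_row_order():
    t, ld = mixed_example()
    baseline = clump(t, ld).frame["variant_id"].tolist()
    rng = np.random.default_rng(0)
    for _ in range(10):
        perm = rng.permutation(len(t.frame))
        shuffled = SummaryTable(
            trait_label=t.trait_label,
            frame=t.frame.iloc[perm].reset_index(drop=True),
        )
        assert clump(shuffled, ld).frame["variant_id"].tolist() == baseline


def test_ld_matrix_validation():
    with pytest.raises(InputError):
        LDMatrix(["a", "b"], np.array([[1.0, 0.5, 0.1]]))
    with pytest.raises(InputError):
        LDMatrix(["a", "b"], np.array([[1.0, 0.2], [0.5, 1.0]]))
    with pytest.raises(InputError):
        LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 0.7]]))


# ---------------------------------------------- explained variance and F

def test_explained_variance_printed_formula():
    rec = {"eaf": 0.5, "beta": 0.1, "se": 0.01, "n": 10_000}
    r2 = explained_variance(rec)
    assert r2 == pytest.approx(0.005 / 0.505, rel=1e-12)


def test_explained_variance_zero_beta_and_symmetry():
    assert explained_variance({"eaf": 0.3, "beta": 0.0, "se": 0.01, "n": 1000}) == 0
    a = explained_variance({"eaf": 0.2, "beta": 0.1, "se": 0.01, "n": 1000})
    b = explained_variance({"eaf": 0.8, "beta": 0.1, "se": 0.01, "n": 1000})
    assert a == pytest.approx(b, rel=1e-14)


def test_explained_variance_requires_eaf():
    with pytest.raises(ValueError, match="EAF"):
        explained_variance({"eaf": np.nan, "beta": 0.1, "se": 0.01, "n": 1000})


def test_f_statistic_values():
    r2 = 0.005 / 0.505
    f = f_statistic(r2, 10_000)
    assert f == pytest.approx(r2 * 9998 / (1 - r2), rel=1e-12)
    assert f == pytest.approx(99.99, abs=0.05)
    assert f_statistic(0.0, 100) == 0.0
    with pytest.raises(ValueError):
        f_statistic(1.0, 100)


def test_formulas_match_brute_force_on_random_records():
    rng = np.random.default_rng(11)
    for _ in range(200):
        eaf = rng.uniform(0.01, 0.99)
        beta = rng.normal(0, 0.3)
        se = rng.uniform(1e-4, 0.1)
        n = int(rng.integers(100, 1_000_000))
        num = 2 * eaf * (1 - eaf) * beta ** 2
        expected_r2 = num / (num + 2 * eaf * (1 - eaf) * n * se ** 2)
        r2 = explained_variance({"eaf": eaf, "beta": beta, "se": se, "n": n})
        assert r2 == pytest.approx(expected_r2, abs=1e-12)
        assert f_statistic(r2, n) == pytest.approx(
            expected_r2 * (n - 2) / (1 - expected_r2), abs=1e-12
        )


def test_cumulative_r2_mode_matches_reevaluation():
    from tsmr.instruments import cumulative_f
    t = make_summary_table([
        {"eaf": 0.2, "beta": 0.08, "se": 0.008, "n": 50_000},
        {"eaf": 0.4, "beta": 0.06, "se": 0.007, "n": 50_000},
        {"eaf": 0.1, "beta": 0.12, "se": 0.012, "n": 50_000},
    ])
    r2_sum, f = cumulative_f(t)
    expected = sum(
        explained_variance(t.frame.iloc[i]) for i in range(3)
    )
    assert r2_sum == pytest.approx(expected, rel=1e-14)
    assert f == pytest.approx(expected * (50_000 - 2) / (1 - expected), rel=1e-14)


def test_strength_filter_keeps_strong_only():
    t = make_summary_table([
        {"eaf": 0.3, "beta": 0.1, "se": 0.01, "n": 50_000},   # F >> 10
        {"eaf": 0.3, "beta": 0.001, "se": 0.01, "n": 1_000},  # F << 10
    ])
    strong = strength_filter(t)
    assert strong.frame["variant_id"].tolist() == ["rs1"]
    assert (strong.frame["f_stat"] > 10).all()


# ------------------------------------------------------------ harmonization

def test_allele_swap_flips_outcome():
    exp = make_summary_table([{"effect_allele": "A", "other_allele": "G",
                               "beta": 0.10, "eaf": 0.3}])
    out = make_summary_table([{"effect_allele": "G", "other_allele": "A",
                               "beta": -0.05, "eaf": 0.7}])
    h = harmonize(exp, out)
    assert len(h) == 1
    assert h.frame.loc[0, "beta_out"] == pytest.approx(0.05)
    assert h.frame.loc[0, "eaf_out"] == pytest.approx(0.3)
    assert h.audit["flipped"] == 1


def test_palindrome_kept_when_mafs_agree():
    exp = make_summary_table([{"effect_allele": "A", "other_allele": "T",
                               "beta": 0.1, "eaf": 0.10}])
    out = make_summary_table([{"effect_allele": "A", "other_allele": "T",
                               "beta": 0.05, "eaf": 0.12}])
    h = harmonize(exp, out)
    assert len(h) == 1
    assert h.frame.loc[0, "palindromic"]
    assert h.frame.loc[0, "beta_out"] == pytest.approx(0.05)


def test_palindrome_dropped_at_high_maf():
    exp = make_summary_table([{"effect_allele": "C", "other_allele": "G",
                               "beta": 0.1, "eaf": 0.45}])
    out = make_summary_table([{"effect_allele": "C", "other_allele": "G",
                               "beta": 0.05, "eaf": 0.44}])
    h = harmonize(exp, out)
    assert len(h) == 0
    assert h.audit["dropped_ambiguous"] == 1


def test_palindrome_dropped_when_sides_disagree():
    exp = make_summary_table([{"effect_allele": "A", "other_allele": "T",
                               "beta": 0.1, "eaf": 0.1}])
    out = make_summary_table([{"effect_allele": "A", "other_allele": "T",
                               "beta": 0.05, "eaf": 0.9}])
    assert len(harmonize(exp, out)) == 0


def test_strand_flip_detected_for_nonpalindromes():
    exp = make_summary_table([{"effect_allele": "A", "other_allele": "G",
                               "beta": 0.1, "eaf": 0.3}])
    # T/C is the complement strand's representation of A/G
    out_same = make_summary_table([{"effect_allele": "T", "other_allele": "C",
                                    "beta": 0.05, "eaf": 0.31}])
    h = harmonize(exp, out_same)
    assert h.frame.loc[0, "beta_out"] == pytest.approx(0.05)
    out_swapped = make_summary_table([{"effect_allele": "C", "other_allele": "T",
                                       "beta": 0.05, "eaf": 0.69}])
    h2 = harmonize(exp, out_swapped)
    assert h2.frame.loc[0, "beta_out"] == pytest.approx(-0.05)


def test_allele_mismatch_dropped():
    exp = make_summary_table([{"effect_allele": "A", "other_allele": "G"}])
    out = make_summary_table([{"effect_allele": "A", "other_allele": "C"}])
    h = harmonize(exp, out)
    assert len(h) == 0
    assert h.audit["dropped_mismatch"] == 1


def test_proxy_lookup_and_r2_gate():
    exp = make_summary_table([{"effect_allele": "A", "other_allele": "G",
                               "beta": 0.1}])
    out_rows = [{"effect_allele": "A", "other_allele": "G", "beta": 0.05}]
    out = make_summary_table(out_rows)
    out.frame.loc[0, "variant_id"] = "rs_proxy"
    proxies = pd.DataFrame([
        {"iv_id": "rs1", "proxy_id": "rs_proxy", "r2": 0.9,
         "ea_map": "", "oa_map": ""},
    ])
    h = harmonize(exp, out, proxy_table=proxies)
    assert len(h) == 1
    assert h.frame.loc[0, "proxy_of"] == "rs_proxy"
    assert h.audit["proxied"] == 1

    weak = proxies.assign(r2=0.5)
    h2 = harmonize(exp, out, proxy_table=weak)
    assert len(h2) == 0
    assert h2.audit["dropped_missing"] == 1


def test_harmonize_accounting_balances():
    rng = np.random.default_rng(3)
    rows_exp, rows_out = [], []
    for i in range(40):
        pal = i % 5 == 0
        ea, oa = ("A", "T") if pal else ("A", "G")
        eaf = float(rng.uniform(0.05, 0.5))
        rows_exp.append({"effect_allele": ea, "other_allele": oa, "eaf": eaf})
        if i % 7 == 0:
            continue  # missing from outcome
        rows_out.append({"effect_allele": ea, "other_allele": oa,
                         "eaf": eaf + 0.01})
    exp = make_summary_table(rows_exp)
    out = make_summary_table(rows_out)
    # realign outcome ids to the exposure ids that were not skipped
    keep_ids = [f"rs{i + 1}" for i in range(40) if i % 7 != 0]
    out.frame["variant_id"] = keep_ids
    h = harmonize(exp, out)
    a = h.audit
    assert a["retained"] + a["dropped_ambiguous"] + a["dropped_missing"] + \
        a["dropped_mismatch"] == a["n_input"] == 40


def test_harmonize_involution():
    """Re-harmonizing against an already-aligned outcome changes nothing."""
    exp = make_summary_table([
        {"effect_allele": "A", "other_allele": "G", "beta": 0.1, "eaf": 0.3},
        {"effect_allele": "C", "other_allele": "T", "beta": 0.2, "eaf": 0.2},
    ])
    out = make_summary_table([
        {"effect_allele": "G", "other_allele": "A", "beta": -0.05, "eaf": 0.7},
        {"effect_allele": "C", "other_allele": "T", "beta": 0.07, "eaf": 0.21},
    ])
    h1 = harmonize(exp, out)
    aligned = exp.frame.copy()
    aligned["beta"] = h1.frame["beta_out"].to_numpy()
    aligned["eaf"] = h1.frame["eaf_out"].to_numpy()
    aligned["se"] = h1.frame["se_out"].to_numpy()
    out2 = SummaryTable(trait_label="outcome", frame=aligned)
    h2 = harmonize(exp, out2)
    np.testing.assert_allclose(h1.frame["beta_out"], h2.frame["beta_out"])
    np.testing.assert_allclose(h1.frame["beta_exp"], h2.frame["beta_exp"])
    assert h2.audit["flipped"] == 0


def test_exposure_recode_leaves_estimates_identical():
    exp = make_summary_table([
        {"effect_allele": "A", "other_allele": "G", "beta": 0.1, "eaf": 0.3},
        {"effect_allele": "C", "other_allele": "T", "beta": 0.2, "eaf": 0.2},
        {"effect_allele": "G", "other_allele": "T", "beta": 0.15, "eaf": 0.4},
    ])
    out = make_summary_table([
        {"effect_allele": "A", "other_allele": "G", "beta": 0.05, "eaf": 0.3},
        {"effect_allele": "C", "other_allele": "T", "beta": 0.09, "eaf": 0.2},
        {"effect_allele": "G", "other_allele": "T", "beta": 0.08, "eaf": 0.4},
    ])
    base = ivw(harmonize(exp, out))

    recoded = exp.frame.copy()
    recoded.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
    recoded.loc[0, "beta"] = -recoded.loc[0, "beta"]
    recoded.loc[0, "eaf"] = 1 - recoded.loc[0, "eaf"]
    exp2 = SummaryTable(trait_label="exp", frame=recoded)
    flipped = ivw(harmonize(exp2, out))
    assert flipped.beta == pytest.approx(base.beta, rel=1e-12)
    assert flipped.se == pytest.approx(base.se, rel=1e-12)


def test_duplicate_variant_ids_rejected():
    exp = make_summary_table([{}, {}])
    exp.frame["variant_id"] = ["rs1", "rs1"]
    out = make_summary_table([{}])
    with pytest.raises(InputError, match="duplicate"):
        harmonize(exp, out)
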