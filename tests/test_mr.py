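"""Instrument selection, harmonization, MR estimators and sensitivity."""

import numpy as np
import pandas as pd
import pytest

import toxbiome as tb
from toxbiome.mr import HarmonizedSet, mr_estimate, sensitivity


def _stats(rows):
    df = pd.DataFrame(
        rows,
        columns=["snp", "chr", "pos", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pval"],
    )
    return df


def _hset(bx, by, sy, sx=None, snps=None):
    n = len(bx)
    t = pd.DataFrame(
        {
            "snp": snps or [f"rs{i}" for i in range(n)],
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": bx,
            "se_exp": sx if sx is not None else [0.01] * n,
            "beta_out": by,
            "se_out": sy,
            "eaf_exp": 0.3,
            "eaf_out": 0.3,
            "action": "kept",
        }
    )
    return HarmonizedSet(table=t, audit=pd.DataFrame())


# ---------------------------------------------------------------- selection

def test_clumping_keeps_smaller_p_of_correlated_pair():
    exp = _stats([
        ["rs1", 1, 100_000, "A", "G", 0.3, 0.2, 0.02, 1e-8],
        ["rs2", 1, 110_000, "A", "G", 0.3, 0.15, 0.02, 1e-6],
    ])
    ld = pd.DataFrame([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]],
                      index=["rs1", "rs2"], columns=["rs1", "rs2"])
    inst = tb.select_instruments(exp, ld)
    assert list(inst.snps["snp"]) == ["rs1"]
    prov = inst.provenance.set_index("snp")
    assert prov.loc["rs2", "status"] == "removed_by_ld"
    assert prov.loc["rs2", "removed_by"] == "rs1"


def test_independent_snps_all_retained():
    exp = _stats([
        [f"rs{i}", 1, i * 2_000_000, "A", "G", 0.3, 0.2, 0.02, 1e-8]
        for i in range(5)
    ])
    ld = pd.DataFrame(np.eye(5), index=exp.snp, columns=exp.snp)
    inst = tb.select_instruments(exp, ld)
    assert len(inst) == 5


def test_no_candidates_returns_empty_status():
    exp = _stats([["rs1", 1, 100, "A", "G", 0.3, 0.01, 0.02, 0.4]])
    inst = tb.select_instruments(exp, pd.DataFrame())
    assert inst.empty


def test_clumped_set_satisfies_pairwise_constraint():
    rng = np.random.default_rng(0)
    pair = tb.simulate_gwas_pair(tb.GwasSimParams(seed=1, ld_rho=0.6))
    inst = tb.select_instruments(pair.exposure, pair.ld)
    kept = list(inst.snps["snp"])
    pos = pair.exposure.set_index("snp")["pos"]
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            if abs(pos[a] - pos[b]) <= 1_000_000:
                assert float(pair.ld.loc[a, b]) ** 2 <= 0.01
    # greedy oracle, written independently: visit by p, drop conflicting
    cand = pair.exposure[pair.exposure.pval < 1e-5].sort_values(["pval", "snp"])
    oracle = []
    for _, row in cand.iterrows():
        ok = all(
            not (row["chr"] == pair.exposure.set_index("snp").loc[k, "chr"]
                 and abs(pos[k] - row["pos"]) <= 1_000_000
                 and float(pair.ld.loc[k, row["snp"]]) ** 2 > 0.01)
            for k in oracle
        )
        if ok:
            oracle.append(row["snp"])
    assert kept == oracle


# ---------------------------------------------------------------- harmonize

def test_allele_swap_flips_outcome_beta():
    exp = _stats([["rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-9]])
    out = _stats([["rs1", 1, 100, "G", "A", 0.7, -0.05, 0.01, 0.01]])
    h = tb.harmonize(exp, out)
    assert h.table["beta_out"].iloc[0] == pytest.approx(0.05)
    assert h.table["eaf_out"].iloc[0] == pytest.approx(0.3)
    assert h.table["action"].iloc[0] == "flipped"


def test_strand_complement_resolved():
    exp = _stats([["rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-9]])
    out = _stats([["rs1", 1, 100, "T", "C", 0.3, 0.07, 0.01, 0.01]])
    h = tb.harmonize(exp, out)
    assert h.table["beta_out"].iloc[0] == pytest.approx(0.07)
    assert len(h.table) == 1


def test_ambiguous_palindromic_snp_dropped():
    exp = _stats([["rs1", 1, 100, "A", "T", 0.50, 0.1, 0.01, 1e-9]])
    out = _stats([["rs1", 1, 100, "A", "T", 0.50, 0.05, 0.01, 0.01]])
    h = tb.harmonize(exp, out)
    assert h.table.empty
    assert h.audit["action"].iloc[0] == "dropped_palindromic"


def test_palindromic_snp_oriented_by_frequency():
    exp = _stats([["rs1", 1, 100, "A", "T", 0.10, 0.1, 0.01, 1e-9]])
    out = _stats([["rs1", 1, 100, "A", "T", 0.88, 0.05, 0.01, 0.01]])
    h = tb.harmonize(exp, out)  # frequencies disagree in orientation -> flip
    assert h.table["beta_out"].iloc[0] == pytest.approx(-0.05)


def test_proxy_substitution():
    exp = _stats([["rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-9]])
    out = _stats([["rs9", 1, 5_000, "A", "G", 0.3, 0.04, 0.01, 0.01]])
    ld = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]],
                      index=["rs1", "rs9"], columns=["rs1", "rs9"])
    h = tb.harmonize(exp, out, ld)
    assert h.table["action"].iloc[0] == "proxied"
    assert h.table["beta_out"].iloc[0] == pytest.approx(0.04)
    assert "rs9" in h.audit["reason"].iloc[0]


def test_missing_snp_without_proxy_dropped():
    exp = _stats([["rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-9]])
    out = _stats([["rs9", 1, 5_000, "A", "G", 0.3, 0.04, 0.01, 0.01]])
    h = tb.harmonize(exp, out, None)
    assert h.table.empty
    assert "no proxy" in h.audit["reason"].iloc[0]


def test_unmatchable_alleles_dropped_with_reason():
    exp = _stats([["rs1", 1, 100, "A", "C", 0.3, 0.1, 0.01, 1e-9]])
    out = _stats([["rs1", 1, 100, "A", "G", 0.3, 0.04, 0.01, 0.01]])
    h = tb.harmonize(exp, out)
    assert h.table.empty
    assert "unmatchable" in h.audit["reason"].iloc[0]


def test_harmonization_idempotent():
    pair = tb.simulate_gwas_pair(tb.GwasSimParams(seed=3))
    inst = tb.select_instruments(pair.exposure, pair.ld)
    h1 = tb.harmonize(inst.snps, pair.outcome, pair.ld)
    # re-express the harmonized set as exposure/outcome tables and re-run
    exp2 = h1.table.rename(columns={"beta_exp": "beta", "se_exp": "se",
                                    "eaf_exp": "eaf"})
    exp2 = exp2.assign(chr=1, pos=range(len(exp2)), pval=1e-9)[
        ["snp", "chr", "pos", "effect_allele", "other_allele", "eaf", "beta",
         "se", "pval"]]
    out2 = h1.table.rename(columns={"beta_out": "beta", "se_out": "se",
                                    "eaf_out": "eaf"})
    out2 = out2.assign(chr=1, pos=range(len(out2)), pval=0.5)[exp2.columns]
    h2 = tb.harmonize(exp2, out2)
    assert len(h2) == len(h1)
    assert np.allclose(h2.table["beta_out"], h1.table["beta_out"])
    assert (h2.table["action"] == "kept").all()


# ---------------------------------------------------------------- estimators

def test_single_snp_wald_ratio():
    h = _hset([0.2], [0.06], [0.01])
    r = mr_estimate(h, "ivw")
    assert r.estimate == pytest.approx(0.3)
    assert r.se == pytest.approx(0.05)


def test_noiseless_proportional_effects_recovered_by_all_methods():
    rng = np.random.default_rng(1)
    bx = rng.uniform(0.05, 0.3, 10)
    h = _hset(bx, 0.4 * bx, [1e-6] * 10)
    for method in ("ivw", "egger", "weighted_median"):
        r = mr_estimate(h, method, seed=0)
        assert r.estimate == pytest.approx(0.4, abs=1e-6)


def test_exact_affine_line_separates_egger_from_ivw():
    bx = np.linspace(0.05, 0.4, 8)
    by = 0.1 + 0.3 * bx
    h = _hset(bx, by, [1e-4] * 8)
    egger = mr_estimate(h, "egger")
    ivw = mr_estimate(h, "ivw")
    assert egger.estimate == pytest.approx(0.3, abs=1e-6)
    assert abs(ivw.estimate - 0.3) > 0.1  # biased by the unmodelled intercept
    s = sensitivity(h)
    assert s.egger_intercept == pytest.approx(0.1, abs=1e-6)


def test_weighted_median_within_wald_ratio_range():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = rng.integers(3, 12)
        bx = rng.uniform(0.05, 0.3, n)
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.01, 0.1, n)
        h = _hset(bx, by, sy)
        r = mr_estimate(h, "weighted_median", seed=0, n_boot=50)
        ratios = by / bx
        assert ratios.min() - 1e-12 <= r.estimate <= ratios.max() + 1e-12


def test_method_minimum_snp_counts_enforced():
    h = _hset([0.1, 0.2], [0.03, 0.06], [0.01, 0.01])
    with pytest.raises(ValueError, match="egger"):
        mr_estimate(h, "egger")
    with pytest.raises(ValueError, match="weighted_median"):
        mr_estimate(h, "weighted_median")


def test_simulation_recovery_and_pleiotropy_robustness():
    """theta=0.3 recovered by IVW; Egger beats IVW under directional pleiotropy."""
    pair = tb.simulate_gwas_pair(tb.GwasSimParams(seed=4))
    inst = tb.select_instruments(pair.exposure, pair.ld)
    h = tb.harmonize(inst.snps, pair.outcome, pair.ld)
    assert len(h) >= 50
    r = mr_estimate(h, "ivw")
    assert abs(r.estimate - 0.3) <= 0.05

    egger_wins = 0
    reps = 60
    for rep in range(reps):
        p = tb.simulate_gwas_pair(
            tb.GwasSimParams(seed=6000 + rep, n_snps=100, ld_block_size=2,
                             n_instruments=50, pleiotropy_mean=0.05,
                             pleiotropy_sd=0.01))
        i = tb.select_instruments(p.exposure, p.ld)
        hh = tb.harmonize(i.snps, p.outcome, p.ld)
        e = mr_estimate(hh, "egger").estimate
        v = mr_estimate(hh, "ivw").estimate
        egger_wins += abs(e - 0.3) < abs(v - 0.3)
    assert egger_wins / reps > 0.9


# ---------------------------------------------------------------- sensitivity

def test_identical_wald_ratios_give_zero_q():
    bx = np.array([0.1, 0.2])
    h = _hset(bx, 0.25 * bx, [0.01, 0.01])
    s = sensitivity(h)
    assert s.q == pytest.approx(0.0, abs=1e-12)
    assert s.q_p == pytest.approx(1.0)


def test_leave_one_out_matches_direct_recomputation():
    rng = np.random.default_rng(5)
    n = 8
    bx = rng.uniform(0.05, 0.3, n)
    by = rng.normal(0.3 * bx, 0.02)
    sy = rng.uniform(0.01, 0.05, n)
    h = _hset(bx, by, sy)
    s = sensitivity(h)
    assert len(s.leave_one_out) == n
    for i in range(n):
        sub = _hset(np.delete(bx, i), np.delete(by, i), np.delete(sy, i))
        direct = mr_estimate(sub, "ivw")
        row = s.leave_one_out.iloc[i]
        assert row["estimate"] == pytest.approx(direct.estimate, abs=1e-12)
        assert row["se"] == pytest.approx(direct.se, abs=1e-12)


def test_partial_sensitivity_with_two_snps():
    h = _hset([0.1, 0.2], [0.02, 0.07], [0.01, 0.01])
    s = sensitivity(h)
    assert s.q is not None
    assert s.egger_intercept is None  # needs >= 3 SNPs
    assert len(s.leave_one_out) == 2


def test_ivw_and_egger_agree_without_intercept_in_noiseless_limit():
    rng = np.random.default_rng(6)
    bx = rng.uniform(0.05, 0.4, 12)
    h = _hset(bx, 0.25 * bx, [1e-7] * 12)
    assert mr_estimate(h, "ivw").estimate == pytest.approx(
        mr_estimate(h, "egger").estimate, abs=1e-6)
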