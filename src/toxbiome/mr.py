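"""Two-sample Mendelian randomization from GWAS summary statistics.

Instruments are exposure SNPs below a p-value threshold, greedily LD-clumped
(r^2 > 0.01 within a 1000 kb window removes the weaker SNP).  Exposure and
outcome effects are harmonized to a shared effect allele (allele swaps
flipped, strand complements resolved, ambiguous palindromic SNPs dropped,
missing outcome SNPs replaced by LD proxies at r^2 >= 0.8).  Causal effects
are estimated by inverse-variance weighting (multiplicative random-effects),
MR-Egger and the weighted median, with Cochran's Q heterogeneity, the Egger
intercept test for directional pleiotropy, and leave-one-out IVW as
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUMMARY_COLUMNS",
    "InstrumentSet",
    "HarmonizedSet",
    "MrResult",
    "SensitivityResult",
    "validate_summary",
    "select_instruments",
    "harmonize",
    "mr_estimate",
    "sensitivity",
]

#: Required columns of a GWAS summary-statistics table.
SUMMARY_COLUMNS = ("snp", "chr", "pos", "effect_allele", "other_allele",
                   "eaf", "beta", "se", "pval")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def validate_summary(df: pd.DataFrame, name: str = "summary") -> pd.DataFrame:
    """Check a summary-statistics frame for the required columns and ranges."""
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    if (df["se"] <= 0).any():
        raise ValueError(f"{name}: standard errors must be positive")
    alleles = set(df["effect_allele"]) | set(df["other_allele"])
    if alleles - set("ACGT"):
        raise ValueError(f"{name}: alleles must be single bases A/C/G/T")
    eaf = df["eaf"].dropna()
    if ((eaf <= 0) | (eaf >= 1)).any():
        raise ValueError(f"{name}: eaf must lie in (0, 1)")
    return df


@dataclass
class InstrumentSet:
    """Clumped exposure instruments with per-SNP provenance."""

    snps: pd.DataFrame  # retained rows of the exposure table
    provenance: pd.DataFrame  # snp, status in {kept, removed_by_ld}, removed_by

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def empty(self) -> bool:
        return len(self.snps) == 0


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a shared effect allele."""

    table: pd.DataFrame  # snp, effect_allele, other_allele, beta_exp, se_exp,
    #                      beta_out, se_out, eaf_exp, eaf_out, action
    audit: pd.DataFrame  # one row per candidate SNP: action + reason

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MrResult:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snp: int

    @property
    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, lower, upper) on the exponentiated scale."""
        return tuple(np.exp([self.estimate, self.ci_low, self.ci_high]))


@dataclass
class SensitivityResult:
    q: float | None
    q_df: int | None
    q_p: float | None
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    leave_one_out: pd.DataFrame = field(default_factory=pd.DataFrame)


def _r2(ld: pd.DataFrame, a: str, b: str) -> float:
    if a in ld.index and b in ld.columns:
        return float(ld.loc[a, b]) ** 2
    return 0.0


def select_instruments(
    exposure: pd.DataFrame,
    ld: pd.DataFrame,
    p_threshold: float = 1e-5,
    clump_r2: float = 0.01,
    window_kb: float = 1000.0,
) -> InstrumentSet:
    """Greedy LD clumping of sub-threshold exposure SNPs.

    Candidates (p < ``p_threshold``) are visited in ascending p order; each
    kept SNP removes every remaining candidate on the same chromosome within
    ``window_kb`` whose r^2 with it strictly exceeds ``clump_r2``.
    """
    exposure = validate_summary(exposure, "exposure")
    cand = exposure[exposure["pval"] < p_threshold].sort_values(
        ["pval", "snp"], kind="stable"
    )
    if cand.empty:
        return InstrumentSet(
            snps=cand,
            provenance=pd.DataFrame(columns=["snp", "status", "removed_by"]),
        )
    snps = cand["snp"].to_numpy()
    chrom = cand["chr"].to_numpy()
    pos = cand["pos"].to_numpy(dtype=float)
    covered = ld.index.intersection(snps)
    r2 = pd.DataFrame(0.0, index=snps, columns=snps)
    if len(covered):
        sub = ld.loc[covered, ld.columns.intersection(snps)] ** 2
        r2.loc[sub.index, sub.columns] = sub
    r2v = r2.to_numpy()

    kept: list[str] = []
    kept_idx: list[int] = []
    prov = {}
    window = window_kb * 1000.0
    for i, snp in enumerate(snps):
        culprit = None
        for j in kept_idx:
            if (
                chrom[j] == chrom[i]
                and abs(pos[j] - pos[i]) <= window
                and r2v[j, i] > clump_r2
            ):
                culprit = snps[j]
                break
        if culprit is None:
            kept.append(snp)
            kept_idx.append(i)
            prov[snp] = ("kept", "")
        else:
            prov[snp] = ("removed_by_ld", culprit)
    provenance = pd.DataFrame(
        [{"snp": s, "status": st, "removed_by": by} for s, (st, by) in prov.items()]
    )
    return InstrumentSet(
        snps=cand[cand["snp"].isin(kept)].reset_index(drop=True),
        provenance=provenance,
    )


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    instruments: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    proxy_r2: float = 0.8,
    palindromic_maf: float = 0.42,
) -> HarmonizedSet:
    """Align outcome effects to the exposure effect alleles.

    Matching is by SNP id; swapped alleles flip the outcome beta and eaf;
    strand complements are resolved by complementing the outcome alleles
    first.  Palindromic (A/T, C/G) SNPs are kept only when both allele
    frequencies are away from 0.5 (minor-allele frequency <=
    ``palindromic_maf``) and agree in orientation; otherwise they are
    dropped.  Instruments missing from the outcome are replaced by the
    highest-r^2 proxy with r^2 >= ``proxy_r2`` when an LD matrix is given,
    else dropped.  Harmonization is idempotent: already aligned rows come
    back unchanged with action ``kept``.
    """
    instruments = validate_summary(instruments, "exposure instruments")
    outcome = validate_summary(outcome, "outcome")
    out_by_snp = outcome.set_index("snp")
    rows, audit = [], []

    for _, exp in instruments.iterrows():
        snp = exp["snp"]
        action, reason = None, ""
        if snp in out_by_snp.index:
            out = out_by_snp.loc[snp]
            used_snp = snp
        else:
            proxy, best = None, proxy_r2
            if ld is not None and snp in ld.index:
                for cand in out_by_snp.index.intersection(ld.columns):
                    r2 = _r2(ld, snp, cand)
                    if r2 >= best:
                        proxy, best = cand, r2
            if proxy is None:
                audit.append({"snp": snp, "action": "dropped",
                              "reason": "absent from outcome, no proxy"})
                continue
            out = out_by_snp.loc[proxy]
            used_snp = proxy
            action = "proxied"
            reason = f"proxy {proxy} (r2={best:.3f})"

        ea, oa = exp["effect_allele"], exp["other_allele"]
        o_ea, o_oa = out["effect_allele"], out["other_allele"]
        beta_out, eaf_out = float(out["beta"]), out["eaf"]

        if (o_ea, o_oa) == (ea, oa):
            pass
        elif (o_ea, o_oa) == (oa, ea):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if pd.notna(eaf_out) else eaf_out
            action = action or "flipped"
        elif (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (ea, oa):
            action = action or "kept"  # strand complement, same orientation
        elif (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (oa, ea):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if pd.notna(eaf_out) else eaf_out
            action = action or "flipped"
        else:
            audit.append({"snp": snp, "action": "dropped",
                          "reason": f"unmatchable alleles {ea}/{oa} vs {o_ea}/{o_oa}"})
            continue

        if _is_palindromic(ea, oa):
            eaf_e = exp["eaf"]
            if (
                pd.isna(eaf_e) or pd.isna(eaf_out)
                or min(eaf_e, 1 - eaf_e) > palindromic_maf
                or min(eaf_out, 1 - eaf_out) > palindromic_maf
            ):
                audit.append({"snp": snp, "action": "dropped_palindromic",
                              "reason": "ambiguous strand (eaf near 0.5 or missing)"})
                continue
            if (eaf_e - 0.5) * (eaf_out - 0.5) < 0:  # frequencies disagree: flip
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                action = action or "flipped"

        action = action or "kept"
        rows.append(
            {
                "snp": snp,
                "effect_allele": ea,
                "other_allele": oa,
                "beta_exp": float(exp["beta"]),
                "se_exp": float(exp["se"]),
                "beta_out": beta_out,
                "se_out": float(out["se"]),
                "eaf_exp": exp["eaf"],
                "eaf_out": eaf_out,
                "action": action,
            }
        )
        audit.append({"snp": snp, "action": action, "reason": reason})

    return HarmonizedSet(
        table=pd.DataFrame(rows, columns=["snp", "effect_allele", "other_allele",
                                          "beta_exp", "se_exp", "beta_out",
                                          "se_out", "eaf_exp", "eaf_out", "action"]),
        audit=pd.DataFrame(audit, columns=["snp", "action", "reason"]),
    )


def _ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray,
         random_effects: bool = True) -> tuple[float, float]:
    w = 1.0 / sy**2
    est = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    if random_effects and len(bx) > 1:
        phi2 = float(np.sum(w * (by - est * bx) ** 2) / (len(bx) - 1))
        se *= max(1.0, np.sqrt(phi2))
    return est, se


def _egger(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    sign = np.where(bx < 0, -1.0, 1.0)  # orient exposure effects positive
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    x = np.column_stack([np.ones_like(bx), bx])
    wx = x * w[:, None]
    xtx_inv = np.linalg.inv(x.T @ wx)
    coef = xtx_inv @ (wx.T @ by)
    resid = by - x @ coef
    df = len(bx) - 2
    phi2 = float(np.sum(w * resid**2) / df)
    ses = np.sqrt(np.diag(xtx_inv)) * max(1.0, np.sqrt(phi2))
    return coef, ses, df


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta)
    th, w = theta[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2
    return float(np.interp(0.5, cum, th))


def mr_estimate(
    h: HarmonizedSet,
    method: str = "ivw",
    random_effects: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrResult:
    """Causal-effect estimate from a harmonized instrument set.

    ``ivw``: weighted regression of outcome on exposure betas through the
    origin (weights 1/se_out^2), standard error scaled by
    max(1, residual SD) (multiplicative random effects); with a single SNP
    this reduces to the Wald ratio.  ``egger``: the same regression with a
    free intercept, exposure effects oriented positive.  ``weighted_median``:
    weighted median of per-SNP Wald ratios (weights beta_x^2/se_out^2),
    standard error from a seeded parametric bootstrap.
    """
    t = h.table
    minimum = {"ivw": 1, "egger": 3, "weighted_median": 3}
    if method not in minimum:
        raise ValueError(f"unknown method {method!r}")
    n = len(t)
    if n < minimum[method]:
        raise ValueError(f"{method} needs >= {minimum[method]} SNPs, got {n}")
    bx = t["beta_exp"].values.astype(float)
    by = t["beta_out"].values.astype(float)
    sx = t["se_exp"].values.astype(float)
    sy = t["se_out"].values.astype(float)

    if method == "ivw":
        if n == 1:
            est = float(by[0] / bx[0])
            se = float(sy[0] / abs(bx[0]))
        else:
            est, se = _ivw(bx, by, sy, random_effects=random_effects)
        p = 2 * stats.norm.sf(abs(est / se))
    elif method == "egger":
        coef, ses, df = _egger(bx, by, sy)
        est, se = float(coef[1]), float(ses[1])
        p = 2 * stats.t.sf(abs(est / se), df)
    else:  # weighted_median
        theta = by / bx
        weights = bx**2 / sy**2
        est = _weighted_median(theta, weights)
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bx_b = rng.normal(bx, sx)
            by_b = rng.normal(by, sy)
            boots[b] = _weighted_median(by_b / bx_b, bx_b**2 / sy**2)
        se = float(np.std(boots, ddof=1))
        p = 2 * stats.norm.sf(abs(est / se))
    return MrResult(
        method=method,
        estimate=est,
        se=se,
        ci_low=est - 1.96 * se,
        ci_high=est + 1.96 * se,
        p=float(p),
        n_snp=n,
    )


def sensitivity(h: HarmonizedSet, seed: int | None = None) -> SensitivityResult:
    """Heterogeneity, directional-pleiotropy and leave-one-out diagnostics.

    Cochran's Q sums w_i (theta_i - theta_IVW)^2 over per-SNP Wald ratios
    theta_i with first-order weights w_i = (beta_x/se_out)^2, referred to
    chi-square with n-1 df; the Egger intercept is t-tested on n-2 df; the
    leave-one-out table re-estimates IVW dropping each SNP in turn.
    Components whose SNP minimum is not met are returned as None.
    """
    t = h.table
    n = len(t)
    bx = t["beta_exp"].values.astype(float)
    by = t["beta_out"].values.astype(float)
    sy = t["se_out"].values.astype(float)

    q = q_df = q_p = None
    if n >= 2:
        theta = by / bx
        w = (bx / sy) ** 2
        ivw_est = float(np.sum(w * theta) / np.sum(w))
        q = float(np.sum(w * (theta - ivw_est) ** 2))
        q_df = n - 1
        q_p = float(stats.chi2.sf(q, q_df))

    intercept = intercept_se = intercept_p = None
    if n >= 3:
        coef, ses, df = _egger(bx, by, sy)
        intercept, intercept_se = float(coef[0]), float(ses[0])
        intercept_p = float(2 * stats.t.sf(abs(intercept / intercept_se), df))

    loo_rows = []
    if n >= 2:
        for i in range(n):
            mask = np.arange(n) != i
            if mask.sum() == 1:
                est = float(by[mask][0] / bx[mask][0])
                se = float(sy[mask][0] / abs(bx[mask][0]))
            else:
                est, se = _ivw(bx[mask], by[mask], sy[mask])
            loo_rows.append(
                {"excluded_snp": t["snp"].iloc[i], "estimate": est, "se": se,
                 "p": float(2 * stats.norm.sf(abs(est / se)))}
            )
    return SensitivityResult(
        q=q, q_df=q_df, q_p=q_p,
        egger_intercept=intercept,
        egger_intercept_se=intercept_se,
        egger_intercept_p=intercept_p,
        leave_one_out=pd.DataFrame(loo_rows,
                                   columns=["excluded_snp", "estimate", "se", "p"]),
    )
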