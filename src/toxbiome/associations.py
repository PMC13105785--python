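"""Differential-abundance screening and multivariable linear associations.

Feature tables (taxa, pathways, metabolites) are prevalence-filtered,
total-sum normalized and log2-transformed with a per-feature half-minimum
pseudocount, then each feature is regressed on a target variable (an AE
grade, sex, ...) plus fixed-effect covariates by ordinary least squares.
Per-target p-values are Benjamini-Hochberg adjusted across features, with
significance called at q < 0.25.  A LEfSe-style screen (Kruskal-Wallis
filter + linear-discriminant effect size on a log10 scale) is provided for
two-group enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TransformSpec",
    "filter_transform",
    "fit_associations",
    "bh_adjust",
    "lefse_like",
]


@dataclass(frozen=True)
class TransformSpec:
    """Normalization/transform settings for association inputs.

    Total-sum normalization followed by log2 with pseudocount equal to half
    the feature's minimum positive (normalized) value; features below the
    prevalence or abundance floor are dropped.
    """

    min_prevalence: float = 0.1
    min_abundance: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_prevalence <= 1.0:
            raise ValueError(f"min_prevalence must be in [0,1], got {self.min_prevalence}")
        if self.min_abundance < 0:
            raise ValueError("min_abundance must be >= 0")


def filter_transform(
    table: pd.DataFrame, spec: TransformSpec = TransformSpec()
) -> pd.DataFrame:
    """Filter + TSS-normalize + log2-transform a samples x features table.

    A feature is kept when the fraction of samples in which it exceeds
    ``min_abundance`` is at least ``min_prevalence``.  Kept features are
    divided by the per-sample total and transformed as
    ``log2(x + pc)`` with ``pc`` = half the feature's minimum positive value.
    """
    x = table.astype(float)
    if (x.values < 0).any():
        raise ValueError("abundances must be non-negative")
    prevalence = (x > spec.min_abundance).mean(axis=0)
    keep = prevalence >= spec.min_prevalence
    dropped = list(x.columns[~keep])
    if dropped:
        warnings.warn(f"{len(dropped)} features below prevalence/abundance floor dropped")
    x = x.loc[:, keep]
    rel = x.div(table.astype(float).sum(axis=1), axis=0)
    out = {}
    for col in rel.columns:
        v = rel[col].values
        positive = v[v > 0]
        pc = positive.min() / 2.0 if positive.size else 1.0
        out[col] = np.log2(v + pc)
    return pd.DataFrame(out, index=rel.index)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _encode(col: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Numeric column -> itself; categorical -> drop-first dummies."""
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float).values[:, None], [col.name]
    d = pd.get_dummies(col.astype(str), drop_first=True)
    return d.values.astype(float), [f"{col.name}[{c}]" for c in d.columns]


def fit_associations(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    targets: list[str],
    covariates: list[str],
    q_threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-feature OLS of transformed abundance on target + fixed covariates.

    For each target variable a single design (intercept + target +
    covariates, all fixed effects) is fit to every feature; the target
    coefficient's t-test p-values are BH-adjusted across features.  Rows
    with missing covariate or target values are dropped (logged).  Returns
    one row per (feature, target term) with ``coef, se, t, p, q, n,
    n_nonzero, significant`` sorted by q then p.
    """
    meta = metadata.copy()
    meta.index = meta.index.astype(str)
    mat = matrix.copy()
    mat.index = mat.index.astype(str)
    meta = meta.loc[mat.index]

    results = []
    for target in targets:
        cols = [target] + [c for c in covariates if c != target]
        complete = meta[cols].notna().all(axis=1)
        if (~complete).any():
            warnings.warn(f"{(~complete).sum()} samples with missing {cols} dropped")
        m, y_all = meta.loc[complete], mat.loc[complete].values
        n = len(m)
        t_cols, t_names = _encode(m[target])
        blocks, names = [np.ones((n, 1))], ["(Intercept)"]
        blocks.append(t_cols)
        names.extend(t_names)
        for c in covariates:
            if c == target:
                continue
            cc, cn = _encode(m[c])
            blocks.append(cc)
            names.extend(cn)
        x = np.hstack(blocks)
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            raise ValueError(f"collinear design for target {target!r}")
        df_res = n - x.shape[1]
        if df_res < 1:
            raise ValueError("more model terms than samples")

        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y_all  # p x n_features
        resid = y_all - x @ beta
        sigma2 = (resid**2).sum(axis=0) / df_res
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, 0.0)
        pvals = 2 * stats.t.sf(np.abs(tstat), df_res)

        # on the log2 scale zeros map to the feature minimum, so "strictly
        # above the minimum" recovers the nonzero count of zero-inflated input
        nz = (mat.loc[complete] > mat.loc[complete].min(axis=0)).sum(axis=0)
        for term in t_names:
            i = names.index(term)
            q = bh_adjust(pvals[i])
            for j, feat in enumerate(mat.columns):
                results.append(
                    {
                        "feature": feat,
                        "target": target,
                        "term": term,
                        "coef": beta[i, j],
                        "se": se[i, j],
                        "t": tstat[i, j],
                        "p": pvals[i, j],
                        "q": q[j],
                        "n": n,
                        "n_nonzero": int(nz.iloc[j]),
                        "significant": q[j] < q_threshold,
                    }
                )
    res = pd.DataFrame(results)
    return res.sort_values(["q", "p"], kind="stable").reset_index(drop=True)


def lefse_like(
    table: pd.DataFrame,
    classes,
    kw_alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """LEfSe-style enrichment screen for class-discriminating features.

    Abundances are rescaled per sample to sum to 1e6; each feature is tested
    across classes by Kruskal-Wallis, and survivors (p < ``kw_alpha``) are
    scored with a one-dimensional linear-discriminant effect size:
    ``log10(max(|difference of extreme class means|, 1))``, optionally
    averaged over ``n_boot`` seeded 2/3 subsamples.  Features with effect
    >= ``lda_threshold`` are reported with their enriched class.  The
    classic one-against-all subclass stage is omitted (no subclass design).
    """
    cls = pd.Series(classes, index=table.index).astype(str)
    counts = cls.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"classes with < 3 samples: {small}")
    scaled = table.astype(float)
    scaled = scaled.div(scaled.sum(axis=1), axis=0) * 1e6
    rng = np.random.default_rng(seed)
    groups = {g: scaled.loc[cls == g] for g in counts.index}

    rows = []
    for feat in scaled.columns:
        samples = [g[feat].values for g in groups.values()]
        if np.ptp(np.concatenate(samples)) == 0:
            continue
        try:
            _, p = stats.kruskal(*samples)
        except ValueError:  # all values identical
            continue
        if p >= kw_alpha:
            continue
        means = {g: v[feat].mean() for g, v in groups.items()}
        enriched = max(means, key=means.get)

        def _gap(sub: dict[str, np.ndarray]) -> float:
            m = [v.mean() for v in sub.values()]
            return max(m) - min(m)

        if n_boot <= 0:
            gap = _gap({g: v[feat].values for g, v in groups.items()})
        else:
            gaps = []
            for _ in range(n_boot):
                sub = {
                    g: rng.choice(v[feat].values, size=max(3, int(len(v) * 2 / 3)),
                                  replace=False)
                    for g, v in groups.items()
                }
                gaps.append(_gap(sub))
            gap = float(np.mean(gaps))
        effect = np.log10(max(abs(gap), 1.0))
        if effect >= lda_threshold:
            rows.append(
                {"feature": feat, "enriched_class": enriched, "kw_p": p, "lda": effect}
            )
    return pd.DataFrame(rows, columns=["feature", "enriched_class", "kw_p", "lda"])
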