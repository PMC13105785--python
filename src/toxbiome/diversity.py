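"""Alpha/beta diversity, ordination and rank-based longitudinal tests.

Counts are total-sum normalized before every diversity computation (no
rarefaction, so results are deterministic).  Shannon entropy uses the
natural log.  Beta diversity is Bray-Curtis on relative abundances,
ordinated by classical PCoA (Gower double-centering + eigendecomposition).
Group effects on community composition are quantified by PERMANOVA with
sequential (type-I) partitioning over an ordered term list, and diversity
trajectories over treatment time points are compared with the
Scheirer-Ray-Hare two-factor rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "scheirer_ray_hare",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with zero diagonal."""

    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(d) != 0).any() or (d < 0).any():
            raise ValueError("distances must be non-negative with zero diagonal")
        object.__setattr__(self, "data", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA coordinates with raw eigenvalues and proportion explained."""

    ids: tuple[str, ...]
    coordinates: np.ndarray  # n_samples x n_positive_eigenvalues
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending (may be < 0)
    proportion_explained: np.ndarray  # per positive axis, vs sum of positive


def _relative(table: pd.DataFrame) -> pd.DataFrame:
    x = table.astype(float)
    if (x.values < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = x.sum(axis=1)
    if (totals == 0).any():
        empty = list(x.index[totals == 0])
        warnings.warn(f"samples with zero total abundance: {empty}")
        totals = totals.replace(0, np.nan)
    return x.div(totals, axis=0)


def alpha_diversity(table: pd.DataFrame, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity on a samples x features count table.

    ``shannon`` is -sum p_i ln p_i over nonzero relative abundances
    (natural log); ``inv_simpson`` is 1 / sum p_i^2.  Empty samples yield
    NaN with a warning.
    """
    rel = _relative(table).values
    if metric == "shannon":
        with np.errstate(invalid="ignore"):
            terms = np.where(rel > 0, rel * np.log(np.where(rel > 0, rel, 1.0)), 0.0)
        vals = -np.nansum(terms, axis=1)
        vals[np.isnan(rel).all(axis=1)] = np.nan
    elif metric == "inv_simpson":
        with np.errstate(divide="ignore"):
            vals = 1.0 / np.nansum(rel**2, axis=1)
        vals[np.isnan(rel).all(axis=1)] = np.nan
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'shannon' or 'inv_simpson'")
    return pd.Series(vals, index=table.index, name=metric)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on total-sum-normalized abundances."""
    rel = _relative(table)
    if rel.isna().any(axis=1).sum() > 1:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(rel.values, metric="braycurtis"))
    return DistanceMatrix(ids=tuple(map(str, table.index)), data=d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) principal coordinates analysis.

    Gower double-centering of -d^2/2 followed by eigendecomposition.
    Negative eigenvalues are reported raw (no correction); coordinates are
    returned only for positive eigenvalues and the proportion explained is
    relative to the sum of the positive eigenvalues.
    """
    g = _gower_center(dm.data)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(eigval.max(), 1.0)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    prop = eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        ids=dm.ids,
        coordinates=coords,
        eigenvalues=eigval,
        proportion_explained=prop,
    )


def _design_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-encode one model term (drop-first for categoricals)."""
    col = meta[term]
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
        x = col.astype(float).values[:, None]
        return x
    levels = pd.unique(col)
    if len(levels) < 2:
        raise ValueError(f"term {term!r} has a single level")
    return pd.get_dummies(col.astype(str), drop_first=True).values.astype(float)


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multi-term PERMANOVA with sequential (type-I) sums of squares.

    The total sum of squares is sum_{i<j} d_ij^2 / n; each term's SS is the
    increment in explained SS (trace of the hat-matrix projection of the
    Gower-centered distance matrix) when the term is added after the
    preceding ones, so term order matters.  p-values come from whole-row
    permutations of the samples: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    Returns a frame indexed by term (plus ``Residual`` and ``Total``) with
    columns ``ss, df, pseudo_F, R2, p, n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    meta = metadata.copy()
    meta.index = meta.index.astype(str)
    missing = set(dm.ids) - set(meta.index)
    if missing:
        raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
    meta = meta.loc[list(dm.ids)]

    n = len(dm)
    g = _gower_center(dm.data)
    ss_total = np.trace(g)

    # hat matrices for nested models intercept + terms[:k]
    blocks = [np.ones((n, 1))]
    dfs: list[int] = []
    hats: list[np.ndarray] = []
    for t in terms:
        cols = _design_columns(meta, t)
        blocks.append(cols)
        x = np.hstack(blocks)
        q, r = np.linalg.qr(x)
        rank = int((np.abs(np.diag(r)) > 1e-10).sum())
        q = q[:, :rank]
        hats.append(q @ q.T)
        dfs.append(rank - (1 + sum(dfs)))
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("model saturates the samples; no residual df")

    def partition(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        explained = np.array([np.sum(h * gmat) for h in hats])
        ss_terms = np.diff(explained, prepend=0.0)
        ss_res = np.trace(gmat) - explained[-1]
        return ss_terms, ss_res

    ss_terms, ss_res = partition(g)
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    # tie tolerance: label-equivalent permutations reproduce F_obs up to
    # floating-point noise and must count as "as extreme"
    f_floor = f_obs - 1e-9 * np.maximum(1.0, np.abs(f_obs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_rp = partition(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_rp / df_res)
        exceed += f_p >= f_floor
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = {
        t: {
            "ss": ss_terms[i],
            "df": dfs[i],
            "pseudo_F": f_obs[i],
            "R2": ss_terms[i] / ss_total,
            "p": pvals[i],
            "n_perm": n_perm,
        }
        for i, t in enumerate(terms)
    }
    rows["Residual"] = {
        "ss": ss_res, "df": df_res, "pseudo_F": np.nan,
        "R2": ss_res / ss_total, "p": np.nan, "n_perm": n_perm,
    }
    rows["Total"] = {
        "ss": ss_total, "df": n - 1, "pseudo_F": np.nan,
        "R2": 1.0, "p": np.nan, "n_perm": n_perm,
    }
    return pd.DataFrame(rows).T


def scheirer_ray_hare(
    values,
    factor_a,
    factor_b,
) -> pd.DataFrame:
    """Scheirer-Ray-Hare two-factor rank test (Kruskal-Wallis extension).

    All N observations are mid-ranked jointly; two-way ANOVA sums of squares
    on the ranks (sequential: A, then B, then A:B) are divided by the total
    rank mean square SS_total/(N-1) to give H statistics, referred to
    chi-square with (levels-1) or product df.  Because the empirical
    SS_total of mid-ranks already shrinks under ties, this H equals the
    classical tie-corrected H' = H/D with D = 1 - sum(t^3 - t)/(N^3 - N);
    D is reported alongside.  With one constant factor, the other factor's H
    reduces exactly to the tie-corrected Kruskal-Wallis statistic.
    """
    y = np.asarray(values, dtype=float)
    a = pd.Series(factor_a).astype(str).values
    b = pd.Series(factor_b).astype(str).values
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    n = len(y)
    ranks = stats.rankdata(y)

    _, counts = np.unique(y, return_counts=True)
    d_corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)

    ss_total = float(np.sum((ranks - ranks.mean()) ** 2))
    if ss_total == 0:
        warnings.warn("all values identical; H defined as 0")
        out = []
        for eff, df in (("A", 0), ("B", 0), ("A:B", 0)):
            out.append({"effect": eff, "H": 0.0, "df": df, "p": 1.0, "D": 0.0})
        return pd.DataFrame(out).set_index("effect")

    meta = pd.DataFrame({"a": a, "b": b})
    levels_a, levels_b = meta["a"].nunique(), meta["b"].nunique()
    if levels_a < 2 and levels_b < 2:
        raise ValueError("at least one factor needs >= 2 levels")
    if levels_a < 2 or levels_b < 2:
        # single-level factor collapses the design to one-way Kruskal-Wallis
        warnings.warn("a factor has a single level; reducing to Kruskal-Wallis")

    def fitted_ss(cols: list[np.ndarray]) -> float:
        x = np.hstack([np.ones((n, 1))] + cols)
        fitted = x @ np.linalg.lstsq(x, ranks, rcond=None)[0]
        return float(np.sum((fitted - ranks.mean()) ** 2))

    da = pd.get_dummies(meta["a"], drop_first=True).values.astype(float)
    db = pd.get_dummies(meta["b"], drop_first=True).values.astype(float)
    dab = np.einsum("ij,ik->ijk", da, db).reshape(n, -1)

    ss_a = fitted_ss([da])
    ss_ab_model = fitted_ss([da, db])
    ss_full = fitted_ss([da, db, dab])
    ss_b = ss_ab_model - ss_a
    ss_int = ss_full - ss_ab_model

    ms_total = ss_total / (n - 1)
    out = []
    for eff, ss, df in (
        ("A", ss_a, levels_a - 1),
        ("B", ss_b, levels_b - 1),
        ("A:B", ss_int, (levels_a - 1) * (levels_b - 1)),
    ):
        h = max(ss, 0.0) / ms_total
        p = float(stats.chi2.sf(h, df)) if df > 0 else 1.0
        out.append({"effect": eff, "H": h, "df": df, "p": p, "D": d_corr})
    return pd.DataFrame(out).set_index("effect")
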