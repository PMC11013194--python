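"""Alpha/beta diversity and covariate-adjusted PERMANOVA.

Alpha diversity uses the Shannon (natural log) and Simpson (1 - sum p^2)
indices with pairwise Wilcoxon rank-sum tests between DII tertiles.
Beta diversity supports Bray-Curtis on normalized abundances and the
unweighted, normalized UniFrac distance on presence/absence against a
rooted phylogeny.  Group effects on distances are tested with a
sequential (covariates-first, exposure-last) PERMANOVA using
Freedman-Lane permutation of reduced-model residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import skbio
from skbio.diversity import beta_diversity as _skbio_beta

__all__ = [
    "alpha_diversity",
    "alpha_test",
    "beta_diversity",
    "permanova",
    "PermanovaResult",
    "load_tree",
]


def load_tree(path) -> skbio.TreeNode:
    """Read a rooted Newick phylogeny, validating branch lengths."""
    tree = skbio.TreeNode.read(str(path))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def _as_matrix(table) -> pd.DataFrame:
    """Accept CountTable/NormalizedTable/DataFrame -> sample x feature frame."""
    if hasattr(table, "counts"):
        return table.counts
    if hasattr(table, "values") and isinstance(getattr(table, "values"), pd.DataFrame):
        return table.values
    if isinstance(table, pd.DataFrame):
        return table
    raise TypeError(f"unsupported table type {type(table)!r}")


def alpha_diversity(table, index: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity.

    Shannon H = -sum p ln p (natural log); Simpson = 1 - sum p^2, with p
    the within-sample relative abundances.
    """
    mat = _as_matrix(table)
    totals = mat.sum(axis=1)
    if (totals <= 0).any():
        empty = totals.index[totals <= 0].tolist()
        raise ValueError(f"empty samples {empty}")
    p = mat.div(totals, axis=0).to_numpy()
    if index == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        vals = -terms.sum(axis=1)
    elif index == "simpson":
        vals = 1.0 - (p**2).sum(axis=1)
    else:
        raise ValueError(f"unknown index {index!r}")
    return pd.Series(vals, index=mat.index, name=index)


def alpha_test(
    values: pd.Series, groups: pd.Series, exact_max_n: int = 25
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of alpha diversity between groups.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and no ties, otherwise the normal
    approximation with tie correction.
    """
    groups = groups.reindex(values.index)
    levels = sorted(groups.dropna().unique())
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            x = values[groups == a].to_numpy()
            y = values[groups == b].to_numpy()
            if len(x) < 2 or len(y) < 2:
                raise ValueError(f"group with <2 samples in pair ({a}, {b})")
            ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            method = (
                "exact"
                if (len(x) <= exact_max_n and len(y) <= exact_max_n and not ties)
                else "asymptotic"
            )
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append({"group_a": a, "group_b": b, "U": stat, "p": p, "method": method})
    return pd.DataFrame(rows)


def beta_diversity(
    table, metric: str, tree: skbio.TreeNode | None = None
) -> skbio.DistanceMatrix:
    """Pairwise sample distances.

    ``metric`` is ``"bray_curtis"`` (on the supplied, typically
    CSS-normalized, abundances) or ``"unifrac"`` (unweighted, normalized
    UniFrac on presence/absence; requires a rooted tree covering every
    feature).
    """
    mat = _as_matrix(table)
    ids = [str(s) for s in mat.index]
    if metric == "bray_curtis":
        return _skbio_beta("braycurtis", mat.to_numpy(dtype=float), ids=ids)
    if metric in ("unifrac", "unifrac_unweighted_normalized"):
        if tree is None:
            raise ValueError("UniFrac requires a phylogenetic tree")
        leaves = {t.name for t in tree.tips()}
        missing = [f for f in mat.columns if f not in leaves]
        if missing:
            raise ValueError(f"features missing from tree: {missing}")
        # unweighted UniFrac: presence/absence only; skbio normalizes by
        # the branch length spanned by either sample's presence set
        return _skbio_beta(
            "unweighted_unifrac",
            (mat.to_numpy() > 0).astype(int),
            ids=ids,
            taxa=[str(c) for c in mat.columns],
            tree=tree,
        )
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class PermanovaResult:
    """Exposure term of a sequential, covariate-adjusted PERMANOVA."""

    pseudo_f: float
    p_value: float
    r_squared: float
    df_exposure: int
    df_residual: int
    n_permutations: int


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova(
    dist: skbio.DistanceMatrix,
    exposure,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    by_tertile: bool = False,
) -> PermanovaResult:
    """Covariate-adjusted PERMANOVA for a continuous (or tertile) exposure.

    Partitions the Gower-centered squared-distance matrix sequentially —
    covariates first, exposure last — and tests the exposure pseudo-F by
    Freedman-Lane permutation of the residuals of the covariate-only
    (reduced) model: ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.

    With ``by_tertile=True`` the exposure is coded as tertile indicator
    contrasts instead of a single continuous column.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    ids = list(dist.ids)
    n = len(ids)
    exposure = pd.Series(exposure).reindex(ids).astype(float)
    if exposure.isna().any():
        raise ValueError("exposure missing for some samples")

    if by_tertile:
        codes = exposure.astype(int)
        levels = sorted(codes.unique())
        x = np.column_stack([(codes == lv).to_numpy(float) for lv in levels[1:]])
    else:
        x = exposure.to_numpy()[:, None]

    z_cols = ["intercept"]
    z = np.ones((n, 1))
    if covariates is not None:
        cov = covariates.reindex(ids)
        if cov.isna().any().any():
            bad = cov.columns[cov.isna().any()].tolist()
            raise ValueError(f"missing covariate values in {bad}")
        cov_num = pd.get_dummies(cov, drop_first=True).astype(float)
        z = np.column_stack([z, cov_num.to_numpy()])
        z_cols += list(cov_num.columns)

    w = np.column_stack([z, x])
    rank = np.linalg.matrix_rank(w)
    if rank < w.shape[1]:
        # identify which columns are linearly dependent on the rest
        collinear = []
        for j in range(w.shape[1]):
            others = np.delete(w, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(w):
                collinear.append(z_cols[j] if j < len(z_cols) else "exposure")
        raise ValueError(f"singular design; collinear columns: {collinear}")

    d2 = np.asarray(dist.data, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j

    h_z = _hat(z)
    h_w = _hat(w)
    i_n = np.eye(n)

    df_x = x.shape[1]
    df_res = n - w.shape[1]
    ss_total = np.trace(g)
    ss_x = np.trace(h_w @ g) - np.trace(h_z @ g)
    ss_res = np.trace((i_n - h_w) @ g)
    f_obs = (ss_x / df_x) / (ss_res / df_res)
    r2 = ss_x / ss_total

    # Freedman-Lane: permute the reduced-model residual structure
    e = (i_n - h_z) @ g @ (i_n - h_z)
    rng = np.random.default_rng(seed)
    count = 0
    hx = h_w - h_z  # exposure increment projector
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ep = e[np.ix_(perm, perm)]
        ss_x_p = np.trace(hx @ ep)
        ss_res_p = np.trace((i_n - h_w) @ ep)
        f_p = (ss_x_p / df_x) / (ss_res_p / df_res)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        r_squared=float(r2),
        df_exposure=df_x,
        df_residual=df_res,
        n_permutations=n_perm,
    )
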