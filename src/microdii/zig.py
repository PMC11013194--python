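"""Zero-inflated Gaussian (ZIG) differential-abundance modeling.

Each feature's log2(CSS + 1) abundance y_ij is modeled as a mixture: a
point mass at zero with probability pi_j — logistic in the sample's log
library size, capturing undersampling — and otherwise a Gaussian
N(x_j' beta, sigma^2) regression on the design (intercept, continuous
DII exposure, covariates).  Parameters are estimated by EM:

  E-step   zero observations receive a responsibility of arising from
           the point mass, r = pi / (pi + (1 - pi) * phi(0 | x'beta, sigma));
           non-zero observations belong to the Gaussian with certainty.
  M-step   weighted least squares for beta (weights 1 - r), a logistic
           regression of r on log library size for pi (Newton steps),
           and a weighted residual variance for sigma^2.

Iteration stops when the observed-data log-likelihood changes by less
than ``tol`` or after ``max_iter`` iterations (non-converged features
are reported but flagged).  The exposure effect is summarized by
t = beta / se(beta) with weighted residual degrees of freedom.  The EM
is vectorized across features; every feature shares the design matrix
but has its own beta, sigma, and zero-model coefficients.

No empirical-Bayes variance moderation is applied: per-feature residual
variances are used as-is, which keeps the estimator simple and the
recovery behavior directly testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DesignMatrix", "ZigFit", "build_design", "fit_zig", "bh_adjust", "rank_report"]

_EPS = 1e-10


def build_design(
    metadata: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the model design: intercept, exposure, dummy-coded covariates.

    The exposure column is placed first after the intercept; categorical
    covariates are expanded to treatment contrasts.  Raises on rank
    deficiency, naming the collinear columns.
    """
    cols = {"intercept": np.ones(len(metadata))}
    cols[exposure] = metadata[exposure].astype(float).to_numpy()
    if covariates:
        cov = pd.get_dummies(metadata[covariates], drop_first=True).astype(float)
        for c in cov.columns:
            cols[c] = cov[c].to_numpy()
    design = pd.DataFrame(cols, index=metadata.index)
    if design.isna().any().any():
        bad = design.columns[design.isna().any()].tolist()
        raise ValueError(f"missing values in design columns {bad}")
    mat = design.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        collinear = [
            c
            for j, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(mat, j, axis=1))
            == np.linalg.matrix_rank(mat)
        ]
        raise ValueError(f"design not full rank; collinear columns: {collinear}")
    return design


@dataclass
class ZigFit:
    """Fitted ZIG models for a feature set against one design."""

    results: pd.DataFrame  # feature_id, beta, se, t, p_raw, p_adj, converged, n_iterations
    coefficients: pd.DataFrame  # feature x design column
    loglik_trace: np.ndarray  # iterations x features (NaN-padded)
    design_columns: list[str]
    skipped: list[str]


def _logistic_newton(
    s: np.ndarray, r: np.ndarray, params: np.ndarray, n_steps: int = 3
) -> np.ndarray:
    """Newton updates for per-feature logistic models pi = sigmoid(S a).

    ``s`` is the shared (n x 2) zero-model design (intercept, log
    library size), ``r`` (n x f) the fractional point-mass targets, and
    ``params`` (2 x f) the current coefficients.  A small ridge keeps
    the Hessian invertible when responsibilities saturate.
    """
    for _ in range(n_steps):
        eta = s @ params
        pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        grad = s.T @ (r - pi)  # 2 x f
        wt = pi * (1.0 - pi)  # n x f
        h00 = (s[:, 0] ** 2)[:, None] * wt
        h01 = (s[:, 0] * s[:, 1])[:, None] * wt
        h11 = (s[:, 1] ** 2)[:, None] * wt
        a = h00.sum(axis=0) + 1e-8
        b = h01.sum(axis=0)
        d = h11.sum(axis=0) + 1e-8
        det = a * d - b * b
        step0 = (d * grad[0] - b * grad[1]) / det
        step1 = (-b * grad[0] + a * grad[1]) / det
        params = params + np.vstack([step0, step1])
        params = np.clip(params, -50, 50)
    return params


def fit_zig(
    y: pd.DataFrame,
    design: pd.DataFrame,
    library_size: pd.Series,
    exposure: str | None = None,
    tol: float = 1e-4,
    max_iter: int = 30,
) -> ZigFit:
    """Fit the zero-inflated Gaussian to every feature.

    Parameters
    ----------
    y:
        Sample x feature matrix of log2(CSS + 1) abundances (zeros are
        the candidate structural zeros).
    design:
        Output of :func:`build_design`; full column rank, samples
        aligned with ``y``.
    library_size:
        Per-sample sequencing depth driving the zero model.
    exposure:
        Design column reported in ``results`` (defaults to the first
        non-intercept column).
    """
    design = design.reindex(y.index)
    library_size = library_size.reindex(y.index).astype(float)
    if (library_size <= 0).any():
        raise ValueError("library sizes must be positive")
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if exposure is None:
        exposure = next(c for c in design.columns if c != "intercept")
    j_exp = list(design.columns).index(exposure)

    ymat = y.to_numpy(dtype=float)
    variances = ymat.var(axis=0)
    all_features = list(y.columns)
    # tolerance absorbs float residue on constant columns
    skipped = [f for f, v in zip(all_features, variances) if v <= 1e-12]
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} zero-variance features", stacklevel=2
        )
    keep = [f for f in all_features if f not in set(skipped)]
    ymat = y[keep].to_numpy(dtype=float)
    f = ymat.shape[1]
    if f == 0:
        raise ValueError("no features with positive variance")

    zero = ymat == 0.0
    s = np.column_stack([np.ones(n), np.log(library_size.to_numpy())])

    # init: OLS on all observations, empirical zero rates for pi
    beta, *_ = np.linalg.lstsq(x, ymat, rcond=None)
    resid = ymat - x @ beta
    sigma2 = np.maximum(resid.var(axis=0), 1e-6)
    zero_rate = np.clip(zero.mean(axis=0), 1e-3, 1 - 1e-3)
    a = np.vstack([np.log(zero_rate / (1 - zero_rate)), np.zeros(f)])

    has_zeros = zero.any(axis=0)
    loglik_trace = np.full((max_iter, f), np.nan)
    prev_ll = np.full(f, -np.inf)
    converged = np.zeros(f, dtype=bool)
    n_iter = np.full(f, max_iter, dtype=int)
    w = np.ones_like(ymat)

    for it in range(max_iter):
        mu = x @ beta
        sd = np.sqrt(sigma2)
        eta = s @ a
        pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        pi = np.where(has_zeros, pi, 0.0)
        pi = np.clip(pi, _EPS, 1 - _EPS)

        # E-step
        phi0 = stats.norm.pdf(0.0, loc=mu, scale=sd)
        r = np.where(zero, pi / (pi + (1.0 - pi) * phi0 + _EPS), 0.0)
        w = 1.0 - r

        # observed-data log-likelihood (before the M-step update)
        dens = stats.norm.pdf(ymat, loc=mu, scale=sd)
        ll_terms = np.where(
            zero,
            np.log(pi + (1.0 - pi) * phi0 + _EPS),
            np.log((1.0 - pi) * dens + _EPS),
        )
        ll = ll_terms.sum(axis=0)
        loglik_trace[it] = ll
        newly = (~converged) & (np.abs(ll - prev_ll) < tol)
        n_iter[newly & (n_iter == max_iter)] = it + 1
        converged |= newly
        prev_ll = ll
        if converged.all():
            break

        # M-step: weighted least squares per feature (batched)
        xtwx = np.einsum("np,nf,nq->fpq", x, w, x)
        xtwy = np.einsum("np,nf->fp", x, w * ymat)
        beta = np.linalg.solve(xtwx + 1e-10 * np.eye(p), xtwy[..., None])[..., 0].T  # p x f
        mu = x @ beta
        rss = (w * (ymat - mu) ** 2).sum(axis=0)
        wsum = w.sum(axis=0)
        sigma2 = np.maximum(rss / np.maximum(wsum, 1.0), 1e-8)

        # logistic zero model (only meaningful where zeros exist)
        if has_zeros.any():
            a[:, has_zeros] = _logistic_newton(
                s, r[:, has_zeros], a[:, has_zeros]
            )

    # final statistics at converged parameters
    mu = x @ beta
    rss = (w * (ymat - mu) ** 2).sum(axis=0)
    wsum = w.sum(axis=0)
    df = np.maximum(wsum - p, 1.0)
    s2_df = rss / df
    xtwx = np.einsum("np,nf,nq->fpq", x, w, x)
    xtwx_inv = np.linalg.inv(xtwx + 1e-10 * np.eye(p))
    se = np.sqrt(np.maximum(xtwx_inv[:, j_exp, j_exp] * s2_df, _EPS**2))
    t = beta[j_exp] / se
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    p_adj = bh_adjust(p_raw)

    results = pd.DataFrame(
        {
            "feature_id": keep,
            "beta": beta[j_exp],
            "se": se,
            "t": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "converged": converged,
            "n_iterations": n_iter,
        }
    ).set_index("feature_id")
    coefficients = pd.DataFrame(beta.T, index=keep, columns=list(design.columns))
    return ZigFit(
        results=results,
        coefficients=coefficients,
        loglik_trace=loglik_trace,
        design_columns=list(design.columns),
        skipped=skipped,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Classic step-up: sort ascending, p_(i) * n / i, enforce a running
    minimum from the largest p downward, cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def lowest_identifiable_rank(taxonomy_row: pd.Series) -> str:
    """Deepest non-empty taxonomic rank label, e.g. 'g__Faecalibacterium'."""
    label = "unclassified"
    for rank, value in taxonomy_row.items():
        if isinstance(value, str) and value.strip():
            label = f"{str(rank)[0].lower()}__{value.strip()}"
    return label


def rank_report(
    results: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    alpha: float = 0.05,
    top_k: int = 10,
    raw_alpha: float | None = None,
) -> pd.DataFrame:
    """Significant features sorted by adjusted p then |t|.

    Features with ``p_adj < alpha`` (and, if ``raw_alpha`` is given,
    additionally ``p_raw < raw_alpha``) are returned sorted by
    (p_adj, -|t|, feature ID); the first ``top_k`` rows are flagged for
    plotting.  Taxon labels use the lowest identifiable rank.
    """
    hits = results[results["p_adj"] < alpha].copy()
    if raw_alpha is not None:
        hits = hits[hits["p_raw"] < raw_alpha]
    hits["abs_t"] = hits["t"].abs()
    hits = hits.sort_values(
        by=["p_adj", "abs_t"], ascending=[True, False], kind="stable"
    )
    # deterministic tie-break on feature ID
    hits = hits.reset_index().sort_values(
        by=["p_adj", "abs_t", "feature_id"],
        ascending=[True, False, True],
        kind="stable",
    ).set_index("feature_id")
    hits = hits.drop(columns=["abs_t"])
    if taxonomy is not None:
        labels = [
            lowest_identifiable_rank(taxonomy.loc[f])
            if f in taxonomy.index
            else "unclassified"
            for f in hits.index
        ]
        hits["taxon_label"] = labels
    hits["top"] = False
    hits.iloc[: min(top_k, len(hits)), hits.columns.get_loc("top")] = True
    return hits
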