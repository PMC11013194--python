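"""Predicted-function modeling and gene-set over-representation.

Consumes PICRUSt2-style predicted KO/pathway abundance tables, fits the
same zero-inflated Gaussian models used for taxa, runs hypergeometric
over-representation analysis (ORA) of DII-associated enzymes against
KO gene sets, and fits the per-nutrient enzyme association models
(one model family per energy-corrected, Z-scored food parameter).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .zig import ZigFit, bh_adjust, fit_zig

__all__ = [
    "FunctionTable",
    "GeneSet",
    "load_gene_sets",
    "zig_functions",
    "ora_enrich",
    "nutrient_models",
]

log = logging.getLogger(__name__)

_KO_RE = re.compile(r"^K\d{5}$")
_PATHWAY_RE = re.compile(r"^[A-Za-z0-9+._-]+$")


@dataclass
class FunctionTable:
    """Sample x function predicted abundance matrix (KO or pathway IDs)."""

    values: pd.DataFrame  # index: sample_id, columns: function IDs
    kind: str = "ko"  # ko | pathway

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("function abundances must be non-negative")
        pattern = _KO_RE if self.kind == "ko" else _PATHWAY_RE
        bad = [c for c in self.values.columns if not pattern.match(str(c))]
        if bad:
            raise ValueError(f"invalid {self.kind} identifiers: {bad[:5]}")


@dataclass(frozen=True)
class GeneSet:
    """Named KO gene set (e.g. two-component system, galactose metabolism)."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


def load_gene_sets(path=None) -> list[GeneSet]:
    """Read gene sets from a three-column TSV (set_id, set_name, ko).

    Without a path, loads the small packaged example covering the
    two-component system, galactose/nitrogen metabolism, biofilm,
    glycolysis, and transporter terms.
    """
    if path is None:
        with resources.as_file(
            resources.files("microdii.data") / "ko_gene_sets.tsv"
        ) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    sets = []
    for (set_id, name), grp in frame.groupby(["set_id", "set_name"], sort=True):
        sets.append(GeneSet(set_id=set_id, name=name, members=frozenset(grp["ko"])))
    return sets


def zig_functions(
    table: FunctionTable,
    design: pd.DataFrame,
    library_size: pd.Series | None = None,
    exposure: str | None = None,
    css: bool = False,
    **kwargs,
) -> ZigFit:
    """ZIG models of log2(x + 1) predicted-function abundances.

    CSS rescaling is off by default: predicted tables are already on a
    relative scale.  The zero model uses the per-sample total predicted
    abundance when no library size is supplied.
    """
    values = table.values
    if css:
        from .prep import CountTable, css_normalize

        rounded = values.round().astype(int)
        ct = CountTable(
            rounded, pd.Series("specimen", index=rounded.index)
        )
        values = css_normalize(ct, quantile=0.5).values
    if library_size is None:
        library_size = table.values.sum(axis=1)
    y = np.log2(values + 1.0)
    return fit_zig(y, design, library_size, exposure=exposure, **kwargs)


def ora_enrich(
    hits: set[str],
    universe: set[str],
    sets: list[GeneSet],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    For a universe of size M with K hits, a set with n members in the
    universe and overlap k has upper-tail p = P(X >= k), X ~
    Hypergeom(M, n, K).  BH adjustment is applied across sets.  Set
    members outside the universe are dropped (logged).
    """
    hits = set(hits)
    universe = set(universe)
    if not hits:
        raise ValueError(
            "empty hit list; relax the significance threshold before ORA"
        )
    stray = hits - universe
    if stray:
        raise ValueError(f"hits not contained in universe: {sorted(stray)[:5]}")
    m = len(universe)
    k_hits = len(hits)
    rows = []
    for gene_set in sets:
        members = gene_set.members & universe
        dropped = len(gene_set.members) - len(members)
        if dropped:
            log.info(
                "ora_enrich: %s: dropped %d members outside universe",
                gene_set.set_id,
                dropped,
            )
        if not members:
            continue
        overlap = len(members & hits)
        expected = len(members) * k_hits / m
        p = stats.hypergeom.sf(overlap - 1, m, len(members), k_hits)
        rows.append(
            {
                "set_id": gene_set.set_id,
                "name": gene_set.name,
                "n_members": len(members),
                "overlap": overlap,
                "expected": expected,
                "p": min(float(p), 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
    return out


def nutrient_models(
    table: FunctionTable,
    intakes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    library_size: pd.Series | None = None,
    direction: str = "enzyme_response",
    alpha: float = 0.05,
    **kwargs,
) -> dict[str, object]:
    """Per-nutrient enzyme association model families.

    ``intakes`` holds energy-corrected nutrient intakes (one column per
    food parameter); each column is Z-scored and used as the exposure in
    a ZIG fit of every enzyme's log2 abundance (one model family per
    nutrient), with BH correction within each family.  Returns the
    enzyme x nutrient coefficient matrix, the adjusted-p matrix, and a
    significance mask at ``alpha``.

    ``direction="nutrient_response"`` fits the transposed reading
    instead (Z-scored nutrient regressed on each enzyme plus the
    covariates by ordinary least squares).
    """
    samples = table.values.index
    intakes = intakes.reindex(samples)
    betas, padjs = {}, {}
    skipped = []
    for nutrient in intakes.columns:
        col = intakes[nutrient].astype(float)
        sd = col.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            skipped.append(nutrient)
            log.warning("nutrient_models: skipping zero-variance nutrient %s", nutrient)
            continue
        z = (col - col.mean()) / sd
        meta = pd.DataFrame({"z_nutrient": z}, index=samples)
        cov_cols = []
        if covariates is not None:
            cov = covariates.reindex(samples)
            meta = pd.concat([meta, cov], axis=1)
            cov_cols = list(cov.columns)
        if direction == "enzyme_response":
            from .zig import build_design

            design = build_design(meta, "z_nutrient", cov_cols)
            fit = zig_functions(
                table, design, library_size=library_size, exposure="z_nutrient", **kwargs
            )
            betas[nutrient] = fit.results["beta"]
            padjs[nutrient] = fit.results["p_adj"]
        elif direction == "nutrient_response":
            from .zig import build_design

            y_log = np.log2(table.values + 1.0)
            raw_p, bs = [], []
            cov_mat = (
                pd.get_dummies(covariates.reindex(samples), drop_first=True)
                .astype(float)
                .to_numpy()
                if covariates is not None
                else np.empty((len(samples), 0))
            )
            zv = z.to_numpy()
            for enzyme in y_log.columns:
                x = np.column_stack(
                    [np.ones(len(samples)), y_log[enzyme].to_numpy(), cov_mat]
                )
                res = np.linalg.lstsq(x, zv, rcond=None)
                coef = res[0]
                resid = zv - x @ coef
                df = len(samples) - x.shape[1]
                s2 = resid @ resid / df
                cov_b = s2 * np.linalg.inv(x.T @ x)
                t = coef[1] / np.sqrt(cov_b[1, 1])
                raw_p.append(2 * stats.t.sf(abs(t), df))
                bs.append(coef[1])
            betas[nutrient] = pd.Series(bs, index=y_log.columns)
            padjs[nutrient] = pd.Series(bh_adjust(raw_p), index=y_log.columns)
        else:
            raise ValueError(f"unknown direction {direction!r}")
    beta_mat = pd.DataFrame(betas)
    padj_mat = pd.DataFrame(padjs)
    return {
        "beta": beta_mat,
        "p_adj": padj_mat,
        "significant": padj_mat < alpha,
        "n_models": len(betas),
        "skipped": skipped,
    }
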