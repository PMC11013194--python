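"""Count-table decontamination, filtering, and CSS normalization.

Turns a raw sample x ASV count table (with sequencing-blank negative
controls) into a modeling-ready matrix: prevalence-based contaminant
removal against the blanks, a library-size floor, a relative-abundance
feature filter, and cumulative sum scaling (CSS) normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountTable",
    "NormalizedTable",
    "flag_contaminants",
    "filter_samples",
    "filter_features",
    "css_normalize",
]

log = logging.getLogger(__name__)

SPECIMEN = "specimen"
CONTROL = "negative_control"


@dataclass
class CountTable:
    """Sample x feature non-negative integer count matrix.

    ``roles`` labels each sample as ``"specimen"`` or
    ``"negative_control"``; blanks carry reagent/environmental
    contamination and are consumed by :func:`flag_contaminants`.
    """

    counts: pd.DataFrame  # index: sample_id, columns: feature_id
    roles: pd.Series  # per sample: specimen | negative_control

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.roles = self.roles.reindex(self.counts.index)
        if self.roles.isna().any():
            missing = self.roles.index[self.roles.isna()].tolist()
            raise ValueError(f"missing role for samples {missing}")
        bad = set(self.roles.unique()) - {SPECIMEN, CONTROL}
        if bad:
            raise ValueError(f"unknown sample roles {sorted(bad)}")

    @property
    def library_size(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def features(self) -> list[str]:
        return list(self.counts.columns)

    def specimens(self) -> "CountTable":
        keep = self.roles[self.roles == SPECIMEN].index
        return CountTable(self.counts.loc[keep], self.roles.loc[keep])

    def drop_features(self, features) -> "CountTable":
        return replace(self, counts=self.counts.drop(columns=list(features)))


def flag_contaminants(
    table: CountTable, threshold: float = 0.5
) -> tuple[pd.Series, pd.Series]:
    """Prevalence-based contaminant scoring against negative controls.

    For every feature a 2x2 presence/absence table (present = count > 0)
    of {control, specimen} x {present, absent} is tested: a chi-square
    score statistic, or Fisher's exact test when any expected cell is
    below 5.  The score is the one-sided tail probability in the
    direction "more prevalent in controls"; features with
    ``score < threshold`` are flagged as contaminants.

    Returns ``(flags, scores)`` indexed by feature.
    """
    is_control = (table.roles == CONTROL).to_numpy()
    n_control = int(is_control.sum())
    n_specimen = int((~is_control).sum())
    if n_control == 0:
        raise ValueError(
            "no negative controls present; skip decontamination explicitly "
            "instead of calling flag_contaminants"
        )
    if n_specimen == 0:
        raise ValueError("no specimens present")

    present = table.counts.to_numpy() > 0
    ctrl_present = present[is_control].sum(axis=0)
    spec_present = present[~is_control].sum(axis=0)

    scores = np.ones(present.shape[1])
    for j in range(present.shape[1]):
        a, c = int(ctrl_present[j]), int(spec_present[j])
        tab = np.array([[a, n_control - a], [c, n_specimen - c]], dtype=float)
        total = tab.sum()
        if total == 0:
            continue
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
        if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
            # degenerate margin (feature everywhere or nowhere): no signal
            scores[j] = 1.0
            continue
        if (expected < 5).any():
            scores[j] = stats.fisher_exact(tab, alternative="greater")[1]
        else:
            chi2, p_two = stats.chi2_contingency(tab, correction=False)[:2]
            control_enriched = a / n_control > c / n_specimen
            scores[j] = p_two / 2 if control_enriched else 1 - p_two / 2
    scores = pd.Series(scores, index=table.counts.columns, name="score")
    flags = scores < threshold
    flags.name = "contaminant"
    return flags, scores


def filter_samples(table: CountTable, min_reads: int = 10) -> CountTable:
    """Drop samples whose library size is below ``min_reads``."""
    if table.counts.empty:
        raise ValueError("empty count table")
    lib = table.library_size
    drop = lib.index[lib < min_reads].tolist()
    if drop:
        log.info("filter_samples: removing %d samples below %d reads: %s",
                 len(drop), min_reads, drop)
    keep = lib.index[lib >= min_reads]
    if len(keep) == 0:
        raise ValueError("all samples removed by library-size filter")
    return CountTable(table.counts.loc[keep], table.roles.loc[keep])


def filter_features(
    table: CountTable, min_rel_abund: float = 0.01, mode: str = "any_sample"
) -> CountTable:
    """Drop low-relative-abundance features.

    ``mode="any_sample"`` (default) retains a feature iff it reaches
    ``min_rel_abund`` of the library size in at least one sample —
    keeping low-prevalence but locally abundant taxa.
    ``mode="global_mean"`` instead thresholds the feature's mean
    relative abundance across samples.
    """
    lib = table.library_size
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive; run filter_samples first")
    rel = table.counts.div(lib, axis=0)
    if mode == "any_sample":
        keep = rel.columns[(rel >= min_rel_abund).any(axis=0)]
    elif mode == "global_mean":
        keep = rel.columns[rel.mean(axis=0) >= min_rel_abund]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(keep) == 0:
        raise ValueError("all features removed by relative-abundance filter")
    dropped = table.counts.shape[1] - len(keep)
    if dropped:
        log.info("filter_features: removed %d/%d features", dropped, table.counts.shape[1])
    return replace(table, counts=table.counts[keep])


@dataclass
class NormalizedTable:
    """CSS-normalized abundance matrix with its per-sample scaling factors."""

    values: pd.DataFrame  # sample x feature, real >= 0
    scaling_factor: pd.Series
    css_quantile: float
    transform: str = "none"  # none | log2p1
    roles: pd.Series | None = None

    def log2(self) -> "NormalizedTable":
        """log2(x + 1) view for Gaussian modeling."""
        if self.transform != "none":
            raise ValueError("table already transformed")
        return replace(self, values=np.log2(self.values + 1.0), transform="log2p1")


def _css_scaling_factors(counts: np.ndarray, quantile: float) -> np.ndarray:
    """Per-sample cumulative sums up to the q-th quantile of positive counts."""
    factors = np.empty(counts.shape[0])
    for i in range(counts.shape[0]):
        row = counts[i]
        positive = row[row > 0]
        if positive.size == 0:
            factors[i] = 0.0
            continue
        cutoff = np.quantile(positive, quantile)
        factors[i] = row[row <= cutoff].sum()
    return factors


def _choose_css_quantile(counts: np.ndarray) -> float:
    """Data-driven CSS quantile.

    Examines the per-sample quantile curves of positive counts against
    their across-sample median reference and picks the smallest
    quantile at which the median absolute deviation from the reference
    begins to grow sharply (relative increase > 0.1) — the point where
    count distributions stop agreeing and cumulative sums become
    unstable.  Falls back to 0.5 when no such point exists.
    Deterministic (no randomness).
    """
    grid = np.arange(0.05, 0.96, 0.01)
    qmat = np.empty((counts.shape[0], grid.size))
    for i in range(counts.shape[0]):
        positive = counts[i][counts[i] > 0]
        if positive.size == 0:
            qmat[i] = 0.0
        else:
            qmat[i] = np.quantile(positive, grid)
    ref = np.median(qmat, axis=0)
    # instability along the quantile grid: median across samples of |q_j(l) - ref(l)|
    inst = np.median(np.abs(qmat - ref), axis=0)
    inst = np.maximum(inst, 1e-12)
    rel_change = np.diff(inst) / inst[:-1]
    jumps = np.nonzero(rel_change > 0.1)[0]
    if jumps.size == 0:
        return 0.5
    q = float(grid[jumps[0]])
    # guard degenerate extremes
    return min(max(q, 0.05), 0.95)


def css_normalize(
    table: CountTable,
    quantile: float | str = "auto",
    scale: float = 1000.0,
) -> NormalizedTable:
    """Cumulative sum scaling normalization.

    Per sample *j* the scaling factor ``s_j`` is the sum of counts of
    features whose count does not exceed the sample's q-th quantile of
    positive counts; normalized value = count / s_j * scale.  With
    ``quantile="auto"`` the quantile is chosen by a deterministic
    instability criterion (fallback 0.5); ``quantile=1.0`` reduces to
    total-sum scaling.
    """
    counts = table.counts.to_numpy(dtype=float)
    if quantile == "auto":
        q = _choose_css_quantile(counts)
    else:
        q = float(quantile)
        if not 0 < q <= 1:
            raise ValueError("quantile must be in (0, 1]")
    factors = _css_scaling_factors(counts, q)
    if (factors <= 0).any():
        bad = [s for s, f in zip(table.samples, factors) if f <= 0]
        raise ValueError(f"zero CSS scaling factor for samples {bad}")
    values = table.counts.div(pd.Series(factors, index=table.counts.index), axis=0) * scale
    return NormalizedTable(
        values=values,
        scaling_factor=pd.Series(factors, index=table.counts.index, name="css_factor"),
        css_quantile=q,
        roles=table.roles,
    )
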