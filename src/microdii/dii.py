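"""Dietary Inflammatory Index (DII) scoring from FFQ nutrient intake tables.

The DII summarizes the inflammatory potential of a diet.  For each food
parameter *i* with reported mean daily intake ``x_i``, the intake is
standardized against a global reference mean ``mu_i`` and standard
deviation ``sigma_i``, converted to a doubled-and-centered normal
percentile, and weighted by the parameter's literature-derived
inflammatory effect score ``S_i``::

    DII = sum_i (2 * Phi((x_i - mu_i) / sigma_i) - 1) * S_i

where ``Phi`` is the standard normal CDF.  Positive scores indicate a
pro-inflammatory diet.  Two reference tables ship with the package: the
27-parameter subset shared by the VioScreen and DHQII instruments, and
the full 45-parameter published index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

__all__ = [
    "FoodParameterSpec",
    "IntakeTable",
    "DiiResult",
    "load_reference",
    "harmonize_parameters",
    "screen_energy",
    "energy_correct",
    "compute_dii",
    "dii_frame",
    "assign_tertiles",
    "dietary_statistics",
    "DietaryStatsReport",
]

#: Documented score range of the full 45-parameter index (most
#: inflammatory diet = +7.98).  A documented bound, not a derived one.
PUBLISHED_RANGE = (-8.87, 7.98)


@dataclass(frozen=True)
class FoodParameterSpec:
    """Reference constants for one DII food parameter.

    ``global_mean``/``global_sd`` describe average daily intake across
    global populations; ``effect_score`` is the literature-derived
    inflammatory weight (positive = pro-inflammatory).
    """

    name: str
    units: str
    global_mean: float
    global_sd: float
    effect_score: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("parameter name must be non-empty")
        if not self.units:
            raise ValueError(f"{self.name}: units must be non-empty")
        if not np.isfinite(self.global_mean) or self.global_mean < 0:
            raise ValueError(f"{self.name}: global_mean must be finite and >= 0")
        if not np.isfinite(self.global_sd) or self.global_sd <= 0:
            raise ValueError(f"{self.name}: global_sd must be > 0")


def load_reference(source: str = "common27") -> list[FoodParameterSpec]:
    """Load a DII reference table.

    Parameters
    ----------
    source:
        ``"common27"`` (the 27 parameters shared by both FFQ
        instruments), ``"full45"`` (the complete published index), or a
        path to a CSV with columns
        ``parameter,units,global_mean,global_sd,effect_score``.
    """
    if source == "common27":
        path = resources.files("microdii.data") / "dii_reference_27.csv"
    elif source == "full45":
        path = resources.files("microdii.data") / "dii_reference_45.csv"
    else:
        path = source
    with resources.as_file(path) if not isinstance(path, str) else _nullcontext(path) as p:
        frame = pd.read_csv(p)
    specs = [
        FoodParameterSpec(
            name=row.parameter,
            units=row.units,
            global_mean=float(row.global_mean),
            global_sd=float(row.global_sd),
            effect_score=float(row.effect_score),
        )
        for row in frame.itertuples()
    ]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate parameter names in reference table")
    return specs


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def reference_frame(reference: list[FoodParameterSpec]) -> pd.DataFrame:
    """Reference table as a DataFrame indexed by parameter name."""
    return pd.DataFrame(
        {
            "units": [s.units for s in reference],
            "global_mean": [s.global_mean for s in reference],
            "global_sd": [s.global_sd for s in reference],
            "effect_score": [s.effect_score for s in reference],
        },
        index=pd.Index([s.name for s in reference], name="parameter"),
    )


@dataclass
class IntakeTable:
    """Subject x parameter daily-intake matrix with per-subject energy.

    ``values`` holds raw daily intakes (units per the reference table);
    NaN marks a missing parameter value for that subject.  ``units``
    optionally records the unit per column so harmonization can detect
    mismatches.
    """

    values: pd.DataFrame  # index: subject_id, columns: parameter names
    energy_kcal: pd.Series
    ffq_type: pd.Series | None = None
    units: dict[str, str] | None = None
    n_common: int | None = None  # set by harmonize_parameters

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.energy_kcal = self.energy_kcal.astype(float).reindex(self.values.index)
        if self.ffq_type is not None:
            self.ffq_type = self.ffq_type.reindex(self.values.index)
        if (self.values < 0).any().any():
            bad = self.values.columns[(self.values < 0).any()].tolist()
            raise ValueError(f"negative intake values in columns {bad}")
        missing = self.energy_kcal.index[self.energy_kcal.isna()].tolist()
        if missing:
            raise ValueError(f"missing energy_kcal for subjects {missing}")
        if (self.energy_kcal <= 0).any():
            bad = self.energy_kcal.index[self.energy_kcal <= 0].tolist()
            raise ValueError(f"non-positive energy_kcal for subjects {bad}")

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def parameters(self) -> list[str]:
        return list(self.values.columns)


def harmonize_parameters(
    tables: list[IntakeTable],
    reference: list[FoodParameterSpec],
    alias_map: dict[str, str] | None = None,
    unit_conversions: dict[tuple[str, str], float] | None = None,
) -> IntakeTable:
    """Merge intake tables from different FFQ instruments.

    Columns are first renamed through ``alias_map`` (instrument header ->
    canonical reference name), units are reconciled to the reference
    units through ``unit_conversions`` (multiplicative factors keyed
    ``(from, to)``), and the merged table is restricted to the
    intersection of parameter sets across all instruments.  The size of
    the intersection is recorded on the result as ``n_common``.
    """
    if not tables:
        raise ValueError("at least one intake table required")
    ref = reference_frame(reference)
    alias_map = alias_map or {}
    unit_conversions = unit_conversions or {}

    renamed: list[IntakeTable] = []
    for table in tables:
        mapped = {}
        for col in table.values.columns:
            name = alias_map.get(col, col)
            if name not in ref.index:
                raise ValueError(
                    f"unmappable parameter name {col!r}: not in reference and no alias"
                )
            mapped[col] = name
        values = table.values.rename(columns=mapped)
        units = None
        if table.units is not None:
            units = {mapped[c]: u for c, u in table.units.items()}
            for name, unit in units.items():
                want = ref.loc[name, "units"]
                if unit != want:
                    factor = unit_conversions.get((unit, want))
                    if factor is None:
                        raise ValueError(
                            f"unit mismatch for {name!r}: table has {unit!r}, "
                            f"reference wants {want!r}, no registered conversion"
                        )
                    values[name] = values[name] * factor
                    units[name] = want
        renamed.append(replace(table, values=values, units=units))

    common = set(renamed[0].values.columns)
    for table in renamed[1:]:
        common &= set(table.values.columns)
    if not common:
        raise ValueError("empty intersection of parameter sets across instruments")
    ordered = [name for name in ref.index if name in common]

    values = pd.concat([t.values[ordered] for t in renamed], axis=0)
    energy = pd.concat([t.energy_kcal for t in renamed])
    ffq = None
    if all(t.ffq_type is not None for t in renamed):
        ffq = pd.concat([t.ffq_type for t in renamed])
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()].tolist()
        raise ValueError(f"duplicate subject IDs across tables: {dup}")
    merged = IntakeTable(values=values, energy_kcal=energy, ffq_type=ffq)
    merged.n_common = len(ordered)
    return merged


def screen_energy(
    table: IntakeTable, low_kcal: float = 500.0, high_kcal: float = 5000.0
) -> tuple[IntakeTable, list[str]]:
    """Exclude subjects with implausible daily energy intake.

    Subjects outside the inclusive [low_kcal, high_kcal] window are
    flagged and removed (the standard FFQ plausibility screen).
    Returns the retained table and the flagged subject IDs.
    """
    energy = table.energy_kcal
    flagged = energy.index[(energy < low_kcal) | (energy > high_kcal)].tolist()
    keep = [s for s in table.subjects if s not in set(flagged)]
    retained = IntakeTable(
        values=table.values.loc[keep],
        energy_kcal=energy.loc[keep],
        ffq_type=None if table.ffq_type is None else table.ffq_type.loc[keep],
        units=table.units,
    )
    retained.n_common = table.n_common
    return retained, flagged


def energy_correct(table: IntakeTable, per_kcal: float = 1000.0) -> IntakeTable:
    """Express intakes as nutrient density per ``per_kcal`` kcal.

    Used for the dietary statistics only; the DII itself is computed on
    raw intakes.  The energy column (if present) is left untouched.
    """
    if (table.energy_kcal <= 0).any():
        raise ValueError("energy must be positive for energy correction")
    values = table.values.div(table.energy_kcal, axis=0) * per_kcal
    if "energy" in values.columns:
        values["energy"] = table.values["energy"]
    out = IntakeTable(
        values=values,
        energy_kcal=table.energy_kcal,
        ffq_type=table.ffq_type,
        units=table.units,
    )
    out.n_common = table.n_common
    return out


@dataclass
class DiiResult:
    """Per-subject DII score and its per-parameter decomposition."""

    subject: str
    contributions: dict[str, float]
    total_score: float
    n_parameters: int
    tertile: int | None = None


def compute_dii(
    table: IntakeTable, reference: list[FoodParameterSpec]
) -> list[DiiResult]:
    """Score each subject's diet with the DII.

    Per parameter: z = (x - mu)/sigma against the global reference,
    centered percentile p = 2*Phi(z) - 1, contribution = p * S.  Missing
    intakes contribute 0 and decrement the per-subject parameter count.
    Raw (not energy-corrected) intakes are expected.
    """
    if not reference:
        raise ValueError("empty reference table")
    ref = reference_frame(reference)
    unknown = [c for c in table.values.columns if c not in ref.index]
    if unknown:
        raise ValueError(f"parameters not in reference: {unknown}")
    values = table.values
    if np.isinf(values.to_numpy()).any():
        raise ValueError("non-finite intake values")
    params = list(values.columns)
    mu = ref.loc[params, "global_mean"].to_numpy()
    sd = ref.loc[params, "global_sd"].to_numpy()
    s = ref.loc[params, "effect_score"].to_numpy()

    x = values.to_numpy(dtype=float)
    z = (x - mu) / sd
    pctl = 2.0 * ndtr(z) - 1.0
    contrib = pctl * s
    missing = np.isnan(x)
    contrib = np.where(missing, 0.0, contrib)

    results = []
    for i, subject in enumerate(values.index):
        contribs = {p: float(contrib[i, j]) for j, p in enumerate(params)}
        results.append(
            DiiResult(
                subject=str(subject),
                contributions=contribs,
                total_score=float(contrib[i].sum()),
                n_parameters=int((~missing[i]).sum()),
            )
        )
    return results


def dii_frame(results: list[DiiResult]) -> pd.DataFrame:
    """Flatten DII results to a DataFrame indexed by subject."""
    return pd.DataFrame(
        {
            "dii": [r.total_score for r in results],
            "n_parameters": [r.n_parameters for r in results],
            "tertile": [r.tertile for r in results],
        },
        index=pd.Index([r.subject for r in results], name="subject_id"),
    )


def assign_tertiles(scores: list[tuple[str, float]]) -> list[tuple[str, int]]:
    """Rank-split subjects into tertiles 1 (least) .. 3 (most inflammatory).

    Group sizes differ by at most one; when N is not divisible by 3 the
    extra members go to the *higher* tertiles (a cohort of 47 splits
    15/16/16).  Ties are broken by stable subject-ID order.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 subjects for tertiles")
    for subject, score in scores:
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for subject {subject!r}")
    order = sorted(range(len(scores)), key=lambda i: (scores[i][1], i))
    n = len(scores)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if t >= 3 - rem else 0) for t in range(3)]
    assignment: dict[int, int] = {}
    pos = 0
    for tertile, size in enumerate(sizes, start=1):
        for i in order[pos : pos + size]:
            assignment[i] = tertile
        pos += size
    return [(scores[i][0], assignment[i]) for i in range(n)]


@dataclass
class DietaryStatsReport:
    """Bundle of the tertile-wise dietary statistics."""

    chi_square: pd.DataFrame  # per categorical variable: statistic, df, p
    anova: pd.DataFrame  # per quantitative variable: F, p
    ttest: pd.DataFrame  # per nutrient (T1 vs T2+3): t, p
    spearman_rho: pd.DataFrame
    spearman_p: pd.DataFrame
    significant_pairs: pd.DataFrame  # rho entries at p < alpha


def dietary_statistics(
    table: IntakeTable,
    tertiles: dict[str, int] | pd.Series,
    demographics: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> DietaryStatsReport:
    """Tertile-wise dietary and demographic statistics.

    ``table`` should be energy-corrected.  Categorical demographic
    columns get a Pearson chi-square on the tertile contingency table;
    quantitative columns a one-way ANOVA across tertiles; each nutrient
    a two-sample t-test of tertile 1 against pooled tertiles 2+3; and
    nutrient pairs a Spearman correlation matrix with p-values.
    """
    tert = pd.Series(tertiles).reindex(table.values.index)
    if tert.isna().any():
        missing = tert.index[tert.isna()].tolist()
        raise ValueError(f"missing tertile assignment for subjects {missing}")
    tert = tert.astype(int)

    chi_rows, anova_rows = [], []
    if demographics is not None:
        demo = demographics.reindex(table.values.index)
        for col in demo.columns:
            series = demo[col]
            if pd.api.types.is_numeric_dtype(series):
                groups = [series[tert == t].dropna().to_numpy() for t in (1, 2, 3)]
                f, p = stats.f_oneway(*groups)
                anova_rows.append({"variable": col, "F": f, "p": p})
            else:
                contingency = pd.crosstab(series, tert)
                empty = contingency.index[(contingency.sum(axis=1) == 0)].tolist()
                if empty:
                    warnings.warn(
                        f"{col}: dropping empty levels {empty}", stacklevel=2
                    )
                    contingency = contingency.loc[contingency.sum(axis=1) > 0]
                res = stats.chi2_contingency(contingency.to_numpy(), correction=False)
                chi_rows.append(
                    {
                        "variable": col,
                        "statistic": res.statistic,
                        "df": res.dof,
                        "p": res.pvalue,
                    }
                )

    ttest_rows = []
    for col in table.values.columns:
        x1 = table.values.loc[tert == 1, col].dropna().to_numpy()
        x23 = table.values.loc[tert != 1, col].dropna().to_numpy()
        groups = [table.values.loc[tert == t, col].dropna().to_numpy() for t in (1, 2, 3)]
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p_anova = stats.f_oneway(*groups)
            t, p_t = stats.ttest_ind(x1, x23, equal_var=True)
            if np.isnan(t):  # zero pooled variance
                if np.isclose(x1.mean(), x23.mean()):
                    t, p_t = 0.0, 1.0
                else:
                    t, p_t = np.inf * np.sign(x1.mean() - x23.mean()), 0.0
        anova_rows.append({"variable": col, "F": f, "p": p_anova})
        ttest_rows.append({"nutrient": col, "t": t, "p": p_t})

    cols = table.values.columns
    if len(cols) < 2:
        rho = np.ones((len(cols), len(cols)))
        pval = np.zeros_like(rho)
    else:
        rho, pval = stats.spearmanr(table.values.to_numpy(), nan_policy="omit")
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
            pval = np.array([[0.0, pval], [pval, 0.0]])
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pval, index=cols, columns=cols)
    np.fill_diagonal(p_df.to_numpy(), 0.0)

    pairs = []
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            if p_df.iloc[i, j] < alpha:
                pairs.append({"a": a, "b": b, "rho": rho_df.iloc[i, j], "p": p_df.iloc[i, j]})

    return DietaryStatsReport(
        chi_square=pd.DataFrame(chi_rows),
        anova=pd.DataFrame(anova_rows),
        ttest=pd.DataFrame(ttest_rows),
        spearman_rho=rho_df,
        spearman_p=p_df,
        significant_pairs=pd.DataFrame(pairs),
    )
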