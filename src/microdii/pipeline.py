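"""End-to-end orchestration: score -> prep -> diversity -> ZIG -> enrichment.

A single :class:`RunConfig` (YAML-serializable) names every input and
threshold; :func:`run_all` executes the stages in order, writes
per-stage TSV outputs under the configured output directory, and
returns a machine-readable manifest with file hashes, versions, seeds
and thresholds.  Any stage failure raises :class:`PipelineError` naming
the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dii import (
    assign_tertiles,
    compute_dii,
    dii_frame,
    dietary_statistics,
    energy_correct,
    load_reference,
    screen_energy,
)
from .diversity import alpha_diversity, alpha_test, beta_diversity, load_tree, permanova
from .functions import nutrient_models, ora_enrich, zig_functions
from .io import (
    read_count_tsv,
    read_function_tsv,
    read_gene_sets,
    read_intake_csv,
    read_metadata_csv,
    read_taxonomy_tsv,
)
from .prep import css_normalize, filter_features, filter_samples, flag_contaminants
from .zig import build_design, fit_zig, rank_report

__all__ = ["RunConfig", "PipelineError", "run_all"]

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "ega", "bmi", "ffq_type", "sample_type"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds, and seeds for one pipeline run."""

    intakes: str
    counts: str
    metadata: str
    outdir: str
    tree: str | None = None
    taxonomy: str | None = None
    ko: str | None = None
    pathways: str | None = None
    gene_sets: str | None = None
    reference: str = "common27"
    energy_low_kcal: float = 500.0
    energy_high_kcal: float = 5000.0
    decontam_threshold: float = 0.5
    min_reads: int = 10
    min_rel_abund: float = 0.01
    css_quantile: str | float = "auto"
    alpha: float = 0.05
    raw_alpha: float = 0.05
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    n_permutations: int = 999
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 < self.decontam_threshold < 1:
            raise ValueError("decontam_threshold must be in (0, 1)")
        if self.min_reads < 0 or not 0 <= self.min_rel_abund < 1:
            raise ValueError("invalid filtering thresholds")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _check_batch_confounding(exposure: pd.Series, batch: pd.Series) -> None:
    """Refuse to model when batch explains essentially all exposure variance."""
    if batch.nunique() < 2:
        return
    grand = exposure.mean()
    ss_total = ((exposure - grand) ** 2).sum()
    ss_within = sum(
        ((grp - grp.mean()) ** 2).sum() for _, grp in exposure.groupby(batch)
    )
    if ss_total > 0 and 1 - ss_within / ss_total > 0.99:
        raise ValueError(
            "batch is confounded with the exposure (eta^2 > 0.99); "
            "resolve the design instead of modeling through it"
        )


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    artifacts: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": [],
    }

    # ---- stage 1: DII scores -------------------------------------------
    stage = "scores"
    try:
        scores_dir = outdir / "scores"
        scores_dir.mkdir(parents=True, exist_ok=True)
        intakes = read_intake_csv(config.intakes)
        reference = load_reference(config.reference)
        retained, flagged = screen_energy(
            intakes, config.energy_low_kcal, config.energy_high_kcal
        )
        results = compute_dii(retained, reference)
        scores = dii_frame(results)
        tert = assign_tertiles(list(scores["dii"].items()))
        scores["tertile"] = pd.Series(dict(tert))
        scores.to_csv(scores_dir / "dii_scores.csv")
        corrected = energy_correct(retained)
        stats_report = dietary_statistics(
            corrected, scores["tertile"], demographics=None
        )
        stats_report.ttest.to_csv(scores_dir / "nutrient_ttests.csv", index=False)
        stats_report.spearman_rho.to_csv(scores_dir / "nutrient_spearman_rho.csv")
        artifacts += [
            scores_dir / "dii_scores.csv",
            scores_dir / "nutrient_ttests.csv",
            scores_dir / "nutrient_spearman_rho.csv",
        ]
        manifest["stages"].append(
            {"stage": stage, "n_subjects": len(scores), "n_energy_flagged": len(flagged)}
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage 2: prep --------------------------------------------------
    stage = "prep"
    try:
        prep_dir = outdir / "prep"
        prep_dir.mkdir(parents=True, exist_ok=True)
        metadata = read_metadata_csv(config.metadata)
        table = read_count_tsv(config.counts, metadata)
        flags, decontam_scores = flag_contaminants(table, config.decontam_threshold)
        decontam_scores.to_frame().assign(contaminant=flags).to_csv(
            prep_dir / "decontam_scores.tsv", sep="\t"
        )
        table = table.drop_features(flags.index[flags])
        table = filter_samples(table, config.min_reads)
        table = table.specimens()
        table = filter_features(table, config.min_rel_abund)
        norm = css_normalize(table, quantile=config.css_quantile)
        norm.values.T.to_csv(prep_dir / "norm.tsv", sep="\t", index_label="feature_id")
        norm.scaling_factor.to_csv(prep_dir / "css_factors.tsv", sep="\t")
        artifacts += [
            prep_dir / "decontam_scores.tsv",
            prep_dir / "norm.tsv",
            prep_dir / "css_factors.tsv",
        ]
        manifest["stages"].append(
            {
                "stage": stage,
                "n_contaminants": int(flags.sum()),
                "n_samples": len(table.samples),
                "n_features": len(table.features),
                "css_quantile": norm.css_quantile,
            }
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # join scores + covariates on the retained specimens
    stage = "diversity"
    try:
        div_dir = outdir / "diversity"
        div_dir.mkdir(parents=True, exist_ok=True)
        samples = [s for s in table.samples]
        meta = metadata.loc[samples].copy()
        link = meta.get("subject_id")
        subject_of = (
            {s: str(link.loc[s]) for s in samples} if link is not None else
            {s: s for s in samples}
        )
        dii_by_sample = pd.Series(
            {s: scores.loc[subject_of[s], "dii"] for s in samples}
        )
        tert_by_sample = pd.Series(
            {s: scores.loc[subject_of[s], "tertile"] for s in samples}
        )
        if "batch" in meta.columns:
            _check_batch_confounding(dii_by_sample, meta["batch"])
        covs = meta[[c for c in config.covariates if c in meta.columns]]

        alpha_rows = {}
        for index in ("shannon", "simpson"):
            vals = alpha_diversity(table, index)
            alpha_rows[index] = vals
            tests = alpha_test(vals, tert_by_sample)
            tests.to_csv(div_dir / f"alpha_{index}_tests.tsv", sep="\t", index=False)
            artifacts.append(div_dir / f"alpha_{index}_tests.tsv")
        pd.DataFrame(alpha_rows).to_csv(div_dir / "alpha.tsv", sep="\t")
        artifacts.append(div_dir / "alpha.tsv")

        perm_rows = []
        metrics = ["bray_curtis"] + (["unifrac"] if config.tree else [])
        tree = load_tree(config.tree) if config.tree else None
        for metric in metrics:
            source = norm if metric == "bray_curtis" else table
            dm = beta_diversity(source, metric, tree=tree)
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                div_dir / f"dist_{metric}.tsv", sep="\t"
            )
            artifacts.append(div_dir / f"dist_{metric}.tsv")
            res = permanova(
                dm,
                dii_by_sample,
                covariates=covs,
                n_perm=config.n_permutations,
                seed=config.seed,
            )
            perm_rows.append(
                {
                    "metric": metric,
                    "pseudo_F": res.pseudo_f,
                    "p": res.p_value,
                    "R2": res.r_squared,
                    "n_permutations": res.n_permutations,
                }
            )
        pd.DataFrame(perm_rows).to_csv(div_dir / "permanova.tsv", sep="\t", index=False)
        artifacts.append(div_dir / "permanova.tsv")
        manifest["stages"].append({"stage": stage, "metrics": metrics})
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage 4: ZIG differential abundance ---------------------------
    stage = "zig"
    try:
        zig_dir = outdir / "zig"
        zig_dir.mkdir(parents=True, exist_ok=True)
        design_meta = covs.copy()
        design_meta["dii"] = dii_by_sample
        design = build_design(design_meta, "dii", list(covs.columns))
        y = norm.log2().values
        fit = fit_zig(y, design, table.library_size, exposure="dii")
        fit.results.to_csv(zig_dir / "zig_results.tsv", sep="\t")
        taxonomy = (
            read_taxonomy_tsv(config.taxonomy) if config.taxonomy else None
        )
        report = rank_report(fit.results, taxonomy, alpha=config.alpha)
        report.to_csv(zig_dir / "significant_taxa.tsv", sep="\t")
        artifacts += [zig_dir / "zig_results.tsv", zig_dir / "significant_taxa.tsv"]
        manifest["stages"].append(
            {
                "stage": stage,
                "n_features": len(fit.results),
                "n_significant": int((fit.results["p_adj"] < config.alpha).sum()),
            }
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage 5: predicted functions ----------------------------------
    stage = "func"
    if config.ko:
        try:
            func_dir = outdir / "func"
            func_dir.mkdir(parents=True, exist_ok=True)
            ko = read_function_tsv(config.ko, kind="ko")
            ko_specimens = ko.values.reindex(samples).dropna()
            from .functions import FunctionTable

            ko = FunctionTable(ko_specimens, kind="ko")
            ko_fit = zig_functions(ko, design, exposure="dii")
            ko_fit.results.to_csv(func_dir / "ko_zig.tsv", sep="\t")
            artifacts.append(func_dir / "ko_zig.tsv")
            n_models = 0
            if config.pathways:
                pw = read_function_tsv(config.pathways, kind="pathway")
                pw = FunctionTable(pw.values.reindex(samples).dropna(), kind="pathway")
                pw_fit = zig_functions(pw, design, exposure="dii")
                pw_fit.results.to_csv(func_dir / "pathway_zig.tsv", sep="\t")
                artifacts.append(func_dir / "pathway_zig.tsv")
            if config.gene_sets:
                hits = set(ko_fit.results.index[ko_fit.results["p_raw"] < config.raw_alpha])
                universe = set(ko_fit.results.index)
                if hits:
                    enrich = ora_enrich(hits, universe, read_gene_sets(config.gene_sets))
                    enrich.to_csv(func_dir / "ora.tsv", sep="\t", index=False)
                    artifacts.append(func_dir / "ora.tsv")
            assoc = ko_fit.results.index[ko_fit.results["p_adj"] < config.alpha]
            if len(assoc) > 0:
                sub = FunctionTable(ko.values[list(assoc)], kind="ko")
                nutrients = energy_correct(retained).values
                nutrients = nutrients.loc[[subject_of[s] for s in samples]]
                nutrients.index = pd.Index(samples, name="sample_id")
                nm = nutrient_models(sub, nutrients, covariates=covs, alpha=config.alpha)
                nm["beta"].to_csv(func_dir / "nutrient_betas.tsv", sep="\t")
                nm["p_adj"].to_csv(func_dir / "nutrient_p_adj.tsv", sep="\t")
                artifacts += [
                    func_dir / "nutrient_betas.tsv",
                    func_dir / "nutrient_p_adj.tsv",
                ]
                n_models = nm["n_models"]
            manifest["stages"].append(
                {
                    "stage": stage,
                    "n_ko": ko.values.shape[1],
                    "n_dii_associated": int(len(assoc)),
                    "n_nutrient_models": int(n_models),
                }
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    manifest["artifacts"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in artifacts
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
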