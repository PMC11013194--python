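"""Synthetic cohort generator with planted ground truth.

Emulates every input the pipeline consumes for a pregnancy cohort of
n = 47: demographics and covariates, FFQ nutrient intakes driven by a
latent diet-quality gradient (pro-inflammatory diets are depleted in
vitamins and minerals), a sample x ASV count table with library-size-
dependent zeros, DII-linked taxa and blank-control-enriched
contaminants, a rooted phylogeny, taxonomy strings, and PICRUSt2-style
predicted KO/pathway tables derived from a taxon-to-KO map.  All
randomness flows from a single seed; the :class:`SyntheticTruth` record
suffices to score any recovery metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .dii import FoodParameterSpec, IntakeTable, compute_dii, dii_frame, load_reference
from .functions import FunctionTable, GeneSet, load_gene_sets
from .prep import CONTROL, SPECIMEN, CountTable

__all__ = [
    "SyntheticTruth",
    "gen_cohort",
    "gen_intakes",
    "gen_counts",
    "gen_functions",
    "simulate_zig_dataset",
    "generate_all",
    "MICRONUTRIENTS",
]

#: Vitamin/mineral parameters depleted along the pro-inflammatory gradient.
MICRONUTRIENTS = frozenset(
    {
        "vitamin_b12",
        "vitamin_b6",
        "beta_carotene",
        "folic_acid",
        "iron",
        "magnesium",
        "niacin",
        "riboflavin",
        "selenium",
        "thiamin",
        "vitamin_a",
        "vitamin_c",
        "vitamin_d",
        "vitamin_e",
        "zinc",
    }
)

_RACE = ["Hispanic", "Non-Hispanic Black", "Other/Unreported"]
_RACE_P = [7 / 47, 21 / 47, 19 / 47]
_INSURANCE = ["Federal Aid", "Private"]
_INSURANCE_P = [35 / 47, 12 / 47]
_EDUCATION = ["Above College", "Below College", "College"]
_EDUCATION_P = [10 / 47, 16 / 47, 21 / 47]
_INCOME = ["<$31k", "$31-76k", "$76k+"]
_INCOME_P = [34 / 47, 7 / 47, 6 / 47]


@dataclass
class SyntheticTruth:
    """Planted parameters of one synthetic dataset."""

    seed: int
    gradient: dict[str, float] = field(default_factory=dict)  # latent diet gradient
    dii: dict[str, float] = field(default_factory=dict)
    planted_taxa: dict[str, float] = field(default_factory=dict)  # taxon -> slope
    contaminants: list[str] = field(default_factory=list)
    ko_links: dict[str, str] = field(default_factory=dict)  # private KO -> planted taxon
    batch: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def gen_cohort(n: int = 47, seed: int = 0) -> pd.DataFrame:
    """Demographics and model covariates for ``n`` pregnant subjects.

    Maternal age ~ N(29, 6), estimated gestational age ~ N(10.9, 3)
    truncated above 4 weeks, BMI ~ N(29.5, 7); categorical demographics
    follow the cohort's marginal proportions; FFQ type splits ~50/50 and
    sample type 42:5 rectal-swab:stool.
    """
    if n < 6:
        raise ValueError("need n >= 6")
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    age = np.clip(rng.normal(29, 6, n), 18, 45)
    ega = rng.normal(10.9, 3, n)
    while (ega <= 4).any():
        ega[ega <= 4] = rng.normal(10.9, 3, int((ega <= 4).sum()))
    bmi = np.clip(rng.normal(29.5, 7, n), 16, 55)
    cohort = pd.DataFrame(
        {
            "age": age,
            "ega": ega,
            "bmi": bmi,
            "race_ethnicity": rng.choice(_RACE, size=n, p=_RACE_P),
            "insurance": rng.choice(_INSURANCE, size=n, p=_INSURANCE_P),
            "education": rng.choice(_EDUCATION, size=n, p=_EDUCATION_P),
            "income": rng.choice(_INCOME, size=n, p=_INCOME_P),
            "ffq_type": rng.choice(["VioScreen", "DHQII"], size=n),
            "sample_type": rng.choice(["rectal", "stool"], size=n, p=[42 / 47, 5 / 47]),
            "batch": rng.integers(1, 5, size=n),
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    return cohort


def gen_intakes(
    cohort: pd.DataFrame,
    reference: list[FoodParameterSpec] | None = None,
    gradient_strength: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.3,
) -> tuple[IntakeTable, pd.Series]:
    """FFQ intakes driven by a latent diet-quality gradient g ~ N(0, 1).

    Vitamins and minerals are log-depleted by ``gradient_strength * g``
    (positive g = pro-inflammatory, micronutrient-poor diet); reported
    energy declines moderately with g, mirroring the cohort's inverse
    energy-DII pattern; all other parameters vary around their global
    means with log-normal noise.  Returns the table and the gradient.
    """
    if reference is None:
        reference = load_reference("common27")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    g = rng.normal(0, 1, n)
    values = {}
    energy = np.exp(
        rng.normal(np.log(1700), 0.35, n) - 0.25 * gradient_strength * g
    )
    energy = np.clip(energy, 600, 4800)
    for spec in reference:
        if spec.name == "energy":
            values[spec.name] = energy
            continue
        shift = (
            -gradient_strength * g if spec.name in MICRONUTRIENTS else np.zeros(n)
        )
        values[spec.name] = np.exp(
            np.log(max(spec.global_mean, 1e-3)) + shift + rng.normal(0, noise_sd, n)
        )
    frame = pd.DataFrame(values, index=cohort.index)
    table = IntakeTable(
        values=frame,
        energy_kcal=pd.Series(energy, index=cohort.index, name="energy_kcal"),
        ffq_type=cohort["ffq_type"],
    )
    return table, pd.Series(g, index=cohort.index, name="gradient")


_PHYLA = ["Firmicutes", "Bacteroidota", "Actinobacteriota", "Proteobacteria"]
_FAMILIES = [
    "Lachnospiraceae",
    "Ruminococcaceae",
    "Bacteroidaceae",
    "Prevotellaceae",
    "Bifidobacteriaceae",
    "Erysipelotrichaceae",
    "Eggerthellaceae",
    "Enterobacteriaceae",
]
_GENERA = [
    "Faecalibacterium",
    "Bacteroides",
    "Prevotella",
    "Blautia",
    "Roseburia",
    "Bifidobacterium",
    "Parabacteroides",
    "Corynebacterium",
    "Gemella",
    "Solobacterium",
]


def _random_taxonomy(features: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Seven-rank taxonomy strings; ~30% unresolved below family."""
    rows = []
    for f in features:
        family = rng.choice(_FAMILIES)
        resolved = rng.random() > 0.3
        genus = rng.choice(_GENERA) if resolved else ""
        species = f"sp{rng.integers(1, 99)}" if resolved and rng.random() > 0.4 else ""
        rows.append(
            {
                "kingdom": "Bacteria",
                "phylum": rng.choice(_PHYLA),
                "class": "Clostridia",
                "order": "Oscillospirales",
                "family": family,
                "genus": genus,
                "species": species,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(features, name="feature_id"))


def _random_tree(features: list[str], rng: np.random.Generator) -> skbio.TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths."""
    nodes = []
    for f in features:
        tip = skbio.TreeNode(name=f, length=float(rng.exponential(0.1)))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = skbio.TreeNode(length=float(rng.exponential(0.1)), children=[a, b])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def gen_counts(
    cohort: pd.DataFrame,
    dii: pd.Series,
    n_taxa: int = 300,
    n_assoc: int = 13,
    n_contam: int = 10,
    n_controls: int = 4,
    assoc_slope: float = 0.8,
    seed: int = 0,
) -> tuple[CountTable, skbio.TreeNode, pd.DataFrame, SyntheticTruth]:
    """Sample x ASV counts with planted DII-linked taxa and contaminants.

    Specimen library sizes are LogNormal(log 3e4, 0.7); per-sample taxon
    probabilities come from a log-linear model in which ``n_assoc``
    planted taxa carry slopes of alternating sign (``assoc_slope`` per
    standardized-DII unit); counts are multinomial with extra structural
    zeros whose probability is logistic in -log library size.  Blank
    negative controls are low-biomass (LogNormal(log 800, 0.5)) and
    dominated (99.9% of mass) by the ``n_contam`` contaminant taxa,
    which are nearly absent from specimens.
    """
    if n_assoc + n_contam >= n_taxa:
        raise ValueError("n_assoc + n_contam must be < n_taxa")
    rng = np.random.default_rng(seed)
    subjects = list(cohort.index)
    n = len(subjects)
    features = [f"ASV{i + 1:04d}" for i in range(n_taxa)]

    contam = features[:n_contam]
    assoc = features[n_contam : n_contam + n_assoc]
    slopes = {
        t: assoc_slope * (1 if i % 2 == 0 else -1) for i, t in enumerate(assoc)
    }

    dii_z = (dii - dii.mean()) / max(dii.std(ddof=0), 1e-9)
    base = rng.normal(0, 1.5, n_taxa)
    base[:n_contam] = -6.8  # contaminants: rare enough for <=10% specimen prevalence

    slope_vec = np.zeros(n_taxa)
    for i, t in enumerate(features):
        if t in slopes:
            slope_vec[i] = slopes[t]

    lib = np.exp(rng.normal(np.log(3e4), 0.7, n)).astype(int)
    lib = np.maximum(lib, 1)

    counts = np.zeros((n, n_taxa), dtype=np.int64)
    z = dii_z.to_numpy()
    for i in range(n):
        logw = base + slope_vec * z[i] + rng.normal(0, 0.5, n_taxa)
        w = np.exp(logw - logw.max())
        p = w / w.sum()
        counts[i] = rng.multinomial(lib[i], p)
        # library-size-driven structural zeros
        p_zero = 1.0 / (1.0 + np.exp(-(3.39 - 0.615 * np.log(lib[i]))))
        drop = rng.random(n_taxa) < p_zero
        counts[i, drop] = 0

    # blank negative controls: contaminant-dominated, low biomass
    ctrl_ids = [f"BLANK{i + 1}" for i in range(n_controls)]
    ctrl_counts = np.zeros((n_controls, n_taxa), dtype=np.int64)
    contam_w = rng.uniform(0.5, 1.5, n_contam)
    clean_w = np.full(n_taxa - n_contam, 1.0)
    profile = np.concatenate(
        [0.999 * contam_w / contam_w.sum(), 0.001 * clean_w / clean_w.sum()]
    )
    for i in range(n_controls):
        clib = max(int(np.exp(rng.normal(np.log(800), 0.5))), 1)
        ctrl_counts[i] = rng.multinomial(clib, profile)

    all_counts = pd.DataFrame(
        np.vstack([counts, ctrl_counts]),
        index=pd.Index(subjects + ctrl_ids, name="sample_id"),
        columns=features,
    )
    roles = pd.Series(
        [SPECIMEN] * n + [CONTROL] * n_controls, index=all_counts.index, name="role"
    )
    table = CountTable(all_counts, roles)
    tree = _random_tree(features, rng)
    taxonomy = _random_taxonomy(features, rng)
    truth = SyntheticTruth(
        seed=int(seed),
        dii={s: float(v) for s, v in dii.items()},
        planted_taxa={t: float(s) for t, s in slopes.items()},
        contaminants=list(contam),
        batch={s: int(b) for s, b in cohort["batch"].items()},
    )
    return table, tree, taxonomy, truth


def gen_functions(
    counts: CountTable,
    truth: SyntheticTruth,
    n_ko: int = 500,
    density: float = 0.05,
    private_per_taxon: int = 3,
    seed: int = 0,
) -> tuple[FunctionTable, FunctionTable, list[GeneSet], pd.DataFrame]:
    """Predicted KO and pathway tables from a sparse taxon-to-KO map.

    The binary taxon x KO map has row density ~``density``; each planted
    taxa additionally receives ``private_per_taxon`` KOs carried by no
    other taxon, so those functions inherit the taxon's DII association
    exactly.  KO abundance = relative taxon abundance x map (scaled),
    with small multiplicative noise on non-zero entries; the pathway
    table aggregates KOs by a set assignment drawn over the packaged
    gene-set names.  Returns (KO table, pathway table, gene sets, map).
    """
    rng = np.random.default_rng(seed)
    spec = counts.specimens()
    rel = spec.counts.div(spec.counts.sum(axis=1).replace(0, 1), axis=0)
    taxa = list(rel.columns)
    planted = [t for t in truth.planted_taxa if t in taxa]

    ko_pool = rng.choice(np.arange(1, 99999), size=n_ko, replace=False)
    ko_ids = sorted(f"K{i:05d}" for i in ko_pool)

    gmat = (rng.random((len(taxa), n_ko)) < density).astype(float)
    # reserve private KOs for planted taxa
    private_idx = rng.choice(
        n_ko, size=min(n_ko, private_per_taxon * len(planted)), replace=False
    )
    ko_links: dict[str, str] = {}
    for k, idx in enumerate(private_idx):
        taxon = planted[k // private_per_taxon]
        gmat[:, idx] = 0.0
        gmat[taxa.index(taxon), idx] = 1.0
        ko_links[ko_ids[idx]] = taxon
    # no empty KOs: give orphans one random carrier
    empty = np.nonzero(gmat.sum(axis=0) == 0)[0]
    for idx in empty:
        gmat[rng.integers(0, len(taxa)), idx] = 1.0

    ko_abund = rel.to_numpy() @ gmat * 1e4
    noise = np.exp(rng.normal(0, 0.1, ko_abund.shape))
    ko_abund = np.where(ko_abund > 0, ko_abund * noise, 0.0)
    ko_table = FunctionTable(
        pd.DataFrame(ko_abund, index=rel.index, columns=ko_ids), kind="ko"
    )

    named_sets = {s.set_id: s.name for s in load_gene_sets()}
    set_ids = sorted(named_sets)
    assignment = rng.choice(set_ids, size=n_ko)
    path_values = {}
    gene_sets = []
    for set_id in set_ids:
        members = [ko for ko, s in zip(ko_ids, assignment) if s == set_id]
        if not members:
            continue
        gene_sets.append(
            GeneSet(set_id=set_id, name=named_sets[set_id], members=frozenset(members))
        )
        path_values[set_id] = ko_table.values[members].sum(axis=1)
    pathway_table = FunctionTable(pd.DataFrame(path_values), kind="pathway")

    truth.ko_links = ko_links
    gmap = pd.DataFrame(gmat, index=pd.Index(taxa, name="feature_id"), columns=ko_ids)
    return ko_table, pathway_table, gene_sets, gmap


def simulate_zig_dataset(
    n_samples: int = 200,
    n_features: int = 100,
    n_planted: int = 10,
    slope: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict[str, object]:
    """Direct draw from the zero-inflated Gaussian model for benchmarking.

    Planted features carry an exposure slope on the Gaussian mean;
    structural zeros occur with probability logistic in -log library
    size, so small libraries are zero-inflated.  Returns the abundance
    matrix, design metadata, library sizes and planted feature IDs.
    """
    rng = np.random.default_rng(seed)
    samples = [f"Z{i + 1:04d}" for i in range(n_samples)]
    features = [f"F{i + 1:04d}" for i in range(n_features)]
    dii = rng.normal(0, 2, n_samples)
    age = rng.normal(29, 6, n_samples)
    bmi = rng.normal(29.5, 7, n_samples)
    lib = np.exp(rng.normal(np.log(3e4), 0.8, n_samples))

    planted = features[:n_planted]
    beta = np.zeros(n_features)
    beta[:n_planted] = slope
    base = rng.normal(6, 1, n_features)
    mu = (
        base[None, :]
        + np.outer(dii, beta)
        + np.outer(0.02 * (age - 29), np.ones(n_features))
        + np.outer(0.01 * (bmi - 29.5), np.ones(n_features))
    )
    y = mu + rng.normal(0, noise_sd, mu.shape)
    y = np.maximum(y, 0.0)
    p_zero = 1.0 / (1.0 + np.exp(-(6.0 - 0.75 * np.log(lib))))
    zeros = rng.random(y.shape) < p_zero[:, None]
    y[zeros] = 0.0

    metadata = pd.DataFrame(
        {"dii": dii, "age": age, "bmi": bmi},
        index=pd.Index(samples, name="sample_id"),
    )
    return {
        "y": pd.DataFrame(y, index=metadata.index, columns=features),
        "metadata": metadata,
        "library_size": pd.Series(lib, index=metadata.index, name="library_size"),
        "planted": planted,
        "slope": slope,
    }


def generate_all(
    outdir,
    n: int = 47,
    seed: int = 17,
    gradient_strength: float = 1.0,
    n_taxa: int = 300,
    n_assoc: int = 13,
    n_contam: int = 10,
    n_ko: int = 500,
) -> SyntheticTruth:
    """Write the full synthetic input bundle to ``outdir``.

    Files: intakes.csv, metadata.csv, counts.tsv (features x samples),
    tree.nwk, taxonomy.tsv, ko.tsv, pathways.tsv, gene_sets.tsv,
    taxon_ko_map.tsv, truth.json.  Deterministic in (seed, parameters).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    s_cohort, s_intake, s_counts, s_func = rng.integers(0, 2**31 - 1, 4)

    cohort = gen_cohort(n=n, seed=int(s_cohort))
    reference = load_reference("common27")
    intakes, gradient = gen_intakes(
        cohort, reference, gradient_strength=gradient_strength, seed=int(s_intake)
    )
    dii = dii_frame(compute_dii(intakes, reference))["dii"]
    counts, tree, taxonomy, truth = gen_counts(
        cohort,
        dii,
        n_taxa=n_taxa,
        n_assoc=n_assoc,
        n_contam=n_contam,
        seed=int(s_counts),
    )
    truth.seed = int(seed)  # record the root seed, not the stage sub-seed
    truth.gradient = {s: float(v) for s, v in gradient.items()}
    ko_table, pathway_table, gene_sets, gmap = gen_functions(
        counts, truth, n_ko=n_ko, seed=int(s_func)
    )

    intake_out = intakes.values.copy()
    intake_out.insert(0, "energy_kcal", intakes.energy_kcal)
    intake_out.insert(0, "ffq_type", intakes.ffq_type)
    intake_out.to_csv(outdir / "intakes.csv")

    meta = cohort.copy()
    meta.index.name = "subject_id"
    meta = meta.reset_index()
    meta.insert(0, "sample_id", meta["subject_id"])
    meta["role"] = SPECIMEN
    ctrl_ids = [s for s in counts.samples if s.startswith("BLANK")]
    ctrl_rows = pd.DataFrame(
        {
            "sample_id": ctrl_ids,
            "subject_id": "",
            "role": CONTROL,
            "batch": [int(b) for b in np.resize([1, 2, 3, 4], len(ctrl_ids))],
            "sample_type": "control",
        }
    )
    meta = pd.concat([meta, ctrl_rows], ignore_index=True)
    meta.to_csv(outdir / "metadata.csv", index=False)

    counts.counts.T.to_csv(outdir / "counts.tsv", sep="\t", index_label="feature_id")
    tree.write(str(outdir / "tree.nwk"))
    taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
    ko_table.values.T.to_csv(outdir / "ko.tsv", sep="\t", index_label="function")
    pathway_table.values.T.to_csv(
        outdir / "pathways.tsv", sep="\t", index_label="function"
    )
    rows = []
    for gs in gene_sets:
        for ko in sorted(gs.members):
            rows.append({"set_id": gs.set_id, "set_name": gs.name, "ko": ko})
    pd.DataFrame(rows).to_csv(outdir / "gene_sets.tsv", sep="\t", index=False)
    gmap.to_csv(outdir / "taxon_ko_map.tsv", sep="\t")
    truth.to_json(outdir / "truth.json")
    return truth
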