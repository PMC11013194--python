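"""Shared fixtures: small intake tables, count tables, and independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from microdii.dii import FoodParameterSpec, IntakeTable


# ---------------------------------------------------------------------------
# independent oracles (never share code with the implementation under test)


def normal_cdf_oracle(z: float) -> float:
    """Standard normal CDF by Simpson numerical integration of the density.

    Independent of scipy; accurate to well below 1e-8 for any z.
    """
    if z < -9.0:
        return 0.0
    if z > 9.0:
        return 1.0
    n = 4000  # even number of Simpson intervals over [0, z]
    xs = np.linspace(0.0, z, n + 1)
    pdf = np.exp(-(xs**2) / 2.0) / math.sqrt(2.0 * math.pi)
    h = (z - 0.0) / n
    integral = h / 3.0 * (
        pdf[0] + pdf[-1] + 4.0 * pdf[1:-1:2].sum() + 2.0 * pdf[2:-1:2].sum()
    )
    return 0.5 + integral


def fisher_one_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """P(control-present >= a) by exhaustive hypergeometric enumeration.

    2x2 table rows: controls (a present, b absent), specimens
    (c present, d absent); margin-conditional upper tail.
    """
    n_ctrl = a + b
    total_present = a + c
    total = a + b + c + d
    denom = math.comb(total, total_present)
    p = 0.0
    for k in range(a, min(n_ctrl, total_present) + 1):
        if total_present - k > total - n_ctrl:
            continue
        p += math.comb(n_ctrl, k) * math.comb(total - n_ctrl, total_present - k) / denom
    return p


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Naive O(n^2) step-up BH: adj_i = min over q >= p_i of q*n/rank(q)."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(n)
    for i in range(n):
        candidates = [sorted_p[j] * n / (j + 1) for j in range(i, n)]
        adj_sorted[i] = min(1.0, min(candidates))
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def bray_curtis_oracle(x: np.ndarray, y: np.ndarray) -> float:
    num = np.abs(x - y).sum()
    den = (x + y).sum()
    return num / den if den > 0 else 0.0


def unifrac_oracle(tree, present_a: set, present_b: set) -> float:
    """Unweighted normalized UniFrac by explicit edge enumeration."""
    unique = 0.0
    spanned = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        in_a = bool(below & present_a)
        in_b = bool(below & present_b)
        if in_a or in_b:
            spanned += length
            if in_a != in_b:
                unique += length
    return unique / spanned if spanned > 0 else 0.0


def auc_oracle(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Rank AUC = P(random positive outranks random negative), ties 0.5."""
    wins = 0.0
    for sp in scores_pos:
        for sn in scores_neg:
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / (len(scores_pos) * len(scores_neg))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy_reference() -> list[FoodParameterSpec]:
    return [
        FoodParameterSpec("fiber", "g", 18.8, 4.9, -0.663),
        FoodParameterSpec("saturated_fat", "g", 28.6, 8.0, 0.373),
        FoodParameterSpec("vitamin_c", "mg", 118.2, 43.46, -0.424),
    ]


@pytest.fixture
def toy_intakes(toy_reference) -> IntakeTable:
    values = pd.DataFrame(
        {
            "fiber": [18.8, 10.0, 30.0],
            "saturated_fat": [28.6, 40.0, 12.0],
            "vitamin_c": [118.2, 60.0, 200.0],
        },
        index=pd.Index(["A", "B", "C"], name="subject_id"),
    )
    energy = pd.Series([2000.0, 2500.0, 1800.0], index=values.index)
    return IntakeTable(values=values, energy_kcal=energy)


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """One full synthetic input bundle shared across tests."""
    from microdii.synth import generate_all

    outdir = tmp_path_factory.mktemp("bundle")
    truth = generate_all(outdir, n=47, seed=17)
    return {"dir": outdir, "truth": truth}


@pytest.fixture(scope="session")
def zig_benchmark():
    """200-sample, 100-feature planted-slope dataset and its fit."""
    from microdii.synth import simulate_zig_dataset
    from microdii.zig import build_design, fit_zig

    data = simulate_zig_dataset(
        n_samples=200, n_features=100, n_planted=10, slope=0.5, seed=42
    )
    design = build_design(data["metadata"], "dii", ["age", "bmi"])
    fit = fit_zig(data["y"], design, data["library_size"], exposure="dii")
    return {"data": data, "design": design, "fit": fit}
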