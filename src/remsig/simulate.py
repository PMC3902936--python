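"""Synthetic NCI-60-style data with planted, recorded ground truth.

The generators emulate the three inputs of the pipeline at desk scale
(default world: 60 cell lines × 200 drugs × 2000 genes):

* per-drug log10 GI50 values with a Gaussian core and planted heavy
  resistant (+shift) and sensitive (−shift) tails;
* a log-scale expression matrix in which planted genes are shifted in the
  planted-resistant cells of their assigned drug *and* co-vary with the
  cells' GI50, making them discoverable by both REM criteria;
* an induction experiment whose per-gene induced-minus-control shifts have
  a chosen population correlation with a REM v-vector.

Everything is deterministic given the seed, and the returned
:class:`~remsig.containers.PlantedTruth` suffices to score every
downstream stage without re-running generation.
"""

from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np
import pandas as pd

from .containers import (
    DoseResponseMatrix,
    ExpressionMatrix,
    PlantedTruth,
    ResponseEngineeringModule,
    SignatureVector,
)

__all__ = [
    "generate_dose_response",
    "generate_expression",
    "generate_induction_experiment",
]


def _drug_ids(n: int) -> list[str]:
    return [f"DRUG{i + 1:04d}" for i in range(n)]


def _cell_ids(n: int) -> list[str]:
    return [f"CL{i + 1:02d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def generate_dose_response(
    n_drugs: int = 200,
    n_cells: int = 60,
    tail_fraction: float = 0.15,
    tail_shift: float = 3.0,
    seed: int = 0,
    mu_range: tuple[float, float] = (-8.0, -5.0),
    sigma_range: tuple[float, float] = (0.3, 0.8),
) -> tuple[DoseResponseMatrix, PlantedTruth]:
    """Simulate a drugs × cells log10 GI50 matrix with planted tails.

    Per drug, the core cells are Normal(μ_d, σ_d) with μ_d uniform on the
    typical log10-molar GI50 range and σ_d uniform on ``sigma_range``;
    ⌈tail_fraction·n_cells⌉ random cells are shifted +tail_shift·σ_d
    (planted resistant) and as many −tail_shift·σ_d (planted sensitive).
    """
    if not 0.0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must lie in (0, 0.5)")
    n_tail = math.ceil(tail_fraction * n_cells)
    if n_cells < 2 * n_tail:
        raise ValueError(
            f"n_cells={n_cells} cannot host two disjoint tails of size {n_tail}"
        )
    rng = np.random.default_rng(seed)
    drugs, cells = _drug_ids(n_drugs), _cell_ids(n_cells)
    gi50 = np.empty((n_drugs, n_cells))
    resistant: dict[str, list[str]] = {}
    sensitive: dict[str, list[str]] = {}
    for i, drug in enumerate(drugs):
        mu = rng.uniform(*mu_range)
        sigma = rng.uniform(*sigma_range)
        row = rng.normal(mu, sigma, size=n_cells)
        picked = rng.choice(n_cells, size=2 * n_tail, replace=False)
        res_idx, sen_idx = picked[:n_tail], picked[n_tail:]
        row[res_idx] += tail_shift * sigma
        row[sen_idx] -= tail_shift * sigma
        gi50[i] = row
        resistant[drug] = sorted(cells[j] for j in res_idx)
        sensitive[drug] = sorted(cells[j] for j in sen_idx)
    truth = PlantedTruth(
        resistant=resistant,
        sensitive=sensitive,
        generator_params={
            "n_drugs": n_drugs,
            "n_cells": n_cells,
            "tail_fraction": tail_fraction,
            "tail_shift": tail_shift,
            "mu_range": list(mu_range),
            "sigma_range": list(sigma_range),
            "seed": seed,
        },
    )
    return (
        DoseResponseMatrix(pd.DataFrame(gi50, index=drugs, columns=cells)),
        truth,
    )


def generate_expression(
    n_genes: int,
    truth: PlantedTruth,
    dose: DoseResponseMatrix,
    n_planted: int,
    effect: float,
    sigma: float = 1.0,
    seed: int = 0,
    gi50_coupling: Optional[float] = None,
) -> ExpressionMatrix:
    """Simulate a genes × cells expression matrix with planted REM genes.

    Background genes are iid Normal(0, σ) per cell. Each planted gene is
    assigned a drug and a sign; it receives a mean shift ``sign·effect`` in
    that drug's planted-resistant cells and, in every cell, an additional
    ``sign·gi50_coupling·z`` where z is the cell's standardized GI50
    deviation for the drug (default coupling: effect/2), so planted genes
    both separate the groups and track GI50. The planted table (gene, drug,
    sign, effect) is recorded on ``truth``.
    """
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    cells = dose.cell_ids
    known = set(cells)
    for d, grp in list(truth.resistant.items()) + list(truth.sensitive.items()):
        unknown = set(grp) - known
        if unknown:
            raise ValueError(f"truth references unknown cell(s) {sorted(unknown)} for {d}")
    if gi50_coupling is None:
        gi50_coupling = effect / 2.0
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    X = rng.normal(0.0, sigma, size=(n_genes, len(cells)))
    drugs = sorted(truth.resistant)
    if not drugs and n_planted > 0:
        raise ValueError("truth contains no planted groups")
    cell_pos = {c: j for j, c in enumerate(cells)}
    planted_rows = []
    z_cache: dict[str, np.ndarray] = {}
    for g in range(n_planted):
        drug = drugs[int(rng.integers(len(drugs)))]
        sign = int(rng.choice((-1, 1)))
        if drug not in z_cache:
            row = dose.row(drug)
            z = (row - row.mean()) / row.std(ddof=1)
            z_cache[drug] = z.fillna(0.0).to_numpy()
        X[g] += sign * gi50_coupling * z_cache[drug]
        res_pos = [cell_pos[c] for c in truth.resistant[drug]]
        X[g, res_pos] += sign * effect
        planted_rows.append((genes[g], drug, sign, effect))
    truth.planted_genes = pd.DataFrame(
        planted_rows, columns=["gene_id", "drug_id", "sign", "effect"]
    )
    truth.generator_params.update(
        {
            "n_genes": n_genes,
            "n_planted": n_planted,
            "effect": effect,
            "sigma": sigma,
            "gi50_coupling": gi50_coupling,
            "expression_seed": seed,
        }
    )
    labels = {c: c for c in cells}
    return ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=cells), sample_labels=labels
    )


def generate_induction_experiment(
    rem_signature: Union[SignatureVector, ResponseEngineeringModule, pd.Series],
    target_correlation: float,
    n_replicates: int = 3,
    noise: float = 0.25,
    seed: int = 0,
    amplitude: float = 1.0,
) -> ExpressionMatrix:
    """Simulate control/induced replicates matched to a REM v-vector.

    Per-gene induced-minus-control shifts are built as
    ``c·ṽ + √(1−c²)·sd(ṽ)·ε`` (ṽ the centered REM v-vector, ε iid standard
    normal), then rescaled to SD ``amplitude`` — their population
    correlation with the v-vector is the target ``c``. Replicate columns
    add iid Normal(0, noise) within-arm variation.
    """
    if abs(target_correlation) > 1:
        raise ValueError("|target_correlation| must be ≤ 1")
    if n_replicates < 2:
        raise ValueError("need ≥2 replicates per arm for a t-test")
    if isinstance(rem_signature, SignatureVector):
        v = rem_signature.table["v"]
    elif isinstance(rem_signature, ResponseEngineeringModule):
        v = rem_signature.table["v_rem"]
    else:
        v = rem_signature
    v = v.astype(float)
    rng = np.random.default_rng(seed)
    c = float(target_correlation)
    vc = v.to_numpy() - v.mean()
    sd_v = vc.std()
    if sd_v == 0 and c != 0:
        raise ValueError("REM v-vector has zero variance; target correlation unreachable")
    delta = c * vc + math.sqrt(1.0 - c**2) * sd_v * rng.standard_normal(v.size)
    sd_d = delta.std()
    if sd_d > 0:
        delta = delta / sd_d * amplitude
    ctrl = rng.normal(0.0, noise, size=(v.size, n_replicates))
    ind = delta[:, None] + rng.normal(0.0, noise, size=(v.size, n_replicates))
    cols = [f"ctrl_{i + 1}" for i in range(n_replicates)] + [
        f"ind_{i + 1}" for i in range(n_replicates)
    ]
    labels = {f"ctrl_{i + 1}": "control" for i in range(n_replicates)}
    labels.update({f"ind_{i + 1}": "induced" for i in range(n_replicates)})
    return ExpressionMatrix(
        pd.DataFrame(np.hstack([ctrl, ind]), index=v.index, columns=cols),
        sample_labels=labels,
    )
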