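"""Resistant/sensitive classification of cell lines per drug.

Two published rules are supported and never reconciled with each other:

* **sd rule** — a cell line is resistant when its log10 GI50 lies at least
  ``multiplier`` sample standard deviations above the drug's mean (more drug
  needed for 50% inhibition), sensitive when at least that far below.
* **fold rule** — a cell line is resistant when its GI50 is at least
  ``fold``-fold above the per-drug average; on the log10 scale this is
  ``gi50 − mean ≥ log10(fold)`` (the mean of log10 values, i.e. fold change
  relative to the geometric-mean GI50).

Missing GI50 entries exclude a cell line from the drug's mean/SD and from
grouping, nothing more.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DoseResponseMatrix, ExpressionMatrix, RunConfig, SensitivityGroups

log = logging.getLogger(__name__)


def classify_by_sd(
    drug_id: str, gi50_row: pd.Series, multiplier: float = 0.8
) -> Optional[SensitivityGroups]:
    """Classify cells by the ±multiplier·SD rule; None when <3 values present."""
    row = gi50_row.dropna()
    if len(row) < 3:
        log.info(
            "drug %s skipped: only %d GI50 value(s) present (need ≥3 for SD)",
            drug_id,
            len(row),
        )
        return None
    mean = float(row.mean())
    sd = float(row.std(ddof=1))
    cutoff = multiplier * sd
    if cutoff > 0:
        resistant = sorted(row.index[row >= mean + cutoff])
        sensitive = sorted(row.index[row <= mean - cutoff])
    else:
        # degenerate threshold (multiplier 0 or all values equal): strict
        # inequalities keep cells exactly at the mean unassigned
        resistant = sorted(row.index[row > mean])
        sensitive = sorted(row.index[row < mean])
    return SensitivityGroups(
        drug_id=drug_id,
        resistant=resistant,
        sensitive=sensitive,
        rule="sd",
        threshold_used=multiplier,
        mean_gi50=mean,
        sd_gi50=sd,
    )


def classify_by_fold(
    drug_id: str, gi50_row: pd.Series, fold: float = 6.0
) -> Optional[SensitivityGroups]:
    """Classify cells by ≥fold-fold deviation from the geometric-mean GI50."""
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    row = gi50_row.dropna()
    if len(row) < 2:
        log.info("drug %s skipped: fewer than 2 GI50 values present", drug_id)
        return None
    mean = float(row.mean())
    cut = math.log10(fold)
    resistant = sorted(row.index[row - mean >= cut])
    sensitive = sorted(row.index[mean - row >= cut])
    return SensitivityGroups(
        drug_id=drug_id,
        resistant=resistant,
        sensitive=sensitive,
        rule="fold",
        threshold_used=fold,
        mean_gi50=mean,
    )


def classify_all(
    dose: DoseResponseMatrix, config: RunConfig
) -> list[SensitivityGroups]:
    """Apply the configured rule to every drug; drugs with too few values skipped."""
    out = []
    for drug_id in dose.drug_ids:
        row = dose.row(drug_id)
        if config.classification_rule == "sd":
            g = classify_by_sd(drug_id, row, config.sd_multiplier)
        else:
            g = classify_by_fold(drug_id, row, config.fold_threshold)
        if g is not None:
            out.append(g)
    return out


def filter_drugs(
    groups: list[SensitivityGroups], min_size: int = 6
) -> list[SensitivityGroups]:
    """Keep drugs with at least ``min_size`` resistant AND sensitive cells."""
    kept = [
        g
        for g in groups
        if len(g.resistant) >= min_size and len(g.sensitive) >= min_size
    ]
    log.info(
        "group-size filter (≥%d/≥%d): kept %d of %d drugs",
        min_size,
        min_size,
        len(kept),
        len(groups),
    )
    return kept


def rank_cells_by_gene(
    expr: ExpressionMatrix, gene_id: str, k: int
) -> tuple[list[str], list[str]]:
    """Top-k (high expression) and bottom-k (low) cells for one gene.

    Ties are broken by cell identifier (lexicographic) so the partition is
    deterministic.
    """
    if gene_id not in expr.values.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    n = len(expr.sample_ids)
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds the {n} available cells")
    df = pd.DataFrame(
        {"value": expr.values.loc[gene_id], "cell": expr.sample_ids}
    ).sort_values(["value", "cell"], ascending=[False, True], kind="mergesort")
    cells = df["cell"].tolist()
    return cells[:k], cells[-k:]


def compare_group_response(
    high: list[str], low: list[str], gi50_row: pd.Series
) -> Optional[tuple[float, float]]:
    """Mean GI50 difference (high − low) and two-sample t-test P for one drug."""
    a = gi50_row.reindex(high).dropna()
    b = gi50_row.reindex(low).dropna()
    if len(a) < 2 or len(b) < 2:
        log.info("drug %s skipped: <2 present GI50 values in a group", gi50_row.name)
        return None
    delta = float(a.mean() - b.mean())
    res = stats.ttest_ind(a.to_numpy(), b.to_numpy(), equal_var=True)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0 if delta == 0 else float(np.finfo(float).tiny)
    return delta, p
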