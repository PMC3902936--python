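"""Construction of drug-specific response engineering modules (REM).

A REM (resistance-minus-sensitive) is the gene signature separating a
drug's resistant cell lines from its sensitive ones under two criteria:

(i)  the gene's expression differs significantly between the resistant and
     sensitive groups (two-sample t-test, p < alpha), and
(ii) the gene's expression significantly correlates with log10 GI50 across
     the grouped cells (Pearson by default, Spearman selectable; two-sided
     p < alpha via the t-transform of r).

Positive ``v_rem`` means the gene is higher in resistant cells. Q-values
for the group test are reported for transparency but never filter genes.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    ResponseEngineeringModule,
    SensitivityGroups,
    SignatureVector,
)
from .stats import storey_qvalues, two_group_test, v_statistic

log = logging.getLogger(__name__)


def correlation_with_gi50(
    expr_values: pd.DataFrame, gi50: pd.Series, method: str = "pearson"
) -> pd.DataFrame:
    """Per-gene correlation of expression with GI50 plus two-sided p.

    Vectorised across genes; the p-value uses the exact t-transform
    t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    cells = list(gi50.index)
    X = expr_values[cells].to_numpy(dtype=float)
    y = gi50.to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need ≥3 cells for a correlation test")
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        y = stats.rankdata(y)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1)) * np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    zero_var = ~np.isfinite(r)
    r[zero_var] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0  # |r| = 1 exactly
    p[zero_var] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"r_gi50": r, "p_gi50": p}, index=expr_values.index)


def build_rem(
    expr: ExpressionMatrix,
    groups: SensitivityGroups,
    gi50_row: pd.Series,
    alpha: float = 0.05,
    min_group_size: int = 6,
    method: str = "pearson",
    equal_var: bool = True,
) -> ResponseEngineeringModule:
    """Build the REM for one drug from its sensitivity groups.

    Genes with any missing expression value over the grouped cells are
    dropped from the contrast. An empty REM is a valid (logged) outcome.
    """
    res, sen = list(groups.resistant), list(groups.sensitive)
    if len(res) < min_group_size or len(sen) < min_group_size:
        raise ValueError(
            f"drug {groups.drug_id}: groups too small "
            f"({len(res)} resistant / {len(sen)} sensitive, need ≥{min_group_size} each)"
        )
    cells = res + sen
    missing_cells = set(cells) - set(expr.values.columns)
    if missing_cells:
        raise ValueError(
            f"drug {groups.drug_id}: grouped cell(s) missing from expression "
            f"matrix: {sorted(missing_cells)}"
        )
    sub = expr.values[cells]
    complete = sub.notna().all(axis=1)
    if not complete.all():
        log.info(
            "drug %s: dropping %d gene(s) with missing expression",
            groups.drug_id,
            int((~complete).sum()),
        )
        sub = sub.loc[complete]
    sub_expr = ExpressionMatrix(sub)

    gi50 = gi50_row.reindex(cells)
    if gi50.isna().any():
        raise ValueError(
            f"drug {groups.drug_id}: grouped cell(s) lack GI50 values: "
            f"{sorted(gi50.index[gi50.isna()])}"
        )

    group_stats = two_group_test(sub_expr, res, sen, equal_var=equal_var)
    q, _ = storey_qvalues(group_stats["p"].to_numpy())
    corr_stats = correlation_with_gi50(sub, gi50, method=method)

    table = group_stats.join(corr_stats)
    table["q_group"] = q
    table["v_rem"] = v_statistic(table["p"].to_numpy(), table["s"].to_numpy())
    passing = (table["p"] < alpha) & (table["p_gi50"] < alpha)
    rem_table = table.loc[
        passing, ["v_rem", "p", "q_group", "r_gi50", "p_gi50", "mean_diff"]
    ].rename(columns={"p": "p_group"})
    if rem_table.empty:
        log.info("drug %s: REM is empty at alpha=%g", groups.drug_id, alpha)
    return ResponseEngineeringModule(
        drug_id=groups.drug_id,
        table=rem_table,
        n_resistant=len(res),
        n_sensitive=len(sen),
        alpha=alpha,
    )


def rem_v_vector(
    rem: ResponseEngineeringModule, signature: SignatureVector
) -> pd.DataFrame:
    """Pair each REM gene's v_rem with the signature's v, in stable REM order."""
    if len(rem) == 0:
        raise ValueError(f"drug {rem.drug_id}: REM is empty, nothing to pair")
    sig_genes = set(signature.table.index)
    keep = [g for g in rem.genes if g in sig_genes]
    dropped = len(rem) - len(keep)
    if dropped:
        log.warning(
            "drug %s: %d REM gene(s) absent from signature %s, dropped",
            rem.drug_id,
            dropped,
            signature.contrast_id,
        )
    if not keep:
        raise ValueError(
            f"drug {rem.drug_id}: no REM genes present in signature "
            f"{signature.contrast_id}"
        )
    return pd.DataFrame(
        {
            "v_rem": rem.table.loc[keep, "v_rem"],
            "v_sig": signature.table.loc[keep, "v"],
        },
        index=pd.Index(keep, name="gene_id"),
    )
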