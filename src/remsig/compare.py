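"""Matching induction signatures against drug REMs, and clustered heatmaps.

The headline statistic is the Pearson correlation between a factor's
induction signature (v per gene, induced minus control) and a drug's REM
v-vector over the REM genes. A significant *negative* correlation predicts
that inducing the factor pushes cells toward the sensitive expression
state (sensitization on induction); a significant positive correlation
predicts sensitization on repression.

Heatmaps use two-dimensional unsupervised hierarchical clustering with
average linkage on the uncentered-correlation distance (the convention of
the classic Eisen-lab clustering software), computed pairwise-complete so
missing GI50 entries are tolerated and rendered white.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import (
    CALL_SENSITIZE_ON_INDUCTION,
    CALL_SENSITIZE_ON_REPRESSION,
    NO_CALL,
    ClusterView,
    ComparisonResult,
    DoseResponseMatrix,
    ExpressionMatrix,
    ResponseEngineeringModule,
    SignatureVector,
)
from .rem import rem_v_vector

log = logging.getLogger(__name__)


def correlate_signatures(
    paired: pd.DataFrame,
    alpha: float = 0.001,
    drug_id: str = "",
    factor_id: str = "",
) -> ComparisonResult:
    """Pearson correlation of paired (v_rem, v_sig) values with a direction call.

    ``call`` is sensitization-on-induction when r < 0 with p < alpha
    (the induction opposes the resistance signature), sensitization-on-
    repression when r > 0 with p < alpha, otherwise no_call.
    """
    if len(paired) < 3:
        raise ValueError(f"need ≥3 gene pairs, got {len(paired)}")
    x = paired["v_rem"].to_numpy(dtype=float)
    y = paired["v_sig"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.info(
            "drug %s / factor %s: zero variance in a v-vector, correlation undefined",
            drug_id,
            factor_id,
        )
        return ComparisonResult(drug_id, factor_id, len(paired), np.nan, np.nan, NO_CALL)
    res = stats.pearsonr(x, y)
    r, p_r = float(res.statistic), float(res.pvalue)
    if p_r < alpha and r < 0:
        call = CALL_SENSITIZE_ON_INDUCTION
    elif p_r < alpha and r > 0:
        call = CALL_SENSITIZE_ON_REPRESSION
    else:
        call = NO_CALL
    return ComparisonResult(drug_id, factor_id, len(paired), r, p_r, call)


def screen_factor(
    induction: SignatureVector,
    rems: list[ResponseEngineeringModule],
    alpha: float = 0.001,
) -> list[ComparisonResult]:
    """Compare one induction signature against many REMs, sorted by r ascending."""
    if not rems:
        raise ValueError("need at least one REM")
    out = []
    for rem in rems:
        try:
            paired = rem_v_vector(rem, induction)
        except ValueError as exc:
            log.info("drug %s skipped in screen: %s", rem.drug_id, exc)
            continue
        if len(paired) < 3:
            log.info("drug %s skipped in screen: <3 shared genes", rem.drug_id)
            continue
        out.append(
            correlate_signatures(
                paired, alpha=alpha, drug_id=rem.drug_id, factor_id=induction.contrast_id
            )
        )
    out.sort(key=lambda c: (np.inf if np.isnan(c.r) else c.r, c.drug_id))
    return out


def uncentered_correlation_distance(values: np.ndarray) -> np.ndarray:
    """Pairwise-complete uncentered-correlation distance between rows.

    d(x, y) = 1 − Σxy / (√Σx² · √Σy²) over the positions where both rows
    are present. Rows are expected pre-filtered so every pair overlaps in
    ≥2 positions.
    """
    X = np.asarray(values, dtype=float)
    M = np.isfinite(X).astype(float)
    X0 = np.where(np.isfinite(X), X, 0.0)
    cross = X0 @ X0.T
    xx = (X0**2) @ M.T  # Σx² over positions present in the *other* row too
    yy = M @ (X0**2).T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - cross / np.sqrt(xx * yy)
    d[~np.isfinite(d)] = 1.0  # zero-norm overlap: maximally dissimilar
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    return d


def _drop_sparse_rows(df: pd.DataFrame, axis_name: str) -> pd.DataFrame:
    """Drop rows lacking ≥2 pairwise-complete overlaps with every other row."""
    present = df.notna().to_numpy().astype(float)
    overlap = present @ present.T
    np.fill_diagonal(overlap, np.inf)
    bad = (overlap < 2).all(axis=1) if len(df) > 1 else np.zeros(len(df), bool)
    if bad.any():
        log.warning(
            "dropping %d %s(s) without enough pairwise-complete overlap",
            int(bad.sum()),
            axis_name,
        )
        df = df.loc[~bad]
    return df


def cluster_heatmap(
    matrix: Union[DoseResponseMatrix, ExpressionMatrix, pd.DataFrame],
) -> ClusterView:
    """Two-dimensional average-linkage clustering on uncentered correlation.

    Rows and columns are pre-sorted lexicographically before linkage so the
    leaf ordering is a pure function of the values, not of input order.
    """
    if isinstance(matrix, DoseResponseMatrix):
        df = matrix.gi50
    elif isinstance(matrix, ExpressionMatrix):
        df = matrix.values
    else:
        df = matrix
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need ≥2 rows and ≥2 columns to cluster")
    df = df.sort_index(axis=0).sort_index(axis=1)
    df = _drop_sparse_rows(df, "row")
    df = _drop_sparse_rows(df.T, "column").T

    def _linkage_and_order(values: np.ndarray, labels: pd.Index):
        d = uncentered_correlation_distance(values)
        Z = hierarchy.linkage(squareform(d, checks=False), method="average")
        order = hierarchy.leaves_list(Z)
        return Z, [labels[i] for i in order]

    row_Z, row_order = _linkage_and_order(df.to_numpy(), df.index)
    col_Z, col_order = _linkage_and_order(df.to_numpy().T, df.columns)
    return ClusterView(
        matrix=df.loc[row_order, col_order],
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_Z,
        col_linkage=col_Z,
    )


def render_heatmap(
    view: ClusterView, path, cmap: str = "RdBu_r", title: Optional[str] = None
) -> None:
    """Write the reordered matrix as a heatmap image; missing cells are white."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.ma.masked_invalid(view.matrix.to_numpy(dtype=float))
    fig, ax = plt.subplots(
        figsize=(
            max(4.0, 0.08 * view.matrix.shape[1] + 1),
            max(4.0, 0.03 * view.matrix.shape[0] + 1),
        )
    )
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("white")
    im = ax.imshow(data, aspect="auto", cmap=cm, interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.6)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
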