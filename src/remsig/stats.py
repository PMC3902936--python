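"""Per-gene two-group statistics and the signed v statistic.

The v statistic condenses a gene's differential expression between two cell
groups into a single signed number ``v = s·(1 − P)``, where ``P`` is the
two-sided Student's t-test P-value and ``s`` the sign of the mean
difference: v approaches +1 (−1) for strongly up- (down-) regulated genes
and is 0 when there is no evidence of a difference. False-discovery rates
use the Storey–Tibshirani q-value estimator with a spline-smoothed π0.

Candidate gene sets are judged against a *random expectation*: the mean
number of nominally differential genes over random same-size sets, compared
by a 1-df chi-square (with an exact binomial cross-check).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .containers import ExpressionMatrix, GeneSet, GeneSetNullResult, SignatureVector

log = logging.getLogger(__name__)

_TINY = float(np.finfo(float).tiny)


def two_group_test(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per gene (a minus b).

    Returns a DataFrame indexed by gene with columns ``mean_diff``, ``s``
    and ``p``. Degenerate genes (zero variance in both groups) get p = 1 /
    s = 0 when the means agree, else the smallest positive p.
    """
    group_a, group_b = list(group_a), list(group_b)
    for name, grp in (("a", group_a), ("b", group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {name} needs ≥2 samples, got {len(grp)}")
        missing = set(grp) - set(expr.values.columns)
        if missing:
            raise ValueError(f"group {name} references unknown sample(s): {sorted(missing)}")
    a = expr.values[group_a].to_numpy(dtype=float)
    b = expr.values[group_b].to_numpy(dtype=float)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    s = np.sign(mean_diff)
    degenerate = ~np.isfinite(p) | (p == 0.0)
    if degenerate.any():
        equal_means = degenerate & (mean_diff == 0.0)
        p[equal_means] = 1.0
        s[equal_means] = 0.0
        sep = degenerate & (mean_diff != 0.0)
        if sep.any():
            log.info(
                "%d gene(s) with zero within-group variance but unequal means; "
                "p set to smallest positive float",
                int(sep.sum()),
            )
            p[sep] = _TINY
    p = np.clip(p, _TINY, 1.0)
    return pd.DataFrame(
        {"mean_diff": mean_diff, "s": s, "p": p}, index=expr.values.index
    )


def v_statistic(
    p: Union[float, np.ndarray], s: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Signed differential score v = s·(1 − p) ∈ [−1, 1]."""
    p_arr = np.asarray(p, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    if ((p_arr <= 0) | (p_arr > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if not np.isin(s_arr, (-1.0, 0.0, 1.0)).all():
        raise ValueError("signs must be −1, 0 or +1")
    v = s_arr * (1.0 - p_arr)
    return float(v) if np.isscalar(p) and np.isscalar(s) else v


_LAMBDA_GRID = np.arange(0.0, 0.901, 0.05)


def storey_pi0(p_values: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Estimate the null proportion π0 by spline extrapolation to λ = 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    spline = interpolate.CubicSpline(lambdas, pi0_lambda, bc_type="natural")
    pi0 = float(spline(1.0))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(
    p_values: Sequence[float], pi0: Optional[float] = None
) -> tuple[np.ndarray, float]:
    """Storey–Tibshirani q-values.

    With fewer than 100 p-values the spline π0 estimate is unstable and π0
    falls back to 1 (conservative; q-values then equal Benjamini–Hochberg
    adjusted p-values). Returns (q, π0).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), 1.0
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            log.info("only %d p-values: π0 fixed at 1 (BH-equivalent)", m)
            pi0 = 1.0
        else:
            pi0 = storey_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("π0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    # enforce monotonicity: q_i = min over j with p_j ≥ p_i
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def make_signature(
    contrast_id: str,
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    equal_var: bool = True,
) -> SignatureVector:
    """Full signed signature (a minus b): mean_diff, s, p, q, v per gene."""
    table = two_group_test(expr, group_a, group_b, equal_var=equal_var)
    q, pi0 = storey_qvalues(table["p"].to_numpy())
    table["q"] = q
    table["v"] = v_statistic(table["p"].to_numpy(), table["s"].to_numpy())
    return SignatureVector(contrast_id=contrast_id, table=table, pi0=pi0)


def induction_signature(
    expr: ExpressionMatrix,
    control: Sequence[str],
    induced: Sequence[str],
    alpha: float = 0.01,
    fdr_max: float = 0.10,
    equal_var: bool = True,
    contrast_id: str = "induction",
) -> tuple[SignatureVector, int, int]:
    """Induced-minus-control signature plus counts of significant genes.

    A gene counts as regulated when p < alpha AND q < fdr_max; the counts
    are split by the sign of the induced-minus-control mean difference.
    Returns (signature, n_up, n_down).
    """
    sig = make_signature(
        contrast_id, expr, list(induced), list(control), equal_var=equal_var
    )
    passing = (sig.table["p"] < alpha) & (sig.table["q"] < fdr_max)
    n_up = int((passing & (sig.table["s"] > 0)).sum())
    n_down = int((passing & (sig.table["s"] < 0)).sum())
    return sig, n_up, n_down


def gene_set_null_test(
    signature: SignatureVector,
    gene_set: GeneSet,
    alpha: float = 0.05,
    n_random: int = 10,
    rng: Union[int, np.random.Generator, None] = None,
    drug_id: Optional[str] = None,
) -> GeneSetNullResult:
    """Compare a gene set's differential count with random expectation.

    ``n_random`` same-size sets are drawn uniformly without replacement from
    all genes in the signature; the mean count of members with p < alpha is
    the *random expectation* E. The observed count O is compared with E by a
    1-df chi-square on the {differential, non-differential} split; an exact
    two-sided binomial test with success probability E/k is reported as a
    cross-check. ``reliable`` is False when an expected cell is < 1.
    """
    rng = np.random.default_rng(rng)
    all_genes = signature.table.index
    members = [g for g in gene_set.genes if g in set(all_genes)]
    dropped = len(gene_set.genes) - len(members)
    if dropped:
        log.warning(
            "gene set %s: %d member(s) absent from the signature, dropped",
            gene_set.name,
            dropped,
        )
    if not members:
        raise ValueError(
            f"gene set {gene_set.name!r} has no members in the signature"
        )
    k = len(members)
    p = signature.table["p"]
    observed = int((p.loc[members] < alpha).sum())
    m = len(all_genes)
    p_arr = p.to_numpy()
    counts = [
        int((p_arr[rng.choice(m, size=k, replace=False)] < alpha).sum())
        for _ in range(n_random)
    ]
    expected = float(np.mean(counts))
    expected = min(max(expected, 0.0), float(k))  # keep both cells defined
    if expected in (0.0, float(k)):
        # degenerate expectation: chi-square undefined on a zero cell
        chi2 = np.inf if observed != expected else 0.0
        p_chi2 = 0.0 if observed != expected else 1.0
        reliable = False
    else:
        chi2 = (observed - expected) ** 2 / expected + (
            (k - observed) - (k - expected)
        ) ** 2 / (k - expected)
        p_chi2 = float(stats.chi2.sf(chi2, df=1))
        reliable = min(expected, k - expected) >= 1.0
    p_binom = float(stats.binomtest(observed, k, min(expected / k, 1.0)).pvalue)
    return GeneSetNullResult(
        drug_id=drug_id or signature.contrast_id,
        set_name=gene_set.name,
        set_size=k,
        observed_count=observed,
        expected_count=expected,
        n_random_sets=n_random,
        chi2=float(chi2),
        p_chi2=p_chi2,
        p_binomial=p_binom,
        reliable=reliable,
    )


def min_set_p(signature: SignatureVector, gene_set: GeneSet) -> float:
    """Smallest member p-value: 'at least one set gene differential' report."""
    members = [g for g in gene_set.genes if g in set(signature.table.index)]
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} absent from signature")
    return float(signature.table.loc[members, "p"].min())
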