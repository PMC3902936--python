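"""Core in-memory containers for the drug-response re-engineering pipeline.

All matrices are thin wrappers around :class:`pandas.DataFrame` with the
orientation fixed by convention: dose–response matrices are drugs × cell
lines (log10 molar GI50, NaN = not assayed), expression matrices are
genes × samples (already on a log scale). Resistant always means *high*
GI50 — more drug is needed for 50% growth inhibition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseMatrix",
    "ExpressionMatrix",
    "GeneSet",
    "RunConfig",
    "SensitivityGroups",
    "SignatureVector",
    "GeneSetNullResult",
    "ResponseEngineeringModule",
    "ComparisonResult",
    "ClusterView",
    "PlantedTruth",
]


def _check_unique(labels, kind: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {kind} identifier(s): {dup}")


@dataclass
class DoseResponseMatrix:
    """log10 GI50 values, drugs × cell lines; NaN marks a missing assay."""

    gi50: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.gi50.index, "drug")
        _check_unique(self.gi50.columns, "cell")
        if self.gi50.shape[0] < 1 or self.gi50.shape[1] < 2:
            raise ValueError("need at least 1 drug and 2 cell lines")
        vals = self.gi50.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("GI50 entries must be finite or missing (NaN)")
        self.gi50 = self.gi50.astype(float)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.gi50.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.gi50.columns)

    def row(self, drug_id: str) -> pd.Series:
        return self.gi50.loc[drug_id]


@dataclass
class ExpressionMatrix:
    """Expression values (log scale), genes × samples.

    ``sample_labels`` optionally maps sample → group label (a cell line for
    panel data, or ``control``/``induced`` for an induction experiment).
    """

    values: pd.DataFrame
    sample_labels: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.sample_labels is not None:
            unknown = set(self.sample_labels) - set(self.values.columns)
            if unknown:
                raise ValueError(
                    f"label(s) refer to unknown sample(s): {sorted(unknown)}"
                )
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_with_label(self, label: str) -> list[str]:
        if self.sample_labels is None:
            return []
        return [s for s in self.sample_ids if self.sample_labels.get(s) == label]


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"member (set {self.name!r})")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RunConfig:
    """Thresholds and knobs for the full pipeline.

    Defaults mirror the published analysis: 0.8-SD grouping, ≥6 cells per
    group, per-gene alpha 0.05, induction filter P<0.01 with FDR<10%,
    10 random gene sets for the chi-square null, top/bottom 15 ranking.
    """

    classification_rule: str = "sd"  # "sd" or "fold"
    sd_multiplier: float = 0.8
    fold_threshold: float = 6.0
    min_group_size: int = 6
    alpha_gene: float = 0.05
    alpha_induction: float = 0.01
    fdr_max: float = 0.10
    n_random_sets: int = 10
    rank_group_size: int = 15
    alpha_rem: float = 0.05
    alpha_call: float = 0.001
    equal_var: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classification_rule not in ("sd", "fold"):
            raise ValueError("classification_rule must be 'sd' or 'fold'")
        for name in ("sd_multiplier", "fold_threshold", "fdr_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be ≥ 2")
        for name in ("alpha_gene", "alpha_induction", "alpha_rem", "alpha_call"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_random_sets < 1:
            raise ValueError("n_random_sets must be ≥ 1")
        if self.rank_group_size < 1:
            raise ValueError("rank_group_size must be ≥ 1")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SensitivityGroups:
    """Resistant/sensitive cell groups for one drug plus the rule that made them."""

    drug_id: str
    resistant: list[str]
    sensitive: list[str]
    rule: str  # "sd" or "fold"
    threshold_used: float
    mean_gi50: float
    sd_gi50: Optional[float] = None  # sd rule only

    def __post_init__(self) -> None:
        overlap = set(self.resistant) & set(self.sensitive)
        if overlap:
            raise ValueError(f"cells in both groups: {sorted(overlap)}")

    @property
    def cells(self) -> list[str]:
        return list(self.resistant) + list(self.sensitive)


@dataclass
class SignatureVector:
    """Per-gene signed differential statistics for one two-group contrast.

    ``table`` is indexed by gene with columns ``mean_diff``, ``s`` (sign of
    the mean difference), ``p`` (two-sided t-test), ``q`` (Storey–Tibshirani)
    and ``v`` = s·(1−p) ∈ [−1, 1].
    """

    contrast_id: str
    table: pd.DataFrame
    pi0: float = 1.0

    REQUIRED = ("mean_diff", "s", "p", "q", "v")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"signature table lacks column(s) {missing}")
        _check_unique(self.table.index, "gene")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def v(self) -> pd.Series:
        return self.table["v"]

    @property
    def p(self) -> pd.Series:
        return self.table["p"]


@dataclass
class GeneSetNullResult:
    """A gene set's differential-expression count versus random expectation."""

    drug_id: str
    set_name: str
    set_size: int
    observed_count: int
    expected_count: float
    n_random_sets: int
    chi2: float
    p_chi2: float
    p_binomial: float
    reliable: bool  # False when an expected cell < 1 (chi-square approximation poor)

    def __post_init__(self) -> None:
        if self.observed_count > self.set_size:
            raise ValueError("observed_count exceeds set size")
        if self.expected_count < 0:
            raise ValueError("expected_count must be ≥ 0")


@dataclass
class ResponseEngineeringModule:
    """Drug-specific REM (resistance-minus-sensitive signature).

    ``table`` is indexed by the genes passing BOTH criteria, with columns
    ``v_rem`` (signed, positive = higher in resistant), ``p_group``, ``q_group``,
    ``r_gi50`` and ``p_gi50``.
    """

    drug_id: str
    table: pd.DataFrame
    n_resistant: int
    n_sensitive: int
    alpha: float

    def __post_init__(self) -> None:
        for c in ("v_rem", "r_gi50", "p_gi50"):
            if c not in self.table.columns:
                raise ValueError(f"REM table lacks column {c!r}")
        if len(self.table) and (self.table["r_gi50"].abs() > 1 + 1e-12).any():
            raise ValueError("|r_gi50| must be ≤ 1")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


# Direction calls for signature comparison.
CALL_SENSITIZE_ON_INDUCTION = "predict_sensitization_on_induction"
CALL_SENSITIZE_ON_REPRESSION = "predict_sensitization_on_repression"
NO_CALL = "no_call"


@dataclass
class ComparisonResult:
    drug_id: str
    factor_id: str
    n_genes: int
    r: float
    p_r: float
    call: str

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be ≤ 1")
        allowed = {CALL_SENSITIZE_ON_INDUCTION, CALL_SENSITIZE_ON_REPRESSION, NO_CALL}
        if self.call not in allowed:
            raise ValueError(f"unknown call {self.call!r}")


@dataclass
class ClusterView:
    """Result of two-dimensional hierarchical clustering of a matrix."""

    matrix: pd.DataFrame  # reordered values
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


@dataclass
class PlantedTruth:
    """Ground truth recorded by the synthetic generators.

    ``resistant``/``sensitive`` map drug → planted cell lists; ``planted_genes``
    is a table (gene_id, drug_id, sign, effect) filled in by the expression
    generator; ``target_correlation`` is the induction generator's population
    correlation with the REM v-vector.
    """

    resistant: dict[str, list[str]] = field(default_factory=dict)
    sensitive: dict[str, list[str]] = field(default_factory=dict)
    planted_genes: Optional[pd.DataFrame] = None
    target_correlation: Optional[float] = None
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in self.resistant:
            overlap = set(self.resistant[d]) & set(self.sensitive.get(d, []))
            if overlap:
                raise ValueError(f"drug {d}: planted groups overlap: {sorted(overlap)}")
        if self.target_correlation is not None and abs(self.target_correlation) > 1:
            raise ValueError("|target_correlation| must be ≤ 1")

    def planted_for(self, drug_id: str) -> pd.DataFrame:
        if self.planted_genes is None:
            return pd.DataFrame(columns=["gene_id", "drug_id", "sign", "effect"])
        return self.planted_genes[self.planted_genes["drug_id"] == drug_id]

    def to_json(self) -> str:
        payload = {
            "resistant": self.resistant,
            "sensitive": self.sensitive,
            "planted_genes": (
                None
                if self.planted_genes is None
                else self.planted_genes.to_dict(orient="list")
            ),
            "target_correlation": self.target_correlation,
            "generator_params": self.generator_params,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        payload = json.loads(text)
        pg = payload.get("planted_genes")
        cols = ["gene_id", "drug_id", "sign", "effect"]
        return cls(
            resistant=payload["resistant"],
            sensitive=payload["sensitive"],
            planted_genes=None if pg is None else pd.DataFrame(pg)[cols],
            target_correlation=payload.get("target_correlation"),
            generator_params=payload.get("generator_params", {}),
        )
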