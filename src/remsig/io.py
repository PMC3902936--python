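"""Readers and writers for on-disk pipeline artifacts.

Matrices travel as tab- or comma-delimited text (first row identifiers,
first column identifiers; empty string or ``NA`` marks a missing GI50);
gene sets as GMT (name, description, members); configuration as flat
``key: value`` text mirroring :class:`~remsig.containers.RunConfig`.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .containers import DoseResponseMatrix, ExpressionMatrix, GeneSet, RunConfig

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_NA_VALUES = ["", "NA"]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_matrix(path: PathLike, kind_row: str, kind_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for labels, kind in ((df.index, kind_row), (df.columns, kind_col)):
        idx = pd.Index(labels)
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate {kind} identifier(s) in {path.name}: {dup}")
    # locate non-numeric cells precisely rather than failing wholesale
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at "
            f"({kind_row} {df.index[r]!r}, {kind_col} {df.columns[c]!r}) in {path.name}"
        )
    return numeric


def read_dose_response(path: PathLike) -> DoseResponseMatrix:
    """Read a drugs × cell-lines log10 GI50 matrix; missing stays missing."""
    return DoseResponseMatrix(_read_matrix(path, "drug", "cell"))


def write_dose_response(dose: DoseResponseMatrix, path: PathLike) -> None:
    dose.gi50.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_expression(
    path: PathLike, label_path: Optional[PathLike] = None
) -> ExpressionMatrix:
    """Read a genes × samples matrix, optionally with a sample→label map."""
    values = _read_matrix(path, "gene", "sample")
    labels = None
    if label_path is not None:
        label_path = Path(label_path)
        if not label_path.exists():
            raise FileNotFoundError(f"label file not found: {label_path}")
        lab = pd.read_csv(
            label_path, sep=_sniff_sep(label_path), header=None, dtype=str
        )
        if lab.shape[1] < 2:
            raise ValueError(f"label file {label_path.name} needs two columns")
        labels = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
    return ExpressionMatrix(values, sample_labels=labels)


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    expr.values.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    if expr.sample_labels:
        lpath = Path(path).with_suffix(".labels.tsv")
        with open(lpath, "w") as fh:
            for s in expr.sample_ids:
                if s in expr.sample_labels:
                    fh.write(f"{s}\t{expr.sample_labels[s]}\n")


def read_gene_sets(path: PathLike) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene-set file not found: {path}")
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs ≥3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    log.warning(
                        "gene set %s: dropping duplicate member %s", name, m
                    )
                seen.setdefault(m)
            sets.append(GeneSet(name=name, genes=list(seen), description=desc))
    return sets


def write_gene_sets(sets: list[GeneSet], path: PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "."] + gs.genes) + "\n")


def read_config(path: PathLike) -> RunConfig:
    """Parse flat ``key: value`` configuration text into a RunConfig."""
    path = Path(path)
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path.name}:{lineno}: expected 'key: value'")
            key, raw = (part.strip() for part in line.split(":", 1))
            if key not in fields:
                raise ValueError(f"{path.name}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce_config_value(key, raw)
    return RunConfig(**kwargs)


def _coerce_config_value(key: str, raw: str):
    defaults = RunConfig()
    current = getattr(defaults, key)
    if isinstance(current, bool):
        if raw.lower() in ("true", "yes", "1"):
            return True
        if raw.lower() in ("false", "no", "0"):
            return False
        raise ValueError(f"config key {key!r}: expected a boolean, got {raw!r}")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw


def write_config(config: RunConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(RunConfig):
            fh.write(f"{f.name}: {getattr(config, f.name)}\n")


# --- result-table serialization (fixed headers, deterministic formatting) ---

_FLOAT_FMT = "%.10g"


def write_groups_table(groups, path: PathLike, kept: Optional[set] = None) -> None:
    """Long-format group table: drug_id, cell_id, group, rule, threshold[, kept]."""
    rows = []
    for g in groups:
        for cell in g.resistant:
            rows.append((g.drug_id, cell, "resistant", g.rule, g.threshold_used))
        for cell in g.sensitive:
            rows.append((g.drug_id, cell, "sensitive", g.rule, g.threshold_used))
    df = pd.DataFrame(
        rows, columns=["drug_id", "cell_id", "group", "rule", "threshold"]
    )
    if kept is not None:
        df["kept"] = df["drug_id"].isin(kept).astype(int)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_groups_table(path: PathLike) -> list:
    """Rebuild SensitivityGroups from a group table (mean/SD not recorded)."""
    from .containers import SensitivityGroups

    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "cell_id": str})
    out = []
    for drug_id, sub in df.groupby("drug_id", sort=True):
        out.append(
            SensitivityGroups(
                drug_id=str(drug_id),
                resistant=sub.loc[sub["group"] == "resistant", "cell_id"].tolist(),
                sensitive=sub.loc[sub["group"] == "sensitive", "cell_id"].tolist(),
                rule=str(sub["rule"].iloc[0]),
                threshold_used=float(sub["threshold"].iloc[0]),
                mean_gi50=float("nan"),
            )
        )
    return out


def write_signature(sig, path: PathLike) -> None:
    df = sig.table[["mean_diff", "s", "p", "q", "v"]].copy()
    df.insert(0, "gene_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_signature(path: PathLike, contrast_id: Optional[str] = None):
    from .containers import SignatureVector

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    return SignatureVector(
        contrast_id=contrast_id or Path(path).stem, table=df
    )


def write_rem(rem, path: PathLike) -> None:
    df = rem.table.copy()
    df.insert(0, "gene_id", df.index)
    df.insert(0, "drug_id", rem.drug_id)
    df["n_resistant"] = rem.n_resistant
    df["n_sensitive"] = rem.n_sensitive
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_rem(path: PathLike):
    from .containers import ResponseEngineeringModule

    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gene_id": str})
    if df.empty:
        raise ValueError(f"REM table {path} is empty")
    return ResponseEngineeringModule(
        drug_id=str(df["drug_id"].iloc[0]),
        table=df.drop(columns=["drug_id", "n_resistant", "n_sensitive"]).set_index(
            "gene_id"
        ),
        n_resistant=int(df["n_resistant"].iloc[0]),
        n_sensitive=int(df["n_sensitive"].iloc[0]),
        alpha=float("nan"),
    )
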