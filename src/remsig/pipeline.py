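"""End-to-end orchestration: classify → signatures → REMs → set tests → matching.

``run_pipeline`` is a pure function of (inputs, config, seed): repeated runs
with identical inputs produce byte-identical output files. All stage output
lands in one run directory as fixed-header TSV tables plus a machine-readable
``summary.json``.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .compare import screen_factor
from .containers import RunConfig
from .grouping import classify_all, filter_drugs
from .rem import build_rem
from .stats import gene_set_null_test, induction_signature, make_signature, min_set_p

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    pass


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(
    config: RunConfig,
    dose_path,
    expr_path,
    genesets_path=None,
    induction_path=None,
    induction_labels_path=None,
    out_dir="remsig_run",
) -> Path:
    """Run every applicable stage and write results under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config)}

    with _stage("read_inputs"):
        dose = io.read_dose_response(dose_path)
        expr = io.read_expression(expr_path)
        gene_sets = io.read_gene_sets(genesets_path) if genesets_path else []
        induction = (
            io.read_expression(induction_path, induction_labels_path)
            if induction_path
            else None
        )

    with _stage("classify"):
        groups_all = classify_all(dose, config)
        kept = filter_drugs(groups_all, config.min_group_size)
        # drugs whose grouped cells lack expression columns cannot proceed
        have_expr = set(expr.values.columns)
        usable = []
        for g in kept:
            missing = set(g.cells) - have_expr
            if missing:
                log.info(
                    "drug %s excluded: no expression for cell(s) %s",
                    g.drug_id,
                    sorted(missing),
                )
            else:
                usable.append(g)
        io.write_groups_table(
            groups_all, out / "groups.tsv", kept={g.drug_id for g in usable}
        )
        summary["n_drugs_input"] = len(dose.drug_ids)
        summary["n_drugs_classified"] = len(groups_all)
        summary["n_drugs_kept"] = len(usable)

    with _stage("signatures_and_rems"):
        sig_frames, rem_frames = [], []
        signatures, rems = {}, []
        for g in usable:
            sig = make_signature(
                g.drug_id, expr, g.resistant, g.sensitive, equal_var=config.equal_var
            )
            signatures[g.drug_id] = sig
            sdf = sig.table[["mean_diff", "s", "p", "q", "v"]].copy()
            sdf.insert(0, "gene_id", sdf.index)
            sdf.insert(0, "drug_id", g.drug_id)
            sig_frames.append(sdf)
            rem = build_rem(
                expr,
                g,
                dose.row(g.drug_id),
                alpha=config.alpha_rem,
                min_group_size=config.min_group_size,
                equal_var=config.equal_var,
            )
            rems.append(rem)
            rdf = rem.table.copy()
            rdf.insert(0, "gene_id", rdf.index)
            rdf.insert(0, "drug_id", g.drug_id)
            rdf["n_resistant"] = rem.n_resistant
            rdf["n_sensitive"] = rem.n_sensitive
            rem_frames.append(rdf)
        _concat(sig_frames, ["drug_id", "gene_id", "mean_diff", "s", "p", "q", "v"]).to_csv(
            out / "signatures.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        rem_cols = [
            "drug_id", "gene_id", "v_rem", "p_group", "q_group", "r_gi50",
            "p_gi50", "mean_diff", "n_resistant", "n_sensitive",
        ]
        _concat(rem_frames, rem_cols).to_csv(
            out / "rem.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        summary["rem_sizes"] = {r.drug_id: len(r) for r in rems}

    if gene_sets:
        with _stage("geneset_tests"):
            rng = np.random.default_rng(config.seed)
            rows = []
            for drug_id in sorted(signatures):
                sig = signatures[drug_id]
                for gs in gene_sets:
                    try:
                        res = gene_set_null_test(
                            sig,
                            gs,
                            alpha=config.alpha_gene,
                            n_random=config.n_random_sets,
                            rng=rng,
                            drug_id=drug_id,
                        )
                    except ValueError as exc:
                        log.warning("gene set %s vs %s skipped: %s", gs.name, drug_id, exc)
                        continue
                    rows.append(
                        (
                            drug_id, gs.name, res.set_size, res.observed_count,
                            res.expected_count, res.chi2, res.p_chi2,
                            res.p_binomial, int(res.reliable),
                            min_set_p(sig, gs),
                        )
                    )
            gdf = pd.DataFrame(
                rows,
                columns=[
                    "drug_id", "set_name", "set_size", "observed", "expected",
                    "chi2", "p_chi2", "p_binomial", "reliable", "min_p",
                ],
            )
            gdf.to_csv(
                out / "geneset_tests.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
            sig_count = int((gdf["p_chi2"] < 0.05).sum()) if len(gdf) else 0
            summary["geneset_tests"] = {
                "n_tests": len(gdf),
                "n_significant_chi2_0.05": sig_count,
            }

    if induction is not None:
        with _stage("induction_comparison"):
            control = induction.samples_with_label("control")
            induced = induction.samples_with_label("induced")
            if len(control) < 2 or len(induced) < 2:
                raise ValueError(
                    "induction experiment needs ≥2 'control' and ≥2 'induced' samples"
                )
            ind_sig, n_up, n_down = induction_signature(
                induction,
                control,
                induced,
                alpha=config.alpha_induction,
                fdr_max=config.fdr_max,
                equal_var=config.equal_var,
            )
            io.write_signature(ind_sig, out / "induction_signature.tsv")
            results = screen_factor(ind_sig, rems, alpha=config.alpha_call)
            cdf = pd.DataFrame(
                [
                    (c.factor_id, c.drug_id, c.n_genes, c.r, c.p_r, c.call)
                    for c in results
                ],
                columns=["factor_id", "drug_id", "n_genes", "r", "p_r", "call"],
            )
            cdf.to_csv(
                out / "comparisons.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
            summary["induction"] = {"n_up": n_up, "n_down": n_down}
            summary["comparisons"] = [
                {
                    "drug_id": c.drug_id,
                    "r": None if np.isnan(c.r) else round(c.r, 10),
                    "p_r": None if np.isnan(c.p_r) else float(f"{c.p_r:.10g}"),
                    "call": c.call,
                }
                for c in results
            ]

    with _stage("write_summary"):
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return out


def _concat(frames: list[pd.DataFrame], columns: list[str]) -> pd.DataFrame:
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]
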