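"""Stress-vs-control fold-change computation and differential-expression labels.

Fold change is computed on +1-offset FPKM:

    log2FC = log2(FPKM_treatment + 1) - log2(FPKM_control + 1)

so zero expression needs no special casing.  A gene/condition is labeled
*significant* when the fold change exceeds 1.5 or drops below 0.5 (strict
inequalities), *moderate* when it exceeds 1.2 or drops below 0.8 without being
significant, and *unchanged* otherwise.  Upregulation is positive by default;
the ``direction`` switch flips the subtraction for workflows that define fold
change the other way around.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import ExpressionTable

log = logging.getLogger(__name__)

SIGNIFICANT_UP = "significant_up"
SIGNIFICANT_DOWN = "significant_down"
MODERATE_UP = "moderate_up"
MODERATE_DOWN = "moderate_down"
UNCHANGED = "unchanged"

LABELS = (SIGNIFICANT_UP, SIGNIFICANT_DOWN, MODERATE_UP, MODERATE_DOWN, UNCHANGED)

#: strict fold-change bounds: significant outside (0.5, 1.5), moderate outside (0.8, 1.2)
SIGNIFICANT_BOUNDS = (0.5, 1.5)
MODERATE_BOUNDS = (0.8, 1.2)


@dataclass(frozen=True)
class ExpressionCall:
    gene_id: str
    condition: str
    log2fc: float
    fold_change: float
    label: str


def label_fold_change(
    fold_change: float,
    significant_bounds: tuple[float, float] = SIGNIFICANT_BOUNDS,
    moderate_bounds: tuple[float, float] = MODERATE_BOUNDS,
) -> str:
    """Partition a fold change into the five labels (strict inequalities)."""
    lo_sig, hi_sig = significant_bounds
    lo_mod, hi_mod = moderate_bounds
    if fold_change > hi_sig:
        return SIGNIFICANT_UP
    if fold_change < lo_sig:
        return SIGNIFICANT_DOWN
    if fold_change > hi_mod:
        return MODERATE_UP
    if fold_change < lo_mod:
        return MODERATE_DOWN
    return UNCHANGED


def fold_changes(
    table: ExpressionTable,
    direction: str = "treatment_minus_control",
) -> list[ExpressionCall]:
    """One call per gene x non-control condition.

    ``direction="control_minus_treatment"`` inverts the sign convention (some
    workflows subtract the treatment from the control, which swaps up/down).
    """
    if direction not in ("treatment_minus_control", "control_minus_treatment"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "control_minus_treatment":
        log.info("fold-change direction inverted: downregulation is positive")
    ctrl_idx = table.conditions.index(table.control)
    calls = []
    for gi, gene in enumerate(table.genes):
        ctrl = table.fpkm[gi, ctrl_idx]
        for ci, cond in enumerate(table.conditions):
            if cond == table.control:
                continue
            treat = table.fpkm[gi, ci]
            log2fc = math.log2(treat + 1.0) - math.log2(ctrl + 1.0)
            if direction == "control_minus_treatment":
                log2fc = -log2fc
            fc = 2.0 ** log2fc
            calls.append(
                ExpressionCall(
                    gene_id=gene,
                    condition=cond,
                    log2fc=log2fc,
                    fold_change=fc,
                    label=label_fold_change(fc),
                )
            )
    return calls


def calls_to_frame(calls: Sequence[ExpressionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "condition": c.condition,
                "log2fc": c.log2fc,
                "fold_change": c.fold_change,
                "label": c.label,
            }
            for c in calls
        ],
        columns=["gene_id", "condition", "log2fc", "fold_change", "label"],
    )


def write_expression_calls(calls: Sequence[ExpressionCall], path) -> None:
    df = calls_to_frame(
        sorted(calls, key=lambda c: (c.gene_id, c.condition))
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def annotate_tree_rings(
    calls: Sequence[ExpressionCall],
    conditions_order: Sequence[str] = ("cold", "heat", "drought", "salt"),
) -> pd.DataFrame:
    """Per-gene ring annotation table for tree viewers (text, no graphics).

    One column per condition in ring order (innermost first); cells are
    ``up``/``down`` for significant regulation and ``none`` otherwise.
    """
    by_gene: dict[str, dict[str, str]] = {}
    for c in calls:
        if c.condition not in conditions_order:
            continue
        symbol = "none"
        if c.label == SIGNIFICANT_UP:
            symbol = "up"
        elif c.label == SIGNIFICANT_DOWN:
            symbol = "down"
        by_gene.setdefault(c.gene_id, {})[c.condition] = symbol
    rows = []
    for gene in sorted(by_gene):
        row = {"gene_id": gene}
        for i, cond in enumerate(conditions_order, start=1):
            row[f"ring{i}_{cond}"] = by_gene[gene].get(cond, "none")
        rows.append(row)
    return pd.DataFrame(rows)
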