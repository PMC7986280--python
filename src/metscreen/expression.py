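"""Relative expression of qPCR targets via the ddCt scheme.

For each well, ``dCt = Ct_target - Ct_reference`` (the reference is a
stable housekeeping gene, e.g. elongation factor 1).  Each treated cell
``(genotype, tissue, time, gene)`` is paired with its control cell;
``ddCt = dCt_treated - mean(dCt_control)`` and relative expression is the
Livak fold ``base**(-ddCt)`` with ``base = 2`` (100 % amplification
efficiency) unless configured otherwise.  Control wells are the baseline
by definition and carry ddCt 0 / fold 1.

``expression_summary`` feeds the folds into a factorial
completely-randomized ANOVA (genotype x time) per gene and tissue and
attaches LSD letter groupings to the cell means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import AnovaTable, LsdResult, anova_factorial_expression, lsd

__all__ = [
    "REQUIRED_COLUMNS",
    "delta_ct",
    "add_relative_expression",
    "expression_summary",
    "ExpressionSummary",
]

REQUIRED_COLUMNS = (
    "genotype", "tissue", "time_h", "gene",
    "replicate", "is_control", "ct_target", "ct_ref",
)
_CELL = ["genotype", "tissue", "time_h", "gene"]


def delta_ct(ct_target, ct_reference):
    """dCt = Ct_target - Ct_reference (elementwise)."""
    if np.any(pd.isna(ct_target)) or np.any(pd.isna(ct_reference)):
        raise ValueError("missing Ct value: every well needs target and reference Ct")
    return np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float)


def _validate(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    cts = table[["ct_target", "ct_ref"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(cts)) or np.any(cts <= 0):
        raise ValueError("Ct values must be finite and positive")


def add_relative_expression(table: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """Return a copy with ``delta_ct``, ``ddct`` and ``fold`` columns.

    Raises ``ValueError`` listing every treated cell that lacks a matching
    control cell.
    """
    if base <= 1:
        raise ValueError("fold base must be > 1")
    _validate(table)
    out = table.copy()
    out["delta_ct"] = delta_ct(out["ct_target"], out["ct_ref"])

    controls = out[out["is_control"]]
    ctrl_mean = controls.groupby(_CELL, observed=True)["delta_ct"].mean()
    treated = out[~out["is_control"]]
    treated_cells = set(map(tuple, treated[_CELL].drop_duplicates().to_numpy()))
    orphans = sorted(treated_cells - set(ctrl_mean.index))
    if orphans:
        raise ValueError(
            "treated cells without a matching control "
            f"(genotype, tissue, time_h, gene): {orphans}"
        )

    key = pd.MultiIndex.from_frame(out[_CELL])
    baseline = ctrl_mean.reindex(key).to_numpy()
    ddct = out["delta_ct"].to_numpy() - baseline
    ddct[out["is_control"].to_numpy()] = 0.0  # controls define the baseline
    out["ddct"] = ddct
    out["fold"] = float(base) ** (-out["ddct"])
    return out


@dataclass
class ExpressionSummary:
    """Per-(gene, tissue) cell means, factorial ANOVA and LSD letters."""

    cell_means: pd.DataFrame
    anova_tables: dict[tuple, AnovaTable]
    lsd_results: dict[tuple, LsdResult]


def expression_summary(
    table: pd.DataFrame,
    base: float = 2.0,
    response: str = "fold",
    alpha: float = 0.05,
) -> ExpressionSummary:
    """Mean folds with SE, ANOVA rows and letter groups per gene/tissue.

    ``response`` may be ``"fold"`` (default) or ``"ddct"`` to run the
    ANOVA on the log scale instead.
    """
    if response not in ("fold", "ddct"):
        raise ValueError("response must be 'fold' or 'ddct'")
    expr = add_relative_expression(table, base=base)
    treated = expr[~expr["is_control"]]
    if treated.empty:
        raise ValueError("no treated records in the Ct table")

    grouped = treated.groupby(_CELL, observed=True)["fold"]
    cell_means = grouped.agg(
        mean_fold="mean",
        se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        n="size",
    ).reset_index()

    anova_tables: dict[tuple, AnovaTable] = {}
    lsd_results: dict[tuple, LsdResult] = {}
    for (gene, tissue), slab in treated.groupby(["gene", "tissue"], observed=True):
        tab = anova_factorial_expression(slab, response=response)
        anova_tables[(gene, tissue)] = tab
        r = int(slab.groupby(["genotype", "time_h"], observed=True).size().iloc[0])
        means = slab.groupby(["genotype", "time_h"], observed=True)[response].mean()
        means.index = [f"{g}@{t}h" for g, t in means.index]
        lsd_results[(gene, tissue)] = lsd(tab, means, r=r, alpha=alpha)
    return ExpressionSummary(
        cell_means=cell_means, anova_tables=anova_tables, lsd_results=lsd_results
    )
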