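"""Stepwise indirect-selection screening of yield on biochemical traits.

Genotype means across years and blocks (one row per genotype) are the
regression units.  Selection follows the SAS-style stepwise algorithm: at
each step the candidate with the smallest partial-F p-value enters if
``p <= sle``, then retained variables with ``p > sls`` are removed, until
no change; entry and stay thresholds default to 0.15, the convention of
the statistical package this procedure reproduces.  The per-step partial
R-squared is the drop in residual sum of squares at entry divided by the
total corrected sum of squares, so the model R-squared is the running sum
of retained contributions.

Ties in F-to-enter are broken by candidate column order (the input file
order).  Collinear candidates (those making the cross-product matrix
numerically singular) are skipped with a warning, and zero-variance
candidates are dropped up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StepwiseResult",
    "genotype_means",
    "stepwise_select",
    "standardized_coefficients",
]

_DESIGN_COLUMNS = ("year", "condition", "block", "genotype")


def genotype_means(
    data: pd.DataFrame, condition: str, columns=None
) -> pd.DataFrame:
    """Per-genotype means over years and blocks for one condition.

    Returns a genotype x variable frame (index = genotype label) over
    ``columns`` (default: every non-design numeric column).
    """
    if condition not in set(data["condition"]):
        raise ValueError(f"unknown condition label {condition!r}")
    sub = data[data["condition"] == condition]
    if columns is None:
        columns = [
            c for c in sub.columns
            if c not in _DESIGN_COLUMNS and pd.api.types.is_numeric_dtype(sub[c])
        ]
    return sub.groupby("genotype", observed=True)[list(columns)].mean().sort_index()


def _fit_sse(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept; returns (coefs, SSE)."""
    design = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("singular design")
    resid = y - design @ coef
    return coef, float(resid @ resid)


@dataclass
class StepwiseResult:
    """Steps, final-model parameters and overall ANOVA of the selection."""

    steps: pd.DataFrame       # step, entered, removed, partial_r2, model_r2, f_value, p_value
    params: pd.DataFrame      # variable, estimate, std_coef, std_error, type2_ss, f_value, p_value
    anova: pd.DataFrame       # source, df, ss, ms, F, p
    selected: tuple[str, ...]
    r2: float
    sle: float
    sls: float


def stepwise_select(
    X: pd.DataFrame, y: pd.Series, sle: float = 0.15, sls: float = 0.15
) -> StepwiseResult:
    """SAS-style stepwise regression of ``y`` on the columns of ``X``."""
    X = X.copy()
    y_arr = y.to_numpy(dtype=float)
    n = len(y_arr)
    sst = float(((y_arr - y_arr.mean()) ** 2).sum())

    drop = [c for c in X.columns if X[c].nunique() <= 1]
    if drop:
        warnings.warn(f"dropping zero-variance candidates: {drop}", stacklevel=2)
        X = X.drop(columns=drop)
    candidates = list(X.columns)
    if n <= 2 and candidates:
        raise ValueError("need more genotypes than parameters to fit any model")

    selected: list[str] = []
    step_rows = []
    seen_models = {tuple()}
    step = 0

    def partial_stats(current, var, direction):
        """F and p for adding (or the current fit of) ``var``."""
        base = [c for c in current if c != var] if direction == "drop" else list(current)
        full = base + [var]
        if n - len(full) - 1 < 1:
            return None
        _, sse_base = _fit_sse(X[base].to_numpy(dtype=float), y_arr)
        try:
            _, sse_full = _fit_sse(X[full].to_numpy(dtype=float), y_arr)
        except np.linalg.LinAlgError:
            return None
        df_err = n - len(full) - 1
        mse = sse_full / df_err
        if mse <= 0:
            f_val = np.inf
            p = 0.0
        else:
            f_val = (sse_base - sse_full) / mse
            p = float(stats.f.sf(f_val, 1, df_err))
        return sse_base, sse_full, f_val, p

    if sst > 0:
        while True:
            changed = False
            # entry
            best = None
            for var in candidates:
                if var in selected:
                    continue
                res = partial_stats(selected, var, "add")
                if res is None:
                    continue
                _, _, f_val, p = res
                if best is None or p < best[1] - 1e-15:
                    best = (var, p, res)
            if best is not None and best[1] <= sle:
                var, p, (sse_base, sse_full, f_val, _) = best
                selected.append(var)
                step += 1
                step_rows.append(
                    (step, var, "", (sse_base - sse_full) / sst,
                     1.0 - sse_full / sst, f_val, p)
                )
                changed = True
            # removal
            while len(selected) > 0:
                worst = None
                for var in selected:
                    res = partial_stats(selected, var, "drop")
                    if res is None:
                        continue
                    _, _, f_val, p = res
                    if worst is None or p > worst[1] + 1e-15:
                        worst = (var, p, res)
                if worst is None or worst[1] <= sls:
                    break
                var, p, (sse_base, sse_full, f_val, _) = worst
                selected.remove(var)
                step += 1
                step_rows.append(
                    (step, "", var, (sse_base - sse_full) / sst,
                     1.0 - sse_base / sst, f_val, p)
                )
                changed = True
            state = tuple(sorted(selected))
            if not changed or state in seen_models:
                break
            seen_models.add(state)

    # final model
    x_sel = X[selected].to_numpy(dtype=float)
    coef, sse = _fit_sse(x_sel, y_arr)
    p_model = len(selected)
    df_err = n - p_model - 1
    mse = sse / df_err if df_err > 0 else np.nan
    ssr = sst - sse

    anova = pd.DataFrame(
        [
            ("model", p_model, ssr, ssr / p_model if p_model else np.nan,
             (ssr / p_model) / mse if p_model and mse > 0 else np.nan,
             float(stats.f.sf((ssr / p_model) / mse, p_model, df_err))
             if p_model and mse > 0 else np.nan),
            ("error", df_err, sse, mse, np.nan, np.nan),
            ("total", n - 1, sst, np.nan, np.nan, np.nan),
        ],
        columns=["source", "df", "ss", "ms", "F", "p"],
    )

    std_coefs = (
        standardized_coefficients(X[selected], y, dict(zip(selected, coef[1:])))
        if selected
        else {}
    )
    design = np.column_stack([np.ones(n), x_sel])
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(xtx_inv) * mse) if df_err > 0 else np.full(p_model + 1, np.nan)

    rows = []
    for i, var in enumerate(["Intercept"] + selected):
        if var == "Intercept":
            ss2 = coef[0] ** 2 / xtx_inv[0, 0]
        else:
            res = partial_stats(selected, var, "drop")
            ss2 = res[0] - res[1] if res else np.nan
        f_val = ss2 / mse if mse and mse > 0 else np.nan
        p_val = float(stats.f.sf(f_val, 1, df_err)) if np.isfinite(f_val) else np.nan
        rows.append(
            (var, coef[i], np.nan if var == "Intercept" else std_coefs[var],
             se[i], ss2, f_val, p_val)
        )
    params = pd.DataFrame(
        rows,
        columns=["variable", "estimate", "std_coef", "std_error",
                 "type2_ss", "f_value", "p_value"],
    )
    steps = pd.DataFrame(
        step_rows,
        columns=["step", "entered", "removed", "partial_r2", "model_r2",
                 "f_value", "p_value"],
    )
    return StepwiseResult(
        steps=steps,
        params=params,
        anova=anova,
        selected=tuple(selected),
        r2=1.0 - sse / sst if sst > 0 else 0.0,
        sle=sle,
        sls=sls,
    )


def standardized_coefficients(X: pd.DataFrame, y: pd.Series, coefs: dict) -> dict:
    """Unitless coefficients ``b_std = b * sd(x) / sd(y)``.

    Sample standard deviations (ddof=1).  With a single predictor this
    equals the Pearson correlation of x and y.
    """
    sd_y = float(y.std(ddof=1))
    if sd_y == 0 or not np.isfinite(sd_y):
        warnings.warn("sd(y) = 0: standardized coefficients undefined", stacklevel=2)
        return {var: float("nan") for var in coefs}
    return {
        var: float(b) * float(X[var].std(ddof=1)) / sd_y for var, b in coefs.items()
    }
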