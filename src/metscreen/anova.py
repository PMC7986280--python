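"""Balanced-design analysis of variance for multi-environment trials.

Implements the classical moment-based ANOVA for complete, balanced layouts
with crossed and nested factors, as used for randomized complete block
designs repeated over years (combined ANOVA) and for factorial completely
randomized designs (expression data).  Sums of squares are the classical
marginal-mean contrasts, computed by the standard containment recursion

    SS(T) = R(T) - CF - sum of SS(S) over model terms S strictly
            contained in T,

where ``R(T)`` is the sum over the cells of term ``T`` of
``(cell total)^2 / cell size`` and ``CF`` the correction factor.  On
balanced data these equal the sequential (type-I) regression sums of
squares in any order, which is the oracle the test-suite checks against.

Unbalanced or incomplete data are rejected explicitly: the estimators fed
by these tables (expected-mean-square variance components) presuppose
balance, and a silent fallback would corrupt them.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Term",
    "ModelSpec",
    "AnovaTable",
    "LsdResult",
    "UnbalancedDataError",
    "ModelSpecError",
    "anova_balanced",
    "anova_factorial_expression",
    "lsd",
]


class UnbalancedDataError(ValueError):
    """Raised when the data do not form a complete balanced layout."""


class ModelSpecError(ValueError):
    """Raised when a model specification does not match the data."""


_NESTED_RE = re.compile(r"^\s*([\w./-]+)\s*\(\s*([\w./:-]+)\s*\)\s*$")


@dataclass(frozen=True)
class Term:
    """One source of variation: crossed factors, optionally nested in parents.

    ``Term.parse`` accepts ``"year"``, ``"genotype:year"`` (crossed) and
    ``"block(year)"`` (block nested within year).
    """

    factors: tuple[str, ...]
    nested_in: tuple[str, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "Term":
        m = _NESTED_RE.match(text)
        if m:
            child, parents = m.groups()
            return cls((child,), tuple(p.strip() for p in parents.split(":")))
        factors = tuple(f.strip() for f in text.split(":") if f.strip())
        if not factors:
            raise ModelSpecError(f"empty term specification: {text!r}")
        return cls(factors)

    @property
    def all_factors(self) -> frozenset[str]:
        return frozenset(self.factors) | frozenset(self.nested_in)

    @property
    def name(self) -> str:
        base = ":".join(self.factors)
        if self.nested_in:
            return f"{base}({':'.join(self.nested_in)})"
        return base


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of ANOVA terms plus the F-test denominator map.

    ``denominators`` maps a term name to the name of the mean square used
    as its F denominator; unspecified terms are tested against the
    residual.  ``"residual"`` always refers to the within-cell remainder.
    """

    terms: tuple[Term, ...]
    denominators: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_strings(cls, terms, denominators=None) -> "ModelSpec":
        return cls(tuple(Term.parse(t) for t in terms), dict(denominators or {}))

    @classmethod
    def per_condition(cls, ems: bool = False) -> "ModelSpec":
        """RCBD repeated over years, one irrigation condition at a time.

        With ``ems=True``, genotype is tested against the genotype:year
        interaction and year against block(year), following the expected
        mean squares of the random model; the default tests every source
        against the residual (fixed-effects GLM behaviour).
        """
        denom = {"genotype": "genotype:year", "year": "block(year)"} if ems else {}
        return cls.from_strings(
            ["year", "block(year)", "genotype", "genotype:year"], denom
        )

    @classmethod
    def full_trial(cls) -> "ModelSpec":
        """Both irrigation conditions crossed with year and genotype."""
        return cls.from_strings(
            [
                "year",
                "stress",
                "stress:year",
                "genotype",
                "genotype:year",
                "genotype:stress",
                "genotype:stress:year",
            ]
        )

    @classmethod
    def expression(cls) -> "ModelSpec":
        """Factorial CRD for qPCR relative expression: genotype x time."""
        return cls.from_strings(["genotype", "time_h", "genotype:time_h"])

    @property
    def factor_columns(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.terms:
            for f in (*t.nested_in, *t.factors):
                if f not in seen:
                    seen.append(f)
        return tuple(seen)


@dataclass
class AnovaTable:
    """ANOVA results: one row per source plus the residual.

    ``table`` columns: source, df, ss, ms, F, p, denominator.
    """

    table: pd.DataFrame
    response: str
    n_obs: int

    def _row(self, source: str) -> pd.Series:
        hit = self.table[self.table["source"] == source]
        if hit.empty:
            raise KeyError(
                f"ANOVA table for {self.response!r} has no source {source!r}; "
                f"available: {list(self.table['source'])}"
            )
        return hit.iloc[0]

    def ms(self, source: str) -> float:
        return float(self._row(source)["ms"])

    def ss(self, source: str) -> float:
        return float(self._row(source)["ss"])

    def df_of(self, source: str) -> int:
        return int(self._row(source)["df"])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _check_balance(data: pd.DataFrame, factors: tuple[str, ...]) -> int:
    """Return the common cell size, or raise naming the first missing cell."""
    levels = {f: sorted(data[f].unique(), key=str) for f in factors}
    counts = data.groupby(list(factors), observed=True, sort=False).size()
    expected = int(np.prod([len(v) for v in levels.values()]))
    if len(counts) != expected:
        present = set(counts.index if len(factors) > 1 else [(i,) for i in counts.index])
        for cell in itertools.product(*(levels[f] for f in factors)):
            key = cell if len(factors) > 1 else cell
            if key not in present:
                named = ", ".join(f"{f}={v!r}" for f, v in zip(factors, cell))
                raise UnbalancedDataError(f"missing cell: {named}")
    if counts.nunique() != 1:
        bad = counts[counts != counts.iloc[0]].index[0]
        raise UnbalancedDataError(
            f"unequal replication: cell {bad!r} has {counts.max()} != {counts.min()} "
            "observations elsewhere"
        )
    return int(counts.iloc[0])


def anova_balanced(data: pd.DataFrame, response: str, model: ModelSpec) -> AnovaTable:
    """Classical balanced ANOVA of ``response`` under ``model``.

    Parameters
    ----------
    data
        Long-format table, one row per observational unit, containing every
        factor column referenced by the model and the response column.
    response
        Name of the numeric response column.
    model
        Term list and F-denominator map.

    Raises
    ------
    UnbalancedDataError
        If any cell of the full factor cross is missing or unequally
        replicated (no silent fallback).
    ModelSpecError
        If a referenced factor column is absent or a term has zero df.
    """
    for f in model.factor_columns:
        if f not in data.columns:
            raise ModelSpecError(f"factor column {f!r} not in data")
    if response not in data.columns:
        raise ModelSpecError(f"response column {response!r} not in data")

    _check_balance(data, model.factor_columns)

    y = data[response].to_numpy(dtype=float)
    n = y.size
    cf = y.sum() ** 2 / n
    ss_total = float((y**2).sum() - cf)

    # containment recursion over model terms, smallest factor sets first
    order = sorted(range(len(model.terms)), key=lambda i: len(model.terms[i].all_factors))
    ss: dict[str, float] = {}
    dfs: dict[str, int] = {}
    for i in order:
        term = model.terms[i]
        cols = sorted(term.all_factors)
        g = data.groupby(cols, observed=True)[response]
        r_t = float((g.sum() ** 2 / g.size()).sum())
        n_cells = g.ngroups
        contained = [
            s for s in model.terms
            if s.all_factors < term.all_factors and s.name in ss
        ]
        ss_t = r_t - cf - sum(ss[s.name] for s in contained)
        df_t = n_cells - 1 - sum(dfs[s.name] for s in contained)
        if df_t < 1:
            raise ModelSpecError(
                f"term {term.name!r} has {df_t} degrees of freedom; "
                "check factor levels"
            )
        ss[term.name] = max(ss_t, 0.0) if abs(ss_t) < 1e-10 * max(ss_total, 1.0) else ss_t
        dfs[term.name] = df_t

    ss_res = ss_total - sum(ss.values())
    if abs(ss_res) < 1e-10 * max(ss_total, 1.0):
        ss_res = max(ss_res, 0.0)
    df_res = n - 1 - sum(dfs.values())
    ss["residual"] = ss_res
    dfs["residual"] = df_res

    rows = []
    names = [t.name for t in model.terms] + ["residual"]
    ms = {
        name: (ss[name] / dfs[name] if dfs[name] > 0 else np.nan) for name in names
    }
    for name in names:
        if name == "residual":
            rows.append((name, dfs[name], ss[name], ms[name], np.nan, np.nan, ""))
            continue
        denom = model.denominators.get(name, "residual")
        if denom not in ms:
            raise ModelSpecError(f"denominator {denom!r} for {name!r} not in model")
        ms_d, df_d = ms[denom], dfs[denom]
        if not np.isfinite(ms_d) or df_d < 1:
            f_stat, p = np.nan, np.nan
        elif ms_d == 0.0:
            f_stat = np.inf if ms[name] > 0 else np.nan
            p = 0.0 if ms[name] > 0 else np.nan
        else:
            f_stat = ms[name] / ms_d
            p = float(stats.f.sf(f_stat, dfs[name], df_d))
        rows.append((name, dfs[name], ss[name], ms[name], f_stat, p, denom))

    table = pd.DataFrame(
        rows, columns=["source", "df", "ss", "ms", "F", "p", "denominator"]
    )
    return AnovaTable(table=table, response=response, n_obs=n)


def anova_factorial_expression(
    expr: pd.DataFrame, response: str = "fold", model: ModelSpec | None = None
) -> AnovaTable:
    """Factorial CRD ANOVA for one gene/tissue slice of an expression set.

    Requires at least two replicates per (genotype, time) cell so a
    within-cell residual exists.
    """
    model = model or ModelSpec.expression()
    cell_sizes = expr.groupby(list(model.factor_columns), observed=True).size()
    if (cell_sizes < 2).any():
        bad = cell_sizes[cell_sizes < 2].index[0]
        raise UnbalancedDataError(
            f"cell {bad!r} has a single replicate: no residual degrees of freedom"
        )
    return anova_balanced(expr, response, model)


@dataclass
class LsdResult:
    """Least-significant-difference mean separation.

    ``letters`` maps each level to its letter group(s); levels whose means
    differ by more than ``value`` never share a letter.
    """

    alpha: float
    df_error: int
    ms_error: float
    r: int
    value: float
    means: pd.Series
    letters: dict


def _letter_groups(means: pd.Series, threshold: float) -> dict:
    """Compact letter display by maximal non-significant ranges."""
    ordered = means.sort_values(ascending=False, kind="stable")
    vals = ordered.to_numpy(dtype=float)
    n = len(vals)
    intervals = []
    for i in range(n):
        j = i
        while j + 1 < n and vals[i] - vals[j + 1] <= threshold + 1e-12:
            j += 1
        intervals.append((i, j))
    maximal = [
        (a, b) for a, b in intervals
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in intervals)
    ]
    maximal = sorted(set(maximal))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lvl: "" for lvl in ordered.index}
    for idx, (a, b) in enumerate(maximal):
        letter = alphabet[idx % len(alphabet)] * (1 + idx // len(alphabet))
        for pos in range(a, b + 1):
            letters[ordered.index[pos]] += letter
    return letters


def lsd(
    anova: AnovaTable,
    means: pd.Series,
    r: int,
    alpha: float = 0.05,
    error_source: str = "residual",
) -> LsdResult:
    """LSD mean comparison: ``t(1-alpha/2, df_e) * sqrt(2*MS_e/r)``.

    ``means`` is a level -> mean Series; ``r`` the replication count behind
    each mean.
    """
    if r < 1:
        raise ValueError("replication count r must be >= 1")
    df_e = anova.df_of(error_source)
    ms_e = anova.ms(error_source)
    if df_e < 1:
        raise ValueError("error degrees of freedom must be >= 1 for the LSD")
    value = float(stats.t.ppf(1 - alpha / 2, df_e) * np.sqrt(2.0 * ms_e / r))
    return LsdResult(
        alpha=alpha,
        df_error=df_e,
        ms_error=float(ms_e),
        r=r,
        value=value,
        means=means.sort_values(ascending=False, kind="stable"),
        letters=_letter_groups(means, value),
    )
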