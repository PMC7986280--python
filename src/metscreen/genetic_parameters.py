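"""Expected-mean-square variance components and genetic indices.

Converts the per-condition combined-ANOVA mean squares of a balanced
RCBD-over-years trial into variance components and the standardized
indices used to rank traits for indirect selection: broad-sense
heritability, genotypic coefficient of variation (GCV) and phenotypic
coefficient of variation (PCV).

The component estimators are the published ones, implemented verbatim
(``blk`` = blocks per environment, ``yr`` = environments, ``gn`` =
genotypes)::

    s2_res     = MS_res
    s2_blk(yr) = (MS_blk(yr) - MS_res) / (yr * gn)
    s2_gxy     = (MS_gxy    - MS_res) / blk
    s2_gn      = (MS_gn     - MS_res) / (blk * yr)
    s2_yr      = (MS_blk(yr) - MS_gxy + s2_res) / (blk * gn)
    s2_pn      = s2_gn + s2_yr / (blk * yr) + s2_gxy / yr

Two of these deviate from the textbook moment estimators (the genotypic
component subtracts MS_res rather than MS_gxy, and the year component has
an unusual numerator); ``genotype_formula="textbook"`` switches the
genotypic component to ``(MS_gn - MS_gxy)/(blk*yr)``.  The analytic
expectations of the published estimators under the random model
``y = mu + year + block(year) + genotype + genotype:year + residual`` are
available from :func:`formula_expectations`, so simulation recovery can be
checked against what the estimators actually converge to.

Two CV conventions are provided.  ``methods_sqrt`` is the conventional
``100*sqrt(variance)/mean``; ``table_ratio`` is ``100*variance/mean``
(variance, not standard deviation, over the mean), which is the convention
every printed index in the reference trial satisfies and is therefore the
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .anova import AnovaTable, ModelSpec, anova_balanced

__all__ = [
    "VarianceComponents",
    "variance_components",
    "formula_expectations",
    "heritability_percent",
    "cv_percent",
    "genetic_summary",
]

_REQUIRED_MS = ("residual", "block(year)", "genotype", "genotype:year")


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components in trait units squared.

    ``environment_effective`` is defined as phenotypic minus genotypic
    variance, which is the quantity that makes the three reported
    variances additive; the raw ``year`` component from its own formula is
    kept alongside because the two are not mutually consistent.
    """

    residual: float
    block_in_year: float
    gxy: float
    genotype: float
    year: float
    phenotypic: float
    blk: int
    yr: int
    gn: int
    genotype_formula: str = "published"

    @property
    def environment_effective(self) -> float:
        return self.phenotypic - self.genotype

    def truncated(self) -> "VarianceComponents":
        """Negative components clipped to zero (the common convention for
        index computation); the phenotypic variance is kept as computed."""
        return replace(
            self,
            residual=max(self.residual, 0.0),
            block_in_year=max(self.block_in_year, 0.0),
            gxy=max(self.gxy, 0.0),
            genotype=max(self.genotype, 0.0),
            year=max(self.year, 0.0),
            phenotypic=max(self.phenotypic, 0.0),
        )


def variance_components(
    anova: AnovaTable,
    blk: int,
    yr: int,
    gn: int,
    genotype_formula: str = "published",
) -> VarianceComponents:
    """Invert the per-condition ANOVA mean squares into variance components.

    Raises ``KeyError`` naming the first missing mean-square row, and
    ``ValueError`` if any design count is below 2 (the denominators of the
    estimators degenerate).
    """
    if min(blk, yr, gn) < 2:
        raise ValueError("blk, yr and gn must all be >= 2")
    if genotype_formula not in ("published", "textbook"):
        raise ValueError(f"unknown genotype_formula {genotype_formula!r}")
    for source in _REQUIRED_MS:
        anova._row(source)  # raises KeyError with context if absent

    ms_res = anova.ms("residual")
    ms_blk = anova.ms("block(year)")
    ms_gn = anova.ms("genotype")
    ms_gxy = anova.ms("genotype:year")

    s2_res = ms_res
    s2_blk = (ms_blk - ms_res) / (yr * gn)
    s2_gxy = (ms_gxy - ms_res) / blk
    if genotype_formula == "published":
        s2_gn = (ms_gn - ms_res) / (blk * yr)
    else:
        s2_gn = (ms_gn - ms_gxy) / (blk * yr)
    s2_yr = (ms_blk - ms_gxy + s2_res) / (blk * gn)
    s2_pn = s2_gn + s2_yr / (blk * yr) + s2_gxy / yr

    return VarianceComponents(
        residual=float(s2_res),
        block_in_year=float(s2_blk),
        gxy=float(s2_gxy),
        genotype=float(s2_gn),
        year=float(s2_yr),
        phenotypic=float(s2_pn),
        blk=blk,
        yr=yr,
        gn=gn,
        genotype_formula=genotype_formula,
    )


def formula_expectations(
    sigma2: dict, blk: int, yr: int, gn: int, genotype_formula: str = "published"
) -> VarianceComponents:
    """Analytic expectations of the component estimators under the model.

    ``sigma2`` holds the true simulation variances with keys ``year``,
    ``block_in_year``, ``genotype``, ``gxy`` and ``residual``.  Uses the
    balanced-design expected mean squares

        E[MS_res]     = s_res
        E[MS_gxy]     = s_res + blk*s_gxy
        E[MS_gn]      = s_res + blk*s_gxy + blk*yr*s_gn
        E[MS_blk(yr)] = s_res + gn*s_blk

    pushed through the estimator formulas; e.g. the published genotypic
    estimator converges to ``s_gn + s_gxy/yr``, not to ``s_gn``.
    """
    s_res = sigma2["residual"]
    s_blk = sigma2["block_in_year"]
    s_gxy = sigma2["gxy"]
    s_gn = sigma2["genotype"]

    e_res = s_res
    e_blk = (gn * s_blk) / (yr * gn)
    e_gxy = s_gxy
    if genotype_formula == "published":
        e_gn = s_gn + s_gxy / yr
    else:
        e_gn = s_gn
    e_yr = (gn * s_blk - blk * s_gxy + s_res) / (blk * gn)
    e_pn = e_gn + e_yr / (blk * yr) + e_gxy / yr
    return VarianceComponents(
        residual=e_res,
        block_in_year=e_blk,
        gxy=e_gxy,
        genotype=e_gn,
        year=e_yr,
        phenotypic=e_pn,
        blk=blk,
        yr=yr,
        gn=gn,
        genotype_formula=genotype_formula,
    )


def heritability_percent(
    components: VarianceComponents, truncate: bool = True
) -> float:
    """Broad-sense heritability ``100 * s2_gn / s2_pn`` in percent.

    In truncated mode (default) negative components are clipped first and
    the result lies in [0, 100].  A non-positive phenotypic variance makes
    the ratio undefined: NaN is returned with a warning.
    """
    vc = components.truncated() if truncate else components
    if vc.phenotypic <= 0:
        warnings.warn(
            "phenotypic variance <= 0: heritability undefined", RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    h2 = 100.0 * vc.genotype / vc.phenotypic
    return float(np.clip(h2, 0.0, 100.0)) if truncate else float(h2)


def cv_percent(variance: float, mean: float, convention: str = "table_ratio") -> float:
    """Coefficient-of-variation index in percent.

    ``table_ratio``: ``100*variance/mean`` (default; reproduces the
    reference trial's printed GCV/PCV).  ``methods_sqrt``:
    ``100*sqrt(variance)/mean`` (conventional CV).
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if mean == 0:
        warnings.warn("mean is 0: CV undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    if convention == "table_ratio":
        return 100.0 * variance / mean
    if convention == "methods_sqrt":
        return 100.0 * float(np.sqrt(variance)) / mean
    raise ValueError(f"unknown CV convention {convention!r}")


def genetic_summary(
    data: pd.DataFrame,
    traits,
    blk: int,
    yr: int,
    gn: int,
    cv_convention: str = "table_ratio",
    genotype_formula: str = "published",
) -> pd.DataFrame:
    """Per-trait genetic parameters for one condition's trial table.

    Runs the per-condition combined ANOVA for every trait and returns a
    table with rows: genotypic, environmental and phenotypic variance,
    heritability, PCV, GCV and the trait mean (one column per trait).
    """
    model = ModelSpec.per_condition()
    out = {}
    for trait in traits:
        tab = anova_balanced(data, trait, model)
        vc = variance_components(tab, blk, yr, gn, genotype_formula=genotype_formula)
        vct = vc.truncated()
        mean = float(data[trait].mean())
        out[trait] = {
            "genotypic_variance": vct.genotype,
            "environmental_variance": vct.environment_effective,
            "phenotypic_variance": vct.phenotypic,
            "heritability": heritability_percent(vc),
            "PCV": cv_percent(vct.phenotypic, mean, cv_convention),
            "GCV": cv_percent(vct.genotype, mean, cv_convention),
            "mean": mean,
        }
    return pd.DataFrame(out)
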