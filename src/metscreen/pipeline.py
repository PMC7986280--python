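"""End-to-end orchestration: field-trial, expression and promoter runs.

Each run reads its inputs, executes the corresponding analysis stages and
writes a report bundle of CSV/JSON artifacts plus a ``manifest.json``
recording inputs, configuration, seed and the SHA-256 of every output, so
reruns with identical inputs are verifiably identical.  Tabular output
uses a fixed column order and 6-significant-digit floats.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .anova import ModelSpec, anova_balanced
from .expression import expression_summary
from .feature_selection import genotype_means, stepwise_select
from .genetic_parameters import genetic_summary
from .promoters import (
    DEFAULT_MOTIF_CLASSES,
    aggregate_summary,
    parse_promoters,
    read_motif_tsv,
    scan_motifs,
    write_motif_tsv,
    write_promoters,
)
from .screening import build_screening_bundle, select_contrast_pair_by_priority

__all__ = ["RunConfig", "run_simulate", "run_field_analysis", "run_expression", "run_promoters"]

_FLOAT_FMT = "%.6g"
_TRIAL_COLUMNS = ("year", "condition", "block", "genotype")


@dataclass
class RunConfig:
    """Shared run configuration; unused fields are ignored by each stage."""

    out_dir: str = "results"
    seed: int = 0
    trial_csv: str | None = None
    ct_csv: str | None = None
    fasta: str | None = None
    motif_tsv: str | None = None
    conditions: tuple[str, ...] = ("normal", "stress")
    sle: float = 0.15
    sls: float = 0.15
    k: int = 3
    ward_variant: str = "D2"
    cv_convention: str = "table_ratio"
    ddct_base: float = 2.0
    target_traits: tuple[str, ...] = ("SOD", sd.YIELD)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("conditions", "target_traits"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, float_format=_FLOAT_FMT, index=index)


def _manifest(out_dir: Path, config: dict, inputs: dict) -> None:
    outputs = {}
    for p in sorted(out_dir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        outputs[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    payload = {"inputs": inputs, "config": config, "outputs": outputs}
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(config: RunConfig) -> dict:
    raw = asdict(config)
    return {k: list(v) if isinstance(v, tuple) else v for k, v in raw.items()}


def _load_trial(path: str, conditions) -> pd.DataFrame:
    data = pd.read_csv(path)
    missing = set(_TRIAL_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    unknown = set(conditions) - set(data["condition"])
    if unknown:
        raise ValueError(f"conditions absent from trial table: {sorted(unknown)}")
    return data


def run_simulate(config: RunConfig) -> Path:
    """Generate the full synthetic input bundle under the study conditions."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = sd.default_design()
    trial = sd.simulate_trial(design, sd.default_variance_specs(design), seed=config.seed)
    _write_csv(trial, out / "trial.csv")
    ct = sd.simulate_ct_table(sd.default_ct_spec(), seed=config.seed + 1)
    _write_csv(ct, out / "ct.csv")
    records, truth = sd.simulate_promoters(sd.default_promoter_spec(), seed=config.seed + 2)
    write_promoters(records, out / "promoters.fasta")
    _write_csv(truth, out / "promoter_truth.csv")
    write_motif_tsv(DEFAULT_MOTIF_CLASSES, out / "motifs.tsv")
    _manifest(out, _jsonable(config), {"generator": "metscreen.synthetic_data"})
    return out


def run_field_analysis(config: RunConfig) -> Path:
    """Full field-trial analysis: per-condition ANOVA per trait, genetic
    parameters, stepwise yield model, screening bundle and contrast pair."""
    if not config.trial_csv:
        raise ValueError("trial_csv is required for the field analysis")
    data = _load_trial(config.trial_csv, config.conditions)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    traits = [
        c for c in data.columns
        if c not in _TRIAL_COLUMNS and pd.api.types.is_numeric_dtype(data[c])
    ]
    model = ModelSpec.per_condition()
    bundles = {}
    pair_traits = [t for t in config.target_traits]
    for cond in config.conditions:
        sub = data[data["condition"] == cond]
        blk = sub["block"].nunique()
        yr = sub["year"].nunique()
        gn = sub["genotype"].nunique()

        anova_rows = []
        for trait in traits:
            tab = anova_balanced(sub, trait, model)
            t = tab.to_frame()
            t.insert(0, "trait", trait)
            anova_rows.append(t)
        _write_csv(pd.concat(anova_rows, ignore_index=True), out / f"anova_{cond}.csv")

        params = genetic_summary(
            sub, traits, blk=blk, yr=yr, gn=gn, cv_convention=config.cv_convention
        )
        _write_csv(params, out / f"genetic_parameters_{cond}.csv", index=True)

        means = genotype_means(data, cond)
        x_cols = [c for c in means.columns if c != sd.YIELD]
        fit = stepwise_select(means[x_cols], means[sd.YIELD], sle=config.sle, sls=config.sls)
        _write_csv(fit.steps, out / f"stepwise_steps_{cond}.csv")
        _write_csv(fit.params, out / f"stepwise_params_{cond}.csv")
        _write_csv(fit.anova, out / f"stepwise_anova_{cond}.csv")

        bundle = build_screening_bundle(
            means, k=config.k, ward_variant=config.ward_variant
        )
        bundles[cond] = bundle
        _write_csv(bundle.distances, out / f"distances_{cond}.csv", index=True)
        _write_csv(bundle.pca.scores, out / f"pca_scores_{cond}.csv", index=True)
        _write_csv(bundle.pca.loadings, out / f"pca_loadings_{cond}.csv", index=True)
        _write_csv(bundle.bins, out / f"heatmap_bins_{cond}.csv", index=True)
        merge_list = {
            "linkage": np.round(bundle.row_linkage, 10).tolist(),
            "labels": list(bundle.z.index),
            "clusters": {g: int(c) for g, c in bundle.clusters.items()},
            "pct_variance": np.round(bundle.pca.pct_variance, 6).tolist(),
        }
        (out / f"dendrogram_{cond}.json").write_text(json.dumps(merge_list, indent=2))

    pair = select_contrast_pair_by_priority(
        bundles, target_traits=pair_traits, priority=tuple(config.conditions[::-1])
        if "stress" not in config.conditions else ("stress", "normal"),
    )
    (out / "contrast_pair.json").write_text(
        json.dumps(
            {
                "high": pair.high,
                "low": pair.low,
                "alternates_high": list(pair.alternates_high),
                "alternates_low": list(pair.alternates_low),
                "deciding_condition": pair.trace.get("deciding_condition"),
                "max_distance": pair.trace.get("max_distance"),
            },
            indent=2,
        )
    )
    _manifest(out, _jsonable(config), {"trial_csv": str(config.trial_csv)})
    return out


def run_expression(config: RunConfig) -> Path:
    """Relative-expression report: folds, factorial ANOVA, LSD letters."""
    if not config.ct_csv:
        raise ValueError("ct_csv is required for the expression analysis")
    table = pd.read_csv(config.ct_csv)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = expression_summary(table, base=config.ddct_base)
    _write_csv(summary.cell_means, out / "expression_means.csv")
    anova_rows = []
    letter_rows = []
    for (gene, tissue), tab in summary.anova_tables.items():
        t = tab.to_frame()
        t.insert(0, "tissue", tissue)
        t.insert(0, "gene", gene)
        anova_rows.append(t)
        res = summary.lsd_results[(gene, tissue)]
        for level, letters in res.letters.items():
            letter_rows.append(
                {"gene": gene, "tissue": tissue, "cell": level,
                 "mean": float(res.means[level]), "letters": letters,
                 "lsd": res.value}
            )
    _write_csv(pd.concat(anova_rows, ignore_index=True), out / "expression_anova.csv")
    _write_csv(pd.DataFrame(letter_rows), out / "expression_lsd.csv")
    _manifest(out, _jsonable(config), {"ct_csv": str(config.ct_csv)})
    return out


def run_promoters(config: RunConfig) -> Path:
    """Promoter scan: per-sequence hits plus the aggregated summary table."""
    if not config.fasta:
        raise ValueError("fasta is required for the promoter analysis")
    dictionary = (
        read_motif_tsv(config.motif_tsv)
        if config.motif_tsv
        else dict(DEFAULT_MOTIF_CLASSES)
    )
    records = parse_promoters(config.fasta)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_record = [scan_motifs(r, dictionary) for r in records]
    hits = pd.DataFrame(
        [
            {"sequence": r.header(), "gene": r.gene, "genome_set": r.genome_set,
             **counts}
            for r, counts in zip(records, per_record)
        ]
    )
    _write_csv(hits, out / "promoter_hits.csv")
    summary = aggregate_summary(records, per_record, classes=tuple(dictionary))
    _write_csv(summary.to_table(), out / "promoter_summary.csv", index=True)
    _manifest(out, _jsonable(config), {"fasta": str(config.fasta)})
    return out
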