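"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators replace the field study, the greenhouse qPCR assay and
the promoter downloads:

* :func:`simulate_trial` draws balanced RCBD-over-years trial tables from
  the additive random-effects model
  ``y = mu + year + block(year) + genotype + genotype:year + residual``
  per irrigation condition, with cross-trait correlation applied to the
  genotype effects only (the screening stages operate on genotype means)
  and grain yield built as a linear combination of a subset of traits
  plus white noise.
* :func:`simulate_ct_table` emits qPCR Ct records with a stable reference
  gene and planted fold changes, so a planted fold ``f`` yields an
  expected ddCt of ``-log2(f)`` downstream.
* :func:`simulate_promoters` emits 1000-bp promoter sequences whose motif
  content is exact by construction: backgrounds are scrubbed of chance
  dictionary matches before the requested motifs are planted, and the
  emitted truth table equals a brute-force scan of the FASTA.

Year and location are confounded in multi-location-over-years trials of
this layout; the generators expose only "year" as the environment factor.

The module-level ``default_*`` constructors encode the reference study
conditions: 30 genotypes, 6 year/location environments, 3 blocks, two
irrigation conditions, 11 biochemical traits plus grain yield, with
per-trait variance magnitudes and means calibrated to a published
triticale panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import promoters as _pm

__all__ = [
    "SpecificationError",
    "TrialDesign",
    "TraitVariance",
    "VarianceSpec",
    "CtSpec",
    "PromoterEntry",
    "PromoterSpec",
    "simulate_trial",
    "simulate_ct_table",
    "simulate_promoters",
    "default_design",
    "default_variance_specs",
    "default_ct_spec",
    "default_promoter_spec",
    "TRAITS",
    "YIELD",
]


class SpecificationError(ValueError):
    """Raised when a simulation specification violates its invariants."""


TRAITS = (
    "H2O2", "MDH", "TChl", "Car", "Prtn", "PRL",
    "POD", "CAT", "APX", "GR", "SOD",
)
YIELD = "Yld"


@dataclass(frozen=True)
class TrialDesign:
    """Counts and labels of the balanced multi-environment trial."""

    n_years: int = 6
    n_blocks: int = 3
    n_genotypes: int = 30
    conditions: tuple[str, ...] = ("normal", "stress")
    trait_names: tuple[str, ...] = TRAITS

    def __post_init__(self):
        if min(self.n_years, self.n_blocks, self.n_genotypes) < 2:
            raise SpecificationError(
                "n_years, n_blocks and n_genotypes must all be >= 2 "
                "(variance-component denominators degenerate otherwise)"
            )
        if len(set(self.trait_names)) != len(self.trait_names):
            raise SpecificationError("trait names must be unique")
        if len(set(self.conditions)) != len(self.conditions):
            raise SpecificationError("condition labels must be unique")

    @property
    def years(self) -> tuple[str, ...]:
        return tuple(f"Y{i+1}" for i in range(self.n_years))

    @property
    def blocks(self) -> tuple[str, ...]:
        return tuple(f"B{i+1}" for i in range(self.n_blocks))

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(f"G{i+1:02d}" for i in range(self.n_genotypes))


@dataclass(frozen=True)
class TraitVariance:
    """Ground-truth moments for one trait (trait units / units squared)."""

    mean: float
    year: float
    block_in_year: float
    genotype: float
    gxy: float
    residual: float

    def __post_init__(self):
        for name in ("year", "block_in_year", "genotype", "gxy", "residual"):
            if getattr(self, name) < 0:
                raise SpecificationError(f"variance {name} must be >= 0")


@dataclass(frozen=True)
class VarianceSpec:
    """Simulation ground truth for one condition.

    ``genotype_corr`` (optional) is the correlation matrix of genotype
    effects across traits, in ``trait order``; residual, year and block
    effects stay independent across traits.  Yield is
    ``yield_mean + sum coef_t * (x_t - mean_t) + N(0, yield_noise_sigma2)``
    per plot.
    """

    traits: Mapping[str, TraitVariance]
    yield_coefs: Mapping[str, float] = field(default_factory=dict)
    yield_mean: float = 0.0
    yield_noise_sigma2: float = 1.0
    genotype_corr: np.ndarray | None = None

    def validate(self, trait_names) -> None:
        missing = set(trait_names) - set(self.traits)
        if missing:
            raise SpecificationError(f"no variance spec for traits {sorted(missing)}")
        unknown = set(self.yield_coefs) - set(trait_names)
        if unknown:
            raise SpecificationError(f"yield coefficients for unknown traits {sorted(unknown)}")
        if self.yield_noise_sigma2 < 0:
            raise SpecificationError("yield noise variance must be >= 0")
        if self.genotype_corr is not None:
            corr = np.asarray(self.genotype_corr, dtype=float)
            t = len(trait_names)
            if corr.shape != (t, t):
                raise SpecificationError(
                    f"genotype_corr must be {t}x{t} in trait order, got {corr.shape}"
                )
            if not np.allclose(corr, corr.T, atol=1e-10):
                raise SpecificationError("genotype_corr must be symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
                raise SpecificationError("genotype_corr must have unit diagonal")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise SpecificationError("genotype_corr must be positive semi-definite")


def _corr_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T = corr, valid for singular PSD matrices."""
    vals, vecs = np.linalg.eigh(corr)
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def simulate_trial(
    design: TrialDesign,
    spec: VarianceSpec | Mapping[str, VarianceSpec],
    seed: int,
) -> pd.DataFrame:
    """Draw one complete balanced trial table.

    ``spec`` is either one :class:`VarianceSpec` reused for every
    condition, or a condition -> spec mapping.  Returns a long-format
    frame with columns ``year, condition, block, genotype, <traits>...,
    Yld``, one row per plot; identical seeds give identical tables.
    """
    specs = (
        {c: spec for c in design.conditions}
        if isinstance(spec, VarianceSpec)
        else dict(spec)
    )
    missing = set(design.conditions) - set(specs)
    if missing:
        raise SpecificationError(f"no variance spec for conditions {sorted(missing)}")
    for s in specs.values():
        s.validate(design.trait_names)

    rng = np.random.default_rng(seed)
    ny, nb, ng = design.n_years, design.n_blocks, design.n_genotypes
    traits = list(design.trait_names)
    t = len(traits)
    frames = []
    for cond in design.conditions:
        s = specs[cond]
        tv = [s.traits[tr] for tr in traits]
        sd_gn = np.array([np.sqrt(v.genotype) for v in tv])

        z = rng.standard_normal((ng, t))
        if s.genotype_corr is not None:
            z = z @ _corr_factor(np.asarray(s.genotype_corr, dtype=float)).T
        g_eff = z * sd_gn  # (gn, trait)

        a_eff = rng.standard_normal((ny, t)) * np.array([np.sqrt(v.year) for v in tv])
        b_eff = rng.standard_normal((ny, nb, t)) * np.array(
            [np.sqrt(v.block_in_year) for v in tv]
        )
        ag_eff = rng.standard_normal((ny, ng, t)) * np.array(
            [np.sqrt(v.gxy) for v in tv]
        )
        e_eff = rng.standard_normal((ny, nb, ng, t)) * np.array(
            [np.sqrt(v.residual) for v in tv]
        )
        mu = np.array([v.mean for v in tv])

        x = (
            mu[None, None, None, :]
            + a_eff[:, None, None, :]
            + b_eff[:, :, None, :]
            + g_eff[None, None, :, :]
            + ag_eff[:, None, :, :]
            + e_eff
        )  # (yr, blk, gn, trait)

        centred = x - mu[None, None, None, :]
        coef = np.array([s.yield_coefs.get(tr, 0.0) for tr in traits])
        y = (
            s.yield_mean
            + centred @ coef
            + rng.standard_normal((ny, nb, ng)) * np.sqrt(s.yield_noise_sigma2)
        )

        idx = pd.MultiIndex.from_product(
            [design.years, design.blocks, design.genotypes],
            names=["year", "block", "genotype"],
        )
        frame = pd.DataFrame(x.reshape(-1, t), columns=traits, index=idx)
        frame[YIELD] = y.reshape(-1)
        frame = frame.reset_index()
        frame.insert(1, "condition", cond)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CtSpec:
    """Ground truth for the qPCR generator.

    ``fold_changes`` maps ``(genotype, tissue, time_h, gene)`` to the
    planted induction fold (treated vs control); unlisted cells default
    to 1.  ``noise_sd`` is the per-well Ct noise in cycles.
    """

    genotypes: tuple[str, ...] = ("G28", "G03")
    tissues: tuple[str, ...] = ("shoot", "root")
    time_points_h: tuple[int, ...] = (12, 36, 72)
    genes: tuple[str, ...] = ("Mn-SOD", "Cu/Zn-SOD", "Fe-SOD")
    reference_gene: str = "EF1"
    baseline_ct: Mapping = field(default_factory=dict)  # (gene, tissue) -> cycles
    default_baseline_ct: float = 26.0
    reference_ct: float = 20.0
    fold_changes: Mapping = field(default_factory=dict)
    noise_sd: float = 0.2
    n_replicates: int = 3

    def __post_init__(self):
        if self.noise_sd < 0:
            raise SpecificationError("noise SD must be >= 0")
        if self.n_replicates < 1:
            raise SpecificationError("need at least one replicate")
        for key, f in self.fold_changes.items():
            if f <= 0:
                raise SpecificationError(f"fold change for {key!r} must be > 0")


def simulate_ct_table(spec: CtSpec, seed: int) -> pd.DataFrame:
    """Emit Ct records: per (genotype, tissue, time, gene) one control pot
    with ``n_replicates`` wells and ``n_replicates`` treated wells.

    With zero noise the planted fold ``f`` gives ddCt exactly
    ``-log2(f)`` downstream.  Columns: ``genotype, tissue, time_h, gene,
    replicate, is_control, ct_target, ct_ref``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in spec.genotypes:
        for tissue in spec.tissues:
            for time_h in spec.time_points_h:
                for gene in spec.genes:
                    base = spec.baseline_ct.get(
                        (gene, tissue), spec.default_baseline_ct
                    )
                    fold = spec.fold_changes.get(
                        (genotype, tissue, time_h, gene), 1.0
                    )
                    for is_control in (True, False):
                        shift = 0.0 if is_control else -np.log2(fold)
                        for rep in range(1, spec.n_replicates + 1):
                            rows.append(
                                {
                                    "genotype": genotype,
                                    "tissue": tissue,
                                    "time_h": time_h,
                                    "gene": gene,
                                    "replicate": rep,
                                    "is_control": is_control,
                                    "ct_target": base
                                    + shift
                                    + rng.normal(0.0, spec.noise_sd),
                                    "ct_ref": spec.reference_ct
                                    + rng.normal(0.0, spec.noise_sd),
                                }
                            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PromoterEntry:
    """Planted motif composition for one (gene, genome set)."""

    gene: str
    genome_set: str
    n_sequences: int = 2
    length: int = 1000
    planted: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.genome_set not in ("A", "B", "D"):
            raise SpecificationError("genome_set must be one of A, B, D")
        if self.n_sequences < 1 or self.length < 1:
            raise SpecificationError("n_sequences and length must be >= 1")
        for cls, count in self.planted.items():
            if count < 0:
                raise SpecificationError(f"planted count for {cls!r} must be >= 0")


@dataclass(frozen=True)
class PromoterSpec:
    """Promoter generator ground truth: entries plus the motif dictionary
    used both for planting and for scrubbing chance background matches."""

    entries: tuple[PromoterEntry, ...]
    dictionary: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_pm.DEFAULT_MOTIF_CLASSES)
    )
    background: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)

    def validate(self) -> None:
        _pm.validate_dictionary(dict(self.dictionary))
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise SpecificationError("background composition must be a probability vector")
        for e in self.entries:
            unknown = set(e.planted) - set(self.dictionary)
            if unknown:
                raise SpecificationError(
                    f"entry {e.gene}/{e.genome_set}: planted classes not in "
                    f"dictionary: {sorted(unknown)}"
                )
            load = sum(
                count * max(len(m) for m in self.dictionary[cls])
                for cls, count in e.planted.items()
                if count
            )
            if load > e.n_sequences * e.length:
                raise SpecificationError(
                    f"entry {e.gene}/{e.genome_set}: planted motifs need {load} bp "
                    f"but only {e.n_sequences * e.length} bp are available"
                )


def _scrub_background(seq: list, dictionary: dict, rng, max_iter: int = 60) -> bool:
    """Re-randomize every dictionary match until the sequence is clean."""
    bases = "ACGT"
    for _ in range(max_iter):
        text = "".join(seq)
        spans = []
        for motifs in dictionary.values():
            for motif in motifs:
                for pat in {motif.upper(), _pm.reverse_complement(motif)}:
                    regex = _pm._motif_regex(pat)
                    spans.extend(
                        (m.start(), m.start() + len(pat))
                        for m in regex.finditer(text)
                    )
        if not spans:
            return True
        for start, stop in spans:
            for i in range(start, stop):
                seq[i] = bases[rng.integers(4)]
    return False


def _concretize(motif: str, rng) -> str:
    return "".join(
        _pm.IUPAC_CODES[c][rng.integers(len(_pm.IUPAC_CODES[c]))]
        for c in motif.upper()
    )


def simulate_promoters(
    spec: PromoterSpec, seed: int
) -> tuple[list[_pm.PromoterRecord], pd.DataFrame]:
    """Emit promoter records and the planted-truth table.

    Backgrounds are drawn from ``spec.background`` and scrubbed of chance
    dictionary matches by rejection/re-randomization; planted motifs are
    then inserted at non-overlapping positions and the finished sequence
    re-scanned, retrying until the scan equals the planted composition,
    so the truth table is exact by construction.  Truth columns: gene,
    genome_set, element_class, count.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    dictionary = dict(spec.dictionary)
    bases = np.array(list("ACGT"))
    records: list[_pm.PromoterRecord] = []
    truth_rows = []
    chrom_cycle = (1, 2, 3, 4, 5, 6, 7)

    for entry in spec.entries:
        # distribute each class's count across the entry's sequences
        per_seq: list[dict[str, int]] = [dict() for _ in range(entry.n_sequences)]
        for cls, count in sorted(entry.planted.items()):
            for _ in range(count):
                order = rng.permutation(entry.n_sequences)
                motif_len = max(len(m) for m in dictionary[cls])
                for si in order:
                    load = sum(
                        c * max(len(m) for m in dictionary[k])
                        for k, c in per_seq[si].items()
                    )
                    if load + motif_len <= entry.length // 2:
                        per_seq[si][cls] = per_seq[si].get(cls, 0) + 1
                        break
                else:
                    si = int(order[0])
                    per_seq[si][cls] = per_seq[si].get(cls, 0) + 1

        for si in range(entry.n_sequences):
            target = per_seq[si]
            for attempt in range(40):
                seq = list(bases[rng.choice(4, size=entry.length, p=spec.background)])
                if not _scrub_background(seq, dictionary, rng):
                    continue
                occupied: list[tuple[int, int]] = []
                ok = True
                for cls, count in sorted(target.items()):
                    for _ in range(count):
                        motif = dictionary[cls][rng.integers(len(dictionary[cls]))]
                        site = _concretize(motif, rng)
                        placed = False
                        for _ in range(200):
                            start = int(rng.integers(0, entry.length - len(site) + 1))
                            span = (start, start + len(site))
                            if all(
                                span[1] <= a or span[0] >= b for a, b in occupied
                            ):
                                seq[span[0]:span[1]] = list(site)
                                occupied.append(span)
                                placed = True
                                break
                        if not placed:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    continue
                text = "".join(seq)
                counts = _pm.scan_motifs(text, dictionary)
                if all(counts.get(c, 0) == target.get(c, 0) for c in dictionary):
                    chrom = f"{chrom_cycle[si % len(chrom_cycle)]}{entry.genome_set}"
                    records.append(
                        _pm.PromoterRecord(
                            gene=entry.gene,
                            chromosome=chrom,
                            seq_id=f"{entry.gene}_{entry.genome_set}_{si+1}",
                            sequence=text,
                        )
                    )
                    break
            else:
                raise SpecificationError(
                    f"could not realize planted composition for "
                    f"{entry.gene}/{entry.genome_set} sequence {si+1}; "
                    "composition too dense for the sequence length"
                )
        for cls in sorted(dictionary):
            truth_rows.append(
                {
                    "gene": entry.gene,
                    "genome_set": entry.genome_set,
                    "element_class": cls,
                    "count": int(entry.planted.get(cls, 0)),
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "genome_set", "element_class", "count"]
    )
    return records, truth


# ---------------------------------------------------------------------------
# Reference study conditions
# ---------------------------------------------------------------------------

# Per-trait (genotypic variance, environmental variance, mean) magnitudes of
# the calibrating triticale panel, one block per irrigation condition.
_TRAIT_CALIBRATION = {
    "normal": {
        "H2O2": (0.05, 0.20, 3.33),
        "MDH": (0.70, 1.01, 4.05),
        "TChl": (2.10, 5.84, 18.1),
        "Car": (0.83, 0.51, 5.19),
        "Prtn": (0.31, 4.22, 14.5),
        "PRL": (1.20, 5.02, 8.91),
        "POD": (1.03, 2.90, 13.2),
        "CAT": (0.04, 0.45, 2.07),
        "APX": (21.87, 19.18, 122.8),
        "GR": (0.70, 0.73, 2.61),
        "SOD": (1.64, 4.05, 12.0),
    },
    "stress": {
        "H2O2": (0.27, 4.56, 7.69),
        "MDH": (0.95, 3.76, 14.1),
        "TChl": (6.06, 5.26, 13.2),
        "Car": (2.05, 1.05, 6.06),
        "Prtn": (0.77, 17.7, 35.0),
        "PRL": (6.85, 6.78, 19.18),
        "POD": (13.42, 20.68, 43.51),
        "CAT": (0.52, 1.59, 6.28),
        "APX": (38.55, 115.3, 168.5),
        "GR": (0.93, 1.73, 6.75),
        "SOD": (20.06, 12.85, 43.21),
    },
}

# Environmental variance split across the random effects of the model:
# chosen once to give each component a realistic share of non-genetic
# spread (years dominate, blocks contribute least).
_ENV_SPLIT = {"year": 1.5, "block_in_year": 0.25, "gxy": 0.6, "residual": 1.0}

_YIELD_MODELS = {
    # stress: yield driven positively by SOD, negatively by proline and GR
    "stress": ({"SOD": 4.66, "PRL": -4.15, "GR": -8.44}, 305.1, 3500.0),
    # normal: protein content alone, with a negative slope
    "normal": ({"Prtn": -27.79}, 741.1, 1700.0),
}

# modest genotype-effect correlation inside the two trait groups that
# co-cluster in practice (oxidative-load markers; osmotic/redox markers)
_CORR_GROUPS = (("APX", "H2O2", "SOD", "MDH"), ("GR", "PRL", "CAT"))
_CORR_RHO = 0.4


def default_design() -> TrialDesign:
    return TrialDesign()


def _default_corr(trait_names) -> np.ndarray:
    t = len(trait_names)
    corr = np.eye(t)
    index = {name: i for i, name in enumerate(trait_names)}
    for group in _CORR_GROUPS:
        members = [index[g] for g in group if g in index]
        for i in members:
            for j in members:
                if i != j:
                    corr[i, j] = _CORR_RHO
    return corr


def default_variance_specs(design: TrialDesign | None = None) -> dict[str, VarianceSpec]:
    """The reference study conditions as simulation ground truth."""
    design = design or default_design()
    specs = {}
    for cond in design.conditions:
        calib = _TRAIT_CALIBRATION[cond]
        traits = {}
        for name in design.trait_names:
            s_gn, s_env, mean = calib[name]
            traits[name] = TraitVariance(
                mean=mean,
                year=_ENV_SPLIT["year"] * s_env,
                block_in_year=_ENV_SPLIT["block_in_year"] * s_env,
                genotype=s_gn,
                gxy=_ENV_SPLIT["gxy"] * s_env,
                residual=_ENV_SPLIT["residual"] * s_env,
            )
        coefs, y_mean, y_noise = _YIELD_MODELS[cond]
        specs[cond] = VarianceSpec(
            traits=traits,
            yield_coefs=coefs,
            yield_mean=y_mean,
            yield_noise_sigma2=y_noise,
            genotype_corr=_default_corr(design.trait_names),
        )
    return specs


def default_ct_spec() -> CtSpec:
    """Greenhouse assay conditions: a tolerant and a susceptible genotype,
    shoot and root, 12/36/72 h after stress, three SOD isozymes.

    Planted folds mirror the qualitative expression contrasts of the
    reference assay: Mn-SOD induced in both genotypes and rising with
    time, Cu/Zn-SOD induced genotype-specifically (higher in the tolerant
    genotype), Fe-SOD declining with time in both.
    """
    folds = {}
    mn = {12: 1.5, 36: 2.5, 72: 4.0}
    fe = {12: 1.6, 36: 1.1, 72: 0.7}
    for tissue in ("shoot", "root"):
        for t, f in mn.items():
            folds[("G28", tissue, t, "Mn-SOD")] = f * 3.0
            folds[("G03", tissue, t, "Mn-SOD")] = f
        for t, f in fe.items():
            folds[("G28", tissue, t, "Fe-SOD")] = f * 1.1
            folds[("G03", tissue, t, "Fe-SOD")] = f
    cu28 = {12: 1.5, 36: 2.8, 72: 5.0}
    cu3 = {12: 1.2, 36: 1.6, 72: 1.7}
    for t in (12, 36, 72):
        folds[("G28", "shoot", t, "Cu/Zn-SOD")] = cu28[t]
        folds[("G28", "root", t, "Cu/Zn-SOD")] = cu28[t] * 1.3
        folds[("G03", "shoot", t, "Cu/Zn-SOD")] = cu3[t]
        folds[("G03", "root", t, "Cu/Zn-SOD")] = {12: 1.4, 36: 0.8, 72: 1.2}[t]
    return CtSpec(fold_changes=folds)


def default_promoter_spec() -> PromoterSpec:
    """Planted promoter compositions: the SOD family rich in stress-related
    elements concentrated in the A (and D) genome sets, the remaining
    antioxidant genes sparser — a scaled-down echo of wheat promoter
    annotation."""
    rich = {
        "circadian control": 2,
        "abscisic acid responsive": 3,
        "auxin-responsive": 2,
        "MYB binding site": 3,
        "MeJA-responsive": 3,
        "gibberellin-responsive": 2,
        "light responsive": 3,
    }
    moderate = {
        "abscisic acid responsive": 1,
        "light responsive": 2,
        "MeJA-responsive": 1,
        "MYB binding site": 1,
    }
    sparse = {"light responsive": 1, "endosperm expression": 1}
    entries = [
        PromoterEntry("SOD", "A", n_sequences=2, planted=rich),
        PromoterEntry("SOD", "B", n_sequences=1, planted={}),
        PromoterEntry("SOD", "D", n_sequences=2, planted=moderate),
        PromoterEntry("APX", "A", n_sequences=2, planted=moderate),
        PromoterEntry("APX", "B", n_sequences=1, planted=sparse),
        PromoterEntry("APX", "D", n_sequences=1, planted=sparse),
        PromoterEntry("CAT", "A", n_sequences=2, planted=moderate),
        PromoterEntry("CAT", "B", n_sequences=1, planted=sparse),
        PromoterEntry("CAT", "D", n_sequences=1, planted=sparse),
        PromoterEntry("POD", "A", n_sequences=1, planted=sparse),
        PromoterEntry("POD", "B", n_sequences=1, planted={}),
        PromoterEntry("POD", "D", n_sequences=1, planted=sparse),
        PromoterEntry("GR", "A", n_sequences=1, planted=moderate),
        PromoterEntry("GR", "B", n_sequences=1, planted={}),
        PromoterEntry("GR", "D", n_sequences=1, planted=sparse),
    ]
    return PromoterSpec(entries=tuple(entries))
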