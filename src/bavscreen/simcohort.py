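"""Synthetic cohort generator.

Emulates the statistical structure the pipeline assumes, at the
annotated-variant level (no reads, alignment or calling error):

* a discovery cohort (default 20 exomes) of background SNVs whose
  functional-class mix follows the published per-sample count
  proportions, whose population MAFs are log-uniform straddling the 0.05
  rarity threshold, and whose in-silico scores straddle the SIFT and
  PolyPhen cutoffs — plus *planted* deleterious variants realized with
  exact carrier counts and recorded in a ground-truth ledger;
* a validation + control cohort (defaults 137 and 130 patients) in which
  per-gene carrier status is Bernoulli at configurable per-cohort rates,
  and quantitative phenotypes (LVEF %, valve calcification volume mm3)
  are truncated Gaussians whose means shift with carrier status
  (dominant model, two-group mean shift);
* a deterministic fixture cohort realizing the published per-gene
  carrier counts and the 87/12 carrier/non-carrier phenotype split
  exactly, with group means and SDs matched to machine precision by
  affine-standardized Gaussian scores.

Everything is driven by one integer seed through numpy's PCG64
generator; a fixed seed reproduces cohorts bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .cohort_model import (
    MISSING_DOSAGE,
    GenotypeMatrix,
    PhenotypeRecord,
    ValidationError,
    VariantRecord,
    fixtures,
)

__all__ = [
    "ScoreModel",
    "MafModel",
    "PlantedVariant",
    "PhenotypeModel",
    "GroupModel",
    "SimSpec",
    "default_planted",
    "simulate_discovery",
    "simulate_validation",
    "table_fixture_cohort",
    "spec_from_dict",
    "spec_to_dict",
]

#: Functional-class mix of background variants, proportional to the
#: published mean per-exome counts (total 299,980: 12,009 missense, 108
#: stopgain, 15 stoploss, 12,347 synonymous, 150,250 intronic, 97,272
#: intergenic; splicing and the remaining categories folded into small
#: "splicing"/"other" masses).
DEFAULT_CLASS_COUNTS = {
    "missense": 12009,
    "stopgain": 108,
    "stoploss": 15,
    "splicing": 300,
    "synonymous": 12347,
    "intronic": 150250,
    "intergenic": 97272,
    "other": 27679,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ScoreModel:
    """Uniform ranges the background SIFT / PolyPhen scores are drawn from.

    The defaults span [0, 1] so background scores straddle both cutoffs;
    ``clean_background`` shifts both ranges above the deleterious region
    so no background variant can pass the implication filter, which makes
    planted-variant recovery exact by construction.
    """

    sift_range: tuple[float, float] = (0.0, 1.0)
    polyphen_range: tuple[float, float] = (0.0, 1.0)

    @classmethod
    def clean_background(cls) -> "ScoreModel":
        return cls(sift_range=(0.06, 1.0), polyphen_range=(0.0, 0.45))


@dataclass(frozen=True)
class MafModel:
    """Log-uniform global MAF with correlated East Asian MAF.

    The EAS frequency is the global one perturbed by a lognormal factor
    (sd on the log scale), clipped to [0, 0.5]; the default range
    straddles the 0.05 rarity threshold.
    """

    low: float = 1e-4
    high: float = 0.5
    eas_log_sd: float = 0.5


@dataclass(frozen=True)
class PlantedVariant:
    """Ground-truth deleterious variant injected into simulated cohorts."""

    gene: str
    discovery_carriers: int = 2
    validation_carrier_p: float = 0.1
    control_carrier_p: float = 0.01
    sift: float = 0.01
    polyphen: float = 0.99
    maf_1kg: float = 0.005
    maf_1kg_eas: float = 0.01

    def __post_init__(self) -> None:
        for name in ("validation_carrier_p", "control_carrier_p", "sift", "polyphen",
                     "maf_1kg", "maf_1kg_eas"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GroupModel:
    mean: float
    sd: float


@dataclass(frozen=True)
class PhenotypeModel:
    """Truncated-Gaussian phenotype models by carrier status.

    Defaults are the published validation-cohort summaries: LVEF 63.8 +/-
    7.5 % in non-carriers vs 58.4 +/- 5.2 % in carriers, calcification
    volume 1129.3 +/- 154 vs 1261.8 +/- 123 mm3.  LVEF is truncated to
    (0, 100], calcification to [0, inf).
    """

    lvef_noncarrier: GroupModel = GroupModel(63.8, 7.5)
    lvef_carrier: GroupModel = GroupModel(58.4, 5.2)
    calc_noncarrier: GroupModel = GroupModel(1129.3, 154.0)
    calc_carrier: GroupModel = GroupModel(1261.8, 123.0)

    @classmethod
    def null(cls) -> "PhenotypeModel":
        """Carrier status has no phenotype effect (type-I-error studies)."""
        return cls(
            lvef_noncarrier=GroupModel(63.8, 7.5),
            lvef_carrier=GroupModel(63.8, 7.5),
            calc_noncarrier=GroupModel(1129.3, 154.0),
            calc_carrier=GroupModel(1129.3, 154.0),
        )


def default_planted() -> tuple[PlantedVariant, ...]:
    """Planted variants for the nine validation-panel genes.

    Discovery carrier counts and annotations come from the published
    candidate table; validation/control carrier probabilities are the
    published per-gene carrier counts over the cohort sizes (137, 130).
    """
    fx = fixtures()
    by_gene = {row.variant.gene: row for row in fx.table3}
    planted = []
    for t4 in fx.table4:
        cand = by_gene[t4.gene]
        planted.append(
            PlantedVariant(
                gene=t4.gene,
                discovery_carriers=cand.case_count,
                validation_carrier_p=t4.validation_carriers / fx.n_validation,
                control_carrier_p=t4.control_carriers / fx.n_control,
                sift=cand.variant.sift,
                polyphen=cand.variant.polyphen,
                maf_1kg=cand.variant.maf_1kg,
                maf_1kg_eas=cand.variant.maf_1kg_eas,
            )
        )
    return tuple(planted)


@dataclass(frozen=True)
class SimSpec:
    """Full configuration of a simulated study.

    Cohort sizes default to the study's (20 discovery, 137 validation,
    130 control); the background variant count defaults to 2,000, a
    scaled-down stand-in for the ~300,000 SNVs of a real exome that keeps
    simulation fast — full-scale runs are a matter of raising
    ``n_variants``.
    """

    seed: int = 0
    n_discovery: int = 20
    n_validation: int = 137
    n_control: int = 130
    n_variants: int = 2000
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    maf_model: MafModel = MafModel()
    score_model: ScoreModel = ScoreModel()
    planted: tuple[PlantedVariant, ...] = field(default_factory=default_planted)
    phenotype_model: PhenotypeModel = PhenotypeModel()

    def __post_init__(self) -> None:
        for name in ("n_discovery", "n_validation", "n_control"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_variants < 0:
            raise ValidationError("n_variants must be >= 0")
        if any(w < 0 for w in self.class_mix.values()) or sum(self.class_mix.values()) <= 0:
            raise ValidationError("class_mix weights must be non-negative and sum > 0")
        for pv in self.planted:
            if pv.discovery_carriers > self.n_discovery:
                raise ValidationError(
                    f"planted {pv.gene}: {pv.discovery_carriers} carriers exceed "
                    f"discovery cohort size {self.n_discovery}"
                )

    def replace(self, **kwargs) -> "SimSpec":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Discovery cohort


def _background_variant(i: int, rng: np.random.Generator, spec: SimSpec,
                        classes: list[str], probs: np.ndarray) -> VariantRecord:
    chrom = str(rng.integers(1, 23))
    pos = int(1 + i * 1000 + rng.integers(0, 1000))
    ref, alt = rng.choice(4, size=2, replace=False)
    func = classes[rng.choice(len(classes), p=probs)]
    mm = spec.maf_model
    maf = float(np.exp(rng.uniform(np.log(mm.low), np.log(mm.high))))
    eas = float(np.clip(maf * np.exp(rng.normal(0.0, mm.eas_log_sd)), 0.0, 0.5))
    sm = spec.score_model
    sift = float(rng.uniform(*sm.sift_range))
    pph = float(rng.uniform(*sm.polyphen_range))
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=str(_BASES[ref]),
        alt=str(_BASES[alt]),
        gene=f"BG{i:05d}",
        func_class=func,
        maf_1kg=round(maf, 6),
        maf_1kg_eas=round(eas, 6),
        sift=round(sift, 6),
        polyphen=round(pph, 6),
    )


def simulate_discovery(
    spec: SimSpec,
) -> tuple[list[VariantRecord], GenotypeMatrix, dict]:
    """Simulate the discovery cohort: background + planted variants.

    Background dosages are Binomial(2, MAF) per sample (Hardy-Weinberg
    carriage at the panel frequency); planted variants get exactly their
    intended number of heterozygous carriers, drawn without replacement.
    The ledger records ground truth for every planted variant.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"D{i + 1:03d}" for i in range(spec.n_discovery)]
    classes = sorted(spec.class_mix)
    weights = np.array([spec.class_mix[c] for c in classes], dtype=float)
    probs = weights / weights.sum()

    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    for i in range(spec.n_variants):
        v = _background_variant(i, rng, spec, classes, probs)
        variants.append(v)
        dosage_cols.append(rng.binomial(2, v.maf_1kg, size=spec.n_discovery).astype(np.int8))

    ledger: dict = {"planted": []}
    base_pos = (spec.n_variants + 1) * 1000
    for j, pv in enumerate(spec.planted):
        v = VariantRecord(
            chrom=str(1 + j % 22),
            pos=base_pos + j * 1000,
            ref="C",
            alt="T",
            gene=pv.gene,
            func_class="missense",
            maf_1kg=pv.maf_1kg,
            maf_1kg_eas=pv.maf_1kg_eas,
            sift=pv.sift,
            polyphen=pv.polyphen,
        )
        carriers = rng.choice(spec.n_discovery, size=pv.discovery_carriers, replace=False)
        col = np.zeros(spec.n_discovery, dtype=np.int8)
        col[carriers] = 1  # heterozygous carriers
        variants.append(v)
        dosage_cols.append(col)
        ledger["planted"].append(
            {
                "gene": pv.gene,
                "variant_key": v.key,
                "discovery_carriers": int(pv.discovery_carriers),
                "carrier_sample_ids": sorted(sample_ids[i] for i in carriers),
                "sift": pv.sift,
                "polyphen": pv.polyphen,
                "maf_1kg": pv.maf_1kg,
                "maf_1kg_eas": pv.maf_1kg_eas,
            }
        )

    dosage = np.stack(dosage_cols, axis=1) if dosage_cols else np.zeros(
        (spec.n_discovery, 0), dtype=np.int8
    )
    matrix = GenotypeMatrix(
        sample_ids, [v.key for v in variants], dosage, [v.gene for v in variants]
    )
    return variants, matrix, ledger


# ---------------------------------------------------------------------------
# Validation cohort


def _truncated_normal(
    rng: np.random.Generator, model: GroupModel, low: float, high: float
) -> float:
    """Redraw until inside bounds (bounds are many SDs out for defaults)."""
    for _ in range(1000):
        x = rng.normal(model.mean, model.sd)
        if low < x <= high:
            return float(x)
    raise RuntimeError("truncated normal failed to converge")


def simulate_validation(
    spec: SimSpec,
) -> tuple[GenotypeMatrix, list[PhenotypeRecord], dict]:
    """Simulate validation (cases) and control cohorts with phenotypes.

    Carrier status per planted gene is Bernoulli at the per-cohort rate;
    patients carrying at least one planted variant draw phenotypes from
    the carrier models, the rest from the non-carrier models.
    """
    rng = np.random.default_rng(spec.seed + 1)  # decoupled from discovery stream
    val_ids = [f"V{i + 1:03d}" for i in range(spec.n_validation)]
    ctl_ids = [f"C{i + 1:03d}" for i in range(spec.n_control)]
    sample_ids = val_ids + ctl_ids
    n = len(sample_ids)

    keys, genes, cols = [], [], []
    for j, pv in enumerate(spec.planted):
        key = f"{1 + j % 22}:{(j + 1) * 1000}:C:T"
        carrier_val = rng.random(spec.n_validation) < pv.validation_carrier_p
        carrier_ctl = rng.random(spec.n_control) < pv.control_carrier_p
        col = np.concatenate([carrier_val, carrier_ctl]).astype(np.int8)
        keys.append(key)
        genes.append(pv.gene)
        cols.append(col)
    dosage = np.stack(cols, axis=1) if cols else np.zeros((n, 0), dtype=np.int8)
    matrix = GenotypeMatrix(sample_ids, keys, dosage, genes)

    pm = spec.phenotype_model
    any_carrier = (dosage >= 1).any(axis=1)
    phenotypes: list[PhenotypeRecord] = []
    for i, sid in enumerate(sample_ids):
        cohort = "validation" if i < spec.n_validation else "control"
        carrier = bool(any_carrier[i])
        lvef_model = pm.lvef_carrier if carrier else pm.lvef_noncarrier
        calc_model = pm.calc_carrier if carrier else pm.calc_noncarrier
        phenotypes.append(
            PhenotypeRecord(
                sample_id=sid,
                cohort=cohort,
                sex="male" if rng.random() < 0.55 else "female",
                age=float(np.round(_truncated_normal(rng, GroupModel(64.6, 10.8), 18, 100), 1)),
                lvef=float(np.round(_truncated_normal(rng, lvef_model, 0.0, 100.0), 2)),
                calc_volume=float(np.round(_truncated_normal(rng, calc_model, 0.0, np.inf), 1)),
            )
        )

    ledger = {
        "planted": [
            {
                "gene": pv.gene,
                "variant_key": keys[j],
                "validation_carriers": int(dosage[: spec.n_validation, j].sum()),
                "control_carriers": int(dosage[spec.n_validation:, j].sum()),
            }
            for j, pv in enumerate(spec.planted)
        ],
        "carrier_sample_ids": sorted(
            sid for sid, c in zip(sample_ids, any_carrier) if c
        ),
        "n_validation_carriers": int(any_carrier[: spec.n_validation].sum()),
    }
    return matrix, phenotypes, ledger


# ---------------------------------------------------------------------------
# Deterministic fixture cohort realizing the printed marginals


def _standardized_scores(n: int, seed: int) -> np.ndarray:
    """Gaussian quantile scores affine-standardized to mean 0, SD 1 (ddof=1)."""
    z = _stats.norm.ppf((np.arange(n) + 0.5) / n)
    rng = np.random.default_rng(seed)
    rng.shuffle(z)
    z = (z - z.mean()) / z.std(ddof=1)
    return z


def table_fixture_cohort() -> tuple[GenotypeMatrix, list[PhenotypeRecord]]:
    """Deterministic cohort whose marginals equal the printed tables.

    Per-gene carrier counts in validation (n=137) and control (n=130)
    equal the published values exactly; the 123 validation gene-carrier
    slots are distributed round-robin over the first 87 patients, so the
    carrier/non-carrier split is (87, 50).  Phenotypes are
    affine-standardized Gaussian scores, so each group's sample mean and
    SD equal the published summaries to machine precision.  The overlap
    arrangement is one of many consistent with the marginals.
    """
    fx = fixtures()
    n_val, n_ctl = fx.n_validation, fx.n_control
    val_ids = [f"V{i + 1:03d}" for i in range(n_val)]
    ctl_ids = [f"C{i + 1:03d}" for i in range(n_ctl)]
    n_carriers = 87

    genes = [row.gene for row in fx.table4]
    dosage = np.zeros((n_val + n_ctl, len(genes)), dtype=np.int8)
    pointer = 0
    for j, row in enumerate(fx.table4):
        for _ in range(row.validation_carriers):
            dosage[pointer % n_carriers, j] = 1
            pointer += 1
    ctl_pointer = 0
    for j, row in enumerate(fx.table4):
        for _ in range(row.control_carriers):
            dosage[n_val + (ctl_pointer % n_ctl), j] = 1
            ctl_pointer += 1

    keys = [f"{1 + j}:{(j + 1) * 1000}:C:T" for j in range(len(genes))]
    matrix = GenotypeMatrix(val_ids + ctl_ids, keys, dosage, genes)

    carrier_mask = (dosage[:n_val] >= 1).any(axis=1)
    assert carrier_mask.sum() == n_carriers

    lvef_c = fx.table5[("lvef", "with_mutation")]
    lvef_n = fx.table5[("lvef", "no_mutation")]
    calc_c = fx.table5[("calc_volume", "with_mutation")]
    calc_n = fx.table5[("calc_volume", "no_mutation")]
    z_c = _standardized_scores(n_carriers, seed=20)
    z_n = _standardized_scores(n_val - n_carriers, seed=21)
    z_c2 = _standardized_scores(n_carriers, seed=22)
    z_n2 = _standardized_scores(n_val - n_carriers, seed=23)

    phenotypes: list[PhenotypeRecord] = []
    ic = inc = 0
    for i, sid in enumerate(val_ids):
        if carrier_mask[i]:
            lvef = lvef_c.mean + lvef_c.sd * z_c[ic]
            calc = calc_c.mean + calc_c.sd * z_c2[ic]
            ic += 1
        else:
            lvef = lvef_n.mean + lvef_n.sd * z_n[inc]
            calc = calc_n.mean + calc_n.sd * z_n2[inc]
            inc += 1
        phenotypes.append(
            PhenotypeRecord(
                sample_id=sid, cohort="validation", lvef=float(lvef), calc_volume=float(calc)
            )
        )
    for sid in ctl_ids:
        phenotypes.append(PhenotypeRecord(sample_id=sid, cohort="control"))
    return matrix, phenotypes


# ---------------------------------------------------------------------------
# YAML-friendly (de)serialization of SimSpec


def spec_to_dict(spec: SimSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["planted"] = [dataclasses.asdict(p) for p in spec.planted]
    return d


def spec_from_dict(d: dict) -> SimSpec:
    """Build a SimSpec from a plain dict (e.g. parsed YAML).

    Unknown keys raise a :class:`ValidationError` naming the key.
    """
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SimSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "maf_model" in d and isinstance(d["maf_model"], dict):
        d["maf_model"] = MafModel(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in d["maf_model"].items()})
    if "score_model" in d and isinstance(d["score_model"], dict):
        d["score_model"] = ScoreModel(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in d["score_model"].items()}
        )
    if "planted" in d:
        d["planted"] = tuple(
            PlantedVariant(**p) if isinstance(p, dict) else p for p in d["planted"]
        )
    if "phenotype_model" in d and isinstance(d["phenotype_model"], dict):
        pm = {
            k: GroupModel(**v) if isinstance(v, dict) else v
            for k, v in d["phenotype_model"].items()
        }
        d["phenotype_model"] = PhenotypeModel(**pm)
    return SimSpec(**d)
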