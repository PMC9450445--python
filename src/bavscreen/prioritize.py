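"""Discovery-stage rare-variant prioritization cascade.

Ordered filters over annotated SNVs from a sequenced case cohort:

1. nonsynonymous — keep protein-altering or splice-site classes
   (missense, stopgain, stoploss, splicing);
2. rarity — both population MAFs (global and East Asian 1000 Genomes)
   strictly below ``maf_max`` (default 0.05);
3. in-silico implication — unanimous agreement of SIFT (score strictly
   below ``sift_max``, default 0.05) and PolyPhen (class D, probably
   damaging, or optionally P, possibly damaging);
4. recurrence — carried by at least ``min_case_count`` distinct patients
   (default 2; a homozygote counts once);
5. optional gene allow-list — stands in for a manual curation step.

Stage order is part of the contract: the filters commute as predicates,
but the surviving-count report depends on the order they are applied.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_model import (
    NONSYNONYMOUS_CLASSES,
    CandidateRow,
    CascadeReport,
    GenotypeMatrix,
    PipelineConfig,
    VariantRecord,
)

__all__ = [
    "is_nonsynonymous",
    "passes_maf",
    "sift_deleterious",
    "polyphen_class",
    "is_implicated",
    "carrier_count",
    "is_recurrent",
    "run_cascade",
    "STAGE_NAMES",
    "per_sample_counts",
    "summarize_count_table",
]


def is_nonsynonymous(func_class: str) -> bool:
    """True for protein-altering or splice-disrupting functional classes."""
    return func_class in NONSYNONYMOUS_CLASSES


def passes_maf(maf_1kg: float, maf_1kg_eas: float, maf_max: float = 0.05) -> bool:
    """True iff both population MAFs are strictly below the threshold."""
    for maf in (maf_1kg, maf_1kg_eas):
        if not 0.0 <= maf <= 1.0:
            raise ValueError(f"MAF {maf} outside [0, 1]")
    return maf_1kg < maf_max and maf_1kg_eas < maf_max


def sift_deleterious(score: float | None, sift_max: float = 0.05) -> bool:
    """True iff the SIFT score is present and strictly below the cutoff.

    SIFT estimates the probability that a substitution is tolerated, so
    low scores mean deleterious.  A missing score is non-deleterious under
    the default policy (unscored variants cannot claim implication).
    """
    if score is None:
        return False
    return score < sift_max


def polyphen_class(
    score: float,
    benign_max: float = 0.452,
    possible_max: float = 0.956,
) -> str:
    """Bin a PolyPhen probability into B (benign), P (possibly damaging)
    or D (probably damaging).

    The published bins are B: 0-0.452, P: 0.453-0.956, D: 0.957-1, which
    leave open gaps between bin edges; a score strictly inside a gap
    (e.g. 0.4525 or 0.9565) resolves to the upper, more damaging class —
    conservative for a screening filter.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PolyPhen score {score} outside [0, 1]")
    if score <= benign_max:
        return "B"
    if score > possible_max:
        return "D"
    return "P"


def is_implicated(v: VariantRecord, cfg: PipelineConfig | None = None) -> bool:
    """Unanimous in-silico implication: SIFT deleterious AND PolyPhen damaging.

    Either score missing breaks unanimity and the variant is not implicated.
    """
    cfg = cfg or PipelineConfig()
    if v.sift is None or v.polyphen is None:
        return False
    if not sift_deleterious(v.sift, cfg.sift_max):
        return False
    cls = polyphen_class(v.polyphen, cfg.polyphen_benign_max, cfg.polyphen_possible_max)
    return cls in cfg.polyphen_damaging_classes


def carrier_count(g: GenotypeMatrix, variant_key: str) -> int:
    """Number of distinct samples with allele dosage >= 1 at the variant.

    Missing dosages do not count as carriage.
    """
    return int((g.dosages(variant_key) >= 1).sum())


def is_recurrent(case_count: int, min_case_count: int = 2) -> bool:
    """True iff the variant was seen in at least ``min_case_count`` patients."""
    if case_count < 0 or min_case_count < 0:
        raise ValueError("counts must be non-negative")
    return case_count >= min_case_count


STAGE_NAMES = (
    "input",
    "nonsynonymous",
    "rare_both_panels",
    "in_silico_implicated",
    "recurrent",
    "gene_allowlist",
)


def run_cascade(
    variants: Sequence[VariantRecord],
    g: GenotypeMatrix,
    cfg: PipelineConfig | None = None,
) -> tuple[list[CandidateRow], CascadeReport]:
    """Apply the filter cascade and report surviving counts per stage.

    Returns candidates (each with its carrier count) sorted by chromosomal
    sequence, and a :class:`CascadeReport` whose first entry is the input
    count.  The allow-list stage appears only when ``cfg.gene_allowlist``
    is set.
    """
    cfg = cfg or PipelineConfig()
    stages: list[tuple[str, int]] = [("input", len(variants))]

    surviving = [v for v in variants if is_nonsynonymous(v.func_class)]
    stages.append(("nonsynonymous", len(surviving)))

    surviving = [v for v in surviving if passes_maf(v.maf_1kg, v.maf_1kg_eas, cfg.maf_max)]
    stages.append(("rare_both_panels", len(surviving)))

    surviving = [v for v in surviving if is_implicated(v, cfg)]
    stages.append(("in_silico_implicated", len(surviving)))

    counted = [(v, carrier_count(g, v.key)) for v in surviving]
    counted = [(v, c) for v, c in counted if is_recurrent(c, cfg.min_case_count)]
    stages.append(("recurrent", len(counted)))

    if cfg.gene_allowlist is not None:
        counted = [(v, c) for v, c in counted if v.gene in cfg.gene_allowlist]
        stages.append(("gene_allowlist", len(counted)))

    counted.sort(key=lambda vc: vc[0].sort_key)
    candidates = [CandidateRow(variant=v, case_count=c) for v, c in counted]
    return candidates, CascadeReport(stages=tuple(stages))


def per_sample_counts(
    variants: Sequence[VariantRecord], g: GenotypeMatrix
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample counts of carried variants, overall and by functional class.

    Returns the per-sample table (one row per sample; columns ``total``
    plus one per functional class observed) and the cross-sample means
    rounded to the nearest integer, the convention used when reporting
    per-exome variant yields.
    """
    if g.n_samples == 0:
        raise ValueError("genotype matrix has no samples")
    classes = sorted({v.func_class for v in variants})
    # align columns to the variant list rather than assuming matrix order
    cols = np.stack([g.dosages(v.key) for v in variants], axis=1) if variants else np.zeros(
        (g.n_samples, 0), dtype=np.int8
    )
    carried = cols >= 1  # samples x variants
    class_of = np.array([v.func_class for v in variants])
    data = {"total": carried.sum(axis=1)}
    for cls in classes:
        data[cls] = carried[:, class_of == cls].sum(axis=1)
    table = pd.DataFrame(data, index=pd.Index(g.sample_ids, name="sample_id"))
    return table, summarize_count_table(table)


def summarize_count_table(table: pd.DataFrame) -> pd.Series:
    """Cross-sample means of a per-sample count table, nearest-integer rounded."""
    return table.mean(axis=0).round().astype(int)
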