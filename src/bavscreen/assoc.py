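"""Validation-stage association statistics.

Gene-level carrier (dominant) coding throughout: a patient is a carrier
of a gene iff allele dosage >= 1 at any variant assigned to it, so every
2x2 table counts patients, not allele copies.  Carrier frequencies are
compared between cohorts with an uncorrected Pearson chi-square or
Fisher's exact test (automatic selection by the minimum expected count
rule), and quantitative phenotypes are compared between carriers and
non-carriers with unpaired two-sided t-tests, either from raw values or
from published n/mean/SD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort_model import (
    GenotypeMatrix,
    PhenotypeRecord,
    PipelineConfig,
    SummaryStat,
)

__all__ = [
    "TwoByTwo",
    "AssocResult",
    "TTestResult",
    "DegenerateTableError",
    "InsufficientDataError",
    "carrier_2x2",
    "chi2_2x2",
    "fisher_2x2",
    "auto_test",
    "ttest_from_summary",
    "split_by_carrier",
    "compare_phenotype_by_gene",
    "gene_panel_association",
]


class DegenerateTableError(ValueError):
    """A 2x2 table has a zero row or column margin where the test needs one."""


class InsufficientDataError(ValueError):
    """A comparison group has fewer than two usable observations."""


@dataclass(frozen=True)
class TwoByTwo:
    """Carrier counts: a/b case carriers/non-carriers, c/d control ditto."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 entries must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def expected(self) -> np.ndarray:
        """Expected counts under row/column independence."""
        arr = self.as_array().astype(float)
        rows = arr.sum(axis=1, keepdims=True)
        cols = arr.sum(axis=0, keepdims=True)
        if self.n == 0:
            return np.zeros((2, 2))
        return rows @ cols / self.n


@dataclass(frozen=True)
class AssocResult:
    gene: str
    table: TwoByTwo
    test_used: str
    p_value: float
    statistic: float | None = None
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df <= 0:
            raise ValueError(f"degrees of freedom {self.df} must be > 0")


def carrier_2x2(
    g: GenotypeMatrix,
    gene: str,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
) -> TwoByTwo:
    """Gene-level carrier counts in two cohorts.

    A patient with all-missing dosages for the gene counts as a
    non-carrier (carriage must be observed to be claimed).  A gene with no
    variants in the matrix yields zero carriers in both cohorts.
    """
    keys = g.keys_for_gene(gene)

    def carriers(ids: Sequence[str]) -> int:
        count = 0
        for sid in ids:
            row = g.sample_row(sid)  # raises KeyError for unknown ids
            if any(row[g.variant_keys.index(k)] >= 1 for k in keys):
                count += 1
        return count

    a = carriers(case_ids)
    c = carriers(control_ids)
    return TwoByTwo(a=a, b=len(case_ids) - a, c=c, d=len(control_ids) - c)


def chi2_2x2(t: TwoByTwo, continuity_correction: bool = False) -> AssocResult:
    """Pearson chi-square on a 2x2 table (1 df), two-sided p.

    No continuity correction by default; Yates' correction via flag.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"zero margin in table {t}")
    res = stats.chi2_contingency(arr, correction=continuity_correction)
    return AssocResult(
        gene="",
        table=t,
        test_used="chi2",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def fisher_2x2(t: TwoByTwo) -> AssocResult:
    """Fisher's exact test, two-sided by the minimum-likelihood rule.

    The p-value sums hypergeometric probabilities, over all tables with
    the observed margins, of every table at most as probable as the
    observed one.  Degenerate margins give p = 1.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return AssocResult(gene="", table=t, test_used="fisher", p_value=1.0)
    res = stats.fisher_exact(arr, alternative="two-sided")
    return AssocResult(
        gene="", table=t, test_used="fisher", p_value=float(min(res.pvalue, 1.0))
    )


def auto_test(t: TwoByTwo, cfg: PipelineConfig | None = None) -> AssocResult:
    """Chi-square when every expected count is adequate, else Fisher.

    The classical rule: if any expected count under independence falls
    below ``cfg.expected_count_min`` (default 5), the asymptotic
    chi-square approximation is not trusted and the exact test is used.
    Degenerate tables take the Fisher path (p = 1).
    """
    cfg = cfg or PipelineConfig()
    arr = t.as_array()
    degenerate = (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any()
    if degenerate or t.expected().min() < cfg.expected_count_min:
        return fisher_2x2(t)
    return chi2_2x2(t, continuity_correction=cfg.continuity_correction)


def ttest_from_summary(
    x: SummaryStat, y: SummaryStat, method: str = "welch"
) -> TTestResult:
    """Unpaired two-sided t-test from n/mean/SD summaries.

    ``welch`` (default) uses the unequal-variance statistic with
    Welch-Satterthwaite degrees of freedom; ``pooled`` the classical
    equal-variance form with n_x + n_y - 2 df.  Degenerate case of both
    SDs zero: equal means give t = 0, p = 1; unequal means give an
    infinite statistic with p = 0.
    """
    if method not in {"welch", "pooled"}:
        raise ValueError(f"unknown t-test method {method!r}")
    if x.sd == 0.0 and y.sd == 0.0:
        df = x.n + y.n - 2
        if x.mean == y.mean:
            return TTestResult(t=0.0, df=df, p_value=1.0, method=method)
        t = np.inf if x.mean > y.mean else -np.inf
        return TTestResult(t=t, df=df, p_value=0.0, method=method)
    res = stats.ttest_ind_from_stats(
        mean1=x.mean,
        std1=x.sd,
        nobs1=x.n,
        mean2=y.mean,
        std2=y.sd,
        nobs2=y.n,
        equal_var=(method == "pooled"),
    )
    df = x.n + y.n - 2 if method == "pooled" else _welch_df(x, y)
    return TTestResult(t=float(res.statistic), df=float(df), p_value=float(res.pvalue), method=method)


def _welch_df(x: SummaryStat, y: SummaryStat) -> float:
    vx, vy = x.sd**2 / x.n, y.sd**2 / y.n
    return (vx + vy) ** 2 / (vx**2 / (x.n - 1) + vy**2 / (y.n - 1))


def split_by_carrier(
    g: GenotypeMatrix,
    gene_panel: Sequence[str],
    patients: Sequence[PhenotypeRecord],
) -> tuple[list[PhenotypeRecord], list[PhenotypeRecord]]:
    """Partition patients into panel carriers and non-carriers.

    A carrier has dosage >= 1 at any variant of any panel gene.  The two
    groups are disjoint and exhaust the input.
    """
    keys: list[str] = []
    for gene in gene_panel:
        keys.extend(g.keys_for_gene(gene))
    key_idx = [g.variant_keys.index(k) for k in keys]
    carriers, noncarriers = [], []
    for p in patients:
        row = g.sample_row(p.sample_id)
        if key_idx and (row[key_idx] >= 1).any():
            carriers.append(p)
        else:
            noncarriers.append(p)
    return carriers, noncarriers


def compare_phenotype_by_gene(
    g: GenotypeMatrix,
    gene: str,
    patients: Sequence[PhenotypeRecord],
    phenotype: str,
    method: str = "welch",
) -> TTestResult:
    """t-test of a quantitative phenotype between one gene's carriers and
    wild-type patients.

    Patients with the phenotype missing are excluded; each group must
    retain at least two usable values.
    """
    carriers, wildtype = split_by_carrier(g, [gene], patients)
    x = [getattr(p, phenotype) for p in carriers if getattr(p, phenotype) is not None]
    y = [getattr(p, phenotype) for p in wildtype if getattr(p, phenotype) is not None]
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError(
            f"{gene}/{phenotype}: need >= 2 usable values per group, "
            f"got {len(x)} carriers and {len(y)} wild-type"
        )
    res = stats.ttest_ind(x, y, equal_var=(method == "pooled"))
    if method == "pooled":
        df = len(x) + len(y) - 2
    else:
        df = _welch_df(
            SummaryStat(len(x), float(np.mean(x)), float(np.std(x, ddof=1))),
            SummaryStat(len(y), float(np.mean(y)), float(np.std(y, ddof=1))),
        )
    return TTestResult(t=float(res.statistic), df=float(df), p_value=float(res.pvalue), method=method)


def gene_panel_association(
    g: GenotypeMatrix,
    panel: Sequence[str],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    cfg: PipelineConfig | None = None,
) -> list[AssocResult]:
    """Per-gene carrier-frequency association for a gene panel.

    One result per panel gene in the given order.  With
    ``cfg.adjust_bh`` set, Benjamini-Hochberg adjusted p-values are
    appended (no multiplicity correction is applied by default).
    """
    cfg = cfg or PipelineConfig()
    results: list[AssocResult] = []
    for gene in panel:
        t = carrier_2x2(g, gene, case_ids, control_ids)
        if cfg.test_policy == "chi2":
            res = chi2_2x2(t, continuity_correction=cfg.continuity_correction)
        elif cfg.test_policy == "fisher":
            res = fisher_2x2(t)
        else:
            res = auto_test(t, cfg)
        results.append(replace(res, gene=gene))
    if cfg.adjust_bh and results:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        results = [replace(r, p_adjusted=float(q)) for r, q in zip(results, p_adj)]
    return results
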