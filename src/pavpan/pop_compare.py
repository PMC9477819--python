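"""Cohort comparison of gene absence frequencies.

For each gene, a 2x2 table of absent/present counts in two cohorts is
tested with Fisher's exact test (two-sided, probability-ordering
convention), corrected by Benjamini-Hochberg FDR over the gene family of
that comparison, and summarized by an odds ratio (Haldane-Anscombe 0.5
correction when a cell is empty). Genes with q below the FDR threshold
and/or OR above the flag threshold are marked; the most frequently absent
genes are split into highly (HAG) vs low (LAG) absent by their typical
CDS coverage in absence-called samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import Thresholds
from .pav import CHRY, PAVMatrix, SampleMeta

__all__ = [
    "GeneFrequencyComparison",
    "AbsenceCategory",
    "absence_table",
    "fisher_exact_two_sided",
    "bh_fdr",
    "odds_ratio",
    "compare_cohorts",
    "hag_lag",
    "phenotype_association",
]


@dataclass(frozen=True)
class GeneFrequencyComparison:
    """Per-gene 2x2 absence table across two cohorts with its statistics.

    a/b = absent/present in the case cohort, c/d in the control cohort.
    """

    gene_id: str
    a: int
    b: int
    c: int
    d: int
    p: float
    q: float
    or_value: float
    flagged: bool
    or_flagged: bool

    @property
    def freq_case(self) -> float:
        return self.a / (self.a + self.b) if (self.a + self.b) else float("nan")

    @property
    def freq_control(self) -> float:
        return self.c / (self.c + self.d) if (self.c + self.d) else float("nan")


@dataclass(frozen=True)
class AbsenceCategory:
    """HAG/LAG split of the top-ranked distributed genes."""

    categories: dict[str, str]  # gene_id -> "HAG" | "LAG"
    ranks: dict[str, int]  # selection rank, 1 = most absent


def absence_table(
    matrix_case: PAVMatrix, matrix_control: PAVMatrix, gene_id: str
) -> tuple[int, int, int, int]:
    """Absent/present counts per cohort; chrY genes counted over males only."""

    def counts(matrix: PAVMatrix) -> tuple[int, int]:
        if gene_id not in matrix.presence.columns:
            raise KeyError(f"gene {gene_id} missing from matrix")
        col = matrix.presence[gene_id]
        gene = matrix.genes[gene_id]
        if gene.host == CHRY:
            males = [s for s in matrix.samples if matrix.meta[s].sex == "male"]
            col = col.loc[males]
        present = int(col.sum())
        return len(col) - present, present

    a, b = counts(matrix_case)
    c, d = counts(matrix_control)
    return a, b, c, d


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by the probability-ordering convention.

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed that of the observed table.
    Evaluated in exact integer arithmetic (a single shared denominator),
    so no floating-point comparison tolerance is needed.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    obs = weights[a]
    num = sum(w for w in weights.values() if w <= obs)
    return min(1.0, num / comb(n, c1))


def bh_fdr(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    if len(pvals) == 0:
        return []
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(x) for x in q]


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c), Haldane-Anscombe corrected (+0.5 everywhere) on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def compare_cohorts(
    matrix_case: PAVMatrix, matrix_control: PAVMatrix, t: Thresholds
) -> list[GeneFrequencyComparison]:
    """One comparison record per gene present in both matrices.

    The FDR family is exactly the set of genes tested here; results are
    sorted by (q, gene id).
    """
    genes = sorted(set(matrix_case.gene_ids) & set(matrix_control.gene_ids))
    if not genes:
        return []
    tables = [absence_table(matrix_case, matrix_control, g) for g in genes]
    pvals = [fisher_exact_two_sided(*tab) for tab in tables]
    qvals = bh_fdr(pvals)
    out = []
    for g, (a, b, c, d), p, q in zip(genes, tables, pvals, qvals):
        orv = odds_ratio(a, b, c, d)
        out.append(
            GeneFrequencyComparison(
                gene_id=g,
                a=a,
                b=b,
                c=c,
                d=d,
                p=p,
                q=q,
                or_value=orv,
                flagged=q < t.fdr_alpha,
                or_flagged=orv > t.or_flag_threshold,
            )
        )
    out.sort(key=lambda r: (r.q, r.gene_id))
    return out


def hag_lag(
    matrix: PAVMatrix,
    comparisons: list[GeneFrequencyComparison],
    t: Thresholds,
    top_n: int = 20,
) -> AbsenceCategory:
    """Split the top-N most absent distributed genes into HAG vs LAG.

    Ranking is by case absence frequency, descending. Within the top N a
    gene is HAG when the median CDS coverage over its absence-called
    samples is below the HAG cut-off, LAG otherwise.
    """
    by_freq = sorted(
        (r for r in comparisons if r.a > 0),
        key=lambda r: (-r.freq_case, r.gene_id),
    )
    top = by_freq[:top_n]
    categories, ranks = {}, {}
    for rank, r in enumerate(top, start=1):
        cov = matrix.coverage[r.gene_id]
        absent = cov[~matrix.presence[r.gene_id]]
        med = float(absent.median()) if len(absent) else 0.0
        categories[r.gene_id] = "HAG" if med < t.hag_cds_coverage else "LAG"
        ranks[r.gene_id] = rank
    return AbsenceCategory(categories=categories, ranks=ranks)


def _subset_matrix(matrix: PAVMatrix, samples: list[str]) -> PAVMatrix:
    return PAVMatrix(
        coverage=matrix.coverage.loc[samples],
        presence=matrix.presence.loc[samples],
        genes=matrix.genes,
        meta={s: matrix.meta[s] for s in samples},
    )


def phenotype_association(
    matrix: PAVMatrix,
    meta: list[SampleMeta],
    phenotype: str,
    t: Thresholds,
) -> list[GeneFrequencyComparison]:
    """Fisher association of gene PAVs with a binary clinical phenotype.

    The two phenotype levels define case/control (lexicographically first
    level is the case). chrY genes are excluded when testing sex, where
    absence is confounded by design.
    """
    values: dict[str, str] = {}
    for m in meta:
        if m.sample_id not in matrix.meta:
            continue
        v = m.sex if phenotype == "sex" else m.phenotype(phenotype)
        if v is not None:
            values[m.sample_id] = v
    levels = sorted(set(values.values()))
    if len(levels) != 2:
        raise ValueError(
            f"phenotype {phenotype!r} must have exactly two levels, got {levels}"
        )
    case = [s for s in matrix.samples if values.get(s) == levels[0]]
    control = [s for s in matrix.samples if values.get(s) == levels[1]]
    m_case = _subset_matrix(matrix, case)
    m_control = _subset_matrix(matrix, control)
    if phenotype == "sex":
        # chrY absence is confounded by design: exclude before forming the
        # FDR family, not after
        keep = [g for g in matrix.gene_ids if matrix.genes[g].host != CHRY]
        for m in (m_case, m_control):
            m.coverage = m.coverage[keep]
            m.presence = m.presence[keep]
    return compare_cohorts(m_case, m_control, t)
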