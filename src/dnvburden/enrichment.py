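"""Poisson burden testing of de novo variant counts.

The statistical model: in a cohort of N probands, the number of de novo
events of class *c* in gene *g* is Poisson with mean

    E_{g,c} = 2 * N * p_{g,c},

where p_{g,c} is the per-chromosome, per-generation mutation probability
and the factor 2 accounts for the two transmitted haplotypes.  Observed
counts are compared to this expectation with a one-sided Poisson test,
p = P(X >= observed | X ~ Poisson(E)).  Gene-level significance applies a
Bonferroni correction across the gene universe and the number of class
groups tested (0.05 / (3 x 19,347) = 8.6e-7 at the defaults).

Both raw and Bonferroni-adjusted p-values (min(1, p * n_tests)) are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import ObservedCounts
from .variants import MutationRateTable, ValidationError

__all__ = [
    "EnrichmentResult",
    "DEFAULT_CLASS_GROUPS",
    "DEFAULT_GENE_UNIVERSE",
    "DEFAULT_N_TESTS_PER_GENE",
    "expected_count",
    "poisson_upper_tail",
    "bonferroni_alpha",
    "bonferroni_adjust",
    "gene_level_test",
    "cohort_burden_test",
]

#: Class groups tested by default (one Bonferroni "test" per group).
DEFAULT_CLASS_GROUPS = ("protein_altering", "protein_damaging", "lof")
DEFAULT_N_TESTS_PER_GENE = len(DEFAULT_CLASS_GROUPS)
#: Gene universe of genome-wide mutation-rate models.
DEFAULT_GENE_UNIVERSE = 19_347


@dataclass(frozen=True)
class EnrichmentResult:
    """One burden test: a gene, named gene set, or the whole cohort."""

    unit: str
    class_group: str
    observed: int
    expected: float
    p_value: float
    p_adjusted: float
    alpha: float

    @property
    def rate_ratio(self) -> float:
        if self.expected == 0.0:
            return float("nan") if self.observed == 0 else float("inf")
        return self.observed / self.expected

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def expected_count(
    table: MutationRateTable,
    genes: Iterable[str],
    class_group: str,
    n_probands: int,
    missing: str = "error",
) -> float:
    """Expected DNV count 2 * N * sum_g p_{g, class_group}.

    ``missing`` ("error" | "zero") controls genes absent from the table.
    """
    if n_probands < 0:
        raise ValidationError(f"n_probands must be >= 0, got {n_probands}")
    total_p = sum(table.probability(g, class_group, missing=missing) for g in genes)
    return 2.0 * n_probands * total_p


def poisson_upper_tail(observed, expected):
    """P(X >= observed) for X ~ Poisson(expected).

    Accepts scalars or array-likes (broadcast together).  Computed with the
    regularized incomplete gamma function (via the Poisson survival
    function), which is stable far into the tail.  Edge cases:
    P(X >= 0) = 1 for any rate; a zero rate gives probability 0 for any
    positive observed count.
    """
    k = np.asarray(observed)
    lam = np.asarray(expected, dtype=float)
    if np.any(k < 0):
        raise ValidationError("observed count must be >= 0")
    if np.any(lam < 0):
        raise ValidationError("expected rate must be >= 0")
    if not np.all(np.equal(np.mod(k, 1), 0)):
        raise ValidationError("observed count must be an integer")
    k = k.astype(np.int64)
    with np.errstate(invalid="ignore"):
        out = stats.poisson.sf(k - 1, lam)
    # scipy defines the mu=0 distribution as a point mass at 0.
    out = np.where(k == 0, 1.0, out)
    out = np.where((lam == 0) & (k > 0), 0.0, out)
    if np.isscalar(observed) and np.isscalar(expected):
        return float(out)
    return out


def bonferroni_alpha(family_alpha: float, n_tests_per_gene: int, n_genes: int) -> float:
    """Per-test significance threshold: family_alpha / (n_tests_per_gene * n_genes)."""
    if family_alpha <= 0:
        raise ValidationError(f"family_alpha must be > 0, got {family_alpha}")
    if n_tests_per_gene <= 0 or n_genes <= 0:
        raise ValidationError("n_tests_per_gene and n_genes must be positive")
    return family_alpha / (n_tests_per_gene * n_genes)


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value min(1, p * n_tests)."""
    if n_tests <= 0:
        raise ValidationError("n_tests must be positive")
    return min(1.0, p * n_tests)


def _result(unit, class_group, observed, expected, alpha, n_tests) -> EnrichmentResult:
    p = poisson_upper_tail(observed, expected)
    return EnrichmentResult(
        unit=unit,
        class_group=class_group,
        observed=int(observed),
        expected=float(expected),
        p_value=p,
        p_adjusted=bonferroni_adjust(p, n_tests),
        alpha=alpha,
    )


def gene_level_test(
    counts: ObservedCounts,
    table: MutationRateTable,
    class_group: str,
    family_alpha: float = 0.05,
    n_tests_per_gene: int = DEFAULT_N_TESTS_PER_GENE,
    include_zero_observed: bool = False,
    missing: str = "error",
) -> list[EnrichmentResult]:
    """Per-gene Poisson burden test of one class group.

    By default only genes with at least one observed DNV are reported
    (genes at zero observed have p = 1 by construction); pass
    ``include_zero_observed=True`` to report every gene in the table.
    Results are sorted by ascending p-value, ties broken by gene name.
    """
    alpha = bonferroni_alpha(family_alpha, n_tests_per_gene, table.n_genes)
    n_tests = n_tests_per_gene * table.n_genes
    genes = sorted(table.genes) if include_zero_observed else counts.genes()
    results = []
    for gene in genes:
        observed = counts.count(gene, class_group)
        expected = expected_count(table, [gene], class_group, counts.n_probands, missing=missing)
        results.append(_result(gene, class_group, observed, expected, alpha, n_tests))
    results.sort(key=lambda r: (r.p_value, r.unit))
    return results


def cohort_burden_test(
    counts: ObservedCounts,
    table: MutationRateTable,
    class_groups: Sequence[str] = DEFAULT_CLASS_GROUPS,
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    family_alpha: float = 0.05,
    missing: str = "error",
) -> list[EnrichmentResult]:
    """Cohort-wide and gene-set burden tests.

    For each class group, one row for the whole gene universe present in
    the table (unit ``"cohort"``) plus one row per named gene set.  The
    Bonferroni family here is the number of (class, set) pairs tested.
    """
    gene_sets = dict(gene_sets or {})
    units: list[tuple[str, list[str]]] = [("cohort", sorted(table.genes))]
    for name, genes in gene_sets.items():
        units.append((name, sorted(set(genes))))
    n_tests = len(class_groups) * len(units)
    alpha = family_alpha / n_tests
    results = []
    for class_group in class_groups:
        for name, genes in units:
            observed = sum(counts.count(g, class_group) for g in genes)
            expected = expected_count(table, [g for g in genes if g in table],
                                      class_group, counts.n_probands, missing=missing)
            results.append(_result(name, class_group, observed, expected, alpha, n_tests))
    return results
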