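"""Damaging-variant classification and per-gene count aggregation.

A DNV is classified from its annotated consequence plus the missense
deleteriousness predictors:

* predicted loss-of-function (``lof``): stop-gain, stop-loss, frameshift,
  canonical splice-site, start-loss;
* damaging missense (``misD``): missense predicted deleterious by MetaSVM
  *or* with MPC >= 2 (inclusive or);
* other missense (``mis``), ``synonymous``, and ``other``.

LoF and misD together form the *protein-damaging* group; adding mis gives
the *protein-altering* group.  A missense variant with neither a MetaSVM
call nor an MPC score cannot meet the damaging rule and falls back to
``mis``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .variants import (
    AnnotatedDNV,
    CLASS_GROUPS,
    LOF_CONSEQUENCES,
    VariantClass,
)

__all__ = ["classify_variant", "tally_counts", "ObservedCounts", "MPC_DAMAGING_THRESHOLD"]

#: MPC score at or above which a missense variant counts as damaging.
MPC_DAMAGING_THRESHOLD = 2.0


def classify_variant(ann: AnnotatedDNV) -> VariantClass:
    """Pure, deterministic classification of one annotated DNV."""
    csq = ann.consequence
    if csq in LOF_CONSEQUENCES:
        return VariantClass("lof")
    if csq == "missense":
        if ann.metasvm == "deleterious":
            return VariantClass("misD")
        if ann.mpc is not None and ann.mpc >= MPC_DAMAGING_THRESHOLD:
            return VariantClass("misD")
        return VariantClass("mis")
    if csq == "synonymous":
        return VariantClass("synonymous")
    return VariantClass("other")


@dataclass
class ObservedCounts:
    """Observed DNV counts per gene, by atomic class, for a cohort of
    ``n_probands`` probands.

    Composite groups (protein_altering, protein_damaging) are computed on
    demand from the atomic tallies, so the identity
    ``lof + misD + mis == protein_altering`` holds by construction.
    """

    n_probands: int
    atomic: dict[str, Counter] = field(default_factory=dict)  # gene -> class counter
    probands: dict[str, set] = field(default_factory=dict)    # gene -> proband ids

    def count(self, gene: str, class_group: str) -> int:
        if class_group not in CLASS_GROUPS:
            raise KeyError(f"unknown class group: {class_group!r}")
        counter = self.atomic.get(gene)
        if counter is None:
            return 0
        return sum(counter[c] for c in CLASS_GROUPS[class_group])

    def total(self, class_group: str) -> int:
        return sum(self.count(g, class_group) for g in self.atomic)

    def genes(self) -> list[str]:
        return sorted(self.atomic)

    def n_probands_with_dnv(self, gene: str) -> int:
        return len(self.probands.get(gene, ()))


def tally_counts(dnvs: Iterable[AnnotatedDNV], n_probands: int) -> ObservedCounts:
    """Aggregate classified DNVs into per-gene, per-class observed counts.

    Permutation-invariant; each DNV occurrence counts once, and distinct
    probands per gene are tracked separately (recurrent variants in
    different probands are independent events).
    """
    counts = ObservedCounts(n_probands=n_probands)
    for ann in dnvs:
        label = classify_variant(ann).label
        if label == "other":
            continue
        counts.atomic.setdefault(ann.gene, Counter())[label] += 1
        counts.probands.setdefault(ann.gene, set()).add(ann.proband_id)
    return counts
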