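"""Protein-coordinate variant density mapping.

Variants are placed on 1-based protein residues; the per-residue count
track is smoothed with a running average over a window of +/- ``w``
residues (default 10) around each position.  At the protein ends the
window is truncated and, by default, the mean is taken over the residues
actually in the window; a fixed-denominator mode (always 2w+1) is
available for emulating plots produced with zero padding.

Domain annotations are closed residue intervals; overlap counts include
both boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variants import AnnotatedDNV, ValidationError

__all__ = [
    "DomainAnnotation",
    "DensityTrack",
    "running_average",
    "domain_overlap",
    "build_track",
    "read_domain_table",
]


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain over a closed 1-based residue interval."""

    name: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"domain {self.name!r}: require 1 <= start <= end, got [{self.start}, {self.end}]"
            )

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


def running_average(counts: Sequence[float], w: int, fixed_denominator: bool = False) -> np.ndarray:
    """Windowed mean of ``counts`` over positions i-w .. i+w.

    Windows are truncated at the track ends; the denominator is the
    truncated window's actual length unless ``fixed_denominator`` is set,
    in which case it is always 2w+1.
    """
    if w < 0:
        raise ValidationError(f"window half-width must be >= 0, got {w}")
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValidationError("counts must be a non-empty 1-D sequence")
    n = c.size
    cum = np.concatenate([[0.0], np.cumsum(c)])
    idx = np.arange(n)
    lo = np.maximum(idx - w, 0)
    hi = np.minimum(idx + w, n - 1)
    window_sum = cum[hi + 1] - cum[lo]
    denom = np.full(n, 2 * w + 1, dtype=float) if fixed_denominator else (hi - lo + 1).astype(float)
    return window_sum / denom


def domain_overlap(variants: Iterable[AnnotatedDNV], domain: DomainAnnotation) -> int:
    """Number of variants whose protein position falls inside the domain
    (closed interval).  Variants without a protein position are skipped
    with a warning."""
    count = 0
    for v in variants:
        if v.protein_pos is None:
            warnings.warn(
                f"variant {v.protein_change or v.cdna_change or v.proband_id} has no protein "
                "position; excluded from domain overlap",
                stacklevel=2,
            )
            continue
        if domain.contains(v.protein_pos):
            count += 1
    return count


@dataclass
class DensityTrack:
    """Per-residue variant counts and their running-average density."""

    protein_length: int
    counts: np.ndarray
    density: np.ndarray
    window: int

    def peak_residue(self) -> int:
        """Residue (1-based) of maximal density.

        A single variant cluster produces a plateau of tied density values;
        ties are broken in favour of the residue with the highest raw
        count (the cluster centre), then the smallest residue index.
        """
        best = self.density.max()
        tied = np.flatnonzero(self.density == best)
        order = np.lexsort((tied, -self.counts[tied]))
        return int(tied[order[0]]) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.protein_length + 1),
                "count": self.counts.astype(int),
                "density": self.density,
            }
        )


def build_track(
    variants: Iterable[AnnotatedDNV],
    protein_length: int,
    w: int = 10,
    fixed_denominator: bool = False,
) -> DensityTrack:
    """Accumulate per-residue counts (once per variant *report*, so
    recurrent variants add multiplicity) and smooth them.

    Raises on positions outside 1..protein_length, naming the variant.
    """
    if protein_length < 1:
        raise ValidationError(f"protein_length must be >= 1, got {protein_length}")
    counts = np.zeros(protein_length, dtype=float)
    for v in variants:
        if v.protein_pos is None:
            warnings.warn(
                f"variant {v.protein_change or v.proband_id} has no protein position; "
                "excluded from density track",
                stacklevel=2,
            )
            continue
        if not (1 <= v.protein_pos <= protein_length):
            raise ValidationError(
                f"variant {v.protein_change or v.proband_id} position {v.protein_pos} "
                f"outside protein of length {protein_length}"
            )
        counts[v.protein_pos - 1] += 1
    density = running_average(counts, w, fixed_denominator=fixed_denominator)
    return DensityTrack(protein_length=protein_length, counts=counts, density=density, window=w)


def read_domain_table(path) -> list[DomainAnnotation]:
    """Read domain annotations from a tab-separated file with columns
    ``name  start  end`` (1-based, closed) and optional ``source``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "start", "end"}
    if not required.issubset(df.columns):
        raise ValidationError(f"domain table needs columns {sorted(required)}")
    return [
        DomainAnnotation(
            name=str(r["name"]),
            start=int(r["start"]),
            end=int(r["end"]),
            source=str(r.get("source", "") or ""),
        )
        for r in df.to_dict(orient="records")
    ]
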