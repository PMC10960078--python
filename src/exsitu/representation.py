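"""Ex situ representation of wild allelic diversity.

An allele is *captured* when it is observed in at least one non-missing
garden call.  Wild allele frequencies are computed with per-locus
denominators (missing cells excluded), and alleles are binned into
deliberately overlapping frequency categories:

========  =====================
category  wild frequency p
========  =====================
very_common   p > 0.10
common        p > 0.05
low_frequency 0.01 <= p <= 0.10
rare          0 < p < 0.01
total         p > 0
========  =====================

Boundary inclusivity at exactly 1% and 10% is a convention of this package
(configurable via custom :class:`FrequencyCategory` lists) and is echoed in
every report header so the binning is always auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from exsitu.genotype_io import GenotypeMatrix, SamplePartition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyCategory:
    """A half-open-or-closed frequency interval with a name."""

    name: str
    lower: float
    upper: float
    lower_inclusive: bool = False
    upper_inclusive: bool = True

    def contains(self, p: float | np.ndarray) -> bool | np.ndarray:
        lo = p >= self.lower if self.lower_inclusive else p > self.lower
        hi = p <= self.upper if self.upper_inclusive else p < self.upper
        return lo & hi

    def describe(self) -> str:
        lo_b = "[" if self.lower_inclusive else "("
        hi_b = "]" if self.upper_inclusive else ")"
        return f"{self.name}: p in {lo_b}{self.lower:g}, {self.upper:g}{hi_b}"


DEFAULT_CATEGORIES: tuple[FrequencyCategory, ...] = (
    FrequencyCategory("very_common", 0.10, 1.0),
    FrequencyCategory("common", 0.05, 1.0),
    FrequencyCategory("low_frequency", 0.01, 0.10,
                      lower_inclusive=True, upper_inclusive=True),
    FrequencyCategory("rare", 0.0, 0.01,
                      lower_inclusive=False, upper_inclusive=False),
    FrequencyCategory("total", 0.0, 1.0),
)


@dataclass
class WildAlleleFrequencies:
    """Per-allele wild copy counts and frequencies, matrix-column aligned.

    ``pairs[j] = (locus_id, allele_label)`` names flattened allele column
    ``j`` of the source matrix; ``counts[j]`` is the number of non-missing
    wild gene copies carrying that allele and ``column_totals[j]`` the total
    non-missing wild copies at its locus.  Loci with zero typed wild
    individuals are listed in ``loci_without_data`` and their columns carry
    NaN frequencies (they are excluded from every category count).
    """

    pairs: list[tuple[str, str]]
    counts: np.ndarray
    column_totals: np.ndarray
    loci_without_data: list[str] = field(default_factory=list)

    @property
    def freqs(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.column_totals > 0,
                self.counts / np.maximum(self.column_totals, 1),
                np.nan,
            )

    def defined(self) -> np.ndarray:
        """Columns belonging to the wild allele universe (count > 0)."""
        return (self.column_totals > 0) & (self.counts > 0)

    def table(self) -> pd.DataFrame:
        """Wild alleles only (zero-count / undefined columns omitted)."""
        keep = self.defined()
        return pd.DataFrame(
            {
                "locus": [p[0] for p, k in zip(self.pairs, keep) if k],
                "allele": [p[1] for p, k in zip(self.pairs, keep) if k],
                "count": self.counts[keep],
                "total_copies": self.column_totals[keep],
                "frequency": self.freqs[keep],
            }
        )


@dataclass
class CategoryScore:
    n_wild_alleles: int
    n_captured: int

    @property
    def percent(self) -> float | None:
        if self.n_wild_alleles == 0:
            return None
        return 100.0 * self.n_captured / self.n_wild_alleles


@dataclass
class RepresentationResult:
    """Per-category capture scores plus the garden-only allele count."""

    scores: dict[str, CategoryScore]
    garden_only_alleles: int
    categories: tuple[FrequencyCategory, ...]

    def to_frame(self, label: str = "dataset") -> pd.DataFrame:
        """One table row in the per-category percent layout (2 decimals)."""
        row: dict[str, object] = {"dataset": label}
        for cat in self.categories:
            s = self.scores[cat.name]
            row[cat.name] = (
                "NA" if s.percent is None else f"{s.percent:.2f}%"
            )
        return pd.DataFrame([row])

    def counts_frame(self, label: str = "dataset") -> pd.DataFrame:
        rows = [
            {
                "dataset": label,
                "category": name,
                "n_wild_alleles": s.n_wild_alleles,
                "n_captured": s.n_captured,
                "percent": np.nan if s.percent is None else s.percent,
            }
            for name, s in self.scores.items()
        ]
        df = pd.DataFrame(rows)
        df["garden_only_alleles"] = self.garden_only_alleles
        return df


def wild_allele_frequencies(
    gm: GenotypeMatrix, partition: SamplePartition
) -> WildAlleleFrequencies:
    """Allele frequencies among wild, non-excluded individuals.

    Each non-missing call contributes two gene copies (a homozygote counts
    twice for its allele); denominators are per-locus, so loci with patchy
    typing are not diluted by globally missing samples.
    """
    wild = partition.wild_ids(gm.individuals)
    if not wild:
        raise ValueError("no wild, non-excluded individuals in the matrix")
    pos = {s: i for i, s in enumerate(gm.individuals)}
    rows = [pos[s] for s in wild]
    counts = gm.allele_copy_counts(rows)
    locus_totals = gm.locus_copy_totals(counts)
    sizes = [len(l.allele_labels) for l in gm.loci]
    column_totals = np.repeat(locus_totals, sizes)
    no_data = [
        gm.loci[l].locus_id for l in range(gm.n_loci) if locus_totals[l] == 0
    ]
    if no_data:
        logger.info(
            "%d locus/loci with zero typed wild individuals excluded from "
            "the wild allele universe", len(no_data),
        )
    return WildAlleleFrequencies(
        pairs=gm.allele_pairs(),
        counts=counts,
        column_totals=column_totals,
        loci_without_data=no_data,
    )


def categorize(
    freqs: WildAlleleFrequencies,
    categories: tuple[FrequencyCategory, ...] = DEFAULT_CATEGORIES,
) -> dict[str, set[tuple[str, str]]]:
    """Assign wild alleles to (possibly several) frequency categories."""
    p = freqs.freqs
    defined = freqs.defined()
    out: dict[str, set[tuple[str, str]]] = {}
    for cat in categories:
        with np.errstate(invalid="ignore"):
            mask = defined & cat.contains(p)
        out[cat.name] = {
            pair for pair, m in zip(freqs.pairs, mask) if m
        }
    return out


def exsitu_representation(
    gm: GenotypeMatrix,
    partition: SamplePartition,
    categories: tuple[FrequencyCategory, ...] = DEFAULT_CATEGORIES,
) -> RepresentationResult:
    """Score garden capture of wild alleles, per frequency category.

    Percentages are over wild alleles only; alleles observed in garden but
    absent from wild are counted in ``garden_only_alleles`` and never enter
    any percentage.
    """
    garden = partition.garden_ids(gm.individuals)
    if not garden:
        raise ValueError("no garden, non-excluded individuals in the matrix")
    wf = wild_allele_frequencies(gm, partition)
    pos = {s: i for i, s in enumerate(gm.individuals)}
    presence = gm.presence_matrix()
    captured = presence[[pos[s] for s in garden]].any(axis=0)
    p = wf.freqs
    defined = wf.defined()
    scores: dict[str, CategoryScore] = {}
    for cat in categories:
        with np.errstate(invalid="ignore"):
            mask = defined & cat.contains(p)
        scores[cat.name] = CategoryScore(
            n_wild_alleles=int(mask.sum()),
            n_captured=int((mask & captured).sum()),
        )
    garden_only = int((captured & ~defined).sum())
    return RepresentationResult(
        scores=scores,
        garden_only_alleles=garden_only,
        categories=tuple(categories),
    )
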