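"""Core genotype containers and filters.

Genotype calls are stored as per-locus integer allele indices in a dense
``(n_individuals, n_loci, 2)`` array; ``-1`` marks a missing slot.  A cell is
either fully typed or fully missing — half-called genotypes (one allele typed,
one missing) are collapsed to missing on construction, because every
downstream computation (presence filters, allele frequencies, capture) treats
a cell as an all-or-nothing observation of two gene copies.

Allele labels per locus are kept exactly in sync with the calls: after any
subsetting or filtering operation, ``allele_labels`` is recomputed so it lists
precisely the codes observed in non-missing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MISSING = -1


class GenotypeFormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class Locus:
    """A single co-dominant marker.

    Parameters
    ----------
    locus_id:
        Text identifier, unique within a matrix.
    allele_labels:
        Ordered tuple of the distinct allele codes observed in non-missing
        calls at this locus (fragment sizes for microsatellites, nucleotides
        or 0/1 codes for SNPs).
    source_group:
        Optional grouping key, e.g. the assembled-locus ID that several SNPs
        share; used by :func:`first_variant_per_group`.
    """

    locus_id: str
    allele_labels: tuple[str, ...]
    source_group: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.allele_labels)) != len(self.allele_labels):
            raise ValueError(
                f"duplicate allele labels at locus {self.locus_id!r}"
            )


@dataclass
class SamplePartition:
    """Origin and population assignment of the individuals in a matrix.

    ``origin`` maps every sample ID to ``"garden"`` or ``"wild"``;
    ``wild_population`` labels wild samples with their source population;
    ``excluded`` lists samples dropped before any analysis.
    """

    origin: dict[str, str]
    wild_population: dict[str, str] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {v for v in self.origin.values()} - {"garden", "wild"}
        if bad:
            raise ValueError(f"origin values must be garden|wild, got {bad}")

    def wild_ids(self, individuals: Sequence[str]) -> list[str]:
        """Wild, non-excluded sample IDs, in matrix order."""
        return [
            i
            for i in individuals
            if self.origin.get(i) == "wild" and i not in self.excluded
        ]

    def garden_ids(self, individuals: Sequence[str]) -> list[str]:
        """Garden, non-excluded sample IDs, in matrix order."""
        return [
            i
            for i in individuals
            if self.origin.get(i) == "garden" and i not in self.excluded
        ]

    def populations(self, individuals: Sequence[str]) -> dict[str, list[str]]:
        """Wild population label -> member IDs (non-excluded, matrix order)."""
        out: dict[str, list[str]] = {}
        for i in self.wild_ids(individuals):
            pop = self.wild_population.get(i)
            if pop is None:
                raise ValueError(
                    f"wild sample {i!r} has no population label"
                )
            out.setdefault(pop, []).append(i)
        return out


class GenotypeMatrix:
    """Diploid co-dominant genotypes for a set of individuals and loci."""

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[Locus],
        calls: np.ndarray,
        provisional_populations: dict[str, str] | None = None,
        *,
        validate: bool = True,
    ) -> None:
        self.individuals: list[str] = list(individuals)
        self.loci: list[Locus] = list(loci)
        self.calls: np.ndarray = np.asarray(calls, dtype=np.int32)
        #: POP-block labels recorded while reading Genepop; advisory only.
        self.provisional_populations = provisional_populations or {}
        if validate:
            self._validate()

    # ------------------------------------------------------------------ #
    # construction

    @classmethod
    def from_calls(
        cls,
        individuals: Sequence[str],
        locus_ids: Sequence[str],
        label_calls: Sequence[Sequence[tuple[str, str] | None]],
        source_groups: Sequence[str | None] | None = None,
        provisional_populations: dict[str, str] | None = None,
        label_order: Sequence[Sequence[str]] | None = None,
    ) -> "GenotypeMatrix":
        """Build a matrix from per-cell allele-label pairs.

        ``label_calls[i][l]`` is ``(a1, a2)`` or ``None`` for missing.  A pair
        in which either member is ``None`` is collapsed to missing.
        ``label_order`` optionally fixes the preferred ordering of allele
        labels per locus (e.g. REF before ALTs); labels never observed are
        dropped regardless.
        """
        n, m = len(individuals), len(locus_ids)
        calls = np.full((n, m, 2), MISSING, dtype=np.int32)
        loci: list[Locus] = []
        groups = source_groups or [None] * m
        for l in range(m):
            index: dict[str, int] = {}
            if label_order is not None:
                observed = set()
                for i in range(n):
                    pair = label_calls[i][l]
                    if pair is not None and pair[0] is not None and pair[1] is not None:
                        observed.update(pair)
                for lab in label_order[l]:
                    if lab in observed:
                        index[lab] = len(index)
            for i in range(n):
                pair = label_calls[i][l]
                if pair is None or pair[0] is None or pair[1] is None:
                    continue
                for s, lab in enumerate(pair):
                    if lab not in index:
                        index[lab] = len(index)
                    calls[i, l, s] = index[lab]
            loci.append(
                Locus(
                    locus_id=str(locus_ids[l]),
                    allele_labels=tuple(index),
                    source_group=groups[l],
                )
            )
        return cls(individuals, loci, calls,
                   provisional_populations=provisional_populations)

    def _validate(self) -> None:
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)"
            )
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate sample IDs")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-called cells are not allowed")
        for l, locus in enumerate(self.loci):
            col = self.calls[:, l, :]
            obs = col[col >= 0]
            k = len(locus.allele_labels)
            if obs.size and obs.max() >= k:
                raise ValueError(
                    f"allele index out of range at locus {locus.locus_id!r}"
                )
            if len(np.unique(obs)) != k:
                raise ValueError(
                    f"allele_labels out of sync with calls at locus "
                    f"{locus.locus_id!r}"
                )

    # ------------------------------------------------------------------ #
    # basic views

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)``; True where the cell is missing."""
        return self.calls[:, :, 0] == MISSING

    def locus_presence_counts(self) -> np.ndarray:
        """Per locus: number of individuals with a non-missing call."""
        return (~self.missing_mask()).sum(axis=0)

    def allele_offsets(self) -> np.ndarray:
        """Start column of each locus in the flattened allele space."""
        sizes = np.fromiter(
            (len(l.allele_labels) for l in self.loci), dtype=np.int64,
            count=self.n_loci,
        )
        return np.concatenate([[0], np.cumsum(sizes)])

    def allele_pairs(self) -> list[tuple[str, str]]:
        """``(locus_id, allele_label)`` for every flattened allele column."""
        return [
            (locus.locus_id, lab)
            for locus in self.loci
            for lab in locus.allele_labels
        ]

    def presence_matrix(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_alleles)``: carries >=1 copy, typed.

        Columns follow :meth:`allele_pairs` order.
        """
        offsets = self.allele_offsets()
        n_alleles = int(offsets[-1])
        out = np.zeros((self.n_individuals, n_alleles), dtype=bool)
        typed = self.calls >= 0  # (n, m, 2)
        gidx = self.calls + offsets[:-1][None, :, None]
        rows = np.broadcast_to(
            np.arange(self.n_individuals)[:, None, None], self.calls.shape
        )
        out[rows[typed], gidx[typed]] = True
        return out

    def allele_copy_counts(
        self, row_indices: Sequence[int] | None = None
    ) -> np.ndarray:
        """Copy counts per flattened allele column over the given rows."""
        offsets = self.allele_offsets()
        calls = self.calls if row_indices is None else self.calls[list(row_indices)]
        typed = calls >= 0
        gidx = (calls + offsets[:-1][None, :, None])[typed]
        return np.bincount(gidx, minlength=int(offsets[-1])).astype(np.int64)

    def locus_copy_totals(self, counts: np.ndarray) -> np.ndarray:
        """Sum flattened per-allele values back to per-locus totals.

        Robust to loci with zero allele columns (e.g. all calls missing),
        which ``np.add.reduceat`` alone cannot segment.
        """
        offsets = self.allele_offsets()
        sizes = np.diff(offsets)
        out = np.zeros(self.n_loci, dtype=np.asarray(counts).dtype)
        nonempty = sizes > 0
        if nonempty.any():
            out[nonempty] = np.add.reduceat(counts, offsets[:-1][nonempty])
        return out

    def label_calls(self) -> list[list[tuple[str, str] | None]]:
        """Calls as allele-label pairs (``None`` for missing cells)."""
        out: list[list[tuple[str, str] | None]] = []
        for i in range(self.n_individuals):
            row: list[tuple[str, str] | None] = []
            for l, locus in enumerate(self.loci):
                a, b = self.calls[i, l]
                if a == MISSING:
                    row.append(None)
                else:
                    row.append(
                        (locus.allele_labels[a], locus.allele_labels[b])
                    )
            out.append(row)
        return out

    # ------------------------------------------------------------------ #
    # subsetting

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeMatrix":
        """Restrict to the given sample IDs (allele labels recomputed)."""
        wanted = list(ids)
        pos = {s: i for i, s in enumerate(self.individuals)}
        missing_ids = [s for s in wanted if s not in pos]
        if missing_ids:
            raise KeyError(f"unknown sample IDs: {missing_ids}")
        idx = [pos[s] for s in wanted]
        calls = self.calls[idx].copy()
        loci = _recompute_labels(calls, self.loci)
        provisional = {
            s: p for s, p in self.provisional_populations.items() if s in set(wanted)
        }
        return GenotypeMatrix(wanted, loci, calls,
                              provisional_populations=provisional,
                              validate=False)

    def subset_loci(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """Restrict to loci at the given positions (order preserved)."""
        idx = list(indices)
        calls = self.calls[:, idx].copy()
        loci = [self.loci[i] for i in idx]
        return GenotypeMatrix(self.individuals, loci, calls,
                              provisional_populations=dict(self.provisional_populations),
                              validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x "
            f"{self.n_loci} loci)"
        )


def _recompute_labels(calls: np.ndarray, loci: Sequence[Locus]) -> list[Locus]:
    """Remap per-locus allele indices so labels == observed codes exactly.

    Mutates ``calls`` in place and returns the rebuilt locus list.  Label
    order of surviving alleles is preserved.
    """
    out: list[Locus] = []
    for l, locus in enumerate(loci):
        col = calls[:, l, :]
        obs = np.unique(col[col >= 0])
        if len(obs) == len(locus.allele_labels):
            out.append(locus)
            continue
        remap = np.full(len(locus.allele_labels), MISSING, dtype=np.int32)
        remap[obs] = np.arange(len(obs), dtype=np.int32)
        typed = col >= 0
        col[typed] = remap[col[typed]]
        out.append(
            Locus(
                locus_id=locus.locus_id,
                allele_labels=tuple(locus.allele_labels[i] for i in obs),
                source_group=locus.source_group,
            )
        )
    return out


# ---------------------------------------------------------------------- #
# filters and subsetting operations


def first_variant_per_group(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only the first locus (in file order) of each source group.

    Loci with an empty (``None``) group are always kept.  Output order
    preserves input order.
    """
    seen: set[str] = set()
    keep: list[int] = []
    for i, locus in enumerate(gm.loci):
        g = locus.source_group
        if g is None:
            keep.append(i)
        elif g not in seen:
            seen.add(g)
            keep.append(i)
    return gm.subset_loci(keep)


def apply_missing_filter(gm: GenotypeMatrix, r: float) -> GenotypeMatrix:
    """Drop every locus typed in fewer than ``r * n_individuals`` samples.

    ``r = 0`` is the identity (no filter on missing data); ``r = 0.8`` is the
    conventional "present in at least 80% of samples" filter.  The threshold
    is strict: loci typed in exactly ``r * n`` individuals are kept.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    if r == 0.0:
        return gm
    counts = gm.locus_presence_counts()
    # epsilon guards r*n against float representation (e.g. 0.8 * 5)
    keep = np.nonzero(counts >= r * gm.n_individuals - 1e-9)[0]
    return gm.subset_loci(keep.tolist())


def _normalize_id(s: str) -> str:
    return s.strip().casefold()


def subset_shared(
    gm_a: GenotypeMatrix, gm_b: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict both matrices to their shared samples.

    IDs are compared after trimming whitespace and case-folding; the
    intersection keeps ``gm_a``'s row order.  Locus sets are untouched
    (allele labels are recomputed per the class invariant).
    """
    norm_a = {_normalize_id(s): s for s in gm_a.individuals}
    norm_b = {_normalize_id(s): s for s in gm_b.individuals}
    if len(norm_a) != gm_a.n_individuals or len(norm_b) != gm_b.n_individuals:
        raise ValueError("sample IDs collide after normalization")
    shared = [k for k in (_normalize_id(s) for s in gm_a.individuals)
              if k in norm_b]
    if not shared:
        raise ValueError("no shared samples between the two matrices")
    return (
        gm_a.subset_individuals([norm_a[k] for k in shared]),
        gm_b.subset_individuals([norm_b[k] for k in shared]),
    )


def drop_samples(gm: GenotypeMatrix, partition: SamplePartition) -> GenotypeMatrix:
    """Remove the partition's excluded samples from the matrix.

    Exclusion IDs not present in the matrix produce a warning, not an error:
    collection records are messy, and batch runs should not abort on a stale
    exclusion list.  Alleles private to excluded samples vanish from
    ``allele_labels``.
    """
    present = set(gm.individuals)
    unknown = sorted(partition.excluded - present)
    if unknown:
        warnings.warn(
            f"exclusion list contains {len(unknown)} unknown sample ID(s): "
            f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}",
            stacklevel=2,
        )
    keep = [s for s in gm.individuals if s not in partition.excluded]
    if len(keep) == gm.n_individuals:
        return gm
    return gm.subset_individuals(keep)
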