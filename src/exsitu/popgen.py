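"""Population-genetic summaries: allele counts, expected heterozygosity,
rarefied allelic richness, and pairwise Nei FST among wild populations.

Estimator variants are explicit flags rather than silent defaults, because
absolute values differ across conventions:

- ``expected_heterozygosity`` defaults to plain gene diversity
  ``1 - sum(p^2)`` averaged over loci; ``unbiased=True`` applies the
  ``2n/(2n-1)`` small-sample correction per locus.
- ``pairwise_nei_fst`` defaults to the Gst-style ratio of locus-averages
  ``(Ht_bar - Hs_bar) / Ht_bar``.  ``unbiased=True`` adds the Nei–Chesser
  sample-size corrections to Hs and Ht; ``population_correction=True`` adds
  the finite-number-of-populations correction (Dst scaled by
  ``np/(np-1)``), which makes the estimator recover the generating
  differentiation parameter of an island/Dirichlet model instead of the
  downward-shrunk two-population Gst.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from exsitu.genotype_io import GenotypeMatrix, SamplePartition

logger = logging.getLogger(__name__)


def _row_indices(gm: GenotypeMatrix, ids: Sequence[str]) -> list[int]:
    pos = {s: i for i, s in enumerate(gm.individuals)}
    try:
        return [pos[s] for s in ids]
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"unknown sample ID {exc.args[0]!r}") from exc


def _locus_stats(
    gm: GenotypeMatrix, rows: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(per-column copy counts, per-locus copy totals, per-column totals)."""
    counts = gm.allele_copy_counts(rows)
    locus_totals = gm.locus_copy_totals(counts)
    sizes = [len(l.allele_labels) for l in gm.loci]
    return counts, locus_totals, np.repeat(locus_totals, sizes)


def _gene_diversity(
    gm: GenotypeMatrix, rows: Sequence[int], unbiased: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus h = 1 - sum p^2 (NaN where untyped) and typed copy totals."""
    counts, locus_totals, column_totals = _locus_stats(gm, rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = (counts / np.maximum(column_totals, 1)) ** 2
    sumsq = gm.locus_copy_totals(sq)
    h = np.where(locus_totals > 0, 1.0 - sumsq, np.nan)
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            h = np.where(
                locus_totals > 1,
                h * locus_totals / (locus_totals - 1),
                np.nan,
            )
    return h, locus_totals


def expected_heterozygosity(
    gm: GenotypeMatrix,
    group: Sequence[str],
    unbiased: bool = False,
) -> float:
    """Mean over loci of ``1 - sum_a p_a^2`` for the given samples.

    Frequencies are per-locus missing-aware; loci with no typed individual
    in the group are skipped.  Returns NaN if no locus has data.
    """
    rows = _row_indices(gm, group)
    h, totals = _gene_diversity(gm, rows, unbiased)
    if not (totals > 0).any():
        return float("nan")
    return float(np.nanmean(h))


def _rarefied_richness(
    gm: GenotypeMatrix, counts: np.ndarray, column_totals: np.ndarray, g: int
) -> np.ndarray:
    """Per-locus expected allele count in a rarefied draw of g gene copies.

    AR_locus = sum_a [1 - C(N - N_a, g) / C(N, g)], with the hypergeometric
    term zero when N - N_a < g.  Loci with fewer than g typed copies yield
    NaN (too sparse to rarefy).
    """
    N = column_totals.astype(np.float64)
    Na = counts.astype(np.float64)
    rem = N - Na
    with np.errstate(invalid="ignore", divide="ignore"):
        log_ratio = (
            gammaln(rem + 1)
            - gammaln(rem - g + 1)
            - gammaln(N + 1)
            + gammaln(N - g + 1)
        )
    term = np.where(rem >= g, np.exp(log_ratio), 0.0)
    contrib = 1.0 - term
    per_locus = gm.locus_copy_totals(contrib)
    locus_totals = gm.locus_copy_totals(counts).astype(np.int64)
    return np.where(locus_totals >= g, per_locus, np.nan)


def allelic_richness(
    gm: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    g: int | None = None,
) -> dict[str, float]:
    """Mean rarefied allelic richness per locus for each sample group.

    ``g`` is the rarefaction gene-copy count; by default it is twice the
    smallest per-locus typed-individual count over all groups and loci with
    any data, so every group is rarefied to the same base.  Loci with fewer
    than ``g`` typed copies in a group are skipped for that group (logged).
    """
    stats = {
        name: _locus_stats(gm, _row_indices(gm, ids))
        for name, ids in groups.items()
    }
    if g is None:
        positive = [
            lt[lt > 0] for _, lt, _ in stats.values()
        ]
        if not any(len(p) for p in positive):
            raise ValueError("no typed data in any group")
        g = int(min(p.min() for p in positive if len(p)))
    if g < 2:
        raise ValueError(f"rarefaction size g must be >= 2, got {g}")
    out: dict[str, float] = {}
    for name, (counts, locus_totals, column_totals) in stats.items():
        ar = _rarefied_richness(gm, counts, column_totals, g)
        skipped = int(np.isnan(ar).sum())
        if skipped:
            logger.info(
                "group %r: %d locus/loci too sparse for g=%d skipped",
                name, skipped, g,
            )
        out[name] = float(np.nanmean(ar)) if skipped < len(ar) else float("nan")
    return out


def _pair_fst(
    gm: GenotypeMatrix,
    rows1: Sequence[int],
    rows2: Sequence[int],
    unbiased: bool,
    population_correction: bool,
) -> float:
    counts1, lt1, ct1 = _locus_stats(gm, rows1)
    counts2, lt2, ct2 = _locus_stats(gm, rows2)
    shared = (lt1 > 0) & (lt2 > 0)
    if unbiased:
        shared &= (lt1 > 1) & (lt2 > 1)
    if not shared.any():
        return float("nan")
    h1, _ = _gene_diversity(gm, rows1, unbiased)
    h2, _ = _gene_diversity(gm, rows2, unbiased)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = counts1 / np.maximum(ct1, 1)
        p2 = counts2 / np.maximum(ct2, 1)
    pbar = (p1 + p2) / 2.0
    ht = 1.0 - gm.locus_copy_totals(pbar**2)
    hs = (h1 + h2) / 2.0
    if unbiased:
        # Nei–Chesser: Ht_hat = 1 - sum(pbar^2) + Hs_hat / (2 * n_tilde * np)
        n1 = lt1 / 2.0
        n2 = lt2 / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            n_tilde = 2.0 / (1.0 / n1 + 1.0 / n2)
        ht = ht + hs / (2.0 * n_tilde * 2.0)
    hs_bar = float(np.mean(hs[shared]))
    ht_bar = float(np.mean(ht[shared]))
    dst = ht_bar - hs_bar
    if population_correction:
        dst *= 2.0  # np / (np - 1) with np = 2 populations
        ht_bar = hs_bar + dst
    if ht_bar == 0.0:
        return float("nan")
    return dst / ht_bar


def pairwise_nei_fst(
    gm: GenotypeMatrix,
    partition: SamplePartition,
    unbiased: bool = False,
    population_correction: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Pairwise Nei FST among wild populations, plus the pairwise mean.

    Per pair, FST is the ratio of locus-averages ``(Ht_bar - Hs_bar) /
    Ht_bar`` (not an average of per-locus ratios); only loci typed in both
    populations contribute.  Negative values are reported as computed.
    Pairs sharing no typed locus are NaN and excluded from the mean.
    """
    pops = partition.populations(gm.individuals)
    if len(pops) < 2:
        raise ValueError("need at least 2 wild populations")
    names = list(pops)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    vals: list[float] = []
    for a, b in combinations(names, 2):
        fst = _pair_fst(
            gm,
            _row_indices(gm, pops[a]),
            _row_indices(gm, pops[b]),
            unbiased,
            population_correction,
        )
        mat.loc[a, b] = fst
        mat.loc[b, a] = fst
        if not np.isnan(fst):
            vals.append(fst)
    mean = float(np.mean(vals)) if vals else float("nan")
    return mat, mean


def allele_count(gm: GenotypeMatrix) -> int:
    """Distinct (locus, allele) pairs with at least one non-missing call.

    Because ``allele_labels`` always mirror the observed calls, this is just
    the total label count.
    """
    return sum(len(l.allele_labels) for l in gm.loci)


def popgen_summary(
    gm: GenotypeMatrix,
    partition: SamplePartition,
    unbiased: bool = False,
    population_correction: bool = False,
    rarefaction_g: int | None = None,
    label: str = "dataset",
) -> pd.DataFrame:
    """One summary row: sample sizes, allele count, AR, He, mean pairwise FST.

    FST uses wild samples only (grouped by population); allele count, AR and
    He use garden and wild samples.  If fewer than two wild populations are
    labelled, FST is NaN.
    """
    garden = partition.garden_ids(gm.individuals)
    wild = partition.wild_ids(gm.individuals)
    groups = {}
    if garden:
        groups["garden"] = garden
    if wild:
        groups["wild"] = wild
    ar = allelic_richness(gm, groups, g=rarefaction_g) if groups else {}
    try:
        _, mean_fst = pairwise_nei_fst(
            gm, partition, unbiased=unbiased,
            population_correction=population_correction,
        )
    except ValueError:
        mean_fst = float("nan")
    return pd.DataFrame(
        [
            {
                "dataset": label,
                "n_garden": len(garden),
                "n_wild": len(wild),
                "allele_count": allele_count(gm),
                "ar_garden": ar.get("garden", float("nan")),
                "ar_wild": ar.get("wild", float("nan")),
                "he_garden": (
                    expected_heterozygosity(gm, garden, unbiased)
                    if garden else float("nan")
                ),
                "he_wild": (
                    expected_heterozygosity(gm, wild, unbiased)
                    if wild else float("nan")
                ),
                "mean_pairwise_fst_wild": mean_fst,
            }
        ]
    )
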