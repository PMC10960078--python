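"""Capture curves and minimum wild sample size estimation.

For each resampling replicate, wild individuals are drawn without
replacement; capture at subsample size ``n`` is the percentage of the total
wild allele set observed (with at least one non-missing copy) among the
first ``n`` drawn.  The default scheme is *nested*: one uniform random
permutation per replicate, whose prefixes form the subsamples.  Nesting
makes capture monotone within a replicate and therefore gives every
replicate a well-defined threshold crossing point; an independent-draw-per-
size mode is available for sensitivity analysis.

:func:`analytic_expected_capture` provides the exact expectation under
without-replacement sampling (a hypergeometric miss-probability average) and
serves as an independent oracle for the Monte-Carlo engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from exsitu.genotype_io import GenotypeMatrix, SamplePartition
from exsitu.representation import (
    DEFAULT_CATEGORIES,
    FrequencyCategory,
    wild_allele_frequencies,
)


@dataclass
class ResamplingCurve:
    """Replicate-by-size capture percentages for one allele universe."""

    sizes: np.ndarray            # subsample sizes, 2..N_wild
    capture: np.ndarray          # (n_replicates, len(sizes)), percent
    n_replicates: int
    seed: int
    nested: bool = True
    category: str = "total"

    @property
    def n_wild(self) -> int:
        return int(self.sizes[-1])

    def mean(self) -> np.ndarray:
        return self.capture.mean(axis=0)

    def sd(self) -> np.ndarray:
        if self.n_replicates < 2:
            return np.full(len(self.sizes), np.nan)
        return self.capture.std(axis=0, ddof=1)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "category": self.category,
                "mean_percent": self.mean(),
                "sd_percent": self.sd(),
            }
        )

    def long_frame(self) -> pd.DataFrame:
        """Long format (replicate, size, category, percent)."""
        reps = np.repeat(np.arange(1, self.n_replicates + 1), len(self.sizes))
        return pd.DataFrame(
            {
                "replicate": reps,
                "size": np.tile(self.sizes, self.n_replicates),
                "category": self.category,
                "percent": self.capture.ravel(),
            }
        )


@dataclass
class MinSampleEstimate:
    """Per-replicate minimum sizes reaching a capture threshold."""

    threshold: float
    per_replicate: np.ndarray
    n_wild: int

    @property
    def mean(self) -> float:
        return float(self.per_replicate.mean())

    @property
    def sd(self) -> float:
        if len(self.per_replicate) < 2:
            return float("nan")
        return float(self.per_replicate.std(ddof=1))

    def format_cell(self) -> str:
        """Report cell: integer-rounded mean, 2-decimal SD, N in parens."""
        sd = "NA" if np.isnan(self.sd) else f"{self.sd:.2f}"
        return f"{round(self.mean)} ± {sd} ({self.n_wild})"


def _replicate_rngs(seed: int, n_replicates: int) -> list[np.random.Generator]:
    # one derived stream per replicate, so a parallel map reproduces the
    # serial result bit for bit
    return [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(seed).spawn(n_replicates)
    ]


def _capture_counts(
    presence: np.ndarray,
    perm: np.ndarray,
    nested: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cumulative distinct-allele counts at sizes 1..N for one replicate."""
    n = presence.shape[0]
    if nested:
        cum = np.logical_or.accumulate(presence[perm], axis=0)
        return cum.sum(axis=1)
    counts = np.empty(n, dtype=np.int64)
    for size in range(1, n + 1):
        pick = rng.choice(n, size=size, replace=False)
        counts[size - 1] = presence[pick].any(axis=0).sum()
    return counts


def capture_curve(
    gm_wild: GenotypeMatrix,
    n_replicates: int,
    seed: int,
    nested: bool = True,
) -> ResamplingCurve:
    """Monte-Carlo capture curve over subsample sizes 2..N for wild data.

    ``gm_wild`` must contain wild individuals only; its full allele set is
    the capture universe (so capture reaches exactly 100% at size N in every
    replicate under nesting).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n = gm_wild.n_individuals
    if n < 2:
        raise ValueError("need at least 2 wild individuals")
    presence = gm_wild.presence_matrix()
    n_alleles = presence.shape[1]
    if n_alleles == 0:
        raise ValueError("no alleles in the wild matrix")
    sizes = np.arange(2, n + 1)
    capture = np.empty((n_replicates, len(sizes)))
    for r, rng in enumerate(_replicate_rngs(seed, n_replicates)):
        perm = rng.permutation(n)
        counts = _capture_counts(presence, perm, nested, rng)
        capture[r] = 100.0 * counts[1:] / n_alleles
    return ResamplingCurve(
        sizes=sizes, capture=capture, n_replicates=n_replicates,
        seed=seed, nested=nested,
    )


def analytic_expected_capture(gm_wild: GenotypeMatrix, n: int) -> float:
    """Exact expected capture fraction for a random subsample of size ``n``.

    For an allele carried (with a non-missing call) by ``c`` of ``N`` wild
    individuals, the probability a without-replacement subsample of ``n``
    individuals misses it is ``C(N-c, n) / C(N, n)``; the expected captured
    fraction is the mean over alleles of one minus that.  Computed in exact
    rational arithmetic, so it equals the brute-force all-subsets average.
    """
    N = gm_wild.n_individuals
    if n > N:
        raise ValueError(f"subsample size {n} exceeds {N} wild individuals")
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    carriers = gm_wild.presence_matrix().sum(axis=0)
    denom = comb(N, n)
    total = Fraction(0)
    for c in carriers:
        misses = comb(N - int(c), n) if N - int(c) >= n else 0
        total += 1 - Fraction(misses, denom)
    return float(total / len(carriers))


def min_sample_size(
    curve: ResamplingCurve, threshold: float = 0.95
) -> MinSampleEstimate:
    """Smallest size whose capture reaches ``100 * threshold``, per replicate.

    Requires a nested curve (monotone within replicate); the threshold is
    always reached because capture is 100% at size N.  SD uses the n-1
    sample estimator.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if not curve.nested:
        raise ValueError(
            "min_sample_size requires a nested curve (monotone replicates)"
        )
    # small epsilon so 100*k/A == 100*threshold comparisons are not broken
    # by float representation
    ok = curve.capture >= 100.0 * threshold - 1e-9
    if not ok[:, -1].all():
        raise AssertionError("capture did not reach 100% at size N")
    idx = ok.argmax(axis=1)
    return MinSampleEstimate(
        threshold=threshold,
        per_replicate=curve.sizes[idx],
        n_wild=curve.n_wild,
    )


@dataclass
class ResamplingReport:
    """Per-category curves plus the total-category minimum-size estimate."""

    curves: dict[str, ResamplingCurve]
    estimate: MinSampleEstimate
    threshold: float
    nested: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.concat(
            [c.summary_frame() for c in self.curves.values()],
            ignore_index=True,
        )

    def long_frame(self) -> pd.DataFrame:
        return pd.concat(
            [c.long_frame() for c in self.curves.values()], ignore_index=True
        )

    def format_cell(self) -> str:
        return self.estimate.format_cell()


def resampling_report(
    gm: GenotypeMatrix,
    partition: SamplePartition,
    categories: tuple[FrequencyCategory, ...] = DEFAULT_CATEGORIES,
    n_replicates: int = 5000,
    seed: int = 0,
    threshold: float = 0.95,
    nested: bool = True,
) -> ResamplingReport:
    """Capture curves per frequency category and the threshold estimate.

    The wild submatrix defines both the allele universe and the category
    bins; all categories share the same permutations, so curves are
    comparable replicate by replicate.  The threshold applies to the total
    category only.  Categories containing zero alleles are omitted (logged).
    """
    import logging

    logger = logging.getLogger(__name__)
    wild_ids = partition.wild_ids(gm.individuals)
    gm_wild = gm.subset_individuals(wild_ids)
    wf = wild_allele_frequencies(gm_wild, partition)
    p = wf.freqs
    defined = wf.defined()
    masks: dict[str, np.ndarray] = {}
    for cat in categories:
        with np.errstate(invalid="ignore"):
            mask = defined & cat.contains(p)
        if not mask.any():
            logger.info("category %r has zero wild alleles; curve omitted",
                        cat.name)
            continue
        masks[cat.name] = mask
    if "total" not in masks:
        raise ValueError("total category is empty; nothing to resample")

    n = gm_wild.n_individuals
    presence = gm_wild.presence_matrix()
    sizes = np.arange(2, n + 1)
    capture = {
        name: np.empty((n_replicates, len(sizes))) for name in masks
    }
    for r, rng in enumerate(_replicate_rngs(seed, n_replicates)):
        perm = rng.permutation(n)
        if nested:
            cum = np.logical_or.accumulate(presence[perm], axis=0)
            for name, mask in masks.items():
                counts = cum[:, mask].sum(axis=1)
                capture[name][r] = 100.0 * counts[1:] / mask.sum()
        else:
            picks = [
                rng.choice(n, size=s, replace=False) for s in range(1, n + 1)
            ]
            for name, mask in masks.items():
                sub = presence[:, mask]
                counts = np.array(
                    [sub[pick].any(axis=0).sum() for pick in picks]
                )
                capture[name][r] = 100.0 * counts[1:] / mask.sum()
    curves = {
        name: ResamplingCurve(
            sizes=sizes, capture=capture[name], n_replicates=n_replicates,
            seed=seed, nested=nested, category=name,
        )
        for name in masks
    }
    estimate = min_sample_size(curves["total"], threshold)
    return ResamplingReport(
        curves=curves, estimate=estimate, threshold=threshold, nested=nested
    )
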