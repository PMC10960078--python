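"""Synthetic structured metapopulations and garden collections.

The generator emulates the statistical structure the analyses assume:

- ``K`` discrete wild populations whose allele frequencies are drawn around
  ancestral frequencies from a Dirichlet with concentration ``(1 - F) / F``
  (an island-model prior giving expected differentiation ``F``);
- two marker regimes — tens of multiallelic loci (symmetric-Dirichlet
  ancestral frequencies) vs thousands of biallelic loci with a Beta minor-
  allele-frequency spectrum skewed toward rare variants;
- garden collections built by copying sampled wild founders (accessions in
  living collections are predominantly wild-collected individuals, and
  capture depends only on which alleles enter the collection — no meiosis
  is simulated);
- per-cell missingness with per-sample and optional per-locus rate
  heterogeneity (emulating variable sequencing depth across both axes);
- private artifact alleles: brand-new singleton codes injected per
  (sample, locus), the mechanism by which sample-specific sequencing error
  masquerades as genuine rare polymorphism in de-novo-assembled datasets.
  Artifact injection can be weighted by per-locus quality so artifacts
  co-occur with high-missingness loci, which is what makes presence filters
  preferentially remove them.

All draws flow from one seed; every function also accepts a pre-built
``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from exsitu.genotype_io import GenotypeMatrix, Locus, SamplePartition

GARDEN_SCHEMES = ("random", "stratified", "skewed")


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic dataset."""

    n_populations: int = 4
    n_per_population: int = 25
    fst: float = 0.10
    regime: str = "biallelic"            # "biallelic" | "multiallelic"
    n_loci: int = 1000
    k_alleles: int = 6                   # multiallelic regime
    dirichlet_alpha: float = 1.0         # multiallelic ancestral spectrum
    maf_beta: tuple[float, float] = (0.3, 3.0)  # biallelic MAF spectrum
    garden_scheme: str = "random"
    garden_size: int = 30
    garden_weights: tuple[float, ...] | None = None  # skewed scheme
    missing_rate: float = 0.0
    missing_heterogeneity: float = 20.0  # per-sample Beta concentration
    locus_missing_rates: tuple[float, ...] | None = None
    error_allele_rate: float = 0.0
    couple_errors_to_locus_rates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.regime not in ("biallelic", "multiallelic"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.k_alleles < 2:
            raise ValueError("k_alleles must be >= 2")
        for name in ("missing_rate", "error_allele_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.garden_scheme not in GARDEN_SCHEMES:
            raise ValueError(f"unknown garden scheme {self.garden_scheme!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _safe_dirichlet(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw robust to very small concentrations.

    With alpha << 1 the underlying gamma draws can all underflow to zero;
    in that case the mass collapses onto one component chosen by the mean.
    """
    g = rng.gamma(alpha)
    s = g.sum()
    if s == 0.0:
        out = np.zeros_like(alpha)
        out[int(np.argmax(alpha))] = 1.0
        return out
    return g / s


def simulate_base_frequencies(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> list[np.ndarray]:
    """Ancestral per-locus allele-frequency vectors.

    Multiallelic: symmetric Dirichlet over ``k_alleles``.  Biallelic: the
    minor-allele frequency is Beta-distributed (skewed toward small values
    so the rare class is populated), halved-and-folded to stay in (0, 0.5].
    """
    rng = _rng(config.seed if seed is None else seed)
    out: list[np.ndarray] = []
    if config.regime == "multiallelic":
        alpha = np.full(config.k_alleles, config.dirichlet_alpha)
        for _ in range(config.n_loci):
            out.append(rng.dirichlet(alpha))
    else:
        a, b = config.maf_beta
        for _ in range(config.n_loci):
            maf = rng.beta(a, b)
            maf = min(max(maf, 1e-6), 0.5)
            out.append(np.array([1.0 - maf, maf]))
    return out


def simulate_population_frequencies(
    base: Sequence[np.ndarray],
    fst: float,
    n_populations: int,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Per-population frequencies from a Dirichlet island-model prior.

    For each population and locus, frequencies are Dirichlet with
    ``alpha_a = p_a * (1 - F) / F``: expectation equals the ancestral
    frequencies and among-population variance is ``F * p * (1 - p)``.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    rng = _rng(seed)
    scale = (1.0 - fst) / fst
    out: list[np.ndarray] = []
    for p in base:
        alpha = np.asarray(p, dtype=float) * scale
        pops = np.stack(
            [_safe_dirichlet(alpha, rng) for _ in range(n_populations)]
        )
        out.append(pops)
    return out


def simulate_genotypes(
    pop_freqs: Sequence[np.ndarray],
    n_per_population: int,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, SamplePartition]:
    """Draw diploid wild genotypes under Hardy–Weinberg within population.

    ``pop_freqs[l]`` has shape ``(n_populations, k_l)``.  Individuals are
    named ``P<p>_<i>`` and labelled wild in population ``pop<p>``.
    """
    rng = _rng(seed)
    n_pops = pop_freqs[0].shape[0]
    n_loci = len(pop_freqs)
    n = n_pops * n_per_population
    calls = np.empty((n, n_loci, 2), dtype=np.int32)
    for l, freqs in enumerate(pop_freqs):
        for p in range(n_pops):
            rows = slice(p * n_per_population, (p + 1) * n_per_population)
            draw = rng.choice(
                freqs.shape[1],
                size=(n_per_population, 2),
                p=freqs[p],
            )
            calls[rows, l, :] = draw
    individuals = [
        f"P{p + 1}_{i + 1}"
        for p in range(n_pops)
        for i in range(n_per_population)
    ]
    label_pool = [f"{a + 1}" for a in range(max(f.shape[1] for f in pop_freqs))]
    loci = []
    for l, freqs in enumerate(pop_freqs):
        loci.append(
            Locus(f"sim{l + 1}", tuple(label_pool[: freqs.shape[1]]))
        )
    gm = GenotypeMatrix(individuals, loci, calls, validate=False)
    # drop allele codes never drawn so labels mirror the calls
    gm = gm.subset_individuals(individuals)
    partition = SamplePartition(
        origin={s: "wild" for s in individuals},
        wild_population={
            s: f"pop{p + 1}"
            for p in range(n_pops)
            for s in individuals[p * n_per_population:(p + 1) * n_per_population]
        },
    )
    return gm, partition


def sample_garden(
    gm_wild: GenotypeMatrix,
    partition: SamplePartition,
    scheme: str = "random",
    size: int = 30,
    seed: int | np.random.Generator = 0,
    weights: Sequence[float] | None = None,
) -> tuple[GenotypeMatrix, SamplePartition]:
    """Append a garden collection of copies of sampled wild founders.

    Founders are sampled without replacement (``size`` must not exceed the
    wild count); each garden individual ``G<j>_<founder>`` duplicates its
    founder's genotypes.  Schemes: ``random`` (uniform over all wild),
    ``stratified`` (as equal as possible per population), ``skewed``
    (populations drawn with the given weights).  The wild set is retained.
    """
    rng = _rng(seed)
    wild = partition.wild_ids(gm_wild.individuals)
    if size > len(wild):
        raise ValueError(
            f"garden size {size} exceeds {len(wild)} available wild founders"
        )
    pops = partition.populations(gm_wild.individuals)
    names = list(pops)
    if scheme == "random":
        founders = list(rng.choice(wild, size=size, replace=False))
    elif scheme == "stratified":
        founders = []
        base, extra = divmod(size, len(names))
        per_pop = {nm: base for nm in names}
        for nm in list(rng.permutation(names))[:extra]:
            per_pop[nm] += 1
        for nm in names:
            members = pops[nm]
            take = min(per_pop[nm], len(members))
            founders.extend(rng.choice(members, size=take, replace=False))
        # top up from the remainder if some population was too small
        if len(founders) < size:
            rest = [s for s in wild if s not in set(founders)]
            founders.extend(
                rng.choice(rest, size=size - len(founders), replace=False)
            )
    elif scheme == "skewed":
        if weights is None or len(weights) != len(names):
            raise ValueError(
                "skewed scheme needs one weight per wild population"
            )
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative and not all zero")
        pool_ids: list[str] = []
        pool_w: list[float] = []
        for nm, wt in zip(names, w):
            for s in pops[nm]:
                pool_ids.append(s)
                pool_w.append(wt)
        pw = np.asarray(pool_w)
        if (pw > 0).sum() < size:
            raise ValueError(
                "not enough founders with positive weight for garden size"
            )
        probs = pw / pw.sum()
        founders = list(
            rng.choice(pool_ids, size=size, replace=False, p=probs)
        )
    else:
        raise ValueError(f"unknown garden scheme {scheme!r}")

    pos = {s: i for i, s in enumerate(gm_wild.individuals)}
    garden_ids = [f"G{j + 1}_{f}" for j, f in enumerate(founders)]
    garden_calls = gm_wild.calls[[pos[f] for f in founders]]
    calls = np.concatenate([gm_wild.calls, garden_calls], axis=0)
    gm = GenotypeMatrix(
        list(gm_wild.individuals) + garden_ids,
        gm_wild.loci,
        calls,
        validate=False,
    )
    new_partition = SamplePartition(
        origin={**partition.origin, **{g: "garden" for g in garden_ids}},
        wild_population=dict(partition.wild_population),
        excluded=set(partition.excluded),
    )
    return gm, new_partition


def inject_missingness(
    gm: GenotypeMatrix,
    rate: float,
    heterogeneity: float = 20.0,
    seed: int | np.random.Generator = 0,
    locus_rates: Sequence[float] | None = None,
) -> GenotypeMatrix:
    """Set cells missing with per-sample (and optionally per-locus) rates.

    Per-sample rates are Beta-distributed around ``rate`` with concentration
    ``heterogeneity`` (larger = more homogeneous).  With ``locus_rates``,
    the per-cell probability is ``sample_rate * locus_rate / rate``
    (clipped to [0, 1]) so locus quality modulates the sample baseline.
    ``rate = 0`` without locus rates is the identity.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = _rng(seed)
    n, m = gm.n_individuals, gm.n_loci
    if rate == 0.0 and locus_rates is None:
        return gm
    if rate > 0:
        a = rate * heterogeneity
        b = (1.0 - rate) * heterogeneity
        sample_rates = rng.beta(a, b, size=n)
    else:
        sample_rates = np.zeros(n)
    if locus_rates is not None:
        lr = np.asarray(locus_rates, dtype=float)
        if len(lr) != m:
            raise ValueError("locus_rates length must equal n_loci")
        if rate > 0:
            cell = np.clip(sample_rates[:, None] * lr[None, :] / rate, 0, 1)
        else:
            cell = np.broadcast_to(lr[None, :], (n, m))
    else:
        cell = np.broadcast_to(sample_rates[:, None], (n, m))
    drop = rng.random((n, m)) < cell
    calls = gm.calls.copy()
    calls[drop] = -1
    new = GenotypeMatrix(
        list(gm.individuals), gm.loci, calls,
        provisional_populations=dict(gm.provisional_populations),
        validate=False,
    )
    return new.subset_individuals(list(gm.individuals))  # recompute labels


def inject_error_alleles(
    gm: GenotypeMatrix,
    error_allele_rate: float,
    seed: int | np.random.Generator = 0,
    locus_weights: Sequence[float] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Replace allele copies with brand-new private artifact codes.

    Each typed (sample, locus) cell independently receives an artifact with
    probability ``error_allele_rate`` (optionally scaled by normalized
    ``locus_weights``): one of its two copies is overwritten with a fresh
    allele code unique to that sample and locus (``err_<sample>_<locus>``),
    so every artifact is a singleton.  Returns the mutated matrix and a
    truth table (sample_id, locus_id, allele) of injected artifacts.
    """
    if not 0.0 <= error_allele_rate <= 1.0:
        raise ValueError("error_allele_rate must be in [0, 1]")
    rng = _rng(seed)
    if error_allele_rate == 0.0:
        return gm, pd.DataFrame(columns=["sample_id", "locus_id", "allele"])
    n, m = gm.n_individuals, gm.n_loci
    if locus_weights is not None:
        w = np.asarray(locus_weights, dtype=float)
        if len(w) != m:
            raise ValueError("locus_weights length must equal n_loci")
        probs = np.clip(error_allele_rate * w / w.mean(), 0, 1)
        cell_probs = np.broadcast_to(probs[None, :], (n, m))
    else:
        cell_probs = np.full((n, m), error_allele_rate)
    typed = ~gm.missing_mask()
    hit = (rng.random((n, m)) < cell_probs) & typed
    label_calls = gm.label_calls()
    records: list[dict[str, str]] = []
    for i, l in zip(*np.nonzero(hit)):
        pair = label_calls[i][l]
        assert pair is not None
        code = f"err_{gm.individuals[i]}_{gm.loci[l].locus_id}"
        slot = int(rng.integers(2))
        new_pair = (code, pair[1]) if slot == 0 else (pair[0], code)
        label_calls[i][l] = new_pair
        records.append(
            {
                "sample_id": gm.individuals[i],
                "locus_id": gm.loci[l].locus_id,
                "allele": code,
            }
        )
    out = GenotypeMatrix.from_calls(
        list(gm.individuals),
        [l.locus_id for l in gm.loci],
        label_calls,
        source_groups=[l.source_group for l in gm.loci],
        provisional_populations=dict(gm.provisional_populations),
    )
    truth = pd.DataFrame(records, columns=["sample_id", "locus_id", "allele"])
    return out, truth


@dataclass
class SimulatedDataset:
    """Everything one simulation run produced."""

    genotypes: GenotypeMatrix
    partition: SamplePartition
    truth: pd.DataFrame                  # injected artifact alleles
    config: SimulationConfig
    base_frequencies: list[np.ndarray] = field(repr=False, default_factory=list)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full recipe: ancestral -> population -> genotypes -> garden
    -> artifact alleles -> missingness.

    Artifacts are injected before missingness, and (by default) both are
    weighted by the same per-locus rates, so artifact-bearing loci tend to
    be high-missingness loci — the coupling that makes a presence filter
    informative.  Garden founders are copied before artifact injection, so
    wild artifacts are never pre-captured in the garden.
    """
    root = np.random.SeedSequence(config.seed)
    streams = [np.random.Generator(np.random.PCG64(s)) for s in root.spawn(5)]
    base = simulate_base_frequencies(config, streams[0])
    pop_freqs = simulate_population_frequencies(
        base, config.fst, config.n_populations, streams[1]
    )
    gm, partition = simulate_genotypes(
        pop_freqs, config.n_per_population, streams[2]
    )
    if config.garden_size > 0:
        gm, partition = sample_garden(
            gm,
            partition,
            scheme=config.garden_scheme,
            size=config.garden_size,
            seed=streams[3],
            weights=config.garden_weights,
        )
    locus_rates = (
        np.asarray(config.locus_missing_rates, dtype=float)
        if config.locus_missing_rates is not None
        else None
    )
    truth = pd.DataFrame(columns=["sample_id", "locus_id", "allele"])
    if config.error_allele_rate > 0:
        weights = (
            locus_rates
            if (config.couple_errors_to_locus_rates and locus_rates is not None)
            else None
        )
        gm, truth = inject_error_alleles(
            gm, config.error_allele_rate, streams[4], locus_weights=weights
        )
    if config.missing_rate > 0 or locus_rates is not None:
        gm = inject_missingness(
            gm,
            config.missing_rate,
            heterogeneity=config.missing_heterogeneity,
            seed=streams[4],
            locus_rates=locus_rates,
        )
    return SimulatedDataset(
        genotypes=gm,
        partition=partition,
        truth=truth,
        config=config,
        base_frequencies=base,
    )
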