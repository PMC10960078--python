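import numpy as np
import pytest
from hypothesis import strategies as st

from exsitu.genotype_io import GenotypeMatrix, SamplePartition


def make_matrix(label_calls, individuals=None, locus_ids=None,
                source_groups=None):
    """Build a GenotypeMatrix from nested label-pair lists.

    ``label_calls[i][l]`` is ``("a", "b")`` or ``None``.
    """
    n = len(label_calls)
    m = len(label_calls[0]) if n else 0
    if individuals is None:
        individuals = [f"S{i + 1}" for i in range(n)]
    if locus_ids is None:
        locus_ids = [f"L{j + 1}" for j in range(m)]
    return GenotypeMatrix.from_calls(
        individuals, locus_ids, label_calls, source_groups=source_groups
    )


def all_wild(gm, populations=None):
    pops = populations or {}
    return SamplePartition(
        origin={s: "wild" for s in gm.individuals},
        wild_population={s: pops.get(s, "pop1") for s in gm.individuals},
    )


@pytest.fixture
def toy_garden_wild():
    """One locus, wild alleles A:0.5 B:0.4 C:0.1, garden {(A,A),(A,B)}."""
    # 20 wild gene copies: 10 A, 8 B, 2 C
    wild_calls = (
        [[("A", "A")]] * 4 + [[("A", "B")]] * 2 + [[("B", "B")]] * 3
        + [[("C", "C")]] * 1
    )
    garden_calls = [[("A", "A")], [("A", "B")]]
    calls = wild_calls + garden_calls
    inds = [f"W{i}" for i in range(10)] + ["G1", "G2"]
    gm = make_matrix(calls, individuals=inds)
    partition = SamplePartition(
        origin={s: ("wild" if s.startswith("W") else "garden") for s in inds},
        wild_population={s: "pop1" for s in inds if s.startswith("W")},
    )
    return gm, partition


@st.composite
def genotype_matrices(draw, max_ind=8, max_loci=6, max_alleles=4,
                      allow_missing=True):
    """Random small matrices with numeric allele labels (Genepop-safe)."""
    n = draw(st.integers(2, max_ind))
    m = draw(st.integers(1, max_loci))
    calls = []
    for _ in range(n):
        row = []
        for _ in range(m):
            if allow_missing and draw(st.booleans()) and draw(st.booleans()):
                row.append(None)
            else:
                # two-digit codes survive Genepop's fixed-width coding as-is
                a = draw(st.integers(10, 9 + max_alleles))
                b = draw(st.integers(10, 9 + max_alleles))
                row.append((str(a), str(b)))
        calls.append(row)
    # ensure every locus has at least one typed call so it has alleles
    for l in range(m):
        if all(calls[i][l] is None for i in range(n)):
            calls[0][l] = ("10", "10")
    return make_matrix(calls)


def rng(seed=0):
    return np.random.default_rng(seed)
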