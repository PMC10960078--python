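"""File-format support: Genepop, STRUCTURE, VCF, and sample metadata.

Genepop and STRUCTURE are parsed and written natively (both dialects are
line-oriented and simple); VCF is read through :mod:`cyvcf2` and written as
plain-text VCF 4.2.  Only GT fields are consumed from VCF — no coordinate
arithmetic is performed anywhere, so positions stay 1-based as in the file.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from exsitu.genotype_io.core import (
    GenotypeFormatError,
    GenotypeMatrix,
    SamplePartition,
)

# ---------------------------------------------------------------------- #
# Genepop


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a Genepop file (2- or 3-digit allele coding, auto-detected).

    POP block membership is recorded in ``provisional_populations``
    (``pop1``, ``pop2``, ... in file order).  All-zero allele codes mark
    missing data; a half-typed cell is collapsed to missing.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeFormatError("genepop file too short")
    # line 0 is the title; locus names run until the first POP separator
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].replace(",", " ").split():
            locus_ids.append(name)
        i += 1
    if i == len(lines):
        raise GenotypeFormatError("no POP separator found")
    if not locus_ids:
        raise GenotypeFormatError("no locus names before first POP")

    individuals: list[str] = []
    label_calls: list[list[tuple[str, str] | None]] = []
    pops: dict[str, str] = {}
    width: int | None = None
    pop_no = 0
    while i < len(lines):
        line = lines[i]
        i += 1
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop_no += 1
            continue
        lineno = i  # 1-based line number of this sample row
        if "," not in line:
            raise GenotypeFormatError(
                f"line {lineno}: expected 'sampleID , genotypes'"
            )
        sid, _, geno = line.partition(",")
        sid = sid.strip()
        tokens = geno.split()
        if len(tokens) != len(locus_ids):
            raise GenotypeFormatError(
                f"line {lineno}: {len(tokens)} genotype fields for "
                f"{len(locus_ids)} loci"
            )
        if sid in pops:
            raise GenotypeFormatError(f"duplicate sample ID {sid!r}")
        row: list[tuple[str, str] | None] = []
        for l, tok in enumerate(tokens):
            if width is None:
                if len(tok) == 4:
                    width = 2
                elif len(tok) == 6:
                    width = 3
                else:
                    raise GenotypeFormatError(
                        f"line {lineno}: odd-length allele field {tok!r}"
                    )
            if len(tok) != 2 * width:
                if len(tok) in (4, 6):
                    raise GenotypeFormatError(
                        f"mixed allele digit widths at locus "
                        f"{locus_ids[l]!r} (expected {2 * width}-character "
                        f"fields, got {tok!r})"
                    )
                raise GenotypeFormatError(
                    f"line {lineno}: odd-length allele field {tok!r}"
                )
            a, b = tok[:width], tok[width:]
            zero = "0" * width
            row.append(None if a == zero or b == zero else (a, b))
        individuals.append(sid)
        label_calls.append(row)
        pops[sid] = f"pop{pop_no}"
    return GenotypeMatrix.from_calls(
        individuals, locus_ids, label_calls, provisional_populations=pops
    )


def write_genepop(
    gm: GenotypeMatrix,
    path: str | Path,
    partition: SamplePartition | None = None,
    title: str = "exsitu export",
) -> None:
    """Write a Genepop file.

    Allele labels must be numeric strings of at most three digits (the
    format's coding).  With a partition, wild samples are grouped into one
    POP block per population and garden samples into a final block;
    without one, all samples form a single block.
    """
    width = 2
    for locus in gm.loci:
        for lab in locus.allele_labels:
            if not lab.isdigit() or len(lab) > 3 or int(lab) == 0:
                raise ValueError(
                    f"allele label {lab!r} at locus {locus.locus_id!r} "
                    "cannot be Genepop-coded (need nonzero integers < 1000)"
                )
            if len(lab) > 2 or int(lab) > 99:
                width = 3
    calls = gm.label_calls()

    def row(i: int) -> str:
        fields = []
        for pair in calls[i]:
            if pair is None:
                fields.append("0" * (2 * width))
            else:
                fields.append(
                    f"{int(pair[0]):0{width}d}{int(pair[1]):0{width}d}"
                )
        return f"{gm.individuals[i]} ,  " + " ".join(fields)

    blocks: list[list[int]] = []
    if partition is not None:
        by_pop: dict[str, list[int]] = {}
        garden: list[int] = []
        for i, sid in enumerate(gm.individuals):
            if sid in partition.excluded:
                continue
            if partition.origin.get(sid) == "garden":
                garden.append(i)
            else:
                by_pop.setdefault(
                    partition.wild_population.get(sid, "wild"), []
                ).append(i)
        blocks = [idx for _, idx in sorted(by_pop.items())]
        if garden:
            blocks.append(garden)
    else:
        blocks = [list(range(gm.n_individuals))]

    out = [title]
    out.extend(locus.locus_id for locus in gm.loci)
    for block in blocks:
        out.append("POP")
        out.extend(row(i) for i in block)
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------- #
# STRUCTURE


def _structure_rows(path: str | Path) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        toks = line.split()
        if toks:
            rows.append(toks)
    return rows


def read_structure(
    path: str | Path,
    one_row_per_individual: bool = False,
    missing_code: str = "-9",
    header: bool | None = None,
) -> GenotypeMatrix:
    """Read a STRUCTURE file (two rows per individual, or one row with two
    columns per locus).

    ``header=None`` auto-detects an optional first line of locus names by
    column count.  Any genotype in which either allele equals
    ``missing_code`` is collapsed to missing.
    """
    rows = _structure_rows(path)
    if not rows:
        raise GenotypeFormatError("empty STRUCTURE file")
    cols_per_locus = 2 if one_row_per_individual else 1
    if header is None:
        header = len(rows) > 1 and (
            len(rows[1]) == 1 + cols_per_locus * len(rows[0])
        )
    locus_ids: list[str] | None = None
    if header:
        locus_ids = rows[0]
        rows = rows[1:]
    if not rows:
        raise GenotypeFormatError("STRUCTURE file has a header but no data")
    n_fields = len(rows[0])
    for r, toks in enumerate(rows):
        if len(toks) != n_fields:
            raise GenotypeFormatError(
                f"ragged STRUCTURE row at data row {r}: "
                f"{len(toks)} fields, expected {n_fields}"
            )
    n_loci = (n_fields - 1) // cols_per_locus
    if n_fields != 1 + cols_per_locus * n_loci or n_loci < 1:
        raise GenotypeFormatError(
            f"cannot split {n_fields} columns into ID + "
            f"{cols_per_locus} column(s) per locus"
        )
    if locus_ids is None:
        locus_ids = [f"L{j + 1}" for j in range(n_loci)]
    elif len(locus_ids) != n_loci:
        raise GenotypeFormatError(
            f"{len(locus_ids)} locus names in header for {n_loci} loci"
        )

    individuals: list[str] = []
    label_calls: list[list[tuple[str, str] | None]] = []

    def cell(a: str, b: str) -> tuple[str, str] | None:
        return None if a == missing_code or b == missing_code else (a, b)

    if one_row_per_individual:
        for toks in rows:
            individuals.append(toks[0])
            label_calls.append(
                [cell(toks[1 + 2 * j], toks[2 + 2 * j]) for j in range(n_loci)]
            )
    else:
        if len(rows) % 2:
            raise GenotypeFormatError(
                "odd number of data rows in two-row STRUCTURE layout"
            )
        for r in range(0, len(rows), 2):
            top, bot = rows[r], rows[r + 1]
            if top[0] != bot[0]:
                raise GenotypeFormatError(
                    f"row pair at data rows {r},{r + 1} has mismatched IDs "
                    f"({top[0]!r} vs {bot[0]!r})"
                )
            individuals.append(top[0])
            label_calls.append(
                [cell(top[1 + j], bot[1 + j]) for j in range(n_loci)]
            )
    if len(set(individuals)) != len(individuals):
        raise GenotypeFormatError("duplicate sample IDs")
    return GenotypeMatrix.from_calls(individuals, locus_ids, label_calls)


def write_structure(
    gm: GenotypeMatrix,
    path: str | Path,
    one_row_per_individual: bool = False,
    missing_code: str = "-9",
    header: bool = True,
) -> None:
    """Write a STRUCTURE file in either layout (locus-name header optional)."""
    calls = gm.label_calls()
    lines: list[str] = []
    if header:
        lines.append("\t".join(l.locus_id for l in gm.loci))
    for i, sid in enumerate(gm.individuals):
        pairs = [
            (missing_code, missing_code) if c is None else c for c in calls[i]
        ]
        if one_row_per_individual:
            lines.append(
                "\t".join([sid] + [t for p in pairs for t in p])
            )
        else:
            lines.append("\t".join([sid] + [p[0] for p in pairs]))
            lines.append("\t".join([sid] + [p[1] for p in pairs]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------- #
# VCF


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF (v4.x) via cyvcf2.

    One locus per record; ``./.`` and half-calls become missing; phased and
    unphased separators are treated identically.  A non-``.`` ID column
    populates ``source_group`` (the shared assembled-locus key when several
    SNPs come from one locus).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeFormatError("VCF has no sample columns")
    locus_ids: list[str] = []
    groups: list[str | None] = []
    columns: list[list[tuple[str, str] | None]] = []
    orders: list[list[str]] = []
    for var in vcf:
        if "GT" not in (var.FORMAT or []):
            raise GenotypeFormatError(
                f"record {var.CHROM}:{var.POS} has no GT format key"
            )
        alleles = [var.REF] + list(var.ALT)
        col: list[tuple[str, str] | None] = []
        for s, gt in zip(samples, var.genotypes):
            ploidy = len(gt) - 1  # last element is the phased flag
            if ploidy != 2:
                raise GenotypeFormatError(
                    f"sample {s!r} at {var.CHROM}:{var.POS} is not diploid "
                    f"(ploidy {ploidy})"
                )
            a, b = gt[0], gt[1]
            col.append(None if a < 0 or b < 0 else (alleles[a], alleles[b]))
        locus_ids.append(f"{var.CHROM}:{var.POS}")
        groups.append(var.ID if var.ID not in (None, ".") else None)
        columns.append(col)
        orders.append(alleles)
    vcf.close()
    if not locus_ids:
        raise GenotypeFormatError("VCF contains no variant records")
    label_calls = [
        [columns[l][i] for l in range(len(locus_ids))]
        for i in range(len(samples))
    ]
    return GenotypeMatrix.from_calls(
        samples, locus_ids, label_calls, source_groups=groups,
        label_order=orders,
    )


def _vcf_allele_codes(k: int) -> list[str]:
    """Distinct ACGT strings for k synthetic alleles."""
    bases = "ACGT"
    codes: list[str] = []
    for width in itertools.count(1):
        for combo in itertools.product(bases, repeat=width):
            codes.append("".join(combo))
            if len(codes) == k:
                return codes
    raise AssertionError  # pragma: no cover


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal plain-text VCF 4.2 (GT only).

    Allele labels that are not pure A/C/G/T sequences are replaced by
    generated nucleotide codes (label order preserved), since VCF restricts
    REF/ALT to sequence strings; the original labels survive in Genepop or
    STRUCTURE exports, not here.  Locus IDs are written to the ID column.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.individuals),
    ]
    valid = set("ACGT")
    for l, locus in enumerate(gm.loci):
        labels = locus.allele_labels
        if not labels:
            continue  # locus with no typed calls cannot be represented
        if all(set(lab) <= valid for lab in labels):
            codes = list(labels)
        else:
            codes = _vcf_allele_codes(len(labels))
        ref, alts = codes[0], codes[1:]
        gts = []
        for i in range(gm.n_individuals):
            a, b = gm.calls[i, l]
            gts.append("./." if a < 0 else f"{a}/{b}")
        lines.append(
            "\t".join(
                [
                    "1",
                    str(l + 1),
                    locus.source_group or locus.locus_id,
                    ref,
                    ",".join(alts) if alts else ".",
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------- #
# sample metadata


def read_metadata(path: str | Path) -> SamplePartition:
    """Read a delimited sample table into a :class:`SamplePartition`.

    Required columns: ``sample_id``, ``origin`` (garden|wild).  Optional:
    ``population`` (wild source population) and ``excluded`` (0/1).  The
    delimiter is sniffed (TSV and CSV both work).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample_id", "origin"):
        if col not in df.columns:
            raise GenotypeFormatError(f"metadata is missing column {col!r}")
    origin: dict[str, str] = {}
    wild_population: dict[str, str] = {}
    excluded: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        orig = str(row["origin"]).strip().lower()
        if orig not in ("garden", "wild"):
            raise GenotypeFormatError(
                f"sample {sid!r}: origin must be garden|wild, got {orig!r}"
            )
        origin[sid] = orig
        pop = row.get("population")
        if orig == "wild" and pop is not None and not pd.isna(pop):
            wild_population[sid] = str(pop).strip()
        exc = row.get("excluded")
        if exc is not None and not pd.isna(exc) and str(exc).strip() in (
            "1", "true", "True",
        ):
            excluded.add(sid)
    return SamplePartition(
        origin=origin, wild_population=wild_population, excluded=excluded
    )


def write_metadata(partition: SamplePartition, path: str | Path,
                   individuals: Sequence[str] | None = None) -> None:
    """Write the partition as a TSV (columns: sample_id, origin, population,
    excluded)."""
    ids = list(individuals) if individuals is not None else list(partition.origin)
    rows = [
        {
            "sample_id": sid,
            "origin": partition.origin.get(sid, ""),
            "population": partition.wild_population.get(sid, ""),
            "excluded": int(sid in partition.excluded),
        }
        for sid in ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
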