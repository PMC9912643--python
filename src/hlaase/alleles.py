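"""Personalized HLA class I reference construction.

The quantification step needs, per sample, the cDNA sequences of the two
genotyped alleles of each HLA-I gene (HLA-A, -B, -C), taken from an
IMGT/HLA-style allele database.  This module parses such a database, resolves
a genotype against it (exact name first, otherwise a unique colon-field
prefix match so that a two-field genotype like ``A*02:01`` can select a
four-field database entry), and collapses allele pairs whose cDNA is
identical — reads cannot distinguish those, so the gene is flagged as not
assessable for allele-specific expression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import AlleleLookupError, AmbiguousAlleleError, FormatError
from . import io

HLA_GENES = ("A", "B", "C")

_NAME_RE = re.compile(r"^(?:HLA-)?([A-Za-z0-9]+)\*(\d+(?::\d+)*)[A-Z]?$")

_VALID_BASES = frozenset("ACGTN")


def parse_allele_name(name: str) -> tuple[str, tuple[str, ...]]:
    """Split an allele name into (gene, colon-separated fields).

    Accepts ``A*02:01:01:01`` or ``HLA-A*02:01``; raises FormatError otherwise.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise FormatError(f"cannot parse allele name {name!r}")
    return m.group(1), tuple(m.group(2).split(":"))


@dataclass(frozen=True)
class AlleleSequence:
    """One HLA allele cDNA with its parsed gene."""

    name: str
    gene: str
    sequence: str

    def __post_init__(self):
        gene, _fields = parse_allele_name(self.name)
        if gene != self.gene:
            raise FormatError(
                f"gene {self.gene!r} inconsistent with allele name {self.name!r}"
            )
        if not self.sequence:
            raise FormatError(f"allele {self.name!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"allele {self.name!r} contains invalid characters {sorted(bad)}"
            )

    @classmethod
    def from_name(cls, name: str, sequence: str) -> "AlleleSequence":
        gene, _ = parse_allele_name(name)
        return cls(name=name, gene=gene, sequence=sequence.upper())

    @property
    def fields(self) -> tuple[str, ...]:
        return parse_allele_name(self.name)[1]


@dataclass(frozen=True)
class Genotype:
    """Two allele names per HLA-I gene; identical names mean homozygous."""

    calls: Mapping[str, tuple[str, str]]

    def __post_init__(self):
        for gene, pair in self.calls.items():
            if len(pair) != 2:
                raise FormatError(f"gene {gene}: genotype needs exactly two alleles")

    def zygosity(self, gene: str) -> str:
        a1, a2 = self.calls[gene]
        return "homozygous" if a1 == a2 else "heterozygous"

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.calls)


@dataclass
class PersonalizedReference:
    """Per-sample reference: at most two distinct allele cDNAs per gene.

    ``collapse_map`` sends every genotype allele name to its representative;
    a heterozygous pair with identical cDNA collapses onto one representative
    and the gene joins ``collapsed_genes``.  ``assessable(gene)`` is True only
    for heterozygous genes whose two cDNAs are distinct — the only situation
    in which an allele frequency is measurable from reads.
    """

    sequences: list[AlleleSequence]
    collapse_map: dict[str, str]
    zygosity: dict[str, str]
    collapsed_genes: set[str] = field(default_factory=set)

    def representatives(self, gene: str) -> list[AlleleSequence]:
        return sorted(
            (s for s in self.sequences if s.gene == gene), key=lambda s: s.name
        )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({s.gene for s in self.sequences}))

    def assessable(self, gene: str) -> bool:
        return (
            self.zygosity.get(gene) == "heterozygous"
            and gene not in self.collapsed_genes
        )

    def min_length(self) -> int:
        return min(len(s.sequence) for s in self.sequences)


def load_allele_database(fasta_path) -> dict[str, AlleleSequence]:
    """Parse a multi-FASTA allele database into {name: AlleleSequence}.

    The allele name is the first header token parseable as ``gene*ff:ff...``
    (IMGT accession-prefixed headers like ``HLA:HLA00001 A*01:01:01:01 ...``
    are handled by scanning tokens).  Duplicate names and unparseable headers
    are errors; lowercase bases are uppercased.
    """
    records = io.read_fasta(fasta_path)
    if not records:
        raise FormatError(f"{fasta_path}: no FASTA records found")
    db: dict[str, AlleleSequence] = {}
    for header, seq in records:
        name = None
        for token in header.split():
            try:
                parse_allele_name(token)
            except FormatError:
                continue
            name = token
            break
        if name is None:
            raise FormatError(f"no allele name found in FASTA header {header!r}")
        if name in db:
            raise FormatError(f"duplicate allele name {name!r} in {fasta_path}")
        db[name] = AlleleSequence.from_name(name, seq)
    return db


def resolve_allele(name: str, db: Mapping[str, AlleleSequence]) -> AlleleSequence:
    """Resolve a (possibly lower-resolution) allele name in the database.

    Exact match wins; otherwise the name's colon fields must be a prefix of
    exactly one database entry of the same gene.
    """
    if name in db:
        return db[name]
    gene, fields = parse_allele_name(name)
    matches = [
        a
        for a in db.values()
        if a.gene == gene and a.fields[: len(fields)] == fields
    ]
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        raise AmbiguousAlleleError(name, sorted(a.name for a in matches))
    near = sorted(
        a.name for a in db.values() if a.gene == gene and a.fields[0] == fields[0]
    ) or sorted(a.name for a in db.values() if a.gene == gene)
    raise AlleleLookupError(name, near[:5])


def resolve_genotype(
    genotype: Genotype, db: Mapping[str, AlleleSequence]
) -> PersonalizedReference:
    """Select the genotyped allele sequences and collapse indistinguishable ones."""
    sequences: list[AlleleSequence] = []
    collapse: dict[str, str] = {}
    zygosity: dict[str, str] = {}
    collapsed: set[str] = set()
    for gene in sorted(genotype.calls):
        name1, name2 = genotype.calls[gene]
        a1 = resolve_allele(name1, db)
        a2 = resolve_allele(name2, db)
        zygosity[gene] = "homozygous" if a1.name == a2.name else "heterozygous"
        if a1.name == a2.name:
            sequences.append(a1)
            collapse[a1.name] = a1.name
        elif a1.sequence == a2.sequence:
            # reads cannot tell these apart: keep one, flag the gene
            rep, other = sorted((a1, a2), key=lambda a: a.name)
            sequences.append(rep)
            collapse[rep.name] = rep.name
            collapse[other.name] = rep.name
            collapsed.add(gene)
        else:
            for a in sorted((a1, a2), key=lambda a: a.name):
                sequences.append(a)
                collapse[a.name] = a.name
    return PersonalizedReference(
        sequences=sequences,
        collapse_map=collapse,
        zygosity=zygosity,
        collapsed_genes=collapsed,
    )


def read_genotype_tsv(path, sample: str | None = None) -> Genotype:
    """Read a genotype TSV with columns sample, gene, allele1, allele2."""
    df = io.read_tsv(path, dtype=str)
    required = {"sample", "gene", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: genotype TSV must have columns {sorted(required)}")
    if sample is not None:
        df = df[df["sample"] == sample]
        if df.empty:
            raise FormatError(f"{path}: no genotype rows for sample {sample!r}")
    calls = {}
    for _, row in df.iterrows():
        gene = row["gene"].removeprefix("HLA-")
        if gene in calls:
            raise FormatError(f"{path}: duplicate genotype rows for gene {gene}")
        calls[gene] = (row["allele1"], row["allele2"])
    return Genotype(calls=calls)


def write_reference_fasta(reference: PersonalizedReference, path) -> None:
    records = sorted(
        ((s.name, s.sequence) for s in reference.sequences), key=lambda r: r[0]
    )
    io.write_fasta(records, path)


def write_collapse_map(reference: PersonalizedReference, path) -> None:
    import pandas as pd

    rows = [
        {"allele": a, "representative": r}
        for a, r in sorted(reference.collapse_map.items())
    ]
    io.write_tsv(pd.DataFrame(rows, columns=["allele", "representative"]), path)


def reference_from_sequences(
    alleles: Iterable[AlleleSequence],
    zygosity: Mapping[str, str] | None = None,
) -> PersonalizedReference:
    """Build a PersonalizedReference directly from allele sequences.

    Used when a personalized FASTA already exists (CLI ``quantify``) or by the
    simulator.  Genes with two sequences are taken as heterozygous; genes with
    one are taken as homozygous unless ``zygosity`` says otherwise.
    """
    seqs = sorted(alleles, key=lambda s: (s.gene, s.name))
    zyg: dict[str, str] = {}
    for gene in {s.gene for s in seqs}:
        reps = [s for s in seqs if s.gene == gene]
        if len(reps) > 2:
            raise FormatError(f"gene {gene}: more than two allele sequences")
        default = "heterozygous" if len(reps) == 2 else "homozygous"
        zyg[gene] = (zygosity or {}).get(gene, default)
    return PersonalizedReference(
        sequences=seqs,
        collapse_map={s.name: s.name for s in seqs},
        zygosity=zyg,
    )
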