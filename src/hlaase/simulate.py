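"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the tumor/normal mixture the ASE model assumes: each
HLA-I gene carries two allele cDNAs differing at a handful of substitution
sites, tumor cells express the alleles at specified expressed copy numbers
(summing to the ploidy), normal cells express them in balance, and bulk
reads draw their allele with probability equal to the mixture allele
frequency.  Read start positions are uniform, strands are random, and
sequencing errors are i.i.d. substitutions.

Defaults are the desk-scale study conditions: 500 nt alleles with 5 variant
sites spaced at least one k-mer apart (so every site yields allele-specific
k-mers), 2,000 single-end 100 nt reads per gene at a 0.1% error rate,
ploidy 2, and cohort purities uniform on [0.2, 0.9].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _dna, io
from .alleles import AlleleSequence, PersonalizedReference, reference_from_sequences
from .ase import PurityPloidy, forward_allele_frequency
from .errors import ParameterError

GENES = ("A", "B", "C")

DEFAULT_ALLELE_LENGTH = 500
DEFAULT_N_VARIANT_SITES = 5
DEFAULT_MIN_SPACING = 31
DEFAULT_READ_LENGTH = 100
DEFAULT_READS_PER_GENE = 2000
DEFAULT_ERROR_RATE = 1e-3
DEFAULT_PSI = 2.0
DEFAULT_PURITY_RANGE = (0.2, 0.9)
LOSS_CN_RANGE = (0.0, 0.4)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_allele_pair(
    length: int = DEFAULT_ALLELE_LENGTH,
    n_variant_sites: int = DEFAULT_N_VARIANT_SITES,
    seed=None,
    *,
    min_spacing: int = DEFAULT_MIN_SPACING,
    gene: str = "A",
    group: int = 90,
) -> tuple[AlleleSequence, AlleleSequence]:
    """Two allele cDNAs of one gene differing at ``n_variant_sites``
    substitutions spaced at least ``min_spacing`` apart.

    Spacing >= k guarantees each site yields fully allele-specific k-mers,
    keeping identifiability under the control of the generator rather than
    the estimator.  Deterministic under ``seed``.
    """
    if n_variant_sites < 1:
        raise ParameterError("alleles must differ at >= 1 site to be distinguishable")
    span = (n_variant_sites - 1) * min_spacing
    if span >= length:
        raise ParameterError(
            f"cannot place {n_variant_sites} sites spaced >= {min_spacing} "
            f"in {length} nt"
        )
    rng = _rng(seed)
    slack = length - 1 - span
    offsets = np.sort(rng.integers(0, slack + 1, size=n_variant_sites))
    sites = offsets + np.arange(n_variant_sites) * min_spacing
    seq1 = rng.integers(0, 4, size=length, dtype=np.uint8)
    seq2 = seq1.copy()
    seq2[sites] = (seq1[sites] + rng.integers(1, 4, size=n_variant_sites)) % 4
    s1, s2 = _dna.decode(np.stack([seq1, seq2]))
    name1 = f"{gene}*{group:02d}:01"
    name2 = f"{gene}*{group:02d}:02"
    return (
        AlleleSequence(name=name1, gene=gene, sequence=s1),
        AlleleSequence(name=name2, gene=gene, sequence=s2),
    )


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of one simulated case."""

    exp_cn: Mapping[str, tuple[float, float]]  # per gene, sums to psi
    rho: float
    psi: float = DEFAULT_PSI
    reads_per_gene: int = DEFAULT_READS_PER_GENE
    read_length: int = DEFAULT_READ_LENGTH
    error_rate: float = DEFAULT_ERROR_RATE
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.rho <= 1:
            raise ParameterError(f"purity rho must be in (0, 1], got {self.rho}")
        for gene, (c1, c2) in self.exp_cn.items():
            if c1 < 0 or c2 < 0:
                raise ParameterError(f"gene {gene}: expressed copy numbers must be >= 0")
            if abs((c1 + c2) - self.psi) > 1e-9:
                raise ParameterError(
                    f"gene {gene}: exp_CN must sum to psi = {self.psi}"
                )

    def allele_frequency(self, gene: str) -> float:
        c1, c2 = self.exp_cn[gene]
        return forward_allele_frequency(c1, c2, self.rho)


@dataclass
class GeneReads:
    """Encoded simulated reads for one gene, with per-read truth labels."""

    gene: str
    reads: np.ndarray  # (n, read_length) uint8
    allele_idx: np.ndarray  # (n,) 0/1 = which representative the read came from


def simulate_gene_reads(
    allele1: AlleleSequence,
    allele2: AlleleSequence,
    af1: float,
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed=None,
) -> GeneReads:
    """Draw reads from a two-allele gene at bulk allele-1 frequency ``af1``.

    Per read: allele ~ Bernoulli(af1), start uniform over valid positions,
    strand fair coin, bases substituted i.i.d. at ``error_rate``.
    """
    rng = _rng(seed)
    length = len(allele1.sequence)
    if len(allele2.sequence) != length:
        raise ParameterError("allele pair must have equal cDNA lengths")
    if read_length > length:
        raise ParameterError(
            f"read length {read_length} exceeds allele length {length}"
        )
    templates = np.stack(
        [_dna.encode_seq(allele1.sequence), _dna.encode_seq(allele2.sequence)]
    )
    allele_idx = (rng.random(n_reads) >= af1).astype(np.int8)  # 0 = allele1
    starts = rng.integers(0, length - read_length + 1, size=n_reads)
    cols = starts[:, None] + np.arange(read_length)
    reads = templates[allele_idx[:, None], cols]
    flip = rng.random(n_reads) < 0.5
    reads[flip] = _dna.revcomp(reads[flip])
    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        n_err = int(err.sum())
        if n_err:
            reads[err] = (reads[err] + rng.integers(1, 4, size=n_err)) % 4
    return GeneReads(gene=allele1.gene, reads=reads, allele_idx=allele_idx)


@dataclass
class SimulatedCase:
    """Everything the pipeline needs for one case, plus the truth."""

    sample: str
    alleles: list[AlleleSequence]
    genotype: dict[str, tuple[str, str]]
    pp: PurityPloidy
    truth: SimTruth
    reads: dict[str, GeneReads]
    label_loss: bool
    loss_gene: Optional[str] = None

    @property
    def reference(self) -> PersonalizedReference:
        return reference_from_sequences(self.alleles)

    def read_batch(self) -> np.ndarray:
        """All reads of the case, genes concatenated in sorted order."""
        return np.concatenate([self.reads[g].reads for g in sorted(self.reads)])

    def read_sequences(self) -> tuple[list[str], list[str]]:
        names, seqs = [], []
        for gene in sorted(self.reads):
            gr = self.reads[gene]
            for i, seq in enumerate(_dna.decode(gr.reads)):
                names.append(f"{self.sample}:{gene}:{i}:a{gr.allele_idx[i] + 1}")
                seqs.append(seq)
        return names, seqs


def simulate_reads(
    truth: SimTruth, reference: PersonalizedReference, seed=None
) -> dict[str, GeneReads]:
    """Simulate reads for every gene of a personalized reference.

    Heterozygous genes draw alleles at the mixture AF implied by ``truth``;
    single-representative genes emit all reads from that representative.
    """
    rng = _rng(seed if seed is not None else truth.seed)
    out: dict[str, GeneReads] = {}
    for gene in reference.genes:
        reps = reference.representatives(gene)
        if gene not in truth.exp_cn:
            raise ParameterError(f"truth has no expressed copy numbers for gene {gene}")
        if len(reps) == 2:
            af1 = truth.allele_frequency(gene)
            out[gene] = simulate_gene_reads(
                reps[0],
                reps[1],
                af1,
                truth.reads_per_gene,
                truth.read_length,
                truth.error_rate,
                rng,
            )
        else:
            gr = simulate_gene_reads(
                reps[0],
                reps[0],
                1.0,
                truth.reads_per_gene,
                truth.read_length,
                truth.error_rate,
                rng,
            )
            out[gene] = GeneReads(gene=gene, reads=gr.reads, allele_idx=gr.allele_idx)
    return out


@dataclass(frozen=True)
class CaseParams:
    sample: str
    label_loss: bool
    loss_gene: Optional[str]
    loss_minor_cn: Optional[float]
    rho: float
    psi: float
    seed: int


@dataclass
class CohortPlan:
    """Deterministic plan of a simulated cohort; cases materialize lazily."""

    cases: list[CaseParams]
    reads_per_gene: int
    read_length: int
    error_rate: float
    allele_length: int
    n_variant_sites: int
    min_spacing: int
    seed: int

    def labels(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": c.sample,
                    "label": int(c.label_loss),
                    "loss_gene": c.loss_gene or "NA",
                    "loss_minor_expCN": (
                        c.loss_minor_cn if c.loss_minor_cn is not None else np.nan
                    ),
                    "purity": c.rho,
                    "ploidy": c.psi,
                }
                for c in self.cases
            ]
        )

    def materialize(self, params: CaseParams) -> SimulatedCase:
        rng = np.random.default_rng(params.seed)
        alleles: list[AlleleSequence] = []
        genotype: dict[str, tuple[str, str]] = {}
        exp_cn: dict[str, tuple[float, float]] = {}
        loss_gene = params.loss_gene
        for gi, gene in enumerate(GENES):
            a1, a2 = simulate_allele_pair(
                self.allele_length,
                self.n_variant_sites,
                rng,
                min_spacing=self.min_spacing,
                gene=gene,
                group=90 + gi,
            )
            alleles += [a1, a2]
            genotype[gene] = (a1.name, a2.name)
            if gene == loss_gene:
                minor = float(params.loss_minor_cn)
                exp_cn[gene] = (minor, params.psi - minor)
            else:
                exp_cn[gene] = (params.psi / 2.0, params.psi / 2.0)
        truth = SimTruth(
            exp_cn=exp_cn,
            rho=params.rho,
            psi=params.psi,
            reads_per_gene=self.reads_per_gene,
            read_length=self.read_length,
            error_rate=self.error_rate,
            seed=params.seed,
        )
        reference = reference_from_sequences(alleles)
        reads = simulate_reads(truth, reference, rng)
        return SimulatedCase(
            sample=params.sample,
            alleles=alleles,
            genotype=genotype,
            pp=PurityPloidy(rho=params.rho, psi=params.psi),
            truth=truth,
            reads=reads,
            label_loss=params.label_loss,
            loss_gene=loss_gene,
        )

    def iter_cases(self) -> Iterator[SimulatedCase]:
        for params in self.cases:
            yield self.materialize(params)

    def write(self, outdir) -> Path:
        """Write the full input bundle: per-case FASTA/FASTQ/TSVs, a cohort
        manifest TSV, truth labels, and a manifest JSON with parameters."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        genotype_rows = []
        purity_rows = []
        for case in self.iter_cases():
            case_dir = outdir / case.sample
            case_dir.mkdir(exist_ok=True)
            io.write_fasta(
                sorted((a.name, a.sequence) for a in case.alleles),
                case_dir / "alleles.fa",
            )
            names, seqs = case.read_sequences()
            io.write_fastq(names, seqs, case_dir / "reads.fq")
            for gene in GENES:
                a1, a2 = case.genotype[gene]
                genotype_rows.append(
                    {"sample": case.sample, "gene": gene, "allele1": a1, "allele2": a2}
                )
            purity_rows.append(
                {"sample": case.sample, "purity": case.pp.rho, "ploidy": case.pp.psi}
            )
            # paths relative to the bundle dir keep the output reproducible
            manifest_rows.append(
                {
                    "sample": case.sample,
                    "reads1": f"{case.sample}/reads.fq",
                    "reads2": "",
                    "database": f"{case.sample}/alleles.fa",
                }
            )
        io.write_tsv(pd.DataFrame(genotype_rows), outdir / "genotypes.tsv")
        io.write_tsv(pd.DataFrame(purity_rows), outdir / "purity_ploidy.tsv")
        io.write_tsv(pd.DataFrame(manifest_rows), outdir / "manifest.tsv")
        io.write_tsv(self.labels(), outdir / "labels.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "n_cases": len(self.cases),
                    "reads_per_gene": self.reads_per_gene,
                    "read_length": self.read_length,
                    "error_rate": self.error_rate,
                    "allele_length": self.allele_length,
                    "n_variant_sites": self.n_variant_sites,
                    "min_spacing": self.min_spacing,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return outdir


def simulate_cohort(
    n_cases: int,
    loss_fraction: float,
    purity_range: tuple[float, float] = DEFAULT_PURITY_RANGE,
    seed: int = 0,
    *,
    reads_per_gene: int = DEFAULT_READS_PER_GENE,
    read_length: int = DEFAULT_READ_LENGTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    allele_length: int = DEFAULT_ALLELE_LENGTH,
    n_variant_sites: int = DEFAULT_N_VARIANT_SITES,
    min_spacing: int = DEFAULT_MIN_SPACING,
    psi: float = DEFAULT_PSI,
    loss_cn_range: tuple[float, float] = LOSS_CN_RANGE,
) -> CohortPlan:
    """Plan a labeled cohort: exactly round(n * loss_fraction) loss cases.

    Loss cases get one random gene with true minor expressed copy number
    drawn uniformly from ``loss_cn_range`` (below the 0.5 calling threshold);
    all other genes, and all genes of non-loss cases, express in balance.
    Purities are uniform on ``purity_range``.
    """
    if not 0 <= loss_fraction <= 1:
        raise ParameterError(f"loss_fraction must be in [0, 1], got {loss_fraction}")
    rng = np.random.default_rng(seed)
    n_loss = int(round(n_cases * loss_fraction))
    loss_flags = np.zeros(n_cases, dtype=bool)
    loss_flags[rng.permutation(n_cases)[:n_loss]] = True
    lo, hi = purity_range
    purities = rng.uniform(lo, hi, size=n_cases)
    loss_genes = rng.integers(0, len(GENES), size=n_cases)
    minor_cns = rng.uniform(loss_cn_range[0], loss_cn_range[1], size=n_cases)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cases) >> np.uint32(1)
    width = len(str(max(n_cases - 1, 1)))
    cases = [
        CaseParams(
            sample=f"sim{idx:0{width}d}",
            label_loss=bool(loss_flags[idx]),
            loss_gene=GENES[loss_genes[idx]] if loss_flags[idx] else None,
            loss_minor_cn=float(minor_cns[idx]) if loss_flags[idx] else None,
            rho=float(purities[idx]),
            psi=psi,
            seed=int(child_seeds[idx]),
        )
        for idx in range(n_cases)
    ]
    return CohortPlan(
        cases=cases,
        reads_per_gene=reads_per_gene,
        read_length=read_length,
        error_rate=error_rate,
        allele_length=allele_length,
        n_variant_sites=n_variant_sites,
        min_spacing=min_spacing,
        seed=seed,
    )
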