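"""Read-to-allele assignment and EM abundance estimation.

Reads are pseudo-mapped to the personalized reference by exact canonical
k-mer compatibility: a read's compatibility set is the intersection of the
allele sets of its k-mers that occur in the index (k-mers absent from the
index are skipped, which tolerates sequencing errors; a read with no indexed
k-mer at all, or an empty intersection, is discarded).  Reads whose
compatibility set spans more than one gene are discarded as cross-gene
ambiguous.  Within a gene, reads accumulate into equivalence classes keyed
by the compatible allele subset, and a multinomial EM distributes shared
classes over alleles to produce estimated per-allele read counts and allele
frequencies (AF).

For a heterozygous gene the minor allele is the one with AF <= 0.5; its AF
feeds the expressed-copy-number model downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _dna, io
from .alleles import AlleleSequence, PersonalizedReference
from .errors import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_K = 31
EM_TOL = 1e-8
EM_MAX_ITER = 1000
MIN_K = 11


@dataclass
class KmerIndex:
    """Sorted canonical k-mer codes with per-k-mer allele bit masks."""

    k: int
    codes: np.ndarray  # (m,) uint64, sorted
    masks: np.ndarray  # (m,) uint32, bit i set iff alleles[i] contains the k-mer
    alleles: tuple[str, ...]
    genes: tuple[str, ...]  # gene of each allele, parallel to `alleles`

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def allele_set(self, mask: int) -> frozenset[str]:
        return frozenset(
            self.alleles[i] for i in range(self.n_alleles) if mask >> i & 1
        )

    def gene_of_mask(self, mask: int):
        """Gene shared by all alleles in the mask, or None if cross-gene."""
        genes = {self.genes[i] for i in range(self.n_alleles) if mask >> i & 1}
        return genes.pop() if len(genes) == 1 else None


def build_index(
    reference: PersonalizedReference | Sequence[AlleleSequence], k: int = DEFAULT_K
) -> KmerIndex:
    """Index every canonical k-mer of every reference allele.

    k must be at least 11 (shorter k-mers match everywhere in random
    sequence) and no longer than the shortest allele.  k-mers containing an
    ambiguous base are never indexed.
    """
    seqs = (
        reference.sequences
        if isinstance(reference, PersonalizedReference)
        else list(reference)
    )
    if not seqs:
        raise ParameterError("reference contains no sequences")
    if not MIN_K <= k <= _dna.MAX_K:
        raise ParameterError(f"k must be in [{MIN_K}, {_dna.MAX_K}], got {k}")
    shortest = min(len(s.sequence) for s in seqs)
    if k > shortest:
        raise ParameterError(
            f"k = {k} exceeds the shortest reference sequence ({shortest} nt)"
        )
    if len(seqs) > 32:
        raise ParameterError("more than 32 reference alleles are not supported")
    names = tuple(s.name for s in seqs)
    genes = tuple(s.gene for s in seqs)
    table: dict[int, int] = {}
    for bit, allele in enumerate(seqs):
        mat = _dna.encode_seq(allele.sequence)[None, :]
        codes, valid = _dna.window_codes(mat, k)
        for code in codes[valid]:
            table[int(code)] = table.get(int(code), 0) | (1 << bit)
    if table:
        order = np.argsort(np.fromiter(table.keys(), dtype=np.uint64))
        codes_arr = np.fromiter(table.keys(), dtype=np.uint64)[order]
        masks_arr = np.fromiter(table.values(), dtype=np.uint32)[order]
    else:
        codes_arr = np.zeros(0, dtype=np.uint64)
        masks_arr = np.zeros(0, dtype=np.uint32)
    return KmerIndex(k=k, codes=codes_arr, masks=masks_arr, alleles=names, genes=genes)


@dataclass
class EquivalenceClassTable:
    """Per-gene read counts keyed by compatible-allele subsets."""

    classes: dict[str, dict[frozenset[str], int]]
    discarded: int = 0
    cross_gene: int = 0  # subset of `discarded`
    too_short: int = 0  # subset of `discarded`
    n_reads: int = 0

    def gene_total(self, gene: str) -> int:
        return sum(self.classes.get(gene, {}).values())

    def total_assigned(self) -> int:
        return sum(self.gene_total(g) for g in self.classes)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"gene": gene, "alleles": ",".join(sorted(subset)), "count": count}
            for gene in sorted(self.classes)
            for subset, count in sorted(
                self.classes[gene].items(), key=lambda kv: sorted(kv[0])
            )
        ]
        rows.append({"gene": "*", "alleles": "*discarded*", "count": self.discarded})
        return pd.DataFrame(rows, columns=["gene", "alleles", "count"])


def _classify_matrix(mat: np.ndarray, index: KmerIndex):
    """Vectorised compatibility masks for a batch of encoded reads.

    Returns (masks, informative) where masks[i] is the AND over the read's
    indexed k-mers (0 if none matched or the intersection is empty) and
    informative[i] is the number of indexed k-mers found in read i.
    """
    codes, valid = _dna.window_codes(mat, index.k)
    n = mat.shape[0]
    if codes.shape[1] == 0 or len(index.codes) == 0:
        return np.zeros(n, dtype=np.uint32), np.zeros(n, dtype=np.int64)
    pos = np.searchsorted(index.codes, codes)
    pos_c = np.minimum(pos, len(index.codes) - 1)
    hit = valid & (index.codes[pos_c] == codes)
    full = np.uint32((1 << index.n_alleles) - 1)
    kmask = np.where(hit, index.masks[pos_c], full)
    inter = np.bitwise_and.reduce(kmask, axis=1)
    n_hits = hit.sum(axis=1)
    return np.where(n_hits > 0, inter, 0).astype(np.uint32), n_hits


def _combine_pairs(m1, h1, m2, h2):
    """Pair class = intersection of the mates' classes; singletons allowed."""
    both = (h1 > 0) & (h2 > 0)
    out = np.where(both, m1 & m2, np.where(h1 > 0, m1, m2))
    return out.astype(np.uint32), h1 + h2


def _as_matrix(reads) -> np.ndarray:
    if isinstance(reads, np.ndarray):
        return np.atleast_2d(reads)
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        return _dna.encode_batch(io.read_fastq_seqs(reads))
    return _dna.encode_batch(list(reads))


def classify_reads(
    reads, index: KmerIndex, reads2=None
) -> EquivalenceClassTable:
    """Assign reads (FASTQ path, sequence iterable, or encoded matrix) to
    equivalence classes.

    With ``reads2`` the inputs are treated as read pairs in file order; each
    mate is classified independently and the pair's class is the intersection
    of the informative mates.  Reads shorter than k carry no k-mer and are
    discarded (with a warning), as are reads with no indexed k-mer, empty
    intersections, and cross-gene ambiguous compatibility sets.
    """
    mat1 = _as_matrix(reads)
    masks, hits = _classify_matrix(mat1, index)
    lengths1 = (mat1 < 4).sum(axis=1)
    short = lengths1 < index.k
    if reads2 is not None:
        mat2 = _as_matrix(reads2)
        if mat2.shape[0] != mat1.shape[0]:
            raise ParameterError("paired FASTQ inputs differ in read count")
        m2, h2 = _classify_matrix(mat2, index)
        masks, hits = _combine_pairs(masks, hits, m2, h2)
        short &= (mat2 < 4).sum(axis=1) < index.k
    n_short = int(short.sum())
    if n_short:
        warnings.warn(
            f"{n_short} read(s) shorter than k = {index.k} were discarded",
            stacklevel=2,
        )
    table: dict[str, dict[frozenset[str], int]] = {}
    discarded = 0
    cross_gene = 0
    uniq, counts = np.unique(masks, return_counts=True)
    for mask, count in zip(uniq.tolist(), counts.tolist()):
        if mask == 0:
            discarded += count
            continue
        gene = index.gene_of_mask(mask)
        if gene is None:
            logger.info("discarding %d cross-gene ambiguous read(s)", count)
            cross_gene += count
            discarded += count
            continue
        subset = index.allele_set(mask)
        table.setdefault(gene, {})[subset] = (
            table.get(gene, {}).get(subset, 0) + count
        )
    return EquivalenceClassTable(
        classes=table,
        discarded=discarded,
        cross_gene=cross_gene,
        too_short=n_short,
        n_reads=int(mat1.shape[0]),
    )


@dataclass
class GeneQuant:
    """EM result for one gene: allele counts, AFs, and the minor allele."""

    gene: str
    alleles: tuple[str, ...]
    est_counts: np.ndarray
    assessable: bool
    n_iter: int = 0
    log_likelihoods: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.est_counts.sum())

    @property
    def afs(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.full(len(self.alleles), np.nan)
        return self.est_counts / total

    @property
    def minor_index(self) -> int:
        # ties (AF exactly 0.5) break to the first allele in sorted order
        return int(np.argmin(self.est_counts))

    @property
    def minor_allele(self) -> str:
        return self.alleles[self.minor_index]

    @property
    def minor_af(self) -> float:
        return float(self.afs[self.minor_index])


def _em_gene(
    alleles: Sequence[str],
    classes: Mapping[frozenset[str], int],
    tol: float,
    max_iter: int,
):
    """Multinomial EM over equivalence classes for one gene.

    Returns (est_counts, n_iter, log-likelihood trace).  The log-likelihood
    is checked to be non-decreasing at every step; a decrease beyond
    round-off indicates a bug and raises.
    """
    r = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}
    subsets = [np.array(sorted(idx[a] for a in s), dtype=int) for s in classes]
    counts = np.array([classes[s] for s in classes], dtype=float)
    total = counts.sum()
    theta = np.full(r, 1.0 / r)
    ll_trace: list[float] = []
    est = np.zeros(r)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        est = np.zeros(r)
        ll = 0.0
        for members, cnt in zip(subsets, counts):
            mass = theta[members].sum()
            ll += cnt * np.log(mass)
            est[members] += cnt * theta[members] / mass
        if ll_trace and ll < ll_trace[-1] - 1e-9 * max(1.0, abs(ll_trace[-1])):
            raise RuntimeError(
                f"EM log-likelihood decreased: {ll_trace[-1]} -> {ll}"
            )
        ll_trace.append(float(ll))
        new_theta = est / total
        if np.max(np.abs(new_theta - theta)) < tol:
            theta = new_theta
            break
        theta = new_theta
    return est, n_iter, ll_trace


def em_quantify(
    table: EquivalenceClassTable,
    reference: PersonalizedReference,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> dict[str, GeneQuant]:
    """Resolve shared equivalence classes into per-allele counts per gene.

    Genes with a single representative (homozygous, or heterozygous with
    identical cDNA) get all their reads on that representative and are not
    assessable; so are genes with zero assigned reads.
    """
    out: dict[str, GeneQuant] = {}
    for gene in reference.genes:
        reps = tuple(s.name for s in reference.representatives(gene))
        classes = table.classes.get(gene, {})
        total = sum(classes.values())
        if total == 0:
            out[gene] = GeneQuant(
                gene=gene,
                alleles=reps,
                est_counts=np.zeros(len(reps)),
                assessable=False,
            )
            continue
        if len(reps) == 1:
            out[gene] = GeneQuant(
                gene=gene,
                alleles=reps,
                est_counts=np.array([float(total)]),
                assessable=False,
            )
            continue
        est, n_iter, ll = _em_gene(reps, classes, tol, max_iter)
        out[gene] = GeneQuant(
            gene=gene,
            alleles=reps,
            est_counts=est,
            assessable=reference.assessable(gene),
            n_iter=n_iter,
            log_likelihoods=ll,
        )
    return out


def quant_to_frame(quants: Mapping[str, GeneQuant], sample: str):
    """Flatten per-gene quantifications into the output TSV layout."""
    import pandas as pd

    rows = []
    for gene in sorted(quants):
        q = quants[gene]
        afs = q.afs
        for i, allele in enumerate(q.alleles):
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "allele": allele,
                    "est_count": float(q.est_counts[i]),
                    "AF": float(afs[i]) if np.isfinite(afs[i]) else np.nan,
                    "minor": bool(i == q.minor_index and len(q.alleles) > 1),
                    "assessable": q.assessable,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "gene", "allele", "est_count", "AF", "minor", "assessable"],
    )
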