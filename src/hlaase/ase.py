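"""Purity/ploidy-adjusted expressed copy number and ASE-loss calling.

A bulk tumor RNA-seq sample mixes tumor cells (purity rho) with normal
cells.  Writing exp_CN_i for the expression of allele i in a tumor cell
relative to a normal cell (where both alleles express at 1), the bulk
allele frequency is the mixture

    AF_i = (rho * exp_CN_i + (1 - rho)) / (rho * (exp_CN_1 + exp_CN_2) + 2 * (1 - rho)).

Normalizing the allelic sum to the tumor ploidy, exp_CN_1 + exp_CN_2 = psi,
and inverting gives the expressed copy number of each allele:

    exp_CN_i = (1 / rho) * (2 * AF_i * (1 + rho * (psi - 2) / 2) - (1 - rho)).

ASE loss is called for a heterozygous gene when the minor allele's
expressed copy number falls strictly below 0.5 (by analogy with DNA-level
LOH callers), and for a case when at least one of HLA-A/B/C shows loss.
Cases with purity below 0.1 are excluded as unreliable.  When no DNA is
available (e.g. microdissected samples) the convention rho = 1, psi = 2
reduces exp_CN_i to 2 * AF_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .errors import ParameterError
from .quantify import GeneQuant

LOSS_THRESHOLD = 0.5
MIN_PURITY = 0.1


@dataclass(frozen=True)
class PurityPloidy:
    """Tumor purity rho in (0, 1] and tumor ploidy psi > 0."""

    rho: float
    psi: float = 2.0

    def __post_init__(self):
        if not 0 < self.rho <= 1:
            raise ParameterError(f"purity rho must be in (0, 1], got {self.rho}")
        if not self.psi > 0:
            raise ParameterError(f"ploidy psi must be > 0, got {self.psi}")


ASSUME_PURE = PurityPloidy(rho=1.0, psi=2.0)


def expressed_copy_number(af, rho, psi):
    """Expressed copy number of an allele from its bulk allele frequency.

    Raw values are returned: the formula can go negative at extreme AF and
    low purity, and the raw value is what the loss caller and ROC scoring
    use.  Clamping at zero is a reporting concern only.  Accepts scalars or
    numpy arrays for ``af``.
    """
    rho = float(rho)
    psi = float(psi)
    if not 0 < rho <= 1:
        raise ParameterError(f"purity rho must be in (0, 1], got {rho}")
    if not psi > 0:
        raise ParameterError(f"ploidy psi must be > 0, got {psi}")
    af = np.asarray(af, dtype=float)
    if np.any((af < 0) | (af > 1)):
        raise ParameterError("allele frequency must be in [0, 1]")
    result = (2.0 * af * (1.0 + rho * (psi - 2.0) / 2.0) - (1.0 - rho)) / rho
    return float(result) if result.ndim == 0 else result


def forward_allele_frequency(exp_cn_1, exp_cn_2, rho):
    """Bulk allele frequency implied by the tumor/normal mixture model.

    Exact inverse of :func:`expressed_copy_number` when
    exp_cn_1 + exp_cn_2 = psi.
    """
    rho = float(rho)
    if not 0 < rho <= 1:
        raise ParameterError(f"purity rho must be in (0, 1], got {rho}")
    denom = rho * (exp_cn_1 + exp_cn_2) + 2.0 * (1.0 - rho)
    if np.any(np.asarray(denom) <= 0):
        raise ParameterError("degenerate mixture: zero total expression")
    result = (rho * np.asarray(exp_cn_1, dtype=float) + (1.0 - rho)) / denom
    return float(result) if np.ndim(result) == 0 else result


@dataclass
class GeneCall:
    """Per-gene ASE-loss call."""

    gene: str
    assessable: bool
    minor_allele: Optional[str] = None
    minor_af: Optional[float] = None
    minor_exp_cn: Optional[float] = None  # raw, may be negative
    major_exp_cn: Optional[float] = None
    loss: Optional[bool] = None  # None when not assessable


def call_gene_loss(
    quant: GeneQuant, pp: PurityPloidy, threshold: float = LOSS_THRESHOLD
) -> GeneCall:
    """Call ASE loss for one gene: loss iff minor exp_CN < threshold (strict).

    Non-assessable genes (homozygous, collapsed identical cDNAs, or zero
    reads) return a not-assessable call and never loss.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be > 0, got {threshold}")
    if not quant.assessable:
        return GeneCall(gene=quant.gene, assessable=False)
    minor_af = quant.minor_af
    minor_cn = expressed_copy_number(minor_af, pp.rho, pp.psi)
    return GeneCall(
        gene=quant.gene,
        assessable=True,
        minor_allele=quant.minor_allele,
        minor_af=minor_af,
        minor_exp_cn=minor_cn,
        major_exp_cn=pp.psi - minor_cn,
        loss=bool(minor_cn < threshold),
    )


@dataclass
class CaseCall:
    """Case-level summary: any-gene loss plus continuous loss scores."""

    sample: str
    purity_pass: bool
    n_assessable: int
    any_loss: Optional[bool]  # None if excluded or no assessable gene
    min_minor_exp_cn: Optional[float]  # raw minimum across assessable genes
    min_minor_af: Optional[float]
    gene_calls: dict


def call_case(
    sample: str,
    gene_calls: Iterable[GeneCall],
    pp: PurityPloidy,
    min_purity: float = MIN_PURITY,
) -> CaseCall:
    """Aggregate gene calls: loss in at least one assessable HLA-I gene.

    Cases with purity below ``min_purity`` are excluded (no loss status);
    cases with zero assessable genes are not assessable.  The per-case
    continuous scores are the minimum raw minor exp_CN and the minimum raw
    minor AF across assessable genes (low = loss-like), for ROC use.
    """
    if not 0 <= min_purity < 1:
        raise ParameterError(f"min_purity must be in [0, 1), got {min_purity}")
    calls = {c.gene: c for c in gene_calls}
    if not calls:
        raise ParameterError(f"sample {sample}: no gene calls provided")
    if pp.rho < min_purity:
        return CaseCall(
            sample=sample,
            purity_pass=False,
            n_assessable=0,
            any_loss=None,
            min_minor_exp_cn=None,
            min_minor_af=None,
            gene_calls=calls,
        )
    assessable = [c for c in calls.values() if c.assessable]
    if not assessable:
        return CaseCall(
            sample=sample,
            purity_pass=True,
            n_assessable=0,
            any_loss=None,
            min_minor_exp_cn=None,
            min_minor_af=None,
            gene_calls=calls,
        )
    return CaseCall(
        sample=sample,
        purity_pass=True,
        n_assessable=len(assessable),
        any_loss=any(c.loss for c in assessable),
        min_minor_exp_cn=min(c.minor_exp_cn for c in assessable),
        min_minor_af=min(c.minor_af for c in assessable),
        gene_calls=calls,
    )


def calls_to_frame(case: CaseCall, pp: PurityPloidy):
    """Per-gene calls TSV layout; exp_CN columns are clamped at 0 for
    reporting while the raw values drive the loss flags and scores."""
    import pandas as pd

    rows = []
    for gene in sorted(case.gene_calls):
        c = case.gene_calls[gene]
        rows.append(
            {
                "sample": case.sample,
                "gene": gene,
                "minor_allele": c.minor_allele if c.assessable else "NA",
                "minor_expCN": max(c.minor_exp_cn, 0.0) if c.assessable else np.nan,
                "major_expCN": max(c.major_exp_cn, 0.0) if c.assessable else np.nan,
                "minor_expCN_raw": c.minor_exp_cn if c.assessable else np.nan,
                "minor_AF": c.minor_af if c.assessable else np.nan,
                "loss": bool(c.loss) if c.assessable else False,
                "assessable": c.assessable,
                "purity_pass": case.purity_pass,
            }
        )
    return pd.DataFrame(rows)


def case_summary_row(case: CaseCall, pp: PurityPloidy) -> dict:
    losses = {
        g: (c.loss if c.assessable else False) for g, c in case.gene_calls.items()
    }
    return {
        "sample": case.sample,
        "purity": pp.rho,
        "ploidy": pp.psi,
        "purity_pass": case.purity_pass,
        "n_assessable": case.n_assessable,
        "any_loss": case.any_loss if case.any_loss is not None else np.nan,
        "min_minor_expCN": (
            case.min_minor_exp_cn if case.min_minor_exp_cn is not None else np.nan
        ),
        "min_minor_AF": (
            case.min_minor_af if case.min_minor_af is not None else np.nan
        ),
        **{f"loss_{g}": losses.get(g, False) for g in ("A", "B", "C")},
    }


def read_purity_ploidy_tsv(path, sample: str | None = None) -> PurityPloidy:
    """Read purity/ploidy for one sample from a TSV with columns
    sample, purity, ploidy."""
    from . import io
    from .errors import FormatError

    df = io.read_tsv(path)
    required = {"sample", "purity", "ploidy"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: purity TSV must have columns {sorted(required)}")
    if sample is not None:
        df = df[df["sample"] == sample]
        if df.empty:
            raise FormatError(f"{path}: no purity row for sample {sample!r}")
    row = df.iloc[0]
    return PurityPloidy(rho=float(row["purity"]), psi=float(row["ploidy"]))
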