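"""End-to-end orchestration: reference -> quantify -> call -> evaluate.

Two entry points: :func:`run_sample` for a single file-based sample and
:func:`run_cohort` for a manifest of samples, plus an in-memory fast path
(:func:`quantify_case`, :func:`evaluate_cohort_plan`) used by the simulator
round-trip validation so large cohorts never touch the filesystem.

All tables are sorted by (sample, gene) and floats written with six
significant digits so that identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, io
from .alleles import (
    load_allele_database,
    read_genotype_tsv,
    resolve_genotype,
    write_collapse_map,
    write_reference_fasta,
)
from .ase import (
    ASSUME_PURE,
    LOSS_THRESHOLD,
    MIN_PURITY,
    CaseCall,
    PurityPloidy,
    call_case,
    call_gene_loss,
    calls_to_frame,
    case_summary_row,
    read_purity_ploidy_tsv,
)
from .errors import HlaaseError, ParameterError, PipelineError
from .quantify import DEFAULT_K, build_index, classify_reads, em_quantify, quant_to_frame
from .simulate import CohortPlan, SimulatedCase
from .stats import evaluate_calls

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    database: Optional[Path] = None
    genotype: Optional[Path] = None
    reads1: Optional[Path] = None
    reads2: Optional[Path] = None
    purity_ploidy: Optional[Path] = None
    out_dir: Path = Path("hlaase_out")
    sample: Optional[str] = None
    k: int = DEFAULT_K
    threshold: float = LOSS_THRESHOLD
    min_purity: float = MIN_PURITY
    assume_pure: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.threshold <= 0:
            raise ParameterError("threshold must be > 0")
        if not 0 <= self.min_purity < 1:
            raise ParameterError("min_purity must be in [0, 1)")

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        paths = {"database", "genotype", "reads1", "reads2", "purity_ploidy", "out_dir"}
        data = {
            k: (Path(v) if k in paths and v is not None else v)
            for k, v in data.items()
        }
        return cls(**data)


def _stage(name: str):
    """Decorator tagging exceptions with the failing pipeline stage."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except (HlaaseError, OSError, ValueError) as exc:
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


@_stage("reference")
def _build_reference(config: RunConfig):
    db = load_allele_database(config.database)
    genotype = read_genotype_tsv(config.genotype, sample=config.sample)
    return resolve_genotype(genotype, db)


@_stage("quantify")
def _quantify(config: RunConfig, reference):
    index = build_index(reference, k=config.k)
    table = classify_reads(config.reads1, index, reads2=config.reads2)
    quants = em_quantify(table, reference)
    return table, quants


@_stage("call")
def _call(config: RunConfig, quants) -> tuple[CaseCall, PurityPloidy]:
    if config.assume_pure:
        pp = ASSUME_PURE
    else:
        pp = read_purity_ploidy_tsv(config.purity_ploidy, sample=config.sample)
    gene_calls = [
        call_gene_loss(quants[g], pp, threshold=config.threshold)
        for g in sorted(quants)
    ]
    case = call_case(
        config.sample or "sample",
        gene_calls,
        pp,
        min_purity=config.min_purity,
    )
    return case, pp


def run_sample(config: RunConfig) -> dict:
    """Run reference -> quantify -> call for one sample, writing every
    intermediate TSV under ``out_dir``.  Partially written outputs are
    removed if any stage fails."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample = config.sample or "sample"
    try:
        reference = _build_reference(config)
        write_reference_fasta(reference, out / "reference.fa")
        write_collapse_map(reference, out / "collapse_map.tsv")
        table, quants = _quantify(config, reference)
        io.write_tsv(table.to_frame(), out / "eqclasses.tsv")
        quant_df = quant_to_frame(quants, sample).sort_values(
            ["sample", "gene", "allele"], kind="stable"
        )
        io.write_tsv(quant_df, out / "quant.tsv")
        case, pp = _call(config, quants)
        calls_df = calls_to_frame(case, pp).sort_values(
            ["sample", "gene"], kind="stable"
        )
        io.write_tsv(calls_df, out / "calls.tsv")
        summary = pd.DataFrame([case_summary_row(case, pp)])
        io.write_tsv(summary, out / "case_summary.tsv")
        _write_run_log(out, config)
    except PipelineError:
        for name in (
            "reference.fa",
            "collapse_map.tsv",
            "eqclasses.tsv",
            "quant.tsv",
            "calls.tsv",
            "case_summary.tsv",
        ):
            (out / name).unlink(missing_ok=True)
        raise
    return {"case": case, "quants": quants, "out_dir": out}


def _write_run_log(out: Path, config: RunConfig) -> None:
    entry = {
        "hlaase_version": __version__,
        "k": config.k,
        "threshold": config.threshold,
        "min_purity": config.min_purity,
        "assume_pure": config.assume_pure,
        "seed": config.seed,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(entry, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_cohort(
    config: RunConfig,
    manifest_path,
    labels_path=None,
) -> dict:
    """Run every sample in a manifest TSV and aggregate.

    Manifest columns: ``sample``, ``reads1`` and optionally ``reads2`` plus a
    per-sample ``database`` column overriding the shared one.  Per-sample
    failures are collected (the failing sample is marked in the summary) and
    do not stop the cohort.
    """
    manifest = io.read_tsv(manifest_path, dtype=str).fillna("")
    if "sample" not in manifest.columns or "reads1" not in manifest.columns:
        raise PipelineError("cohort", "manifest needs columns sample, reads1")
    base = Path(manifest_path).parent  # relative manifest paths resolve here
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries = []
    failures = {}
    for _, row in manifest.iterrows():
        sample = row["sample"]
        def _resolve(value):
            path = Path(value)
            return path if path.is_absolute() else base / path

        sample_config = replace(
            config,
            sample=sample,
            reads1=_resolve(row["reads1"]),
            reads2=_resolve(row["reads2"]) if row.get("reads2") else None,
            database=_resolve(row["database"])
            if row.get("database")
            else config.database,
            out_dir=out / sample,
        )
        try:
            result = run_sample(sample_config)
        except PipelineError as exc:
            logger.error("sample %s failed: %s", sample, exc)
            failures[sample] = str(exc)
            shutil.rmtree(out / sample, ignore_errors=True)
            continue
        case = result["case"]
        pp = (
            ASSUME_PURE
            if config.assume_pure
            else read_purity_ploidy_tsv(config.purity_ploidy, sample=sample)
        )
        summaries.append(case_summary_row(case, pp))
    summary_df = pd.DataFrame(summaries)
    if not summary_df.empty:
        summary_df = summary_df.sort_values("sample", kind="stable")
    if failures:
        failed = pd.DataFrame(
            [{"sample": s, "error": e} for s, e in sorted(failures.items())]
        )
        io.write_tsv(failed, out / "failed_samples.tsv")
    io.write_tsv(summary_df, out / "cohort_summary.tsv")
    metrics = None
    if labels_path is not None and not summary_df.empty:
        labels = io.read_tsv(labels_path)
        metrics = evaluate_calls(summary_df, labels)
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return {"summary": summary_df, "failures": failures, "metrics": metrics}


# ---------------------------------------------------------------------------
# In-memory fast path over simulated cases


def quantify_case(
    case: SimulatedCase,
    k: int = DEFAULT_K,
    threshold: float = LOSS_THRESHOLD,
    min_purity: float = MIN_PURITY,
) -> CaseCall:
    """Classify + EM + call one simulated case without touching disk."""
    reference = case.reference
    index = build_index(reference, k=k)
    table = classify_reads(case.read_batch(), index)
    quants = em_quantify(table, reference)
    gene_calls = [
        call_gene_loss(quants[g], case.pp, threshold=threshold)
        for g in sorted(quants)
    ]
    return call_case(case.sample, gene_calls, case.pp, min_purity=min_purity)


def evaluate_cohort_plan(
    plan: CohortPlan,
    k: int = DEFAULT_K,
    threshold: float = LOSS_THRESHOLD,
    min_purity: float = MIN_PURITY,
) -> dict:
    """Run the full pipeline over a simulated cohort plan and score the
    calls against the generator's labels."""
    rows = []
    for case in plan.iter_cases():
        call = quantify_case(case, k=k, threshold=threshold, min_purity=min_purity)
        rows.append(case_summary_row(call, case.pp))
    summary = pd.DataFrame(rows)
    labels = plan.labels()[["sample", "label"]]
    metrics = evaluate_calls(summary, labels)
    return {"summary": summary, "metrics": metrics}
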