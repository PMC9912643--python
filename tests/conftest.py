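import numpy as np
import pytest

from hlaase.alleles import AlleleSequence, Genotype, reference_from_sequences


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


DB_FASTA = f"""\
>A*01:01:01:01 some description
{random_sequence(60, 11)}
>A*02:01:01:01
{random_sequence(60, 12).lower()}
>B*07:02
{random_sequence(60, 13)}
>B*08:01
{random_sequence(60, 14)}
>B*15:01:01
{random_sequence(60, 15)}
>B*15:01:02
{random_sequence(60, 16)}
>C*07:01
{random_sequence(60, 17)}
>C*07:02
{random_sequence(60, 17)}
"""


@pytest.fixture
def db_fasta(tmp_path):
    """Eight-record allele database; C*07:01 and C*07:02 share one cDNA."""
    path = tmp_path / "db.fa"
    path.write_text(DB_FASTA)
    return path


@pytest.fixture
def genotype_het():
    return Genotype(
        calls={
            "A": ("A*01:01:01:01", "A*02:01:01:01"),
            "B": ("B*07:02", "B*08:01"),
            "C": ("C*07:01", "C*07:02"),
        }
    )


@pytest.fixture
def two_allele_reference():
    """A single gene-A pair differing at one central substitution."""
    seq1 = random_sequence(200, 21)
    pos = 100
    base = seq1[pos]
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[base]
    seq2 = seq1[:pos] + alt + seq1[pos + 1 :]
    a1 = AlleleSequence(name="A*01:01", gene="A", sequence=seq1)
    a2 = AlleleSequence(name="A*02:01", gene="A", sequence=seq2)
    return reference_from_sequences([a1, a2]), pos
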