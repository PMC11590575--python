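import numpy as np
import pytest

from exorcise import (
    Exon,
    ExonSet,
    GenomeIndex,
    GuideLibrary,
    GuideRecord,
)

SPACER = "ACGTACGTACGTACGTACGT"  # 20-mer used across fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_genome():
    # spacer+AGG at 0 on contig a; reverse-complement occurrence on contig b
    return GenomeIndex(
        {
            "a": SPACER + "AGG" + "TTTTT",
            "b": "CCT" + "ACGTACGTACGTACGTACGT"[::-1].translate(
                str.maketrans("ACGT", "TGCA")
            ) + "AAAAA",
        }
    )


@pytest.fixture
def toy_exome():
    return ExonSet(
        [
            Exon("a", 10, 50, "GENEA", "protein_coding"),
            Exon("b", 0, 12, "GENEB", "protein_coding"),
        ]
    )


@pytest.fixture
def toy_library():
    return GuideLibrary(
        [
            GuideRecord("g1", SPACER, "GENEA"),
            GuideRecord("g2", "TTTTTTTTTTTTTTTTTTTT", "GENEX"),
            GuideRecord("g3", "GGGGGGGGGGGGGGGGGGGG", "non-targeting control"),
        ]
    )


def random_genome(rng, n_contigs=None, max_len=50_000):
    """A random A/C/G/T/N genome for oracle comparisons."""
    if n_contigs is None:
        n_contigs = int(rng.integers(1, 6))
    bases = np.array(list("ACGTN"))
    contigs = {}
    for i in range(n_contigs):
        n = int(rng.integers(200, max_len // n_contigs + 201))
        probs = [0.2425, 0.2425, 0.2425, 0.2425, 0.03]
        contigs[f"c{i}"] = "".join(bases[rng.choice(5, n, p=probs)])
    return GenomeIndex(contigs)


def naive_find(probe_seq, genome):
    """Brute-force sliding-window matcher; the oracle for the scanner.

    Probe N matches {A,C,G,T}; genome N matches nothing.
    """
    from exorcise import Alignment, revcomp

    def matches(window, pattern):
        return all(
            (p == g) if p != "N" else (g in "ACGT") for p, g in zip(pattern, window)
        )

    L = len(probe_seq)
    rc = revcomp(probe_seq)
    hits = []
    for contig, seq in genome.items():
        for i in range(len(seq) - L + 1):
            w = seq[i : i + L]
            if matches(w, probe_seq):
                hits.append(Alignment(contig, i, i + L, "+"))
            if matches(w, rc):
                hits.append(Alignment(contig, i, i + L, "-"))
    hits.sort(key=lambda a: (a.contig, a.match_start, a.strand))
    return hits
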