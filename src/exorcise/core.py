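"""Exome-guided re-annotation of CRISPR guides.

The algorithm: each spacer is appended with the spCas9 PAM "NGG" at its 3'
end, the probe is matched at perfect identity against both strands of the
genome, the Cas9 blunt cut is placed between the 3rd and 4th nucleotide 5'
of the PAM as a zero-width coordinate, and the guide inherits the gene
symbol of every exon whose interior contains one of its cuts.  Guides with
no overlapping exon are re-annotated as non-targeting.

Matching semantics: N in the probe (the PAM wildcard) matches any of
{A,C,G,T}; N in the genome is unknown sequence and matches nothing.  The
search is exact, full-length and ungapped — with a perfect-identity
requirement and a fixed cut-interval rule, only contiguous perfect matches
of spacer+PAM are actionable, so an exact scanner replaces a seeded
aligner without loss.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .reference_io import (
    BIOTYPE_RANK,
    Exon,
    ExonSet,
    GenomeIndex,
    GuideLibrary,
    GuideRecord,
)

NON_TARGETING = "non-targeting"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Probe:
    """A spacer with the PAM appended at the 3' end."""

    spacer: str
    pam: str = "NGG"

    def __post_init__(self) -> None:
        if len(self.spacer) < 17:
            raise ValueError(f"spacer too short ({len(self.spacer)} < 17 nt)")
        bad = set(self.spacer) - set("ACGT")
        if bad:
            raise ValueError(f"spacer contains invalid characters {sorted(bad)}")
        if not re.fullmatch(r"[ACGTN]{3}", self.pam):
            raise ValueError(f"PAM must match [ACGTN]{{3}}, got {self.pam!r}")

    @property
    def sequence(self) -> str:
        return self.spacer + self.pam

    def __len__(self) -> int:
        return len(self.spacer) + len(self.pam)


def append_pam(spacer: str, pam: str = "NGG") -> Probe:
    """Append the Cas9 PAM to a spacer, validating the alphabet."""
    return Probe(spacer.upper(), pam.upper())


@dataclass(frozen=True, order=True)
class Alignment:
    """A perfect full-length match of spacer+PAM, in plus-strand coordinates."""

    contig: str
    match_start: int
    match_end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class CutSite:
    """Zero-width Cas9 cut coordinate between the 3rd and 4th nt 5' of the PAM."""

    contig: str
    coord: int
    strand: str
    alignment: Alignment


def _pattern(seq: str) -> re.Pattern:
    """Overlap-aware regex for a probe; probe N matches ACGT, genome N nothing."""
    body = "".join(c if c in "ACGT" else "[ACGT]" for c in seq)
    return re.compile(f"(?={body})")


def find_alignments(probe: Probe, genome: GenomeIndex) -> list[Alignment]:
    """All perfect-identity matches of the probe on either strand.

    Results are sorted by (contig, match_start, strand); overlapping and
    palindromic matches are all reported.
    """
    L = len(probe)
    fwd = _pattern(probe.sequence)
    rev = _pattern(revcomp(probe.sequence))
    hits: list[Alignment] = []
    for contig, seq in genome.items():
        for m in fwd.finditer(seq):
            hits.append(Alignment(contig, m.start(), m.start() + L, "+"))
        for m in rev.finditer(seq):
            hits.append(Alignment(contig, m.start(), m.start() + L, "-"))
    hits.sort(key=lambda a: (a.contig, a.match_start, a.strand))
    return hits


def cut_coordinate(a: Alignment, spacer_length: int, pam_length: int = 3) -> CutSite:
    """Place the Cas9 cut for an alignment.

    On the plus strand the PAM occupies the last ``pam_length`` bases of the
    match, so the cut falls at ``match_start + spacer_length - 3``.  On the
    minus strand the PAM complement occupies the first ``pam_length``
    plus-strand bases, mirroring the cut to ``match_start + pam_length + 3``.
    """
    if a.strand == "+":
        coord = a.match_start + spacer_length - 3
    else:
        coord = a.match_start + pam_length + 3
    return CutSite(a.contig, coord, a.strand, a)


@dataclass
class GuideAnnotation:
    """A guide's alignments, cut sites and re-annotated gene set."""

    guide_id: str
    alignments: list[Alignment] = field(default_factory=list)
    cut_sites: list[CutSite] = field(default_factory=list)
    genes: set[tuple[str, str]] = field(default_factory=set)  # (symbol, biotype)

    @property
    def is_non_targeting(self) -> bool:
        return not self.genes

    @property
    def symbols(self) -> set[str]:
        return {sym for sym, _ in self.genes}

    @property
    def n_unique_genes(self) -> int:
        return len(self.symbols)

    @property
    def n_alignments(self) -> int:
        return len(self.alignments)

    @property
    def reannotation(self) -> str:
        if self.is_non_targeting:
            return NON_TARGETING
        return ";".join(sorted(self.symbols))


def annotate_guide(
    guide_id: str,
    alignments: Sequence[Alignment],
    cut_sites: Sequence[CutSite],
    exome: ExonSet,
) -> GuideAnnotation:
    """Annotate one guide from its cut sites against an exome.

    An exon is hit only when its strict interior contains the cut
    (exon.start < coord < exon.end): a cut flush against a boundary is a
    non-overlap.  Exon strand is not consulted — a double-strand break
    disrupts an exon regardless of orientation.
    """
    genes: set[tuple[str, str]] = set()
    for cut in cut_sites:
        for ex in exome.overlapping(cut.contig, cut.coord):
            genes.add((ex.gene, ex.biotype))
    return GuideAnnotation(guide_id, list(alignments), list(cut_sites), genes)


# ---------------------------------------------------------------------------
# Batched genome scan

def _pam_positions(seq: str, pam: str) -> list[int]:
    body = "".join(c if c in "ACGT" else "[ACGT]" for c in pam)
    return [m.start() for m in re.finditer(f"(?={body})", seq)]


def scan_genome(
    spacers: Iterable[str], genome: GenomeIndex, pam: str = "NGG"
) -> dict[str, list[Alignment]]:
    """Find all perfect spacer+PAM matches for many spacers in one pass.

    The genome is scanned once per contig: candidate PAM sites are located
    with a regex, and the window 5' of each site (or 3' of the reverse
    complement site) is looked up in a spacer hash, one hash per spacer
    length.  Equivalent to per-probe ``find_alignments`` but linear in
    genome size rather than in guides x genome.
    """
    by_len: dict[int, set[str]] = {}
    for sp in spacers:
        by_len.setdefault(len(sp), set()).add(sp)
    hits: dict[str, list[Alignment]] = {sp: [] for s in by_len.values() for sp in s}
    pam = pam.upper()
    p = len(pam)
    rc_pam = revcomp(pam)
    for contig, seq in genome.items():
        n = len(seq)
        fwd_sites = _pam_positions(seq, pam)
        rev_sites = _pam_positions(seq, rc_pam)
        for L, spset in by_len.items():
            for j in fwd_sites:
                i = j - L
                if i >= 0:
                    window = seq[i:j]
                    if window in spset:
                        hits[window].append(Alignment(contig, i, j + p, "+"))
            for j in rev_sites:
                end = j + p + L
                if end <= n:
                    candidate = revcomp(seq[j + p : end])
                    if candidate in spset:
                        hits[candidate].append(Alignment(contig, j, end, "-"))
    for sp in hits:
        hits[sp].sort(key=lambda a: (a.contig, a.match_start, a.strand))
    return hits


def exorcise_library(
    lib: GuideLibrary,
    genome: GenomeIndex,
    exome: ExonSet,
    pam: str = "NGG",
) -> list[GuideAnnotation]:
    """Re-annotate a whole library: one GuideAnnotation per guide, in order."""
    pam = pam.upper()
    aln_by_spacer = scan_genome({g.spacer for g in lib}, genome, pam)
    annos: list[GuideAnnotation] = []
    for g in lib:
        alignments = aln_by_spacer[g.spacer]
        cuts = [cut_coordinate(a, len(g.spacer), len(pam)) for a in alignments]
        annos.append(annotate_guide(g.guide_id, alignments, cuts, exome))
    return annos


# ---------------------------------------------------------------------------
# Gene-level mapping

@dataclass
class GeneMappingEntry:
    original_annotation: str
    accepted: str
    candidates: Counter
    guide_ids: list[str]


@dataclass
class GeneMapping:
    """Per original annotation: the accepted re-annotated symbol and evidence.

    Original annotations with no candidate symbols get no entry.
    """

    entries: dict[str, GeneMappingEntry]

    def accepted_for(self, original: str) -> str | None:
        e = self.entries.get(original)
        return e.accepted if e else None

    def relabelled(self, lib: GuideLibrary) -> list[str]:
        """The accepted symbol for every guide (original kept when unmapped)."""
        return [
            self.accepted_for(g.original_annotation) or g.original_annotation
            for g in lib
        ]


def _accept_candidate(
    original: str, candidates: Counter, biotype_rank: Mapping[str, int]
) -> str:
    top = max(candidates.values())
    tied = [s for s, c in candidates.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    # tie-break hierarchy: same as original > protein-coding > ncRNA >
    # pseudogene > anything else; residual ties broken lexicographically.
    def key(sym: str) -> tuple:
        return (sym != original, biotype_rank.get(sym, len(BIOTYPE_RANK)), sym)

    return min(tied, key=key)


def gene_level_mapping(
    lib: GuideLibrary, annos: Sequence[GuideAnnotation]
) -> GeneMapping:
    """Map each original library annotation onto an accepted re-annotation.

    Candidates are the multiset of re-annotated symbols across all guides
    sharing the original annotation; the most frequent wins, ties fall
    through the biotype hierarchy.  Deterministic under guide reordering.
    """
    if len(lib) != len(annos):
        raise ValueError("library and annotations must be aligned")
    groups: dict[str, list[tuple[GuideRecord, GuideAnnotation]]] = {}
    for g, a in zip(lib, annos):
        groups.setdefault(g.original_annotation, []).append((g, a))
    entries: dict[str, GeneMappingEntry] = {}
    for original, members in groups.items():
        candidates: Counter = Counter()
        best_rank: dict[str, int] = {}
        guide_ids = sorted(g.guide_id for g, _ in members)
        for _, anno in members:
            for sym in anno.symbols:  # each guide votes once per symbol
                candidates[sym] += 1
            for sym, biotype in anno.genes:
                r = BIOTYPE_RANK[biotype]
                if r < best_rank.get(sym, len(BIOTYPE_RANK)):
                    best_rank[sym] = r
        if not candidates:
            continue
        accepted = _accept_candidate(original, candidates, best_rank)
        entries[original] = GeneMappingEntry(original, accepted, candidates, guide_ids)
    return GeneMapping(entries)
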