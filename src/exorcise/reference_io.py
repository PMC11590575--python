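"""Readers and writers for the formats the toolkit touches.

Genomes are plain FASTA, exomes are BED4/BED6+1 intervals (column 7 holds
an optional biotype), guide libraries and TPM tables are delimited text
with a header.  All coordinates are 0-based half-open throughout; BED is
already 0-based half-open so no shift is applied on read.
"""

from __future__ import annotations

import logging
import re
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger("exorcise")

VALID_BASES = frozenset("ACGTN")
#: ordered by preference in the gene-mapping tie-break hierarchy
BIOTYPES = ("protein_coding", "ncRNA", "pseudogene", "other", "unknown")
BIOTYPE_RANK = {b: i for i, b in enumerate(BIOTYPES)}

#: case-insensitive synonyms mapped onto the 5-value biotype vocabulary
DEFAULT_BIOTYPE_SYNONYMS = {
    "protein_coding": "protein_coding",
    "coding": "protein_coding",
    "mrna": "protein_coding",
    "ncrna": "ncRNA",
    "lncrna": "ncRNA",
    "lincrna": "ncRNA",
    "mirna": "ncRNA",
    "snorna": "ncRNA",
    "snrna": "ncRNA",
    "rrna": "ncRNA",
    "trna": "ncRNA",
    "non_coding": "ncRNA",
    "noncoding": "ncRNA",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "unknown": "unknown",
}


def normalise_biotype(raw: str | None, synonyms: Mapping[str, str] | None = None) -> str:
    """Map a free-text biotype onto the 5-value vocabulary.

    Matching is case-insensitive via a configurable synonym table; anything
    unrecognised becomes ``other`` and an absent value becomes ``unknown``.
    """
    if raw is None or raw == "" or (isinstance(raw, float) and pd.isna(raw)):
        return "unknown"
    table = DEFAULT_BIOTYPE_SYNONYMS if synonyms is None else synonyms
    return table.get(str(raw).strip().lower(), "other")


@dataclass
class GenomeIndex:
    """Named contigs over the alphabet {A,C,G,T,N}."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} contains invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.contigs)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def items(self):
        return self.contigs.items()


@dataclass(frozen=True)
class Exon:
    contig: str
    start: int
    end: int
    gene: str
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid exon interval [{self.start}, {self.end}) for {self.gene}"
            )
        if self.biotype not in BIOTYPE_RANK:
            raise ValueError(f"unknown biotype {self.biotype!r}")


class ExonSet:
    """Exon intervals on 0-based half-open coordinates, indexed for point queries.

    Queries against contigs absent from the set simply return nothing.
    """

    def __init__(self, exons: Iterable[Exon]):
        self.exons: list[Exon] = list(exons)
        self._trees: dict[str, IntervalTree] = {}
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        by_contig: dict[str, list[Exon]] = {}
        for ex in self.exons:
            by_contig.setdefault(ex.contig, []).append(ex)
        for contig, exs in by_contig.items():
            tree = IntervalTree()
            for ex in exs:
                tree.addi(ex.start, ex.end, ex)
            self._trees[contig] = tree
            self._starts[contig] = sorted(e.start for e in exs)
            self._ends[contig] = sorted(e.end for e in exs)

    def __len__(self) -> int:
        return len(self.exons)

    def __iter__(self):
        return iter(self.exons)

    def genes(self) -> set[str]:
        return {e.gene for e in self.exons}

    def overlapping(self, contig: str, coord: int) -> list[Exon]:
        """Exons whose strict interior contains the zero-width point ``coord``.

        A cut flush against an exon boundary (coord == start or coord == end)
        does not overlap.
        """
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(coord) if iv.begin < coord]

    def nearest_distance(self, contig: str, coord: int) -> int | None:
        """Linear distance in nucleotides from ``coord`` to the nearest exon.

        0 when the point is interior to or flush against an exon; None when
        the contig carries no exons.
        """
        starts = self._starts.get(contig)
        if starts is None:
            return None
        ends = self._ends[contig]
        if self.overlapping(contig, coord):
            return 0
        best: int | None = None
        i = bisect_left(starts, coord)
        if i < len(starts):
            best = starts[i] - coord
        j = bisect_right(ends, coord)
        if j > 0:
            d = coord - ends[j - 1]
            best = d if best is None else min(best, d)
        return best


@dataclass(frozen=True)
class GuideRecord:
    guide_id: str
    spacer: str
    original_annotation: str
    score: float | None = None


class GuideLibrary:
    """A list of guides with unique ids; duplicate spacers are permitted."""

    def __init__(self, guides: Iterable[GuideRecord]):
        self.guides: list[GuideRecord] = list(guides)
        seen: set[str] = set()
        for g in self.guides:
            if g.guide_id in seen:
                raise ValueError(f"duplicate guide_id {g.guide_id!r}")
            seen.add(g.guide_id)
            bad = set(g.spacer) - set("ACGT")
            if bad:
                raise ValueError(
                    f"guide {g.guide_id!r}: spacer contains invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.guides)

    def __iter__(self):
        return iter(self.guides)

    def __getitem__(self, i: int) -> GuideRecord:
        return self.guides[i]


# ---------------------------------------------------------------------------
# FASTA

_AMBIGUITY = re.compile(r"[RYSWKMBDHV]")


def read_fasta(path: str | Path) -> GenomeIndex:
    """Read a genome FASTA into memory.

    Sequences are uppercased; IUPAC ambiguity codes other than N are
    converted to N with a logged warning.  Empty files and duplicate record
    names are hard errors.
    """
    contigs: dict[str, str] = {}
    n_ambiguous = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        seq, n = _AMBIGUITY.subn("N", seq)
        n_ambiguous += n
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    if n_ambiguous:
        log.warning(
            "%d IUPAC ambiguity bases converted to N while reading %s", n_ambiguous, path
        )
    return GenomeIndex(contigs)


def write_fasta(genome: GenomeIndex, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED exomes


def read_exome_bed(
    path: str | Path, biotype_synonyms: Mapping[str, str] | None = None
) -> ExonSet:
    """Read a BED4 / BED6+1 exome; column 7, when present, is the biotype."""
    exons: list[Exon] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, gene = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start >= end or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            biotype = normalise_biotype(
                fields[6] if len(fields) >= 7 else None, biotype_synonyms
            )
            exons.append(Exon(chrom, start, end, gene, biotype))
    return ExonSet(exons)


def write_exome_bed(exome: ExonSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ex in exome:
            fh.write(f"{ex.contig}\t{ex.start}\t{ex.end}\t{ex.gene}\t0\t+\t{ex.biotype}\n")


# ---------------------------------------------------------------------------
# Guide libraries and annotation tables

DEFAULT_COLUMN_MAP = {
    "guide_id": "guide_id",
    "spacer": "spacer",
    "original_annotation": "original_annotation",
    "score": "score",
}


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_library(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> GuideLibrary:
    """Read a delimited guide table (CSV or TSV, sniffed from the header).

    ``column_map`` maps the canonical field names (guide_id, spacer,
    original_annotation, score) onto the file's column names.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", dtype=str)
    for field_name in ("guide_id", "spacer", "original_annotation"):
        if cmap[field_name] not in df.columns:
            raise ValueError(
                f"{path}: missing mandatory column {cmap[field_name]!r} (for {field_name})"
            )
    has_score = cmap["score"] in df.columns
    guides = []
    for _, row in df.iterrows():
        score = float(row[cmap["score"]]) if has_score and pd.notna(row[cmap["score"]]) else None
        guides.append(
            GuideRecord(
                guide_id=str(row[cmap["guide_id"]]),
                spacer=str(row[cmap["spacer"]]).upper(),
                original_annotation=str(row[cmap["original_annotation"]]),
                score=score,
            )
        )
    return GuideLibrary(guides)


def write_library(lib: GuideLibrary, path: str | Path, header: str | None = None) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        cols = ["guide_id", "spacer", "original_annotation"]
        has_score = any(g.score is not None for g in lib)
        if has_score:
            cols.append("score")
        fh.write(sep.join(cols) + "\n")
        for g in lib:
            row = [g.guide_id, g.spacer, g.original_annotation]
            if has_score:
                row.append("" if g.score is None else repr(g.score))
            fh.write(sep.join(row) + "\n")


def write_guide_annotations(rows: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write the guide-level re-annotation table (TSV)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        rows.to_csv(fh, sep="\t", index=False)


def write_gene_mapping(rows: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write the gene-level mapping table (TSV)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        rows.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TPM tables and exome inference


def read_tpm(path: str | Path) -> pd.DataFrame:
    """Read a gene/transcript x sample TPM table (first column = identifier)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", index_col=0)
    values = df.to_numpy()
    if (values < 0).any() or not pd.notna(values).all():
        raise ValueError(f"{path}: TPM values must be non-negative and finite")
    return df


def exome_from_tpm(
    tpm: Mapping[str, float] | pd.Series,
    catalog: ExonSet,
    threshold: float = 1.0,
) -> ExonSet:
    """Infer a cell-line exome from transcript abundance.

    Keeps exactly the exons of ``catalog`` whose gene or transcript is
    expressed at ``threshold`` TPM or higher (boundary inclusive).  An empty
    intersection between the TPM identifiers and the catalog gene symbols
    yields an empty ExonSet with a warning.
    """
    if isinstance(tpm, pd.Series):
        tpm = tpm.to_dict()
    if not set(tpm) & catalog.genes():
        warnings.warn("no TPM identifiers match the exon catalog; exome is empty")
        return ExonSet([])
    kept = [ex for ex in catalog if tpm.get(ex.gene, float("-inf")) >= threshold]
    return ExonSet(kept)
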