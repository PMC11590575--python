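"""Library-health audit: mis-annotation categories, distances, design filter.

Category definitions: an off-target guide carries more than one unique gene
symbol after re-annotation — same-locus when a single alignment hits
overlapping features, other-locus when multiple alignments are responsible.
A missed-target guide has a non-control original annotation but re-annotates
as non-targeting.  Non-targeting and intergenic control guides are
recognised by configurable regexes on the original annotation and excluded
from summary denominators.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import GuideAnnotation
from .reference_io import ExonSet, GuideLibrary, GuideRecord

log = logging.getLogger("exorcise")

CATEGORIES = (
    "on_target",
    "off_target_same_locus",
    "off_target_other_locus",
    "missed_target",
    "non_targeting_control",
    "intergenic_control",
)
CONTROL_CATEGORIES = ("non_targeting_control", "intergenic_control")

DEFAULT_NON_TARGETING_PATTERNS = (r"non.?target", r"^control")
DEFAULT_INTERGENIC_PATTERNS = (r"intergenic",)


@dataclass(frozen=True)
class GuideClassification:
    guide_id: str
    category: str
    n_unique_genes: int
    n_alignments: int

    @property
    def is_control(self) -> bool:
        return self.category in CONTROL_CATEGORIES


def classify_guides(
    lib: GuideLibrary,
    annos: Sequence[GuideAnnotation],
    non_targeting_patterns: Iterable[str] = DEFAULT_NON_TARGETING_PATTERNS,
    intergenic_patterns: Iterable[str] = DEFAULT_INTERGENIC_PATTERNS,
) -> list[GuideClassification]:
    """Assign exactly one category to every guide.

    Priority for audited guides: off-target (same/other locus by alignment
    count) > missed target > on target.
    """
    if len(lib) != len(annos):
        raise ValueError("library and annotations must be aligned")
    nt_res = [re.compile(p, re.IGNORECASE) for p in non_targeting_patterns]
    ig_res = [re.compile(p, re.IGNORECASE) for p in intergenic_patterns]
    out: list[GuideClassification] = []
    for g, a in zip(lib, annos):
        n_genes = a.n_unique_genes
        n_aln = a.n_alignments
        if any(r.search(g.original_annotation) for r in ig_res):
            cat = "intergenic_control"
        elif any(r.search(g.original_annotation) for r in nt_res):
            cat = "non_targeting_control"
        elif n_genes > 1:
            cat = "off_target_same_locus" if n_aln == 1 else "off_target_other_locus"
        elif n_genes == 0:
            cat = "missed_target"
        else:
            cat = "on_target"
        out.append(GuideClassification(g.guide_id, cat, n_genes, n_aln))
    return out


@dataclass
class LibrarySummary:
    """Counts and fractions per category over the audited (non-control) guides."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n_audited: int
    n_controls: int


def library_summary(classifications: Sequence[GuideClassification]) -> LibrarySummary:
    audited = [c for c in classifications if not c.is_control]
    if not audited:
        raise ValueError("no audited guides: every guide matched a control pattern")
    counts = Counter(c.category for c in audited)
    n = len(audited)
    audited_cats = [c for c in CATEGORIES if c not in CONTROL_CATEGORIES]
    return LibrarySummary(
        counts={c: counts.get(c, 0) for c in audited_cats},
        fractions={c: counts.get(c, 0) / n for c in audited_cats},
        n_audited=n,
        n_controls=len(classifications) - n,
    )


def nearest_exon_distance(anno: GuideAnnotation, exome: ExonSet) -> int | None:
    """Linear distance from a guide's nearest cut site to the nearest exon.

    0 when a cut is interior to or flush against an exon; the minimum is
    taken over all of the guide's cut sites.  None when the guide has no cut
    sites or no cut lands on a contig that carries exons.
    """
    best: int | None = None
    for cut in anno.cut_sites:
        d = exome.nearest_distance(cut.contig, cut.coord)
        if d is not None and (best is None or d < best):
            best = d
    return best


def false_non_targeting_counts(
    lib: GuideLibrary, annos: Sequence[GuideAnnotation]
) -> dict[str, int]:
    """Genes gained per guide by re-annotation relative to the original label.

    A positive count flags valid guide-to-gene relationships that the
    original single annotation was missing.  Reported per guide, as a
    property of annotations rather than a guide category.
    """
    out: dict[str, int] = {}
    for g, a in zip(lib, annos):
        gained = a.symbols - {g.original_annotation}
        out[g.guide_id] = len(gained)
    return out


def design_filter(
    scored: GuideLibrary,
    annos: Sequence[GuideAnnotation],
    n_intermediate: int = 20,
    n_final: int = 6,
) -> GuideLibrary:
    """Guide-selection filter used to build clean libraries from scored pools.

    Per gene: take the top ``n_intermediate`` guides by score, remove
    other-locus off-targets and missed targets, and accept the top
    ``n_final`` survivors by score.  Genes left with fewer than ``n_final``
    clean guides are retained with a warning.
    """
    if n_final > n_intermediate:
        raise ValueError("n_final must be <= n_intermediate")
    if any(g.score is None for g in scored):
        raise ValueError("design_filter requires a score for every guide")
    cls = {c.guide_id: c for c in classify_guides(scored, annos)}
    by_gene: dict[str, list[GuideRecord]] = {}
    for g in scored:
        by_gene.setdefault(g.original_annotation, []).append(g)
    kept: list[GuideRecord] = []
    for gene in by_gene:  # insertion order: first appearance in the library
        ranked = sorted(by_gene[gene], key=lambda g: (-g.score, g.guide_id))
        pool = ranked[:n_intermediate]
        clean = [
            g
            for g in pool
            if cls[g.guide_id].category
            not in ("off_target_other_locus", "missed_target")
        ]
        if len(clean) < n_final:
            log.warning(
                "gene %s: only %d clean guides (requested %d)", gene, len(clean), n_final
            )
        kept.extend(clean[:n_final])
    return GuideLibrary(kept)
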