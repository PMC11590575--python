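"""Synthetic chemo-genetic screen generator.

Builds a synthetic genome of independent gene contigs, each carrying ten
CRISPR target sites (three inside exons, seven outside) plus one intergenic
contig with ten extra sites; prescribes per-gene chemo-genetic interaction
values

    beta = (phi + c) ** N(mu, sigma),        phi = (1 + sqrt(5)) / 2

with a control treatment fixed at beta = 1 and a random 5% of genes marked
essential and overwritten with beta = 0.1 in every treatment including the
control; and simulates pooled-screen read counts

    X = alpha + k * beta + U(a, b)

rounded to integers and clamped at zero.  beta < 1 is hypersensitivity to
the drug on knockout, beta > 1 resistance, beta = 1 neutral.  Guides at
exonic sites inherit their gene's beta; guides at non-exonic or intergenic
sites behave as non-targeting (beta = 1 under every treatment).

Five exome schemes re-draw the exon annotation over the same genome:
``ground_truth`` (exons exactly around the three targeting sites per gene),
``false_non_targeting`` (1-3 targeting guides kept per gene),
``missed_targets`` (the 3 true exons plus 0-7 non-targeting sites promoted
into exons), ``boundary`` (0-2 targeting sites per gene re-assigned to a
neighbouring gene's exons) and ``random`` (three exons per gene at sites
drawn uniformly across the genome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .core import NON_TARGETING, revcomp, scan_genome
from .reference_io import Exon, ExonSet, GenomeIndex, GuideLibrary, GuideRecord

PHI = (1 + math.sqrt(5)) / 2

SCHEMES = ("ground_truth", "false_non_targeting", "missed_targets", "boundary", "random")

INTERGENIC_LABEL = "intergenic"


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; the defaults are the study conditions."""

    n_genes: int = 4000
    sites_per_gene: int = 10
    exonic_sites_per_gene: int = 3
    n_intergenic_sites: int = 10
    essential_fraction: float = 0.05
    n_drugs: int = 12
    c: float = 0.5
    mu: float = 1.0
    sigma: float = 1.0
    essential_beta: float = 0.1
    alpha: float = 200.0
    k: float = 1000.0
    noise_a: float = -150.0
    noise_b: float = 150.0
    n_replicates: int = 1
    spacer_length: int = 20
    pad: int = 12  # random filler between site cassettes, >= 6

    def __post_init__(self) -> None:
        if self.exonic_sites_per_gene > self.sites_per_gene:
            raise ValueError("exonic_sites_per_gene must be <= sites_per_gene")
        if self.noise_a > self.noise_b:
            raise ValueError("noise bounds must satisfy a <= b")
        if self.alpha + self.k * min(self.essential_beta, 1.0) + self.noise_a < 0:
            raise ValueError("count parameters admit negative expected reads")
        if self.pad < 6:
            raise ValueError("pad must be >= 6 to fit exon margins")

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.sites_per_gene + self.n_intergenic_sites

    @property
    def drug_names(self) -> list[str]:
        names = [f"drug{i:02d}" for i in range(1, self.n_drugs + 1)]
        if names:
            names[0] = "ausostam"
        return names


@dataclass
class SyntheticGenome:
    """A synthetic genome, its ground-truth exome and the full guide library.

    ``sites`` has one row per guide: guide_id, gene ("" for intergenic
    sites), contig, site_index, strand, cassette_start, cut_coord, exonic.
    """

    genome: GenomeIndex
    exome: ExonSet
    library: GuideLibrary
    sites: pd.DataFrame
    gene_symbols: list[str]
    config: SimConfig


def _as_rng(rng: int | np.random.Generator) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _cassette(rng: np.random.Generator, spacer: str, strand: str) -> str:
    """A concrete spacer+NGG occurrence, written in plus-strand orientation."""
    n_base = _BASES[rng.integers(0, 4)]
    if strand == "+":
        return spacer + n_base + "GG"
    return "CC" + n_base + revcomp(spacer)


def build_synthetic_genome(
    cfg: SimConfig, rng: int | np.random.Generator
) -> SyntheticGenome:
    """Assemble the genome, verify spacer uniqueness, and emit the library.

    Spacers are drawn at random and required to align exactly once
    genome-wide; the assembled genome is scanned with the package's own
    aligner and any spacer with a stray or missing hit is redrawn (bounded
    retry budget), so the uniqueness invariant holds by verification, not
    by chance.
    """
    rng = _as_rng(rng)
    L = cfg.spacer_length
    gene_symbols = [f"SIM{i:04d}" for i in range(1, cfg.n_genes + 1)]

    # one site record per guide
    records: list[dict] = []
    spacer_pool: set[str] = set()

    def draw_spacer() -> str:
        for _ in range(1000):
            sp = _random_seq(rng, L)
            if sp not in spacer_pool:
                spacer_pool.add(sp)
                return sp
        raise RuntimeError("unable to draw a unique spacer")

    contig_names = [f"gene_{s}" for s in gene_symbols] + ["intergenic"]
    plan: dict[str, list[dict]] = {name: [] for name in contig_names}
    for gi, sym in enumerate(gene_symbols):
        contig = f"gene_{sym}"
        exonic_idx = set(
            rng.choice(cfg.sites_per_gene, cfg.exonic_sites_per_gene, replace=False)
        )
        for si in range(cfg.sites_per_gene):
            plan[contig].append(
                {
                    "guide_id": f"{sym}_s{si:02d}",
                    "gene": sym,
                    "contig": contig,
                    "site_index": si,
                    "strand": "+" if rng.integers(0, 2) else "-",
                    "spacer": draw_spacer(),
                    "exonic": si in exonic_idx,
                }
            )
    for si in range(cfg.n_intergenic_sites):
        plan["intergenic"].append(
            {
                "guide_id": f"IGR_s{si:02d}",
                "gene": "",
                "contig": "intergenic",
                "site_index": si,
                "strand": "+" if rng.integers(0, 2) else "-",
                "spacer": draw_spacer(),
                "exonic": False,
            }
        )

    # fixed padding per contig; cassettes get patched in on retries
    pads: dict[str, list[str]] = {
        name: [_random_seq(rng, cfg.pad) for _ in range(len(plan[name]) + 1)]
        for name in contig_names
    }

    def assemble() -> GenomeIndex:
        contigs: dict[str, str] = {}
        for name in contig_names:
            parts: list[str] = []
            pos = 0
            for k, rec in enumerate(plan[name]):
                parts.append(pads[name][k])
                pos += cfg.pad
                rec["cassette_start"] = pos
                cassette = _cassette_cache[rec["guide_id"]]
                parts.append(cassette)
                pos += len(cassette)
            parts.append(pads[name][-1])
            contigs[name] = "".join(parts)
        return GenomeIndex(contigs)

    _cassette_cache: dict[str, str] = {}
    for name in contig_names:
        for rec in plan[name]:
            _cassette_cache[rec["guide_id"]] = _cassette(rng, rec["spacer"], rec["strand"])

    genome = assemble()
    all_recs = [rec for name in contig_names for rec in plan[name]]
    for attempt in range(20):
        hits = scan_genome({r["spacer"] for r in all_recs}, genome, "NGG")
        bad = [r for r in all_recs if len(hits[r["spacer"]]) != 1]
        if not bad:
            break
        for rec in bad:
            spacer_pool.discard(rec["spacer"])
            rec["spacer"] = draw_spacer()
            _cassette_cache[rec["guide_id"]] = _cassette(rng, rec["spacer"], rec["strand"])
        genome = assemble()
    else:
        raise RuntimeError("spacer uniqueness not achievable within the retry budget")

    for rec in all_recs:
        s = rec["cassette_start"]
        rec["cut_coord"] = s + L - 3 if rec["strand"] == "+" else s + 3 + 3

    sites = pd.DataFrame(all_recs).set_index("guide_id", drop=False)
    exons = [
        Exon(r["contig"], r["cut_coord"] - 6, r["cut_coord"] + 6, r["gene"], "protein_coding")
        for r in all_recs
        if r["exonic"]
    ]
    library = GuideLibrary(
        GuideRecord(
            r["guide_id"],
            r["spacer"],
            r["gene"] if r["gene"] else INTERGENIC_LABEL,
        )
        for r in all_recs
    )
    return SyntheticGenome(genome, ExonSet(exons), library, sites, gene_symbols, cfg)


@dataclass
class ChemoGeneticMatrix:
    """Per-gene multiplicative fitness effects under each treatment."""

    beta: pd.DataFrame  # genes x (control + drugs)
    essential: pd.Series  # bool per gene


def draw_chemo_genetic_matrix(
    cfg: SimConfig, rng: int | np.random.Generator
) -> ChemoGeneticMatrix:
    """Draw beta = (phi + c)^N(mu, sigma) per gene x drug; control fixed at 1.

    ceil(essential_fraction * n_genes) genes, chosen uniformly at random,
    are overwritten with ``essential_beta`` in every column including the
    control.
    """
    rng = _as_rng(rng)
    genes = [f"SIM{i:04d}" for i in range(1, cfg.n_genes + 1)]
    exponents = rng.normal(cfg.mu, cfg.sigma, size=(cfg.n_genes, cfg.n_drugs))
    beta = pd.DataFrame(
        (PHI + cfg.c) ** exponents, index=genes, columns=cfg.drug_names
    )
    beta.insert(0, "control", 1.0)
    n_ess = math.ceil(cfg.essential_fraction * cfg.n_genes)
    ess_idx = rng.choice(cfg.n_genes, n_ess, replace=False)
    essential = pd.Series(False, index=genes)
    essential.iloc[ess_idx] = True
    beta.loc[essential] = cfg.essential_beta
    return ChemoGeneticMatrix(beta, essential)


def simulate_counts(
    sg: SyntheticGenome,
    cgm: ChemoGeneticMatrix,
    cfg: SimConfig,
    rng: int | np.random.Generator,
) -> pd.DataFrame:
    """Simulated integer read counts, guides x (control + drugs) x replicates.

    Guides at exonic sites inherit their gene's beta; all other guides are
    non-targeting and carry beta = 1 under every treatment.  Counts are
    rounded to the nearest integer and clamped at zero.
    """
    rng = _as_rng(rng)
    treatments = list(cgm.beta.columns)
    guide_beta = np.ones((len(sg.sites), len(treatments)))
    exonic_mask = sg.sites["exonic"].to_numpy()
    gene_rows = cgm.beta.reindex(sg.sites.loc[exonic_mask, "gene"]).to_numpy()
    guide_beta[exonic_mask] = gene_rows
    cols: dict[str, np.ndarray] = {}
    for _, t in enumerate(treatments):
        for rep in range(cfg.n_replicates):
            noise = rng.uniform(cfg.noise_a, cfg.noise_b, len(sg.sites))
            x = cfg.alpha + cfg.k * guide_beta[:, treatments.index(t)] + noise
            name = t if cfg.n_replicates == 1 else f"{t}_rep{rep + 1}"
            cols[name] = np.clip(np.rint(x), 0, None).astype(int)
    return pd.DataFrame(cols, index=sg.sites.index.copy())


def _exon_at(site: pd.Series, gene: str) -> Exon:
    c = int(site["cut_coord"])
    return Exon(site["contig"], c - 6, c + 6, gene, "protein_coding")


def make_exome_scheme(
    sg: SyntheticGenome, scheme: str, rng: int | np.random.Generator
) -> ExonSet:
    """Build one of the five exome annotation schemes over the genome."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    rng = _as_rng(rng)
    sites = sg.sites
    exons: list[Exon] = []
    if scheme == "ground_truth":
        return sg.exome
    if scheme == "random":
        all_ids = sites.index.to_numpy()
        k = sg.config.exonic_sites_per_gene
        for sym in sg.gene_symbols:
            for gid in rng.choice(all_ids, k, replace=False):
                exons.append(_exon_at(sites.loc[gid], sym))
        return ExonSet(exons)
    for gi, sym in enumerate(sg.gene_symbols):
        gene_sites = sites[sites["gene"] == sym]
        exonic = gene_sites[gene_sites["exonic"]]
        non_exonic = gene_sites[~gene_sites["exonic"]]
        if scheme == "false_non_targeting":
            # drop 0..k-1 targeting guides, always keeping at least one
            n_drop = int(rng.integers(0, len(exonic)))
            dropped = set(rng.choice(exonic.index.to_numpy(), n_drop, replace=False))
            for gid, site in exonic.iterrows():
                if gid not in dropped:
                    exons.append(_exon_at(site, sym))
        elif scheme == "missed_targets":
            for _, site in exonic.iterrows():
                exons.append(_exon_at(site, sym))
            n_add = int(rng.integers(0, len(non_exonic) + 1))
            for gid in rng.choice(non_exonic.index.to_numpy(), n_add, replace=False):
                exons.append(_exon_at(sites.loc[gid], sym))
        elif scheme == "boundary":
            neighbours = [j for j in (gi - 1, gi + 1) if 0 <= j < len(sg.gene_symbols)]
            n_disp = int(rng.integers(0, 3)) if neighbours else 0
            n_disp = min(n_disp, len(exonic))
            displaced = set(rng.choice(exonic.index.to_numpy(), n_disp, replace=False))
            for gid, site in exonic.iterrows():
                if gid in displaced:
                    owner = sg.gene_symbols[neighbours[int(rng.integers(0, len(neighbours)))]]
                else:
                    owner = sym
                exons.append(_exon_at(site, owner))
    return ExonSet(exons)


def guide_gene_map(annos) -> dict[str, frozenset[str]]:
    """guide_id -> re-annotated symbol set (empty set = non-targeting)."""
    return {a.guide_id: frozenset(a.symbols) for a in annos}
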