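# Methods

## Guide re-annotation

### Probe construction and alignment

Each spacer (≥ 17 nt over {A,C,G,T}) is appended with the spCas9 PAM,
`NGG` by default, at its 3′ end. The probe is matched at **perfect
identity, full length, ungapped** against both strands of the genome.
With a perfect-identity requirement and a fixed cut-interval rule, only
contiguous perfect matches of spacer+PAM can produce a cut coordinate, so
an exact scanner is used rather than a seeded aligner; it has no seeding
heuristics to miss hits and no external binary to install.

Wildcard semantics are asymmetric by design: `N` in the probe (the PAM
wildcard) matches any of {A,C,G,T}, but `N` in the genome matches nothing
— an ambiguous genome base is unknown sequence, not a licence to declare
a perfect match. IUPAC codes other than N in input FASTA are converted to
N on read, with a warning.

Two equivalent search paths exist: `find_alignments` (per-probe regex,
overlap-aware, used for point queries) and `scan_genome` (one pass per
contig: PAM sites located by regex, the adjacent window looked up in a
spacer hash, one hash per spacer length — linear in genome size rather
than guides × genome, used by `exorcise_library`). A property test holds
them equal to a brute-force sliding-window oracle on random genomes.

### Cut-site geometry

spCas9 cuts bluntly between the 3rd and 4th nucleotide 5′ of the PAM. The
cut is represented as a **zero-width between-base coordinate**:

- `+` strand match `[s, s+L+3)`: `cut = s + L − 3`;
- `−` strand match: the PAM complement occupies the first three
  plus-strand bases, so the geometry mirrors to `cut = s + 6`.

Both formulas place the cut strictly inside the match span, and
reverse-complementing a contig of length G maps every cut to `G − cut`
(tested as an invariant).

### Exon overlap and annotation

A guide is annotated with the gene of every exon whose **strict interior**
contains one of its cuts (`start < cut < end`). A cut flush against an
exon boundary is deliberately a non-overlap: a blunt cut at the boundary
leaves the exon body intact on one side, and treating it as a hit would
make the distance-to-nearest-exon statistic ambiguous at zero. Exon
strand is ignored — a double-strand break disrupts an exon regardless of
which strand the guide annealed to. Guides with no overlapping exon are
re-annotated `non-targeting`.

### Gene-level mapping

For each unique original annotation, the multiset of re-annotated symbols
over its guides ("candidates", one vote per guide per symbol) is
reconciled to one accepted symbol: most frequent wins; ties fall through
the hierarchy *same-as-original → protein-coding → non-coding RNA →
pseudogene → other/unknown*; residual ties break lexicographically so the
mapping is deterministic under any guide ordering (tested by permutation).
Original annotations with no candidates are left unmapped. Biotypes come
from the exome input (BED column 7), normalised case-insensitively
through a configurable synonym table; where a symbol carries several
biotypes across exons the most-preferred rank is used.

## Library audit

Categories are assigned with priority off-target > missed target > on
target, after control guides are set aside:

- *off_target_same_locus*: > 1 unique symbol from exactly 1 alignment
  (overlapping features at one locus);
- *off_target_other_locus*: > 1 unique symbol from > 1 alignment;
- *missed_target*: non-control original annotation, empty re-annotation;
- *on_target*: exactly one symbol.

Controls are recognised by configurable regexes on the original
annotation (defaults: `/non.?target/i`, `/^control/i` → non-targeting
control; `/intergenic/i` → intergenic control) because real libraries
encode them heterogeneously; they are excluded from summary denominators.
False non-targeting effects are reported separately as the count of
symbols each guide *gains* relative to its original single annotation —
they are a property of annotations, not a guide category.

Cut-to-exon distance is 0 for interior or flush cuts, otherwise the
linear gap to the nearest exon start/end on the same contig, minimised
over a guide's cut sites; it is undefined for guides with no alignment or
no exon-bearing contig.

The design filter used to assemble clean libraries takes, per gene, the
top `n_intermediate` guides by score, drops other-locus off-targets and
missed targets, and accepts the top `n_final` survivors; genes left short
are retained with a warning rather than silently dropped.

## Synthetic screen

### Genome construction

One contig per gene. Each of the 10 sites per gene is a 23-nt cassette —
a random 20-nt spacer plus a concrete `NGG` instance, written on a random
strand — separated by 12 nt of random sequence, with 3 sites per gene
designated exonic and a ground-truth exon `[cut−6, cut+6)` placed around
each exonic cut. One extra contig carries the 10 intergenic sites.
Spacer uniqueness is enforced **by verification, not by chance**: after
assembly the package's own scanner aligns every spacer, and any spacer
with a stray or missing hit is redrawn and its cassette patched (bounded
retry budget). The closure test — annotating the generator's own library
against its own exome recovers exactly 3 guides per gene and every
intergenic guide as non-targeting at the full 40,010-guide scale — is the
end-to-end self-test of the alignment/annotation stack.

### Interactions and counts

Per gene × drug, β = (φ+c)^n with n ~ N(μ, σ) (defaults c = 0.5, μ = 1,
σ = 1): the exponent's unit scale spans strong and intermediate effects
(median β ≈ 2.12, ≈ 16 % of gene-drug pairs hypersensitive). The control
column is 1; ⌈5 %⌉ of genes, chosen uniformly, are essential and
overwritten with β = 0.1 in *every* column including the control (their
fold changes are therefore null — essentiality drops out of a
treatment-vs-control comparison). Guides at exonic sites inherit their
gene's β; all other guides are non-targeting with β = 1 under every
treatment. Counts are X = α + kβ + U(a,b) (α = 200, k = 1000,
a = −150, b = 150), rounded to the nearest integer and clamped at zero —
downstream scorers expect integer counts, and with these parameters the
clamp is essentially never active. One replicate per treatment by
default (`n_replicates` is a config knob).

### Exome schemes

All schemes annotate the *same* counts; only the exon map changes.

- **ground_truth** — exons exactly around the 3 targeting cuts per gene.
- **false_non_targeting** — per gene, 0–2 targeting guides (uniform) are
  removed from exons, always keeping at least one, so genes carry 1–3
  guides.
- **missed_targets** — the 3 true exons plus 0–7 (uniform) of the gene's
  non-targeting sites promoted into exons (3–10 guides per gene; the
  correct 3 always retained).
- **boundary** — per gene, 0–2 (uniform) of its targeting sites are
  re-assigned to the exome of a uniformly chosen adjacent gene (gene
  order is index order; ends clamp), so a gene keeps 1–3 of its own
  guides and can absorb up to 4 foreign ones (≤ 7 total, ≤ 4 off-target).
- **random** — each gene receives 3 exons at sites drawn uniformly from
  the whole genome, breaking any relationship between annotation and
  signal.

### What the generator does and does not emulate

It emulates the *annotation-transfer* failure modes of real libraries on
an idealised count model. It does not model PCR amplification noise,
overdispersion, guide-efficiency variation, dropout kinetics, or
chromatin effects; counts are uniform-noised means. Passing tests
therefore demonstrate the behaviour of the re-annotation and scoring
machinery under controlled mis-annotation, not the full error structure
of experimental screens.

## normZ scoring

Per control/treatment pair: columns are scaled to a common total of 10⁷
reads; a pseudocount of 5 is added; per-guide fold change
fc = log₂(treat/control). Guides are ranked by control abundance and an
empirical-Bayes standard deviation is taken as the rolling SD of fc over
windows of 1000 guides (half-window 500), forced monotone non-decreasing
as abundance falls — low-count guides never get a smaller variance than
high-count ones. Guide z = fc/σ; per gene, sumZ = Σz over guides and
replicates, normZ = sumZ/√n; one-sided normal p-values in each direction
(hypersensitising = negative, resisting = positive) with
Benjamini–Hochberg FDR per direction. A guide annotated to several genes
contributes its z to each; guides mapped to nothing or to the
non-targeting label inform normalisation and variance estimation but are
excluded from gene aggregation.

Two deliberate conventions:

- **Fold changes are not re-centred and gene scores are not
  re-standardised.** Common-total normalisation deflates neutral guides
  in treatments whose strong responders absorb read share, tilting
  neutral guides mildly toward the hypersensitising side; this
  compositional artefact is a documented property of the normZ family
  and is kept so the scorer's calls behave like the field's reference
  tool. Re-standardising against the all-gene distribution would also
  destroy the absolute effect scale on data where most genes carry real
  effects, collapsing the directional FDR call sets.
- FDR is controlled separately per direction (two one-sided families),
  matching the output shape screens are analysed with in practice.

Degenerate inputs: a byte-identical treatment/control pair has
zero-variance fold changes and raises; zero-σ windows yield z = 0 rather
than ±∞.

## ROC evaluation

Actual positives: genes the ground-truth scoring calls at FDR ≤ 0.5 in
their normZ-sign direction (0.5 keeps strong and intermediate signals
while excluding noise-level genes). Candidate positives: the candidate
scheme's calls at the same cutoff, ranked by ascending FDR (ties by
descending |normZ|, then symbol). A call is a true positive only if it is
an actual positive *in the same direction*; anything else — including an
actual positive called in the opposite direction — is a false positive.

The ROC curve walks the ranked calls with axes normalised within the
called set (x = cumulative FP / total FP, y = cumulative TP / total TP),
is anchored at (0,0) and (1,1), and is integrated by the trapezoid rule.
The AUC therefore measures whether false calls concentrate late in the
ranking — a rank statistic on the calls — and is deliberately decoupled
from *how many* truths are recovered, which precision (TP/calls) and
recall (TP/actual positives) report at the threshold. A candidate
identical to the truth scores AUC = precision = recall = 1 exactly; a
candidate whose ranking is unrelated to the truth scores AUC ≈ 0.5.

Bundle analysis groups genes by candidate guides-per-gene and fits the
through-origin least-squares slope of candidate vs truth normZ per
stratum (undefined below 3 genes): super- or sub-numerary guides shrink
the slope toward zero while largely preserving sign and order, which is
the visual "bundling" signature of dilution-type mis-annotation.

## Problem sizes and numerical choices

The benchmark harness runs the full study scale (4000 genes, 40,010
guides, 12 drugs + control) per screen; `scripts/acceptance.py` averages
8 independent screens (~25 s each), a sample size at which the
seed-to-seed SD of every reported metric is below 0.02. The acceptance
test suite asserts the same quantities over 3 seeds. All randomness flows
through `numpy.random.SeedSequence` children of a single seed, so every
artefact — genome, interactions, counts, schemes — is reproducible
bit-for-bit; CLI outputs embed the seed and input hashes in a provenance
header, and contain no timestamps so repeated runs are byte-identical.

## Known limitations

- The exact matcher will not report gapped or split matches; mismatch-
  tolerant off-target prediction is out of scope.
- PAM placement is fixed at the 3′ end (spCas9-style); 5′-PAM nucleases
  are not supported.
- The audit's control-guide recognition is regex-based and will misfile
  libraries with exotic control naming unless patterns are supplied.
- The TPM-based exome inference matches identifiers by exact symbol; it
  does not resolve transcript-to-gene mappings.
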