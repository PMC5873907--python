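# Methods

This note documents the models, conventions, parameter choices and known
limitations of `balancerscan`: the synthetic forge that generates
balancer/reference-heterozygote sequencing with ground truth, and the four
analysis stages (junction calling, depth segmentation, SNP-panel
classification, effect annotation) run on it.

## Coordinates and the retained-flank convention

All reported coordinates are 1-based inclusive. A rearrangement junction is
described by its two *retained flanks*: the junction-adjacent reference base
of each retained block, with a side code ('+' when the retained block
occupies coordinates ≤ pos, '−' when ≥ pos). Under this convention a simple
inversion produces one (+,+) junction (the two breakpoint-left blocks joined
head-to-head) and one (−,−) junction. Each breakpoint *site* of a paired
aberration combines one '+' flank at position *p* with one '−' flank at
position *m*; the signed junction delta is

    Δ = p − m + 1

so Δ > 0 counts bases present on both sides (a junction duplication), Δ = 0
is a blunt junction, and Δ < 0 counts bases deleted strictly between the
flanks. This single formula reproduces the eight self-consistent printed
deltas of the published second-chromosome breakpoint table shipped in
`data/balancer_breakpoints.tsv` (+280, −153, −4, −12, −7, −10, −475, 0); the
two remaining published rows (+4, +2) are internally inconsistent with their
own coordinates by one base and are flagged by
`catalog.check_breakpoint_deltas` rather than matched. Duplicated-segment
sizes follow the published table's `end − start` convention; the one row
whose printed size (712,929) disagrees with its printed coordinates (which
differ by 717,890) is likewise flagged, with coordinates treated as
authoritative.

**Micro-homology canonicalization.** When the reference base beyond one flank
equals the base the other side contributes at that derivative position, the
breakpoint placement is ambiguous: the boundary can slide without changing
the derivative sequence. Calls and forge ground truth are both normalized to
the leftmost-in-derivative representation (`svscan.canonicalize_junction`),
making base-exact comparison well defined.

## The forge

### Reference genomes

`forge_reference` draws i.i.d. A/C/G/T sequence, places transcripts in
quasi-regular slots at the requested gene density (three-quarters
protein-coding with 2–4 exons and a frame-consistent CDS; the rest
ncRNA/tRNA/snoRNA), and converts ~2% of each chromosome into 2-kb two-letter
tracts. These tracts stand in for centric heterochromatin: k-mer anchoring
legitimately fails in them, so junctions whose flanks fall there are
unresolvable by design — mirroring the real situation where breakpoints in
repeat-rich sequence resist short-read analysis. Synthetic CDSs are random
sequence; they are frame-consistent but make no promise of starting with ATG
or lacking internal stops, and the annotator assumes neither.

### Derivative chromosomes

A derivative is an ordered list of oriented reference segments
(`SegmentMap`), the coordinate backbone for everything else: sequence
splicing, forward lift-over (derivative → reference base and strand) and
inverse lift-over (reference → all derivative preimages, multi-valued inside
duplications). Operations compose on derivative coordinates:

* `apply_inversion(left_flank, right_flank, delta_left, delta_right)` —
  flanks are the last retained base on each side; positive deltas duplicate
  that many flank bases into the inverted core, negative deltas delete core
  bases adjacent to the junction.
* `apply_tandem_duplication(start, end)` — in-place tandem copy; the joint
  records Δ = interval length.
* `apply_complex_duplication(dupA, dupB, inverted_seg, spacer)` — the
  mirror-image double duplication. The duplicated unit D = A+B must be the
  derivative interval immediately following the inverted segment I (in the
  real chromosome the copied unit spans an existing inversion junction, which
  is why the two duplicated segments lie far apart on the reference). The
  result is `prefix + revcomp(I) + revcomp(D) + D + spacer + spacer +
  suffix`: A and B each end up in two copies in mirror-image orientation
  around a blunt mirror junction with identical flanks, joined to the
  inverted segment, with the low-complexity spacer juxtaposed to the distal
  end of the second copy. This layout was chosen over placing the spacer
  between the mirror halves because it leaves three *placeable* junctions
  whose flanks chain by proximity — including the blunt Δ=0 mirror junction —
  matching the junction anatomy actually resolved for the real rearrangement;
  a spacer at the mirror point would make that junction unresolvable. The
  derivative grows by |A| + |B| + 2·|spacer| exactly.

### Variants and crossovers

`plant_variants` draws per-branch Poisson variant counts (rate × genome
length) on an arbitrary acyclic stock lineage; ancestral-branch variants
appear in every descendant (shared), leaf-branch variants are stock-unique.
Variants are 90% SNVs and 10% short (≤5 bp) indels; quality scores are
uniform on [150, 320], deliberately spanning the 220 filter threshold so the
quality filter does real work. `plant_crossover` replaces the recipient's
variants inside an exchanged tract with the donor's — one breakpoint gives an
SCO running to the chromosome end, two give an interior DCO — and returns the
tract as ground truth.

The packaged mini panel (`forge.scenario`) uses branch rates of 10⁻³/bp for
the shared ancestral branch, 2·10⁻⁴ for type branches, 5·10⁻⁶ for individual
stock branches, and 10⁻³ for the wild donor chromosomes that supply
crossover tracts. The strong contrast between donor density and stock-branch
density is the biology being modeled: standing natural variation between
independent chromosomes is orders of magnitude denser than de novo mutation
accumulated by a balancer in stock, and it is exactly this contrast that
makes crossover tracts stand out as runs of stock-unique SNPs.

### Read simulation

`simulate_alignments` draws fragments along the two haplotypes of the
heterozygote with insert length ~ Normal(mean, sd) truncated at twice the
read length, and projects each read analytically through the segment map — no
alignment search. A read crossing a junction becomes a primary plus
supplementary record with complementary soft clips; a pair straddling a
junction inherits whatever orientation/insert anomaly the lift-over implies;
reads landing in spacer sequence are unmapped. Sequencing error is uniform
substitution (default 10⁻³); no indel errors, base qualities or PCR
duplicates are modeled, since none of them participate in the detection logic
under test.

`haplotype_fraction` is interpreted as the *molar* ratio of the two
haplotypes: a fragment comes from a haplotype with probability proportional
to fraction × haplotype length. With the default 0.5 (one copy of each
haplotype per cell, the real heterozygote), per-bp coverage is equal on both
haplotypes regardless of how long the derivative is, and one extra copy of a
segment yields the 3:2 depth signature exactly. Fixed-probability assignment
would instead dilute the longer haplotype's per-bp coverage and bias the
duplication signal downward (to ≈1.45 for a 400-kb duplication on a 2-Mb
genome). For equal-length haplotypes the two interpretations coincide, which
is how the haplotype-balance invariant is tested.

Defaults: 150-bp reads, insert 400 ± 40 bp, depth 30×. The published study
fixes only the read length; insert parameters were chosen so that
junction-straddling pairs are common at 30×.

## Junction calling

Thresholds (all in `SvConfig`, all exposed in the run config): minimum clip
20 bp; discordance at non-FR orientation, different chromosomes, or insert
beyond 3 estimated SDs (median/scaled-MAD from proper pairs); joint
single-linkage cluster radius 500 bp; minimum support 2 split or 3 discordant
observations; assembly minimum exact overlap 20 bp (a Hamming-tolerant mode
allowing one mismatch per 50 bp of overlap exists for error-rate simulations,
off by default); anchor k-mer 31 with anchors occurring more than 4 times in
the genome discarded; minimum placed block 30 bp; contig ends shorter than k
may remain uncovered (they cannot anchor, and greedy assembly occasionally
leaves a chimeric tail at palindromic mirror junctions). A contig qualifies
iff exactly two maximal ungapped blocks on distinct loci cover it; colinear
same-strand placements with modest spacing are classified local indels and
excluded from aberration pairing. Clusters whose evidence footprint is more
than half masked are reported in a separate heterochromatic/ambiguous
section. Ties everywhere break lexicographically on (chromosome, position,
sequence), making the whole chain deterministic.

Pairing: junction calls whose flanks lie within `pair_window` (default
2,000 bp — comfortably above any plausible junction micro-delta, far below
the spacing between distinct aberrations) form a group; a group of two with
the inversion strand signature is an inversion with per-site deltas from the
formula above; larger or inconsistent groups are complex. Fingerprinting
requires every coordinate-known site of a catalog aberration to match a
called site within 100 bp; the balancer with all required aberrations matched
(most matches wins, ties unresolved) is reported, so a subset composition
(e.g. a two-inversion balancer) never masquerades as its superset.

## Depth segmentation

Read-start counting (not per-base coverage) keeps window counts approximately
Poisson; windows are 1 kb by default; windows more than half-masked are
excluded from the normalization median. Counts are overdispersed relative to
pure Poisson by up to ~2× because the two reads of a fragment often start in
the same window. Binary segmentation uses the exhaustive least-squares single
split per segment, accepted when the SSE reduction exceeds 4·σ̂²·log n, with
σ̂ estimated robustly from first differences; the factor 4 keeps the
expected extreme spurious gain (which itself grows like 2σ²·log n) safely
below threshold while remaining an order of magnitude below the signal of a
half-copy step. Adjacent segments shorter than 3 windows merge into the
neighbor with the closer mean. For single-step tracks the result provably
coincides with the exhaustive optimum, which is the test oracle. Gain/loss
thresholds sit at the midpoints between expected heterozygote ratios; no
GC-bias correction is applied (synthetic reads are unbiased; the config
leaves a hook).

## SNP panel

Merging is positional on (chromosome, position, ref, alt); multiallelic
records are split; indels are retained but flagged; presence means any
non-reference genotype (balancer stocks are sequenced over the reference
strain, so every balancer variant is heterozygous). The `shared_all` class
follows the operational definition "present in every stock of at least two
balancer types"; the strict all-types intersection count is also computed and
stored on the panel. Tract detection uses runs of ≥ 10 stock-unique loci with
gaps ≤ 100 kb (published tracts span hundreds of kb to Mb; both knobs are
config-exposed). Tract boundaries are the interval between the outermost
unique locus and the nearest flanking informative locus, where *informative*
means a non-unique locus the stock actually carries — inside an exchanged
tract the stock also lacks the balancer-shared variants, so absence is not
evidence of balancer sequence. SCO/DCO classification is purely geometric
(within one gap of a chromosome end or not); no mechanistic claim is made
about subtelomeric exchanges. Classification is set-theoretic, so no
multiple-testing machinery applies.

## Effect annotation

Codon-level evaluation on the coding strand with the standard nuclear code
only; splice sites are the two intronic bases at each exon boundary;
start-loss requires the annotated initiator (when it is ATG) to be abolished;
the worst-effect order is start_loss > nonsense > splice_site > missense >
synonymous > noncoding > intronic > intergenic. Exonic positions outside any
CDS and coding indels receive the `noncoding` class with a detail note — the
four headline census classes are SNV-only, matching how the published census
was built. Junction flanks inside a transcribed span are gene disruptions
(with the exon/intron named); genes wholly inside a duplicated segment are
copy gains. Multi-transcript genes report the worst effect per gene in
summaries while retaining all per-transcript calls.

## The packaged mini panel

`build_mini_world` forges one chromosome carrying four balancer types that
share one inversion (with the published-style +280/−153 micro-deltas),
distinguished by three further inversions and, for the complex type, the
mirror-image double duplication whose duplicated unit spans the shared
inversion's tail junction — so the two duplicated segments (expected ratio
1.5) are distant in reference coordinates, as in the real chromosome. Four
stocks (two per type, one deliberately mislabeled) descend from a two-level
lineage; one stock carries an interior DCO and another a distal SCO donated
by wild chromosomes. Masked tracts are re-drawn (deterministically, by
salting the seed) until none falls within 1 kb of a planted flank, so that
every planted junction is euchromatic by construction. The default scale is a
5-Mb chromosome at 30×; tests run the full simulate-and-call chain once at
that scale and use 0.25–1-Mb scales for the orchestration and CLI checks.

## What passing tests do and do not show

The forge reproduces the statistical structure the analysis relies on —
split/discordant geometry, 3:2 and 1:2 copy ratios, quality-score filtering,
lineage sharing structure, dense crossover tracts on a sparse unique-SNP
background, unresolvable low-complexity regions — but not real-genome
nuisances: no repeat families or segmental duplications (beyond the planted
ones), no GC or library bias, no indel sequencing errors, no base-quality
structure, no alignment-search artifacts (alignments are projected
analytically, so mapping ambiguity exists only where k-mer anchoring fails by
construction). Recovery results on the forge therefore demonstrate the
correctness of the algorithms under their stated model, not performance on
real libraries. Base-exact junction recovery is asserted on variant-free,
error-free simulations; planted polymorphisms or errors adjacent to a
junction legitimately shift flank placement by a few bases, which the
catalog-matching tolerance (100 bp) absorbs.

## Reference quantity

`scripts/acceptance.py` recomputes the heterozygote duplication depth
signature from scratch: a 2-Mb diploid whose balancer haplotype carries a
400-kb tandem duplication, 30× error-free 150-bp paired-end coverage, 1-kb
windows, genome-median normalization. It reports the percent elevation of
mean normalized depth inside the duplicated interval relative to background
(the median ratio of windows outside the interval — with the duplication
occupying 20% of this small genome, the raw genome-wide median would itself
be inflated by the duplicated windows). The expected value under the copy
model is +50%; sampling variation at this depth is a percentage point or two.
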