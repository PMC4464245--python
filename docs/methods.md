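# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind mitopop. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The synthetic strain-set generator

`mitopop.simulate.simulate_population_set` builds a set of annotated
mitochondrial genomes with fully known ("planted") truth. It emulates the
statistical structure of intraspecific yeast mtDNA variation, not its
mechanistic detail.

**Ancestor.** A circular genome of `genome_length_target` bp (default
80,000) containing the eight-gene syntenic coding core
cox1(1605)-atp8(147)-atp6(780)-cob(1158)-atp9(228)-rps3(1344)-cox2(756)-
cox3(810) plus the rnl rRNA gene (3402 bp), separated by AT-rich spacers
(default AT fraction 0.84, drawn with A=T and C=G base frequencies). Gene
templates are fixed random in-frame CDS sequences (ATG start, TAA end, no
internal stop under translation table 3, ~80 % AT), generated once from a
frozen seed so they behave as constants. At the default length, coding
sequence is ~8.5 % of the genome and non-genic DNA >= 85 %.

**Substitutions.** Evolved along a user-supplied population tree (Newick,
branch lengths in expected substitutions per intergenic site), each branch
contributing Poisson(branch x L) candidate substitutions with replacement
bases drawn from the AT-biased stationary distribution. Two filters act on
coding positions: an overall rate scale (`cds_rate_scale`, default 0.5) and
acceptance of nonsynonymous changes with probability
`nonsynonymous_acceptance` (default 0.15); in-frame stops are never
created. The two filters are a minimal stand-in for purifying selection so
that planted coding diversity and pN/pS sit in the empirically observed
regime (coding diversity a few-fold below intergenic; pN/pS well under 1)
rather than at neutrality. Each strain receives additional substitutions at
`within_population_divergence` (default 0.001) on top of its population's
backbone.

**Introns.** Presence at each of the 18 known insertion sites (11 in cox1,
6 in cob, the omega site in rnl; 1-based "CDS base preceding the
insertion") is an independent Bernoulli draw per strain from its
population's profile. The default profiles encode the field's observed
population signatures at observed frequencies — e.g. aI1 universal in the
sake- and West-African-like populations, 38 % in the wine/European-like
one, bI4/bI5 invariably present, bI1b/bI2 nearly absent in sake-like
strains, aI5b/aI5g absent in West-African-like strains, aI3b and aI4g never
present. Intron sequences are random AT-rich strings (800-2500 bp) with
fixed terminal motifs, one fixed sequence per site shared by all carriers;
no self-splicing structure is modeled, and intron interiors carry no
between-strain divergence. Exon reading frames are preserved exactly
(splice round trip is an identity).

`distinct_intron_profiles()` provides the same signatures binarized at 0.5.
This is the regime in which binary intron characters can recover population
clades; the frequency-faithful defaults deliberately retain enough
within-population intron polymorphism that wine/European- and mosaic-like
populations are *not* expected to come out monophyletic in a
binary-character tree — matching what is observed in real strain panels.

**GC clusters.** Per-strain class counts are rounded draws from
Normal(mean, sd) per the population profile, clipped at zero. Each cluster
is a concrete instantiation of its class consensus (IUPAC codes resolved
uniformly at random) inserted at a random intergenic position, with a
minimum spacing of `min_insert_separation` (120 bp) between insertion
anchors so that each planted cluster occupies its own GC-rich region and
count recovery is well defined. V-class clusters are the exception: they go
in frame inside rps3 at codon boundaries (the V consensus is a multiple of
3 and cannot produce a stop codon in any instantiation). With
`m4_pairing` (default on) every M4 is planted as one contiguous block
immediately 5' of an M1 partner (reversed with probability
`m4_downstream_prob`, default 0.05), producing the observed M4-M1 tandem
arrays. `n_conserved_clusters` (default 2) clusters are planted at the same
ancestral position with identical sequence in every strain, giving
alignment-conserved positions.

**Default populations.** wine_euro, west_african, sake and mosaic_a — the
four populations for which the source tables contain at least five strains,
i.e. the only ones whose count dispersions are estimable rather than
invented. Their GC count means/sds and intron frequencies follow the
published per-population tables; the West-African-like population carries
the M4 expansion (mean 18 +- 5.8 vs <= 2.7 elsewhere). The default
population tree is balanced with ~0.02 substitutions/site between
populations.

**Indels.** Intergenic only (deletions and insertions, 50/50), with counts
Poisson(rate x intergenic kb x root-to-tip branch length) at
`intergenic_indel_rate` = 50 events/kb per unit branch length and geometric
sizes (mean 8 bp). Deletions never touch genes or insertion anchors.

**Truth and the joint alignment.** Every event is recorded: per-strain
cluster intervals with class and pair orientation, the intron matrix, indel
events, population labels. The true multiple alignment is built by
construction — ancestor columns plus insertion-block columns (shared blocks
for introns and conserved clusters, private blocks otherwise) — with
per-column region labels (exon/intron/intergenic; rnl columns are labeled
exon) and per-column host gene. Per-strain genomes are the ungapped
alignment rows, which guarantees genome/alignment consistency. Randomness
derives from one root `rng_seed` via deterministic stream splitting in
strain order; a whole run is bit-reproducible, but per-strain outputs are
not invariant to changing the set size.

**What the simulator does not emulate** (hence what passing tests do not
show about real data): sequencing error and assembly artifacts; tRNA genes
and ori elements; degenerate/decayed cluster copies (real genomes average
~40 unclassified GC-rich regions per strain; simulated backgrounds produce
nearly none); recombination and introgression (mosaicism is emulated only
as intermediate profile frequencies); within-intron sequence evolution;
rps3 length variation beyond V-cluster insertions; genome rearrangement.

## GC-cluster scanning and classification

Windows of 30 bp (step 1) with GC strictly > 0.60 are merged (overlapping
or bookended) into maximal regions; per-region GC is recomputed over the
merged interval. Circular genomes are scanned with the first window-1
bases appended, and a region spanning the origin is merged across the
seam, making counts rotation invariant.

Classification aligns each IUPAC class consensus against the +-20 bp padded
region on both strands with a semi-global aligner (free end gaps; match +1
when the genome base is compatible with the consensus code, otherwise -1;
internal gaps -4/-1). Identity is matches divided by *all* internal
alignment columns — gap columns on either side count against identity — and
coverage is the aligned fraction of the consensus; both default thresholds
are 0.80. Counting gap columns matters: classification should be
substitution-dominated, since the class consensi themselves encode the
family-specific indels (M1' vs M1 etc.), and it prevents a consensus from
gap-stitching onto a different family's instance. Same-class copies in one
region are enumerated by iterative masking; overlapping hits of different
classes are all retained, overlapping same-class hits keep the best
identity. With the shipped placeholder table the best cross-class identity
over instantiations (either strand, gapped) is about 0.71, comfortably
below threshold, which is what makes exact planted-count recovery possible.

Tandem arrays are GC-rich regions overlapped by >= 2 classified hits.
One-way ANOVA (`count ~ population`) uses scipy's F test per class with
Bonferroni multiplication by the number of classes tested; populations with
fewer than two strains are excluded with a warning; all-identical counts
give F = 0, p = 1, and zero within-group variance with differing means
gives F = inf, p = 0.

## Intron calling

For each host gene the caller walks the insertion sites left to right,
maintaining a cursor at the genome position of the current CDS coordinate
(initially anchored by local alignment of the first site's 5' flank,
searched on both strands and across contigs). At each site, absence is a
*fixed-position* test — the next inter-site exon piece must match
immediately at the cursor — and presence is a windowed search for where
exon sequence resumes (window `max_intron_len`, default 5000 bp), with the
intervening distance > `min_intron_len` (50 bp) calling presence, <= 10 bp
slack calling absence, and intermediate distances flagged atypical. Flank
pieces are truncated at the neighboring site so they never span another
insertion point; the two site pairs closer than 20 bp (cox1 709/720 and cob
415/429) are resolved jointly: the next strong anchor is located first and
the short inter-site piece is then tested at the two fixed positions its
presence hypotheses allow. Fixed-position tests avoid the spurious-match
problem that plagues searching an 11-14 bp probe in an AT-rich window.
Default `min_flank_identity` is 0.90 with 40 bp reference flanks, tolerant
of the few-percent exon divergence between populations. Unanchorable sites
are reported missing, so partial contigs yield partial rows rather than
errors.

## Diversity statistics

Per-column π uses allele-frequency summation with the unbiased n/(n-1)
factor, which makes it identical to the mean pairwise difference per
usable site (the property the test oracle checks to 1e-12). In
`with_indels` mode a gap is a fifth allele state, so a k-bp indel
contributes k polymorphic columns; this is the mode in which
indel-inclusive intergenic diversity greatly exceeds the indel-free value,
reproducing the qualitative signature of mobile-element-driven intergenic
variation. N is always dropped; columns with fewer than two usable
characters are skipped and excluded from region means. Window scans tile
alignment columns (window 100, step 50), including a flagged partial final
window.

pN/pS is Nei-Gojobori: expected synonymous/nonsynonymous site counts per
codon (changes to stops counted nonsynonymous) averaged over sequences;
observed changes per polymorphic codon classified by averaging over minimal
mutational paths, excluding paths through stop codons unless all paths are
blocked. With more than two distinct codons in a column, pairwise path
classifications over distinct codon pairs are averaged and rescaled so the
total equals the parsimony minimum number of changes; for two codons this
reduces exactly to the standard pairwise computation, which an exhaustive
enumeration oracle verifies. Codons containing gaps or N are dropped for
that sequence only. The ratio is reported as undefined (None/NaN) when
Sd = 0, never as infinity.

Pairwise indel accounting chains k-mers (k = 20) unique in both genomes,
takes the longest colinear subsequence, prunes overlaps, and aligns the
inter-anchor segments globally (match +1, mismatch -1, gap open -4, extend
-1); each maximal gap run is one event. Planted events are recovered
exactly when separated by at least 2k; very close events can merge, and
duplicated sequence (non-unique k-mers) locally removes anchors.

## Phylogeny

p-distance (differing / shared usable sites; gaps dropped pairwise by
default, a Jukes-Cantor corrector is provided but at <7 % divergence it is
nearly the identity). Neighbor joining is the standard Saitou-Nei
agglomeration with the Q criterion; ties are broken toward the lowest
taxon-index pair so trees are reproducible, and negative branch lengths are
clamped to zero with the deficit moved to the sister branch (the final
trifurcation clamps only). On additive matrices the algorithm is exact in
topology and path lengths, which the test suite verifies on 200 random
trees and cross-checks topologically against an independent implementation.
Population-level concordance is summarized by `population_rf`: 0 iff every
population is monophyletic (as an unrooted bipartition) and the induced
population topology matches the planted tree; otherwise the induced RF
plus 2 per non-monophyletic population.

## Assembly QC

End overlaps are computed for all suffix/prefix lengths at once by FFT
cross-correlation of one-hot base channels (N never matches); among lengths
>= 360 bp meeting 80 % ungapped identity, the one maximizing (matches,
identity) is reported — preferring that over the literal longest avoids
extending an exact overlap by lucky random matches. The circularity check
is the same computation of a sequence against itself capped at half its
length. The qPCR enrichment ratio is fixed as
2^(CTnuc − CTmt) x (size_nuc / size_mt); the phrase it operationalizes is
arithmetically ambiguous in the literature, so this documented convention
is a deliberate design choice.

## Problem sizes and determinism

The default test suite runs planted-truth recovery at 4 populations x 10
strains of ~80 kb (one seed, about half a minute) plus property checks at
the scales stated in their docstrings; `scripts/acceptance.py` re-runs the
same study size from scratch for any `--seed`. All randomness in library
code flows through explicitly passed numpy Generators or seeds; there is no
hidden global RNG state, and pipeline reruns with the same configuration
and seed produce byte-identical tables.

## Known limitations

- Class-level GC results are defined relative to the configured consensus
  table; with the synthetic placeholder consensi, absolute counts are not
  comparable to published per-class tables.
- The intron caller assumes colinear exons and intron lengths under
  `max_intron_len`; nested or rearranged structures are out of scope.
- `pairwise_indels` reports alignment-level gap runs, not parsimonious
  event histories; adjacent events closer than the anchor spacing merge.
- ANOVA assumes (approximately) normal within-population counts; for the
  small overdispersed counts of real data the F test is a screening tool,
  as it is used here.
- The binary-character intron tree resolves populations only when
  within-population intron polymorphism is low relative to
  between-population signature differences (see the generator section);
  this is a property of the data regime, not of the tree method.
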