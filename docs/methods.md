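# Methods

This note documents the models and procedures implemented in
`ltrcensus`, the defaults they run under, and the boundaries of what the
synthetic benchmark can and cannot show.

## Structural detection

Candidate elements are pairs of direct repeats. The detector builds the
set of exact `k`-mer matches (`seed_k = 20`) between positions of one
contig whose spacing falls inside the inter-LTR distance window, chains
seeds that share a diagonal within `max_band` (50 bp, which tolerates
small indels between the two LTR copies) and are near-contiguous along
the contig, and treats each maximal chain as a repeat pair. The two
repeat copies are then aligned globally (bit-parallel edit distance,
gap columns counted as mismatch) for the identity call. Bounds applied
to every candidate: each LTR in [80, 1500] bp, start-to-start distance
in [2500, 11000] bp, identity ≥ 80%. The distance is start-to-start by
default; an end-to-start mode is available (`distance_mode`) because the
convention is ambiguous in common usage.

Only direct orientation is searched: LTRs are oriented direct repeats,
and a reverse-complemented element still presents direct repeats, so
strand is deliberately left to the translated-search stage.

Overlapping candidates are resolved by maximum-weight interval
scheduling with weight = total matched repeat length × identity. This
matters when two copies of one family insert within 11 kb of each
other: the LTRs of *different* copies then also form in-window repeat
pairs, and a greedy best-first rule can discard both true elements in
favour of the spurious bridging pair. The exact dynamic program keeps
the two true elements because their combined weight is larger. With
this rule, recall of unmutated full-length plants is exact (100% with
coordinate-exact spans) on 5 Mb simulations.

## Scoring, calibration and E-values

Nucleotide searches use +2/−3 with affine gap costs 5/2; protein
searches use BLOSUM62 with 11/1 (the defaults of BLAST-family tools,
which the census thresholds implicitly assume). For each scheme, lambda
is the unique positive root of Σᵢⱼ pᵢpⱼ e^(λ·sᵢⱼ) = 1 (Brent's method,
residual < 1e-9; backgrounds are uniform ACGT and Robinson–Robinson
amino-acid frequencies). K uses the first-order approximation
K = H/λ, with H the relative entropy of the induced aligned-pair
distribution. This reproduces the right magnitude (0.50 vs the exact
0.46 for +1/−1 uniform ACGT) and is adequate because the pipeline uses
E-values as deterministic monotone thresholds (1e-5, 1e-10, 1e-40,
1e-70), not as calibrated tail probabilities. Gapped scores are plugged
into the ungapped formula for the same reason. The local aligner is
Biopython's `PairwiseAligner` (C backend) configured for affine-gap
local alignment; tests verify exact score agreement against an
independent naive Gotoh dynamic program on hundreds of random pairs.

Database length `n` in E = K·m·n·e^(−λS) is the total residue count of
the subject set, in the alphabet of the alignment (nucleotide lengths
divided by three in translated modes).

## The 80-80-80 comparator

`passes_80_80_80(a, b)` maps the shorter sequence into the longer by
infix alignment and requires identity ≥ 80% over aligned columns (gaps
count against identity), ≥ 80 aligned bp, and the aligned region to
cover ≥ 80% of *each* sequence. Both the within-cluster check ("at
least 80%") and the merge rule ("more than 80%") use ≥ 80.0 — one
consistent comparator, boundary-tested. Cluster merging compares
longest-member representatives by default (an any-member mode exists);
the merge relation is closed transitively via union-find, so merging is
idempotent and order-independent.

Curation removes, for each copy, alignment columns occupied by that
copy alone in runs strictly longer than 20 bp (runs of ≤ 20 bp are
kept). Cluster families also carry a majority consensus of the cluster
alignment, used as the sequence for domain extraction: individual
copies of decayed elements routinely carry private stop codons and
frameshifts, and the consensus reconstructs a clean element the way
manual curation of a family alignment would. The longest member remains
the representative for length and naming semantics
(`<Superfamily>-<n>_<SpeciesCode>`).

Orphans (copies joining no cluster) become one-member families only if
the best translated panel hit covers an open frame — no stop codon
inside the hit envelope — of at least `min_domain_aa` (100) residues.
This filter is strict for orphans but relaxed for cluster families at
domain-extraction time (below), mirroring the asymmetry that single
unconfirmed copies are treated conservatively.

## Genome annotation

The scan library holds cluster-derived families from *all* species;
orphan families are excluded from scanning (their single copies may
contain unrecognised insertions) but participate in assignment. The
scanner is the same seed-and-chain engine (k = 13, both strands) with
per-chain identity from global alignment of the chained segments; hits
with divergence > 20% (100 − percent identity, no substitution-model
correction) are dropped. Defragmentation merges same-superfamily,
same-strand fragments whose gap is strictly less than 500 bp — the
boundary case at exactly 500 bp stays split — and the merged copy spans
the intervening sequence. Assignment takes the best family at
E ≤ 1e-10; a best family from another species flags the copy as a
cross-species candidate, and candidates passing the translatable-domain
filter are clustered into new `annotation_derived` families, after
which all copies are re-assigned against the augmented library. Copies
with no qualifying hit form the discarded extra set.

Genomic proportions are unions of copy intervals per group over the
genome length, so overlapping copies are never double-counted.

## Phylogeny and clade definition

Domains are the translated envelopes of the best panel hit on the
family sequence. Frameshift-corrupted domains are spliced: qualifying
hits from other frames on the same strand and panel subject are chained
in subject order and concatenated with overlap trimming, giving one
chimeric protein. Isolated stop codons (decay substitutions) are
excised the same way, capped at 5% of the domain; beyond that the
family is excluded with a logged reason.

Alignment is delegated to the `mafft` executable (`--auto`): it is the
field-standard aligner, already required by the workflow's provenance,
and writing a progressive aligner in-package would add an inferior
duplicate. Distances use pairwise deletion (per pair, only columns
where either row is gapped are skipped; complete deletion is
available). The default model is a gamma-corrected proportion of
differences, d = α((1−p)^(−1/α) − 1) with shape α = 1.0 — the standard
correction for among-site rate variation; the shape is a convention
here, not an estimate, and a plain p-distance mode exists for oracle
tests. Saturated pairs are capped at p = 0.95.

Neighbor joining follows the standard Q-criterion with two deterministic
conventions: ties in Q break by the lexicographically smallest pair of
subtree labels, and negative limb lengths are clamped to zero with the
length moved to the sibling (distances reduced from non-additive input
can also go negative and are clamped). On additive matrices the
implementation recovers topology and branch lengths exactly (tested on
100 random trees, and cross-checked topologically against scikit-bio's
independent implementation). Bootstrap support is the percentage of 100
column-resampled replicates whose NJ tree contains the same bipartition;
supports attach to bipartitions, not node labels, for unrooted
correctness. A replicate in which some pair loses all shared columns is
skipped (counted as non-support).

Clade definition operates on bipartition sides. A side qualifies when
its support exceeds 70 (or it is named in an explicit override list —
the escape hatch for manually accepted low-support groups) and its
non-reference leaves span ≥ 2 species. When labelled reference leaves
are present in the tree (the normal pipeline case), the clade for label
c is the largest qualifying side containing all of c's references and
none of any other clade's; reference-free qualifying sides become novel
clades, largest first among disjoint ones. Without references, the
smaller side of each qualifying edge is the candidate and maximal
disjoint groups are kept. A qualifying side that contains two or more
whole clade calls names a lineage, recorded on each member call.
Important consequence: a tree containing a single clade and no
outgroup cannot delimit that clade — per-superfamily trees should
include references from at least two clades of the superfamily.

## Similarity-route assignment and mining

The five-best-hit rule assigns a domain to a clade when the five best
hits against the classified database all carry one clade label and the
best other-clade E-value is at least ten orders of magnitude weaker
than the best same-clade E-value (vacuously satisfied when no other
clade hits at all). Two implementation choices matter. First, hits
enter the rule only at E ≤ 1e-10 — the same stringency as family
assignment; with a permissive floor, near-noise hits from a single
clade can satisfy both clauses vacuously and the measured
false-assignment rate on clade-less queries rises above 5%. Second, the
gap is a magnitude (log10) gap by default. The literal arithmetic
difference is implemented and selectable (`gap_mode="arithmetic"`, and
the mode is echoed in output metadata), but for homologous domains the
arithmetic reading collapses to "no other clade hit stronger than
1e-10" and leaves about half of genuinely clade-typical queries
unassigned on the synthetic benchmark; the magnitude reading restores
the rule's evident intent. Measured behaviour under the defaults:
200/200 agreement with the tree route, 0/30 false assignments when the
query's clade is withheld from the database.

External collections are mined by translated search with E ≤ 1e-70 and
query cover > 80%, relaxed to 1e-40 and > 50% for Copia queries (the
scarcer superfamily). Hit envelopes are extracted as amino-acid
sequences, clustered with the family comparator, and the largest
sequence represents each mined family. Overlapping fragments of one
family can be merged into a chimeric element when they overlap by
≥ 20 aa at ≥ 90% identity; disagreements resolve by majority with ties
to the earliest fragment, and non-tiling fragments raise an error that
names the gap.

## Synthetic genomes and what they show

The generator builds, per superfamily, an ancestral element (random LTR,
random stop-free RT/RNaseH coding stretch, random internal sequence);
clade ancestors diverge from it at `clade_divergence` substitutions per
site and families from their clade ancestor at `family_divergence`,
with coding-region substitutions redrawn when they would create an
in-frame stop. The RT/RNaseH stretch sits early in the internal region
for Copia and late for Gypsy/BEL-Pao, reflecting the superfamilies'
integrase placement. Defaults: 300 bp LTRs, 4200 bp internal regions
(start-to-start distance 4500 bp, mid-window), 300-residue domains.
The labelled reference panel carries 3 entries per clade at 10%
divergence from the clade ancestor.

Plants are inserted into i.i.d. uniform-ACGT background contigs
(GC configurable) with ≥ 2 kb spacing; per copy, the generator draws a
state — full, solo LTR, truncated (a uniform 20–80% fraction removed
from a random end, which always destroys one LTR), or nested (a full
copy of another family inserted mid-internal) — applies i.i.d.
substitutions and geometric-length indels, and reverse-complements with
probability 0.5. One background base on each side of a full plant is
set to differ from the corresponding element-internal base so that the
maximal exact repeat ends exactly at the planted LTR boundary; without
this, chance flank matches extend the repeat by a base or two and
coordinate-exact recall is unattainable by any detector. Genome length
equals background plus planted lengths, every record's span reproduces
the mutated copy exactly, and identical seeds give byte-identical
output.

Benchmark conditions used by the tests and the acceptance script:
detection on 5 Mb with 3 superfamilies × 3 families × 10 unmutated
copies; family recovery with within-family copy divergence ≈ 8%
(sub_rate 0.04 per copy) and between-family divergence ≥ 25% over
5 seeds; clade recovery at clade divergence 0.3 and family divergence
0.10 with 2 host species; the annotation-gain scenario plants half the
families only as truncated copies in one species and intact in another.
Problem sizes (hundreds of kb to a few Mb, tens of families) are chosen
so the full suite runs in minutes; the pipeline is linear in genome
size through the seed index, so the sizes affect runtime, not the
logic exercised.

What passing these tests does *not* show: the background model is
neutral (uniform i.i.d.), so nothing is claimed about detection
specificity in repeat-rich or GC-skewed real genomes; divergence is
homogeneous per copy, unlike the age structure of real element
families; tandem-repeat masking is a simple period-scan stand-in and is
not claimed to match dedicated tools; and the published mollusc counts
are verified only as internal arithmetic of the packaged transcription,
not recomputed from the nine assemblies.

## Known limitations

- Solo LTRs and target-site duplications are not called structurally;
  solo LTRs are recovered only through the library scan.
- The gamma shape (1.0) and the JTT-style correction are conventions;
  no model selection is performed and no maximum-likelihood tree is
  built.
- Karlin–Altschul K is approximate (see above); absolute E-values are
  comparable within this package but not to BLAST output.
- The similarity rule requires at least five classified references per
  clade to be able to assign at all; sparser databases leave families
  in "other".
- Cross-species family recognition in annotation requires the two
  species' copies to sit within the 20% scan divergence; families
  beyond that are genuinely invisible to the scan, as in the original
  workflow.
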