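# Methods

This note records the models implemented in `crac_atlas`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Coordinates and orientation

All internal coordinates are 0-based half-open on the genome; GTF conversion
(1-based inclusive) happens only at the file boundary. Every per-transcript
computation (metagene bins, pA flanks, motif offsets, junction coordinates)
is done 5′→3′ in transcript orientation; minus-strand windows are extracted
and reversed, and motifs are given in DNA sense (U→T).

## Synthetic CRAC libraries

The generator emulates the statistical structure of a crosslinking library,
not yeast sequence content.

**Genome and annotation.** Two 50 kb contigs of i.i.d. sequence at GC = 0.40,
carrying ~60 non-overlapping transcripts: 26 mRNAs (500–1500 nt, three with
one 80–200 nt intron), 8 CUTs, 8 SUTs, 4 XUTs, 5 snoRNAs, 3 snRNAs, 6 tRNAs.
mRNAs and SUTs get planted 3′-end signals: an A/T-biased stretch over the
80 nt upstream of the major poly(A) site, a UAUAUA efficiency element 36–70 nt
upstream, an AAUAAA positioning element 10–25 nt upstream in half of genes,
an adenosine as the last encoded base, and non-A bases immediately downstream
of the cleavage point. Half of these genes also carry a minor pA site
25–60 nt upstream at 20% usage. CUTs and XUTs carry no cleavage signals —
that asymmetry is what drives the class contrasts the downstream analyses
detect. All placement and sequence choices come from one `numpy` generator
seeded by `GenomeSpec.seed`, so equal seeds give byte-identical FASTA/GTF.

**Binding models.** A `ProteinBindingModel` mixes five positional archetypes
(5′ peak, 3′ peak, uniform body, motif-anchored, promoter-proximal ≤400 nt),
optionally per transcript class; presets named after the factors they imitate
(cbc1, mtr4, nab2, pab1, mex67, xrn1, ski2, hrp1, hek2) encode the expected
biology, e.g. the pab1 preset peaks at mRNA/SUT cleavage sites but binds
CUTs diffusely. Transcripts are drawn with probability ∝ class weight ×
length; fragment lengths are uniform 20–45 nt (short RNase footprints);
crosslink deletions are planted with probability `deletion_prob` (default
0.15; 0.3 for the motif-anchored preset, inside the motif), at least 2 nt
from the fragment 5′ end and 5 nt from the 3′ end so a single-deletion
alignment is unambiguous.

**Tails.** Three regimes per transcript class: oligo(A) 4–5 nt (TRAMP-like
surveillance marks), deadenylated 10–12 nt, and long poly(A) with geometric
length of mean 40 nt. For a 3′-peaked factor, tailed fragments end exactly at
a sampled pA site; otherwise at the archetype-chosen position. One
identifiability constraint is imposed: a tail is only attached where the next
two encoded bases are not A (the end is nudged by up to 10 nt). Without it a
templated adenosine is indistinguishable from a tail adenosine — the same
ambiguity any alignment-extension pipeline has — and ground truth would be
ill-defined at exactly the positions being scored.

**Read structure.** read = 5 nt barcode + random 3 nt tag + insert + tail +
3′ adaptor, truncated at 54 nt (a short-read sequencer); constant quality
(Q40). This truncation produces the intended censoring: tails longer than
~15–20 nt lose their adaptor and drop out of the mapped-tail census, which is
why the raw-read terminal-A census (30–35 nt reads, no mapping requirement)
exists as a complement. PCR duplication draws family sizes from a geometric
law (memoryless amplification); family tags are re-drawn on (tag, 5′
coordinate) collision so families remain distinguishable — with 64 tags and
thousands of distinct 5′ positions this changes almost nothing but makes
duplicate-collapse scoring exact. Sequencing error is off by default
(optional uniform substitution rate).

**Not emulated:** real yeast sequence composition and gene structure,
ligation bias, quality-score structure, RNase sequence preferences, and
reverse-transcription artifacts other than the crosslink deletion. Passing
tests therefore demonstrate correctness of the analysis logic under the
stated generative assumptions, not performance on real libraries.

## Preprocessing and duplicate collapse

Reads failing Q20 at any position are dropped (operationalizing "high
quality throughout"); reads whose modal base exceeds 90% are dropped as
homopolymer artifacts. After demultiplexing on the 5 nt barcode (validated
prefix-free) and removal of the random 3 nt tag, the 3′ adaptor is clipped:
a full match anywhere, or a terminal prefix. Only a terminal overlap of
≥6 nt counts as a confident detection (`adaptor_found`); shorter terminal
prefixes are still clipped — they are overwhelmingly adaptor remnants from
read-length truncation, and leaving them attached lets chance matches extend
alignments one or two bases past the true fragment end. Tail and motif
analyses use only `adaptor_found` reads, since only there has the true 3′
end been observed.

Duplicates are collapsed twice, as the linker design permits: identical
(tag, sequence) pairs before mapping, then authoritatively after mapping on
(sample, tag, strand-aware 5′ coordinate), keeping the longest member (ties:
lexicographically smallest sequence, then id — total order, so the collapse
is deterministic and order-invariant).

## Alignment

A deliberately narrow seed-and-extend aligner for the toy genome: exact
12-mer seeds at read offsets 0 and 13, plus a gapped-prefix rescue (the seed
with one base re-inserted) so a crosslink deletion anywhere is still seeded.
Extension is anchored at the read 5′ end, scored +1/−2/−3 for
match/mismatch/deletion with ≤2 mismatches and at most one single-nucleotide
deletion, placed at the first ungapped mismatch (where a true crosslink
deletion must sit). The best-scoring read prefix is the alignment; the
unaligned 3′ suffix is the candidate non-encoded tail. Ties between distinct
loci are discarded as ambiguous rather than placed randomly — deterministic
output was preferred over sensitivity. Alignments shorter than 18 nt are
unmapped. SAM round-trip (pysam) encodes deletions as CIGAR `D`, tails as 3′
soft clips (reference-left for minus-strand records), and the tag/sample/
adaptor flags as `XT`/`XS`/`XF`; real aligner output can be imported the
same way.

## Hit tables, normalization, profiles

A hit is a deduplicated mapped read. Hit tables count a read toward every
same-strand feature overlapped by ≥1 nt, with mRNA spans extended 50 nt
5′ / 300 nt 3′ (truncated at same-strand neighbours) to catch misannotated
ends. Hits per million use either the full Pol II set
(mRNA+CUT+SUT+snRNA+snoRNA) or the mRNA+CUT+SUT denominator used for
clustering. Class breakdowns instead assign each read once by precedence
(rRNA > tRNA > snoRNA > snRNA > mRNA > CUT > SUT > XUT > intergenic) so
proportions partition the library. Replicate agreement is Spearman's ρ over
features with ≥1 hit in both tables.

Metagene profiles use 120 bins: 10 per 100 nt flank and 100 across the body.
Per-nucleotide hits are summed into bins by `floor(i·100/L)` and divided by
the exact bin length L/100, each transcript's 120 densities are scaled to
sum to 100, and transcripts are averaged unweighted, so every transcript
contributes equally regardless of expression. Transcripts shorter than
100 nt (sub-nucleotide bins) and transcripts whose flank leaves the contig
are skipped. Profiles run over the unspliced genomic span; the toy
annotation, like the yeast transcriptome, is almost entirely intronless, and
splicing-stage analysis has its own junction-library route. Heatmaps are
TSS-aligned, length-sorted and per-row max-scaled (all-zero rows stay zero).
Anchored averages optionally flatten overlapping reads into maximal
single-weight contigs first, removing abundance bias.

## Splicing stage

Per intron-containing gene, a spliced and an unspliced template are built
and reads are mapped against both with the same aligner. A read spanning an
EE junction cannot map contiguously to the unspliced template and vice
versa, while purely exonic reads map equally well to both and are discarded
by the ambiguity rule — so only junction-informative reads survive. A read
spans a junction if it covers ≥3 nt on each side (the original overhang is
unpublished; 3 nt excludes 1–2 nt terminal overlaps that map ambiguously).
EE/IE with IE = 0 is reported as an infinite sentinel with counts, never
silently; zero junction reads give an explicit "undefined" status.

## Tails and poly(A) sites

The tail classifier is a pure function of the clipped string: accepted iff
it contains ≥2 As and strictly fewer than len/5 non-A residues (the literal
reading of "fewer than one in five"). Tail spectra are reported per length,
optionally relative to 2 nt tails. pA sites are the last encoded nucleotide
of accepted A-tailed reads after two exclusions: genome-encoded portions
with <8 nonmodal nucleotides (A-rich mismapping guard) and reads whose 5′
end lies within 200 nt downstream of the assigned gene's TSS (upstream
transcripts). The filters examine independent read properties, so their
order is immaterial. The major site per gene is the most frequent
coordinate; ties break to the 3′-most (distal sites define mature ends;
configurable). Flank analyses report per-position base frequencies (each
position sums to 1) and per-offset motif occurrence fractions.

## Motif statistics

k-mer Z scores compare observed counts over genome-encoded read sequences
(adaptor-confirmed, ≥7 nonmodal nucleotides) with a null that re-places each
read uniformly within its source transcript, re-counted per randomization
(default 100; the published randomization internals are unavailable, so this
is the package's own operationalization of a composition-aware null).
σ = 0 with obs = μ gives Z = 0, σ = 0 otherwise an infinite sentinel. The
implementation is validated against an exhaustive enumeration of every
placement on a tiny instance. Binding sites are maximal overlapping-read
runs with ≥5 deduplicated reads; "3′-terminal" means the site midpoint falls
in the last quarter of the transcript span + 300 nt flank (both thresholds
configurable — the notion of "binding site" is this package's definition).
The (CNN)_n census reports, per class, the distribution of the longest run
of cytosines spaced 3 apart in transcript orientation.

## Peak-sharpness score and clustering

For each transcript the poly(A)-binding coverage peak is divided by the mean
over 100 randomizations of the maximum coverage when every read overlapping
the 400 nt window centred on the peak is re-placed uniformly within it; the
mean (rather than a single draw) was chosen because the singular "the
maximum when placed randomly" is ambiguous and the mean is stable. Raw
ratios are min–max scaled to [0,1] across the analysis set (all-equal ratios
map to 0). Windows truncate at transcript edges.

RNP profiles take six protein channels (hpm, mRNA+CUT+SUT denominator),
keep transcripts with ≥50 hpm in ≥2 of the datasets and replicate Spearman
ρ ≥ 0.37 between the first two replicates (additional replicates join only
the averaging), average replicates, and scale each gene to Σᵢ² = 1 — making
profiles invariant to expression level. The peak score is appended on its
own [0,1] scale rather than entering the Σᵢ² normalization.

k-medians assigns points to the nearest centroid in Euclidean distance and
updates centroids to coordinate-wise medians, best of 20 seeded restarts
(initial centroids drawn without replacement from the distinct profiles).
The coordinate-wise median minimizes an L1 objective, not the Euclidean one,
so a median update can in principle worsen the Euclidean objective; the
update is therefore accepted only when it does not increase it, otherwise
the previous state is kept and iteration stops. The recorded objective
history is consequently non-increasing by construction, and empty clusters
are reseeded from the point farthest from its centroid.

The three-archetype profile simulation used for recovery experiments
(surveillance-bound lncRNA-like: high Mtr4, low Mex67, low peak score;
exported mRNA-like: high Mex67/Xrn1/Ski2, high peak score; intermediate)
multiplies class templates by log-normal noise (σ = 0.35 per channel,
moderate replicate-level scatter) before unit-norm scaling, with Beta-
distributed peak scores.

## Problem sizes and determinism

Library simulations in the test suite and acceptance script use 2,000–20,000
fragments on the 100 kb toy genome — enough for ≥20× coverage at poly(A)
sites and stable profiles while keeping any single check within minutes on
one CPU. The pipeline fans one global seed out to per-stage seeds through a
SHA-256 hash (always < 2³¹), so reruns are byte-identical for deterministic
stages and no two stages share an RNG stream.

## Known limitations

* The aligner supports one deletion and no insertions; it is adequate for
  the generator's error model and the toy genome, not for real data (use SAM
  import).
* Deletion positions inside homopolymers are inherently ambiguous; the
  aligner reports the first consistent position.
* Tail detection is censored by read length; quantitative tail-length
  spectra above ~15 nt require the raw-read census, which cannot separate
  encoded from non-encoded As.
* The k-mer null conditions on the transcript assignment of each read; reads
  overlapping two features are assigned by class precedence.
* Metagene profiles use the unspliced span; for heavily intron-containing
  annotations the body bins would mix intronic and exonic signal.
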