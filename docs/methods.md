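# Methods

This note records the models, conventions and numerical choices behind
`insertmap`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not show.

## Read model and structure parsing

A junction read is modelled as
`adapter + barcode + UMI + payload_end + genomic flank`, where the flank
begins at the genomic base adjacent to the payload junction and extends in
the orientation of the insertion ('+' rightward, '−' leftward as reverse
complement). Reads may be sequenced in either orientation; parsing searches
the adapter in both and flips the read into structure orientation, so the
emitted fragment is always payload-first and the junction coordinate is the
fragment's position 0.

Element matching tolerances are edit-distance based: an element of length
`m` may mismatch up to `⌊f·m⌋` edits (default `f = 0.1`). The barcode is
matched against the catalogue at its expected offset with tolerance one
edit; two equidistant barcodes are rejected as ambiguous rather than
force-assigned. QC thresholds are mean Phred strictly above 10 and read
length strictly above 200 bp.

## UMI deduplication and consensus

Reads sharing a barcode are collapsed to molecules by greedy centroid
clustering, visited in order of descending mean quality (ties by read id
for determinism). A read joins the first cluster whose centroid UMI is
within one edit *and* whose centroid fragment has identity ≥ 0.9; otherwise
it founds a new cluster.

Sequence identity throughout the package is **containment identity**: the
shorter sequence is aligned infix into the longer and identity is
`1 − d/len(shorter)`. Junction fragments from one molecule share their
start coordinate but have broadly distributed lengths, so end-to-end
identity would split a single molecule's reads by length alone; containment
identity is invariant to that.

Cluster consensus is per-column plurality over members globally aligned to
the longest member, ties broken by summed base quality, plurality
deletions removed. This is a deterministic, dependency-free stand-in for
iterative polishing; an external polisher can be substituted behind the
same function contract.

## Alignment and the anchored/unanchored split

The default backend is an exact-seed matcher: 31-mers sampled every 50 bp
along the fragment (densely for the short-read preset) are looked up in a
sorted 2-bit-packed k-mer index of the reference; candidate loci are
verified by edlib infix alignment and accepted when the edit distance is at
most `0.15·len` (pipeline runs use the configured structure tolerance plus
0.05). A fragment with one accepted locus receives surrogate MAPQ 60;
several accepted loci give MAPQ 0 with the surplus counted as secondary
alignments. Primary/secondary records from an external long-read mapper can
be ingested from SAM instead; both routes satisfy the same contract.

A read is **anchored** iff mapped, without secondary alignments, with MAPQ
strictly above 30. The junction coordinate is the alignment start on '+'
and the alignment end on '−' (0-based, half-open intervals everywhere;
BED6 output matches natively).

## Peak calling and the beta-RSS shape filter

Candidate peaks are maximal connected unions of anchored alignment
intervals (gap 0 by default); candidate formation is deliberately the
minimal assumption, since genuine junction pileups are contiguous by
construction. For a candidate with coverage `c` over `L` positions, map
positions to midpoints `x_i = (i+0.5)/L`, rescale to a discrete density
`d_i = c_i·L/Σc` (so `Σd_i/L = 1`), and minimise

    RSS(α, β) = (1/L)·Σ_i (d_i − f(x_i; α, β))²

over the beta density `f`. The optimiser is a full grid over
α, β ∈ [0.1, 50] at step 0.1 — evaluated exactly via a rank-one log-space
factorisation that reduces the grid to two matrix products — followed by a
bounded Nelder–Mead polish that can only lower the RSS. The fit is defined
by its residual, so direct RSS minimisation (not moment or ML fitting) is
the statistic itself. Properties that make the printed threshold
meaningful:

* scale invariance: multiplying coverage by any constant leaves RSS
  unchanged, so depth does not enter the filter;
* uniform coverage is exactly Beta(1,1) with RSS 0; clean unimodal pileups
  score ≈ 0.01–0.05; two-mode mixtures score above 1 under this
  normalisation.

Coverage vectors longer than 512 positions are averaged into 512 equal
bins before fitting; the statistic depends only on profile shape, and the
bound keeps the grid cost flat. Degenerate candidates (span < 3 bp) bypass
the fit and are rejected.

A candidate becomes a call iff RSS < 1 (strict) and it is supported by at
least `min_call_dedup` distinct molecules (default 3). The molecule floor
is not part of the original filter cascade; it is the standard guard
against singleton artifacts and is what bounds the limit of detection in
the dilution study. The call coordinate is the modal member junction, ties
toward the smaller coordinate.

## Repetitive regions

Reads that cannot be anchored are processed family-wise: (1) reads whose
sequence aligns at ≥ 0.9 identity into ±2 kb of an already-called site are
discarded as belonging to that call; (2) the rest are classified to a
repeat family, either from an external profile-HMM hit table or by
containment identity against the family consensuses (threshold 0.75, ties
lexicographic); (3) each family's reads are identity-clustered (≥ 0.9,
longest-first greedy) to separate source loci; (4) a cluster is called iff
its molecule count reaches 50 % (inclusive) of the mean molecule count of
the anchored calls — molecule counts on both sides, since comparing raw
reads to deduplicated peaks would be incoherent — and its pileup on family
consensus coordinates passes the same beta-RSS filter. With no anchored
calls the `unanchored_min_dedup` floor (default 3) applies. All such peaks
are flagged *putative*: the family is identified, the genomic copy is
inherently not.

## Annotation and feature association

Repeat overlap uses a closed ±10 bp probe around the call site, expressed
half-open as `[site−10, site+11)` — exactly a 21-bp window; largest
overlap wins, ties lexicographic. Genomic features are labelled with
priority exon > promoter > intron > intergenic, promoter being 2 kb
upstream of the strand-aware transcription start.

Association with an interval track is the rank-based (Mann–Whitney) ROC
AUC of the number of track intervals within ±100 kb of each position,
insertion sites versus random genomic positions (10 000 by default,
uniform over contigs weighted by length, excluding positions within one
window of a contig edge so every probe is full width). Ties contribute ½.
The ±window reading of "within 100 kb surrounding" (a 200-kb span) is
configurable.

## Synthetic data: what it emulates, what it does not

The generator builds i.i.d. uniform A/C/G/T background (maximal
mappability contrast), plants repeat families as consensus copies with
independent per-base substitutions at the family divergence, and plants
insertion sites — a configurable fraction inside repeats — that exist only
in the truth set, as in real mapping where the reference lacks the
integrations. Junction reads follow the read structure with
Normal(mean, sd) flank lengths (resampled below 1 bp; truncated, not
discarded, at contig edges), per-base substitution/indel errors, constant
Phred qualities with optional jitter, and uniformly random emission
orientation. PCR duplication re-reads a molecule (same UMI and flank) with
independent errors.

Deliberately not modelled: homopolymer-conditioned nanopore error
profiles, basecalling, chimeras, coverage biases, and nested/fragmented
real repeat structure. Passing tests therefore demonstrate the logic and
the calibration of the statistics on idealised data, not performance on a
real flow cell; the alignment and consensus contracts are where production
backends (a long-read mapper, a polisher, a profile-HMM search) plug in.

The read-length study samples positions uniformly (positions and flank
directions depend only on seed and replicate, never on the length
setting, so lengths are compared at identical junctions) and applies
alignment and classification but no peak calling. The dilution study mixes
binomially sampled minor-sample reads into a major sample at fixed total
depth; its per-dilution RNG substreams are a documented contract
(`sample_dilution_counts`) so an independent sampling oracle can predict
the detection limit exactly.

## Problem sizes and defaults

Benchmark scales were chosen as the smallest that leave the measured
properties far from their thresholds: recovery runs use a ~2 Mb genome
with 50 insertions and 10 reads each; the length study 30 sites × 10
replicates per length on a 150-kb genome with a 10-copy 2-kb family; the
calibration analog 42 positive and 400 negative profiles; the dilution
series 600 reads across ratios 1:1 … 1:10⁴. Key defaults: UMI length
12 nt, UMI tolerance 1 edit, fragment identity 0.9, seed stride 50 bp,
alignment tolerance 0.15, RSS threshold 1, molecule floor 3, repeat window
±10 bp, association window ±100 kb, 10 000 random negatives. Every
threshold lives in `PipelineConfig` and is configurable; none is
hard-coded.

## Known limitations

* The exact-seed aligner requires an error-free 31-mer in a unique region;
  at raw nanopore error rates a production mapper should be used via the
  SAM route (consensus fragments after UMI collapse are much cleaner, which
  is what the built-in backend is sized for).
* The RSS normalisation is one concrete choice that makes the threshold
  1 dimensionless and scale-invariant; a pipeline using a different
  normalisation would need to recalibrate the threshold against labelled
  peaks (`evaluate_shape_threshold` exists for exactly that).
* Unanchored calling reports families, never copies; insertions in repeat
  families whose copies also flank called insertions can be absorbed by the
  discard step, which is conservative by design.
* 5′- and 3′-junction coordinate pairing is left to downstream analysis;
  the caller reports raw junction sides.
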