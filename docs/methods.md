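# Methods

This note records the model assumptions, parameter choices, numerical
conventions, and known limitations of the `mirnovel` pipeline, in the
package's own terms.  Thresholds named below are fields of
`mirnovel.types.Thresholds`; every default is the value used by the
reference rat-kidney discovery procedure, so a default run *is* that
procedure.

## Read model and preprocessing

Reads are collapsed to unique sequences with per-sample counts
(`CollapsedRead`); T and U are equivalent and stored as U.  Cleaning
drops reads containing any non-ACGU character and reads shorter than
`min_len = 17` nt, and truncates reads longer than `max_len = 26` nt at
the 3′ end (small-RNA inserts read 5′→3′ into the adapter, so excess
length is adapter-side sequence), re-collapsing afterwards.  Input is
assumed adapter-trimmed; qualities are never used.  Counts are conserved
up to the dropped reads, and cleaning is idempotent — both are tested
properties.

## Alignment contract

Mapping uses a 5′-anchored exact seed of `seed_len = 19` nt with at most
`max_mm = 1` mismatch over the full read (necessarily 3′ of the seed),
mirroring classic seed-and-extend short-read mapping and the premise
that miRNA 5′ ends are conserved.  The minus strand is searched through
the reverse complement; the same contract is applied to reference sets
and to the genome.  Reads shorter than the seed are skipped with a
warning — at the 17–18 nt margin this under-maps a small tail of the
length distribution, which we accept for contract uniformity.  The
implementation is a k-mer-indexed scan designed for desk-scale
references (≤ ~10 Mb); a brute-force Hamming scan is kept alongside as
the test oracle.

Routing applies the two discovery passes' hierarchy: the homologous pass
removes reads matching known miRNAs of the target species, then keeps
only reads matching known mature miRNAs of *other* species; the
species-specific pass keeps only reads matching no reference set (known
miRNAs plus the exclusion classes: e.g. rRNA/tRNA/piRNA/mRNA/repeats).
Buckets form an exhaustive, disjoint partition.  Multi-mapping reads
contribute to every locus (`max_hits` caps this if desired).

## Clusters and windows

Genome alignments merge into strand-aware read clusters by
single-linkage interval overlap (`max_gap = 0`: true overlap required,
since Dicer stacks overlap by construction; a positive gap is exposed
for exploration).  The predominant read — highest summed count, ties to
the longer then 5′-most read — defines the putative mature product and
its length.

Each cluster is tried under both arm hypotheses: as the hairpin's 5′ arm
(window extended 90 nt transcript-3′) and as its 3′ arm (extended 90 nt
transcript-5′), in both cases keeping 25 nt of context behind the
cluster (`BACK_MARGIN`), because the mature product starts up to ~20 nt
inside the precursor (lower stem plus the 5′-side processing offset).
Without that margin the lower stems of real precursors are cut off and
the screen fails on known-good loci.  When neither window passes, a
second pass at twice the flank covers long precursors.  Windows are
clipped (and flagged) at contig edges; minus-strand windows are
reverse-complemented before folding so window coordinates always read
5′→3′ along the transcript.

## Folding

Two energy models sit behind `fold()`:

* `thermo` — ViennaRNA's nearest-neighbor MFE model with default
  parameters (37 °C), used whenever the bindings are importable.  It is
  the model used for the published-precursor computations.
* `maxpair` — a deterministic maximum-weighted-pairing dynamic program
  (GC = 3, AU = 2, GU = 1, hairpin loop ≥ 3 nt; ties broken toward more
  pairs, then the 5′-most partner).  All downstream filters are
  pair-count and topology thresholds, so the pipeline remains functional
  without the thermodynamic engine; an exhaustive enumeration oracle
  checks the DP on short sequences.

**Forcing a hairpin.**  A raw window with genomic flanks almost never
folds into a single stem–loop — the flanks form side stems — so the
literal single-hairpin test would reject essentially everything,
including known precursors.  `crop_to_hairpin` therefore walks the
window structure's tree from the top-level component that overlaps the
read cluster, descending through multiloops toward the branch covering
the cluster, and crops the window (with 15 nt of unpaired padding) to
the first single stem–loop.  The pairing screen (≥ 19 pairs total,
≥ 11 touching the cluster region) then applies to that crop.  This is
the operational meaning of "forcing a hairpin" here: evaluate the
stem–loop component containing the evidence, not the whole window.

## Precursor trimming

The precursor starts at the first bulge 5′ of the 5′-arm product —
scanning outward from the mature 5′ end (or, for a 3′-arm mature, from
the partner of its innermost paired base), a bulge is the first position
unpaired on either strand — and ends at the structure-paired position
corresponding to that boundary.  When the scan reaches no bulge, the
duplex span is extended symmetrically to the 65-nt floor
(`min_precursor_len`); a found bulge is authoritative even when the
resulting precursor is shorter than 65 nt.  The trimmed precursor keeps
the *window's* structure restricted to its span (pairs crossing the
boundary dropped) rather than being refolded: refolding the excised
sequence in isolation was observed to shift the duplex register near the
terminal loop and misreport the overhang that the full-context structure
shows.

## Dicer-pattern criteria

Reads are realigned to the precursor by exact substring match (the full
cleaned pool, not only routed reads, so the star strand is recoverable
even when it matches no reference).  Arms are split at the terminal
loop; each arm's product is its predominant read; the mature is the
higher-count arm.

**Overhang convention.**  The 3′ overhang at a duplex end is the number
of 3′ nucleotides of one strand extending past the pair partner of the
other strand's 5′ terminus, read from the pair table.  Because helix
ends fray and small asymmetric loops shift naive per-position lookups,
the antiparallel register (the constant *i* + partner(*i*)) is anchored
at a *paired* 5′ terminus and projected to an end whose own terminus is
unpaired; the last resort is the nearest paired position within 2 nt,
corrected for the shift, and an end with no anchor at all is undefined
(the criterion then fails).  This convention reproduces the canonical
(2, 2) geometry for the packaged rno-mir-1839 fixture, where the mature
5′ terminus is frayed.  Its known limitation is the converse case:
when the MFE structure *over-pairs* through the loop-side cleavage site
(observed for the packaged rno-mir-509 precursor, whose star 5′ terminus
pairs bluntly with the mature 3′ terminus), the loop-end overhang
honestly measures 0 and the homolog-mode filter rejects the locus, even
though the reported geometry of that miRNA is a 2-nt overhang.  We keep
the honest measurement rather than special-casing it.

When the most expressed star read is an extension isomiR whose duplex is
not canonical, the highest-count star read showing the perfect overhang
is used for scoring (flagged `star_isomir_rescored`); both reads remain
in the pileup.

Start fluctuation is the maximum |5′ start − predominant 5′ start| over
same-arm reads of the pooled pileup, and must be < 2 nt ("less than 2"
is strict).  3′ heterogeneity is recorded as isomiRs but never filtered.
Homolog mode requires mature and mature\* with both overhangs in
[1, 4] nt; species-specific mode requires only the fluctuation
criterion, recording star and overhang as evidence flags.

## Consensus, expression, naming

Candidates at overlapping precursor intervals (same chromosome and
strand) merge into one locus whose consensus is the highest-pooled-count
candidate; a call needs detection (≥ 1 mature read) in ≥ 4 of the 8
sequencing samples.  Expression cutoffs follow the two published modes:
homolog calls need counts > 10 in ≥ 4 samples, or array rescue;
species-specific calls need counts ≥ 10 in every sample and intensity
≥ 32 in every array.  Calls whose arms match the known-miRNA set of the
target species — or, in the specific pass, whose mature aligns into an
exclusion-class sequence — are dropped: 5′-shifted isomiRs escape
read-level removal (their seed no longer matches the reference), and
without this call-level re-check known loci get re-reported as novel.
Calls classified homologous are likewise excluded from the specific
pass's output, which by definition reports candidates matching no known
miRNA.

Homology between an arm and a known mature uses a 5′-anchored 18-nt core
with ≤ 1 substitution and a 5′ offset of ≤ 1 nt, with the 3′ tail free —
the tolerance implied by the packaged divergent homolog pairs (a core
substitution with a divergent 4-nt 3′ tail; a 1-nt 5′ extension).
Homologous calls inherit the matched family number
(`rno-mir-<family>`, matures `rno-miR-<family>-5p/-3p`); species-specific
calls receive sequential indices from `next_free_index` (default 5001 —
real registry indices are assigned externally, so the package's are
arbitrary but deterministic).

## Array validation

The pipeline consumes an already-normalized probe × sample intensity
matrix (background subtraction, LOWESS and centering are vendor-side).
A probe is expressed in a sample at intensity ≥ 32 (`array_cutoff`).
Probe↔call linkage is by exact mature-sequence match when probe
sequences are supplied, else by name.  The group test is a two-sample
t-test on log2 intensities (zeros floored at ε = 0.01; Welch default,
pooled selectable).  No multiple-testing correction is applied — the
procedure reports a single uncorrected test per probe of interest.  The
published t-test for the treatment-responsive probe used an unspecified
gene-centering step, so its printed p-value is reproduced only
qualitatively (significant, direction up), not digit-for-digit.

## Synthetic benchmark

`plant_genome` plants hairpin loci in a uniform-random contig
(default one 1 Mb contig, mirroring desk scale).  A designed locus is a
random 20–24 nt mature, a star built as the reverse complement of the
mature minus its last two bases plus two free 3′ bases — fixing the 2-nt
3′ overhang at both duplex ends — softened by 1–3 interior G·U wobbles,
a 4–10 nt loop, an 8-bp lower stem behind a 1-nt bulge (the
precursor-boundary landmark), and 100-nt flanks.  Every designed locus
is **verified at construction** by running the pipeline's own
cluster→candidate stage and requiring a perfect-overhang pass;
non-conforming draws are rejected and redrawn, so the generator
guarantees the geometry it claims to plant.  Verbatim planting of real
precursor sequences redraws the flanks until the hairpin screen passes
for realistic isomiR-widened cluster extents (Dicer criteria are *not*
required, so precursors that honestly fail them can still be planted and
tested for that failure).

Read simulation draws per-locus, per-sample molecule counts from a
negative binomial (dispersion size 10, giving the ~1.5× between-sample
spread seen in deep-locus count tables) around a per-locus mean sampled
log-uniformly from [150, 3000]; the mature:star ratio defaults to 10:1.
5′ starts jitter by a discretized Normal(0, `fluct_sd` = 0.3) — shifts
of ±1 at ~5 %, |shift| ≥ 2 negligible, matching the "conserved 5′ end"
premise; 3′ ends jitter more (`isomir_rate` = 0.3, biased toward +1
extensions), and a flagged subset of loci puts 60 % of star mass on the
+1 3′-extension isomiR, emulating the star-extension regime seen in real
pileups.  Decoys are degradation regions (uniform read starts — these
fail the fluctuation criterion with probability → 1 as depth grows) and
shuffled-composition windows with stacked reads (these fail the hairpin
screen and array validation).  Planted known-miRNA and ncRNA loci
exercise routing.  Arrays are 3 control + 3 treated; expressed loci get
log-normal intensities around 200 (above the 32 cutoff with configurable
dropout), background probes stay below 32, and treatment-responsive loci
are scaled by `group_effect` in treated arrays.

What the benchmark does *not* emulate: sequencing error and quality
structure, multi-mapping repeat families, realistic genome composition
(GC structure, repeats), cross-hybridization on the array, and RNA
editing.  Passing tests therefore demonstrate the pipeline's logic under
the stated statistical structure, not performance on real libraries.

**Problem sizes.**  The reference benchmark used by the acceptance suite
is 10 seeds × (6 true + 6 decoy loci on 1 Mb, 8 samples); unit and
integration tests use 3–4 loci on 60–300 kb contigs.  These sizes were
chosen so the full suite exercises every stage end to end in about a
minute while keeping ≥ 60 planted-locus trials behind the recovery
property.

## Known limitations

* The loop-side overhang is only measurable insofar as the hairpin
  structure leaves the cleavage site unpaired (see rno-mir-509 above).
* One published precursor (rno-mir-1839, 64 nt) folds with 18 base pairs
  under current thermodynamic parameters, one short of the ≥ 19 screen;
  the screen passes it in genomic context (the windowed stem extends
  into pri-miRNA flank pairing) but the isolated printed sequence does
  not meet the floor.  The acceptance suite reports this honestly.
* Two of the packaged rat-specific mature sequences differ from their
  printed precursors at the 5′-most base (a discrepancy in the printed
  tables); exact-placement tests use the two consistent precursors.
* The aligner is a desk-scale scan, not an FM-index; whole mammalian
  genomes are out of scope.
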