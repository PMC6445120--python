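# Methods

## The event model

Two homozygous cultivar genomes are modelled as descendants of a common
ancestor separated by `divergence_time_years` (T_div). Differences between
the two assemblies are individual events, each of one category:

* **SNPs** — point substitutions derived in one lineage, placed uniformly
  outside event footprints. A per-site rate (`snp_rate`) sets the expected
  A–B divergence; the realised count is the rounded expectation, so small
  configured panels are exact.
* **Small indels** — 1 to `indel_max_len` bp, geometric length
  distribution, one lineage each.
* **LTR retrotransposon insertions** — an element (LTR + internal + LTR,
  LTRs starting TG and ending CA) inserts at a host site, duplicating the
  4–6 bp target sequence (TSD) on both sides. Shared elements (age ≥
  T_div) appear at the orthologous point in both descendants; a
  genome-specific insertion (age < T_div) leaves exactly one TSD copy and
  no intervening sequence in the non-carrier. Elements are instantiated
  per event from a consensus library and aged under the clock below.
* **Eliminations** — a shared element lost from lineage B, either
  *remnant* mode (both TSD copies survive around a <100-bp scrap of
  unrelated sequence — the remains of other transposition events, not of
  the eliminated element, which is what makes the no-similarity
  elimination test meaningful) or *replacement* mode (the whole site
  overwritten by unrelated sequence, no TSDs). The remnant fraction
  defaults to 0.66, matching the reported preponderance of short residues
  at eliminated sites.
* **N-gaps** — fixed-length runs masked in genome B at positions chosen to
  avoid every other event, so the pre-masking truth is recoverable and
  closure precision is well defined.
* **Telomeres** — terminal tandem arrays of TTTAGGG (reverse complement at
  the 5' end), 100–400 copies per end by default, identical in both
  descendants.

Every event is recorded in a `TruthSet` ledger with final (post-editing,
0-based half-open) coordinates plus the per-genome edit scripts in
ancestor coordinates; tests rebuild both descendants from the ledger with
an independent string-surgery path and require byte identity.

### Mutation clock

A single uniform substitution process (Jukes–Cantor-style, no rate
heterogeneity) at `substitution_rate` = 1.3 × 10⁻⁸ per site per year: each
LTR and the element body accumulate Poisson(r·t·L) substitutions
independently, so the expected raw LTR–LTR divergence is 2·r·t and
parameter-recovery checks stay closed-form. Shared elements evolve along
the tree: a common branch of length (age − T_div), then two independent
branches of length T_div, which makes within-genome LTR divergence date
the insertion while cross-genome element identity dates the split. The
terminal dinucleotides of each LTR are shielded from mutation so that
motif-based detectability is age-independent.

Two optional local processes extend the clock: a `te_proximal_snp_multiplier`
that scales the background SNP rate within `te_proximal_window` (500 bp) of
elements, and a `te_flank_divergence_rate` that adds A/B flank divergence
proportional to each element's age (expected 2·r·age per site), emulating
the elevated mutation load observed next to insertions. Both default off.

### Determinism and placement

All randomness flows from one seed through named per-category RNG streams
(ancestor, library, placement, elements, SNPs, indels, gaps, telomeres,
genes, depth), so changing the SNP rate never reshuffles element
placements. Events are placed uniformly with rejection sampling, excluding
10 kb at chromosome ends and enforcing `min_event_spacing` (20 kb default,
the flank-anchoring window) between events; over-dense configurations fail
loudly. TSD sites whose sequence begins with CA or ends with TG are
resampled: such sites make the element boundary formally ambiguous against
the TG…CA terminal motif, so the implanted coordinates would not be a
well-defined truth.

### Simulated depth

`simulate_depth` emulates mapping uniform reads from the *other* genome:
constant coverage (30× default) everywhere, zero over segments without a
counterpart (genome-specific element bodies, elimination replacements,
lineage-specific indel insertions, N-gaps). It reproduces the information
content of a cross-mapping depth track without simulating reads; no
sampling noise, GC bias, or mapping ambiguity is modelled, so depth-filter
behaviour under realistic noise is *not* established by these tests.

## Anchoring engine

All stages share one primitive: place a fragment on a genome. The engine
seeds with exact 15-mers from a sorted 2-bit numpy index (k-mers occurring
>400 times are skipped as repetitive), clusters seed hits by diagonal, and
verifies each candidate window with edlib in semi-global mode. A placement
reports coverage (fraction of the query in aligned match/mismatch columns)
and identity (matches over alignment columns); both thresholds default to
0.8, matching the coverage ≥80% criterion of the protocols that consume
them. `global_identity` is the Levenshtein form (max(|a|,|b|) − d) /
max(|a|,|b|): deterministic across co-optimal alignment paths, symmetric,
and invariant under joint reverse complement, which the matches-per-column
form of a single returned path is not. Substitution counting aligns
globally and excludes gap and N columns from both numerator and
denominator.

## Gap closure

Merged gaps (N-runs ≤500 bp apart, the merged span running from first run
start to last run end) are closed by the four criteria listed in the
README, evaluated in order with the first failure recorded. Decisions
where the protocol is underspecified: the 500-kb window is measured
between the inner edges of the two flank placements; "total alignment
positions of both fragments <5" is read as a sum (n₅ + n₃ < 5), with a
per-flank mode available; when several placement pairs satisfy criterion
i, the pair minimising the intervening span wins and exact ties fail as
ambiguous; the two corroboration routes of criterion iv are alternatives
(either suffices), and when neither a parity assembly nor a depth track is
supplied the criterion passes with an explicit `unchecked` flag rather
than silently failing every gap. Patches insert the donor sequence
verbatim (no polishing step). Gaps within 500 bp of a sequence end fail
with a reason code outside i–iv.

## SV validation and PAV detection

Candidate indels (strictly >100 bp) are validated by anchoring the two
500-bp flanks of the candidate window in the other genome and walking
base-by-base from each anchored flank to the divergence junction
(isolated mismatches stepped over; four consecutive mismatches terminate;
the junction is placed after the last ≥6-base solid match run, so chance
single-base matches beyond the true boundary do not inflate it). A
deletion is confirmed when the carrier-only run matches the candidate
length within ±20% or ±50 bp (whichever is larger), an insertion by the
mirror gap on the other genome; borders and length are recalculated from
the junctions. On implanted truth this recovers borders to ±2 bp.

The whole-genome comparison tiles each genome (250-bp tiles), anchors
every tile in the other genome, and keeps only placements on the best
collinear chain per chromosome (dynamic-programming chaining with a 10-kb
diagonal-shift bound) — the analogue of a filtered one-to-one whole-genome
alignment. The chaining step is essential: an insertion whose TE family
has copies elsewhere would otherwise "align" to another copy and never
surface as unaligned. Unaligned regions are merged across ≤50-bp breaks,
refined by the junction walk, split at N bases, required to exceed 100 bp
strictly, and kept as PAVs only when their mean cross-genome depth is
below 10% of the genome-wide mean (missing depth skips the filter and
flags every emitted PAV). PAVs on genome B are deletions, on genome A
insertions. Sharing classification is definitional: present in every
parity assembly and absent from the donor set; presence is decided by
anchoring the variant's context. Repeat-class annotation resolves
overlapping classes by the fixed precedence LTR > DNA > SINE > LINE >
Other ('Non' when nothing overlaps), with both breakpoints annotated for
inversions.

## LTR element detection and classification

The detector targets simulator-grade genomes, not repeat-dense real
chromosomes: repeated 21-mers within element-scale distance seed candidate
LTR pairs, clustered by diagonal; boundaries are then pinned exactly by
requiring the TG…CA motif at both ends of both LTRs, identical 4–6-bp TSD
copies immediately outside, length within [100, 7000] bp and LTR–LTR
identity ≥0.9. Among competing parses the alignment-style score
(match +1, mismatch/gap −2) decides: trimming a mismatch-dense LTR tail
loses score, and so does extending into flanking sequence, where even
optimally gapped unrelated DNA matches only ~55% of columns — a +1/−1
score would drift on exactly those extensions.

Classification anchors the element's outer 500-bp flanks, first in its own
genome, then in the other (unique placement, same orientation, within
20 kb — non-unique elements are discarded and counted per stage). The
intervening sequence at the orthologous site decides the class: >100 bp
with local similarity to the element ⇒ Shared, split at 99% global
identity into high/low; a single TSD copy with no intervening sequence
(≤10 bp jitter tolerated, since alignment edges are not base-exact in
principle) ⇒ Insertion; no local similarity with two or zero TSD copies ⇒
Elimination; anything else ⇒ Unknown. "Local similarity" is two shared
exact 16-mers on either strand — a stand-in for a low-stringency local
aligner, calibrated so unrelated multi-kilobase sequences essentially
never qualify while homologous copies at any divergence in range share
hundreds of intact 16-mers; no e-value analogue is reimplemented.

Dating uses the element's own two LTRs: K is the substitution fraction of
their global alignment and T = K/(2r), raw by default with Jukes–Cantor
correction available (undefined at K ≥ 0.75, signalled). K is Poisson
distributed with mean 2·r·L·T, so the age estimator carries an
irreducible noise floor RMSE = √(T̄/(2rL)) — about 19% of the mean age for
1-kb LTRs over ages 0.1–2 My. The recovery tests therefore check that the
estimator sits within 20% of that floor (efficiency) and that the
range-normalised NRMSE stays ≤15%; no estimator can beat the floor, and
mean-normalised relative error figures below ~19% are unattainable under
these conditions.

The CNS analyses measure substitution frequencies between orthologous A/B
sequence: sliding 400-bp windows (100-bp step) along the flanks out to
2 kb, ten equal bins across the element interior, a control distribution
from randomly placed 20-kb genome blocks anchored in the other genome
(3000 blocks at full scale; tests and the acceptance run use 10–40 blocks,
which already pins the control mean to ±0.003 at the simulated rates), the
V-rate formula evaluated exactly, insertion-site distances to genes in
100-bp bins against a uniform-random control, and mean flank CNS in
sliding 100,000-year windows of element age. The age-trend test regresses
flank divergence on ledger (true) ages: regressing on estimated ages is
attenuated ~25% by age-estimate noise (regression dilution), which is a
property of the estimator, not of the clock.

## Markers and co-segregation

A junction marker is a ≥20-base sequence spanning an insertion boundary:
carriers contain it contiguously, non-carriers only its two halves
separated by the element. Search tolerates a configurable number of
mismatches (pigeonhole-seeded, substitutions only; default 0 in assembly
mode, 1 suggested for read sets). In-silico PCR requires the forward
primer on the plus strand and the reverse primer's reverse complement
downstream within the product ceiling, scans both template orientations,
reports the outer span as the product length, and demands an exact 3'
terminal 3-mer on both primers (polymerase extension needs a paired 3'
end). Co-segregation is a 2×2 table of marker state against phenotype
over samples with known phenotype; concordance 1.0 sets the
perfect-association flag.

## Assembly QC

Telomere arrays are counted at each chromosome end within a 50-kb search
window (defaults: ≥100 copies, array reaching within 1 kb of the
terminus; up to 10% interrupting bases tolerated inside an array, with a
strict mode available). The search window and copy minimum are declared
defaults — the source protocol quantifies neither, only reporting arrays
of 294–1073 units. Heterochromatin blocks merge 1-Mb windows (250-kb
step) whose repeat coverage strictly exceeds 90%; a window at exactly 90%
does not qualify. Contig N50 is computed on gap-delimited segments, so
the statistic reflects the gap structure the per-chromosome table counts.
The published per-chromosome statistics of the two apple assemblies ship
as package data for reference tabulations (total telomere count
2·Both + Single, both-end chromosome count, maximum chromosome length).

## Problem sizes

The test suite and the acceptance script run on genome pairs of 0.3–5 Mb
with tens of implanted events per category — large enough that every
detection step works at realistic density (events ≥20 kb apart, multiple
TE families, telomere and gap structure present) while a full run of the
suite stays under two minutes and the acceptance script under one. The
published headline counts of the real assemblies (thousands of SVs and
intact elements on 700-Mb genomes) depend on the real data and are out of
scope here; what the synthetic conditions establish is correctness and
calibration of each computation, not those counts.

## Known limitations

* Both genomes are homozygous and collinear: no heterozygosity, no
  inversions or translocations in the simulator, so the inversion
  annotation path is exercised only on constructed inputs.
* The depth tracks are idealised (no sampling noise or mappability
  structure); PAV depth-filter behaviour under real read noise is
  untested.
* The LTR detector assumes intact terminal motifs and TSDs (the simulator
  preserves them); it is not a replacement for LTRharvest-class tools on
  real repeat landscapes.
* The anchoring engine's N handling treats N as never matching but does
  not split alignments at long N runs; gap-closure criterion iii makes
  this moot on the paths that matter.
* Elimination modes are two idealisations of an unobserved process; the
  simulator takes no position on which is biologically correct.
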