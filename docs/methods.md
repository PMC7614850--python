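# Methods

This document describes the generative model, the processing pipeline,
the evaluation metrics, and the numerical choices behind `cellosim`.
Default parameter values are stated with the reason they were chosen.
Nothing here is an empirical claim about real sequencing data; every
quantity named below is computed by the package from its own simulations.

## 1. Synthetic repeat families (`cellosim.reference`)

A repeat family is simulated forward from a single ancestral sequence:

1. **Ancestral sequence.** i.i.d. bases at a configurable GC content
   (default 0.5, a neutral composition). Default length 3,000 bp —
   long enough to carry several 2 kb read windows, short enough for
   desk-scale runtimes.
2. **Divergence.** Each copy receives substitutions at a per-site rate
   given by its milliDivergence (substitutions per 1,000 sites,
   0–750), drawn per copy either uniformly from a range or cycled from
   an explicit grid. Substituted bases always change (the realized
   divergence is re-measured and recorded in the annotation). An
   optional per-site indel rate adds single-base insertions/deletions.
   The default fixture cycles the grid {5, 20, 80, 200} mDiv so the
   family spans near-identical "young" copies through clearly
   distinguishable "old" copies.
3. **Placement.** Copies are planted at uniformly drawn, non-overlapping
   positions on a random background genome (default 300 kb), each on a
   uniformly random strand (minus-strand copies are inserted as the
   reverse complement). Rejection sampling enforces non-overlap; an
   impossible packing raises an error rather than degrading silently.

Annotations are 0-based half-open intervals (BED convention) carrying
element id, strand, subfamily label and realized milliDivergence; they
round-trip through FASTA/BED/TSV writers.

**Element age.** Observed divergence p (= milliDivergence / 1000) is
converted to an age estimate with the Jukes–Cantor correction
`d = -(3/4) ln(1 - 4p/3)` and `age = d / (2r)`, reported in millions of
years. The default substitution rate r = 2.2e-9 per site per year is a
standard mammalian neutral-rate figure; it is a display conversion only
and affects no simulation or grouping behaviour.

## 2. Read simulation (`cellosim.readsim`)

**Rolling windows.** cDNA molecules from an oligo-dT-primed long-read
protocol start at the transcript 3' end. The simulator mirrors this:
for each element, fixed-length windows (default 2,000 bp; 1/2/3 kb
studied) are anchored at the element's biological 3' end and stepped
5'-ward at a fixed stride (default 500 bp). Only windows fully inside
the element are emitted; a 3 kb element therefore yields three 2 kb
windows. Minus-strand elements mirror the construction.

**Molecules and UMIs.** Each (element, window) pair is one molecule,
tagged with a fresh UMI. The default UMI is 22 nt in the RYN pattern —
cycling purine (A/G), pyrimidine (C/T), any base — which bounds
homopolymer runs at two. Molecule UMIs within one simulated arm are
drawn until unique. Each molecule is emitted `coverage` times
(1x/5x/10x studied), emulating PCR duplicates with independent errors.

**Read layout.** Every read is `TSO + cDNA + UMI + barcode + dT-adapter`
(5'→3'). The adapter/barcode literals are fixed synthetic sequences
(27 nt TSO, 30 nt dT-side adapter, 16 nt barcode); any real oligo set
can be substituted through `AdapterLayout` / `AdapterConfig`. The
dT-side default is 30 nt because end-adapter detection by local
alignment needs enough aligned columns to stay above the score floor on
low-identity reads. Simulation truth (molecule id, source element and
interval, strand, true UMI) is encoded in the read name, so evaluation
needs no side files.

**Error model.** Two identity modes:

* `perfect` — the read is the template, constant Q40 quality.
* `ont` — a per-read alignment identity is drawn as
  `max_identity x Beta(a, b)`, with (a, b) set by method of moments so
  the draws have mean 92%, standard deviation 2.5%, and never exceed
  the 96% maximum (defaults; all three are configurable). The read is
  then corrupted by independent per-base events split
  substitution : insertion : deletion = 0.50 : 0.25 : 0.25 by default.
  The per-base event rate is solved from the drawn identity:
  with mix (ms, mi, md) the expected alignment identity of the
  corrupted read is `(1 - eps(ms+md)) / (1 + eps*mi)`, so
  `eps = (1 - t) / (ms + md + t*mi)` reproduces target t in
  expectation. This is a deliberately simple surrogate for trained
  nanopore error models: it matches the identity *moments* exactly but
  places errors uniformly, without k-mer or homopolymer context and
  without junk/chimeric artefact reads (see Limitations).

## 3. Preprocessing (`cellosim.preprocess`)

Mirrors the front half of a long-read consensus pipeline:

1. **Internal-adapter screen.** Adapters are locally aligned against the
   read interior (outside the two 250 bp end windows). If more than 20%
   of reads carry an internal adapter the library is treated as
   ligation-chimera-rich and affected reads are split at the internal
   hit; otherwise affected reads are dropped. Internal calls use a
   stricter score floor (75% of the adapter self-score vs 60% at the
   ends) because a kilobase-scale interior produces chance local hits
   at the laxer floor.
2. **Full-length filter.** A read is kept iff a TSO aligns at one end
   and the dT-side adapter at the other, in a consistent orientation
   (score ≥ 60% of self-score within 250 bp end windows, Smith–Waterman
   with match +1, mismatch −1, gap open −2, extend −1). Kept reads are
   re-oriented canonically (TSO first). Alignment spans are
   extrapolated to full-adapter spans so clipped local alignments do
   not shift downstream positional extraction.
3. **Demultiplexing.** The barcode segment (a small slack window before
   the dT call) is compared to the whitelist by infix Levenshtein
   distance; a read is assigned iff the minimum distance is ≤ 3 and
   uniquely attained.
4. **UMI extraction.** Positional: the 22 nt immediately 5' of the
   barcode, anchored on the called adapters; the cDNA is everything
   between the TSO and the UMI.

Every excluded read carries a reason code and `kept + excluded` always
equals the input count.

## 4. UMI grouping and consensus (`cellosim.umi`)

**Grouping.** Reads are clustered by single-linkage connected
components: two reads join when the Levenshtein distance between their
observed UMIs is ≤ the threshold (studied grid {2, 6, 10, 14}).
Duplicate UMI strings are collapsed before the quadratic pass, and
distances are computed with early abandoning at the threshold.
Pregrouping bounds the quadratic search: reads may be pre-partitioned
by truth blocks (100 distinct true UMIs per block, the studied design)
or by alignment target; pregroups are hard boundaries.

**Consensus ("corrected").** A group's sequences are collapsed by a
star multiple alignment anchored at the medoid (the member minimizing
summed edit distance to the rest): every other member is globally
aligned to the medoid, alignment columns (medoid positions plus
insertion columns) are voted per column, majority wins, ties prefer a
base over a gap and then alphabetical order; gap-majority columns are
deleted. Groups larger than 50 members are subsampled uniformly to 50
— beyond that the consensus is saturated and cost grows linearly.

**Deduplication.** A uniformly random member represents the group
(seed-deterministic).

**Truth assessment.** A group is *pure* iff all members carry the same
true UMI. Summary statistics are the fraction of pure groups and the
group-size histogram.

## 5. Mapping and evaluation (`cellosim.mapping`)

**Oracle mapper.** Desk-scale instances are mapped internally: the
query is placed by optimal semi-global (infix) edit distance against
both strands of every chromosome (bit-vector algorithm, exact).
Equal-best loci are resolved uniformly at random under the run seed —
exactly the ambiguity a real aligner faces on identical repeat copies.
The chosen locus is re-aligned globally for an extended (=/X/I/D)
CIGAR; placements under 70% identity are unmapped (a conventional
long-read floor). Production-scale alignments can be imported from PAF
with `cg:Z:` extended CIGARs instead; plain-M CIGARs are rejected
because they hide mismatches.

**Read identity.** `matches / (matches + mismatches + insertions +
deletions)` over CIGAR columns.

**Classes.** Each unit (read, or UMI-group output) is classified
against truth: `mapped` (alignment overlaps the true interval by ≥ 1
bp), `mismapped` (aligned elsewhere), `unmapped`, or `unresolved` (the
unit came from a UMI group mixing molecules — counted as its own class
so accounting stays exact). Per element, mapped + mismapped + unmapped
+ unresolved equals the number of simulated units.

**Specificity.** Per element:
`n_mapped / (n_mapped + n_mismapped_in)`, where `n_mismapped_in`
counts foreign mismapped units whose alignment overlaps the element.
Undefined (None) when no unit maps in. For n identical copies the
expected specificity is 1/n (the ambiguity floor); fully diverged
copies score 1.

## 6. Experiments (`cellosim.experiments`)

**Mapping experiment.** All arms share one molecule set (windows +
true UMIs); each arm re-emits reads at its own coverage and error
mode. Arms: `perfect` (Q40 reads, mapped directly), `ont_naive` (ONT
reads mapped directly — every PCR duplicate counts, producing the
coverage-fold inflation of apparent expression), `sarlacc_corrected`
(preprocess → group at threshold 6 → consensus per pure group → map)
and `sarlacc_dedup` (same, but a random representative instead of the
consensus). Impure groups become `unresolved` units attributed to
their plurality molecule. Outputs are tidy tables: class counts,
group-size-by-class, per-element specificity, and mean post-processing
identity against the true cDNA.

**UMI design sweep.** 10,000 UMI-only molecules per length in
{10, 20, 30, 40, 50} nt (RYN pattern), read 5x with ONT identity,
grouped at thresholds {2, 6, 10, 14} within pregroups of 100 distinct
true UMIs. UMIs are drawn with replacement: a 10 nt RYN space holds
only 2^7 x 4^3 = 8,192 strings, so collisions are an intrinsic failure
mode of short UMIs, not an implementation artefact. A length is
*adequate* when at some threshold the fraction of pure groups is
≥ 0.95 **and** the group count is within 5% of the true molecule
count; the sweep reports the smallest adequate length.

## 7. Numerical and reproducibility choices

* All randomness flows through explicitly seeded NumPy generators;
  fixed seeds give bit-identical FASTQ output and identical tables.
* Edit distances and alignments use exact algorithms (bit-vector edit
  distance, full dynamic programming) — no heuristics, so test oracles
  can be independent reimplementations.
* Pairwise UMI distance passes are early-abandoned at the largest
  threshold in play and shared across thresholds in the sweep.
* Beta shape parameters come from closed-form method of moments; the
  parameterization is validated eagerly (infeasible mean/sd pairs
  raise).

## 8. Limitations

* The error model matches per-read identity moments but not nanopore
  error *structure*: no homopolymer bias, no k-mer-conditioned errors,
  no quality-score correlation, no junk or split reads. Consequences
  that depend on error clustering (e.g. the exact UMI length at which
  grouping degrades) can differ from trained-model simulators.
* Adapter and barcode sequences are synthetic stand-ins; absolute
  preprocessing yields depend on oligo composition.
* The oracle mapper is exhaustive and exact, feasible only at desk
  scale (hundreds of kb); genome-scale runs must import external
  aligner PAF.
* Specificity is defined over simulated units; with few reads per
  element the estimate is coarse.
* Single-linkage grouping chains: at thresholds near the inter-UMI
  distance scale whole pregroups collapse into one group.
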