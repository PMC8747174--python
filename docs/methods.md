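# Methods

This note documents the models, conventions and numerical choices behind
`mirprof`, and what its synthetic-data validation does and does not show.

## Alphabets and canonicalization

All comparisons (homology, mapping, folding, target scoring) run in
uppercase DNA space with U mapped to T; raw reads and the packaged tables
keep their original alphabet for display. The packaged conserved table
prints T-containing sequences while the novel table prints U-containing
ones, so a single canonical space is the only way to make the two
comparable. Several rows of the conserved table print a length that
disagrees with the character length of the printed sequence; the loader
carries both values verbatim and flags the discrepancy
(`length_discrepancy`) rather than guessing a correction.

## Read cleaning

* **Adapter trimming** removes the suffix from the leftmost position
  where at least `min_overlap` (default 8) characters of the 3′ adapter
  prefix match; quality is truncated in lockstep. A read equal to the
  adapter becomes empty and is removed later by the length filter.
* **Quality rule**: the published workflows state only "< Q30"; here it
  is read as *mean* Phred ≥ 30 per read (the common sRNA-workbench
  interpretation), configurable. FASTA input skips the stage with a
  logged notice.
* **Length filter**: inclusive 16–40 nt bounds.
* **ncRNA removal** treats a tag as contaminant when it occurs as a
  substring of any rRNA/tRNA/snRNA/snoRNA record on either strand
  (tags are fragments of longer ncRNAs, not vice versa), with an optional
  substitution budget. When a tag matches several classes, attribution
  follows the fixed order rRNA, snoRNA, snRNA, tRNA so removal counts are
  deterministic.
* The cleaning report is conservation-checked: total reads equal
  surviving reads plus every removal category, and the check is executed
  (not just documented) on every run.

## Conserved annotation

Homology is ungapped and substitution-only, matching the "mismatch"
vocabulary of mature-miRNA reference tables: the shorter of tag and
reference slides fully inside the longer, overhangs are free, and the
minimum substitution count over offsets is the distance (ties resolve to
the smallest |offset|, negative first). A tag is conserved when its best
reference is within `max_mismatch` (default 1); ties go to the
lexicographically smallest reference id, and assignments whose tied
references disagree on family are flagged. BLAST-style seeding is
deliberately replaced by the exhaustive offset scan: collapsed tag sets
are small and exactness/determinism matter more than speed here.
E-values in the packaged table are opaque metadata (they depend on the
original search database) and are never recomputed.

Family summaries count *distinct member sequences* per family, not
distinct assigned names — names legitimately repeat across sequence
variants of the same mature (e.g. three distinct miR166b variants), and
the member counts of the packaged table (16/12/12/10 for
MIR166/MIR159/MIR396/MIR167_1) are reproduced only under this reading.

## Fold engine

The bundled engine folds over *stem-loop forests*: any nested pair set in
which each closed pair encloses at most one branch (simple stems with
bulges/interior loops), with any number of adjacent stems at the external
level. Multibranch loops are outside the model — appropriate for an
engine whose job is precursor hairpin evaluation, and it keeps the fold
exactly solvable by a two-table dynamic program (closed-stem table plus a
prefix table) in roughly O(n²·b²) for bulge budget b.

Energy terms (kcal/mol, all in `FoldParams`): pair energies G:C −3.0,
A:U −2.0; optional G:U wobble −1.0, **off by default** so that the
parameterization is symmetric under reverse complementation (a G:U pair
maps to an unpairable A:C under reverse complement, so admitting wobble
breaks the |MFE| symmetry property); stacking bonus −1.0 per directly
stacked pair; +3.0 per hairpin loop; +0.5 per unpaired interior-loop
base, at most 8 such bases per loop. MFE ≤ 0 always (the empty structure
is admissible). The engine is deterministic, with ties resolved toward
smaller spans and leftmost stems.

`structure_energy` scores an explicit pair set by loop decomposition
under the same model and is the independent route used in tests: the DP
optimum is cross-checked against exhaustive enumeration of all nested
structures at n ≤ 15, and the reported MFE must be reproducible from the
reported structure. ViennaRNA is wired as a substitutable engine
(`get_fold_engine("vienna")`) and serves in tests only as a qualitative
cross-check; its nearest-neighbor energies are not comparable in scale to
the bundled model, so MFEI magnitudes depend on the engine choice.

**Duplex energies** use a separate local DP over antiparallel pairings
with a 2.0/base gap penalty; wobble is admitted intermolecularly
(hybridization screens are conventionally permissive). The value is
symmetric in argument order and 0 for non-complementary strands.

## Novel discovery

Mapping is exact-match by default (budget configurable up to 2
substitutions, no indels) via a vectorized sliding-window comparison on
both strands; the synthetic genomes are exact, and cross-species mapping
heuristics are not reproduced. Around each hit two windows are excised —
[start − flank, end + 20) and [start − 20, end + flank), flank 150,
clipped to contig bounds, minus-strand windows reverse-complemented — so
that whichever arm hosts the mature, one window spans the full hairpin.

The hairpin screen operates on the helix containing the mature rather
than on the whole window, so random flank structure cannot fail a genuine
hairpin: pass requires (a) every paired mature base's partner on one side
(defining the 5p/3p arm) and no overlap with a terminal loop, (b) at
least 16 mature bases paired with no unpaired run over 4, (c) exactly one
terminal loop inside the innermost mature pair (single stem-loop), and
(d) at least 18 pairs inside the outermost mature pair. Thresholds are
package defaults, logged per run, not published constants.

MFEI uses |MFE| so the index is positive, GC% on the 0–100 scale over the
full excised window; AMFE = (|MFE|/L)×100 and MFEI = AMFE/GC%. Calls
require MFEI ≥ 0.70 (boundary retained) and read count ≥ 5 (the copy
gate is applied both here and before target scanning, separately
configurable, since published practice is ambiguous about where it
binds). Multiple loci of one mature collapse to the max-MFEI locus, and
names are assigned `mko-miRN<k>-<arm>` in descending read-count order.

## Target prediction

Plant-mode scoring follows the psRNATarget-style penalty scheme with the
tool's published parameters unavailable: mismatch 1.0, G:U 0.5, each gap
2.0, doubled over miRNA positions 2–13, expectation cutoff 5.0. The
default scanner is ungapped — it scores every same-length transcript
window and keeps the best site per transcript (5′-most on ties); the gap
penalty is retained in the configuration for completeness. Silencing
mode is the package's documented convention, not a published rule:
translational repression iff any of miRNA positions 9–11 is imperfect,
cleavage otherwise.

Cross-kingdom mode requires perfect Watson–Crick pairing at seed
positions 2–8 (wobbles rejected) and filters on |ΔG| ≥ 25 kcal/mol. The
stated rule "minimum free energy ≥ −25" is read as ΔG ≤ −25 (a literal
reading would admit the weakest duplexes); the literal rule is available
via `literal_energy_rule=True`. The strongest surviving site per
transcript is emitted. The network export writes one edge per hit with
the duplex energy as weight and a weak flag above a configurable cutoff
(default −15 kcal/mol) for dashed rendering.

## qPCR quantification

Per replicate ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the
calibrator's mean ΔCt; fold = 2^−ΔΔCt. The summary reports the
arithmetic mean and sd of replicate folds plus the geometric-mean fold
(2^−meanΔΔCt), which is exactly 1 for the calibrator — the arithmetic
mean is slightly above 1 under noise (Jensen). Technical replicates can
be averaged into biological replicates first (`average_technical`,
matching a two-biological × three-technical design). Letter groups come
from one-way ANOVA on log10 folds gated at α, statsmodels' Tukey HSD for
all pairs, and an insert-and-absorb compact-letter display ordered by
descending mean. Fold changes are strictly positive; depleted miRNAs are
representable only as negative values on the log scale.

## Synthetic data

The generator emulates a plant leaf sRNA library: inserts drawn from a
21–24-nt-dominant length distribution (24 nt at 35%), each read written
as insert + 3′ adapter truncated to 50 cycles at uniform Q40; conserved
matures and hairpin-arm matures planted at exact copy numbers (defaults
span 5–95 copies, the range real desk-scale candidates occupy);
contaminant reads cut from random per-class ncRNA records; the remainder
random noise. Planting is exact — no sequencing-error model — because
the pipeline operates on collapsed exact tags; an error model would only
exercise the (configurable) mismatch budgets. Hairpins are constructed
as mature + loop + near-reverse-complement star (arm order per design)
with up to 2 star substitutions, inserted into a symmetric-base random
genome at non-overlapping coordinates on either strand.

What passing therefore shows: the machinery is exact — conservation,
classification, mapping, folding, gating and quantification do what they
claim on data matching their assumptions, with recall/precision 1.0 and
zero count error. What it does not show: robustness to sequencing error,
ligation bias, UMI structure, quality-profile artifacts, cross-species
divergence, or thermodynamically realistic fold energies — real-data
MFEI magnitudes depend on the fold engine and are not comparable to the
bundled model's values.

## Problem sizes

Defaults used by the analysis scripts and the acceptance script:
10,000-read libraries, a 50 kb single-contig genome, 10 planted conserved
miRNAs, 3 planted hairpins, 40 transcripts of 400 nt for target scans,
and 8 miRNAs × 6 replicates for qPCR. These sizes exercise every code
path while the whole acceptance run completes in well under a minute on
one CPU; all thresholds and gates are independent of the sizes.
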