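# Methods

## Repeat model

A reportable STR locus is a **maximal perfect tandem run** of a primitive
motif: `sequence[start:end] == motif * units` with `unit_size = |motif| ∈
{2..5}`, `units ≥ min_units`, no `N` inside the run, and no whole-unit
extension possible on either side. The motif is reported as phased at the
run start (the leftmost base of the maximal match run), and a locus appears
exactly once, at its primitive unit size: a non-primitive unit (`ATAT`,
`AA`) is suppressed because the same run is already reported at the shorter
period. With `min_units ≥ 5` primitivity alone is sufficient — by the
Fine–Wilf periodicity lemma a run long enough to be reported cannot carry a
primitive motif at one unit size while having a smaller period, so no extra
minimal-period check is needed. Overlapping runs of *different* unit sizes
are genuinely distinct loci and are all kept. Mononucleotide runs are never
reported; imperfect, compound and interrupted repeats are out of scope.

The production scanner vectorises the lag-`k` self-match profile
(`seq[i] == seq[i+k]`) with numpy and converts its maximal True runs into
loci: a run of `L` matching positions spans a repeat region of `L + k`
bases holding `(L + k) // k` whole units. `polystr.reference` carries an
independent brute-force implementation (per-(start, unit size) forward unit
counting with explicit left-maximality and primitivity checks, quadratic)
used only to validate the scanner.

## Variant handling

VCF records are read with pysam and exploded into bi-allelic variants;
allele-depth (AD) columns are re-sliced per alternate. Indels are
**left-normalized** against the assembly (shared trailing bases dropped
while re-anchoring one base to the left, then shared leading bases trimmed
to a single anchor) so that an event inside a repeat run always sits at the
run's leftmost equivalent position; the operation is semantically
equivalence-preserving and idempotent, and a reference-allele mismatch with
the assembly is a hard error. Pool allele support prefers AD; when absent
the genotype call is used with a logged warning, since diploid genotype
semantics are unreliable for pooled libraries. A missing QUAL fails any
positive quality threshold. The FILTER column is ignored unless
`--require-pass` is given.

## Assignment and population status

An indel is assigned to a repeat when its normalized edit interval lies
within `[start − unit_size, end)` — the one-unit extension to the left
accounts for the anchor base preceding a left-normalized event. When
several loci qualify, the locus whose unit size divides the length change
wins, then the longest locus, then the smallest start. Each assigned
length change `Δ` that is a whole multiple of the unit size implies an
alternate allele of `units + Δ/unit_size` repeats; any non-multiple `Δ`
(or a deletion implying a negative count) marks the locus
unit-inconsistent, mirroring bench markers whose fragment patterns are
inconsistent with their unit size.

Fixation is defined on pooled allele fractions, since pools of many
individuals cannot be genotyped diploid-wise. Per pool,
`f = alt/(ref + alt)` is taken as the maximum over the locus's assigned
variants (most permissive evidence of polymorphism), using only variants
whose pool depth reaches `min_depth`; with no adequately covered variant
the pool is `no_data`. `f ≤ fixed_low` → fixed for the reference,
`f ≥ fixed_high` → fixed for the alternate, otherwise polymorphic. A locus
is *fixed-in-some* when at least one pool is fixed while another is
polymorphic or fixed on the other allele; with a single pool the flag is
always false.

## Candidate filters, ranking, output

Exclusion reasons are assigned in a fixed order so each excluded locus
carries exactly one primary reason: motif size (default: tri-nucleotide
only), low variant quality (`QUAL < qual_min`), incomplete flank (locus too
close to a contig end), `N` inside a flank, then unit-inconsistency. In
concatenation mode a flank that reaches into the 100-N spacer is excluded
by the flank-N rule automatically — no special casing. Kept candidates are
ranked by maximum implied repeat count (descending), then reference repeat
count, then (contig, start); the order is a total order, so selection is
invariant to input permutation. Output records are
`left_flank + repeat + right_flank` with a pipe-delimited title
(`contig|start-end|motif×units|alleles=lo-hi|pops=...`, 1-based inclusive
coordinates); fragment-length arithmetic for scored markers is
`max_len = min_len + unit_size × (max_units − min_units)`.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `unit_sizes` | {2,3,4,5} | bp | di- to penta-nucleotide motifs |
| `min_units` | 5 (inclusive) | units | shorter runs are poor length markers; configurable |
| `flank_len` | 300 | bp | room for primer design on both sides |
| `spacer_len` | 100 | bp | ≥ `max(unit_sizes)·min_units`, so no STR bridges a junction |
| `qual_min` | 20 | phred | standard "high-quality call" floor |
| `fixed_low` / `fixed_high` | 0.05 / 0.95 | allele fraction | tolerate ~1 stray read in 20 at a truly fixed site |
| `min_depth` | 8 | reads/pool | below this a pooled fraction is uninformative |
| `top_k` | 20 | markers | a practical PCR screening panel |
| `candidate_unit_sizes` | {3} | bp | tri-nucleotide markers avoid di-nucleotide stutter |

`min_units` is inclusive (a 5-unit run is reported). Summary tables
tabulate repeat counts from 5 upward with a pooled `21+` row and a percent
row across motif-size columns.

## Synthetic data

The generator emulates the targeted study design — a draft assembly plus a
two-pool indel report — not the sequencing itself. Background sequence is
i.i.d. at a chosen GC content (default 0.38, insect-like) and
rejection-cleaned: any accidental repeat meeting the scan thresholds is
resampled until a scan finds exactly the planted loci, so the truth table
is exact rather than probabilistic. Planted run boundaries are constrained
(the base before the run differs from the motif's last base, the base after
from its first) so no run can extend. The VCF is fabricated directly:
per-pool depths are Poisson (`depth_mean` 30 reads/pool — a realistic
modern pooled-library depth chosen so the `min_depth` gate is exercised
meaningfully), alternate counts binomial at the stated pool allele
frequency, QUAL uniform on 30–100 for clean records and 5 for low-quality
traps, plus decoy SNPs in the background. The benchmark scenario
(`standard_scenario`) plants tri-nucleotide loci of 8–20 units: polymorphic
loci at pool frequencies (0.5, 0.4), fixed-pattern loci at (1.0, 0.3),
monomorphic loci with no variant, and the three trap categories
(non-unit-multiple indel, low QUAL, N in flank). The default acceptance
benchmark is 200 kb in four contigs with 60 planted loci — large enough to
exercise every rule, small enough that the whole suite runs in seconds.

What passing tests do **not** show about real data: no read-level error
model, no mapping artifacts or paralog collapse (a common source of false
STR polymorphism in draft assemblies), no imperfect repeats, and planted
truth frequencies far from the fixation thresholds — binomial sampling
noise at depth 30 makes a misclassified pool (e.g. a 0.3-frequency pool
drawn below 0.05) possible in principle, with probability well under 1%
per locus; the expected verdicts in the truth table are computed from the
planted frequencies, not from the draws.

## Numerical and design choices

- Coordinates are 0-based half-open internally; all human-facing output is
  1-based inclusive (VCF input positions are 1-based).
- Lowercase (soft-masked) bases are uppercased rather than masked — masking
  provenance of draft assemblies is unreliable; ambiguity codes other than
  `N` are rejected at parse time because the downstream filters reason only
  about `N`.
- Canonical motif classes use the lexicographically minimal rotation
  without reverse-complement folding by default (`ATC` and `GAT` stay
  distinct, matching how markers are reported per reference strand); an
  `rc_canonical` flag folds strands for users who want strand-free classes.
- The tab assembly dialect takes everything before the first (and only)
  tab as the record name; `dialect=auto` sniffs the first non-empty
  character.
- The original interactive prompt-driven workflow is expressed
  non-interactively as flags plus a YAML config (flags win) for
  scriptability and testing; behaviour-equivalent defaults are preserved.

## Limitations

- Perfect repeats only; an interrupted run is reported as its perfect
  sub-runs (or not at all).
- Fixation calls are threshold rules on pooled fractions, not a population
  genetic model; no significance statement is attached.
- Headline marker *counts* from any particular organism depend on the
  upstream assembly and variant calling, which sit outside this package;
  the acceptance benchmark therefore measures exact recovery of planted
  truth and worked arithmetic rather than organism-specific totals.
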