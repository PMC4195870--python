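# polystr

Discovery of **polymorphic microsatellite (STR) markers** from a draft
assembly plus a variant report of pooled, barcoded population sequencing
libraries.

Classical STR-mining tools scan assembled sequence for tandem repeats and
return thousands of candidate loci — with no indication of which are
actually polymorphic in the populations under study, so most wet-lab
screening effort is wasted on monomorphic markers. When each population is
sequenced as its own barcoded pool and the reads are mapped back to the
assembly, repeat copy-number variation shows up directly as **indels in the
VCF**, and per-pool allele depths say *where* the variation lives. polystr
exploits exactly this:

1. **scan** the assembly for maximal perfect tandem repeats — primitive
   motifs of 2–5 bp repeated ≥ 5 times, phased at the run start, never
   crossing an `N`;
2. **intersect** them with the VCF's indels (multi-allelics split,
   left-normalized against the assembly): an indel inside
   `[start − unit_size, end)` of a repeat is evidence for alternate repeat
   counts `units + Δ/unit_size`;
3. **classify** each pool from its pooled alternate-allele read fraction
   *f* = alt/(ref+alt): fixed for the reference if *f* ≤ 0.05, fixed for
   the alternate if *f* ≥ 0.95, polymorphic in between, "no data" below a
   depth gate (8 reads);
4. **filter** candidates the way markers are validated for the bench —
   tri-nucleotide motifs only (di-nucleotide markers suffer PCR "stutter"),
   variant QUAL ≥ 20, complete N-free 300 bp flanks, and every supporting
   length change a whole number of units;
5. **rank** by greatest implied repeat count, keep the top 20, and emit
   primer-ready FASTA records (`left flank + repeat + right flank`), with
   the subset **fixed in one population** in a separate file.

Multi-contig assemblies can be scanned as-is or joined into one strand with
a 100-`N` spacer (long enough that no reportable STR can bridge a
junction); a coordinate map translates everything back to contig space.

A first-class synthetic-data generator (`polystr simulate` /
`polystr.standard_scenario`) builds seed-deterministic assemblies with
planted repeats and matched two-pool VCFs whose truth table is exact, so
the whole pipeline is testable without any sequencing data.

## Worked example

```bash
python examples/discover_markers.py
```

builds a simulated 60 kb two-pool dataset (5 polymorphic loci, 2 fixed in
one pool, 2 monomorphic, 3 traps) and runs discovery:

```
scanned 2 contigs -> 12 STR loci
10 indels -> 10 polymorphic repeats
kept 7, excluded {'flank-N': 1, 'low-qual': 1, 'non-unit-multiple': 1}

selected candidates (ranked by largest implied repeat count):
  contig01:8521-8577 TCAx19  alleles 19-22 units  (popA=polymorphic, popB=polymorphic)
  contig01:12826-12882 CAGx19  alleles 19-22 units  (popA=polymorphic, popB=polymorphic)
  contig01:17131-17175 TGAx15  alleles 15-17 units  (popA=fixed_alt, popB=polymorphic) [fixed in one pool]
  ...
```

Each line is one candidate: its repeat (1-based coordinates, motif ×
reference repeat count), the repeat-count range implied by the ref and all
assigned indel alleles, and each pool's status. `TGAx15, alleles 15-17` at a
tri-nucleotide locus means amplicons will differ by 3 bp per repeat unit —
a marker fixed in `popA` but polymorphic in `popB` is immediately useful
for between-population assignment. The two monomorphic planted loci never
appear, and each trap locus is excluded with its planted reason.

The same run from the shell:

```bash
polystr simulate --out-dir sim --seed 7
polystr discover --fasta sim/ref.fa --vcf sim/calls.vcf \
    --out candidates.fa --fixed-out fixed.fa --report report.tsv \
    --summary-json summary.json
polystr scan --fasta sim/ref.fa --bed loci.bed --summary table.tsv
```

Amplicon arithmetic for scored markers
(`examples/fragment_spans.py`): a marker with alleles of 14–18 units of a
3 bp motif and a smallest amplicon of 366 bp spans fragments 366–378 bp.

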