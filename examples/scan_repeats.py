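"""Scan a small assembly for perfect tandem repeats and summarise them.

Builds a two-contig toy assembly with three planted repeats, scans it with
the default thresholds (unit sizes 2-5, at least 5 units), and prints the
loci plus the motif-size x repeat-count table.
"""
from polystr import Assembly, SequenceRecord, scan_assembly, summarize_counts

background = "GATTACCAGTTGACCGTTAGGCATTGCCAGGTAACCGTTAGCATGGACCTTAG"
contigs = [
    SequenceRecord("tig1", background + "ATC" * 9 + background),
    SequenceRecord("tig2", background + "TA" * 7 + background[::-1] + "ATCGA" * 5 + background),
]
assembly = Assembly(contigs)

loci = scan_assembly(assembly)
print("loci found:")
for locus in loci:
    # coordinates printed 1-based inclusive; units = number of motif copies
    print(f"  {locus}")

print("\nmotif-size x repeat-count summary (columns: unit size):")
print(summarize_counts(loci).to_string())
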