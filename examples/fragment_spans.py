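"""Amplicon-size arithmetic for marker sanity checks.

A marker's PCR fragment length changes by one unit size per repeat-count
difference between alleles. Given the smallest observed amplicon and the
allele repeat-count range, `expected_fragment_span` predicts the largest
amplicon — useful for checking scored fragment ranges against a marker's
expected behaviour.
"""
from polystr import expected_fragment_span

markers = [
    ("(ATC) 14-18 units, smallest amplicon 366 bp", 366, 3, 14, 18),
    ("(ATC)  6-20 units, smallest amplicon 345 bp", 345, 3, 6, 20),
    ("(CGA)  4-10 units, smallest amplicon 475 bp", 475, 3, 4, 10),
    ("(GAC)  5-10 units, smallest amplicon 305 bp", 305, 3, 5, 10),
]
for label, min_len, unit, lo, hi in markers:
    hi_len = expected_fragment_span(min_len, unit, lo, hi)
    print(f"{label} -> fragment range {min_len}-{hi_len} bp")
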