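"""Slow brute-force reference scanner used to validate the production scanner.

Independent of :mod:`polystr.str_scanner`'s run-profile algorithm: for every
(start, unit size) pair it counts whole repeat units forward one character
at a time, then keeps the run only if it is primitive, long enough, and
left-maximal. Quadratic in the worst case — intended for validation on
kilobase-scale sequences, never for production scans.
"""
from __future__ import annotations

from .config import Config
from .sequence_io import SequenceRecord
from .str_scanner import StrLocus, is_primitive

__all__ = ["brute_force_strs"]


def brute_force_strs(record: SequenceRecord, config: Config | None = None) -> list[StrLocus]:
    config = config or Config()
    seq = record.sequence
    n = len(seq)
    loci: list[StrLocus] = []
    for k in sorted(config.unit_sizes):
        for start in range(0, n - k * config.min_units + 1):
            motif = seq[start : start + k]
            if "N" in motif:
                continue
            # left-maximality: one more unit to the left must break the phase
            if start > 0 and seq[start - 1] != "N" and seq[start - 1] == seq[start - 1 + k]:
                continue
            units = 1
            pos = start + k
            while pos + k <= n and seq[pos : pos + k] == motif:
                units += 1
                pos += k
            if units < config.min_units:
                continue
            if not is_primitive(motif):
                continue
            loci.append(StrLocus(contig=record.name, start=start, end=start + units * k, motif=motif))
    loci.sort(key=lambda l: (l.start, l.unit_size))
    return loci
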