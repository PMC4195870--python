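"""Perfect tandem-repeat detection.

Finds every maximal perfect run of a primitive 2-5 bp motif repeated at
least ``min_units`` times, excluding anything containing an N. A run is
reported once, phased at its leftmost base, at its primitive unit size;
overlapping runs of *different* unit sizes are all reported.

The scan is vectorised: for each unit size ``k`` the boolean profile
``seq[i] == seq[i+k]`` is computed with numpy and its maximal True runs are
converted to repeat loci.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import Config
from .errors import DataError
from .sequence_io import Assembly, SequenceRecord

__all__ = [
    "StrLocus",
    "find_strs",
    "scan_assembly",
    "canonical_motif",
    "is_primitive",
    "summarize_counts",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def is_primitive(motif: str) -> bool:
    """True iff the motif is not itself a repetition of a shorter string."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def canonical_motif(motif: str, rc_fold: bool = False) -> str:
    """Lexicographically minimal rotation of a primitive motif.

    With ``rc_fold`` the reverse complement's rotations compete too, folding
    opposite-strand classes (ATC/GAT) together. Deterministic.
    """
    if not motif or set(motif) - set("ACGT"):
        raise DataError(f"motif {motif!r} must be non-empty over A/C/G/T")
    if not is_primitive(motif):
        raise DataError(f"motif {motif!r} is not primitive")
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    if rc_fold:
        rc = motif.translate(_COMPLEMENT)[::-1]
        rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


@dataclass(frozen=True)
class StrLocus:
    """A maximal perfect tandem repeat on one contig.

    ``sequence[start:end] == motif * units`` exactly; the motif is the unit
    as phased at ``start`` and is primitive; coordinates are 0-based
    half-open.
    """

    contig: str
    start: int
    end: int
    motif: str

    @property
    def unit_size(self) -> int:
        return len(self.motif)

    @property
    def units(self) -> int:
        return (self.end - self.start) // self.unit_size

    @property
    def canonical(self) -> str:
        return canonical_motif(self.motif)

    def __str__(self) -> str:  # 1-based inclusive for humans
        return f"{self.contig}:{self.start + 1}-{self.end} {self.motif}x{self.units}"


def find_strs(record: SequenceRecord, config: Config | None = None) -> list[StrLocus]:
    """All maximal perfect STRs in one contig, sorted by start.

    For each configured unit size ``k``, positions where ``seq[i] ==
    seq[i+k]`` (both non-N) form runs; a run of length L spanning a repeat
    region of ``L + k`` bases holds ``(L + k) // k`` whole units anchored at
    the run start. Non-primitive motifs are suppressed so every locus
    appears exactly once, at its primitive unit size.
    """
    config = config or Config()
    seq = record.sequence
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = arr != ord("N")
    loci: list[StrLocus] = []
    for k in sorted(config.unit_sizes):
        if len(arr) < k * config.min_units:
            continue
        match = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for a, b in zip(edges[0::2], edges[1::2]):
            units = (b - a + k) // k
            if units < config.min_units:
                continue
            motif = seq[a : a + k]
            if not is_primitive(motif):
                continue
            loci.append(StrLocus(contig=record.name, start=int(a), end=int(a + units * k), motif=motif))
    loci.sort(key=lambda l: (l.start, l.unit_size))
    return loci


def scan_assembly(assembly: Assembly, config: Config | None = None) -> list[StrLocus]:
    """Scan every contig; loci sorted by (contig, start, unit size)."""
    loci: list[StrLocus] = []
    for rec in assembly:
        loci.extend(find_strs(rec, config))
    loci.sort(key=lambda l: (l.contig, l.start, l.unit_size))
    return loci


def summarize_counts(
    loci: Iterable[StrLocus],
    unit_sizes: Sequence[int] = (2, 3, 4, 5),
    max_row: int = 20,
    min_row: int = 5,
) -> pd.DataFrame:
    """Motif-size x repeat-count summary table.

    Rows are repeat counts ``min_row..max_row`` plus ``"21+"`` (counts above
    ``max_row`` pooled), ``SUM`` and ``Percent``; columns are unit sizes.
    Column sums equal the number of loci of that unit size and the Percent
    row expresses each column as a share of all loci (summing to 100).
    """
    counts: Counter[tuple[int, int]] = Counter()
    for locus in loci:
        counts[(locus.unit_size, locus.units)] += 1
    rows = [str(u) for u in range(min_row, max_row + 1)] + [f"{max_row + 1}+"]
    table = pd.DataFrame(0, index=rows, columns=list(unit_sizes), dtype=float)
    for (size, units), n in counts.items():
        if size not in table.columns:
            continue
        row = str(units) if units <= max_row else f"{max_row + 1}+"
        table.loc[row, size] += n
    sums = table.sum(axis=0)
    total = sums.sum()
    table.loc["SUM"] = sums
    table.loc["Percent"] = (100.0 * sums / total).round(1) if total else 0.0
    return table
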