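"""Assembly input/output and coordinate handling.

Two on-disk dialects are supported, plain or gzip-compressed:

* standard FASTA (``>name`` line, sequence on one or more following lines);
* a tab dialect with one record per line: ``name<TAB>sequence``.

An assembly is an ordered list of named contigs. For whole-genome-style use
the contigs can be concatenated into a single strand, the junctions padded
with a run of ``N`` so that no tandem repeat can be created artificially
across a join; a coordinate map translates concatenated positions back to
(contig, local position).

Coordinates are 0-based half-open internally; human-facing output is
1-based inclusive.
"""
from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .config import Config
from .errors import ConfigError, DataError, ParseError

__all__ = [
    "SequenceRecord",
    "Assembly",
    "CoordinateMap",
    "read_assembly",
    "write_assembly",
    "concat_with_spacer",
    "extract_flanks",
]

_VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named contig: uppercase DNA over {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.name:
            raise DataError("sequence record with empty name")
        if not self.sequence:
            raise DataError(f"record {self.name!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise DataError(
                f"record {self.name!r} contains illegal characters {sorted(bad)}; "
                "only A/C/G/T/N are accepted"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CoordinateMap:
    """Maps positions on a concatenated strand back to source contigs.

    ``blocks`` holds one ``(concat_start, length, contig_name)`` triple per
    source contig, in strand order; positions between blocks fall in the N
    spacer and map to nothing.
    """

    blocks: tuple[tuple[int, int, str], ...]

    def to_contig(self, pos: int) -> tuple[str, int] | None:
        """Return (contig name, contig-local position) or None for spacer/N."""
        starts = [b[0] for b in self.blocks]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        start, length, name = self.blocks[i]
        if pos < start + length:
            return name, pos - start
        return None

    def to_concat(self, name: str, pos: int) -> int:
        """Inverse lookup: contig-local position -> concatenated position."""
        for start, length, block_name in self.blocks:
            if block_name == name:
                if not 0 <= pos < length:
                    raise DataError(f"position {pos} outside contig {name!r}")
                return start + pos
        raise DataError(f"contig {name!r} not in coordinate map")


@dataclass
class Assembly:
    """An ordered collection of contigs with unique names."""

    records: list[SequenceRecord]
    dialect: str = "fasta"
    coordinate_map: CoordinateMap | None = None
    _index: dict[str, SequenceRecord] = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {}
        for rec in self.records:
            if rec.name in self._index:
                raise DataError(f"duplicate record name {rec.name!r} in assembly")
            self._index[rec.name] = rec

    def get(self, name: str) -> SequenceRecord:
        try:
            return self._index[name]
        except KeyError:
            raise DataError(f"contig {name!r} not found in assembly") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
    elif str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_dialect(path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped:
                return "fasta" if stripped.startswith(">") else "tab"
    raise ParseError(f"{path}: empty file, cannot determine dialect")


def _read_tab(fh: IO[str]) -> Iterator[SequenceRecord]:
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        n_tabs = line.count("\t")
        if n_tabs != 1:
            raise ParseError(
                f"tab dialect requires exactly one tab per line, found {n_tabs}",
                line=lineno,
            )
        name, seq = line.split("\t")
        yield SequenceRecord(name=name.strip(), sequence=seq.strip().upper())


def _read_fasta(fh: IO[str], path) -> Iterator[SequenceRecord]:
    # Reject leading junk explicitly: Bio.SeqIO silently skips text before '>'.
    first = None
    for line in fh:
        if line.strip():
            first = line
            break
    if first is None:
        raise ParseError(f"{path}: empty FASTA file")
    if not first.lstrip().startswith(">"):
        raise ParseError(f"{path}: FASTA must start with '>', found {first.strip()[:30]!r}", line=1)
    fh.seek(0)
    for rec in SeqIO.parse(fh, "fasta"):
        yield SequenceRecord(name=rec.id, sequence=str(rec.seq).upper())


def read_assembly(path, dialect: str = "auto") -> Assembly:
    """Read an assembly from FASTA or the tab dialect.

    ``dialect='auto'`` sniffs the first non-empty character ('>' means
    FASTA, anything else the tab dialect). Lowercase (soft-masked) bases are
    uppercased; IUPAC ambiguity codes other than N are rejected.
    """
    if dialect not in ("fasta", "tab", "auto"):
        raise ConfigError(f"unknown dialect {dialect!r}")
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    with _open_text(path) as fh:
        if dialect == "tab":
            records = list(_read_tab(fh))
        else:
            records = list(_read_fasta(fh, path))
    if not records:
        raise ParseError(f"{path}: no records found")
    return Assembly(records=records, dialect=dialect)


def write_assembly(assembly: Assembly, path, dialect: str | None = None, width: int = 70) -> None:
    """Write an assembly in either dialect (gzip if the path ends in .gz)."""
    dialect = dialect or assembly.dialect
    if dialect not in ("fasta", "tab"):
        raise ConfigError(f"unknown dialect {dialect!r}")
    with _open_text(path, "wt") as fh:
        if dialect == "tab":
            for rec in assembly:
                fh.write(f"{rec.name}\t{rec.sequence}\n")
        else:
            bio = [_BioRecord(Seq(r.sequence), id=r.name, description="") for r in assembly]
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(bio)


def concat_with_spacer(
    assembly: Assembly,
    spacer_len: int = 100,
    *,
    config: Config | None = None,
    name: str = "concat",
) -> Assembly:
    """Join all contigs into one strand separated by runs of N.

    The spacer must be at least ``max(unit_sizes) * min_units`` bases so no
    reportable STR can bridge a junction; a :class:`CoordinateMap` records
    where each contig landed.
    """
    if not assembly.records:
        raise DataError("cannot concatenate an empty assembly")
    bound = (config or Config()).min_safe_spacer
    if spacer_len < bound:
        raise ConfigError(
            f"spacer_len {spacer_len} < {bound}: an STR could bridge a contig junction"
        )
    parts: list[str] = []
    blocks: list[tuple[int, int, str]] = []
    offset = 0
    spacer = "N" * spacer_len
    for i, rec in enumerate(assembly):
        if i:
            parts.append(spacer)
            offset += spacer_len
        blocks.append((offset, len(rec), rec.name))
        parts.append(rec.sequence)
        offset += len(rec)
    combined = SequenceRecord(name=name, sequence="".join(parts))
    return Assembly(
        records=[combined],
        dialect=assembly.dialect,
        coordinate_map=CoordinateMap(blocks=tuple(blocks)),
    )


def extract_flanks(assembly: Assembly, locus, flank_len: int = 300) -> tuple[str, str, bool]:
    """Return (left, right, complete) flanking sequence around a repeat locus.

    ``left``/``right`` are the up-to-``flank_len`` bases adjacent to the
    locus on its contig; ``complete`` is true iff both have exactly
    ``flank_len`` bases. Truncation at contig ends is reported via the flag,
    never as an error.
    """
    rec = assembly.get(locus.contig)
    if not (0 <= locus.start < locus.end <= len(rec)):
        raise DataError(
            f"locus [{locus.start},{locus.end}) outside contig {locus.contig!r} (len {len(rec)})"
        )
    left = rec.sequence[max(0, locus.start - flank_len) : locus.start]
    right = rec.sequence[locus.end : locus.end + flank_len]
    complete = len(left) == flank_len and len(right) == flank_len
    return left, right, complete
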