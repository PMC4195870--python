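"""Candidate filtering, ranking, output, and the end-to-end discover run.

The candidate filters mirror the validation rules used when taking markers
to the bench: (a) keep only the configured motif sizes (tri-nucleotide by
default, to avoid di-nucleotide "stutter" scoring problems), (b) require
high-quality variant support, (c) require complete, N-free flanks long
enough to design primers in, and finally require every supporting length
change to be a whole number of repeat units. Kept candidates are ranked by
their largest implied repeat count and the top k written out as
primer-ready FASTA, with the fixed-in-one-population subset in a separate
file.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .config import Config
from .errors import DataError
from .polymorphism import PolymorphicStr, call_polymorphic_strs
from .sequence_io import Assembly, extract_flanks
from .str_scanner import StrLocus, scan_assembly
from .variant_io import Variant, parse_vcf, normalize_indel, select_indels

__all__ = [
    "CandidateMarker",
    "DiscoveryResult",
    "filter_candidates",
    "rank_and_select",
    "expected_fragment_span",
    "write_candidate_fasta",
    "write_fixed_fasta",
    "write_report",
    "discover",
]

logger = logging.getLogger(__name__)

REASON_MOTIF_SIZE = "motif-size"
REASON_LOW_QUAL = "low-qual"
REASON_FLANK_INCOMPLETE = "flank-incomplete"
REASON_FLANK_N = "flank-N"
REASON_NON_UNIT_MULTIPLE = "non-unit-multiple"


@dataclass
class CandidateMarker:
    """A polymorphic repeat with primer-design flanks, or its exclusion."""

    pstr: PolymorphicStr
    left_flank: str = ""
    right_flank: str = ""
    exclusion_reason: str | None = None

    @property
    def locus(self) -> StrLocus:
        return self.pstr.locus

    @property
    def kept(self) -> bool:
        return self.exclusion_reason is None

    def title(self) -> str:
        """Pipe-delimited FASTA title; coordinates 1-based inclusive."""
        locus = self.locus
        units = sorted(self.pstr.allele_units)
        pops = ",".join(f"{p}:{s}" for p, s in sorted(self.pstr.pop_status.items()))
        return (
            f"{locus.contig}|{locus.start + 1}-{locus.end}|{locus.motif}x{locus.units}"
            f"|alleles={units[0]}-{units[-1]}|pops={pops}"
        )

    def sequence(self, assembly: Assembly) -> str:
        locus = self.locus
        repeat = assembly.get(locus.contig).sequence[locus.start : locus.end]
        return self.left_flank + repeat + self.right_flank


def _classify(pstr: PolymorphicStr, assembly: Assembly, config: Config) -> CandidateMarker:
    left, right, complete = extract_flanks(assembly, pstr.locus, config.flank_len)
    marker = CandidateMarker(pstr=pstr, left_flank=left, right_flank=right)
    # Single primary reason, first failing rule in filter order.
    if pstr.locus.unit_size not in config.candidate_unit_sizes:
        marker.exclusion_reason = REASON_MOTIF_SIZE
    elif any(v.qual is None or v.qual < config.qual_min for v in pstr.variants):
        marker.exclusion_reason = REASON_LOW_QUAL
    elif not complete:
        marker.exclusion_reason = REASON_FLANK_INCOMPLETE
    elif "N" in left or "N" in right:
        marker.exclusion_reason = REASON_FLANK_N
    elif not pstr.unit_consistent:
        marker.exclusion_reason = REASON_NON_UNIT_MULTIPLE
    return marker


def filter_candidates(
    pstrs: Iterable[PolymorphicStr], assembly: Assembly, config: Config | None = None
) -> tuple[list[CandidateMarker], list[CandidateMarker]]:
    """Partition polymorphic repeats into (kept, excluded-with-reason)."""
    config = config or Config()
    kept: list[CandidateMarker] = []
    excluded: list[CandidateMarker] = []
    for pstr in pstrs:
        marker = _classify(pstr, assembly, config)
        (kept if marker.kept else excluded).append(marker)
    return kept, excluded


def rank_and_select(kept: Sequence[CandidateMarker], top_k: int = 20) -> list[CandidateMarker]:
    """Top-k candidates by greatest implied repeat count.

    Sort key: max allele repeat count descending, reference repeat count
    descending, then (contig, start) ascending — a stable total order, so
    the selection is invariant to input permutation.
    """
    ranked = sorted(
        kept,
        key=lambda m: (
            -max(m.pstr.allele_units),
            -m.locus.units,
            m.locus.contig,
            m.locus.start,
        ),
    )
    return ranked[:top_k]


def expected_fragment_span(
    min_len_bp: int, unit_size: int, min_units: int, max_units: int
) -> int:
    """Largest PCR fragment length implied by a marker's allele range.

    Alleles differing by repeat count differ in amplicon size by
    ``unit_size`` bp per unit, so the maximum fragment is
    ``min_len_bp + unit_size * (max_units - min_units)``.
    """
    if max_units < min_units or min_units < 0:
        raise DataError("need max_units >= min_units >= 0")
    return min_len_bp + unit_size * (max_units - min_units)


def _write_fasta(markers: Sequence[CandidateMarker], assembly: Assembly, path) -> None:
    with open(path, "w") as fh:
        for marker in markers:
            fh.write(f">{marker.title()}\n{marker.sequence(assembly)}\n")


def write_candidate_fasta(markers: Sequence[CandidateMarker], assembly: Assembly, path) -> None:
    """Primer-ready FASTA: left flank + repeat + right flank per candidate."""
    _write_fasta(markers, assembly, path)


def write_fixed_fasta(markers: Sequence[CandidateMarker], assembly: Assembly, path) -> None:
    """The subset fixed in at least one population, same record format."""
    _write_fasta([m for m in markers if m.pstr.fixed_in_some], assembly, path)


def write_report(markers: Sequence[CandidateMarker], path) -> pd.DataFrame:
    """Tab-separated audit of every polymorphic repeat, kept or excluded."""
    rows = []
    for marker in markers:
        locus = marker.locus
        units = sorted(marker.pstr.allele_units)
        rows.append(
            {
                "contig": locus.contig,
                "start": locus.start + 1,
                "end": locus.end,
                "motif": locus.motif,
                "units": locus.units,
                "allele_units": ",".join(map(str, units)),
                "unit_consistent": marker.pstr.unit_consistent,
                "n_variants": len(marker.pstr.variants),
                "min_qual": marker.pstr.min_qual,
                "pop_status": ";".join(f"{p}:{s}" for p, s in sorted(marker.pstr.pop_status.items())),
                "fixed_in_some": marker.pstr.fixed_in_some,
                "kept": marker.kept,
                "exclusion_reason": marker.exclusion_reason or "",
            }
        )
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


@dataclass
class DiscoveryResult:
    """Everything one discover run produced, with stage counts."""

    assembly: Assembly
    loci: list[StrLocus]
    n_indels: int
    pstrs: list[PolymorphicStr]
    kept: list[CandidateMarker]
    excluded: list[CandidateMarker]
    selected: list[CandidateMarker]
    config: Config

    @property
    def fixed(self) -> list[CandidateMarker]:
        return [m for m in self.selected if m.pstr.fixed_in_some]

    def counts(self) -> dict:
        by_reason: dict[str, int] = {}
        for m in self.excluded:
            by_reason[m.exclusion_reason] = by_reason.get(m.exclusion_reason, 0) + 1
        loci_by_size: dict[int, int] = {}
        for locus in self.loci:
            loci_by_size[locus.unit_size] = loci_by_size.get(locus.unit_size, 0) + 1
        return {
            "records": len(self.assembly),
            "str_loci": len(self.loci),
            "str_loci_by_unit_size": {str(k): v for k, v in sorted(loci_by_size.items())},
            "indels": self.n_indels,
            "assigned_loci": len(self.pstrs),
            "kept": len(self.kept),
            "excluded_by_reason": by_reason,
            "selected": len(self.selected),
            "fixed_in_some": len(self.fixed),
        }


def discover(
    assembly: Assembly,
    variants: Sequence[Variant],
    config: Config | None = None,
    *,
    require_pass: bool = False,
) -> DiscoveryResult:
    """Run the full marker-discovery pipeline on in-memory inputs.

    Scans the assembly for repeats, left-normalizes and assigns the VCF's
    indels, classifies per-population status, applies the candidate
    filters, and ranks the kept markers.
    """
    config = config or Config()
    loci = scan_assembly(assembly, config)
    if require_pass:
        variants = [v for v in variants if v.filter_pass]
    indels = select_indels(variants)
    normalized = [normalize_indel(v, assembly) for v in indels]
    pstrs = call_polymorphic_strs(loci, normalized, config)
    kept, excluded = filter_candidates(pstrs, assembly, config)
    selected = rank_and_select(kept, config.top_k)
    return DiscoveryResult(
        assembly=assembly,
        loci=loci,
        n_indels=len(indels),
        pstrs=pstrs,
        kept=kept,
        excluded=excluded,
        selected=selected,
        config=config,
    )


def discover_files(
    fasta_path,
    vcf_path,
    config: Config | None = None,
    *,
    dialect: str = "auto",
    concat: bool = False,
    require_pass: bool = False,
) -> DiscoveryResult:
    """File-level convenience wrapper around :func:`discover`."""
    from .sequence_io import concat_with_spacer, read_assembly

    config = config or Config()
    assembly = read_assembly(fasta_path, dialect)
    if concat:
        assembly = concat_with_spacer(assembly, config.spacer_len, config=config)
    variants = parse_vcf(vcf_path)
    return discover(assembly, variants, config, require_pass=require_pass)
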