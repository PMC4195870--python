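"""VCF parsing, indel selection and left-normalization.

Records are read with pysam and exploded into bi-allelic
:class:`Variant` objects (one per alternate allele, allele-depth columns
re-sliced per alternate). Indels are left-normalized against the assembly
so that an insertion or deletion inside a repeat run is always anchored at
the leftmost equivalent position — different variant callers place such
events differently, and the repeat-assignment step depends on a canonical
placement.

Per-sample allele support prefers the AD (allele depth) FORMAT field; when
absent, the genotype call is used with unknown depth and a logged warning
(pooled libraries make diploid genotype semantics unreliable).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pysam

from .errors import DataError, ParseError
from .sequence_io import Assembly

__all__ = [
    "AlleleSupport",
    "Variant",
    "parse_vcf",
    "select_indels",
    "normalize_indel",
    "write_vcf",
]

logger = logging.getLogger(__name__)

_SYMBOLIC = ("<", "[", "]", ".")


@dataclass(frozen=True)
class AlleleSupport:
    """Read support for (ref, alt) in one population pool at one variant."""

    ref_count: int = 0
    alt_count: int = 0
    depth: int | None = None
    genotype: tuple[int | None, ...] | None = None

    @property
    def total(self) -> int:
        if self.depth is not None:
            return self.depth
        return self.ref_count + self.alt_count

    @property
    def alt_fraction(self) -> float | None:
        covered = self.ref_count + self.alt_count
        if covered == 0:
            return None
        return self.alt_count / covered


@dataclass(frozen=True)
class Variant:
    """One bi-allelic variant (a multi-allelic VCF line yields several)."""

    contig: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    qual: float | None
    samples: dict[str, AlleleSupport]
    filter_pass: bool = True

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        if len(self.ref) != len(self.alt):
            return "INDEL"
        return "OTHER"

    @property
    def length_delta(self) -> int:
        """Signed size change in bp (insertion positive)."""
        return len(self.alt) - len(self.ref)

    @property
    def start0(self) -> int:
        """0-based start of the reference allele."""
        return self.pos - 1

    @property
    def edit_interval(self) -> tuple[int, int]:
        """0-based half-open reference interval touched by the edit."""
        return self.pos - 1, self.pos - 1 + len(self.ref)


def _support_from_sample(sample, alt_index: int) -> AlleleSupport:
    """Build AlleleSupport for alternate ``alt_index`` (1-based ALT slot)."""
    gt = sample.get("GT")
    genotype = tuple(gt) if gt is not None else None
    ad = sample.get("AD")
    dp = sample.get("DP")
    if ad is not None and any(a is not None for a in ad):
        ref_count = int(ad[0] or 0)
        alt_count = int(ad[alt_index] or 0) if alt_index < len(ad) else 0
        depth = int(dp) if dp is not None else sum(int(a or 0) for a in ad)
        return AlleleSupport(ref_count=ref_count, alt_count=alt_count, depth=depth, genotype=genotype)
    # No AD: fall back to the genotype call with unknown depth.
    if genotype is not None and any(g is not None for g in genotype):
        alleles = [g for g in genotype if g is not None]
        ref_count = sum(1 for g in alleles if g == 0)
        alt_count = sum(1 for g in alleles if g == alt_index)
        return AlleleSupport(
            ref_count=ref_count,
            alt_count=alt_count,
            depth=int(dp) if dp is not None else None,
            genotype=genotype,
        )
    return AlleleSupport(depth=int(dp) if dp is not None else None, genotype=genotype)


def parse_vcf(path) -> list[Variant]:
    """Read a VCF 4.x file (plain or gzipped) into Variant objects.

    Multi-allelic records are split into one Variant per alternate with the
    AD column re-sliced per alternate; symbolic alternates (<DEL>,
    breakends, '*') are skipped with a warning. Sample names come from the
    header.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: not a parseable VCF ({exc})") from exc
    sample_names = list(vcf.header.samples)
    warned_gt_fallback = False
    variants: list[Variant] = []
    with vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            filter_keys = list(rec.filter.keys())
            filter_pass = not filter_keys or filter_keys == ["PASS"]
            for alt_index, alt in enumerate(rec.alts, start=1):
                if any(c in alt for c in _SYMBOLIC) or alt == "*":
                    logger.warning(
                        "skipping symbolic alternate %s at %s:%s", alt, rec.contig, rec.pos
                    )
                    continue
                samples = {}
                for name in sample_names:
                    sample = rec.samples[name]
                    if not warned_gt_fallback and sample.get("AD") is None and sample.get("GT"):
                        logger.warning(
                            "VCF has no AD field; falling back to genotype calls for allele support"
                        )
                        warned_gt_fallback = True
                    samples[name] = _support_from_sample(sample, alt_index)
                variants.append(
                    Variant(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        qual=rec.qual,
                        samples=samples,
                        filter_pass=filter_pass,
                    )
                )
    return variants


def select_indels(variants: Iterable[Variant]) -> list[Variant]:
    """Exactly the kind == INDEL subset, input order preserved."""
    return [v for v in variants if v.kind == "INDEL"]


def normalize_indel(variant: Variant, assembly: Assembly) -> Variant:
    """Left-align an indel against the assembly and trim to anchored form.

    The returned representation is the leftmost equivalent (applying ref->alt
    to the contig yields the same edited sequence) with a single shared
    anchor base; the operation is idempotent. A reference-allele mismatch
    with the assembly is a hard error.
    """
    if variant.kind != "INDEL":
        raise DataError(f"normalize_indel requires an INDEL, got {variant.kind}")
    seq = assembly.get(variant.contig).sequence
    pos0 = variant.pos - 1
    if seq[pos0 : pos0 + len(variant.ref)] != variant.ref:
        raise DataError(
            f"{variant.contig}:{variant.pos}: VCF ref {variant.ref!r} does not match assembly "
            f"{seq[pos0:pos0 + len(variant.ref)]!r}"
        )
    ref, alt = variant.ref, variant.alt
    # Left-shift: drop shared trailing bases, re-anchoring from the reference.
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos0 == 0:
                    base = "N"  # cannot anchor left of the contig; keep degenerate
                    ref, alt = base + ref, base + alt
                    break
                pos0 -= 1
                base = seq[pos0]
                ref, alt = base + ref, base + alt
            continue
        break
    # Trim shared leading bases beyond the single anchor.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    if ref == variant.ref and alt == variant.alt and pos0 == variant.pos - 1:
        return variant
    return replace(variant, pos=pos0 + 1, ref=ref, alt=alt)


def write_vcf(
    variants: Sequence[Variant],
    path,
    sample_names: Sequence[str],
    contigs: dict[str, int],
) -> None:
    """Write variants as a minimal VCF 4.2 text file (GT:AD:DP per sample)."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += list(sample_names)
    lines.append("\t".join(header))
    for v in sorted(variants, key=lambda v: (v.contig, v.pos, v.alt)):
        qual = "." if v.qual is None else f"{v.qual:g}"
        fields = [v.contig, str(v.pos), ".", v.ref, v.alt, qual, "PASS" if v.filter_pass else "q10", ".", "GT:AD:DP"]
        for name in sample_names:
            sup = v.samples.get(name, AlleleSupport())
            if sup.genotype is not None:
                gt = "/".join("." if g is None else str(g) for g in sup.genotype)
            elif sup.alt_count and sup.ref_count:
                gt = "0/1"
            elif sup.alt_count:
                gt = "1/1"
            else:
                gt = "0/0"
            depth = sup.total
            fields.append(f"{gt}:{sup.ref_count},{sup.alt_count}:{depth}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
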