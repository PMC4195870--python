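"""Synthetic assemblies with planted STRs and matched pooled-population VCFs.

The generator emulates the study design the pipeline targets: a draft
assembly scanned for repeats, and a two-pool variant report in which repeat
copy-number variation shows up as indels whose per-pool allele depths
reflect each pool's allele frequency. Background sequence is drawn from an
i.i.d. base model at a chosen GC content and then *rejection-cleaned*: any
accidental repeat meeting the scan thresholds is resampled, so the planted
truth table is exact rather than probabilistic. Read-level simulation is
deliberately absent — the VCF is fabricated directly, since mapping and
variant calling sit upstream of this tool.

Planted loci fall into categories with known expected outcomes:

* ``polymorphic``      — unit-multiple indel(s), clean quality and flanks;
* ``monomorphic``      — no variant at all (must never be reported);
* ``trap-non-multiple``— an indel whose length is not a unit multiple;
* ``trap-low-qual``    — an indel below the quality threshold;
* ``trap-flank-n``     — clean indel but an N planted inside a flank.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import Config
from .errors import DataError
from .pipeline import (
    REASON_FLANK_N,
    REASON_LOW_QUAL,
    REASON_NON_UNIT_MULTIPLE,
)
from .polymorphism import (
    STATUS_FIXED_ALT,
    STATUS_FIXED_REF,
    STATUS_POLYMORPHIC,
)
from .sequence_io import Assembly, SequenceRecord
from .str_scanner import StrLocus, find_strs
from .variant_io import AlleleSupport, Variant, write_vcf

__all__ = [
    "PlantSpec",
    "TruthLocus",
    "generate_genome",
    "generate_vcf",
    "standard_scenario",
    "write_truth_table",
    "TRI_MOTIFS",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Primitive tri-nucleotide motifs in the style reported for these markers.
TRI_MOTIFS = ("ATC", "TCA", "AAG", "ATT", "CAG", "TGA", "ACG", "CGT", "TAC", "AAC")

CATEGORIES = ("polymorphic", "monomorphic", "trap-non-multiple", "trap-low-qual", "trap-flank-n")


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: a motif repeated ``units`` times, plus its scenario."""

    motif: str
    units: int
    category: str = "polymorphic"
    pop_freqs: tuple[float, ...] = (0.5, 0.4)
    unit_changes: tuple[int, ...] = (2,)  # repeat-count change per planted indel

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise DataError(f"unknown category {self.category!r}")


@dataclass
class TruthLocus:
    """One planted repeat with every parameter needed to predict its verdict."""

    contig: str
    start: int
    motif: str
    units: int
    category: str
    pop_freqs: dict[str, float]
    indel_deltas: list[int]  # signed bp
    qual: float | None = None
    expected_reason: str | None = None  # None => expected candidate
    expected_fixed: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.motif) * self.units

    @property
    def is_polymorphic(self) -> bool:
        return self.category != "monomorphic"

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.motif)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]


def _expected_reason(spec: PlantSpec, config: Config) -> str | None:
    if spec.category == "monomorphic":
        return None
    if len(spec.motif) not in config.candidate_unit_sizes:
        return "motif-size"
    if spec.category == "trap-low-qual":
        return REASON_LOW_QUAL
    if spec.category == "trap-flank-n":
        return REASON_FLANK_N
    if spec.category == "trap-non-multiple":
        return REASON_NON_UNIT_MULTIPLE
    return None


def _expected_fixed(freqs: Sequence[float], config: Config) -> bool:
    def status(f: float) -> str:
        if f <= config.fixed_low:
            return STATUS_FIXED_REF
        if f >= config.fixed_high:
            return STATUS_FIXED_ALT
        return STATUS_POLYMORPHIC

    statuses = [status(f) for f in freqs]
    fixed = [s for s in statuses if s != STATUS_POLYMORPHIC]
    if not fixed:
        return False
    return STATUS_POLYMORPHIC in statuses or len(set(fixed)) > 1


def generate_genome(
    n_contigs: int,
    contig_len: int,
    gc: float,
    plants: Sequence[PlantSpec],
    seed: int,
    config: Config | None = None,
    pop_names: Sequence[str] = ("popA", "popB"),
) -> tuple[Assembly, list[TruthLocus]]:
    """Build an assembly with exactly the planted repeats and nothing else.

    Loci are spread round-robin over contigs at even spacing (at least one
    flank length from every contig end and two flank lengths apart).
    Background is resampled until a scan finds exactly the planted loci;
    boundary bases are constrained so no planted run can extend. Fully
    deterministic under ``seed``.
    """
    config = config or Config()
    rng = np.random.default_rng(seed)
    per_contig: list[list[PlantSpec]] = [[] for _ in range(n_contigs)]
    for i, spec in enumerate(plants):
        per_contig[i % n_contigs].append(spec)

    records: list[SequenceRecord] = []
    truth: list[TruthLocus] = []
    for ci in range(n_contigs):
        name = f"contig{ci + 1:02d}"
        specs = per_contig[ci]
        repeat_lens = [len(s.motif) * s.units for s in specs]
        # Two flank lengths between loci keeps every flank window disjoint
        # (a planted flank N must never bleed into a neighbour's window).
        margin = 2 * config.flank_len + 10
        need = sum(repeat_lens) + (len(specs) + 1) * margin
        if need > contig_len:
            raise DataError(
                f"cannot pack {len(specs)} loci into a {contig_len} bp contig "
                f"(needs >= {need} bp)"
            )
        gap = (contig_len - sum(repeat_lens)) // (len(specs) + 1) if specs else contig_len
        arr = _random_bases(rng, contig_len, gc).copy()
        starts: list[int] = []
        cursor = 0
        for spec, rlen in zip(specs, repeat_lens):
            start = cursor + gap
            repeat = (spec.motif * spec.units).encode("ascii")
            arr[start : start + rlen] = np.frombuffer(repeat, dtype=np.uint8)
            starts.append(start)
            cursor = start + rlen
        seq_bytes = bytearray(arr.tobytes())

        def _resample_base(idx: int, forbidden: set[int]) -> None:
            choices = [b for b in BASES if b not in forbidden]
            seq_bytes[idx] = int(rng.choice(choices))

        planted_spans = []
        for spec, start in zip(specs, starts):
            rlen = len(spec.motif) * spec.units
            planted_spans.append((start, start + rlen))
            first, last = ord(spec.motif[0]), ord(spec.motif[-1])
            if start > 0 and seq_bytes[start - 1] == last:
                _resample_base(start - 1, {last})
            end = start + rlen
            if end < contig_len and seq_bytes[end] == first:
                _resample_base(end, {first})

        def _in_planted(i: int) -> bool:
            return any(a <= i < b for a, b in planted_spans)

        expected_keys = {
            (name, start, start + len(spec.motif) * spec.units, spec.motif)
            for spec, start in zip(specs, starts)
        }
        for _ in range(200):
            record = SequenceRecord(name=name, sequence=seq_bytes.decode("ascii"))
            found = {(l.contig, l.start, l.end, l.motif) for l in find_strs(record, config)}
            rogue = found - expected_keys
            if not rogue and expected_keys <= found:
                break
            for _, a, b, _motif in rogue:
                for i in range(max(0, a - 1), min(contig_len, b + 1)):
                    if not _in_planted(i):
                        seq_bytes[i] = int(rng.choice(BASES))
            # Re-pin planted boundaries in case resampling touched them.
            for spec, start in zip(specs, starts):
                first, last = ord(spec.motif[0]), ord(spec.motif[-1])
                if start > 0 and seq_bytes[start - 1] == last:
                    _resample_base(start - 1, {last})
                end = start + len(spec.motif) * spec.units
                if end < contig_len and seq_bytes[end] == first:
                    _resample_base(end, {first})
        else:
            raise DataError("failed to clean accidental repeats from background sequence")

        # Plant flank Ns for trap-flank-n loci (N cannot create a repeat).
        for spec, start in zip(specs, starts):
            if spec.category == "trap-flank-n":
                seq_bytes[start - config.flank_len // 2] = ord("N")

        record = SequenceRecord(name=name, sequence=seq_bytes.decode("ascii"))
        found = {(l.contig, l.start, l.end, l.motif) for l in find_strs(record, config)}
        if found != expected_keys:
            raise DataError("planted locus verification failed after N placement")
        records.append(record)

        for spec, start in zip(specs, starts):
            k = len(spec.motif)
            deltas = []
            if spec.category == "trap-non-multiple":
                deltas = [d for d in spec.unit_changes]  # already raw bp offsets
            elif spec.category != "monomorphic":
                deltas = [c * k for c in spec.unit_changes]
            truth.append(
                TruthLocus(
                    contig=name,
                    start=start,
                    motif=spec.motif,
                    units=spec.units,
                    category=spec.category,
                    pop_freqs={p: f for p, f in zip(pop_names, spec.pop_freqs)},
                    indel_deltas=deltas,
                    expected_reason=_expected_reason(spec, config),
                    expected_fixed=(
                        spec.category == "polymorphic"
                        and _expected_fixed(spec.pop_freqs, config)
                    ),
                )
            )
    truth.sort(key=lambda t: (t.contig, t.start))
    return Assembly(records=records, dialect="fasta"), truth


def generate_vcf(
    truth: Sequence[TruthLocus],
    assembly: Assembly,
    seed: int,
    pops: Sequence[str] = ("popA", "popB"),
    depth_mean: float = 30.0,
    qual_range: tuple[float, float] = (30.0, 100.0),
    low_qual: float = 5.0,
    n_decoy_snps: int = 20,
    path=None,
) -> list[Variant]:
    """Fabricate the pooled-library variant report matching a truth table.

    Each non-monomorphic locus receives one left-normalized indel per
    planted length change; per-pool allele depths are binomial draws at the
    stated allele frequency with Poisson-distributed depth. Decoy SNPs are
    sprinkled into the background to exercise the indel filter. Writes a
    VCF 4.2 text file when ``path`` is given.
    """
    rng = np.random.default_rng(seed)
    variants: list[Variant] = []
    spans: dict[str, list[tuple[int, int]]] = {}
    for t in truth:
        spans.setdefault(t.contig, []).append((t.start, t.end))
    for t in truth:
        seq = assembly.get(t.contig).sequence
        anchor = seq[t.start - 1]
        for delta in t.indel_deltas:
            if delta > 0:
                if delta % len(t.motif) == 0:
                    ins = t.motif * (delta // len(t.motif))
                else:
                    # Raw-length trap insertion; last base chosen so the
                    # record is already left-normalized (cannot shift left).
                    body = (t.motif * (delta // len(t.motif) + 2))[: delta - 1]
                    last = next(b for b in "ACGT" if b != anchor)
                    ins = body + last
                ref, alt = anchor, anchor + ins
            else:
                if t.units * len(t.motif) < -delta:
                    raise DataError("deletion larger than the planted run")
                ref, alt = anchor + seq[t.start : t.start - delta], anchor
            qual = low_qual if t.category == "trap-low-qual" else float(rng.uniform(*qual_range))
            if t.qual is None:
                t.qual = qual
            samples = {}
            for pop in pops:
                freq = t.pop_freqs.get(pop, 0.5)
                depth = max(1, int(rng.poisson(depth_mean)))
                alt_count = int(rng.binomial(depth, freq))
                ref_count = depth - alt_count
                if alt_count and ref_count:
                    gt = (0, 1)
                elif alt_count:
                    gt = (1, 1)
                else:
                    gt = (0, 0)
                samples[pop] = AlleleSupport(
                    ref_count=ref_count, alt_count=alt_count, depth=depth, genotype=gt
                )
            variants.append(
                Variant(
                    contig=t.contig,
                    pos=t.start,  # 1-based position of the 0-based anchor (start-1)
                    ref=ref,
                    alt=alt,
                    qual=qual,
                    samples=samples,
                )
            )
    # Decoy SNPs in background sequence, away from planted repeats.
    contig_names = [r.name for r in assembly]
    for _ in range(n_decoy_snps):
        cname = contig_names[int(rng.integers(len(contig_names)))]
        seq = assembly.get(cname).sequence
        for _attempt in range(50):
            pos0 = int(rng.integers(10, len(seq) - 10))
            near_repeat = any(a - 10 <= pos0 < b + 10 for a, b in spans.get(cname, []))
            if seq[pos0] != "N" and not near_repeat:
                break
        else:
            continue
        ref = seq[pos0]
        alt = next(b for b in "ACGT" if b != ref)
        samples = {}
        for pop in pops:
            depth = max(1, int(rng.poisson(depth_mean)))
            alt_count = int(rng.binomial(depth, 0.5))
            samples[pop] = AlleleSupport(
                ref_count=depth - alt_count, alt_count=alt_count, depth=depth,
                genotype=(0, 1) if 0 < alt_count < depth else (1, 1),
            )
        variants.append(
            Variant(
                contig=cname,
                pos=pos0 + 1,
                ref=ref,
                alt=alt,
                qual=float(rng.uniform(*qual_range)),
                samples=samples,
            )
        )
    variants.sort(key=lambda v: (v.contig, v.pos, v.alt))
    if path is not None:
        contigs = {r.name: len(r) for r in assembly}
        write_vcf(variants, path, sample_names=list(pops), contigs=contigs)
    return variants


def standard_scenario(
    seed: int,
    *,
    n_poly: int = 30,
    n_fixed: int = 10,
    n_mono: int = 10,
    n_trap_multiple: int = 4,
    n_trap_qual: int = 3,
    n_trap_flankn: int = 3,
    n_contigs: int = 4,
    contig_len: int = 50_000,
    gc: float = 0.38,
    depth_mean: float = 30.0,
    pops: Sequence[str] = ("popA", "popB"),
    config: Config | None = None,
) -> tuple[Assembly, list[TruthLocus], list[Variant]]:
    """The benchmark dataset: a 200 kb two-pool design with planted truth.

    Tri-nucleotide loci only (the validation filter's default):
    ``n_poly`` polymorphic in both pools (frequencies 0.5/0.4), ``n_fixed``
    fixed in one pool and polymorphic in the other (1.0/0.3), ``n_mono``
    with no variant, plus the three trap categories.
    """
    config = config or Config()
    rng = np.random.default_rng(seed + 7)
    specs: list[PlantSpec] = []

    def motif_units(i: int) -> tuple[str, int]:
        motif = TRI_MOTIFS[i % len(TRI_MOTIFS)]
        units = int(rng.integers(8, 21))
        return motif, units

    i = 0
    for _ in range(n_poly):
        motif, units = motif_units(i)
        change = int(rng.integers(1, 5))
        specs.append(
            PlantSpec(motif, units, "polymorphic", (0.5, 0.4), (change,))
        )
        i += 1
    for _ in range(n_fixed):
        motif, units = motif_units(i)
        specs.append(PlantSpec(motif, units, "polymorphic", (1.0, 0.3), (2,)))
        i += 1
    for _ in range(n_mono):
        motif, units = motif_units(i)
        specs.append(PlantSpec(motif, units, "monomorphic", (0.0, 0.0), ()))
        i += 1
    for _ in range(n_trap_multiple):
        motif, units = motif_units(i)
        specs.append(PlantSpec(motif, units, "trap-non-multiple", (0.5, 0.5), (4,)))
        i += 1
    for _ in range(n_trap_qual):
        motif, units = motif_units(i)
        specs.append(PlantSpec(motif, units, "trap-low-qual", (0.5, 0.5), (2,)))
        i += 1
    for _ in range(n_trap_flankn):
        motif, units = motif_units(i)
        specs.append(PlantSpec(motif, units, "trap-flank-n", (0.5, 0.5), (2,)))
        i += 1

    order = rng.permutation(len(specs))
    specs = [specs[j] for j in order]
    assembly, truth = generate_genome(
        n_contigs, contig_len, gc, specs, seed=seed, config=config, pop_names=pops
    )
    variants = generate_vcf(
        truth, assembly, seed=seed + 1, pops=pops, depth_mean=depth_mean
    )
    return assembly, truth, variants


def write_truth_table(truth: Sequence[TruthLocus], path) -> pd.DataFrame:
    """Tab-separated truth table (1-based inclusive coordinates)."""
    rows = []
    for t in truth:
        rows.append(
            {
                "contig": t.contig,
                "start": t.start + 1,
                "end": t.end,
                "motif": t.motif,
                "units": t.units,
                "category": t.category,
                "pop_freqs": ";".join(f"{p}={f:g}" for p, f in t.pop_freqs.items()),
                "indel_deltas": ",".join(map(str, t.indel_deltas)),
                "expected_verdict": (
                    "candidate"
                    if t.is_polymorphic and t.expected_reason is None
                    else ("absent" if not t.is_polymorphic else f"excluded:{t.expected_reason}")
                ),
                "expected_fixed": t.expected_fixed,
            }
        )
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
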