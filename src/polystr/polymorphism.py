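"""Join indels to repeat loci and classify per-population status.

An indel whose (left-normalized) edit interval falls inside the window
``[locus.start - unit_size, locus.end)`` is evidence that the repeat's
copy number varies: each unit-multiple length change implies an alternate
repeat count. Per population pool, the alternate-allele read fraction at
the supporting indel(s) decides whether the pool is polymorphic or fixed
for one allele, subject to a minimum-depth gate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import Config
from .errors import DataError
from .str_scanner import StrLocus
from .variant_io import Variant

__all__ = ["PolymorphicStr", "assign_indels", "population_status", "call_polymorphic_strs"]

logger = logging.getLogger(__name__)

STATUS_POLYMORPHIC = "polymorphic"
STATUS_FIXED_REF = "fixed_ref"
STATUS_FIXED_ALT = "fixed_alt"
STATUS_NO_DATA = "no_data"


@dataclass
class PolymorphicStr:
    """A repeat locus supported by at least one indel.

    ``allele_units`` is the set of repeat counts implied by the reference
    and each assigned alternate; ``unit_consistent`` is false when any
    length change is not a whole number of units (or would delete more than
    the run holds), which mirrors markers whose observed fragment patterns
    are inconsistent with the repeat's unit size.
    """

    locus: StrLocus
    variants: list[Variant]
    pop_status: dict[str, str] = field(default_factory=dict)

    @property
    def allele_units(self) -> set[int]:
        units = {self.locus.units}
        k = self.locus.unit_size
        for v in self.variants:
            if v.length_delta % k == 0:
                implied = self.locus.units + v.length_delta // k
                if implied >= 0:
                    units.add(implied)
        return units

    @property
    def unit_consistent(self) -> bool:
        k = self.locus.unit_size
        for v in self.variants:
            if v.length_delta % k != 0:
                return False
            if self.locus.units + v.length_delta // k < 0:
                return False
        return True

    @property
    def fixed_in_some(self) -> bool:
        """True when one pool is fixed while variation exists elsewhere."""
        statuses = [s for s in self.pop_status.values() if s != STATUS_NO_DATA]
        fixed = [s for s in statuses if s in (STATUS_FIXED_REF, STATUS_FIXED_ALT)]
        if not fixed:
            return False
        if any(s == STATUS_POLYMORPHIC for s in statuses):
            return True
        return len(set(fixed)) > 1  # fixed on different alleles

    @property
    def min_qual(self) -> float | None:
        quals = [v.qual for v in self.variants]
        if any(q is None for q in quals):
            return None
        return min(quals)


def _overlapping_loci(locus_list: Sequence[StrLocus], variant: Variant) -> list[StrLocus]:
    lo, hi = variant.edit_interval
    hits = []
    for locus in locus_list:
        if lo >= locus.start - locus.unit_size and hi <= locus.end:
            hits.append(locus)
    return hits


def assign_indels(loci: Sequence[StrLocus], indels: Iterable[Variant]) -> list[PolymorphicStr]:
    """Assign each indel to at most one repeat locus.

    A locus qualifies when the indel's edit interval lies within
    ``[start - unit_size, end)`` (left-normalized indels anchor one base
    before the event, hence the one-unit extension to the left). Among
    qualifying loci the one whose unit size divides the length change wins;
    ties go to the longest locus, then the smallest start. Indels matching
    no locus are counted and logged, never errors.
    """
    by_contig: dict[str, list[StrLocus]] = {}
    for locus in loci:
        by_contig.setdefault(locus.contig, []).append(locus)
    assigned: dict[StrLocus, list[Variant]] = {}
    unassigned = 0
    for variant in indels:
        candidates = _overlapping_loci(by_contig.get(variant.contig, []), variant)
        if not candidates:
            unassigned += 1
            continue
        dividing = [l for l in candidates if abs(variant.length_delta) % l.unit_size == 0]
        pool = dividing or candidates
        best = min(pool, key=lambda l: (-(l.end - l.start), l.start))
        assigned.setdefault(best, []).append(variant)
    if unassigned:
        logger.info("%d indels matched no repeat locus", unassigned)
    out = [PolymorphicStr(locus=locus, variants=vs) for locus, vs in assigned.items()]
    out.sort(key=lambda p: (p.locus.contig, p.locus.start, p.locus.unit_size))
    return out


def population_status(pstr: PolymorphicStr, config: Config | None = None) -> PolymorphicStr:
    """Classify each population as polymorphic / fixed_ref / fixed_alt / no_data.

    Per population the alternate-allele fraction is taken as the maximum
    over the locus's assigned variants (most permissive evidence of
    polymorphism), using only variants whose pool depth meets ``min_depth``;
    pools with no adequately covered variant get no_data.
    """
    config = config or Config()
    sample_names: list[str] = []
    for v in pstr.variants:
        for name in v.samples:
            if name not in sample_names:
                sample_names.append(name)
    pops = list(config.populations) if config.populations is not None else sample_names
    unknown = set(pops) - set(sample_names)
    if unknown:
        raise DataError(f"configured populations {sorted(unknown)} not present in the VCF samples")
    status: dict[str, str] = {}
    for pop in pops:
        best_fraction: float | None = None
        for v in pstr.variants:
            sup = v.samples.get(pop)
            if sup is None or sup.total < config.min_depth:
                continue
            frac = sup.alt_fraction
            if frac is None:
                continue
            if best_fraction is None or frac > best_fraction:
                best_fraction = frac
        if best_fraction is None:
            status[pop] = STATUS_NO_DATA
        elif best_fraction <= config.fixed_low:
            status[pop] = STATUS_FIXED_REF
        elif best_fraction >= config.fixed_high:
            status[pop] = STATUS_FIXED_ALT
        else:
            status[pop] = STATUS_POLYMORPHIC
    pstr.pop_status = status
    return pstr


def call_polymorphic_strs(
    loci: Sequence[StrLocus], indels: Iterable[Variant], config: Config | None = None
) -> list[PolymorphicStr]:
    """assign_indels + population_status over all loci."""
    config = config or Config()
    pstrs = assign_indels(loci, indels)
    for pstr in pstrs:
        population_status(pstr, config)
    return pstrs
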