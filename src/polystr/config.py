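"""Run configuration.

One :class:`Config` object carries every tunable of the marker-discovery
pipeline: which repeat unit sizes to scan for, the minimum repeat count,
flank length for primer design, the contig-join spacer, and the quality /
depth / fixation thresholds used when classifying pooled-population status.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import yaml

from .errors import ConfigError

__all__ = ["Config"]


@dataclass(frozen=True)
class Config:
    """Pipeline parameters.

    Parameters
    ----------
    unit_sizes:
        Repeat unit lengths (bp) to scan for; subset of {2, 3, 4, 5}.
        Mononucleotide runs are never reported.
    min_units:
        Minimum number of repeat units for a run to count as an STR
        (inclusive).
    flank_len:
        Length (bp) of leading and trailing sequence emitted around each
        candidate repeat, sized for PCR primer design.
    spacer_len:
        Number of ``N`` bases inserted between contigs when an assembly is
        concatenated into a single strand. Must be long enough that no
        reportable STR can bridge a junction.
    qual_min:
        Minimum VCF QUAL for a variant to count as high-quality support.
    fixed_low, fixed_high:
        Pooled alternate-allele fraction thresholds: a population with
        fraction <= fixed_low is fixed for the reference allele, >= fixed_high
        fixed for the alternate; in between it is polymorphic.
    min_depth:
        Minimum per-population read depth at a variant for the population's
        status to be called at all (below it: no data).
    top_k:
        Number of top-ranked candidates to keep.
    candidate_unit_sizes:
        Unit sizes admitted by the candidate filter (the validation default
        keeps tri-nucleotide repeats only, which avoids the PCR "stutter"
        scoring problems of di-nucleotide markers).
    populations:
        Optional explicit population (VCF sample) names; default: all samples
        found in the VCF, in header order.
    rc_canonical:
        If true, canonical motif classes additionally fold reverse
        complements together (ATC and GAT become one class).
    """

    unit_sizes: frozenset[int] = frozenset({2, 3, 4, 5})
    min_units: int = 5
    flank_len: int = 300
    spacer_len: int = 100
    qual_min: float = 20.0
    fixed_low: float = 0.05
    fixed_high: float = 0.95
    min_depth: int = 8
    top_k: int = 20
    candidate_unit_sizes: frozenset[int] = frozenset({3})
    populations: tuple[str, ...] | None = None
    rc_canonical: bool = False

    def __post_init__(self):
        object.__setattr__(self, "unit_sizes", frozenset(int(u) for u in self.unit_sizes))
        object.__setattr__(
            self, "candidate_unit_sizes", frozenset(int(u) for u in self.candidate_unit_sizes)
        )
        if self.populations is not None:
            object.__setattr__(self, "populations", tuple(self.populations))
        if not self.unit_sizes or not self.unit_sizes <= {2, 3, 4, 5}:
            raise ConfigError(f"unit_sizes must be a non-empty subset of {{2,3,4,5}}, got {set(self.unit_sizes)}")
        if self.min_units < 2:
            raise ConfigError("min_units must be >= 2")
        if self.flank_len <= 0:
            raise ConfigError("flank_len must be > 0")
        if not (0 <= self.fixed_low < self.fixed_high <= 1):
            raise ConfigError("need 0 <= fixed_low < fixed_high <= 1")
        if self.min_depth < 0 or self.top_k < 0:
            raise ConfigError("min_depth and top_k must be >= 0")
        if self.spacer_len < self.min_safe_spacer:
            raise ConfigError(
                f"spacer_len {self.spacer_len} < {self.min_safe_spacer}; an STR could bridge a contig junction"
            )

    @property
    def min_safe_spacer(self) -> int:
        """Shortest N spacer that no reportable STR can span."""
        return max(self.unit_sizes) * self.min_units

    def with_updates(self, **kwargs) -> "Config":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        """Load a config from a YAML mapping whose keys mirror the fields."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a YAML mapping")
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "unit_sizes": sorted(self.unit_sizes),
            "min_units": self.min_units,
            "flank_len": self.flank_len,
            "spacer_len": self.spacer_len,
            "qual_min": self.qual_min,
            "fixed_low": self.fixed_low,
            "fixed_high": self.fixed_high,
            "min_depth": self.min_depth,
            "top_k": self.top_k,
            "candidate_unit_sizes": sorted(self.candidate_unit_sizes),
            "populations": list(self.populations) if self.populations else None,
            "rc_canonical": self.rc_canonical,
        }
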