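"""Domain types shared by every stage of the pipeline.

The vocabulary follows multiplexed (TMT) quantitative proteomics with
spike-in internal standards:

* **spike peptides** are synthetic peptides doped into each sample at a
  known amount, either *before* protein extraction (they report extraction
  losses) or *after* labeling (they report instrument/ionization drift);
* the **carrier digest** is a pre-digested bovine serum albumin (BSA)
  standard of known amount that anchors arbitrary instrument intensities
  to micrograms;
* **samples** live in multiplex batches ("plexes"), one tag (reporter
  channel) per sample.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class RegennormError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RegennormError):
    """A spike configuration, simulation config or CLI option is invalid."""

    exit_code = 2


class SchemaError(RegennormError):
    """An input table is missing a required column."""

    exit_code = 3


class ValidationError(RegennormError):
    """An input value violates a domain invariant."""

    exit_code = 3


class UndefinedReferenceError(RegennormError):
    """A normalization denominator (BSA or tier summary) is zero/missing."""

    exit_code = 3


class AnchorError(RegennormError):
    """An anchor-protein amount is non-positive; normativity is undefined."""

    exit_code = 3


class Tier(str, enum.Enum):
    """When a spike standard enters the workflow."""

    PRE_EXTRACTION = "pre_extraction"
    POST_EXTRACTION = "post_extraction"
    CARRIER_DIGEST = "carrier_digest"


class FeatureKind(str, enum.Enum):
    PROTEIN = "protein"
    SPIKE_PEPTIDE = "spike_peptide"
    CARRIER_PEPTIDE = "carrier_peptide"
    METABOLITE = "metabolite"
    LIPID = "lipid"


class Ome(str, enum.Enum):
    PROTEOME = "proteome"
    METABOLOME = "metabolome"
    LIPIDOME = "lipidome"


class Condition(str, enum.Enum):
    CONTROL = "control"
    CRUSH = "crush"
    REGENERATION = "regeneration"


class TrendLabel(str, enum.Enum):
    """Qualitative control -> crush -> regeneration pattern of a level."""

    AXON_CONSISTENT = "axon_consistent"  # down in crush, back up in regeneration
    INVERSE = "inverse"
    FLAT_THEN_UP = "flat_then_up"
    OTHER = "other"


#: Molar mass of bovine serum albumin, g/mol, used for pmol -> µg conversion.
BSA_MOLAR_MASS = 66_463.0


def bsa_pmol_to_ug(pmol: float) -> float:
    """Convert a BSA amount in pmol to micrograms (100 pmol = 6.65 µg)."""
    return pmol * BSA_MOLAR_MASS * 1e-6


@dataclass(frozen=True)
class SpikeStandard:
    """One doped internal standard.

    ``spiked_amount`` is the known per-sample amount in micrograms (or a
    consistent nominal unit); it is the quantity all ratios are anchored to.
    ``spiked_concentration`` (µM) is informational.
    """

    name: str
    tier: Tier
    spiked_amount: float
    spiked_concentration: float | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("spike standard needs a non-empty name")
        if not isinstance(self.tier, Tier):
            object.__setattr__(self, "tier", Tier(self.tier))
        if not (self.spiked_amount > 0) or not math.isfinite(self.spiked_amount):
            raise ValidationError(
                f"spike standard {self.name!r}: spiked_amount must be > 0, "
                f"got {self.spiked_amount!r}"
            )


@dataclass(frozen=True)
class SpikeConfig:
    """Tier-indexed, validated collection of spike standards.

    Construct through :func:`validate_spike_config` (or ``SpikeConfig.validate``)
    so the three-tier completeness and name-uniqueness invariants hold.
    """

    standards: tuple[SpikeStandard, ...]

    @classmethod
    def validate(cls, standards) -> "SpikeConfig":
        standards = tuple(standards)
        names = [s.name for s in standards]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigurationError(
                f"duplicate spike standard names: {sorted(dupes)}"
            )
        present = {s.tier for s in standards}
        for tier in Tier:
            if tier not in present:
                raise ConfigurationError(
                    f"spike configuration has no standard in tier {tier.value!r}"
                )
        return cls(standards)

    def tier(self, tier: Tier | str) -> tuple[SpikeStandard, ...]:
        tier = Tier(tier)
        return tuple(s for s in self.standards if s.tier == tier)

    def names(self, tier: Tier | str) -> tuple[str, ...]:
        return tuple(s.name for s in self.tier(tier))

    def mean_amount(self, tier: Tier | str) -> float:
        """Mean spiked amount per standard in a tier (µg)."""
        amounts = [s.spiked_amount for s in self.tier(tier)]
        return sum(amounts) / len(amounts)


def validate_spike_config(standards) -> SpikeConfig:
    """Validate a collection of spike standards.

    Requires at least one standard in each of the three tiers
    (pre-extraction, post-extraction, carrier digest) and unique names.
    """
    return SpikeConfig.validate(standards)


def regen_v_default(bsa_amount_ug: float | None = None) -> SpikeConfig:
    """The default Regen V + BSA configuration.

    Three pre-extraction peptides (SEB, LLO, CFP) at 36 µM each, two
    post-extraction peptides (HH4B, A1315) at 54 µM each, and a BSA tryptic
    digest carrier at 100 pmol (6.65 µg).  Per-standard amounts are taken
    proportional to concentration (equal spike volumes), so the ideal
    pre/post correction factor is 36/54 = 0.667.
    """
    if bsa_amount_ug is None:
        bsa_amount_ug = bsa_pmol_to_ug(100.0)
    pre = [
        SpikeStandard("LLO", Tier.PRE_EXTRACTION, 36.0, 36.0, "GYKDGNEYI"),
        SpikeStandard("SEB", Tier.PRE_EXTRACTION, 36.0, 36.0, "KKKVTAQELD"),
        SpikeStandard("CFP", Tier.PRE_EXTRACTION, 36.0, 36.0, "EISTNIRQAGVQYSR"),
    ]
    post = [
        SpikeStandard("A1315", Tier.POST_EXTRACTION, 54.0, 54.0),
        SpikeStandard("HH4B", Tier.POST_EXTRACTION, 54.0, 54.0),
    ]
    carrier = [SpikeStandard("BSA", Tier.CARRIER_DIGEST, bsa_amount_ug)]
    return SpikeConfig.validate(pre + post + carrier)


@dataclass(frozen=True)
class SampleDesign:
    """One biological sample: its multiplex position and biology."""

    sample_id: str
    batch_id: str
    tag_id: str
    condition: Condition
    replicate: int
    total_protein: float
    timepoint_days: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.condition, Condition):
            object.__setattr__(self, "condition", Condition(self.condition))
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive "
                f"integer, got {self.replicate!r}"
            )
        if not (self.total_protein > 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: total_protein must be > 0, "
                f"got {self.total_protein!r}"
            )

    @property
    def condition_key(self) -> str:
        """Condition label including the time point, e.g. ``regeneration@14``."""
        if self.timepoint_days is None:
            return self.condition.value
        return f"{self.condition.value}@{self.timepoint_days:g}"


@dataclass(frozen=True)
class AbundanceRecord:
    """One raw intensity / peak area for one feature in one sample."""

    feature_id: str
    feature_kind: FeatureKind
    sample_id: str
    raw_abundance: float | None  # None = missing (never imputed as zero)

    def __post_init__(self) -> None:
        if not isinstance(self.feature_kind, FeatureKind):
            object.__setattr__(self, "feature_kind", FeatureKind(self.feature_kind))
        v = self.raw_abundance
        if v is not None and (not math.isfinite(v) or v < 0):
            raise ValidationError(
                f"feature {self.feature_id!r}, sample {self.sample_id!r}: "
                f"raw_abundance must be >= 0 or missing, got {v!r}"
            )

    @property
    def missing(self) -> bool:
        return self.raw_abundance is None


@dataclass(frozen=True)
class PathwayAnnotation:
    """Pathway memberships of one entity (protein, metabolite or lipid)."""

    entity_id: str
    ome: Ome
    pathway_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not isinstance(self.ome, Ome):
            object.__setattr__(self, "ome", Ome(self.ome))
        if not isinstance(self.pathway_ids, frozenset):
            object.__setattr__(self, "pathway_ids", frozenset(self.pathway_ids))
        if not self.pathway_ids:
            raise ValidationError(
                f"entity {self.entity_id!r}: pathway_ids must be non-empty"
            )
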