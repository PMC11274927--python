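"""Synthetic multi-batch spike-in experiments with known ground truth.

The generative model mirrors the optic-nerve study design this package is
built around: several TMT plexes ("batches") of samples spanning control,
crush and regeneration conditions, with

* a per-sample **extraction efficiency** multiplying everything present
  before protein extraction (pre-extraction spikes and proteins),
* a per-batch **labeling multiplier** and per-sample **instrument
  response** multiplying every observed intensity,
* mean-one log-normal **measurement noise** on every observation, and
* metabolite/lipid peak areas tied to an anchor protein through a fixed
  **normative ratio**.

Because post-extraction spikes and the BSA carrier share every multiplier
except the extraction term, the normalization chain can in principle
recover protein amounts and efficiencies exactly in the noise-free limit;
the simulator is the harness that tests exactly that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclasses_fields, replace

import numpy as np
import pandas as pd

from . import spike as sp
from .io import abundance_frame, design_frame
from .types import (
    AbundanceRecord,
    Condition,
    ConfigurationError,
    FeatureKind,
    SampleDesign,
    SpikeConfig,
    Tier,
    regen_v_default,
)

#: arbitrary instrument intensity scale so raw abundances look like intensities
INTENSITY_SCALE = 1.0e6


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition with its protein effect multiplier."""

    condition: Condition
    timepoint_days: float | None
    effect: float
    n_replicates: int = 6

    def __post_init__(self) -> None:
        if not isinstance(self.condition, Condition):
            object.__setattr__(self, "condition", Condition(self.condition))
        if not self.effect > 0:
            raise ConfigurationError(f"condition effect must be > 0, got {self.effect}")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


def default_conditions() -> tuple[ConditionSpec, ...]:
    """Six conditions × six replicates: control, crush, and a regeneration
    time course with progressively recovering protein levels."""
    return (
        ConditionSpec(Condition.CONTROL, None, 1.0),
        ConditionSpec(Condition.CRUSH, 0.0, 0.5),
        ConditionSpec(Condition.REGENERATION, 7.0, 0.7),
        ConditionSpec(Condition.REGENERATION, 14.0, 0.9),
        ConditionSpec(Condition.REGENERATION, 21.0, 1.1),
        ConditionSpec(Condition.REGENERATION, 28.0, 1.3),
    )


@dataclass(frozen=True)
class AnalyteSpec:
    """An analyte tied to one anchor protein by a true normative ratio
    (peak-area units per µg of anchor)."""

    analyte_id: str
    anchor_id: str
    ratio: float
    ome: str = "metabolome"

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ConfigurationError(f"normative ratio must be > 0, got {self.ratio}")


def default_analytes() -> tuple[AnalyteSpec, ...]:
    return (
        AnalyteSpec("citrate", "P001", 2500.0, "metabolome"),
        AnalyteSpec("malate", "P002", 1500.0, "metabolome"),
        AnalyteSpec("ceramide_NS", "P003", 40.0, "lipidome"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic experiment.

    Defaults mirror the reference study: 3 batches of 12 channels, 6
    conditions × 6 replicates, pre-extraction spikes at 36 (amount units)
    vs post-extraction at 54, one BSA carrier per channel, extraction
    efficiency 0.757 and 10% measurement CV.
    """

    n_batches: int = 3
    samples_per_batch: int = 12
    conditions: tuple[ConditionSpec, ...] = field(default_factory=default_conditions)
    n_proteins: int = 40
    protein_base_range: tuple[float, float] = (0.5, 10.0)
    biological_cv: float = 0.2
    extraction_efficiency: float = 0.757
    efficiency_sd: float = 0.0
    labeling_sd: float = 0.25
    response_sd: float = 0.25
    noise_cv: float = 0.1
    total_protein_mean: float = 70.0
    total_protein_cv: float = 0.1
    spike_config: SpikeConfig = field(default_factory=regen_v_default)
    analytes: tuple[AnalyteSpec, ...] = field(default_factory=default_analytes)
    seed: int = 0

    def validate(self) -> None:
        if self.n_batches < 1 or self.samples_per_batch < 1:
            raise ConfigurationError("need >= 1 batch and >= 1 sample per batch")
        if not 0 < self.extraction_efficiency <= 1:
            raise ConfigurationError(
                f"extraction_efficiency must be in (0, 1], got {self.extraction_efficiency}"
            )
        for name in ("noise_cv", "labeling_sd", "response_sd", "biological_cv",
                     "efficiency_sd", "total_protein_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        n_samples = sum(c.n_replicates for c in self.conditions)
        if n_samples != self.n_batches * self.samples_per_batch:
            raise ConfigurationError(
                f"condition replicates sum to {n_samples} samples but the "
                f"plex layout holds {self.n_batches * self.samples_per_batch}"
            )
        if self.n_proteins < 0:
            raise ConfigurationError("n_proteins must be >= 0")
        lo, hi = self.protein_base_range
        if not 0 < lo <= hi:
            raise ConfigurationError("protein_base_range must satisfy 0 < lo <= hi")
        protein_ids = {f"P{i + 1:03d}" for i in range(self.n_proteins)}
        for a in self.analytes:
            if a.anchor_id not in protein_ids:
                raise ConfigurationError(
                    f"analyte {a.analyte_id!r}: anchor {a.anchor_id!r} is not a "
                    f"simulated protein"
                )


def simconfig_from_mapping(mapping: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain (YAML-loaded) mapping.

    ``conditions`` and ``analytes`` entries are mappings with the fields of
    :class:`ConditionSpec` / :class:`AnalyteSpec`; unknown keys raise.
    """
    mapping = dict(mapping)
    kwargs = {}
    if "conditions" in mapping:
        kwargs["conditions"] = tuple(
            ConditionSpec(**c) for c in mapping.pop("conditions")
        )
    if "analytes" in mapping:
        kwargs["analytes"] = tuple(AnalyteSpec(**a) for a in mapping.pop("analytes"))
    known = {f.name for f in dataclasses_fields(SimConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
    for key in ("protein_base_range",):
        if key in mapping:
            mapping[key] = tuple(mapping[key])
    return SimConfig(**kwargs, **mapping)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated experiment."""

    protein_amounts: pd.DataFrame       # protein_id, sample_id, true_amount_ug
    efficiencies: pd.DataFrame          # sample_id, extraction_efficiency
    label_multipliers: pd.DataFrame     # batch_id, label_multiplier
    response_multipliers: pd.DataFrame  # sample_id, response_multiplier
    analyte_levels: pd.DataFrame        # analyte_id, anchor_id, true_ratio, sample_id, expected_peak_area


@dataclass(frozen=True)
class SimResult:
    designs: list[SampleDesign]
    design: pd.DataFrame
    abundances: pd.DataFrame
    analytes: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with E[factor] = 1 (the σ²/2 offset removes
    the log-normal mean bias)."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _efficiencies(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    m, s = config.extraction_efficiency, config.efficiency_sd
    if s == 0:
        return np.full(n, m)
    # Beta with matched mean/sd; keeps draws inside (0, 1]
    v = s * s
    if v >= m * (1 - m):
        raise ConfigurationError("efficiency_sd too large for a Beta draw at this mean")
    k = m * (1 - m) / v - 1
    return rng.beta(m * k, (1 - m) * k, size=n)


def simulate_experiment(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Generate a complete synthetic experiment.

    Returns the sample design, the long abundance table (spikes, carrier
    and proteins), the analyte peak-area table, and the ground truth.
    Identical config + seed yield identical tables.
    """
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- design: expand conditions, deal samples round-robin over batches
    slots = [
        (spec, r + 1) for spec in config.conditions for r in range(spec.n_replicates)
    ]
    designs: list[SampleDesign] = []
    batch_fill = {b: 0 for b in range(config.n_batches)}
    total_protein = config.total_protein_mean * _mean_one_lognormal(
        rng, config.total_protein_cv, len(slots)
    )
    for i, (spec, rep) in enumerate(slots):
        b = i % config.n_batches
        designs.append(
            SampleDesign(
                sample_id=f"S{i + 1:03d}",
                batch_id=f"batch{b + 1}",
                tag_id=f"tag{batch_fill[b] + 1:02d}",
                condition=spec.condition,
                replicate=rep,
                total_protein=float(total_protein[i]),
                timepoint_days=spec.timepoint_days,
            )
        )
        batch_fill[b] += 1
    design = design_frame(designs)
    n = len(designs)

    # --- latent multipliers
    eff = _efficiencies(rng, config, n)
    label_by_batch = {
        f"batch{b + 1}": float(np.exp(rng.normal(0.0, config.labeling_sd)))
        for b in range(config.n_batches)
    }
    label = np.array([label_by_batch[d.batch_id] for d in designs])
    response = INTENSITY_SCALE * np.exp(rng.normal(0.0, config.response_sd, size=n))
    gain = label * response  # shared by every observation of a sample

    # --- true protein amounts: baseline × condition effect × biological noise
    protein_ids = [f"P{i + 1:03d}" for i in range(config.n_proteins)]
    lo, hi = config.protein_base_range
    base = np.exp(rng.uniform(math.log(lo), math.log(hi), size=config.n_proteins))
    effect = np.array([
        next(c.effect for c in config.conditions
             if c.condition == d.condition and c.timepoint_days == d.timepoint_days)
        for d in designs
    ])
    bio = _mean_one_lognormal(rng, config.biological_cv, (config.n_proteins, n))
    true_amount = base[:, None] * effect[None, :] * bio  # µg, proteins × samples

    # --- observed abundances
    records: list[AbundanceRecord] = []
    sample_ids = [d.sample_id for d in designs]

    def emit(feature_id: str, kind: FeatureKind, values: np.ndarray) -> None:
        for s, v in zip(sample_ids, values):
            records.append(AbundanceRecord(feature_id, kind, s, float(v)))

    for std in config.spike_config.standards:
        noise = _mean_one_lognormal(rng, config.noise_cv, n)
        extracted = eff if std.tier == Tier.PRE_EXTRACTION else 1.0
        observed = std.spiked_amount * extracted * gain * noise
        kind = (
            FeatureKind.CARRIER_PEPTIDE
            if std.tier == Tier.CARRIER_DIGEST
            else FeatureKind.SPIKE_PEPTIDE
        )
        emit(std.name, kind, observed)
    for i, pid in enumerate(protein_ids):
        noise = _mean_one_lognormal(rng, config.noise_cv, n)
        emit(pid, FeatureKind.PROTEIN, true_amount[i] * eff * gain * noise)
    abundances = abundance_frame(records)

    # --- analytes coupled to anchors through fixed normative ratios
    pid_index = {p: i for i, p in enumerate(protein_ids)}
    analyte_rows, truth_rows = [], []
    for a in config.analytes:
        anchor_amounts = true_amount[pid_index[a.anchor_id]]
        noise = _mean_one_lognormal(rng, config.noise_cv, n)
        peaks = anchor_amounts * a.ratio * noise
        for s, peak, expected in zip(sample_ids, peaks, anchor_amounts * a.ratio):
            analyte_rows.append(
                {"analyte_id": a.analyte_id, "ome": a.ome, "sample_id": s,
                 "peak_area": float(peak)}
            )
            truth_rows.append(
                {"analyte_id": a.analyte_id, "anchor_id": a.anchor_id,
                 "true_ratio": a.ratio, "sample_id": s,
                 "expected_peak_area": float(expected)}
            )
    analytes = pd.DataFrame(
        analyte_rows, columns=["analyte_id", "ome", "sample_id", "peak_area"]
    )

    truth = SimTruth(
        protein_amounts=pd.DataFrame(
            {
                "protein_id": np.repeat(protein_ids, n),
                "sample_id": sample_ids * config.n_proteins,
                "true_amount_ug": true_amount.ravel(),
            }
        ),
        efficiencies=pd.DataFrame(
            {"sample_id": sample_ids, "extraction_efficiency": eff}
        ),
        label_multipliers=pd.DataFrame(
            {"batch_id": list(label_by_batch), "label_multiplier": list(label_by_batch.values())}
        ),
        response_multipliers=pd.DataFrame(
            {"sample_id": sample_ids, "response_multiplier": response}
        ),
        analyte_levels=pd.DataFrame(
            truth_rows,
            columns=["analyte_id", "anchor_id", "true_ratio", "sample_id",
                     "expected_peak_area"],
        ),
    )
    return SimResult(designs, design, abundances, analytes, truth, config)


def recover_efficiency(sim: SimResult) -> tuple[pd.DataFrame, dict]:
    """Run the normalization chain on simulated data and compare the
    recovered per-sample extraction efficiencies with the ground truth.

    Returns the per-sample table (estimate, truth, relative error) and a
    summary with the mean estimate, mean truth, mean correction factor and
    the relative bias of the mean.
    """
    corrections = sp.correction_sets(sim.abundances, sim.config.spike_config)
    per_sample = corrections.merge(sim.truth.efficiencies, on="sample_id",
                                   suffixes=("_est", "_true"))
    per_sample = per_sample.rename(
        columns={
            "extraction_efficiency_est": "estimated_efficiency",
            "extraction_efficiency_true": "true_efficiency",
        }
    )
    per_sample["relative_error"] = (
        per_sample["estimated_efficiency"] / per_sample["true_efficiency"] - 1.0
    )
    mean_est = float(per_sample["estimated_efficiency"].mean())
    mean_true = float(per_sample["true_efficiency"].mean())
    summary = {
        "mean_estimated_efficiency": mean_est,
        "mean_true_efficiency": mean_true,
        "mean_correction_factor": float(per_sample["correction_factor"].mean()),
        "relative_bias": mean_est / mean_true - 1.0,
        "n_samples": int(len(per_sample)),
    }
    return per_sample, summary
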