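"""Delimited-table readers and writers.

All tables are long-form TSV/CSV with a header row (UTF-8; delimiter
auto-detected between tab and comma, tab preferred).  Readers validate
against the domain invariants and never silently drop rows: a row either
becomes a record or raises a named error.  Blank abundance cells become
explicit missing values, never zeros.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .types import (
    AbundanceRecord,
    Ome,
    PathwayAnnotation,
    SampleDesign,
    SchemaError,
    SpikeConfig,
    SpikeStandard,
    ValidationError,
)

DESIGN_COLUMNS = (
    "sample_id",
    "batch_id",
    "tag_id",
    "condition",
    "timepoint_days",
    "replicate",
    "total_protein_ug",
)
ABUNDANCE_COLUMNS = ("feature_id", "feature_kind", "sample_id", "raw_abundance")
SPIKE_COLUMNS = ("name", "sequence", "tier", "spiked_concentration_uM", "spiked_amount_ug")
PATHWAY_COLUMNS = ("entity_id", "ome", "pathway_id")
ANALYTE_COLUMNS = ("analyte_id", "ome", "sample_id", "peak_area")

#: float format preserving round-trips for <= 12 significant digits
FLOAT_FORMAT = "%.12g"


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path, required: tuple[str, ...], optional: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def _to_float(cell: str, what: str):
    """Parse a numeric cell; blank/NA-like cells are missing (None)."""
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "NAN", "N/A", "NULL"}:
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ValidationError(f"{what}: cannot parse {cell!r} as a number") from exc


def read_design(path) -> list[SampleDesign]:
    """Read a sample design table.

    Required columns: sample_id, batch_id, tag_id, condition, replicate,
    total_protein_ug; optional timepoint_days.  Enforces unique sample ids
    and unique (batch, tag) pairs.
    """
    df = _read_table(path, tuple(c for c in DESIGN_COLUMNS if c != "timepoint_days"))
    has_tp = "timepoint_days" in df.columns
    designs: list[SampleDesign] = []
    for row in df.itertuples(index=False):
        tp = _to_float(getattr(row, "timepoint_days"), "timepoint_days") if has_tp else None
        total = _to_float(row.total_protein_ug, f"sample {row.sample_id!r} total_protein_ug")
        rep = _to_float(row.replicate, f"sample {row.sample_id!r} replicate")
        if total is None or rep is None:
            raise ValidationError(
                f"sample {row.sample_id!r}: replicate and total_protein_ug are required"
            )
        designs.append(
            SampleDesign(
                sample_id=row.sample_id,
                batch_id=row.batch_id,
                tag_id=row.tag_id,
                condition=row.condition,
                replicate=int(rep),
                total_protein=total,
                timepoint_days=tp,
            )
        )
    ids = [d.sample_id for d in designs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id values: {dupes}")
    slots = [(d.batch_id, d.tag_id) for d in designs]
    if len(set(slots)) != len(slots):
        dupes = sorted({s for s in slots if slots.count(s) > 1})
        raise ValidationError(f"duplicate (batch_id, tag_id) pairs: {dupes}")
    return designs


def design_frame(designs: list[SampleDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in designs],
            "batch_id": [d.batch_id for d in designs],
            "tag_id": [d.tag_id for d in designs],
            "condition": [d.condition.value for d in designs],
            "timepoint_days": [d.timepoint_days for d in designs],
            "replicate": [d.replicate for d in designs],
            "total_protein_ug": [d.total_protein for d in designs],
            "condition_key": [d.condition_key for d in designs],
        }
    )


def read_abundances(path) -> list[AbundanceRecord]:
    """Read a long-form abundance table.

    Blank cells become missing records (never zeros); negative abundances
    raise; duplicate (feature_id, sample_id) pairs raise.
    """
    df = _read_table(path, ABUNDANCE_COLUMNS)
    records: list[AbundanceRecord] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.feature_id, row.sample_id)
        if key in seen:
            raise ValidationError(
                f"duplicate abundance for feature {key[0]!r} in sample {key[1]!r}"
            )
        seen.add(key)
        value = _to_float(
            row.raw_abundance, f"feature {row.feature_id!r}, sample {row.sample_id!r}"
        )
        records.append(
            AbundanceRecord(
                feature_id=row.feature_id,
                feature_kind=row.feature_kind,
                sample_id=row.sample_id,
                raw_abundance=value,
            )
        )
    return records


def abundance_frame(records: list[AbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "feature_kind": [r.feature_kind.value for r in records],
            "sample_id": [r.sample_id for r in records],
            "raw_abundance": [
                math.nan if r.raw_abundance is None else r.raw_abundance for r in records
            ],
        }
    )


def read_spike_config(path) -> SpikeConfig:
    """Read and validate a spike-standard configuration table."""
    df = _read_table(path, ("name", "tier", "spiked_amount_ug"))
    standards = []
    for row in df.itertuples(index=False):
        conc = (
            _to_float(row.spiked_concentration_uM, f"standard {row.name!r} concentration")
            if "spiked_concentration_uM" in df.columns
            else None
        )
        amount = _to_float(row.spiked_amount_ug, f"standard {row.name!r} amount")
        if amount is None:
            raise ValidationError(f"standard {row.name!r}: spiked_amount_ug is required")
        seq = getattr(row, "sequence", "") or None
        standards.append(
            SpikeStandard(
                name=row.name,
                tier=row.tier,
                spiked_amount=amount,
                spiked_concentration=conc,
                sequence=seq,
            )
        )
    return SpikeConfig.validate(standards)


def spike_frame(config: SpikeConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [s.name for s in config.standards],
            "sequence": [s.sequence or "" for s in config.standards],
            "tier": [s.tier.value for s in config.standards],
            "spiked_concentration_uM": [s.spiked_concentration for s in config.standards],
            "spiked_amount_ug": [s.spiked_amount for s in config.standards],
        }
    )


def read_pathway_map(path) -> list[PathwayAnnotation]:
    """Read an entity -> pathway map (one (entity, pathway) pair per row)."""
    df = _read_table(path, PATHWAY_COLUMNS)
    grouped: dict[tuple[str, str], set[str]] = {}
    for row in df.itertuples(index=False):
        Ome(row.ome)  # validate early with a clear row context
        grouped.setdefault((row.entity_id, row.ome), set()).add(row.pathway_id)
    return [
        PathwayAnnotation(entity_id=e, ome=o, pathway_ids=frozenset(p))
        for (e, o), p in sorted(grouped.items())
    ]


def read_analytes(path) -> pd.DataFrame:
    """Read a metabolite/lipid peak-area table into a long DataFrame."""
    df = _read_table(path, ANALYTE_COLUMNS)
    out = df.copy()
    out["peak_area"] = [
        v if (v := _to_float(c, f"analyte {a!r}, sample {s!r}")) is not None else math.nan
        for c, a, s in zip(df["peak_area"], df["analyte_id"], df["sample_id"])
    ]
    neg = out["peak_area"] < 0
    if neg.any():
        bad = out.loc[neg, "analyte_id"].iloc[0]
        raise ValidationError(f"analyte {bad!r}: peak_area must be >= 0")
    for o in out["ome"].unique():
        if Ome(o) not in (Ome.METABOLOME, Ome.LIPIDOME):
            raise ValidationError(f"analyte ome must be metabolome or lipidome, got {o!r}")
    return out


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a DataFrame as a delimited text table (12-digit round-trip safe)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)
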