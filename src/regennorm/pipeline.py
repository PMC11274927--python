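"""End-to-end orchestration: normalization → normativity → pathways.

One call wires the stages together on file inputs, writes every
intermediate table as TSV, and records a run manifest (config hash, input
digests, seed, chosen conventions) so a rerun on identical inputs is
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, io, normativity as nv, pathways as pw, spike as sp
from .types import Condition, ConfigurationError, Ome, RegennormError

logger = logging.getLogger(__name__)


@dataclass
class PipelineOptions:
    """Everything that determines a run besides the input files."""

    bsa_amount_ug: float | None = None  # None = use the spike table's carrier amount
    min_replicates: int = 2
    alpha: float = 0.05
    fdr: bool = False
    multiplier_mode: str = "efficiency"
    merge_rule: str = "mean"
    rel_tol: float = 0.05
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    anchors: tuple[str, ...] = ()
    regeneration_conditions: tuple[str, ...] = (Condition.REGENERATION.value,)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def build_manifest(inputs: dict[str, Path], options: PipelineOptions, seed: int | None) -> dict:
    opts = dataclasses.asdict(options)
    config_hash = hashlib.sha256(
        json.dumps(opts, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {
        "tool": "regennorm",
        "version": __version__,
        "config_hash": config_hash,
        "inputs": {k: {"path": str(p), "sha256_16": _digest(p)} for k, p in inputs.items()},
        "seed": seed,
        "conventions": opts,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "platform": platform.python_version(),
    }


def _require(path, what: str) -> Path:
    if path is None:
        raise ConfigurationError(f"missing required input: {what}")
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"{what} file not found: {path}")
    return path


def run_pipeline(
    abundances_path,
    design_path,
    spikes_path,
    out_dir,
    analytes_path=None,
    pathway_map_path=None,
    options: PipelineOptions | None = None,
    seed: int | None = None,
) -> dict:
    """Run every applicable stage and write outputs under ``out_dir``.

    Returns the manifest.  Raises ConfigurationError for bad inputs and
    data-level errors from the stages; the CLI maps these to exit codes.
    """
    options = options or PipelineOptions()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        "abundances": _require(abundances_path, "--abundances"),
        "design": _require(design_path, "--design"),
        "spikes": _require(spikes_path, "--spikes"),
    }
    if analytes_path is not None:
        inputs["analytes"] = _require(analytes_path, "--analytes")
    if pathway_map_path is not None:
        inputs["pathway_map"] = _require(pathway_map_path, "--map")

    stage = "read_inputs"
    try:
        designs = io.read_design(inputs["design"])
        design = io.design_frame(designs)
        abundances = io.abundance_frame(io.read_abundances(inputs["abundances"]))
        config = io.read_spike_config(inputs["spikes"])
        if options.bsa_amount_ug is not None:
            from .types import SpikeStandard, Tier, validate_spike_config

            replaced = [
                dataclasses.replace(s, spiked_amount=options.bsa_amount_ug)
                if s.tier == Tier.CARRIER_DIGEST
                else s
                for s in config.standards
            ]
            config = validate_spike_config(replaced)

        stage = "correction_sets"
        corrections = sp.correction_sets(abundances, config, options.multiplier_mode)
        io.write_table(corrections, out / "correction_sets.tsv")

        stage = "normalize_proteins"
        normalized = sp.normalize_proteins(abundances, corrections, config)
        normalized, n_kept = sp.filter_min_replicates(
            normalized, design, options.min_replicates
        )
        logger.info("replicate filter retained %d proteins", n_kept)
        consensus = sp.batch_average(normalized)
        io.write_table(consensus, out / "normalized_proteins.tsv")

        stage = "group_test"
        regen = set(options.regeneration_conditions)
        group_regen = design.loc[design["condition"].isin(regen), "sample_id"]
        group_other = design.loc[~design["condition"].isin(regen), "sample_id"]
        tests = sp.group_test(
            consensus, group_regen, group_other, options.alpha, options.fdr
        )
        io.write_table(tests, out / "protein_tests.tsv")

        normativity_df = pd.DataFrame()
        analytes = None
        if "analytes" in inputs:
            stage = "normativity"
            analytes = io.read_analytes(inputs["analytes"])
            analytes = nv.merge_duplicates(analytes, options.merge_rule)
            totals = design.set_index("sample_id")["total_protein_ug"]
            analytes["per_total_protein"] = [
                nv.per_total_protein(v, totals[s])
                for v, s in zip(analytes["peak_area"], analytes["sample_id"])
            ]
            if options.anchors:
                cond_design = design.assign(condition_key=design["condition"])
                levels = nv.condition_means(
                    analytes, cond_design, value_col="per_total_protein"
                ).rename(columns={"per_total_protein": "level"})
                anchor_rows = consensus[consensus["protein_id"].isin(options.anchors)]
                if anchor_rows.empty:
                    raise ConfigurationError(
                        f"anchor proteins {options.anchors} absent from the "
                        f"normalized consensus table"
                    )
                anchor_cond = (
                    anchor_rows.merge(design[["sample_id", "condition"]], on="sample_id")
                    .groupby("condition")["normalized_amount"]
                    .mean()
                    .to_dict()
                )
                normativity_df = nv.normativity_table(
                    levels,
                    anchor_cond,
                    conditions=(
                        Condition.CONTROL.value,
                        Condition.CRUSH.value,
                        Condition.REGENERATION.value,
                    ),
                    rel_tol=options.rel_tol,
                    anchor_ids=options.anchors,
                )
                io.write_table(normativity_df, out / "normativity.tsv")

        intersections = pd.DataFrame()
        if "pathway_map" in inputs:
            stage = "pathways"
            annotations = io.read_pathway_map(inputs["pathway_map"])
            per_ome: dict[Ome, set[str]] = {}
            sig_prot = (
                set(tests.loc[tests["significant"], "protein_id"])
                if "significant" in tests.columns
                else set()
            )
            per_ome[Ome.PROTEOME] = pw.pathways_for_ome(sig_prot, annotations, Ome.PROTEOME)
            if analytes is not None:
                wide = analytes.pivot_table(
                    index="analyte_id", columns="sample_id", values="per_total_protein"
                )
                for ome in (Ome.METABOLOME, Ome.LIPIDOME):
                    ids = analytes.loc[analytes["ome"] == ome.value, "analyte_id"].unique()
                    sub = wide.reindex(ids)
                    volcano = nv.volcano_significant(
                        sub, group_other, group_regen,
                        options.p_threshold, options.fc_threshold,
                    )
                    sig = set(volcano.loc[volcano["significant"], "feature_id"])
                    per_ome[ome] = pw.pathways_for_ome(sig, annotations, ome)
            if len(per_ome) >= 2:
                intersections = pw.intersections_frame(pw.all_intersections(per_ome))
                io.write_table(intersections, out / "pathway_intersections.tsv")

        stage = "report"
        manifest = build_manifest(inputs, options, seed)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        _write_report(out, design, corrections, n_kept, tests, normativity_df, intersections)
        return manifest
    except RegennormError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise


def _write_report(
    out: Path,
    design: pd.DataFrame,
    corrections: pd.DataFrame,
    n_kept: int,
    tests: pd.DataFrame,
    normativity_df: pd.DataFrame,
    intersections: pd.DataFrame,
) -> None:
    merged = corrections.merge(design[["sample_id", "batch_id"]], on="sample_id")
    per_batch = (
        merged.groupby("batch_id")[["correction_factor", "extraction_efficiency"]]
        .mean()
        .reset_index()
    )
    def table(df: pd.DataFrame) -> list[str]:
        return ["```", df.to_string(index=False), "```", ""]

    lines = ["# regennorm run report", ""]
    lines += ["## Per-batch correction factors", ""] + table(per_batch.round(4))
    lines += [
        f"Mean correction factor: {merged['correction_factor'].mean():.4f} "
        f"(ideal {merged['ideal_factor'].iloc[0]:.4f}); mean extraction "
        f"efficiency: {merged['extraction_efficiency'].mean():.1%}.",
        "",
        f"Proteins retained by the replicate filter: {n_kept}.",
        f"Significant proteins (group test): "
        f"{int(tests['significant'].sum()) if 'significant' in tests else 0}.",
        "",
    ]
    if not normativity_df.empty:
        lines += ["## Normative trends", ""] + table(normativity_df.round(4))
    if not intersections.empty:
        lines += ["## Ome pathway intersections", ""] + table(
            intersections[["combination", "n_pathways"]]
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")
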