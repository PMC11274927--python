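"""Two-tier spike-in normalization for multiplexed proteomics.

The chain converts arbitrary instrument intensities into extraction-loss-
corrected microgram equivalents, per sample:

1. every feature is anchored to the carrier digest (BSA) of known amount,
   ``µg-equivalent = raw × bsa_amount / bsa_raw`` — this cancels labeling
   and instrument response shared within a channel;
2. the pre-extraction spike tier (doped before protein extraction) and the
   post-extraction tier (doped after labeling) are summarised per sample;
   their ratio is the **correction factor**;
3. at 100% extraction the factor equals the configured spiked-amount ratio
   (the **ideal factor**, ≈ 0.66 for 36 µM pre vs 54 µM post tiers); the
   shortfall is the **extraction efficiency**, and its reciprocal scales
   protein µg-equivalents back to pre-extraction amounts.

Downstream utilities implement the replicate filter, cross-batch
averaging, and per-protein group testing.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ConfigurationError,
    SpikeConfig,
    Tier,
    UndefinedReferenceError,
)

logger = logging.getLogger(__name__)

#: correction-factor -> protein-multiplier conventions
MULTIPLIER_MODES = ("efficiency", "literal")


# ---------------------------------------------------------------------------
# scalar building blocks

def bsa_equivalents(raw_abundance: float, bsa_amount: float, bsa_raw_abundance: float) -> float:
    """Convert a raw intensity to µg-equivalents via the carrier digest.

    ``raw_abundance × bsa_amount / bsa_raw_abundance``: linear in the raw
    intensity and invariant to any gain applied to the whole channel.
    """
    if not bsa_raw_abundance > 0:
        raise UndefinedReferenceError(
            f"BSA raw abundance must be > 0, got {bsa_raw_abundance!r}"
        )
    if not bsa_amount > 0:
        raise ConfigurationError(f"BSA amount must be > 0, got {bsa_amount!r}")
    return raw_abundance * bsa_amount / bsa_raw_abundance


def recovery_fraction(
    raw_abundance: float,
    bsa_amount: float,
    spiked_amount: float,
    bsa_raw_abundance: float,
) -> float:
    """Recovered fraction of a spiked standard.

    The standard's µg-equivalent divided by the amount actually spiked;
    1.0 means full recovery at equal response factors.
    """
    if not spiked_amount > 0:
        raise ConfigurationError(f"spiked amount must be > 0, got {spiked_amount!r}")
    return bsa_equivalents(raw_abundance, bsa_amount, bsa_raw_abundance) / spiked_amount


def tier_summary(equivalents: Iterable[float]) -> float:
    """Summarise one tier for one sample: mean µg-equivalent over its
    standards, missing (NaN) standards excluded.

    Returns NaN (with a warning upstream) when every standard is missing.
    """
    arr = np.asarray(list(equivalents), dtype=float)
    if arr.size == 0 or np.isnan(arr).all():
        return float("nan")
    return float(np.nanmean(arr))


def ideal_correction_factor(config: SpikeConfig) -> float:
    """Correction factor expected at 100% extraction efficiency.

    The ratio of the mean spiked amount per pre-extraction standard to the
    mean per post-extraction standard (36/54 ≈ 0.667 for the default
    configuration).
    """
    pre = config.mean_amount(Tier.PRE_EXTRACTION)
    post = config.mean_amount(Tier.POST_EXTRACTION)
    if not post > 0:
        raise ConfigurationError("post-extraction tier amount must be > 0")
    return pre / post


def correction_factor(pre_summary: float, post_summary: float) -> float:
    """Per-sample pre/post ratio of tier summaries (µg-equivalents)."""
    if not post_summary > 0:
        raise UndefinedReferenceError(
            f"post-extraction summary must be > 0, got {post_summary!r}"
        )
    return pre_summary / post_summary


def extraction_efficiency(cf: float, ideal: float) -> float:
    """Fraction of material surviving extraction: ``cf / ideal``."""
    if not ideal > 0:
        raise ConfigurationError(f"ideal correction factor must be > 0, got {ideal!r}")
    return cf / ideal


def protein_multiplier(cf: float, ideal: float, mode: str = "efficiency") -> float:
    """Scale factor applied to protein µg-equivalents.

    ``efficiency`` (default): ideal/cf — the reciprocal of the extraction
    efficiency, so a fully extracted sample is left untouched.
    ``literal``: post/pre = 1/cf — the uncorrected tier ratio, which differs
    from the default by the constant ideal factor.
    """
    if mode not in MULTIPLIER_MODES:
        raise ConfigurationError(f"unknown multiplier mode {mode!r}")
    if not cf > 0:
        raise UndefinedReferenceError(f"correction factor must be > 0, got {cf!r}")
    return (ideal / cf) if mode == "efficiency" else (1.0 / cf)


def normalize_protein(
    raw_abundance: float,
    bsa_amount: float,
    bsa_raw_abundance: float,
    multiplier: float,
) -> float:
    """Extraction-corrected protein amount in µg-equivalents."""
    if not multiplier > 0:
        raise ConfigurationError(f"multiplier must be > 0, got {multiplier!r}")
    return bsa_equivalents(raw_abundance, bsa_amount, bsa_raw_abundance) * multiplier


# ---------------------------------------------------------------------------
# table-level chain

def _bsa_reference(sample_abund: pd.DataFrame, config: SpikeConfig) -> float:
    """Per-sample carrier reference intensity (mean over carrier features)."""
    names = set(config.names(Tier.CARRIER_DIGEST))
    vals = sample_abund.loc[
        sample_abund["feature_id"].isin(names), "raw_abundance"
    ].dropna()
    if vals.empty:
        return float("nan")
    return float(vals.mean())


def correction_sets(
    abundances: pd.DataFrame,
    config: SpikeConfig,
    mode: str = "efficiency",
) -> pd.DataFrame:
    """Compute the per-sample correction set from spike abundances.

    Parameters
    ----------
    abundances
        Long table with columns feature_id, feature_kind, sample_id,
        raw_abundance (NaN = missing).
    config
        Validated spike configuration; the carrier standard supplies both
        its name and its known amount.
    mode
        Protein-multiplier convention, ``"efficiency"`` or ``"literal"``.

    Returns one row per sample: pre_summary, post_summary,
    correction_factor, ideal_factor, extraction_efficiency,
    protein_multiplier.  Samples whose carrier reference or a whole tier is
    missing get NaN entries and a warning; they are excluded downstream.
    """
    if mode not in MULTIPLIER_MODES:
        raise ConfigurationError(f"unknown multiplier mode {mode!r}")
    ideal = ideal_correction_factor(config)
    carrier = config.tier(Tier.CARRIER_DIGEST)
    bsa_amount = sum(s.spiked_amount for s in carrier) / len(carrier)
    pre_names = set(config.names(Tier.PRE_EXTRACTION))
    post_names = set(config.names(Tier.POST_EXTRACTION))

    rows = []
    for sample_id, sub in abundances.groupby("sample_id", sort=True):
        bsa_raw = _bsa_reference(sub, config)
        if not bsa_raw > 0:
            logger.warning(
                "sample %s: carrier (BSA) reference missing or non-positive; "
                "sample excluded from normalization", sample_id
            )
            rows.append(
                dict.fromkeys(
                    ("pre_summary", "post_summary", "correction_factor",
                     "extraction_efficiency", "protein_multiplier"), np.nan
                )
                | {"sample_id": sample_id, "ideal_factor": ideal}
            )
            continue

        summaries = {}
        for label, names in (("pre", pre_names), ("post", post_names)):
            tier_rows = sub[sub["feature_id"].isin(names)]
            eqs = [
                bsa_equivalents(v, bsa_amount, bsa_raw)
                for v in tier_rows["raw_abundance"]
                if not np.isnan(v)
            ]
            summaries[label] = tier_summary(eqs)
            if np.isnan(summaries[label]):
                logger.warning(
                    "sample %s: all %s-extraction standards missing; "
                    "correction undefined", sample_id, label
                )

        pre_s, post_s = summaries["pre"], summaries["post"]
        if np.isnan(pre_s) or np.isnan(post_s) or not post_s > 0:
            cf = eff = mult = np.nan
        else:
            cf = correction_factor(pre_s, post_s)
            eff = extraction_efficiency(cf, ideal)
            mult = protein_multiplier(cf, ideal, mode)
        rows.append(
            {
                "sample_id": sample_id,
                "pre_summary": pre_s,
                "post_summary": post_s,
                "correction_factor": cf,
                "ideal_factor": ideal,
                "extraction_efficiency": eff,
                "protein_multiplier": mult,
            }
        )
    return pd.DataFrame(rows)


def normalize_proteins(
    abundances: pd.DataFrame,
    corrections: pd.DataFrame,
    config: SpikeConfig,
) -> pd.DataFrame:
    """Normalize protein abundances to corrected µg-equivalents.

    Returns a long table (protein_id, sample_id, normalized_amount);
    proteins stay missing (NaN) where they were missing, and samples with
    an undefined correction set are dropped with a warning.
    """
    carrier = config.tier(Tier.CARRIER_DIGEST)
    bsa_amount = sum(s.spiked_amount for s in carrier) / len(carrier)
    prot = abundances[abundances["feature_kind"] == "protein"]
    mult = corrections.set_index("sample_id")["protein_multiplier"]

    out_rows = []
    for sample_id, sub in prot.groupby("sample_id", sort=True):
        if sample_id not in mult.index or np.isnan(mult.loc[sample_id]):
            logger.warning(
                "sample %s: no valid correction set; proteins dropped", sample_id
            )
            continue
        bsa_raw = _bsa_reference(
            abundances[abundances["sample_id"] == sample_id], config
        )
        m = float(mult.loc[sample_id])
        for row in sub.itertuples(index=False):
            v = row.raw_abundance
            amount = np.nan if np.isnan(v) else normalize_protein(v, bsa_amount, bsa_raw, m)
            out_rows.append(
                {"protein_id": row.feature_id, "sample_id": sample_id,
                 "normalized_amount": amount}
            )
    return pd.DataFrame(out_rows, columns=["protein_id", "sample_id", "normalized_amount"])


def filter_min_replicates(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    k: int = 2,
) -> tuple[pd.DataFrame, int]:
    """Keep proteins observed in at least ``k`` biological replicates.

    A protein passes if any single condition (condition label + time point)
    holds >= k non-missing values.  Returns the filtered table and the
    retained-protein count.
    """
    if k < 1:
        raise ConfigurationError(f"replicate threshold must be >= 1, got {k}")
    merged = normalized.merge(
        design[["sample_id", "condition_key"]], on="sample_id", how="left"
    )
    observed = merged[merged["normalized_amount"].notna()]
    counts = (
        observed.groupby(["protein_id", "condition_key"])["sample_id"]
        .nunique()
        .groupby("protein_id")
        .max()
    )
    keep = set(counts[counts >= k].index)
    out = normalized[normalized["protein_id"].isin(keep)].reset_index(drop=True)
    return out, len(keep)


def batch_average(normalized: pd.DataFrame) -> pd.DataFrame:
    """Average normalized values across batches into a consensus table.

    Per (protein, sample) arithmetic mean with missing values excluded,
    yielding one value per protein per sample.  With each sample measured
    in a single batch this is an assembly; with cross-batch technical
    replication it is a true average.
    """
    out = (
        normalized.groupby(["protein_id", "sample_id"], sort=True)["normalized_amount"]
        .mean()  # skips NaN
        .reset_index()
    )
    return out.dropna(subset=["normalized_amount"]).reset_index(drop=True)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # scipy yields NaN for two zero-variance groups; resolve the edge
    # cases the way the test statistic's limit behaves.
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def group_test(
    consensus: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Two-sided Welch t-test per protein between two sample groups.

    Proteins with fewer than two non-missing values in either group are
    flagged untested.  ``fdr=True`` adds Benjamini–Hochberg adjusted
    p-values and gates significance on them.
    """
    group_a, group_b = list(group_a), list(group_b)
    wide = consensus.pivot_table(
        index="protein_id", columns="sample_id", values="normalized_amount"
    )
    rows = []
    for protein_id, series in wide.iterrows():
        a = series.reindex(group_a).dropna().to_numpy()
        b = series.reindex(group_b).dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append({"protein_id": protein_id, "t": np.nan, "p": np.nan,
                         "tested": False})
            continue
        t, p = _welch(a, b)
        rows.append({"protein_id": protein_id, "t": t, "p": p, "tested": True})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(significant=pd.Series(dtype=bool))
    if fdr:
        tested = out["tested"]
        q = np.full(len(out), np.nan)
        if tested.any():
            q[tested.to_numpy()] = stats.false_discovery_control(
                out.loc[tested, "p"].to_numpy()
            )
        out["q"] = q
        out["significant"] = out["tested"] & (out["q"] < alpha)
    else:
        out["significant"] = out["tested"] & (out["p"] < alpha)
    return out
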