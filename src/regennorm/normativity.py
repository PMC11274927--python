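"""Proteome-anchored ("normative") quantification of metabolites and lipids.

Small molecules cannot be normalized with a handful of internal standards
the way proteins can, because instrument response is non-linear across
even narrow m/z ranges.  The *normative level* of an analyte expresses
its peak area per µg of a spike-normalized **anchor protein** from a
relevant pathway (e.g. citrate per µg of aconitate hydratase), instead of
per µg of total protein.  Because anchor amounts change with biological
state, normative levels can show different condition trends than
total-protein-normalized ones — that contrast is the point.

Also provided: lipid class-standard normalization, MetaboAnalyst-style
preprocessing (IQR filter, log10, autoscale), volcano significance and
duplicate merging.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .spike import _welch
from .types import AnchorError, ConfigurationError, TrendLabel, ValidationError

logger = logging.getLogger(__name__)


def per_total_protein(peak_area: float, total_protein: float) -> float:
    """Peak area per µg of total sample protein."""
    if not total_protein > 0:
        raise ValidationError(f"total_protein must be > 0, got {total_protein!r}")
    return peak_area / total_protein


def class_standard_normalize(
    peak_area: float, class_standard_area: float, standard_amount: float
) -> float:
    """Normalize a lipid to its class internal standard of known amount."""
    if not class_standard_area > 0:
        raise ValidationError(
            f"class standard area must be > 0, got {class_standard_area!r}"
        )
    return peak_area * standard_amount / class_standard_area


def anchor_amount(normalized_amounts: Iterable[float]) -> float:
    """Anchor-protein denominator: mean of one or more normalized µg values."""
    vals = list(normalized_amounts)
    if not vals:
        raise AnchorError("at least one anchor-protein amount is required")
    if any(not v > 0 for v in vals):
        raise AnchorError(f"anchor amounts must all be > 0, got {vals}")
    return float(np.mean(vals))


def normative_level(analyte_value: float, anchor: float) -> float:
    """Analyte level per µg of anchor protein."""
    if not anchor > 0:
        raise AnchorError(f"anchor amount must be > 0, got {anchor!r}")
    return analyte_value / anchor


def classify_trend(
    control: float, crush: float, regeneration: float, rel_tol: float = 0.05
) -> TrendLabel:
    """Label the control → crush → regeneration pattern of a level.

    ``axon_consistent``: a drop at crush followed by a rise with
    regeneration — the pattern expected of an axon-resident molecule lost
    with the axons and restored as they regrow.  ``inverse`` is the mirror
    image; ``flat_then_up`` is no appreciable change at crush then a rise.
    Changes smaller than ``rel_tol`` (relative) do not count as changes.
    """
    if min(control, crush, regeneration) < 0:
        raise ValidationError("trend inputs must be non-negative")
    down = crush < control * (1 - rel_tol)
    up_after = regeneration > crush * (1 + rel_tol)
    if down and up_after:
        return TrendLabel.AXON_CONSISTENT
    if crush > control * (1 + rel_tol) and regeneration < crush * (1 - rel_tol):
        return TrendLabel.INVERSE
    if abs(crush - control) <= rel_tol * control and up_after:
        return TrendLabel.FLAT_THEN_UP
    return TrendLabel.OTHER


def condition_means(
    analytes: pd.DataFrame,
    design: pd.DataFrame,
    value_col: str = "peak_area",
    id_col: str = "analyte_id",
) -> pd.DataFrame:
    """Per-(analyte, condition) mean level, missing values excluded."""
    merged = analytes.merge(design[["sample_id", "condition_key"]], on="sample_id")
    return (
        merged.groupby([id_col, "condition_key"])[value_col]
        .mean()
        .reset_index()
    )


def normativity_table(
    analyte_condition_levels: pd.DataFrame,
    anchor_condition_amounts: Mapping[str, float],
    conditions: tuple[str, str, str],
    rel_tol: float = 0.05,
    anchor_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Normative levels per condition, with trend labels.

    Parameters
    ----------
    analyte_condition_levels
        Columns analyte_id, condition_key, level (condition-mean analyte
        levels, typically already per-total-protein).
    anchor_condition_amounts
        condition_key -> anchor µg (mean over replicates and, for a
        multi-protein anchor, over proteins).
    conditions
        The (control, crush, regeneration) condition keys used for trend
        classification.
    """
    ctrl_k, crush_k, regen_k = conditions
    for key in conditions:
        if key not in anchor_condition_amounts:
            raise AnchorError(f"anchor amount missing for condition {key!r}")
    anchors = {k: anchor_amount([v]) for k, v in anchor_condition_amounts.items()}
    wide = analyte_condition_levels.pivot_table(
        index="analyte_id", columns="condition_key", values="level"
    )
    rows = []
    for analyte_id, series in wide.iterrows():
        if series.reindex(conditions).isna().any():
            logger.warning(
                "analyte %s: missing a condition mean; skipped", analyte_id
            )
            continue
        norm = {k: normative_level(series[k], anchors[k]) for k in conditions}
        raw_trend = classify_trend(
            series[ctrl_k], series[crush_k], series[regen_k], rel_tol
        )
        norm_trend = classify_trend(
            norm[ctrl_k], norm[crush_k], norm[regen_k], rel_tol
        )
        rows.append(
            {
                "analyte_id": analyte_id,
                "anchor_ids": ";".join(anchor_ids),
                "control": norm[ctrl_k],
                "crush": norm[crush_k],
                "regeneration": norm[regen_k],
                "trend_label": norm_trend.value,
                "input_trend_label": raw_trend.value,
                "trend_differs": norm_trend != raw_trend,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MetaboAnalyst-style preprocessing

def preprocess_analytes(
    levels: pd.DataFrame,
    log_base10: bool = True,
    iqr_filter: bool = True,
    autoscale: bool = False,
    iqr_drop_fraction: float = 0.25,
) -> pd.DataFrame:
    """Filter and transform an analyte × sample matrix.

    In order: drop the ``iqr_drop_fraction`` of features with the lowest
    interquartile range (near-constant features carry no contrast), log10
    transform (non-positive values are masked with a warning, never
    offset), then per-feature autoscaling to mean 0 / sd 1 (zero-variance
    features are dropped with a warning).

    ``levels`` is wide: rows = features, columns = samples.
    """
    if not 0 <= iqr_drop_fraction < 1:
        raise ConfigurationError(
            f"iqr_drop_fraction must be in [0, 1), got {iqr_drop_fraction}"
        )
    out = levels.astype(float).copy()
    if iqr_filter and len(out) > 1:
        iqr = out.quantile(0.75, axis=1) - out.quantile(0.25, axis=1)
        n_drop = int(np.floor(len(out) * iqr_drop_fraction))
        if n_drop:
            keep = iqr.sort_values(ascending=False, kind="stable").index[: len(out) - n_drop]
            out = out.loc[out.index.intersection(keep, sort=False)]
    if log_base10:
        nonpos = (out <= 0).to_numpy().sum()
        if nonpos:
            logger.warning("log10: masked %d non-positive values", nonpos)
        out = out.where(out > 0)
        out = np.log10(out)
    if autoscale:
        sd = out.std(axis=1, ddof=1)
        constant = sd.fillna(0) == 0
        if constant.any():
            logger.warning(
                "autoscale: dropped %d constant feature(s): %s",
                int(constant.sum()), list(out.index[constant])[:5],
            )
            out = out[~constant]
            sd = sd[~constant]
        out = out.sub(out.mean(axis=1), axis=0).div(sd, axis=0)
    return out


def fold_change(mean_a: float, mean_b: float) -> float:
    """Raw-scale fold change b/a (values < 1 mean a decrease)."""
    if mean_a <= 0:
        return float("inf") if mean_b > 0 else float("nan")
    return mean_b / mean_a


def volcano_significant(
    levels: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Volcano-style selection: Welch p below and |fold change| beyond
    threshold (two-sided: a fold change of 1/fc also qualifies).

    ``levels`` is wide (features × samples) on the raw scale; the t-test
    runs on log10 values, the fold-change gate on raw means.
    """
    rows = []
    ga, gb = list(group_a), list(group_b)
    for feature, series in levels.iterrows():
        a = series.reindex(ga).dropna().to_numpy(dtype=float)
        b = series.reindex(gb).dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        fc = fold_change(float(np.mean(a)), float(np.mean(b)))
        with np.errstate(divide="ignore"):
            la, lb = np.log10(a[a > 0]), np.log10(b[b > 0])
        if len(la) < 2 or len(lb) < 2:
            continue
        _, p = _welch(la, lb)
        two_sided_fc = max(fc, 1.0 / fc) if fc > 0 else float("inf")
        rows.append(
            {
                "feature_id": feature,
                "p": p,
                "fold_change": fc,
                "significant": bool(p < p_threshold and two_sided_fc >= fc_threshold),
            }
        )
    return pd.DataFrame(rows, columns=["feature_id", "p", "fold_change", "significant"])


def merge_duplicates(
    analytes: pd.DataFrame,
    rule: str = "mean",
    id_col: str = "analyte_id",
    value_col: str = "peak_area",
) -> pd.DataFrame:
    """Merge duplicate analyte records (e.g. the same metabolite seen in
    positive and negative ionization mode) into one record per analyte per
    sample.  ``rule`` is ``"mean"`` (default) or ``"sum"``.
    """
    if rule not in ("mean", "sum"):
        raise ConfigurationError(f"merge rule must be 'mean' or 'sum', got {rule!r}")
    keys = [id_col, "sample_id"]
    extra = [c for c in analytes.columns if c not in keys + [value_col]]
    agg = {value_col: rule} | {c: "first" for c in extra}
    return analytes.groupby(keys, as_index=False, sort=True).agg(agg)
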