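"""Reporter-fluorescence correction and CRISPR-screen score differencing.

A codon-optimized destabilized GFP reporter (all Ser codons recoded to one
codon) with an IRES-mCherry internal control reads out the translation
efficiency of that codon.  Per condition, the reporter value is the
geometric mean of GFP divided by the geometric mean of mCherry; the value
measured under cycloheximide (CHX, translation fully blocked) is subtracted
as background, and the deprived/rich ratio of the corrected values
(-SG/+SG) quantifies the translational effect of Ser/Gly withdrawal.

Gene-level CRISPR screen effect sizes (beta scores, estimated upstream by
MAGeCK MLE) are consumed as tables; differencing the beta scores of two
reporter screens isolates codon-specific regulators, selected by a strict
threshold on the difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReporterMeasurement",
    "CorrectedRatio",
    "geometric_mean",
    "reporter_value",
    "corrected_ratio",
    "beta_diff_rank",
    "BETA_DIFF_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Selection threshold on the beta-score difference (strict inequality).
BETA_DIFF_THRESHOLD = 0.25


@dataclass(frozen=True)
class ReporterMeasurement:
    """Per-cell GFPd2 and mCherry fluorescence for one sample."""

    sample_id: str
    condition: str  # rich / deprived / chx
    gfp_values: tuple[float, ...]
    mcherry_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, values in (
            ("gfp", self.gfp_values),
            ("mcherry", self.mcherry_values),
        ):
            values = tuple(float(v) for v in values)
            object.__setattr__(self, f"{name}_values", values)
            if not values:
                raise ValueError(f"{self.sample_id}: empty {name} values")
            if any(v <= 0 for v in values):
                raise ValueError(
                    f"{self.sample_id}: non-positive {name} events must be "
                    "filtered upstream"
                )


@dataclass(frozen=True)
class CorrectedRatio:
    """Background-corrected -SG/+SG reporter ratio.

    ``defined`` is False when the rich-condition signal does not exceed the
    CHX background; ``negative`` flags a deprived signal below background
    (reported as-is rather than clipped, so background problems stay
    visible).
    """

    value: float
    defined: bool
    negative: bool


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean of strictly positive values.

    Computed as (prod x)^(1/n), which is exact for small hand-checked
    inputs; falls back to the log-space form (scipy's gmean) when the
    product over- or underflows.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty set")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    with np.errstate(over="ignore", under="ignore"):
        prod = float(np.prod(arr))
    if 0.0 < prod < np.inf:
        return float(prod ** (1.0 / arr.size))
    return float(stats.gmean(arr))


def reporter_value(measurement: ReporterMeasurement) -> float:
    """Per-condition normalized reporter value: gmean(GFP) / gmean(mCherry)."""
    return geometric_mean(measurement.gfp_values) / geometric_mean(
        measurement.mcherry_values
    )


def corrected_ratio(
    rich: ReporterMeasurement,
    deprived: ReporterMeasurement,
    chx: ReporterMeasurement,
) -> CorrectedRatio:
    """Background-corrected -SG/+SG ratio.

    ratio = (v_deprived - v_chx) / (v_rich - v_chx), with each v the
    mCherry-normalized geometric-mean GFP of that condition.  CHX
    subtraction operates on the normalized per-condition values, not per
    cell.  Undefined (NaN, flagged) when the rich signal does not exceed
    background.
    """
    v_rich = reporter_value(rich)
    v_dep = reporter_value(deprived)
    v_chx = reporter_value(chx)
    denom = v_rich - v_chx
    num = v_dep - v_chx
    if denom <= 0:
        logger.warning(
            "corrected_ratio: rich signal %.4g does not exceed CHX "
            "background %.4g", v_rich, v_chx,
        )
        return CorrectedRatio(float("nan"), defined=False, negative=num < 0)
    return CorrectedRatio(num / denom, defined=True, negative=num < 0)


def beta_diff_rank(
    table_a: Mapping[str, float],
    table_b: Mapping[str, float],
    threshold: float = BETA_DIFF_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene beta-score difference (A minus B), ranked descending.

    Genes outside the intersection of the two screens are dropped with a
    logged count; selection uses a strict ``beta_diff > threshold``.  Ties
    in beta_diff are ranked alphabetically by gene.
    """
    shared = sorted(set(table_a) & set(table_b))
    if not shared:
        raise ValueError("the two beta tables share no genes")
    dropped = (len(table_a) - len(shared)) + (len(table_b) - len(shared))
    if dropped:
        logger.info("beta_diff_rank: dropped %d non-overlapping genes", dropped)
    df = pd.DataFrame(
        {
            "gene_id": shared,
            "beta_a": [float(table_a[g]) for g in shared],
            "beta_b": [float(table_b[g]) for g in shared],
        }
    )
    df["beta_diff"] = df["beta_a"] - df["beta_b"]
    df = df.sort_values(
        ["beta_diff", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = df["beta_diff"] > threshold
    return df
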