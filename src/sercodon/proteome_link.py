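"""Coupling codon composition to newly synthesized protein output.

SILAC heavy-channel intensities mark proteins synthesized after the label
switch; log2 fold changes between conditions therefore isolate translational
output from pre-existing protein pools.  Gene-level fold changes (or naive
differential-TE values) are joined to Ser-codon composition profiles,
averaged within percentage bins to suppress gene-specific regulatory noise,
correlated (Spearman) against bin midpoints, fitted with a quadratic trend
(with explicit exclusion of outlier bins such as 91-100%), and p-values are
adjusted with the two-stage Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codon_metrics import BinScheme, FINE_BINS, assign_bin

__all__ = [
    "CorrelationResult",
    "silac_fold_change",
    "bin_average",
    "bin_midpoints",
    "spearman_r",
    "binned_spearman",
    "fit_trend",
    "bh_adjust",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its provenance.

    ``basis`` records whether r was computed over individual genes or over
    bin means; ``defined`` is False when either vector is constant (rank
    correlation undefined).
    """

    r: float
    n: int
    basis: str
    defined: bool = True


def silac_fold_change(
    heavy_a: Mapping[str, float],
    heavy_b: Mapping[str, float],
    policy: str = "drop",
) -> pd.DataFrame:
    """Per-protein log2(heavy_a / heavy_b) of heavy-channel intensities.

    Only proteins quantified (finite, positive) in both conditions receive
    a fold change; under the default ``drop`` policy the rest are omitted
    with a logged count.  No imputation is offered — imputed values would
    inject exactly the structure the downstream correlation measures.
    """
    if policy != "drop":
        raise ValueError(f"unknown missing-data policy {policy!r}")
    rows = []
    n_dropped = 0
    for pid in sorted(set(heavy_a) | set(heavy_b)):
        a = float(heavy_a.get(pid, np.nan))
        b = float(heavy_b.get(pid, np.nan))
        if a < 0 or b < 0:
            raise ValueError(f"{pid}: negative intensity")
        if not (np.isfinite(a) and np.isfinite(b)) or a == 0 or b == 0:
            n_dropped += 1
            continue
        rows.append(
            {
                "protein_id": pid,
                "heavy_a": a,
                "heavy_b": b,
                "log2_fc": float(np.log2(a / b)),
            }
        )
    if n_dropped:
        logger.info(
            "silac_fold_change: dropped %d proteins not quantified in both "
            "conditions", n_dropped,
        )
    return pd.DataFrame(rows, columns=["protein_id", "heavy_a", "heavy_b", "log2_fc"])


def bin_average(
    values: Mapping[str, float],
    bins: Mapping[str, str],
    all_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-bin n, mean and SEM of gene-level values.

    ``bins`` maps each gene to its bin label; genes missing from either
    mapping are ignored (profiles must be resolved upstream).  Bins listed
    in ``all_labels`` but empty are reported with n=0; SEM is NaN for
    n < 2.
    """
    per_bin: dict[str, list[float]] = {}
    for gene, value in values.items():
        label = bins.get(gene)
        if label is None:
            continue
        per_bin.setdefault(label, []).append(float(value))
    labels = list(all_labels) if all_labels is not None else sorted(per_bin)
    rows = []
    for label in labels:
        vals = np.asarray(per_bin.get(label, []), dtype=float)
        n = len(vals)
        rows.append(
            {
                "bin": label,
                "n": n,
                "mean_fc": float(vals.mean()) if n else float("nan"),
                "sem": float(stats.sem(vals)) if n >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["bin", "n", "mean_fc", "sem"])


def bin_midpoints(scheme: BinScheme) -> dict[str, float]:
    """Midpoint percentage of each bin interval, keyed by label."""
    return {
        label: (lo + hi) / 2.0
        for lo, hi, label in zip(scheme.edges, scheme.edges[1:], scheme.labels)
    }


def spearman_r(
    x: Sequence[float], y: Sequence[float], basis: str = "individual"
) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties).

    Requires n >= 3 finite pairs; a constant vector yields an undefined
    (NaN) coefficient flagged via ``defined=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 finite pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), n, basis, defined=False)
    r = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(r, n, basis)


def binned_spearman(
    values: Mapping[str, float],
    pct: Mapping[str, float],
    scheme: BinScheme = FINE_BINS,
) -> CorrelationResult:
    """Spearman r of bin means against bin midpoints.

    Genes are binned by their codon-class percentage, bin means are taken
    unweighted, and only non-empty bins enter the correlation.
    """
    bins = {
        g: assign_bin(p, scheme) for g, p in pct.items() if np.isfinite(p)
    }
    summary = bin_average(values, bins, all_labels=scheme.labels)
    mids = bin_midpoints(scheme)
    nonempty = summary[summary["n"] > 0]
    return spearman_r(
        [mids[b] for b in nonempty["bin"]],
        nonempty["mean_fc"].to_numpy(),
        basis="binned",
    )


def fit_trend(
    midpoints: Sequence[float],
    means: Sequence[float],
    labels: Sequence[str] | None = None,
    exclude_bins: Sequence[str] = (),
) -> pd.DataFrame:
    """Ordinary least-squares quadratic over retained bins.

    Returns one row per bin with fitted values and an ``excluded`` flag,
    plus the coefficients (c0, c1, c2 of c0 + c1 x + c2 x^2) attached in
    ``DataFrame.attrs['coefficients']``.  Refuses to fit fewer than 3
    retained points.
    """
    midpoints = np.asarray(midpoints, dtype=float)
    means = np.asarray(means, dtype=float)
    if labels is None:
        labels = [str(m) for m in midpoints]
    labels = list(labels)
    if not (len(midpoints) == len(means) == len(labels)):
        raise ValueError("midpoints, means and labels must align")
    excluded = np.array([lab in set(exclude_bins) for lab in labels])
    keep = ~excluded & np.isfinite(means)
    if keep.sum() < 3:
        raise ValueError(
            f"only {int(keep.sum())} retained bins; need >= 3 for a "
            "quadratic fit"
        )
    coeffs = npoly.polyfit(midpoints[keep], means[keep], deg=2)
    fitted = npoly.polyval(midpoints, coeffs)
    out = pd.DataFrame(
        {
            "bin": labels,
            "midpoint": midpoints,
            "mean_fc": means,
            "fitted": fitted,
            "excluded": excluded,
        }
    )
    out.loc[excluded, "fitted"] = np.nan
    out.attrs["coefficients"] = tuple(float(c) for c in coeffs)
    return out


def bh_adjust(
    p_values: Sequence[float],
    two_stage: bool = True,
    alpha: float = 0.05,
) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, two-stage step-up by default.

    The two-stage procedure estimates the number of true nulls m0 from a
    first BH pass at level ``alpha`` (m0 = m - rejections) and rescales the
    BH-adjusted values by m0/m when the first pass rejects some but not all
    hypotheses, which is the adjustment reported alongside tRNA pool
    comparisons.  Plain BH is available with ``two_stage=False``.  Adjusted
    values are monotone non-decreasing in rank order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    method = "fdr_tsbh" if two_stage else "fdr_bh"
    return multipletests(p, alpha=alpha, method=method)[1]
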