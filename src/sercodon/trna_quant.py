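"""Charged DM-tRNA-seq downstream quantification.

Periodate oxidation destroys the 3'-terminal ribose of uncharged tRNAs
(the esterified amino acid protects charged molecules), so after repair and
sequencing a charged mature tRNA reads out with an intact 3' CCA while an
uncharged one ends in CC.  Reads extending past the mature boundaries into
the genomically encoded leader or trailer come from unprocessed pre-tRNAs.
This module starts from such classified (or classifiable) read counts per
isodecoder and performs the downstream arithmetic: charging percentages,
isodecoder-to-isoacceptor aggregation, charged-pool levels (percent charged
times mature level) and within-amino-acid isoacceptor ratios.

Alignment, demethylation chemistry and multi-mapper resolution are upstream
concerns; input tables are assumed uniquely assigned.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "READ_CLASSES",
    "TrnaReference",
    "classify_read_end",
    "charging_fraction",
    "parse_isodecoder",
    "sum_isoacceptors",
    "charged_level",
    "isoacceptor_ratio_table",
    "cpm_normalize",
    "charging_table",
]

READ_CLASSES = ("charged_mature", "uncharged_mature", "pre", "ambiguous")

_COUNT_COLS = ("n_cca", "n_cc", "n_pre")


@dataclass(frozen=True)
class TrnaReference:
    """Mature tRNA reference plus pre-tRNA flank lengths.

    ``mature_sequence`` ends at the discriminator base; the CCA tail is
    added post-transcriptionally and is treated as occupying the three
    positions immediately 3' of the mature sequence.  Coordinates used by
    :func:`classify_read_end` run over leader | mature | CCA, with the
    trailer beginning where the CCA would sit in the unprocessed precursor.
    """

    isodecoder_id: str
    mature_sequence: str
    leader_len: int = 0
    trailer_len: int = 0

    def __post_init__(self) -> None:
        if self.leader_len < 0 or self.trailer_len < 0:
            raise ValueError(f"{self.isodecoder_id}: negative flank length")
        if not 50 <= len(self.mature_sequence) <= 150:
            raise ValueError(
                f"{self.isodecoder_id}: mature length "
                f"{len(self.mature_sequence)} outside the 50-150 nt range"
            )

    @property
    def mature_end(self) -> int:
        """Coordinate one past the 3' A of the CCA tail."""
        return self.leader_len + len(self.mature_sequence) + 3


def classify_read_end(
    read_3prime_alignment_end: int,
    terminal_bases: str,
    ref: TrnaReference,
    read_start: int | None = None,
) -> str:
    """Classify a tRNA-seq read by its 3' end.

    * ends flush with the mature 3' end with terminal ...CCA -> charged_mature
    * ends one base short with terminal ...CC -> uncharged_mature
    * extends >= 1 nt into the trailer (or starts in the leader) -> pre
    * anything else -> ambiguous (a counted category, not an error)
    """
    end = read_3prime_alignment_end
    limit = ref.mature_end + ref.trailer_len
    if not 0 < end <= max(limit, ref.mature_end):
        raise ValueError(
            f"{ref.isodecoder_id}: alignment end {end} outside reference"
        )
    terminal = terminal_bases.upper().replace("U", "T")
    if read_start is not None and read_start < ref.leader_len:
        return "pre"
    if end > ref.mature_end:
        return "pre"
    if end == ref.mature_end and terminal.endswith("CCA"):
        return "charged_mature"
    if end == ref.mature_end - 1 and terminal.endswith("CC"):
        return "uncharged_mature"
    return "ambiguous"


def charging_fraction(n_cca: int, n_cc: int) -> float:
    """Percent charged: 100 * n_cca / (n_cca + n_cc).

    NaN (undefined) when no mature reads were observed.  Ambiguous reads do
    not enter the denominator.
    """
    if n_cca < 0 or n_cc < 0:
        raise ValueError("read counts must be non-negative")
    total = n_cca + n_cc
    if total == 0:
        return float("nan")
    return 100.0 * n_cca / total


_ISODECODER_RE = re.compile(
    r"^(?:tRNA-)?(?P<aa>[A-Za-z]{3,4})-(?P<anticodon>[ACGTUacgtu]{3})"
    r"(?:-\d+){0,2}$"
)


def parse_isodecoder(isodecoder_id: str) -> tuple[str, str]:
    """Split an isodecoder id into (amino acid, anticodon).

    Accepts e.g. ``Ser-AGA-1``, ``tRNA-Ser-GCU-1-1``, ``iMet-CAT``.  The
    anticodon is reported in RNA alphabet uppercase (AGA, GCU, ...).
    """
    m = _ISODECODER_RE.match(isodecoder_id.strip())
    if m is None:
        raise ValueError(f"unparseable isodecoder id {isodecoder_id!r}")
    anticodon = m.group("anticodon").upper().replace("T", "U")
    return m.group("aa"), anticodon


def sum_isoacceptors(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate isodecoder counts into per-isoacceptor totals.

    Input columns: isodecoder_id, condition, n_cca, n_cc, n_pre and
    optionally library_size (validated constant within a condition).
    Output: one row per (amino_acid, anticodon, condition) with summed
    counts plus mature = n_cca + n_cc.  Grand totals are conserved.
    """
    required = {"isodecoder_id", "condition", *_COUNT_COLS}
    if not required.issubset(table.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    if len(table) == 0:
        return pd.DataFrame(
            columns=[
                "amino_acid", "anticodon", "isoacceptor_id", "condition",
                *_COUNT_COLS, "mature", "library_size",
            ]
        )
    if (table[list(_COUNT_COLS)] < 0).any().any():
        raise ValueError("read counts must be non-negative")
    parsed = table["isodecoder_id"].map(parse_isodecoder)
    work = table.copy()
    work["amino_acid"] = parsed.map(lambda t: t[0])
    work["anticodon"] = parsed.map(lambda t: t[1])
    keys = ["amino_acid", "anticodon", "condition"]
    agg = work.groupby(keys, sort=True)[list(_COUNT_COLS)].sum().reset_index()
    agg["mature"] = agg["n_cca"] + agg["n_cc"]
    agg["isoacceptor_id"] = agg["amino_acid"] + "-" + agg["anticodon"]
    if "library_size" in table.columns:
        sizes = work.groupby("condition")["library_size"].nunique()
        if (sizes > 1).any():
            raise ValueError("library_size differs within a condition")
        lib = work.groupby("condition")["library_size"].first()
        agg["library_size"] = agg["condition"].map(lib)
    cols = [
        "amino_acid", "anticodon", "isoacceptor_id", "condition",
        *_COUNT_COLS, "mature",
    ]
    if "library_size" in agg.columns:
        cols.append("library_size")
    return agg[cols]


def charged_level(pct_charged: float, mature_level: float) -> float:
    """Charged pool: (percent charged / 100) x mature level.

    An undefined (NaN) charging percentage propagates to NaN.
    """
    if math.isnan(pct_charged):
        return float("nan")
    if not 0.0 <= pct_charged <= 100.0:
        raise ValueError(f"pct_charged {pct_charged!r} outside [0, 100]")
    if mature_level < 0:
        raise ValueError("mature_level must be non-negative")
    return (pct_charged / 100.0) * mature_level


def isoacceptor_ratio_table(
    charged_levels: Mapping[str, float],
    pair: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Within-amino-acid pool composition plus one pairwise ratio.

    ``charged_levels`` maps isoacceptor ids (e.g. anticodons) of one amino
    acid to charged-pool levels.  Returns a table with
    ratio_in_pool = level / sum(levels) (NaN when the pool is all zero) and
    the pairwise ratio level[pair[0]] / level[pair[1]] (NaN when the
    denominator is zero or no pair was requested).
    """
    if not charged_levels:
        raise ValueError("no isoacceptor levels supplied")
    ids = sorted(charged_levels)
    levels = np.array([charged_levels[i] for i in ids], dtype=float)
    if np.any(levels < 0):
        raise ValueError("charged levels must be non-negative")
    total = levels.sum()
    ratios = levels / total if total > 0 else np.full_like(levels, np.nan)
    table = pd.DataFrame(
        {"isoacceptor_id": ids, "charged_level": levels, "ratio_in_pool": ratios}
    )
    pairwise = float("nan")
    if pair is not None:
        a, b = pair
        if a not in charged_levels or b not in charged_levels:
            raise ValueError(f"pair {pair!r} not present in the pool")
        if charged_levels[b] > 0:
            pairwise = charged_levels[a] / charged_levels[b]
    return table, pairwise


def cpm_normalize(count: float, library_size: int) -> float:
    """Counts per million: count * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1e6 / library_size


def charging_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Full per-isoacceptor charging summary from an isodecoder count table.

    For each (isoacceptor, condition): percent charged, CPM-normalized
    mature and pre levels (when library_size is present; raw counts
    otherwise), the charged level, and the charged-pool composition within
    each amino acid (ratio_in_pool, NaN for all-zero pools).
    """
    agg = sum_isoacceptors(counts)
    if len(agg) == 0:
        agg["pct_charged"] = agg["mature_level"] = agg["pre_level"] = []
        agg["charged_level"] = agg["ratio_in_pool"] = []
        return agg
    agg["pct_charged"] = [
        charging_fraction(int(r.n_cca), int(r.n_cc))
        for r in agg.itertuples()
    ]
    if "library_size" in agg.columns:
        agg["mature_level"] = [
            cpm_normalize(r.mature, int(r.library_size))
            for r in agg.itertuples()
        ]
        agg["pre_level"] = [
            cpm_normalize(r.n_pre, int(r.library_size))
            for r in agg.itertuples()
        ]
    else:
        agg["mature_level"] = agg["mature"].astype(float)
        agg["pre_level"] = agg["n_pre"].astype(float)
    agg["charged_level"] = [
        charged_level(r.pct_charged, r.mature_level)
        for r in agg.itertuples()
    ]
    pool = agg.groupby(["amino_acid", "condition"])["charged_level"].transform(
        "sum"
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["ratio_in_pool"] = np.where(
            pool > 0, agg["charged_level"] / pool, np.nan
        )
    return agg
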