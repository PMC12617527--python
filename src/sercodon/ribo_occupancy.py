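"""Codon-centric ribosome density from footprint alignments.

Ribosome stalling on a codon raises footprint coverage around its
occurrences.  The statistic implemented here is a codon metagene: per-CDS
coverage is normalized to its own mean, then averaged position-by-position
over a window extending 150 nt on either side of every occurrence of a
codon, pooled across transcripts.  Subtracting the rich-condition metagene
from the deprived-condition metagene gives a per-position delta whose mean
over a footprint-sized span centred on the codon ("pause score") summarizes
the condition-specific stall.  Ranking pause scores across the 61 sense
codons recovers which codons stall under a given perturbation.

Coordinates are 0-based half-open CDS nucleotide positions throughout;
relative metagene position 0 is the first nucleotide of the codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_metrics import CodingSequence, SENSE_CODONS, _VALID

__all__ = [
    "DEFAULT_HALF_WINDOW",
    "DEFAULT_PAUSE_SPAN",
    "DEFAULT_FOOTPRINT_RANGE",
    "CoverageTrack",
    "MetageneResult",
    "DeltaDensity",
    "coverage_from_alignments",
    "normalize_track",
    "build_tracks",
    "metagene_around_codon",
    "metagene_all_codons",
    "delta_density",
    "pause_rank_table",
    "differential_te",
]

logger = logging.getLogger(__name__)

#: Metagene half-window, nt on either side of the codon.
DEFAULT_HALF_WINDOW = 150
#: Pause-score span: a ~33-nt footprint whose A site sits on the codon
#: covers roughly positions -15 ... +17 relative to the codon start.
DEFAULT_PAUSE_SPAN = (-15, 17)
#: Accepted footprint lengths (gel-excised 26-34 nt band).
DEFAULT_FOOTPRINT_RANGE = (26, 34)
#: Occurrences within this many codons of the CDS ends are excluded from
#: metagenes to keep initiation/termination signal out of pause scores.
DEFAULT_EDGE_EXCLUSION_CODONS = 20

_MIN_FOOTPRINTS = 100
_MIN_MEAN_COVERAGE = 0.5


@dataclass
class CoverageTrack:
    """Per-position footprint coverage over one CDS."""

    transcript_id: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be 1-D")


@dataclass
class MetageneResult:
    """Mean normalized density around all occurrences of one codon.

    positions run -half_window ... half_window+2 (the window flanks plus the
    codon's three nucleotides); density is NaN where no occurrence
    contributes (edge truncation or empty input).
    """

    codon: str
    positions: np.ndarray
    density: np.ndarray
    n_occurrences: np.ndarray

    @property
    def half_window(self) -> int:
        return int(-self.positions[0])


@dataclass
class DeltaDensity:
    """Deprived-minus-rich metagene delta and its pause-score summary."""

    codon: str
    positions: np.ndarray
    delta: np.ndarray
    pause_score: float


def coverage_from_alignments(
    alignments: Iterable[tuple[int, int]] | pd.DataFrame,
    cds_length: int,
    transcript_id: str = "",
    footprint_range: tuple[int, int] | None = DEFAULT_FOOTPRINT_RANGE,
    mode: str = "full",
    a_site_offset: int = 15,
) -> CoverageTrack:
    """Per-base footprint coverage over one CDS.

    In the default ``full`` mode values[p] counts the footprints overlapping
    CDS position p; in ``asite`` mode each footprint contributes a single
    count at its inferred A site (5' end + ``a_site_offset``), which
    collapses the read to the position being decoded.  ``alignments`` is an
    iterable of (start, end) pairs (0-based half-open) or a DataFrame with
    ``start``/``end`` columns.  Out-of-bounds intervals raise with the
    offending record; footprints outside ``footprint_range`` raise likewise
    (pass None to skip the length check).
    """
    if mode not in ("full", "asite"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    if isinstance(alignments, pd.DataFrame):
        pairs = alignments[["start", "end"]].itertuples(index=False)
    else:
        pairs = alignments
    if cds_length <= 0:
        raise ValueError(f"{transcript_id}: non-positive CDS length")
    # difference-array trick: O(reads + length)
    diff = np.zeros(cds_length + 1, dtype=float)
    for start, end in pairs:
        if not (0 <= start < end <= cds_length):
            raise ValueError(
                f"{transcript_id}: alignment [{start}, {end}) outside "
                f"CDS of length {cds_length}"
            )
        if footprint_range is not None:
            lo, hi = footprint_range
            if not (lo <= end - start <= hi):
                raise ValueError(
                    f"{transcript_id}: footprint [{start}, {end}) has "
                    f"length {end - start}, outside {lo}-{hi}"
                )
        if mode == "asite":
            p = min(start + a_site_offset, cds_length - 1)
            diff[p] += 1.0
            diff[p + 1] -= 1.0
        else:
            diff[start] += 1.0
            diff[end] -= 1.0
    return CoverageTrack(
        transcript_id=transcript_id,
        values=np.cumsum(diff[:-1]),
        normalized=False,
    )


def normalize_track(
    track: CoverageTrack, min_mean: float = _MIN_MEAN_COVERAGE
) -> CoverageTrack | None:
    """Divide a track by its own per-position mean coverage.

    Returns None ("filtered") for tracks whose mean falls below
    ``min_mean`` — including all-zero tracks — rather than raising; a track
    that is already normalized is a hard error (normalizing twice would
    silently re-base the metagene).
    """
    if track.normalized:
        raise ValueError(
            f"{track.transcript_id}: track is already normalized"
        )
    mean = float(track.values.mean())
    if mean < min_mean or mean == 0.0:
        return None
    return CoverageTrack(
        transcript_id=track.transcript_id,
        values=track.values / mean,
        normalized=True,
    )


def build_tracks(
    alignments: pd.DataFrame,
    cds_set: Mapping[str, CodingSequence],
    min_footprints: int = _MIN_FOOTPRINTS,
    min_mean: float = _MIN_MEAN_COVERAGE,
    footprint_range: tuple[int, int] | None = DEFAULT_FOOTPRINT_RANGE,
    mode: str = "full",
    a_site_offset: int = 15,
) -> dict[str, CoverageTrack]:
    """Normalized coverage tracks for every sufficiently covered transcript.

    ``alignments`` must have transcript_id/start/end columns; transcripts
    with fewer than ``min_footprints`` reads or mean coverage below
    ``min_mean`` are dropped (counts logged).  Transcripts are keyed by
    ``transcript_id`` matching ``cds_set``.
    """
    required = {"transcript_id", "start", "end"}
    if not required.issubset(alignments.columns):
        raise ValueError(f"alignments need columns {sorted(required)}")
    tracks: dict[str, CoverageTrack] = {}
    n_low_reads = n_low_mean = 0
    for tid, group in alignments.groupby("transcript_id", sort=False):
        if tid not in cds_set:
            raise ValueError(f"alignments reference unknown transcript {tid!r}")
        if len(group) < min_footprints:
            n_low_reads += 1
            continue
        raw = coverage_from_alignments(
            group, len(cds_set[tid]), str(tid), footprint_range,
            mode=mode, a_site_offset=a_site_offset,
        )
        norm = normalize_track(raw, min_mean)
        if norm is None:
            n_low_mean += 1
            continue
        tracks[str(tid)] = norm
    logger.info(
        "build_tracks: kept %d transcripts, filtered %d (<%d reads), "
        "%d (mean < %.3g)",
        len(tracks), n_low_reads, min_footprints, n_low_mean, min_mean,
    )
    return tracks


def _codon_starts(
    sequence: str, codon: str, edge_exclusion_codons: int
) -> np.ndarray:
    """In-frame nucleotide start positions of ``codon``, excluding the first
    and last ``edge_exclusion_codons`` codons of the CDS."""
    n_codons = len(sequence) // 3
    lo = edge_exclusion_codons
    hi = n_codons - edge_exclusion_codons
    return np.array(
        [
            3 * i
            for i in range(lo, max(lo, hi))
            if sequence[3 * i : 3 * i + 3] == codon
        ],
        dtype=int,
    )


def _accumulate_window(
    values: np.ndarray,
    starts: np.ndarray,
    half_window: int,
    acc: np.ndarray,
    counts: np.ndarray,
) -> None:
    length = len(values)
    for c in starts:
        lo = max(0, c - half_window)
        hi = min(length, c + half_window + 3)
        off = lo - (c - half_window)
        acc[off : off + (hi - lo)] += values[lo:hi]
        counts[off : off + (hi - lo)] += 1


def metagene_around_codon(
    tracks: Mapping[str, CoverageTrack],
    cds_set: Mapping[str, CodingSequence],
    codon: str,
    half_window: int = DEFAULT_HALF_WINDOW,
    edge_exclusion_codons: int = DEFAULT_EDGE_EXCLUSION_CODONS,
) -> MetageneResult:
    """Mean normalized coverage around all occurrences of ``codon``.

    All (occurrence, transcript) pairs are pooled with equal weight; at each
    relative position the mean runs over the occurrences for which that
    position lies inside the CDS, so edge-truncated occurrences contribute
    only where defined.  A codon absent from every retained transcript
    yields a result with all-zero ``n_occurrences`` and NaN density.
    """
    result = metagene_all_codons(
        tracks, cds_set, (codon,), half_window, edge_exclusion_codons
    )
    return result[codon]


def metagene_all_codons(
    tracks: Mapping[str, CoverageTrack],
    cds_set: Mapping[str, CodingSequence],
    codons: Sequence[str] = SENSE_CODONS,
    half_window: int = DEFAULT_HALF_WINDOW,
    edge_exclusion_codons: int = DEFAULT_EDGE_EXCLUSION_CODONS,
) -> dict[str, MetageneResult]:
    """Metagenes for many codons in one pass over the tracks."""
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    for codon in codons:
        if len(codon) != 3 or set(codon) - _VALID:
            raise ValueError(f"invalid codon {codon!r}")
    width = 2 * half_window + 3
    positions = np.arange(-half_window, half_window + 3)
    acc = {c: np.zeros(width) for c in codons}
    counts = {c: np.zeros(width, dtype=int) for c in codons}
    for tid, track in tracks.items():
        if not track.normalized:
            raise ValueError(f"{tid}: track is not normalized")
        if tid not in cds_set:
            raise ValueError(f"track {tid!r} has no matching CDS")
        seq = cds_set[tid].sequence
        if len(seq) != len(track.values):
            raise ValueError(f"{tid}: track length does not match CDS")
        for codon in codons:
            starts = _codon_starts(seq, codon, edge_exclusion_codons)
            if len(starts):
                _accumulate_window(
                    track.values, starts, half_window, acc[codon], counts[codon]
                )
    out = {}
    for codon in codons:
        with np.errstate(invalid="ignore"):
            density = np.where(
                counts[codon] > 0, acc[codon] / np.maximum(counts[codon], 1), np.nan
            )
        out[codon] = MetageneResult(
            codon=codon,
            positions=positions.copy(),
            density=density,
            n_occurrences=counts[codon],
        )
    return out


def delta_density(
    deprived: MetageneResult,
    rich: MetageneResult,
    pause_span: tuple[int, int] = DEFAULT_PAUSE_SPAN,
) -> DeltaDensity:
    """Per-position deprived-minus-rich density delta and pause score.

    The pause score is the mean delta over ``pause_span`` (inclusive
    relative positions, default -15 ... +17), taken over positions where
    both metagenes are defined.
    """
    if deprived.codon != rich.codon:
        raise ValueError(
            f"codon mismatch: {deprived.codon!r} vs {rich.codon!r}"
        )
    if not np.array_equal(deprived.positions, rich.positions):
        raise ValueError("metagene windows do not match")
    delta = deprived.density - rich.density
    lo, hi = pause_span
    in_span = (deprived.positions >= lo) & (deprived.positions <= hi)
    span_vals = delta[in_span]
    score = (
        float(np.nanmean(span_vals))
        if np.any(np.isfinite(span_vals))
        else float("nan")
    )
    return DeltaDensity(
        codon=deprived.codon,
        positions=deprived.positions.copy(),
        delta=delta,
        pause_score=score,
    )


def pause_rank_table(deltas: Iterable[DeltaDensity]) -> pd.DataFrame:
    """Codons ranked by descending pause score, ties broken alphabetically."""
    deltas = list(deltas)
    if not deltas:
        raise ValueError("no pause scores to rank")
    df = pd.DataFrame(
        {
            "codon": [d.codon for d in deltas],
            "pause_score": [d.pause_score for d in deltas],
        }
    )
    df = df.sort_values(
        ["pause_score", "codon"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def differential_te(
    rpf_rich: Mapping[str, float],
    rpf_deprived: Mapping[str, float],
    rna_rich: Mapping[str, float],
    rna_deprived: Mapping[str, float],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Naive differential translation efficiency.

    TE_cond(g) = ((rpf_g + pc) / sum(rpf + pc)) / ((rna_g + pc) / sum(rna + pc))
    and delta_log2_te = log2(TE_deprived / TE_rich).  This is a deliberately
    simple library-normalized double ratio (no dispersion model, no
    significance test); outputs are labelled ``naive`` accordingly.
    """
    keys = set(rpf_rich)
    if not (
        keys == set(rpf_deprived) == set(rna_rich) == set(rna_deprived)
    ):
        raise ValueError("gene sets of the four count vectors differ")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    genes = sorted(keys)

    def _te(rpf: Mapping[str, float], rna: Mapping[str, float]) -> np.ndarray:
        rpf_v = np.array([rpf[g] for g in genes], dtype=float) + pseudocount
        rna_v = np.array([rna[g] for g in genes], dtype=float) + pseudocount
        if np.any(rpf_v < pseudocount) or np.any(rna_v < pseudocount):
            raise ValueError("counts must be non-negative")
        return (rpf_v / rpf_v.sum()) / (rna_v / rna_v.sum())

    te_rich = _te(rpf_rich, rna_rich)
    te_dep = _te(rpf_deprived, rna_deprived)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "rpf_rich": [rpf_rich[g] for g in genes],
            "rpf_deprived": [rpf_deprived[g] for g in genes],
            "rna_rich": [rna_rich[g] for g in genes],
            "rna_deprived": [rna_deprived[g] for g in genes],
            "te_rich_naive": te_rich,
            "te_deprived_naive": te_dep,
            "delta_log2_te": np.log2(te_dep / te_rich),
        }
    )
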