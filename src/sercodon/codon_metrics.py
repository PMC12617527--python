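"""Per-gene serine-codon composition metrics.

Serine is the only amino acid encoded by two disjoint codon boxes, UCN and
AGPy, which are decoded by different tRNA(Ser) isoacceptors.  Under serine
limitation ribosomes stall preferentially on one box or the other depending
on the state of the tRNA maturation machinery, so the *composition* of a
gene's Ser codons — how many fall in UC[C/U] vs AG[U/C] vs UC[G/A] — becomes
a predictor of how strongly its translation responds.  This module computes
those compositions over the longest CDS per gene: class counts, percentages
of total Ser codons, a codon-balance z-score contrasting AG[U/C] against
UC[C/U], and percentage-bin assignment.

All sequences are handled in the DNA alphabet (TCC/TCT, AGT/AGC, TCG/TCA);
output labels use the RNA-style class names UC[C/U], AG[U/C] and UC[G/A]
conventional in the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CdsError",
    "FrameError",
    "AlphabetError",
    "CodingSequence",
    "CodonCounts",
    "SerCodonProfile",
    "BinScheme",
    "FINE_BINS",
    "COARSE_BINS",
    "UCC_UCU",
    "AGU_AGC",
    "UCG_UCA",
    "SER_CODONS",
    "STOP_CODONS",
    "SENSE_CODONS",
    "enumerate_codons",
    "count_ser_classes",
    "ser_percentages",
    "codon_balance_zscore",
    "assign_bin",
    "select_longest_cds",
    "profile_table",
]


class CdsError(ValueError):
    """Invalid coding sequence."""


class FrameError(CdsError):
    """CDS length is not a multiple of 3."""


class AlphabetError(CdsError):
    """CDS contains characters outside A/C/G/T after normalization."""


#: Serine codon classes, DNA alphabet.
UCC_UCU = ("TCC", "TCT")
AGU_AGC = ("AGT", "AGC")
UCG_UCA = ("TCG", "TCA")
SER_CODONS = UCC_UCU + AGU_AGC + UCG_UCA
STOP_CODONS = ("TAA", "TAG", "TGA")

_BASES = "TCAG"
#: The 61 sense codons, alphabetical.
SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in STOP_CODONS
    )
)

_VALID = frozenset("ACGT")


def _normalize_sequence(sequence: str) -> str:
    # RNA input (U) is accepted and mapped onto the DNA alphabet.
    return sequence.upper().replace("U", "T")


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame nucleotide CDS (longest transcript of a gene).

    The sequence is normalized to uppercase DNA on construction; a frame or
    alphabet violation raises immediately so downstream codon arithmetic can
    assume a clean substrate.
    """

    gene_id: str
    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = _normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise CdsError(
                f"{self.gene_id}|{self.transcript_id}: empty sequence"
            )
        if len(seq) % 3 != 0:
            raise FrameError(
                f"{self.gene_id}|{self.transcript_id}: length {len(seq)} "
                "is not a multiple of 3"
            )
        bad = set(seq) - _VALID
        if bad:
            raise AlphabetError(
                f"{self.gene_id}|{self.transcript_id}: invalid characters "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3


@dataclass(frozen=True)
class CodonCounts:
    """Ser-codon class counts for one gene."""

    gene_id: str
    n_ucc_ucu: int
    n_agu_agc: int
    n_ucg_uca: int
    n_codons_total: int

    @property
    def n_ser_total(self) -> int:
        return self.n_ucc_ucu + self.n_agu_agc + self.n_ucg_uca

    def __post_init__(self) -> None:
        counts = (self.n_ucc_ucu, self.n_agu_agc, self.n_ucg_uca)
        if any(c < 0 for c in counts) or self.n_codons_total < 0:
            raise ValueError(f"{self.gene_id}: negative codon count")
        if self.n_ser_total > self.n_codons_total:
            raise ValueError(
                f"{self.gene_id}: Ser codon count exceeds total codons"
            )


@dataclass(frozen=True)
class SerCodonProfile:
    """Percent composition of a gene's Ser codons plus the balance z-score.

    ``defined`` is False for genes without any Ser codon; such genes carry
    NaN percentages and are excluded from binning and correlation rather
    than treated as 0%.
    """

    gene_id: str
    pct_ucc_ucu: float
    pct_agu_agc: float
    pct_ucg_uca: float
    z_agu_vs_ucc: float
    defined: bool


def enumerate_codons(cds: CodingSequence | str) -> list[str]:
    """Partition a CDS into its ordered frame-0 codons.

    Accepts either a :class:`CodingSequence` or a raw nucleotide string (the
    string is normalized and validated the same way).
    """
    if isinstance(cds, str):
        cds = CodingSequence(gene_id="", transcript_id="", sequence=cds)
    seq = cds.sequence
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def count_ser_classes(
    codons: Sequence[str], gene_id: str = ""
) -> CodonCounts:
    """Count Ser codons by class over an ordered codon list.

    All codons are counted, including the initiator and stop-adjacent
    positions; no positional exclusion is applied.
    """
    n_ucc = n_agu = n_ucg = 0
    for codon in codons:
        if codon in UCC_UCU:
            n_ucc += 1
        elif codon in AGU_AGC:
            n_agu += 1
        elif codon in UCG_UCA:
            n_ucg += 1
    return CodonCounts(
        gene_id=gene_id,
        n_ucc_ucu=n_ucc,
        n_agu_agc=n_agu,
        n_ucg_uca=n_ucg,
        n_codons_total=len(codons),
    )


def ser_percentages(counts: CodonCounts) -> SerCodonProfile:
    """Convert class counts to percentages of total Ser codons.

    pct_class = 100 * n_class / n_ser_total.  Genes with no Ser codon are
    returned with ``defined=False`` and NaN percentages.
    """
    total = counts.n_ser_total
    z = codon_balance_zscore(counts.n_agu_agc, counts.n_ucc_ucu)
    if total == 0:
        nan = float("nan")
        return SerCodonProfile(counts.gene_id, nan, nan, nan, z, False)
    return SerCodonProfile(
        gene_id=counts.gene_id,
        pct_ucc_ucu=100.0 * counts.n_ucc_ucu / total,
        pct_agu_agc=100.0 * counts.n_agu_agc / total,
        pct_ucg_uca=100.0 * counts.n_ucg_uca / total,
        z_agu_vs_ucc=z,
        defined=True,
    )


def codon_balance_zscore(n_a: int, n_b: int) -> float:
    """Binomial-proportion z contrasting two codon-class counts.

    z = (n_a - n_b) / sqrt(n_a + n_b), the standardized departure from a
    50:50 split under a p=0.5 null; 0 when both counts are zero.  With
    n_a = AG[U/C] and n_b = UC[C/U] counts, positive values mark genes whose
    Ser demand leans on the AGPy box.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("codon counts must be non-negative")
    n = n_a + n_b
    if n == 0:
        return 0.0
    return (n_a - n_b) / math.sqrt(n)


@dataclass(frozen=True)
class BinScheme:
    """Partition of [0, 100] into labelled percentage intervals.

    Intervals are half-open [lo, hi) except the last, which is closed at
    100, so every percentage maps to exactly one label.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(edges) - 1:
            raise ValueError("need exactly one label per interval")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if edges[0] != 0.0 or edges[-1] != 100.0:
            raise ValueError("edges must cover [0, 100]")

    def assign(self, pct: float) -> str:
        return assign_bin(pct, self)


#: Decile scheme with the integer-percent labels used in binned plots.
FINE_BINS = BinScheme(
    edges=(0, 11, 21, 31, 41, 51, 61, 71, 81, 91, 100),
    labels=(
        "0-10",
        "11-20",
        "21-30",
        "31-40",
        "41-50",
        "51-60",
        "61-70",
        "71-80",
        "81-90",
        "91-100",
    ),
)

#: Coarse grouping separating the informative 61-90% range from the
#: short-CDS-dominated 91-100% bin.
COARSE_BINS = BinScheme(
    edges=(0, 61, 91, 100),
    labels=("0-60", "61-90", "91-100"),
)


def assign_bin(pct: float, scheme: BinScheme = FINE_BINS) -> str:
    """Label of the scheme interval containing ``pct``."""
    if not (0.0 <= pct <= 100.0) or math.isnan(pct):
        raise ValueError(f"percentage {pct!r} outside [0, 100]")
    edges = scheme.edges
    for lo, hi, label in zip(edges, edges[1:], scheme.labels):
        if lo <= pct < hi:
            return label
    return scheme.labels[-1]  # pct == 100 falls in the closed last interval


def select_longest_cds(
    transcripts_by_gene: Mapping[str, Sequence[CodingSequence]],
) -> dict[str, CodingSequence]:
    """Pick one representative CDS per gene: maximal CDS length, ties broken
    by lexicographically smallest transcript_id."""
    out: dict[str, CodingSequence] = {}
    for gene, transcripts in transcripts_by_gene.items():
        if not transcripts:
            raise ValueError(f"gene {gene!r} has no transcripts")
        out[gene] = min(transcripts, key=lambda t: (-len(t), t.transcript_id))
    return out


def profile_table(
    cds_set: Iterable[CodingSequence],
    fine_scheme: BinScheme = FINE_BINS,
    coarse_scheme: BinScheme = COARSE_BINS,
) -> pd.DataFrame:
    """Full per-gene composition table over a set of representative CDSs.

    Columns: gene_id, transcript_id, cds_len, n_ser_total, class counts,
    class percentages, z_agu_vs_ucc and the fine/coarse UC[C/U]-percentage
    bins (NaN bins for genes without Ser codons).
    """
    rows = []
    for cds in cds_set:
        counts = count_ser_classes(enumerate_codons(cds), cds.gene_id)
        prof = ser_percentages(counts)
        rows.append(
            {
                "gene_id": cds.gene_id,
                "transcript_id": cds.transcript_id,
                "cds_len": len(cds),
                "n_codons_total": counts.n_codons_total,
                "n_ser_total": counts.n_ser_total,
                "n_ucc_ucu": counts.n_ucc_ucu,
                "n_agu_agc": counts.n_agu_agc,
                "n_ucg_uca": counts.n_ucg_uca,
                "pct_ucc_ucu": prof.pct_ucc_ucu,
                "pct_agu_agc": prof.pct_agu_agc,
                "pct_ucg_uca": prof.pct_ucg_uca,
                "z_agu_vs_ucc": prof.z_agu_vs_ucc,
                "defined": prof.defined,
                "bin_fine": assign_bin(prof.pct_ucc_ucu, fine_scheme)
                if prof.defined
                else None,
                "bin_coarse": assign_bin(prof.pct_ucc_ucu, coarse_scheme)
                if prof.defined
                else None,
            }
        )
    return pd.DataFrame(rows)
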