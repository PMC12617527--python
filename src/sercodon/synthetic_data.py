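"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of a :class:`SimulationConfig` (including
its seed) and returns both the dataset and the ground truth used to make
it, so every downstream module has a recovery target:

* ``gen_transcriptome`` — CDSs with controlled Ser-codon density and
  per-gene class composition;
* ``simulate_footprints`` — ribosome footprints whose A-site codon is drawn
  with codon-class-specific dwell weights per condition (the stalling the
  metagene measures);
* ``simulate_trna_seq`` — isodecoder read-class counts with known charging
  and pre-tRNA fractions;
* ``simulate_silac`` — newly-synthesized-protein log2 fold changes with a
  codon-composition-dependent effect plus Gaussian noise;
* ``simulate_reporter`` — per-cell lognormal GFP/mCherry fluorescence.

The A-site-weighted sampling is a deliberate simplification of elongation:
it produces exactly the at-codon coverage enrichment the metagene measures
without simulating ribosome transit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .codon_metrics import (
    AGU_AGC,
    CodingSequence,
    SENSE_CODONS,
    SER_CODONS,
    STOP_CODONS,
    UCC_UCU,
    UCG_UCA,
)

__all__ = [
    "CLASS_NAMES",
    "ConfigError",
    "SimulationConfig",
    "TrnaTruth",
    "gen_transcriptome",
    "simulate_footprints",
    "simulate_trna_seq",
    "simulate_silac",
    "simulate_reporter",
]

#: Ser codon class keys used throughout the config.
CLASS_NAMES = ("ucc_ucu", "agu_agc", "ucg_uca")

_CLASS_CODONS = {
    "ucc_ucu": UCC_UCU,
    "agu_agc": AGU_AGC,
    "ucg_uca": UCG_UCA,
}

_NON_SER_SENSE = tuple(c for c in SENSE_CODONS if c not in SER_CODONS)


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class TrnaTruth:
    """Ground truth for one isodecoder in one condition."""

    level: float  # expected relative abundance (reads at unit depth)
    charging_fraction: float  # fraction of mature molecules charged
    pre_fraction: float  # fraction of reads from unprocessed precursors

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ConfigError("tRNA level must be non-negative")
        for name in ("charging_fraction", "pre_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} {v!r} outside [0, 1]")


def _default_dwell() -> dict[str, dict[str, float]]:
    # Parental-cell regime: serine starvation slows UC[C/U] decoding
    # four-fold; rich medium is uniform.
    return {
        "rich": {"ucc_ucu": 1.0, "agu_agc": 1.0, "ucg_uca": 1.0, "other": 1.0},
        "deprived": {
            "ucc_ucu": 4.0,
            "agu_agc": 1.0,
            "ucg_uca": 1.0,
            "other": 1.0,
        },
    }


def _default_trna_truth() -> dict[str, dict[str, TrnaTruth]]:
    # Ser isodecoder panel: near-complete charging in rich medium, reduced
    # charging on starvation; two isodecoders each for the AGA and GCU
    # anticodons mirroring the multi-copy Ser tRNA gene families.
    rich = {
        "Ser-AGA-1": TrnaTruth(1.2, 0.90, 0.10),
        "Ser-AGA-2": TrnaTruth(0.8, 0.90, 0.10),
        "Ser-CGA-1": TrnaTruth(0.6, 0.88, 0.10),
        "Ser-UGA-1": TrnaTruth(0.9, 0.88, 0.10),
        "Ser-GCU-1": TrnaTruth(1.0, 0.92, 0.10),
        "Ser-GCU-2": TrnaTruth(0.7, 0.92, 0.10),
    }
    deprived = {
        iso: replace(t, charging_fraction=0.70) for iso, t in rich.items()
    }
    return {"rich": rich, "deprived": deprived}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study conditions as
    defaults.

    ``class_mix`` is the population-average composition of Ser codons over
    (UC[C/U], AG[U/C], UC[G/A]); per-gene compositions are drawn from a
    Dirichlet centred on it with concentration ``class_mix_concentration``,
    emulating gene-to-gene codon-usage heterogeneity (None = identical mix
    for every gene).  Dwell multipliers are relative A-site dwell times per
    (condition, codon class); ``reads_per_transcript`` footprints of
    ``read_length`` nt are placed with the A site ``a_site_offset`` nt from
    the footprint 5' end.
    """

    seed: int = 0
    n_genes: int = 200
    cds_length_range: tuple[int, int] = (150, 450)  # codons, incl. start/stop
    ser_density: float = 0.10
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    class_mix_concentration: float | None = 3.0
    dwell_multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_dwell
    )
    reads_per_transcript: int = 2000
    read_length: int = 30
    a_site_offset: int = 15
    trna_truth: Mapping[str, Mapping[str, TrnaTruth]] = field(
        default_factory=_default_trna_truth
    )
    trna_depth: int = 1000
    trna_overdispersion: float | None = None  # NB size param; None = Poisson
    silac_beta: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CLASS_NAMES}
    )
    silac_sigma: float = 0.3
    reporter_cells: int = 2000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.cds_length_range
        if lo < 3 or hi < lo:
            raise ConfigError("cds_length_range must satisfy 3 <= lo <= hi")
        if not 0.0 <= self.ser_density <= 1.0:
            raise ConfigError("ser_density must lie in [0, 1]")
        if self.ser_density > 0 and lo < 3:
            raise ConfigError("CDS too short to hold a Ser codon")
        mix = tuple(float(m) for m in self.class_mix)
        if len(mix) != 3 or any(m < 0 for m in mix) or abs(sum(mix) - 1) > 1e-9:
            raise ConfigError("class_mix must be a 3-simplex")
        object.__setattr__(self, "class_mix", mix)
        for cond, table in self.dwell_multipliers.items():
            for cls, mult in table.items():
                if mult <= 0:
                    raise ConfigError(
                        f"dwell multiplier ({cond}, {cls}) must be > 0"
                    )
        if self.read_length < 1 or not 0 <= self.a_site_offset < self.read_length:
            raise ConfigError(
                "need 0 <= a_site_offset < read_length and read_length >= 1"
            )
        if self.silac_sigma < 0:
            raise ConfigError("silac_sigma must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for one named stream of the simulation."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(stream + 1)[stream]
        )


_STREAM_TRANSCRIPTOME = 0
_STREAM_FOOTPRINTS = 1
_STREAM_TRNA = 2
_STREAM_SILAC = 3
_STREAM_REPORTER = 4


def gen_transcriptome(
    cfg: SimulationConfig,
) -> tuple[dict[str, CodingSequence], pd.DataFrame]:
    """Generate one CDS per gene plus a truth table of class compositions.

    Each CDS starts with ATG, ends with a single stop codon, and draws each
    interior codon as Ser with probability ``ser_density``; Ser codons pick
    a class from the gene's class mix and a codon uniformly within the
    class, non-Ser codons are uniform over the 55 non-Ser sense codons.
    The truth table records realized per-gene counts and percentages.
    """
    rng = cfg.rng(_STREAM_TRANSCRIPTOME)
    lo, hi = cfg.cds_length_range
    mix = np.asarray(cfg.class_mix)
    genes: dict[str, CodingSequence] = {}
    rows = []
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        gene_id = f"G{i + 1:0{width}d}"
        n_codons = int(rng.integers(lo, hi + 1))
        n_interior = n_codons - 2
        if cfg.class_mix_concentration is not None:
            alpha = mix * cfg.class_mix_concentration
            # Dirichlet needs strictly positive alpha; zero-weight classes
            # stay at exactly zero.
            pos = alpha > 0
            gene_mix = np.zeros(3)
            if pos.sum() == 1:
                gene_mix[pos] = 1.0
            else:
                gene_mix[pos] = rng.dirichlet(alpha[pos])
        else:
            gene_mix = mix
        is_ser = rng.random(n_interior) < cfg.ser_density
        codons = np.empty(n_interior, dtype=object)
        n_ser = int(is_ser.sum())
        if n_ser:
            classes = rng.choice(3, size=n_ser, p=gene_mix)
            picks = rng.integers(0, 2, size=n_ser)
            ser_codons = [
                _CLASS_CODONS[CLASS_NAMES[c]][p]
                for c, p in zip(classes, picks)
            ]
            codons[is_ser] = ser_codons
        if n_interior - n_ser:
            codons[~is_ser] = rng.choice(
                _NON_SER_SENSE, size=n_interior - n_ser
            )
        stop = STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))]
        seq = "ATG" + "".join(codons.tolist()) + stop
        cds = CodingSequence(gene_id, f"{gene_id}.t1", seq)
        genes[gene_id] = cds
        n_by_class = {
            cls: sum(c in _CLASS_CODONS[cls] for c in codons.tolist())
            for cls in CLASS_NAMES
        }
        total = sum(n_by_class.values())
        rows.append(
            {
                "gene_id": gene_id,
                "transcript_id": cds.transcript_id,
                "n_codons": n_codons,
                "n_ser_total": total,
                **{f"n_{cls}": n_by_class[cls] for cls in CLASS_NAMES},
                **{
                    f"pct_{cls}": 100.0 * n_by_class[cls] / total
                    if total
                    else np.nan
                    for cls in CLASS_NAMES
                },
            }
        )
    return genes, pd.DataFrame(rows)


def _codon_class_array(sequence: str) -> np.ndarray:
    """Class index per codon: 0/1/2 for the Ser classes, 3 otherwise."""
    lookup = {c: i for i, cls in enumerate(CLASS_NAMES) for c in _CLASS_CODONS[cls]}
    return np.array(
        [
            lookup.get(sequence[i : i + 3], 3)
            for i in range(0, len(sequence), 3)
        ],
        dtype=int,
    )


def simulate_footprints(
    cds_set: Mapping[str, CodingSequence],
    cfg: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Footprint alignments per condition with class-weighted A-site draws.

    For each transcript and condition, ``reads_per_transcript`` A-site
    codon indices are drawn with probability proportional to the dwell
    multiplier of the codon's class; each footprint is placed with its A
    site ``a_site_offset`` nt from the 5' end; placements that would
    overhang a CDS end are shifted inward so every footprint keeps its full
    length (and still covers its A-site codon).  Alignments are keyed by
    transcript_id and returned as TSV-ready DataFrames (transcript_id,
    start, end).
    """
    shortest = min(len(c) for c in cds_set.values())
    if cfg.read_length > shortest:
        raise ConfigError(
            f"read_length {cfg.read_length} exceeds shortest CDS ({shortest} nt)"
        )
    rng = cfg.rng(_STREAM_FOOTPRINTS)
    out: dict[str, pd.DataFrame] = {}
    class_arrays = {
        tid: _codon_class_array(c.sequence) for tid, c in cds_set.items()
    }
    for condition in sorted(cfg.dwell_multipliers):
        dwell = cfg.dwell_multipliers[condition]
        weights_by_class = np.array(
            [dwell.get(cls, 1.0) for cls in CLASS_NAMES] + [dwell.get("other", 1.0)]
        )
        tids, starts, ends = [], [], []
        for tid in sorted(cds_set):
            classes = class_arrays[tid]
            length = len(cds_set[tid])
            w = weights_by_class[classes]
            p = w / w.sum()
            a_codons = rng.choice(len(classes), size=cfg.reads_per_transcript, p=p)
            a_nt = 3 * a_codons + 1  # middle base of the A-site codon
            start = np.clip(
                a_nt - cfg.a_site_offset, 0, length - cfg.read_length
            )
            end = start + cfg.read_length
            tids.extend(
                [cds_set[tid].transcript_id] * cfg.reads_per_transcript
            )
            starts.append(start)
            ends.append(end)
        out[condition] = pd.DataFrame(
            {
                "transcript_id": tids,
                "start": np.concatenate(starts),
                "end": np.concatenate(ends),
            }
        )
    return out


def simulate_trna_seq(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isodecoder read-class counts per condition plus the truth table.

    Reads per isodecoder are Poisson around level x depth (negative
    binomial when ``trna_overdispersion`` is set), split multinomially into
    pre / charged-mature (CCA) / uncharged-mature (CC) classes by the truth
    fractions.  ``library_size`` is the per-condition total.
    """
    rng = cfg.rng(_STREAM_TRNA)
    count_rows = []
    truth_rows = []
    for condition in sorted(cfg.trna_truth):
        cond_rows = []
        for iso in sorted(cfg.trna_truth[condition]):
            truth = cfg.trna_truth[condition][iso]
            expected = truth.level * cfg.trna_depth
            if cfg.trna_overdispersion is not None:
                size = cfg.trna_overdispersion
                n_reads = (
                    int(rng.negative_binomial(size, size / (size + expected)))
                    if expected > 0
                    else 0
                )
            else:
                n_reads = int(rng.poisson(expected))
            p_pre = truth.pre_fraction
            p_cca = (1 - p_pre) * truth.charging_fraction
            p_cc = (1 - p_pre) * (1 - truth.charging_fraction)
            n_pre, n_cca, n_cc = rng.multinomial(n_reads, [p_pre, p_cca, p_cc])
            cond_rows.append(
                {
                    "isodecoder_id": iso,
                    "condition": condition,
                    "n_cca": int(n_cca),
                    "n_cc": int(n_cc),
                    "n_pre": int(n_pre),
                }
            )
            truth_rows.append(
                {
                    "isodecoder_id": iso,
                    "condition": condition,
                    "level": truth.level,
                    "charging_fraction": truth.charging_fraction,
                    "pre_fraction": truth.pre_fraction,
                }
            )
        library_size = sum(
            r["n_cca"] + r["n_cc"] + r["n_pre"] for r in cond_rows
        )
        for r in cond_rows:
            r["library_size"] = library_size
        count_rows.extend(cond_rows)
    return pd.DataFrame(count_rows), pd.DataFrame(truth_rows)


def simulate_silac(
    truth_profiles: pd.DataFrame,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Newly-synthesized-protein fold changes coupled to codon composition.

    log2_fc(g) = sum_class beta_class * pct_class(g) / 100 + Normal(0,
    sigma^2).  Heavy intensities are emitted for both conditions (lognormal
    baseline; deprived = baseline * 2**log2_fc) so the table round-trips
    through :func:`sercodon.proteome_link.silac_fold_change`.  Genes with
    undefined profiles (no Ser codons) are omitted.
    """
    rng = cfg.rng(_STREAM_SILAC)
    defined = truth_profiles.dropna(subset=[f"pct_{c}" for c in CLASS_NAMES])
    n = len(defined)
    effect = np.zeros(n)
    for cls in CLASS_NAMES:
        beta = float(cfg.silac_beta.get(cls, 0.0))
        effect += beta * defined[f"pct_{cls}"].to_numpy() / 100.0
    noise = (
        rng.normal(0.0, cfg.silac_sigma, size=n)
        if cfg.silac_sigma > 0
        else np.zeros(n)
    )
    log2_fc = effect + noise
    baseline = rng.lognormal(mean=20.0, sigma=1.0, size=n)
    return pd.DataFrame(
        {
            "protein_id": defined["gene_id"].to_numpy(),
            "heavy_rich": baseline,
            "heavy_deprived": baseline * np.exp2(log2_fc),
            "log2_fc": log2_fc,
            "true_effect": effect,
        }
    )


def simulate_reporter(
    cfg: SimulationConfig,
    true_ratio: float = 0.5,
    background: float = 0.2,
) -> pd.DataFrame:
    """Per-cell lognormal GFP/mCherry draws for rich/deprived/chx samples.

    Conditions are constructed so that the background-corrected -SG/+SG
    ratio of the expected values equals ``true_ratio``: rich GFP centres on
    1 + background, deprived on true_ratio + background, CHX on background.
    """
    rng = cfg.rng(_STREAM_REPORTER)
    levels = {
        "rich": 1.0 + background,
        "deprived": true_ratio + background,
        "chx": background,
    }
    rows = []
    for condition, level in levels.items():
        gfp = level * rng.lognormal(0.0, 0.25, size=cfg.reporter_cells)
        mch = rng.lognormal(0.0, 0.25, size=cfg.reporter_cells)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": f"sim_{condition}",
                    "condition": condition,
                    "gfp": gfp,
                    "mcherry": mch,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
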