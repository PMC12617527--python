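"""Coverage, metagene, pause-score and naive differential-TE behavior."""

import numpy as np
import pandas as pd
import pytest

from sercodon import (
    CodingSequence,
    SimulationConfig,
    gen_transcriptome,
    simulate_footprints,
)
from sercodon.ribo_occupancy import (
    CoverageTrack,
    build_tracks,
    coverage_from_alignments,
    delta_density,
    differential_te,
    metagene_all_codons,
    metagene_around_codon,
    normalize_track,
    pause_rank_table,
)


def brute_force_metagene(tracks, cds_set, codon, half_window,
                         edge_exclusion=20):
    """Independent oracle: explicit double loop over transcripts and
    occurrences, per-position mean over in-bounds contributions."""
    width = 2 * half_window + 3
    total = np.zeros(width)
    count = np.zeros(width, dtype=int)
    for tid, track in tracks.items():
        seq = cds_set[tid].sequence
        n_codons = len(seq) // 3
        for i in range(n_codons):
            if i < edge_exclusion or i >= n_codons - edge_exclusion:
                continue
            if seq[3 * i : 3 * i + 3] != codon:
                continue
            c = 3 * i
            for k, rel in enumerate(range(-half_window, half_window + 3)):
                pos = c + rel
                if 0 <= pos < len(seq):
                    total[k] += track.values[pos]
                    count[k] += 1
    with np.errstate(invalid="ignore"):
        density = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return density, count


class TestCoverage:
    def test_single_read(self):
        t = coverage_from_alignments([(0, 30)], 100)
        assert t.values[:30].tolist() == [1.0] * 30
        assert t.values[30:].sum() == 0

    def test_no_reads(self):
        assert coverage_from_alignments([], 50).values.sum() == 0

    def test_overlap_adds(self):
        t = coverage_from_alignments([(0, 30), (15, 45)], 100)
        assert np.all(t.values[15:30] == 2)
        assert np.all(t.values[0:15] == 1)
        assert np.all(t.values[30:45] == 1)

    def test_out_of_bounds_named(self):
        with pytest.raises(ValueError, match=r"\[90, 120\)"):
            coverage_from_alignments([(90, 120)], 100, "tx1")

    def test_footprint_length_gate(self):
        with pytest.raises(ValueError, match="length 10"):
            coverage_from_alignments([(0, 10)], 100, footprint_range=(26, 34))
        coverage_from_alignments([(0, 10)], 100, footprint_range=None)


class TestNormalize:
    def test_constant_becomes_one(self):
        t = CoverageTrack("t", np.full(10, 5.0))
        assert np.allclose(normalize_track(t).values, 1.0)

    def test_mean_one_unchanged(self):
        t = CoverageTrack("t", np.array([0.0, 2.0]))
        assert normalize_track(t, min_mean=0.0).values.tolist() == [0.0, 2.0]

    def test_all_zero_filtered(self):
        assert normalize_track(CoverageTrack("t", np.zeros(10))) is None

    def test_low_mean_filtered(self):
        assert normalize_track(CoverageTrack("t", np.full(10, 0.1))) is None

    def test_double_normalization_rejected(self):
        t = normalize_track(CoverageTrack("t", np.full(10, 5.0)))
        with pytest.raises(ValueError, match="already normalized"):
            normalize_track(t)

    def test_normalized_mean_is_one(self, rng):
        t = CoverageTrack("t", rng.poisson(3.0, size=200).astype(float))
        assert normalize_track(t).values.mean() == pytest.approx(1.0)


class TestMetagene:
    def test_uniform_tracks_give_unit_density(self, toy_cds):
        tracks = {
            toy_cds.transcript_id: CoverageTrack(
                toy_cds.transcript_id, np.ones(len(toy_cds)), normalized=True
            )
        }
        cds = {toy_cds.transcript_id: toy_cds}
        # GCT occurs throughout the interior
        res = metagene_around_codon(tracks, cds, "GCT", half_window=10,
                                    edge_exclusion_codons=2)
        defined = res.n_occurrences > 0
        assert defined.any()
        assert np.allclose(res.density[defined], 1.0)

    def test_single_occurrence_equals_direct_slice(self, rng):
        # one transcript, one eligible TCC occurrence: the window is the
        # track re-indexed to that occurrence
        interior = ["GGC"] * 28
        interior[14] = "TCC"
        cds = CodingSequence("g", "t", "ATG" + "".join(interior) + "TGA")
        values = rng.random(len(cds)) + 0.5
        values /= values.mean()
        tracks = {"t": CoverageTrack("t", values, normalized=True)}
        W = 12
        res = metagene_around_codon(tracks, {"t": cds}, "TCC", half_window=W,
                                    edge_exclusion_codons=5)
        c = 3 * 15  # occurrence is codon index 15 (after ATG)
        expected = values[c - W : c + W + 3]
        assert np.allclose(res.density, expected)
        assert np.all(res.n_occurrences == 1)

    def test_matches_bruteforce_double_loop(self, small_transcriptome):
        cfg, cds_by_gene, _ = small_transcriptome
        cds = {c.transcript_id: c for c in cds_by_gene.values()}
        aln = simulate_footprints(cds, cfg)["deprived"]
        tracks = build_tracks(aln, cds, min_footprints=1, min_mean=0.0)
        for codon in ("TCC", "AGT", "GCT"):
            res = metagene_around_codon(tracks, cds, codon, half_window=40,
                                        edge_exclusion_codons=3)
            density, count = brute_force_metagene(
                tracks, cds, codon, 40, edge_exclusion=3
            )
            assert np.array_equal(res.n_occurrences, count)
            both = count > 0
            assert np.array_equal(res.density[both], density[both])
            assert np.all(np.isnan(res.density[~both]))

    def test_invalid_codon_rejected(self, toy_cds):
        with pytest.raises(ValueError, match="invalid codon"):
            metagene_around_codon({}, {}, "NNN")

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError, match="half_window"):
            metagene_around_codon({}, {}, "TCC", half_window=0)

    def test_absent_codon_gives_empty_result(self, toy_cds):
        tracks = {
            toy_cds.transcript_id: CoverageTrack(
                toy_cds.transcript_id, np.ones(len(toy_cds)), normalized=True
            )
        }
        res = metagene_around_codon(
            tracks, {toy_cds.transcript_id: toy_cds}, "TGG", half_window=5
        )
        assert res.n_occurrences.sum() == 0
        assert np.all(np.isnan(res.density))

    def test_unnormalized_track_rejected(self, toy_cds):
        tracks = {
            toy_cds.transcript_id: CoverageTrack(
                toy_cds.transcript_id, np.ones(len(toy_cds)), normalized=False
            )
        }
        with pytest.raises(ValueError, match="not normalized"):
            metagene_around_codon(
                tracks, {toy_cds.transcript_id: toy_cds}, "GCT"
            )


class TestDeltaDensity:
    def _uniform_result(self, codon="TCC", shift=0.0):
        from sercodon.ribo_occupancy import MetageneResult

        positions = np.arange(-20, 23)
        return MetageneResult(
            codon=codon,
            positions=positions,
            density=np.ones(len(positions)) + shift,
            n_occurrences=np.full(len(positions), 5),
        )

    def test_identical_inputs_zero(self):
        d = delta_density(self._uniform_result(), self._uniform_result())
        assert np.allclose(d.delta, 0.0)
        assert d.pause_score == 0.0

    def test_constant_offset(self):
        d = delta_density(self._uniform_result(shift=0.5),
                          self._uniform_result())
        assert np.allclose(d.delta, 0.5)
        assert d.pause_score == pytest.approx(0.5)

    def test_antisymmetry(self, rng):
        from sercodon.ribo_occupancy import MetageneResult

        positions = np.arange(-20, 23)
        a = MetageneResult("TCC", positions, rng.random(43),
                           np.full(43, 3))
        b = MetageneResult("TCC", positions, rng.random(43),
                           np.full(43, 3))
        dab = delta_density(a, b)
        dba = delta_density(b, a)
        assert np.allclose(dab.delta, -dba.delta)
        assert dab.pause_score == pytest.approx(-dba.pause_score)

    def test_codon_mismatch_rejected(self):
        with pytest.raises(ValueError, match="codon mismatch"):
            delta_density(self._uniform_result("TCC"),
                          self._uniform_result("AGT"))


class TestPauseRank:
    def test_descending_order(self):
        from sercodon.ribo_occupancy import DeltaDensity

        pos = np.arange(-1, 2)
        deltas = [
            DeltaDensity("AGT", pos, np.zeros(3), 0.1),
            DeltaDensity("TCC", pos, np.zeros(3), 0.4),
        ]
        assert pause_rank_table(deltas)["codon"].tolist() == ["TCC", "AGT"]

    def test_ties_alphabetical(self):
        from sercodon.ribo_occupancy import DeltaDensity

        pos = np.arange(-1, 2)
        deltas = [
            DeltaDensity(c, pos, np.zeros(3), 0.0)
            for c in ("TGG", "AAA", "CCC")
        ]
        assert pause_rank_table(deltas)["codon"].tolist() == [
            "AAA", "CCC", "TGG",
        ]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pause_rank_table([])


class TestStallSimulation:
    def test_uniform_dwell_density_flattens_with_depth(self):
        """Max |density-1| at interior positions shrinks as depth grows."""
        dwell = {
            "rich": {"ucc_ucu": 1.0, "agu_agc": 1.0, "ucg_uca": 1.0,
                     "other": 1.0},
        }
        devs = []
        for depth in (500, 8000):
            cfg = SimulationConfig(
                seed=7, n_genes=20, cds_length_range=(200, 200),
                reads_per_transcript=depth, dwell_multipliers=dwell,
            )
            cds_by_gene, _ = gen_transcriptome(cfg)
            cds = {c.transcript_id: c for c in cds_by_gene.values()}
            aln = simulate_footprints(cds, cfg)["rich"]
            tracks = build_tracks(aln, cds, min_footprints=1, min_mean=0.0)
            interior = slice(60, 540)  # away from ramp at CDS ends
            dev = max(
                np.abs(t.values[interior] - 1.0).max()
                for t in tracks.values()
            )
            devs.append(dev)
        assert devs[1] < devs[0]

    def test_dwell_multiplier_recovered_at_codon(self):
        """In A-site-collapsed coverage, the deprived/rich at-codon density
        ratio at the stalled class is ~k times the background ratio
        (within 15%)."""
        k = 4.0
        cfg = SimulationConfig(seed=11, n_genes=60,
                               reads_per_transcript=2000)
        cds_by_gene, _ = gen_transcriptome(cfg)
        cds = {c.transcript_id: c for c in cds_by_gene.values()}
        aln = simulate_footprints(cds, cfg)
        tracks = {
            cond: build_tracks(
                aln[cond], cds, min_footprints=1, min_mean=0.0, mode="asite"
            )
            for cond in aln
        }
        ratios = {}
        for codon in ("TCC", "GCT"):
            at = {}
            for cond in ("deprived", "rich"):
                res = metagene_around_codon(
                    tracks[cond], cds, codon, half_window=1
                )
                at[cond] = np.nanmean(res.density[1:4].astype(float))
            ratios[codon] = at["deprived"] / at["rich"]
        assert ratios["TCC"] / ratios["GCT"] == pytest.approx(k, rel=0.15)


class TestDifferentialTe:
    def test_identical_inputs_zero(self):
        counts = {f"g{i}": float(i + 1) for i in range(10)}
        te = differential_te(counts, counts, counts, counts)
        assert np.allclose(te["delta_log2_te"], 0.0)

    def test_single_gene_doubled_rpf_matches_hand_formula(self):
        # spreadsheet-style oracle on a 100-gene table
        genes = [f"g{i:03d}" for i in range(100)]
        rpf_rich = {g: 100.0 for g in genes}
        rpf_dep = dict(rpf_rich)
        rpf_dep["g000"] = 200.0
        rna = {g: 50.0 for g in genes}
        pc = 0.5
        te = differential_te(rpf_rich, rpf_dep, rna, rna, pseudocount=pc)
        total_rich = 100 * (100 + pc)
        total_dep = 99 * (100 + pc) + (200 + pc)
        expected = np.log2(
            ((200 + pc) / total_dep) / ((100 + pc) / total_rich)
        )  # rna terms cancel
        row = te.set_index("gene_id").loc["g000"]
        assert row["delta_log2_te"] == pytest.approx(expected)

    def test_zero_counts_finite_with_pseudocount(self):
        zero = {"a": 0.0, "b": 0.0}
        some = {"a": 10.0, "b": 0.0}
        te = differential_te(zero, some, zero, zero, pseudocount=0.5)
        assert np.isfinite(te["delta_log2_te"]).all()

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError):
            differential_te({"a": 1}, {"b": 1}, {"a": 1}, {"a": 1})
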