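import warnings

import numpy as np
import pytest

from conftest import brute_force_snf, random_prediction_table, random_protein

from epitopemap.scoring import (DEFAULT_STRATA, PredictionRow, PredictionTable,
                                ScoringConfig, accumulate_residue_scores,
                                assign_ranks, assign_stratum, assign_strata,
                                load_predictions, percent_of_max, render_heatmap,
                                score_protein, select_top_k, track_to_frame,
                                weight_of_rank)
from epitopemap.sequence_io import ProteinRecord


def make_table(protein, rows):
    return PredictionTable(protein_id=protein.id, rows=rows)


class TestLoadPredictions:
    def _write(self, tmp_path, body, header="algorithm\tallele\tstart\tpeptide\tmetric"):
        path = tmp_path / "pred.tsv"
        path.write_text(header + "\n" + body)
        return path

    def test_well_formed(self, tmp_path, small_protein):
        body = (
            "alg1\tA\t1\tACDEF\t0.5\n"
            "alg1\tA\t3\tDEFGH\t0.2\n"
            "alg1\tA\t5\tFGHIK\t0.9\n"
        )
        table = load_predictions(self._write(tmp_path, body), small_protein)
        assert len(table.rows) == 3
        by_start = {r.start: r.rank for r in table.rows}
        assert by_start == {3: 1, 1: 2, 5: 3}  # ranked by ascending metric

    def test_peptide_mismatch_names_row(self, tmp_path, small_protein):
        body = "alg1\tA\t1\tACDEX\t0.5\n"
        with pytest.raises(ValueError, match="row 1"):
            load_predictions(self._write(tmp_path, body), small_protein)

    def test_duplicate_row_errors(self, tmp_path, small_protein):
        body = "alg1\tA\t1\tACDEF\t0.5\nalg1\tA\t1\tACDEF\t0.7\n"
        with pytest.raises(ValueError, match="duplicate"):
            load_predictions(self._write(tmp_path, body), small_protein)

    def test_metric_tie_broken_by_ascending_start(self, tmp_path):
        protein = ProteinRecord(id="p", sequence="A" * 20)
        body = "alg1\tA\t10\tAAAAA\t0.5\nalg1\tA\t4\tAAAAA\t0.5\n"
        table = load_predictions(self._write(tmp_path, body), protein)
        assert {r.start: r.rank for r in table.rows} == {4: 1, 10: 2}

    def test_comments_ignored_and_explicit_ranks_kept(self, tmp_path, small_protein):
        path = tmp_path / "pred.tsv"
        path.write_text(
            "# comment\nalgorithm\tallele\tstart\tpeptide\tmetric\trank\n"
            "alg1\tA\t1\tACDEF\t0.9\t2\nalg1\tA\t3\tDEFGH\t0.1\t1\n"
        )
        table = load_predictions(path, small_protein)
        assert {r.start: r.rank for r in table.rows} == {1: 2, 3: 1}


class TestSelectTopK:
    def test_keeps_top_k_per_group(self):
        protein = ProteinRecord(id="p", sequence="A" * 40)
        rows = [PredictionRow("alg1", "A", s, "AAAAA", float(s)) for s in range(1, 26)]
        table = PredictionTable("p", assign_ranks(rows))
        kept = select_top_k(table, ScoringConfig(top_k=20))
        assert len(kept.rows) == 20
        assert {r.rank for r in kept.rows} == set(range(1, 21))

    def test_underfull_group_kept_with_warning(self):
        rows = assign_ranks(
            [PredictionRow("alg1", "A", s, "AAAAA", float(s)) for s in range(1, 6)])
        with pytest.warns(UserWarning, match="only 5 rows"):
            kept = select_top_k(PredictionTable("p", rows), ScoringConfig(top_k=20))
        assert len(kept.rows) == 5

    def test_top_1_boundary(self):
        rows = assign_ranks(
            [PredictionRow("alg1", "A", s, "AAAAA", float(s)) for s in range(1, 6)]
            + [PredictionRow("alg2", "B", s, "AAAAA", float(-s)) for s in range(1, 6)])
        kept = select_top_k(PredictionTable("p", rows), ScoringConfig(top_k=1))
        assert sorted((r.algorithm, r.start) for r in kept.rows) == \
            [("alg1", 1), ("alg2", 5)]


class TestWeightOfRank:
    @pytest.mark.parametrize("scheme", ["linear", "reciprocal", "uniform"])
    def test_rank_one_is_unity(self, scheme):
        assert weight_of_rank(1, ScoringConfig(weight_scheme=scheme)) == 1.0

    def test_linear_rank_twenty(self):
        assert weight_of_rank(20, ScoringConfig(top_k=20)) == pytest.approx(0.05)

    def test_reciprocal(self):
        assert weight_of_rank(4, ScoringConfig(weight_scheme="reciprocal")) == 0.25

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError):
            weight_of_rank(21, ScoringConfig(top_k=20))
        with pytest.raises(ValueError):
            weight_of_rank(0, ScoringConfig())


class TestAccumulate:
    def test_single_peptide_hand_computed(self):
        protein = ProteinRecord(id="p", sequence="ACDEFGHIKL")
        rows = [PredictionRow("alg1", "A", 3, "DEFG", 0.1, rank=1)]
        track = accumulate_residue_scores(
            PredictionTable("p", rows), protein, ScoringConfig())
        assert track.S.tolist() == [0, 0, 1, 1, 1, 1, 0, 0, 0, 0]
        assert track.N.tolist() == [0, 0, 1, 1, 1, 1, 0, 0, 0, 0]
        assert track.F.tolist() == [0, 0, 1, 1, 1, 1, 0, 0, 0, 0]

    def test_two_alleles_two_algorithms_multiply(self):
        protein = ProteinRecord(id="p", sequence="ACDEFGHIKL")
        rows = [
            PredictionRow("alg1", "A", 3, "DEFG", 0.1, rank=1),
            PredictionRow("alg2", "B", 3, "DEFG", 0.2, rank=1),
        ]
        track = accumulate_residue_scores(
            PredictionTable("p", rows), protein, ScoringConfig())
        assert track.S[2] == 2
        assert track.N[2] == 2
        assert track.F[2] == 4

    def test_same_allele_across_algorithms_counts_once_in_union_mode(self):
        protein = ProteinRecord(id="p", sequence="ACDEFGHIKL")
        rows = [
            PredictionRow("alg1", "A", 3, "DEFG", 0.1, rank=1),
            PredictionRow("alg2", "A", 3, "DEFG", 0.2, rank=1),
        ]
        union = accumulate_residue_scores(
            PredictionTable("p", rows), protein, ScoringConfig())
        pairs = accumulate_residue_scores(
            PredictionTable("p", rows), protein,
            ScoringConfig(n_mode="allele_algorithm_pairs"))
        assert union.N[2] == 1 and pairs.N[2] == 2

    def test_empty_selection_gives_zero_track_with_warning(self, small_protein):
        with pytest.warns(UserWarning, match="zeros"):
            track = accumulate_residue_scores(
                PredictionTable("toy", []), small_protein, ScoringConfig())
        assert not track.S.any() and not track.N.any() and not track.F.any()

    def test_oracle_equivalence_random_instances(self):
        """Brute-force per-residue loop reproduces S, N and F exactly."""
        rng = np.random.default_rng(20230917)
        for _ in range(60):
            protein = random_protein(rng, int(rng.integers(15, 61)))
            table = random_prediction_table(rng, protein)
            config = ScoringConfig(
                top_k=int(rng.integers(1, 9)),
                weight_scheme=str(rng.choice(["linear", "reciprocal", "uniform"])),
                n_mode=str(rng.choice(["allele_union", "allele_algorithm_pairs"])),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected = select_top_k(table, config)
            track = accumulate_residue_scores(selected, protein, config)
            S, N, F = brute_force_snf(selected, protein, config)
            np.testing.assert_allclose(track.S, S, rtol=0, atol=1e-12)
            assert track.N.tolist() == N
            np.testing.assert_allclose(track.F, F, rtol=0, atol=1e-12)
            # F is zero exactly on uncovered residues
            assert all((f == 0) == (n == 0) for f, n in zip(track.F, track.N))

    def test_monotonicity_adding_a_peptide(self):
        """One more selected peptide never decreases any S, N or F."""
        rng = np.random.default_rng(7)
        protein = random_protein(rng, 40)
        config = ScoringConfig(top_k=8)
        table = random_prediction_table(rng, protein, max_rows_per_group=6)
        with pytest.warns(UserWarning):
            selected = select_top_k(table, config)
        base = accumulate_residue_scores(selected, protein, config)
        extra = PredictionRow("alg9", "alleleZ", protein.anchor + 5,
                              protein.sequence[5:14], -9.9, rank=1)
        grown = accumulate_residue_scores(
            PredictionTable("p", selected.rows + [extra]), protein, config)
        assert (grown.S >= base.S).all()
        assert (grown.N >= base.N).all()
        assert (grown.F >= base.F).all()


class TestPercentAndStrata:
    def test_percent_proportional(self):
        track = score_track_from_F([0.0, 2.0, 4.0])
        percent_of_max(track)
        assert track.pct.tolist() == [0, 50, 100]

    def test_all_zero(self):
        track = score_track_from_F([0.0, 0.0])
        percent_of_max(track)
        assert track.pct.tolist() == [0, 0]

    def test_single_nonzero_normalises_to_100(self):
        track = score_track_from_F([0.0, 3.7, 0.0])
        percent_of_max(track)
        assert track.pct[1] == 100

    @pytest.mark.parametrize(
        "pct, expected",
        [(80, "dark_red"), (100, "dark_red"), (75, "dark_red"), (50, "red"),
         (74.999, "red"), (45, "orange"), (35, "yellow"), (25, "green"),
         (15, "blue"), (5, "light_blue"), (0, "light_blue")],
    )
    def test_stratum_anchors_and_boundaries(self, pct, expected):
        assert assign_stratum(pct, ScoringConfig()) == expected

    def test_pct_out_of_range_errors(self):
        for bad in (-0.1, 100.1):
            with pytest.raises(ValueError):
                assign_stratum(bad, ScoringConfig())

    def test_every_pct_maps_to_exactly_one_stratum(self):
        """The strata intervals tile [0, 100]."""
        config = ScoringConfig()
        for pct in np.linspace(0, 100, 2001):
            name = assign_stratum(float(pct), config)
            lowers = {n: b for b, n in config.strata_bounds}
            lower = lowers[name]
            uppers = [b for b, _ in config.strata_bounds if b > lower]
            upper = min(uppers) if uppers else 100.0
            assert lower <= pct <= 100
            if name != "dark_red":
                assert pct < upper

    def test_scale_free_strata(self):
        """Multiplying all metrics by a positive constant leaves pct/strata unchanged."""
        rng = np.random.default_rng(11)
        protein = random_protein(rng, 40)
        table = random_prediction_table(rng, protein)
        config = ScoringConfig(top_k=5)
        scaled = PredictionTable(
            protein.id,
            assign_ranks([PredictionRow(r.algorithm, r.allele, r.start, r.peptide,
                                        r.metric * 37.5) for r in table.rows]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = score_protein(table, protein, config)
            b = score_protein(scaled, protein, config)
        np.testing.assert_allclose(a.pct, b.pct)
        assert a.strata == b.strata


def score_track_from_F(values):
    from epitopemap.scoring import ResidueScoreTrack

    track = ResidueScoreTrack(protein_id="p", length=len(values))
    track.F = np.array(values, dtype=float)
    return track


class TestRenderHeatmap:
    def _track(self, protein, rows, config=ScoringConfig()):
        return score_protein(PredictionTable(protein.id, rows), protein, config)

    def test_tsv_row_count_and_columns(self, tmp_path, small_protein):
        rows = [PredictionRow("alg1", "A", 3, "DEFG", 0.1, rank=1)]
        with pytest.warns(UserWarning):
            track = self._track(small_protein, rows)
        out = tmp_path / "track.tsv"
        render_heatmap(track, small_protein, out, format="tsv")
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["position", "residue", "S", "N", "F",
                                        "pct", "stratum"]
        assert len(lines) == 11

    def test_all_zero_track_is_uniform_light_blue(self, tmp_path, small_protein):
        with pytest.warns(UserWarning):
            track = self._track(small_protein, [])
        frame = track_to_frame(track, small_protein)
        assert set(frame["stratum"]) == {"light_blue"}

    def test_html_marks_exactly_the_dark_red_run(self, tmp_path, small_protein):
        rows = [PredictionRow("alg1", "A", 3, "DEFG", 0.1, rank=1)]
        with pytest.warns(UserWarning):
            track = self._track(small_protein, rows)
        out = tmp_path / "hm.html"
        render_heatmap(track, small_protein, out, format="html")
        text = out.read_text()
        # residues D, E, F, G (positions 3-6) and only they carry dark_red
        dark = [s.split(">", 1)[1][0]
                for s in text.split('class="aa dark_red" title=')[1:]]
        assert "".join(dark) == "DEFG"
        assert text.count('class="aa light_blue" title=') == 6
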