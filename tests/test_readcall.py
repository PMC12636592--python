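"""Filter cascade, colony detection, base calling and barcode matching."""

import edlib
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

from issq import (
    BarcodeLibrary,
    CellReadTable,
    ColonyTable,
    SequencingStack,
    assign_to_cells,
    background_subtract,
    call_reads,
    consensus_reads,
    detect_colonies,
    extract_and_call,
    generate_sequencing_stack,
    levenshtein,
    linear_background_ramp,
    make_barcode_library,
    match_barcodes,
    second_max_suppress,
    temporal_std_projection,
    zscore_normalize,
)
from issq.readcall import chunked_gaussian_filter


def _stack(data, stage="raw"):
    return SequencingStack(np.asarray(data, dtype=float), stage=stage)


class TestBackgroundSubtract:
    def test_constant_image_maps_to_zero(self):
        out = background_subtract(_stack(np.full((2, 4, 32, 32), 7.0)))
        assert np.abs(out.data).max() < 1e-6
        assert out.stage == "background_filtered"

    def test_impulse_keeps_most_of_its_height(self):
        data = np.zeros((1, 4, 51, 51))
        data[0, 0, 25, 25] = 1.0
        out = background_subtract(_stack(data), sigma=3.0)
        # oracle: central weight of the discrete blur kernel
        impulse = np.zeros((51, 51))
        impulse[25, 25] = 1.0
        center_weight = gaussian_filter(impulse, 3.0)[25, 25]
        assert out.data[0, 0, 25, 25] == pytest.approx(1.0 - center_weight)

    def test_narrow_features_survive_wide_ones_do_not(self):
        yy, xx = np.mgrid[:101, :101] - 50.0
        wide = np.exp(-(yy**2 + xx**2) / (2 * 20.0**2))
        narrow = np.exp(-(yy**2 + xx**2) / (2 * 1.0**2))
        data = np.zeros((1, 4, 101, 101))
        data[0, 0], data[0, 1] = wide, narrow
        out = background_subtract(_stack(data), sigma=3.0)
        ratio = out.data[0, 1, 50, 50] / max(out.data[0, 0, 50, 50], 1e-12)
        assert ratio > 5

    def test_chunked_filter_matches_unchunked(self):
        rng = np.random.default_rng(0)
        plane = rng.random((130, 97))
        np.testing.assert_allclose(
            chunked_gaussian_filter(plane, 3.0, 48),
            gaussian_filter(plane, 3.0),
            atol=1e-12,
        )


class TestZScore:
    def test_standardized_plane_unchanged(self):
        rng = np.random.default_rng(1)
        plane = rng.standard_normal((40, 40))
        plane = (plane - plane.mean()) / plane.std()
        out = zscore_normalize(_stack(plane[None, None]))
        np.testing.assert_allclose(out.data[0, 0], plane, atol=1e-12)

    def test_hand_computed_values(self):
        plane = np.array([[0.0, 0.0], [10.0, 10.0]])
        out = zscore_normalize(_stack(plane[None, None]))
        np.testing.assert_allclose(out.data[0, 0], [[-1, -1], [1, 1]])

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.random((2, 4, 16, 16))
        a = zscore_normalize(_stack(data)).data
        b = zscore_normalize(_stack(7.0 * data)).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_variance_plane_zeroed_with_warning(self):
        data = np.zeros((1, 4, 8, 8))
        data[0, 1] = np.random.default_rng(3).random((8, 8))
        with pytest.warns(UserWarning, match="zero variance"):
            out = zscore_normalize(_stack(data))
        assert not out.data[0, 0].any()


class TestSuppression:
    def test_worked_pixel_example(self):
        data = np.array([5.0, 3.0, 2.0, 1.0]).reshape(1, 4, 1, 1)
        out = second_max_suppress(_stack(data), blur_sigma=0)
        np.testing.assert_allclose(out.data[0, :, 0, 0], [2, 0, 0, 0])

    def test_tied_maxima_cancel(self):
        data = np.array([5.0, 5.0, 1.0, 0.0]).reshape(1, 4, 1, 1)
        out = second_max_suppress(_stack(data), blur_sigma=0)
        assert not out.data.any()

    def test_all_equal_channels_zero(self):
        out = second_max_suppress(_stack(np.full((1, 4, 4, 4), 3.0)), blur_sigma=0)
        assert not out.data.any()

    def test_at_most_one_nonzero_channel_per_pixel(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((3, 4, 10, 10))
        out = second_max_suppress(_stack(data), blur_sigma=0)
        nonzero_per_pixel = (out.data > 0).sum(axis=1)
        assert nonzero_per_pixel.max() <= 1

    def test_requires_multiple_channels(self):
        with pytest.raises(ValueError):
            second_max_suppress(_stack(np.zeros((1, 1, 4, 4))))


class TestStdProjection:
    def test_cycle_constant_stack_is_zero(self):
        data = np.tile(np.random.default_rng(5).random((1, 4, 8, 8)), (3, 1, 1, 1))
        proj = temporal_std_projection(_stack(data, stage="suppressed"))
        np.testing.assert_allclose(proj, 0.0, atol=1e-12)

    def test_alternating_channel_hand_value(self):
        data = np.zeros((4, 4, 1, 1))
        data[:, 0, 0, 0] = [0, 1, 0, 1]
        proj = temporal_std_projection(_stack(data, stage="suppressed"))
        assert proj[0, 0] == pytest.approx(0.5)  # population sd of {0,1,0,1}

    def test_nonnegative(self):
        rng = np.random.default_rng(6)
        proj = temporal_std_projection(
            _stack(rng.standard_normal((5, 4, 6, 6)), stage="suppressed")
        )
        assert proj.min() >= 0

    def test_single_cycle_rejected(self):
        with pytest.raises(ValueError):
            temporal_std_projection(_stack(np.zeros((1, 4, 4, 4)), stage="suppressed"))


class TestDetection:
    def test_blank_projection_no_colonies(self):
        assert len(detect_colonies(np.zeros((64, 64)))) == 0

    def test_known_dots_recovered_within_one_pixel(self):
        yy, xx = np.mgrid[:128, :128]
        truth = [(20, 30), (60, 90), (100, 15), (45, 60), (110, 110)]
        proj = np.zeros((128, 128))
        for y, x in truth:
            proj += 5.0 * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * 1.5**2))
        table = detect_colonies(proj).table
        assert len(table) == 5
        for y, x in truth:
            d = np.hypot(table.x - x, table.y - y).min()
            assert d <= 1.0

    def test_nearby_dots_not_merged(self):
        yy, xx = np.mgrid[:64, :64]
        proj = sum(
            5.0 * np.exp(-((yy - 32) ** 2 + (xx - x) ** 2) / (2 * 1.5**2))
            for x in (22, 42)
        )
        assert len(detect_colonies(proj)) == 2


class TestExtractAndCall:
    def test_argmax_against_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.random((6, 4, 16, 16))
        stack = _stack(data, stage="normalized")
        colonies = ColonyTable(pd.DataFrame({"x": [3.0, 10.0], "y": [5.0, 12.0],
                                             "sigma": [1.0, 1.0]}))
        out = extract_and_call(stack, colonies)
        for k, (x, y) in enumerate([(3, 5), (10, 12)]):
            expected = "".join(
                "GTAC"[int(np.argmax([data[t, c, y, x] for c in range(4)]))]
                for t in range(6)
            )
            assert out.table.read[k] == expected
            assert not out.table.tie[k]

    def test_exact_tie_uses_priority_and_flags(self):
        data = np.zeros((1, 4, 4, 4))
        data[0, 1, 2, 2] = 1.0
        data[0, 3, 2, 2] = 1.0  # T and C tie; T earlier in channel order
        stack = _stack(data, stage="normalized")
        out = extract_and_call(
            stack, ColonyTable(pd.DataFrame({"x": [2.0], "y": [2.0], "sigma": [1.0]}))
        )
        assert out.table.read[0] == "T"
        assert bool(out.table.tie[0])

    def test_out_of_frame_center_rejected(self):
        stack = _stack(np.zeros((1, 4, 8, 8)), stage="normalized")
        bad = ColonyTable(pd.DataFrame({"x": [9.0], "y": [0.0], "sigma": [1.0]}))
        with pytest.raises(ValueError):
            extract_and_call(stack, bad)


class TestCellAssignment:
    def test_labels_read_at_exact_center_pixel(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[2:6, 2:6] = 7
        colonies = ColonyTable(pd.DataFrame({
            "x": [3.0, 8.0, 2.0], "y": [3.0, 8.0, 2.0], "sigma": [1.0] * 3,
            "read": ["G", "T", "A"],
        }))
        out = assign_to_cells(colonies, mask)
        assert list(out.table.cell) == [7, 0, 7]  # boundary pixel (2,2) is inside

    def test_background_excluded_from_consensus(self):
        colonies = ColonyTable(pd.DataFrame({
            "x": [1.0, 2.0], "y": [1.0, 2.0], "sigma": [1.0, 1.0],
            "read": ["GG", "TT"], "cell": [0, 3],
        }))
        cells = consensus_reads(colonies)
        assert list(cells.table.cell) == [3]


class TestConsensus:
    def _colonies(self, reads_by_cell):
        rows = [
            {"x": 0.0, "y": 0.0, "sigma": 1.0, "read": r, "cell": cell}
            for cell, reads in reads_by_cell.items() for r in reads
        ]
        return ColonyTable(pd.DataFrame(rows))

    def test_top_two_by_count(self):
        cells = consensus_reads(self._colonies({1: ["AAA"] * 5 + ["CCC"] * 3 + ["GGG"]}))
        assert cells.table.reads[0] == ["AAA", "CCC"]
        assert cells.table.counts[0] == [5, 3]

    def test_single_read_kept(self):
        cells = consensus_reads(self._colonies({1: ["GTA"]}))
        assert cells.table.reads[0] == ["GTA"]

    def test_three_way_tie_lexicographic_and_flagged(self):
        cells = consensus_reads(
            self._colonies({1: ["GGG", "GGG", "CCC", "CCC", "AAA", "AAA"]})
        )
        assert cells.table.reads[0] == ["AAA", "CCC"]
        assert bool(cells.table.count_tie[0])

    def test_k_is_honoured(self):
        cells = consensus_reads(
            self._colonies({1: ["AAA"] * 3 + ["CCC"] * 2 + ["GGG"]}), k=1
        )
        assert cells.table.reads[0] == ["AAA"]


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a, b, d",
        [("GTAC", "GTAC", 0), ("GTAC", "GGAC", 1), ("kitten", "sitting", 3),
         ("", "AAA", 3), ("GATTACA", "", 7)],
    )
    def test_known_distances(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_against_edlib_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a = "".join(rng.choice(list("GTAC"), size=rng.integers(0, 15)))
            b = "".join(rng.choice(list("GTAC"), size=rng.integers(1, 15)))
            expected = edlib.align(a, b, task="distance")["editDistance"]
            assert levenshtein(a, b) == expected

    @settings(derandomize=True, deadline=None, max_examples=150)
    @given(
        a=st.text(alphabet="GTAC", min_size=1, max_size=14),
        b=st.text(alphabet="GTAC", min_size=1, max_size=14),
    )
    def test_agrees_with_edlib_and_is_symmetric(self, a, b):
        assert levenshtein(a, b) == edlib.align(a, b, task="distance")["editDistance"]
        assert levenshtein(a, b) == levenshtein(b, a)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a, b, c = (
                "".join(rng.choice(list("GTAC"), size=rng.integers(1, 10)))
                for _ in range(3)
            )
            assert levenshtein(a, b) == levenshtein(b, a)
            assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


def _cells(reads_per_cell):
    rows = [{"cell": k + 1, "reads": reads, "counts": [1] * len(reads),
             "count_tie": False} for k, reads in enumerate(reads_per_cell)]
    return CellReadTable(pd.DataFrame(rows))


class TestMatching:
    def test_verbatim_match_distance_zero(self):
        lib = BarcodeLibrary(["GTAC", "CCCC"])
        out = match_barcodes(_cells([["GTAC"]]), lib)
        row = out.table.iloc[0]
        assert (row.match, row.distance, row.status) == ("GTAC", 0, "matched")

    def test_nearest_entry_wins(self):
        lib = BarcodeLibrary(["AAAA", "TTTT"])
        out = match_barcodes(_cells([["AAAT"]]), lib)
        row = out.table.iloc[0]
        assert row.match == "AAAA" and row.distance == 1

    def test_tied_entries_are_ambiguous(self):
        lib = BarcodeLibrary(["AAAA", "AATT"])
        # oracle: full distance matrix confirms the tie before asserting
        dists = {e: levenshtein("AAAT", e) for e in lib.entries}
        assert dists["AAAA"] == dists["AATT"] == 1
        out = match_barcodes(_cells([["AAAT"]]), lib)
        assert out.table.iloc[0].status == "ambiguous"
        assert out.table.iloc[0].match is None

    def test_max_distance_gives_unmatched(self):
        lib = BarcodeLibrary(["AAAAAAAA"])
        out = match_barcodes(_cells([["TTTTTTTT"]]), lib, max_distance=2)
        assert out.table.iloc[0].status == "unmatched"

    def test_best_read_of_the_pair_decides(self):
        lib = BarcodeLibrary(["GGGG", "CCCC"])
        out = match_barcodes(_cells([["GGGT", "AAAA"]]), lib)
        assert out.table.iloc[0].match == "GGGG"

    def test_double_mode_tries_both_slot_assignments(self):
        lib = BarcodeLibrary([("GGGG", "CCCC"), ("TTTT", "AAAA")], mode="double")
        out = match_barcodes(_cells([["CCCC", "GGGG"]]), lib)
        row = out.table.iloc[0]
        assert row.match == ("GGGG", "CCCC") and row.distance == 0

    def test_double_mode_combined_distance_and_ambiguity(self):
        lib = BarcodeLibrary([("GGGG", "CCCC"), ("GGGT", "CCCA")], mode="double")
        # read pair at combined distance 1 from both entries -> ambiguous
        out = match_barcodes(_cells([["GGGT", "CCCC"]]), lib)
        # oracle: combined distances by brute force over pairings
        def combined(entry, r1, r2):
            return min(levenshtein(r1, entry[0]) + levenshtein(r2, entry[1]),
                       levenshtein(r2, entry[0]) + levenshtein(r1, entry[1]))
        d0 = combined(lib.entries[0], "GGGT", "CCCC")
        d1 = combined(lib.entries[1], "GGGT", "CCCC")
        assert d0 == d1 == 1
        assert out.table.iloc[0].status == "ambiguous"

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            BarcodeLibrary([])


class TestPipelineContracts:
    def test_stage_order_enforced(self):
        raw = _stack(np.random.default_rng(10).random((2, 4, 8, 8)))
        suppressed = second_max_suppress(zscore_normalize(background_subtract(raw)))
        with pytest.raises(ValueError, match="stage"):
            background_subtract(suppressed)
        with pytest.raises(ValueError, match="stage"):
            temporal_std_projection(raw)

    def test_called_reads_invariant_to_per_plane_affine_rescale(self):
        lib = make_barcode_library(16, 5, 0)
        stack, truth = generate_sequencing_stack(
            6, lib, 5, shape=(256, 256), decay=0.9, noise_sd=2.0, rng_seed=11,
        )
        rng = np.random.default_rng(12)
        gains = rng.uniform(0.5, 4.0, size=(5, 4, 1, 1))
        offs = rng.uniform(-30, 30, size=(5, 4, 1, 1))
        rescaled = SequencingStack(stack.data * gains + offs)
        lb = BarcodeLibrary(lib)
        _, cells_a = call_reads(stack, truth.cell_labels, lb)
        _, cells_b = call_reads(rescaled, truth.cell_labels, lb)
        pd.testing.assert_frame_equal(cells_a.table, cells_b.table)

    def test_end_to_end_noiseless_all_cells_recovered(self):
        lib = make_barcode_library(32, 6, 1)
        stack, truth = generate_sequencing_stack(
            10, lib, 6, shape=(320, 320), rng_seed=13,
        )
        _, cells = call_reads(stack, truth.cell_labels, BarcodeLibrary(lib))
        assert len(cells.table) == len(truth.cell_barcodes)
        for row in cells.table.itertuples():
            assert row.status == "matched"
            assert row.match == truth.cell_barcodes[row.cell]
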