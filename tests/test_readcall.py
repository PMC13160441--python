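import numpy as np
import pytest
from scipy import ndimage

from conftest import levenshtein
from insitucall.readcall import (
    BarcodeLibrary,
    DotRecord,
    assign_dots_to_cells,
    background_subtract,
    call_reads,
    channel_isolation,
    consensus_and_match,
    cycle_std_projection,
    detect_dots,
    filter_stack,
    zscore_normalize,
)


def stack_of(arr):
    return np.asarray(arr, dtype=float)


class TestBackgroundSubtract:
    def test_constant_goes_to_zero(self):
        stack = np.full((2, 4, 16, 16), 9.0)
        np.testing.assert_allclose(background_subtract(stack), 0.0, atol=1e-9)

    def test_impulse_response_oracle(self):
        # center value of a subtracted impulse is v * (1 - g0) where g0 is
        # the blur kernel's central weight, measured on a unit impulse
        impulse = np.zeros((33, 33))
        impulse[16, 16] = 1.0
        g0 = ndimage.gaussian_filter(impulse, 3.0)[16, 16]
        v = 250.0
        stack = np.zeros((1, 4, 33, 33))
        stack[0, 0, 16, 16] = v
        out = background_subtract(stack, sigma=3.0)
        assert out[0, 0, 16, 16] == pytest.approx(v * (1 - g0), rel=1e-9)


class TestZscore:
    def test_moments(self, rng):
        stack = rng.uniform(5, 50, size=(3, 4, 32, 32))
        out = zscore_normalize(stack)
        means = out.mean(axis=(-2, -1))
        stds = out.std(axis=(-2, -1))
        np.testing.assert_allclose(means, 0.0, atol=1e-6)
        np.testing.assert_allclose(stds, 1.0, atol=1e-6)

    def test_idempotent_on_standardized(self, rng):
        plane = rng.standard_normal((1, 4, 64, 64))
        once = zscore_normalize(plane)
        np.testing.assert_allclose(zscore_normalize(once), once, atol=1e-9)

    def test_zero_variance_plane_warns_and_zeroes(self, rng):
        stack = rng.random((2, 4, 8, 8))
        stack[1, 2] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = zscore_normalize(stack)
        np.testing.assert_array_equal(out[1, 2], 0.0)

    def test_equalizes_contrast_across_scaled_planes(self, rng):
        base = rng.random((32, 32)) + 1
        stack = np.stack([base, 10 * base])[:, None]
        stack = np.repeat(stack, 4, axis=1)
        out = zscore_normalize(stack)
        np.testing.assert_allclose(out[0], out[1], atol=1e-9)


class TestChannelIsolation:
    def test_uniform_patch_arithmetic(self):
        # per-pixel values (4, 3, 2, 1): second max 3 -> (1, 0, -1, -2),
        # blur is identity on uniform planes, negatives clipped
        stack = np.zeros((1, 4, 8, 8))
        for ch, v in enumerate([4.0, 3.0, 2.0, 1.0]):
            stack[0, ch] = v
        out = channel_isolation(stack)
        np.testing.assert_allclose(out[0, 0], 1.0, atol=1e-9)
        for ch in (1, 2, 3):
            np.testing.assert_allclose(out[0, ch], 0.0, atol=1e-9)

    def test_equal_channels_zero(self):
        stack = np.full((1, 4, 8, 8), 5.0)
        np.testing.assert_allclose(channel_isolation(stack), 0.0, atol=1e-9)

    def test_at_most_one_positive_channel_before_blur(self, rng):
        stack = rng.random((2, 4, 16, 16))
        second = np.partition(stack, -2, axis=1)[:, -2:-1]
        pre = stack - second
        assert ((pre > 0).sum(axis=1) <= 1).all()


class TestCycleStdProjection:
    def test_constant_zero(self):
        stack = np.full((3, 4, 8, 8), 2.0)
        np.testing.assert_allclose(cycle_std_projection(stack), 0.0)

    def test_alternating_pixel_population_std(self):
        stack = np.zeros((2, 4, 4, 4))
        stack[0, 1, 2, 2] = 1.0  # alternates 1, 0 across the two cycles
        out = cycle_std_projection(stack)
        assert out[2, 2] == pytest.approx(0.5)

    def test_dot_beats_static_debris(self):
        stack = np.zeros((4, 4, 8, 8))
        for c in range(4):  # colony: switches channel every cycle
            stack[c, c % 4, 2, 2] = 1.0
        stack[:, :, 5, 5] = 1.0  # debris: bright in all channels every cycle
        out = cycle_std_projection(stack)
        assert out[2, 2] > out[5, 5]

    def test_single_cycle_rejected(self):
        with pytest.raises(ValueError, match="2 cycles"):
            cycle_std_projection(np.zeros((1, 4, 8, 8)))


class TestDetectDots:
    def test_single_gaussian_spot(self):
        img = np.zeros((64, 64))
        img[30, 40] = 100.0
        img = ndimage.gaussian_filter(img, 1.5)
        dots = detect_dots(img, threshold=0.05)
        assert len(dots) == 1
        assert abs(dots[0, 0] - 40) <= 1 and abs(dots[0, 1] - 30) <= 1

    def test_blank_image(self):
        assert len(detect_dots(np.zeros((32, 32)))) == 0


class TestCallReads:
    def test_argmax_channel_mapping(self):
        stack = np.zeros((4, 4, 4, 4))
        for c, ch in enumerate([0, 2, 1, 3]):
            stack[c, ch, 1, 2] = 5.0
        (dot,) = call_reads(stack, np.array([[2.0, 1.0, 1.0]]), channel_map="GTAC")
        assert dot.read == "GATC"

    def test_read_length_matches_cycles(self, rng):
        stack = rng.random((12, 4, 8, 8))
        (dot,) = call_reads(stack, np.array([[3, 3, 1.0]]))
        assert len(dot.read) == 12

    def test_out_of_bounds_rejected(self, rng):
        with pytest.raises(ValueError, match="outside"):
            call_reads(rng.random((2, 4, 8, 8)), np.array([[20.0, 1.0, 1.0]]))

    def test_scale_equivariance_of_filter_chain(self, rng):
        # multiplying one (cycle, channel) plane by a positive constant
        # must not change any call: z-scoring removes the scale
        stack = rng.random((3, 4, 32, 32))
        stack[0, 1, 10, 10] = 5.0
        scaled = stack.copy()
        scaled[1, 2] *= 37.0
        ex1, _ = filter_stack(stack)
        ex2, _ = filter_stack(scaled)
        locs = np.array([[10.0, 10.0, 1.0]])
        assert call_reads(ex1, locs)[0].read == call_reads(ex2, locs)[0].read
        np.testing.assert_allclose(ex1, ex2, atol=1e-9)


class TestAssignDots:
    def test_mask_lookup_and_background(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[4:7, 4:7] = 7
        dots = [
            DotRecord(x=5.2, y=4.8, radius=1, intensities=np.zeros((1, 4)), read="A"),
            DotRecord(x=0.0, y=0.0, radius=1, intensities=np.zeros((1, 4)), read="C"),
        ]
        assign_dots_to_cells(dots, mask)
        assert dots[0].cell_label == 7
        assert dots[1].cell_label == 0

    def test_counts_match_bruteforce(self, rng):
        mask = rng.integers(0, 5, size=(30, 30)).astype(np.int32)
        dots = [
            DotRecord(x=float(x), y=float(y), radius=1,
                      intensities=np.zeros((1, 4)), read="A")
            for x, y in rng.integers(0, 30, size=(50, 2))
        ]
        assign_dots_to_cells(dots, mask)
        for d in dots:
            assert d.cell_label == mask[int(round(d.y)), int(round(d.x))]

    def test_frame_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            assign_dots_to_cells([], np.zeros((5, 5)), image_shape=(6, 6))


def make_dots(reads_by_cell):
    dots = []
    for cell, reads in reads_by_cell.items():
        for read in reads:
            dots.append(
                DotRecord(x=0, y=0, radius=1, intensities=np.zeros((1, 4)),
                          read=read, cell_label=cell)
            )
    return dots


class TestConsensusAndMatch:
    def test_top_two_retention(self):
        lib = BarcodeLibrary([("ACGT",)], ["v1"])
        dots = make_dots({1: ["ACGT"] * 3 + ["TTTT"] * 2 + ["GGGG"]})
        (g,) = consensus_and_match(dots, lib)
        assert [r for r, _ in g.reads] == ["ACGT", "TTTT"]
        assert g.reads[0][1] == 3

    def test_distance_one_match(self):
        lib = BarcodeLibrary([("ACGT",)], ["v1"])
        (g,) = consensus_and_match(make_dots({1: ["ACGA"]}), lib)
        assert g.status == "matched"
        assert g.distance == 1
        assert g.identifier == "v1"

    def test_symmetric_tie_is_ambiguous(self):
        lib = BarcodeLibrary([("AAAA",), ("TTTT",)], ["a", "t"])
        (g,) = consensus_and_match(make_dots({1: ["AATT"]}), lib)
        assert g.status == "ambiguous"
        assert g.distance == 2

    def test_cells_without_reads_omitted(self):
        lib = BarcodeLibrary([("ACGT",)], ["v1"])
        out = consensus_and_match(make_dots({0: ["ACGT"]}), lib)  # background
        assert out == []

    def test_double_mode_ordered_pairs(self):
        lib = BarcodeLibrary([("AAAA", "CCCC"), ("GGGG", "TTTT")], ["p1", "p2"])
        dots = make_dots({1: ["CCCC", "AAAA", "AAAA"]})
        (g,) = consensus_and_match(dots, lib, double_barcode=True)
        assert g.status == "matched"
        assert g.identifier == "p1"
        assert g.distance == 0

    def test_oracle_equivalence_small(self, rng):
        bases = "ACGT"
        lib_codes = ["".join(rng.choice(list(bases), 6)) for _ in range(12)]
        lib_codes = list(dict.fromkeys(lib_codes))
        lib = BarcodeLibrary([(c,) for c in lib_codes], [f"v{k}" for k in range(len(lib_codes))])
        for trial in range(30):
            reads = ["".join(rng.choice(list(bases), 6)) for _ in range(2)]
            (g,) = consensus_and_match(make_dots({1: reads}), lib)
            best = min(levenshtein(r, c) for r in reads for c in lib_codes)
            winners = {c for c in lib_codes for r in reads if levenshtein(r, c) == best}
            if len(winners) == 1:
                assert g.status == "matched"
                assert g.barcodes == (winners.pop(),)
                assert g.distance == best
            else:
                assert g.status == "ambiguous"

    def test_retained_reads_bounded_by_n_keep(self, rng):
        lib = BarcodeLibrary([("ACGT",)], ["v1"])
        reads = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(30)]
        (g,) = consensus_and_match(make_dots({1: reads}), lib, n_keep=2)
        assert len(g.reads) <= 2

    def test_paired_library_requires_double_mode(self):
        lib = BarcodeLibrary([("AAAA", "CCCC")], ["p1"])
        with pytest.raises(ValueError):
            consensus_and_match(make_dots({1: ["AAAA"]}), lib, double_barcode=False)


class TestBarcodeLibrary:
    def test_uniform_length_enforced(self):
        with pytest.raises(ValueError, match="length"):
            BarcodeLibrary([("ACGT",), ("ACGTA",)], ["a", "b"])

    def test_unique_entries_enforced(self):
        with pytest.raises(ValueError, match="duplicate"):
            BarcodeLibrary([("ACGT",), ("ACGT",)], ["a", "b"])

    def test_frame_round_trip(self):
        lib = BarcodeLibrary([("ACGT", "TTAA")], ["p1"])
        lib2 = BarcodeLibrary.from_frame(lib.to_frame())
        assert lib2.entries == lib.entries
        assert lib2.double
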