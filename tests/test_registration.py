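import warnings

import numpy as np
import pytest

from insitucall.tiles import Tile, Constraint, ConstraintGraph
from insitucall.registration import (
    RansacParams,
    compute_score_threshold,
    filter_and_impute,
    phase_correlate,
    refine_constraints,
    zncc,
)


class TestZncc:
    def test_self_similarity(self, rng):
        a = rng.random((30, 30))
        assert zncc(a, a) == pytest.approx(1.0)

    def test_negation(self, rng):
        a = rng.random((30, 30))
        assert zncc(a, -a) == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        for _ in range(20):
            a = rng.random((16, 16))
            alpha = rng.uniform(0.1, 10)
            beta = rng.uniform(-50, 50)
            assert abs(zncc(a, alpha * a + beta) - 1.0) < 1e-9

    def test_zero_variance_scores_zero(self, rng):
        a = rng.random((10, 10))
        assert zncc(np.full((10, 10), 7.0), a) == 0.0

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            zncc(rng.random((4, 4)), rng.random((5, 5)))

    def test_bounded(self, rng):
        for _ in range(20):
            s = zncc(rng.random((8, 8)), rng.random((8, 8)))
            assert -1.0 <= s <= 1.0


class TestPhaseCorrelate:
    def test_circular_shift_recovered(self, rng):
        base = rng.random((128, 128))
        shifted = np.roll(base, shift=(3, -5), axis=(0, 1))  # content offset (5, -3)
        res = phase_correlate(base, shifted)
        assert (res.dx, res.dy) == (5, -3)
        assert res.score == pytest.approx(1.0)

    def test_identical_tiles(self, rng):
        a = rng.random((64, 64))
        res = phase_correlate(a, a)
        assert (res.dx, res.dy) == (0, 0)
        assert res.score == pytest.approx(1.0)

    def test_cropped_translation_with_noise(self, rng):
        scene = rng.random((400, 400))
        a = scene[50:250, 60:260]
        b = scene[57:257, 72:272] + rng.normal(0, 0.02, (200, 200))
        res = phase_correlate(a, b, initial_offset=(10.0, 5.0))
        assert (res.dx, res.dy) == (12, 7)
        assert res.score > 0.9

    def test_antisymmetry(self, rng):
        scene = rng.random((400, 400))
        a = scene[50:250, 60:260]
        b = scene[41:241, 74:274]
        fwd = phase_correlate(a, b)
        rev = phase_correlate(b, a)
        assert (rev.dx, rev.dy) == (-fwd.dx, -fwd.dy)
        assert rev.score == pytest.approx(fwd.score)

    def test_score_beats_initial_offset_when_peak_found(self, rng):
        scene = rng.random((300, 300))
        a = scene[20:220, 20:220]
        b = scene[25:225, 28:228]
        init = (6.0, 3.0)  # 2 px off the true (8, 5)
        res = phase_correlate(a, b, initial_offset=init)
        from insitucall.registration import _score_offset

        assert res.score >= _score_offset(a, b, 6, 3)

    def test_mixed_resolution_pair(self, rng):
        # coarse tile at scale 2 vs fine tile at scale 1: offsets come back
        # in common-frame pixels
        scene = rng.random((300, 300))
        fine = scene[50:178, 60:188]
        coarse_raw = scene[60:188:2, 70:198:2]  # every 2nd px, scale 2
        t_fine = Tile(id=0, image=fine, x=0, y=0, w=128, h=128, cycle=0, scale=1.0)
        t_coarse = Tile(id=1, image=coarse_raw, x=0, y=0, w=128, h=128, cycle=1, scale=2.0)
        res = phase_correlate(t_fine, t_coarse)
        assert abs(res.dx - 10) <= 1 and abs(res.dy - 10) <= 1

    def test_blank_pair_unusable(self):
        res = phase_correlate(np.zeros((32, 32)), np.zeros((32, 32)), initial_offset=(4, 0))
        assert res.score == 0.0
        assert not res.usable
        assert (res.dx, res.dy) == (4, 0)


def _texture_tiles(rng, n=6, cycle_split=False):
    tiles = []
    scene = rng.random((900, 900))
    for k in range(n):
        x = int(rng.integers(0, 700))
        y = int(rng.integers(0, 700))
        tiles.append(
            Tile(
                id=k,
                image=scene[y : y + 128, x : x + 128],
                x=x,
                y=y,
                w=128,
                h=128,
                cycle=k % 2 if cycle_split else 0,
            )
        )
    return tiles


class TestScoreThreshold:
    def test_deterministic_given_seed(self, rng):
        tiles = _texture_tiles(rng, n=8)
        t1 = compute_score_threshold(tiles, n_pairs=10, seed=7)
        t2 = compute_score_threshold(tiles, n_pairs=10, seed=7)
        assert t1 == t2

    def test_noise_tiles_threshold_small(self):
        rng = np.random.default_rng(0)
        tiles = [
            Tile(id=k, image=rng.random((64, 64)), x=(k % 4) * 400, y=(k // 4) * 400,
                 w=64, h=64, cycle=0)
            for k in range(12)
        ]
        thresh = compute_score_threshold(tiles, n_pairs=30, seed=0)
        # Monte-Carlo oracle: best ZNCC over 8 random candidate overlaps of
        # independent noise pairs; the threshold must sit inside that null
        # distribution's range
        mc = []
        for _ in range(200)        :
            a, b = rng.random((64, 64)), rng.random((64, 64))
            offs = rng.integers(-60, 61, size=(8, 2))
            best = max(
                zncc(a[max(0, dy):64 + min(0, dy), max(0, dx):64 + min(0, dx)],
                     b[max(0, -dy):64 - max(0, dy), max(0, -dx):64 - max(0, dx)])
                for dx, dy in offs
                if min(64 + min(0, dy) - max(0, dy), 64 + min(0, dx) - max(0, dx)) > 0
            )
            mc.append(best)
        assert 0.0 <= thresh <= np.percentile(mc, 100) + 0.1
        assert abs(thresh) < 0.5

    def test_no_qualifying_pairs(self, rng):
        tiles = _texture_tiles(rng, n=2)
        tiles[1].x = tiles[0].x + 10
        tiles[1].y = tiles[0].y
        with pytest.warns(UserWarning):
            assert compute_score_threshold(tiles) == 0.0


def _linear_graph(n=21, slope=(2.0, -1.0)):
    """Constraints obeying dx' = dx + 2, dy' = dy - 1 exactly."""
    rng = np.random.default_rng(5)
    tiles = [Tile(id=k, image=None, x=0, y=0, w=10, h=10, cycle=0) for k in range(n + 1)]
    cons = []
    for k in range(n):
        dx = float(rng.integers(-100, 100))
        dy = float(rng.integers(-100, 100))
        c = Constraint(k, k + 1, dx, dy, "intra_cycle")
        c.dx_refined = dx + slope[0]
        c.dy_refined = dy + slope[1]
        c.score = 0.9
        c.status = "refined"
        cons.append(c)
    return ConstraintGraph(tiles, cons)


class TestFilterAndImpute:
    def test_exact_linear_relation_imputed(self):
        g = _linear_graph()
        g.constraints[0].score = 0.1
        g.constraints[0].dx = 100.0
        g.constraints[0].dy = 0.0
        filter_and_impute(g, s_thresh=0.5)
        c = g.constraints[0]
        assert c.status == "imputed"
        assert c.dx_refined == pytest.approx(102.0, abs=1e-6)
        assert c.dy_refined == pytest.approx(-1.0, abs=1e-6)

    def test_wild_outlier_flagged_and_replaced(self):
        g = _linear_graph()
        c = g.constraints[7]
        c.dx_refined = c.dx + 400.0  # inconsistent with the linear trend
        filter_and_impute(g, s_thresh=0.5)
        assert c.status == "imputed"
        assert c.dx_refined == pytest.approx(c.dx + 2.0, abs=1e-6)

    def test_idempotent_when_nothing_filtered(self):
        g = _linear_graph()
        before = [(c.dx_refined, c.dy_refined, c.status) for c in g]
        filter_and_impute(g, s_thresh=0.5)
        assert [(c.dx_refined, c.dy_refined, c.status) for c in g] == before

    def test_constraint_count_preserved_and_all_refined(self):
        g = _linear_graph()
        for c in g.constraints[::3]:
            c.score = 0.0
        n = len(g)
        filter_and_impute(g, s_thresh=0.5)
        assert len(g) == n
        assert all(c.dx_refined is not None and c.dy_refined is not None for c in g)

    def test_imputed_weight_capped_by_survivors(self):
        g = _linear_graph()
        g.constraints[0].score = 0.2
        filter_and_impute(g, s_thresh=0.5)
        cap = min(c.score for c in g if c.status == "refined")
        assert g.constraints[0].score <= cap

    def test_too_few_survivors_identity_fallback(self):
        g = _linear_graph(n=4)
        for c in g.constraints:
            c.score = 0.1
        with pytest.warns(UserWarning):
            filter_and_impute(g, s_thresh=0.5)
        for c in g:
            assert c.status == "imputed"
            assert c.dx_refined == c.dx

    def test_per_cycle_plate_offsets_survive(self):
        # inter-cycle constraints with a common per-cycle translation are
        # explained by the stage model, not flagged as outliers
        rng = np.random.default_rng(9)
        tiles = [Tile(id=k, image=None, x=0, y=0, w=10, h=10, cycle=k % 2) for k in range(30)]
        cons = []
        for k in range(0, 30, 2):
            c = Constraint(k, k + 1, 0.0, 0.0, "inter_cycle")
            c.dx_refined, c.dy_refined = 9.0, -6.0  # plate shift cycle 0 -> 1
            c.score, c.status = 1.0, "refined"
            cons.append(c)
        for k in range(0, 28, 2):
            c = Constraint(k, k + 2, 120.0, 0.0, "intra_cycle")
            c.dx_refined, c.dy_refined = 120.0, 0.0
            c.score, c.status = 1.0, "refined"
            cons.append(c)
        g = ConstraintGraph(tiles, cons)
        filter_and_impute(g, s_thresh=0.5)
        assert all(c.status == "refined" for c in g)


class TestRefineConstraints:
    def test_known_shift_graph(self, rng):
        scene = rng.random((600, 600))
        true_pos = {0: (100, 100), 1: (205, 103), 2: (98, 207)}
        tiles = [
            Tile(id=k, image=scene[y : y + 128, x : x + 128], x=x - (3 if k else 0),
                 y=y + (2 if k == 2 else 0), w=128, h=128, cycle=0)
            for k, (x, y) in true_pos.items()
        ]
        cons = [Constraint(0, 1, 105, 3, "intra_cycle"), Constraint(0, 2, -2, 107, "intra_cycle")]
        g = ConstraintGraph(tiles, cons)
        refine_constraints(g)
        assert (g.constraints[0].dx_refined, g.constraints[0].dy_refined) == (105, 3)
        assert (g.constraints[1].dx_refined, g.constraints[1].dy_refined) == (-2, 107)
        assert all(c.score == pytest.approx(1.0) for c in g)

    def test_blank_tile_scores_zero(self, rng):
        tiles = [
            Tile(id=0, image=np.zeros((64, 64)), x=0, y=0, w=64, h=64, cycle=0),
            Tile(id=1, image=rng.random((64, 64)), x=30, y=0, w=64, h=64, cycle=0),
        ]
        g = ConstraintGraph(tiles, [Constraint(0, 1, 30, 0, "intra_cycle")])
        refine_constraints(g)
        assert g.constraints[0].score == 0.0
        assert g.constraints[0].status == "refined"
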