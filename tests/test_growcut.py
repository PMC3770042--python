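"""GrowCut automaton: energies, evolution rule, convergence, oracle equivalence.

The oracle here is a deliberately naive per-pixel transcription of the
evolution rule (nested loops, scalar arithmetic); the engine is vectorised.
Both must agree bit-exactly on arbitrary states.
"""

from __future__ import annotations

import numpy as np
import pytest

from liverseg import growcut
from liverseg.growcut import GrowCutConfig, CellState
from liverseg.image_io import SeedMap


# ---------------------------------------------------------------- naive oracle

def _offsets(neighborhood):
    if neighborhood == "moore":
        return growcut.MOORE_OFFSETS
    return growcut.VON_NEUMANN_OFFSETS


def _naive_energy(cp, cq, config, dist):
    if config.energy == "traditional":
        v = 1.0 - abs(cp - cq) / config.feature_norm
        return min(max(v, 0.0), 1.0)
    d = cp - cq
    return float(np.exp(-(d * d) / (2.0 * config.sigma2))) / dist


def _naive_enemies(lab, r, c, offsets):
    h, w = lab.shape
    counts = {}
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            l = int(lab[rr, cc])
            if l != 0 and l != lab[r, c]:
                counts[l] = counts.get(l, 0) + 1
    return max(counts.values(), default=0)


def naive_evolve_step(state, config):
    """Reference per-pixel implementation of one synchronous step."""
    lab, th, feat = state.label, state.strength, state.feature
    h, w = lab.shape
    offsets = _offsets(config.neighborhood)
    enemies = None
    if config.smoothing:
        enemies = np.array(
            [[_naive_enemies(lab, r, c, offsets) for c in range(w)] for r in range(h)]
        )
    new_lab, new_th = lab.copy(), th.copy()
    for r in range(h):
        for c in range(w):
            best = th[r, c]
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w):
                    continue
                if lab[rr, cc] == 0:
                    continue
                if config.smoothing and enemies[rr, cc] >= config.t1:
                    continue
                dist = float(np.sqrt(dr * dr + dc * dc))
                atk = _naive_energy(feat[r, c], feat[rr, cc], config, dist) * th[rr, cc]
                if atk > best:
                    best = atk
                    new_lab[r, c] = lab[rr, cc]
                    new_th[r, c] = atk
    if config.smoothing:
        for r in range(h):
            for c in range(w):
                if enemies[r, c] < config.t2:
                    continue
                weakest = np.inf
                chosen = None
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    if lab[rr, cc] == 0 or lab[rr, cc] == lab[r, c]:
                        continue
                    if th[rr, cc] < weakest:
                        weakest = th[rr, cc]
                        dist = float(np.sqrt(dr * dr + dc * dc))
                        g = _naive_energy(feat[r, c], feat[rr, cc], config, dist)
                        chosen = (lab[rr, cc], g * th[rr, cc])
                if chosen is not None:
                    new_lab[r, c], new_th[r, c] = chosen
    changed = int(np.count_nonzero(new_lab != lab))
    return CellState(label=new_lab, strength=new_th, feature=feat), changed


def random_state(rng, shape=(6, 6), labels=(0, 1, -1)):
    lab = rng.choice(np.array(labels), size=shape)
    th = np.where(lab != 0, rng.uniform(0, 1, shape), 0.0)
    feat = rng.uniform(0, 255, shape)
    return CellState(label=lab.astype(np.int64), strength=th, feature=feat)


# ------------------------------------------------------------------- energies

class TestEnergies:
    def test_traditional_closed_form(self):
        assert growcut.energy_traditional(100.0, 100.0) == 1.0
        assert growcut.energy_traditional(0.0, 255.0) == 0.0
        assert growcut.energy_traditional(100.0, 150.0, 255.0) == pytest.approx(
            1.0 - 50.0 / 255.0
        )

    def test_improved_closed_form(self):
        assert growcut.energy_improved(50.0, 50.0, 10.0, 1.0) == 1.0
        assert growcut.energy_improved(10.0, 20.0, 50.0, 1.0) == pytest.approx(
            np.exp(-1.0)
        )
        axial = growcut.energy_improved(30.0, 30.0, 5.0, 1.0)
        diag = growcut.energy_improved(30.0, 30.0, 5.0, np.sqrt(2.0))
        assert diag == pytest.approx(axial / np.sqrt(2.0))

    def test_random_tuples_match_direct_arithmetic(self, rng):
        for _ in range(1000):
            cp, cq = rng.uniform(0, 255, 2)
            s2 = rng.uniform(1, 500)
            dist = rng.choice([1.0, np.sqrt(2.0)])
            gt = growcut.energy_traditional(cp, cq, 255.0)
            assert abs(gt - min(max(1 - abs(cp - cq) / 255.0, 0.0), 1.0)) < 1e-12
            gi = growcut.energy_improved(cp, cq, s2, dist)
            assert abs(gi - np.exp(-((cp - cq) ** 2) / (2 * s2)) / dist) < 1e-12
            # gi may underflow to exactly 0 for large |dI| at small sigma2
            assert 0.0 <= gt <= 1.0 and 0.0 <= gi <= 1.0

    def test_monotone_decreasing_in_difference(self):
        diffs = np.linspace(0, 255, 100)
        gt = [growcut.energy_traditional(0.0, d) for d in diffs]
        gi = [growcut.energy_improved(0.0, d, 100.0, 1.0) for d in diffs]
        assert (np.diff(gt) <= 0).all() and (np.diff(gi) < 0).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            growcut.energy_traditional(0, 1, 0.0)
        with pytest.raises(ValueError):
            growcut.energy_improved(0, 1, -1.0, 1.0)


# ------------------------------------------------------------------ init/state

class TestInitState:
    def test_seed_strengths(self):
        seeds = SeedMap(np.array([0, 4]), np.array([0, 4]), np.array([1, -1]))
        st = growcut.init_state(np.zeros((5, 5)), seeds)
        assert (st.strength == 1.0).sum() == 2
        assert (st.strength == 0.0).sum() == 23
        assert set(np.unique(st.label).tolist()) == {-1, 0, 1}

    def test_single_class_rejected(self):
        seeds = SeedMap(np.array([0]), np.array([0]), np.array([1]))
        with pytest.raises(ValueError):
            growcut.init_state(np.zeros((5, 5)), seeds)

    def test_out_of_bounds_rejected(self):
        seeds = SeedMap(np.array([0, 9]), np.array([0, 9]), np.array([1, -1]))
        with pytest.raises(ValueError):
            growcut.init_state(np.zeros((5, 5)), seeds)


class TestEnemiesCount:
    def test_uniform_neighborhood_has_no_enemies(self):
        lab = np.ones((3, 3), dtype=np.int64)
        st = CellState(lab, np.ones((3, 3)), np.zeros((3, 3)))
        assert growcut.enemies_count(st, (1, 1)) == 0

    def test_direct_count(self):
        lab = np.full((3, 3), -1, dtype=np.int64)
        lab[1, 1] = 1
        lab[0, 0] = lab[0, 1] = lab[0, 2] = -1
        lab[2, 2] = 0  # unlabeled neighbours do not count
        st = CellState(lab, np.ones((3, 3)), np.zeros((3, 3)))
        assert growcut.enemies_count(st, (1, 1)) == 7

    def test_max_over_rival_labels(self):
        lab = np.array([[2, 2, 2], [3, 1, 3], [0, 0, 0]], dtype=np.int64)
        st = CellState(lab, np.ones((3, 3)), np.zeros((3, 3)))
        assert growcut.enemies_count(st, (1, 1)) == 3


# -------------------------------------------------------------------- evolve

class TestEvolveStep:
    def test_tie_breaks_to_first_offset(self):
        # 1x3 uniform strip, equal-strength attackers on both sides; the
        # E offset precedes W in the fixed order, so the left seed's label
        # (attacking eastward... the winner is the neighbour listed first)
        img = np.full((1, 3), 100.0)
        seeds = SeedMap(np.array([0, 0]), np.array([0, 2]), np.array([1, -1]))
        st = growcut.init_state(img, seeds)
        cfg = GrowCutConfig(energy="traditional", sigma2=1.0)
        new, changed = growcut.evolve_step(st, cfg)
        assert changed == 1
        # offsets order: E=(0,1) comes before W=(0,-1): attacker at col 2 wins
        assert new.label[0, 1] == -1

    def test_flood_fills_constant_image(self):
        img = np.full((4, 4), 50.0)
        seeds = SeedMap(np.array([1, 0]), np.array([1, 3]), np.array([1, -1]))
        cfg = GrowCutConfig(energy="traditional")
        res = growcut.run(img, seeds, cfg)
        assert res.converged
        assert (res.label != 0).all()

    def test_fixed_point_is_idempotent(self):
        img = np.full((5, 5), 10.0)
        seeds = SeedMap(np.array([2, 0]), np.array([2, 0]), np.array([1, -1]))
        res = growcut.run(img, seeds, GrowCutConfig(energy="traditional"))
        st = CellState(res.label, res.strength, np.full((5, 5), 10.0))
        new, changed = growcut.evolve_step(st, GrowCutConfig(energy="traditional"))
        assert changed == 0
        np.testing.assert_array_equal(new.label, st.label)
        np.testing.assert_array_equal(new.strength, st.strength)

    def test_boundary_lands_on_intensity_step(self):
        img = np.zeros((8, 8))
        img[:, :4] = 50.0
        img[:, 4:] = 200.0
        seeds = SeedMap(np.array([4, 4]), np.array([0, 7]), np.array([1, -1]))
        cfg = GrowCutConfig(energy="improved", sigma2=100.0)
        res = growcut.run(img, seeds, cfg)
        np.testing.assert_array_equal(res.label[:, :4], 1)
        np.testing.assert_array_equal(res.label[:, 4:], -1)

    def test_max_iter_zero_returns_seed_labels_flagged(self):
        img = np.zeros((4, 4))
        seeds = SeedMap(np.array([0, 3]), np.array([0, 3]), np.array([1, -1]))
        with pytest.warns(RuntimeWarning, match="converge"):
            res = growcut.run(img, seeds, GrowCutConfig(energy="traditional", max_iter=0))
        assert not res.converged and res.iterations == 0
        assert (res.label != 0).sum() == 2


@pytest.mark.parametrize("energy", ["traditional", "improved"])
@pytest.mark.parametrize("neighborhood", ["moore", "von_neumann"])
@pytest.mark.parametrize("smoothing", [False, True])
def test_oracle_equivalence(rng, energy, neighborhood, smoothing):
    """Vectorised step equals the naive per-pixel rule bit-exactly."""
    t1, t2 = (6, 7) if neighborhood == "moore" else (3, 4)
    for trial in range(25):
        labels = (0, 1, -1) if trial % 3 else (0, 1, 2, 3)
        st = random_state(rng, shape=(6, 6), labels=labels)
        cfg = GrowCutConfig(
            energy=energy,
            neighborhood=neighborhood,
            sigma2=float(rng.uniform(10, 200)),
            smoothing=smoothing,
            t1=t1,
            t2=t2,
        )
        fast, ch_f = growcut.evolve_step(st, cfg)
        slow, ch_s = naive_evolve_step(st, cfg)
        np.testing.assert_array_equal(fast.label, slow.label)
        np.testing.assert_array_equal(fast.strength, slow.strength)
        assert ch_f == ch_s


class TestConvergenceProperties:
    def test_convergence_and_seed_conservation_on_fixtures(self):
        from liverseg import phantom

        for fx in phantom.fixture_suite(n_per_difficulty=1, base_seed=3, shape=(64, 64)):
            res = growcut.run(fx.image, fx.seeds, GrowCutConfig(max_iter=500))
            assert res.converged, fx.name
            np.testing.assert_array_equal(
                res.label[fx.seeds.rows, fx.seeds.cols], fx.seeds.labels
            )
            assert res.strength.min() >= 0.0 and res.strength.max() <= 1.0

    def test_strengths_non_decreasing_without_smoothing(self, rng):
        st = random_state(rng, shape=(8, 8))
        cfg = GrowCutConfig(energy="traditional")
        for _ in range(10):
            new, _ = growcut.evolve_step(st, cfg)
            assert (new.strength >= st.strength - 1e-15).all()
            st = new


class TestEstimateSigma2:
    def test_constant_image_floored_with_warning(self):
        with pytest.warns(RuntimeWarning):
            val = growcut.estimate_sigma2(np.full((8, 8), 7.0))
        assert val == growcut.SIGMA2_FLOOR

    def test_checkerboard_value(self):
        img = 255.0 * ((np.indices((16, 16)).sum(axis=0)) % 2)
        assert growcut.estimate_sigma2(img) == pytest.approx(65025.0)

    def test_shift_invariance(self, rng):
        img = rng.uniform(0, 100, (16, 16))
        assert growcut.estimate_sigma2(img) == pytest.approx(
            growcut.estimate_sigma2(img + 55.0)
        )
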