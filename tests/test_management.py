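import numpy as np
import pytest

from stoatsim import calendar as cal
from stoatsim import life_history as lh
from stoatsim import management as mgmt
from stoatsim.config import SimConfig
from stoatsim.engine import Landscape, make_world
from stoatsim.geometry import make_point_grid


def day_of(year, doy):
    return cal.to_day_index(year, doy)


class TestTrapSchedule:
    @pytest.mark.parametrize("doy,active", [
        (25, True),    # 25 Jan: day 6 of the 20 Jan session
        (41, False),   # 10 Feb: session over
        (324, True),   # 20 Nov: session start
        (337, True),   # 3 Dec: last baited day
        (338, False),
        (201, True),   # 20 Jul session
        (60, False),   # 1 Mar
    ])
    def test_session_windows(self, doy, active):
        assert mgmt.traps_active(doy) is active


class TestDecoyDeployment:
    def test_age_after_single_deployment(self):
        dep = mgmt.DecoyDeployment(n_deployments=1)
        dep.update(day_of(0, cal.OESTRUS_START), cal.OESTRUS_START, True)
        # queried on 30 September: 15 days old
        assert dep.age_days(day_of(0, 273)) == 15
        dep.update(day_of(0, cal.REDEPLOY_DAY), cal.REDEPLOY_DAY, True)
        assert dep.age_days(day_of(0, 320)) == 62  # no refresh with 1 deploy

    def test_second_deployment_resets_age(self):
        dep = mgmt.DecoyDeployment(n_deployments=2)
        dep.update(day_of(0, cal.OESTRUS_START), cal.OESTRUS_START, True)
        dep.update(day_of(0, cal.REDEPLOY_DAY), cal.REDEPLOY_DAY, True)
        # queried 16 November: one day since the 15 Nov refresh
        assert dep.age_days(day_of(0, 320)) == 1

    def test_inactive_outside_window(self):
        dep = mgmt.DecoyDeployment(n_deployments=1)
        dep.update(day_of(0, cal.OESTRUS_START), cal.OESTRUS_START, True)
        dep.update(day_of(1, 60), 60, True)  # 1 March
        assert not dep.active

    def test_bad_deployment_count_rejected(self):
        with pytest.raises(ValueError):
            mgmt.DecoyDeployment(n_deployments=3)

    def test_weight_decays_between_deployments(self):
        dep = mgmt.DecoyDeployment(n_deployments=2)
        start = day_of(0, cal.OESTRUS_START)
        dep.update(start, cal.OESTRUS_START, True)
        gamma = 0.02
        w = [dep.weight(start + k, gamma) for k in range(0, 60, 10)]
        assert all(a > b for a, b in zip(w, w[1:]))  # monotone decay
        dep.update(day_of(0, cal.REDEPLOY_DAY), cal.REDEPLOY_DAY, True)
        assert dep.weight(day_of(0, cal.REDEPLOY_DAY), gamma) == 1.0


def _tiny_world(square_island, **cfg_kwargs):
    """Two stoats (M, F) on a square island with a 500 m decoy grid."""
    cfg = SimConfig(initial_n=2, traps_on=False, decoys_on=True,
                    decoy_spacing=500.0, **cfg_kwargs)
    decoys = make_point_grid(square_island, 500.0)
    ls = Landscape(square_island, np.empty((0, 2)), decoys)
    rng = np.random.default_rng(0)
    world = make_world(cfg, rng, ls)
    # deterministic layout: male at centre, female 100 m east
    pop = world.pop
    pop.male[0], pop.male[1] = True, False
    pop.x[0] = pop.hx[0] = 1000.0
    pop.y[0] = pop.hy[0] = 1000.0
    pop.x[1] = pop.hx[1] = 1100.0
    pop.y[1] = pop.hy[1] = 1000.0
    pop.pregnant[:2] = False
    pop.due_year[:2] = -1
    pop.ms[:2] = True
    pop.attractive[:2] = True
    world.day_index = day_of(0, cal.OESTRUS_START)
    world.decoy_state.update(world.day_index, cal.OESTRUS_START, True)
    return world


class TestVisibleCoas:
    def test_candidates_within_detection_radius(self, square_island):
        world = _tiny_world(square_island)
        cands = mgmt.visible_coas(world, 0)
        kinds = {c.kind for c in cands}
        assert "mate" in kinds and "decoy" in kinds
        assert all(c.distance <= world.config.detection_radius for c in cands)

    def test_equal_distance_mate_and_fresh_decoy_equal_kappa(self, square_island):
        world = _tiny_world(square_island)
        pop = world.pop
        # decoy grid point at (1000, 1500) is 500 m north of the male;
        # move the female 500 m east for symmetry
        pop.x[1] = 1500.0
        cands = {c.kind: c for c in mgmt.visible_coas(world, 0)
                 if abs(c.distance - 500.0) < 1e-6}
        assert cands["mate"].kappa == pytest.approx(cands["decoy"].kappa)

    def test_habituated_target_excluded(self, square_island):
        world = _tiny_world(square_island)
        pop = world.pop
        lh.add_habituation(pop, 0, lh.STOAT_CODE_BASE + 1,
                           world.day_index + 10)
        assert not any(c.kind == "mate"
                       for c in mgmt.visible_coas(world, 0))

    def test_decoy_age_lowers_kappa(self, square_island):
        world = _tiny_world(square_island, gamma=0.05)
        fresh = [c.kappa for c in mgmt.visible_coas(world, 0)
                 if c.kind == "decoy"]
        world.day_index += 20
        aged = [c.kappa for c in mgmt.visible_coas(world, 0)
                if c.kind == "decoy"]
        assert np.mean(aged) < np.mean(fresh)

    def test_kernel_scan_agrees_with_reference(self, square_island):
        from stoatsim._kernel import _scan_coas
        world = _tiny_world(square_island)
        pop, ls, cfg = world.pop, world.landscape, world.config
        dg = ls.decoy_grid
        dec_w = world.decoy_state.weight(world.day_index, cfg.gamma)
        n = pop.n
        _, _, _, _, total = _scan_coas(
            0, -1.0, n, pop.male[:n], pop.x[:n], pop.y[:n], pop.alive[:n],
            pop.attractive[:n], pop.hab_code[:n], pop.hab_exp[:n],
            world.day_index,
            world.nests.x, world.nests.y, world.nests.fem,
            world.nests.mated, world.nests.alive,
            True, dg.x, dg.y, dec_w,
            dg.start, dg.items, dg.x0, dg.y0, dg.cell, dg.nx, dg.ny,
            cfg.detection_radius, cfg.delta)
        # kernel accumulates kappa * minK (the 1/minK factor cancels in
        # the multinomial); the reference lists kappa itself
        ref = sum(c.kappa for c in mgmt.visible_coas(world, 0)) * cfg.min_k
        assert total == pytest.approx(ref, rel=1e-9)


class TestEncounters:
    def test_selected_mate_within_radius_mates(self, square_island):
        world = _tiny_world(square_island, p_pregnancy=1.0)
        pop = world.pop
        pop.x[1] = 1020.0  # 20 m away
        sel = [c for c in mgmt.visible_coas(world, 0) if c.kind == "mate"][0]
        out = mgmt.resolve_encounters(world, 0, world.rng, selected=sel)
        assert out == "mate" and pop.pregnant[1] and not pop.ms[1]

    def test_mate_preferred_over_closer_decoy(self, square_island):
        world = _tiny_world(square_island, p_pregnancy=1.0)
        pop = world.pop
        # stand on a decoy grid point; female 20 m away
        pop.x[0], pop.y[0] = 1000.0, 1495.0
        pop.x[1], pop.y[1] = 1000.0, 1515.0
        sel = min(mgmt.visible_coas(world, 0), key=lambda c: c.distance)
        assert sel.kind == "decoy"
        out = mgmt.resolve_encounters(world, 0, world.rng, selected=sel)
        assert out == "mate" and pop.pregnant[1]

    def test_lone_decoy_habituates(self, square_island):
        world = _tiny_world(square_island)
        pop = world.pop
        pop.x[0], pop.y[0] = 1000.0, 1495.0   # 5 m from decoy (1000, 1500)
        pop.x[1], pop.y[1] = 1900.0, 100.0    # female far away
        sel = min(mgmt.visible_coas(world, 0), key=lambda c: c.distance)
        out = mgmt.resolve_encounters(world, 0, world.rng, selected=sel)
        assert out == "decoy"
        assert lh.is_habituated(pop, 0, sel.target_id, world.day_index)

    def test_unselected_coa_is_walked_past(self, square_island):
        # selected-COA semantics: a distant selected COA means no
        # interaction, even with a potential mate 20 m away
        world = _tiny_world(square_island)
        world.config.encounter_selected_only = True
        pop = world.pop
        pop.x[1] = 1020.0
        far_decoy = max(mgmt.visible_coas(world, 0), key=lambda c: c.distance)
        out = mgmt.resolve_encounters(world, 0, world.rng, selected=far_decoy)
        assert out is None and not pop.pregnant[1]

    def test_opportunistic_mode_interacts_with_anything_near(self, square_island):
        world = _tiny_world(square_island, p_pregnancy=1.0)
        world.config.encounter_selected_only = False
        pop = world.pop
        pop.x[1] = 1020.0
        out = mgmt.resolve_encounters(world, 0, world.rng, selected=None)
        assert out == "mate" and pop.pregnant[1]

    def test_nothing_in_range_no_interaction(self, square_island):
        world = _tiny_world(square_island)
        world.config.encounter_selected_only = False
        pop = world.pop
        pop.x[0], pop.y[0] = 1250.0, 1250.0  # ≥ 25 m from everything
        pop.x[1], pop.y[1] = 1900.0, 100.0
        assert mgmt.resolve_encounters(world, 0, world.rng) is None


class TestTrapCapture:
    def _trap_world(self, square_island, doy):
        cfg = SimConfig(initial_n=1, traps_on=True, decoys_on=False)
        traps = np.array([[1000.0, 1010.0]])
        ls = Landscape(square_island, traps, np.empty((0, 2)))
        world = make_world(cfg, np.random.default_rng(1), ls)
        world.pop.x[0], world.pop.y[0] = 1000.0, 1000.0
        world.day_index = day_of(0, doy) if doy >= cal.OESTRUS_START \
            else day_of(1, doy)
        return world

    def test_capture_frequency_at_close_range(self, square_island):
        world = self._trap_world(square_island, 324)  # 20 Nov session
        hits = sum(mgmt.check_trap_capture(world, 0, world.rng)
                   for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.2, abs=0.01)

    def test_out_of_radius_never_captures(self, square_island):
        world = self._trap_world(square_island, 324)
        world.pop.y[0] = 1030.0  # 20 m from the trap
        assert not any(mgmt.check_trap_capture(world, 0, world.rng)
                       for _ in range(200))

    def test_no_session_never_captures(self, square_island):
        world = self._trap_world(square_island, 60)  # 1 March
        assert not any(mgmt.check_trap_capture(world, 0, world.rng)
                       for _ in range(200))
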