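"""Cell agents: speed law, remodelling, mechanics, motility, fate rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gliosim as g
from gliosim.agents import (
    AgentError,
    Cell,
    CellPopulation,
    CellState,
    CollagenKinetics,
    FateThresholds,
    MechanicsParams,
    MotilityParams,
    mechanics_velocity,
    migration_speed,
    ph_from_proton,
    remodel_collagen,
    update_motility,
    update_phenotype,
)
from gliosim.metabolism import MetabolicParams
from gliosim.microenv import VoxelGrid

K = CollagenKinetics()


class TestMigrationSpeed:
    @pytest.mark.parametrize("C_t", [0.0, 0.3, 0.49, 4.01, 4.5, 100.0])
    def test_zero_outside_permissive_window(self, C_t):
        assert migration_speed(C_t) == 0.0

    def test_optimal_density_value(self):
        # direct polynomial evaluation at the reference density
        assert migration_speed(2.5) == pytest.approx(0.7536, abs=1e-12)

    def test_peak_inside_window(self):
        # the quadratic has its maximum near 2.11 mg/mL: biphasic
        C = np.linspace(0.5, 4.0, 400)
        v = migration_speed(C)
        peak = C[np.argmax(v)]
        assert 1.9 < peak < 2.3
        assert v[0] < v.max() and v[-1] < v.max()

    def test_clamped_to_base_speed(self):
        v = migration_speed(np.linspace(0, 5, 200))
        assert np.all((v >= 0) & (v <= 0.8))

    def test_negative_density_raises(self):
        with pytest.raises(AgentError):
            migration_speed(-0.1)

    @settings(deadline=None, max_examples=50)
    @given(C=st.floats(0, 10))
    def test_speed_vs_independent_polynomial(self, C):
        expected = 0.0
        if 0.5 <= C <= 4.0:
            expected = min(max(0.8 * np.polyval([-0.23, 0.971, -0.048], C), 0.0), 0.8)
        assert migration_speed(C) == pytest.approx(expected, rel=1e-12)


class TestRemodelling:
    def test_no_substrate_only_secretion(self):
        cell = Cell()
        f_C, f_Cr = remodel_collagen(cell, 0.0, K)
        assert f_C == pytest.approx(K.beta_p)
        assert f_Cr == 0.0

    def test_saturated_michaelis_terms(self):
        cell = Cell()
        f_C, f_Cr = remodel_collagen(cell, 1e6, K)
        assert f_C == pytest.approx(K.beta_p - K.beta_m - K.beta_r, rel=1e-6)
        assert f_Cr == pytest.approx(K.beta_r, rel=1e-6)

    def test_no_lox_no_crosslinking(self):
        cell = Cell()
        cell.genes.r = 0.0
        for C in (0.0, 0.5, 2.5, 10.0):
            assert remodel_collagen(cell, C, K)[1] == 0.0

    def test_rates_scale_with_gene_levels(self):
        cell = Cell()
        cell.genes.p, cell.genes.m, cell.genes.r = 2.0, 3.0, 4.0
        f_C, f_Cr = remodel_collagen(cell, 2.5, K)
        assert f_Cr == pytest.approx(4 * K.beta_r * 2.5 / (K.K_r + 2.5), rel=1e-9)
        expected = 2 * K.beta_p - 3 * K.beta_m * 2.5 / (K.K_m + 2.5) - f_Cr
        assert f_C == pytest.approx(expected, rel=1e-9)


class TestMechanics:
    def test_isolated_cell_zero_velocity(self):
        assert mechanics_velocity(Cell(id=1, position=(50, 50)), []) == (0.0, 0.0)

    def test_overlapping_pair_equal_opposite(self):
        a = Cell(id=1, position=(50.0, 50.0))
        b = Cell(id=2, position=(58.0, 50.0))  # overlap: d < 16.8
        va = mechanics_velocity(a, [b])
        vb = mechanics_velocity(b, [a])
        assert va[0] == pytest.approx(-vb[0]) and va[1] == pytest.approx(-vb[1])
        assert va[0] < 0  # a pushed away from b

    def test_out_of_range_no_adhesion_zero(self):
        # at 1.5 cell diameters the pair sits exactly at the maximum
        # interaction distance: no repulsion, and with adhesion off, no force
        a = Cell(id=1, position=(0.0, 0.0))
        b = Cell(id=2, position=(1.5 * 16.8, 0.0))
        params = MechanicsParams(adhesion_strength=0.0)
        assert mechanics_velocity(a, [b], params) == (0.0, 0.0)

    def test_adhesion_attracts_at_distance(self):
        a = Cell(id=1, position=(0.0, 0.0))
        b = Cell(id=2, position=(20.0, 0.0))  # beyond contact, within reach
        vx, _ = mechanics_velocity(a, [b], MechanicsParams())
        assert vx > 0  # net pull of a toward b

    def test_coincident_positions_resolved(self):
        a = Cell(id=1, position=(10.0, 10.0))
        b = Cell(id=2, position=(10.0, 10.0))
        rng = np.random.default_rng(0)
        vx, vy = mechanics_velocity(a, [b], rng=rng)
        assert np.isfinite(vx) and np.isfinite(vy)
        assert (vx, vy) != (0.0, 0.0)


class TestMotility:
    def grid(self):
        return VoxelGrid(10, 10, 30.0)

    def test_zero_speed_pure_mechanics_displacement(self):
        grid = self.grid()
        grid.fields["C"][:] = 0.1  # below the permissive window
        cell = Cell(id=0, position=(150.0, 150.0))
        update_motility(cell, grid, np.random.default_rng(0), dt=1.0,
                        mech_velocity=(0.5, -0.25))
        assert cell.speed == 0.0
        assert cell.position == pytest.approx((150.5, 149.75))

    def test_necrotic_cell_does_not_move(self):
        grid = self.grid()
        cell = Cell(id=0, position=(150.0, 150.0), state=CellState.NECROTIC)
        update_motility(cell, grid, np.random.default_rng(0), dt=1.0)
        assert cell.position == (150.0, 150.0) and cell.speed == 0.0

    def test_seeded_trajectory_reproducible(self):
        grid = self.grid()
        def walk(seed):
            cell = Cell(id=0, position=(150.0, 150.0))
            rng = np.random.default_rng(seed)
            for _ in range(100):
                update_motility(cell, grid, rng, dt=1.0)
            return cell.position
        assert walk(7) == walk(7)
        assert walk(7) != walk(8)

    def test_msd_grows_linearly_at_long_lag(self):
        # persistent random walk: ballistic below the persistence time,
        # diffusive (MSD ~ t) well above it
        grid = VoxelGrid(400, 400, 30.0)
        rng = np.random.default_rng(0)
        n = 300
        pop = CellPopulation(n)
        pop.x[:] = 6000.0
        pop.y[:] = 6000.0
        pop.cycle_clock[:] = 0
        traj = []
        mot = MotilityParams(persistence_time=5.0)
        for step in range(400):
            pop.move(grid, rng, 1.0, mot, np.zeros(n), np.zeros(n))
            traj.append((pop.x.copy(), pop.y.copy()))
        def msd(lag):
            d = [(traj[t + lag][0] - traj[t][0]) ** 2 + (traj[t + lag][1] - traj[t][1]) ** 2
                 for t in range(0, 380 - lag, 17)]
            return np.mean(d)
        ratio = msd(200) / msd(100)
        assert 1.6 < ratio < 2.5  # ~2 for diffusive scaling


class TestPhenotype:
    ENV = (0.056, 5.0, 3.98e-5, 2.5)

    def test_zero_atp_is_lethal(self):
        cell = Cell(atp_generated=0.0)
        update_phenotype(cell, self.ENV, FateThresholds(), 6.0)
        assert cell.state == CellState.NECROTIC
        assert cell.speed == 0.0 and cell.rates.f_O == 0.0

    def test_acidosis_is_lethal(self):
        cell = Cell(atp_generated=1.0)
        acidic = (0.056, 5.0, 5e-3, 2.5)  # pH 5.3
        update_phenotype(cell, acidic, FateThresholds(), 6.0)
        assert cell.state == CellState.NECROTIC

    def test_division_ignores_crowding(self):
        met = MetabolicParams()
        cell = Cell(atp_generated=met.A_0 * 6.0, cycle_clock=2000.0)
        daughter = update_phenotype(cell, self.ENV, FateThresholds(), 6.0,
                                    rng=np.random.default_rng(1))
        assert daughter is not None
        assert cell.cycle_clock == 0.0 and daughter.cycle_clock == 0.0
        d = np.hypot(daughter.position[0] - cell.position[0],
                     daughter.position[1] - cell.position[1])
        assert d == pytest.approx(cell.radius)
        assert daughter.genes == cell.genes

    def test_intermediate_atp_quiesces_then_recovers(self):
        met = MetabolicParams()
        thr = FateThresholds()
        cell = Cell(atp_generated=0.5 * met.A_0 * 6.0)
        update_phenotype(cell, self.ENV, thr, 6.0)
        assert cell.state == CellState.QUIESCENT
        cell.atp_generated = met.A_0 * 6.0
        update_phenotype(cell, self.ENV, thr, 6.0)
        assert cell.state == CellState.CYCLING

    def test_necrotic_cell_is_inert(self):
        cell = Cell(state=CellState.NECROTIC, atp_generated=10.0)
        assert update_phenotype(cell, self.ENV, FateThresholds(), 6.0) is None
        assert cell.state == CellState.NECROTIC

    def test_threshold_ordering_enforced(self):
        with pytest.raises(AgentError):
            FateThresholds(atp_death_fraction=0.9, atp_divide_fraction=0.8)


class TestPopulation:
    def test_seed_disc_geometry_and_clocks(self):
        rng = np.random.default_rng(0)
        pop = CellPopulation.seed_disc(200, (500.0, 500.0), 80.0, rng)
        r = np.hypot(pop.x - 500, pop.y - 500)
        assert r.max() <= 80.0
        assert len(np.unique(np.round(pop.cycle_clock, 6))) > 150  # randomised
        assert pop.living.all()

    def test_necrotic_never_consumes_or_remodels(self):
        rng = np.random.default_rng(0)
        pop = CellPopulation.seed_disc(5, (150.0, 150.0), 40.0, rng)
        pop.state[2] = CellState.NECROTIC
        O = np.full(5, 0.056)
        G = np.full(5, 5.0)
        pop.update_metabolism(O, G, MetabolicParams(), 1.0)
        assert pop.f_O[2] == 0.0 and pop.f_A[2] == 0.0
        genes_before = pop.genes[2].copy()
        pop.integrate_genes_step(O, g.GrnParams(), 1.0)
        np.testing.assert_array_equal(pop.genes[2], genes_before)

    def test_starvation_never_increases_living_count(self):
        from gliosim.microenv import BoundaryProtocol

        cfg = g.build_scenario(
            "reference", nx=10, ny=10, voxel_size=30.0, duration_min=720.0,
            n_initial_cells=20, seeding_radius=40.0, dt_diffusion=3.0,
            dt_mechanics=3.0, snapshot_interval=60.0,
            boundary=BoundaryProtocol(o2_high=0.0, glucose=0.0),
        )
        grid = g.init_grid(cfg)
        grid.fields["O"][:] = 0.0
        grid.fields["G"][:] = 0.0
        rep = g.run_simulation(cfg, grid=grid)
        living = rep.counts["living"]
        assert all(b <= a for a, b in zip(living, living[1:]))
        assert living[-1] == 0  # everyone starves

    def test_uniform_collagen_uniform_speed(self):
        # without remodelling, every living cell moves at the reference
        # speed of the 2.5 mg/mL matrix
        cfg = g.build_scenario(
            "reference", nx=10, ny=10, voxel_size=30.0, duration_min=30.0,
            n_initial_cells=15, seeding_radius=40.0, dt_diffusion=3.0,
            dt_mechanics=3.0, snapshot_interval=30.0,
            collagen_kinetics=CollagenKinetics(beta_p=0, beta_m=0, beta_r=0),
        )
        rep = g.run_simulation(cfg)
        speeds = rep.final_cells["speed"]
        np.testing.assert_allclose(speeds, 0.7536, rtol=1e-9)


class TestPh:
    def test_ph_of_initial_protons(self):
        assert ph_from_proton(3.98e-5) == pytest.approx(7.4, abs=3e-3)

    def test_ph_death_level(self):
        assert ph_from_proton(1e-3) == pytest.approx(6.0)
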