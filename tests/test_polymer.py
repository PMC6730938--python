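import math

import numpy as np
import pytest

import nucleomix as nm
from nucleomix.polymer import (
    ConfigurationError,
    SimParams,
    SimState,
    StabilityError,
    compute_forces,
    genome_preset,
    init_configuration,
    match_crosslinks,
    nucleolus_preset,
    sample_state_durations,
    simulate,
    step_dynamics,
    update_activity,
)


def marko_siggia(r, L0, kT, Lp, cap=0.95):
    x = min(r / L0, cap)
    return kT / Lp * (0.25 / (1 - x) ** 2 - 0.25 + x)


def free_bead_topology(n=1):
    return nm.GenomeTopology(n_beads=n, chains=[(0, n - 1, None, None)],
                             nucleolar_mask=np.zeros(n, dtype=bool))


def state_at(positions, params, active=None, links=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    partner = np.full(n, -1, dtype=np.int64)
    if links:
        for i, j in links:
            partner[i], partner[j] = j, i
    if active is None:
        active = np.zeros(n, dtype=bool)
    return SimState(positions, np.asarray(active, dtype=bool),
                    np.full(n, np.inf), partner)


class TestTopology:
    def test_genome_preset_headline_numbers(self):
        topo = genome_preset()
        assert topo.n_beads == 2803
        assert len(topo.chains) == 32
        assert topo.nucleolar_mask.sum() == 361
        idx = np.flatnonzero(topo.nucleolar_mask)
        assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))

    def test_chains_partition_validation(self):
        with pytest.raises(ValueError):
            nm.GenomeTopology(n_beads=4, chains=[(0, 1, None, None)],
                              nucleolar_mask=np.zeros(4, dtype=bool))

    def test_non_contiguous_nucleolus_rejected(self):
        mask = np.array([True, False, True])
        with pytest.raises(ValueError):
            nm.GenomeTopology(n_beads=3, chains=[(0, 2, None, None)],
                              nucleolar_mask=mask)


class TestInitConfiguration:
    def test_two_bead_chain_on_antipodal_tethers(self):
        topo = nm.GenomeTopology(
            n_beads=2, chains=[(0, 1, (0, 0, 1.0), (0, 0, -1.0))],
            nucleolar_mask=np.zeros(2, dtype=bool))
        params = SimParams(mu=0.1, total_time=1.0, contour_length=2500.0)
        state = init_configuration(topo, params, 0)
        R = params.nucleus_radius
        assert np.allclose(state.positions[0], [0, 0, R])
        assert np.allclose(state.positions[1], [0, 0, -R])
        assert np.linalg.norm(state.positions, axis=1) == pytest.approx(R)

    def test_genome_preset_confined(self):
        topo = genome_preset()
        params = SimParams(mu=0.09, total_time=1.0)
        state = init_configuration(topo, params, 3)
        r = np.linalg.norm(state.positions, axis=1)
        assert len(state.positions) == 2803
        assert np.all(r <= params.nucleus_radius + 1e-9)

    def test_same_seed_bitwise_identical(self):
        topo = nucleolus_preset(50)
        params = SimParams(mu=0.2, total_time=1.0)
        a = init_configuration(topo, params, 11)
        b = init_configuration(topo, params, 11)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.active, b.active)
        assert np.array_equal(a.state_timer, b.state_timer)

    def test_unreachable_tethers_rejected(self):
        topo = nm.GenomeTopology(
            n_beads=3, chains=[(0, 2, (0, 0, 1.0), (0, 0, -1.0))],
            nucleolar_mask=np.zeros(3, dtype=bool))
        params = SimParams(mu=0.1, total_time=1.0, contour_length=200.0)
        with pytest.raises(ConfigurationError):
            init_configuration(topo, params, 0)


class TestForces:
    def test_coincident_neighbors_zero_spring_force(self):
        # the WLC spring's zero-force extension is zero separation
        topo = nm.GenomeTopology(n_beads=2, chains=[(0, 1, None, None)],
                                 nucleolar_mask=np.zeros(2, dtype=bool))
        params = SimParams(mu=0.1, total_time=1.0)
        state = state_at([[0, 0, 0], [0, 0, 0]], params)
        F = compute_forces(state, topo, params)
        assert np.allclose(F, 0.0)

    def test_isolated_bead_zero_force(self):
        params = SimParams(mu=0.1, total_time=1.0)
        state = state_at([[0, 0, 0]], params)
        F = compute_forces(state, free_bead_topology(), params)
        assert np.allclose(F, 0.0)

    def test_linked_pair_marko_siggia_value(self):
        """Two crosslinked beads at 90 nm with L0 = 200 nm: force matches
        a hand evaluation of the Marko-Siggia interpolation at the
        crosslink spring scale (extension below the saturation cap)."""
        topo = nm.GenomeTopology(
            n_beads=2, chains=[(0, 0, None, None), (1, 1, None, None)],
            nucleolar_mask=np.zeros(2, dtype=bool))
        params = SimParams(mu=0.1, total_time=1.0, repulsion_radius=30.0)
        state = state_at([[0, 0, 0], [90.0, 0, 0]], params,
                         active=[True, True], links=[(0, 1)])
        F = compute_forces(state, topo, params)
        expect = marko_siggia(90.0, params.contour_length, params.kT,
                              params.link_persistence_length)
        assert F[0, 0] == pytest.approx(expect)     # pulled toward +x
        assert F[1, 0] == pytest.approx(-expect)    # equal and opposite
        assert np.allclose(F[0] + F[1], 0.0)

    def test_repulsion_below_contact(self):
        params = SimParams(mu=0.1, total_time=1.0)
        topo = nm.GenomeTopology(
            n_beads=2, chains=[(0, 0, None, None), (1, 1, None, None)],
            nucleolar_mask=np.zeros(2, dtype=bool))
        state = state_at([[0, 0, 0], [40.0, 0, 0]], params)
        F = compute_forces(state, topo, params)
        overlap = 2 * params.repulsion_radius - 40.0
        assert F[0, 0] == pytest.approx(-params.repulsion_strength * overlap)
        assert F[1, 0] == pytest.approx(params.repulsion_strength * overlap)

    def test_non_finite_positions_rejected(self):
        params = SimParams(mu=0.1, total_time=1.0)
        state = state_at([[np.nan, 0, 0]], params)
        with pytest.raises(FloatingPointError):
            compute_forces(state, free_bead_topology(), params)


class TestStepDynamics:
    def test_zero_forces_zero_diffusion_static(self):
        params = SimParams(mu=0.1, total_time=1.0, kT=0.0)
        state = state_at([[100.0, 50.0, 0.0]], params)
        rng = np.random.default_rng(0)
        out = step_dynamics(state, free_bead_topology(), params, rng)
        assert np.array_equal(out.positions, state.positions)

    def test_free_diffusion_msd(self):
        """Mean-squared displacement of a free bead matches 6 D t within
        3 standard errors (closed-form oracle)."""
        params = SimParams(mu=0.1, total_time=1.0)
        topo = free_bead_topology()
        rng = np.random.default_rng(42)
        n_steps, n_rep = 400, 300
        msds = []
        for _ in range(n_rep):
            state = state_at([[0.0, 0.0, 0.0]], params)
            for _ in range(n_steps):
                state = step_dynamics(state, topo, params, rng)
            msds.append((state.positions[0] ** 2).sum())
        t = n_steps * params.dt
        expect = 6 * params.diffusivity * t
        se = np.std(msds, ddof=1) / math.sqrt(n_rep)
        assert abs(np.mean(msds) - expect) < 3 * se

    def test_outside_bead_projected_back(self):
        params = SimParams(mu=0.1, total_time=1.0)
        state = state_at([[1500.0, 0, 0]], params)
        rng = np.random.default_rng(1)
        out = step_dynamics(state, free_bead_topology(), params, rng)
        assert np.linalg.norm(out.positions[0]) <= params.nucleus_radius

    def test_stability_bound_enforced(self):
        params = SimParams(mu=0.1, total_time=1.0, dt=0.05)
        topo = nm.GenomeTopology(n_beads=2, chains=[(0, 1, None, None)],
                                 nucleolar_mask=np.zeros(2, dtype=bool))
        state = state_at([[0, 0, 0], [190.0, 0, 0]], params)
        with pytest.raises(StabilityError):
            step_dynamics(state, topo, params, np.random.default_rng(0))


class TestActivity:
    def test_active_duration_mean(self):
        durations = sample_state_durations(0.19, 10_000, seed=1, active=True)
        se = durations.std(ddof=1) / 100
        assert abs(durations.mean() - 0.19) < 3 * se

    def test_inactive_duration_mean(self):
        durations = sample_state_durations(0.9, 10_000, seed=2, active=False)
        se = durations.std(ddof=1) / 100
        assert abs(durations.mean() - 0.1) < 3 * se

    def test_long_run_active_fraction(self):
        """Renewal theory: fraction of time active = mu / (mu + mu/9)."""
        params = SimParams(mu=0.19, total_time=1.0)
        topo = nucleolus_preset(12)
        state = init_configuration(topo, params, 5)
        rng = np.random.default_rng(5)
        dt = 0.002
        active_time = np.zeros(12)
        for _ in range(20_000):
            state, _ = update_activity(state, params, rng, dt,
                                       topo.nucleolar_mask)
            active_time += state.active * dt
        frac = active_time[1:-1].mean() / (20_000 * dt)
        assert abs(frac - 0.9) < 0.02

    def test_inactivation_breaks_links(self):
        params = SimParams(mu=0.1, total_time=1.0)
        topo = nucleolus_preset(4)
        state = state_at(np.zeros((4, 3)), params,
                         active=[False, True, True, False],
                         links=[(1, 2)])
        state.state_timer[:] = 1e-9  # all timers expire on the next tick
        rng = np.random.default_rng(0)
        out, broken = update_activity(state, params, rng, 0.01,
                                      topo.nucleolar_mask)
        assert broken == [(1, 2)]
        assert out.link_partner[1] == -1 and out.link_partner[2] == -1


class TestMatching:
    def make(self, positions, active):
        """Single all-nucleolar chain; non-adjacent beads can link."""
        params = SimParams(mu=0.1, total_time=1.0)
        n = len(positions)
        topo = nm.GenomeTopology(
            n_beads=n, chains=[(0, n - 1, None, None)],
            nucleolar_mask=np.ones(n, dtype=bool))
        return state_at(positions, params, active=active), topo, params

    def test_greedy_ascending_distance(self):
        """A=bead0, B=bead2, C=bead4 (mutually non-adjacent on the chain):
        d(A,B)=50, d(B,C)=60, d(A,C)=110 with d_link=90 links {A,B} only;
        C stays unmatched.  Beads 1 and 3 are parked far away, inactive."""
        far = 5000.0
        pos = [[0, 0, 0], [0, far, 0], [50.0, 0, 0], [0, far, far],
               [110.0, 0, 0]]
        state, topo, params = self.make(
            pos, [True, False, True, False, True])
        out, formed = match_crosslinks(state, topo, params)
        assert formed == [(0, 2)]
        assert out.link_partner[4] == -1

    def test_chain_neighbors_never_link(self):
        params = SimParams(mu=0.1, total_time=1.0)
        topo = nucleolus_preset(4)
        pos = np.zeros((4, 3))
        pos[:, 0] = [0, 10, 20, 30]
        state = state_at(pos, params, active=[True] * 4)
        out, formed = match_crosslinks(state, topo, params)
        for i, j in formed:
            assert abs(i - j) > 1

    def test_inactive_beads_form_no_links(self):
        pos = np.zeros((3, 3))
        pos[1, 0] = 5000.0
        pos[2, 0] = 50.0
        state, topo, params = self.make(pos, [False, False, False])
        out, formed = match_crosslinks(state, topo, params)
        assert formed == []
        assert np.all(out.link_partner == -1)

    def test_one_link_per_bead(self, short_sim):
        for i, j, t_on, t_off in short_sim.link_log:
            assert abs(i - j) > 1
        # no bead holds two overlapping link intervals
        by_bead = {}
        for i, j, t_on, t_off in short_sim.link_log:
            for b in (int(i), int(j)):
                by_bead.setdefault(b, []).append((t_on, t_off))
        for ivs in by_bead.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 >= e1 - 1e-9


class TestSimulate:
    def test_contract_frames_and_invariants(self):
        topo = nucleolus_preset(30)
        params = SimParams(mu=0.09, total_time=5.0, seed=7,
                           nucleus_radius=400.0)
        traj = simulate(topo, params)
        assert traj.n_frames == 51
        r = np.linalg.norm(traj.positions, axis=2)
        assert np.all(r <= params.nucleus_radius + 1e-6)
        # tethered ends stay on the wall
        assert np.allclose(r[:, 0], params.nucleus_radius)
        assert np.allclose(r[:, -1], params.nucleus_radius)

    def test_chain_connectivity_bounded_by_contour(self, short_sim):
        L0 = short_sim.params.contour_length
        seg = np.linalg.norm(np.diff(short_sim.positions, axis=1), axis=2)
        assert seg.max() <= L0

    def test_same_seed_identical_positions(self):
        topo = nucleolus_preset(25)
        params = SimParams(mu=0.19, total_time=2.0, seed=3,
                           nucleus_radius=400.0)
        a = simulate(topo, params)
        b = simulate(topo, params)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.link_log, b.link_log)

    def test_link_log_legality(self, short_sim):
        ll = short_sim.link_log
        if len(ll):
            assert np.all(ll[:, 3] > ll[:, 2])
            nuc = short_sim.topology.nucleolar_mask
            assert nuc[ll[:, 0].astype(int)].all()
            assert nuc[ll[:, 1].astype(int)].all()

    def test_activity_duration_parameter_recovery(self):
        """Fitting a normal to logged active durations recovers
        (mu, mu/5) within 3 standard errors."""
        topo = nucleolus_preset(60)
        mu = 0.09
        params = SimParams(mu=mu, total_time=10.0, seed=21,
                           nucleus_radius=500.0)
        traj = simulate(topo, params)
        on = traj.activity_log[traj.activity_log[:, 1] == 1.0][:, 2]
        assert len(on) >= 1000
        se_mean = on.std(ddof=1) / math.sqrt(len(on))
        assert abs(on.mean() - mu) < 3 * se_mean
        se_sd = on.std(ddof=1) / math.sqrt(2 * (len(on) - 1))
        assert abs(on.std(ddof=1) - mu / 5) < 3 * se_sd

    def test_mean_link_lifetime_matches_renewal_oracle(self):
        """Observed link lifetimes agree with a renewal-process simulation
        of min(residual on-times of the two endpoints)."""
        topo = nucleolus_preset(60)
        mu = 0.09
        params = SimParams(mu=mu, total_time=10.0, seed=2,
                           nucleus_radius=500.0)
        traj = simulate(topo, params)
        ll = traj.link_log
        closed = ll[ll[:, 3] < params.total_time]
        lifetimes = closed[:, 3] - closed[:, 2]
        # oracle: event-driven renewal simulation of two independent on/off
        # beads; a link spans from both-active to the first inactivation
        rng = np.random.default_rng(0)

        def renewal_bead(T=2000.0):
            # (time, becomes_active) event list for one bead
            t, on, events = 0.0, True, []
            while t < T:
                dur = max(params.dt,
                          rng.normal(mu, mu / 5) if on
                          else rng.normal(mu / 9, mu / 45))
                t += dur
                on = not on
                events.append((t, on))
            return events

        a, b = renewal_bead(), renewal_bead()
        times = sorted(a + b)
        state = {id(a): True, id(b): True}
        lookup = {}
        for ev, who in sorted([(e, id(a)) for e in a] + [(e, id(b)) for e in b]):
            lookup.setdefault(ev[0], []).append((who, ev[1]))
        both_since, oracle_lt = None, []
        for t in sorted(lookup):
            for who, on in lookup[t]:
                state[who] = on
            if state[id(a)] and state[id(b)]:
                if both_since is None:
                    both_since = t
            else:
                if both_since is not None:
                    oracle_lt.append(t - both_since)
                    both_since = None
        oracle = float(np.mean(oracle_lt))
        assert lifetimes.mean() == pytest.approx(oracle, rel=0.25)

    def test_save_load_round_trip(self, tmp_path, short_sim):
        path = tmp_path / "traj.h5"
        short_sim.save(path)
        back = nm.Trajectory.load(path)
        assert np.allclose(back.positions, short_sim.positions)
        assert np.array_equal(back.topology.nucleolar_mask,
                              short_sim.topology.nucleolar_mask)
        assert back.params.mu == short_sim.params.mu
        assert np.allclose(back.link_log, short_sim.link_log)
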