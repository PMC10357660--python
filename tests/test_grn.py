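"""Boolean network update, behaviour state machine, mutation, fixtures."""

import numpy as np
import pytest

from evocpm.grn import (Behaviour, GRNGenome, GRNState, SensoryInput,
                        behaviour_update, grn_step, mutate_grn,
                        reset_grn, response_profile, steady_state_output,
                        N_PARAMS)
from evocpm.io_config import make_fixture_genome


def brute_force_step(genome, reg_states, conc, ndiv):
    """Independent oracle: direct elementwise evaluation of the update
    equations with plain Python loops."""
    s_in = [genome.phi[0] * conc, genome.phi[1] * ndiv]
    new_reg = []
    for i in range(3):
        r = 0.0
        for j in range(2):
            r += genome.w_in[j, i] * s_in[j]
        for k in range(3):
            r += genome.w_reg[k, i] * reg_states[k]
        new_reg.append(1 if r > genome.rho_reg[i] else 0)
    r_out = sum(genome.w_out[k] * reg_states[k] for k in range(3))
    new_out = 1 if r_out > genome.rho_out else 0
    return new_reg, new_out


class TestGRNStep:
    def test_zero_weights_positive_thresholds_stay_off(self):
        g = GRNGenome()
        g.rho_reg[:] = 0.1
        g.rho_out = 0.1
        s = grn_step(g, GRNState(), SensoryInput(25.0, 3))
        assert not s.regulatory.any() and s.output == 0

    def test_self_loop_latches(self):
        g = GRNGenome()
        g.w_reg[0, 0] = 1.0
        g.rho_reg[:] = 0.5
        g.rho_out = 10.0
        state = GRNState(regulatory=np.array([1, 0, 0], dtype=np.int8))
        for _ in range(5):
            state = grn_step(g, state, SensoryInput(0.0, 0))
            assert state.regulatory[0] == 1

    def test_threshold_ties_give_zero(self):
        g = GRNGenome()           # r = 0 and rho = 0 everywhere
        state = GRNState(regulatory=np.ones(3, dtype=np.int8))
        # w all zero: r_i = 0, rho_i = 0 -> strict comparison gives 0
        s = grn_step(g, state, SensoryInput(5.0, 1))
        assert not s.regulatory.any() and s.output == 0

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(1000):
            g = GRNGenome.random(rng, -2, 2)
            reg = rng.integers(0, 2, 3).astype(np.int8)
            conc = float(rng.uniform(0, 29))
            ndiv = int(rng.integers(0, 4))
            got = grn_step(g, GRNState(regulatory=reg.copy()),
                           SensoryInput(conc, ndiv))
            want_reg, want_out = brute_force_step(g, reg, conc, ndiv)
            assert got.regulatory.tolist() == want_reg
            assert got.output == want_out

    def test_deterministic(self, rng):
        g = GRNGenome.random(rng)
        s0 = GRNState(regulatory=np.array([1, 0, 1], dtype=np.int8))
        inp = SensoryInput(3.7, 2)
        a = grn_step(g, s0.copy(), inp)
        b = grn_step(g, s0.copy(), inp)
        assert a.regulatory.tolist() == b.regulatory.tolist()
        assert a.output == b.output

    def test_synchronous_update_uses_old_states_only(self):
        # chain reg0 -> reg1: reg1 must react one tick late
        g = GRNGenome()
        g.w_reg[0, 1] = 1.0
        g.rho_reg[:] = 0.5
        g.rho_reg[0] = -0.5      # reg0 switches on from zero input
        g.rho_out = 10.0
        s = grn_step(g, GRNState(), SensoryInput(0, 0))
        assert s.regulatory.tolist() == [1, 0, 0]
        s = grn_step(g, s, SensoryInput(0, 0))
        assert s.regulatory.tolist() == [1, 1, 0]


class TestReset:
    def test_reset_zeroes_everything(self):
        s = GRNState(regulatory=np.ones(3, dtype=np.int8), output=1,
                     output_one_streak=7)
        reset_grn(s)
        assert not s.regulatory.any()
        assert s.output == 0 and s.output_one_streak == 0

    def test_reset_idempotent(self):
        s = GRNState()
        assert reset_grn(reset_grn(s)) is s


class TestBehaviourStateMachine:
    ETA = 10000  # MCS of sustained output 1 before growth

    def run_ticks(self, outputs, divisions_done=0, max_div=3):
        state = GRNState()
        b = Behaviour.MIGRATORY
        history = []
        for o in outputs:
            state.output = o
            b = behaviour_update(b, state, divisions_done, max_div,
                                 self.ETA)
            history.append(b)
        return history

    def test_sustained_output_commits_to_growth(self):
        h = self.run_ticks([1] * 500)
        assert h[-2] == Behaviour.MIGRATORY   # 499 ticks: still waiting
        assert h[-1] == Behaviour.GROWING     # 500 * 20 MCS = eta_init

    def test_capped_cell_becomes_quiescent(self):
        h = self.run_ticks([1] * 600, divisions_done=3)
        assert h[-1] == Behaviour.QUIESCENT
        assert Behaviour.GROWING not in h

    def test_interruption_restarts_the_wait(self):
        outputs = [1] * 499 + [0] + [1] * 499
        h = self.run_ticks(outputs)
        assert h[499] == Behaviour.MIGRATORY
        assert Behaviour.GROWING not in h     # wait restarted from 0

    def test_output_zero_reverts_growth(self):
        state = GRNState()
        b = Behaviour.MIGRATORY
        for _ in range(500):
            state.output = 1
            b = behaviour_update(b, state, 0, 3, self.ETA)
        assert b == Behaviour.GROWING
        state.output = 0
        b = behaviour_update(b, state, 0, 3, self.ETA)
        assert b == Behaviour.MIGRATORY
        assert state.output_one_streak == 0

    def test_never_growing_at_division_cap(self, rng):
        for _ in range(200):
            state = GRNState(output=int(rng.integers(0, 2)),
                             output_one_streak=int(rng.integers(0, 1000)))
            b = behaviour_update(
                Behaviour(int(rng.integers(1, 4))), state, 3, 3, self.ETA)
            assert b != Behaviour.GROWING


class TestMutation:
    def test_zero_probability_identity(self, rng):
        g = GRNGenome.random(rng)
        assert mutate_grn(g, 0.0, 0.05, rng) == g

    def test_zero_sd_identity(self, rng):
        g = GRNGenome.random(rng)
        assert mutate_grn(g, 1.0, 0.0, rng) == g

    def test_mean_hit_count_matches_binomial(self, rng):
        g = GRNGenome.random(rng)
        mu, n = 0.02, 100_000
        hits = np.empty(n)
        v0 = g.to_vector()
        for k in range(n):
            hits[k] = (mutate_grn(g, mu, 0.05, rng).to_vector()
                       != v0).sum()
        expected = N_PARAMS * mu
        se = np.sqrt(N_PARAMS * mu * (1 - mu) / n)
        assert abs(hits.mean() - expected) < 3 * se

    def test_untouched_parameters_bit_identical(self, rng):
        g = GRNGenome.random(rng)
        m = mutate_grn(g, 0.3, 0.05, rng)
        same = m.to_vector() == g.to_vector()
        # unchanged entries are exact copies, not re-rounded values
        assert same.sum() + (~same).sum() == N_PARAMS
        assert same.any()


class TestFixtureStrategies:
    def test_division_counter_profile(self):
        bundle = make_fixture_genome("division_early_counter")
        prof = response_profile(bundle.grn, np.linspace(0, 28, 15),
                                range(4))
        assert (prof[:, :3] == 1).all()    # keeps dividing before cap
        assert (prof[:, 3] == 0).all()     # migrates after 3rd division

    def test_concentration_threshold_profile(self):
        c_star = 9.0
        bundle = make_fixture_genome("division_late_threshold",
                                     threshold_concentration=c_star)
        concs = np.linspace(0, 28, 57)
        prof = response_profile(bundle.grn, concs, range(4))
        for row, c in zip(prof, concs):
            assert (row == (1 if c >= c_star else 0)).all()

    def test_constitutive_fixtures(self):
        up = make_fixture_genome("constitutive_divider")
        down = make_fixture_genome("constitutive_migrator")
        assert steady_state_output(up.grn, 0.0, 0) == 1
        assert steady_state_output(down.grn, 28.0, 3) == 0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_fixture_genome("nope")
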