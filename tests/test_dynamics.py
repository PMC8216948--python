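import numpy as np
import pytest

from maternalcomp import (
    BAD,
    GOOD,
    CompetitionMatrix,
    ParameterError,
    SpeciesParams,
    classify_outcome,
    generate_environment,
    matching,
    none,
    realized_fecundity,
    silver_spoon,
    simulate,
)
from maternalcomp.dynamics import CommunityState, Trajectory, bh_step
from maternalcomp.environment import EnvSequence
from maternalcomp.presets import VULPIA_ALPHA, VULPIA_I, species_60_10


class TestBhStep:
    def test_direct_arithmetic(self):
        state = CommunityState(0, 2.0, 2.0)
        out = bh_step(state, 60.0, 60.0, CompetitionMatrix.neutral(), GOOD)
        assert out.n_i == pytest.approx(24.0)
        assert out.n_j == pytest.approx(24.0)
        assert out.t == 1

    def test_zero_abundance_is_absorbing(self):
        out = bh_step(CommunityState(0, 0.0, 5.0), 60.0, 60.0, CompetitionMatrix.neutral())
        assert out.n_i == 0.0

    def test_vulpia_good_year_hand_arithmetic(self):
        # N_i=2, N_j=2: 2*236 / (1 + 0.099*2 + 0.083*2) = 472/1.364
        out = bh_step(CommunityState(0, 2.0, 2.0), 236.0, 924.0, VULPIA_ALPHA, GOOD)
        assert out.n_i == pytest.approx(472 / 1.364)
        assert out.n_i == pytest.approx(346.04, abs=0.01)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ParameterError):
            bh_step(CommunityState(0, -1.0, 2.0), 60.0, 60.0, CompetitionMatrix.neutral())


class TestCompetitionMatrix:
    def test_neutral_preset(self):
        assert CompetitionMatrix.neutral().entries(GOOD) == (1.0, 1.0, 1.0, 1.0)

    def test_non_neutral_preset(self):
        assert CompetitionMatrix.non_neutral().entries(BAD) == (1.25, 1.0, 0.8, 1.0)

    def test_per_environment_entries(self):
        assert VULPIA_ALPHA.entries(GOOD) == (0.099, 0.083, 0.302, 0.456)
        assert VULPIA_ALPHA.entries(BAD) == (0.082, 0.002, 0.574, 0.515)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ParameterError):
            CompetitionMatrix(aii=-0.5)


def _naive_simulation(species_i, species_j, alphas, env, intro_time, intro_abundance, threshold):
    """Deliberately plain re-implementation used as an independent oracle."""
    T = len(env)
    ni = [0.0] * T
    nj = [0.0] * T
    ni[intro_time - 1] = intro_abundance
    nj[intro_time - 1] = intro_abundance
    for idx in range(intro_time - 1, T - 1):
        e_m, e_o = env[idx - 1], env[idx]
        li = realized_fecundity(species_i, e_m, e_o)
        lj = realized_fecundity(species_j, e_m, e_o)
        aii, aij, aji, ajj = alphas.entries(e_o)
        a = ni[idx] * li / (1.0 + aii * ni[idx] + aij * nj[idx])
        b = nj[idx] * lj / (1.0 + ajj * nj[idx] + aji * ni[idx])
        ni[idx + 1] = a if a >= threshold else 0.0
        nj[idx + 1] = b if b >= threshold else 0.0
    return np.array(ni), np.array(nj)


class TestSimulate:
    def test_identical_species_stay_identical(self):
        env = generate_environment(200, 0.5, 0.5, seed=3)
        sp = species_60_10("i", silver_spoon())
        traj = simulate(sp, sp, CompetitionMatrix.neutral(), env)
        assert np.array_equal(traj.n_i, traj.n_j)

    def test_single_species_fixed_point(self):
        """In a constant good environment with no maternal effect the total
        abundance settles on the Beverton-Holt fixed point
        N* = (lambda - 1)/alpha = 59; with an identical neutral pair the total
        follows the single-species map exactly."""
        env = generate_environment(200, 1.0, 1.0, seed=0)
        sp = species_60_10("i")
        solo = simulate(sp, species_60_10("j"), CompetitionMatrix.neutral(), env,
                        extinction_threshold=0.0)
        assert abs(solo.n_i[-1] + solo.n_j[-1] - 59.0) < 1e-6

    def test_determinism(self):
        env = generate_environment(300, 0.4, 0.5, seed=8)
        cfg = dict(intro_time=2, intro_abundance=2.0, extinction_threshold=1.0)
        a = simulate(species_60_10("i"), species_60_10("j", matching()),
                     CompetitionMatrix.neutral(), env, **cfg)
        b = simulate(species_60_10("i"), species_60_10("j", matching()),
                     CompetitionMatrix.neutral(), env, **cfg)
        assert a.n_i.tobytes() == b.n_i.tobytes()
        assert a.n_j.tobytes() == b.n_j.tobytes()

    def test_label_swap_symmetry(self):
        """Swapping species roles (and transposing alpha) swaps the series."""
        env = generate_environment(150, 0.3, 0.5, seed=5)
        si = species_60_10("i", silver_spoon())
        sj = species_60_10("j", matching())
        alphas = CompetitionMatrix.non_neutral()
        fwd = simulate(si, sj, alphas, env)
        rev = simulate(sj, si, alphas.transposed(), env)
        assert np.array_equal(fwd.n_i, rev.n_j)
        assert np.array_equal(fwd.n_j, rev.n_i)

    def test_matches_naive_oracle_on_random_instances(self):
        """The optimized loop agrees with a plainly coded one to the last bit
        on 20 random parameter draws."""
        rng = np.random.default_rng(2024)
        strategies = [none, silver_spoon, matching]
        for _ in range(20):
            env = generate_environment(80, rng.uniform(0, 1), 0.5, seed=int(rng.integers(1e6)))
            si = SpeciesParams("i", rng.uniform(5, 300), rng.uniform(5, 300),
                               strategies[rng.integers(3)]())
            sj = SpeciesParams("j", rng.uniform(5, 300), rng.uniform(5, 300),
                               strategies[rng.integers(3)]())
            alphas = CompetitionMatrix(*(tuple(rng.uniform(0.01, 1.5, 2)) for _ in range(4)))
            thr = float(rng.choice([0.0, 1e-6, 1.0]))
            traj = simulate(si, sj, alphas, env, extinction_threshold=thr)
            oi, oj = _naive_simulation(si, sj, alphas, env, 2, 2.0, thr)
            assert np.array_equal(traj.n_i, oi)
            assert np.array_equal(traj.n_j, oj)

    def test_abundances_zero_before_introduction(self):
        env = generate_environment(50, 0.5, 0.5, seed=1)
        traj = simulate(species_60_10("i"), species_60_10("j"),
                        CompetitionMatrix.neutral(), env, intro_time=10)
        assert np.all(traj.n_i[:9] == 0)
        assert traj.n_i[9] == 2.0

    def test_intro_time_before_maternal_env_rejected(self):
        env = generate_environment(50, 0.5, 0.5, seed=1)
        with pytest.raises(ParameterError):
            simulate(species_60_10("i"), species_60_10("j"),
                     CompetitionMatrix.neutral(), env, intro_time=1)


class TestClassifyOutcome:
    def _traj(self, fi, fj):
        env = generate_environment(5, 0.5, 0.5, seed=0)
        n = np.zeros(5)
        ni, nj = n.copy(), n.copy()
        ni[-1], nj[-1] = fi, fj
        return Trajectory(env=env, n_i=ni, n_j=nj)

    def test_final_state_labels(self):
        assert classify_outcome(self._traj(0.0, 50.0)) == "only_j"
        assert classify_outcome(self._traj(30.0, 30.0)) == "both"
        assert classify_outcome(self._traj(12.0, 0.0)) == "only_i"

    def test_neither_warns(self):
        with pytest.warns(RuntimeWarning):
            assert classify_outcome(self._traj(0.0, 0.0)) == "neither"

    def test_matching_species_excluded_under_strict_alternation(self):
        """At k=0 the matching phenotype is penalized every generation after
        the first, so the no-effect species always wins."""
        env = generate_environment(500, 0.0, 0.5, seed=17)
        traj = simulate(species_60_10("i"), species_60_10("j", matching()),
                        CompetitionMatrix.neutral(), env)
        assert classify_outcome(traj) == "only_i"

    def test_silver_spoon_excluded_in_constant_bad(self):
        """Constant bad conditions: per-step fecundity 8 vs 10 drives the
        spoon species out."""
        env = generate_environment(500, 1.0, 0.0, seed=4)
        traj = simulate(species_60_10("i"), species_60_10("j", silver_spoon()),
                        CompetitionMatrix.neutral(), env)
        assert classify_outcome(traj) == "only_i"
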