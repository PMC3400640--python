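"""Sampler contracts: Metropolis, insertion provenance, annealing and
hill-climbing behaviour."""

import math

import numpy as np
import pytest

from edafold import PMFSet, TorsionDecoy
from edafold.fragments import decode_fragment_key, encode_fragment_key
from edafold.sampling import (SamplerParams, StageStep, _temperature,
                              default_schedule, hill_climb_iteration,
                              insert_fragment, iterated_hill_climb,
                              metropolis_accept, random_initial_decoy,
                              sample_and_minimize, simulated_annealing)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-1.0, t, rng) for t in (0.01, 1.0, 100.0))

    def test_acceptance_rate_matches_boltzmann(self):
        rng = np.random.default_rng(42)
        n = 100_000
        accepted = sum(metropolis_accept(1.0, 1.0, rng) for _ in range(n))
        assert accepted / n == pytest.approx(math.exp(-1.0), abs=0.01)

    def test_hopeless_move_rejected(self):
        rng = np.random.default_rng(7)
        # acceptance probability exp(-1000) ~ 0
        assert not any(metropolis_accept(10.0, 0.01, rng) for _ in range(100_000))

    def test_non_positive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)


class TestTemperatureSchedule:
    def test_endpoints(self):
        p = SamplerParams()
        n = 1000
        assert _temperature(0, n, p) == pytest.approx(p.t_init)
        assert _temperature(n - 1, n, p) == pytest.approx(p.t_final)

    def test_geometric_decay(self):
        p = SamplerParams()
        n = 101
        ts = np.array([_temperature(i, n, p) for i in range(n)])
        ratios = ts[1:] / ts[:-1]
        assert np.allclose(ratios, ratios[0])


class TestInsertFragment:
    def test_nine_mer_sets_provenance_keys(self, planted40, toy40):
        lib = planted40.lib9
        decoy = TorsionDecoy(toy40.sequence, np.zeros(40), np.zeros(40),
                             np.full(40, 180.0))
        frag = lib.fragment(1, 4)
        out = insert_fragment(decoy, frag, lib.n_per_window)
        for p in range(9):
            assert out.provenance[p] == encode_fragment_key(p, 4, lib.n_per_window)
        assert np.all(out.provenance[9:] == -1)
        np.testing.assert_array_equal(out.phi[:9], frag.torsions[:, 0])

    def test_three_mer_preserves_provenance(self, planted40, toy40):
        decoy = TorsionDecoy(toy40.sequence, np.zeros(40), np.zeros(40),
                             np.full(40, 180.0))
        decoy = insert_fragment(decoy, planted40.lib9.fragment(1, 2),
                                planted40.lib9.n_per_window)
        before = decoy.provenance.copy()
        out = insert_fragment(decoy, planted40.lib3.fragment(2, 5))
        np.testing.assert_array_equal(out.provenance, before)
        np.testing.assert_array_equal(
            out.phi[1:4], planted40.lib3.fragment(2, 5).torsions[:, 0]
        )

    def test_idempotent_on_torsions(self, planted40, toy40):
        decoy = TorsionDecoy(toy40.sequence, np.zeros(40), np.zeros(40),
                             np.full(40, 180.0))
        frag = planted40.lib9.fragment(5, 3)
        once = insert_fragment(decoy, frag, planted40.lib9.n_per_window)
        twice = insert_fragment(once, frag, planted40.lib9.n_per_window)
        np.testing.assert_array_equal(once.phi, twice.phi)

    def test_overlapping_insertion_newer_keys_win(self, planted40, toy40):
        lib = planted40.lib9
        decoy = TorsionDecoy(toy40.sequence, np.zeros(40), np.zeros(40),
                             np.full(40, 180.0))
        decoy = insert_fragment(decoy, lib.fragment(1, 2), lib.n_per_window)
        decoy = insert_fragment(decoy, lib.fragment(4, 7), lib.n_per_window)
        # residues 4..12 (1-based) now belong to the window-4 insertion
        for r in range(3, 12):
            p, k = decode_fragment_key(int(decoy.provenance[r]), lib.n_per_window)
            assert k == 7 and r - p == 3
        for r in range(3):
            p, k = decode_fragment_key(int(decoy.provenance[r]), lib.n_per_window)
            assert k == 2 and r - p == 0

    def test_out_of_bounds_rejected(self, planted40, toy40):
        from edafold.fragments import Fragment
        decoy = TorsionDecoy(toy40.sequence, np.zeros(40), np.zeros(40),
                             np.full(40, 180.0))
        bad = Fragment(40, np.zeros((9, 3)), 0)
        with pytest.raises(ValueError):
            insert_fragment(decoy, bad, planted40.lib9.n_per_window)


def _uniform_pmfs(lib, top_k=None):
    return PMFSet.uniform(lib.n_windows, lib.n_per_window, top_k=top_k)


class TestSimulatedAnnealing:
    def test_zero_moves_is_identity(self, toy40, planted40, scorer40,
                                    desk_params, rng):
        start = random_initial_decoy(toy40.sequence, planted40.lib9,
                                     desk_params, rng)
        out = simulated_annealing(start, planted40.lib9, planted40.lib3,
                                  _uniform_pmfs(planted40.lib9), 0, 0,
                                  desk_params, rng, scorer40)
        np.testing.assert_array_equal(out.phi, start.phi)
        np.testing.assert_array_equal(out.provenance, start.provenance)

    def test_stage0_reduces_clash(self, toy40, planted40, scorer40, desk_params):
        rng = np.random.default_rng(3)
        start = random_initial_decoy(toy40.sequence, planted40.lib9,
                                     desk_params, rng)
        e0 = scorer40.score_decoy(start, 0)
        out = simulated_annealing(start, planted40.lib9, planted40.lib3,
                                  _uniform_pmfs(planted40.lib9), 0, 2000,
                                  desk_params, rng, scorer40)
        assert scorer40.score_decoy(out, 0) <= e0

    def test_concentrated_pmfs_reach_native(self, toy40, planted40, scorer40):
        """All PMF mass on the planted ranks drives annealing below 1 A."""
        from edafold import build_backbone, carmsd
        lib = planted40.lib9
        probs = np.zeros((lib.n_windows, lib.n_per_window))
        for start, rank in planted40.manifest9.items():
            probs[start - 1, rank] = 1.0
        pmfs = PMFSet(probs=probs)
        params = SamplerParams.desk(frag9_prob=1.0, top_k_ranks=lib.n_per_window)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d = random_initial_decoy(toy40.sequence, lib, params, rng)
            d = simulated_annealing(d, lib, None, pmfs, 3, 800, params, rng,
                                    scorer40)
            if carmsd(build_backbone(d), toy40.native_coords) < 1.0:
                hits += 1
        assert hits >= 9

    def test_seeded_determinism(self, toy40, planted40, scorer40, desk_params):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            d = random_initial_decoy(toy40.sequence, planted40.lib9,
                                     desk_params, rng)
            d = simulated_annealing(d, planted40.lib9, planted40.lib3,
                                    _uniform_pmfs(planted40.lib9), 1, 200,
                                    desk_params, rng, scorer40)
            outs.append(d)
        np.testing.assert_array_equal(outs[0].phi, outs[1].phi)
        assert outs[0].energy == outs[1].energy

    def test_energy_cache_consistent(self, toy40, planted40, scorer40,
                                     desk_params):
        rng = np.random.default_rng(5)
        d = random_initial_decoy(toy40.sequence, planted40.lib9, desk_params,
                                 rng)
        d = simulated_annealing(d, planted40.lib9, planted40.lib3,
                                _uniform_pmfs(planted40.lib9), 2, 300,
                                desk_params, rng, scorer40)
        assert d.energy == pytest.approx(scorer40.score_decoy(d, 2), abs=1e-9)


class _RecordingRNG:
    """Delegating proxy that records permutation calls."""

    def __init__(self, rng):
        self._rng = rng
        self.permutations = []

    def permutation(self, n):
        p = self._rng.permutation(n)
        self.permutations.append(p.copy())
        return p

    def __getattr__(self, name):
        return getattr(self._rng, name)


class TestHillClimb:
    def test_never_increases_energy(self, toy40, planted40, scorer40,
                                    desk_params):
        pmfs = _uniform_pmfs(planted40.lib9, desk_params.top_k_ranks)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d = random_initial_decoy(toy40.sequence, planted40.lib9,
                                     desk_params, rng)
            e0 = scorer40.score_decoy(d, 3)
            out = hill_climb_iteration(d, planted40.lib9, planted40.lib3,
                                       pmfs, 3, desk_params, rng, scorer40)
            assert out.energy <= e0 + 1e-12

    def test_local_minimum_unchanged(self, toy40, planted40, scorer40):
        """Native with all PMF mass on planted ranks: every candidate
        insertion re-inserts the native torsions, which never strictly
        decreases energy, so the decoy is untouched."""
        lib = planted40.lib9
        probs = np.zeros((lib.n_windows, lib.n_per_window))
        for start, rank in planted40.manifest9.items():
            probs[start - 1, rank] = 1.0
        params = SamplerParams.desk(top_k_ranks=lib.n_per_window)
        rng = np.random.default_rng(0)
        out = hill_climb_iteration(toy40.native, lib, planted40.lib3,
                                   PMFSet(probs=probs), 3, params, rng,
                                   scorer40)
        np.testing.assert_array_equal(out.phi, toy40.native.phi)

    def test_visits_each_window_once(self, toy40, planted40, scorer40,
                                     desk_params):
        rec = _RecordingRNG(np.random.default_rng(1))
        d = random_initial_decoy(toy40.sequence, planted40.lib9, desk_params,
                                 np.random.default_rng(1))
        hill_climb_iteration(d, planted40.lib9, planted40.lib3,
                             _uniform_pmfs(planted40.lib9, 25), 3,
                             desk_params, rec, scorer40)
        assert len(rec.permutations) == 1
        assert sorted(rec.permutations[0]) == list(range(planted40.lib9.n_windows))


class TestIteratedHillClimb:
    def test_returns_best_visited(self, toy40, planted40, scorer40, desk_params):
        pmfs = _uniform_pmfs(planted40.lib9, desk_params.top_k_ranks)
        rng = np.random.default_rng(2)
        d = random_initial_decoy(toy40.sequence, planted40.lib9, desk_params,
                                 rng)
        e0 = scorer40.score_decoy(d, 3)
        out = iterated_hill_climb(d, planted40.lib9, planted40.lib3, pmfs, 3,
                                  desk_params, rng, scorer40)
        assert out.energy <= e0
        assert out.energy == pytest.approx(scorer40.score_decoy(out, 3),
                                           abs=1e-9)

    def test_single_iteration_equals_one_hill_climb(self, toy40, planted40,
                                                    scorer40):
        params = SamplerParams.desk(hc_iterations=1)
        pmfs = _uniform_pmfs(planted40.lib9, params.top_k_ranks)
        d0 = random_initial_decoy(toy40.sequence, planted40.lib9, params,
                                  np.random.default_rng(9))
        a = iterated_hill_climb(d0, planted40.lib9, planted40.lib3, pmfs, 3,
                                params, np.random.default_rng(4), scorer40)
        b = hill_climb_iteration(d0, planted40.lib9, planted40.lib3, pmfs, 3,
                                 params, np.random.default_rng(4), scorer40)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_escapes_local_minima_more_often(self, toy24, planted24, scorer24):
        """Three iterations beat a single sweep on most seeded starts."""
        lib9, lib3 = planted24.lib9, planted24.lib3
        p3 = SamplerParams.desk(hc_iterations=3)
        p1 = SamplerParams.desk(hc_iterations=1)
        pmfs = _uniform_pmfs(lib9, p3.top_k_ranks)
        wins = ties = 0
        n = 50
        for seed in range(n):
            d0 = random_initial_decoy(toy24.sequence, lib9, p3,
                                      np.random.default_rng(1000 + seed))
            e3 = iterated_hill_climb(d0, lib9, lib3, pmfs, 3, p3,
                                     np.random.default_rng(seed), scorer24).energy
            e1 = iterated_hill_climb(d0, lib9, lib3, pmfs, 3, p1,
                                     np.random.default_rng(seed), scorer24).energy
            if e3 < e1:
                wins += 1
            elif e3 == e1:
                ties += 1
        assert (wins + ties) / n >= 0.6


class TestSampleAndMinimize:
    def test_empty_schedule_returns_initial(self, toy40, planted40, scorer40,
                                            desk_params):
        pmfs = _uniform_pmfs(planted40.lib9, desk_params.top_k_ranks)
        ref = random_initial_decoy(toy40.sequence, planted40.lib9, desk_params,
                                   np.random.default_rng(21))
        out = sample_and_minimize(toy40.sequence, planted40.lib9,
                                  planted40.lib3, pmfs, [], desk_params,
                                  np.random.default_rng(21), scorer40)
        np.testing.assert_array_equal(out.phi, ref.phi)

    def test_seeded_determinism_bitwise(self, toy40, planted40, scorer40,
                                        desk_params):
        pmfs = _uniform_pmfs(planted40.lib9, desk_params.top_k_ranks)
        schedule = default_schedule(desk_params)
        a = sample_and_minimize(toy40.sequence, planted40.lib9, planted40.lib3,
                                pmfs, schedule, desk_params,
                                np.random.default_rng(8), scorer40)
        b = sample_and_minimize(toy40.sequence, planted40.lib9, planted40.lib3,
                                pmfs, schedule, desk_params,
                                np.random.default_rng(8), scorer40)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.psi, b.psi)
        assert a.energy == b.energy

    def test_improves_over_initialization(self, toy24, planted24, scorer24,
                                          desk_params):
        pmfs = _uniform_pmfs(planted24.lib9, desk_params.top_k_ranks)
        schedule = default_schedule(desk_params)
        finished, initial = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            initial.append(scorer24.score_decoy(
                random_initial_decoy(toy24.sequence, planted24.lib9,
                                     desk_params, np.random.default_rng(seed))
            ))
            finished.append(sample_and_minimize(
                toy24.sequence, planted24.lib9, planted24.lib3, pmfs,
                schedule, desk_params, rng, scorer24
            ).energy)
        assert np.mean(finished) < np.mean(initial)

    def test_energy_cache_matches_rescoring(self, toy40, planted40, scorer40,
                                            desk_params):
        pmfs = _uniform_pmfs(planted40.lib9, desk_params.top_k_ranks)
        out = sample_and_minimize(toy40.sequence, planted40.lib9,
                                  planted40.lib3, pmfs,
                                  default_schedule(desk_params), desk_params,
                                  np.random.default_rng(14), scorer40)
        assert out.energy == pytest.approx(scorer40.score_decoy(out), abs=1e-9)


class TestSchedule:
    def test_default_schedule_structure(self):
        params = SamplerParams()
        steps = default_schedule(params)
        assert [s.stage_id for s in steps] == [0, 1, 2, 2, 3, 3, 3, 3, 3, 3]
        sa_steps = [s for s in steps if s.protocol == "sa"]
        assert [s.sa_moves for s in sa_steps] == [2000, 2000, 2000,
                                                  4000, 4000, 4000, 4000]

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            StageStep(0, "bogus")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SamplerParams(t_init=0.4, t_final=0.5)
        with pytest.raises(ValueError):
            SamplerParams(hc_iterations=0)
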