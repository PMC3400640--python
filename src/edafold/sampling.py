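"""Sample-and-minimize: fragment-insertion simulated annealing followed by
iterated hill climbing, per energy stage.

One decoy is produced by (i) seeding the chain with uniform fragment
insertions covering every window in random order, then (ii) running a staged
schedule: annealing alone at the cheap early stages, annealing plus iterated
hill climbing once the energy reaches its fuller forms, with the annealing
move budget doubled in the extensive final stage.  9-mer proposals are drawn
by roulette over the current per-window PMFs; 3-mer proposals are uniform
over the top ranks (a deliberate diversity-preserving choice — PMFs are
learned on 9-mers only).  Every operation is a pure function of its inputs
and the supplied random generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .eda import PMFSet
from .energy import StagedScorer
from .exceptions import ConfigurationError
from .fragments import Fragment, FragmentLibrary, encode_fragment_key
from .geometry import TorsionDecoy


@dataclass
class SamplerParams:
    """Tunables of one sample-and-minimize run.

    Defaults are the full-scale operating point: 4000 extensive annealing
    moves (the non-extensive budget is half that), temperature 3.5 -> 0.5,
    3 hill-climbing iterations.  ``top_k_ranks`` restricts annealing and
    hill-climbing proposals to the best-ranked library entries for cost;
    perturbation moves ignore the restriction.  ``desk()`` returns a
    reduced-budget preset for laptop-scale experiments.
    """

    sa_moves_extensive: int = 4000
    t_init: float = 3.5
    t_final: float = 0.5
    hc_iterations: int = 3
    frag9_prob: float = 0.5
    top_k_ranks: int = 25
    hc_draw_cap: int = 25
    jitter_sigma: float = 0.0   # optional Gaussian phi/psi jitter after insertion

    def __post_init__(self):
        if not self.t_init > self.t_final > 0:
            raise ValueError("need t_init > t_final > 0")
        if self.sa_moves_extensive < 1:
            raise ValueError("sa_moves_extensive must be >= 1")
        if self.hc_iterations < 1:
            raise ValueError("hc_iterations must be >= 1")
        if not 0.0 <= self.frag9_prob <= 1.0:
            raise ValueError("frag9_prob must lie in [0, 1]")

    @property
    def sa_moves(self) -> int:
        """Non-extensive annealing budget (half the extensive one)."""
        return self.sa_moves_extensive // 2

    @classmethod
    def desk(cls, **overrides) -> "SamplerParams":
        """Laptop-scale preset: same protocol, reduced budgets."""
        kw = dict(sa_moves_extensive=200, hc_draw_cap=3)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class StageStep:
    """One schedule entry: an energy stage plus either an annealing pass of
    ``sa_moves`` moves ('sa') or one iterated-hill-climb run ('hc')."""

    stage_id: int
    protocol: str
    sa_moves: int = 0

    def __post_init__(self):
        if self.protocol not in ("sa", "hc"):
            raise ValueError("protocol must be 'sa' or 'hc'")


def default_schedule(params: SamplerParams) -> list[StageStep]:
    """Annealing alone in stages 0-1; annealing + hill climbing at stage 2;
    at stage 3 two passes of (anneal, anneal, hill-climb) with the doubled
    extensive move budget."""
    m = params.sa_moves
    m_ext = params.sa_moves_extensive
    steps = [
        StageStep(0, "sa", m),
        StageStep(1, "sa", m),
        StageStep(2, "sa", m),
        StageStep(2, "hc"),
    ]
    for _ in range(2):
        steps += [
            StageStep(3, "sa", m_ext),
            StageStep(3, "sa", m_ext),
            StageStep(3, "hc"),
        ]
    return steps


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Accept iff delta_e <= 0 or uniform(0,1) < exp(-delta_e / T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


def insert_fragment(decoy: TorsionDecoy, frag: Fragment,
                    n_per_window: int | None = None) -> TorsionDecoy:
    """Overwrite the covered residues' torsions with the fragment's.

    When ``n_per_window`` is given (9-mer insertions) each covered residue's
    provenance is set to ``encode(position, rank)``; 3-mer insertions pass
    ``None`` and leave the 9-mer attribution intact.  The energy cache is
    invalidated.  Returns a new decoy.
    """
    out = decoy.copy()
    _insert_inplace(out, frag.window_start, frag.torsions, frag.rank, n_per_window)
    out.energy = None
    return out


def _insert_inplace(decoy, window_start, torsions, rank, n_per_window):
    length = torsions.shape[0]
    lo = window_start - 1
    hi = lo + length
    if lo < 0 or hi > decoy.L:
        raise ValueError(
            f"window [{window_start}, {window_start + length - 1}] outside "
            f"1..{decoy.L}"
        )
    decoy.phi[lo:hi] = torsions[:, 0]
    decoy.psi[lo:hi] = torsions[:, 1]
    decoy.omega[lo:hi] = torsions[:, 2]
    if n_per_window is not None:
        decoy.provenance[lo:hi] = (
            np.arange(length, dtype=np.int64) * n_per_window + rank
        )


class _Mover:
    """Precomputed per-run state for fast in-place insertion moves."""

    def __init__(self, lib9: FragmentLibrary, lib3: FragmentLibrary | None,
                 pmfs: PMFSet, params: SamplerParams):
        if lib9.n_windows < 1:
            raise ConfigurationError("9-mer library has no insertion windows")
        if pmfs.n_windows != lib9.n_windows or pmfs.n_per_window != lib9.n_per_window:
            raise ConfigurationError("PMF set does not match the 9-mer library")
        self.t9 = lib9.torsion_tensor()
        self.n9 = lib9.n_per_window
        self.ws9 = lib9.window_size
        self.cdf9 = pmfs.proposal_cdfs(params.top_k_ranks)
        self.keys9 = (
            np.arange(self.ws9, dtype=np.int64)[:, None] * self.n9
            + np.arange(self.n9, dtype=np.int64)[None, :]
        )
        self.lib3 = lib3
        if lib3 is not None:
            self.t3 = lib3.torsion_tensor()
            self.ws3 = lib3.window_size
            self.k3 = min(params.top_k_ranks, lib3.n_per_window)
        self.sigma = params.jitter_sigma

    def apply9(self, decoy, w, rank, rng):
        """Insert 9-mer ``rank`` at window index ``w`` (0-based); returns an
        undo record."""
        lo, hi = w, w + self.ws9
        undo = (lo, hi, decoy.phi[lo:hi].copy(), decoy.psi[lo:hi].copy(),
                decoy.omega[lo:hi].copy(), decoy.provenance[lo:hi].copy())
        t = self.t9[w, rank]
        decoy.phi[lo:hi] = t[:, 0]
        decoy.psi[lo:hi] = t[:, 1]
        decoy.omega[lo:hi] = t[:, 2]
        decoy.provenance[lo:hi] = self.keys9[:, rank]
        if self.sigma > 0:
            decoy.phi[lo:hi] += rng.normal(0.0, self.sigma, hi - lo)
            decoy.psi[lo:hi] += rng.normal(0.0, self.sigma, hi - lo)
        return undo

    def apply3(self, decoy, w, rank, rng):
        lo, hi = w, w + self.ws3
        undo = (lo, hi, decoy.phi[lo:hi].copy(), decoy.psi[lo:hi].copy(),
                decoy.omega[lo:hi].copy(), decoy.provenance[lo:hi].copy())
        t = self.t3[w, rank]
        decoy.phi[lo:hi] = t[:, 0]
        decoy.psi[lo:hi] = t[:, 1]
        decoy.omega[lo:hi] = t[:, 2]
        if self.sigma > 0:
            decoy.phi[lo:hi] += rng.normal(0.0, self.sigma, hi - lo)
            decoy.psi[lo:hi] += rng.normal(0.0, self.sigma, hi - lo)
        return undo

    @staticmethod
    def undo(decoy, rec):
        lo, hi, phi, psi, omega, prov = rec
        decoy.phi[lo:hi] = phi
        decoy.psi[lo:hi] = psi
        decoy.omega[lo:hi] = omega
        decoy.provenance[lo:hi] = prov


def _temperature(step, n_moves, params):
    # geometric decay; first move at t_init, last at t_final
    if n_moves <= 1:
        return params.t_init
    frac = step / (n_moves - 1)
    return params.t_init * (params.t_final / params.t_init) ** frac


def simulated_annealing(decoy: TorsionDecoy, lib9: FragmentLibrary,
                        lib3: FragmentLibrary | None, pmfs: PMFSet,
                        stage_id: int, n_moves: int, params: SamplerParams,
                        rng: np.random.Generator,
                        scorer: StagedScorer) -> TorsionDecoy:
    """Metropolis fragment insertion with geometric temperature decay."""
    cur = decoy.copy()
    if n_moves == 0:
        return cur
    mover = _Mover(lib9, lib3, pmfs, params)
    nw9 = lib9.n_windows
    nw3 = lib3.n_windows if lib3 is not None else 0
    e = scorer.score(cur.phi, cur.psi, cur.omega, stage_id)
    for step in range(n_moves):
        temp = _temperature(step, n_moves, params)
        use9 = lib3 is None or rng.random() < params.frag9_prob
        if use9:
            w = int(rng.integers(nw9))
            rank = int(np.searchsorted(mover.cdf9[w], rng.random(), side="right"))
            undo = mover.apply9(cur, w, rank, rng)
        else:
            w = int(rng.integers(nw3))
            rank = int(rng.integers(mover.k3))
            undo = mover.apply3(cur, w, rank, rng)
        e_new = scorer.score(cur.phi, cur.psi, cur.omega, stage_id)
        if metropolis_accept(e_new - e, temp, rng):
            e = e_new
        else:
            mover.undo(cur, undo)
    cur.energy = e
    return cur


def hill_climb_iteration(decoy: TorsionDecoy, lib9: FragmentLibrary,
                         lib3: FragmentLibrary | None, pmfs: PMFSet,
                         stage_id: int, params: SamplerParams,
                         rng: np.random.Generator,
                         scorer: StagedScorer) -> TorsionDecoy:
    """One non-exhaustive local-search sweep.

    Visits every 9-mer insertion window exactly once in a random
    permutation; at each window draws up to ``hc_draw_cap`` distinct
    candidate ranks by roulette (without replacement) and keeps the first
    insertion that strictly decreases the stage energy.
    """
    cur = decoy.copy()
    mover = _Mover(lib9, lib3, pmfs, params)
    e = scorer.score(cur.phi, cur.psi, cur.omega, stage_id)
    cdf = mover.cdf9
    k_restricted = cdf.shape[1]
    for w in rng.permutation(lib9.n_windows):
        p = np.diff(cdf[w], prepend=0.0)
        n_support = int(np.count_nonzero(p > 0))
        m = min(params.hc_draw_cap, n_support)
        if m == 0:
            continue
        candidates = rng.choice(k_restricted, size=m, replace=False, p=p)
        for rank in candidates:
            undo = mover.apply9(cur, int(w), int(rank), rng)
            e_new = scorer.score(cur.phi, cur.psi, cur.omega, stage_id)
            if e_new < e:
                e = e_new
                break
            mover.undo(cur, undo)
    cur.energy = e
    return cur


def iterated_hill_climb(decoy: TorsionDecoy, lib9: FragmentLibrary,
                        lib3: FragmentLibrary | None, pmfs: PMFSet,
                        stage_id: int, params: SamplerParams,
                        rng: np.random.Generator,
                        scorer: StagedScorer) -> TorsionDecoy:
    """Alternate local search and random perturbation; return the best state
    visited.

    The perturbation is one 9-mer insertion drawn uniformly over *all*
    ranks — it deliberately ignores both the PMFs and the top-rank
    restriction, which is what lets the search escape the learned basin.
    No perturbation follows the last local search.
    """
    mover = _Mover(lib9, lib3, pmfs, params)
    cur = decoy
    best = None
    for it in range(params.hc_iterations):
        cur = hill_climb_iteration(cur, lib9, lib3, pmfs, stage_id, params,
                                   rng, scorer)
        if best is None or cur.energy < best.energy:
            best = cur.copy()
        if it < params.hc_iterations - 1:
            cur = cur.copy()
            w = int(rng.integers(lib9.n_windows))
            rank = int(rng.integers(lib9.n_per_window))
            mover.apply9(cur, w, rank, rng)
            cur.energy = scorer.score(cur.phi, cur.psi, cur.omega, stage_id)
    return best


def random_initial_decoy(sequence: str, lib9: FragmentLibrary,
                         params: SamplerParams,
                         rng: np.random.Generator) -> TorsionDecoy:
    """Seed a decoy by uniform fragment insertion covering every window in
    random order (ranks drawn from the restricted top range)."""
    L = len(sequence)
    if L != lib9.target_length:
        raise ConfigurationError(
            f"library target length {lib9.target_length} != sequence length {L}"
        )
    decoy = TorsionDecoy(
        sequence=sequence,
        phi=np.zeros(L), psi=np.zeros(L), omega=np.full(L, 180.0),
    )
    tensor = lib9.torsion_tensor()
    k = min(params.top_k_ranks, lib9.n_per_window)
    for w in rng.permutation(lib9.n_windows):
        rank = int(rng.integers(k))
        lo, hi = int(w), int(w) + lib9.window_size
        t = tensor[w, rank]
        decoy.phi[lo:hi] = t[:, 0]
        decoy.psi[lo:hi] = t[:, 1]
        decoy.omega[lo:hi] = t[:, 2]
        decoy.provenance[lo:hi] = (
            np.arange(lib9.window_size, dtype=np.int64) * lib9.n_per_window + rank
        )
    return decoy


def sample_and_minimize(sequence: str, lib9: FragmentLibrary,
                        lib3: FragmentLibrary | None, pmfs: PMFSet,
                        schedule: list[StageStep], params: SamplerParams,
                        rng: np.random.Generator,
                        scorer: StagedScorer) -> TorsionDecoy:
    """Produce one finished decoy: random initialization, then the staged
    schedule, with the final-stage energy cached on the result."""
    decoy = random_initial_decoy(sequence, lib9, params, rng)
    for step in schedule:
        if step.protocol == "sa":
            decoy = simulated_annealing(decoy, lib9, lib3, pmfs, step.stage_id,
                                        step.sa_moves, params, rng, scorer)
        else:
            decoy = iterated_hill_climb(decoy, lib9, lib3, pmfs, step.stage_id,
                                        params, rng, scorer)
    decoy.energy = scorer.score_decoy(decoy)
    decoy.iteration_born = pmfs.iteration
    return decoy
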