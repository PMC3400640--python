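"""Main loop: iterate (re-initialize population -> sample-and-minimize ->
select top fraction -> update PMFs) and accumulate the final decoy pool.

The population is regenerated from the sequence at every iteration; the
decoys used to estimate the distribution are not discarded but stored in the
final pool, so an equal fraction of the pool comes from each iteration.
Decoys within an iteration are embarrassingly parallel — the only
synchronization point is the PMF update between iterations — and per-decoy
seeds are derived from (master seed, iteration, index) so results do not
depend on scheduling or worker count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .eda import (DEFAULT_KAPPA, DEFAULT_TOP_FRACTION, PMFSet,
                  estimate_frequencies, select_top_decoys, update_pmfs)
from .energy import EnergyStage, StagedScorer, default_stages
from .fragments import FragmentLibrary
from .geometry import TorsionDecoy, build_backbone, carmsd, write_pdb
from .sampling import (SamplerParams, StageStep, default_schedule,
                       sample_and_minimize)

#: full-scale population size per iteration; desk-scale runs default to 100
FULL_SCALE_POOL = 50_000


@dataclass
class RunConfig:
    """Everything one prediction run needs, in memory."""

    sequence: str
    ss_target: str
    lib9: FragmentLibrary
    lib3: FragmentLibrary | None = None
    n_iterations: int = 4
    pool_per_iteration: int = 100
    top_fraction: float = DEFAULT_TOP_FRACTION
    kappa: float = DEFAULT_KAPPA
    sampler: SamplerParams = field(default_factory=SamplerParams)
    schedule: list[StageStep] | None = None
    stages: list[EnergyStage] | None = None
    seed: int = 0
    workers: int = 1

    def __post_init__(self):
        if self.n_iterations < 1 or self.pool_per_iteration < 1:
            raise ValueError("n_iterations and pool_per_iteration must be >= 1")


@dataclass
class DecoyPool:
    """All finished decoys across iterations, plus the PMF history."""

    decoys: list[TorsionDecoy]
    pmf_history: list[PMFSet]
    config: RunConfig | None = None
    carmsd: np.ndarray | None = None   # filled by evaluate_pool

    @property
    def energies(self) -> np.ndarray:
        return np.array([d.energy for d in self.decoys])

    @property
    def iterations_born(self) -> np.ndarray:
        return np.array([d.iteration_born for d in self.decoys])

    def from_iteration(self, t: int) -> list[TorsionDecoy]:
        return [d for d in self.decoys if d.iteration_born == t]

    def __len__(self) -> int:
        return len(self.decoys)


def decoy_rng(master_seed: int, iteration: int, index: int) -> np.random.Generator:
    """Scheduling-invariant per-decoy generator."""
    ss = np.random.SeedSequence((master_seed, iteration, index))
    return np.random.default_rng(ss)


def _make_decoy(args):
    (sequence, lib9, lib3, pmfs, schedule, params, scorer,
     master_seed, iteration, index) = args
    rng = decoy_rng(master_seed, iteration, index)
    return sample_and_minimize(sequence, lib9, lib3, pmfs, schedule, params,
                               rng, scorer)


def run_edafold(config: RunConfig, progress=None) -> DecoyPool:
    """Run the full iterated algorithm and return the accumulated pool.

    ``progress``, when given, is called after each finished decoy (the CLI
    hooks a progress bar in here).
    """
    scorer = StagedScorer(config.sequence, config.ss_target,
                          config.stages)
    schedule = (config.schedule if config.schedule is not None
                else default_schedule(config.sampler))
    pmfs = PMFSet.uniform(config.lib9.n_windows, config.lib9.n_per_window,
                          top_k=config.sampler.top_k_ranks)
    pool: list[TorsionDecoy] = []
    history: list[PMFSet] = [pmfs]
    for t in range(1, config.n_iterations + 1):
        jobs = [
            (config.sequence, config.lib9, config.lib3, pmfs, schedule,
             config.sampler, scorer, config.seed, t, i)
            for i in range(config.pool_per_iteration)
        ]
        if config.workers > 1:
            from joblib import Parallel, delayed
            decoys = Parallel(n_jobs=config.workers)(
                delayed(_make_decoy)(j) for j in jobs
            )
            if progress is not None:
                for _ in decoys:
                    progress()
        else:
            decoys = []
            for j in jobs:
                decoys.append(_make_decoy(j))
                if progress is not None:
                    progress()
        pool.extend(decoys)
        selected = select_top_decoys(decoys, config.top_fraction)
        freq = estimate_frequencies(selected, config.lib9.n_windows,
                                    config.lib9.n_per_window,
                                    window_size=config.lib9.window_size)
        pmfs = update_pmfs(pmfs, freq, config.kappa)
        history.append(pmfs)
    return DecoyPool(decoys=pool, pmf_history=history, config=config)


@dataclass
class PoolSummary:
    """Evaluation of a pool against a native structure."""

    n: int
    carmsd_top1: float                 # best CARMSD in the pool
    carmsd_top1pct_mean: float         # mean over the best 1% by CARMSD
    carmsd_by_energy_top1: float       # CARMSD of the lowest-energy decoy
    carmsd_by_energy_top1pct_mean: float
    fraction_below: pd.DataFrame       # threshold grid vs fraction, per iteration
    energy_hist: pd.DataFrame          # per-iteration energy histograms
    carmsd_hist: pd.DataFrame          # per-iteration CARMSD histograms
    scatter: pd.DataFrame              # energy vs CARMSD, per decoy

    def headline(self) -> dict:
        return {
            "n": self.n,
            "carmsd_top1": self.carmsd_top1,
            "carmsd_top1pct_mean": self.carmsd_top1pct_mean,
            "carmsd_by_energy_top1": self.carmsd_by_energy_top1,
            "carmsd_by_energy_top1pct_mean": self.carmsd_by_energy_top1pct_mean,
        }


def pool_carmsd(pool: DecoyPool, native) -> np.ndarray:
    """CARMSD of every decoy to the native CA trace; cached on the pool."""
    values = np.array(
        [carmsd(build_backbone(d), native) for d in pool.decoys]
    )
    pool.carmsd = values
    return values


def evaluate_pool(pool: DecoyPool, native,
                  thresholds=None, n_bins: int = 30) -> PoolSummary:
    """Summaries of prediction quality: best-by-CARMSD and best-by-energy
    averages, fraction-below-threshold curves and per-iteration histograms."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    rmsds = pool.carmsd if pool.carmsd is not None else pool_carmsd(pool, native)
    energies = pool.energies
    iters = pool.iterations_born
    n = len(pool)
    n_top = max(1, math.ceil(n / 100))
    by_rmsd = np.sort(rmsds)
    by_energy = rmsds[np.argsort(energies, kind="stable")]
    if thresholds is None:
        thresholds = np.linspace(0.0, 10.0, 21)

    frac_rows = []
    for thr in thresholds:
        row = {"threshold": thr, "all": float(np.mean(rmsds < thr))}
        for t in np.unique(iters):
            row[f"iter{t}"] = float(np.mean(rmsds[iters == t] < thr))
        frac_rows.append(row)
    fraction_below = pd.DataFrame(frac_rows)

    def _hists(values, label):
        edges = np.histogram_bin_edges(values, bins=n_bins)
        rows = []
        for t in np.unique(iters):
            h, _ = np.histogram(values[iters == t], bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], h):
                rows.append({"iteration": int(t), f"{label}_lo": lo,
                             f"{label}_hi": hi, "count": int(c)})
        return pd.DataFrame(rows)

    scatter = pd.DataFrame(
        {"energy": energies, "carmsd": rmsds, "iteration": iters}
    )
    return PoolSummary(
        n=n,
        carmsd_top1=float(by_rmsd[0]),
        carmsd_top1pct_mean=float(by_rmsd[:n_top].mean()),
        carmsd_by_energy_top1=float(by_energy[0]),
        carmsd_by_energy_top1pct_mean=float(by_energy[:n_top].mean()),
        fraction_below=fraction_below,
        energy_hist=_hists(energies, "energy"),
        carmsd_hist=_hists(rmsds, "carmsd"),
        scatter=scatter,
    )


@dataclass
class CompareReport:
    """Two-sided Mann-Whitney U comparison of two pools on one metric."""

    metric: str
    u_statistic: float
    p_value: float
    direction: str          # 'a_lower', 'b_lower' or 'none'
    n_a: int
    n_b: int
    underpowered: bool
    alpha: float


def mann_whitney_report(a, b, metric: str, alpha: float = 0.05) -> CompareReport:
    """Two-sided Mann-Whitney U on two per-decoy value arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(a, b):
        # identical samples: every rank comparison ties
        u, p = float(len(a)) * len(b) / 2.0, 1.0
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    if p < alpha:
        direction = "a_lower" if np.median(a) < np.median(b) else "b_lower"
    else:
        direction = "none"
    return CompareReport(
        metric=metric, u_statistic=float(u), p_value=float(p),
        direction=direction, n_a=len(a), n_b=len(b),
        underpowered=min(len(a), len(b)) < 8, alpha=alpha,
    )


def compare_pools(pool_a: DecoyPool, pool_b: DecoyPool, metric: str = "carmsd",
                  alpha: float = 0.05) -> CompareReport:
    """Mann-Whitney U test on per-decoy CARMSD or energy."""
    def _values(pool):
        if metric == "energy":
            return pool.energies
        if metric == "carmsd":
            if pool.carmsd is None:
                raise ValueError(
                    "pools must be evaluated against a native before a "
                    "CARMSD comparison"
                )
            return pool.carmsd
        raise ValueError(f"unknown metric {metric!r}")

    return mann_whitney_report(_values(pool_a), _values(pool_b), metric, alpha)


def write_pool(pool: DecoyPool, out_dir, native=None) -> Path:
    """Write per-decoy PDBs, an index TSV, per-iteration PMF TSVs and a
    summary JSON.  Returns the output directory."""
    out_dir = Path(out_dir)
    decoy_dir = out_dir / "decoys"
    decoy_dir.mkdir(parents=True, exist_ok=True)
    rmsds = None
    if native is not None:
        rmsds = pool.carmsd if pool.carmsd is not None else pool_carmsd(pool, native)
    rows = []
    for i, d in enumerate(pool.decoys):
        name = f"decoy_{i:06d}.pdb"
        write_pdb(d, build_backbone(d), decoy_dir / name)
        rows.append({
            "decoy": name,
            "iteration": d.iteration_born,
            "energy": d.energy,
            "carmsd": float(rmsds[i]) if rmsds is not None else float("nan"),
        })
    pd.DataFrame(rows).to_csv(out_dir / "index.tsv", sep="\t", index=False)
    for pmfs in pool.pmf_history:
        rows = []
        for w in range(pmfs.n_windows):
            for k in range(pmfs.n_per_window):
                rows.append({"window_start": w + 1, "rank": k,
                             "probability": pmfs.probs[w, k]})
        pd.DataFrame(rows).to_csv(
            out_dir / f"pmfs_iter{pmfs.iteration}.tsv", sep="\t", index=False
        )
    if native is not None:
        summary = evaluate_pool(pool, native)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary.headline(), fh, indent=2)
        summary.fraction_below.to_csv(out_dir / "fraction_below.csv", index=False)
        summary.scatter.to_csv(out_dir / "energy_vs_carmsd.csv", index=False)
        summary.energy_hist.to_csv(out_dir / "energy_hist.csv", index=False)
        summary.carmsd_hist.to_csv(out_dir / "carmsd_hist.csv", index=False)
    return out_dir
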