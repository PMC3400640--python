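"""Estimation-of-distribution core: per-window PMFs over fragment ranks.

The learned state of the search is one probability mass function per 9-mer
insertion window, defined over fragment ranks.  After each iteration the
lowest-energy fraction of the population is selected, the observed frequency
of each fragment in those decoys is reconstructed from residue provenance
keys, and the PMFs are relaxed toward the frequencies under a conservation
rate kappa:

    P_{t+1}(k) = kappa * P_t(k) + (1 - kappa) * F_t(k)

kappa = 1 freezes the PMFs (the uniform-proposal control arm); kappa = 0
replaces them outright.  Fragment selection during sampling is roulette-wheel
over the current PMF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fragments import decode_fragment_key
from .geometry import TorsionDecoy

DEFAULT_TOP_FRACTION = 15.0
DEFAULT_KAPPA = 0.6
_NORM_TOL = 1e-6


@dataclass
class PMFSet:
    """Per-window probability vectors over fragment ranks.

    ``probs`` has shape (n_windows, N); row ``w`` is the PMF of window start
    ``w + 1``.  ``iteration`` is the EDA iteration the set will drive.
    """

    probs: np.ndarray
    iteration: int = 1
    window_size: int = 9

    @classmethod
    def uniform(cls, n_windows: int, n_per_window: int,
                top_k: int | None = None, window_size: int = 9) -> "PMFSet":
        """Iteration-1 state: uniform mass, restricted to the first ``top_k``
        ranks when a rank restriction is active."""
        probs = np.zeros((n_windows, n_per_window))
        k = n_per_window if top_k is None else min(top_k, n_per_window)
        probs[:, :k] = 1.0 / k
        return cls(probs=probs, iteration=1, window_size=window_size)

    @property
    def n_windows(self) -> int:
        return self.probs.shape[0]

    @property
    def n_per_window(self) -> int:
        return self.probs.shape[1]

    def validate(self) -> None:
        if np.any(self.probs < 0):
            raise ValueError("PMFs must be non-negative")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("every PMF must sum to 1")

    def proposal_cdfs(self, top_k: int | None = None) -> np.ndarray:
        """Cumulative distributions for roulette proposals, restricted and
        renormalized to the first ``top_k`` ranks."""
        k = self.n_per_window if top_k is None else min(top_k, self.n_per_window)
        p = self.probs[:, :k].copy()
        s = p.sum(axis=1, keepdims=True)
        # a window whose mass escaped the restricted range falls back to uniform
        empty = s[:, 0] <= 0
        if np.any(empty):
            p[empty] = 1.0 / k
            s = p.sum(axis=1, keepdims=True)
        cdf = np.cumsum(p / s, axis=1)
        cdf[:, -1] = 1.0
        return cdf


@dataclass
class FrequencyTable:
    """Observed per-window fragment frequencies in the selected decoys."""

    freqs: np.ndarray            # (n_windows, N), rows sum to 1 or are all 0
    empty: np.ndarray            # (n_windows,) bool: no attribution survived


def select_top_decoys(pool: list[TorsionDecoy], fraction: float) -> list[TorsionDecoy]:
    """The ceil(|pool| * fraction / 100) lowest-energy decoys, stable order."""
    if not pool:
        raise ValueError("empty decoy pool")
    if not 0 < fraction <= 100:
        raise ValueError("fraction must be in (0, 100]")
    n_keep = math.ceil(len(pool) * fraction / 100.0)
    order = np.argsort([d.energy for d in pool], kind="stable")
    return [pool[i] for i in order[:n_keep]]


def estimate_frequencies(selected: list[TorsionDecoy], n_windows: int,
                         n_per_window: int, window_size: int = 9,
                         min_agreement: int = 5) -> FrequencyTable:
    """Reconstruct per-window fragment frequencies from provenance keys.

    Each attributed residue decodes to (position-in-window p, rank k) and
    votes for rank k at window ``residue - p``.  A decoy contributes one
    count to (w, k) when at least ``min_agreement`` of the window's residues
    agree — full window_size/window_size agreement is routinely destroyed by
    later overlapping insertions, so majority attribution is used
    (set ``min_agreement=window_size`` for strict mode).
    """
    counts = np.zeros((n_windows, n_per_window))
    for decoy in selected:
        keys = decoy.provenance
        attributed = np.nonzero(keys >= 0)[0]
        if attributed.size == 0:
            continue
        votes = np.zeros((n_windows, n_per_window), dtype=np.int32)
        for r in attributed:
            p, k = decode_fragment_key(int(keys[r]), n_per_window)
            if p >= window_size:
                raise ValueError(
                    f"provenance key {keys[r]} out of range for window size "
                    f"{window_size}"
                )
            w = r - p
            if 0 <= w < n_windows:
                votes[w, k] += 1
        counts += votes >= min_agreement
    sums = counts.sum(axis=1, keepdims=True)
    empty = sums[:, 0] == 0
    freqs = np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)
    return FrequencyTable(freqs=freqs, empty=empty)


def update_pmfs(prev: PMFSet, freq: FrequencyTable, kappa: float) -> PMFSet:
    """Linear mixing update; empty-frequency windows keep their PMF."""
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    if freq.freqs.shape != prev.probs.shape:
        raise ValueError("frequency table shape mismatch")
    if kappa == 1.0:
        # exact fixed point; skip renormalization so the control arm is
        # bit-stable across iterations
        return PMFSet(prev.probs.copy(), prev.iteration + 1, prev.window_size)
    new = kappa * prev.probs + (1.0 - kappa) * freq.freqs
    new[freq.empty] = prev.probs[freq.empty]
    new /= new.sum(axis=1, keepdims=True)
    return PMFSet(probs=new, iteration=prev.iteration + 1,
                  window_size=prev.window_size)


def roulette_select(pmf: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a rank with probability pmf[rank] (inverse-CDF lookup)."""
    pmf = np.asarray(pmf, dtype=float)
    if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > _NORM_TOL:
        raise ValueError("pmf must be non-negative and sum to 1")
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    return int(np.searchsorted(cdf, rng.random(), side="right"))
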