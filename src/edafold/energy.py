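"""Staged coarse-grained energy.

Four CA-level terms mirror the progressive structure of coarse-grained
fragment assembly scoring: a steric clash term alone in the first stage, then
local secondary-structure agreement, chain compaction and hydrophobic
contacts switched on stage by stage.  The search engine is agnostic to the
scorer: anything exposing ``score(phi, psi, omega, stage_id)`` can be
plugged in.

Terms (all rigid-transform invariant — they depend only on internal
distances and torsions):

``clash``     sum over CA pairs (|i-j| >= 3) of max(0, 4.0 - d)^2
``rg``        (Rg - 2.2 * L**0.38)^2, Rg the CA radius of gyration
``contact``   -1 per hydrophobic pair (|i-j| >= 4) within 8 A
``ss_local``  count of residues whose (phi, psi) falls outside the basin of
              the target secondary structure (H/E; L is always inside)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import _kernels
from .exceptions import ConfigurationError
from .geometry import BackboneCoords, TorsionDecoy, build_backbone

TERMS = ("clash", "rg", "contact", "ss_local")

HYDROPHOBIC = frozenset("AVLIMFWYC")

D_CLASH = _kernels.D_CLASH
CONTACT_CUTOFF = _kernels.CONTACT_CUTOFF
RG_COEF = _kernels.RG_COEF
RG_EXP = _kernels.RG_EXP

_SS_CODE = {"H": 0, "E": 1, "L": 2}


@dataclass(frozen=True)
class EnergyStage:
    """One stage: an id and non-negative weights for the active terms."""

    stage_id: int
    weights: Mapping[str, float]

    def weight_vector(self) -> np.ndarray:
        for name in self.weights:
            if name not in TERMS:
                raise ConfigurationError(f"unknown energy term {name!r}")
        return np.array([float(self.weights.get(t, 0.0)) for t in TERMS])


def default_stages() -> list[EnergyStage]:
    """Progressive term enabling: steric only first, full set last."""
    return [
        EnergyStage(0, {"clash": 1.0}),
        EnergyStage(1, {"clash": 1.0, "ss_local": 1.0}),
        EnergyStage(2, {"clash": 1.0, "ss_local": 1.0, "rg": 1.0}),
        EnergyStage(3, {"clash": 1.0, "ss_local": 1.0, "rg": 1.0, "contact": 1.0}),
    ]


def validate_stages(stages: list[EnergyStage]) -> None:
    """Active-term sets must grow monotonically across stages."""
    prev: set[str] = set()
    for s in stages:
        active = {t for t, w in s.weights.items() if w != 0.0}
        if not prev <= active:
            raise ConfigurationError(
                f"stage {s.stage_id} drops terms {prev - active} active earlier"
            )
        prev = active


def hydrophobic_mask(sequence: str) -> np.ndarray:
    return np.array([c in HYDROPHOBIC for c in sequence], dtype=np.uint8)


def ss_codes(ss_target: str) -> np.ndarray:
    try:
        return np.array([_SS_CODE[c] for c in ss_target], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid secondary-structure character {exc}") from None


def score_clash(coords: BackboneCoords) -> float:
    return float(_kernels.clash_score(np.ascontiguousarray(coords.ca)))


def score_rg(coords: BackboneCoords) -> float:
    if coords.L < 2:
        raise ValueError("radius of gyration needs at least 2 residues")
    return float(_kernels.rg_score(np.ascontiguousarray(coords.ca)))


def score_contact(coords: BackboneCoords, sequence: str) -> float:
    if len(sequence) != coords.L:
        raise ValueError("sequence/coords length mismatch")
    return float(
        _kernels.contact_score(
            np.ascontiguousarray(coords.ca), hydrophobic_mask(sequence)
        )
    )


def score_ss_local(decoy: TorsionDecoy, ss_target: str) -> float:
    if len(ss_target) != decoy.L:
        raise ValueError("ss_target length mismatch")
    return float(_kernels.ss_local_score(decoy.phi, decoy.psi, ss_codes(ss_target)))


def score_total(decoy: TorsionDecoy, coords: BackboneCoords,
                stage: EnergyStage, ss_target: str) -> float:
    """Weighted sum of active terms; lower is better."""
    w = stage.weight_vector()
    e = 0.0
    if w[0]:
        e += w[0] * score_clash(coords)
    if w[1]:
        e += w[1] * score_rg(coords)
    if w[2]:
        e += w[2] * score_contact(coords, decoy.sequence)
    if w[3]:
        e += w[3] * score_ss_local(decoy, ss_target)
    return float(e)


class StagedScorer:
    """Binds a target (sequence + secondary-structure string) to the staged
    energy so the sampler can score torsion arrays directly."""

    def __init__(self, sequence: str, ss_target: str,
                 stages: list[EnergyStage] | None = None):
        if len(ss_target) != len(sequence):
            raise ValueError("ss_target must match sequence length")
        self.sequence = sequence
        self.ss_target = ss_target
        self.stages = stages if stages is not None else default_stages()
        validate_stages(self.stages)
        self._hydro = hydrophobic_mask(sequence)
        self._ss = ss_codes(ss_target)
        self._weights = {s.stage_id: s.weight_vector() for s in self.stages}

    @property
    def final_stage_id(self) -> int:
        return self.stages[-1].stage_id

    def score(self, phi: np.ndarray, psi: np.ndarray, omega: np.ndarray,
              stage_id: int) -> float:
        try:
            w = self._weights[stage_id]
        except KeyError:
            raise ConfigurationError(f"unknown stage id {stage_id}") from None
        return float(
            _kernels.staged_score(phi, psi, omega, self._hydro, self._ss, w)
        )

    def score_decoy(self, decoy: TorsionDecoy, stage_id: int | None = None) -> float:
        if stage_id is None:
            stage_id = self.final_stage_id
        return self.score(decoy.phi, decoy.psi, decoy.omega, stage_id)
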