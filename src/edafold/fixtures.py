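"""Synthetic targets and planted fragment libraries.

Everything the sampler and the EDA need can be generated here with no
downloads: toy native backbones built from ideal secondary-structure
torsions, fragment libraries in which each insertion window hides the native
fragment at a known rank among wrong-basin noise fragments, and instrumented
decoy populations whose insertion history is known exactly (the ground truth
for frequency estimation).

The planted libraries are constructed to realize a *suitable* energy
landscape: because noise fragments are drawn from the wrong secondary-
structure basins, decoys rich in native fragments score lower, so energy and
CARMSD to the toy native correlate positively — the regime in which an
energy-guided resampling method can work.  A deceptive variant (scorer built
against a swapped secondary-structure target) realizes the opposite regime
for documentation tests.

What these fixtures do NOT emulate: real fragment libraries carry
near-native fragments at many ranks with realistic torsion noise, and real
energy landscapes are far less separable.  Passing tests on the planted
fixture demonstrate the machinery, not field performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .energy import StagedScorer
from .fragments import FragmentLibrary, Fragment, write_fragment_file
from .geometry import BackboneCoords, TorsionDecoy, build_backbone, write_pdb
from .sampling import insert_fragment

DEFAULT_TOPOLOGY = "HHHHHHHHHHHHLLHHHHHHHHHHHHLLHHHHHHHHHHHH"  # 40-res helix bundle

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-135.0, 135.0)
# broad coil set the loop torsions are drawn from (common turn/coil conformers)
COIL_CONFORMERS = (
    (-75.0, 145.0),   # polyproline II
    (-135.0, 135.0),  # extended
    (-60.0, -30.0),   # alpha-like turn
    (-90.0, 0.0),     # bridge
    (60.0, 30.0),     # left-handed turn
)
COIL_JITTER = 10.0
_COIL_DRAWS = 256     # seeded draws scored to pick the native's loop torsions

# residue alphabets: hydrophobic positions are chosen from the native
# geometry (residues forming native contacts), the rest stay polar
_HYDRO_CYCLE = "LVIF"
_POLAR_CYCLE = {"H": "KEQN", "E": "TSKN", "L": "GSGS"}
_MAX_HYDRO = 14       # cap on hydrophobic residues per toy target

_BASINS = {
    "H": ((-100.0, -30.0), (-80.0, -5.0)),
    "E": ((-180.0, -90.0), (90.0, 180.0)),
}


@dataclass
class ToyTarget:
    """A synthetic native: sequence, secondary structure and torsions."""

    sequence: str
    ss_target: str
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    native: TorsionDecoy
    native_coords: BackboneCoords
    pdb_path: Path | None = None

    @property
    def L(self) -> int:
        return len(self.sequence)


@dataclass
class PlantedLibrary:
    """Planted 9-mer and 3-mer libraries plus the plant manifests
    (window start -> rank of the native fragment)."""

    lib9: FragmentLibrary
    lib3: FragmentLibrary
    manifest9: dict[int, int]
    manifest3: dict[int, int]


def _round3(a):
    # quantize so fragment-file round trips (%.3f) are exact
    return np.round(a, 3)


def _design_sequence(topology, phi, psi, omega):
    """Place hydrophobics on native-contact pairs, polar elsewhere.

    Pairs (|i-j| >= 4, CA distance < 8 A in the native) are taken closest
    first; a pair is accepted while the running hydrophobic count stays
    under the cap.  This ties the contact term to the native packing instead
    of rewarding arbitrary collapse.
    """
    from .geometry import TorsionDecoy as _TD

    L = len(topology)
    ca = build_backbone(
        _TD(sequence="A" * L, phi=phi, psi=psi, omega=omega)
    ).ca
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    pairs = [
        (d[i, j], i, j)
        for i in range(L) for j in range(i + 4, L)
        if d[i, j] < 8.0
    ]
    hydro = set()
    for _, i, j in sorted(pairs):
        new = {i, j} - hydro
        if len(hydro) + len(new) <= _MAX_HYDRO:
            hydro |= new
    chars = []
    counters = {"hydro": 0, "H": 0, "E": 0, "L": 0}
    for i, c in enumerate(topology):
        if i in hydro:
            chars.append(_HYDRO_CYCLE[counters["hydro"] % len(_HYDRO_CYCLE)])
            counters["hydro"] += 1
        else:
            cyc = _POLAR_CYCLE[c]
            chars.append(cyc[counters[c] % len(cyc)])
            counters[c] += 1
    return "".join(chars)


def make_toy_target(topology: str = DEFAULT_TOPOLOGY, seed: int = 0,
                    out_dir=None) -> ToyTarget:
    """Build a toy native from a secondary-structure topology string.

    H gets ideal helix torsions, E ideal strand torsions.  Loop torsions are
    drawn (seeded) from a broad coil-conformer set; among a fixed number of
    joint draws the one minimizing the contact-free stage energy (steric +
    local ss + compaction) is kept, which makes the native compact and
    clash-free.  Hydrophobic residues are then placed from the native
    geometry — on residue pairs that are actually in contact in the native,
    capped at a small total — so the contact term rewards the native packing
    rather than generic collapse.  Together these realize the designed
    "suitable landscape" the resampling tests rely on; the native's local
    secondary-structure term is zero by construction.
    """
    bad = set(topology) - set("HEL")
    if bad:
        raise ValueError(f"invalid topology characters {sorted(bad)}")
    if not 9 <= len(topology) <= 200:
        raise ValueError("topology length must be in [9, 200]")
    rng = np.random.default_rng(seed)
    L = len(topology)
    phi = np.empty(L)
    psi = np.empty(L)
    omega = np.full(L, 180.0)
    coil_idx = []
    for i, c in enumerate(topology):
        if c == "H":
            phi[i], psi[i] = HELIX_PHI_PSI
        elif c == "E":
            phi[i], psi[i] = STRAND_PHI_PSI
        else:
            coil_idx.append(i)
    if coil_idx:
        # contact-free stage: sequence-independent, so a placeholder works
        scorer = StagedScorer("A" * L, topology)
        conf = np.array(COIL_CONFORMERS)
        best = None
        for _ in range(_COIL_DRAWS):
            pick = rng.integers(len(conf), size=len(coil_idx))
            jit = rng.uniform(-COIL_JITTER, COIL_JITTER, size=(len(coil_idx), 2))
            phi[coil_idx] = conf[pick, 0] + jit[:, 0]
            psi[coil_idx] = conf[pick, 1] + jit[:, 1]
            e = scorer.score(phi, psi, omega, 2)
            if best is None or e < best[0]:
                best = (e, phi[coil_idx].copy(), psi[coil_idx].copy())
        phi[coil_idx] = best[1]
        psi[coil_idx] = best[2]
    phi = _round3(phi)
    psi = _round3(psi)
    sequence = _design_sequence(topology, phi, psi, omega)
    native = TorsionDecoy(sequence=sequence, phi=phi.copy(), psi=psi.copy(),
                          omega=omega.copy())
    coords = build_backbone(native)
    pdb_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pdb_path = out_dir / "native.pdb"
        write_pdb(native, coords, pdb_path)
        (out_dir / "target.fasta").write_text(f">toy_target\n{sequence}\n")
        (out_dir / "target.ss").write_text(topology + "\n")
    return ToyTarget(sequence=sequence, ss_target=topology, phi=phi, psi=psi,
                     omega=omega, native=native, native_coords=coords,
                     pdb_path=pdb_path)


def _wrong_basin_torsions(rng, ss_char, length):
    """Noise fragment: per-residue torsions from a wrong basin or broad coil."""
    mode = rng.integers(3)
    phi = np.empty(length)
    psi = np.empty(length)
    wrong = [b for b in "HE" if b != ss_char]
    for i in range(length):
        if mode == 2:   # broad coil
            phi[i] = rng.uniform(-179.0, 180.0)
            psi[i] = rng.uniform(-179.0, 180.0)
        else:
            basin = wrong[mode % len(wrong)]
            (plo, phi_hi), (slo, shi) = _BASINS[basin]
            phi[i] = rng.uniform(plo, phi_hi)
            psi[i] = rng.uniform(slo, shi)
    return phi, psi


def _planted_windows(target, window_size, n_per_window, plant_rank_range,
                     jitter_sigma, rng):
    lo_rank, hi_rank = plant_rank_range
    if not 0 <= lo_rank < hi_rank <= n_per_window:
        raise ValueError(
            f"plant_rank_range {plant_rank_range} incompatible with "
            f"n_per_window {n_per_window}"
        )
    windows = {}
    manifest = {}
    n_windows = target.L - window_size + 1
    for start in range(1, n_windows + 1):
        native_rank = int(rng.integers(lo_rank, hi_rank))
        manifest[start] = native_rank
        sl = slice(start - 1, start - 1 + window_size)
        ss_window = target.ss_target[sl]
        frags = []
        for rank in range(n_per_window):
            if rank == native_rank:
                phi = target.phi[sl].copy()
                psi = target.psi[sl].copy()
                if jitter_sigma > 0:
                    phi = phi + rng.normal(0.0, jitter_sigma, window_size)
                    psi = psi + rng.normal(0.0, jitter_sigma, window_size)
            else:
                # dominant ss character of the window picks the wrong basins
                dom = max(set(ss_window), key=ss_window.count)
                phi, psi = _wrong_basin_torsions(
                    rng, dom if dom in "HE" else "H", window_size
                )
            torsions = np.column_stack(
                [_round3(phi), _round3(psi), np.full(window_size, 180.0)]
            )
            frags.append(
                Fragment(window_start=start, torsions=torsions, rank=rank,
                         ss=ss_window)
            )
        windows[start] = tuple(frags)
    lib = FragmentLibrary(
        window_size=window_size, n_per_window=n_per_window,
        target_length=target.L, windows=windows,
    )
    lib.validate()
    return lib, manifest


def make_planted_library(target: ToyTarget, n_per_window: int = 25,
                         plant_rank_range: tuple[int, int] | None = None,
                         jitter_sigma: float = 0.0, seed: int = 0,
                         window_sizes: tuple[int, int] = (9, 3),
                         out_dir=None) -> PlantedLibrary:
    """Plant the native fragment at a seeded random rank in every window.

    Remaining ranks hold wrong-basin noise fragments, so the native rank is
    identifiable by energy but not by position.  Optionally writes both
    libraries in the Rosetta dialect plus a manifest TSV.
    """
    if n_per_window < 2:
        raise ValueError("n_per_window must be >= 2")
    if plant_rank_range is None:
        plant_rank_range = (0, n_per_window)
    rng = np.random.default_rng(seed)
    ws9, ws3 = window_sizes
    lib9, manifest9 = _planted_windows(target, ws9, n_per_window,
                                       plant_rank_range, jitter_sigma, rng)
    lib3, manifest3 = _planted_windows(target, ws3, n_per_window,
                                       plant_rank_range, jitter_sigma, rng)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fragment_file(lib9, out_dir / f"frags.{ws9}mers")
        write_fragment_file(lib3, out_dir / f"frags.{ws3}mers")
        with open(out_dir / "plant_manifest.tsv", "w") as fh:
            fh.write("window_size\twindow_start\tnative_rank\n")
            for start, rank in sorted(manifest9.items()):
                fh.write(f"{ws9}\t{start}\t{rank}\n")
            for start, rank in sorted(manifest3.items()):
                fh.write(f"{ws3}\t{start}\t{rank}\n")
    return PlantedLibrary(lib9=lib9, lib3=lib3, manifest9=manifest9,
                          manifest3=manifest3)


def reassemble_from_manifest(target: ToyTarget,
                             planted: PlantedLibrary) -> TorsionDecoy:
    """Insert the planted (native) rank at every 9-mer window in order."""
    decoy = TorsionDecoy(
        sequence=target.sequence,
        phi=np.zeros(target.L), psi=np.zeros(target.L),
        omega=np.full(target.L, 180.0),
    )
    for start, rank in sorted(planted.manifest9.items()):
        decoy = insert_fragment(decoy, planted.lib9.fragment(start, rank),
                                planted.lib9.n_per_window)
    return decoy


def make_instrumented_population(target: ToyTarget, library: FragmentLibrary,
                                 log, seed: int = 0):
    """Decoys built by exactly the logged insertions.

    ``log`` entries are either ``(window_start, rank, count)`` triples (count
    decoys with that single insertion) or ``(insertions, count)`` with
    ``insertions`` a list of (window_start, rank) pairs applied in order (for
    overlapping-insertion cases).  Returns (decoys, normalized_log) where the
    normalized log lists (insertions, count) pairs — the ground truth for
    frequency estimation.
    """
    normalized = []
    for entry in log:
        if len(entry) == 3 and np.isscalar(entry[0]):
            w, k, count = entry
            normalized.append(([(int(w), int(k))], int(count)))
        elif len(entry) == 2:
            insertions, count = entry
            normalized.append(
                ([(int(w), int(k)) for w, k in insertions], int(count))
            )
        else:
            raise ValueError(f"malformed log entry {entry!r}")
    decoys = []
    for insertions, count in normalized:
        for _ in range(count):
            decoy = TorsionDecoy(
                sequence=target.sequence,
                phi=target.phi.copy(), psi=target.psi.copy(),
                omega=target.omega.copy(),
            )
            for w, k in insertions:
                decoy = insert_fragment(decoy, library.fragment(w, k),
                                        library.n_per_window)
            decoys.append(decoy)
    return decoys, normalized


def make_deceptive_scorer(target: ToyTarget) -> StagedScorer:
    """Scorer whose secondary-structure target swaps H and E: its low-energy
    region lies away from the toy native (the failure regime in which
    energy-guided resampling converges to the wrong basin)."""
    swapped = target.ss_target.translate(str.maketrans("HE", "EH"))
    return StagedScorer(target.sequence, swapped)
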