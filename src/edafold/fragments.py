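"""Fragment libraries and fragment identity keys.

A fragment library holds, for every insertion window of the target sequence,
a rank-ordered list of candidate fragments.  Each fragment is a window of
per-residue backbone torsions (phi, psi, omega) excised from known structures
(or synthesized by :mod:`edafold.fixtures`).  Libraries are read and written
in the classic whitespace-column Rosetta/Robetta fragment-file dialect.

Provenance tracking assigns every inserted residue an integer *fragment key*
that is unique relative to that residue: ``key = p * N + k`` where ``p`` is
the residue's position inside the insertion window, ``N`` the number of
fragments per window and ``k`` the fragment's rank.  The inverse is
``(key // N, key % N)``.  Keys are what the EDA later decodes to recover
which fragment produced each residue of a low-energy decoy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, FragmentParseError, FragmentStructureError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZES = (9, 3)
DEFAULT_N_PER_WINDOW = 200


def wrap_angles(a):
    """Map angles (degrees) into the half-open interval (-180, 180].

    Values already in range pass through bitwise unchanged.
    """
    a = np.asarray(a, dtype=float)
    w = np.mod(a, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    return np.where((a > -180.0) & (a <= 180.0), a, w)


@dataclass(frozen=True)
class Fragment:
    """One library entry: a torsion window with a rank.

    Parameters
    ----------
    window_start : int
        1-based index of the first target residue the fragment covers.
    torsions : ndarray, shape (length, 3)
        Per-residue (phi, psi, omega) in degrees, each in (-180, 180].
    rank : int
        0-based position of the fragment in its window's candidate list.
    ss : str, optional
        Per-residue secondary structure characters (H/E/L) when known.
    """

    window_start: int
    torsions: np.ndarray
    rank: int
    ss: str | None = None

    def __post_init__(self):
        t = np.asarray(self.torsions, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("torsions must have shape (length, 3)")
        if np.any(t <= -180.0) or np.any(t > 180.0):
            raise ValueError("torsion angles must lie in (-180, 180]")
        if self.window_start < 1:
            raise ValueError("window_start is 1-based and must be >= 1")
        if self.rank < 0:
            raise ValueError("rank must be non-negative")
        if self.ss is not None and len(self.ss) != t.shape[0]:
            raise ValueError("ss must have one character per covered residue")
        t = t.copy()
        t.flags.writeable = False
        object.__setattr__(self, "torsions", t)

    @property
    def length(self) -> int:
        return self.torsions.shape[0]


@dataclass
class FragmentLibrary:
    """All fragments for one window size of one target.

    ``windows`` maps each 1-based window start to its rank-ordered fragment
    tuple; starts must cover exactly ``1 .. target_length - window_size + 1``.
    """

    window_size: int
    n_per_window: int
    target_length: int
    windows: dict[int, tuple[Fragment, ...]] = field(default_factory=dict)

    def validate(self) -> None:
        expected = list(range(1, self.target_length - self.window_size + 2))
        if sorted(self.windows) != expected:
            raise FragmentStructureError(
                f"window starts {sorted(self.windows)} != expected {expected}"
            )
        for start, frags in self.windows.items():
            if len(frags) != self.n_per_window:
                raise FragmentStructureError(
                    f"window {start} holds {len(frags)} fragments, "
                    f"expected {self.n_per_window}"
                )
            for i, f in enumerate(frags):
                if f.rank != i:
                    raise FragmentStructureError(
                        f"window {start}: fragment at index {i} has rank {f.rank}"
                    )
                if f.length != self.window_size:
                    raise FragmentStructureError(
                        f"window {start} rank {i}: length {f.length} != "
                        f"window size {self.window_size}"
                    )

    @property
    def n_windows(self) -> int:
        return self.target_length - self.window_size + 1

    def fragment(self, window_start: int, rank: int) -> Fragment:
        return self.windows[window_start][rank]

    def torsion_tensor(self) -> np.ndarray:
        """Dense (n_windows, n_per_window, window_size, 3) torsion array.

        Window index ``w`` corresponds to window start ``w + 1``.  Cached.
        """
        cached = getattr(self, "_tensor", None)
        if cached is None:
            cached = np.empty(
                (self.n_windows, self.n_per_window, self.window_size, 3)
            )
            for start, frags in self.windows.items():
                for k, f in enumerate(frags):
                    cached[start - 1, k] = f.torsions
            cached.flags.writeable = False
            self._tensor = cached
        return cached


def encode_fragment_key(pos_in_window: int, rank: int, n_per_window: int,
                        window_size: int | None = None) -> int:
    """Unique per-residue identifier of the (position, rank) pair."""
    if rank < 0 or rank >= n_per_window:
        raise ValueError(f"rank {rank} outside [0, {n_per_window})")
    if pos_in_window < 0 or (window_size is not None and pos_in_window >= window_size):
        raise ValueError(f"pos_in_window {pos_in_window} out of range")
    return pos_in_window * n_per_window + rank


def decode_fragment_key(key: int, n_per_window: int,
                        window_size: int | None = None) -> tuple[int, int]:
    """Inverse of :func:`encode_fragment_key`: ``(key // N, key % N)``."""
    if key < 0 or (window_size is not None and key >= window_size * n_per_window):
        raise ValueError(f"key {key} out of range")
    return divmod(key, n_per_window)


def parse_fragment_file(path, expected_window_size: int | None = None) -> FragmentLibrary:
    """Parse a classic Rosetta fragment file.

    The dialect is ``position:`` / ``neighbors:`` headers followed by blocks
    of whitespace-column residue rows (pdb-id, chain, residue, aa, ss, phi,
    psi, omega); blank lines separate fragments.  Extra trailing columns are
    ignored with a logged warning.  Torsions are wrapped into (-180, 180].
    """
    windows: dict[int, list[Fragment]] = {}
    current_start: int | None = None
    rows: list[tuple[float, float, float]] = []
    ss_chars: list[str] = []
    window_size: int | None = None   # inferred; compared to expected at the end
    extra_warned = False

    def close_fragment(lineno):
        nonlocal window_size
        if not rows:
            return
        if window_size is None:
            window_size = len(rows)
        if len(rows) != window_size:
            raise FragmentStructureError(
                f"line {lineno}: fragment with {len(rows)} residue rows, "
                f"expected window size {window_size}"
            )
        frags = windows[current_start]
        frags.append(
            Fragment(
                window_start=current_start,
                torsions=wrap_angles(np.array(rows)),
                rank=len(frags),
                ss="".join(ss_chars),
            )
        )
        rows.clear()
        ss_chars.clear()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                close_fragment(lineno)
                continue
            if line.startswith("position:"):
                close_fragment(lineno)
                tok = line.split()
                try:
                    start = int(tok[1])
                except (IndexError, ValueError) as exc:
                    raise FragmentParseError(
                        f"line {lineno}: malformed position header: {line!r}"
                    ) from exc
                if start in windows:
                    raise FragmentStructureError(
                        f"line {lineno}: duplicate window start {start}"
                    )
                windows[start] = []
                current_start = start
                continue
            if current_start is None:
                raise FragmentParseError(
                    f"line {lineno}: residue row before any position header"
                )
            tok = line.split()
            if len(tok) < 8:
                raise FragmentParseError(
                    f"line {lineno}: expected >= 8 columns, got {len(tok)}: {line!r}"
                )
            if len(tok) > 8 and not extra_warned:
                logger.warning(
                    "%s line %d: ignoring %d extra columns",
                    path, lineno, len(tok) - 8,
                )
                extra_warned = True
            try:
                phi, psi, omega = float(tok[5]), float(tok[6]), float(tok[7])
            except ValueError as exc:
                raise FragmentParseError(
                    f"line {lineno}: non-numeric torsion columns: {line!r}"
                ) from exc
            rows.append((phi, psi, omega))
            ss_chars.append(tok[4])
        close_fragment(lineno="<eof>")

    if not windows:
        raise FragmentStructureError(f"{path}: no fragment windows found")
    if expected_window_size is not None and window_size != expected_window_size:
        raise ConfigurationError(
            f"{path}: window size {window_size} != expected {expected_window_size}"
        )
    counts = {len(v) for v in windows.values()}
    if len(counts) != 1:
        raise FragmentStructureError(
            f"{path}: inconsistent fragments-per-window counts {sorted(counts)}"
        )
    n_per_window = counts.pop()
    target_length = max(windows) + window_size - 1
    lib = FragmentLibrary(
        window_size=window_size,
        n_per_window=n_per_window,
        target_length=target_length,
        windows={s: tuple(v) for s, v in windows.items()},
    )
    lib.validate()
    return lib


def write_fragment_file(library: FragmentLibrary, path) -> None:
    """Write a library in the same Rosetta dialect the parser reads."""
    with open(path, "w") as fh:
        for start in sorted(library.windows):
            frags = library.windows[start]
            fh.write(f" position: {start:12d} neighbors: {len(frags):10d}\n\n")
            for frag in frags:
                for i in range(frag.length):
                    ss = frag.ss[i] if frag.ss else "L"
                    phi, psi, omega = frag.torsions[i]
                    fh.write(
                        f" synt A {start + i:5d} A {ss} "
                        f"{phi:9.3f} {psi:9.3f} {omega:9.3f}\n"
                    )
                fh.write("\n")
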