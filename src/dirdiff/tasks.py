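"""Synthetic tasks, validators and I/O: Sudoku, i.i.d. categorical
toys, and PWM-planted promoter-like sequences with initiation profiles.

Sudoku grids are (N, N) integer arrays with N = n^2 (n=2 mini, n=3
standard), entries 1..N and 0 for blanks. Generation is randomized
backtracking, so every generated grid is valid by construction; puzzle
creation removes cells, optionally verifying solution uniqueness with
an exhaustive solver. Validity ("every row, column and n x n box
contains each symbol exactly once") is the all-or-nothing quality
metric for generated grids.

The promoter-like generator emulates the *shape* of a TSS-centered
promoter dataset: random background sequence, a position-weight-matrix
motif planted upstream of the center, and a per-position transcription
initiation signal profile built from Gaussian bumps keyed to the
planted motif, scaled to a configured expression level, plus noise. It
is a synthetic stand-in — it reproduces data layout and simple
composition signals, not real promoter biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "generate_full_grid",
    "make_puzzle",
    "is_valid",
    "solves",
    "count_solutions",
    "grid_to_string",
    "string_to_grid",
    "grids_to_onehot",
    "write_grids",
    "read_grids",
    "iid_categorical_batches",
    "onehot",
    "DNA_ALPHABET",
    "TATA_PWM",
    "SyntheticPromoterRecord",
    "generate_promoter_like",
    "pwm_scan",
    "write_fasta",
    "read_fasta",
    "write_profiles",
    "read_profiles",
]

DNA_ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# Sudoku


def _unit_ok(vals: np.ndarray, N: int) -> bool:
    return len(np.unique(vals)) == N and vals.min() == 1 and vals.max() == N


def is_valid(grid: np.ndarray) -> bool:
    """True iff every row, column and box holds each symbol once."""
    grid = np.asarray(grid)
    N = grid.shape[0]
    n = int(round(N ** 0.5))
    if grid.shape != (N, N) or n * n != N:
        return False
    for i in range(N):
        if not _unit_ok(grid[i], N) or not _unit_ok(grid[:, i], N):
            return False
    for bi in range(n):
        for bj in range(n):
            if not _unit_ok(grid[bi * n:(bi + 1) * n, bj * n:(bj + 1) * n].ravel(), N):
                return False
    return True


def _candidates(grid: np.ndarray, r: int, c: int, n: int) -> np.ndarray:
    N = n * n
    used = set(grid[r]) | set(grid[:, c]) | set(
        grid[(r // n) * n:(r // n) * n + n, (c // n) * n:(c // n) * n + n].ravel()
    )
    return np.array([d for d in range(1, N + 1) if d not in used])


def _fill(grid: np.ndarray, cells: list[tuple[int, int]], i: int, n: int,
          rng: np.random.Generator | None) -> bool:
    if i == len(cells):
        return True
    r, c = cells[i]
    cand = _candidates(grid, r, c, n)
    if rng is not None:
        rng.shuffle(cand)
    for d in cand:
        grid[r, c] = d
        if _fill(grid, cells, i + 1, n, rng):
            return True
    grid[r, c] = 0
    return False


def generate_full_grid(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random valid (n^2 x n^2) grid by randomized backtracking."""
    N = n * n
    grid = np.zeros((N, N), dtype=int)
    cells = [(r, c) for r in range(N) for c in range(N)]
    if not _fill(grid, cells, 0, n, rng):
        raise RuntimeError("backtracking failed (cannot happen for valid n)")
    return grid


def count_solutions(puzzle: np.ndarray, limit: int = 2) -> int:
    """Number of completions of a puzzle (0 = blank), up to ``limit``."""
    puzzle = np.asarray(puzzle)
    N = puzzle.shape[0]
    n = int(round(N ** 0.5))
    grid = puzzle.copy()
    blanks = [(r, c) for r in range(N) for c in range(N) if grid[r, c] == 0]
    count = 0

    def rec(i: int) -> None:
        nonlocal count
        if count >= limit:
            return
        if i == len(blanks):
            count += 1
            return
        r, c = blanks[i]
        for d in _candidates(grid, r, c, n):
            grid[r, c] = d
            rec(i + 1)
            grid[r, c] = 0

    rec(0)
    return count


def make_puzzle(
    grid: np.ndarray,
    n_clues: int,
    rng: np.random.Generator,
    unique: bool = False,
) -> np.ndarray:
    """Blank cells down to ``n_clues`` clues (0 marks blanks).

    With ``unique=True``, a removal that would admit more than one
    completion is skipped (so the result may keep more than ``n_clues``
    clues if uniqueness cannot be maintained).
    """
    grid = np.asarray(grid)
    N = grid.shape[0]
    if not 0 <= n_clues <= N * N:
        raise ValueError("n_clues out of range")
    puzzle = grid.copy()
    order = rng.permutation(N * N)
    remaining = N * N
    for idx in order:
        if remaining <= n_clues:
            break
        r, c = divmod(int(idx), N)
        saved = puzzle[r, c]
        puzzle[r, c] = 0
        if unique and count_solutions(puzzle, limit=2) > 1:
            puzzle[r, c] = saved
        else:
            remaining -= 1
    return puzzle


def solves(puzzle: np.ndarray, grid: np.ndarray) -> bool:
    """True iff ``grid`` is valid and agrees with the puzzle's clues."""
    puzzle, grid = np.asarray(puzzle), np.asarray(grid)
    clues = puzzle != 0
    return bool(is_valid(grid) and np.all(grid[clues] == puzzle[clues]))


def grid_to_string(grid: np.ndarray) -> str:
    """Row-major digit string; 0 for blanks (e.g. 81 chars for 9x9)."""
    return "".join(str(d) for d in np.asarray(grid).ravel())


def string_to_grid(s: str) -> np.ndarray:
    s = s.strip().replace(".", "0")
    N = int(round(len(s) ** 0.5))
    if N * N != len(s):
        raise ValueError("grid string length must be a perfect square")
    return np.array([int(ch) for ch in s], dtype=int).reshape(N, N)


def grids_to_onehot(grids: np.ndarray) -> np.ndarray:
    """(B, N, N) grids with entries 1..N -> one-hot (B, N*N, N)."""
    grids = np.asarray(grids)
    B, N, _ = grids.shape
    return np.eye(N)[grids.reshape(B, N * N) - 1]


def write_grids(path, grids) -> None:
    with open(path, "w") as f:
        for g in grids:
            f.write(grid_to_string(g) + "\n")


def read_grids(path) -> list[np.ndarray]:
    with open(path) as f:
        return [string_to_grid(line) for line in f if line.strip()]


# ---------------------------------------------------------------------------
# i.i.d. categorical toy


def iid_categorical_batches(
    probs, length: int, batch_size: int, rng: np.random.Generator
):
    """Infinite iterator of one-hot (B, L, k) batches with i.i.d. positions."""
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    k = len(probs)
    eye = np.eye(k)
    while True:
        cats = rng.choice(k, size=(batch_size, length), p=probs)
        yield eye[cats]


def onehot(seq: str, alphabet: str = DNA_ALPHABET) -> np.ndarray:
    idx = np.array([alphabet.index(ch) for ch in seq])
    return np.eye(len(alphabet))[idx]


# ---------------------------------------------------------------------------
# synthetic promoter-like records

#: A TATA-box-like position weight matrix (columns A, C, G, T); sharply
#: informative so planted instances are recoverable by log-odds
#: scanning at a modest threshold.
TATA_PWM = np.array([
    [0.02, 0.02, 0.02, 0.94],  # T
    [0.94, 0.02, 0.02, 0.02],  # A
    [0.02, 0.02, 0.02, 0.94],  # T
    [0.94, 0.02, 0.02, 0.02],  # A
    [0.94, 0.02, 0.02, 0.02],  # A
    [0.94, 0.02, 0.02, 0.02],  # A
])


@dataclass
class SyntheticPromoterRecord:
    """One synthetic promoter-like example (sequence, profile, truth)."""

    sequence: str
    profile: np.ndarray
    motif_positions: tuple[int, ...]
    expression: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.profile):
            raise ValueError("sequence and profile lengths must match")


def _draw_from_pwm(pwm: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(DNA_ALPHABET[rng.choice(4, p=row / row.sum())] for row in pwm)


def generate_promoter_like(
    n_records: int,
    rng: np.random.Generator,
    pwm: np.ndarray = TATA_PWM,
    length: int = 1024,
    expression: float = 10.0,
    motif_offset: int = -28,
    profile_sd: float = 4.0,
    noise: float = 0.02,
    plant_motif: bool = True,
) -> list[SyntheticPromoterRecord]:
    """Generate TSS-centered records with a planted motif and profile.

    The motif is planted at center + ``motif_offset`` (a TATA-like
    element sits ~25-30 bp upstream of the TSS); the initiation profile
    is a Gaussian bump of width ``profile_sd`` at the TSS, scaled to
    integrate to ``expression``, with nonnegative multiplicative noise.
    ``plant_motif=False`` yields a motif-free null model with uniform
    base composition.
    """
    center = length // 2
    out = []
    for _ in range(n_records):
        seq = list(DNA_ALPHABET[i] for i in rng.integers(4, size=length))
        positions: tuple[int, ...] = ()
        if plant_motif:
            pos = center + motif_offset
            if not 0 <= pos <= length - len(pwm):
                raise ValueError("motif does not fit in the sequence")
            seq[pos:pos + len(pwm)] = _draw_from_pwm(pwm, rng)
            positions = (pos,)
        grid = np.arange(length)
        bump = np.exp(-0.5 * ((grid - center) / profile_sd) ** 2)
        bump = bump / bump.sum() * expression
        profile = bump * np.clip(1.0 + noise * rng.standard_normal(length), 0.0, None)
        profile = profile / max(profile.sum(), 1e-12) * expression
        out.append(SyntheticPromoterRecord(
            sequence="".join(seq), profile=profile,
            motif_positions=positions, expression=expression,
        ))
    return out


def pwm_scan(seq: str, pwm: np.ndarray, background: float = 0.25) -> np.ndarray:
    """Log-odds PWM scores at every placement of ``pwm`` along ``seq``."""
    x = onehot(seq)
    logodds = np.log(pwm / background)
    m = len(pwm)
    L = len(seq)
    return np.array([
        float(np.sum(x[i:i + m] * logodds)) for i in range(L - m + 1)
    ])


# ---------------------------------------------------------------------------
# I/O round-trips


def write_fasta(path, sequences: list[str], ids: list[str] | None = None) -> None:
    ids = ids or [f"seq_{i}" for i in range(len(sequences))]
    records = [
        SeqRecord(Seq(s), id=name, description="") for s, name in zip(sequences, ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def write_profiles(path, profiles: np.ndarray) -> None:
    """Tab-delimited (record, position, signal) long format."""
    profiles = np.atleast_2d(profiles)
    rows = [
        (r, p, profiles[r, p])
        for r in range(profiles.shape[0])
        for p in range(profiles.shape[1])
    ]
    pd.DataFrame(rows, columns=["record", "position", "signal"]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    n_rec = df["record"].max() + 1
    n_pos = df["position"].max() + 1
    out = np.zeros((n_rec, n_pos))
    out[df["record"], df["position"]] = df["signal"]
    return out
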