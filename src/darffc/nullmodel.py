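"""Degree-preserving randomization of the connection matrix.

The null model shuffles edges by repeated 2x2 "checkerboard" swaps: draw a
pair of distinct TF columns (a, b) and a pair of distinct gene rows (m, n);
if M[m,a] = 1, M[n,b] = 1, M[n,a] = 0 and M[m,b] = 0, replace that 2x2
submatrix by its complement.  Each swap conserves every row sum (number of
TFs targeting each gene) and every column sum (each TF's out-degree), so a
long run of swaps samples matrices with exactly the real network's degree
sequences.  A "step" counts one attempted draw, whether or not the
checkerboard condition holds and a swap is applied.

Diagonal (autoregulation) entries are not protected: swaps may create or
destroy self-edges, so the autoregulation count itself has a null
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .netio import ConnectionMatrix, write_connection_matrix

__all__ = [
    "SwapRecord",
    "attempt_swap",
    "randomize",
    "make_ensemble",
    "convergence_curve",
]

DEFAULT_STEPS = 500_000
DEFAULT_ENSEMBLE_SIZE = 1000

_BATCH = 1 << 15


@dataclass
class SwapRecord:
    """Bookkeeping for one randomization run."""

    attempts: int
    applied_swaps: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.applied_swaps > self.attempts:
            raise ValueError("applied_swaps cannot exceed attempts")


def attempt_swap(entries: np.ndarray, rng: np.random.Generator) -> bool:
    """One draw-check-swap step on ``entries`` in place; True iff applied."""
    G, T = entries.shape
    a = int(rng.integers(T))
    b = (a + 1 + int(rng.integers(T - 1))) % T
    m = int(rng.integers(G))
    n = (m + 1 + int(rng.integers(G - 1))) % G
    if entries[m, a] == 1 and entries[n, b] == 1 and entries[n, a] == 0 and entries[m, b] == 0:
        entries[m, a] = 0
        entries[n, b] = 0
        entries[n, a] = 1
        entries[m, b] = 1
        return True
    return False


def randomize(
    matrix: ConnectionMatrix,
    steps: int = DEFAULT_STEPS,
    seed: int | np.random.SeedSequence | None = None,
    return_record: bool = False,
) -> ConnectionMatrix | tuple[ConnectionMatrix, SwapRecord]:
    """Return a degree-preserving randomization after ``steps`` attempted swaps.

    Bit-reproducible for a fixed seed.  ``steps = 0`` returns an identical
    copy.  Random draws are batched for speed, so the draw order differs
    from looping :func:`attempt_swap` with the same generator; the batched
    order is this function's own fixed convention.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    M = matrix.entries.copy()
    G, T = M.shape
    rng = np.random.default_rng(seed)
    applied = 0
    done = 0
    while done < steps:
        k = min(_BATCH, steps - done)
        a = rng.integers(0, T, size=k)
        b = (a + 1 + rng.integers(0, T - 1, size=k)) % T
        m = rng.integers(0, G, size=k)
        n = (m + 1 + rng.integers(0, G - 1, size=k)) % G
        for i in range(k):
            ai, bi, mi, ni = a[i], b[i], m[i], n[i]
            if M[mi, ai] == 1 and M[ni, bi] == 1 and M[ni, ai] == 0 and M[mi, bi] == 0:
                M[mi, ai] = 0
                M[ni, bi] = 0
                M[ni, ai] = 1
                M[mi, bi] = 1
                applied += 1
        done += k
    out = matrix.with_entries(M)
    if return_record:
        seed_val = seed if isinstance(seed, int) else None
        return out, SwapRecord(attempts=steps, applied_swaps=applied, seed=seed_val)
    return out


def make_ensemble(
    matrix: ConnectionMatrix,
    n: int = DEFAULT_ENSEMBLE_SIZE,
    steps: int = DEFAULT_STEPS,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> Iterator[ConnectionMatrix]:
    """Yield ``n`` independent randomizations of ``matrix``.

    Per-matrix seeds derive from the master seed via a counter
    (``SeedSequence([seed, i])``), so any member is reproducible in
    isolation.  If ``out_dir`` is given each member is also written as
    ``random_####.tsv``.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i in range(n):
        rnd = randomize(matrix, steps=steps, seed=np.random.SeedSequence([seed, i]))
        if out_path is not None:
            write_connection_matrix(rnd, out_path / f"random_{i:04d}.tsv")
        yield rnd


def convergence_curve(
    matrix: ConnectionMatrix,
    step_grid: Sequence[int],
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean/sd Hamming distance to the original versus number of swap steps.

    Used to choose a step count on the plateau of the curve, i.e. where
    further swapping no longer changes more matrix entries on average.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    for steps in step_grid:
        dists = []
        for r in range(reps):
            rnd = randomize(
                matrix, steps=steps, seed=np.random.SeedSequence([seed, steps, r])
            )
            dists.append(int((rnd.entries != matrix.entries).sum()))
        rows.append(
            {
                "steps": steps,
                "mean_changed": float(np.mean(dists)),
                "sd_changed": float(np.std(dists, ddof=1)) if reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
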