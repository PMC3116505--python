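"""TF-mode perturbation robustness analysis.

The global activator/repressor modes are literature-curated, so individual
connections may in reality act with the opposite sign.  To probe robustness,
every present edge of a moded (activator/repressor) TF carries a sign
inherited from its TF; a stated proportion of these signed edges, selected
uniformly without replacement from the joint pool (optionally per mode
pool), has its sign flipped.  Circuits are then re-classified from their
edges' signs — the X->Z and Y->Z edge signs give the circuit's mode pair —
and category Z scores are recomputed against the *same* null ensemble, with
the flip selection applied to null-matrix edges as well (an edge present
only in a null matrix inherits its TF-level sign).

At proportion 0 every edge keeps its inherited sign and the classification
reduces exactly to the TF-level scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .census import CircuitCategory, full_census
from .ensemble_stats import z_score
from .netio import ConnectionMatrix, TFModeTable

__all__ = [
    "EdgeModeAssignment",
    "perturb_edge_modes",
    "perturbation_scan",
    "DEFAULT_PROPORTIONS",
    "DEFAULT_SCAN_CATEGORIES",
    "plot_scan",
]

DEFAULT_PROPORTIONS = (0.01, 0.05, 0.10, 0.15, 0.20)

#: categories tracked by default: the DAR-FFC motif, the coherent type-1
#: effecter motif, and the two originating-only-autoregulated antimotifs.
DEFAULT_SCAN_CATEGORIES = (
    CircuitCategory("combined", "NN", "double", "effecter"),
    CircuitCategory("coherence", "PP", "any", "effecter"),
    CircuitCategory("combined", "NN", "originating_only", "effecter"),
    CircuitCategory("combined", "NP", "originating_only", "effecter"),
)


@dataclass
class EdgeModeAssignment:
    """Per-edge sign map for one perturbation draw.

    ``signs`` is the G x T sign matrix for the real matrix's edges;
    ``flip_mask`` marks the selected (gene, TF) cells, which is what carries
    the perturbation onto null matrices.
    """

    signs: np.ndarray  # int8, nonzero only on signed present edges
    flip_mask: np.ndarray  # bool G x T, the stored selection
    tf_signs: np.ndarray  # int8 per TF column (inherited, TF-level)
    proportion: float
    n_signed: int
    n_perturbed: int

    def signs_for(self, entries: np.ndarray) -> np.ndarray:
        """Sign matrix for any matrix sharing the gene/TF labelling.

        Present edges inherit their TF-level sign; edges under the stored
        flip selection are sign-swapped.
        """
        S = entries.astype(np.int8) * self.tf_signs[None, :]
        S = np.where(self.flip_mask & (entries > 0), -S, S)
        return S


def perturb_edge_modes(
    matrix: ConnectionMatrix,
    modes: TFModeTable,
    proportion: float,
    seed: int | np.random.SeedSequence | None = None,
    pool: Literal["joint", "per_mode"] = "joint",
) -> EdgeModeAssignment:
    """Flip the sign of ``round(proportion * n_signed_edges)`` edges.

    Signed edges are the present edges of activator/repressor TFs.  With
    ``pool="per_mode"`` the rounding and sampling are done separately within
    the positively and negatively regulated edge pools.
    """
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tf_signs = np.array([modes.sign_of(s) for s in matrix.tf_symbols], dtype=np.int8)
    signs = matrix.entries.astype(np.int8) * tf_signs[None, :]
    flip = np.zeros(matrix.entries.shape, dtype=bool)

    def select(candidate_mask: np.ndarray) -> None:
        idx = np.flatnonzero(candidate_mask.ravel())
        k = int(round(proportion * idx.size))
        if k:
            chosen = rng.choice(idx, size=k, replace=False)
            flip.ravel()[chosen] = True

    if pool == "joint":
        select(signs != 0)
    elif pool == "per_mode":
        select(signs > 0)
        select(signs < 0)
    else:
        raise ValueError(f"unknown pool {pool!r}")

    return EdgeModeAssignment(
        signs=np.where(flip, -signs, signs),
        flip_mask=flip,
        tf_signs=tf_signs,
        proportion=proportion,
        n_signed=int((signs != 0).sum()),
        n_perturbed=int(flip.sum()),
    )


def perturbation_scan(
    matrix: ConnectionMatrix,
    modes: TFModeTable,
    ensemble: Sequence[ConnectionMatrix],
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    reps: int = 10,
    categories: Sequence[CircuitCategory] = DEFAULT_SCAN_CATEGORIES,
    master_seed: int = 0,
    tf_gene_ids: Sequence[str] | None = None,
    pool: Literal["joint", "per_mode"] = "joint",
) -> pd.DataFrame:
    """Z per (proportion, replicate, category) under perturbed edge signs.

    The ensemble is built once by the caller and reused across the whole
    scan, mirroring the main analysis; each (proportion, replicate) draw is
    seeded from ``master_seed`` via a counter.
    """
    null_entries = [m.entries for m in ensemble]
    rows = []
    for pi, prop in enumerate(proportions):
        for rep in range(reps):
            assignment = perturb_edge_modes(
                matrix,
                modes,
                prop,
                seed=np.random.SeedSequence([master_seed, pi, rep]),
                pool=pool,
            )
            real = full_census(
                matrix, modes, edge_signs=assignment.signs, tf_gene_ids=tf_gene_ids
            )
            null_counts = {c: [] for c in categories}
            for entries in null_entries:
                nm = matrix.with_entries(entries)
                nc = full_census(
                    nm,
                    modes,
                    edge_signs=assignment.signs_for(entries),
                    tf_gene_ids=tf_gene_ids,
                )
                for c in categories:
                    null_counts[c].append(nc.counts[c])
            for c in categories:
                null = np.asarray(null_counts[c], dtype=float)
                sd = float(null.std(ddof=1))
                z = z_score(real.counts[c], float(null.mean()), sd) if sd > 0 else float("nan")
                rows.append(
                    {
                        "proportion": prop,
                        "rep": rep,
                        "scheme": c.scheme,
                        "mode_pair": c.mode_pair,
                        "autoconfig": c.autoconfig,
                        "target_kind": c.target_kind,
                        "z": z,
                    }
                )
    return pd.DataFrame(rows)


def plot_scan(scan: pd.DataFrame, ax=None, baseline_z: float | None = None):
    """Z versus perturbed proportion, one line of markers per category."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    key = ["scheme", "mode_pair", "autoconfig", "target_kind"]
    for label, grp in scan.groupby(key):
        means = grp.groupby("proportion")["z"].mean()
        ax.plot(means.index, means.to_numpy(), marker="^", label="/".join(label))
    if baseline_z is not None:
        ax.axhline(baseline_z, ls="--", color="gray", lw=1)
    ax.set_xlabel("proportion of mode-perturbed connections")
    ax.set_ylabel("Z")
    ax.legend(fontsize=7)
    return ax
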