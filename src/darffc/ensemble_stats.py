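"""Z scores and one-sided P values against the randomized ensemble.

For each censused category, the real count is standardized against the
category's distribution over the null ensemble:

    Z = (real - mean_null) / sd_null

with the sample standard deviation (n-1 denominator).  The P value is the
standard-normal tail in the direction of the deviation: 1 - Phi(Z) for
Z >= 0, Phi(Z) for Z < 0, so P(Z) = P(-Z) and a negative Z flags
underrepresentation (an antimotif) just as a positive one flags a motif.
No multiple-testing correction is applied across categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .census import CircuitCategory, MotifCensus

__all__ = [
    "UndefinedScoreError",
    "CategorySummary",
    "EnsembleSummary",
    "z_score",
    "one_sided_p",
    "summarize_ensemble",
    "plot_z_heatmap",
]


class UndefinedScoreError(ValueError):
    """Raised when a Z score is requested for a zero-variance null."""

    def __init__(self, category=None):
        self.category = category
        super().__init__(f"null sd is zero; Z undefined (category={category})")


@dataclass
class CategorySummary:
    category: CircuitCategory
    real_count: int
    null_mean: float
    null_sd: float
    z: float  # nan when null_sd == 0
    p: float  # nan when null_sd == 0
    degenerate: bool = False  # True when null_sd == 0


@dataclass
class EnsembleSummary:
    """Per-category ensemble statistics; ``n_random`` is the ensemble size."""

    rows: dict[CircuitCategory, CategorySummary]
    n_random: int

    def __getitem__(self, category: CircuitCategory) -> CategorySummary:
        return self.rows[category]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for c, r in sorted(self.rows.items(), key=lambda kv: kv[0]):
            recs.append(
                {
                    "scheme": c.scheme,
                    "mode_pair": c.mode_pair,
                    "autoconfig": c.autoconfig,
                    "target_kind": c.target_kind,
                    "real_count": r.real_count,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "z": r.z,
                    "p": r.p,
                    "degenerate": r.degenerate,
                }
            )
        return pd.DataFrame(recs)


def z_score(real: float, null_mean: float, null_sd: float) -> float:
    """Standardized deviation of the real count from the null mean."""
    if null_sd <= 0:
        raise UndefinedScoreError()
    return (real - null_mean) / null_sd


def one_sided_p(z: float) -> float:
    """Standard-normal tail probability in the direction of the deviation."""
    return float(stats.norm.sf(abs(z)))


def summarize_ensemble(
    census_real: MotifCensus, censuses_null: Sequence[MotifCensus]
) -> EnsembleSummary:
    """Compare a real census with >= 2 null censuses, category by category.

    Categories whose null counts have zero variance are flagged as
    degenerate (z and p set to NaN) rather than dropped.
    """
    if len(censuses_null) < 2:
        raise ValueError("need at least 2 null censuses")
    keys = set(census_real.counts)
    for c in censuses_null:
        if set(c.counts) != keys:
            raise ValueError("null census category set differs from the real census")
    rows: dict[CircuitCategory, CategorySummary] = {}
    for cat in keys:
        null = np.array([c.counts[cat] for c in censuses_null], dtype=float)
        mean = float(null.mean())
        sd = float(null.std(ddof=1))
        real = census_real.counts[cat]
        if sd > 0:
            z = z_score(real, mean, sd)
            p = one_sided_p(z)
            rows[cat] = CategorySummary(cat, real, mean, sd, z, p)
        else:
            rows[cat] = CategorySummary(
                cat, real, mean, sd, float("nan"), float("nan"), degenerate=True
            )
    return EnsembleSummary(rows=rows, n_random=len(censuses_null))


def plot_z_heatmap(summary: EnsembleSummary, scheme: str = "combined", ax=None):
    """Z scores of one scheme as a heatmap (mode/autoconfig x target kind)."""
    import matplotlib.pyplot as plt

    df = summary.to_frame()
    df = df[df["scheme"] == scheme]
    if df.empty:
        raise ValueError(f"no categories under scheme {scheme!r}")
    df = df.assign(row=df["mode_pair"] + "/" + df["autoconfig"])
    pivot = df.pivot_table(index="row", columns="target_kind", values="z")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 0.4 * len(pivot) + 1))
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns)
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.figure.colorbar(im, ax=ax, label="Z")
    ax.set_title(f"{scheme} Z scores")
    return ax
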