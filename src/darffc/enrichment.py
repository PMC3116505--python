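"""Redundant-annotation binomial GO enrichment.

Annotations are counted with multiplicity ("redundant counting"): every
(gene, term) record counts, and an effecter targeted by k distinct DAR-FFC
TF-TF connections contributes its annotations k times to the target-side
totals.  GO terms are opaque labels — no DAG propagation.

Notation (per namespace):

* background, over all effecter genes: E = total redundant term appearances,
  N = distinct terms, F_g = appearances of term g, r_g = F_g / E;
* target side, over the targeted effecters with multiplicity: D = total
  appearances, f_g = appearances of term g (and D_i, f_{g,i} per TF-TF
  connection i).

Under the null that targeted effecters sample annotations at background
rates, f_g ~ Binomial(D, r_g); the enrichment P value is the upper tail
P(K >= f_g), computed with the regularized incomplete beta function so it
stays accurate far below 1e-40.  Terms are ranked by increasing P_g; rare
terms are filtered (global list: F_g <= 0.1% of E discarded; per-connection
lists: F_g <= 0.05% of E or P >= 0.01 discarded).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .netio import GOAnnotationTable

__all__ = [
    "BackgroundFrequencies",
    "TargetFrequencies",
    "EnrichmentTable",
    "background_frequencies",
    "target_frequencies",
    "combine_targets",
    "binomial_tail_p",
    "enrich_global",
    "enrich_per_connection",
]

GLOBAL_LOW_FREQ = 0.001  # discard terms with F_g <= this fraction of E
CONNECTION_LOW_FREQ = 0.0005
CONNECTION_MAX_P = 0.01


@dataclass
class BackgroundFrequencies:
    """Term frequencies over the effecter background of one namespace."""

    E: int
    F_g: dict[str, int]
    namespace: str

    @property
    def N(self) -> int:
        return len(self.F_g)

    def r(self, term: str) -> float:
        return self.F_g[term] / self.E


@dataclass
class TargetFrequencies:
    """Redundant term counts over a (multiply counted) target gene set."""

    D: int
    f_g: dict[str, int]
    namespace: str
    label: str = ""


@dataclass
class EnrichmentTable:
    """Ranked enrichment result; ``table`` keeps all scored terms with
    filter flags, ``surviving`` only the filtered, P-ascending rows."""

    table: pd.DataFrame
    label: str = ""

    @property
    def surviving(self) -> pd.DataFrame:
        return self.table[~self.table["filtered"]].reset_index(drop=True)


def background_frequencies(
    annotations: GOAnnotationTable, effecter_genes: Iterable[str], namespace: str
) -> BackgroundFrequencies:
    """E, N, F_g and r_g over the effecter gene set for one namespace."""
    effecters = set(effecter_genes)
    if not effecters:
        raise ValueError("effecter gene set is empty")
    F: Counter[str] = Counter(
        term for gene, term in annotations.for_namespace(namespace) if gene in effecters
    )
    if not F:
        raise ValueError(
            f"no {namespace} annotations intersect the effecter set"
        )
    return BackgroundFrequencies(E=sum(F.values()), F_g=dict(F), namespace=namespace)


def target_frequencies(
    annotations: GOAnnotationTable,
    target_genes: Iterable[str],
    namespace: str,
    label: str = "",
) -> TargetFrequencies:
    """D and f_g over one target gene collection.

    ``target_genes`` is treated as a multiset: passing a gene twice (e.g.
    because two circuits target it) doubles its annotation contribution.
    """
    targets = Counter(target_genes)
    f: Counter[str] = Counter()
    for gene, term in annotations.for_namespace(namespace):
        k = targets.get(gene, 0)
        if k:
            f[term] += k
    return TargetFrequencies(D=sum(f.values()), f_g=dict(f), namespace=namespace, label=label)


def combine_targets(parts: Sequence[TargetFrequencies]) -> TargetFrequencies:
    """Pool per-connection target frequencies into the global D / f_g."""
    if not parts:
        raise ValueError("nothing to combine")
    ns = {p.namespace for p in parts}
    if len(ns) != 1:
        raise ValueError(f"mixed namespaces: {sorted(ns)}")
    f: Counter[str] = Counter()
    for p in parts:
        f.update(p.f_g)
    return TargetFrequencies(D=sum(f.values()), f_g=dict(f), namespace=ns.pop())


def binomial_tail_p(f: int, D: int, r: float, inclusive: bool = True) -> float:
    """Upper-tail binomial probability P(K >= f) for K ~ Binomial(D, r).

    ``inclusive=False`` gives the strict tail P(K > f).  The inclusive tail
    is the default: it is the standard enrichment convention and satisfies
    P = 1 at f = 0.
    """
    if not 0 <= f <= D:
        raise ValueError(f"need 0 <= f <= D, got f={f}, D={D}")
    if not 0 < r <= 1:
        raise ValueError(f"need 0 < r <= 1, got r={r}")
    k = f - 1 if inclusive else f
    if k < 0:
        return 1.0
    return float(stats.binom.sf(k, D, r))


def _score(
    bg: BackgroundFrequencies,
    targets: TargetFrequencies,
    low_freq: float,
    max_p: float | None,
    inclusive: bool,
    label: str,
) -> EnrichmentTable:
    if targets.namespace != bg.namespace:
        raise ValueError("background and target namespaces differ")
    cutoff = low_freq * bg.E
    rows = []
    for term, F in bg.F_g.items():
        f = targets.f_g.get(term, 0)
        r = bg.r(term)
        p = binomial_tail_p(min(f, targets.D), targets.D, r, inclusive) if targets.D else 1.0
        low = F <= cutoff
        high_p = (max_p is not None) and (p >= max_p)
        rows.append(
            {
                "term": term,
                "F_g": F,
                "f_g": f,
                "r_g": r,
                "P_g": p,
                "low_frequency": low,
                "high_p": high_p,
                "filtered": low or high_p,
            }
        )
    df = pd.DataFrame(rows)
    # rank ascending by P; ties by descending target frequency then term ID
    df = df.sort_values(
        ["P_g", "f_g", "term"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return EnrichmentTable(table=df, label=label)


def enrich_global(
    bg: BackgroundFrequencies, targets: TargetFrequencies, inclusive: bool = True
) -> EnrichmentTable:
    """Global enrichment over the pooled target set (low-frequency filter only)."""
    return _score(bg, targets, GLOBAL_LOW_FREQ, None, inclusive, targets.label)


def enrich_per_connection(
    bg: BackgroundFrequencies,
    per_connection_targets: Sequence[TargetFrequencies],
    inclusive: bool = True,
) -> list[EnrichmentTable]:
    """Per TF-TF connection enrichment with the stricter frequency + P filters."""
    if not per_connection_targets:
        raise ValueError("need at least one connection")
    return [
        _score(bg, t, CONNECTION_LOW_FREQ, CONNECTION_MAX_P, inclusive, t.label)
        for t in per_connection_targets
    ]
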