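"""Feedforward-circuit census and classification.

A feedforward circuit (FFC) is an ordered triple (X, Y, Z): originating
regulator X targets intermediary regulator Y, and both target gene Z.  Z may
be any gene other than the genes encoding X and Y; it is classified as a
``TF`` target when its gene is annotated as a transcription factor and as an
``effecter`` (terminal, non-TF) target otherwise.

Three classification schemes are censused, plus their supporting pieces:

* **coherence** — by the modes of X and Y.  With each edge signed by its
  regulator's global mode, the direct X->Z sign equals the X->Y->Z product
  sign exactly when Y is an activator, so coherent = "Y activates"; type 1/2
  = "X activates / represses".
* **autoconfig** — by which of X and Y are autoregulated (matrix diagonal on
  their own gene rows): ``double``, ``intermediary_only``,
  ``originating_only`` or ``none``.
* **combined** — the (mode pair) x (autoconfig) product.  The ``(NN, double,
  effecter)`` cell of this scheme is the double-autorepression FFC (DAR-FFC).

Regulator chain *backbones* — ordered TF->TF edges X->Y irrespective of any
shared target — are censused under the same autoconfig and combined splits.
Mode-dependent categories exclude circuits containing a bimodal or
mode-unspecified TF; mode-independent categories include them.

Counting is pure matrix algebra on the binary connection matrix (verified
against brute-force triple enumeration in the test-suite); an explicit
generator over circuit instances is provided for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .netio import ConnectionMatrix, TFModeTable

__all__ = [
    "MODE_PAIRS",
    "AUTOCONFIGS",
    "TARGET_KINDS",
    "FFCInstance",
    "CircuitCategory",
    "MotifCensus",
    "classify_mode_pair",
    "classify_autoconfig",
    "count_ffcs",
    "iter_ffcs",
    "count_autoregulation",
    "full_census",
    "census_to_frame",
]

MODE_PAIRS = ("PP", "PN", "NP", "NN")
AUTOCONFIGS = ("double", "intermediary_only", "originating_only", "none")
TARGET_KINDS = ("TF", "effecter")

#: mode pair -> coherence label.  Coherent iff the intermediary (second
#: letter) is positive; type 1 iff the originating regulator (first letter)
#: is positive.
_COHERENCE = {
    "PP": "coherent_type1",
    "NP": "coherent_type2",
    "PN": "incoherent_type1",
    "NN": "incoherent_type2",
}

_SIGN_LETTER = {1: "P", -1: "N"}


@dataclass(frozen=True)
class FFCInstance:
    """One concrete circuit: TF indices x, y and gene-row index z."""

    x: int
    y: int
    z: int
    target_kind: str


@dataclass(frozen=True, order=True)
class CircuitCategory:
    """Canonical, hashable key for one censused circuit class."""

    scheme: str  # coherence | autoconfig | combined | backbone_autoconfig |
    #              backbone_combined | autoregulation | total
    mode_pair: str = "any"
    autoconfig: str = "any"
    target_kind: str = "any"


@dataclass
class MotifCensus:
    """Counts per circuit category for one connection matrix."""

    counts: dict[CircuitCategory, int]
    excluded_unmoded: int = 0

    def __getitem__(self, key: CircuitCategory) -> int:
        return self.counts[key]

    def total_ffcs(self) -> int:
        return self.counts[CircuitCategory("total")]

    def coherent(self, target_kind: str = "any") -> int:
        return self._coherence_sum(("PP", "NP"), target_kind)

    def incoherent(self, target_kind: str = "any") -> int:
        return self._coherence_sum(("PN", "NN"), target_kind)

    def _coherence_sum(self, pairs: tuple[str, ...], target_kind: str) -> int:
        kinds = TARGET_KINDS if target_kind == "any" else (target_kind,)
        return sum(
            self.counts[CircuitCategory("coherence", mp, "any", tk)]
            for mp in pairs
            for tk in kinds
        )


def classify_mode_pair(mode_x: str, mode_y: str) -> str:
    """Coherence label of a circuit from its regulators' global modes.

    Bimodal or unspecified in either slot yields ``excluded`` — the sign of
    such a TF's individual connections is uncertain, so the circuit cannot be
    placed in a mode-dependent category.
    """
    signs = {"activator": 1, "repressor": -1}
    sx, sy = signs.get(mode_x, 0), signs.get(mode_y, 0)
    if sx == 0 or sy == 0:
        return "excluded"
    return _COHERENCE[_SIGN_LETTER[sx] + _SIGN_LETTER[sy]]


def classify_autoconfig(auto_x: bool, auto_y: bool) -> str:
    """Autoregulation configuration label from the two diagonal flags."""
    if auto_x and auto_y:
        return "double"
    if auto_y:
        return "intermediary_only"
    if auto_x:
        return "originating_only"
    return "none"


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _tf_gene_mask(matrix: ConnectionMatrix, tf_gene_ids: Iterable[str] | None) -> np.ndarray:
    """Boolean per gene row: counted as a TF gene for target classification.

    Defaults to the genes encoding the matrix's TF columns; ``tf_gene_ids``
    extends the set (e.g. with TF-annotated genes lacking a matrix column).
    """
    mask = np.zeros(matrix.n_genes, dtype=bool)
    mask[matrix.tf_rows] = True
    if tf_gene_ids is not None:
        index = {g: i for i, g in enumerate(matrix.gene_ids)}
        for gid in tf_gene_ids:
            if gid in index:
                mask[index[gid]] = True
    return mask


def iter_ffcs(
    matrix: ConnectionMatrix, tf_gene_ids: Iterable[str] | None = None
) -> Iterator[FFCInstance]:
    """Yield every FFC instance exactly once (exhaustive, duplicate-free).

    Ordered TF pairs: when X->Y and Y->X both exist, (X, Y, Z) and (Y, X, Z)
    are distinct circuits.
    """
    M = matrix.entries
    rows = matrix.tf_rows
    is_tf_gene = _tf_gene_mask(matrix, tf_gene_ids)
    T = matrix.n_tfs
    for x in range(T):
        for y in range(T):
            if x == y or not M[rows[y], x]:
                continue
            common = np.flatnonzero(M[:, x] & M[:, y])
            for z in common:
                if z == rows[x] or z == rows[y]:
                    continue
                yield FFCInstance(
                    x, y, int(z), "TF" if is_tf_gene[z] else "effecter"
                )


def count_ffcs(
    matrix: ConnectionMatrix, tf_gene_ids: Iterable[str] | None = None
) -> int:
    """Total FFC count by matrix algebra (equals exhausting :func:`iter_ffcs`)."""
    census = full_census(matrix, modes=None, tf_gene_ids=tf_gene_ids)
    return census.total_ffcs()


def count_autoregulation(matrix: ConnectionMatrix) -> int:
    """Number of TFs with a binding site upstream of their own gene."""
    M = matrix.entries
    rows = matrix.tf_rows
    return int(sum(M[rows[j], j] for j in range(matrix.n_tfs)))


# ---------------------------------------------------------------------------
# algebraic census
# ---------------------------------------------------------------------------

def _mode_signs(matrix: ConnectionMatrix, modes: TFModeTable | None) -> np.ndarray:
    if modes is None:
        return np.zeros(matrix.n_tfs, dtype=np.int8)
    return np.array([modes.sign_of(s) for s in matrix.tf_symbols], dtype=np.int8)


def full_census(
    matrix: ConnectionMatrix,
    modes: TFModeTable | None,
    *,
    edge_signs: np.ndarray | None = None,
    tf_gene_ids: Iterable[str] | None = None,
) -> MotifCensus:
    """Count every censused category on one matrix.

    ``modes`` may be None, in which case only mode-independent categories are
    populated (mode-dependent counts are zero and every circuit counts as
    excluded).  ``edge_signs`` optionally overrides the TF-level modes with a
    per-edge sign matrix (G x T, values in {-1, 0, +1}; 0 = unsigned) used to
    classify each circuit by the signs of its X->Z and Y->Z edges — the
    generalization exercised by the mode-perturbation analysis.  With signs
    inherited from TF modes the two classifications coincide.
    """
    M = matrix.entries.astype(np.int64)
    G, T = M.shape
    rows = matrix.tf_rows
    auto = M[rows, np.arange(T)].astype(bool)  # autoregulation flag per TF
    A = M[rows, :].T  # A[x, y] = 1 iff edge X->Y
    gate = A * (1 - np.eye(T, dtype=np.int64))  # ordered pairs x != y with X->Y

    is_tf_gene = _tf_gene_mask(matrix, tf_gene_ids)
    M_by_kind = {"TF": M * is_tf_gene[:, None], "effecter": M * (~is_tf_gene)[:, None]}

    # Common-target counts per ordered TF pair, split by target kind.  For TF
    # targets the rows encoding X and Y themselves must be excluded: the
    # z = row(X) term is auto[x] * edge(Y->X), the z = row(Y) term is
    # edge(X->Y) * auto[y].  (Those rows are TF genes, so effecter counts
    # need no correction.)
    def common_counts(Mx: np.ndarray, My: np.ndarray, kind: str) -> np.ndarray:
        C = Mx.T @ My
        if kind == "TF":
            u1 = Mx[rows, np.arange(T)]  # signed/plain auto indicator of X
            u2 = My[rows, np.arange(T)]
            V2 = My[rows, :]  # V2[x, y] = My[row(x), y] = edge y->x in My
            A1 = Mx[rows, :].T  # A1[x, y] = edge x->y in Mx
            C = C - u1[:, None] * V2 - A1 * u2[None, :]
        return C

    # mode-independent per-pair FFC counts
    F_any = {k: gate * common_counts(M_by_kind[k], M_by_kind[k], k) for k in TARGET_KINDS}

    # signed per-pair FFC counts: split each kind by (sign of X->Z, sign of Y->Z)
    if edge_signs is None:
        sign_vec = _mode_signs(matrix, modes)
        S = M * sign_vec[None, :]
    else:
        S = np.asarray(edge_signs, dtype=np.int64) * M  # restrict to present edges
    S_by = {1: (S > 0).astype(np.int64), -1: (S < 0).astype(np.int64)}
    F_signed: dict[str, dict[str, np.ndarray]] = {k: {} for k in TARGET_KINDS}
    for kind in TARGET_KINDS:
        kind_mask = is_tf_gene[:, None] if kind == "TF" else (~is_tf_gene)[:, None]
        for s1 in (1, -1):
            for s2 in (1, -1):
                Mx = S_by[s1] * kind_mask
                My = S_by[s2] * kind_mask
                mp = _SIGN_LETTER[s1] + _SIGN_LETTER[s2]
                F_signed[kind][mp] = gate * common_counts(Mx, My, kind)

    # pair-class masks
    ac_masks = {
        "double": np.outer(auto, auto),
        "intermediary_only": np.outer(~auto, auto),
        "originating_only": np.outer(auto, ~auto),
        "none": np.outer(~auto, ~auto),
    }
    sign_vec = _mode_signs(matrix, modes)
    mp_masks = {
        _SIGN_LETTER[s1] + _SIGN_LETTER[s2]: np.outer(sign_vec == s1, sign_vec == s2)
        for s1 in (1, -1)
        for s2 in (1, -1)
    }

    counts: dict[CircuitCategory, int] = {}

    # totals and autoregulation
    for tk in TARGET_KINDS:
        counts[CircuitCategory("total", target_kind=tk)] = int(F_any[tk].sum())
    counts[CircuitCategory("total")] = sum(
        counts[CircuitCategory("total", target_kind=tk)] for tk in TARGET_KINDS
    )
    counts[CircuitCategory("autoregulation")] = int(auto.sum())

    # coherence (mode pair, any autoconfig) and combined (mode pair x autoconfig)
    moded_total = 0
    for tk in TARGET_KINDS:
        for mp in MODE_PAIRS:
            F = F_signed[tk][mp]
            counts[CircuitCategory("coherence", mp, "any", tk)] = int(F.sum())
            moded_total += int(F.sum())
            for ac, mask in ac_masks.items():
                counts[CircuitCategory("combined", mp, ac, tk)] = int(F[mask].sum())

    # autoconfig scheme (mode-independent)
    for tk in TARGET_KINDS:
        for ac, mask in ac_masks.items():
            counts[CircuitCategory("autoconfig", "any", ac, tk)] = int(
                F_any[tk][mask].sum()
            )

    # backbones: ordered TF->TF pairs, by autoconfig and by TF-level mode pair
    for ac, mask in ac_masks.items():
        counts[CircuitCategory("backbone_autoconfig", "any", ac)] = int(
            gate[mask].sum()
        )
        for mp in MODE_PAIRS:
            counts[CircuitCategory("backbone_combined", mp, ac)] = int(
                gate[mask & mp_masks[mp]].sum()
            )

    excluded = counts[CircuitCategory("total")] - moded_total
    return MotifCensus(counts=counts, excluded_unmoded=excluded)


def census_to_frame(census: MotifCensus) -> pd.DataFrame:
    """Census as a tidy table: scheme, mode_pair, autoconfig, target_kind, count."""
    rows = [
        {
            "scheme": c.scheme,
            "mode_pair": c.mode_pair,
            "autoconfig": c.autoconfig,
            "target_kind": c.target_kind,
            "count": n,
        }
        for c, n in sorted(census.counts.items())
    ]
    return pd.DataFrame(rows)
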