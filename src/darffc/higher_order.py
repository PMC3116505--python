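"""DAR-FFC TF-TF connections, higher-order DAR-FFCs and originating hubs.

A DAR-FFC (double-autorepression feedforward circuit) is an FFC whose two
regulators are both repressors and both autoregulated.  Collapsing each such
circuit family onto its TF-TF edge gives the set of *DAR connections*:
ordered pairs X -> Y of autoregulated repressors with the X -> Y edge present
and at least one jointly repressed effecter target.

When three TFs are wired so that (X, Y), (X, Z) and (Y, Z) are all DAR
connections, the connections themselves form a feedforward-shaped triangle —
a *higher-order* DAR-FFC whose target is a TF rather than an effecter set.
Roles follow from the triangle: the out-degree-2 node is the originating
regulator X, the in-degree-2 node the target Z, the remaining node the
intermediary Y.  A TF that appears in at least two higher-order circuits and
always in role X is an originating-regulator hub.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .census import _tf_gene_mask
from .netio import ConnectionMatrix, TFModeTable

__all__ = [
    "DARConnection",
    "HigherOrderFFC",
    "RoleProfile",
    "dar_connections",
    "find_higher_order",
    "find_hubs",
    "connections_to_frame",
    "export_dot",
]


@dataclass(frozen=True)
class DARConnection:
    """Ordered TF-TF edge of a DAR-FFC with its shared effecter targets."""

    x: str
    y: str
    shared_effecter_targets: frozenset[str]

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("DAR connection endpoints must differ")
        if not self.shared_effecter_targets:
            raise ValueError("DAR connection requires >= 1 shared effecter target")


@dataclass(frozen=True)
class HigherOrderFFC:
    """Triangle of DAR connections; x/y/z are originating/intermediary/target."""

    x: str
    y: str
    z: str


@dataclass
class RoleProfile:
    tf: str
    n_x: int
    n_y: int
    n_z: int

    @property
    def total(self) -> int:
        return self.n_x + self.n_y + self.n_z

    @property
    def is_hub(self) -> bool:
        """In >= 2 higher-order circuits, always as originating regulator."""
        return self.total >= 2 and self.n_y == 0 and self.n_z == 0


def dar_connections(
    matrix: ConnectionMatrix,
    modes: TFModeTable,
    tf_gene_ids: Sequence[str] | None = None,
) -> list[DARConnection]:
    """All ordered (X, Y) pairs carrying at least one DAR-FFC.

    Requires: both TFs repressor-moded, both autoregulated, edge X -> Y
    present, and >= 1 common effecter target (the targets of the circuits the
    pair supports).  Each qualifying pair is reported once with its full
    shared target set.
    """
    M = matrix.entries
    rows = matrix.tf_rows
    T = matrix.n_tfs
    is_tf_gene = _tf_gene_mask(matrix, tf_gene_ids)
    eligible = [
        j
        for j in range(T)
        if modes.mode_of.get(matrix.tf_symbols[j]) == "repressor" and M[rows[j], j]
    ]
    out: list[DARConnection] = []
    for x in eligible:
        for y in eligible:
            if x == y or not M[rows[y], x]:
                continue
            common = np.flatnonzero(M[:, x] & M[:, y] & ~is_tf_gene)
            if common.size:
                out.append(
                    DARConnection(
                        matrix.tf_symbols[x],
                        matrix.tf_symbols[y],
                        frozenset(matrix.gene_ids[i] for i in common),
                    )
                )
    return out


def find_higher_order(
    connections: Sequence[DARConnection],
    *,
    matrix: ConnectionMatrix | None = None,
    xy_edge: Literal["dar", "matrix"] = "dar",
) -> list[HigherOrderFFC]:
    """Feedforward triangles among the DAR connections.

    Default (``xy_edge="dar"``): all three edges (X,Y), (X,Z), (Y,Z) must be
    DAR connections.  With ``xy_edge="matrix"`` the X -> Y edge only needs to
    be present in the connection matrix (the two target-sharing edges must
    still be DAR connections) — a looser reading in which the target TF's
    two incoming connections define the circuit.
    """
    edges = {(c.x, c.y) for c in connections}
    nodes = sorted({n for c in connections for n in (c.x, c.y)})
    if xy_edge == "matrix":
        if matrix is None:
            raise ValueError('xy_edge="matrix" requires the connection matrix')
        present = {
            (a, b)
            for a in matrix.tf_symbols
            for b in matrix.tf_symbols
            if a != b and matrix.entries[matrix.tf_row_of[b], matrix.tf_symbols.index(a)]
        }
        xy_ok = present
    else:
        xy_ok = edges
    out = []
    for x, y, z in permutations(nodes, 3):
        if (x, y) in xy_ok and (x, z) in edges and (y, z) in edges:
            out.append(HigherOrderFFC(x, y, z))
    return out


def find_hubs(hoffcs: Sequence[HigherOrderFFC]) -> list[RoleProfile]:
    """Role profile per TF, sorted by pure-X hubs first then involvement."""
    tally: dict[str, list[int]] = {}
    for h in hoffcs:
        for tf, slot in ((h.x, 0), (h.y, 1), (h.z, 2)):
            tally.setdefault(tf, [0, 0, 0])[slot] += 1
    profiles = [RoleProfile(tf, *counts) for tf, counts in tally.items()]
    profiles.sort(key=lambda p: (not p.is_hub, -p.total, p.tf))
    return profiles


def connections_to_frame(connections: Sequence[DARConnection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": c.x,
                "y": c.y,
                "n_shared_targets": len(c.shared_effecter_targets),
                "target_ids": ",".join(sorted(c.shared_effecter_targets)),
            }
            for c in connections
        ],
        columns=["x", "y", "n_shared_targets", "target_ids"],
    )


def export_dot(
    connections: Sequence[DARConnection],
    hoffcs: Sequence[HigherOrderFFC] = (),
    path: str | Path | None = None,
) -> str:
    """DOT digraph of the DAR connection network (triangle edges highlighted)."""
    tri_edges = {(h.x, h.y) for h in hoffcs} | {(h.x, h.z) for h in hoffcs} | {
        (h.y, h.z) for h in hoffcs
    }
    lines = ["digraph dar_ffc {", "  node [shape=oval];"]
    for c in sorted(connections, key=lambda c: (c.x, c.y)):
        style = ' [color=blue, penwidth=2]' if (c.x, c.y) in tri_edges else ""
        lines.append(f'  "{c.x}" -> "{c.y}"{style};')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
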