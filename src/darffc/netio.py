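"""Readers and writers for the regulatory-network input tables.

Three flat tab-separated inputs drive the analysis:

* a binary **connection matrix** with genes in rows (keyed by gene ID) and
  transcription factors (TFs) in columns (keyed by gene symbol); entry
  ``(i, j) = 1`` means TF *j* has a predicted binding site upstream of gene
  *i* and therefore targets it,
* a **TF mode table** assigning each TF a global regulatory mode
  (``activator``, ``repressor``, ``bimodal`` or ``unspecified``), and
* a **GO annotation table** in gene2go-style columns (gene ID, GO term,
  namespace), where duplicate records are meaningful and preserved.

Every TF is itself encoded by one of the gene rows, which is what makes
autoregulation (the matrix diagonal restricted to TF rows) observable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "MODES",
    "NAMESPACES",
    "ConnectionMatrix",
    "TFModeTable",
    "GOAnnotationTable",
    "read_connection_matrix",
    "write_connection_matrix",
    "read_mode_table",
    "write_mode_table",
    "read_go_annotations",
    "write_go_annotations",
]

logger = logging.getLogger(__name__)

MODES = ("activator", "repressor", "bimodal", "unspecified")

#: GO namespaces retained by the enrichment analysis.
NAMESPACES = ("molecular_function", "biological_process")

_GO_ID = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


@dataclass
class ConnectionMatrix:
    """Binary TF-to-gene targeting matrix.

    ``entries[i, j] == 1`` iff TF ``tf_symbols[j]`` targets gene
    ``gene_ids[i]``.  ``tf_row_of`` maps each TF symbol to the row index of
    the gene that encodes it, so ``entries[tf_row_of[s], j]`` with
    ``s == tf_symbols[j]`` is that TF's autoregulation flag.
    """

    gene_ids: list[str]
    tf_symbols: list[str]
    entries: np.ndarray
    tf_row_of: dict[str, int]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.uint8)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        G, T = self.entries.shape
        if len(self.gene_ids) != G or len(self.tf_symbols) != T:
            raise ValidationError(
                f"entries shape {self.entries.shape} does not match "
                f"{len(self.gene_ids)} gene IDs x {len(self.tf_symbols)} TF symbols"
            )
        if len(set(self.gene_ids)) != G:
            raise ValidationError("duplicate gene IDs")
        if len(set(self.tf_symbols)) != T:
            raise ValidationError("duplicate TF symbols")
        bad = (self.entries != 0) & (self.entries != 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary cell at gene {self.gene_ids[i]!r} / TF {self.tf_symbols[j]!r}"
            )
        missing = [s for s in self.tf_symbols if s not in self.tf_row_of]
        if missing:
            raise ValidationError(f"TF symbols without a gene row: {missing}")
        for s, r in self.tf_row_of.items():
            if not 0 <= r < G:
                raise ValidationError(f"TF {s!r} maps to out-of-range row {r}")
        if len(set(self.tf_row_of[s] for s in self.tf_symbols)) != T:
            raise ValidationError("two TF symbols map to the same gene row")

    # -- accessors ----------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_tfs(self) -> int:
        return self.entries.shape[1]

    @property
    def tf_rows(self) -> np.ndarray:
        """Row index of each TF column's own gene, aligned with ``tf_symbols``."""
        return np.array([self.tf_row_of[s] for s in self.tf_symbols], dtype=np.intp)

    def row_sums(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.entries.sum(axis=0)

    def with_entries(self, entries: np.ndarray) -> "ConnectionMatrix":
        """Same gene/TF labelling with a replacement entry array."""
        return ConnectionMatrix(
            gene_ids=list(self.gene_ids),
            tf_symbols=list(self.tf_symbols),
            entries=np.asarray(entries, dtype=np.uint8),
            tf_row_of=dict(self.tf_row_of),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.gene_ids, columns=self.tf_symbols)


@dataclass
class TFModeTable:
    """Global regulatory mode per TF, plus the symbol -> gene ID join.

    The (symbol, gene ID) pairs are the authoritative mapping used to locate
    each TF's own gene row in the connection matrix.
    """

    mode_of: dict[str, str]
    gene_id_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: m for s, m in self.mode_of.items() if m not in MODES}
        if bad:
            raise ValidationError(f"modes outside {MODES}: {bad}")

    def cross_validate(self, matrix: ConnectionMatrix) -> list[str]:
        """Return warnings for symbols not shared between table and matrix."""
        warnings = []
        for s in self.mode_of:
            if s not in matrix.tf_row_of:
                warnings.append(f"mode table symbol {s!r} absent from matrix")
        for s in matrix.tf_symbols:
            if s not in self.mode_of:
                warnings.append(f"matrix TF {s!r} has no mode annotation")
        return warnings

    def sign_of(self, symbol: str) -> int:
        """+1 for activator, -1 for repressor, 0 for bimodal/unspecified."""
        m = self.mode_of.get(symbol, "unspecified")
        return {"activator": 1, "repressor": -1}.get(m, 0)


@dataclass
class GOAnnotationTable:
    """Flat gene -> GO-term records; duplicates retained (redundant counting)."""

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        bad = {ns for _, _, ns in self.records if ns not in NAMESPACES}
        if bad:
            raise ValidationError(f"namespaces outside {NAMESPACES}: {sorted(bad)}")

    def for_namespace(self, namespace: str) -> list[tuple[str, str]]:
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        return [(g, t) for g, t, ns in self.records if ns == namespace]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["gene_id", "term_id", "namespace"])


# ---------------------------------------------------------------------------
# connection matrix
# ---------------------------------------------------------------------------

def read_connection_matrix(
    path: str | Path,
    symbol_to_gene_id: Mapping[str, str] | None = None,
) -> ConnectionMatrix:
    """Read a gene x TF 0/1 matrix from TSV.

    The file has one header row of TF symbols and a leading key column of
    gene IDs.  ``symbol_to_gene_id`` resolves each TF column to its own gene
    row (normally the mode table's symbol/gene-ID pairs); when omitted, a TF
    symbol is assumed to appear verbatim as a gene ID (the convention used by
    the synthetic generator).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    tf_symbols = [str(c) for c in df.columns]
    if len(set(tf_symbols)) != len(tf_symbols):
        raise ValidationError(f"{path}: repeated TF symbol in header")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"{path}: duplicate gene ID in key column")

    values = df.to_numpy()
    entries = np.zeros(values.shape, dtype=np.uint8)
    for (i, j), v in np.ndenumerate(values):
        v = str(v).strip()
        if v not in ("0", "1"):
            raise FormatError(
                f"{path}: non-binary cell {v!r} at gene {gene_ids[i]!r} / TF {tf_symbols[j]!r}"
            )
        entries[i, j] = int(v)

    row_index = {g: i for i, g in enumerate(gene_ids)}
    tf_row_of: dict[str, int] = {}
    for s in tf_symbols:
        gid = symbol_to_gene_id.get(s, s) if symbol_to_gene_id else s
        if gid not in row_index:
            raise ValidationError(
                f"{path}: TF {s!r} (gene ID {gid!r}) has no gene row in the matrix"
            )
        tf_row_of[s] = row_index[gid]

    return ConnectionMatrix(gene_ids, tf_symbols, entries, tf_row_of)


def write_connection_matrix(matrix: ConnectionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# TF mode table
# ---------------------------------------------------------------------------

def read_mode_table(path: str | Path, lenient: bool = False) -> TFModeTable:
    """Read the TF mode table (symbol, gene ID, mode[, source] columns).

    Unrecognized mode strings raise unless ``lenient`` is set, in which case
    they map to ``unspecified``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("symbol", "gene_id", "mode"):
        if needed not in cols:
            raise FormatError(f"{path}: missing required column {needed!r}")
    mode_of: dict[str, str] = {}
    gene_id_of: dict[str, str] = {}
    for _, row in df.iterrows():
        sym = str(row[cols["symbol"]])
        mode = str(row[cols["mode"]]).strip().lower()
        if mode not in MODES:
            if not lenient:
                raise FormatError(f"{path}: unknown mode {mode!r} for TF {sym!r}")
            logger.warning("TF %s: unknown mode %r mapped to 'unspecified'", sym, mode)
            mode = "unspecified"
        mode_of[sym] = mode
        gene_id_of[sym] = str(row[cols["gene_id"]])
    return TFModeTable(mode_of=mode_of, gene_id_of=gene_id_of)


def write_mode_table(modes: TFModeTable, path: str | Path) -> None:
    rows = [
        {"symbol": s, "gene_id": modes.gene_id_of.get(s, s), "mode": m}
        for s, m in modes.mode_of.items()
    ]
    pd.DataFrame(rows, columns=["symbol", "gene_id", "mode"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def read_go_annotations(path: str | Path) -> GOAnnotationTable:
    """Read gene2go-style records, keeping duplicates.

    Records in namespaces other than molecular_function/biological_process
    are dropped (count logged); records with malformed GO IDs are skipped
    with a warning.  An empty file yields an empty table.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return GOAnnotationTable(records=[])
    cols = {c.lower(): c for c in df.columns}
    for needed in ("gene_id", "term_id", "namespace"):
        if needed not in cols:
            raise FormatError(f"{path}: missing required column {needed!r}")
    records: list[tuple[str, str, str]] = []
    dropped_ns = 0
    for _, row in df.iterrows():
        gene = str(row[cols["gene_id"]])
        term = str(row[cols["term_id"]])
        ns = str(row[cols["namespace"]]).strip().lower()
        if not _GO_ID.match(term):
            logger.warning("skipping record with malformed GO ID %r (gene %s)", term, gene)
            continue
        if ns not in NAMESPACES:
            dropped_ns += 1
            continue
        records.append((gene, term, ns))
    if dropped_ns:
        logger.info("dropped %d records in unanalyzed namespaces", dropped_ns)
    return GOAnnotationTable(records=records)


def write_go_annotations(table: GOAnnotationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
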