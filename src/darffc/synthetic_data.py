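"""Synthetic regulatory networks and annotation tables with known ground truth.

The generator emulates the structural features the pipeline is sensitive to:
a binary TF -> gene matrix whose TF genes are a subset of the gene rows,
heavy-tailed TF out-degrees (discretized log-normal by default), a
controllable repressor/activator/bimodal mix, controllable autoregulation
density, optional planted DAR-FFCs (ordered pairs of autoregulated
repressors sharing effecter targets), and gene2go-style annotation tables
with planted term enrichment among chosen target genes.  Every generated
quantity needed to predict the censused outcome is recorded in a
:class:`SyntheticTruth` sidecar.

Gene IDs follow the convention the readers default to: each TF's own gene
row is keyed by the TF symbol itself, the remaining rows by ``G####``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .netio import ConnectionMatrix, GOAnnotationTable, TFModeTable

__all__ = ["SyntheticTruth", "generate_network", "plant_dar_ffcs", "generate_annotations"]


@dataclass
class SyntheticTruth:
    """Ground-truth record sufficient to recompute planted quantities."""

    seed: int | None = None
    n_tf: int = 0
    n_genes: int = 0
    repressor_fraction: float = 0.0
    autoregulation_prob: float = 0.0
    out_degrees: list[int] = field(default_factory=list)
    planted_dar_count: int = 0
    planted_dar_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_dar_targets: dict[str, list[str]] = field(default_factory=dict)
    planted_enriched_terms: list[str] = field(default_factory=list)
    enrichment_multiplier: float = 1.0
    expected_f_g: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _seed_int(seed) -> int | None:
    return seed if isinstance(seed, (int, np.integer)) else None


def generate_network(
    n_tf: int,
    n_genes: int,
    mean_out_degree: float | None = None,
    out_degree_sigma: float = 0.8,
    out_degrees: Sequence[int] | None = None,
    repressor_fraction: float = 0.5,
    bimodal_fraction: float = 0.0,
    autoregulation_prob: float = 0.3,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[ConnectionMatrix, TFModeTable, SyntheticTruth]:
    """Random degree-heterogeneous binary regulatory matrix plus mode table.

    Out-degrees are drawn from a discretized log-normal with the requested
    mean (default ``0.12 * n_genes``, a broad, dense regime comparable to a
    conserved-TFBS-derived matrix) and clipped to ``[1, n_genes]``; pass
    ``out_degrees`` to fix them exactly.  Modes are drawn independently per
    TF: repressor with ``repressor_fraction``, bimodal with
    ``bimodal_fraction``, activator otherwise.  Each TF's diagonal
    (autoregulation) entry is then forced present with probability
    ``autoregulation_prob`` and absent otherwise.
    """
    if n_tf <= 0:
        raise ValueError("n_tf must be positive")
    if n_tf > n_genes:
        raise ValueError("TF genes must be a subset of the gene rows (n_tf <= n_genes)")
    if not 0 <= repressor_fraction <= 1 or not 0 <= bimodal_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if repressor_fraction + bimodal_fraction > 1:
        raise ValueError("repressor_fraction + bimodal_fraction must be <= 1")
    if not 0 <= autoregulation_prob <= 1:
        raise ValueError("autoregulation_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    width = max(2, len(str(n_tf)))
    tf_symbols = [f"TF{j + 1:0{width}d}" for j in range(n_tf)]
    gene_ids = tf_symbols + [f"G{i + 1:04d}" for i in range(n_genes - n_tf)]

    if out_degrees is not None:
        degrees = np.asarray(out_degrees, dtype=int)
        if degrees.shape != (n_tf,):
            raise ValueError(f"out_degrees must have length {n_tf}")
        if degrees.min() < 0 or degrees.max() > n_genes:
            raise ValueError("out_degrees must lie in [0, n_genes]")
    else:
        if mean_out_degree is None:
            mean_out_degree = 0.12 * n_genes
        if not 0 < mean_out_degree <= n_genes:
            raise ValueError("mean_out_degree must lie in (0, n_genes]")
        # log-normal parameterized so the distribution mean hits the request
        mu = np.log(mean_out_degree) - out_degree_sigma**2 / 2
        draws = rng.lognormal(mu, out_degree_sigma, size=n_tf)
        degrees = np.clip(np.rint(draws), 1, n_genes).astype(int)

    entries = np.zeros((n_genes, n_tf), dtype=np.uint8)
    for j in range(n_tf):
        targets = rng.choice(n_genes, size=degrees[j], replace=False)
        entries[targets, j] = 1
    diag = rng.random(n_tf) < autoregulation_prob
    entries[np.arange(n_tf), np.arange(n_tf)] = diag.astype(np.uint8)

    u = rng.random(n_tf)
    mode_of = {}
    for j, s in enumerate(tf_symbols):
        if u[j] < repressor_fraction:
            mode_of[s] = "repressor"
        elif u[j] < repressor_fraction + bimodal_fraction:
            mode_of[s] = "bimodal"
        else:
            mode_of[s] = "activator"

    matrix = ConnectionMatrix(
        gene_ids=gene_ids,
        tf_symbols=tf_symbols,
        entries=entries,
        tf_row_of={s: j for j, s in enumerate(tf_symbols)},
    )
    modes = TFModeTable(mode_of=mode_of, gene_id_of={s: s for s in tf_symbols})
    truth = SyntheticTruth(
        seed=_seed_int(seed),
        n_tf=n_tf,
        n_genes=n_genes,
        repressor_fraction=repressor_fraction,
        autoregulation_prob=autoregulation_prob,
        out_degrees=[int(d) for d in matrix.col_sums()],
    )
    return matrix, modes, truth


def plant_dar_ffcs(
    matrix: ConnectionMatrix,
    modes: TFModeTable,
    k: int,
    targets_per: int = 3,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[ConnectionMatrix, SyntheticTruth]:
    """Plant ``k`` DAR-FFC TF-TF connections into a copy of ``matrix``.

    Each planted connection picks a fresh ordered pair of distinct repressor
    TFs, sets both autoregulation diagonals, adds the X -> Y edge and gives
    the pair ``targets_per`` common non-TF targets.  The census of the
    result therefore finds at least ``k * targets_per`` circuits in the
    (NN, double, effecter) category and :func:`~darffc.higher_order.
    dar_connections` at least the ``k`` planted pairs.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if targets_per < 1:
        raise ValueError("targets_per must be >= 1")
    rng = np.random.default_rng(seed)
    entries = matrix.entries.copy()
    T = matrix.n_tfs
    repressors = [
        j for j in range(T) if modes.mode_of.get(matrix.tf_symbols[j]) == "repressor"
    ]
    if len(repressors) < 2 and k > 0:
        raise ValueError("need at least 2 repressor TFs to plant DAR-FFCs")
    pairs = [(x, y) for x in repressors for y in repressors if x != y]
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the {len(pairs)} available repressor pairs")
    chosen_idx = rng.choice(len(pairs), size=k, replace=False)

    tf_row_set = set(int(r) for r in matrix.tf_rows)
    non_tf_rows = np.array(
        [i for i in range(matrix.n_genes) if i not in tf_row_set], dtype=int
    )
    if k > 0 and non_tf_rows.size < targets_per:
        raise ValueError("not enough non-TF genes for the requested targets_per")

    truth = SyntheticTruth(seed=_seed_int(seed), planted_dar_count=k)
    rows = matrix.tf_rows
    for idx in chosen_idx:
        x, y = pairs[idx]
        entries[rows[x], x] = 1
        entries[rows[y], y] = 1
        entries[rows[y], x] = 1  # edge X -> Y
        targets = rng.choice(non_tf_rows, size=targets_per, replace=False)
        entries[targets, x] = 1
        entries[targets, y] = 1
        sx, sy = matrix.tf_symbols[x], matrix.tf_symbols[y]
        truth.planted_dar_pairs.append((sx, sy))
        truth.planted_dar_targets[f"{sx}->{sy}"] = [
            matrix.gene_ids[t] for t in targets
        ]
    return matrix.with_entries(entries), truth


def generate_annotations(
    genes: Sequence[str],
    vocabulary_size: int = 200,
    mean_terms_per_gene: float = 2.5,
    zipf_exponent: float = 1.0,
    namespace: str = "molecular_function",
    planted_terms: Sequence[str] = (),
    target_genes: Sequence[str] = (),
    multiplier: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[GOAnnotationTable, SyntheticTruth]:
    """gene2go-style table with optional planted enrichment.

    Background: each gene receives ``Poisson(mean_terms_per_gene)`` records
    drawn from a Zipf-weighted vocabulary (``GO:0000001`` ...); the mean of
    2.5 terms per gene matches a typical curated-annotation density.
    Planting: each target gene additionally receives
    ``Poisson((multiplier - 1) * rate_g)`` copies of each planted term, so a
    planted term's appearance rate among targets is ``multiplier`` times its
    background rate; ``multiplier = 1`` plants nothing.  Expected target
    counts are recorded in the truth sidecar.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    vocab = [f"GO:{i + 1:07d}" for i in range(vocabulary_size)]
    for t in planted_terms:
        if t not in vocab:
            raise ValueError(f"planted term {t!r} outside the vocabulary")
    records: list[tuple[str, str, str]] = []
    truth = SyntheticTruth(
        seed=_seed_int(seed),
        planted_enriched_terms=list(planted_terms),
        enrichment_multiplier=multiplier,
    )
    if vocabulary_size == 0:
        return GOAnnotationTable(records=[]), truth

    weights = 1.0 / np.arange(1, vocabulary_size + 1) ** zipf_exponent
    probs = weights / weights.sum()
    for g in genes:
        n = rng.poisson(mean_terms_per_gene)
        for t_idx in rng.choice(vocabulary_size, size=n, p=probs):
            records.append((g, vocab[t_idx], namespace))
    target_set = list(dict.fromkeys(target_genes))
    for term in planted_terms:
        rate = mean_terms_per_gene * probs[vocab.index(term)]
        extra_rate = (multiplier - 1.0) * rate
        for g in target_set:
            for _ in range(rng.poisson(extra_rate)):
                records.append((g, term, namespace))
        truth.expected_f_g[term] = multiplier * rate * len(target_set)
    return GOAnnotationTable(records=records), truth
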