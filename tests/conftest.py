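import numpy as np
import pytest

from darffc import ConnectionMatrix, TFModeTable


def make_matrix(entries, tf_symbols=None, gene_ids=None):
    """ConnectionMatrix from a dense 0/1 array; TF j's gene is row j."""
    entries = np.asarray(entries, dtype=np.uint8)
    G, T = entries.shape
    tf_symbols = tf_symbols or [f"TF{j + 1:02d}" for j in range(T)]
    gene_ids = gene_ids or (tf_symbols + [f"G{i + 1:04d}" for i in range(G - T)])
    return ConnectionMatrix(
        gene_ids=gene_ids,
        tf_symbols=tf_symbols,
        entries=entries,
        tf_row_of={s: j for j, s in enumerate(tf_symbols)},
    )


def make_modes(matrix, modes):
    """TFModeTable assigning the listed modes to the matrix's TFs in order."""
    return TFModeTable(
        mode_of=dict(zip(matrix.tf_symbols, modes)),
        gene_id_of={s: s for s in matrix.tf_symbols},
    )


def random_matrix(rng, n_tf, n_genes, density=0.3, autoreg_prob=0.4):
    entries = (rng.random((n_genes, n_tf)) < density).astype(np.uint8)
    entries[np.arange(n_tf), np.arange(n_tf)] = (
        rng.random(n_tf) < autoreg_prob
    ).astype(np.uint8)
    return make_matrix(entries)


def random_modes(rng, matrix, weights=(0.4, 0.4, 0.1, 0.1)):
    choices = ["activator", "repressor", "bimodal", "unspecified"]
    drawn = rng.choice(choices, size=matrix.n_tfs, p=weights)
    return make_modes(matrix, drawn)


@pytest.fixture
def triangle_matrix():
    """Single FFC: TF1 -> TF2, both -> gene G0001 (row 2)."""
    entries = np.zeros((3, 2), dtype=np.uint8)
    entries[1, 0] = 1  # X -> Y
    entries[2, 0] = 1  # X -> Z
    entries[2, 1] = 1  # Y -> Z
    return make_matrix(entries, tf_symbols=["TF1", "TF2"])
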