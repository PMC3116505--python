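"""Census a small synthetic regulatory network.

Generates a 16-TF x 120-gene binary connection matrix, counts feedforward
circuits (FFCs) and classifies them by regulator modes, autoregulation
configuration and target kind.
"""

from darffc import CircuitCategory, count_autoregulation, full_census, generate_network

matrix, modes, _ = generate_network(
    n_tf=16, n_genes=120, mean_out_degree=22,
    repressor_fraction=0.5, autoregulation_prob=0.4, seed=0,
)

census = full_census(matrix, modes)
print(f"total FFCs:            {census.total_ffcs()}")
print(f"  coherent:            {census.coherent()}")
print(f"  incoherent:          {census.incoherent()}")
print(f"  (both regulators moded; excluded: {census.excluded_unmoded})")
print(f"autoregulated TFs:     {count_autoregulation(matrix)} of {matrix.n_tfs}")
dar = census.counts[CircuitCategory("combined", "NN", "double", "effecter")]
print(f"DAR-FFCs (NN/double/effecter): {dar}")

# coherent + incoherent = total when every TF is an activator or repressor;
# the DAR-FFC count is the cell of the combined classification where both
# regulators are autoregulated repressors and the target is a non-TF gene.
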