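# darffc

Network-motif analysis for transcriptional regulatory networks: a census of
feedforward circuits (FFCs) under mode-based, autoregulation-based and
combined classifications, significance against a degree-preserving
randomized ensemble, redundant-count binomial GO enrichment of
double-autorepression FFC (DAR-FFC) targets, higher-order DAR-FFC
detection, and robustness analysis under TF-mode perturbation.

## The problem

A transcriptional network is summarized as a binary connection matrix
`M` (genes × TFs, `M[i,j] = 1` iff TF *j* targets gene *i*; every TF is
itself one of the genes, so the diagonal of a TF's own row records
autoregulation). A **feedforward circuit** is an ordered triple (X, Y, Z):
originating regulator X targets intermediary regulator Y and both target
gene Z. Circuits are classified by

- the regulators' modes: with edges signed by regulator mode, a circuit is
  *coherent* iff Y is an activator and *type 1* iff X is an activator;
- the autoregulation configuration of X and Y: double / intermediary-only /
  originating-only / none;
- the target kind: a TF gene (the circuit feeds further regulation) or an
  *effecter* (terminal output);

and each category count is compared with its distribution over an ensemble
of degree-preserving randomizations (checkerboard edge swaps preserving
every row and column sum):

    Z = (N_real − ⟨N_null⟩) / sd(N_null),   P = normal tail toward the deviation.

Positive Z marks a network motif, negative Z an antimotif. The
(NN, double, effecter) cell of the combined classification — both
regulators autoregulated repressors, effecter target — is the **DAR-FFC**.
For the effecter genes targeted by DAR-FFC TF–TF connections, GO term
enrichment uses redundant counting (an effecter targeted by k connections
contributes its annotations k times) with a binomial upper-tail P:
f_g ~ Binomial(D, r_g), r_g = F_g/E over the effecter background. DAR
connections that themselves form feedforward triangles are higher-order
DAR-FFCs, whose target is a TF; a TF acting only as originating regulator
in ≥ 2 of them is an originating-regulator hub.

The package is aimed at systems-biology analyses of curated or predicted
TF→target matrices, and ships a synthetic-data generator (planted
DAR-FFCs, planted GO enrichment, known ground truth) so the whole pipeline
is exercisable and testable without any external data.

## Worked example

```python
import numpy as np
from darffc import (CircuitCategory, full_census, generate_network,
                    plant_dar_ffcs, randomize, summarize_ensemble)

matrix, modes, truth = generate_network(
    n_tf=16, n_genes=120, mean_out_degree=22,
    repressor_fraction=0.5, autoregulation_prob=0.4, seed=0)
matrix, _ = plant_dar_ffcs(matrix, modes, k=12, targets_per=5, seed=1)

ensemble = [randomize(matrix, steps=5000, seed=np.random.SeedSequence([2, i]))
            for i in range(60)]
summary = summarize_ensemble(full_census(matrix, modes),
                             [full_census(m, modes) for m in ensemble])
dar = summary[CircuitCategory("combined", "NN", "double", "effecter")]
print(f"DAR-FFC: real={dar.real_count} null={dar.null_mean:.2f}"
      f"±{dar.null_sd:.2f} Z={dar.z:.2f} P={dar.p:.4f}")
```

prints

```
DAR-FFC: real=159 null=40.27±25.42 Z=4.67 P=0.0000
```

— the 12 planted DAR connections with 5 shared targets each (plus
background coincidences) put 159 circuits in the category, against a null
expectation of ~40 under identical degree sequences: a strongly
overrepresented motif. The `examples/` scripts walk through each
capability (census, significance, DAR/higher-order + enrichment,
perturbation) and print what the numbers mean; a thin CLI
(`darffc simulate|census|randomize|all …`) runs the same stages from the
shell with a YAML config and a reproducibility manifest.

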