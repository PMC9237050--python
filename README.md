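# neurocrit

Personalized whole-brain criticality analysis on structural connectomes.

The package simulates a stochastic three-state excitable network
(inactive / active / refractory) on individual structural connectivity
matrices whose rows are homeostatically normalized to unit input. Sweeping
the activation threshold `T` yields per-subject criticality profiles —
average activity, its variability, and the largest (`S1`) and second-largest
(`S2`) clusters of simultaneously active, structurally connected nodes. The
critical point `T_c` is the `S2` peak; the curve integrals `I1`, `I2` are
threshold-independent criticality indexes. On top of that the package
provides:

- a **synthetic cohort generator** (parcellations, calibrated healthy
  connectomes, focal lesions, longitudinal remodeling, behavior scores) so
  every analysis stage runs without any external data;
- **structural graph metrics**: average degree, Louvain modularity, global
  efficiency, and the connectivity disorder (normalized entropy of the
  normalized weight matrix);
- **BOLD / functional connectivity synthesis**: double-gamma HRF
  convolution, zero-lag FIR band-pass (0.01–0.1 Hz), Pearson FC with mean,
  homotopic and entropy summaries;
- **structure-to-criticality mapping**: PCA + closed-form ridge regression
  with leave-one-out cross-validation, inner-loop regularization tuning,
  permutation inference, FDR-screened consensus edge weights, and
  network-pair averages;
- a **pipeline/CLI** orchestrating cohort-level analyses end to end.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` contains the full-scale (324-node) acceptance
checks and dominates the runtime (~15 min on one CPU); the rest of the suite
finishes in a few seconds.

## CLI

```sh
# generate a cohort of synthetic connectomes as TSV matrices
neurocrit synth cohort --n-controls 6 --n-patients 6 --seed 1 --out-dir cohort/

# lesion / remodel a single connectome
neurocrit synth lesion --connectome cohort/con000_t1.tsv \
    --parcellation cohort/parcellation.tsv --size 30 --out lesioned.tsv
neurocrit synth recover --lesioned lesioned.tsv --template cohort/con000_t1.tsv \
    --parcellation cohort/parcellation.tsv --recovery 0.8 --out remodeled.tsv

# threshold sweep and criticality profile for one subject
neurocrit dynamics sweep --connectome cohort/con000_t1.tsv \
    --parcellation cohort/parcellation.tsv --seed 1 --out profile.tsv

# ridge mapping from edge features to criticality values
neurocrit map fit --features X.tsv --outcome y.tsv \
    --parcellation cohort/parcellation.tsv --n-perm 1000 --out-dir map/

# full cohort analysis from a YAML config
neurocrit run --config config.yaml --out-dir results/
```

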