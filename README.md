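# molflow

Flow-matching generative modeling of mixed continuous/categorical molecular
data: atom positions together with atom types, formal charges and bond
orders, where categorical variables live on the probability simplex. The
package implements

- per-modality cosine interpolant schedules with exponent `nu`, their
  closed-form derivatives, and the clamped training loss weight;
- conditional interpolants and vector fields, with both the vector-field and
  the endpoint-parameterized training objectives (cross-entropy for
  categorical modalities under the endpoint objective);
- simplex-constrained categorical flows: exact Euclidean simplex projection,
  uniform-simplex / marginal-simplex / barycenter priors with Gaussian
  "blur", a Gaussian baseline prior, and Dirichlet conditional paths;
- full molecule priors (centered Gaussian positions + factorized categorical
  priors + empirical atom-count histogram);
- training-time OT alignment of prior and data point clouds (linear
  assignment alternated with Kabsch superposition, multi-restart);
- an SE(3)-equivariant graph network built on geometric vector perceptrons
  with optional cross-product channels (reflection-sensitive when enabled),
  organized into molecule update blocks (node feature / node position / edge
  feature updates) with symmetric per-pair bond prediction heads;
- Euler-integration sampling with a simplex-preserving convex-update rule for
  the endpoint field;
- molecule-quality metrics: valency-table stability, RDKit-sanitization
  validity, and Jensen-Shannon divergence of MMFF94 energy histograms;
- a download-free synthetic fixture generator (valence-exact random tree
  molecules, toy categorical tasks) so everything is testable offline.

The network and training loop run on a small numpy reverse-mode autodiff
engine (`molflow.autodiff`), so no deep-learning framework is required;
everything is desk-scale by design.

## CLI

```bash
molflow make-fixtures --n 200 --seed 0 --out fixtures.sdf
molflow train --data fixtures.sdf --config run.yaml --out model.json
molflow sample --checkpoint model.json --n 100 --steps 100 --seed 0 --out gen.sdf
molflow evaluate --generated gen.sdf --reference fixtures.sdf --report report.json
molflow ablate --configs grid.yaml --out ablation.csv
```

A run config (YAML) selects the ablation axes, e.g.:

```yaml
flow_type: endpoint            # endpoint | vector-field | dirichlet
categorical_prior: marginal-simplex  # gaussian | uniform-simplex | marginal-simplex | barycenter
blur_sigma: 0.15
nus: [1.0, 1.0, 1.0, 1.0]      # schedule exponents for X, A, C, E
eta: [3.0, 0.4, 1.0, 2.0]      # loss combination weights
train_steps: 200
```

`dirichlet` flow type requires (and enforces) the uniform-simplex prior.

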