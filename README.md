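# alfgp

Training pipeline for per-atom Gaussian-process force-field models of the
kriging family. The package takes ensembles of molecular conformers,
expresses each atom's environment in its **atomic local frame** (ALF) as a
3N−6-dimensional internal-coordinate feature vector, and fits one GP per atom
and per property (IQA-style atomic energies, atomic multipole moments). It is
aimed at people building machine-learnt potentials from quantum-topological
atomic properties, and at anyone who wants a self-contained, desk-scale
reference implementation of the ALF/GPR/active-learning stack: every stage
can be exercised with built-in synthetic surrogate labels — no molecular
dynamics engine, electronic-structure code or QTAIM integrator required.

## The model

For one atom and one scalar property, the prediction at a query feature
vector **x\*** is ordinary kriging with a constant mean:

    ŷ(x*) = μ̂ + rᵀ R⁻¹ (y − 1μ̂),         μ̂ = (1ᵀR⁻¹y)/(1ᵀR⁻¹1)

where `R = K(X,X) + σ²I` is the training correlation matrix with a
jitter-level nugget σ² (default 1e-8) and `r = k(X, x*)`. The kernel is a
product over feature dimensions: squared-exponential factors
`exp(−Δ²/2l²)` for ordinary dimensions and exponential-sine-squared factors
`exp(−2 sin²(Δ/2)/l²)` for azimuthal angles, whose period is fixed at 2π.
Lengthscales are found by **particle-swarm optimization** of the
concentrated log-likelihood (mean and process variance profiled out
analytically), in log₁₀ space. Training sets are grown by **highest-variance
active learning**: starting from a min–max–mean seed, each iteration labels
the sample-pool points with the largest kriging variance

    s²(x*) = 1 − rᵀR⁻¹r + (1 − 1ᵀR⁻¹r)²/(1ᵀR⁻¹1)

after scrubbing points whose integration error L(Ω) exceeds 0.001 a.u.
Multipole-moment models (real spherical components Q_lm up to hexadecapole,
L′ = 4) are rotated between the global frame and the ALF, and validated
through L′-truncated multipolar interaction energies of dimers against exact
point-charge Coulomb sums.

## Worked example

```python
import numpy as np
from alfgp import alf, synthetic
from alfgp.active_learning import ActiveLearner, ALConfig
from alfgp.pso import PSOConfig

mol = synthetic.load_template("glycine19")          # 19 atoms -> 51 features
alf_def = alf.determine_alf(mol)
frames, _ = synthetic.sample_conformers(mol, 400, seed=1)
F = alf.features_matrix(frames, alf_def, atom_index=0)
mask = alf.cyclic_mask_for(mol.n_atoms)

spec = synthetic.OracleSpec(
    alf.compute_features(mol, alf_def, 0).values, mask, seed=1)
learner = ActiveLearner(
    F, synthetic.SyntheticOracle(F, spec), cyclic_mask=mask,
    config=ALConfig(batch=5, iterations=5, random_extra=20,
                    sample_size=150, validation_size=60, seed=2,
                    pso=PSOConfig(swarm_size=12, iterations=40,
                                  stall_iterations=15)))
result = learner.run()
print(result.curve[["iteration", "n_train", "val_rmse"]].to_string(index=False))
print(result.results.summary())
```

prints the learning curve

```
 iteration  n_train  val_rmse
         0      144  0.015104
         1      149  0.013918
         2      153  0.013986
         3      158  0.013860
         4      163  0.005951
         5      168  0.005880
```

— validation RMSE (surrogate a.u.) falling as highest-variance selection
adds five labelled conformers per iteration — followed by a model summary:

```
Atomic GPR results
==================
property:           iqa   atom: atom0
training points:    168
feature dimension:  51 (16 cyclic)
kernel form:        rbf-expsin2-v1 (unit: angstrom)
nugget:             1.000e-08
concentrated logL:  464.628
mean (mu-hat):      0.2097567
process variance:   0.453835
lengthscale range:  [0.8482, 1000] (median 20.93)
far-field variance: 1.29308 (correlation scale)
```

Large lengthscales mark feature dimensions the property barely depends on;
the short ones carry the signal. The same objects handle file-backed labels
(`alfgp.io.FileOracle`), model serialization (`GPRResults.save/load`) and the
multipole/electrostatics analysis (`alfgp.multipoles`). A thin CLI wraps the
pipeline: `alfgp synth`, `featurize`, `train`, `learn`, `validate`,
`interact`.

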