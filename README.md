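# srnfshape

Elastic shape analysis of closed genus-zero surfaces, built for
subcortical brain morphometry: hippocampi, amygdalae and putamina
segmented from T1-weighted MRI arrive as triangle meshes, and the
scientific questions — does shape covary with post-traumatic stress
symptoms, with childhood trauma scores? — require comparing those
shapes in a way that is invariant to translation, scale, rotation and,
crucially, to how each surface happens to be parameterized.

The package represents a parameterized surface `f : S² → ℝ³` by its
**square-root normal field** (SRNF)

    q(s) = n(s) / |n(s)|^½ ,     n = f_u × f_v ,

whose key property is that the L² distance between two SRNFs is
unchanged when both surfaces are rotated by the same `O ∈ SO(3)` and
reparameterized by the same sphere diffeomorphism `γ` (the SRNF of
`f∘γ` being `(q∘γ)√J_γ`). Minimizing over these nuisance
transformations yields a proper distance on shape space:

    d_s([q₁],[q₂]) = inf_{O,γ} ‖ q₁ − O (q₂∘γ) √J_γ ‖ .

On top of this metric the package provides registration (Procrustes
rotation + coarse icosahedral pole search + gradient descent over γ),
geodesic visualization, Karcher means, shape PCA with invertible
principal scores, and a regression layer that models clinical outcomes
(PTSD symptom scale, childhood-trauma total) from principal scores with
score×age and score×BDI interactions, including bidirectional stepwise
selection and classical MDS/2-medoid diagnostics.

Because the motivating clinical dataset is restricted, the package
ships a first-class synthetic-data module: analytic base shapes with
planted smooth deformation modes, random sphere diffeomorphisms, the
two-class "line through the mean" simulation, and clinical tables with
planted regression structure — all seeded and reproducible, all with
closed-form oracles for testing.

## Worked example

```python
import numpy as np
import srnfshape as ss

grid = ss.make_grid(32, 32)
spec = ss.SurfaceFamilySpec(n=20, n_modes=2, mode_sds=(0.05, 0.025),
                            seed=0, grid=grid)
surfaces, planted, modes = ss.generate_family(spec)

# scramble one surface's parameterization, then register it to another
gamma = ss.random_diffeomorphism(grid, amplitude=0.3, seed=1)
scrambled = ss.center_and_scale(ss.apply_reparam(surfaces[0], gamma))
d0 = ss.preshape_distance(ss.srnf(surfaces[1]), ss.srnf(scrambled))
res = ss.register_pair(surfaces[1], scrambled)
print(f"distance before registration {d0:.4f}, after {res.distance:.4f}")

# shape PCA about the family mean (the family is generated aligned)
mu = ss.GridSurface(grid, np.mean([s.f for s in surfaces], axis=0))
basis = ss.shape_pca(ss.KarcherMean(mu=mu, registered=surfaces, variance_trace=[]))
print("cumulative variance:", np.round(ss.cumulative_variance(basis)[:3], 3))
z = np.stack([ss.principal_scores(s, basis, k=2).scores for s in surfaces])
print("score/planted correlations:",
      np.round(np.corrcoef(z[:, 0], planted[:, 0])[0, 1], 4),
      np.round(np.corrcoef(z[:, 1], planted[:, 1])[0, 1], 4))
```

prints (seeds fixed, so exactly reproducible):

```
distance before registration 1.5443, after 0.0320
cumulative variance: [0.905 1.    1.   ]
score/planted correlations: 0.9961 0.7659
```

Registration collapses the parameterization-confounded distance by a
factor of ~50, leaving the genuine shape difference between the two
family members. PCA finds exactly two non-null directions (the family
has two planted modes); the first recovered score tracks the planted
coefficient almost perfectly, while the second is partly mixed at this
small sample size (the per-sample unit-area normalization perturbs the
planted linear structure slightly).

A command-line interface covers the same pipeline for files on disk
(`srnfshape param | register | geodesic | mean | pca | scores |
reconstruct | simulate | regress | run`); `srnfshape run --config
cfg.yaml --out out/` executes the full synthetic pipeline and writes
`mean.h5`, `basis.h5`, `scores.csv`, `clinical.csv`, `fit.json`.

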