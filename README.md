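# ramus

**Randomized multiresolution scanning (RAMUS) for focal E/MEG source
reconstruction at variable depth.**

Electro-/magnetoencephalography source imaging solves the ill-posed
linear model `y = L x + n`, where `y` holds scalp potentials and/or
magnetic fields, `L` is the lead field and `x` is the primary current
density (three Cartesian dipole components at each of `K` source
positions).  Most sparsity-seeking solvers are depth-biased: deep
(thalamic) activity is silently explained away by superficial
surrogates.  This package implements randomized multiresolution
scanning: a hierarchical-Bayesian MAP estimate -- the iterative
alternating sequential (IAS) scheme with a conditionally Gaussian prior
and a gamma or inverse-gamma hyperprior `(beta, theta0)` -- is computed
coarse-to-fine over many randomly drawn nested decompositions of the
source space, with chained initial guesses, and averaged:

    xbar_k  = sum_l x^(l) / sum_l s^(L-l)      (per decomposition k)
    x_final = (1/D) sum_k xbar_k

Coarse levels (about as many source positions as sensors) make deep
activity detectable; fine levels restore superficial resolution; the
averaging over `D` random decompositions marginalizes discretization
and optimization error.  No depth weighting or prior conditioning is
required.

The package ships a complete spherical-head laboratory: an analytic
three-layer (Ary) EEG forward model, the Sarvas radial-magnetometer MEG
model, a two-dipole (deep thalamic + superficial somatosensory)
simulation battery with ROI metrics, and configuration-driven
replications of the validation cases (A)-(I).  Intended users are
methods researchers in E/MEG inverse problems who want a reproducible,
dependency-light reference implementation.

## Worked example

Reconstruct simultaneous deep and superficial activity on a small
sphere (600 source candidates, 30 electrodes) and score the deep region
of interest:

```python
import numpy as np
from ramus import (HeadModel, RamusConfig, ROISpec, build_source_space,
                   eeg_leadfield, upper_hemisphere_sensors, simulate_data,
                   ramus_reconstruct, roi_metrics, ias_map,
                   HyperpriorSpec, IASConfig)
from ramus.experiments import tilted_dipole

head = HeadModel()                                   # Ary sphere
space = build_source_space(600, 0, 85, seed=11, head=head)
lead = eeg_leadfield(space, upper_hemisphere_sensors(30, 100.0), head)

deep = tilted_dipole((7, 0, 5), 68, 10.0)            # thalamic, amplitude 10
sup  = tilted_dipole((-50, 7, 71), 1, 5.0)           # somatosensory, amplitude 5
data = simulate_data(lead, [deep, sup], noise_pct=3.0, seed=100)

res = ramus_reconstruct(lead, data, space,
                        RamusConfig(n_levels=3, sparsity=8,
                                    n_decompositions=10, seed=200))
roi = ROISpec(center=(7, 0, 5))                      # 60 mm deep ROI
multi = roi_metrics(res.x_final, space, roi, deep)

single = ias_map(lead.matrix, data.y, HyperpriorSpec(),
                 IASConfig(sigma=data.sigma))        # plain fine-grid IAS
flat = roi_metrics(single.x, space, roi, deep)

print(f"deep relative maximum: RAMUS {multi.relative_maximum:.3f} "
      f"vs single-level IAS {flat.relative_maximum:.3f}")
```

Output:

```
deep relative maximum: RAMUS 0.411 vs single-level IAS 0.001
```

The deep source reaches 41% of the global reconstruction maximum under
RAMUS (detected: the criterion is >10%), while plain fine-grid IAS-IG
leaves it at 0.1% -- invisible.  The full-scale experiments
(10000 sources, 102 sensors) are run through the case drivers, e.g.

```bash
ramus run --case A --scale 0.2 --seed 0 --out results/
ramus suite --case A --case G --scale 0.1 --out results/
```

which print per-ROI detection rates and median position/orientation/
amplitude errors and write per-realization CSV tables.

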