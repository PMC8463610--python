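# vortexmelt

Emergence and melting of self-organized **active vortex crystals** in a
continuum model of dense active suspensions — a pseudo-spectral solver
plus the complete crystalline-order analysis pipeline, at desk scale.

## The problem

Dense suspensions of swimming cells (bacteria, spermatozoa) behave as
*active fluids*: they can be spatiotemporally chaotic ("active
turbulence") or spontaneously order into striking patterns, among them
triangular lattices of same-sign vortices.  Whether such active vortex
lattices constitute a genuine two-dimensional *crystal* — and how that
crystal melts — connects active matter to the classical KTHNY picture
of 2D melting (solid → hexatic → liquid).  This package implements the
model and every measurement needed to pose those questions numerically:

* a generalized Toner–Tu equation for the incompressible velocity field,

  ∂t **u** + λ **u**·∇**u** = −∇p − (1+Δ)²**u** − (α + β|**u**|²)**u**,  ∇·**u** = 0,

  solved in vorticity form with a dealiased pseudo-spectral method and
  integrating-factor RK4 (module `solver`, `model`);
* vortex-core detection, polarity census, transient-duration
  measurement and the melting order parameter A_AVL/A_total
  (`vortexfield`, `experiments`);
* periodic Voronoi adjacency, 5-/7-fold defect census,
  bond-orientational order ψ6, orientational correlation G6(r),
  vortex tracking and the dynamic Lindemann parameter γ_L(t)
  (`crystal_order`);
* dynamical-state classification from energy-density PDFs, AVL time
  fraction, hysteresis scans (`phases`);
* the extreme-value law for the transient time until a uniform lattice
  forms, P(T) = (δ/τ)(1−e^{−T/τ})^{δ−1}e^{−T/τ}, with inverse-CDF
  sampling and maximum-likelihood fitting (`transients`);
* synthetic fixtures with exact ground truth for every diagnostic
  (`synthetic`), HDF5/CSV persistence and a CLI (`io`, `cli`).

## Worked example

Fit the transient-duration law to samples drawn from itself (the
max-of-exponentials construction):

```python
>>> import vortexmelt as vm
>>> model = vm.TransientModel(tau=54.59, delta=4.97)
>>> sample = vm.sample_transients(100_000, model, seed=1)
>>> print(vm.fit_transients(sample).summary())
Transient-duration extreme-value fit (maximum likelihood)
============================================================
n observations          100000
log-likelihood          -547292.4759
converged               True
------------------------------------------------------------
param         estimate     std err                    band
tau            54.5983      0.1656            [54.2, 55.4]
delta           4.9663      0.0287            [4.86, 5.04]
============================================================
```

The estimates recover the generating (τ, δ) within their standard
errors; the band is the min–max over five disjoint subsamples.

Simulate the vortex-crystal regime and inspect the crystalline order
(about a minute on one CPU):

```python
import numpy as np, vortexmelt as vm
from vortexmelt import studies

out = studies.avl_state_study(studies.SOLID_20PI, seed=41, T_max=250.0)
print(out["order"])
print("transient time:", out["t_converged"],
      "lattice spacing:", round(out["lattice_spacing"], 2))
```

```
OrderSummary(n_vortices=23, n_positive=23, n_negative=0, mean_abs_psi6=0.9366650063681282, n_defects=0, single_polarity=True)
transient time: 63.99999999998629 lattice spacing: 13.06
```

The run starts from band-limited random noise, passes through a
turbulent transient, spontaneously breaks the ± polarity symmetry at
t ≈ 50 and crystallizes into a defect-free triangular lattice of 23
same-sign vortices with mean |ψ6| = 0.94 and spacing ≈ 13.  The same pipeline is
scriptable from the shell (`vortexmelt simulate / detect / order /
lindemann / classify / scan / melt / transients / synth`).

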