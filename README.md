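# microvas

Simulation-informed analysis of microvascular perfusion with diffusion MRI.

At low diffusion weightings (b <= 100 s/mm^2), the MRI signal of a perfused
voxel is attenuated by blood flowing through the capillary bed — the
intravoxel incoherent motion (IVIM) effect. `microvas` asks how much
microstructural information that signal actually carries: it synthesises
ensembles of capillary networks, solves their blood flow, generates the
dMRI signals they would produce under flow-compensated (FC) and
non-compensated (NC) gradient waveforms, and then measures

* how many independent **degrees of freedom** of the vascular signal survive
  noise (singular-value analysis against a noise-free reference, with
  Marchenko-Pastur PCA for measurement-rich protocols), and
* which of 12 microvascular descriptors — moments of the blood speed v and
  volumetric flow rate q (vm, vs, qm, qs), path-weighted means (vw, qw, rw),
  geometry (rm, Lm, Lmp, Npaths) and the apparent network branching ANB —
  are **recoverable** from noisy signals, via leave-one-network-out
  RBF-dictionary maximum-likelihood fitting ranked by Spearman rs and a
  Bias Index.

The two leading metrics (mean volumetric flow rate qm and ANB, the number of
capillary segments a spin traverses in 100 ms) can then be mapped voxel-wise
from IVIM-style acquisitions through segmented fitting (extravascular signal
estimated at high b and subtracted at low b) and a simulation-trained
dictionary matched to the exact acquired (b, delta, Delta) table.

It is written for researchers in quantitative MRI and vascular
microstructure who want a self-contained, reproducible in-silico test bed
for IVIM-type protocol design and parameter mapping.

## The model in brief

A capillary network is a geometric graph with radii r and one inlet/outlet.
Steady flow follows the electric-hydraulic analogy (Poiseuille conductance
pi r^4 / (8 mu L), Kirchhoff balance, prescribed inflow qin). Spins undergo
plug flow, branch with probability proportional to outgoing flow, and
accrue phase phi_n = gamma int p_n(t) . G(t) dt; the voxel signal is
s = |(1/N) sum_n exp(-i phi_n)|, sampled at dt = 10 us. NC waveforms carry
b = gamma^2 G^2 delta^2 (Delta - delta/3); FC waveforms null the first
gradient moment and carry b = (4/3) gamma^2 G^2 tau^3. Rician noise is
applied at the stated b=0 SNR per measurement.

## Worked example

```python
import numpy as np
from microvas import (build_ensemble, default_base_set, build_protocol,
                      ExperimentConfig)
from microvas.simulate import ensemble_signal_matrices
from microvas.dof import SignalMatrix, modal_np

bases = default_base_set(15, seed=0)              # 15 synthetic base networks
ensemble = build_ensemble(bases, realisations_per_network=20, seed=7)
prot = build_protocol("NC")                       # b={0,10,20,40,70,100}, D=30ms
(signals,) = ensemble_signal_matrices(ensemble, [prot], n_spins=2000, seed=11)
mat = SignalMatrix(signals, protocol="NC")
for snr in (5, 20):
    print(snr, modal_np(mat, prot, snr=snr, seed=101))
```

prints

```
5 2
20 3
```

i.e. after directional averaging only two independent signal components
survive SNR 5 and about three survive SNR 20 — the vascular signal is
information-poor, which is why only a handful of microvascular metrics are
estimable. A full experiment (signals + metrics + rankings + theta sweeps)
runs from the CLI:

```bash
microvas simulate --seed 0 --outdir run --realisations 20
microvas dof      --outdir run
microvas rank     --outdir run
microvas phantom  --outdir run --snr 40
```

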