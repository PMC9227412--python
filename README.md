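# radialdce

Quantitative validation of accelerated breast DCE-MRI reconstruction on a
digital reference object (DRO) with known pharmacokinetics.

Dynamic contrast-enhanced MRI of the breast needs ~5 s frames to capture
lesion kinetics, far beyond what fully-sampled Cartesian imaging allows at
clinical spatial resolution. Golden-angle radial acquisition with
model-based reconstruction closes that gap — but every reconstruction
prior leaves a fingerprint on the recovered concentration-time curves,
and hence on the pharmacokinetic parameters fitted to them. This package
measures that fingerprint. It is written for MRI reconstruction and
quantitative-imaging researchers who want a fully simulated, ground-truth
validation loop:

1. **Phantom** — a 2D breast-like object whose lesions enhance according
   to the extended Tofts model,
   `C_t = v_p C_p + K^trans (C_p ⊛ exp(−K^trans t / v_e))`, driven by a
   population arterial input function, converted to signal via the SPGR
   steady-state equation (T10 = 1444 ms, FA = 30°, TR/TE = 4.7/2.4 ms,
   r1 = 4.9 mM⁻¹s⁻¹), with K^trans swept over 0.01–1.5 min⁻¹ at fixed
   v_e = 0.3, v_p = 0.001.
2. **Acquisition** — multi-coil golden-angle radial k-space through a
   Kaiser–Bessel gridding NUFFT, 8 spokes per 5 s frame against a
   fully-sampled arm (undersampling factor R = 88), optional complex
   Gaussian noise at 20% of the mean k-space magnitude.
3. **Reconstruction** — iterative SENSE (reference), PCB (reconstruction
   confined to a rank-K temporal subspace), MOCCO
   (`argmin_s ‖Es − m‖² + λ‖(I − ĨĨ*)s‖₁`, an l1 model-consistency
   penalty that steers without confining, yielding full-rank solutions),
   and CS-TV (temporal total variation). Temporal models are either the
   exact lesion curve plus a constant (HR) or a rank-3 basis learned from
   central k-space by spline smoothing + ICA (LR).
4. **Analysis** — voxel-wise bounded extended-Tofts fits, percent-error
   maps and tables, Bland–Altman summaries, Monte-Carlo noise studies.

## Worked example

```python
import numpy as np
from radialdce import *

prot = ScanProtocol(matrix=48, n_frames=64, fov=72.9)       # scaled slice
aif = population_aif(prot, bolus_arrival=60.0)
ph = build_phantom(PhantomGeometry(matrix=48),
                   default_lesions((0.3,)), prot, aif)       # one lesion
coils = simulate_coil_maps(4, 48, seed=1, support=ph.support)
traj = golden_angle_trajectory(8 * 64, 96, 8)                # R = 88
enc = EncodingSeries(coils, traj)
ks = sample_kspace(ph, coils, traj, enc)

basis = learn_lr_basis(ks, coils, rank=3, kmax=0.1,
                       knot_spacing=12, encoding=enc)        # data-driven
rec = mocco_reconstruct(ks, coils, traj, basis,
                        ReconConfig(lam=10, max_iter=100), encoding=enc)

conc = signal_to_concentration(rec, 11, 1444.0, prot)
roi = ph.lesion_mask(0)
fit = fit_image(conc, aif, prot.frame_times, roi, seed=5)
kt = fit.ktrans_map[roi]
print(f"fitted Ktrans {np.nanmean(kt):.4f} 1/min, "
      f"bias {np.nanmean(100 * (kt - 0.3) / 0.3):+.1f}%")
```

Output:

```
fitted Ktrans 0.2897 1/min, bias -3.4%
```

The lesion was simulated at K^trans = 0.3 min⁻¹; after 88-fold
undersampling and MOCCO reconstruction with a temporal model learned from
the data itself, the refitted transfer constant is biased by about −3% —
the quantity the whole pipeline exists to measure. Running the same data
through `pcb_reconstruct` (the hard subspace constraint) makes that bias
several times larger, and at K^trans = 1.5 min⁻¹ the subspace method underestimates
by >50% while MOCCO stays within ~10%.

The experiment grid (9 kinetic conditions × 6 reconstruction arms ×
noise levels) is driven by `ExperimentConfig` presets:

```bash
radialdce all --preset smoke --seed 7 --out results/smoke
```

writes `summary.csv`, a conditions-by-arms error table
(`table1_style.csv`), Bland–Altman figures and a file manifest with
content hashes. See `docs/methods.md` for the model details, solver
internals, and what the scaled phantom does and does not emulate.

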