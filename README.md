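# repimap

Dynamic ΔB₀ field mapping and EPI distortion correction with
blip-rewound EPI (rEPI), exercised end-to-end on a synthetic multi-coil
k-space scanner.

Single-shot EPI is the workhorse of fMRI, but its low phase-encode
bandwidth makes it sensitive to B₀ inhomogeneity: an off-resonance of
ΔB₀(r) Hz displaces signal by

    shift(r) = ΔB₀(r) · n_pe · esp / R   voxels along the PE axis,

and the field *changes* during a scan (head motion, respiration), so a
static field map cannot correct the whole time series.  rEPI acquires
several EPI images per readout in an **interleaved** order, decoupling
the echo-time difference from the number of phase-encode lines:

    ΔB₀(r) = ΔΦ(r) / (2π · ΔTE),        ΔTE = k · esp  (k small),

so every readout yields its own, nearly wrap-free field map.  The
individually undersampled echo images (factor `n_echoes · R`) are
recovered jointly by structured low-rank (block-Hankel) matrix
reconstruction, exploiting that echoes a millisecond apart are nearly
identical.

The package is aimed at MR-physics researchers who want to study the
trajectory design, the joint reconstruction and the field-mapping /
unwarping chain without scanner access: a synthetic scanner generates
phantoms, smooth complex coil maps, ground-truth fields (smooth
polynomial background + localized susceptibility-like blobs, with
rigid-motion-dependent changes for time series) and acquires multi-coil
k-space line by line with physical off-resonance phase evolution — so
geometric distortion *emerges* from the simulation rather than being
painted on.

## Modules

| module | contents |
| --- | --- |
| `repimap.trajectory` | EPI / me-EPI / rEPI designers, feasibility, timing, validation |
| `repimap.simulate`   | phantom, coil, field generators; k-space acquisition; motion series |
| `repimap.recon`      | block-Hankel operators, joint low-rank solver, SENSE baseline, coil compression |
| `repimap.fieldmap`   | phase differences, 3-echo averaging, 2-D unwrapping, polynomial fitting, Hz conversion |
| `repimap.unwarp`     | Hz → voxel-shift conversion, forward warp, distortion correction |
| `repimap.pipeline`   | end-to-end demos (stationary and motion series), metrics (NRMSE, tSNR) |
| `repimap.io`         | NIfTI, HDF5 k-space container, YAML/JSON configs |
| `repimap.cli`        | thin `repimap` command-line wrapper |

## Worked example

```python
import numpy as np
from repimap.trajectory import design_repi, echo_times, per_echo_sampling
from repimap.simulate import make_phantom, make_coils, make_field, acquire
from repimap.recon import solve_joint, combine_sos
from repimap.fieldmap import estimate_b0
from repimap.unwarp import shift_map, unwarp_image

traj = design_repi(n_pe=66, n_echoes=3, dte_factor=2, R=1, esp=0.76, te1=31.0)
print(echo_times(traj))            # ([31.0, 32.52, 34.04], 1.52)
print(per_echo_sampling(traj)[0])  # 3

phantom = make_phantom(66, 66, seed=1)
coils   = make_coils(66, 66, 8, seed=11)
field   = make_field(66, 66, "polynomial", 60.0, seed=21)
kspace  = acquire(phantom, coils, field, traj, noise_sigma=1/40, seed=31)

echoes = solve_joint(kspace, coils)          # joint low-rank reconstruction
fmap   = estimate_b0(echoes)                 # dB0 map from the echo phases
mag    = combine_sos(echoes)
corrected = unwarp_image(mag, shift_map(fmap, traj))

err = fmap.b0_hz - field.b0_hz
print(round(float(np.sqrt(np.mean(err[fmap.mask]**2))), 2), "Hz field-map RMSE")
```

Running this prints

```
([31.0, 32.52, 34.04], 1.52)
3
3.85 Hz field-map RMSE
```

i.e. the three echoes sit 1.52 ms apart (twice the echo spacing), each
echo image is 3-fold undersampled, and the field estimated from a
single simulated readout matches the ground-truth field to under 4 Hz
RMS over the whole validity mask (under 2 Hz in the object interior) —
a fifth of a voxel of residual distortion at this protocol.
`examples/` contains one narrative script per capability.

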