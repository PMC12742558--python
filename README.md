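# cptmorph

Continuous spatial-temporal deformable image registration (DIR) and 4D frame
interpolation for volumetric medical images, with an evaluation metric suite
and a synthetic 4D motion-phantom generator.

## The problem

Radiotherapy workflows (contour propagation, dose accumulation, 4D dose
calculation) need a dense spatial map `phi_{0->1}` aligning a fixed CT volume
`I0` with a moving one `I1`. Conventional methods optimize the displacement
field on a discrete voxel or spline grid, which struggles with nonlinear
motion over time and with sliding boundaries such as the lung-chest wall
interface, and ties every intermediate-frame query to interpolation on that
grid.

`cptmorph` instead represents motion with an implicit neural representation:
a small sine-activated coordinate network (Siren, frequency scale
`omega_0`) fitted **per case** by test-time optimization — no training
dataset, no learned prior. Two variants:

* **E2E** (spatial-only): the network `g_theta(x)` is the displacement
  field, `phi(x) = x + g_theta(x)`;
* **LDD** (spatio-temporal): the network `h_omega(x, t)` is a velocity
  field, and the map is its time integral along each particle's trajectory,

      phi_{t0->t1}(x) = x + sum_t h_omega(x_t, t) * dt,
      x_{t + 1/T} = x_t + h_omega(x_t, t) / T          (explicit Euler),

  so the reverse map comes from the same field integrated backward in time,
  and the transformation is diffeomorphism-friendly by construction.

Both are fitted by minimizing the negative zero-normalized cross-correlation
(NCC) between the fixed image and the backward-warped moving image — for
LDD, symmetrically in both directions plus an L2 penalty `lambda_2 sum_t
||v_t||^2` on the velocity samples.

A fitted velocity field yields **training-free continuous frame
interpolation**: for any `t in (0, 1)`,

    I_t = (1 - t) * I0 o phi_{t->0}  +  t * I1 o phi_{t->1},

with both maps obtained by direct (reverse-time) integration from the output
grid — no forward warping, no refinement network.

The whole stack — network, hand-written reverse-mode gradients (including
backpropagation through the Euler loop), Adam with warmup + cosine schedule,
warping, metrics — is pure NumPy/SciPy.

## Worked example

Generate a synthetic respiratory phantom with analytically known motion,
register its extreme phases with the LDD model, and interpolate the
mid-phase frame:

```python
import cptmorph as cm
import cptmorph.metrics as M
from cptmorph.presets import demo_config

# a 32^3 synthetic respiratory phantom with known ground-truth motion
spec = cm.default_spec(seed=0, shape=(32, 32, 32), noise_sd=5.0, n_landmarks=20)
series = cm.generate(spec, [0.0, 0.5, 1.0])
I0, I1 = series.frames[0], series.frames[-1]

model = cm.CPTRegistration(I0, I1, config=demo_config("ldd", "small", seed=0))
res = model.fit()
print(res.summary())

lm0, lm1 = series.landmarks[0], series.landmarks[-1]
_, pre, _ = M.tre(lm0, lm1, lm0.points, I0.spacing)
_, post, _ = M.tre(lm0, lm1, res.map_points(lm0.points), I0.spacing)
print(f"\nlandmark TRE: {pre:.2f} mm unregistered -> {post:.2f} mm registered")
print(f"negative-Jacobian ratio: {res.neg_jacdet_ratio():.4f} %")

mid = res.interpolate([0.5])[0]
blend = cm.ImageVolume(0.5 * (I0.voxels + I1.voxels), I0.spacing)
truth = series.frame_at(0.5)
print(f"mid-frame MAE: {M.mae(truth, mid):.2f} HU (static blend: {M.mae(truth, blend):.2f} HU)")
```

Output:

```
CPT-DIR registration results
==============================================
mode:                 LDD (time-dependent velocity)
grid:                 (32, 32, 32)
network:              4x48 Siren, omega0=12, 7443 parameters
steps / batch:        250 / 1200
Euler steps T:        4
weights:              l1=0 l2=0.0001 l3=0
seed:                 0
initial loss:         -1.530494
final loss:           -1.980004
mean |displacement|:  0.7726 voxels
elapsed:              26.14 s

landmark TRE: 1.97 mm unregistered -> 0.26 mm registered
negative-Jacobian ratio: 0.0000 %
mid-frame MAE: 4.96 HU (static blend: 6.18 HU)
```

The landmark target registration error (TRE) drops to about an eighth of the
unregistered value; the fitted map has no folding (0% of voxels with a
non-positive Jacobian determinant); and the motion-compensated mid-frame is
closer to the ground-truth intermediate phase than the static intensity
blend `0.5 I0 + 0.5 I1`.

The loss values are the symmetric objective: `-2` corresponds to perfect
NCC in both warp directions.

A command-line interface wraps the same pipeline:

```sh
cptmorph simulate --shape 32 32 32 --times 0 0.5 1 --seed 0 --out sim/
cptmorph register --fixed sim/phase_000.nii.gz --moving sim/phase_100.nii.gz \
                  --mode ldd --out reg/
cptmorph interpolate --model reg/model --i0 sim/phase_000.nii.gz \
                     --i1 sim/phase_100.nii.gz --times 0.5 --out interp/
cptmorph evaluate --reference sim/phase_050.nii.gz \
                  --test interp/interp_0500.nii.gz --out eval/
```

Volumes are read and written as NIfTI (`.nii`, `.nii.gz`) or MetaImage
(`.mha`, `.mhd`); landmarks as whitespace-separated voxel-index triples
(DIR-Lab text dialect, 0- or 1-based); displacement fields as 4D NIfTI in mm
with a JSON sidecar stating the convention.

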