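# dictsir

Sparse-view fan-beam CT reconstruction with dictionary-learning
regularization and **automatic selection of the regularization parameter**.

## The problem

Lowering CT dose by acquiring fewer projection views makes the
reconstruction problem underdetermined: unregularized algebraic methods
(SART) leave streak artifacts, and compressed-sensing reconstructions need
a prior — total variation, or a learned dictionary of image patches.
Statistical iterative reconstruction (SIR) with a patch dictionary solves

```
min_{μ, α, D}  Σ_i (ω_i/2) ([Aμ]_i − l̂_i)²  +  λ Σ_s ‖E_s μ − D α_s‖²
```

where `A` is the ray/pixel intersection matrix, `l̂` the measured line
integrals, `ω_i = (y_i − r_i)²/y_i` the per-ray statistical weights from
the transmission photon model, `E_s` extracts overlapping 8×8 patches, `D`
is an overcomplete learned dictionary and `α_s` are sparse codes. The
catch is `λ`: its proper value depends on the scan, the object and the
noise, and finding it empirically costs ten or more full reconstructions.

`dictsir` implements the *adaptive-weight* reformulation: reweighting the
patch penalty per pixel by `r_j = p_j/(2q_j)` gives the data and prior
terms a common curvature, so the image update collapses to the closed form

```
μ_j ← [ (c_j + λ d_j) / (1 + λ) ]₊
```

(`c` = data target, `d` = patch-model target). In this form `λ` is a pure
blending weight, and one extra reconstruction pass run at `λ = ∞` yields a
scalar diagnostic — the weighted relative data-fidelity error

```
δ_∞ = Σ (ω_i/2)([Aμ_∞]_i − l̂_i)² / Σ (ω_i/2) l̂_i²,    δ_G = 10⁶ δ_∞
```

— that predicts the proper `λ` through a fitted piecewise-quadratic map:

```
λ* =  1.74485 δ_G² + 0.58883 δ_G − 6.88253    (δ_G > 1.96)
λ* = −0.21545 δ_G² + 1.08602 δ_G − 0.32634    (δ_G ≤ 1.96)
```

The full workflow is exactly **two** reconstruction passes: one at
`λ = ∞` to measure `δ_G`, one at `λ*`. SART and GPBB
(TV-minimization with Barzilai–Borwein projected gradient) baselines, a
Shepp-Logan fan-beam simulator with photon statistics, K-SVD/OMP
dictionary tooling and NMAD/SNR evaluation are included. See
`docs/methods.md` for the model details and design decisions.

## Worked example

```python
import dictsir as ds
from dictsir.reconstruct import ReconConfig, sart_reconstruct
from dictsir.lambda_model import awr_pipeline

mu   = 0.07 * ds.make_shepp_logan(256)                 # attenuation map
geom = ds.build_geometry(120, 3.0, 512, 256, 2.0)      # 120 views, 512 dets
A    = ds.build_system_matrix(geom)
sino = ds.simulate_scan(mu, geom, noise_level=0.0, seed=101, A=A)

sart = sart_reconstruct(sino, A, ReconConfig())
recon, report = awr_pipeline(sino, A, "adaptive", ReconConfig(),
                             init_image=sart.image)
print(f"delta_G = {report.delta_g:.4f}  lambda* = {report.lam:.4f} "
      f"passes = {report.passes}")
print(f"SART NMAD = {ds.nmad(sart.image, mu):.3f}%  "
      f"AWR NMAD = {ds.nmad(recon.image, mu):.3f}%")
```

prints (exact decimals vary with the seed):

```
delta_G = 1.8928  lambda* = 0.9574 passes = 2
SART NMAD = 4.134%  AWR NMAD = 0.940%
```

`δ_G = 1.89` falls on the low branch of the selector, which recommends
`λ* ≈ 0.96` — an even balance of data and patch-model targets. With it the
two-pass reconstruction cuts the normalized mean absolute deviation from
4.1% (streaky SART) to below 1%; under growing projection noise `δ_G` and
hence `λ*` rise automatically, shifting weight to the denoising prior.

The same flows are available from a shell:

```
dictsir simulate --views 120 --step-deg 3 --detectors 512 --image-n 256 \
        --noise-pct 0.2 --seed 7 --out scan.sino
dictsir reconstruct --sino scan.sino --views 120 --step-deg 3 \
        --detectors 512 --image-n 256 --algorithm awr-adsir --lambda auto \
        --out recon.txt --png recon.png --window 0.0105,0.0315
dictsir select-lambda --sino scan.sino --views 120 --step-deg 3 \
        --detectors 512 --image-n 256
dictsir evaluate --truth phantom.txt --test recon.txt
```

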