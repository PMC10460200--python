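# fdot

Frequency-domain diffuse optical tomography (FD-DOT) forward modelling
and atlas approximation-error analysis for the neonatal head, on
synthetic phantom populations.

In neonatal DOT the anatomical model behind image reconstruction is
usually an *atlas* head individualized to the subject from surface
measurements, because MRI of newborns is rarely practical.  Using the
wrong inner anatomy injects a modelling error into the simulated
measurements and sensitivities.  `fdot` provides the full machinery to
quantify that error:

* **Monte Carlo solver** (`fdot.mc`, `fdot.mc_jacobian`): voxel photon
  transport under the microscopic Beer–Lambert law, with exact
  per-voxel partial path lengths, bit-exact replay from per-photon
  seeds, FD measurements `X = Σ w_p cos(2πf t_p)`,
  `Y = Σ w_p sin(2πf t_p)`, and exact "replay" Jacobians
  `∂X/∂μₐⱼ = −Σ l_pj w_p cos(2πf t_p)` reduced to log-amplitude and
  phase rows via `∂lnA = (X∂X + Y∂Y)/A²`, `∂φ = (X∂Y − Y∂X)/A²`.
* **Diffusion-approximation solver** (`fdot.da`): P1 finite elements
  for `−∇·(κ∇Φ) + (iω/c + μₐ)Φ = 0` with Robin boundary condition
  `(1−ρ)Φ + 2(1+ρ)ν·κ∇Φ = 4Q`, patch sensor functionals, adjoint
  solves sharing one factorization, and discrete-exact Fréchet
  absorption derivatives.
* **CSF segmentation** (`fdot.csf`): splits the cerebrospinal fluid
  into a semidiffusive subarachnoid layer and clearer sulci CSF by
  thresholding a harmonic function solved on the CSF domain with mixed
  Dirichlet/Neumann conditions (level set θ = 0.6 by default).
* **Registration** (`fdot.registration`): weighted affine fit of dense
  cranial point sets (`RE = SRE + γ₁·LRE1 + γ₂·LRE2`), probe-region
  anisotropic scaling, and filling of the reference scalp-and-skull
  shell with the warped interior under quality-control rules — so every
  registered anatomy shares the reference exterior and optode placement
  bit-exactly.
* **Phantom population** (`fdot.phantom`): layered ellipsoidal head
  phantoms with sinusoidal CSF-filled sulci, ventricles, cranial
  point grids and planar-probe placement, with controllable
  inter-individual variation — a synthetic stand-in for a segmented-MRI
  database.
* **Approximation-error statistics** (`fdot.approx_error`): sample mean
  `μ_e` and covariance `Γ_e` of `y_ref − y_i` over the population,
  eigenanalysis via the Gram trick (rank N−1), `STD_e = √tr(Γ_e)`,
  visibility ratios `‖P_v Δy_ref‖ / STD_e`, difference-mode statistics
  of `(J_ref − J_i)Δx`, tissue sweeps and cylinder depth-sensitivity
  profiles.
* **Study driver and CLI** (`fdot.pipeline`, `fdot` command):
  reproducible end-to-end studies from a serializable config.

## Worked example

Run a small approximation-error study: 8 phantom anatomies are
registered into one reference head, FD measurements (100 MHz) and ball
sensitivities are simulated with the diffusion solver, and the
detectability ratios are printed.

```python
from fdot.pipeline import StudyConfig, run_study

cfg = StudyConfig(N=8, seed=42)
res = run_study(cfg)
print(res.summary_frame().round(3).to_string(index=False))
print(f"accepted {res.n_accepted}/{cfg.N} subjects; "
      f"cranial RMSE {res.registration_rmse['before_mean']:.2f} -> "
      f"{res.registration_rmse['after_mean']:.2f} mm")
```

Output (about three minutes on one CPU):

```
     quantity  mu_ratio  STD_abs  STD_diff  ball_abs_visibility  ball_diff_mu_ratio  ball_diff_visibility  eig95_abs  visibility_GM_-60pct  visibility_SCALP_SKULL_+60pct
log_amplitude     0.207    3.381     0.031                 0.06              15.460                 6.869          4                 1.387                          0.520
        phase     0.366    0.149     0.001                 0.03              19.067                 5.740          3                 1.589                          0.898
accepted 8/8 subjects; cranial RMSE 1.09 -> 0.45 mm
```

Reading the numbers: `mu_ratio` (= ‖P_v μ_e‖/STD_e ≈ 0.2–0.4) says the
reference head sits near the anatomical average — the expected
anatomy-induced shift is a fraction of the anatomy-induced spread.  A
−60% grey-matter absorption change is visible over the anatomical
variation (ratios > 1), a +60% scalp-and-skull change mostly is not.
The local activation ball (radius 5 mm, Δμₐ = 0.005 mm⁻¹, a ~10%
cortical absorption increase) is invisible in *absolute* measurements
(`ball_abs_visibility` ≪ 1) but clearly detectable in *difference*
measurements (`ball_diff_visibility` ≫ 1): anatomical modelling error
largely cancels in difference imaging.  `eig95_abs` is the number of
covariance eigenvalues carrying 95% of the error variance — a handful,
which is what makes an approximation-error noise model practical.

The same pipeline runs from the shell:

```bash
fdot run-study --n 8 --seed 42 --solver da --out study_out
fdot phantom --seed 0 --out head.nii.gz
fdot csf-split head.nii.gz --theta 0.6 --out head_split.nii.gz
```

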