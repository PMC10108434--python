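# saltfold

Analysis toolkit for the folding electrostatics of highly charged protein
domains — built around the case of a ~60-residue acidic SH3 domain whose
peptide-binding surface carries a large net negative charge, so that
electrostatic repulsion competes with hydrophobic collapse during folding
and added salt (NaCl/KCl) stabilises the fold by Debye–Hückel screening and
territorial ion binding.

It is written for biophysicists who measure chemical denaturation and
folding kinetics by fluorescence, backbone ¹⁵N relaxation by NMR, and ion
behaviour by MD, and who want those analyses as one reproducible, tested
pipeline with seeded synthetic data standing in for raw measurements.

## What it computes

**Equilibrium stability.** Two-state linear-extrapolation fits of
fluorescence denaturation curves,

    signal(u) = [F_N + a·u + (F_D + b·u)·K(u)] / (1 + K(u)),
    K(u) = exp(−(ΔG° − m_eq·u)/RT),

and the ionic-strength dependence of stability under three competing
models — the Debye–Hückel form ΔG(I) = ΔG° + m_eq^salt·√I against linear-I
(Hofmeister/direct binding) and log-I alternatives, ranked by R².

**Folding kinetics.** Single-exponential unfolding traces, the linear
unfolding arm of the chevron plot (ln k_u vs [urea], extrapolated to water),
folding rates from detailed balance k_f = k_u·exp(ΔG°/RT), the Tanford beta

    β_urea = 1 − RT·m_ku / m_eq,

and the salt Φ-value that locates electrostatic strain on the pathway:

    ΔΔG_{D→‡} = −RT·ln(k_f^high/k_f^low),
    ΔΔG_{D→N} = −RT·ln(K^high/K^low),   K = k_f/k_u,
    Φ_f^salt  = ΔΔG_{D→‡} / ΔΔG_{D→N}.

**NMR relaxation.** Chemical-shift perturbations √((0.1·ΔδN)² + ΔδH²),
off-resonance spin-lock conversion R₁ρ = R₁cos²θ + R₂sin²θ with
θ = tan⁻¹(ν_SL/Ω), and Lipari–Szabo model-free "model 2" fitting of
(S², τ_e) per residue with one global τ_c from ¹⁵N R₁/R₂/NOE at 600 MHz.

**Trajectory ion statistics.** Per-residue ion-contact fractions (4 Å
heavy-atom criterion), distinct cation/anion counts per frame, salt-bridge
occupancies (Lys NZ to Asp CG / Glu CD), backbone RMSF after Kabsch
superposition, and hydrogen-bond counts — each averaged per independent run
with cross-run mean ± SD.

**Sequence charge and covariation.** Integer net charge (+1 K/R, −1 D/E),
ortholog-alignment charge statistics with 95% CIs, and mutual-information
covariation with APC correction, a permutation null, and
Benjamini–Hochberg FDR control.

A seeded generator module produces every input type (denaturation curves,
kinetic traces, stability series, relaxation records, multi-model PDB toy
trajectories with prescribed contact occupancies, ortholog-like alignments
with a planted covarying pair), so the entire pipeline is testable offline.

## Worked example

Feed the measured rate constants of the acidic SH3 domain at 0 and 800 mM
NaCl (k_u 0.088 → 0.12 s⁻¹, k_f 0.5 → 297 s⁻¹, 303.15 K) to the Φ-value
decomposition:

```python
import saltfold as sf

res = sf.compute_salt_ddG(kf_low=0.5, kf_high=297.0,
                          ku_low=0.088, ku_high=0.12, T=303.15)
print(f"ddG(D->TS) = {res.ddG_Ddagger:+.1f} kJ/mol")
print(f"ddG(D->N)  = {res.ddG_DN:+.1f} kJ/mol")
print(f"phi_f_salt = {res.phi_f_salt:.2f}")

beta, err = sf.compute_beta_urea(m_ku=0.177, m_eq=5.0, T=303.15)
print(f"beta_urea  = {beta:.3f}")
```

prints

```
ddG(D->TS) = -16.1 kJ/mol
ddG(D->N)  = -15.3 kJ/mol
phi_f_salt = 1.05
beta_urea  = 0.911
```

Salt lowers the transition-state barrier slightly more than it stabilises
the native state (Φ > 1): essentially all of the electrostatic repulsion —
and, with β_urea ≈ 0.91, almost all of the hydrophobic collapse — is
already present at the transition state. The same decomposition is exposed
on the command line:

```bash
$ saltfold phi-salt --kf-low 5.5 --kf-high 25 --ku-low 0.08 \
      --ku-high 0.09 --temperature 293.15
{
  "ddG_Ddagger_kJ_mol": -3.69,
  "ddG_DN_kJ_mol": -3.40,
  "phi_f_salt": 1.08,
  "phi_defined": true
}
```

An end-to-end synthetic run of every analysis block:

```bash
saltfold run --demo --seed 1 --out demo_out --format csv
```

writes a JSON report plus a folding-summary CSV with columns
`condition,ku,kf,beta_urea,phi_f_salt`.

## Layout

```
src/saltfold/
  constants.py    gas constant, gyromagnetic ratios, NMR defaults
  equilibrium.py  two-state LEM fits, ionic strength, salt-model comparison
  kinetics.py     trace/arm fits, beta_urea, salt phi decomposition
  relaxation.py   CSP, R1rho->R2, spectral density, model-free fitting
  trajectory.py   contacts, salt bridges, RMSF, H-bonds, PDB I/O
  sequence.py     net charge, alignment statistics, MI covariation
  synthetic.py    seeded generators for every input type
  pipeline.py     config-driven orchestration and reports
  cli.py          `saltfold` command-line interface
docs/methods.md   model assumptions, defaults, numerical choices
```
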