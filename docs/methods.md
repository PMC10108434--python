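# Methods

This note records the models implemented in `saltfold`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Units and constants

Energies are kJ/mol (R = 8.314 J mol⁻¹ K⁻¹), temperatures kelvin,
concentrations molar, rates s⁻¹, distances ångström, correlation times
seconds. ΔG_{N→D} > 0 means the folded state is favoured. The default
temperature is 303.15 K (30 °C plate-reader experiments); cross-study
kinetic comparisons for the Fyn SH3 mutant use 293.15 K, which reproduces
the published ΔΔG pair at one decimal. NMR constants: γ_H = 2.675×10⁸,
γ_N = −2.713×10⁷ rad s⁻¹ T⁻¹, r_NH = 1.02 Å, Δσ(¹⁵N) = −160 ppm, field
600 MHz (14.1 T).

## Two-state equilibrium model

The linear extrapolation model with linear native/denatured baselines is
fitted by nonlinear least squares over six parameters
(ΔG°, m_eq, two baseline intercepts, two slopes). Choices:

* **Multistart.** A deterministic 8-point grid over (ΔG° ∈ {2, 5, 10, 20}
  kJ/mol) × (m_eq ∈ {2, 8} kJ/mol/M); baselines are seeded from the curve
  ends; lowest residual sum of squares wins.
* **Label-swap symmetry.** The model is exactly invariant under
  (ΔG°, m_eq, native, denatured) → (−ΔG°, −m_eq, denatured, native); fits
  are canonicalised to the m_eq > 0 branch before validation.
* **No-transition guards.** A curve is rejected when (i) the signal range
  does not exceed 3× the noise estimated from second differences, (ii) the
  fitted midpoint C_m = ΔG°/m_eq falls outside the measured urea range, or
  (iii) the fitted native–denatured separation at C_m is below 10% of the
  signal range (a straight line can always be absorbed by the baselines).
* **Identifiability limit.** For a marginally stable domain
  (ΔG° ≈ 4.4 kJ/mol, C_m ≈ 0.9 M) the native baseline is never sampled
  cleanly — at the lowest non-zero urea the domain is already ~17%
  unfolded. Above roughly 5% noise-to-range the global least-squares
  optimum can become a runaway-baseline solution; the fitter reports this
  as "no transition" rather than returning it. Parameter standard errors
  are large in this regime and the error-consistency tests operate below
  it.

Ionic strength is I = ½ Σ c_i z_i², computed over explicitly listed ionic
species; buffer ions are excluded unless listed, matching how salt-only
concentrations are plotted in practice.

## Salt dependence of stability

Three two-parameter linear models of ΔG vs ionic strength are fitted by
(weighted) least squares on the transformed predictor — √I (Debye–Hückel
screening), I (Hofmeister/direct binding), ln I (site-binding signature) —
and ranked by R², ties broken by RSS. All three fits are always reported.
The comparison requires ≥ 4 points; the log model requires I > 0.

The generator's default ionic-strength grid is five log-spaced points from
5 mM to 800 mM. The top matches the highest salt condition studied; the
dilute decade is included because that is where the three predictors
diverge — across a narrow 80–800 mM window the models are statistically
indistinguishable at realistic noise. With 5 points and noise at 5% of the
ΔG range, the √I model is selected in ≈96% of seeded series.

## Unfolding kinetics and the salt Φ-value

Unfolding traces are fitted as offset + A·exp(−k·t) with bounds k > 0 and a
no-decay guard analogous to the equilibrium one. The unfolding arm is an
OLS fit of ln k_u on urea over the measured limb (7–9 M); k_u° = exp of the
intercept. Folding rates follow from detailed balance,
k_f° = k_u°·exp(ΔG°/RT), with first-order (delta-method) error propagation
throughout.

β_urea is defined through the free-energy m-values, β = 1 − RT·m_ku/m_eq —
the standard Tanford convention, which reproduces the published magnitude
(0.911 from m_ku = 0.177 M⁻¹, m_eq = 5 kJ/mol/M at 303.15 K). The salt
Φ-value is the ratio ΔΔG_{D→‡}/ΔΔG_{D→N} computed from the four rate
constants; RT cancels, so Φ is exactly temperature-invariant. When
|ΔΔG_{D→N}| < 0.1 kJ/mol the ratio is numerically meaningless and Φ is
reported as undefined (a flag, not an exception). Energy diagrams report
only between-condition differences of the TS and N levels with D pinned at
0: the absolute barrier contains an arbitrary kinetic prefactor that
cancels between conditions. Only the unfolding arm is modelled; refolding
kinetics and chevron curvature are out of scope.

**Extrapolation error budget.** Extrapolating ln k_u from 7–9 M to water
amplifies single-trace rate errors about five-fold (regression leverage).
A single 1-minute trace sampled at 10 Hz with noise at 2% of amplitude
carries a ~1% rate uncertainty near the Cramér–Rao bound, hence ~5%
uncertainty on k_u°. The recovery tests therefore use triplicate traces
per urea concentration — mirroring the assay's repeated wells — which
brings the median k_u° error under 3%.

## NMR relaxation

The model-free spectral density is

    J(ω) = (2/5)[S²τc/(1+(ωτc)²) + (1−S²)τ/(1+(ωτ)²)],  1/τ = 1/τc + 1/τe,

with the standard dipolar + CSA expressions for R₁, R₂ and NOE
(d = (μ₀/4π)ħγ_Hγ_N/r³, c = ω_N·Δσ/√3; the NOE keeps the signed γ_H/γ_N
ratio, so ¹⁵N NOEs fall below 1). R₂ is derived from the measured R₁ρ via
the tilted-frame relation; θ → 90° on resonance. Isotropic tumbling is the
implemented diffusion model — an axially symmetric tensor would need
per-residue N–H orientation vectors that the CSV interface does not carry,
and is recorded as an extension.

"Model 2" fitting minimises χ² over (S², τe) per residue at fixed τc
(12×12 grid over S² ∈ [0.05, 1] and log-spaced τe, refined from the three
best cells — the surface has shallow secondary valleys that can trap a
single start), wraps a bounded 1-D search for the global τc over
[1, 20] ns, and finishes with a joint Levenberg–Marquardt polish of
(τc, all S², all τe). The polish is parameterised in (ns, unitless, ps):
finite-difference Jacobians on SI-scale times are numerically degenerate,
and the rescaled joint refinement is what carries the zero-noise fixed
point to machine precision. Per-rate σ weight χ² when present, equal
weights otherwise. Residues with R₂ < R₁ — impossible for ns-scale
tumbling — are excluded with a warning. In the extreme-narrowing limit the
dipolar parts of R₁ and R₂ coincide but the CSA contribution keeps a 7/6
ratio, so R₁ ≈ R₂ holds only to ~1.5% there.

## Trajectory statistics

Contacts use heavy atoms only: Lys {NZ}, Asp {CG, OD1, OD2},
Glu {CD, OE1, OE2}. An ion contact is any oppositely charged monovalent
ion within 4 Å (inclusive) of any charged-group atom; a salt bridge is the
Lys NZ to distal-carbon (Asp CG / Glu CD) distance within the same cutoff.
A stricter named-atom-only contact rule is available as an option. Each
statistic is computed per independent run; the cross-run mean and standard
deviation (ddof = 1) are reported, with SD = 0 for a single run.

RMSF superposes every frame on an iterated mean structure (two passes,
Kabsch via quaternion alignment), computes per-atom √⟨|r−⟨r⟩|²⟩ and
averages over the backbone selection {N, CA, C, O} per residue. Hydrogen
bonds require a protein N/O donor with a covalently attached hydrogen
(inferred from ≤ 1.25 Å in the first frame), a donor–acceptor heavy-atom
distance ≤ 3.0 Å, and a donor–H–acceptor angle ≥ 135°; the criterion is
configurable since published analyses rarely print theirs. Trajectories
are assumed pre-imaged (no periodic-boundary handling); I/O goes through
MDAnalysis behind one loading interface, with multi-model PDB as the text
interchange format.

## Sequence charge and covariation

Net charge is the integer count (+1 Lys/Arg, −1 Asp/Glu, His and termini
neutral) — the convention used when comparing charged surfaces at neutral
pH. Alignment charge statistics ignore gaps and use a normal-approximation
95% CI. Domain boundaries are caller-supplied; nothing is hard-coded.

Covariation is mutual information in bits over column pairs (gaps a 21st
symbol; columns encoded over their observed alphabet, which changes
nothing mathematically), corrected with the average-product correction
MI_apc(i,j) = MI − MI_i·MI_j/⟨MI⟩. Significance uses a permutation null —
every column shuffled independently within itself, which preserves
composition while destroying covariation — with the APC-MI values of **all
pairs of all shuffled alignments pooled** into one null sample. Pooling is
deliberate: with L ≈ 60 columns there are ~1800 pairs, and a per-pair-only
null of ~10³ draws cannot yield p-values small enough to survive
Benjamini–Hochberg across pairs; the pooled null has resolution
~1/(n_permutations × n_pairs). The method is labelled as such in outputs.
One intrinsic limit: with a single strong pair, BH at q < 0.05 admits a
second (spurious) pair in ≈9–10% of datasets regardless of permutation
depth — detection of the true pair is essentially certain, exclusivity is
~90%.

## Synthetic data: what it emulates, and what it does not

All generators draw from an explicitly seeded NumPy Generator (one stream
per call, no global state), add i.i.d. Gaussian noise on the measured
signal, and are byte-reproducible. Defaults encode the study system:
ΔG° = 4.4 kJ/mol, m_eq = 5 kJ/mol/M, m_eq^salt = 17 kJ mol⁻¹ M^(−1/2)
(consistent with stability rising to ~20 kJ/mol at 800 mM NaCl),
k_u° = 0.088 s⁻¹, m_ku = 0.177 M⁻¹, S² ≈ 0.85, τe = 50 ps, τc = 5.76 ns,
an ion atmosphere with frequent Na⁺ contacts at 15 acidic residues and
rare Cl⁻ contacts at 3 lysines, four salt bridges at 35–55% occupancy, and
262 ortholog-like sequences with mean net charge −10 and one planted
covarying pair. The urea grid is a serial-dilution series from 10.5 M
(plus a buffer well): the assay starts concentrated and dilutes, which
samples the low-urea transition of a marginally stable domain densely.
Kinetic traces default to one minute at 10 Hz. The fluorescence noise
magnitude is not a published quantity and remains a free parameter.

Toy trajectories are geometric, not physical: each tagged ion (or
salt-bridge partner group) is placed 3 Å from its target in "contact"
frames and 9 Å away otherwise by a seeded Bernoulli draw, on residues
spaced 25 Å apart so sites are independent, plus 0.02 Å jitter. Occupancy
of the 4 Å shell is the only contract the analysis code depends on — there
is no water, no forces, no correlation between frames. Alignment
background columns use a consensus letter plus three alternates at 70%
conservation: a flat 16-letter column would carry ~0.6 bits of pure
finite-sample MI bias at n ≈ 260, which no real ortholog column does.

Consequently, passing tests demonstrate correctness of the estimators and
their statistical calibration under the stated noise model — not
robustness to baseline curvature, correlated noise, exchange contributions
to R₂, unimaged periodic boundaries, or phylogenetic correlation between
sequences, none of which the generators produce.

## Problem sizes

Default test-suite problem sizes: 2000-seed salt-model sweeps, 100-seed
covariation and chevron-recovery sweeps, 30-seed model-free noise sweeps,
2000-frame occupancy checks, ≤ 10-frame oracle-equivalence fixtures. The
acceptance script uses 500 salt-model seeds and 20 covariation seeds; all
other quantities are deterministic given the seed.
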