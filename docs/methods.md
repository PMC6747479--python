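# Methods

`micellenmr` implements the quantitative NMR chain used to characterise a
transmembrane peptide solubilised in detergent micelles: translational
diffusion from pulsed-field-gradient spin echoes, overall rotational
tumbling from 15N relaxation, and micro-to-millisecond chemical exchange
from 31P CPMG relaxation dispersion, plus chemical-shift-perturbation and
helical-wheel summaries. This note records the models, the numerical
choices, and the places where the design was genuinely open.

## Physical constants and referencing

Gyromagnetic ratios are CODATA values. Larmor frequencies are computed as
the IUPAC frequency ratio Xi times the spectrometer's calibrated 1H
frequency (599.98 MHz at 14.1 T, 799.94 MHz at 18.8 T), the convention
used for indirect referencing; Xi(13C) = 0.251449530 and
Xi(15N) = 0.101329118 are the DSS-referenced constants. Xi and
|gamma|/gamma_H differ at the fourth decimal (Xi is defined against a
reference compound); the registry enforces agreement to 0.1%.

Solvent viscosity, needed only by Stokes–Einstein, comes from a pure-water
anchor table (5 K steps, 273.15–373.15 K, standard reference values)
interpolated linearly in log(eta) — viscosity is nearly Arrhenius over
this range, so the interpolation passes through every anchor exactly and
is smooth between them. Heavy water is handled by a multiplicative factor
linear in the D2O volume fraction, reaching 1.23 at pure D2O (the known
viscosity ratio near room temperature). Both the table and the micelle
stoichiometry defaults (CMC 8.3 mM, aggregation number 55 for SDS) can be
overridden from a JSON config.

Micelle stoichiometry is reported by default without subtracting the free
monomer (CMC) pool, because that is the convention under which a 110 mM
SDS / 1 mM peptide sample with aggregation number 55 is quoted as 2:1;
the CMC-corrected form is available behind a flag.

## PGSE diffusion

Echo attenuation follows the Stejskal–Tanner law
I(G) = I0·exp(−D·(G·gamma·delta)²·(Delta − delta/3)). Gradients are
carried internally in T/m; readers accept G/cm with an explicit column
name (`gradient_gcm`), since published gradient strengths mix both units.
The diffusion times used by the synthetic generator default to 40 ms
(1H), 60 ms (31P) and 200 ms (2H), but analysis readers always require
the geometry explicitly.

Fitting is unweighted nonlinear least squares in amplitude space
(weighted when per-point errors are supplied), initialised from the
log-linear regression of amplitude on b-factor. On noiseless data the
linearised and nonlinear estimates agree to better than 1e-6 relative; on
1%-noise 25-point series the median recovered D over 100 realizations is
within 1% of truth.

Polydispersity is probed by a regularised inverse Laplace inversion: the
amplitudes are projected onto a log-spaced grid of diffusion coefficients
(default 64 points over 4 decades centred on the single-component fit) by
non-negative least squares with a first-difference smoothness penalty.
The first-difference operator makes the infinite-regularisation limit a
flat distribution, a convenient diagnostic. The penalty weight is chosen
by the discrepancy principle: the largest weight whose reconstruction
misfit stays at the noise floor estimated from the single-component fit
residuals. Two components separated by a factor of 10 in D are resolved
at 0.5% noise; closer pairs merge, as for any smoothing inversion.

Stokes–Einstein, Rh = kB·T/(6·pi·eta·D), assumes a sphere; no shape or
obstruction corrections are applied. A micelle-scale D of 8.2e-11 m²/s at
303 K with eta = 0.797 mPa·s gives Rh ≈ 34 Å.

## Relaxation rates

Two fit forms, selected by the series kind: a two-parameter
mono-exponential decay I0·exp(−R·t) (15N longitudinal and transverse
series, 31P spin-echo decays) and a three-parameter inversion recovery
I0·(1 − A·exp(−R1·t)) with A ≈ 2 for ideal inversion (31P longitudinal).
Initialisation is deterministic: the rate from a log-linear regression
between the first- and last-third means, the amplitude from the first
point. Uncertainties are taken from the fit covariance.

A goodness-of-fit gate flags — never rejects — series a single
exponential describes poorly: reduced chi-square > 3 when per-point
errors are known, otherwise a residual-sign runs test (|z| > 2.5). A
bi-exponential decay with well-separated rates trips the gate, which is
the relevant diagnostic when deciding whether a slowly exchanging second
population is visible in a decay.

## Rotational correlation time

The forward model is the standard rigid-rotor dipolar + CSA expression
for amide 15N with the Lorentzian spectral density
J(w) = (2/5)·tau_c/(1 + w²·tau_c²):

    R1 = (d²/4)[J(wH−wN) + 3J(wN) + 6J(wH+wN)] + c²·J(wN)
    R2 = (d²/8)[4J(0) + J(wH−wN) + 3J(wN) + 6J(wH) + 6J(wH+wN)]
         + (c²/6)[4J(0) + 3J(wN)]

with d = mu0·hbar·gammaH·gammaN/(4·pi·rNH³) and c = dSigma·wN/sqrt(3).
Defaults rNH = 1.02 Å and dSigma = −160 ppm are the conventional
backbone-amide values and are configurable.

The primary estimator is the classic closed form obtained by keeping only
the J(0) and J(wN) terms, so that R2/R1 = (7 + 4·wN²·tau_c²)/6 and

    tau_c = sqrt(6·R2/R1 − 7) / (4·pi·nuN).

It requires R2/R1 > 7/6; below that (extreme narrowing) there is no real
solution and the code raises. Note the 7/6 limit belongs to this reduced
ratio, not to the full expressions above, whose ratio tends to ≈1.03 as
tau_c → 0. A second estimator inverts the full forward ratio by bracketed
root finding on tau_c ∈ [0.1, 100] ns; the two agree within 5% for
tau_c between 4 and 25 ns at 14.1 T, which brackets both micelle regimes
(≈7 ns anionic, ≈21 ns zwitterionic). Uncertainties propagate to first
order from the rate uncertainties, treating R1 and R2 as independent.

The static field enters only through nuN and is a mandatory parameter:
the source measurements carry conflicting field annotations, and only the
14.1 T (1H 599.98 MHz) choice reproduces both printed correlation times
from their printed rate pairs — the package ships that consistency check
as a test rather than hard-coding a resolution.

## CPMG relaxation dispersion

### Closed form

Two-site exchange (populations p_a, p_b, rate k_ex = k_ab + k_ba, angular
shift difference dw, intrinsic rates R2a, R2b) under a CPMG train with
pi–pi spacing tau_cp follows the Carver–Richards closed form

    R2eff = ½[R2a + R2b + kex − (1/tau_cp)·acosh(D+·cosh(eta+) − D−·cos(eta−))]
    psi   = (R2a − R2b − pa·kex + pb·kex)² − dw² + 4·pa·pb·kex²
    zeta  = 2·dw·(R2a − R2b − pa·kex + pb·kex)
    D±    = ½[±1 + (psi + 2·dw²)/sqrt(psi² + zeta²)]
    eta±  = (tau_cp/sqrt 2)·sqrt(±psi + sqrt(psi² + zeta²))

dw is interpreted in rad/s throughout. For large eta+ the cosh overflows
double precision; the implementation switches to the asymptotic
log-domain form acosh(x) ≈ eta+ + log(2·bracket) above eta+ = 300, so the
function is total over the valid parameter box. Degenerate cases (p_b = 0,
k_ex = 0, or dw = 0 with equal intrinsic rates) return their exact limits.

### Timing convention, validated not assumed

Published forms of this expression differ by factors of two in how the
pulse spacing enters. The convention above — eta built on the pi–pi
spacing itself — was validated against a Bloch–McConnell propagation of
the actual sequence pi/2x–[tau_cp/2–pi_y–tau_cp/2–echo]^n: free evolution
by the matrix exponential of the 2×2 complex evolution operator (state a
at offset 0, state b at +dw, exchange rates k_ab = p_b·kex,
k_ba = p_a·kex), ideal pi_y pulses as M → −conj(M). The halved-spacing
variant disagrees by up to a factor ~3 in the fast-pulsing limit; the
adopted form agrees to better than 0.5% (see below).

### What the oracle measures

A real constant-time measurement reports the single-shot rate
−ln(|M(T)|/|M(0)|)/T. In slow exchange this includes an amplitude
transient of order ln(1/p_a)/T from the rapid loss of the minor-state
coherence — up to ~5% of R2eff at p_b = 0.05 over a 40 ms train. The
closed form predicts the asymptotic per-echo decay rate instead.
`bm_r2eff` therefore offers both: the single-shot default, and
`transient_free=True`, which measures −ln(|M(2T)|/|M(T)|)/T after the
transient has passed. Comparing like with like (closed form vs
transient-free rate), the worst deviation over the slow-exchange box
(p_b ≤ 0.05, k_ex ∈ [100, 1000] /s, dw ∈ [2e3, 5.2e3] rad/s, all 17
delays) is 0.4%.

### Identifiability and the reported parameter convention

The closed form depends on its five free parameters only through four
combinations:

    u1 = R2a + R2b + kex
    u2 = |R2a − R2b − (pa − pb)·kex|
    u3 = pa·pb·kex²          (and |dw|)

so every dispersion curve is produced by an exact one-parameter family of
parameter sets (solve for the family by choosing p_b and back-computing
kex = sqrt(u3/(pa·pb)), R2a = (u1+u2s)/2 − pb·kex,
R2b = (u1−u2s)/2 − pa·kex). This is not a numerical artifact: the
asymptotic Bloch–McConnell rate is degenerate along the same family to
<0.01%. Single-field, single-temperature dispersion data therefore
determine the invariants, not the individual parameters; the
discriminating physics lives only in echo-train amplitude transients that
rate-only data do not retain.

`fit_dispersion` handles this honestly: multi-start least squares (a
deterministic Latin hypercube over the parameter box, p_b ∈ (1e-4, 0.5),
k_ex ∈ (1, 1e5) /s and dw ∈ (10, 1e5) rad/s sampled log-uniformly,
R2 ∈ (0.1, 200) /s, default 32 starts) estimates the invariants, and the
reported parameter set is a canonical representative of the fitted
family: the smallest minor population consistent with the data and the
box — the most parsimonious two-site reading, asserting the weakest minor
state the data allow. The representative reproduces the fitted curve
bit-for-bit (asserted at fit time), is deterministic, and typically parks
R2b at the box floor; R2b should accordingly be read as "not determined
by a single curve". When an independent handle on one parameter exists
(e.g. the intrinsic 31P rate of the empty micelle), the family can be
re-anchored with `params_from_invariants`. Uncertainties come from the
pseudo-inverse of J^T·J at the reported point and are conservative along
the flat direction.

Consequence for simulation studies: noiseless round trips recover the
invariants to 1e-4 and the curve exactly, but not the generating 5-tuple
(no estimator can). At the study conditions used in the recovery tests
(17-delay schedule, sigma = 0.3 /s), the minor population, major-state
rate and shift difference are recovered at the ensemble median, while the
exchange rate itself is information-limited: its profile chi-square is
flat (Delta-chi2 < 1) over roughly [60, 600] /s, and the median estimate
lands ~40% high. At sigma ≤ 0.15 /s the same estimator recovers the rate
within 8%. This is a property of the data's information content, not of
the optimizer, and is reported as such.

### Exchange detection

`detect_exchange` compares the flat one-parameter model (weighted mean
rate) against the five-parameter CR fit with an F-test,
F = [(RSS0 − RSS1)/4] / [RSS1/(n−5)]. The boundary-constrained nesting
makes the test conservative in practice: on 500 flat 10-delay curves with
sigma = 0.3 /s it fires well under the nominal 5%, while exchange curves
of the study regime (dispersion amplitude ≈ 8.6 /s) are detected
essentially always. Perfect fits (RSS1 = 0) are resolved by convention:
no evidence when the flat model is also perfect, otherwise detection.

## Shift perturbation and helical wheel

CSP is the signed per-residue difference delta_b − delta_a for one atom
type (amide proton by default); negative is upfield in medium b. Residues
covered by only one table are listed as missing, never imputed as zero.
The combined magnitude sqrt(dH² + (dN/5)²) is available but off by
default, since the primary use here is the signed single-atom pattern.

The helical wheel places residue i at (i − start)·100° mod 360 (ideal
alpha-helix; the rotation is configurable) and classifies faces by
membership in a hydrophobic set (default {A,C,F,I,L,M,V,W}).
Amphipathicity is summarised by the circular mean resultant length of the
hydrophobic residues' angles: 1 when they coincide, 0 when uniform. The
"amphipathic" flag uses a documented heuristic threshold of 0.4. A
caveat worth stating plainly: this is a sequence-composition statistic.
The helix window of the studied transmembrane segment (residues 258–271)
is predominantly hydrophobic (9 of 14 residues), so its hydrophobic
angles tile the wheel nearly uniformly (resultant ≈ 0.03) and the
sequence-only projection does not call it amphipathic — the one-sided
hydrophobic face observed for that helix in a zwitterionic micelle
emerges from lipid contacts (an MD-level observable), which are outside
this package's scope. A designed sequence with hydrophobics confined to
one half-circle scores resultant > 0.4 and is flagged.

## Synthetic data

The generators produce exactly what the readers consume, with ground
truth and seed embedded in a provenance record. Acquisition schedules are
the studied experiments' printed ones: the ten-point 15N longitudinal set
(10–1250 ms), the eight-point 15N transverse set (10–210 ms), the
ten-point 31P inversion recovery (0.0625–32 s), the nine-point 31P decay
(1.25–320 ms), the 17-delay CPMG list (50 us – 2.0 ms, with 0.2, 0.9 and
1.1 ms duplicated as independent rows) and the 10-delay empty-micelle
list. The proton gradient ramp is 25 steps up to 0.6 T/m (60 G/cm); the
X-nucleus ramp spans 0.09–8.26 T/m, the high-gradient-probe range.

Noise is additive i.i.d. Gaussian with a per-call sigma. Randomness comes
from one documented generator: each generator name is hashed (CRC32) into
a `SeedSequence` spawn key together with the user seed, so equal seeds
reproduce series bit-for-bit while the three generators draw from
provably distinct streams. What the generators do NOT emulate:
lineshapes, baseline and phase errors, temperature drift, correlated
noise between replicate delays, pulse miscalibration in the CPMG train,
or polydispersity of the micelle ensemble. Recovery tests passing on this
synthetic data therefore validate the estimators against their own
forward models under honest noise, not against every systematic of a real
spectrometer.

Simulation sizes used by the shipped studies — 50 replicates for
dispersion recovery, 100–500 seeds for detection calibration and
diffusion recovery, 200 seeds for relaxation-rate calibration — were
chosen as the package's own desk-scale defaults; medians over these
ensembles are stable to well under the tolerances they are compared
against.

## Known limitations

- Stokes–Einstein assumes spheres; prolate/oblate micelles bias Rh.
- No Lipari–Szabo internal-motion analysis: one labelled site does not
  constrain an order parameter, so tau_c is an overall-tumbling estimate
  contaminated by any exchange contribution to R2.
- The CR fit reports a convention-resolved representative (see above);
  individual exchange parameters from a single field/temperature should
  be quoted together with the invariants.
- The inverse Laplace step shares the usual ill-posedness of its class:
  resolution depends on noise, and the regularisation choice is a
  documented heuristic.
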