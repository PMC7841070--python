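# Methods

## Physical model

The analyte is a micelle-forming amphiphile (a polycationic
calix[4]arene with long alkoxy tails) at 0.2 mM — well into its
aggregated regime — titrated with a small-molecule guest. Binding is
modelled as a single mass-action equilibrium between the guest and the
micellar pseudo-component,

    H + G ⇌ HG,    K = [HG]/([H][G]),

with the host expressed on its analytical per-monomer concentration
scale. This is a deliberate bookkeeping choice: no aggregation number
is assumed, so K and ΔH are per mole of amphiphile monomer, which is
also the scale on which the experimental concentrations (0.2 mM) and
published binding constants are quoted. Multi-site, cooperative and
competitive schemes are out of scope.

Speciation at given totals (h, g) is the physical root of the
mass-action quadratic, evaluated as

    [HG] = 2hg / (b + √disc),  b = h + g + 1/K,
    disc = (h − g)² + 2(h + g)/K + 1/K²

The expanded discriminant is manifestly non-negative and avoids the
b² − 4hg cancellation, so the root stays accurate for K·h ≫ 1 and for
h ≈ g; K = 0 returns [HG] = 0 exactly. For the free species near
saturation, `solve_1to1` solves the deficient component's own quadratic
in the same rational form and uses the identity free_G − free_H = g − h
rather than subtracting [HG] from a total, which would lose all digits
when [HG] approaches the smaller total. Agreement with a bracketing
bisection oracle is at the 1e−15 relative level over
K ∈ [1, 10¹²], concentrations ∈ [10⁻⁹, 10⁻¹] M.

## Overfilled-cell dilution model

The instrument keeps a constant active volume V₀ = 988 µl; each
injection of volume vⱼ (10 µl by default) expels the same volume. The
package adopts the discrete-plug convention: the expelled plug carries
the *pre-injection* cell composition, the injected titrant is fully
retained, and mixing is instantaneous. This yields the recurrence
hⱼ = hⱼ₋₁dⱼ, gⱼ = gⱼ₋₁dⱼ + c_syr vⱼ/V₀ with dⱼ = 1 − vⱼ/V₀. The
alternative continuous-perfusion convention differs by under 0.5% at
the 250/988 total-injection ratio used here.

The heat of injection j counts complex formed over the active volume,
with the dⱼ factor crediting complex carried out in the expelled plug:

    Qⱼ = −δnⱼ·ΔH⁰,  δnⱼ = V₀([HG]ⱼ − [HG]ⱼ₋₁dⱼ)

so an exothermic reaction (ΔH⁰ < 0) evolves positive heat. Two
consequences worth knowing: (i) in the strong-binding, guest-limited
regime ΣQ = −ΔH⁰ × (total injected guest moles) exactly, because the
expelled complex is counted when formed; (ii) the discrete-plug
convention makes ΣQ depend weakly on how a given titrant volume is
split — halving all injections shifts ΣQ by O(n·(v/V₀)²) ≈ 0.25% for
the default design. This is a property of the convention, not a bug;
the test suite pins the magnitude and its first-order scaling.

Demicellisation heats on diluting the host are not modelled: in every
fitted experiment the host stays above its aggregation threshold.

## Peak integration and blanks

Raw thermograms are integrated per injection above a piecewise-linear
baseline anchored at the median power in the quiet window (default
10 s) just before each injection and just before the next. Medians
resist single-sample spikes; the price is that integration is strictly
linear in the trace only when the quiet windows are flat (medians are
not additive in general). Gross heats are trapezoidal integrals of
power minus baseline; a constant power offset therefore cancels
exactly, and a 50 µJ Gaussian pulse (σ = 2 s, 1 Hz sampling) is
recovered to well under 1%.

Blank correction is strictly by injection index against a
matched-schedule guest-into-buffer run (equal counts and volumes to
1e−12 L); interpolating a blank against titrant concentration is
rejected by design so that no hidden model enters the net heats.

## Global fit

The estimator minimises U = Σ(Q_obs − Q_calc)², unweighted, summed over
all injections of all titrations, in the parameters (log K, ΔH).
Fitting log K rather than K matches the symmetric uncertainties with
which binding constants are reported and conditions the optimiser.
Minimisation is Levenberg–Marquardt with an analytic Jacobian
(d[HG]/dlog K from implicit differentiation) and a deterministic
multistart over log K ∈ {1, …, 8}, ΔH seeded from the first-injection
heat; the best converged solution is polished by Gauss–Newton on the
normal equations, whose sums are dataset-order invariant, so fits are
reproducible to ~1e−10 under dataset permutation. No per-titration
offset or stoichiometry parameter is refined: blanks are subtracted
upstream and n = 1 is fixed by the model class.

Uncertainties are asymptotic: cov = s²(JᵀJ)⁻¹ with s² = U/(n − 2) and
replicates pooled into one degree-of-freedom budget. Confidence
intervals use Student's t on n − 2 degrees of freedom. sd(ΔS) is
propagated from the full (log K, ΔH) covariance including their
correlation. In Monte-Carlo calibration (200 experiments, log K ∈
[2, 6], ΔH ∈ [−25, 25] kJ/mol, three pooled replicates, 2% noise) the
95% CIs cover the generating values at 94–97%.

A fit is refused — `IndeterminateParametersError`, surfaced as
"no detectable binding" in reports — when the normal equations are
numerically singular (condition number above 1e12, e.g. all-zero
heats) or when a partial F-test at 5% cannot distinguish the fitted
model from Q ≡ 0. The second gate operationalises the null outcome of
a monomer-control titration: parameters are only reported when the
data contain a statistically detectable binding signal. Because the
synthetic monomer control retains a sub-noise residual signal by
construction, individual seeded runs are declared indeterminate in
roughly 60–80% of cases, and the tests assert a majority over ~40
replicates rather than any single run.

## Synthetic data

The generator emulates the experiment classes the analysis must
handle, with defaults fixed at the study conditions: 988 µl cell,
25 × 10 µl injections exhausting the 250 µl syringe, host 0.2 mM
(micellar) or 2.5 µM (monomer control), guest 2 mM, 25 °C. Where the
study protocol leaves a quantity unstated, one realistic value is
fixed: i.i.d. Gaussian heat noise with sd 2% of the largest noiseless
heat (a proxy for shot plus baseline noise of a modern nano-ITC);
blank heats linear in injected guest moles, sized at 10% of the peak
reaction heat; 25 equal injections; Gaussian instrument response of
σ = 2 s at 300 s spacing for trace synthesis. All randomness flows
from one seeded PCG64 generator, so fixed recipes are byte-identical.

What the generator does *not* emulate — and hence what passing tests
cannot certify about real data: instrument response-time distortion
and its deconvolution, baseline wander beyond a linear drift,
correlated noise, demicellisation transients, titrant-concentration
errors, and vendor file formats. Acceptance of the pipeline on these
fixtures shows the estimator is correct for its stated model, not that
the model captures every instrumental artefact.

## Numerical and formatting choices

- R = 8.314462618 J/(mol K); 25 °C = 298.15 K; standard state
  1 mol/L. Table units at the boundary (kJ/mol for ΔH/ΔG/TΔS,
  J/(mol K) for ΔS), SI internally; heats in µJ at file boundaries.
- Parenthetical uncertainties round the sd to one significant digit
  and the value to that digit's place ("5.1 (3)" = 5.1 ± 0.3); the
  formatter and parser round-trip.
- Monoisotopic masses use IUPAC/NIST most-abundant-isotope values
  embedded as data; the electron mass (0.00055 Da/charge) is neglected,
  which is far below the 0.001 Da precision of quoted calcd values.
  Formula charge suffixes accept only unambiguous spellings ("+",
  "++", " 2+"): in flat text "O122+" cannot be split reliably between
  element count and charge.
- The simulated-trace pulse is centred 6σ after the injection time and
  rejected if more than 1e−6 of its area would leak outside the
  injection's integration window.

## Known limitations

- Asymptotic (linearised) uncertainties only; no profile likelihood or
  bootstrap. At very low c (≲ 0.01) intervals become approximate.
- The one-site model is fixed; lack-of-fit against other
  stoichiometries is not assessed.
- Heat-capacity changes (ΔCp) are out of scope — single-temperature
  data only.
- The indeterminacy F-test assumes i.i.d. Gaussian residuals, the same
  assumption the least-squares objective already makes.
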