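# itcfit

Analysis of nano isothermal-titration-calorimetry (ITC) experiments on
drug–micelle association: peak integration of raw thermograms, blank
(dilution) subtraction, and simultaneous nonlinear least-squares
refinement of the binding constant and enthalpy for a 1:1
guest + micellar-host equilibrium in an overfilled cell, plus the
derived thermodynamic signature (ΔG, ΔS, TΔS).

The package targets the common supramolecular/drug-delivery situation:
an amphiphilic macrocycle (here a polycationic calix[4]arene) that
self-assembles into micelles which entrap an antibiotic guest. Several
titrations of guest (2–10 mM) into the micellar host (0.2 mM, 988 µl
overfilled cell, 250 µl syringe, 25 °C, heat-neutral buffer) are
refined together against matched guest-into-buffer blanks.

## Model

The one-site model treats the micellar pseudo-component H (analytical,
per-monomer concentration) and guest G as

    H + G ⇌ HG,    K = [HG] / ([H][G])

In overfilled mode each injection of volume *v* expels an equal volume
of pre-injection cell liquid, so after injection *j* (dilution factor
*d*ⱼ = 1 − *v*ⱼ/V₀):

    hⱼ = hⱼ₋₁·dⱼ,   gⱼ = gⱼ₋₁·dⱼ + c_syr·vⱼ/V₀

The heat of injection *j* follows from the change in moles of complex
in the active volume,

    Qⱼ = −δnⱼ·ΔH⁰,   δnⱼ = V₀·([HG]ⱼ − [HG]ⱼ₋₁·dⱼ)

and (log K, ΔH⁰) are estimated by minimising the unweighted objective

    U = Σ (Q_obs − Q_calc)²

summed over every injection of every titration (Levenberg–Marquardt,
deterministic multistart over log K = 1…8). From the estimates,
ΔG = −RT ln 10 · log K and TΔS = ΔH − ΔG. A titration whose heats do
not carry a statistically detectable binding signal (e.g. host diluted
below its critical micelle concentration) is reported as
"no detectable binding" rather than as meaningless numbers.

A small monoisotopic-mass module covers the ESI-MS characterisation
arithmetic for the synthesised amphiphiles.

## Worked example

```python
import itcfit as it

# simulate three replicate titrations: log K = 5.1, ΔH = +2.41 kJ/mol
rec = it.micellar_recipe(log_k=5.1, delta_h=2.41, seed=11)
rng = rec.rng()
curves = []
for _ in range(3):
    gross, blank = it.simulate_titration(rec, rng=rng)
    curves.append((rec.schedule, it.subtract_blank(gross, blank).net))

res = it.OneSiteBindingModel(curves).fit()
print(res.summary())
```

```
One-site (1:1) global binding fit
=================================================
datasets: 3    points: 75    dof: 73
T = 298.15 K    U = 9.3760e-11 J^2
-------------------------------------------------
log K   =       5.11 (3)   95% CI [5.060, 5.169]
dH      =       2.39 (2) kJ/mol   95% CI [2.354, 2.425]
dG      =         -29.19 kJ/mol
dS      =      105.9 (5) J/(mol K)
TdS     =          31.58 kJ/mol
corr(log K, dH) = -0.710    Wiseman c = 26
=================================================
```

The fit recovers the generating values within a few standard
deviations (parenthetical digits apply to the last printed decimal).
ΔG ≈ −29 kJ/mol with TΔS ≈ +32 kJ/mol marks an entropy-driven
association; the Wiseman parameter c = K·[H] ≈ 26 indicates a
well-curved isotherm, so both parameters are well determined.

The same workflow is available from the shell:

```
itcfit simulate  --recipe recipe.toml --outdir fixtures/ --traces
itcfit integrate --trace fixtures/gross_trace.csv --schedule fixtures/schedule.csv --out gross.csv
itcfit fit       --data net1.csv net2.csv net3.csv --config expt.toml --out result.json
itcfit report    --results result.json
itcfit mass      --formula C100H176Cl3N4O12 --charge 1
```

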