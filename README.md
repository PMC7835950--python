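# oxokinetics

Isoenzyme-resolved inhibition kinetics for 2-oxo acid dehydrogenases:
deconvolution of one- vs two-site Michaelis–Menten saturation, competitive
inhibition constants per site class via Cornish-Bowden secondary plots in
three fitting coordinate systems, and inhibitor selectivity summaries — with
a synthetic assay generator for end-to-end parameter-recovery validation.

## The problem

Mammalian tissues express two closely related 2-oxo acid dehydrogenases: the
ubiquitous 2-oxoglutarate dehydrogenase (OGDH) and the *DHTKD1*-encoded
2-oxoadipate dehydrogenase (OADH).  Phosphonate analogs of their dicarboxylic
2-oxo acid substrates — succinyl (SP), glutaryl (GP) and adipoyl (AP)
phosphonate — are competitive inhibitors whose selectivity between the
isoenzymes makes them pharmacological tools.  Quantifying that selectivity
from spectrophotometric assays of tissue preparations requires:

1. recognizing when a preparation contains **two independent classes of
   substrate-binding sites** (biphasic saturation, affinities ~60-fold apart)
   and deconvolving them,
2. estimating a **site-specific competitive Ki** for each inhibitor, and
3. doing both consistently across the field's three classical fitting
   coordinate systems (direct nonlinear Michaelis–Menten, Lineweaver–Burk,
   Eadie–Hofstee).

## The model

Specific activity `a` at substrate concentration `[S]` follows

    a = Amax·[S]/(Km + [S])                         (one site class)
    a = Amax,1·[S]/(Km,1+[S]) + Amax,2·[S]/(Km,2+[S])   (two classes, Km,1 < Km,2)

with the two-site model selected only when the one-site fit is poor
(R² < 0.98).  A competitive inhibitor at concentration `[I]` rescales each
site's Michaelis constant, `Km,eff = Km·(1 + [I]/Ki)`, leaving `Amax`
unchanged, so the ratio `q = Km,eff/Amax,eff` is linear in `[I]`:

    Km,eff/Amax,eff = (Km/Amax)·(1 + [I]/Ki),   Ki = intercept/slope.

Ki is estimated from this secondary plot per coordinate system and reported
as the cross-method mean ± SEM.  Errors of all ratio estimators propagate by
relative-error quadrature.  See `docs/methods.md` for the full treatment,
including site tracking by Amax and cross-site background subtraction in the
two-site path.

## Worked example

No raw rate data from the original study are deposited, so the package ships
generator presets encoding its published kinetic parameters as ground truth.
Reproduce the cardiac-preparation Ki table from synthetic panels (3%
multiplicative noise, 3 replicates, AP's dose grid extended to 5,000 µM
because it is a ~2 mM-scale inhibitor of this reaction):

```
python analysis/01_simulate_panels.py
python analysis/02_fit_saturation.py
python analysis/03_estimate_ki.py
python analysis/04_two_site_selectivity.py
```

At seed 1 the third driver prints

```
cardiac OG reaction, cross-method Average Ki (µM):
  AP: 2151 ± 29
  GP: 33.7 ± 1.5
  SP: 15.76 ± 0.41
```

— one realization's estimates of the ground-truth values 2129, 33 and 16 µM:
SP and GP inhibit the cardiac OGDH reaction in the low-µM range while AP is
about two orders of magnitude weaker.  The second driver shows the model
selection that motivates the site-resolved analysis: all panels are one-site
(R² > 0.99) except the hepatic OA reaction, whose one-site fit fails the
R² < 0.98 rule (0.976 at this seed) and is resolved into high-affinity
(Km ≈ 0.008 mM, attributable to OADH) and low-affinity (Km ≈ 0.45 mM) sites.
The fourth driver resolves per-site Ki on that biphasic panel and prints the
selectivity ratios — AP prefers the high-affinity OADH sites by ~3 orders of
magnitude, SP prefers the low-affinity sites, GP has little preference.

The same pipeline is available as a CLI (`oxokinetics simulate | fit | ki |
report`) and accepts measured data in the same tidy CSV schema the simulator
writes (`preparation_id, substrate_id, substrate_conc_mM, inhibitor_id,
inhibitor_conc_uM, rate_umol_min_mg, replicate`).

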