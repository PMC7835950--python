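# Methods

## The model

The package analyzes steady-state saturation kinetics of 2-oxo acid
dehydrogenase preparations that may contain one or two independent classes of
active sites.  Because the enzyme preparations are not homogeneous, maximal
rates are expressed as maximal specific activities, `Amax`
(µmol·min⁻¹·mg⁻¹ protein), standing in for `Vmax`; the measured rate is the
specific activity `a`.

One site class follows the Michaelis–Menten law

    a(S) = Amax · S / (Km + S),

two classes follow the sum of two such terms with `Km,1 < Km,2` (canonical
ordering: the high-affinity site is always listed first).  A purely
competitive inhibitor at concentration `I` rescales each site's Michaelis
constant independently,

    Km,eff = Km · (1 + I / Ki),        Amax,eff = Amax,

with a site-specific inhibition constant `Ki`.  Substrate concentrations are
in mM, inhibitor concentrations and `Ki` in µM; the two scales only ever meet
inside the dimensionless ratio `I/Ki`.

## Fitting coordinate systems

Each saturation series (all measurements at one fixed inhibitor
concentration) is fitted three ways:

* **NLS** — nonlinear least squares on the hyperbola itself (reported as "MM"
  in tables), multi-start over a log-spaced Km grid ({1/100, 1/10, 1, 10} ×
  the geometric mean of the substrate grid), best SSE wins, ties broken toward
  the smaller Km.  Standard errors are asymptotic (from the covariance of the
  fit).
* **LB** — Lineweaver–Burk: straight line in (1/S, 1/a); Km = slope/intercept,
  Amax = 1/intercept, SEs by relative-error quadrature of the line
  coefficients.
* **EH** — Eadie–Hofstee: straight line in (a/S, a); Km = −slope,
  Amax = intercept.

Least squares is unweighted everywhere by default (a weighted option exists
but is off), and replicates enter as individual points rather than means,
preserving degrees of freedom.  On noise-free model data all three coordinate
systems agree to 1e-8 relative — the central consistency oracle of the test
suite.

Points outside a transform's domain (S ≤ 0 or a ≤ 0) are excluded from the
linearized fits and counted; so are measurements flagged below the detection
floor, because reciprocal-style coordinates amplify the noise of the smallest
rates.  Below-floor points stay in the nonlinear fits.

## Model selection

The one-site model is fitted first; the two-site model is tried only when the
one-site coefficient of determination falls below a threshold (default
R² < 0.98) and the series has at least 7 distinct substrate concentrations.
R² is 1 − SS_res/SS_tot about the observed mean, allowed to go negative.  A
two-site solution is flagged degenerate — and model escalation rejected —
when the fitted affinities lie within a factor of two of each other or when
one site carries less than 1% of the summed Amax (both patterns mean the data
are effectively one-site).  The rule is applied per series; both fits and
both R² values are always reported.

## Ki from secondary plots

For competitive inhibition the ratio q = Km,eff/Amax,eff is linear in `I`:

    q(I) = (Km/Amax) · (1 + I/Ki),

so an ordinary least-squares line of q on `I` has intercept `Km/Amax`, slope
`Km/(Amax·Ki)`, and `Ki = intercept/slope`.  The SE of this ratio — and of
every other ratio estimator in the package — is propagated by relative-error
quadrature, `|a/b|·sqrt((se_a/a)² + (se_b/b)²)`, ignoring the
intercept–slope covariance (documented assumption).  A non-positive slope is
reported as "no measurable inhibition" rather than a negative constant.

Ki values from the three coordinate systems are averaged; the spread is
reported as SEM with the n−1 (sample) standard deviation.  This averaging
convention reproduces the published multi-method kinetic tables it mirrors
(verified against their printed cells to within one unit in the last printed
digit; one printed cell appears to carry a rounding slip of that size).

The mechanism itself is checked, not assumed: the Amax,eff trend over
I ≤ 200 µM is tested with a 95% confidence interval on its OLS slope, and the
verdict is "competitive" unless the interval lies entirely below zero.  At
the 3% noise level the test keeps the competitive verdict in ≳ 95% of runs;
by construction ~2.5% of purely competitive panels will still be called
"mixed" at a single seed.

## Two-site (biphasic) preparations

Site-resolved Ki estimation combines three ingredients:

1. **Full-range two-site NLS fits per inhibitor concentration.**  Site
   identity across concentrations is matched by Amax proximity to the
   uninhibited baseline, not by Km ordering: Amax is the invariant of
   competitive inhibition, whereas strong inhibition of the high-affinity
   site can push its Km,eff past the other site's and silently swap
   Km-ordered labels.
2. **Range splitting for the linearized methods.**  Because the two
   affinities differ ~60-fold, LB/EH fits are done separately on a low
   ([0, 0.05] mM, dominated by the high-affinity sites) and a high
   ([0.1, 10] mM) substrate interval (closed bounds; points in the gap belong
   to neither and are counted).
3. **Cross-site background subtraction.**  Within each interval the other
   site class still contributes up to ~30% of the signal; each range is
   corrected by subtracting the other site's fitted per-concentration
   contribution before the line fit.  Without this correction the
   high-affinity Ki is overestimated by 50–80% (measured in the recovery
   studies) — the pseudo-one-site line absorbs the background into both
   intercept and slope.

Each site's per-method Ki then comes from its own secondary plot, and
failures are local: a concentration whose fit collapses (degenerate sites,
too few usable points after floor exclusion) is dropped from that method with
a log entry, a method with fewer than three surviving concentrations is
dropped from the average, and a site the dose grid never usefully probed is
returned as "not probed" rather than as a number.

### Known limitation: the weakly probed site under strong doses

When the dose grid is matched to one site's Ki but the other site's Ki is
three orders of magnitude larger (adipoyl phosphonate on the hepatic
preparation: 0.048 µM vs 47 µM), doses of tens of µM shift the high-affinity
site's Km,eff to 1.6–16 mM — into, and past, the observable substrate range.
The residual contribution of that site is then quasi-degenerate with the
low-affinity site, and no estimator tried (plain range fits,
background-subtracted fits, Amax-constrained fits) recovers the low-affinity
Ki to better than roughly −25…−40% median at 3% noise.  The high-affinity Ki
from a dose grid matched to it is unaffected (recovered to a few percent).
This is an identifiability property of the data-generating model, not a
numerical artifact; the recovery test for this case asserts only factor-2
agreement and the reported SEMs are honestly wide.

## Progress curves

Absorbance traces (NADH at 340 nm) are reduced to initial rates by a sliding
linear-window search: all contiguous windows of ≥ 2 min between a
configurable initial exclusion (default 0.5 min, covering mixing and
solubilization artifacts) and 10 min are scored by |r| of their line fit;
highest |r| wins, ties (within 1e-12) broken toward the longer window.  The
result is invariant to constant absorbance offsets.  Slopes below
ΔA340 = 0.001/min are flagged as below the reliable detection floor.
Conversion to specific activity uses the NADH extinction coefficient
6.22 mM⁻¹·cm⁻¹ (standard value, configurable) with cuvette volume, path
length and protein mass from the curve metadata.

## The synthetic-data generator

No raw rate data are deposited for the study this package emulates, so every
downstream stage is validated on synthetic panels whose generative model is
exactly the analysis model: one- or two-site Michaelis–Menten rates with
site-specific competitive Km scaling, evaluated on a semi-log substrate grid
(1–2.5–5 spacing over 0.0025–10 mM, 13 points including the zero blank) for
each dose in the inhibitor grid (default {0, 10, 25, 50, 100, 200} µM,
extendable to 5,000 µM for weak inhibitors and to sub-µM doses for very tight
ones).

Noise is multiplicative: rate × (1 + ε), ε ~ N(0, cv), truncated at zero,
with an optional additive term (off by default).  cv defaults to 0.03, which
at 3 replicates produces parameter SEs of the magnitude seen in the published
saturation table.  The replicate count (not stated in the source study)
defaults to 3.  Per-series RNG streams are derived from the master seed plus
CRC32 tags of (preparation, substrate, inhibitor, dose), so any one series is
bit-reproducible regardless of which other series are generated.

The detection floor is carried in specific-activity units.  The assay it
emulates chose enzyme amounts so that the rate at 0.01 mM OA equals the
smallest reliably measurable absorbance slope (0.001/min); since cuvette
volume and path length are not stated, the presets set the floor to each
preparation's noiseless rate at 0.01 mM OA (1.18·10⁻³ µmol·min⁻¹·mg⁻¹ for the
hepatic preparation, 1.82·10⁻³ for the cardiac one).  Measurements below the
floor are flagged, kept in nonlinear fits, and withheld from linearized fits.

Four presets encode the published ground truth (Km/Amax per site; Ki per
inhibitor per site): cardiac and hepatic preparations × 2-oxoglutarate and
2-oxoadipate, the hepatic OA case being the biphasic one.  What the generator
deliberately does not emulate: tight-binding/slow-onset inhibition kinetics
(the real phosphonates show Amax losses at very high doses), preparation
impurities, non-oxidative side reactions, and any systematic (non-random)
error — so passing recovery tests demonstrate correctness of the estimation
machinery under the stated statistical model, not robustness to every
pathology of real assay data.

## Problem sizes and numerical choices

Recovery studies use 200 independent seeded realizations per experiment and
summarize by the median, the natural summary for ratio-type estimators with
right-skewed seed-to-seed distributions; the full acceptance computation runs
in about 90 seconds on one core.  Optimizer details: `scipy.optimize.curve_fit`
(bounded trust-region), Km bounded below at 1e-9 (a fit driven to that bound
is reported as unidentifiable rather than returned), line fits via
`scipy.stats.linregress`.  Dataclasses are frozen; all randomness flows
through `numpy.random.Generator` seeded as described above.
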