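# Methods

## Design geometry

The pipeline targets a six-array FACE design: three elevated-CO₂ and three
ambient arrays (the array is the only true replicate), four seasonal
campaigns (late growth, leaf fall, pre-budburst, peak growing season), six
root-exudation pseudoreplicates per array (three root boxes × two root
systems), five ingrowth-bag locations per array, and staggered ingrowth
bags collected at 3, 6 and 12 months from a single installation date.
Annual pools are therefore n = 18 pseudoreplicates per treatment and
timepoint for exudation/traits and n = 15 for ECM measures, while
array-level inference has n = 3 per treatment.

## Measurement models

**Exudation.** Each incubation recovers a total solution C and N mass
(collection plus washes pooled into one total — a conservative
total-recovery convention, since partial wash accounting is rarely
reported). One rootless blank per box and timepoint estimates background
input; blank matching falls back from box+timepoint to array+timepoint to
the global timepoint mean, and the level used is recorded. Net rates are
corrected mass / root dry mass / days (and per root surface area, and per
m² ground using the array's nearest standing fine-root census, <1 mm plus
1–2 mm classes summed; equidistant censuses resolve to the later one).
Negative net rates are genuine (reuptake can exceed release over 24 h) and
are flagged, never floored. C:N is the ratio of rates, undefined when the
N rate is non-positive. Dissolved oxidizable C is treated as fully organic.

**Root traits.** SRL = length / dry mass, reported in m g⁻¹ (ecological
convention); branching frequency = branch points / length (mm⁻¹); tissue
C:N on a mass basis. Root-order diameter classes are metadata only — no
order-specific statistics are computed.

**ECM biomass.** Ergosterol → fungal biomass at 3.3 µg ergosterol per mg
biomass (configurable); all ergosterol in bags is attributed to
ectomycorrhizal fungi, an assumption appropriate for root-excluded sand
bags in ECM-dominated stands. Seasonal production = biomass per g sand /
exact installed days, quarterly bags only.

**Turnover.** μ = −ln((B₁₂−B₆b)/B₆a)/(t₂−t₁), the unique reading of the
staggered-bag estimator consistent with the mass balance
B₁₂ = B₆a·e^(−μΔt) + B₆b, which holds for *any* production history because
only first-half biomass decays over the second half. Δt uses exact days /
365.25. Bags with B₁₂ ≤ B₆b carry no information about μ (the log argument
is non-positive) and propagate as missing — not zero — into array means, to
avoid biasing μ upward; survival fractions above 1 yield a negative μ that
is reported with a warning rather than clamped. Bags are averaged per array
before estimation; treatment summaries give the mean with SEs over both
arrays (n = 3) and locations, since the proper replication level for the
SE is ambiguous at this design.

**Response ratios.** RR = ln(mean_e/mean_a) with
v = σe²/(nₑRe²) + σa²/(nₐRa²). Annual pools default to all
pseudoreplicates across timepoints within a treatment (array-mean-first
pooling is an option). Significance is a normal-approximation CI from
√v — a package decision recorded in output metadata, since forest plots of
this kind conventionally show ±v error bars, which are a variance and carry
no significance rule. Folds with |RR| < ln(1.005) display as 1.0 (raw value
retained). The field's branching response has been printed both as RR 0.54
and 0.55 in different summaries; the generator default uses 0.55 (the
cross-mechanism comparison value) and this note records the discrepancy.

**Metabolomics.** Abundances are normalized to the root dry mass behind
each sample; ordination uses ln(x + pseudocount) with per-feature
unit-variance scaling (pseudocount default 1 abundance unit; zero-variance
ions dropped and counted), separately per compartment and ionization mode.
The treatment test per ion is a tie-corrected Kruskal–Wallis (χ², df 1 for
two groups) on mass-normalized abundances — rank-based, hence invariant to
the transform choices. No multiplicity correction by default, so ion counts
are raw-p bookkeeping as is common in untargeted screens; BH-FDR is a flag.
Folds are signed ratios of group means (medians available); classification:
accumulated (p < α, fold ≥ 1), depleted (p < α, fold ≤ −1), else
unchanged. Shared ions between roots and exudates are matched greedily
one-to-one within 10 ppm m/z and 0.1 min RT, same ionization mode only —
tolerance matching rather than string identity, since "same ion" across
separately processed tables is not a string equality.

**Small-sample inference.** The Wilcoxon rank-sum test enumerates all
C(n, n_x) mid-rank assignments exactly for pooled n ≤ 12 (tie-aware);
larger samples use the normal approximation with tie and continuity
corrections (within 0.02 of enumeration at 8 vs 8). Treatment effects at
the array level use an exact permutation test on array means in place of a
mixed-model fit — with 3 vs 3 arrays the two-sided p-value floor is
0.1 = 2/20 and is printed with every result; no degrees-of-freedom
approximation is attempted. Correlation networks are Pearson r over array
means with edges kept at |r| ≥ 0.5 — absolute value, so negative
(trade-off) relationships such as production-versus-exudation can appear;
per-treatment and pooled networks are both emitted because edge retention
could defensibly be done either way. Normality screening uses
bias-corrected skewness and excess kurtosis.

## The synthetic generator

Every measured variable follows
`baseline × seasonal_multiplier × exp(treatment·RR + array_effect) ×
lognormal noise` — multiplicative because these are positive, right-skewed
rates. Array effects (log-scale SD 0.10) are drawn once per variable and
array and shared across timepoints, the repeated-measures structure of the
design. Residual noise is mean-one lognormal with CV 0.15 by default
(measurement plus within-array biological scatter; the field study reports
no CVs, so this is the package's calibration, exposed in config). Seasonal
multipliers are per variable (exudation peaks in the growing season, N
exudation in autumn, branching in spring). Root-system geometry (dry mass,
length, surface area) is drawn once per sampling slot and shared between
treatments — a paired design that makes the no-effect/no-noise dataset
exactly equal across treatments and reduces nuisance variance in recovery
tests. Blanks are 5% of the timepoint's mean signal (no published blank
magnitudes exist; configurable).

Ingrowth-bag biomass follows the production–decay model with production P
piecewise-constant per quarter (matching the 3-month bag resolution) and
treatment-specific truth μ of 1.96 and 7.13 y⁻¹. Because a quarterly bag
nets production discounted by within-bag decay, the generator's underlying
P values are set so the *measured* net rates reproduce the study pattern
(elevated enhanced ~17% in the late growing season, suppressed in winter,
annual measured RR ≈ 0.15); the recorded ground truth for the production
RR is the measured-rate estimand, computed exactly from P, μ and the
quarter lengths. Noise multiplies the final ergosterol value per bag.
Output records ergosterol, so the conversion step is always exercised.

Metabolome matrices draw per-ion baselines lognormal (median 10⁴, log-SD
1), per-sample log-normal noise (log-SD 0.3), an affected fraction (default
6%) with signed folds log-uniform on [1.2, 9] and 20% accumulated, and a
shared-ion fraction (default 0.42) carried with identical (m/z, RT, mode)
keys. One global seed drives a named, independent substream per table
(array effects, exudates, geometry, biomass, bags, metabolome), so adding
a table never perturbs another and identical seeds give byte-identical
datasets.

**What the generator does not emulate:** treatment-by-season interactions
(one RR per variable; the field data show, e.g., a June exudation
reversal), correlated responses between variables beyond shared array
effects (trade-off correlations in synthetic data arise from treatment
contrasts, not a built-in dependence), drift or batch structure in LC–MS
intensities, censored/below-detection values, and spatial structure within
arrays. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated sampling model, not robustness to those
real-data features.

## Numerical choices and degenerate inputs

Doubled mid-ranks are integers, so exact enumeration uses integer
comparison (no float-equality hazards). The zero-variance drop in scaling
uses a relative 1e-10 tolerance to absorb float residue of constant ions
after the log. Permutation and enumeration p-values compare with a 1e-12
slack to make ties of the statistic inclusive. All-tied samples give p = 1.
PCA caps components at matrix rank. Degenerate cases raise informative
errors naming the offending sample/array (orphan incubations without any
blank, missing standing-biomass arrays, non-positive root masses, B₆a ≤ 0).

## Problem sizes in the test and acceptance runs

Recovery properties are verified at the study's own geometry: 200 replicate
studies for turnover recovery, 20 for RR recovery, 5,000 null ions for the
type-I calibration, 500 random instances for the exact-test oracle, and
2,000-ion metabolomes in the end-to-end demo — sizes at which the whole
suite completes in well under a minute while Monte-Carlo error stays an
order of magnitude below the tolerances asserted.

## Known limitations

- At fast turnover (μ ≈ 7 y⁻¹), six-month survival (~2.5% of B₆a) falls
  below realistic measurement noise; the estimator then loses precision,
  some bags/arrays become unestimable, and the treatment mean acquires a
  downward nonlinear bias. This is an identifiability limit of the
  staggered-bag design itself — the package reports missingness explicitly
  and both SE levels, but cannot manufacture information the design does
  not contain.
- The array permutation test's p-value floor (0.1 at 3 vs 3) means no
  array-level result can reach conventional 0.05 significance at this
  design; it is a transparency tool, not a mixed-model replacement.
- Ion matching is greedy one-to-one; in dense m/z regions a globally
  optimal assignment could differ at the margin.
- The RR variance formula is a delta-method approximation, poor when
  either treatment mean approaches zero.
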