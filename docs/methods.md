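# Methods

## The analysis

`fluxmap` implements a system-identification analysis of the coupling between
the mean blood flux (MBF, in perfusion units, PU) of the left and right Hegu
(LI4) acupoints, measured bilaterally by full-field laser perfusion imaging
under three interventions: left-hand acupuncture (group A), right-hand
acupuncture (group B) and no intervention (group C).

### Measurement protocol

Each subject is measured in seven phases 30 minutes apart (three before the
intervention, four after), ten image frames per phase, giving 70 bilateral
sample pairs.  The ten frames of the phase immediately after needling
("post-0") are excluded to remove the nonspecific effect of the procedure,
leaving 60 retained pairs per subject and 2400 per 40-subject group.

### Model family

Per group and mapping direction, a single time-invariant model is identified
over all retained pairs:

    y(k) = a y(k-1) + b [y(k-1)]^0.3 + c u(k) + d [u(k)]^0.3

where `y` is the declared input side (left in the primary direction) and `u`
the contemporaneous contralateral side.  The structure is fixed: one lag, a
fractional-power companion term for each regressor, exponent 0.3, no
intercept.  The model is linear in (a, b, c, d), so ordinary least squares is
the estimator; rank (checked on the column-scaled design at relative
condition 1e-10) guards against degenerate inputs such as a constant
regressor, whose fractional column is collinear with its linear partner.
Lags never cross subject boundaries: each block of n retained samples
contributes n - 1 regression rows (2360 per group at full size).  A toggle
for the flat-concatenation alternative is deliberately not offered; the
block-wise layout is the only defensible reading.

Two mapping modes exist because the printed model family places the declared
*input* on the left-hand side while the study design calls the other side the
output:

* **regress-and-invert** (default): fit the equations literally, then recover
  the mapped contralateral value at each k by solving the scalar static
  nonlinearity `c x + d x^0.3 = y(k) - a y(k-1) - b [y(k-1)]^0.3`.
* **direct-regression**: swap the regressand and run the fitted recursion
  forward from a stated initial value (the mean of the training regressand).

### Static-nonlinearity inversion

Fractional powers of negative arguments arise when the model is probed with a
zero-mean signal; all arithmetic stays real through the odd extension
`sign(x)|x|^p`.  For same-sign (c, d) the map is strictly monotone and odd:
the root is found by doubling an initial bracket (at most 60 doublings) and
Brent/bisection iteration to machine precision, verified against a residual
tolerance of `1e-9 * max(1, |target|)`.  Mixed-sign coefficients make the map
non-monotone inside |x| < x0 = (p|d|/|c|)^(1/(1-p)); targets beyond the local
extremum are solved on the outer monotone branch, targets inside the fold are
located on a sign-change grid and the root nearest the caller's bracket hint
is returned with the total root count flagged.  An exhausted bracket
expansion raises an error carrying the searched interval — mapping never
silently fabricates values.

### Evaluation and probing

Mapped values are compared against the measured contralateral series through
the error series `d(k) = f*(k) - f(k)` and the signal-to-noise ratio
`sn = (sum f*^2 / sum d^2)^e`.  The printed form of the SNR ends in a
typographically ambiguous exponent token; the default here is e = 1/2 (an
amplitude ratio, commensurate with the PU scale of `sn + d(k)`), with the
alternative reading (1/2400) available in configuration.  An identically zero
error series raises a dedicated perfect-fit error rather than returning an
infinite ratio; an error series whose energy is below the floating-point
residue of the estimate (relative amplitude 1e-12) is likewise classified as
a perfect fit, since a noiseless dataset mapped through its own generating
model leaves only root-finding round-off.

Every fitted model is then probed with the same deterministic standard
signal, a sum of eight unit-amplitude sinusoids scaled by 10 (|s(k)| <= 80;
in practice |s| < 51 on k = 1..2400), over k = 1..2400 by default.  The lag
at k = 1 is seeded by evaluating the formula at k = 0 (s(0) = 40) so all 2400
probe points map.  The probe output f''(k) and the measured-data error series
form the characteristic cloud, the 2-D point set (sn + d(k), f''(k)); when
the two series differ in length (the probe keeps 2400 points, the error
series loses one lag per subject), both are truncated from the front to the
common length, which is logged.  The cloud's centroid is the group's
"distribution center"; the headline scalar is the mean of f'' by default,
with the centroid's Euclidean norm as a configurable alternative.

### Group comparison

Groups are ranked per direction by the *magnitude* of the scalar center, and
amplification is the ratio of a stimulated group's magnitude to the
control's.  The sign of the probe-output mean is not meaningful in this model
family: the family has no intercept, so the fitted coefficients must absorb
the data's mean level through the near-constant fractional-power columns, and
which side of that allocation the least-squares solution lands on flips the
sign of the extrapolated probe mean without changing its scale.  The
magnitude tracks the coupling gain monotonically in both directions; the sign
does not.  A direction-invariance flag records whether both directions
produce the same ranking.

## Synthetic data generator

The study's human measurements are not deposited, so the generator produces
bilateral series with the protocol's exact layout and a known ground truth.
It emulates: positive PU-scale signals, within-subject temporal correlation,
cross-side coupling with group-dependent strength, additive Gaussian
measurement noise, and the phase/frame/exclusion structure.  It does not
emulate: spatial perfusion images, slow physiological drifts across the
3-hour session, the post-stimulus perfusion rise at the needled site (see
below), subject-level heterogeneity of coupling parameters, or the absolute
PU scale of any particular imager.

**Driver/response mode** (groups with an intervention): the driving side
(left, by convention, for every group) is a mean-reverting positive AR(1)
around `baseline_PU` (default 60 PU, marginal SD 25 PU, lag-1 autocorrelation
0.3).  The response side satisfies the coupling model plus N(0, noise_sd_PU)
noise (default 12 PU), with the model's own lag taken on the retained grid
(the excluded post-0 frames are bridged), so that with zero noise every
retained lagged pair satisfies the generating equation to machine precision.
Positivity is enforced by redrawing an offending draw at most 100 times
(counted in the series metadata) and never by clipping; an exhausted budget
is a hard error.  Per-subject seeds derive deterministically from
(master seed, group index, subject index).

**Amplification.** `intervention_gain` g is the cross-side amplification of
the identified mapping: from the intervention onset the effective coupling
coefficients become (c/g, d/g).  In this family the probed mapping output
scales inversely with the coupling coefficients (the mapped value solves
`c_eff x + d_eff x^0.3 = residual`), so a weaker per-PU forward coefficient
is precisely a stronger amplification of a fixed probe signal — in both
mapping directions: the forward direction through the fitted coefficients
themselves, the reverse direction through the attenuation of the inverse
regression.  Default gains are B: 9, A: 3, C: 1, mirroring the qualitative
study finding (right-side stimulation amplifies most).

**Symmetric mode** (the control group's default): both sides observe one
common latent AR(1) drive plus independent Gaussian noise.  The sides are
exchangeable, so fits and probe outputs are statistically identical in the
two mapping directions — the resting state carries no lateralized structure,
which is what the control group's direction-symmetry checks require.  With
zero noise both sides coincide and satisfy the coupling identity with
coefficients (0, 0, 1, 0).

**Deliberately stationary defaults.** The generator supports a post-onset
step in the driver's mean (`step_gain`) and fluctuation SD (`post_sd_gain`),
but both default to 1.  A mid-record level step interacts badly with the
no-intercept model family: the lag coefficient absorbs the level change,
drifts toward (or past) 1, and the standard-signal probe — an extrapolation
to near-zero signal values — becomes sign- and scale-unstable.  Since the
analysis pools all retained samples into one time-invariant model, the
default study conditions keep each group's joint process stationary and
encode the intervention purely as coupling attenuation.

**Scale.** The default baseline of 60 PU places the data on the same scale
as the probe signal (|s| < 51), so the probe interrogates the fitted model
inside its identified range rather than far below it, and the fractional
basis column varies enough to be identifiable.  Absolute PU values of
full-field imagers are device-dependent; no attempt is made to match any
specific instrument beyond order of magnitude.

**What passing tests show.** The pipeline reproduces the study's qualitative
pattern (distribution-center magnitudes ordered B > A > C in both directions,
control direction-symmetric) on data generated under these conditions in at
least 95% of seeded replicates.  This validates the machinery and the
direction-invariance of the coupling-gain ordering, not the physiological
claim: real perfusion series have drifts, heteroscedasticity and
between-subject parameter variation that the generator does not model, and
the study's numeric Table-2 centers derive from undeposited human data and
are out of scope.

## Numerical choices

* OLS via `numpy.linalg.lstsq`; coefficient standard errors from
  `sigma^2 (X^T X)^{-1}` with the residual variance at n - 4 degrees of
  freedom.
* Rank guard: smallest singular value of the column-normalized design below
  1e-10 of the largest raises a rank-deficiency error naming the collinear
  columns (dominant components of the terminal right-singular vector).
* Inversion: bracket doubling (<= 60 doublings, overflow-checked) plus
  200-iteration vectorized bisection or Brent's method; residual tolerance
  1e-9 relative to the target; warm-started hints when mapping a series.
* Probe lag seed: s(0) = 40 exactly; series mapping without a seed emits one
  value fewer than its input per subject block.
* Determinism: all randomness flows from `numpy.random.SeedSequence` tuples;
  rerunning a configuration byte-reproduces model JSON and comparison CSV.

## Known limitations

* The two mapping modes bracket the study's ambiguous orientation; no claim
  is made about which the original Matlab analysis used.
* The probe-output mean is sign-indefinite (see above); magnitudes are
  compared.  The signed value is still reported in every artifact.
* The control group's printed model contains an inconsistent subscript in
  its fractional input term (a right-side series of another group); it is
  treated as the control group's own right-side series.
* Heavy positivity redrawing (very low baselines with large noise) truncates
  the noise distribution; the generator counts redraws in the series
  metadata so such configurations are visible.
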