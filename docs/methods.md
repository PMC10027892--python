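# Methods

`rtiol` models the question a cataract surgeon faces in an irregular
cornea: which intraocular lens (IOL) power and cylinder give the best
*retinal image*, rather than the smallest residual refraction?  In the
presence of higher-order aberrations (HOAs) these two criteria diverge:
a modest amount of residual defocus or astigmatism can interact
favourably with coma, trefoil or spherical aberration and raise the
visual quality above the fully-corrected state.

## Optical model

**Cornea.** Two refracting surfaces in a single right-handed frame
(z toward the retina, origin at the anterior vertex).  Each surface is a
conicoid (curvature c, asphericity Q) plus a 28-term, 6th-order Zernike
elevation in micrometres over a 3.25-mm normalization radius (6.5-mm
corneal zone).  Refractive indices: air 1.0, cornea 1.376, aqueous 1.334.

**Wavefront.** An array of collimated 555-nm rays (square grid, 33 across
the 4-mm pupil, ~830 rays) is traced through the surfaces with exact
vector Snell refraction; ray/surface intersections use Newton iteration
(1e-11 mm tolerance, Brent fallback on steep keratoconic slopes).  The
optical path difference relative to the chief ray, referenced to a sphere
centred at the best focus (the axial point minimizing RMS wavefront
error; bounded scalar search, ~1e-4 D resolution), is fitted with the
28-term orthonormal Zernike expansion over the 4-mm pupil; piston and
tilt are removed.  Signs follow the power-vector literature: a myopic eye
has c(2,0) > 0 and refraction M = -4*sqrt(3) c(2,0)/r^2 < 0.

**Pseudophakic eye.** Four surfaces: the two corneal surfaces plus a
generic equi-biconvex thick IOL (index 1.46, central thickness 0.9 mm) at
the estimated lens position ELP = ACD + 0.3 x lens thickness, with the
cylinder realized as a biconic back surface.  The commercial lens the
model stands in for publishes only its index, so the generic geometry is
constrained by the testable contract that the labelled sphere/cylinder
equal the paraxial thick-lens powers in aqueous to 0.05 D.  The wavefront
is referenced to a sphere centred on the retina at the axial length; its
second-order terms are the residual refraction at the corneal plane.

## Visual Strehl (VSOTF)

Optical quality is the neural-weighted Visual Strehl of the optical
transfer function,

    VSOTF = sum_f CSF_N(f) Re OTF(f) / sum_f CSF_N(f) OTF_DL(f),

with the Mannos–Sakrison parametric contrast sensitivity
`2.6 (0.0192 + 0.114 f) exp(-(0.114 f)^1.1)` (f in cycles/degree) as the
neural weighting — the form most VSOTF implementations use; the exact
parameters used in earlier work on this metric are not published, which
is why all population-level checks here are statistical rather than
bit-exact.  A diffraction-limited pupil scores exactly 1; values are
never clipped — severe phase reversals can make VSOTF slightly negative.
Vision is called acceptable at VSOTF >= 0.12 (inclusive).  The visual
*benefit* ratio floors both its terms at 0.001 so it stays defined and
>= 1 when the zero-target VSOTF sits at or below the noise level.

**Numerical evaluation.** VSOTF is computed through the pupil
autocorrelation identity: by Parseval, the CSF-weighted sum of Re[OTF]
equals a fixed-kernel dot product with |FFT(pupil)|^2.  Because the
circular autocorrelation equals the linear one for every shift up to
(grid - pupil) pixels, the weighted OTF band is *exact* even when the
through-focus sweep applies 10 D of defocus whose PSF would alias badly —
the aliasing lives entirely outside the autocorrelation band the metric
reads.  Single evaluations default to a 256-px grid (padding 2); the
population engine uses 48 pupil samples in an 80-px grid, which keeps the
weighted band exact to ~84 cyc/deg (the CSF is ~1e-4 of its peak there)
and agrees with the 512-px direct PSF->OTF route to about 0.001 in VSOTF
while evaluating a full keratoconic search grid (113,805 corrections) in
roughly 10 s per eye on one CPU.  The defocus phasors of the sweep are
precomputed once per eye and shared across all cylinder/axis candidates;
results are independent of evaluation order.

## The optimization (the method's core)

For each cornea the sweep combines every sphero-cylindrical correction on
the prescribed grid with the eye's natural HOAs: defocus ±5 D and
cylinders -0.5..-5 D for eyes with RMS HOA < 0.5 um, ±10 D and -0.5..-10 D
at or above 0.5 um (inclusive), all in 0.25 D steps, axes 0–175° in 5°
steps, plus the zero-cylinder column.  The *zero target* (exact
cancellation of defocus and second-order astigmatism) is always scored as
an explicit member of the candidate set, so the visual benefit
VSOTF_opt/VSOTF_zero is >= 1 by construction.  Ties break toward the
smaller |M|, then |C|, then axis.  The reported target is the *residual*
refraction (optimal correction minus full low-order correction) — what a
surgeon would enter as target refraction; for an HOA-free eye it is
plano.

## IOL selection and SRK/T

A vergence solution seeds the catalogue search (spheres 1–35 D, cylinders
0 and 1–10 D, 0.5 D steps); a per-eye linear response model (three exact
traces: base sphere, +1 D, +1 D cylinder at axis 0) predicts the residual
refraction of every nearby label at every 5° axis, and the best eight
predictions are verified by full ray traces.  The lens is accepted when
the power-vector distance between its traced residual and the target is
within 5% of the eye's *aphakic refractive error* at the corneal plane
(about +12 D in an average eye, so a ~0.6 D band), floored at 0.25 D;
"the refractive error" the matching rule references is the error the
implant corrects, which keeps the acceptance band commensurate with the
0.5 D label quantization and the axis resolution at high cylinders.
Beyond the band the eye is flagged *not available in catalogue* (the
best lens is still reported) and excluded from the comparison
statistics, mirroring how out-of-range keratoconic eyes are handled
clinically.  The reference arm is the published SRK/T formula
(A-constant 118.6; corneal radius 337.5/K; the ametropic case solved by
the same model's vergence chain, which reduces algebraically to the
published emmetropia closed form).  Tolerance analyses re-score the final
wavefront with ±0.5 D defocus and re-trace the eye with the toric axis
rotated ±5°.

## Synthetic corneas

Seven progression groups (0–120 months of simulated keratoconus
development, 30 eyes each in the reference population) are emulated from
their marginal statistics: K1/K2, corneal astigmatism, RMS HOA and
spherical aberration at the 4-mm pupil, each given as mean ± SD with
[min, max].  Design choices:

* **Moment-matched truncated normals.**  The printed mean/SD are treated
  as the realized (bounded-sample) moments; the latent location/scale are
  solved so the truncated distribution reproduces them (mean prioritized
  where the printed SD is unattainable under the printed bounds).
  Quantile-stratified sampling with a shuffled stratum order keeps n = 30
  group means tight while remaining seeded and random.
* **Keratometry.**  Mean K and astigmatism magnitude are sampled and
  split as K1 = Km + |A|/2, K2 = Km - |A|/2 (the reference table's
  K1 - K2 equals its astigmatism column).  Anterior radius from Km with
  the 1.3375 keratometric index; Q = -0.26; posterior radius 0.82 x
  anterior; central thickness 0.55 mm, thinning ~12 um per simulated year
  in the keratoconic groups.
* **Aberration structure.**  The HOA budget (RMS target, c(4,0) pinned to
  the sampled spherical aberration) is shaped by a decentred inferior
  cone — a Gaussian elevation bump (centre 0.4–1.1 mm inferior, sigma
  0.5–0.9 mm) fitted to the Zernike basis, vertical-coma dominant — mixed
  85/15 with a broadband random component for the >= 24-month groups, and
  by the random component alone (1/n^2 magnitude decay) for the 0/12-month
  groups.  Astigmatism enters as second-order anterior elevation with a
  with-the-rule steep-axis distribution (steep meridian ~N(90°, 15°)).
* **Calibrated elevation.**  The anterior Zernike elevation is computed
  as (W_target - W_traced)/(n_cornea - 1) and iterated (at most 4 traces)
  until the traced wavefront matches the sampled targets to 0.005 um, so
  the *realized optical* statistics — not merely nominal surface inputs —
  reproduce the group statistics.  The validation utility checks realized
  means within 2 SE and all values within the printed ranges (±10% of the
  span).
* **Biometry (invented).**  The group statistics say nothing about axial
  biometry.  ACD ~ N(3.1, 0.3) mm, lens thickness ~ N(4.5, 0.3) mm, and
  axial length coupled to keratometry (AL = 23.3 - 0.37 (Km - 44) +
  N(0, 0.8) mm, clipped to [20.5, 28]) so the phakic population is
  realistically near-emmetropic; independent AL sampling produced
  implausible multi-dioptre ametropias that no clinical cohort shows.

**What the generator does not emulate.**  Only marginal statistics are
matched: the source population's covariance between aberration modes,
between astigmatism axis and cone orientation, and between K and HOAs is
not reproduced, and corneal thickness maps reduce to central thinning.
Consequently population results that depend on *mode correlations* — most
visibly the mean visual benefit of the 12-month group, where broadband
coma/trefoil mixtures exploit sphero-cylindrical interactions more than
the source population's morphology did (we obtain ~1.16 against the
reference 1.06 ± 0.15) — carry a generator-fidelity offset, while
quantities dominated by the marginal RMS level (normal-group benefit,
pooled peak VSOTF, most ordering/trend claims) reproduce well.  One
consequence worth flagging: in these synthetic keratoconic eyes the
zero-target state sits one to three dioptres off its own through-focus
peak with a VSOTF near zero, so adding ±0.5 D of defocus often *raises*
it — the optimized correction, sitting exactly at its peak, then shows
the larger absolute defocus loss, and the defocus-tolerance comparison
between the two corrections comes out in the opposite direction to what
populations with higher zero-target image quality show.  Passing
population tests therefore demonstrates the pipeline's behaviour under
Table-level conditions, not a per-eye reproduction of the original
cohort.

## Problem sizes and runtime

Population checks use 30 eyes for the 0- and 12-month groups and 10 eyes
per group (70 total) for the pooled statistics, with the 80/48 metric
grid — about 10 minutes end to end on one CPU for the full acceptance
run.  Single-eye analyses default to the 256-px metric grid.

## Known limitations

Monochromatic 555 nm only; no Stiles–Crawford apodization, scattering or
photoreceptor sampling; the anatomical pupil is idealized as a 4-mm
aperture at the corneal vertex; IOL tilt is not modelled (decentration
and toric rotation are); the generic equi-biconvex IOL ignores the
aspheric/transitional surface design of commercial lenses, so absolute
pseudophakic VSOTF values are conservative; SRK/T cylinder handling in
the comparison takes the corneal astigmatism at face value rather than a
vertex-corrected toric calculation.
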