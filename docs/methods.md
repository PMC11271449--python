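# Methods

`cuffsim` simulates extracellular electrical stimulation of a
multi-fascicular peripheral nerve by a multi-contact cuff electrode and
predicts which fibers fire. This note records the model, its
assumptions, the numerical choices, and what the synthetic data do and
do not represent.

## Model overview

The pipeline is the standard hybrid approach of the field, split into
independent stages:

1. **Geometry.** A nerve is a set of circular-cross-section fascicles
   with smooth (PCHIP) centerlines inside an epineurium envelope, z
   increasing rostro-caudally (mm). Merging/branching is represented as
   fascicle links: parents end at the event level and children exist
   caudal to it; fibers are re-parented at the transition. The default
   nerve is 35 mm long with the fiber-placement (reference)
   cross-section at mid-length. The epineurium radius may taper
   linearly along z, emulating the sheath thickening toward the rostral
   (nodose) side that makes linearly extruded models systematically
   misestimate electrode–fiber distances.

2. **Fibers.** Populations follow the standard fiber classes (Aalpha,
   Abeta, Agamma, Adelta, B myelinated; C unmyelinated). Default
   per-type fractions are the sampled-population proportions of the
   reference histology-derived model (C 81.3%, B 9.3%, Adelta 7.4%,
   Agamma 1.4%, Abeta 0.56%, Aalpha 0.07%). Unmyelinated diameters are
   drawn by inverse-CDF sampling from gamma distributions truncated to
   fitted intervals (afferent a=80.8746, b=0.00456138 on [0.3, 0.45] um;
   efferent a=8.54092, b=0.227013 on [0.73, 4.36] um). Myelinated
   diameters use per-type uniform ranges (Aalpha 12–16, Abeta 6–12,
   Agamma 3–8, Adelta 1–5, B 1–3 um); histology-specific diameter maps
   are not reproducible synthetically. Myelinated fibers outside
   [1, 18] um are rejected (the myelinated model is not trusted there).
   C fibers default to 75% afferent (vagal C fibers are predominantly
   afferent); the split is configurable.

3. **Placement and clustering.** Fiber groups cluster by type and
   modality. Placement draws, with probability equal to
   `clustering_strength` s, from a per-group 2D Gaussian blob inside a
   designated fascicle (blob sigma shrinking from fascicle-wide to
   0.1 R as s goes 0 to 1), otherwise uniformly over all fascicle areas.
   s=0 is exactly area-proportional uniform; s=1 concentrates a group
   entirely in its designated fascicles. Shuffling redraws all
   placements uniformly while preserving the (type, modality, diameter)
   multiset, for paired clustered-vs-uniform comparisons.

4. **Fields.** Quasi-static potentials (div sigma grad V = 0). The
   analytic path treats each active site as a point source in a
   homogeneous effective medium, V = I/(4 pi sigma r) (mV per uA with r
   in mm and sigma in S/m), with optional per-axis conductivity scaling
   and optional subgrid averaging over the 0.25 mm^2 pad. The default
   effective conductivity is 0.3 S/m — between epineurium (0.083) and
   saline (2.0); the personalization stage absorbs global scale
   discrepancies of the interface, and externally computed fields
   (e.g. finite-element solutions honouring perineurium and
   anisotropy) can be imported through the tabular interface and feed
   the identical downstream pipeline. Arbitrary multipolar policies are
   pure linear superpositions of per-site unit fields, encoded as
   time-stamped pulse matrices (uA per site).

5. **Membranes.** Three mechanisms behind one contract:
   * **Myelinated (MRG-type double cable).** One node of Ranvier + ten
     internodal sections (2 MYSA, 2 FLUT, 6 STIN) per period, all
     geometry diameter-dependent. Published anchors exist at nine
     diameters (5.7–16 um); parameters are interpolated by
     shape-preserving PCHIP through the anchors augmented with guide
     points at 1 and 18 um (internodal length pinned near 100x the
     fiber diameter at the low end, end-slope extension at the high
     end), keeping the internodal length strictly increasing.
     Shape-preserving interpolation was chosen over a global polynomial
     because polynomials oscillate at the extrapolated ends. The fiber
     is a true double cable: the axolemma faces a periaxonal space that
     conducts longitudinally (resistance rho_a/annulus with published
     space widths 0.002 um at node/MYSA and 0.004 um at FLUT/STIN) and
     is closed by the myelin sheath (0.1 uF/cm^2 and 0.001 S/cm^2 per
     lamella membrane, divided across 2*nl lamellae); at nodes the
     space opens to the extracellular medium. This pathway is essential:
     collapsing it into a series-lumped single cable removes the
     paranodal leak load and destabilizes the resting node. Nodal
     channels are fast Na (m^3 h), persistent Na (p^3), slow K (s) with
     36 C rate constants, plus a leak rebalanced so the total nodal
     current is exactly zero at the -80 mV resting potential
     (g_leak = -(i_Na + i_Nap + i_K)/(V_init - E_leak)); with these
     kinetics the rebalanced value sits ~25% below the nominal
     0.007 S/cm^2 at all anchor diameters.
   * **Unmyelinated C fiber.** Continuous channel distribution (no
     nodal structure): a TTX-sensitive Nav1.7-type current (m^3 h s,
     with slow inactivation), a TTX-resistant Nav1.8-type current
     (m^3 h, depolarized inactivation — the main spike current of C
     fibers), a delayed rectifier (n^4), and a mixed-cation background
     leak (reversal -30 mV, standing in for pump and background
     currents) rebalanced at the depolarized C-fiber rest of -55 mV.
     Axoplasm resistivity 35.4 Ohm*cm; conduction velocity comes out
     ~0.4–0.6 m/s around 1 um and grows with sqrt(diameter), in the
     physiological C-fiber range.
   * **Test mechanism.** The classic squid-axon four-state membrane,
     used to exercise the solver and threshold search cheaply.

   All rate functions clip the voltage used for rate evaluation to
   [-150, 150] mV; gates are saturated outside this range and the clip
   prevents overflow under extreme stimulus artifacts near the
   electrode.

6. **Solver.** Compartmental cable equation with the extracellular
   potential as per-section drive. Time integration is implicit on the
   linearized system: Crank–Nicolson by default with gate states
   advanced by exponential Euler (staggered half a step), backward
   Euler available via `order=1`. Crank–Nicolson is the package's
   deliberate choice: at the efficient 13 us step, backward Euler's
   first-order threshold error reached 7–17% for small myelinated
   fibers, while Crank–Nicolson keeps the 5->13 us deviation at ~0.1%
   (double cable) — the property the 13 us step was validated for. The
   per-step drive is the exact time average of the piecewise-constant
   pulse over the step, so pulse edges are not quantized to the time
   grid. Myelinated fibers solve the two-layer (axon + periaxonal)
   system as a pentadiagonal banded matrix with the nodal periaxonal
   potential constrained to the local extracellular potential.

7. **Spike detection and thresholds.** A fiber counts as recruited when
   the membrane potential crosses 0 mV upward at two detector sections
   on either side of the peak-drive section (propagation check,
   rejecting local stimulus artifacts). Detectors sit on nodes of
   Ranvier for myelinated fibers (the internodal double-cable membrane
   barely swings during an AP) at a 5 mm margin; continuous mechanisms
   use a 0.75 mm margin, the distance a C-fiber spike can actually
   cover within the 3 ms window at ~0.5 m/s. Fibers shorter than the
   margins use their outermost active sections. The recruitment
   threshold is the bisection-found scale factor of the pulse matrix
   (accuracy 0.01 uA myelinated, 0.1 uA unmyelinated; initial bracket
   from a drive-scaled guess, doubling up to a configurable cap, ties
   toward the lower bound); "no spike at the cap" is reported as an
   infinite threshold (not recruitable), which recruitment curves
   handle naturally.

## Efficiency methods

* **Dynamic discretization** (unmyelinated fibers). The activation
  function — second spatial derivative of the extracellular potential —
  is estimated from the 10 um potential samples: linear-extrapolation
  padding by 5% of the fiber length, 2nd-order central differences,
  zero-phase 2nd-order Butterworth low-pass (SOS, forward-backward)
  with normalized cutoff 0.001 (interpreted as a fraction of the
  spatial Nyquist frequency; the alternative, a fraction of the
  sampling frequency, differs only by a factor of two at this nearly
  flat setting), padding removed, positive and negative parts
  normalized independently to [0, 1] (making the profile invariant to
  potential scale, sign, and any added affine ramp; an all-zero part,
  including one at the numerical noise floor, maps to 0 and a constant
  nonzero part to 1). Section lengths follow the affine map
  L(p) = L_max - (L_max - L_min) p with defaults 20–200 um — the
  simplest monotone realization of "resolution proportional to the
  AF" — accumulated greedily left to right, a final sub-L_min remainder
  merged into the last section.
* **Longitudinal truncation.** Fiber ends whose normalized |potential|
  falls below a diameter-dependent cutoff are not simulated (|.| makes
  anodic and cathodic drives symmetric). The cutoff function is fitted
  a-priori: per study fiber, bisection on the cutoff accepts the
  largest value whose truncated threshold deviates < 0.5% from the
  full-length threshold (terminating when two consecutive iterations
  map to the same retained nodes); cutoffs are grouped by diameter
  class and a conservative PCHIP function is drawn through the 0.5th
  percentile per class (clamped outside the studied diameter range).
* **Time step.** 13 us default (5 us fine baseline), validated by the
  time-step study below.

## Study conditions and problem sizes

The numerical-fidelity studies (also reproduced by
`scripts/acceptance.py`) use straight fibers at seeded radial distances
from a point source in the homogeneous medium, 500 us cathodic pulses
and a 3 ms window:

* time-step study: 20 myelinated (2–16 um) + 20 unmyelinated
  (0.3–3 um) fibers at 0.5–3 mm, 20 mm spans; statistic = mean
  |relative threshold deviation| between dt = 5 and 13 us;
* truncation study: 60 study + 60 held-out fibers over six diameter
  classes (myelinated 2/6/12 um, unmyelinated 0.3/1.3/2.3 um), 15 mm
  spans; statistic = held-out mean |deviation| under the fitted
  cutoffs;
* discretization study: 200 (C fiber, site) pairs with gamma-sampled
  efferent diameters, 15 mm spans; statistic = 99th percentile of
  |deviation| between dynamic and fixed-20 um thresholds.

These sizes are the package's chosen desk-scale study conditions; the
statistics are relative deviations between numerical schemes and are
insensitive to the overall threshold scale set by the effective medium.

## What the synthetic data are and are not

The generator emulates the structural features the analyses depend on:
clustered type/modality groups, gamma-distributed C-fiber diameters,
area-proportional uniform placement, fascicle confluence, epineurium
taper, and "experimental" recordings built by rotating/scaling/noising
model outputs with stored ground truth. It does not reproduce any real
nerve's fascicle map, the histology-specific myelinated diameter
distributions, perineurium contact impedance, or curvilinear
endoneurial anisotropy. Passing tests therefore validate procedures
(threshold numerics, selectivity and personalization algorithms,
direction-of-effect findings), not subject-specific recruitment values;
subject-level numbers additionally require imported FEM fields and real
recordings.

## Personalization and functional mapping

Personalization fits two global parameters against measured
recruitment-like curves: a cyclic rotation of the active sites
(exhaustive over all shifts) and a positive threshold scale (50
log-spaced candidates in [0.1, 10] + golden-section refinement)
maximizing the R^2 of a no-intercept regression from model large-
efferent recruitment to the target curves. R^2 is computed about zero,
the standard convention for forced-zero models. Validation computes
per-site Pearson correlations, level-crossing thresholds (10–70%),
per-level Spearman site rankings, and a shuffled-site null (default
100 repetitions). Heart-rate mapping selects fascicles by 2-means on
per-fascicle B-efferent totals (dropping the low cluster and
never-recruited fascicles; seeded initialization) and fits
non-negative, no-intercept least squares from recruited counts to the
measured rate change. The tripolar builder reproduces the printed
asymmetric waveform verbatim (cathode -A with +A/2 neighbours for
200 us, then signs flipped at A/10 for 20 us); as printed the two
phases are not charge-balanced, so a `charge_balanced=True` option
instead uses 10x the amplitude over the short phase, which balances
exactly. Injected charge is reported as the pseudo-cathode's cathodic
charge.

## Known limitations

* The analytic field ignores perineurium and anisotropic endoneurium;
  absolute thresholds carry the effective-medium scale (import FEM
  fields for absolute fidelity).
* The unmyelinated mechanism is a reduced biophysical C-fiber membrane
  (no Nav1.9, K_A, K_Na, h-current, pump, or ion-concentration
  dynamics), sufficient for threshold/propagation studies; its
  recovery-cycle behaviour is only qualitatively correct.
* Fascicle cross-sections are circular; merges/branches are
  geometric confluences, not lofted histology.
* Modality-specific channel variants and kHz stimulation regimes are
  out of scope; the discretization/truncation calibrations assume
  conventional pulse widths.
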