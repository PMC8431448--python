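# Methods

This note records the models, conventions and numerical choices behind
`molstack`, and what the synthetic-data tests do and do not demonstrate.

## Contact criterion and aggregates

Two molecules are in contact when the distance between their mass-weighted
centres of mass is **strictly below** the cutoff (default 6.0 Å, i.e.
0.6 nm) under the minimum-image convention in an orthorhombic periodic
box. The strict inequality at the boundary is a documented convention; for
continuous coordinates the tie set has measure zero. Before any COM or
plane fit a molecule is *made whole*: every atom is imaged to within half
a box length of the molecule's first atom, which is valid because all
molecules handled here are far smaller than half the box. The resulting
COM is wrapped back into the primary cell.

Contact detection uses a periodic cell list (cells no smaller than the
cutoff, 27-neighbour stencil); along any axis with fewer than three cells
the stencil would double-count periodic images, so the implementation
falls back to all pairs there. The cell list is validated against an
all-pairs brute-force oracle in the tests. A cutoff at or beyond half the
smallest box edge is rejected because the minimum image is then ambiguous.

Aggregates are connected components of the undirected contact graph
(via networkx); isolated molecules count as singleton aggregates so the
components partition the molecule set exactly, which is asserted on every
analyzed frame.

## Ring planes and stacking angles

The plane of a (near-)planar molecule is fitted by least squares to its
annotated ring atoms: the normal is the smallest-variance principal axis
of the centred ring coordinates (SVD). Ring sets need at least three
non-collinear atoms; collinearity is detected from the second-smallest
singular value. Plane normals are axial — they have no physical sign — so
the angle between two normals is folded to the acute range,
θ = arccos|n̂₁·n̂₂| ∈ [0°, 90°].

The angle distribution over a (meta)trajectory takes one sample per
in-contact pair per frame. Summary statistics:

* **mean** — arithmetic mean of the folded angles;
* **dispersion** — root-mean-square angular deviation from perfect
  coplanar alignment (0°). The aligned state is the physical reference
  for π-stacking, and for half-normal tilt noise with scale σ the RMS
  about zero is a consistent estimator of σ, which is what the
  parameter-recovery tests exploit. For isotropically oriented planes the
  dispersion approaches ≈65°;
* **stacked fraction** — fraction of samples below a stacking threshold
  (default 30°, the conventional π-stacking tolerance; 18 histogram bins
  of 5° by default). Both are configurable.

Under the axial isotropic measure cos θ = |û·v̂| is uniform on [0, 1], so
the expected pair angle is ∫₀¹ arccos x dx = 1 rad ≈ 57.30° — the
closed-form anchor used by the Monte-Carlo acceptance check.

A trajectory with no contacts returns an empty, flagged distribution
rather than raising: an all-monomeric system is a valid result. Ensembles
are contrasted (e.g. pure monomer vs +inhibitor) by differences in mean,
dispersion and stacked fraction plus a two-sample Kolmogorov–Smirnov
statistic on the raw angle samples.

## Metatrajectory

Independent replicas are combined by retaining the final `retain_tail`
nanoseconds of each (inclusive at the cut point) and concatenating,
preserving replica labels and time stamps. Discarding the head of each
run removes the approach to steady state; the retained total is
`n_replicas × retain_tail` (e.g. 4 × 200 ns = 800 ns). Occupancies and
angle statistics are invariant to the concatenation order, which is
tested.

## Hydrogen bonds

A donor–hydrogen⋯acceptor triple is a hydrogen bond when the donor-heavy
to acceptor minimum-image distance is ≤ 3.5 Å and the D–H⋯A angle at the
hydrogen is ≥ 120°. These are the common geometric defaults — the choice
of criteria is a convention, and both are configurable. Distances and
angles are evaluated in the hydrogen's local frame so one consistent
periodic image is used. Only intermolecular bonds count.

**Occupancy** of an acceptor class is the fraction of analyzed frames
("configurations") containing at least one bond of the class — not the
event count — matching how sporadic-interaction percentages are usually
quoted. Classes with no annotated acceptors report zero occupancy rather
than failing, so hydrophobic chaperones without hydrogen-bonding
machinery run through the same pipeline and simply yield empty H-bond
reports.

## Kinetics and potency

Aggregation curves are fitted with a four-parameter logistic
F(t) = b + A/(1 + exp(−k(t − t½))) by bounded least squares (A ≥ 0,
k > 0), with a Gompertz alternative behind a flag. Initial values come
from the data (min, span, half-rise time); non-convergence is reported in
the fit record, never raised. The lag time is t½ − 2/k, undefined (None)
for effectively flat curves (A below 1% of the signal span).

Percent inhibition at the endpoint (default 1000 min) is
100 × (1 − treated/control) on baseline-subtracted signals, with the
endpoint value linearly interpolated between the two bracketing samples.
The default baseline is the fitted logistic baseline — it uses the whole
curve and is therefore much less noisy than the first sample; `first` and
`none` modes are available. Replicates sharing a time grid are averaged
before the endpoint read; per-replicate inhibition values are also
computed and summarised as a standard deviation. A control whose
baseline-subtracted endpoint is non-positive (within numerical tolerance
of the signal range) makes inhibition undefined and raises.

The **relative concentration** is dose / percent-inhibition (mM per 1%
inhibition); it is linear in dose at fixed inhibition and undefined for
non-inhibitors (inhibition ≤ 0), which are flagged rather than given a
number. Dose-response matrices tabulate percent inhibition per compound ×
dose, positive = inhibition/rescue, negative = acceleration.

## SAR association

Molecular weight is the only descriptor computed in-package (sum of IUPAC
2021 conventional atomic weights, reported to 2 decimals); the remaining
descriptors are consumed from an external table because they originate
from dedicated prediction software, and the "flexibility" column is
carried as an opaque numeric. Association with potency uses the Spearman
rank correlation of each descriptor against −log₁₀(relative
concentration), so positive coefficients always mean "more of the
property, more potent". P-values come from a label-permutation null
(default 999 permutations, seeded, bit-reproducible). Compounds without a
defined relative concentration (accelerators/non-inhibitors) are excluded
from the association and reported separately; constant descriptor columns
are flagged undefined. Rank methods are invariant under strictly monotone
transforms of the descriptor, which is property-tested.

## Synthetic-data generator

The generator produces what the analysis assumes, with exact bookkeeping:

* **Mock geometry.** The monomer is a regular 9-gon ring of radius 1.4 Å
  with purine-like N/C masses and one ring-nitrogen donor carrying a
  radial N–H (1.0 Å). The inhibitor is a 6-ring containing a sulfur and an
  intra-ring oxygen acceptor, plus two out-of-plane sulfur-bound oxygen
  acceptors. Fidelity to real molecular geometry is unnecessary for
  exercising contact/plane/H-bond machinery and is not attempted.
* **Stacks.** Non-hijacked monomers are partitioned into stacks with
  sizes 1 + Poisson(mean − 1), capped at 12. Stack COMs lie on a rigid,
  randomly oriented axis at the stacking rise (default 3.4 Å, so only
  adjacent stack members fall within the 6 Å contact cutoff); each
  molecule's plane is tilted relative to its predecessor by |N(0, σ)|
  about a random in-plane axis, so the ground-truth adjacent pair angle
  *is* the drawn tilt, and the RMS dispersion of the recovered angles
  estimates σ (folding into [0°, 90°] biases the recovery by ≈ −4% at
  σ = 40°, well inside the ±20% recovery tolerance).
* **Hijacked complexes.** One inhibitor caps two monomers, each
  donor-bonded to one sulfur-bound oxygen with ideal geometry (D→A
  2.9 Å, 180°) but fully random ring orientation; orientations are
  redrawn until the monomer COM is within 5.8 Å of the inhibitor COM
  (guaranteeing contact) and the donor stays ≥ 4.2 Å from the intra-ring
  oxygen (so no accidental intra-ring bonds contaminate the planted
  rate). Hijacked monomer–monomer angles are therefore isotropic, which
  is what drives the "larger and more widely distributed" angle signal
  and the smaller monomer aggregates in the inhibitor condition.
* **Planted hydrogen bonds.** A reserved probe monomer and a reserved
  inhibitor form an ideal intra-ring-oxygen bond in a Bernoulli(rate)
  subset of frames and are dispersed beyond contact range otherwise; the
  truth record stores the exact planted frames, so recovered occupancy
  must equal the recorded binomial draw exactly.
* **Placement.** Units (stacks, complexes, free molecules) are placed by
  rejection sampling with at least 7 Å atom-level clearance between
  units under the torus metric — beyond both the contact cutoff and the
  H-bond distance — so the truth partition is exactly the unit
  membership. Overcrowding raises a generation error suggesting a larger
  box. Frames are independent configurations; one master seed spawns a
  substream per frame (and per replica), so regeneration is stable and
  byte-identical.
* **Kinetics.** Treated curves scale the logistic amplitude by
  1 − inhibition/100, making the true baseline-subtracted endpoint
  inhibition exact by construction; Gaussian noise (default 5 a.u. = 5%
  of the default amplitude) is added per point and replicate.

**What passing tests show.** Parameter recovery on this generator
demonstrates that the estimators are unbiased and correctly plumbed under
the generator's assumptions: rigid planar molecules, independent frames,
well-separated aggregates, stationary noise. Real trajectories add
conformational flexibility, transient boundary-crossing aggregates,
frame-to-frame correlation and force-field physics, and real assays add
drift and heteroscedastic noise — none of which the generator emulates.
Recovery results therefore validate the analysis code, not any claim
about specific experimental systems.

## Problem sizes

Default verification runs use 4 replicas × 125 frames (500 analyzed
configurations, 44 monomers + 5 inhibitors in a 100 Å box), 200-frame
condition contrasts, and 20-assay kinetics ensembles — sizes at which
binomial/Monte-Carlo error is small relative to every tested tolerance
while the full suite completes in well under a minute per criterion.

## Known limitations

* Orthorhombic boxes only; no triclinic support, no binary (DCD/XTC)
  readers — trajectories are exchanged as XYZ or multi-model PDB.
* Molecules must be small relative to the box for make-whole imaging.
* H-bond scoring is purely geometric; no energetic model.
* The logistic/Gompertz families assume a single growth phase; biphasic
  curves will fit poorly (reported via residuals, not detected
  automatically).
* Descriptors other than molecular weight are taken on trust from the
  input table.
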