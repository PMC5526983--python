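# Methods

This note records the models and conventions behind each analysis, the
choices made where the underlying definitions are genuinely open, and
what the synthetic-data validation does and does not establish.

Units follow the GROMACS convention throughout: nm, ps, kJ/mol,
k_B = 0.0083145 kJ mol⁻¹ K⁻¹, default temperature 310 K. Boxes are
orthorhombic; triclinic input is rejected at the I/O layer rather than
silently mishandled. The membrane normal is fixed to z and never
auto-detected.

## Contact analysis

Lipid–lipid contacts are molecule pairs whose head-group beads
(phosphate for phospholipids, hydroxyl for cholesterol) lie within a
strict `d < 1.1 nm` under the minimum-image convention; polymer–lipid
contacts count all bead pairs within `d < 0.8 nm`, without
deduplicating multiple bead pairs of the same molecule pair. Strict
inequality fixes the boundary case so exact tests are possible.

The mixing fraction is formed per DLiPC molecule: a DLiPC–DPPC pair
contributes one contact to the DLiPC side, while a DLiPC–DLiPC pair is
seen from both ends and contributes two. With this convention f_mix of
an ideally mixed membrane converges to the DPPC share of the
DPPC+DLiPC pool (27.2 % at 598:1598) and f_chol/f_pol to the DLiPC
share (72.8 %) — the values the ideal-mixing helper returns. The
lower-level pair counter itself reports unordered pairs once, also for
same-species counts; the doubling is applied when the fractions are
assembled, and the consistency between the two layers is tested.

Counts are averaged over the analysis window first and ratios formed
afterwards (ratio of means), which stays stable when per-frame
denominators are small. The default window keeps the trailing 40 % of
the trajectory, mirroring the practice of analysing only the
equilibrated tail of a production run. Uncertainties come from 5-block
averaging; fractions whose species are absent (or whose denominator is
zero over the whole window) are reported as undefined, never as 0.
Fractions are exposed on the 0–100 scale everywhere; ideal-mixing
reference values are often quoted on the 0–1 scale, related by the
factor 100.

Neighbor search uses a periodic k-d tree (cell-list asymptotics) with
the tree's `≤` query filtered back to the strict `<`; equality with an
O(n²) brute-force double loop over pairs and periodic images is part of
the test suite, including configurations lying outside the box.

Stationarity of the contact metrics is judged by an ordinary
least-squares line through the per-frame series: "no drift" means
|slope| < 2·SE. On stationary noise this flag is correct ~95 % of the
time by construction, which is what the replicate test asserts.

## Leaflet assignment

Lipids are split by the median of head-bead z per frame (ties go to the
upper leaflet, making the split deterministic); non-lipid molecules are
labelled midplane. Cholesterol is reassigned each frame by its hydroxyl
bead, so flip-flop between frames is representable. The median split
assumes a quasi-planar membrane: it remains exact on buckled
geometries only while the buckle amplitude stays below half the
leaflet separation, and it will happily split a single-leaflet sheet
into two groups — validating the geometry is the caller's
responsibility, as documented on the function.

## Area compressibility

`K_A = k_B T A₀ / ⟨(A − A₀)²⟩` with the population variance (ddof 0) of
the projected area A = Lx·Ly, converted to mN/m via
1 kJ mol⁻¹ nm⁻² = 1.6606 mN/m. The estimator uses moments only, so it
is invariant under reordering of the series; the error is a 5-block
standard error. K_A is intensive: doubling A₀ at doubled fluctuation
variance leaves it unchanged, whereas rescaling all areas by 2 (which
quadruples the variance) halves it — both scalings are asserted in the
tests.

## Bending modulus from buckling

A membrane buckled along x at fixed box is a periodic Euler elastica.
With strain γ = 1 − Lx/L (L the flat-state contour length — the strain
convention is configurable since both engineering and L-based
conventions appear in the literature), the first periodic mode obeys

    γ = 2(1 − E(m)/K(m)),    f̃ ≡ f L²/K_c = 16 K(m)²,

with K, E the complete elliptic integrals of parameter m. The solver
inverts the strain relation by bisection to machine precision; the
Euler threshold f̃ → 4π² and the leading slope
f̃/4π² = 1 + γ/2 + O(γ²) emerge as limits and are tested, as is
agreement to 1e−6 relative with an independent solver that evaluates
the same integrals by adaptive quadrature instead of special-function
routines.

The force per unit length is f = −⟨σ_xx⟩·Lz, with the stress converted
from bar via 1 bar = 0.06022 kJ mol⁻¹ nm⁻³; compressive stress is
negative in input files (asserted on synthetic data). The leading half
of the stress series is discarded as equilibration by default,
mirroring the use of only the trailing half of a fixed-box production
run; a drift test on the remainder warns if the series still trends.
K_c is reported in k_BT at the dataset's temperature. Whether the
original stress-to-force conversions used instantaneous or average box
heights is not derivable from the data layout; this implementation
takes Lz as a fixed dataset property, consistent with a constant-box
buckling run.

## Lateral diffusion

MSD is computed on unwrapped (x, y) tracks reconstructed from wrapped
coordinates and the box history (valid while no particle moves more
than half a box edge between frames, which the generators guarantee),
averaged over particles and multiple time origins. Center-of-mass
motion of the selection is removed per frame by default so collective
drift does not masquerade as diffusion — with the documented
consequence that a single particle's drift-removed MSD is identically
zero. The fit `MSD = 4 D t` has no intercept by default, matching the
pure-diffusion form; a free-intercept variant is available because real
coarse-grained data carries a short-time ballistic/smoothing offset.
The fit window is configurable (production analyses of microsecond
trajectories typically use 10 ns–4 μs; synthetic tests rescale it to
their span).

## Order parameter, profiles, maps

`p = (3⟨cos²θ⟩ − 1)/2` is averaged flat over all acyl-chain bonds of
all selected lipids of all frames, bounded in [−0.5, 1] (property
tested on random inputs). 1D profiles are membrane-centered per frame
by the mean head-bead z; density is a number density (counts nm⁻³,
mass-weighting not applied) using the per-frame box cross-section, and
the order profile assigns each bond to the z-bin of its midpoint — the
midpoint choice is one of several defensible binnings and is therefore
an explicit parameter of the implementation, not hard-coded deep in it.

2D maps bin in fractional (x/Lx, y/Ly) coordinates so the fluctuating
NpT box maps onto one fixed 100×100 grid (the default; configurable).
Local thickness is the difference of the per-cell centers of mass of
head-bead z between the two leaflets, computed per frame and averaged
only over frames where both leaflets occupy the cell; unoccupied cells
are masked (NaN), never an error. Maps can be recentered per frame on
the center of mass of a molecule set (made whole across PBC first) so
a diffusing aggregate stays stationary on the map.

## Polymer shape and aggregation

The gyration tensor is mass-weighted, taking per-bead masses as an
argument; when none are given, beads are treated as equal-mass (which
is also the uniform-weight convention — for standard coarse-grained
beads of equal mass the two coincide). Molecules are made whole
across periodic boundaries first by walking consecutive beads through
minimum-image displacements, which fails loudly once a molecule's
extent reaches half the box. Aggregation is single-linkage clustering
of chains, linking two molecules when any inter-molecular bead pair is
within the cutoff (default 0.8 nm, the polymer contact cutoff; no
quantitative aggregation criterion is standard, so the cutoff is an
exposed parameter). Labels follow the lowest molecule index per
cluster, making output deterministic. Contacts per monomer count, for
each monomer, the foreign-chain monomers within the cutoff, i.e.
2·pairs/monomers; a `monomers_per_bead` factor rescales bead counts for
coarse-grained chains representing several monomers per bead.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their parameters and a seed, and every
artifact carries the ground truth needed by the corresponding recovery
test. Lipids are geometric bead stacks on jittered square lattices
(default spacing 0.8 nm ≈ 0.65 nm² per lipid, leaflet separation 4 nm,
three beads per acyl chain): no forces or dynamics are simulated
anywhere. Demixed arrangements place the DPPC+CHOL (Lo) pool in a
compact disk or stripe with an optional empty margin; a margin wider
than the contact cutoff guarantees f_mix = 0 by construction. Area
series are i.i.d. Gaussian with the variance the fluctuation formula
implies; random walks have exact Gaussian steps of variance 2·D·dt per
lateral dimension; bond orientations are rejection-sampled from a
tilted distribution `∝ exp(a cos²θ)` whose concentration is solved so
the expected second-Legendre moment hits the target; buckling records
are the exact elastica force plus optional multiplicative Gaussian
noise, with the midplane profile available for draping a bead bilayer
over it.

Consequently, passing tests establish correctness of the estimators —
unit chains, periodic geometry, averaging conventions, statistical
calibration — but not fidelity to real membranes: the synthetic
bilayers have no thermal undulations, no area–thickness coupling, no
correlated lipid motion, no realistic chain conformations, and their
area and stress series are white rather than autocorrelated. Absolute
published values for microsecond-scale MARTINI systems (e.g. areas per
lipid of 0.65–0.69 nm², K_A of 250–330 mN/m, K_c of 17–37 k_BT, R_g of
long PP chains in a membrane, contacts per monomer of aggregating PE)
are therefore out of reach of this test harness by design and are not
asserted anywhere.

## Problem sizes used in validation

The shipped validation runs at desk scale, chosen so the statistical
tolerances are meaningful: contact analyses on 2838-lipid bilayers
(the study's ternary composition) in a single frame per seed;
compressibility on 10⁵-sample series over 50 seeds (bias < 1 %);
buckling recovery on 10⁴-sample stress records (within 10 % at 5 %
noise, exact to 1e−4 without noise); diffusion on 256 walkers × 4000
frames (within 5 %); order recovery on 10⁵ bonds (±0.01); oracle
equivalence on 100 random 30–200-bead configurations.

## Known limitations

Orthorhombic boxes only; the membrane normal must be z; leaflet
assignment is quasi-planar (see above); MSD unwrapping requires
sufficiently fine frame spacing; the buckling analysis assumes the
first periodic elastica mode (strains in (0, 0.5), in practice ≤ 0.3
for a well-conditioned inversion) and a stationary stress record; and
the plain-text frame format stores positions at fixed 6-decimal
precision, which bounds round-trip fidelity for fixtures written
through it.
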