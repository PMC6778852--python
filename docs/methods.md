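# Methods

This note records the statistical models, conventions, numerical
choices and known limitations behind `refltriage`, in the spirit of a
methods appendix.  The README gives the user-facing summary; this
document says *why* things are computed the way they are.

## Conventions

- **Miller-index action.** Symmetry rotations act on Miller indices as
  row vectors, `h′ = h·R`; the same matrix acts on fractional
  coordinates as a column action `x′ = R·x + t`, which keeps the phase
  `h·x` consistent between the two. Translations are exact
  `fractions.Fraction` triples. Lattice centring is represented by
  including the centring translations as ordinary group elements, so
  absence and merging logic needs no special cases.
- **Canonical asymmetric unit.** The representative of an orbit of
  symmetry-equivalent indices (plus Friedel mates unless the set is
  anomalous) is the lexicographically greatest `(h,k,l)`. This is
  group-agnostic, a total order, and trivially testable; it is *not*
  the International Tables ASU, which no statistic here needs.
- **ε factor.** ε counts *distinct rotations* fixing `h`. Counting all
  group elements would double ε uniformly in centred settings (the
  centring copies carry identity rotations), which cancels in every
  normalized statistic but contradicts the crystallographic convention;
  distinct-rotation counting matches it.
- **Debye–Waller / Wilson convention.** Amplitudes carry
  `exp(−B s²)` with `s² = (sinθ/λ)² = 1/(4d²)`; intensities therefore
  decay as `exp(−2B s²)` and the Wilson plot
  `ln(⟨I/ε⟩/Σf²)` vs `s²` has slope `−2B`. The simulator and both
  Wilson fits share this convention, so recovery tests are exact in the
  noise-free limit.
- **Form factors.** 4-Gaussian coefficients for H, C, N, O, P, S ship
  as a JSON data file; other elements fall back to a constant equal to
  the electron count when supplied. The heavy-atom rows agree with
  gemmi's tables to 1e-4 relative; the H row is the classic
  parameterization, which differs from gemmi's substituted H fit by
  < 0.1 e⁻ — irrelevant at Wilson-statistics level.

## Normalization and the moment screen

`E²(h) = I(h) / (ε·⟨I/ε⟩_shell)` with shell means computed over the
working set excluding systematic absences; per shell ⟨E²⟩ = 1 holds
to machine precision by construction. Resolution shells are
equal-reciprocal-volume (equal 1/d³ increments), coalesced to hold at
least 40 reflections each.

All twinning-sensitive ratios (⟨I²⟩/⟨I⟩², ⟨|E²−1|⟩, ⟨F⟩²/⟨F²⟩, the
L statistic, twin-pair correlation) are computed on shell-normalized
intensities. Raw-intensity ratios pooled across the resolution range
are inflated by the Wilson falloff itself (≈ 3.2 instead of 2.0 on
clean data at typical B values) and would bury the twinning signal.
Reference values for the untwinned (exponential) and perfect-twin
(mean of two exponentials) cases are produced at run time by a seeded
Monte-Carlo oracle rather than hard-coded, so the acceptance tests
compare two independent routes to the same number.

## L-test pairing

Pairs are `(h, h+δ)` with δ drawn per reflection (seeded) from the
fixed all-even offset set {(0,0,2), (0,2,0), (2,0,0), (0,2,2), (2,0,2),
(2,2,0), (2,2,2)}. All-even offsets make `δ·t` integral for the common
tNCS translations with components in {0, ½}, so the intensity
modulation cancels within a pair — the package's regression test shows
naive unit-offset pairing is biased by > 0.05 in ⟨|L|⟩ under a
(½, 0, 0) translation while the even-offset rule is not. L is computed
on E² values so that the mean-intensity difference between pair members
(up to ~30% at offset 2 and B ≈ 20 Å²) does not bias the statistic.
Pairs are discarded when a member is missing, absent, centric, or
symmetry-related to its partner, or when the pair sum is non-positive.

## Twin laws

Rather than a static table, candidate laws are enumerated: all integer
matrices with entries in {−1,0,1} and det ±1 that preserve the
reciprocal metric within a relative tolerance (default 0.02, which
admits ≈ 0.5° of metric specialization), reduced modulo the group's
point group and Friedel inversion (double cosets), keeping per coset a
representative whose square is a group rotation. This reproduces the
textbook merohedral cases (one 2-fold for P4x, three laws for P3x, …)
and discovers pseudo-merohedral laws automatically when the cell metric
is accidentally special (monoclinic β ≈ 90°, etc.); the metric
deviation is reported with each law. Exact metric preservation in a
tetragonal/trigonal/hexagonal/cubic family is labelled merohedral,
anything else pseudo-merohedral.

## Twin-fraction estimators

- **H-test**: `α = 1/2 − ⟨H⟩` is the headline estimate. The
  cumulative-slope estimate fits `S(H) = H/(1−2α)` through the origin
  over the region `S ≤ 0.8` — far enough from the tail that the
  truncation at `H = 1−2α` does not distort the fit.
- **Britton**: trial α from 0 to 0.49 in steps of 0.01; negative
  detwinned intensities are counted over both pair members. The line is
  fit where counts lie between 10% and 60% of the maximum (below the
  noisy toe, above the saturating head) and its α-axis intercept is
  clipped to [0, 0.5).
- Estimates are reported per law, never averaged: on noise-free
  simulations both track the true α to ≤ 0.01 and the spec-level
  tolerances (±0.03 / ±0.05) leave room for noisy data.
- **Detwinning** uses the exact algebraic inverse
  `I₁′ = ((1−α)I₁ − αI₂)/(1−2α)`, σ propagated in quadrature;
  reflections without a measured twin mate are left unchanged and
  counted (`n_unpaired`). Reflections fixed by the law are unchanged by
  construction.

## Native Patterson and tNCS

Coefficients are the raw merged intensities (the classic native
Patterson), symmetry- and Friedel-expanded to the full sphere; the map
is an inverse FFT on a grid with spacing ≤ d_min/3 per axis, dimensions
rounded up to 5-smooth sizes, origin normalized to 100. A brute-force
direct-summation Patterson ships alongside as the test oracle (they
agree to < 1e-6 of the origin on small sets). Peak search: 3³
maximum-filter local maxima, ≥ 10 Å from the origin and its lattice
images (min-image Cartesian distance), height ≥ 20% of origin, per-axis
quadratic interpolation, ±u mates collapsed. For two equal copies the
cross-vector weight is ~half the origin, so genuine tNCS peaks sit near
50%; random coincidence peaks scale like 1/N in the atom count and stay
below ~10% for N ≥ 80 sites, which is why 20% is a safe default
threshold.

## Screw axes

For each axis and each screw hypothesis compatible with the crystal
family, axial reflections are split into the classes the hypothesis
predicts absent/present; a screw is called when ⟨I/σ⟩(absent class) < 1
and ⟨I/σ⟩(present class) > 3 (both configurable). Hypotheses are
ordered so that a 4₁ (condition mod 4) supersedes the weaker 4₂
(mod 2) when both pass. 4₁/4₃-type enantiomorph pairs are
indistinguishable from absences and are reported as a pair.

## Ice rings and mean-intensity anomalies

Thin shells of width 0.005 Å⁻² in 1/d²; each shell's mean normalized
intensity Z is compared to the median of its 10 neighbors, in units of
the standard error expected from the neighbors' within-shell scatter
(so the spike cannot inflate its own noise estimate). Shells with
z > 5 are flagged — as an ice ring if they intersect the built-in
hexagonal-ice list (3.90, 3.67, 3.44, 2.67, 2.25, 2.07, 1.95, 1.92 Å),
otherwise as a generic anomaly. The width was chosen so that a
0.03 Å-wide ring is a dominant fraction of its shell; a coarser
0.02 Å⁻² shell dilutes such a ring below any usable threshold.

## Anisotropy

Least-squares fit of `ln(I/ε/Σf²) = ln K − ½ sᵀB s` over reflections
beyond 4.5 Å with positive intensity, `s` the reciprocal vector in
Cartesian Å⁻¹ and `B` expanded in symmetric basis matrices restricted
by the crystal family (monoclinic keeps the xz cross term; tetragonal,
trigonal and hexagonal are axially symmetric; cubic is isotropic by
constraint). The per-reflection log-intensity scatter (≈ 1.28
variance for exponential intensities) averages out over the ≥ 1000
reflections required; eigenvalue recovery on simulated
diag(10,10,40) Å² tensors is well within 15%. The
isotropic-constrained path delegates to the shell-binned Wilson fit so
the two B estimates agree exactly, by construction rather than by
tolerance. A likelihood-based treatment of anisotropic scaling is
deliberately out of scope; this is a symmetry-constrained least-squares
Wilson model.

## Anomalous measurability

Bijvoet mates live in `Iplus/Iminus` columns of a merged set (the
merger fills them when the input is unmerged and anomalous); centric
reflections are excluded since their true anomalous difference is zero.
Measurability is the fraction of pairs with
`|ΔI|/σ(ΔI) > 3` (cut configurable). Under pure noise this is the
two-sided normal tail, 0.0027 — the simulator's f″ = 0 null reproduces
it within Monte-Carlo error, and measurability rises monotonically with
f″. The anomalous-completeness denominator is the observed acentric
uniques (matched + singles), not a theoretical sphere.

## The simulator and what it does (not) emulate

Random uniform atom positions with a protein-like element mix
(C/N/O/S ≈ 62/17/19/2), per-atom B uniform in a configurable range (or
a global anisotropic tensor), expanded to P1 with the space-group
operators; structure factors by direct summation (so absences,
centric statistics, ε enhancement and Friedel breaking all *emerge*
from the physics rather than being stamped on); twinning applied as
`I ← (1−α)I(h) + αI(Th)`; tNCS as a literal second copy of every atom
at `x+t`; noise as Gaussian with
`σ = k·√(max(I, ⟨I⟩/100)·⟨I⟩)` — a two-parameter counting-like model.
Defaults (150 atoms, P2₁, 2 Å, k = 0.03) give a realistic ~28 I/σ
dataset of several thousand uniques in well under a second.

Not emulated: bulk solvent (so low-resolution intensities lack the
solvent dip), radiation damage, absorption, detector effects,
partiality, and outliers. Consequently a passing recovery test shows
the *statistic* is implemented correctly under its own model
assumptions, not that the default thresholds are optimal for real
detector data — which is why every verdict threshold is a config key
echoed in the report.

When twinning is combined with anomalous output, twin mixing is applied
within each Bijvoet column separately; strictly the twin operator can
exchange mates, but at the small f″ simulated the approximation is far
below the noise.

## Triage verdicts

Defaults: twinning *warning* if ⟨|L|⟩ < 0.465 or acentric
⟨I²⟩/⟨I⟩² < 1.7, *severe* if additionally any α estimate > 0.1; tNCS
*warning* on any Patterson peak ≥ 20%; symmetry-too-low *warning* if a
twin law shows correlation > 0.95 with pair-R < 0.1; anomalous signal
marked useful at measurability ≥ 0.05; data-quality *warning* below
I/σ = 2 or completeness 0.9; anisotropy *warning* at ΔB > 10 Å² with
ΔB/⟨B⟩ > 0.5. All thresholds live in one config dict, are overridable
from YAML, and are echoed verbatim in the report; the CLI exit code is
the worst verdict. On 20 clean simulations the measured false-warning
rate for twinning and tNCS is 0/20 each; 20/20 injected pathologies
(α = 0.4 twins, (½,0,¼) translations) are flagged.

## Problem sizes

The test suite and the acceptance script run at "desk scale": cells of
30–50 Å, 2.0–2.5 Å resolution, 80–200 atoms, 4k–22k unique reflections
per dataset — large enough that the binomial/moment standard errors sit
comfortably inside the stated tolerances (e.g. ⟨I²⟩/⟨I⟩² has SE ≈ 0.03
at n = 20 000), small enough that the whole battery completes in tens
of seconds.

## Known limitations

- Space-group symbols are limited to a documented list of common
  macromolecular groups; anything else must be supplied as explicit
  `x,y,z` triplets (arbitrary settings work that way).
- Merging handles one sweep; multi-sweep scaling is out of scope.
- Twin-law enumeration covers operators with entries in {−1,0,1} —
  the merohedral and common pseudo-merohedral cases — not arbitrary
  reticular (lattice-reindexing) twins.
- The Britton intercept is ill-defined for α ≳ 0.45 (the rising region
  vanishes as the twin becomes perfect); the H-test remains informative
  there.
- French–Wilson conversion of intensities to amplitudes is not
  implemented; amplitude input is squared for the intensity statistics.
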