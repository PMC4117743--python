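# Methods

## The model

A chromatin fiber is coarse-grained as a chain of touching hard spheres of
diameter `d_f = 30 nm`, each carrying 3 kbp of DNA.  Five consecutive beads
form one rigid *persistence unit* of length `L_p = 150 nm`: the unit
boundary beads are the chain's degrees of freedom and the interior beads
are interpolated on the straight segment between boundaries, mimicking the
bending stiffness of the 30-nm fiber.  A chain of `N` units carries
`N' = N + (N-1)(L_p/d_f - 1)` beads; the headline condition `N = 1000`
(4996 beads, ~15 Mbp) is confined to a sphere of diameter `D = 1.5 µm`,
the volume share a 15 Mb region receives in an 11 µm human nucleus at
uniform DNA density (`D = 11 µm · (15 Mb / 6 Gb)^{1/3}`).  Conversely,
~400 such regions close-pack into a sphere of `400^{1/3} · 1.5 ≈ 11 µm`.

Self-avoidance: no two non-bonded beads may approach closer than `d_f`.
Confinement: every bead must lie entirely inside the sphere (centre within
`D/2 - d_f/2`); this is the strict reading of "not growing beyond the
boundary" and can be relaxed to a centre-only test if desired.

## Chain growth (geometric sequential importance sampling)

Chains are grown one persistence unit at a time.  At each step, `k = 100`
candidate directions — a Fibonacci-sphere set given one uniformly random
rotation per chain, which restores the rotational isotropy a fixed
discrete set would break — are screened: a direction is *feasible* when
the new boundary bead **and** all four interpolated beads violate neither
excluded volume (against every bead already placed) nor confinement.  One
feasible direction is drawn uniformly; the chain's importance weight
accumulates the factor `m_t / k` where `m_t` is the number of feasible
directions.  This normalized Rosenbluth weight makes weighted ensemble
averages target the uniform distribution over all realizable confined
chains — verified in the tests by exhaustive enumeration on a 6-direction
orthogonal candidate set, where weighted shape frequencies reproduce the
uniform SAW distribution.

**Population resampling.**  The Rosenbluth weights of long chains are
heavy-tailed: the per-unit log-weight variance is ~0.05 in free space and
~0.2 under nuclear-density confinement, so independent growth leaves one
chain carrying essentially all of a 500-chain ensemble's weight at
`N = 1000, D = 1.5 µm` (effective sample size ≈ 1) — every weighted
estimate then degenerates to a single conformation.  `grow_ensemble`
therefore grows the population in lockstep and applies systematic
resampling (sequential Monte Carlo): every 5 units, when the running
effective sample size falls below half the population — or any chain has
died — chains are resampled in proportion to their weights and the
weights reset to their mean.  This keeps the final ESS at tens of percent
of the nominal ensemble size under all studied conditions.

Resampling correlates chains through shared ancestry (over a long run the
genealogy largely coalesces), with two consequences.  First, chain-level
bootstrap intervals on one population understate protocol noise, so
uncertainties that matter — e.g. the baseline intervals against which the
binder-reweighting deltas are judged — are measured from independent
replicate runs (different master seeds) and variance-scaled to the
production ensemble size.  Second, splitting the population into
independent islands (``island_size``) restores an internal independence
unit (recorded as ``family_ids`` and respected by all bootstrap helpers),
but small islands reintroduce per-island self-normalization bias, so the
default is a single population and replicate runs are preferred for
uncertainty.  Plain independent growth with restart-on-dead-end remains
available (`resample_interval=None`) and is used to validate the
weighting itself on enumerable cases.  Dead ends are pruned by the
resampling step and counted as *attrition*; attrition rises as `D`
shrinks at fixed `N` and an attrition-rate ceiling (default 0.999) aborts
pathological conditions.

The first bead is placed uniformly at random in the allowed sphere
(confined) or at the origin (free space, where translational invariance
makes the choice immaterial).

Overlap checks run against a uniform spatial hash (cell edge `4 d_f`).
For a neighbour bead `y` and candidate direction `u`, the squared distance
to the unit's j-th interpolated bead is convex in `j`, so only the nearest
integer `j` needs testing; both accelerations are exact and are asserted
equal to a brute-force all-pairs oracle in the test suite.

## Estimators under heavy-tailed importance weights

Even with population resampling, importance weighting shapes the
estimator design; the choices below were diagnosed against an independent
pivot-MCMC sampler of the identical chain model (uniform, unweighted —
used only as a test oracle, never as the production method), which also
verified the growth sampler itself: e.g. the mean end-to-end distance at
`N = 200…1000` in free space agrees between the two samplers within their
joint errors, with slope 0.59.

* **Standard errors** are computed by chain bootstrap (resampling whole
  chains — or genealogy families — with their weights), not by the ESS
  variance formula, which underestimates under heavy-tailed weights.
* **Power-law fits across chain length** use variance-weighted least
  squares in log-log space (`fit_power_law_wls`), so precisely estimated
  points dominate and noisy points contribute what they can.
* **Small-probability observables** (end-contact probability of a free
  chain, ~1e-3…1e-7 over the studied lengths) cannot be estimated by a
  plain indicator at feasible ensemble sizes.  The package uses a
  one-step look-ahead (Rao–Blackwellized ring-closure) estimator:
  `Pc(N+1) = E_w[#(feasible ∧ closing)/k] / E_w[#feasible/k]` evaluated on
  `N`-unit ensembles, averaged over both chain ends (the ensemble is
  reversal symmetric) with a fine 400-direction look-ahead set, and a
  free-space validation contact radius of `2 L_p = 300 nm`.  Points whose
  bootstrap relative error exceeds 0.75 are excluded from the fit; in
  practice the fit is carried by `N ≲ 400`, which is also where any
  feasible direct estimate would live.

## Observables

* `R²(s)`: squared distance between unit boundary beads `i, i+s`, averaged
  with equal weight over windows within a chain, then by importance weight
  across chains.  `s` is measured in persistence units; 1 `L_p` = 5 beads
  = 15 kbp for genomic labeling.
* `Pc(s)`: fraction of windows within the contact radius
  (`r_c = 2 d_f = 60 nm` by default; the contact criterion is a parameter
  and exponents are insensitive to its prefactor).  Adjacent-unit
  boundaries sit exactly `L_p = 150 nm` apart, so `Pc(1) = 0` at the
  default radius; fits start at `s = 5`.  Contact probabilities pool
  windows from independent ensembles of different full length (every
  ensemble longer than `s` contributes its weighted window fraction;
  contributing ensembles average with equal weight), removing the
  self-correlation a single fixed-length ensemble would impose.
* Exponents: `R²(s) ~ s^{2ν}` fitted on `s ∈ [5, 25] L_p` (the regime
  matched to FISH measurements via the common leveling-off onset);
  `Pc(s) ~ 1/s^α` fitted on the *pre-plateau* range — from `s = 5` up to
  the leveling-off onset measured on the companion R²(s) profile (module
  default `[5, 125]` when no profile is at hand), since the power law is
  only defined before confinement saturates both observables.
  The leveling-off onset is the smallest grid point beyond which the
  running five-point log-log slope stays below 0.1 — judged by the median
  of the remaining local slopes, so Monte-Carlo noise in the saturated
  regime cannot mask a real plateau (a strict all-windows criterion is
  available).
* Bootstrap confidence intervals resample whole chains (percentile
  method), matching the chain-level independence structure.

## Substructure (domain) detection

For every persistence unit, a sphere of diameter 800 nm is centred on its
boundary bead and the contiguous run of units staying inside is measured.
Units whose run carries more than 400 kbp qualify; overlapping fragments
of qualifying units merge into maximal substructure intervals.  Each
substructure reports the exact minimal enclosing sphere (Welzl's
algorithm, oracle-tested against exhaustive support-set search) of its
beads; a merged interval's sphere may slightly exceed the 800 nm detection
stencil.  A substructure is *interactive* when more than 20% of its
persistence-unit blocks have any bead within the contact radius of a
different substructure of the same chain, else *independent*; the
stricter "no proximal unit at all" reading is reported separately
(`strictly_isolated`).  An earlier candidate policy — greedy maximal
windows under a minimal-enclosing-sphere diameter bound — was rejected
because overlapping candidate spheres in a severely confined chain tile
most of the nucleus and report the same dense region repeatedly
(~16 substructures/chain covering half the chain), which is not a useful
notion of *distinct* domains.

## Conformational clustering and compactness

Chains are compared by the RMS difference of their unit-level distance
matrices (subsampled to ~150 units for tractability), clustered by
average-linkage hierarchical clustering, and each cluster's contact
exponent is fitted from its members' windows.  Because the clustering
metric of the original supplement is unavailable, the per-cluster α range
is a qualitative, not exact, reproduction goal.  Compactness classes
(open / intermediate / compact) cut the rod-normalized radius of gyration
at absolute thresholds, by default the 0.2/0.8 weighted quantiles of a
pooled reference distribution.

## Binder reweighting

Binding sites occupy a uniformly random fraction (10–50%) of persistence
units.  A chain with `n` non-adjacent site pairs within the contact
radius has energy `-n ε` (`ε = 6 k_BT`), so its log-weight gains
`n ε / τ` at relative temperature `τ ∈ {1, 10}`.  Reweighting the
confinement-only ensemble keeps the base ensemble reusable across the
whole grid and is exact up to the effective-sample-size loss it induces,
which is reported per grid point with a low-ESS warning flag (default
floor 30).  Each proximal pair contributes independently (no valence
cap).  Log-space arithmetic makes the reweighting overflow-free up to
`n ε / τ = 700` and beyond.

## Problem sizes and reproducibility

Production-scale studies of this kind typically run 10,000 chains per
condition; this package's validation suite and reproduction script use
scaled-down ensembles (500 confined chains at `N = 1000`; 250–300 chains
per condition for the multi-length contact protocol and the confinement
sweep; 2000–3000 free-space chains per length), sized so that a complete
validation runs on one CPU in tens of minutes while keeping every
estimate statistically meaningful.  Every source of randomness derives from a
single master seed through `numpy.random.SeedSequence` spawn keys, so any
run is exactly reproducible; per-chain seeds are counter-based and
independent of execution order.

## What the synthetic conditions do and do not show

All inputs are generated by the simulator itself; there is no external
data.  The model emulates excluded volume, bending stiffness at the
persistence-unit scale, and spherical confinement — nothing else: no
nucleosome-scale structure, no heterogeneous fiber diameter or mass
density along the genome, no binder chemistry beyond the random
reweighting test, and no inter-chromosomal contacts (single chains only).
Passing tests therefore demonstrate the *confinement mechanism* —
severe spatial confinement alone produces Hi-C/FISH-like scaling
exponents, leveling-off, and domain-like substructures — not agreement
with any particular experimental chromosome.

## Known limitations

* Importance-weight degeneracy limits honest precision for rare events
  (free-space end contacts of long chains most of all); quantities there
  carry bootstrap errors and the fit machinery is variance-aware.
  Population resampling trades this for genealogical correlation, which
  the family-aware bootstraps account for.
* Binder reweighting at `τ = 1` and high coverage concentrates the
  ensemble on few chains (ESS flagged); deltas there are noisy and should
  be read against the baseline bootstrap interval.
* The substructure scan and the contact criterion contain conventions the
  original description leaves open (documented above); counts and
  interactive fractions are reproducible under the stated conventions but
  carry that interpretive freedom.
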