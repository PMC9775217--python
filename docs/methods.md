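# Methods

`phremc` implements constant-pH protonation sampling with a transmembrane
pH gradient, pH replica exchange (pHRE), and the downstream analyses that
turn simulation records into membrane-insertion pKa profiles. This note
documents the model, the numerical choices, and what the synthetic test
systems do and do not establish.

## Semi-grand titration model

A titratable system is a set of sites, each with a deprotonated tautomer
and one or more protonated tautomers. A microstate `x` assigns one tautomer
per site. Its free energy, in pK (log10) units, is

    G(x) = sum_i [ g_i(tau_i) + n_i(tau_i) * pH_b(i) ] + sum_{i<j} W_ij(tau_i, tau_j)

where `g_i` is the conformation-specific intrinsic term (produced
externally, e.g. by a Poisson–Boltzmann solver; for a two-form site
`pK_int = -g(prot) + g(deprot)`), `n_i` the bound-proton count of the
tautomer, `W_ij` the pairwise coupling, and `pH_b(i)` the pH of the proton
bath site `i` is coupled to. The statistical weight of `x` is `10^-G(x)`,
so an isolated two-form site reproduces Henderson–Hasselbalch exactly.

Working in log10 units end to end avoids kT conversions and matches the
units in which intrinsic and coupling terms are tabulated.

### The two-bath gradient

A transmembrane gradient assigns every site statically to the inner or
outer proton bath by its setup position relative to the membrane center
(above → outer, below → inner; an explicit override wins; an exact tie
goes to the outer bath with a warning). The gradient is specified either
as `(pH_in, pH_out)` or as a midpoint plus difference via
`pH ± ΔpH/2`, with the sign convention `ΔpH = pH_in − pH_out`. The
convention is a package choice; only the pair of endpoint values matters
physically.

## Metropolis protonation sampling

One MC cycle visits every site in randomised order (uniform proposal among
the site's other tautomers, acceptance `min(1, 10^-dG)`), then every
strongly coupled pair (simultaneous independent redraws of both members,
same rule). A pair is "strongly coupled" when any tautomer combination has
`|W| > 2` pK units (strict inequality). Randomising the site order removes
sweep-order bias; the pair proposal is symmetric, so the chain satisfies
detailed balance. The default chain length for a standalone titration is
10^5 cycles.

Standard errors come from batch means over 20 contiguous blocks, with an
Agresti–Coull binomial floor: a site whose occupancy is near 0 or 1 can go
through a whole run without a single flip, in which case batch means
degenerate to zero error; the floor reports the resolution a binomial
estimator actually has at the boundary. For sites whose rare state is
visited in long multi-cycle episodes, the effective sample unit is the
episode and even this floor understates the error — means for sites with
expected event counts of order one should be read as order-of-magnitude
estimates. The exact-enumeration oracle (`enumerate_exact`, stable
log-sum reduction, guarded at 10^6 microstates) is the reference all
sampler tests compare against.

## pH replica exchange

Replicas run one per ladder pH (default 4.0–7.0 in steps of 1.0). Adjacent
pairs attempt exchanges with alternating even/odd parity; a swap between
the state at `pH_m` (proton count `N_i`) and the state at `pH_l` (`N_j`)
is accepted with

    p = min(1, 10^{(pH_m - pH_l)(N_i - N_j)})

which is exactly the semi-grand weight ratio of the swapped configuration
pair. The swap is implemented as a pH-label exchange (equivalent to
swapping conformation + protonation, and cheaper); record streams are
keyed by pH.

In gradient mode the interior pH is fixed (default 7.2, the physiological
value) and only the exterior pH exchanges. The proton count entering the
acceptance ratio is then restricted to exterior-bath sites: the interior
terms are identical on both sides of the proposed swap and cancel exactly,
so including them would only add noise-free constants. When the interior
pH is not fixed (the degenerate zero-gradient setup used as a consistency
check), all sites count and the run reproduces the nongradient driver
bit for bit under equal seeds.

Each cycle interleaves: a protonation MC update (default 50 MC cycles —
the surrogate systems have one or two sites, for which a short chain fully
decorrelates; systems with many coupled sites should raise this), a short
relaxation advance of the propagator, and a production advance with the
exchange attempt phased halfway through. The first half of each
replicate's cycles is discarded as burn-in by default. One base seed per
replicate makes record streams exactly reproducible.

The conformational propagator is a contract (`advance(conformation,
microstate, n_steps, rng)`), not an MD engine: any Markov kernel that
preserves its declared conformational distribution at fixed protonation
plugs in.

## The insertion surrogate

The bundled surrogate stands in for atomistic constant-pH MD at desk
scale. It has a single key acidic site whose intrinsic pK depends on a 1D
insertion coordinate `z` (Å, negative = buried):

    pK_int(z) = pK_mod + dpK_desolv * S((z_mid - z) / z_width),    S = logistic

so the pK rises sigmoidally from its solution value `pK_mod` (default 5.5)
by up to `dpK_desolv` (default 2.0) with burial — the desolvation effect
that drives insertion-dependent pKa shifts in membrane peptides. The
conformational potential is a harmonic well in `z` (default spring
0.02 pK/Å², giving a z spread of ~4.7 Å across the sigmoid); because the
protonated form carries the `-pK_int(z)` stabilisation, protonation and
insertion are thermodynamically coupled: the neutral form prefers the
membrane interior, the charged form the aqueous side. The propagator is a
Metropolis random walk on `z` (step half-width 1.5 Å) under the total
energy, verified against direct quadrature of its declared density.
`analytic_pka_profile` returns `pK_int(z)` exactly and is the ground truth
the full pipeline must recover.

Defaults were chosen once so that the pK profile (5.5–7.5) straddles the
4–7 pH ladder and the z distribution populates ~10 unit-width insertion
bins. What the surrogate does not emulate: lipid packing and explicit
desolvation (water counts), multi-site electrostatic networks (an optional
fixed partner coupling exists but is excluded from the analytic oracle),
and any conformational coordinate beyond `z`. Passing the end-to-end test
therefore shows the sampling and analysis machinery is unbiased, not that
a particular peptide's pKa is predicted.

## Membrane geometry

Synthetic frames place one P and two O "phosphate" atoms per lipid on two
sheets at `z = ±(h_bulk + A exp(-r²/2σ²))` plus Gaussian z noise, with the
deformation centered on a peptide marker (stratified-uniform xy positions;
defaults: 256 lipids/monolayer, bulk half thickness 19.5 Å — the fluid
POPC range — spacing 8 Å ≈ 64 Å² per lipid, noise 0.5 Å). A dimple toward
the membrane interior corresponds to `A < 0`.

Analyses: the membrane center is the mean z of P atoms; the local
monolayer surface under a probe is the mean z of that monolayer's P/O
atoms within a 6 Å xy radius, falling back to the 10 xy-nearest atoms when
fewer than 10 qualify (the proximity test is in the xy plane — a 3D radius
would conflict with the xy fallback for inserted probes); signed insertion
is the probe's offset from that surface, negative toward the interior.
The annulus scan bins `|z - center|` by xy distance to the peptide
centroid in 1 Å rings, stopping at half the box length (annuli beyond are
corner-only); the deformation profile subtracts the bulk half thickness
computed from all atoms beyond 15 Å. Monolayer membership is a setup-time
tag, not re-derived per frame, to avoid flip-flopping near the center. SEM
is taken across replicates when labels are given, across frames otherwise.
All xy distances use minimum-image conventions.

## Profiles, criteria, Hill fits, bootstrap

Observations (replicate, pH, frame, insertion, protonated) are binned into
half-open 1 Å insertion windows `[k, k+1)` anchored at zero, after
discarding a per-(replicate, pH) burn-in fraction. Three robustness
criteria gate the fits:

1. each (bin, pH, replicate) cell needs ≥ 10 conformations of each
   protonation state (tautomers of the protonated form are pooled — the
   profiled quantity is binary occupancy);
2. ≥ 3 replicates must survive at a pH for it to count, and ≥ 2 surviving
   pH values are needed for a pKa fit;
3. along surviving pH values in ascending order, the pooled average
   protonation may not rise by more than 0.05 above the previous value.

Protonation profiles require only 1–2; pKa profiles require all three.
Pooled averages are unweighted means of replicate-level averages — the
same samples the bootstrap reweights.

The Hill curve `⟨prot⟩(pH) = 1/(1 + 10^{n(pH - pKa)})` is fitted by
weighted least squares (weights default to the number of contributing
conformations per pH; `n` constrained to (0, 10] to stabilise two-point
fits). The fitter is a damped Gauss–Newton initialised from the exact
logit-linear solution, vectorised across bootstrap resamples; it is
cross-checked against `scipy.optimize.curve_fit` in the test suite and
recovers noiseless curves to machine precision. Fits on flat data (all ~0
or ~1) or a single pH are refused.

Errors come from a Bayesian bootstrap: 1000 resamples, each drawing flat
Dirichlet weights over the replicate-level average-protonation samples at
each pH, recomputing weighted averages, re-checking the monotonicity
criterion (the count-based criteria depend only on the original samples),
and refitting. The reported pKa and error are the mean and standard
deviation over criteria-passing resamples; a bin where more than half the
resamples fail is rejected as unreliable. On independent synthetic
replicates the reported error tracks the true estimator spread to within
~10–15% (flat Dirichlet weighting is mildly conservative, ratio
≈ √((R−1)/(R+1)) for R replicates) and ±2·error covers the truth ≳ 90% of
the time.

## Problem sizes used in validation

Sampler-vs-enumeration checks use 20 random systems of up to 8 sites and
3 tautomers (couplings up to ±3 pK, mixed baths) at 10^5 MC cycles. The
end-to-end surrogate validation mirrors a full study design: 4 pH
replicas × 10 replicates × 5000 cycles with 50% burn-in, giving ~10 valid
insertion bins whose fitted pKa lands within ~0.05 pK of the analytic
profile (bound tested: 0.15). Geometry recovery uses 60 frames of 256
lipids per monolayer, asserted at 4×SEM per bin — a simultaneous bound
across ~150 bins; a 1×SEM band would be violated by ~32% of bins under
the null by construction.

## Known limitations

- The MC kernel is pure Python over a pre-compiled integer representation;
  it handles ~10^5 cycles × ~10 sites in seconds but is not meant for
  hundreds of sites.
- Rare-event sites (occupancy ≲ 10/n_cycles) report boundary-floor errors
  that can understate episodic correlation (see above).
- Frames are read from GRO stacks / multi-model PDB only; compressed MD
  trajectory formats are out of scope, as are helicity and water-shell
  analyses.
- The exchange-count restriction in gradient mode assumes the interior pH
  is common to all replicas; multi-dimensional ladders are not supported.
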