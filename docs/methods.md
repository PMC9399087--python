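# Methods

This note documents the models and procedures implemented in `cysbond`,
the assumptions behind them, and the design choices made where the design
was genuinely open.

## The cysteine index

A *clone* is a unique combination of V gene and CDR3 nucleotide sequence
within one sample; each clone counts once regardless of how many reads or
molecular-identifier groups support it. CDR3 coordinates are 1-based on
the CDR3-IMGT string, which excludes the conserved N-terminal Cys and
C-terminal Trp/Phe of the junction.

For a CDR3 of *n* amino acids the **apex** is the residue at the largest
position not greater than n/2 + 1, i.e. `floor(n/2) + 1`. The **cysteine
index** of a sample is the percentage of clones with a Cys within 2
positions (inclusive, a 5-residue window clipped at the CDR3 boundaries)
of the apex. Two exclusion rules apply before counting:

- clones detected only once or twice in the sample are removed (default
  minimum detection count 3);
- beta-chain TRBV1 clones with CDR3 shorter than 8 amino acids are
  removed, because TRBV1 can carry a germline-encoded Cys at CDR3
  position 2, and position 2 lies inside the apex window precisely for
  CDR3 lengths ≤ 7 (a property the tests verify for all lengths 4–20).

Both exclusions apply to numerator and denominator alike. When no
eligible clone carries an apex Cys the index is defined as the reciprocal
of the eligible clone count, as a percentage, so the statistic stays
strictly positive; we resolved the open question of the fallback
denominator in favour of the *post-exclusion* count, since excluded
clones never enter the calculation at all. A sample with zero eligible
clones is an error, distinct from the fallback. Alpha and beta chains are
never pooled.

Non-standard residues (`X`) are permitted in CDR3 strings and never count
as Cys.

## Reference catalogs and clonotype distribution

A lineage *reference catalog* aggregates every clone detected in samples
of that lineage, without cross-sample deduplication — the same sequence
seen in two mice contributes two entries. A *clonotype* is a unique
(V gene, CDR3 amino-acid) pair. Its intra-lineage frequency is the number
of catalog clones encoding it divided by the catalog size; its
distribution across the four catalogs normalizes those frequencies to
percentages summing to 100. Catalogs do not apply the cysteine-index
eligibility filters. Gene names are allele-stripped before matching.

## Synthetic repertoire generator

The generator emulates post-error-correction clone tables: per clone a V
gene from a configurable panel (TRBV1 included), a CDR3 length drawn from
a distribution over 4–20 aa (default unimodal around 11–12 aa, typical of
mouse CDR3β), residues i.i.d. from a background table, and a detection
count. Defaults, chosen once as study conditions:

- `apex_cys_prob` — probability of forcing a Cys uniformly into the apex
  window. Wild-type lineage defaults: conventional T cells 0.01,
  preselection thymocytes 0.03, CD8αα IEL lineage 0.08 (anchored to the
  reported 6–10% Cys-containing CDR3s in that lineage).
- Background residue frequencies are uniform with Cys down-weighted to
  1%, so the measured index tracks `apex_cys_prob` plus a small leakage
  that tests measure by oracle recount rather than assume.
- TRBV1 clones get a germline-style Cys at CDR3 position 2 (toggleable),
  exercising the TRBV1 exclusion.
- Detection counts place 10% mass on singletons and 10% on doubletons by
  default (80% of clones at count ≥ 3), exercising the low-count filter.
- Nucleotide junctions are seeded codon back-translations, so distinct
  nucleotide clones can encode one amino-acid clonotype.

Genotypes modelling attenuated TCR signaling or MHC deficiency flatten
all lineages to the preselection `apex_cys_prob`. The study config spans
lineages × genotypes × mice, each sample seeded deterministically from
the root seed.

What the generator does **not** emulate: V(D)J recombination statistics,
insertion/deletion profiles, generation probabilities, position-dependent
residue usage, or clone-size distributions tied to clonal expansion.
Passing recovery tests therefore shows the *statistic and its filters*
are computed correctly, not that real repertoires satisfy the generator's
independence assumptions.

## Two-phase binding kinetics

Binding of analyte (pMHC) at concentration C to immobilized receptor
(TCR) follows a reversible 1:1 Langmuir step with an irreversible
covalent (disulfide) conversion of the bound state:

    dB_nc/dt = kon·C·(Rmax − B_nc − B_cov) − (koff + kcov)·B_nc
    dB_cov/dt = kcov·B_nc

with C piecewise-constant over the injection schedule and zero during
dissociation. Assumptions: no analyte depletion or mass-transport
limitation; state carries over between sequential injections without
reset; covalent complexes are fully irreversible (reducing conditions are
modelled as kcov = 0, not as a reverse rate). Monomeric 1:1 binding only.

Each segment is linear and affine, so the model has a piecewise
matrix-exponential closed form. The simulator integrates with an adaptive
stiff-capable method (LSODA, rtol 1e-8, atol 1e-9·Rmax); tests require
agreement with the independent closed-form oracle to 1e-3·Rmax across a
3×3×3 grid of (kon, koff, kcov). The `dt` argument sets only the output
grid.

Derived quantities:

- **Persistent fraction** — of the response at injection end, the part
  that never decays: `(B_cov + B_nc·kcov/(koff+kcov)) / (B_nc + B_cov)`,
  since each noncovalent complex converts with probability
  kcov/(koff+kcov) before dissociating. Zero iff kcov = 0; strictly
  increasing in injection duration and in kcov.
- **Steady-state fit** — least squares on R_eq = Rmax·C/(K_eq + C) with
  standard errors from the fit covariance; flat responses or a fitted
  K_eq beyond 100× the largest sampled concentration flag the fit as
  degenerate (Rmax unidentifiable).
- **Occupancy normalization** — at equilibrium, occupancy is
  C/(K_eq + C), so the RU at full occupancy is (K_eq + C)/C times the
  equilibrium RU of a reference injection (1.641 for K_eq = 64.1 μM at
  C = 100 μM).
- **Dissociation decomposition** — least-squares fit of
  A·exp(−λ(t−t₀)) + P to the post-injection window; half-life ln2/λ,
  plateau P. A rising tail beyond 1e-3 of the signal range yields a
  warning status. Under the model the tail is exactly single-exponential
  with λ = koff + kcov and plateau B_cov(t₀) + B_nc(t₀)·kcov/(koff+kcov).
- **Tetramer decay** — with rebinding blocked, percent remaining is
  100·[f_cov + (1−f_cov)(e^(−kt) + (kcov/k)(1−e^(−kt)))], k = koff+kcov,
  where f_cov is the covalently bound fraction at blocker addition.
  f_cov depends on the loading history, not on the rate constants alone,
  so it is an explicit argument.

Default rate magnitudes in examples and tests (kon ~1e4 /M/s, koff
~0.7 /s, kcov ~1e-3 /s) are chosen so the noncovalent half-life is below
1 s while covalent accumulation plays out over minutes; the true rates of
the motivating system are free parameters.

## Dose-response fitting

The 4PL model Y = bottom + (top − bottom)/(1 + (EC50/X)^h) is fitted on
log-dose internally for optimizer stability and reported on the linear
scale. Zero-dose control wells are excluded from the fit (log-dose
undefined) but kept alongside.

Confidence intervals are percentile intervals from a seeded parametric
bootstrap (default 1000 resamples). The bootstrap error model is
heteroscedastic: per-point noise SD is proportional to the fitted
response with a floor at 5% of the curve maximum, and the relative scale
is estimated from degrees-of-freedom-corrected residuals. This matches
immunoassay readouts, whose noise scales with signal; Monte-Carlo checks
in the tests confirm 90–99% coverage of the true EC50 under 10%
multiplicative noise. Bootstrap intervals were chosen over asymptotic
ones deliberately: they are distribution-honest and reproducible from the
seed.

The plateau convention (the exact criterion being unstated in the source
protocol) declares the upper plateau reached when the bootstrap CI of
`top` is narrower than half the fitted `top` *and* the mean response at
the highest dose is at least 90% of the fitted `top`; otherwise the EC50
is flagged as a minimum estimate. Fits with negative Hill slope or
inverted plateaus carry a sign warning.

## Numerical choices and degenerate inputs

- Cysteine index: exact integer counting; no floating-point thresholds.
- ODE integration: LSODA, rtol 1e-8, atol 1e-9·Rmax; closed-form
  agreement required to 1e-3·Rmax in tests.
- Curve fits: bounded trust-region least squares with data-derived
  starting values; 4PL non-convergence raises a diagnostic error rather
  than returning silently.
- AIRR parsing: rows without a junction are dropped and logged; missing
  mandatory columns raise a format error naming the column; an empty file
  is an empty-sample error.

## Problem sizes

The test suite and the reproduction script use 100 random 50-clone
fixtures for oracle equivalence, 27 rate combinations for the kinetics
oracle, 200 replicates for noisy K_eq recovery, 200 simulations × 200
bootstrap resamples for EC50 coverage, and a 2-genotype × 4-lineage ×
4-mouse study at 5000 clones per sample — sizes at which the binomial and
Monte-Carlo tolerances quoted in the tests are comfortably resolved.

## Known limitations

- The repertoire generator's i.i.d. residue model understates the
  positional biases of real CDR3s; measured backgrounds will differ.
- The kinetics model omits mass transport, analyte depletion, bulk-shift
  and drift terms, heterogeneous analyte, and any reverse covalent rate;
  it is not a full sensorgram-fitting engine.
- Steady-state fitting assumes equilibrium was reached within each
  injection; with slow kinetics the K_eq estimate is biased.
- The plateau criterion for minimum-estimate EC50s is a declared
  convention, not a community standard.
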