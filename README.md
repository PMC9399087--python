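# cysbond

Analysis tools for a question at the interface of T-cell repertoire
statistics and binding biochemistry: **how often do T-cell receptors
carry a cysteine at the tip of their CDR3 loop, and what does such a
cysteine do to receptor–ligand binding when it can form a disulfide bond
with the peptide?**

The package provides, for repertoire scientists and biophysicists:

1. **The cysteine index** — for each repertoire sample, the percentage of
   clones with a Cys within 2 positions of the CDR3 apex (the residue at
   the largest position ≤ n/2 + 1 of an n-residue CDR3-IMGT), with the
   field's exclusion rules: clones detected only once or twice are
   dropped, and short TRBV1 CDR3s (< 8 aa) are dropped because their
   germline position-2 Cys falls inside the apex window only at those
   lengths. Samples with no apex-Cys clone score the reciprocal of their
   eligible clone count, as a percentage.
2. **Reference-catalog distributions** — aggregate lineage-level clone
   catalogs and normalize each clonotype's intra-lineage frequencies
   across the four catalogs to percentages summing to 100.
3. **Two-phase binding kinetics** — a 1:1 Langmuir association step with
   an irreversible covalent (disulfide) conversion:
   `dB_nc/dt = kon·C·(Rmax − B_nc − B_cov) − (koff + kcov)·B_nc`,
   `dB_cov/dt = kcov·B_nc`; SPR-style sensorgram simulation,
   steady-state K_eq fitting (R_eq = Rmax·C/(K_eq + C)), occupancy
   normalization, dissociation decomposition into a fast exponential plus
   persistent plateau, and tetramer-decay curves with rebinding blocked.
4. **4PL dose-response fitting** — Y = bottom + (top − bottom)/(1 +
   (EC50/X)^h) with seeded parametric-bootstrap confidence intervals and
   a minimum-estimate flag for curves that never reach a plateau.
5. **Synthetic data generators** for all of the above, so every pipeline
   is testable end to end from a single seed.

AIRR Rearrangement TSV is the interchange format for clone tables
(`v_call`, `junction`, `junction_aa`, `duplicate_count`, `productive`).

## Worked example

```python
from cysbond import (LineageProfile, generate_sample, filter_productive,
                     cysteine_index, normalization_factor,
                     KineticParams, persistent_fraction)

# A synthetic CD8aa-IEL-like sample: 5000 clones, 8% forced apex-Cys.
profile = LineageProfile(n_clones=5000, apex_cys_prob=0.08)
sample = generate_sample(profile, seed=42, sample_id="iel_demo")
print(cysteine_index(filter_productive(sample)).to_dict())
```

prints

```python
{'sample_id': 'iel_demo', 'chain': 'beta', 'n_eligible': 3990,
 'n_apex_cys': 513, 'index_percent': 12.857142857142858,
 'zero_fallback_used': False, 'n_excluded_low_count': 992,
 'n_excluded_trbv1': 18}
```

Of 5000 clones, 992 were singletons/doubletons and 18 were short TRBV1
clones; 513 of the 3990 eligible clones carry an apex-window Cys, giving
an index of 12.9% — the forced 8% plus measurable leakage from the 1%
background Cys rate across the 5-residue window.

```python
# The occupancy normalization: K_eq = 64.1 uM at 100 uM analyte.
print(normalization_factor(64.1e-6, 100e-6))   # 1.641

# Covalent conversion makes persistent binding grow with contact time.
p = KineticParams(kon=1e4, koff=0.7, kcov=1e-3, rmax=100)
for minutes, seconds in ((1, 60), (5, 300), (20, 1200)):
    print(minutes, round(persistent_fraction(p, seconds, 100e-6), 4))
# 1 0.0584
# 5 0.2477
# 20 0.6359
```

Even though each individual binding event converts with probability only
kcov/(koff + kcov) ≈ 0.0014, repeated rebinding during a 20-minute
injection drives 64% of the end-of-injection signal into the permanent,
covalent pool — the signature that distinguishes disulfide-capable
receptor–ligand pairs from conventional ones, and that vanishes entirely
(fraction 0) under reducing conditions (kcov = 0).

A command-line interface mirrors the library
(`cysbond cys-index`, `simulate-repertoire`, `catalog-dist`,
`simulate-spr`, `fit-spr`, `simulate-dr`, `fit-dose-response`,
`full-study`); run `cysbond --help` for details.

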