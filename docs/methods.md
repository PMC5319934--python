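# Methods

## Model

`ppb` implements ligand-based target prediction by multi-fingerprint
nearest-neighbor search. The operating assumption is the similarity
principle — structurally similar molecules tend to share targets — plus the
observation that "similar" is representation-dependent: different
fingerprints rank different neighbors first, so querying several
representations and voting recovers targets any single one would miss.

All similarity is the city-block distance CBD(A,B) = Σ|A_j − B_j|, chosen
for speed (one pass over integer vectors, no normalization) and because its
integer-valued distribution admits a discrete null model.

### Base fingerprints

| scheme | dim | encoding | perceives |
|---|---|---|---|
| APfp | 21 | counts of heavy-atom pairs per shortest topological path length 1..21 (longer clamped into bin 21) | molecular shape |
| Xfp | 55 | atom-category pairs, 5 channels × 11 distance bins (1..10, ≥ 11 clamped): (any,any), (HBA,HBA), (HBD,HBD), (HBA,HBD), (aromatic,aromatic) | pharmacophores |
| MQN | 42 | molecular quantum numbers (atom/bond/polarity/ring counts), computed by RDKit's standard implementation in its canonical order | constitution, topology |
| SMIfp | 34 | character counts over the canonical SMILES; fixed alphabet `C c N n O o S s P F Cl Br I B H ( ) [ ] = # + - . % 1-9`, two-character halogens tokenized first | rings, aromaticity, polarity |
| Sfp | 1024 | Daylight-type hashed linear/branched paths up to length 7, 2 bits per path (RDKit `RDKFingerprint`) | substructures |
| ECfp4 | 1024 | circular connectivity, radius 2 (bond diameter 4), folded to 1024 bits | substructures, pharmacophores |

Design choices made where only dimension and intent constrained the layout:
the APfp bin-21 clamp preserves the total pair count across molecule sizes;
the Xfp channel/bin layout above is the simplest 55-D realization of
category atom pairs, with hydrogen-bond donors/acceptors taken from the
toolkit's standard Lipinski SMARTS definitions; the SMIfp alphabet is the
34 symbols covering drug-like SMILES vocabulary. These layouts are
normative for this package. The Xfp (any,any) channel restricted to bins
1–10 equals APfp bins 1–10 by construction, which is property-tested.

### Standardization

Inputs are parsed from SMILES (or SDF), stripped of stereochemistry, and
ionized at pH 7.4 by explicit structural rules: carboxylic, sulfonic and
phosphonic acids and tetrazoles are deprotonated; aliphatic primary/
secondary/tertiary amines and amidines/guanidines are protonated. The rule
patterns match only neutral forms, so standardization is idempotent
(re-standardizing a canonical output is a no-op), and the rules are logged
when applied. Ionization is a flag (`StandardizationOptions.ionize`,
default on). Commercial pKa engines handle more chemistry (aromatic
heterocycle basicity, multiprotic equilibria); the rule set trades that
coverage for reproducibility.

### Mode-matched fusion

Base schemes have incommensurate distance scales (a typical random-pair MQN
distance is tens, an Sfp distance hundreds). Before fusing, every scheme is
scaled so the mode of its random-pair distance distribution matches Xfp's:
`scale(s) = mode(Xfp) / mode(s)`. The mode is estimated on unit-width
integer bins (unscaled CBDs are integers), ties broken toward the smaller
distance. The fused distance is Σ_components scale(c) × CBD_c, identical by
linearity to the CBD of scaled concatenated vectors (asserted to 1e-9
relative in tests). Fusions are fixed: Ffp1 = Xfp+SMIfp+Sfp, Ffp2 =
Xfp+MQN+SMIfp, Ffp3 = Ffp1+ECfp4, Ffp4 = Xfp+MQN+SMIfp+Sfp+ECfp4. The
production default for calibration is 50 M random pairs; tests and the
bundled examples use 10⁴–10⁵ seeded pairs, which fixes the mode of these
small worlds exactly.

### Reference database

A ChEMBL-style activity table (TSV/CSV with a YAML column mapping) is
filtered to actives: potency types IC50/EC50/GI50/Ki/KD/Potency at ≤ 10 µM
(boundary inclusive; nM/µM/mM/M converted, unconvertible units dropped with
a warning), or percent inhibition strictly > 50%. Structures are
standardized, deduplicated per target by canonical SMILES (keeping the
lexicographically smallest compound id, so membership is independent of row
order), and targets with ≥ 10 distinct actives are retained. The database
persists as `groups.json` + `profiles.tsv` + SHA-256 checksums, with a
format version checked on load.

### Negative-binomial p-values

For each (target group, fingerprint space), distances between group members
and background molecules are sampled (all pairs when ≤ 1 M, otherwise a
seeded uniform subsample), rounded to integers, and fitted with a negative
binomial by maximum likelihood — the discrete, overdispersed shape of
city-block distance distributions motivates this family. The optimization
runs over (log r, logit p) from a method-of-moments start (Nelder–Mead,
objective tolerance 1e-8), with per-evaluation cost reduced by aggregating
the sample over unique values. Underdispersed samples (variance ≤ mean),
where the NB MLE diverges, fall back to a Poisson fit flagged in the entry;
constant samples are recorded as degenerate and excluded from p-value
ranking. The p-value of an observed nearest-neighbor distance d is
P(D ≤ round(d)) under the fitted CDF — the chance a random molecule lies at
least as close. It is valid only within its own (target, fingerprint) pair
and is never compared across targets or spaces; ranking uses it only as
per-target sums and thresholds.

### Search and consensus

Each fingerprint independently sorts all reference compounds by distance to
the query (ties broken by compound id for cross-platform determinism) and
the first 20 distinct targets are collected (configurable `n_targets`),
each scored by its nearest member. The merged ranking sorts by votes
(number of fingerprint spaces listing the target, descending), then summed
p-value over voting spaces (an uncalibrated hit contributes p = 1.0,
ranking it below calibrated ties), then best p, then target id — a total
order. The combined prediction is the votes ≥ 2 subset. p ≤ 0.01 is exposed
as a high-confidence flag, and distance 0 flags that the identical
structure is in the reference set.

## Validation machinery

Per prediction list: fraction of known targets found = |known ∩
predicted|/|known|; hit rate = |known ∩ predicted|/|predicted|; top-5
success = any known target in the first five consensus ranks. Metrics are
computed per fingerprint, for the combined list, and stratified at
p ≤ 0.01 (per-drug and pooled). Pairwise overlap between fingerprints is
row-normalized (|T_i ∩ T_j|/|T_i|, deliberately asymmetric) with a
unique-target fraction per scheme. Screens are scored by ROC AUC computed
as the Mann–Whitney rank statistic with midrank tie correction
(cross-checked against explicit ROC integration in tests) and by the
enrichment factor EF(f) = (actives found in top f)/(all actives)/f. The
benchmark driver removes every panel drug's structure from the database
before querying; attempting to benchmark an un-removed member raises.

## Synthetic worlds

The fixture generator fabricates reference data from a bundled library of
25 curated drug-like scaffold templates (benzanilides, sulfonamides,
benzimidazoles, flavones, …), each with two substitution sites filled from
11 small substituents (H, methyl, halogens, hydroxy, amino, methoxy, cyano,
ethyl, trifluoromethyl). One scaffold per synthetic target yields
`group_size` distinct actives plus held-out query analogs; unassigned
scaffolds supply background/decoy molecules. Activity values are
log-uniform in [1 nM, 10 µM]; ~15% deliberately failing rows (20 µM
potency, exactly 50% inhibition) exercise the filters. Defaults — 5 targets
× 12 actives, 30 background molecules, 3 queries per target — keep every
stage of the pipeline exercised at interactive speed, and these are the
problem sizes the test suite and `scripts/acceptance.py` run.

The generator verifies its own ground truth: every query's brute-force
ECfp4 nearest neighbor must lie in its true target family, else the
assignment is reshuffled and ultimately fails loudly rather than emitting a
broken world. Because targets are scaffold-separated, synthetic worlds are
*easier* than real bioactivity data — real target families overlap in
chemical space, share ligands, and contain activity cliffs. Passing the
planted-recovery tests therefore demonstrates the machinery (ranking,
voting, calibration plumbing) is correct, not that real-data recovery rates
will match; recovery on a real ChEMBL-scale database must be measured with
`ppb benchmark` on that database.

## Numerical notes and limitations

- Distances of unscaled fingerprints are exact integers; scaled/fused
  distances are kept as floats for ranking and rounded to the nearest
  integer only where the null model requires discreteness.
- NB parameter recovery is tested on a 3×3 (size, prob) grid at 10⁵ draws
  within 5% relative error, averaging five fixed replicate fits because the
  size parameter is weakly identified near the Poisson limit (large size ×
  large prob), where a single fit's sampling spread alone approaches the
  tolerance.
- Scale factors are undefined for degenerate molecule sets whose modal
  distance is 0 (near-identical structures); calibration raises rather than
  emitting infinite factors.
- The engine is exact exhaustive search (O(N) distances per query per
  scheme); no index structure is provided, which is fine up to ~10⁶
  compounds per the design goal but has no sub-linear path beyond that.
- Tautomer enumeration, stereochemistry-aware comparison and 3D descriptors
  are out of scope by design.
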