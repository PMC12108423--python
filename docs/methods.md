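# Methods

## Screening model

The consensus screen treats similarity searching as a rank-aggregation
problem over several binary fingerprint representations. For a query *q*
and a library of *N* standardized molecules:

1. **Standardization.** Every structure (query included — both sides pass
   through the identical pipeline) is reduced to its largest organic
   fragment (salt removal), neutralized where chemically valid, tautomer
   canonicalized, and emitted as canonical SMILES. The order — salt strip,
   then neutralize, then tautomer-canonicalize — is fixed so counter-ions
   can never influence tautomer choice. The pipeline is idempotent, which
   the test suite checks property-wise over the whole decoy corpus.
2. **Fingerprinting.** Each molecule is encoded per requested family.
   Bit-level outputs of any fingerprint family differ between toolkits, so
   correctness is tied to backend-agnostic properties — determinism across
   processes, invariance to input atom ordering, metric behaviour of the
   bit sets — rather than to reproducing any particular toolkit's bits.
3. **Distances.** Per family, the Euclidean distance from the query to
   each library member is computed as the square root of the exact integer
   Hamming count (set symmetric difference), never as a floating
   coordinate sum; squared distances are therefore exactly integers, which
   tests assert as a guard against drift.
4. **Normalization.** Each family's N distances are z-scored with the
   population standard deviation (ddof = 0, configurable). With only a
   mean and a standard deviation named by the procedure, the population
   form is the natural default: at library scale (thousands of compounds)
   ddof 0 vs 1 is indistinguishable, and at test scale the explicit choice
   keeps oracles exact. A zero-variance family aborts the screen with a
   dedicated error (CLI exit code 4) instead of silently producing NaNs.
5. **Consensus and ranking.** The consensus score is the arithmetic mean
   of the per-family z-scores; rows are sorted ascending (most negative =
   most similar) with ties broken lexicographically by compound id, so the
   ranking is a pure function of the molecule set, independent of input
   order. An optional cutoff keeps rows with consensus **strictly** below
   the threshold; a row exactly on the boundary is excluded.

A query already present in the library is screened like any other member;
removing it would silently shift every family's mean and standard
deviation.

## Fingerprint families

| kind           | backend            | n_bits (default) | notes                          |
|----------------|--------------------|------------------|--------------------------------|
| `avalon`       | RDKit Avalon       | 512              | path/feature enumeration       |
| `ecfp`         | RDKit Morgan       | 2048             | radius pinned to 3 (diameter 6)|
| `maccs_keys`   | RDKit MACCS        | 167 (fixed)      | published 166-key dictionary   |
| `morgan_ecfp4` | RDKit Morgan       | 2048             | radius pinned to 2; novelty    |
| `pubchem_keys` | —                  | 881              | registered but unavailable     |

Bit lengths are configurable; the defaults are common toolkit conventions
(881 matches the published PubChem key count). No installed backend
provides the full published 881-key PubChem SMARTS dictionary, so
`pubchem_keys` is registered as *unavailable*: requesting it logs a warning
and the consensus proceeds on the remaining kinds, erroring only when no
requested kind has a backend. `maccs_keys` supplies a third,
dictionary-based family so three-family consensus runs (path-based +
circular + substructure-key) remain available out of the box.

Duplicate ids are a hard error at ingestion. Duplicate *structures* under
distinct ids are kept: dropping them would silently change the z-score
distributions. Invalid records are carried flagged with a reason, excluded
from indexing (from **all** families, to keep per-family arrays aligned),
and counted in the logs.

## Novelty analysis

Each hit is compared against a local actives file by Tanimoto similarity
over Morgan radius-2/2048-bit fingerprints; the maximal-similarity active
is reported with the comparison count. Ties break lexicographically by
active id, making the result independent of actives order. Actives pass
through the same standardization pipeline as hits, so a salt or charge
variant of a known active is recognized at similarity 1.0 instead of being
scored as distant. Two empty fingerprints score 0 by convention: a pair
sharing no set bits offers no evidence of similarity. The complementary
quantity 1 − Tanimoto (Soergel distance) satisfies the triangle
inequality, which the suite spot-checks on real drug structures.

## Synthetic benchmark

The generator emulates the one thing a screening benchmark needs: a
library in which ground truth is known by construction. It samples
`n_decoys` structures without replacement from a curated in-package corpus
of 255 drug-like molecules, then plants `n_analogs` variants of the query
produced by `analog_edit_depth` successive edits drawn from a whitelist of
valence-safe transformations (O-methylation of a hydroxyl, halogen swap,
terminal-methyl chain extension, aromatic C–H methylation), so generated
structures always sanitize and fixtures are never flaky. All randomness
flows through one PCG64 generator (`numpy.random.default_rng(seed)`),
giving byte-identical libraries for identical specs on any platform.

The standard benchmark is 100 decoys + 5 depth-1 analogs at seed 7 with
curcumin as the query — a drug-like natural product carrying sites for
every whitelisted edit. On it, consensus screening places all five analogs
in the top 10 (enrichment at k = 10 of 1.0), and consensus enrichment is
never below the worst single-family enrichment.

What the generator does **not** emulate: property-matched decoys (decoys
are not matched to the query's physicochemical profile, unlike e.g.
DUD-E-style benchmarks), activity cliffs, stereochemistry-only analogs, or
assay noise. Passing the planted-analog tests therefore demonstrates that
the ranking machinery is correct and that consensus aggregation behaves as
designed at desk scale — not that the method will retrieve actives from a
real vendor library, where true hits are not single edits away from the
query.

`enrichment(ranking, planted, k)` is the fraction of planted ids in the
top *k* rows. For a uniformly random ranking its expectation is k/N
(hypergeometric sampling), which the suite and the acceptance script
verify over 200 seeded permutations against a ±0.03 band (more than three
standard errors of the 200-draw mean).

## Numeric output conventions

Result tables render distances, z-scores and consensus at 3 decimals and
Tanimoto at 4, rounding ties away from zero; full precision is kept on the
row objects. Published tables of this kind are typically computed from
*unrounded* normalized scores, so re-averaging printed 3-decimal z-scores
can legitimately differ from a printed consensus in the last digit; the
worked-example checks therefore use a ±0.002 band, which is exactly the
worst case for a mean of three values each off by ≤ 0.0005, plus the
final rounding step.

## Problem sizes

The test suite and acceptance script run the oracle-equivalence check on a
50-molecule, three-family library, the metric suite on 1000 random
512-bit pairs, and recovery on the 105-molecule standard benchmark —
sizes at which the naive loop-based reference implementations used as
oracles remain exact and fast while exercising every code path of the
vectorized screen.

## Known limitations

- Bit-level parity with other toolkits' Avalon/ECFP/PubChem
  implementations is explicitly a non-goal; raw distances are
  backend-relative even though rankings are robust in practice.
- Tautomer canonicalization (RDKit's enumerator) can drop stereo flags on
  bonds involved in tautomerism; canonical SMILES may differ from the
  input's depiction while denoting the standardized structure.
- The novelty step reads a local actives file; assembling a comprehensive
  actives export for a given target is the user's responsibility.
- Manual triage of near-rediscoveries (deciding whether a 0.55-similar
  hit is "novel enough") is human judgment and out of scope.
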