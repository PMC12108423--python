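# fpscreen

Consensus fingerprint similarity screening and hit-novelty analysis for
small molecules.

`fpscreen` is a ligand-based virtual screening toolkit for medicinal and
computational chemists who have one interesting query compound and a large
library of candidate structures, and who want a ranking of the library that
is not hostage to the quirks of any single molecular fingerprint.

## The method

Every library compound and the query are standardized (salt removal, charge
neutralization, tautomer canonicalization) and encoded as several families
of binary fingerprints — by default Avalon path-based fingerprints (512
bits), extended-connectivity circular fingerprints of diameter 6 (ECFP6,
2048 bits), and the 166-key MACCS substructure dictionary.

For each fingerprint family *f*, the distance from the query *q* to library
compound *i* is the Euclidean distance between bit vectors, which for binary
vectors reduces to

    d_f(q, i) = sqrt( |B_f(q) XOR B_f(i)| )

i.e. the square root of the Hamming count. Each family's distance
distribution over the library is z-score normalized,

    z_f(i) = (d_f(i) - mean_f) / sd_f ,

and the **consensus score** is the arithmetic mean of the normalized scores
across families:

    c(i) = (1/K) * sum_f z_f(i) .

More negative means more similar. Because a compound must sit in the lower
tail of *every* family's distance distribution to score well, the consensus
damps fingerprint-specific artifacts and tends to surface chemically
diverse, consistently similar hits. A cutoff (e.g. keep only `c(i) < -2.5`,
strictly) turns the ranking into a hit list.

Selected hits can then be checked for novelty against a local file of known
actives: each hit is compared with every active by Tanimoto similarity
`|A AND B| / |A OR B|` over Morgan radius-2/2048-bit (ECFP4) fingerprints,
and the closest active is reported — a similarity near 1 flags a likely
rediscovery of a known compound rather than a new scaffold.

A seeded synthetic-library generator (`make-library`) plants close
structural analogs of the query among drug-like decoys so the whole
pipeline, including the enrichment behaviour of the consensus, can be
benchmarked without any external database.

## Worked example

Build a benchmark library of 100 drug-like decoys plus 5 single-edit
analogs of curcumin (the default query), then screen it:

```sh
fpscreen make-library --seed 7 --n-decoys 100 --n-analogs 5 --out lib.smi
fpscreen screen \
    --query "COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O" \
    --library lib.smi --kinds avalon,ecfp,maccs_keys \
    --cutoff -1.5 --out hits.tsv
```

which prints `screened 105 records -> 5 rows in hits.tsv`, and `hits.tsv`
contains:

```
CompoundID  avalon_dist  avalon_norm  ecfp_dist  ecfp_norm  maccs_keys_dist  maccs_keys_norm  consensus
analog_2    1.414        -2.525       2.828      -3.772     1.414            -2.963           -3.087
analog_3    1.414        -2.525       2.828      -3.772     1.414            -2.963           -3.087
analog_1    3.317        -1.937       4.359      -2.576     1.000            -3.265           -2.592
analog_4    3.317        -1.937       4.359      -2.576     1.000            -3.265           -2.592
analog_5    3.317        -1.937       4.359      -2.576     1.000            -3.265           -2.592
```

All five planted analogs — and nothing else — pass the cutoff: each has a
small raw distance in every family (e.g. `analog_2`, curcumin with both
phenols O-methylated, differs from the query by 2 Avalon bits, hence
distance sqrt(2) = 1.414), so its z-score is deeply negative in every
column and the consensus average keeps it at the top. A decoy that happened
to look close under one fingerprint alone would be pulled back toward zero
by the other two columns.

Checking those hits against a three-compound actives file reports, per hit,
its nearest known active and the ECFP4 Tanimoto similarity:

```
hit_id    closest_active_id  tanimoto
analog_1  curcumin           0.7381
analog_2  curcumin           0.9118
...
```

`analog_2` at similarity 0.91 would be flagged as a near-rediscovery of
curcumin; a genuinely novel scaffold would score far lower.

Every run writes a `<out>.meta.json` sidecar (tool version, effective
configuration, input checksums, timestamp) next to its output, and a YAML
`--config` file can pre-set any flag (explicit flags win).

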