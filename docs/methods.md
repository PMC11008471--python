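# Methods

## Distance contract

All five similarity measures are exposed as distances: symmetric,
non-negative, zero on identical inputs. Sequence-flavored measures live on
[0, 1] as 1 − identity, so a published identity cutoff *t* (e.g. 80%
clonotype identity) is the distance threshold 1 − *t*. This one convention
lets a single clustering engine serve every method. Threshold comparisons
are *inclusive* (d ≤ threshold joins), so identity ≥ t joins, threshold 0 on
distinct items yields singletons, and an identity threshold of exactly 1.0
still groups exact duplicates.

### Sequence / clonotype

Identity is normalized Levenshtein: 1 − L(a,b)/max(|a|,|b|), with both-empty
→ 1 and one-empty → 0. Levenshtein (not Hamming) is used even on
length-matched strings. Clonotype is the sequence method plus gene
stratification — one code path — with heavy-chain V (default) or V+J calls,
allele suffixes stripped (`IGHV3-23*01` → `IGHV3-23`) so allele-level calls
do not fragment clonotypes; stripping can be disabled. Light-chain genes do
not participate by default.

### Paratope

Per-residue paratope probabilities are an *input* (the predictor is
upstream), binarized at a configurable threshold, default 0.5. Identity is
computed on the union of flagged positions. Cross-antibody position matching
is deliberately weak, since no inter-record numbering is assumed: under
length stratification positions match by raw (chain, index); otherwise by
(chain, region, offset-within-region) for positions inside an annotated CDR.
Positions flagged in only one record count against identity; an empty union
gives distance 1.0 with a warning.

### Structure

Cα RMSD after optimal rigid superposition (Kabsch: centered SVD of the
covariance with a determinant correction restricting to proper rotations).
By default the superposition region equals the measured region, giving the
minimal RMSD of the selection; a separate `superpose_on` region (e.g.
framework) is supported, in which case the fitted transform is applied and
the selection RMSD measured without further fitting. RMSD needs
length-matched selections, so the structure method requires a length
stratification, and each stratum key is additionally extended by the tuple
of selected-region lengths. This makes parametrizations that stratify only
on CDR-H3 length while measuring all CDRs safe: records whose other CDR
lengths differ simply land in different strata rather than erroring.

### Embedding

Per-residue vectors (fixed dimension, e.g. 144 or 768) are mean-pooled over
the selected region and compared by cosine distance (euclidean available).
Cosine is the default because it is scale-invariant and consistent with the
very small threshold ranges (≈0.001–0.2) under which embedding clusterings
operate; zero-norm pooled vectors give distance 1.0 with a warning.

## Clustering engine

Records are first partitioned into strata (gene calls, region lengths, or
both); distances are only ever computed within a stratum, and cluster ids
embed the stratum key (`<stratum>|<counter>`) for auditability. Strata of
size 1 become singleton clusters with no distance call.

The default engine is single-pass greedy leader clustering: items are
processed in input order; each joins the first existing cluster whose
representative is within threshold, else founds a new cluster. This is
O(n·k) rather than O(n²) and is the scheme used by greedy structural
clustering tools. First-qualifying assignment is the default (deterministic
and cheapest); nearest-qualifying is an option, as is a seeded shuffle of
the processing order for robustness checks. The exhaustive alternative is
agglomerative linkage (single/complete/average) on the full within-stratum
distance matrix, cut at the same threshold; its representative is the
medoid (ties: lexicographically smallest id). On well-separated data
(between-group distance > threshold > within-group diameter) both engines
provably return the same partition, which the tests assert.

## Evaluation

*Probe mining*: one labeled binder is the probe; all other labels are
occluded; non-probe records co-clustered with the probe are predicted
binders; precision/recall/F1 are computed over all non-probe records.
Clustering never sees labels — occlusion is structural, not procedural.
Aggregation across probes is the arithmetic mean of per-probe metrics over
every labeled binder as sole probe (per-probe tables are always reported;
a fixed probe set evaluated jointly is also supported for
train-set-as-probes designs). Precision with zero predicted positives is
defined as 0 and flagged.

*Sweeps* evaluate a config grid, mark invalid configs failed without
aborting, report the best-F1 row per method, and emit PR points (threshold,
precision, recall, mean predicted positives).

*Jaccard* between two clusterings is pair-based: |S₁∩S₂|/|S₁∪S₂| over
co-clustered unordered pairs, computed in O(n) via joint cluster sizes. It
is 1 exactly when the partitions agree up to relabeling; two all-singleton
partitions are defined as 1.0 (warned).

*MOCM* (multiple-occupancy consistent cluster members): members of size-≥2
clusters whose members share one epitope label, divided by **all** clustered
records (singletons included) — the wording of the benchmarking study this
follows; the alternative denominator (multi-occupancy members only, as in
the metric's original formulation) is a flag. Normalized-threshold curves
map each method's threshold range linearly onto [0, 1] so methods with
incommensurable units (Å vs cosine) can be overlaid.

*Identity distribution*: all-vs-all normalized Levenshtein identity of a
region, exact up to 2,000 records, seeded pair subsampling above.

## Synthetic repertoires

The generator emulates a discovery-campaign dataset: `n_lineages` clonal
lineages, each with a V/J draw, random CDRs, and `members_per_lineage`
members carrying ≤ `within_lineage_mutations` length-preserving CDR-H3
substitutions (an `indel_rate` flag introduces length variants to exercise
stratification). Framework segments are repertoire-wide constants, so CDR
identity is far below full-sequence identity, as in real repertoires.
Binder labels are per-lineage (fraction `binder_lineage_fraction`, flipped
with probability `label_noise`); epitope labels are per-lineage draws from
`n_epitope_groups`. Structures are per-lineage templates (a shared
helix-like Cα trace plus a lineage displacement field, sd
`structure_template_sd` = 1.5 Å) with member noise
(`structure_noise_sd` = 0.1 Å) and a random rigid motion; embeddings are
per-lineage unit-sphere centroids (dim 144 by default, the small-transformer
size) with member noise sd 0.05; paratope probabilities are ≥ 1 − jitter on
a lineage-chosen subset of CDR-H3/L3 offsets and ≤ jitter elsewhere. All
draws flow through per-generator substreams of one seed; the `centroid_of`
option forces two lineages to share an embedding centroid, used to construct
method-orthogonality scenarios.

**Separation conditions.** With defaults (10 lineages × 8 members, CDR-H3
length 10–16, ≤ 1 mutation), within-lineage sequence distance is ≤ 2/L ≤ 0.2
while between-lineage same-stratum distance concentrates near 0.7–0.9, so
any sequence/clonotype/paratope threshold in ≈(0.2, 0.6) recovers the
planted lineage partition exactly; for structures the gap is
≈(3·noise_sd, template_sd) Å and for embeddings ≈(10⁻³, 0.9) cosine. Tests
and the acceptance script use mid-gap thresholds (0.3 distance / 1.0 Å /
0.1 cosine). Passing these recovery tests shows the engine and measures are
correct under planted separation; it does *not* show that any threshold
generalizes to real repertoires, where the published evidence is that best
parametrizations are strongly dataset-dependent.

The sweep-behavior fixture narrows the gene pool to two V genes and CDR-H3
lengths to 10–12 (so every stratum is multiply occupied and an over-large
threshold visibly merges lineages) and plants a single binder lineage with
zero label noise, making the separation gap the unambiguous F1 optimum.

## Numerical and design choices

- Intervals are 0-based, half-open, per chain; `l3_h3` concatenates CDR-L3
  then CDR-H3 (any fixed order gives identical identities; only consistency
  matters), `cdrs_all` is all six CDRs light-then-heavy in numeric order,
  `all` is light + heavy chain.
- Kabsch with < 3 points is computed but flagged degenerate.
- Greedy order = input order unless a seeded shuffle is requested; linkage
  partitions are input-order invariant.
- Paired FASTA without a chain separator is only ingested alongside a
  sidecar annotation table, since splitting concatenated chains would
  require numbering, which is out of scope by design (annotation is
  consumed, not computed).
- Run manifests contain config, seed, package version and input SHA-256
  checksums but no timestamps, making CLI runs byte-reproducible.

## Problem sizes

The test suite and acceptance script run on 80-record repertoires
(10 lineages × 8 members), 3-threshold-per-method sweeps, all partitions of
5–6 items for the metric oracles, 1,000 random string pairs and 100 random
point sets for the distance oracles — sizes at which the brute-force oracles
(full enumeration, numeric rigid-motion minimization) are exact and fast.

## Known limitations

- No numbering, germline alignment, or nucleotide handling; annotation
  quality is the caller's responsibility.
- Greedy partitions depend on input order when separation fails; only the
  separated regime is order-stable.
- The synthetic generator does not emulate somatic-hypermutation biases,
  realistic germline usage, learned embedding geometry, or biophysical
  structures; it plants the *statistical* structure the methods consume.
- Pair-based Jaccard and MOCM compare whole partitions; no per-cluster
  matching is attempted.
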