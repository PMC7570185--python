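# Methods

This note records the modeling choices, defaults and known limitations of
`dtikit`, in the order the pipeline runs.

## Drug featurization: E-state atom-type fingerprints

Each heavy atom of the hydrogen-suppressed molecular graph is assigned one
of the 79 published Kier–Hall electrotopological-state atom types; the
fingerprint is the 79-bit presence vector over those types (counts are
deliberately discarded — only presence/absence is used).

Implementation choices:

- **Typing by graph signature, not SMARTS.** A type is fully determined by
  (element, number of aromatic/triple/double/single bonds to heavy
  neighbours, attached-hydrogen count). The table of 79 signatures ships in
  `src/dtikit/data/estate_types.tsv` in fixed bit order. Two types are
  defined in the literature through bond-order-agnostic terminal oxygens
  and get dedicated rules: `ddsN` (nitro-like N — covers both
  `[N+](=O)[O-]` and `N(=O)=O` spellings) and `ddssS` (sulfone-like S).
  `aasN` additionally admits a third aromatic attachment (bridgehead
  aromatic N). Typing from the graph keeps the implementation independent
  of the SMARTS-based reference fingerprinter used as the parity oracle in
  the tests (agreement is exact on a 63-molecule drug panel).
- **Aromaticity convention.** SMILES parsing, sanitization and aromaticity
  perception are RDKit's defaults; the type table is interpreted under that
  convention. Mixing conventions silently shifts atoms between `aa*` and
  `d*` types, so the convention is pinned by the parity test.
- **Unmatched atoms** (exotic elements, unusual valences, e.g. azide
  nitrogens, naked anions) receive an `untyped` sentinel, are logged at
  warning level, and leave the fingerprint untouched.
- **Salts / multi-fragment SMILES** are typed in full; no largest-fragment
  stripping.

Out of scope: the numeric E-state indices (intrinsic states and
perturbation sums) and all other fingerprint families.

## Protein featurization: APAAC

For a sequence of length N over the 20 canonical residues, with
standardized hydrophobicity h1 and hydrophilicity h2:

    τ_{2j−1} = (1/(N−j)) Σ_{k=1..N−j} h1(R_k) h1(R_{k+j})
    τ_{2j}   = (1/(N−j)) Σ_{k=1..N−j} h2(R_k) h2(R_{k+j})      j = 1..λ
    p_u      = f_u / (1 + w Σ τ)                                u = 1..20
    p_{20+j} = w τ_j / (1 + w Σ τ)                              j = 1..2λ

The amphiphilic trait is the alternation of H1 and H2 correlation factors;
this is what distinguishes the descriptor from type-1 pseudo amino acid
composition. Defaults λ = 30, w = 0.05 → dimension 80.

- **Scales.** Raw H1/H2 values (the tables from the descriptor's source
  publication) ship in `src/dtikit/data/aa_scales.tsv` and are standardized
  at load: subtract the mean over the 20 residues, divide by the
  *population* standard deviation (divide by 20). The standardized values
  are frozen as golden constants in the tests (e.g. h1(Ala) = 0.645957…).
- **Short sequences.** N ≤ λ is an error stating the required minimum
  length, never a silent λ reduction — silent reduction would change the
  output dimension and corrupt matrix assembly.
- **Ambiguous residues** (B, J, O, U, X, Z) are rejected by default;
  `strict=False` drops them (N shrinks) before computation. Characters
  outside even the ambiguity codes are always errors.
- The normalization guarantees Σp = 1 (asserted to 1e-9 in tests) and the
  vector is invariant under sequence reversal (both f and τ are).

## Pair assembly and negative sampling

Pair vectors are drug fingerprint ⊕ APAAC (159 dims), built for the full
drug × target Cartesian product; validated interactions are labeled
positive, everything else unlabeled. Ids missing a feature row are errors,
not drops — a silently shrunken unlabeled pool would bias sampling.

- **Positive center.** Default is the plain mean of positive rows
  ("without-PCA"). The alternative `pca-mean` rotates the space with the
  principal axes of the positives first. The rotation is computed with a
  full SVD (`full_matrices=True`) so that the basis is complete even when
  there are fewer positives than features; with all components kept the
  transform is a pure rotation, distances are preserved, and the selected
  negative set is *identical* to the mean method (asserted in the tests).
  That equivalence is why the cheaper mean method is the default;
  truncation (`pca_components=q`) is exposed as a knob but no truncation
  level is recommended.
- **Ranking.** Unlabeled pairs are sorted by descending Euclidean distance
  from the center; ties break toward the lexicographically smaller pair
  key, so results are platform-reproducible. No feature scaling is applied
  before the distance: fingerprint bits are already 0/1 and APAAC is
  normalized.
- **Sampling.** `distance` takes the top-k (k defaults to the positive
  count, giving a balanced training set); it is deterministic given the
  matrix. `random` draws uniformly without replacement under a seed.

**Caveats on distance sampling.** Negatives are sampled once from the full
unlabeled set and then split into CV folds together with the positives.
Because the same selection rule produced train and test negatives, the
measured performance of the distance method is optimistic (selection
leakage); this mirrors the evaluation protocol the method is known by and
is the main reason its precision sits near 1. Additionally, enrichment of
*true* negatives by the distance rule requires the true negatives to be
displaced from the positive cluster in feature space. The synthetic
generator's class-symmetric studies do not have that geometry (the positive
center falls between the class modes), so the property test constructs a
displaced-cluster dataset directly; on class-symmetric studies the AUC
advantage of distance sampling comes from selecting extreme, easily
separable negatives rather than from cleaner labels.

## Classifier and evaluation

- RBF-kernel C-SVM (libsvm via scikit-learn), defaults C = 4, γ = 0.25.
  `grid_search` scans (2^i, 2^j), i, j ∈ {−10..10} (441 points) by internal
  stratified 5-fold CV AUC; ties resolve toward smaller C, then smaller γ.
- Metrics: accuracy, recall, precision, F1, MCC from the confusion counts;
  AUC from the rank-based (Mann–Whitney) estimator with midranks for ties,
  computed on the SVM's continuous decision values (predictions threshold
  at 0; no probability calibration). Zero-denominator metrics return 0 with
  a warning so long benchmark loops survive degenerate folds.
- `run_benchmark`: per repetition r, sample negatives (random sampling
  reseeds with base_seed + r; distance sampling is deterministic, so its
  set is computed once), stratified 5-fold CV seeded base_seed + r, six
  metrics per test fold. The report pools fold-level values across
  repetitions into mean ± SD (sample SD, ddof = 1); aggregation at
  repetition-level means is available via `aggregate="repetition"` since
  the conventional unit is ambiguous.

## Synthetic studies

`generate_study` plants signal through latent classes (see the module
docstring for the exact construction). Defaults — 40 drugs × 40 targets,
2 classes, signal 0.8, positive rate 0.10, sequence lengths uniform in
[60, 300], Dirichlet concentration 5 for the class residue frequencies —
are the study conditions used throughout the tests and the acceptance
script. The truth labels follow the Bernoulli stage, and the observed
positive list is a subsample of the truth, so the unlabeled pool genuinely
hides true interactions, as in real positive–unlabeled data.

What the generator does *not* emulate: real chemistry (drugs are small
curated molecules, not benchmark compounds), real sequence statistics
(i.i.d. residues, no domains or homology structure), and any dependence of
interaction on anything beyond class identity. Consequences measured on
synthetic studies transfer qualitatively (distance > random sampling; null
studies at AUC ≈ 0.5; monotone response to planted signal), not
quantitatively: published-scale AUC values on the real benchmarks are out
of reach by construction. One structural consequence: because same-class
non-interacting pairs are feature-identical to positives and the unlabeled
pool hides true interactions, random-sampling AUC saturates around 0.6 even
at signal 1 — the distance-sampled benchmark reaches ≈ 0.95–0.97.

`emulate_gold_standard_shape` reproduces the published subdataset shapes;
note the GPCR row: 223 drugs × 95 targets = 21,185 candidate pairs (a
widely reprinted total of 21,180 is inconsistent with its own counts), with
positive proportion 635/21,185 = 3.00%.

## Problem sizes and numerics

Tests and the acceptance script run studies between 10×10 and 40×40 pairs
with 10–20 benchmark repetitions — sizes chosen so the full suite completes
in seconds while keeping the qualitative contrasts (planted vs null,
distance vs random) far outside their noise bands. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; SVM
training is deterministic given its inputs. CSV round trips are bit-exact
(repr-precision printing, `float_precision="round_trip"` parsing).
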