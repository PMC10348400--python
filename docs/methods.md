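# Methods

## The model

The engine treats a molecule collection as a set of four parallel "chemical
spaces" — fingerprint bits, fingerprint counts, molecular descriptors and
quantum properties — on the premise that each captures a complementary
notion of resemblance (shared fragments, shared physicochemical profile,
shared reactivity). Single-element (monoatomic) species are split out of
the two continuous spaces into separate element spaces, because descriptor
and quantum profiles of bare elements are not commensurate with those of
polyatomic molecules.

Each space is processed independently:

1. **Weighting and reduction.** Discrete blocks are TF-IDF weighted —
   molecules as documents, features as terms, tf the raw value and
   idf(j) = ln((1+n)/(1+df_j)) + 1 (smoothed so never-seen features stay
   finite). No output normalization is applied: cosine similarity
   downstream is scale invariant, so L2 normalization would be immaterial.
   The weighted matrix is reduced by latent semantic indexing — a truncated
   SVD of the *uncentered* matrix, with "variance" defined on squared
   singular values — keeping the smallest k whose cumulative share reaches
   80 %. Continuous blocks are median-imputed (columns with > 50 % missing
   are dropped), z-scored, and reduced by PCA; variance here is the usual
   centered explained-variance ratio. Retention is 80 % for wide blocks and
   90 % for blocks with at most `feature_cutoff` (default 50) columns: the
   narrow block in practice is the quantum-property table, where a higher
   retention costs little and preserves more chemistry. The two variance
   conventions differ and are deliberately stated: the first singular
   component of an uncentered TF-IDF matrix is essentially a global mean
   direction, which matters for interpreting cosine floors (below).
   Component signs are fixed by forcing the largest-magnitude loading of
   each component to be positive, so repeated fits are bitwise identical.

2. **Similarity and significance.** Pairwise cosine similarity is computed
   on the reduced matrix (rows with zero norm are flagged and excluded).
   Significance comes from a within-row shuffling permutation test: each of
   N permutations (default 1000) independently shuffles every row's values,
   destroying cross-molecule feature alignment while preserving each row's
   value multiset, and the full cosine matrix is recomputed. The one-sided,
   add-one-corrected p-value is p = (1 + #{null ≥ observed})/(1 + N), so p
   is never 0 and its floor is 1/(N+1). The null loop streams one shuffled
   matrix at a time and accumulates exact pair-level exceedance counts.
   Pairs with p < α become edges of an undirected network weighted by
   cosine similarity; isolated nodes stay in the node list. No
   multiple-testing correction is applied across pairs: the per-pair α
   (0.05 or 0.01) is the operating characteristic of the procedure.

3. **Embedding.** Each network is embedded with the node2vec scheme:
   second-order biased random walks (return parameter p, in–out parameter
   q; the transition weight from t via v to x is w(v,x)·1/p if x = t, 1 if
   x is adjacent to t, 1/q otherwise) followed by skip-gram training with
   negative sampling on the walk corpus. Signature vectors use 36
   dimensions for fingerprint and descriptor spaces and 9 for quantum
   spaces. Isolated nodes are not embedded; queries on them return an
   explicit "no embedding in this space" status rather than a fabricated
   vector. Negative cosine weights, possible on significant
   anti-correlated pairs, are clipped to 1e-6 for walk probabilities
   (random-walk weights must be non-negative); the clip is recorded in the
   model metadata.

4. **Consensus query.** A query's neighbors are collected per space above a
   similarity threshold (entry range 0.75–0.99, default 0.95). Per-space
   hit lists are *unioned* — intersecting them would frequently return
   nothing and contradict the guaranteed-result fallback — and ranked
   lexicographically by (number of intersecting spaces, average similarity
   over those spaces, molecule id), a total order. If no hit exists, the
   threshold relaxes in steps of 0.01, passing below the 0.75 UI floor if
   necessary, until at least one molecule is found; the effective threshold
   is recorded on every result.

5. **Clustering and validation.** Embedding vectors are clustered with
   k-means (k-means++ seeding, 10 restarts, seeded) or agglomerative
   clustering (average/complete/Ward linkage on Euclidean distances, cut at
   k). k is user-supplied; a silhouette scan over k ∈ [2, 15] is provided
   as a labeled convenience, not part of the core procedure. The biological
   sanity check classifies annotated molecule pairs by embedding cosine —
   similar above 0.96, not similar below 0.46, intermediate pairs excluded
   — and cross-tabulates against sharing at least one gene-symbol target.
   Association is tested with Pearson's chi-squared without continuity
   correction (counts in realistic use are large); the odds ratio is ad/bc
   with a Haldane +0.5 only when a cell is zero. "Common target" means a
   shared gene symbol, not an assay-level match.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| LSI/PCA retention | 0.80 / 0.80 or 0.90 | variance kept per space |
| `feature_cutoff` | 50 | widest block that uses 90 % retention |
| `n_permutations` | 1000 | permutation-null size; p-floor 1/(N+1) |
| `alpha` | 0.05 (0.01 supported) | edge significance level |
| walk p, q | 1, 1 | second-order bias; 1,1 = first-order weighted walk |
| walks/node, length | 10, 80 | walk corpus size |
| window, epochs, negatives | 10, 5, 5 | skip-gram training |
| dims | 36 / 9 | embedding size (fingerprint+descriptor / quantum) |
| query threshold, floor, step | 0.95, 0.75, 0.01 | consensus search |
| hi, lo | 0.96, 0.46 | similar / not-similar pair cutoffs |

## Numerical and design choices

- **Skip-gram trainer.** Training is a deterministic single-threaded
  mini-batched SGD in numpy: unigram^0.75 negative sampling, linear
  learning-rate decay from 0.025 to 1e-4, gradient clipping at ±5, and a
  batch cap of 16× the vocabulary size. The cap exists because summed
  updates per node grow with batch/vocabulary; uncapped batches diverge on
  small graphs. Scatter-adds use a bincount formulation for speed. Input
  vectors are the embedding.
- **Duplicate resolution** in curation is first-occurrence-wins on CAS and
  on canonical SMILES — deterministic and auditable. Element inventories
  count implicit hydrogens, so formulas like C2H3Cl2F list H.
- **Desalting is not performed**: multi-fragment SMILES (minerals, salts)
  are accepted as-is and flagged on the record.
- **Fingerprint failures** on exotic inorganics yield a zero row plus a
  warning rather than dropping the molecule; zero rows are excluded from
  cosine (undefined norm) with a logged notice.
- **Validation network.** The target-sharing analysis is run on the
  α = 0.01 network. On uncentered LSI scores all cosines share a positive
  floor (the global mean direction), so at α = 0.05 many weakly-similar
  pairs are significant, the network is dense, and embedding cosines
  compress into the middle of the range; at α = 0.01 the network keeps only
  strongly similar pairs and the embedding separates cleanly around the
  0.96/0.46 cutoffs. Both α values are first-class options.
- **Ties** in query ranking are broken by molecule id, making result order
  a total order; k-means ties are resolved by the seeded restart with the
  best inertia.

## The synthetic generator

`generate_planted_blocks` emulates the three real input kinds with a known
community structure: per community a prototype bit pattern (member bits
flipped at `within_noise`), a sparse prototype count profile (entries
re-drawn from a Poisson at the noise rate), and continuous centroids of
unit spread with members perturbed at sd `within_noise`; continuous blocks
receive missing cells at `missing_rate`. A fraction of features
(`individual_fraction`, default 0.4) is molecule-specific rather than
community-driven — stable idiosyncratic substructures and descriptor
values. This mirrors real chemical tables, where members of a structural
family still differ in many features, and it keeps the reduced spaces at
realistic rank: a pure prototype-plus-noise design is near rank-c, the
reduction then keeps only ~c components, and a within-row shuffle of a
k-component row reproduces the observed similarity with probability about
1/k!, which makes small-k permutation tests uninformative by construction.
Annotations are built pairwise — each sharing pair receives its own fresh
gene symbol, plus one private gene per molecule — so realized within- and
between-community sharing rates match the requested probabilities (defaults
0.6 / 0.1) up to binomial noise.

What the generator does **not** emulate: realistic marginal distributions
of real descriptor software, correlated descriptor families, assay-level
annotation structure, or the size and heterogeneity of a real
pollutant database. Passing tests therefore demonstrate that the machinery
recovers known structure under controlled conditions, not that any
particular real collection clusters well.

The study sizes used by the test suite and the acceptance script — 60
molecules / 3 communities / 2 % noise for end-to-end recovery, 200
molecules / 4 communities for the target-sharing association, 200–1000
permutations depending on the check — are chosen so each property is
measured at the smallest scale where it is stable.

## Known limitations

- The path-hashed fingerprint uses RDKit's subgraph hashing (paths up to 8
  bonds into 1024 bits); it is the same family as, but not bit-identical
  to, the CDK fingerprint other toolkits produce.
- Descriptor and quantum tables are ingested, never computed: the package
  contains no conformer generation or QM machinery.
- The builtin SMARTS set is a compact functional-group vocabulary; larger
  published pattern sets can be supplied as a pattern file.
- Embedding training is deterministic only single-threaded; there is no
  parallel training mode.
- Networks are rebuilt from scratch on every run; there is no incremental
  update path for adding molecules to an existing embedding.
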