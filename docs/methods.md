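# Methods

## Model and procedure

The pipeline infers putative drug–gene associations from matched
pharmacogenomic profiles over a cell-line panel and summarizes drug–drug
relatedness through shared targets.

1. **Inputs.** A gene-expression matrix (genes × cell lines) and a
   drug-activity matrix (drugs × cell lines), both z-scored per profile
   (mean 0, sample sd 1 over non-missing cell lines, ddof = 1). The
   matrices must share cell-line ordering. In the NCI-60 setting activity
   is z-scored −log₁₀ GI₅₀ from the sulforhodamine B assay; the package
   assumes standardization has already happened upstream and does not
   re-derive it from raw multi-platform data.
2. **QC.** Drugs with fewer than `min_n_obs` (default 40 of 60) observed
   values or with profile sd below `min_sd` (default 1e−8) are removed.
   The published procedure for discarding "weak or anomalous" activity
   profiles is not fully specified anywhere we could follow; this
   observations + variance rule is our concretization of it.
3. **Correlation.** For every (drug, gene) pair, Pearson r and Spearman ρ
   (mid-rank ties) on pairwise-complete observations; two-sided p-values
   from the t transform with n−2 df. Pairs with n < 3 or a constant
   profile are flagged untestable and excluded from correction and
   retention, not errored. With complete matrices a vectorized path
   computes all pairs at once; results agree with the per-pair path to
   1e−10 (tested).
4. **Multiple testing.** Holm's step-down adjustment. The family scope is
   per drug by default (all genes tested for that drug form one family,
   matching per-compound reporting conventions), with a `global` switch
   that treats all testable pairs as one family. Note the replicate-level
   consequence: per-drug scope controls FWER at α *per drug*, so the
   probability of at least one false edge anywhere in a panel of d clean
   drugs compounds toward 1−(1−α)^d; panel-level FWER statements are made
   (and tested) under the global scope.
5. **Retention.** Keep records with coefficient ≥ `r_threshold` (default
   0.334, inclusive) and Holm p ≤ α (default 0.05, inclusive). Default
   coefficient is Pearson with Spearman reported alongside; `either`/
   `both` modes combine the two. Default sign mode keeps positive
   correlations only; `both` uses |r|.
6. **Network.** Retained records become a bipartite graph: drug nodes and
   gene nodes, edge weight = signed Pearson r, Holm p as edge attribute.
   Genes missing from the annotation table get category `other`. Nodes
   with no retained edges are absent by construction. Exports: GraphML
   (round-trip tested), SIF, flat TSV.
7. **Drug similarity.** Per-drug target sets are the gene neighborhoods.
   The B-index B(x,y) = ½·|x∩y|·(1/|x|+1/|y|) is computed for every
   unordered drug pair, alongside Jaccard, Sørensen–Dice and Russell–Rao
   (the latter needs an explicit attribute universe; default: all gene
   nodes). Empty-set drugs score 0 against everything and are dropped
   from matrices with a warning — the index is defined for non-empty
   sets, and 0 is its natural limit.
8. **Clustering.** d = 1 − s, Ward linkage in the D2 convention (scipy's
   `linkage(..., "ward")` on the condensed distances, which matches R's
   `hclust(..., "ward.D2")`: the criterion squares distances, heights are
   reported on the distance scale). The cluster count k maximizes the
   relative loss of inertia: the height of the merge collapsing k
   clusters into k−1 divided by the height of the preceding merge; a
   positive height over zero counts as infinite, zero over zero as no
   evidence, and ties resolve to the smallest k. k is always overridable
   (`--k 15`). Cophenetic correlation validates how well a tree preserves
   the distances. Trees export as Newick with child branch length =
   parent merge height − child merge height.
9. **Structural cross-check.** From SMILES, RDKit computes (a) binary
   fingerprints (default path-based, 2048 bits; Morgan and MACCS
   available) with bit-set Tanimoto, and (b) the maximum common
   substructure of each pair, giving the MCS Tanimoto m/(nₐ+n_b−m) and
   the structural overlap m/min(nₐ,n_b), m counted in heavy atoms. The
   overlap coefficient always dominates the MCS Tanimoto. MCS mismatch
   tolerance is off by default (strict element and bond-order matching);
   `atom_mismatch`/`bond_mismatch` > 0 switch to any-atom / any-bond
   comparison. For structural clustering, the matrix (of the three) with
   the highest cophenetic correlation after average-linkage clustering is
   selected. Concordance between structural and target-set partitions is
   scored by the adjusted Rand index with the full contingency table.

## Synthetic panel generator

The generator emulates the *statistical* structure the analysis assumes,
not the biology of any particular screen:

- 60 cell lines in 9 tissue groups by default (5 breast, 6 CNS, 7 colon,
  6 leukemia, 10 melanoma, 9 NSCLC, 7 ovarian, 2 prostate, 8 renal).
  Tissue labels are metadata used for profile ordering and display only;
  they do not enter generation.
- A **target blueprint** partitions drugs into families drawing genes from
  disjoint per-family gene pools. A family picks one set size from
  `targets_per_drug` (default 4–8); `shared_fraction` (default 0.8) of it
  is a family-wide core, the rest are per-drug private genes, disjoint
  across members. Cross-family target sharing is therefore impossible by
  construction, which is what makes family recovery a well-posed test.
- **Exact planting.** Each blueprint drug's activity is built from a
  designated anchor gene (the smallest gene id of the family core, else
  of the drug's own set) so that the *sample* Pearson correlation equals
  `planted_r` (default 0.6) to machine precision: standardize the anchor,
  draw Gaussian noise, remove its in-sample projection on the anchor,
  standardize the residual, and combine as r·ĝ + √(1−r²)·ê. Every other
  truth gene is solved against the activities of *all* drugs targeting it
  (coefficients from the empirical correlation matrix of those
  activities, residual orthogonalized against them, variance completed to
  one), landing each remaining truth pair at exactly 0.95·`planted_r`
  (0.57 by default). This choice makes recovery deterministic — no
  Monte-Carlo flakiness — at the price of slightly idealized data: real
  screens do not have exact sample correlations.
- Non-target genes and non-blueprint drugs are independent standardized
  Gaussian noise. Missing values are masked uniformly at random per cell
  *after* planting (so planted correlations are approximate when
  `missing_rate` > 0, tested with tolerance), and rows are re-standardized
  over the observed entries.
- The marginal distribution of real z-scored profiles is not documented
  beyond standardization; Gaussian noise is assumed. No tissue-specific
  covariance, batch structure, platform averaging, or heavy-tailed
  activity profiles are modeled. Passing recovery tests therefore shows
  the *inference machinery* is correct under its stated assumptions, not
  that those assumptions hold for any real panel.

Default study shape: 124 drugs, 399 genes, 15 families — the scale of the
real FDA-approved-drug / cancer-gene analysis the pipeline is designed
for, small enough that a full run takes seconds on one CPU.

## Numerical choices

- Standardization and planting use ddof = 1; Pearson/Spearman values are
  invariant to that choice.
- Pearson is computed symmetrically (single dot product over centered
  vectors), so corr(x, y) and corr(y, x) agree to the last bit.
- Holm: stable sort, multiply i-th smallest by (m−i+1), running maximum,
  cap at 1; verified against statsmodels and a brute-force oracle.
- Agglomeration delegates to scipy's nearest-neighbor-chain
  implementation, which is deterministic for a fixed input ordering;
  exactly tied merges follow scipy's internal order rather than an
  explicit lexicographic rule. Partitions are invariant to input
  permutation up to relabeling (tested).
- Cluster labels are renumbered 1..k by first appearance in leaf order,
  so labels are stable across platforms.
- MCS searches carry a timeout (default 30 s/pair); a timed-out pair is
  flagged and its coefficients left missing rather than truncated.

## Design decisions taken where the procedure was open

- Retention thresholds are inclusive (≥, ≤).
- Similarity→distance is the complement d = 1 − s: order-preserving and
  range-preserving on [0, 1].
- The inertia criterion is applied to the B-index distances directly (not
  to principal components, where HCPC-style pipelines sometimes live).
- The "structural overlap coefficient" is read as MCS atoms over the
  smaller molecule's heavy-atom count — the standard substructure-
  inclusion reading; published per-pair values match this convention.
- Fingerprint dialects differ across toolchains, so published
  fingerprint-derived values are treated as tolerance checks, never as
  bit-exact targets.

## Known limitations

- Exact-correlation planting makes synthetic panels friendlier than real
  data (no correlated noise between non-target genes and activities
  beyond sampling noise).
- Per-drug Holm controls FWER per drug, not per panel (see above).
- p-values use the t transform; exact permutation p-values are out of
  scope.
- The QC rule is a concretization; it is not calibrated against any
  published compound-removal list.
- 1 − B is not a metric (the triangle inequality fails on concrete
  triples; the suite exhibits one), so Ward heights on it are a heuristic
  ordering, as they are for many non-metric similarity matrices in
  practice.
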