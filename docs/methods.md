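# Methods

## Model

The scoring model treats miRNA–disease association prediction as label
propagation on a three-layer heterogeneous network: a miRNA similarity
layer, a disease similarity layer, and the bipartite layer of known
associations A. Its core assumption is guilt by association — functionally
similar miRNAs tend to associate with semantically similar diseases — plus
the observation that the upstream similarity matrices are sparse (many
node pairs carry a zero, meaning "no information", not "dissimilar").

Three mechanisms implement this:

- **GIP kernels.** The Gaussian interaction-profile kernel scores two
  nodes by the distance between their binary association profiles. The
  effective bandwidth is the raw bandwidth divided by the mean squared
  profile norm, so the kernel scale adapts to the density of A. Zero
  entries of DSS / MFS are replaced by the kernel value; the zero test is
  exact (`== 0`), because the zero pattern encodes missing information and
  a tolerance would clobber genuinely small similarities.
- **Hybrid bipartite spreading.** All three spread operators share the
  core `S_ij = Σ_l a_il a_jl / k(d_l)` (resource flowing disease → miRNA →
  disease) and differ only in degree normalisation: HeatS divides by the
  receiver degree, ProbS by the sender degree, and the hybrid by the
  geometric mix `k(m_i)^{1−λ} k(m_j)^{λ}`. Since S is symmetric, ProbS is
  exactly the transpose of HeatS. The restart matrix P_A = W·A adds
  "virtual edges": candidate miRNAs co-associated with a disease's known
  partners receive restart mass even without a direct edge.
- **Unbalanced bi-random walk.** The two similarity layers have different
  topologies, so the walk runs r steps on the miRNA side and l steps on
  the disease side, averaging the two side-updates while both are active.
  The iteration is step-limited: T = max(r, l) with no convergence
  criterion (r and l are maximal step counts by definition; the walk trace
  exposes per-iteration deltas for stability inspection, but no stopping
  rule is applied).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| λ (`lambda_mix`) | HeatS↔ProbS mix, dimensionless in [0,1] | 0.6 | grid-sweep optimum; 0 = pure HeatS, 1 = pure ProbS |
| α (`alpha`) | restart weight in [0,1] | 0.4 | balance between propagated scores and the prior P_0 |
| r (`r_steps`) | max walk steps, miRNA side | 2 | small integers; the `grid` command sweeps 0–5 |
| l (`l_steps`) | max walk steps, disease side | 1 | |
| r′_m, r′_d (`bandwidth_m/d`) | raw GIP bandwidths, dimensionless | 1.0 | conventional unit value; effective bandwidth auto-scales with density |

## Numerical conventions

- **Zero-degree miRNAs**: the hybrid prefactor divides by `k(m)^power`,
  undefined at degree 0; entries involving a zero-degree miRNA are set to
  0 (an unconnected node neither sends nor receives resource), including
  at λ ∈ {0, 1} where `0^0` would otherwise be ambiguous.
- **Zero-degree diseases** contribute nothing to the spread core
  (vacuously, since their column of A is zero); P_A columns of diseases
  with no known miRNAs stay zero and are populated only through the
  similarity terms of the walk.
- **Degenerate inputs raise** instead of silently defaulting: an all-zero
  A makes the kernel bandwidth undefined (`DegenerateBandwidthError`) and
  makes P_A unnormalisable (`DegenerateRestartError`).
- **Normalisation**: P_0 = P_A / sum(P_A) over all entries (total mass 1).
  The walk is linear with nonnegative coefficients in P_0, so this choice
  is scale-equivariant and rankings are unaffected by it; the restart term
  uses the same normalised P_0 as the initial state.
- **Zero similarity columns** stay zero in the transition matrices rather
  than being uniformly redistributed; such a node simply receives no walk
  mass from that layer.
- **Tie-breaking** in all rankings and output files is descending score,
  then lexicographic miRNA id — output is byte-reproducible for a fixed
  seed.
- Matrix symmetry on file read is enforced as (S + Sᵀ)/2, with a warning
  when the asymmetry exceeds 1e-8; identifier matching is exact and
  case-sensitive, with a near-miss report instead of silent case-folding.

## Cross-validation protocol

For each disease with at least `min_degree` known miRNAs, its known
partners are shuffled and split round-robin into five near-equal folds
(exact equality is impossible for non-divisible counts; sizes differ by at
most 1). Per fold, only the evaluated disease's test edges are masked;
both GIP kernels are then recomputed from the masked matrix — the
evaluation text that motivated this protocol specifies recomputing the
miRNA similarity per round and is silent on the disease side, so the
disease kernel (which also depends on the masked matrix) is recomputed as
well, with a `freeze_disease_kernel` switch for sensitivity checks. The
candidate set is the test positives plus the miRNAs never associated with
the disease; training positives are excluded. AUC is the Mann–Whitney
pairwise statistic computed per fold and then averaged (per disease, then
across diseases); the per-repeat maximum is also reported since both
aggregates are of interest. Each repeat draws fresh fold plans from the
run seed; the whole procedure is bit-reproducible given
(seed, repeats, folds).

The paired t-test between two methods' per-disease AUC vectors is
two-sided (scipy's paired test); zero-variance difference vectors are
reported with a degenerate-variance flag (t=0, p=1 for identical vectors;
the p→0 limit for a constant nonzero difference).

## Synthetic networks

The generator plants shared block structure across all three layers:
miRNAs and diseases are assigned to blocks, same-block pairs associate
with probability 0.15 against a 0.01 background, and similarity entries
are drawn around 0.6 (same block) or 0.1 (different blocks) with Gaussian
noise (sd 0.1), clipped to [0, 1], symmetrised, unit diagonal. A
configurable fraction (default 30%) of off-diagonal similarity pairs is
zeroed to exercise the kernel fallback. Block structure (rather than
degree-preserving rewiring) is the planted signal because the walk can
only exploit structure shared between the similarity layers and the
bipartite layer. All draws flow from one seed in a fixed order, so
fixtures are bit-stable across platforms.

The canonical test network is 200 miRNAs × 40 diseases, 5 blocks, seed 7
(mean disease degree ≈ 7.6). At this scale the evaluation threshold is
`min_degree = 6` — the real-data threshold of 60 known miRNAs is a
property of a network with hundreds of associations per disease and would
leave nothing to evaluate here. Test and acceptance runs use 1–3 repeats
of five-fold CV; the null reference uses within = background = 0.038, the
planted configuration's expected overall density, so the null network is
density-matched and its AUC ≈ 0.5 is measurable on the same evaluable-
disease selection.

What the synthetic experiments do show: the full pipeline recovers planted
structure far above the null, every operator obeys its stochasticity law,
and the implementation agrees with element-wise loop oracles of every
formula to 1e-12. What they do not show: absolute performance on real
data. The block model's similarity layers are clean and informative,
whereas real semantic/functional matrices are mostly isolated nodes; one
visible consequence is that on the synthetic fixture the plain-A restart
ablation scores *higher* than the hybrid restart (the similarity layers
carry more information than the sparse co-association profiles, so the
restart term mixes a weaker signal into a stronger one), while on the real
data regime the hybrid restart is the component that lifts performance.
Conclusions about component contributions on real data should not be read
off the synthetic fixture.

## Known limitations

- DSS and MFS are consumed as inputs; computing them (MeSH DAG semantics,
  associated-disease-set functional similarity) is upstream and out of
  scope.
- Diseases with no training associations in a fold are skipped with a
  logged warning rather than scored from similarity alone.
- The walk is step-limited by design; there is no convergence-based
  variant.
- The synthetic generator does not fit real degree distributions
  (heavy-tailedness arises only from block sampling noise).
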