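# Methods

## The model

kfnet reconstructs a host-microbial covariance network from two matrices
measured on the same samples — OTU read counts (microbes × samples) and
host gene expression (genes × samples) — and ranks nodes that mediate
communication between the microbial community and functional gene groups.

The procedure, stage by stage:

1. **Collapse.** Raw OTUs whose representative sequences share a best
   reference hit (blastn tabular output, kept when `evalue < 1e-5` and
   `pident > 80%`, both strict) are merged by summing their count rows. The
   best hit per query is the lowest e-value, then highest percent identity,
   then lexicographic subject id. Collapsing happens on raw counts, before
   normalization, because summing integer counts is exact whereas summing
   proportions merely commutes with it.
2. **Normalize.** Each sample column is divided by its read total, giving
   per-sample relative abundances. A zero-depth sample is an error, not a
   silent drop.
3. **Select.** The top-k OTUs by mean relative abundance are kept
   (default k = 259). The ranking statistic is the mean of per-sample
   proportions — robust to unequal sequencing depth — with lexicographic
   tie-breaks, so the selection is invariant to input row order.
4. **Correlate.** Spearman's rank correlation is computed for every
   unordered pair over the union of microbe and gene nodes
   (microbe–microbe, microbe–gene and gene–gene; a microbe–gene-only mode
   is a config switch). rho is the Pearson correlation of average-ranked
   values; the two-sided p-value uses the t approximation with n−2 degrees
   of freedom, standard at n ≈ 58. A constant profile has undefined rank
   correlation and yields a sentinel record that can never form an edge.
5. **Threshold.** An edge requires `|rho| > 0.4` and `p < 0.05`, both
   strict; its sign is the sign of rho. No multiple-testing correction is
   applied by default (a Benjamini–Hochberg switch exists); the raw
   p < 0.05 rule is the network's operating definition of "strong".
6. **Error-correct.** Four false-positive scenes are removed: negative
   edges between two genes with the same regulation label; positive edges
   between an up- and a down-regulated gene; self-loops; parallel edges
   (the copy with largest |rho|, then smallest p, survives). The coherence
   rules apply only where both endpoints carry up/down labels — microbes
   have no regulation label, so microbe-involved edges are exempt. False
   negatives are then added: if a collapsed OTU absorbs ≥ 2 sub-OTUs and
   *every* sub-OTU passes the thresholds against a gene with a common
   sign, the missing collapsed-OTU–gene edge is inserted with
   rho = mean(sub-node rhos), p = max(sub-node p-values), origin
   `inferred` (mean/max is this package's attribute rule; the existence
   conditions define only which edges appear). Both passes are idempotent
   and the corrected network is asserted simple.
7. **Rank.** Bi-partite betweenness centrality between a source group and
   a target group:

       g(v) = Σ_{s,t} δ_st(v) / δ_st

   summed over unordered pairs with s in the source group and t in the
   target group, where δ_st counts unweighted shortest s–t paths and
   δ_st(v) those with v strictly interior. Pairs are counted once
   (doubling would rescale all scores uniformly), paths are hop-count
   shortest (a 1−|rho| weighted mode is non-default), scores are raw sums
   (a normalized output is available), and disconnected pairs contribute
   nothing. The implementation is a Brandes-style accumulation — one BFS
   per source with the dependency pass seeded only at target nodes — and
   is required to equal the brute-force definition: the tests enumerate
   all shortest paths in rational arithmetic on 100 seeded random graphs
   and demand exact agreement. Default group pairs: microbe versus each of
   antiviral response, cell cycle, and epithelial cell differentiation.

## Synthetic data

`kfnet.synthetic.generate` emulates the study design the pipeline targets:
two co-measured matrices at n = 58 samples with planted monotone
associations, up/down gene labels, functional groups, and redundant OTU
groups sharing a reference hit.

Dependence is planted through a Gaussian copula: a latent multivariate
normal whose pairwise Pearson correlation is set to `2·sin(π·ρ_s/6)` so
the latent Spearman correlation equals the requested target; the filled
correlation matrix is checked for positive semidefiniteness before
sampling (a strong ±rho chain through a shared node can genuinely be
infeasible and is rejected). Abundances push each OTU's latent normal
through a log-normal intensity (per-OTU base log-mean ~ N(0,1), log-scale
sd 1.0) and draw multinomial read counts per sample at a depth uniform on
[10 000, 50 000] — unequal depths exercise normalization, and the
monotone intensity map preserves the planted rank correlations up to
counting and compositional noise. Expression is the latent normal plus
independent N(0, 0.1²) measurement noise, small enough that a planted
rank correlation of 0.8 attenuates by < 0.01 on the gene side.

Up/down labels are assigned by 2-coloring the constraint graph of planted
gene–gene signs (positive → same label, negative → opposite), so planted
edges are always coherent with the regulation labels; a sign cycle with no
coherent labeling is rejected. Everything is drawn from one
`numpy.random.Generator`, so a fixed seed gives bit-identical outputs.

What the generator does **not** emulate: compositional closure beyond the
multinomial (no zero inflation or overdispersion), sequencing error,
chimeras, taxonomic structure, or realistic expression distributions.
Passing recovery tests therefore show that the pipeline's statistics and
bookkeeping behave as specified under clean monotone dependence — not
that real 16S/expression data would yield comparable precision.

Two hand-built fixtures complement the sampler: `make_fp_fixture` (exactly
one instance of each false-positive scene plus coherent survivors, paired
with its expected corrected network) and `make_bridge_network` (a random
two-cluster network whose single cross-group attachment point is one
microbe, the planted key factor; it attaches to two genes so that no gene
can tie its score).

## Numerical and design choices

- Ranks use the average-tie convention; Spearman agreement with an
  independent rank-then-Pearson oracle is asserted to 1e-12.
- Edge thresholds are strict inequalities; records at exactly rho = 0.4
  or p = 0.05 never form edges.
- Edge endpoints are written lexicographically sorted and rows sorted, so
  repeated runs produce byte-identical outputs; the pipeline manifest
  records parameters and input SHA-256 checksums.
- BpBC tie-breaks in rankings are lexicographic by node id.
- Group labels are a closed vocabulary (four DEG categories plus
  `microbe`); unknown labels are rejected everywhere to prevent silent
  group mismatches in the centrality stage.
- Microbe nodes absent from the annotation table are auto-annotated
  (kind = microbe, regulation = none, group = microbe), since DEG tables
  annotate genes only.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the centrality oracle on
100 random graphs with ≤ 12 nodes, the Spearman oracle on 1000 random
vectors, planted-edge recovery on 50 seeds at the study scale (58 samples,
30 OTUs, 50 genes, 10 disjoint planted microbe–gene pairs at target rho
0.8), and bridge-node recovery on 50 seeded networks. These sizes keep
every property estimable in seconds while leaving the study-scale sample
size and thresholds untouched.

## Known limitations

- With thresholds |rho| > 0.4, p < 0.05 at n = 58, the null rate of
  spurious edges is about 0.002 per pair regardless of the data
  distribution; over thousands of candidate pairs this bounds attainable
  precision well below 1 whenever only a handful of true edges exist.
  kfnet reports the measured precision rather than hiding it; raising
  precision requires stricter thresholds or multiple-testing correction
  (both exposed as options, both off by default to match the network's
  operating definition).
- The compositional denominator attenuates planted microbe-side rank
  correlations when the community has very few OTUs; at a realistic
  community size (≈ 30+ OTUs) the attenuation of a 0.8 target is ≈ 0.04.
- The t-approximation p-value is asymptotic; an exact permutation option
  exists for very small n but is not the default.
- BpBC significance is not assessed (no null model for centrality is
  provided), matching the method's use as a ranking, not a test.
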