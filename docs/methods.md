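# Methods

This note records the models, numerical choices and limitations behind
`linkphase`. Interface-level behaviour is documented in the module
docstrings; here the focus is on *why* the defaults are what they are and
what the desk-scale experiments do and do not demonstrate.

## Problem setting

A K-ploid genome region carries K homologous allele sequences over M
heterozygous SNPs. Linked-read sequencing observes short reads tagged with
a barcode identifying their source molecule's droplet; each droplet holds
on average ~10 molecules of ~10–100 kb, each originating from one random
haplotype. Haplotype assembly reconstructs the K sequences from the
fragments of alleles the reads observed. Three structural difficulties
drive the pipeline design: barcodes mix haplotypes (molecule
deconvolution), weakly connected regions let single spurious fragments
corrupt whole blocks (graph partitioning), and the clustering problem
itself is NP-hard for noisy data (convex relaxation).

## Fragment extraction and merging

Only heterozygous SNPs are informative, so homozygous and non-SNP records
are dropped and the survivors renumbered 1..M. Conflicting allele
observations at one site (overlapping mates, or two reads of one barcode)
keep the higher base quality; an equal-quality conflict between different
alleles drops the site — a conservative choice that avoids an arbitrary
haplotype bias, since the correct allele is unknowable at that point.
Unbarcoded reads covering fewer than two SNPs are uninformative and are
discarded, but *barcoded* single-SNP reads are kept until after barcode
merging: their information becomes usable once linked to the rest of their
barcode (`keep_single_barcoded=False` restores the stricter
filter-then-merge order). Allele codes cover 0–3 (reference plus up to
three alternates); sites with more alternates are dropped with a warning.
Fragment files encode calls as runs of consecutive variant indices with a
Phred-33 quality column, in four dialects differing only in the third
column (none / barcode / barcode / `barcode_ordinal`); read–write round
trips are bit-exact and property-tested.

## Molecule splitting (mean shift)

Each barcode fragment's covered SNP positions are clustered by flat-kernel
mean shift: every point seeds a mode search (iterated mean of points
within one bandwidth, tolerance 1 bp, ≤ 300 iterations), modes within one
bandwidth are merged preferring better-supported modes, and points join
the nearest surviving mode. The bandwidth defaults to half the expected
molecule length (50 kb molecules → 25 kb), which separates molecules whose
spans do not approach each other within a molecule length while keeping
one molecule's calls together. Clusters with fewer than two calls are
dropped, consistent with the informativeness filter. The implementation
matches `sklearn.cluster.MeanShift` semantics (cross-checked in tests) but
is self-contained and deterministic.

One consequence of the flat kernel worth stating: a *chain* of positions
spaced below the bandwidth does **not** collapse into one cluster —
interior chain points are stationary (their in-window mean is themselves)
— so overlapping molecules are merged rather than resolved, and two
molecules from different haplotypes that overlap the same region produce a
chimeric molecule fragment. This is an accepted limitation; it is why
molecule multiplexing beyond `m · L_mol ≈ G` degrades phasing for any
position-based deconvolution.

## Graph partitioning (normalized cut)

The share graph weights fragment pairs by the number of SNPs both cover
(allele values are irrelevant at this stage). Recursive bipartitioning
follows the standard spectral relaxation: split by the sign of the Fiedler
vector of `L_N` (zero entries join the positive side), evaluate the
normalized-cut value of that candidate split *within the current
subgraph*, and stop when it exceeds `t = 0.03` or the part falls below
`min_size = 2K` fragments (below which K haplotypes cannot be supported).
Because the Fiedler vector is degenerate on disconnected graphs, a
connected-components pass precedes every spectral split. Eigenpairs come
from a dense solver below 200 vertices and ARPACK (`which="SA"`, fixed
deterministic start vector) above, with a dense fallback on
non-convergence; both paths produce identical partitions on the test
fixtures. The spectral split is not guaranteed NC-optimal; an exhaustive
oracle in the tests documents the gap on small graphs. The stop rule uses
the spectral split's NC exactly.

## Assembly core (max-K-cut SDP)

Conflict weights `W_ij = (#mismatched − #matched)/#shared` lie in [−1, 1]
with `W_ii = −1`; pairs sharing no SNP contribute zero. The relaxation

    min Tr(WX)  s.t.  diag(X) = 1,  X_ij ≥ −1/(K−1),  X ⪰ 0

requires the diagonal normalization: without it the objective is unbounded
below (diag(W) = −1 admits X = cI with c → ∞), so the constraint from the
standard max-K-cut relaxation is imposed.

**Solver.** The dual augmented-Lagrangian iteration maintains a box-feasible
primal iterate and a PSD iterate, coupled by a multiplier matrix Y updated
with step σ = μ (method of multipliers); the inner subproblem over the box
multipliers and the dual PSD matrix is solved exactly by alternating
closed-form projections (elementwise box projection; PSD projection by
eigendecomposition), with over-relaxation 1.6 and μ rebalanced by factors
of 2 whenever the primal and dual residuals drift apart by more than 5×
(μ₀ = 1). Termination: once the splitting residual is below `inner_tol =
1e-3`, the primal iterate is *polished* onto the exact feasible set —
congruence rescaling by its diagonal (preserves PSD, sets X_ii = 1
exactly) followed by a blend toward the identity sized to clear any
remaining box violation — and the relative duality gap

    (obj_p − obj_d) / (1 + |obj_p| + |obj_d|)

is evaluated against a *certified* dual bound: the dual matrix is the
exact PSD projection residual, negative box multipliers are clipped and
the diagonal dual variables shifted by the resulting minimum eigenvalue,
so `obj_d` is the objective of an explicitly feasible dual point and a
true lower bound. The solve stops at gap ≤ 0.01 (default); reported
feasibility residuals are at machine precision. Absolute values appear in
the gap denominator because the objectives here are negative and the
unsigned denominator can vanish. The solver is deterministic given
(W, K, tolerances).

**Rounding.** Each restart draws K standard-normal N-vectors and labels
fragment i by the argmax inner product with column i of X̂. Two
deterministic polish steps follow: greedy single-fragment moves on the
clustering objective `Σ_{same cluster} W_ij` (strictly decreasing, hence
terminating), then coordinate descent on MEC (alternate majority-vote
consensus with reassignment of each fragment to its least-mismatching
consensus; ties keep the current label). The MEC polish matters for
polyploids: different haplotypes agree at many sites by chance, which
makes some cross-haplotype weights negative, and on realistic noiseless
instances the *pairwise* objective's global optimum can mix haplotypes
(observed: objective −3098.6 with MEC 199 beating the planted partition's
−3052 with MEC 0). MEC is the compatibility criterion the assembly is
judged by, so each restart is driven to an MEC-local optimum. Among
restarts (default 100; fast mode 10) the assignment with minimal MEC wins,
ties broken by the clustering objective; identical rounded partitions are
cached. All randomness flows from one seed; per-component seeds are
derived from the master seed and the component's smallest variant index,
making results independent of component processing order.

**Consensus.** Per (cluster, site), the modal allele among cluster calls;
ties prefer the lowest allele code; uncovered sites are gaps. Support is
the count of calls matching the reported allele.

## Evaluation metrics

*Reconstruction rate*: 1 − (mismatches under the best of K! pairings) /
(number of evaluated alleles). Positions where a reconstructed haplotype
has a gap are excluded from both numerator and denominator by default
(`gaps_as_errors` counts them as errors over the full K·L denominator).

*Vector error rate*: dynamic program over positions with one state per
permutation of the K haplotypes; position cost counts allele mismatches
under the permutation, transition cost counts indices where consecutive
permutations differ. The objective is lexicographic — mismatches first,
switches second — which resolves the otherwise ambiguous interaction
between residual allele errors and switches; the reported rate is
switches / block length, per block, averaged unweighted across blocks
(a length-weighted average is also emitted).

*MEC*: each fragment is charged its mismatch count against the nearest
haplotype, ignoring haplotype gap positions. The minimum is restricted to
haplotypes sharing at least one covered site with the fragment — without
this, an all-gap haplotype (an empty cluster) would absorb every fragment
at zero cost, and best-by-MEC restart selection would actively prefer
degenerate assignments. MEC counts mismatches, i.e. it is a score to
minimize; a formulation that rewards matches is equivalent up to sign and
not used.

*Block statistics*: mean block length in SNPs, N50 block span in bp (span
of the block at which the cumulative span of blocks sorted by decreasing
span first reaches half the total) — the two conventions usual for
linked-read assemblies.

## Simulator

The generator is fragment-level: reads, insert sizes and alignment are
deliberately not modelled (the 151 bp read geometry appears only in the
SAM fixture emitter), because the object that matters downstream is the
per-SNP allele observation process. Planted truth: SNP positions uniform
at `snp_rate` per bp (default 0.01) excluding an optional N-gap interval;
dosage uniform on 1..K−1 with the alternate allele on a uniform row
subset, so every site is heterozygous. Molecules: count =
round(C_mol · G · K / L_mol) with molecule coverage C_mol per haploid
(default 0.2), length fixed or exponential (default 50 kb), start uniform,
haplotype uniform; barcodes group m molecules (default 10, fixed or
Poisson). Each spanned SNP is observed with probability `obs_prob`
(standing in for read coverage within a molecule; the exact conversion to
read coverage depends on read geometry and is not modelled) and flipped
with probability `error_rate` (default 0.001, Illumina-scale). Barcode
merging of simulated molecules reuses the extraction stage's own conflict
rules, so fixture round trips are exact by construction.
`apply_allele_errors` applies the same per-allele error process to an
existing error-free simulation, enabling paired (common-random-numbers)
comparisons across error rates.

What passing simulated tests does *not* show: robustness to alignment
error, barcode sequencing error, indels, PCR duplicates, coverage bias, or
reference bias — all of which exist in real linked-read data and are out
of scope here (barcode correction and alignment are upstream concerns).

## Desk-scale study conditions

The test suite's end-to-end experiments use deliberately small problem
sizes chosen once as this package's desk-scale operating points:

- *Noiseless recovery*: 20 kb region, ~200 SNPs, 5 kb molecules, one
  molecule per barcode, molecule coverage 10 per haploid, triploid and
  tetraploid. Expected: RR = 1.0, VER = 0, MEC = 0 exactly.
- *Error-rate response*: triploid, 100 kb, ~1000 SNPs, 10 kb molecules,
  m = 1, C_mol = 3, obs 0.9, error grid {0, 0.01, 0.02, 0.05}, 20 seeds,
  paired by common random numbers (same molecules and observation
  patterns across the grid).
- *Molecule-splitting benefit*: tetraploid, m = 10, 3 kb molecules in
  100 kb (molecules per barcode well-separated on average), C_mol = 2,
  error 0.01, 20 seeds: average vector error with splitting enabled vs
  disabled.
- *Molecule-length response*: tetraploid, m = 10, C_mol = 1, molecules
  3 kb vs 10 kb, 20 seeds: mean phased block span in bp.

The error-rate and molecule-length effects are small relative to the
discrete switch events that dominate per-seed variability at these sizes,
hence the paired design for the error grid and the directional (rather
than quantitative) assertions throughout.

## Pipeline modes and defaults

`t = 0.03` (normalized-cut threshold), SDP gap tolerance 0.01, 100
restarts, bandwidth = molecule length / 2, `min_size = 2K`. *Fast mode*
lowers restarts to 10 and the gap tolerance to 0.05; both modes share the
components stage, so the partition of SNPs into blocks is identical and
only allele assignments may differ. Components larger than 1500 fragments
are not expected after partitioning at these scales; the dense SDP is the
deliberate trade-off for solver simplicity and a certified gap.

## Known limitations

- Overlapping same-barcode molecules are not resolved (position-only
  deconvolution; no joint or probabilistic assignment across barcodes).
- The vector-error DP enumerates K! permutation states and is limited to
  K ≤ 6; reconstruction rate's exhaustive pairing to K ≤ 8.
- The brute-force max-K-cut oracle refuses N > 12 (it exists for tests).
- Biallelic simulation only (the pipeline itself handles up to 4 alleles).
- MEC optimality and truth accuracy diverge at low coverage: an MEC-optimal
  assignment can contain haplotype switches the data cannot rule out, so
  desk-scale reconstruction rates below 1 at nonzero error rates reflect
  the objective, not only the optimizer.
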