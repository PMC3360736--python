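# Methods

This note documents the models, numerical choices and limitations behind
`drynet`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis chain

**Differential screen.** Welch's unequal-variance t-test is the default
(`equal_var=True` gives the pooled variant); the published rule says only
"t-tests", and Welch is the robust default when replicate variances are not
known to be equal. Fold changes are computed on the log2 scale of the
already-normalized values (symmetric in up/down regulation); a
`linear_fold` option reproduces the convention of averaging linear signal
intensities first. The fold boundary is inclusive (|fc| ≥ 2 passes, "at
least two-fold") and the p boundary strict (p < 0.05). No multiple-testing
correction is applied in the screen — recurrence across ≥ 2 experiment sets
is the false-positive control. Genes with fewer than two usable replicates
in a condition are excluded as untestable rather than imputed or failed.

**Correlation and threshold.** One correlation matrix is computed over the
samples of all sets concatenated (the compendium-wide profile); per-set
correlation averaging is deliberately not implemented. The cutoff grid
defaults to 0.50–0.95 in steps of 0.01 — wide enough to bracket the density
minimum of stress-response compendia; the grid resolution is a choice, not
a published fact. Ties in the density argmin resolve to the smaller cutoff;
a minimum at the grid's last point is reported with a warning since the
characteristic upturn may lie beyond the grid. Density is undefined (and
excluded from the argmin) when fewer than two nodes remain connected.

**Reciprocal top-k pruning.** Edge criterion is strict (r > cutoff).
`k_limit="auto"` takes the preliminary network's average degree over its
non-singleton nodes, rounded half-up — the same convention that yields an
integer link limit from a network's own connectivity scale. Rank ties are
broken by lexicographic gene id, which makes pruning deterministic and
independent of node iteration order.

**MCL.** Implemented from scratch on `scipy.sparse` matrices: self-loops at
each node's maximum incident edge weight, column normalization, then
iterations of expansion (matrix power 2) and inflation (entrywise power,
default 1.2) with pruning of entries below 1e-5 followed by column
renormalization — pruning therefore never breaks column stochasticity
(verified to 1e-9 per iteration in the tests). Convergence is declared when
the maximum absolute matrix change falls below 1e-6 (default cap 200
iterations; non-convergence returns the current interpretation with a
warning flag). Attractors are nodes with positive diagonal in the limit
matrix; attractors sharing an attracted column form one attractor system,
and every node joins the system holding its largest incoming probability,
ties toward the smallest system id. Clusters below `min_module_size=2`
become unassigned genes, mirroring the gray unassigned nodes of module
maps; surviving modules are numbered by decreasing size. Edge weights are
the |r| values (the weighted three-column edge-list dialect); pruning
settings are our choice since none are published.

**Module statistics.** The response statistic is the mean |log2 fold
change| of module genes in one dataset. Significance uses a two-sided
one-sample t-test against the network mean treated as a fixed reference:
published tables report a single network average per dataset, which fits
the one-sample reading of "differences between the module average and the
network average"; a module-vs-rest Welch two-sample option exists behind
`two_sample=True`. The star flag adds the direction condition (module mean
strictly above network mean, p < 0.001) — a module significantly *below*
average is not starred. A module whose values all equal the reference
scores t = 0, p = 1 (the degenerate zero-variance case is handled
explicitly). GO enrichment: upper-tail hypergeometric p with Bonferroni
multiplicity counted per module over the terms present in that module
(k ≥ 1); the exact multiplicity scheme of web tools is not recoverable, so
this documented convention is used. Enrichment threshold: adjusted
p < 0.01.

**Hub genomics.** Intramodular connectivity is the count of a gene's edges
to same-module genes; unassigned genes score 0. Hubs are the top
ceil(0.20 × size) per module, connectivity ties broken by gene id.
Cluster calling bins each chromosome into 1-Mb intervals anchored at
position 0 (sliding windows and bin-maximum scores are plausible
alternatives; summed, zero-anchored bins are implemented). A gene belongs
to the bin containing its start. Runs of adjacent bins with summed
connectivity strictly above 100 merge; the span rule — strictly more than
0.5 Mb — is measured from the first to the last *contributing* gene
(connectivity > 0), start to start: bins are 1 Mb wide, so measuring
bin edges would make a 0.5-Mb rule vacuous. The reported region extends to
the last gene's end, and coordinates are 0-based half-open throughout
(touching intervals do not overlap). The permutation test shuffles the
multiset of connectivity values over the fixed gene positions — one
shuffle realizes both the "connectivity" and the "position" exchange since
only the pairing matters — and counts permutations whose overlap count
strictly exceeds the observed one, p = n/N. The conventional
(n+1)/(N+1) correction is available (`plus_one=True`) but off by default
to match the strict form. With strict counting p = 0 is possible and is
formatted as "< 1/N".

**Motif comparison.** PWM similarity is the Pearson correlation across the
flattened 4×overlap probability values of the best ungapped alignment,
scanning all offsets with ≥ 6 overlapping columns and both strands
(probability values, not log-odds; a profile-comparison convention — the
log-odds alternative was considered and left out as the published
comparison operates on the weight matrices). A zero-variance overlap
defines r = 0. Clustering at r ≥ 0.65 is single linkage (connected
components of the thresholded best-correlation graph), which reproduces
merging of all above-cutoff neighbours; merging aligns members to the
cluster's widest motif (ties: smallest id) and averages covering columns,
renormalized. IUPAC degeneracy in consensus-to-PWM conversion splits
probability equally (K → G/T at 0.5 each). Mono-nucleotide-repeat motifs
(consensus a single repeated base) are screened out at input, the one
discovery-stage filter that is in scope. Motif discovery itself, and the
PLACE/AGRIS databases, are not: references are user-supplied PWMs.

## The synthetic compendium

The generator emulates a five-set rice drought compendium: per set,
3 control + 3 stress replicate arrays on a log2 intensity scale (replicate
count per sample is unpublished; 3 is the free-parameter default), gene
baselines uniform on [5, 10], residual array noise N(0, 0.4²).

Latent structure varies at the (set × condition) *cell* level — biological
replicates share their condition's biology — while noise is per array.
Each planted module follows one latent trajectory over the 10 cells: a
drought-response pattern (the module responds in a random ≥ 2-subset of
sets, sign alternating up/down across modules, per-set magnitude
multipliers uniform on [0.6, 1.4], scaled by `response_effect` = 1.5 on the
log2 scale — the magnitude range of published module-level fold changes)
plus an orthogonal condition-independent factor that tops the trajectory
variance up to c = ρσ²/(1−ρ), the shared-variance budget implied by the
correlation target ρ (`module_correlation`). The factor draw is
residualized against the pattern and standardized across cells, so the
injected shared variance is exact despite only 10 cells. Genes load on
their module trajectory with shares scattered around sqrt(ρ)
(`module_correlation_spread` = 0.06), so pairwise within-module |r|
concentrates near ρ while strong loaders are simultaneously strong
responders — the module's future hubs. A quarter of unassigned genes
respond individually (own subset/sign/magnitudes): they pass the screen but
correlate only moderately with one another, reproducing the
responsive-but-unmodular pool whose progressive disconnection produces the
interior minimum of the density curve; the remaining background genes share
one global factor at the background correlation target (0.2). Modules
alternate induction and repression to exercise the absolute-value response
statistic.

Genome annotation places genes (1–5 kb) uniformly over 12 chromosomes of
30 Mb; planted hub regions receive designated member genes uniformly within
the region. When a connectivity vector from a real network is supplied, the
designated members are the globally most connected genes dealt round-robin
across regions; otherwise synthetic connectivity is drawn — designated
members uniform on [25, 40], background a 65/35 mixture of Poisson(8) and
uniform [12, 36]. That null mixture (and the QTL defaults, 35 intervals of
2–5 Mb) was chosen so the null overlap count takes many distinct values:
the permutation p is a discrete n/N statistic with strict ">" counting, and
a coarse-grained count (few clusters, huge QTLs) would visibly distort its
finite-sample calibration regardless of implementation correctness. QTL
mode "planted" covers every hub region with one QTL (random 0.1–0.8 Mb
flanks) and fills up to `n_qtls` with random intervals; "null" draws all
intervals independently of gene placement. GO labels give each module a
planted term covering 60% of its genes plus 30 background terms hitting 5%
of all genes; motif PWMs are Dirichlet(0.5)-column matrices of width 6–10.

Two study configurations are used by the tests and the acceptance script:

* **Recovery configuration** (the `SimulationConfig` defaults): 2,000
  genes, 10 modules of 150…30 genes, ρ = 0.9 over background 0.2 — the
  regime where planted modules must be recoverable end-to-end.
* **Association configuration** (`planted_association_config`): the same
  compendium with modules at the scale of the smaller published modules
  (20–60 genes) plus 15 two-Mb planted hub regions, each QTL-covered. The
  smaller modules keep the network's summed connectivity per Mb well below
  the cluster threshold outside genuine hub concentrations; with the large
  default modules the genome-wide connectivity mass approaches the
  threshold everywhere and planted regions survive the connectivity
  shuffle through sheer gene density, leaving the permutation test nothing
  to detect — a regime worth knowing about when applying the test to very
  dense networks.

All generators are seed-deterministic; the expression, genome, QTL, GO and
motif stages consume independent streams derived from the configured seed,
and the pipeline derives its permutation seed from the run seed by a fixed
offset, so stage results do not depend on whether other randomized stages
ran.

What the generator does **not** emulate: probe-level intensities and
summarization, array batch effects, spatially varying gene density along
chromosomes, correlated placement of functionally related genes, GO-graph
structure (terms are flat labels), or motif occurrence in actual promoter
sequence. Passing tests therefore certify the statistical machinery —
screen calibration, threshold selection, clustering fidelity, enrichment
and permutation calibration — not robustness to normalization artifacts or
annotation noise in real arrays.

## Problem sizes and numerical notes

The validation suite runs at desk scale by design: oracle equivalence on
50–200-gene random matrices (density recount, pruning re-derivation),
10-node toys against a dense reference MCL, exhaustive hypergeometric
enumeration up to N = 25, module recovery on ten 2,000-gene compendia,
screen calibration on 200,000 simulated null genes against a 400,000-draw
Monte-Carlo estimate, permutation-test calibration on 400 null tracks at
200 permutations plus 20 end-to-end association runs at 1,000
permutations. The acceptance script runs one full association analysis
(2,000 genes, 1,000 permutations) in a few seconds.

Numerical conventions worth knowing: correlations use `numpy.corrcoef`
(zero-variance genes are dropped with a warning, not silently kept);
the one-sample t-test handles zero-variance modules explicitly (t = 0,
p = 1 on the reference; ±inf, p = 0 off it); hypergeometric p-values come
from `scipy.stats.hypergeom.sf(k-1, N, K, n)`; the ARI uses
scikit-learn's permutation-model formula (an exhaustive pair-counting
oracle backs it in the tests); permutation and simulation randomness uses
`numpy.random.default_rng` exclusively.

## Known limitations

* The density-minimum cutoff is grid-resolution-limited and can sit at the
  grid boundary on degenerate inputs (warned, not fixed up).
* MCL at inflation 1.2 on near-clique modules can emit 2-gene splinter
  clusters at the module periphery; they are honest outputs, filtered only
  by `min_module_size`.
* The permutation null preserves gene positions but not local gene-density
  structure beyond them; on networks whose connectivity mass approaches
  the cluster threshold genome-wide, the test loses power (see the
  association configuration above).
* The strict n/N permutation p is slightly anti-conservative under heavy
  ties; the (n+1)/(N+1) option is provided for users who prefer the
  guaranteed-valid form.
* Bonferroni per module is conservative for deeply annotated modules; no
  FDR alternative is implemented by design.
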