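# Methods

## The problem

Synthetic long-read (read-cloud) protocols shear genomic DNA into long
(~10 kb) fragments, dilute them into barcoded wells so that each well holds
a small fraction (~1–2%) of the genome, and sequence the wells shallowly
with accurate short reads. Short reads demultiplexed by well form *read
clouds*: clusters of reads that all came from one hidden long fragment.
Reads overlapping the amplification adapters at a fragment's ends act as
*end-markers* of the fragment boundary. Two coverage parameters describe
such a library: `C_F`, genome coverage by long fragments, and `C_R`,
short-read coverage of each fragment, with total depth `C = C_F × C_R`.

A short read falling inside a segmental duplication (> 5 kb at > 94%
identity) cannot be placed by its own bases. Its cloud can: the cloud
jointly covers enough divergent positions to identify the specific repeat
copy the fragment came from. rfaligner formalises this as joint MAP
alignment of all reads of a well under a generative model of the read-cloud
process.

## Model

Each well contains hidden long molecules `M_c = (L_c, X_c, λ_c, B_c, S_c,
E_c)`: location, hidden sequence, read density, end-marker pair, size, and
an existence indicator `E_c ~ Bernoulli(p_exist)` (candidate molecules are
seeded generously; most are not real). The joint read probability
factorises over molecules,

    P(R) ∝ ∏_c φ_c(R_c),    φ_c(R_c) = Σ_{M_c} P(M_c) P(R_c | M_c),

with read `n` attached to molecule `c` when one of its candidate alignments
falls in the molecule's coordinate range. The prior decomposes as
`P(E) · P(B) · P(S, λ | B) · P(L | E) · ∏_l P(X_l | E)`; everything
conditioned on `E = 0` is 1. `P(L | E=1)` is uniform over the usable
genome. `P(X_l)` is categorical with mass `1 − θ` on the reference base and
`θ/3` on each alternative; θ is the SNP-rate prior, a single shared scalar
(default 1e-3, a typical germline heterozygosity). `P(B)` and
`P(S, λ | B)` are learned (below).

The emission `P(R_c | M_c)` for an active molecule is the standard shotgun
model: read count `n_c ~ Poisson(λ s_c)`; each read start uniform on the
molecule (`1/s_c`); each base emitted from `X_c` with error `e = 10^(−q/10)`
(probability `1 − e` of the molecule base, `e/3` each alternative); a flat
`log 1e-4` penalty per indel event in a candidate alignment (X models
substitutions only). Unassigned reads follow an off-target route with
probability `p_offtarget × (1/4)^L` — a contamination prior (1e-5) times a
uniform background base emission, which puts the two routes on the same
generative scale. A flat constant would be larger than the in-molecule
per-read factor (~`1/s_c`) and would absorb every read carrying a couple of
sequencing errors.

Given an assignment, `L_c`, `S_c`, `B_c`, `E_c` collapse to single values:
existence is "any read assigned", the extent `s_c` is the span of the
assigned alignments, and `B_c` is read off the assigned end-marker reads
near the molecule boundaries. Treating `s_c` as the *assigned-read span*
(rather than the seeded cloud interval) matters: clustering can chimerise a
true cloud with the pass-1 landing zone of another repeat copy's ambiguous
reads, and a frozen, inflated size would let single reads drift into the
phantom extension at almost no cost.

### Variable elimination

`φ_c` is computed without instantiating `X_c` or `λ_c`:

* **X elimination** — positions are independent given the reads, so each
  covered column contributes `Σ_{x∈ACGT} P(x|θ, ref) ∏_{reads} P(obs|x, q)`;
  uncovered columns contribute 1. Cost: O(total aligned bases).
* **λ elimination** — trapezoid quadrature on a fixed 64-point log-spaced
  grid spanning the [1st, 99th] percentile of training densities, weighting
  the KDE prior density by the Poisson count likelihood. The KDE has no
  conjugate form, so quadrature replaces an analytic integral; 64 points
  resolve the (smooth, unimodal) integrand to far below the score
  differences that drive any decision.

Column statistics are additive in the assigned reads, so the engine
maintains per-column log-likelihood tables incrementally: moving one read
costs O(read length), which is what makes local search and the confidence
queries affordable.

## Prior learning

Training wells are aligned once (pass 1); clouds whose members all mapped
uniquely supply features (size in bp, read count, density λ̂ = count/size,
end-marker pair). Outliers are removed: density above the 99th percentile
(copy-number pileups) and clouds overlapping another cloud of the same well
(collision candidates). At least 50 retained clouds are required.

* `P(B)`: empirical frequencies over {00, 01, 10, 11} with add-one
  smoothing.
* `P(S, λ | B)`: a 2-D Gaussian product-kernel KDE on (log S, log λ̂) per
  marker state, pooled when a state has fewer than 20 observations.
  Bandwidths follow Scott's rule per dimension, floored at 0.05 — fragment
  sizes have a heavy right tail, and the floor also covers degenerate
  (all-identical) feature sets.
* `marker_eff`: fraction of the `2 × n_clouds` marker slots occupied.
* `p_exist`: expected true fragments per well (well fraction × genome
  length / mean fragment size) divided by observed candidate clouds per
  well — the probability that a seeded candidate is real.

The prior serialises to one JSON file so wells can be aligned reproducibly
without retraining.

## Seeding and inference

Pass 1 aligns every read to the full reference, one placement per read.
Single-linkage clustering (link distance 3.5 kb, minimum six reads —
overridable; the defaults follow the protocol's training calibration) seeds
candidate clouds. An interior end-marker splits a cloud in two when both
halves keep six reads *and* the junction shows a coverage break (no member
read starts within 500 bp after the marker): merely-adjacent fragments show
a break, overlapping fragments (collisions) do not and are left for the
collision filter. One contig per cloud, padded ±1 kb, forms the per-well
abbreviated reference; pass 2 realigns all reads against it allowing up to
15 placements (reads exceeding the cap are flagged high-copy, excluded from
potentials, and reported at MAPQ 0).

MAP inference is restarted local search: greedy initialisation (best
aligner score), iterated-conditional-modes sweeps in random order over
reads (move = switch one read's candidate or unassign; accept on strict
improvement), interleaved with whole-cloud block moves (relocate all reads
of a molecule into another molecule that can host them). Ten restarts
(greedy + nine random initialisations of the ambiguous reads) guard
against coordination barriers where a subset of reads must move together;
on exhaustive-enumeration benchmarks up to 14 reads this configuration
recovered the global optimum in every tested instance. Ties keep the
current assignment, and all randomness is seeded, so results are
bit-reproducible. The score trajectory is monotone by construction; the
returned assignment is a single-read-move local maximum.

## Confidence queries

* **Read posterior / MAPQ** — with the MAP fixed, reads interact only
  locally. The read (and, when the local neighbourhood of ambiguous reads
  is small — at most 12 reads and ~2,000 joint states — those neighbours
  too) is marginalised over its domain; the posterior mass of the MAP
  placement converts to MAPQ = floor(−10 log10(1 − p)), capped at 60.
  Floor rather than round keeps the contract "posterior ≥ 0.9 ⇔ MAPQ ≥ 10"
  exact. The conventional confidence filter keeps MAPQ ≥ 10.
* **Cloud quality** — `log P(R_c)` at the MAP read set (the potential
  itself); in log space it tracks the number of variants the assignment
  implies in the fragment. Clouds scoring below the 1st percentile of a
  per-well null (reads' bases shuffled within 5-unit quality strata) are
  flagged low-quality.
* **Existence posterior** — the molecule's whole read set is re-placed
  into each inactive candidate molecule that can host every member;
  softmax-renormalising the resulting scores approximates
  `P(E_c | rest of MAP)`. Molecules below 0.9 (mirroring the MAPQ-10
  convention) are excluded: all their reads map equally well elsewhere.
* **Collision detection** — a cloud with more than two distinct marker
  sites, or a surviving interior marker site, is a collision (two
  overlapping fragments); its reads are excluded. With marker efficiency
  `p`, at least one of the two junction-adjacent markers is observed with
  probability `1 − (1 − p)²` (0.947 at p = 0.77); the both-markers
  expression `1 − p²` is logged alongside for comparison.

## Simulator

The simulator generates (i) random genomes with planted duplication pairs
(configurable count, length, identity — the stand-in for real segmental
duplications so no reference download is needed) and (ii) wells: fragment
sizes log-normal (μ = 9.2, σ = 0.3 in log-bp, i.e. ~10 kb), locations
uniform, drawn until the well holds its genome fraction (default 2%; the
final overshooting fragment is accepted with probability deficit/size so
expected coverage is unbiased); with probability `collision_rate` (default
0.02, matching the well genome fraction) a fragment is forced to overlap an
existing one. Each fragment is shot through a *stencil*: parametric by
default (Poisson read count at `C_R`, uniform offsets; flagged end-marker
slots snapped to the fragment ends, since an end-marker read by definition
overlaps the fragment end), or empirical stencils cut from user-supplied
alignments. Base qualities follow a first-order chain (AR(1), coefficient
0.7, innovation SD 3) around a linear profile decaying from Q35 to Q25;
substitutions occur at `10^(−q/10)` per base. Every read carries exactly
one truth record.

What the parametric mode does not emulate: sequence-dependent coverage
bias, GC bias, chimeric (PCR) fragments, indel sequencing errors, and real
stencil irregularity — so passing tests demonstrate correctness of the
inference machinery under the stated generative model, not robustness to
every artefact of real libraries (empirical stencil mode recovers some of
the latter).

## Benchmark design

The evaluation harness compares four selectors on simulated wells after
MAPQ ≥ 10 filtering: **Baseline** (pass-1 single-hit alignment, score-gap
MAPQ), **Naive** (best pass-2 hit on the abbreviated reference, score-gap
MAPQ), **RFA** (this package), and **Oracle** (the true hit whenever the
multi-mapper returned it — the upper limit by construction). A placement is
correct within ±5 bp on the same strand. The built-in mini-mapper is
exact-seed (31-mer, tiled disjointly plus a tail seed) and gapless extend
with ≤ 5 mismatches; for reads of at least three seed lengths every
placement with ≤ 2 mismatches is provably recovered.

The shipped study uses 50 wells from a 5-Mb genome with 10 duplication
pairs (5–20 kb, 94–99% identity), `C_R = 1.5`, 2% well fraction, and 20
separate training wells — sizes chosen so the full benchmark (training,
alignment, queries, evaluation) completes in minutes on one core while
still containing several hundred multimapped reads.

Reads are simulated single-end. The real protocol sequences paired ends;
a pair's wider footprint covers divergent positions more often, so
single-end conditions are the *harder* setting for copy attribution and
the resolvable fraction reported here is conservative in that respect.

## Known limitations

* Wells are independent by assumption (as in the protocol model);
  cross-well information sharing is out of scope.
* Mate pairs are treated as independent single-end fragments.
* Indels are penalised per event but not modelled in the hidden sequence.
* When both homologous copies of a duplication are sampled as fragments in
  the *same* well, reads covering no divergent position are irreducibly
  ambiguous between the two active molecules; the model correctly reports
  ~0.5–0.7 posteriors and the confidence filter removes them, while an
  oracle selector gets them free. This is the dominant residual gap to
  oracle performance in the benchmark.
* The mini-mapper is for desk-scale references (tens of Mb); for real
  genomes, pass-1/pass-2 alignments from an external aligner can be
  supplied as SAM.
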