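# Methods

`cllrs` implements a synchronous Boolean-network toolchain for studying
chronic lymphocytic leukemia (CLL) and its transformation to Richter
syndrome (RS), together with the statistical machinery used to validate
such models: noise-robustness testing against random networks, scale-free
topology checks, graded input–output analysis, and a single-cell
expression-binarization/concordance pipeline. This note documents the
models, algorithms, parameter choices and their limitations.

## Boolean network formalism

A network is a set of named variables `x_1..x_n` with one Boolean function
per variable over AND/OR/NOT and the constants 0/1. All functions update
simultaneously (synchronous scheme); a state is a binary vector, encoded as
an integer with node 0 in the least-significant bit (node order =
declaration order in the rule file). Because the state space is finite and
the update deterministic, every trajectory enters a recurring cycle — an
attractor (a fixed point if of length 1) — and the set of states reaching
an attractor is its basin. Knockout/knockin (KO/KI) interventions clamp a
node to 0/1 throughout the simulation; clamped nodes ignore their
functions. Rule files follow the BoolNet `targets, factors` plain-text
dialect, with `&`/`|`/`!` or `AND`/`OR`/`NOT` spellings and parenthesised
grouping; nested conjunctions/disjunctions are flattened to a canonical
form so that parse(serialize(net)) is the identity.

Asynchronous and probabilistic update schemes are out of scope.

## Attractor landscapes

* **Exhaustive enumeration** (n ≤ 20 by default, 2^20 ≈ 10^6 states):
  the full successor table is built with a vectorised batch-step engine
  (states packed into `uint64`, each node function compiled once into a
  closure over boolean columns), then squared repeatedly so every state
  lands on its cycle, and each cycle is reduced to its minimal-encoding
  state as a canonical attractor identifier. Basin counts partition 2^n.
* **Sampling estimation** (any n ≤ 64): attractors are discovered from
  uniformly random start states via a vectorised variant of Brent's
  cycle-finding algorithm; basin ratios are the fractions of starts
  converging to each attractor. Attractors with basins smaller than
  ~1/n_samples are likely to be missed, so results carry `n_samples` and
  `seed`. On 20 random 10-node networks, 10^5 samples recover the
  exhaustive attractor sets exactly with basin-ratio errors < 0.002
  (tolerance asserted: 0.02).

Cycles are canonicalised by rotating the minimal encoding first, making
attractor identity independent of the entry state.

## Phenotype interpretation

Attractors of the CLL/RS model are read through indicator nodes:

| label | state-level rule |
| --- | --- |
| apoptosis | apoptosis indicator ON (BIM present, AKT absent) |
| proliferation | S-phase indicator ON (E2F and CCNE1 jointly active) |
| cell_cycle_alert | CCND1 and CCNE1 ON without S phase |
| anergy | anergy indicator ON (NFAT present; NF-κB, AKT, S phase absent) |
| quiescent_G0 | none of the above |

The rules are applied per cycle state in the order listed (a precedence:
apoptosis > proliferation > alert > anergy > quiescent). A fixed point gets
its state's label; a cycle whose states agree gets that label; a cycle
mixing labels is reported as `mixed`, with per-indicator activity
fractions (ON share over the cycle) always attached so stricter callers
can be layered on top. State combinations the rules above do not name
(e.g. CCND1 active alone) fall through to `quiescent_G0`.

Two landscape summaries are provided: *fused activities* (per-node mean
activity over each attractor's cycle, weighted by basin ratio — the
collapsed-heatmap representation) and *phenotype fractions* (basin share
per label — the pie-chart representation).

## The reconstructed CLL/RS network

`synthetic_data.reconstructed_cll_network()` packages a 39-node Boolean
model of BCR signalling, the anergy program, the TP53/MYC axis, cyclin
control and the apoptosis machinery. **It is a best-effort reconstruction
from published regulatory statements, not the authoritative supplementary
rule set of the original 49-node model**; every rule carries a provenance
note marking it `stated` (taken from a published statement about the
circuit) or `pass-through` (minimal connecting logic where the sources are
silent). The parser loads the authoritative rule file unchanged if a user
supplies one.

Key circuit choices:

* Anergy locks through BCR → PKCβ ⊣ GSK3B → NFAT, with NFAT driving SHP1,
  PTEN and CD5; PTEN and the SET–PP2A axis keep AKT off.
* MYC requires TP53 absence *and* mitogenic ERK (`MYC = !TP53 & ERK`), and
  SET is driven by MYC alone. These two choices prevent a spurious
  AKT/MYC bootstrap on the canonical start state (all nodes off, BCR on),
  which would otherwise race the anergy program and contradict the
  documented BCR-stimulation trajectory.
* NFAT loss (directly, or via NOTCH1 downstream of AKT) de-represses
  S100A4, which together with MDM2 degrades TP53 — the entry point of all
  three RS programs.
* Cyclin D needs MYC, ERK and INK4 (CDKN2A/B) absence; cyclin E needs E2F
  and CDKN1A/1B absence; S phase = E2F ∧ CCNE1.

Simulated conditions clamp the two input nodes: the baseline is chronic
BCR/IgM stimulation without microenvironmental costimulation (BCR=1,
TME=0); withdrawal and TME conditions override these. Without the clamps,
random starts mix in unstimulated basins and no condition is
interpretable. The TME input activates AKT and NF-κB (an optional flag
adds a TME→BCR edge, which one published passage names and another
omits).

The reconstruction is validated *qualitatively* by
`reconstruction_checklist()`: anergic baseline from the BCR-only start
(NFAT on, AKT off, CD5 on); apoptosis on BCR withdrawal (rescued by BCL2
gain); full S-phase entry under CDKN2A/B+TP53 loss, AKT gain (NFAT off,
S100A4 on) and NFAT loss (AKT on, CDKN2A and CD5 off); BCR dependence of
the CDKN2A/B+TP53 proliferation; anergy/proliferation coexistence under
TME input; and the two-hit requirement (BMI1 gain or TP53 loss alone do
not yield full S phase, their combination does). Quantitative basin
percentages of the original model (99% proliferative under CDKN2A/B+TP53
loss, the 47/53 TME split, the ~16/~2 high-risk split, the 0.02/0.03
bit-flip values) depend on the authoritative rule set and are *reported*
by the analysis scripts but never asserted. Notably, the reconstruction is
**not** more bit-flip robust than its degree-matched random nulls
(p ≈ 0.98) — robustness of the original model is a property of its exact
rules, not of the circuit sketch — while its total-degree distribution is
power-law plausible (bootstrap p ≈ 0.9).

## Perturbation screening

Candidate interventions of size 1..m over c nodes are enumerated in
lexicographic order (node indices, then values); the count obeys
Σ_{i=1..m} C(c,i)·2^i (for c = 49, m = 2: 4802). Screening criteria
combine forbidden phenotypes (basin fraction must be exactly 0 among
sampled starts — report `n_samples`, since a tiny surviving basin may be
missed), an optional required phenotype with a minimum basin fraction, and
per-node constraints that must hold in every cycle state of every
attractor (e.g. `SPhase = 1` operationalises "fully proliferative",
the strictest reading of the published manual filter). Driver screening on
the baseline model forbids anergy and requires full S phase; drug
screening on an RS condition either requires dominant apoptosis or
constrains S phase to 0. Indicator nodes and clamped inputs are excluded
from candidates; an exclusion list supports curation of biologically
nonmeaningful combinations. Per-intervention seeds derive from the master
seed and the candidate index, so results are reproducible and
order-independent.

## Robustness to bit-flip noise

For each of `n_states` random states, one uniformly chosen bit is flipped,
both states advance one synchronous step, and the normalized Hamming
distance HD = (# differing bits)/n between the successors is recorded.
The reference network's mean distance is compared against `n_networks`
random N-K networks that preserve n and the reference's per-node
in-degrees (distinct regulators referenced by each function; constant
nodes map to k = 1): each null network draws k_i distinct regulators
uniformly and i.i.d. fair-coin truth tables. Truth tables are rendered as
normal-form expressions that keep every drawn regulator referenced even
when the table is constant — dropping them would both break the documented
in-degree contract and bias the null (networks conditioned on their
realized expression degrees are systematically more flip-sensitive than
unconditioned ones; the calibration described below fails completely
without this).

The per-network summary is the **mean** normalized distance (the
convention of BoolNet's network-property testing; the full distribution is
also returned along with the null's 5% quantile). The p-value is add-one
corrected, p = (1 + #{null ≤ observed})/(n_networks + 1), with the plain
counting fraction reported alongside; p < 0.05 is called significant.
Calibration: with references drawn from the null generator itself (200
repetitions × 200 nulls × 200 states, 10-node k = 2 networks), the
rejection rate at 0.05 is 3.5% (asserted band 5% ± 2%).

## Scale-freeness

Total degrees (in + out, zero-degree nodes excluded) are fit to a discrete
power law P(k) ∝ k^(−α): α by discrete maximum likelihood
(`scipy.special.zeta`), xmin by scanning candidates and minimising the
Kolmogorov–Smirnov distance between the tail's right-continuous empirical
CDF and the model CDF evaluated over the full integer support of the tail
(gaps carry signal). Candidate xmin values must retain at least a fraction
(default 25%) of the positive degrees: an unrestricted scan can always
escape into a short upper tail where any decaying distribution is locally
power-law-like, which destroys the test's power (Poisson(4) degrees then
pass half the time; with the restriction they are rejected essentially
always at n = 1000). Goodness of fit uses the standard semi-parametric
bootstrap (tail resampled from the fitted law, body from the empirical
distribution, each replicate refit identically); plausibility requires
p > 0.1. Under the true model the test is approximately calibrated
(P(p > 0.1) ≈ 0.91 over 100 runs), so the recovery benchmark (≥ 90% of 50
runs) sits close to its expectation and is the least-margined check in the
suite.

## Graded input–output analysis

An input node's activity is a duty cycle: a percentage p ∈ 1..100 of ON
steps among T simulated steps, realised with exactly round(pT/100) ON
positions placed by a seeded uniform shuffle, freshly per starting state
(a deterministic block layout would phase-lock against network cycles).
Scheduled nodes take their realised value each step, overriding their
functions; all other nodes update synchronously from random starts.
Output activity = mean ON fraction over the final `window` steps,
averaged over starts (defaults 250 starts, T = 500, window = 100). Grids
over two inputs evaluate every percentage combination with per-cell seeds
derived from (master seed, cell coordinates), so cells are independent.

Endpoint consistency: a 100% schedule is exactly a KI, and the graded
activities match the exhaustive KI landscape's fused activities to within
±0.05 on every node whose activity is identical across the KI landscape's
attractors (measured error: 0.0 on the toy suite). Nodes the KI landscape
leaves unconstrained (e.g. free self-copy inputs) have fused values that
are basin averages; a 250-start estimate of such a value carries binomial
noise with sd ≈ 0.032 at activity 0.5, so 1.96σ ≈ 0.063 already exceeds
0.05 and those nodes are held to a 3σ (0.095) bound instead.

## Expression binarization (step-function / BASC-A style)

Per gene, the expressed values are sorted and least-squares optimal step
functions with d = 1..D discontinuities are computed by dynamic
programming over block boundaries (block costs from prefix sums; D capped
at 20 by default, the full d ≤ N−2 range available). In each d-step
function the *strongest discontinuity* maximises the jump between adjacent
block means weighted by the quality of reducing the whole series to a
single step at that position (reciprocal two-block squared error) — a
large jump in a sparse tail approximates the series poorly as a global
threshold and is down-weighted, which is what keeps thresholds at the
biological mode boundary instead of in the log-normal tail. The final
break is the lower median of the per-d strongest breaks; the threshold is
the midpoint of the two flanking sorted values; calls are
`value > threshold`. Ties between equal jumps resolve to the lower break
index.

Significance ("is there a break at all?") uses break strength = the
Gaussian two-block likelihood ratio n·log(SS_total/SS_within) at the
final break (infinite for a perfect step), compared against the same
statistic on *no-jump null* samples — sorted unimodal Gaussian samples of
the same size run through the identical pipeline. The statistic is
location/scale-free, so the null depends only on the sample size and is
cached (bucketed to multiples of 50 above n = 50). p is add-one corrected
over the resamples (default 100 in the matrix pipeline). Design rationale:
a 4σ equal mixture of two Gaussians is nearly indistinguishable from a
*uniform* sample by any shape statistic (their kurtoses are 1.72 vs 1.80),
whereas against the unimodal Gaussian null the mixture's split statistic
separates by a wide margin (minimum observed 494 vs null maximum 419 at
n = 350 over hundreds of draws), and a short linear ramp (n = 20) remains
non-significant (true p ≈ 0.13). The flip side is documented honestly: a
long uniform ramp (hundreds of points) *would* be called significant
against this null.

Matrix pipeline (`binarize_matrix`): genes with no expression at all are
excluded (`all_zero`); fits run on `log1p` of the *positive* values (the
standard normalisation scale; zeros cannot exceed a positive threshold
and are always called OFF, which is what makes the procedure insensitive
to the number of zeros), with the threshold mapped back to the raw scale;
genes whose break is not significant at α = 0.05 are excluded
(`not_significant`). On the synthetic recovery conditions (200 genes ×
500 cells, 4σ mode separation, 30% dropout) cell-call accuracy on
observed entries is 97.4% — close to the 97.7% Bayes limit of any
threshold rule at exactly 4σ — and the excluded set is exactly the
planted all-zero genes.

## Cell selection, concordance and ROC thresholds

Proliferative (RS-like) cells are those with at least one of CCNE1,
CCNE2, CCND1, CCND2, CCND3 ON in the binarized data. Model/data
concordance compares, per model node, the fraction of selected cells in
which the OR over the node's mapped genes (isoform groups, e.g.
NOTCH → NOTCH1..4, NFAT → NFATC1/2) is 1 against the model-side fused
activity restricted to fully proliferative attractors; a side is *active*
at ≥ 30% (the Hans-score convention) and a node matches when both sides
agree. OR-aggregation across isoforms before computing the population
fraction is a recorded choice, overridable through the node→gene map.

Scored markers (e.g. immunohistochemistry H-scores) are binarized at the
ROC threshold maximising Youden's J = sensitivity + specificity − 1 over
midpoints of consecutive unique scores; ties resolve to the smallest
candidate (cross-checked against scikit-learn's ROC curve in the tests).

## Synthetic expression generator

The generator emulates a pooled, normalised single-cell matrix: per gene
and cell a high/low mode is drawn (mixing fraction π, scalar or per-gene),
a log-normal value is drawn from that mode (log-scale means μ_lo/μ_hi,
dispersion σ; defaults 1.0/3.0/0.5, i.e. 4σ separation), and the value is
zeroed with dropout probability δ (default 0.3); a few genes are entirely
silent, and the five cyclin genes are planted with their own mixing
fraction so the proliferative-cell filter has known ground truth. The
returned ground truth is mode membership *plus the dropout mask*: a
dropped-out high-mode cell is unrecoverable from its observed zero, so
recovery is measured on observed entries. What the generator does **not**
emulate: integer counts and library-size variation, gene–gene
correlation, batch effects, and continuous (non-bimodal) expression
gradients — so passing recovery tests demonstrates correctness of the
binarization machinery on separable bimodal signals, not performance on
arbitrary real scRNA-seq data.

## Problem sizes used by the tests and the reproduction script

Oracle comparison: 20 networks × 10^5 samples. Reconstruction checklist:
10 conditions × 10^5-sample basins. Robustness calibration: 200
repetitions × 200 null networks × 200 states (a scaled-down design; the
single-network analysis uses the full 1000 × 1000). Power-law benchmark:
50 + 50 runs at n = 1000 with 100 bootstrap replicates (p-resolution 0.01
against the p > 0.1 cut). Binarization: one 200 × 500 matrix.
Graded-IO: 250 starts × 500 steps × last-100 window, per cell. These are
the package's study conditions; all are seeded and reproducible.

## Known limitations

* The packaged CLL/RS network is a reconstruction; quantitative basin
  shares and robustness readouts of the original model do not transfer.
* Sampling-based screening can miss phenotypes with basins below the
  sampling resolution; "eliminated" means unobserved among `n_samples`.
* The batched engine supports n ≤ 64 nodes (the scalar path has no limit).
* The binarization significance test is tuned to separate step-like
  bimodality from unimodal no-jump data; long uniform ramps are outside
  its null.
* Exact basin computation at n = 49 (2^49 states) is out of scope by
  design; basins there are always estimates.
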