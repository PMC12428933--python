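# cllrs — Boolean-network dynamics of CLL and its Richter transformation

Chronic lymphocytic leukemia (CLL) cells in peripheral blood sit in an
anergic, non-proliferating state; in a fraction of patients the disease
transforms into Richter syndrome (RS), an aggressive large-B-cell
lymphoma. With few cell lines or animal models of the transformation,
logic models are a practical way to reason about which lesions push the
BCR/anergy/TP53/cyclin circuitry from anergy into proliferation, and which
interventions push it back out.

`cllrs` is a Python toolchain for exactly that style of analysis, built
around a packaged 39-node Boolean reconstruction of the CLL→RS signalling
network (BCR signalosome, NFAT-driven anergy program, TP53/MDM2/S100A4
axis, MYC→BMI1→INK4 cascade, cyclin/S-phase machinery, apoptosis
indicators). It is aimed at systems biologists who want a scriptable,
tested alternative to running these analyses ad hoc.

## What it does

* **Synchronous Boolean simulation** of BoolNet-style `targets, factors`
  rule files: states `x(t) ∈ {0,1}^n`, all functions `f_i` applied
  simultaneously, KO/KI as clamped node values.
* **Attractor landscapes**: exhaustive enumeration over all 2^n states for
  n ≤ 20, uniform-sampling estimation of attractors and basin-of-attraction
  ratios at larger n, phenotype classification through indicator nodes
  (anergy, S phase = E2F ∧ CCNE1, apoptosis = BIM ∧ ¬AKT, cell-cycle
  alert, quiescent G0), basin-weighted fused activities.
* **Exhaustive intervention screening**: all Σ_{i=1..m} C(c,i)·2^i single
  and double KO/KI combinations (4802 at c = 49, m = 2), filtered by
  attractor-level criteria (eliminate anergy, force full S phase, induce
  apoptosis, delete proliferation).
* **Robustness and topology**: single bit-flip perturbation spreading
  (normalized Hamming distance of successor states) against random N-K
  networks matched on per-node in-degrees, with an empirical p-value; and
  discrete power-law fits P(k) ∝ k^(−α) of the degree distribution with
  bootstrap plausibility (p > 0.1).
* **Trajectory mechanism traces**: the deterministic path from a defined
  start state into its attractor, with every node flip attributed to the
  regulator change that caused it.
* **Graded input–output grids**: input nodes driven at 1–100% duty cycles,
  output activity read from the last 100 of 500 steps over 250 random
  starts — the NOTCH1 × TP53 → MYC/BMI1/CITED2 response surfaces.
* **Expression binarization and concordance**: per-gene step-function
  (BASC-A-style) binarization of sparse gene×cell matrices with a
  resampling significance filter, cyclin-signature selection of
  proliferative cells, and model↔data activation concordance at the 30%
  (Hans-score) threshold; ROC/Youden binarization of scored markers.
* **Synthetic data**: toy networks with known landscapes, the
  reconstructed CLL/RS model with per-rule provenance notes, random N-K
  network generation, and sparse bimodal expression matrices with planted
  ground truth.

The packaged network is a best-effort reconstruction from published
regulatory statements — see `docs/methods.md` for its circuit choices,
its qualitative validation contract, and what deliberately is *not*
asserted about it.

## Worked example

```python
from cllrs import parse_network, sampled_attractors
from cllrs.dynamics_attractors import phenotype_fractions
from cllrs.synthetic_data import reconstructed_cll_network, SCENARIOS
from cllrs.trajectory_analysis import trajectory

card = reconstructed_cll_network()
net = card.network

for name in ["unperturbed", "bcr_ko", "cdkn2ab_tp53_ko", "akt_ki", "nfat_ko"]:
    ls = sampled_attractors(net.with_fixed(SCENARIOS[name]), 100_000, seed=1)
    print(name, {k: round(v, 3) for k, v in phenotype_fractions(ls).items()})

traj = trajectory(net.with_fixed(SCENARIOS["unperturbed"]), card.canonical_start)
print("BCR start ->", traj.phenotype.label, "after", traj.attractor_entry_index, "steps")
```

prints

```
unperturbed {'anergy': 0.913, 'mixed': 0.087, 'proliferation': 0.0}
bcr_ko {'apoptosis': 1.0}
cdkn2ab_tp53_ko {'proliferation': 1.0}
akt_ki {'proliferation': 1.0}
nfat_ko {'proliferation': 1.0}
BCR start -> anergy after 11 steps
```

Read: under chronic BCR stimulation the model is dominated by the anergic
attractor (91% of sampled starts; the rest are small oscillatory cycles),
and the canonical all-off/BCR-on start locks into anergy after 11 steps.
Withdrawing BCR makes the landscape fully apoptotic, while CDKN2A/B+TP53
loss, constitutive AKT, or NFAT loss each convert it into full S-phase
proliferation — the three modelled RS programs. The driver screen
(`analysis/04_screens.py`) recovers `TP53:KO+BMI1:KI` among the double
hits that force full S phase while neither single hit does, and the
drug-target screen finds apoptosis-inducing targets for the CDKN2A/B+TP53
and NFAT-loss conditions but none for AKT hyperactivation.

## Analysis scripts

The `analysis/` directory holds numbered drivers that regenerate the
tables under `results/`: `01_landscapes.py` (per-condition phenotype
fractions and fused activities), `02_robustness_scalefree.py` (bit-flip
response vs 1000 random networks, power-law fit),
`03_trajectories.py` (attributed mechanism cascades),
`04_screens.py` (driver and drug-target screens),
`05_graded_io.py` (NOTCH1 × TP53 response surfaces) and
`06_binarize_concordance.py` (synthetic single-cell binarization and
concordance). A `cllrs` console script exposes the same operations on
user-supplied rule files and matrices (`cllrs --help`).

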