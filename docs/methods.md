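# Methods

## ADMET screening model

The screen consumes signed class probabilities, the output convention
of admetSAR-style binary classifiers: the sign encodes the predicted
class (absorbable vs not, CYP inhibitor vs not) and the magnitude the
confidence, so every value lies in [−1, 1].

Two rules are applied in order:

1. **Absorption.** Keep a compound iff HIA > 0 and Caco-2 > 0. The
   boundary is strict: a probability of exactly 0 is not a positive
   prediction and fails the filter.
2. **Metabolism.** The composite score is the dot product of the five
   signed CYP inhibition values with the per-isoform overall predictive
   accuracies Q = (0.8147, 0.8018, 0.8551, 0.8054, 0.6450). The weights
   are applied positionally to the CYP columns in the order 1A2, 2C9,
   2D6, 2C19, 3A4 — the column order of the bundled candidate table.
   This positional mapping reproduces every published score in that
   table to eight decimals, which is how it was validated. Compounds
   with score ≤ 0 are discarded (strict floor, configurable).

Discarding on the *composite* score rather than on any single negative
CYP entry is a deliberate choice: most bundled candidates carry one or
two negative CYP entries yet have clearly positive composite scores, so
per-entry discarding would be inconsistent with the candidate set the
screen is meant to produce. Scores are stored at full float precision;
reports print 8 decimals.

Ranking is stable descending by score with lexicographic tie-breaks on
compound id, so equal-scoring flavone isomers (Diosmetin, Chrysoeriol,
Kaempferide) appear in a reproducible order.

## Network model

The cC-cT network is a simple undirected bipartite graph. Compound and
target ids must be disjoint sets; duplicate edges collapse to one with
a recorded count (interaction databases frequently list the same pair
twice). Degree is the only centrality computed; hub extraction uses an
inclusive threshold (degree ≥ 10). Percentages (e.g. hubs as a share of
all targets) are kept at full precision internally — rounding is a
presentation concern.

The target-disease network has three roles (target, disease, disease
group); only target-disease and disease-group edges exist, and a
disease may carry several MeSH-style group codes (a leukemia is both a
neoplasm, C04, and a hemic/lymphatic disease, C15). Strict mode rejects
diseases without a group code; lenient mode files them under
`unclassified`.

Subnetwork extraction by compound family keeps all target nodes by
default (`keep_isolated_targets=True`), so an 11-compound subnetwork of
a 118×141 network has 11 + 141 = 152 nodes; dropping isolated targets
is available for layout-oriented exports.

**Serialization.** GraphML (via networkx) carries roles, degrees and
annotations with full fidelity and round-trips exactly. SIF is
Cytoscape-oriented: edges are `source  ct|td|dg  target` lines and
isolated nodes are single-token lines, which by format cannot carry a
role; the SIF reader therefore assigns isolated nodes a configurable
role (default `target`, the only role that is ever isolated in these
pipelines). Use GraphML when lossless round-tripping matters.

## Bioassay analysis

**Inhibition rate.** `100 · (A_control − A_treated) / A_control` on
490 nm absorbances, computed from replicate means (per-replicate rates
are exposed for dispersion reporting). Negative rates mean growth
promotion and are preserved.

**Dose-response fit.** Responses (% inhibition, all replicates at all
positive doses) are fitted to the 4-parameter log-logistic curve by
least squares in log-dose space (`scipy.optimize.curve_fit`). The fit
is multi-started: the IC50 is seeded at the geometric mean dose and at
both ends of the dose range, with hill slopes ±1, 0.5 and 2; the
lowest-RSS solution wins. Asymptotes are normalized so bottom ≤ top
(swapping asymptotes and negating the slope leaves the curve
unchanged, which also makes the fit agree between inhibition data and
the equivalent viability data 100 − y). `converged=False` is returned
for constant responses, optimizer failure, or an IC50 pinned at the
log-dose bounds (non-identifiable). Parameter-recovery testing on the
synthetic generator — rather than reproduction of a specific published
IC50 — is the accuracy contract, since raw plate readings are not
published.

**qPCR.** 2^−ΔΔCt with ΔΔCt = (Ct_gene,g − Ct_ref,g) −
(Ct_gene,ctrl − Ct_ref,ctrl) on replicate-mean Cts; GAPDH is the
default endogenous control. The statistic is invariant to any constant
Ct shift (plate offset).

**Flow cytometry.** Events are gated by two fixed channel thresholds;
an intensity exactly equal to a gate counts as *negative* — an
arbitrary but fixed convention chosen for bit-reproducibility.
Quadrants follow the Annexin V-FITC (channel 1) / PI (channel 2)
convention: Q1 = A+/PI+ late apoptotic, Q2 = A−/PI+ necrotic, Q3 =
A−/PI− viable, Q4 = A+/PI− early apoptotic. `apoptotic_fraction`
exposes both `early` (Q4) and `total` (Q1 + Q4), since published
"apoptosis %" bars may pool either way.

**JC-1.** No standard numeric gate exists for the aggregate→monomer
shift, so the depolarized fraction is defined as the share of events
whose aggregate:monomer intensity ratio falls strictly below a
configurable threshold (default 1.0). Events with zero monomer signal
are excluded and counted.

**Trend test.** The dose-dependence statistic is the Spearman rank
correlation between dose and response over all replicate wells, with a
two-sided permutation p-value (responses permuted, seeded generator,
default 10,000 permutations). The add-one convention
`p = (1 + #{|ρ*| ≥ |ρ|}) / (1 + B)` makes the test exactly valid under
exchangeability: at B = 999 the rejection rate at α = 0.05 is exactly
5% for continuous responses. Welch's t (no multiplicity correction) is
provided as a presentation-level group-comparison utility.

## Synthetic data generators

All generators hang off one `SimulationConfig`; every generator draws
from its own substream of the config seed, so outputs are bit-identical
across runs and independent of call order, and every planted truth is
returned alongside the dataset.

Defaults are the study-scale conditions the pipeline targets: a
981-compound library of which exactly 121 pass (the pass set is
*planted*, not merely expected, so count assertions are deterministic);
a 118-compound × 141-target network with 46 hub targets of degree
10–30 against a 0–3 background (the gap guarantees exact hub
recovery); MTT doses 0.5–128 µg/mL plus control with a true IC50 of
13.61 µg/mL, hill 1.5 and 3-percentage-point Gaussian noise at 3
replicates; Bcl-2-family fold changes Bad 2.5, Bax 1.5, Bcl-2 0.7,
Bcl-xL 0.4 (pro-apoptotic up, anti-apoptotic down; magnitudes are
realistic choices, not published values) with 0.1-cycle Ct noise; a
(0.05, 0.03, 0.80, 0.12) quadrant mixture; and a 30% depolarized JC-1
component.

Plate noise is added on the inhibition scale to treated wells only;
control wells read exactly the nominal absorbance. This makes the
noiseless generator⊸analyzer composition the exact identity (the
inhibition profile reproduces the 4PL curve to 1e−12), which the tests
rely on. Flow intensities are drawn from log-normal components strictly
on the correct side of each gate — any gate-respecting family would do;
log-normal mimics cytometer channel statistics.

What the generators do *not* emulate: real classifier error structure
(ADMET values are independent uniforms), biological edge correlation
(targets draw compounds independently), absorbance heteroscedasticity,
qPCR efficiency ≠ 2, and flow spillover/compensation. Passing recovery
tests therefore demonstrates correctness of the *analysis code* under
its stated model, not robustness to real-instrument artifacts.

## Pipeline and formats

Stages (screen → network → diseasemap → doseresponse → qpcr → flow) are
driven by a YAML-loadable `PipelineConfig`; CLI flags override file
values. The summary report contains no timestamps and is a pure
function of inputs + config (verified byte-identical across runs);
wall-clock logging goes to a separate ISO-8601 log file. Tables are
CSV/TSV with strict header validation, delimiter inferred from the
extension; the Unicode minus (U+2212, common in copy-pasted tables) is
normalized on read; floats are written with `repr` and parsed with
Python's correctly-rounded `float`, so table round-trips are exact.

## Problem sizes used in the test suite

The suite exercises the study-scale defaults where they are cheap
(981-compound screens, 118×141 networks, 10,000-event flow samples) and
down-scales only iteration counts chosen for statistical, not
computational, reasons: 200 noisy plates for IC50 recovery (median
error < 10% at 3-point noise), 500 null datasets at 999 permutations
for the trend-test calibration, 10 seeds for hub recovery. The whole
suite runs in well under a minute on one core.

## Known limitations

- The screen's score floor reproduces the bundled candidate set, but
  the exact rule that produced that published set is not stated
  anywhere; the floor is configurable precisely because it is a
  modeling choice.
- SIF cannot round-trip roles of isolated nodes (see above).
- The 4PL fit assumes homoscedastic Gaussian response noise; no
  weighting or robust loss is offered.
- JC-1 gating is ratio-based only; quadrant-style JC-1 gating is not
  implemented.
- No SMILES-level chemistry: compound ids are opaque strings, and no
  ADMET prediction is performed — classifier outputs are inputs.
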