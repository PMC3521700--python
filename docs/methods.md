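# Methods

## Assay model

The screen's readout is flow cytometry of a destabilised-GFP reporter of the
naive pluripotent state. Each well holds one siRNA knockdown; at harvest each
cell is either still GFP-high (naive) or has converted to GFP-low
(differentiating). The pipeline models the *per-well conversion fraction* and
nothing mechanistic below it: the simulator is phenomenological, with no
kinetic or transcriptional model of the reporter locus.

A well's events are drawn i.i.d.:

* **GFP intensity** — a two-component log-normal mixture. An event belongs to
  the low component with probability
  `p_low = logistic(logit(b) + s + δ + ε)`, where `b` is the arm's baseline
  conversion fraction, `s` the planted per-gene logit shift, `δ` a per-plate
  effect, and `ε` a per-well effect. Components default to log₁₀ medians 2.0
  (low) and 3.3 (high) with log₁₀ SD 0.25 — a 1.3-decade separation typical
  of a bright reporter; the components overlap by < 1%.
* **Viability dye** — log-normal, median ~200 for live events and ~5000 for
  dead ones; dead flag ~ Bernoulli(0.05).
* **Scatter** — truncated Gaussians (FSC 50 000 ± 8 000, SSC 30 000 ± 6 000,
  arbitrary units); the scatter channels carry no signal and exist to
  exercise the gating path.

### Screen arms

| arm | inhibitors present | harvest (h) | baseline `b` |
|---|---|---|---|
| primary −2i | none | 28 | 0.50 |
| validation (rex1 reporter) −2i | none | 28 | 0.50 |
| validation (oct4 reporter) −2i | none | 72 | 0.50 |
| counter +2i | MEKi + GSK3i | 28 | 0.05 |
| 1i −MEKi | GSK3i | 28 | 0.35 |
| 1i −GSKi | MEKi | 28 | 0.35 |

The −2i baselines are 0.5 because the assay is harvested when control wells
sit at a high/low ratio of 1 — that timing *is* the anchoring condition of
the screen. The 1i arms convert more slowly (one pathway still inhibited),
hence 0.35 at the same harvest time. The +2i counter arm barely converts;
0.05 rather than ~0 keeps the conversion observable at 10,000 events so that
reporter-stabilising artifacts remain detectable under median anchoring (see
*Numerical choices*).

### Planted effect classes

Effects are absolute logit displacements applied in the arms where the class
acts (negative = delayed GFP loss):

| class | fraction | magnitude | acts in |
|---|---|---|---|
| null | remainder (~90%) | 0 | — |
| delay_exit | 1% | 1.9 | any inhibitor withdrawn |
| accelerate_exit | 0.5% | 1.2 (positive) | any inhibitor withdrawn |
| proteasome_artifact | 5% | 1.0 (1.5 in +2i) | every arm |
| erk_specific | 0.75% | 1.6 | MEKi withdrawn |
| gsk_specific | 0.75% | 1.6 | GSK3i withdrawn |
| shared | 0.75% | 1.6 | any inhibitor withdrawn |
| both_required | 0.75% | 1.6 | both withdrawn |

The mix mirrors a genome-wide screen in which a few percent of genes are
true positives. The artifact class is strongest in +2i because
reporter-protein stabilisation is unopposed when no differentiation
programme runs. On the primary screen's linear-ratio scale these planted
hits themselves inflate the plate SD, so magnitudes were chosen such that a
delay-of-exit gene still displaces the well statistic by ≥ 4 plate SDs under
the full mix (asserted by a test). The built-in positive controls carry
gsk3b → GSK3-pathway and fgf4 → ERK-pathway effects of magnitude 2.0 (FGF4
being the autocrine driver of ERK signalling in this system).

Noise defaults: plate effect SD 0.15 logit (the "slight variations in the
timing of pluripotency loss" that motivate plate-wise normalization),
per-well effect SD 0.10 logit (transfection/seeding variability), defective
well rate 1% (defective wells emit 100–800 events). None of these values is
reported by the assay literature at event level; they were fixed once at
values giving realistic plate CVs and are stated here rather than inferred.

### Randomness

Every well draws from `SeedSequence(seed, spawn_key=(arm, replicate, plate,
well))`, so any well is reproducible in isolation and iteration order is
irrelevant. The defect flag and event count are the first draws of the well's
substream. Identical seeds give bit-identical datasets.

## Analysis procedure

1. **Gating.** Scatter gate = central 5–95% quantile box per channel
   (computed on the well's own events; absolute bounds can override), then
   viability ≤ 1000 (dye-positive events are dead). Gating is applied once;
   re-gating a gated table is the identity.
2. **Anchoring.** Per plate (and arm, and replicate), the GFP threshold is
   the *median of the pooled gated NT-control events*. This realises the
   documented 50/50 control split exactly: the pooled control ratio is 1 to
   within one event by construction. At least 100 pooled control events are
   required.
3. **Well statistic.** `ratio = (n_high + ½)/(n_low + ½)` with events equal
   to the threshold counted low (deterministic tie-break, conservative
   toward GFP-high calls); `log2_ratio = log₂(ratio)`. Wells with fewer than
   1000 gated events (10% of the target event count) are defective.
4. **Scoring.** Primary screen: `z = (ratio − mean)/sd` against all
   non-defective sample wells of the plate, linear scale, sample SD (n−1).
   Validation/counter/1i screens: log₂ scale against the arm's NT control
   wells pooled across all plates and replicates. Arm-wide pooling (rather
   than per plate pair) gives the control SD hundreds of degrees of freedom;
   with only the 16 NT wells of one plate pair the null scores are
   noticeably t-inflated and the +2i counter screen false-positives several
   percent of true-null genes. Plate-to-plate timing variation is already
   absorbed by step 2. A residual bias is inherent to control-anchored
   designs: the NT wells both set the plate threshold and serve as the score
   reference, so their post-anchoring spread slightly understates sample-well
   noise and null replicate-average scores have SD modestly above the nominal
   1/√2. Against the permissive 1.25 SD counter rule this removes a few
   percent of true-null genes — the same tolerance the screen design itself
   accepts when eliminating artifacts.
5. **Decision cascades.** All thresholds are inclusive (≥) and configurable;
   defaults: primary 2 / 1.5 / 2.5 / 1.9 (rules R2/R3/R4, R1 = lone
   replicate at 2), validation 1.25 with 0.8/1.0 rescue (V1/V2), counter
   1.25, 1i 1.5. The label R3 is recorded before R2 when both fire; the
   decision itself equals the OR of the rules (tested). Down-direction
   (accelerated exit) hits mirror the primary cascade on negated scores.
   The V2 rescue is a pure score rule — it does not require the gene to be
   positive in either screen first.
6. **Stratification.** Gene symbols are lower-cased and deduplicated.
   `retained = validated \ artifacts`; the partition is ERK only = M\G,
   GSK only = G\M, ERK/GSK = M∩G, ERK and GSK = retained\(M∪G), where M and
   G are the 1i-positive sets (subsets of retained by contract).
7. **Readouts.** qPCR values are divided by the arithmetic mean of the three
   reference genes (geometric mean available), and panels rescaled so their
   maximum is exactly 100. Effect calls are `value ≥ mean ± k·SD` of the
   negative controls, with defaults k = 2 (qPCR markers), 1.5 (pERK/ERK),
   2 (Ras activity). "Reduced" pERK/Ras calls use the below-control
   direction: the assay figures describe the threshold line as above the
   control mean but mark genes falling *below* it; detecting reduced
   activation requires a below-mean cut, so that is the implemented
   direction, with k configurable. Point of action: reduced ERK activation ⇒
   upstream of ERK; among those, reduced Ras activity ⇒ upstream of Ras,
   otherwise between Ras and ERK; Ras is only assayed for ERK-upstream
   genes. Kinetics: a knockdown series is *delayed* if its argmax falls at a
   later sampled time than the control's and *reduced* if its peak is more
   than 10% (configurable) below the control peak; the opposite
   (Dusp-depletion-like) phenotype is annotated as premature/elevated with
   both main flags false.

## What the simulator does and does not show

Passing recovery tests show that the decision cascades, normalization and
set algebra implement the published procedure correctly and recover planted
effects of the configured size under realistic plate structure. They do not
validate biological effect sizes, siRNA off-target structure, spectral
spillover/compensation, doublets, or cell-cycle/size covariation of GFP —
none of which the simulator models. The +2i counter arm under median
anchoring compresses effect sizes strongly (the threshold falls inside the
GFP-high component); detection there leans on the large planted artifact
shift, which is the regime the counter screen is designed for.

## Problem sizes

The bundled recovery benchmark uses 50 plates (4,300 genes) × 2 replicates ×
4 arms at 10,000 events/well; unit tests use one to six plates with reduced
event counts. The acceptance script runs six plates (516 genes) across all
six arms. These sizes give per-class planted-gene counts large enough for
stable rate estimates while keeping a full run in the minutes range on one
CPU.

## Known limitations

* Plates whose sample-well count drops below 3 (a nearly empty final plate)
  cannot be scored in the primary screen, which normalizes per plate;
  screens should fill their last plate or drop it.
* FCS support is a minimal list-mode float32 reader/writer (FCS 3.0/3.1,
  single dataset); compensation matrices and analysis segments are ignored.
* The validation rescue rule and counter-screen threshold follow the
  documented readings noted above; both are single-line config overrides if
  a different reading is wanted.
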