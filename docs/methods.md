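# Methods

## Budding-pattern model

A daughter cell's budding behaviour is summarised by the polar angles of its
first two or three bud sites, measured from the mother–daughter junction
axis: 0° is the junction pole, 180° the opposite pole.  An angle below the
equatorial threshold (default 90°) is called adjacent (`A`), otherwise
opposite (`O`); the tie at exactly the threshold goes to `O`, which is the
conservative choice toward the filamentous call (both the threshold and the
rule are configurable, since manual scoring never defines the boundary
quantitatively).  A sequence of all-`A` calls is axial, all-`O` unipolar,
anything mixed bipolar — exhaustive and mutually exclusive over all 4
two-site and 8 three-site sequences.  The daughter's first bud is scored
like any later bud, relative to the junction.

Proportions are tallied per (condition, window, bud-site depth).  Replicates
are pooled before testing; the scoring aggregates cells across replicate
wells and the per-window totals (hundreds of cells) are what the exact test
consumes.  An empty group (e.g. no three-site cells in the last window,
which the generator reproduces with `frac_three_sites = 0`) is reported with
zero counts and no percentages.

## Fisher exact test

Window-to-window changes are tested per pattern on the 2×2 table
{pattern count, all-other count} × {window a, window b} — the only table
construction consistent with per-pattern significance calls.  The two-sided
p-value sums, over the hypergeometric distribution with the observed margins,
all table probabilities not exceeding the observed table's probability; a
relative tolerance of 1e-7 absorbs floating-point ties.  The p-value is
invariant under row and column swaps and equals an exact rational-arithmetic
enumeration (verified in the test suite against `Fraction`/`math.comb` and
`scipy.stats.fisher_exact`).  Comparisons are made between *consecutive*
windows only, at a per-comparison alpha of 0.05 with no multiplicity
correction by default (a Bonferroni flag divides alpha by the number of
consecutive comparisons for users who want it).  Only *increases* in the
unipolar proportion count as transitions.

## Local cell density and the critical window

Immobilised cells experience the density of the monolayer slab at the well
bottom: `V_bottom = bottom_area × cell_diameter` with units fixed internally
(cm², µm → cm, ml ≡ cm³), giving `local CD = measured CD × V_sample /
V_bottom`.  Defaults (3.85 cm², 10 µm, 1 ml) give V_bottom = 3.85·10⁻³ cm³
and a ≈259.74× amplification.  Growth summaries are replicate means with
sample (n−1) standard deviations; a single replicate yields a mean only.

The *critical window* is the window of the first significant unipolar
increase: for a transition from window i to window i+1, the mean local
densities at the boundary times of window i+1 bracket the switch.  When
several transitions exist the earliest is primary and the rest are carried
as secondary.  Two-site tallies drive the transition search in the pipeline,
because three-site cells can be unobservable in late windows while two-site
scoring remains complete.  Note one internal tension in the source data this
mirrors: an inoculation density of 2×10⁴ cells/ml maps to 5.19×10⁶ cells/ml
under the formula, slightly above the quoted 4.8×10⁶ lower bracket; the
conversion here is kept exact.

## NMR quantification

Absolute concentrations come from `C(X) = Area(X)/Area(Ref) ×
H(Ref)·C(Ref)/H(X)` with TSP as reference (9 equivalent protons).  Proton
counts per metabolite are registry data supplied by configuration, not
hard-coded chemistry — which signal was integrated per compound is a data
property.  Calibration is two-step: per raw-media sample, the known glucose
concentration yields `C(TSP) = C(glc)·Area(TSP)·H(glc)/(Area(glc)·H(TSP))`;
the arithmetic mean over raw-media samples is then used for all culture
samples.  This construction makes the raw-media glucose round trip an exact
identity, and at zero noise the full simulate→calibrate→quantify loop
returns every true concentration to < 1e-9 relative error (a suite
invariant).  Quantification happens per sample, then means ± SD are taken
over biological replicates (SD requires at least two).

Candidate switch metabolites are those not present as raw-media nutrients
whose mean concentration at the critical-window end strictly exceeds the
baseline (earliest-time) mean; an optional fold threshold tightens the
strict inequality.  Physiological ranges are the mean concentrations at the
two window boundaries.  Between-condition differences are reported as
signed percent changes relative to the reference condition, rounded
half-away-from-zero to integers for reporting (full precision internally);
dose comparisons as fold differences.  The published 20 h concentration
pairs used by the worked comparison are stored in `reference.py`; the
printed within-window ranges are sorted min–max brackets, and for tyrosol
and fumarate under high nitrogen the 20 h value is the lower endpoint — the
reading consistent with the reported 63% and 73% decreases.  The
2-oxoglutarate decrease (−79%) is not exactly recoverable from the printed
endpoints (−78.49% from 9.3 → 2.0 µM) and presumably reflects unrounded
table values; it is excluded from the recomputed set.  Both baselines for
the exogenous 2-phenylethanol comparison are exposed: the critical-window
maximum (1.5 µM, giving the 13× fold) and the 30 h maximum (4.3 µM, giving
4.7×).

## Quorum-sensing checklist

Six boolean criteria in two tiers: four for an intercellular signalling
molecule (extracellular and identified; specific signalling mechanism;
response reproducible at physiological concentrations; adaptive at the
community level) and two more for a quorum-sensing molecule (concentration
proportional to cell density; critical threshold trigger).  Verdicts are
pure conjunctions, so quorum sensing implies signalling and turning any
criterion from false to true can never flip a verdict from true to false
(property-tested over all 64 combinations).  The evidence values are
scientific judgements supplied as input — the package deliberately does not
automate them; the bundled 2-phenylethanol evidence encodes the study's
checklist (fails reproducibility and threshold).

## Synthetic-data generator

The generator emulates the *outputs* of the measurement chain, not the
measurements: no images, no spectra.

* **Bud records.**  Each cell draws a latent program from a per-window
  (axial, bipolar, unipolar) simplex; a whole-sequence mixture was chosen
  over per-bud independence because classification operates on whole
  sequences.  Axial targets 0°, unipolar 180°; bipolar targets the opposite
  pole with probability 0.7 for the first bud (the documented opposite-pole
  bias of newborn daughters) and 0.5 for later buds.  Angles get Gaussian
  noise (default sd 20°) clipped to [0°, 180°].  The default weights back
  out the observed two-site unipolar percentages 72% → 91% through the
  bipolar all-opposite probability 0.35 (w_uni = (obs − 0.35)/0.65); the
  third window keeps the second window's mixture and has no three-site
  cells.  250 cells per window mirrors the >200-cell scoring depth.  The
  angle distributions and bias magnitudes are modelling choices, not
  measured values — no quantitative angle distribution exists to fit.
* **Growth.**  Noise-free density is exponential from 10³ cells/ml with the
  doubling time (default 2.6 h, chosen so the local density passes ≈5×10⁷
  cells/ml at 20 h, the observed order of magnitude); after 20 h the rate is
  multiplied by (1 − decline), default decline 1.25 → a slight density
  decrease, matching the qualitative post-20 h decline whose functional form
  is not documented.  Counts carry unit-mean lognormal noise, default
  CV 0.10 (typical hemocytometer variability).
* **Peak areas.**  `area = k · C_true · H · noise` with one global
  instrument factor per simulation and lognormal noise (default CV 0.05).
  Producers follow geometric (log-linear) trajectories between their
  endpoint concentrations — constant fold-change per window, the natural
  shape for exponential-phase fermentation products — with defaults placed
  so the 10 h/20 h values land on the published low-nitrogen ranges
  (e.g. ethanol 369/5403 µM); nutrients decay linearly.  Every sample
  includes TSP; raw-media samples carry glucose at the known concentration.
* **Ground truth** is closed-form (no sampling): pattern probabilities use
  the per-bud mis-call probability eps = P(|noise| > 90°) = Φ̄(90/sd), exact
  under clipping because clipping never moves an angle across the threshold.

Determinism: three independent child streams (buds/growth/areas) are spawned
from the seed, so identical config + seed reproduces byte-identical tables,
and report JSON/Markdown are byte-identical too — provenance embeds the
config hash and seed, and a timestamp only when explicitly supplied.

What the generator does **not** emulate: scoring ambiguity and observer
error, cell-cycle correlation between consecutive buds, replicate-level
batch effects in budding behaviour, spectral overlap/baseline artefacts in
the areas, and density-dependent metabolite feedback.  Passing recovery
tests therefore demonstrates the correctness of the analysis chain under
its own statistical assumptions, not the fidelity of those assumptions to
microscopy or NMR data.

## Problem sizes and numerical choices

The default study (3 windows × 250 cells, 3 replicates, 7 metabolites) runs
in well under a second; recovery tests use 500 cells/window at zero noise
and a 3-binomial-SE band; the Fisher property suite checks ≥ 500 random
tables with totals ≤ 60 plus hypothesis-driven tables against exact
arithmetic.  Degenerate inputs are explicit errors (all-zero Fisher tables,
missing TSP areas named by sample, missing density times named by time,
windows of zero length) rather than NaNs.  Scientifically empty outcomes —
"no switch detected", an empty candidate list — are successful runs with
explicit null sections in the report.

## Known limitations

* Evidence flags for the checklist are inputs; the package computes verdicts,
  never the underlying scientific judgements.
* The pipeline assumes the window structure is shared between the budding
  and density tables (boundary times must match exactly).
* No growth-model fitting, lineage reconstruction, >3-site sequences,
  spectral processing or metabolite identification — all upstream or out of
  scope of the analysis chain.
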