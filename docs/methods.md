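# Methods

This note documents the models, statistical procedures and design choices
behind `abca1func`, the conventions fixed where the underlying study design
left them open, and what the synthetic-data tests do and do not demonstrate.

## Cholesterol-efflux statistic

For one well-set the efflux fraction is

    e = mean(medium) / (mean(medium) + mean(lysate))

over the triplicate BODIPY fluorescence signals. Two background corrections
are applied in sequence:

1. **acceptor-nonspecific leakage** — subtract the no-acceptor well-set of
   the same construct, experiment and treatment;
2. **transporter-nonspecific efflux** — subtract the corrected efflux of the
   mock-transfected construct of the same experiment.

The resulting *specific efflux* is normalized to the same experiment's WT
and expressed as a percentage; replicate experiments (four by default) are
summarized as mean ± sample SD.

**Aggregation order** (a genuine open choice): triplicate signals are
averaged within a well-set, efflux is computed per experiment, normalized to
that experiment's WT, and only then averaged across experiments. The
alternative — pooling means before normalization — is not used; the
per-experiment choice makes the statistic exactly invariant to uniform
rescaling of all signals within an experiment (plate-reader gain,
exposure), which the tests verify.

Corrected and specific efflux may be negative and are *not* clamped, so
mock-level constructs scatter symmetrically around zero. Experiments whose
WT specific efflux is non-positive are dropped from normalization with a
warning; if none survive, the run fails rather than report a meaningless
percentage.

## Functional categories

With the calibrated thresholds (percent of WT):

* `loss_of_function` — mean relative efflux **< 41** (the activity of the
  p.W590S loss-of-function control);
* `normal` — mean **> 80** (between the two high-frequency anchor variants
  p.I883M, 84 %, and p.V2244I, 75 %);
* `uncertain` — the closed interval [41, 80]; both boundaries inclusive,
  because the outer categories are defined by strict inequalities.

An alternative loss-of-function cutoff of **58 %** (the highest efflux
observed among Tangier-disease-associated variants, p.R2080Q) can be
enabled; the boundary value 58 itself stays uncertain under the same
strict-inequality convention.

All thresholds live in `CalibrationConfig` (JSON-serializable); nothing is
hard-coded in the analysis logic.

## Hypothesis testing

Every comparison uses a two-sample t-test gated by an F-test for equality
of variances: if the two-tailed F-test rejects at `variance_test_alpha`
(0.05 — the gate level is a package choice, fixed here), the Welch statistic
is used, otherwise the pooled-variance statistic. The t statistics are
computed from the textbook formulas with `scipy.stats` distributions
supplying p-values, so `scipy.stats.ttest_ind` remains available as an
independent oracle in the tests. Degenerate zero-variance groups (e.g. a
normalized reference that is exactly 100 in every experiment) are handled
explicitly: equal constants give p = 1 (two-sided) or 0.5 (one-sided);
a zero-variance group against a varying one falls through to the Welch
branch, which then reduces to a one-sample test.

Efflux p-values versus WT are computed on the per-experiment *specific
efflux* values (not the normalized percentages, whose WT reference is a
constant). No multiple-testing correction is applied, matching the study
design; p-values are reported as-is.

## Cell-surface quantification

Per experiment, *raw* surface level is `surface / loading` relative to WT's
same ratio (×100); *total-corrected* surface level is `surface / total`
relative to WT (×100). Total ABCA1 serves as its own denominator in the
corrected readout, so the loading control cancels and is not reapplied.

Mechanism call (one-sided "less than WT" tests at alpha 0.05 on the
per-experiment band ratios):

* corrected significantly below WT → `transport_deficient`;
* only raw significantly below WT → `degradation_prone`;
* otherwise `unaffected`.

"Reduced" had no stated statistical criterion in the study; the one-sided
gated t-test is this package's operationalization. The published 50 % figure
is kept as a *severity flag* on the mechanism's relevant percentage
(corrected for transport deficiency, raw otherwise), not as the
significance rule.

## Chaperone rescue and the ATPase-deficiency flag

Both treatment arms (mock, 10 mM 4-PBA — dose and time are metadata, not
model inputs) are normalized to the mock-treated WT per experiment (five
experiments by default). A variant is *rescued* when the one-tailed gated
t-test shows a significant efflux increase under 4-PBA. The
ATPase-deficiency flag fires iff the variant is **not** rescued, its
surface level **does** increase significantly (one-tailed, alpha 0.05)
under 4-PBA, and it sits in an ATP-binding motif (Walker A, Walker B or the
signature motif). No "extreme reduction" efflux cutoff is hard-coded into
the flag: the descriptive ≤ 10 % phrasing in the source material is not a
defined rule, so the flag relies on the three defined conditions only.

## ACMG/AMP engine

Criteria carry a code (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7) and a
strength (stand-alone, very strong, strong, moderate, supporting), which
may be overridden per token (`PM1_supporting`, `PP4_strong`,
`BS3_moderate`). Gene-specific calibrations:

* frequency: BA1 at FAF ≥ 0.005, BS1 at ≥ 0.002, PM2 at ≤ 0.0002;
* phenotype PP4: supporting < 0.5, moderate < 0.3, strong < 0.1 mmol/l
  HDL-C or Tangier disease (strictest satisfied tier wins);
* functional assay: PS3 (loss-of-function) / BS3 (normal) at the strength
  permitted by the validation rule — moderate when the assay has normal and
  null controls, replicates, and ≥ 11 variant controls of class 1/2/4/5;
  supporting otherwise. A benign criterion at moderate strength counts as
  **two supporting** benign criteria; this conversion is applied to any
  benign code given moderate strength. Pathogenic moderate stays moderate.

The combining tables are the standard ones (pathogenic: 1 VS + {1 S | 2 M |
1 M + 1 P | 2 P}, ≥ 2 S, 1 S + {3 M | 2 M + 2 P | 1 M + 4 P}; likely
pathogenic: 1 VS + 1 M, 1 S + 1–2 M, 1 S + ≥ 2 P, ≥ 3 M, 2 M + ≥ 2 P,
1 M + ≥ 4 P; benign: BA1 alone or ≥ 2 benign strong; likely benign:
1 strong + 1 supporting or ≥ 2 supporting). Two very-strong criteria are
also treated as pathogenic. Duplicate criterion codes are rejected;
derived (frequency/phenotype) criteria are skipped when the same code is
already asserted.

**Conflict semantics.** Evidence pointing both ways resolves to class 3.
This package deliberately applies the strict reading of "contradictory": a
met benign combination with *any* pathogenic criterion present (or a met
pathogenic combination with any benign criterion) yields class 3, with BA1
remaining stand-alone. The permissive reading — conflict only when both
sides' combining rules are met — would let every rare, functionally normal
class-3 variant drop to likely benign the moment BS3 at moderate strength
(= two supporting benign criteria) is added, regardless of coexisting PM2
or PP3 evidence, which contradicts the observed behaviour of the
reclassification this package reproduces (twelve changes among 74 variants,
not thirty-five). The strict reading reproduces it exactly and is the
defensible clinical position: unexplained pathogenic evidence should block
an automatic benign call.

## NBD equivalence mapping

The two nucleotide-binding domains are aligned with a deterministic global
(Needleman–Wunsch) pairwise alignment — BLOSUM62, gap open −10, gap extend
−0.5 (EMBOSS-style defaults; all in config) — over the inclusive
full-protein windows 923–1121 (NBD1) and 1936–2134 (NBD2). Matched columns
become position pairs; a variant mirrors into the opposite domain only when
its aligned column is conserved (identical residues). *Identity* is
identical columns over alignment columns and *similarity* is
positively-scoring columns over alignment columns, gaps counted in both
denominators — fixed here because "similarity" is otherwise tool-dependent.
The published inter-domain similarity figure (39 %) is treated as a
method-dependent regression anchor, not an exact target.

The reference protein sequence is not shipped: tests run on a **synthetic**
reference (`simulate.synthetic_reference_protein`) — a random protein of the
correct length whose NBD2 window is a diverged copy of its NBD1 window,
constructed with one deletion and one insertion so that the alignment
reproduces the five published monotone-consistent equivalent pairs
(939↔1952, 1034↔2046, 1064↔2076, 1093↔2106, 1107↔2120) with the wild-type
residues planted at those positions. Any user-provided FASTA (e.g. the real
NM_005502.4 product) can be substituted via `abca1 nbd-map --fasta`. The
published pairing of positions 948 and 1916 cannot coexist with 939↔1952 in
any monotone alignment (the pairs cross, and 1916 lies outside the NBD2
window), so it is excluded from the recovery set.

## Synthetic-data generator

See the `simulate` module docstring for the full plate model. Key
parameters and defaults: four experiments (five for rescue), triplicate
wells, WT efflux fraction 0.30, leakage 0.05, mock fraction 0.02 (the raw
fractions are fixture choices — no published values exist), per-well
multiplicative log-normal sigma 0.10, per-well-set total-signal jitter
sigma 0.20, signal scale 10⁴ a.u. Acceptor-well fractions are
parameterized as

    f = leakage + mock + (activity/100) · (wt_efflux − leakage − mock)

so that the pipeline's two subtractions and WT normalization invert the
model *exactly* at zero noise — the package's central self-consistency
invariant.

What the generator does **not** emulate: plate spatial/edge effects,
instrument drift, saturation, non-multiplicative noise, correlated
replicate errors, transfection-efficiency variation, and any biology
linking efflux to surface levels (the two truths are set independently).
Passing recovery tests therefore demonstrate that the *estimator inverts
its own generative model* under realistic noise magnitudes — not that the
assay itself is unbiased on real plates.

Problem sizes used in the test suite: panels of 3–9 constructs × 4–5
experiments, and 200 seeded replications for the category-recovery and
calibration checks, which keeps the whole suite in the seconds range.

## Study-scale fixture

The per-variant study tables (74 variants with replicate efflux values and
asserted criteria) are not deposited in any machine-readable archive, so
`studydata.py` ships a **synthetic stand-in** constrained to reproduce every
value the study's main text prints: the named variants and their quoted
means ± SD, the 15/35/24 category split, the seven uncertain variants at or
below 58 %, the twelve reclassification-table rows and their criteria,
58 of 74 variants in class 3 before functional evidence and twelve class
changes after it. Unnamed rows are invented filler at plausible
intracellular positions; replicate values are expanded deterministically
from each mean ± SD with exact sample moments. Tests against this fixture
verify the *pipeline logic*, not the wet-lab measurements.

## Numerical conventions

* Sample SDs use ddof = 1 throughout; a single surviving experiment reports
  SD 0 and no p-value.
* Region/motif residue ranges are inclusive, 1-based. Positions outside
  every listed region map to `linker/other`; extracellular/transmembrane
  ranges are deliberately not encoded (they were never printed).
* The R-domain crossover/crossback latch ranges overlap the R-domain ranges
  and are therefore stored as non-partitioning "features", outside the
  region partition and the motif containment invariant.
* Missing values in all TSV interchange are `"."`; tables are UTF-8 with
  fixed headers.
* All generators use NumPy's PCG64 (`default_rng`) with explicit integer
  seeds; fixed seed implies bit-identical output.

## Known limitations

* The ACMG engine evaluates criteria it is given (plus the frequency and
  phenotype rules); it does not derive PVS1/PP3/BP4-style computational or
  transcript evidence, determine PM3 phase, or query population databases.
* Only the simple `p.<ref><pos><alt>` missense subset of protein HGVS is
  parsed; no genome coordinates, no c.↔p. mapping, no stop/frameshift.
* The surface mechanism call is binary per readout and inherits the usual
  small-n t-test caveats at n = 4.
* PP4 is applied per variant, not per carrier; with multiple carriers the
  strictest phenotype would dominate.
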