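# Methods

This note documents the models implemented in `orthoexpress`, the defaults
and unit conventions, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Ortholog classification

Homology pairs form a bipartite graph with species-tagged nodes (identifiers
are opaque, case-sensitive strings; the same string on both sides denotes
two different genes).  Ortholog groups are connected components; the
relationship class is a pure function of the component cardinalities
(1–1 → one-to-one; exactly one side > 1 → one-to-many; both > 1 →
many-to-many).  When a source `homology_label` disagrees with the derived
class, a warning is logged and the derived class wins: the component
structure is reproducible from the data, annotations are not.

High confidence is (GOC ≥ 75 or WGA ≥ 75) and percent identity ≥ 50, all
thresholds inclusive and configurable.  Absent scores fail their clause
rather than erroring, because real Biomart exports contain blanks.  Biomart
exports identities in both directions; the reader maps exactly one
configured column (default query→target) so the choice is explicit.

Redundancy collapse returns each gene of the selected species once across
all groups; because groups partition genes this is a flatten-and-sort, and
it is what makes the mouse ortholog list shorter than the zebrafish one.
Percentages of a protein-coding total are computed at full precision and
rounded half-to-even only for report output.

## Presence calls and the paralog-aware Venn partition

A gene is present when RPKM ≥ 0.1 and detection FDR ≤ 0.10 (both inclusive;
the detection FDR is consumed as a given column, never recomputed).  The
strict `> 10.0` RPKM filter used for highly-expressed-intersection tables is
deliberately exclusive at the boundary, unlike the presence cutoff, because
that is how such tables are conventionally captioned.

Group presence in a cell type is any-member over the genes of the species
measured in that cell type (an all-member variant is exposed as a flag for
sensitivity analysis).  Each group present anywhere is assigned to exactly
one Venn cell — the exact subset of cell types where it is present.  A
cell's paralog increment sums, over its groups and over the
duplicated-species cell types it contains, the expressed duplicated-species
members beyond the first.  Totals per cell type count genes on the
duplicated side (group + extra paralogs) and groups on the collapsed side.
With a single integer increment per cell the per-cell-type partition-sum
identity is exact when exactly one Venn cell type belongs to the duplicated
species, which is the intended design (zHC against IHC and OHC); with
several duplicated-species cell types in one partition the per-type totals
are still computed correctly from member counts, but the per-cell increment
is then a sum over those types.

Unique-expression tables treat a gene unmeasured in a reference cell type as
background (≤ 0.10 RPKM) there.  Top-N ranking breaks RPKM ties
lexicographically by gene identifier so output is deterministic.

## Differential expression

The two-group test is a deliberately transparent negative-binomial Wald
test, labelled "NB Wald stand-in (not DESeq2)" in every output: the
scientific content downstream is the fold-change/FDR thresholds and set
logic, and a small auditable test is preferable to a silent approximation of
a large package.  Per gene, with size-factor-normalized counts (DESeq-style
median-of-ratios, configurable):

* dispersion φ by method of moments from per-group residuals,
  φ = Σ(v_g − m_g)/Σ m_g², floored at 10⁻⁸;
* because the per-gene estimate is noisy at n = 5, φ is additionally floored
  at the cross-gene median of the residual estimates.  This one-sided
  moderation only raises under-estimates (which would otherwise shrink
  standard errors and inflate the type-I error to roughly twice nominal);
  over-estimates are kept and are merely conservative.  With it the null
  rejection rate at α = 0.05 sits near 0.045 at n = 5 vs 5 and dispersion
  0.1, and planted 4-fold effects are recovered with recall ≈ 0.99 — both
  checked in the test suite;
* Wald statistic on the natural-log fold change through pseudocounted means
  (pseudocount 0.5), model-based group-mean variance (m + φm²)/n, two-sided
  p from the normal reference;
* all-zero genes are flagged untestable (estimate 0, p = 1) and excluded
  from the BH denominator.

No dispersion shrinkage across the mean trend, no outlier replacement, no
independent filtering, no fold-change shrinkage, two groups only.  Volcano
summaries default to |log2FC| > 1 with adjusted p < 0.05; the FDR ≤ 0.10
variant used for ranked upregulated tables is a parameter, not a different
code path.

## Enrichment

One-sided over-representation only: p = P(overlap ≥ k) from the
hypergeometric distribution with the universe size, set size and query size
as margins, BH across sets.  The universe is always explicit input — the
recommended choice is the orthologs measured in the relevant cell types, not
the whole genome, to avoid expression-detection bias.  Sets are intersected
with the universe on construction; query genes outside the universe are
dropped with a logged count.

## Electromotility and NLC

Models as in the README.  Unit conventions: V in mV, α in mV⁻¹, Qmax in fC,
capacitance in pF — fC/mV = pF, so no hidden conversion factors.  Some
instruments print the voltage sensitivity as a slope factor in mV (1/α);
`alpha_from_slope_factor` converts explicitly, and nothing converts
silently.  The bell is evaluated as Qmax·α/4·sech²(α(V−V½)/2), which is
symmetric, peaks at Qmax·α/4 + Clin, integrates to Qmax, and does not
overflow for extreme arguments.

Fitting uses bounded trust-region least squares (qmax, clin ≥ 0, α > 0)
with tolerances 10⁻¹⁴, initialized from the trace: Clin ← minimum, V½ ←
voltage at maximum, α₀ = 2/span, Qmax₀ = 4(peak − Clin)/α₀.  Standard
errors come from the Gauss–Newton covariance (JᵀJ)⁻¹·s².  Non-convergence
is reported in flags, never silently defaulted.  A fit whose bell height
Qmax·α/4 does not exceed 3× the residual SD is flagged flat; the motility
fit flags non-motile analogously on Lmax.  Fits require ≥ 8 points spanning
≥ 60 mV.

Dual-sine estimation: stimulus frequencies default to 390.625 and 781.25 Hz
(the 100 kHz/256 and /128 bins conventionally printed as 390.6/781.2) so an
integer number of periods of both fits a power-of-two record; misaligned
frequencies raise an error telling the caller to adjust the record length.
The DFT of current and voltage at exactly the two stimulus bins gives
Y(f) = I(f)/V(f); with Z = 1/Y and W(Rs) = 1/(Z − Rs) = 1/Rm + jωCm, the
real parts of W at the two frequencies must agree, pinning Rs by a Brent
root solve on [−0.01·min Re Z, min Re Z) (the slightly negative lower edge
lets a true Rs of exactly zero bracket; the solution is clamped at zero);
Rm and Cm then follow in closed form and the two Cm estimates are averaged.
Admittances closer than a tolerance (a pure resistor) are flagged
ill-conditioned rather than solved.  Series-resistance voltage error is
corrected off-line as V_command − I·Rs.  The circuit is the minimal
three-element patch model with pipette capacitance assumed neutralized.

Voltage-dependence classification is a nested-model F-test (constant vs the
4-parameter NLC model, F with (3, n−4) degrees of freedom) combined with a
practical-significance guard: the sweep is voltage-dependent only if
p < 0.05 and the bell height exceeds 3× the residual SD.  The guard keeps
tiny but statistically detectable ripples — common in long, quiet sweeps —
from being called NLC.

## Synthetic data

One root seed feeds hierarchically spawned streams (homology, expression,
counts, recording), so adding a generator never perturbs the others, and
identical seed + configuration reproduces outputs exactly.  Truth is always
emitted next to the data.

Defaults emulate the magnitudes of the study being modeled: 13,500 ortholog
components with duplicate retention 0.27 and mouse-side duplication 0.018
(giving a class mix like the published classification table), orphan rates 0.30/0.39, high-confidence
rate 0.33; presence-pattern frequencies over {zHC, IHC, OHC} taken from the
published Venn cell counts, independent zSC presence 0.55, paralog
co-expression 0.14; present-gene RPKM is 0.1 + lognormal(μ=1.5, σ=1.5)
(median ≈ 4.6 RPKM) so planted presence is never destroyed by sampling,
absent-gene RPKM is uniform below the cutoff; counts are gamma–Poisson with
dispersion 0.1 at 20 counts per RPKM unit, 5 replicates per group, size
factors uniform in [0.7, 1.3], and 100 DE genes planted at |log2FC| = 2 on
genes with base mean ≥ 20 (effects planted on undetectable genes would test
nothing).  Recordings default to the published OHC parameter set
(Qmax 1,135 fC, slope factor 27 mV, V½ −54 mV, Clin 7.9 pF) with 0.05 pF
noise on a −120…+60 mV staircase in 4 mV steps.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no shared-mean/dispersion trends or gene-length
and GC biases in counts; RPKM and counts are drawn, not computed from
reads; the expression table and the count matrix are internally consistent
only through the zHC means (the planted DE effect exists in counts, not in
the zSC RPKM column); homology scores are class-conditional draws, not
alignment outputs; recordings have white Gaussian noise, no drift, seal
instability or series-resistance change.  Results on synthetic data
demonstrate correctness of the set algebra, estimators and classifiers
under the stated model, not robustness to everything real instruments and
pipelines produce.

## Problem sizes

Default test and example problem sizes — 600–2,000 ancestral genes for
pipeline runs, 10,000 for the classifier-recovery check, 2,000 genes for
the null-calibration run, 10×10×10 circuit grids and 100-draw fit
round-trips — were chosen as the smallest sizes at which the statistical
checks have comfortable margins (binomial 3σ windows, Monte-Carlo SEs well
below the tolerances they support).

## Known limitations

* Two-group designs only; no batch covariates.
* The Venn per-cell paralog increment is a single integer (see above).
* The enrichment stage does not fetch GO/KEGG databases; users supply GMT.
* The dual-sine estimator assumes steady state within each staircase step
  and bin-aligned stimulus frequencies.
* Cross-species RPKM magnitudes are deliberately incomparable; no operation
  computes a cross-species expression ratio.
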