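# Methods

## Blood acid-base calculus

All formula constants are defined at 37 °C plasma: CO2 solubility
S = 0.0307 mmol·L⁻¹·mmHg⁻¹, carbonic-acid pK1′ = 6.12, and a lumped
non-volatile weak-acid pKa = 7.06. The strong-ion block treats every symbol
as a charge concentration in mEq/L: monovalent ions pass through unchanged,
ionized calcium is weighted ×2, and *total* magnesium ×1.38 (a divalent
cation assumed 69% dissociated — total Mg is what the serum panel measures,
not the ionized fraction). Albumin and total protein enter in g/L; their
buffer totals are the linear bovine calibrations Atot(Alb) = 0.76·Alb and
Atot(Prt) = 0.36·TP.

The pH used in every dissociation and charge formula is the analyzer pH at
37 °C. Temperature-corrected pH/pCO2 (−0.0147 pH per °C; pCO2 ×
10^(0.019·ΔT)) are reported alongside for clinical reading but are never fed
back into the charge formulas, whose calibrations hold at 37 °C.

Field analyzers compute base excess in firmware with undisclosed constants;
this package pins the published Siggaard-Andersen Van Slyke form

    BE = (1 − 0.0143·ctHb)·(cHCO3 − 24.4 + (1.63·ctHb + 9.5)·(pH − 7.40))

with ctHb in g/dL, and models extracellular fluid by attenuating hemoglobin
to ctHb/3. Standard bicarbonate re-equilibrates the sample to pCO2 =
40 mmHg along the buffer line implied by the same constants (base excess
held fixed), solved by damped Newton iteration on the equilibrated pH; the
residual is smooth and strictly increasing, and the solution matches an
independent bracketing root-finder to < 1e-6 in the tests. Consequences of
pinning one Van Slyke form: BE and standard-bicarbonate values can differ
from analyzer printouts by a few tenths of a mmol/L, which is why
classification always uses internally derived intervals (below).

Hematocrit is accepted as an optional input; when absent it falls back to
ctHb/33 g/dL (the MCHC convention), since analyzer hematocrit is itself
firmware-derived.

The unmeasured-anion residual XA is literal electroneutrality bookkeeping:
measured cation charge minus chloride, bicarbonate and the three weak-acid
charges. Under this sign convention a *larger* XA means *more* unmeasured
anions; the formula is implemented exactly as stated, with no silent
negation. Note that XA is algebraically determined by AG, Ca, Mg and the
weak-acid charges (the SID terms cancel), so XA, SIG, AG and Atot cannot be
set independently of one another — relevant to the synthetic design below.

## Urine

Only the numeric outputs of the two-stage titration are modeled: base
excess cBE, acid excess cAE and ammonium cAmm, all mmol/L (NABE's units
follow the titrimetric method). NABE = cBE − (cAE + cAmm); BAR =
cBE/(cAE + cAmm). A zero denominator raises an error rather than returning
infinity: the titration protocol always consumes lye, so a zero records a
data problem, not a physiological state.

## Reference intervals and qualitative calls

Within-study reference intervals are the 25th–75th percentiles of a
designated metabolically unremarkable reference cluster, with numpy's
linear interpolation between order statistics as the pinned quantile
convention. Classification of a value against an interval is inclusive at
the bounds; a call becomes *marked* (double arrow) when the value lies
beyond a bound by more than `marked_margin` × interval width. The margin
defaults to 0.5 and is configurable — the double-arrow notation has no
published numeric definition, so the threshold is an explicit package
choice. One-sided literature bounds (e.g. NEFA < 0.62 mmol/L) are
represented with infinite widths and are never marked.

The strong-ion interpreter maps call patterns to labels: SID below/above →
SID-acidosis/-alkalosis; either Atot above/below → Atot-acidosis/-alkalosis;
XA above or SIG below → increased unmeasured anions; the mirror pattern →
increased unmeasured cations. Combinations are preserved (mixed disorders),
and an unremarkable profile returns "none".

## Clustering pipeline

Candidate segmentation variables are visited in physiological priority
order; a variable is kept only while its absolute Pearson correlation with
every already-kept variable is below 0.75 and the cap of one variable per
ten observations is not exhausted. Retained columns are z-scored with the
sample (n−1) standard deviation. Agglomeration is Ward's minimum-variance
method in the Ward.D2 dialect (Euclidean input distances,
Lance–Williams update) via scipy; the test suite checks it against a
brute-force exhaustive merge-cost search for small n. The cluster number
maximizes the mean silhouette width over a candidate range (ties to the
smaller k). This mechanizes only the internal-validity criterion;
judging the interpretability of competing partitions remains a human step
and is out of automated scope.

Per-cluster profiles report median/Q1/Q3 for every numeric variable;
heatmap-ready scaled medians are (cluster median − overall median)/overall
IQR, with zero-IQR variables flagged as NaN rather than raising. Rows with
missing segmentation values are dropped with a logged count.

## Synthetic cohort design

The generator emulates a 145-cow transition-period cohort in seven
physiological states (sizes 19/37/27/44/5/10/3): salt-loaded fresh cows with
mild acidosis; a metabolically unremarkable reference state; hypoalbuminemic
post-calving cows with acid urine; the modal fresh-cow state with reduced
feed intake and renal acid excretion; a small ketoacidotic group; alkaline
high-lactating cows on rumen buffer; and a tiny group with massive
lipomobilization.

Each state is a prototype of *primitive measured* quantities obtained by
inverting the acid-base formulas: albumin and total protein from the buffer
totals, chloride from the SID target, bicarbonate from SID_m3 − AG and pCO2
from Henderson–Hasselbalch, urine titration components from the BAR target
and a chosen total acid excretion. The reference state sits at the
mid-reference values; other states are displaced by the qualitative
deviation pattern (single arrow = one interval width beyond the bound,
double = two widths, parenthesized = half a width from center, still
inside). Because XA, SIG, AG and Atot are algebraically coupled, not every
tabulated arrow can be realized simultaneously; prototypes prioritize the
segmentation variables plus AG, and the frozen pattern test asserts exactly
the designed directions. Within the normal venous pH band the acid-loaded
states sit at the lower edge and the alkali-loaded state at the upper edge.

Noise is Gaussian on primitives only — sd = `noise_sd` × the
between-prototype standard deviation of each variable, floored by a
per-variable baseline representing assay precision plus within-state
biological variation (large for NEFA, albumin and globulin, which are
genuinely the noisiest panels in fresh cows; small for pH, whose analyzer
precision is ~0.005) — truncated to physiologic bounds. All derived
variables are recomputed forward, so every record satisfies the acid-base
identities exactly. The default `noise_sd` is 0.2. The ground-truth state
is kept in a simulation-only column.

What the emulation does *not* model: real measurement-error correlation
structure (noise is independent per primitive), farm random effects beyond
a cosmetic farm label, γ-globulin as a separate fraction (total globulin
stands in — one consequence is that the albumin/globulin ratio is
correlated > 0.75 with Atot(Alb) in the synthetic data and is removed by
the correlation filter, leaving 10 of the 11 default segmentation
variables), and the absolute level of XA in real cattle (an electroneutral
synthetic panel centered on the reference mid-values implies XA ≈ 3 mEq/L;
classification is unaffected because intervals are internally derived).
Passing the recovery tests therefore demonstrates that the pipeline is
correct and sensitive under the designed separations, not that real herds
separate this cleanly.

## Problem sizes and numerical choices

The invariant suites run on 10,000 random panels; Ward oracle equivalence
on 200 random matrices with n ≤ 7; recovery on the 145-animal default
cohort with k scanned over 2–12. The standard-bicarbonate Newton iteration
runs 60 damped steps from pH 7.40 (far more than needed for double
precision). Quantiles, correlations and silhouettes use numpy/pandas/
scikit-learn defaults as pinned above. Ties in the silhouette criterion
break toward smaller k; ties in Ward merge costs are measure-zero for
continuous data and resolved by scipy's internal ordering.

## Known limitations

- Base excess and standard bicarbonate use one published Van Slyke form;
  analyzer firmware may differ slightly.
- The respiratory component of acid-base status is deliberately not
  evaluated (venous samples cannot support it); no oxygen-status variables.
- The strong-ion interpreter emits label sets, not the clinical narrative;
  interpretability of cluster partitions is not automated.
- Reference intervals from a 37-animal cluster are IQRs, not 95% reference
  ranges; they are within-study values, not population norms.
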