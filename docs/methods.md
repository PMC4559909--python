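# Methods

This note documents the models and procedures implemented in `vegfsema`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design was
genuinely open.

## Gene panel and data model

The curated panel holds 39 genes: the five VEGF ligands (VEGFA, VEGFB,
VEGFC, FIGF/VEGFD, PGF/PlGF), the three receptor tyrosine kinases (FLT1,
KDR, FLT4), both neuropilins, the seven class-3 semaphorins (SEMA3A–G), the
class 4–7 semaphorins, and the plexin A–D receptors. Gene identity is by
HGNC-style symbol; the aliases VEGFD and PLGF are normalised to FIGF and
PGF on input. Expression is log₂ throughout; per-sample metadata carries
dataset, tissue type (normal / primary / metastatic), optional patient id,
and optional BCR event/time annotations (years). Missing values in panel
genes are an input error rather than being imputed — every downstream stage
assumes complete panels. Normal-mean centering subtracts each gene's mean
over the normal-tissue samples, so centred values read as log₂ fold change
against normal; the operation is idempotent and leaves between-sample
differences untouched.

## Synthetic cohort generator

Samples are drawn as

x<sub>ig</sub> = baseline<sub>g</sub> + shift<sub>g</sub>(tissue<sub>i</sub>) + u<sub>p(i),g</sub> + ε<sub>ig</sub>

with Gaussian noise ε (default s.d. 0.5 log₂ units, microarray-like) and,
for metastases, a per-patient random effect u drawn once per patient per
gene (default s.d. 0.8, making patients separable while individual genes
remain noisy). The default effect table plants the direction structure the
analyses look for: VEGFA, VEGFB, VEGFC and SEMA3A–E down one log₂ unit in
primary tumours; in metastases VEGFA up (+1), NRP1/PLXNA1/PLXNA3 up (+1),
KDR/NRP2 down (−1), SEMA3A/B/D/E down (−1.25) and SEMA3C down further
(−1.75). Only directions are constrained by the biology being emulated;
the magnitudes are free parameters chosen once so that planted effects are
detectable at the cohort sizes used (the metastatic semaphorin magnitudes
in particular leave a ~12% margin between the primary and metastatic total
Sema3 output, so the group ordering of the simulated ternary is resolvable
at n = 27).

Three canonical cohorts are provided: a simulation cohort of 12 normal /
49 primary / 27 metastatic samples; a multi-metastasis cohort of 21 normals
plus 18 metastases taken as 4/4/4/3/3 from five patients; and a larger
BCR cohort (50 normals, 250 primaries) for outcome modelling. BCR outcomes
are exponential event times with log-linear hazard h = h₀·exp(score),
where the score is a centred linear combination of the signature genes
FIGF, NRP2, VEGFC and KDR (default weight 1.5 each, h₀ = 0.03/yr), and
censoring is uniform over a 10-year horizon (~20% events). The event count
is what powers signature recovery: at the 10–27 events typical of the real
BCR datasets, no method can reliably rank four planted genes above 35 null
genes, so the BCR cohort is deliberately sized like the RNA-Seq cohorts the
outcome analyses are designed for rather than like the smallest published
ones. All draws come from one `numpy.random.Generator`; a fixed seed
reproduces every cohort exactly, and multi-dataset simulation adds
dataset-specific per-gene baseline offsets (s.d. 0.5) to emulate platform
differences.

What the generator does *not* emulate: probe-level artifacts, mRNA
degradation, batch effects, multifocality, or any correlation structure
among genes beyond the planted shifts and patient effects. Passing tests
therefore demonstrate that the estimators recover the structure they are
designed for at realistic sizes and noise levels — not that real cohorts
contain that structure.

## Differential expression and recurrence

Per-gene two-group comparisons use Welch's unequal-variance *t*-test with
Welch–Satterthwaite degrees of freedom (a pooled-variance variant is
available by flag); the degenerate both-groups-constant, equal-means case
returns t = 0, p = 1. Benjamini–Hochberg adjustment is applied across the
39 panel genes within each comparison (not across datasets — the
alternative pooling is a one-line config change but is not the default
because each dataset is an independent experiment). A gene is flagged
recurrently up/down when significant (q < 0.05) in that direction in at
least two datasets and significant in no other dataset in either direction.
Distribution summaries use a Gaussian KDE with Silverman bandwidth and
type-7 (linear interpolation) quantiles; the convention matters for
box-plot statistics and is therefore pinned by test.

## PLS-DA

`PLSDAClassifier` fits NIPALS PLS1 components to a ±1 class code: per
component w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X is
deflated by t pᵀ. Predictions use the rebuilt regression vector
B = W(PᵀW)⁻¹q and classify by sign relative to the midpoint of the class
mean predictions. Columns are centred and, by default, autoscaled to unit
variance (a constant gene column then raises, naming the gene). Two latent
variables are the default, matching the usual scores/loadings plane.
"Training accuracy ± s.d." is realised as 100 random stratified 70/30
splits with accuracy measured on the training portion; held-out accuracy is
reported alongside, and LOOCV supplies the ROC (threshold sweep over the
held-out predictions) with AUC computed by the Mann–Whitney rank formula.
Outcome cohorts are balanced before fitting: all n events plus exactly the
n non-events with the longest follow-up (short-follow-up negatives may
simply not have recurred yet); ties at the cutoff break by sample id.

## Survival

The Kaplan–Meier estimator uses the events-before-censorings convention at
tied times. The log-rank statistic is the usual (O−E)²/V with
hypergeometric variance per event time, referred to χ²₁. Cox models
maximise the Breslow-ties partial likelihood by Newton–Raphson with
step-halving (the log-likelihood trace is non-decreasing by construction;
Efron weighting available by flag); standard errors come from the inverse
observed information, and the score test at β = 0 is exposed separately —
for one binary covariate without ties it coincides with the log-rank χ²,
which the tests exploit as an oracle. Stratification for the survival
comparison uses the PLS-DA decision threshold (predicted class), not a
median score split, because the class is what the signature claims to
carry; the score-sign alternative is one flag away.

## Consensus clustering

K-means is Lloyd's algorithm from k-means++ seeds, best of `restarts` runs
by within-cluster sum of squares; an emptied cluster is reseeded from the
point farthest from its assigned centre. The consensus matrix over 500
resamples at 80% subsampling records co-clustering frequency conditioned on
co-sampling (never co-sampled pairs are undefined and excluded). K is
chosen from 2–8 by minimising PAC, the fraction of off-diagonal consensus
entries in (0.1, 0.9); ties break toward smaller K, and a best PAC above
0.3 flags the selection as low-confidence (pure noise behaves this way).
Final labels come from full-data K-means at the chosen K, Hungarian-aligned
to an average-linkage cut of the consensus dissimilarity. The
cluster–patient association reports both the asymptotic Pearson χ² p-value
and a permutation p-value; the latter is the one to trust at these table
sizes. Note a genuine property of PAC: when cluster separations are very
unequal, merging at too-small K can be deterministic and PAC-clean, so K
selection is most reliable when candidate clusters are comparably spaced —
the situation the patient random effects create.

## Binding model

**Network.** Thirteen ligand species live in the interstitial fluid:
VEGF165 and VEGF121 (the two major VEGFA isoforms, default 50/50 split of
VEGFA production), VEGFB, VEGFC, VEGFD, PlGF, and SEMA3A–G. Endothelial and
tumour cells each carry VEGFR1/2/3, NRP1/2 and a lumped plexin-A. Binding
rules: VEGF165 → {R1, R2, NRP1, NRP2}; VEGF121 → {R1, R2}; PlGF and VEGFB →
{R1, NRP1}; VEGFC/D → {R2, R3, NRP2}; every Sema3 → {NRP1, NRP2}. The
VEGF165·VEGFR2·NRP1 ternary forms by two routes (NRP1 joining the
VEGF·VEGFR2 binary, or VEGFR2 joining the VEGF·NRP1 binary), and every
Sema3·NRP binary can couple with plexin-A into the anti-angiogenic ternary.
Because an NRP inside a Sema3 ternary is unavailable to VEGF and vice
versa, the two pathways compete for neuropilin. Ligands are secreted
(zeroth order, molecules/cell/s), receptors inserted likewise; every
surface species internalises at k_int = 2.8·10⁻⁴ s⁻¹ (~1 h residence) and
free ligand degrades at k_deg = 5·10⁻⁴ s⁻¹. Not modelled: proteolytic
processing of VEGFC/D and Sema3s, class 4–7 semaphorins, SEMA3E's
NRP-independent plexin-D1 route, intracellular signalling, and drug
pharmacokinetics.

**Units.** All species are held internally in pmol per litre of tissue.
Molar binding constants act on the interstitial-fluid concentration
(tissue concentration / fluid fraction φ = 0.3); per-cell surface rates
convert through the cell densities (tumour 2·10¹¹, endothelial 5·10⁹ cells
per litre tissue) and Avogadro's number. The conversions are centralised in
`CompiledNetwork._compile` and pinned by the closed-form receptor test
(free receptor = insertion/internalisation when no ligand is present).

**Parameters.** The kinetic defaults are literature-nominal VEGF-model
values: VEGFR1 affinity ~33 pM, VEGFR2 ~100 pM, VEGF165–NRP ~310 pM,
Sema3–NRP Kd 10 nM, with all pairs individually overridable. The second
route into the VEGF ternary is not free: its off-rate is derived from
thermodynamic cycle closure Kd(V·R2)·Kc(V·R2+N1) = Kd(V·N1)·Kc(V·N1+R2)
and asserted to 10⁻¹⁰ relative at network construction. Surface densities
put neuropilins (25,000/EC) far above the ligand-occupied pool, which is
what makes VEGF–Sema competition weak at physiological concentrations:
doubling all Sema3 secretion moves endothelial VEGFA·VEGFR2 binding by
under 1% while nearly doubling the Sema3 ternary itself. Tumour receptor
densities and the Sema3 kinetics were chosen (once, as model construction)
so that ligand clearance is not dominated by the per-sample-variable
tumour receptor pools; this keeps the model in the regime where receptor
binding tracks ligand expression, which is the regime the population
analyses probe.

**Per-sample scaling.** For sample s, tumour-cell production of the species
encoded by gene g is multiplied by 2^{x_{sg}} / mean_normals(2^{x_g});
plexin-A insertion uses the same ratio on the summed linear expression of
PLXNA1–4. Endothelial rates stay nominal — the expression data are bulk
and mostly tumour-cell derived, and deconvolution is out of scope. Factors
are clamped to [0.01, 100] against expression outliers.

**Steady state.** The stiff system (115 species, ~340 elementary
reactions) integrates with BDF and an analytic Jacobian from the
ligand-free receptor steady state, in doubling spans until the largest
relative rate of change falls below 10⁻⁶ per simulated hour (typically by
~10⁵ s); rtol 10⁻⁸, per-run absolute tolerance scaled to the receptor
pools. Negative excursions beyond −10⁻¹²·scale abort the run. An optional
cross-check re-solves rhs(x) = 0 with a log-abundance Powell hybrid root
solve started away from the ODE answer and requires agreement within 0.1%.
A full 88-sample population takes well under a minute on one CPU.

**Read-outs.** Aggregates per cell type: VEGFA·VEGFR2 (V165·R2 + V121·R2 +
the ternary), VEGFA·VEGFR1, and the summed Sema3·NRP·PlxnA ternaries.
Group comparisons run Welch tests on log₁₀ aggregates with the standard
*/**/*** annotation at 0.05/0.01/0.001. Variance-explained fits regress
log₁₀ aggregate on VEGFA expression and on log₂ summed linear SEMA3A–G
expression, direct and crossed. Quadrant labels use strict comparison
against the benign-group medians (accelerator ON iff above, brake OFF iff
below; exact ties take the non-extreme side).

## Pipeline

Stages run in dependency order from one config; each stage derives its own
seed from (global seed, stage name) via CRC32 mixing, so any stage is
independently reproducible, and the manifest records config, seed and
per-stage status. Stage failures are recorded and dependents skipped with a
nonzero exit code.

## Known limitations

* Effect magnitudes, hazard scale and kinetic defaults are package choices,
  not fitted quantities; conclusions about real cohorts require real data
  through the same interfaces (`read_expression_tsv` + metadata TSV).
* The lumped plexin-A species ignores differences among PLXNA1–4, and all
  seven Sema3s share default kinetics (overridable per pair).
* Cox fitting assumes proportional hazards and uses Breslow ties; heavy
  ties with Efron weighting are available but not default.
* Consensus clustering with strongly unequal cluster separations can prefer
  a smaller K (see above); the PAC window and K range are configurable.
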