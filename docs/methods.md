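# Methods

This note documents the models and procedures implemented in `paleodairy`,
the defaults chosen where the underlying study design left them open, and
what the synthetic-data tests do and do not demonstrate about real data.

## PSM validation

A peptide spectral match (PSM) is one MS/MS spectrum assigned to one
peptide with a search-engine expectation value and a target/decoy flag.
Acceptance applies two rules in a fixed order: first the e-value cut
(*e* < 0.01, strict), then the minimum-support rule (≥ 2 PSMs per protein
accession, with target and decoy accessions grouped separately, counted
after the e-value cut). Fixing this order matters: a protein with three
PSMs of which one fails the e-value cut keeps its two survivors, whereas
support counted before the cut would differ.

The false-discovery rate is the classical target–decoy estimator

    FDR% = 100 · n_decoy / (n_target − n_decoy)

computed at the PSM level (per match) and protein level (per distinct
accession). When targets do not outnumber decoys the estimator's
denominator is non-positive; we report the FDR as undefined and fail the
sample with reason `degenerate_fdr` rather than raising or clamping. All
threshold comparisons are strict ("under 5%", "under 2%", "below 0.01"):
a sample at protein FDR exactly 5.0% fails. Decoys are identified by the
`is_decoy` column, and additionally by the accession prefix `DECOY_`,
since search-engine export dialects differ.

## Preservation screening

Authentic ancient calculus is dominated by oral-microbiome and host
immune proteins; poorly preserved samples are dominated by handling and
laboratory contaminants. Each sample's validated protein accessions
(set semantics — an accession counts once) are matched against a
four-category oral-signature table, and

    authenticity% = 100 · (oral_bacteria + human_immune_oral) / (all four categories).

A sample passes when authenticity ≥ its period's floor. The Eneolithic
floor is 40%, lowered relative to the Bronze Age floor to allow for
longer diagenesis; the Bronze Age floor defaults to 50% — a configurable
default standing in for a previously published screening standard whose
value is project-specific. The boundary is inclusive (a floor, not a
strict bound). A protein matching multiple table rows is treated as an
input error rather than resolved by silent precedence. Samples with no
table match at all have undefined authenticity and fail with an explicit
reason. Excluded individuals remain listed in every report.

## Dairy assignment

The milk-protein reference set (BLG and the equid variants BLG-I/BLG-II,
αS1- and αS2-casein, α-lactalbumin) is digested in silico with trypsin:
cleavage after K or R except before P, up to 2 missed cleavages, minimum
peptide length 6. The missed-cleavage and length defaults follow common
tryptic-search practice and are configurable; digestion is delegated to
`pyteomics.parser.cleave` and cross-checked in the tests against an
independent scan-and-split implementation.

Every digested peptide is indexed to the exact set of (taxon, protein
family) pairs that could produce it, and an observed peptide is assigned
the **lowest common ancestor** of its taxon set on a small editable
taxonomy (Pecora ⊃ {Bovidae ⊃ {Bovinae ⊃ {Bos, Bubalus, Bison},
Caprinae ⊃ {Ovis, Capra}}, Cervidae ⊃ Cervus}; Equidae ⊃ Equus). A
singleton set returns the leaf. Reference accessions on a contaminant
exclusion list contribute nothing to the index — this handles deposited
bacterial sequences nearly identical to ruminant casein, which would
otherwise destroy the caseins' taxonomic specificity. Peptide matching is
exact string equality; isobaric I/L are *not* collapsed by default
(flag available) because taxon specificity can hinge on an I/L
difference. Possible deamidation sites are counted as N+Q residues — the
chemistry-capable positions — distinct from observed modifications; a
casein peptide with a single site offers little support for
authenticating antiquity.

The per-individual call is: **negative** with no milk peptides;
**equivocal** when only casein families are present (caseins preserve
poorly and rarely appear authentically on their own, so casein-only
evidence does not confirm dairy consumption); **positive** otherwise.
The equivocal family set is configurable. When a peptide maps across
families, its PSM is counted at the peptide's LCA (not the protein's
taxon) in the specificity histogram; the assignment records the PSM's
reported family when the index supports it.

## Diet mixing

The freshwater dietary protein fraction f of a consumer is estimated
from bone-collagen δ¹⁵N with a two-end-member Bayesian mixing model in
the FRUITS style:

    f ~ Uniform(0, 1)
    S_k = N(mean_k, sd_k) + N(o_ce)        k ∈ {terrestrial, freshwater}
    y   = f·S_fresh + (1−f)·S_terr + N(o_dc) + N(0, s_meas)

Defaults (all ‰): terrestrial 7.1 ± 2, freshwater 10.6 ± 1 (regional
bone-collagen reference values), collagen→edible offset −1.0 ± 0.5,
diet→consumer offset +5.5 ± 0.5 (conventional trophic values from the
mixing-model literature, configurable — not measured quantities),
measurement sd 0.2 (typical EA-IRMS precision). Because everything but f
is Gaussian, the nuisance terms marginalize analytically and the
posterior is evaluated exactly on a 2001-point f lattice; this grid is
the reference engine and is bit-reproducible. An emcee ensemble sampler
(16 walkers, 8000 steps, 2000 burn-in, vectorized likelihood) is provided
as an independent engine; it must agree with the grid to |Δmean| ≤ 0.02
and flags non-convergence at split-R̂ > 1.01. δ¹³C and >2-source
generality are deliberately out of scope.

With source spreads of 1–2‰ against a 3.5‰ signal span, a single δ¹⁵N
value is weakly informative: posteriors are wide and their means are
pulled toward 0.5. Point recovery of a known fraction is therefore
checked at the forward-model mean (a deterministic limit), while noisy
replicates are checked by interval coverage, which is the calibrated
property.

For curve mixing the posterior (mean, sd) of f is scaled ×100 and
rounded half-up to integers, the form the calibration stage and the
OxCal emitter consume; unrounded values are kept internally.

## Reservoir-corrected calibration

Consumers of freshwater protein ingest carbon that is already old, so
their collagen 14C ages are too old by a reservoir offset scaled by the
aquatic fraction of the diet. Calibration therefore mixes two curves:
the terrestrial curve, and a freshwater curve defined as the terrestrial
curve plus ΔR ~ Uniform(0, 1000) years; the mixing proportion
p (percent) ~ Normal(mean, sd) truncated and renormalized on [0, 100]
comes from the diet-mixing stage. Negative mixing is disallowed.

Everything is deterministic quadrature, chosen over MCMC for exact
reproducibility (OxCal's own sampler is not reproduced). Plain
calibration evaluates posterior(t) ∝ N(y; μ_curve(t), √(σ_date² +
σ_curve(t)²)) on a uniform calendar grid (default step 1 yr), with the
curve interpolated linearly in cal BP (no spline, keeping the test
oracle simple). Mixed calibration lays a lattice over (ΔR, p) — default
steps 10 yr and 1 percent, with a configuration error below 3 nodes per
non-degenerate dimension — shifts the effective curve mean by
(p/100)·ΔR (curve error unchanged), normalizes each node's posterior,
and averages them under the prior weights. Averaging normalized
per-node posteriors (rather than unnormalized likelihoods) weights every
(ΔR, p) hypothesis by its prior alone; with a flat calendar prior and
slowly varying curve error the two constructions are nearly identical,
and the degenerate limits (all mass at p = 0; fixed ΔR at p = 100) reduce
exactly to plain calibration, which the tests verify. Degenerate priors
(sd = 0, or ΔR_low = ΔR_high) collapse to single lattice nodes rather
than erroring.

Intervals are central 95% credible intervals by cumulative mass with
outward grid snap (the interval always contains ≥ 95%); HPD intervals
were considered and rejected as the default since reported ranges in
this field are quantile-style. cal BP converts to calendar years with no
year zero: year AD = 1950 − cal BP, and year BC = 1 − year AD (1950 cal
BP → 1 BC). The OxCal emitter writes the standard
Plot/Curve/Delta_R/Mix_Curves/R_Date block with ASCII quotes, one
Mix_Curves–R_Date pair per date named Date1, Date2, …, so models can be
re-run in OxCal itself. Mixing is applied per date; whether an external
chronological model should share one p draw across dates is a modelling
decision outside this package.

## Synthetic cohorts

The generator produces every pipeline input with recorded ground truth;
each generator is a pure function of (spec, seed), and identical seeds
yield byte-identical files.

* **Cohort design.** Three periods with 19/17/19 individuals, of whom
  11/16/19 pass preservation; dairy prevalence among preserved
  individuals 0 (plus one equivocal casein-only individual), 15/16 and
  15/19; two Early Bronze Age horse-milk consumers. Counts are exact by
  construction (prevalence × n, half-up); the seeded RNG decides only
  which individual carries which label.
* **PSM tables.** Target e-values ~ LogUniform(10⁻⁸, 10⁻³), decoys ~
  LogUniform(10⁻³, 1): the stated thresholds separate the populations
  cleanly but imperfectly, so occasional samples genuinely fail the FDR
  ceilings and exercise the exclusion path. In `noiseless` mode decoy
  e-values sit entirely above the e-value cut, every FDR is exactly 0,
  and the pipeline must recover the planned dairy calls exactly.
  Background proteins per sample are drawn uniformly from 25–196, with
  2–4 PSMs each; 40 of them are oral-signature accessions whose category
  split realizes a planned authenticity on the correct side of the
  period threshold.
* **Milk reference.** Sequences are concatenations of 9-residue tryptic
  blocks (no internal K/R/P, terminal K/R) shared at designed clade
  levels — a Pecora-wide BLG block, subfamily blocks, a Bovinae-wide
  αS1-casein block carrying exactly one possible deamidation site, and
  taxon-unique blocks — so every peptide's correct LCA is known by
  construction. Blocks are globally unique, and background peptides are
  drawn avoiding the milk set, so no accidental dairy matches occur. A
  casein-mimicking bacterial record shares the Bovinae block and is
  listed for exclusion; its taxon is deliberately absent from the
  taxonomy so that forgetting the exclusion fails loudly.
* **Isotopes and dates.** δ¹⁵N values are drawn from the mixing model's
  forward process at a known f (uniform unless overridden); 14C ages are
  the synthetic curve at a known calendar age plus f·ΔR_true
  (ΔR_true ~ U(0, 1000)) plus N(0, 20 yr) noise. The synthetic curve is
  14C = cal BP + 20·sin(2π·cal/500) with 10-yr errors — enough local
  structure for realistic multimodality without external data.

What passing on synthetic data does **not** show: real calculus
proteomes have correlated protein abundances, spectrum-level score
distributions, shared peptides beyond the designed blocks, and reference
databases with far more sequence redundancy than the block design; the
synthetic cohort validates the pipeline's logic and arithmetic, not
search-engine behaviour on real spectra.

## Summary bookkeeping

Cohort tallies are formatted as "k of n (p%)" with half-up integer
rounding. Note one consequence: 10 of 11 formats as 91%, since
100·10/11 = 90.9; publications occasionally print such tallies rounded
differently, and this package follows the arithmetic. Dairy rates are
computed over preserved individuals only; preservation rates over all
extracted individuals. Equivocal individuals count as non-positive.
Excluded individuals appear exactly once, with a machine-readable
reason.

## Problem sizes and tolerances

The test suite and acceptance script use a 55-individual cohort for
end-to-end checks, 100 random tables/profiles for the FDR and
authenticity oracles, 200 replicates for mixing-interval coverage
(tolerance 95% ± 5 points) and a 501-point grid inside the replicate
loop, 2001 points elsewhere; mixed-calibration property checks run on
coarsened lattices (ΔR step 25–50 yr, p step 2–5) whose refinement
changes 95% bounds by at most one coarse step. These sizes are the
package's own defaults for routine verification; all are configurable.

## Known limitations

* The packaged oral-signature and milk-reference tables are synthetic
  stand-ins; real analyses must supply curated tables in the same
  dialects.
* Single-proxy (δ¹⁵N) two-source mixing only; no δ¹³C, no >2 sources,
  no macronutrient routing.
* No OxCal phase/sequence modelling, marine reservoir curves or wiggle
  matching; per-date mixing only.
* Spectrum-level scoring, search-engine re-implementation and raw/mzML
  parsing are out of scope; the pipeline starts from exported PSM
  tables.
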