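# Methods note

This note documents the models, defaults and numerical choices behind
`cyanopept`, and what the synthetic-data tests do and do not demonstrate
about real data.

## The workflow being modelled

The package targets intracellular extracts of six cyanobacterial strains
grown in quadruplicate and analysed by positive-mode DDA LC-MS/MS on a
high-resolution instrument (survey scans 106.7–1600 *m/z*, top-5
fragmentation). Analysis runs in two branches over a shared feature table:
a statistics branch (intensity threshold 10⁶ counts) feeding PCA,
Kruskal–Wallis/BH significance and volcano-based labelling, and a
networking branch (threshold 10⁵) feeding a GNPS-style molecular network.
Spectrum classification by diagnostic product ions is deliberately
threshold-independent: it is the rescue path by which real but dim
congeners still get identified and counted.

## Deconvolution

* Windows: *m/z* 590–1210 and RT 2.2–5.6 min, both inclusive. The
  intensity criterion is the maximum area over non-blank samples; the
  threshold is applied before blank subtraction (the order in which the
  rules are stated).
* Blank rule: implemented literally as "multiply the sample area by 50 and
  drop it if it is still below the blank area". This direction makes the
  rule a *contamination* filter: trace carryover of genuine analytes into
  the blank (typically ≪ sample/50) never kills them, while blank-origin
  media features are wiped everywhere. The conventional direction
  (comparing against 50× the blank) is available via
  `blank_rule_direction="conventional"`.
* Redundancy collapse: co-elution tolerance 0.05 min and delta-match
  tolerance 5 mDa (neither is dictated by the workflow; both are typical
  for UHPLC peak widths and Orbitrap mass accuracy and are configurable).
  Linking is transitive (union-find), so a chain M, M+1.00336, M+21.9819
  collapses onto M. Isotopologue deltas are tried per charge up to 3+.
* Imputation: zeros become ⅔ × the feature's smallest nonzero area;
  all-zero features are a hard error because they carry no signal and
  would silently become constant rows.
* Scaling: log₁₀ then Pareto (centred values divided by √sd, sample sd
  with ddof 1, per feature across samples). Constant features map to zero
  rows rather than NaNs. Note the scaled output contains non-positive
  values, so the scaling step — unlike filtering, blank subtraction,
  collapse and imputation, which are idempotent — cannot be re-applied to
  its own output; its precondition (strictly positive areas) excludes it.

## Diagnostic classification

* The ion registry is *empirical by design*: it stores the printed
  reference *m/z* values for each diagnostic ion rather than recomputing
  them from formulas. Some entries differ from formula-derived masses by
  ~1 mDa, and the Val–Ahp pair is not the CH₂ homolog of the Lxx–Ahp pair;
  these are kept verbatim and flagged in the CSV, never "corrected".
* Matching is ppm-based (default 10 ppm) because the registry prints
  absolute masses with no tolerance and relative error is what an
  Orbitrap's calibration drift actually produces. Matching picks the most
  intense in-window peak; the matched-ion set is monotone in the
  tolerance.
* "Intense" for the anabaenopeptin lysine-related ion is operationalised
  as ≥ 0.2 × base peak (configurable; no number is given anywhere, and
  0.2 separates the rendered 0.5–1.0 signal band from noise comfortably).
* Cyanopeptolin subclasses require *both* members of a residue-3/Ahp ion
  pair; a single ion is insufficient.
* Group conflicts resolve by most matched required ions; ties set the
  ambiguous flag and fall back to alphabetical order so results are
  deterministic.
* Microviridins carry no fixed product ions; they are recognised by
  charge ≥ 2, neutral mass 1600–1900 Da and ≥ 2 matches in the standard
  20-residue immonium table (Leu/Ile share one entry, "Lxx"). Leucine and
  isoleucine are never resolved by mass: `annotate_lxx` collapses any such
  call to "Lxx".
* Chlorination: one ³⁷Cl raises M+2/M to ≈ 0.320, two to ≈ 0.639; the
  detector windows are [0.20, 0.45] → 1 Cl and [0.55, 0.85] → 2 Cl, wide
  enough to absorb the ¹³C₂ contribution of a mid-size peptide (≤ ~0.1)
  riding on top of the chlorine signal. MS2 evidence ions (Cl-shifted
  Hpla fragments) independently flag chlorination.
* Naming: `CP` + subclass letter (T/L/F/V) + ⌊neutral mass⌋ + elution
  letter, A being the earliest-eluting isobar. The namer enforces
  registration in elution order (the pipeline sorts by RT first) and
  injectivity within an experiment. The floor of the mass is used; for
  the worked example 702.3957 → 702, floor and round agree.

## Molecular networking

* Modified cosine: candidate fragment pairs match directly
  (|Δ*m/z*| ≤ 0.03) or shifted by the precursor *m/z* difference;
  intensities are √-scaled; a one-to-one matching is chosen greedily on
  descending intensity products (the GNPS-era convention, O(n log n)).
  The exhaustive maximum-matching oracle lives in the test suite only;
  on realistic small spectra the greedy matching reproduces it exactly,
  and scores agree with matchms's implementation.
* Consensus merging stands in for MSCluster, whose exact internals are
  not public: spectra within 0.02 Th precursor tolerance and cosine ≥ 0.7
  against the cluster representative merge (aligned peaks averaged);
  groups below the minimum cluster size (2) are dropped unless singletons
  are explicitly kept. Provenance is extract / seed / shared by member
  origin.
* Network pruning: edges need cosine ≥ 0.7 *and* ≥ 7 matched ions; mutual
  TopK (10) keeps an edge only when each endpoint ranks the other in its
  top K; oversized components (> 100) lose their globally weakest edges
  one at a time — one of several historically used behaviours, chosen for
  determinism (ties break lexicographically).
* Post-network cleanup removes blank-derived nodes, nodes outside the
  windows, and singleton nodes unless identified as a cyanopeptide.
  Components are annotated with the majority classifier group, "mixed"
  on ties.
* Two intensity floors coexist deliberately: the 10⁵ feature threshold
  upstream at the feature table and the 5×10⁶ base-peak floor on
  consensus spectra entering the network; the workflow states both and
  they act at different stages.

## Statistics

* PCA keeps all components (full SVD) so scores × loadingsᵀ reconstructs
  the centred matrix; the sign of each component is fixed by making its
  largest-magnitude loading positive.
* Kruskal–Wallis runs on imputed, *unscaled* areas: the test is rank-based
  and the log₁₀/Pareto transform is monotone per feature, so the choice
  cannot change a p-value; unscaled is simply clearer. BH correction is
  applied over all tested features; "significant" means adjusted
  p < 0.01.
* At quadruplicate group sizes the chi-square approximation to the KW null
  distribution is conservative (measured type-I ≈ 0.002 at nominal 0.01
  over 20 000 null simulations) — a property of every standard KW
  implementation, protective rather than inflationary. The calibration
  test therefore checks type-I ≈ α at 20 replicates per strain, where the
  approximation holds (measured 0.009), and checks only non-inflation at
  the quadruplicate design.
* Volcano contrasts are one-vs-rest Welch t-tests per strain (the
  per-strain labelling implies a contrast but never defines one;
  one-vs-rest is the symmetric choice), with log₂ fold change of mean
  areas. "Smallest t-test values" is read as smallest p (equivalently
  largest |t|); ties break by larger |log₂ FC|, then feature id.
* Label selection: union of 3 smallest-p features per strain and 3
  largest loading-vector magnitudes per PC1/PC2 quadrant (quadrants by
  loading signs, exact zeros counting as non-negative); duplicates count
  once. With six strains and fully disjoint selections this yields 30
  labels.
* Biomass normalisation divides each area by its sample's dry biomass
  (mg); means and sds are over the quadruplicates of each strain.

## The synthetic-data generator

The generator *defines the study conditions* for all tests: six strains ×
4 replicates + one media blank, group counts per strain mirroring the
published distribution (≈ 300 compounds plus decoys), precursors uniform
in the 590–1210 window, RT uniform in 2.2–5.6 min, microviridins as 2+/3+
precursors of 1600–1900 Da.

Choices the underlying study does not specify, made once and documented:

* **Mass error is per-scan.** Each rendered spectrum draws one Gaussian
  ppm offset (σ = 5 ppm by default) applied to all its peaks and the
  precursor. Calibration drift dominates Orbitrap mass error, so within a
  scan the diagnostic ions move together while the marginal per-ion error
  stays N(0, σ) — which is also why multi-ion rules recover ≈ 95.4% of
  labels at a 10 ppm tolerance rather than the ~91% that independent
  per-peak errors would give.
* **Abundances** are lognormal (ln-scale mean 17 ≈ 2.4×10⁷ median area,
  σ = 1); replicate scatter is lognormal with CV 0.2 (the
  replicate-to-replicate variance is unreported; 20% is typical for batch
  cultures). Dry biomass is uniform 10–30 mg.
* **Fragmentation structure.** Compounds of one (group, subclass) family
  share a 10-peak fragment backbone (drawn once per family per
  experiment) plus 3 compound-specific peaks and the registry's
  diagnostic ions; this mirrors the shared core structures that make
  molecular networking cluster congeners, and it is what lets same-family
  spectra clear the 7-matched-ion edge requirement. Noise peaks (10 per
  spectrum) are uniform in *m/z* below the precursor, rejected within
  25 ppm of any registry or immonium landmark (so decoys contain no
  diagnostic ion within matching tolerance by construction), with
  intensities 0.1 × lognormal.
* **DDA re-triggering:** 3 MS/MS spectra per feature (from the replicates
  with the largest areas), so consensus clusters of size ≥ 2 exist, as
  the minimum-cluster-size rule assumes.
* **ESI redundancy:** sodium adducts (+21.9819, singly charged species
  only) and ¹³C isotopologues (+1.00336/z) co-elute exactly with their
  parent at 10–40% / 25–50% of its area. Blank handling distinguishes
  trace carryover of real compounds into the blank (1% of mean area,
  retained by the ×50 rule — that is the rule's point) from blank-origin
  media features (strong in the blank, 0.5% leakage into samples,
  removed).
* **Isotope patterns** are first-order: M+1 from binomial ¹³C with an
  averagine carbon estimate (4.9384 C per 111.1254 Da); M+2 from chlorine
  alone for chlorinated species (0.320 per Cl) and from binomial ¹³C₂
  otherwise. The omitted ¹³C₂ term under chlorination (~0.07 at C₃₅)
  would not move a ratio out of the detection windows.
* **No cross-strain sharing:** each synthetic compound belongs to one
  strain, so synthetic group totals equal row sums; union semantics of
  the distribution table are exercised by constructed cases and by the
  shipped reference table, where totals are genuine unions.

What passing tests therefore show: the pipeline's rules are implemented
exactly (hand-computed oracles), its statistics behave as designed
(type-I control, BH step-up, PCA identities), and labels/redundancy are
recovered under the stated error model. What they do not show: behaviour
under chromatographic drift, co-elution of isobars, profile-mode data,
in-source fragmentation, real MSCluster behaviour, or instrument-specific
intensity response — none of which the generator emulates.

## Problem sizes

Defaults keep everything desk-scale: the six-strain scenario (~500
features including redundancy, ~1100 spectra) runs end to end in well
under a minute; the recovery measurement uses 8000 rendered spectra so
the binomial uncertainty on the ≈ 95.4% recovery rate is ±0.2%; the null
simulation uses 500 features as stated above.

## Known limitations

* The classifier cannot place Cl on Tyr versus Hpla (the evidence ion is
  the same), cannot resolve Leu/Ile, and does not attempt de novo
  sequencing of new congeners.
* Anabaenopeptins with Phe/Tyr/Hty-type exo-residues are not claimed:
  those residues also occur in the macrocycle, so their immonium ions are
  not exo-diagnostic.
* Unique-compound identity for counting is (group, subclass, integer
  mass, RT cluster within 0.05 min); congeners of the same subclass whose
  integer masses and RTs collide merge into one count, a rare but real
  event at ~100 compounds per group.
* Distribution-table "detection" is area > 0 in ≥ 1 replicate after blank
  subtraction but before intensity filtering, so rescue-path
  identifications below the statistics threshold still count.
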