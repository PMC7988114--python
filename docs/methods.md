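# Methods

## Scope

proteomap profiles collections of annotated proteomes (multi-FASTA amino-acid
files plus a species/phylum/genome-size metadata table) and produces:
per-protein molecular mass, isoelectric point and composition; per-species
and kingdom-level summaries; the virtual 2-D (pI × MW) proteome map with its
1-D pI profile and detected modes; and a statistical layer (PCA, ordinary
least squares, PPCC normality). A seeded generator of synthetic fungal-like
kingdoms makes every stage testable offline.

## Sequence sanitization

Input sequences are uppercased and whitespace-stripped. Ambiguity codes are
translated by the standard rules — B (Asn/Asp) → N, J (Leu/Ile) → L,
Z (Gln/Glu) → Q — and every substitution is counted per record. Stop symbols
`*` are stripped wherever they occur, not only terminally, because annotated
proteomes occasionally contain internal stops and there is no principled
reason to treat them differently. X (unknown residue, "Xaa") is kept and
counted. Selenocysteine (U) and pyrrolysine (O) are kept in the sanitized
sequence so residue bookkeeping stays exact, but they contribute neither mass
nor charge downstream; fungal proteomes contain none, so on conforming data
this policy is unobservable. Records emptied by sanitization are dropped,
counted and logged rather than aborting a run. Sanitization is idempotent.

The annotation-keyword scan (`scan_descriptions`) is a case-insensitive
substring match over FASTA description lines; it exists to audit annotation
claims such as proteins labelled "selenocysteine" that contain no U residue.

## Molecular mass

Average (not monoisotopic) residue masses are used; a chain's mass is the sum
of residue masses plus one water (18.0153 Da). This is the convention that
reproduces the published masses of small annotated peptides (e.g. the A-L
dipeptide at 0.202 kDa). One published worked value — a tripeptide A-L-K
given as 0.303 kDa — is inconsistent with additive average-mass arithmetic
(which gives 0.330 kDa) and is presumed a digit transposition; it is not used
as a reference value.

X residues take, by default, the unweighted mean of the 20 canonical residue
masses (`x_policy="mean-of-20"`); `"zero"` and `"reject"` are available, and
the policy in force is recorded in the run configuration, since surveys
rarely state how they handled X.

## Isoelectric point

Net charge is the Henderson–Hasselbalch sum over ionizable groups (one free
N-terminus, one free C-terminus, and the C, D, E, H, K, R, Y side chains with
their residue counts). No post-translational modifications are modelled: the
pI is the "native sequence" pI, and phosphorylation-induced shifts discussed
in the literature are out of scope.

The default pKa table is IPC_protein, the protein-optimised set of the
Isoelectric Point Calculator; IPC_peptide and EMBOSS tables can be selected
by name. The choice matters: the most basic protein composition on record
(84 Arg, 21 Lys, no acidic side chains) has the closed-form pI
pKa_R + log10(83), which evaluates to 13.759 exactly under IPC_protein's
Arg pKa of 11.84 — matching the published value — and to different values
under the other tables.

Because Q(pH) is strictly decreasing and continuous, its root is unique.
Bisection runs on [0, 14], widening once to [−2, 16] if the charge does not
change sign in the primary bracket (possible only for extreme compositions),
and stops when the bracket is narrower than `tol` (default 10⁻³ pH). A
vectorised batch solver advances all proteins of a species simultaneously;
it is bit-for-bit the same recurrence as the scalar path and is tested
against it. Reported pI and kDa values are rounded to 3 decimals; internal
math is unrounded.

## Classification and aggregation

A protein is acidic if pI < 7 − ε, basic if pI > 7 + ε, else neutral, with
ε = 0.005 by default — i.e. "neutral" means the pI rounds to 7.00 at two
decimals. The narrow band is deliberate: kingdom-scale surveys report
neutral fractions of order 0.1–0.2%, which only a narrow band produces. ε is
configurable and echoed into every summary. (One published survey reports
61.68% acidic + 38.04% basic alongside a 0.172% neutral average; those
figures do not sum to 100% and the discrepancy is noted here rather than
resolved.)

Species summaries include counts, total residues, mean length, mean and
total mass, class percentages, pI and mass extremes with accessions, and the
composition vector. Ties for extremes are broken by lexicographically
smallest accession, making every output deterministic. The kingdom-level
"average proteome mass" follows the survey convention of a mean over species
of per-species means (mean-of-means); the pooled mass-weighted mean is also
emitted, and the identity pooled mean = total mass / total count is tested.
Per-phylum means are unweighted means over member species. Class percentages
are reported to full precision in TSVs; display rounding is two decimals.

## The virtual 2-D map

Proteins are binned on a pI × MW grid: pI bins of 0.1 pH over [1, 14], mass
bins log10-spaced over [0.1, 3000] kDa with 60 bins by default (published
maps state no binning, so the defaults are explicit configuration). Binning
is half-open [lo, hi) with the last bin closed, so counts are bit-exact and
the marginal of the grid over mass equals the 1-D pI histogram as an integer
identity — a property kept testable by deliberately using a moving-average
smoother (5 bins, centered, edge-truncated) instead of kernel density
estimation. Out-of-range proteins are counted and logged, never silently
dropped.

Modes of the smoothed profile are local maxima with prominence at least 10%
of the maximum smoothed density (scipy `find_peaks`); the profile is padded
below zero at both ends so boundary maxima of monotone profiles are reported,
and plateau maxima report their center bin. No formal dip test is performed:
modality is assessed exactly as in the visual-survey tradition, by counting
detected modes. The rendered PNG is a convenience; the CSVs are the
contract.

## Statistical layer

PCA is computed by SVD of the column-centered (optionally unit-variance
scaled, ddof = 1) matrix. Reported per component: scores, loadings,
explained-variance fractions; per sample: leverage (diagonal of
T(TᵀT)⁻¹Tᵀ over the kept components) and Q residuals (squared reconstruction
error). Component signs are fixed so each loading vector's
largest-magnitude entry is positive, making results deterministic. A
constant column under scaling is an error naming the column; the CLI drops
constant features (with a log line) before the species-level PCA, since tiny
runs can legitimately have an all-zero neutral class. The species feature
matrix for that PCA is the per-species acidic/basic/neutral percentages plus
the 20 composition percentages — published surveys do not state their exact
feature matrix, so this construction is explicit configuration.

Regression (genome size in Mb against total residue count) is ordinary least
squares with the Pearson r. The PPCC is the Pearson correlation between the
ordered sample and standard-normal quantiles at Blom plotting positions
(i − 0.375)/(n + 0.25); it is affine-invariant and near 1 for normal
samples. No p-values or multiple-testing machinery: the survey statistics
this layer mirrors report none.

## Synthetic kingdoms

The generator emulates the statistical structure the analysis assumes, not
biology in detail:

- **Residues** are i.i.d. draws from a kingdom-wide frequency vector — the
  pooled fungal composition (Leu ≈ 9.1% down to Cys ≈ 1.27%), renormalized
  over the 20 canonical letters. No codon or dipeptide structure is
  simulated, because every downstream statistic is composition-level.
- **Acid bias δ** shifts probability mass from {K, R} to {D, E}
  (proportionally within each pair; negative δ shifts the other way). δ is
  drawn per species from a two-regime mixture — acid-shifted
  (δ ≈ +0.020, p = 0.62) and base-shifted (δ ≈ −0.025, p = 0.38), s.d.
  0.005 — which gives the pooled pI distribution its bimodal shape while
  every pI is still computed by the net-charge solver, so the physicochemical
  stage is genuinely exercised.
- **Lengths** are lognormal (μ = 5.978, σ = 0.55 on log residue count,
  truncated to [2, 25000] by resampling), giving a mean length ≈ 459
  residues — the kingdom-wide average reported for fungi — and hence a mean
  protein mass near 51 kDa. Dipeptides are valid: the smallest annotated
  fungal proteins are 2-mers.
- **Ambiguity codes** (X, B, J, Z in ratio 7:1:1:1) are injected at a
  per-residue rate of 2×10⁻⁴, matching the ~0.016% Xaa incidence surveys
  report. U and O are never generated.
- **Genome sizes** are affine in the species' total residue count
  (≈8.5 Mb per 10⁶ residues plus a 2 Mb intercept) plus centered lognormal
  noise scaled to hit a target Pearson correlation (default 0.9; 1.0 gives
  exact linearity, which is tested).
- **Determinism**: every artifact is a pure function of (spec, seed); each
  species uses an independent child stream of the seed, so species i is
  identical whether generated alone or inside a kingdom.

What the generator does *not* emulate: domain structure, paralogy,
GC-content-driven composition gradients, annotation noise other than
ambiguity codes, or real taxonomy (phylum labels simply cycle through the
ten-group fungal vocabulary). Passing tests on synthetic kingdoms therefore
demonstrate the pipeline's correctness and the qualitative phenomena
(bimodality, acid dominance, composition ranking), not quantitative
agreement with any real kingdom's published numbers — those require the
original few-hundred-proteome corpus, which this package deliberately does
not download.

## Problem sizes and numerical choices

The standard synthetic configuration is 100 species × 2,000 proteins
(≈9×10⁷ residues, ≈13 s end-to-end on one core); unit tests use smaller
kingdoms (10 × 150). Bisection tolerance 10⁻³ pH (tested against a 10⁻⁴
grid-search oracle to 2×10⁻³); mass arithmetic is plain float64 with
additivity holding to 10⁻⁹ relative. Degenerate inputs are contracts, not
crashes: empty FASTA → format error; record emptied by sanitization →
dropped and logged; empty species → error; constant regressor or constant
PPCC sample → error.

## Known limitations

- pI values assume free unmodified termini and no PTMs; predicted pI of a
  heavily modified protein can differ by up to ~1 pH unit.
- The i.i.d. residue model understates between-protein composition variance
  relative to real proteomes (real bimodality is sharper than binomial
  fluctuation alone would give); the two-regime δ mixture compensates at the
  species level only.
- PPCC is reported as a descriptive statistic without critical values.
- The survey-printed kingdom aggregates (mean proteome mass 50.96–50.98 kDa,
  61.68% acidic, per-phylum extremes) are corpus-dependent and are not
  asserted anywhere; the package reproduces the printed *desk-scale* worked
  examples exactly and the kingdom-scale phenomena qualitatively.
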