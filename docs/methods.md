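# Methods

`brewomics` re-implements, as a tested library, the computational workflow used
to study how husk separation during mashing (the Kubessa method, line K)
suppresses beer-aging chemistry relative to whole-malt brewing (line T) in
nontargeted, negative-mode ultrahigh-resolution MS metabolomics. This note
documents the models, the defaults and why they were chosen, what the
synthetic benchmark does and does not emulate, and the numerical decisions a
maintainer would want to know.

## Mass arithmetic and ion convention

Neutral monoisotopic masses are sums of IUPAC atomic masses (C 12 exactly,
H 1.00782503, N 14.00307400, O 15.99491462, S 31.97207100, P 30.97376163,
Cl 34.96885268). All ions are deprotonated anions with the electron mass
included:

    m/z([M−H]⁻) = M_neutral − (m_H − m_e) = M_neutral − 1.00727645 Da.

This convention reproduces the bisulfate anion at 96.9601 Th, the reference
value used throughout the sulfur-chemistry rules. Double-bond equivalents
follow the standard ring-plus-double-bond rule
DBE = C + 1 + (N+P)/2 − (H+Cl)/2; non-integer or negative DBE marks an
impossible (radical) neutral composition.

## Formula enumeration

`enumerate_formulas` searches the full element box exhaustively. Because every
element mass except hydrogen exceeds any realistic tolerance window, the H
count of a candidate is uniquely determined by rounding the residual mass;
enumeration therefore reduces to a vectorized sweep over the precomputed
H-free grid, with per-row admissible H ranges (element bounds, H/C in
[0.2, 3.1], O/C ≤ 1.5, 0 ≤ DBE ≤ 40, H parity for integer DBE) folded in at
grid-construction time. The golden-rules-style filters are the conventional
heuristics for small-molecule formula assignment; the DBE ceiling of 40 is the
standard generic upper limit. Candidates are ranked by |ppm error|, then by
total heteroatom count (N+O+S+P+Cl), then by Hill-order string, so results are
deterministic. An independent nested-loop oracle in the test suite confirms
exhaustiveness on random queries.

Default element bounds for *search* are C 1–66, H 0–126, N 0–6, O 0–30,
S 0–3, P 0–2, Cl 0–2, covering m/z ≤ 1000.

**Unique annotation uses a narrower space.** At a 0.2 ppm working tolerance,
exotic multi-heteroatom compositions form sub-tolerance mass doublets with
common CHO formulas (e.g. C26H44O8 vs C22H49ClN4OS2 at 0.028 ppm), so in the
full CHNOSPCl box nearly half of ordinary CHO compositions are not uniquely
assignable from accurate mass alone — resolving them requires isotopologue
verification, which is outside this package's scope. `annotate_matrix`
therefore defaults to the composition classes actually observed in fermented
beverages: CHO, CHNO (N ≤ 3) and CHOS/CHNOS (S ≤ 1). Users can widen the
bounds explicitly; ambiguity is then reported per feature rather than silently
resolved.

Working tolerances: 0.2 ppm in FT-ICR mode, 5 ppm in ToF mode.

## van Krevelen compound classes

Assigned formulas are mapped to (O/C, H/C) and classified by a
priority-ordered table of rectangular regions with heteroatom predicates
(sulfonolipid-like, lipid-like, carbohydrate-like, polyphenol/glycoside-like,
amino-sugar/Maillard-conjugate-like, peptide-like). The boxes are conventional
literature regions; they are data, not code — a JSON/TSV region table can be
supplied. Classification returns the first matching region, so overlaps
resolve deterministically.

In-silico deglycosylation subtracts 1–3 glycosidic residues (hexose 162.0528,
pentose 132.0423, deoxyhexose 146.0579 — sugar minus water, computed from
formulas) down to a 100 Th floor; candidate aglycones are matched against a
plain-text compound library by accurate mass.

## Preprocessing

Per-sample peak lists are filtered to m/z 120–1000 and signal-to-noise ≥ 6.
Replicates are merged by single-linkage clustering on sorted m/z with a ppm
gap threshold (default 1 ppm); a cluster that would contain two peaks from the
same replicate is split at its widest internal gap, so the alignment is a
partition of the input peaks. Clusters present in at least 2 of 3 replicates
become consensus peaks: m/z is the intensity-weighted mean (favoring
well-measured peaks), intensity the arithmetic mean over the contributing
replicates only. Group-level (line × timepoint) consensus lists are aligned
into the feature matrix by the same rule; missing cells stay missing (no
imputation). For supervised statistics a replicate-level matrix (one column
per sample, 24 columns for the full design) is built by aligning the
per-sample lists directly, keeping features that pass the presence rule in at
least one group and are observed in at least half the samples.

## Aging-trajectory extraction (SOM)

Each feature's eight group means (T t0..t3 then K t0..t3) form one
trajectory, z-scored jointly so that shape rather than scale drives
clustering; concatenating both lines makes "consistent behavior in both
lines" a property of a single vector. Missing cells are filled with the
feature's per-line minimum (flagged); features missing an entire line are
excluded.

The map is a classic online Kohonen SOM: 10×10 rectangular grid, Gaussian
neighborhood, 500 epochs (one epoch = each trajectory once, seeded random
order), learning rate 0.5 → 0.01 and radius 5 → 1 with exponential decay,
codebook initialized uniformly inside the per-dimension data span. The inner
loop is numba-compiled; training ~3000 trajectories takes a few seconds.
Final assignments are recomputed in one vectorized pass and verified against
a brute-force argmin oracle in the tests.

A node qualifies as *aging* when its mean member profile, split into per-line
segments, rises with storage time in **both** lines: Spearman ρ with time
≥ ρ_min and last > first in each segment. With four timepoints the achievable
ρ values are {1, 0.8, 0.6, ...}; the default ρ_min = 0.9 therefore demands
strictly monotone segments, which is what "consistent increase" means at this
resolution — at 0.8, profiles with an internal rank swap also qualify and the
false-discovery proportion of the selection roughly doubles. The threshold is
configuration-exposed. The cluster unit is a single SOM node; merging adjacent
nodes is a possible refinement not implemented here.

Line comparison scales each selected feature by its own maximum across all
groups and reports median/quartiles per line, both pooled over timepoints and
time-resolved — the box-plot summary in which the husk-separated line shows
systematically lower relative intensities of aging compounds.

## OPLS-DA

A NIPALS orthogonal-projection implementation with one predictive component:
the predictive weight w ∝ X'y (unit norm) is fixed; orthogonal components are
extracted iteratively from the loading residual p − (w'p)w and deflated; the
predictive component is then fitted on the filtered X. Inputs are
unit-variance scaled (zero-variance columns centered and flagged); the
pipeline log-transforms intensities first, consistent with the multiplicative
noise model. Class coding is y ∈ {0,1} with T = 1, so a positive predictive
weight means elevated in the whole-malt line.

Q² = 1 − PRESS/SS from stratified 7-fold cross-validation with scaling and
centering re-estimated inside every fold. `n_ortho="auto"` grows the
orthogonal block while Q² improves by more than 0.01, up to 3. CV-ANOVA is
the Eriksson-style F-test of (SS − PRESS)/d₁ against PRESS/d₂ with
d₁ = number of model components and d₂ = N − 1 − d₁. With one predictive
component the VIP reduces to √p·|w_j|, preserving the mean-square-one
identity; markers are features with VIP ≥ 2 (the stricter 2.5 used for
printed marker tables is reachable via configuration), tagged with the class
they are elevated in.

Outliers: Hotelling's T² on the (predictive + orthogonal) scores against the
F-based limit k(n−1)/(n−k)·F₁₋α(k, n−k), one flag-and-refit pass. For
in-sample scores this limit is conservative at small n (the exact in-sample
distribution is Beta-based and bounded by (n−1)²/n); the observed null flag
rate approaches the nominal 5% as n grows, which is how the null-rate check
is run.

**Permutation control.** The design is blocked: both lines share a strong
storage-time structure, so a freely permuted label vector can align with time
and be *genuinely* predictable — at n = 24 roughly a tenth of free
permutations exceed Q² = 0.05 for any implementation. The package's
permutation scheme therefore permutes line labels within each timepoint
block, the standard restricted permutation for randomized-block designs;
under that exchangeable null Q² collapses in every permutation tested.

**What the VIP ≥ 2 set contains on the synthetic benchmark.** The generator
plants two kinds of true line differences: 100 explicit markers (3-fold in
their own line) and ~450 aging features whose K baseline and slope are
attenuated (δ = 0.6). Both are genuine T-vs-K discriminators, and the VIP ≥ 2
set consists almost exclusively of them (precision against planted
line-different features ≈ 1.0; essentially no null features enter). Counted
against explicit markers alone, precision is ~0.4 — not a failure of the
discriminant but a property of the planted ground truth, in which attenuated
aging compounds outnumber markers. Both metrics are reported.

## MS² sulfur rules

Sulfonate (C–SO₃⁻) versus aliphatic sulfate (O–SO₃⁻) is decided from
diagnostic evidence in negative-mode product-ion spectra: SO₂⁻ (63.9625) and
SO₃⁻ (79.9574) fragments and the SO₃ neutral loss (79.9568) indicate a
sulfonate; the bisulfate anion HSO₄⁻ (96.9601), produced by cyclic
syn-elimination of an aliphatic sulfate, forces the sulfate verdict and
overrides sulfonate-type evidence. Matching uses the larger of 10 mTh and
15 ppm (ToF-scale fragment accuracy), ignores fragments below 0.5% of the
base peak, and breaks exact ties toward lower m/z. No evidence →
inconclusive. The verdict is invariant to intensity scaling and monotone in
bisulfate evidence.

## Synthetic benchmark

The generator emulates the study design: 2 lines × 4 storage timepoints × 3
replicates, 3000 features drawn by rejection sampling from five
compound-class boxes (25% lipid, 10% sulfonolipid, 25% carbohydrate, 20%
polyphenol/glycoside, 20% N-conjugate) so that each formula lands in its van
Krevelen region and its ion falls in m/z 120–1000. Intensities are
multiplicative: log-normal baselines (median 10⁶, σ_log 1), aging features
(15%, disjoint from markers) grow by (1+β)^t with β ~ U(0.15, 0.6), line K
attenuates both β and the aging baseline by δ = 0.6; markers (50 per line,
drawn from sulfonolipid/glycoside classes for T and N-conjugate classes for
K) are 3-fold elevated in their line; per-sample log-normal noise
(σ_log 0.2), Gaussian m/z error (0.05 ppm FT-ICR scale) and 5% replicate
dropout complete the model. A JSON manifest records every planted parameter,
and scoring helpers compute annotation recovery, selection
sensitivity/false-discovery and marker precision against it.

Not emulated: chromatography and retention time, isotope patterns, profile
spectra, inter-batch drift, correlated (compound-family) intensity structure,
and forced-aging samples. Passing the closed-loop checks therefore shows the
algorithms recover what they are defined to recover under this noise model —
it does not certify performance on real spectra, where peak picking,
calibration drift and isotope interference dominate.

Default sizes keep the full closed loop under two minutes on one CPU; the
acceptance script and test suite use the default 3000-feature design (five
seeds for the recovery means) and reduced designs (~400–600 features) for
unit-level checks.

## Numerical and degenerate-input choices

- Consensus m/z is intensity-weighted; zero-weight clusters fall back to the
  plain mean.
- Constant trajectories normalize to all-zero vectors and can never qualify
  as aging (flat profiles fail last > first).
- Spearman thresholds compare with a 1e-9 slack so exact rank-pattern values
  (0.8, 1.0) are classified by value, not floating-point accident.
- Zero-variance columns are centered, flagged, and excluded from scaling
  rather than producing infinities; `uv_scale` detects them with a
  magnitude-relative tolerance.
- Empty enumeration results, empty MGF files and empty fragment lists are
  valid outputs, not errors; empty aging sets and single-class responses are
  errors.
- Deglycosylation multiplicity is capped at 3 and floored at 100 Th to bound
  the candidate set.

## Known limitations

- No isotopologue scoring: unique annotation relies on the restricted
  element space; in the full CHNOSPCl box ambiguity is intrinsic at 0.2 ppm.
- Single predictive component only (two-class OPLS-DA); no multi-class
  extension.
- The SOM cluster unit is one node; the map granularity (10×10) is a design
  choice, and selections at other granularities will differ at the margins.
- The forced-aged condition and process-stage samples are accepted in
  metadata but excluded from the storage-series analyses by default.
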