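# Methods

This note documents the conventions, defaults and design choices behind
`gwdom`, in the order the pipeline runs.

## Scope and assumptions

Inputs are *assigned* peak lists: neutral CHNOS elemental compositions with
signal magnitudes, as produced by upstream FT-ICR MS processing (phase
correction, calibration, 6σ-rms peak picking and formula assignment are all
instrument-side and out of scope here; intensities are used as loaded).
Formulae are neutral — negative-mode electrospray deprotonation bookkeeping
is assumed already handled — and isomers are indistinguishable at the
formula level. Corrected, Raman-normalised excitation–emission matrices are
likewise assumed as inputs; no inner-filter or scatter correction is
re-applied.

## Per-formula indices

- **DBE** = c − h/2 + n/2 + 1. May be negative for impossible compositions;
  the generator and validators enforce DBE ≥ 0, the index itself does not.
- **AI_mod** = (1 + c − o/2 − s − h/2)/(c − o/2 − s − n). A negative
  numerator or non-positive denominator clamps to 0, and values are capped
  at 1, following the published convention for this index (condensed
  aromatics saturate at 1).
- **NOSC** = 4 − (4c + h − 3n − 2o − 2s)/c, bounded by the carbon oxidation
  states [−4, +4] for valence-feasible formulae (3n + 2o + 2s ≤ 4c + h);
  the tests restrict the bound check accordingly.
- **Kendrick mass** = IUPAC mass × 14/14.01565, mass defect = nominal
  (rounded) − Kendrick mass, so CH2 homologues share a defect.
- **CRAM**: all three ratio windows inclusive (DBE/C ∈ [0.30, 0.68],
  DBE/H ∈ [0.20, 0.95], DBE/O ∈ [0.77, 1.75]). Formulae with h = 0 or
  o = 0 are not CRAM: the defining ratios are undefined and the CRAM
  concept presumes oxygenated molecules.
- **Nitrogen rule**: odd h + n (non-integer DBE) triggers a warning, not an
  error — assigned lists from calibrated instruments are trusted.

### Compound classes

The literature thresholds overlap (an AI_mod band can contain H/C ≥ 1.5
formulae), so labels are resolved by a fixed precedence that makes them
mutually exclusive and total:

1. AI_mod > 0.66 → condensed aromatic
2. 0.5 < AI_mod ≤ 0.66 → polyphenolic
3. O/C > 0.9 → sugar-like
4. 1.5 ≤ H/C ≤ 2.0, O/C ≤ 0.9, N = 0 → aliphatic
5. 1.5 ≤ H/C ≤ 2.0, N > 0 → peptide-like
6. AI_mod ≤ 0.5 and H/C < 1.5 → highly unsaturated & phenolic
7. otherwise → other

The H/C < 1.5 condition on rule 6 keeps the aliphatic/peptide band from
being absorbed into the unsaturated band. An exhaustive enumeration over
c ∈ [1, 40], h ∈ [0, 80], n ∈ {0, 1, 2}, o ∈ [0, 30], s ∈ {0, 1} (602,640
compositions) is checked in the test suite: every formula receives exactly
one known label.

### Reference sets

The Island-of-Stability (IOS) appendix and the ten degradation-index
(I_DEG) formulae come from published appendices and are therefore shipped
as *editable* CSV files, not hard-coded. The packaged defaults are
synthetic stand-ins (flagged in their filenames and headers): CRAM-type CHO
compositions drawn from the H/C ∈ [1.0, 1.5], O/C ∈ [0.42, 0.70] window.
Users holding the original appendices should point the loaders at their own
files. IOS membership is exact element-count matching by default; an
H/C–O/C rectangle mode exists and must be selected explicitly.

## Sample summaries

Alignment zero-fills the formula × sample table exactly (no imputation);
detection below the noise floor is 0. Weighted means are
Σ(Iᵢ·propᵢ)/Σ(Iᵢ); % RA is reported on the 0–100 scale. Within one sample
these ratios are identical for raw and per-sample relative intensities, so
either path may be used; both are exposed. I_DEG is
Σ(neg present)/Σ(all ten present), NaN (never 0) when none of the ten is
detected, with the missing count reported. Operations needing absent
metadata fail loudly per sample rather than dropping samples silently.

## Between-group comparison

Per-group medians are taken over the aligned axis with zeros counted as
observations (even counts: midpoint). Enrichment differencing is
diff = median(b) − median(a); diff < 0 → enriched in a, diff > 0 → enriched
in b, exact ties in neither set. An optional `threshold` widens the tie
band to |diff| ≤ threshold for suppressing noise-level differences; the
default is 0.

The weighted DBE-per-oxygen profile uses absolute median differences as
weights within one enriched set (single-signed there anyway; absolute
values make the operation total). The regression of weighted DBE on nO is
ordinary least squares over the categories nO ∈ [2, 21] by default
(configurable; out-of-range categories are still reported). Slope ≈ 0.5 is
the carboxyl signature (one DBE per two oxygens); steeper slopes indicate
additional rings or C=C bonds.

## Radiocarbon and trend statistics

pMC converts to Δ14C (‰) as (pMC/100 · e^{λ(1950−y)} − 1)·1000 with
λ = 1/8267 yr⁻¹ (5730-yr true half-life); δ13C normalisation is upstream.
A conventional age helper uses the Libby constant (1/8033 yr⁻¹) and is
flagged as such; no calendar calibration or reservoir correction is done.

Spearman correlations use full permutation enumeration for n ≤ 9 (exact
even under ties) and the t-approximation above; Wilcoxon rank-sum tests are
exact for combined n ≤ 12 without ties and otherwise use the tie-corrected
normal approximation without continuity correction (so identical samples
give p = 1 exactly); the variance-ratio test is the two-sided F. Raw
p-values are reported; a Benjamini–Hochberg helper exists but is never
applied by default.

## Fluorescence

Index wavelengths are read off corrected EEMs by bilinear interpolation
(exact at nodes, stable under grid refinement: halving the spacing of a
smooth surface moves BIX/FI by < 1%), rather than nearest-node lookup,
because instrument grids need not contain 310/380/430/370/450/500/275/340 nm
exactly. Zero denominators yield NaN.

## Flux upscaling

1 km³ yr⁻¹ × 1 mg C L⁻¹ = 10⁻³ Tg C yr⁻¹. The default scenario (SGD
2400 km³ yr⁻¹, extraction 982 km³ yr⁻¹, median 1.2 / mean 3.8 mg C L⁻¹,
projected 2099 extraction 1621 km³ yr⁻¹) lives in
`data/flux_defaults.yaml` — these are literature inputs, not computed
quantities. Headline values are rounded half-even to one decimal with the
raw value always reported alongside. The combined row's raw flux is the
exact sum; its headline value is the sum of the per-route *rounded* fluxes
(the convention for totals assembled from already-rounded route values —
note 12.8516 would round directly to 12.9, while 9.1 + 3.7 = 12.8).
The 2099 projection reports this package's own arithmetic,
(1621 − 982)/982 = +65.1%.

## Synthetic studies

The generator draws a shared pool of CHNOS formulae (c ∈ [8, 40],
H/C ∈ (0.3, 2.2), O/C ∈ (0, 1.2), nitrogen-rule parity, DBE ≥ 0), then
gives each environment group a weight per formula: a Gaussian kernel in
(H/C, O/C) around the group centre, optionally times a Gaussian band around
a target DBE = slope·nO relationship, times a heteroatom tilt. Sample
intensities are those weights times independent lognormal magnitudes;
values below the per-sample 30% detection quantile are zeroed. This is the
simplest mechanism producing the observed compositional shifts without
asserting unsupported chemistry.

Default profiles mirror the 3 / 9 / 3 stream / shallow / deep design:
centres move from (H/C 1.10, O/C 0.55) through (1.25, 0.47) to
(1.50, 0.33), DBE/O bands from 0.75 through 0.5 to 1.0, heteroatom tilt
0.35 → 0.40 → 0.65, and Δ14C from near-modern (−30 to +40‰) through
−350…−60‰ to −955…−890‰ (≈19–25 kyr conventional ages). DOC-concentration
ranges follow typical stream (1.3–8.3), shallow (0.5–1.6) and deep
(0.75–1.1 mg C L⁻¹) values. When the pool is drawn internally the packaged
IOS/I_DEG formulae are appended so reference-set metrics are defined, as
they are in real peak lists. Ground truth — profiles, per-sample Δ14C and
the analytically expected weighted H/C, O/C and CRAM % RA per group — is
emitted as a sidecar so tests compare against the design, never against
re-derived values.

What the generator does **not** emulate: instrument noise floors and m/z
calibration, correlated formula families from shared biochemical pathways,
blank contamination, and absolute CRAM/IOS abundances of any specific field
site. Passing recovery tests therefore demonstrates that the pipeline
recovers directional structure it was pointed at (signs, orderings,
regression bands) — not that any particular field value is reproduced.
Problem sizes in the tests and the acceptance script (pools of 800–1000
formulae, 15 samples, 20 replicates) are chosen as comfortable desk-scale
studies that exercise every code path.

## Known limitations

- Class thresholds and CRAM windows are literature conventions; boundary
  formulae are sensitive to upstream assignment choices.
- The shipped IOS/I_DEG lists are synthetic stand-ins (see above) — % RA
  IOS and I_DEG values on real data require the published appendices.
- The Wilcoxon exact path disables itself under ties; tied small samples
  fall back to the approximation.
- Flux scenarios carry no uncertainty propagation; the single-value inputs
  dominate any error budget.
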