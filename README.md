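# gwdom

Molecular-level analysis of dissolved organic matter (DOM) for
ultra-high-resolution mass spectrometry formula lists, oriented at the
question of how DOM is transformed as water moves from streams through
shallow aquifers into old, anoxic, confined groundwater — and how much
dissolved organic carbon (DOC) those groundwaters return to surface
environments.

It is written for biogeochemists and hydrogeologists who hold per-sample
FT-ICR MS peak lists with assigned neutral CHNOS formulae (plus optional
radiocarbon, DOC-concentration and fluorescence data) and want a tested,
scriptable pipeline instead of one-off spreadsheets.

## What it computes

**Per-formula indices** for each composition C<sub>c</sub>H<sub>h</sub>N<sub>n</sub>O<sub>o</sub>S<sub>s</sub>:

- double-bond equivalents, DBE = c − h/2 + n/2 + 1
- modified aromaticity index, AI<sub>mod</sub> = (1 + c − o/2 − s − h/2)/(c − o/2 − s − n), clamped to [0, 1]
- nominal oxidation state of carbon, NOSC = 4 − (4c + h − 3n − 2o − 2s)/c
- Kendrick mass and mass defect (IUPAC mass × 14/14.01565)
- CRAM membership (DBE/C ∈ [0.30, 0.68], DBE/H ∈ [0.20, 0.95], DBE/O ∈ [0.77, 1.75])
- a mutually exclusive van Krevelen class label (condensed aromatic /
  polyphenolic / sugar-like / aliphatic / peptide-like / highly unsaturated
  & phenolic / other) and Island-of-Stability / degradation-index (I_DEG)
  reference-set membership

**Sample and study level:** alignment of peak lists over the formula union
(zero-filled), intensity-weighted means of any index, percent relative
abundance (% RA) per class, I_DEG, between-group median-intensity
enrichment sets, unique/common formula sets, the intensity-weighted
DBE-per-oxygen profile and its OLS slope (≈0.5 indicates carboxyl-dominated
DOM; steeper means more rings and C=C), Spearman trends of any metric
against Δ14C, Wilcoxon and variance-ratio comparisons of O/C–H/C
distributions, fluorescence indices (BIX, FI, Peak T) from corrected EEMs,
pMC → Δ14C conversion, and global groundwater DOC flux upscaling
(km³ yr⁻¹ × mg C L⁻¹ → Tg C yr⁻¹).

A seeded synthetic-study generator (`gwdom.synthgen`) emulates the
stream → shallow → deep compositional trajectory with ground truth emitted
alongside, so the whole pipeline is testable without any data download.

## Worked example

```python
from gwdom import synthgen, spectra, compare, agestats

samples, truth = synthgen.generate_study(seed=42, pool_size=800)
study = spectra.align(samples)
summary = spectra.sample_summary(study)
print(summary.groupby("group")[["weighted_hc", "weighted_oc", "cram_ra"]].mean().round(2))

enr = compare.enrichment(study, "shallow_groundwater", "deep_groundwater")
deep = enr[enr["enriched_in"] == "deep_groundwater"]
fit = compare.dbe_o_slope(compare.weighted_dbe_profile(deep, study.formula_table))
print(f"deep-enriched DBE-O slope: {fit.slope:.2f} (r2={fit.r_squared:.2f})")

res = agestats.rank_correlation(summary["weighted_oc"].to_numpy(),
                                study.metadata["delta14c"].to_numpy(float))
print(f"weighted O/C vs d14C: rho={res.rho:.2f}, p={res.p_value:.1e}")
```

prints

```
                     weighted_hc  weighted_oc  cram_ra
group
deep_groundwater            1.43         0.35    62.13
shallow_groundwater         1.38         0.52    46.22
stream                      1.16         0.56    77.89
deep-enriched DBE-O slope: 0.88 (r2=0.97)
weighted O/C vs d14C: rho=0.65, p=9.2e-03
```

Reading this: intensity-weighted H/C rises and O/C falls from stream to
deep groundwater (the reduced, hydrogenated signature of aged anoxic DOM);
the formulae enriched in deep groundwater gain roughly 0.88 DBE per oxygen
atom — well above the 0.5 carboxyl line, i.e. extra rings/double bonds —
and the positive rank correlation of weighted O/C with Δ14C says the oldest
(most 14C-depleted) samples carry the least oxygenated material.

The flux calculator reproduces the global upscaling table from its shipped
defaults (SGD 2400 and extraction 982 km³ yr⁻¹ at median 1.2 and mean
3.8 mg C L⁻¹):

```python
from gwdom.flux import scenario_table
print(scenario_table()[["scenario", "conc_name", "flux_Tg", "flux_Tg_rounded"]])
```

giving 2.9/9.1 Tg yr⁻¹ (SGD), 1.2/3.7 Tg yr⁻¹ (extraction) and combined
totals of 4.1–12.8 Tg yr⁻¹.

The same stages are available from a shell:

```bash
gwdom simulate --out study/ --seed 1
gwdom classify --study study/ --out classes.csv
gwdom summarize --study study/ --out summary.csv
gwdom compare --study study/ --group-a stream --group-b deep_groundwater --out-prefix cmp
gwdom flux --out flux.csv
```

## Layout

- `gwdom.formula` — parsing, per-formula indices, CRAM and class rules
- `gwdom.reference_sets` — IOS / I_DEG reference lists (editable CSV files)
- `gwdom.spectra` — peak lists, alignment, weighted summaries
- `gwdom.compare` — enrichment, unique/common sets, DBE–O regression
- `gwdom.agestats` — radiocarbon conversion, rank/shift/variance statistics
- `gwdom.fluor` — EEM interpolation, BIX / FI / Peak T
- `gwdom.flux` — DOC flux upscaling scenarios
- `gwdom.synthgen` — seeded synthetic studies and EEMs with ground truth
- `gwdom.io`, `gwdom.cli` — delimited-text interchange and the `gwdom` CLI

See `docs/methods.md` for the scientific conventions, defaults and known
limitations.
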