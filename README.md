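# polymr

Two-sample Mendelian randomization (MR) for drug-target questions with
multiple target genes, plus polygenic-risk-score (PRS) drug-association
analysis.

MR uses genetic variants as instrumental variables to estimate the
causal effect of an exposure on an outcome from GWAS summary statistics
alone. Drug-target MR restricts the instruments to variants in or near
the genes encoding a drug's protein targets, so the estimate proxies
pharmacological perturbation of those targets. When a drug acts on
several targets (polypharmacology — e.g. amlodipine, which inhibits
L-, T- and N-type calcium-channel subunits plus CA1 and SMPD1), the
natural experiment grid is one run per single target gene plus one run
drawing instruments from all target genes jointly. `polymr` implements
that whole workflow:

- **sumstats cleaning & harmonization** — canonical schema, duplicate
  and multi-allelic removal, allele alignment with strand-flip and
  palindromic-variant handling, per-rule reports;
- **instrument selection** — exposure p-value thresholding
  (5e-8 genome-wide / 1e-4 drug-target), flanked gene-region restriction
  (5 kbp default flank), greedy LD clumping (r² < 0.001 / 0.1, 10 Mbp
  window);
- **estimation** — Wald ratio (1 SNP), inverse-variance weighting
  (2 SNPs), and for ≥ 3 SNPs the Rücker model-selection ladder over
  fixed/random IVW and MR-Egger driven by Cochran's Q and Rücker's Q′,
  with an Egger-intercept pleiotropy flag and a full decision trace;
- **the screen** — exposures × gene selections with layered Bonferroni
  correction (α / n_traits / n_selections) and "significant without
  pleiotropy" flags;
- **PRS** — per-chromosome dosage×weight scores aggregated by the
  missingness-aware weighted mean PRS_j = Σᵢ PRS_jᵢ K_jᵢ / Σᵢ K_jᵢ,
  standardization, and logistic models of binary outcomes on PRS and
  drug status;
- **synthetic data** — seeded generators for LD panels, two-sample GWAS
  under a known causal model with optional directional pleiotropy, gene
  annotations with planted signals, and drug-modulated cohorts, so every
  statistical claim is testable against ground truth.

See `docs/methods.md` for the statistical conventions and their
rationale.

## Worked example

```python
import polymr

cfg = polymr.SimConfig(seed=8)            # true causal effect theta = 0.3
panel = polymr.simulate_panel(cfg)
exposure, outcome, truth = polymr.simulate_two_sample_gwas(cfg, panel)

iset = polymr.select_instruments(
    exposure, outcome, mode="genome_wide", ld=panel.ld_reference()
)
res = polymr.mr_analyze(iset)
print(f"method={res.method} estimate={res.estimate:.4f} se={res.se:.4f} "
      f"ci=({res.ci_low:.4f}, {res.ci_high:.4f}) p={res.pvalue:.3g} "
      f"n_snps={res.n_snps} pleiotropy_flag={res.pleiotropy_flag}")
```

prints

```
method=ivw_fixed estimate=0.2997 se=0.0155 ci=(0.2694, 0.3301) p=1.84e-83 n_snps=8 pleiotropy_flag=False
```

Eight independent genome-wide-significant index variants survive
clumping; the ladder finds no heterogeneity and keeps fixed-effect IVW;
the estimate recovers the planted effect of 0.3 log-odds per exposure
unit and the Egger intercept test finds no directional pleiotropy.

The PRS side, on a simulated 20,000-person cohort whose outcome was
generated from logit(p) = −1 + 0.4·PRS − 0.3·drug:

```python
weights = polymr.simulate_weights(cfg)
dosages, pheno, _ = polymr.simulate_prs_cohort(cfg, weights)
scores, _ = polymr.aggregate_prs(polymr.per_chromosome_scores(dosages, weights))
model = polymr.fit_association(
    pheno["outcome"], polymr.standardize(scores), pheno["drug_status"]
)
print(model.table.to_string(index=False))
```

```
  predictor    coef     se  ci_low  ci_high  pvalue
      const -1.0158 0.0173 -1.0496  -0.9819  0.0000
        prs  0.4062 0.0167  0.3734   0.4389  0.0000
drug_status -0.2907 0.0565 -0.4013  -0.1800  0.0000
```

Both planted coefficients are recovered well within their standard
errors; the negative drug coefficient is the analogue of a drug
mitigating an outcome after accounting for genetic liability.

## Command line

`polymr` exposes the same pipeline as subcommands — `simulate`, `munge`,
`harmonize`, `instruments`, `mr`, `screen`, `prs score`, `prs assoc` —
reading and writing tab-delimited text. Every command writes a JSON
manifest recording the package version, input digests and every
threshold actually applied, so runs are auditable and reproducible:

```bash
polymr simulate --seed 7 --out-dir bundle/
polymr instruments --exposure bundle/exposure.tsv --outcome bundle/outcome.tsv \
    --ld bundle/ld_pairs.tsv --out inst.tsv
polymr mr --instruments inst.tsv --out mr_result.tsv
```

The default drug-target screen grid is the packaged amlodipine
catalogue (`polymr.default_amlodipine_targets()`): eight gene
selections — all seven DrugBank target genes combined, plus each of
CACNA1C, CACNB1, CACNA1I, CACNA1B, CACNA2D3, CA1 and SMPD1 singly. The
shipped coordinates are approximate GRCh38 spans in an editable table;
verify them against your datasets' build before real analyses.

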