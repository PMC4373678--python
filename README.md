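# mpsscore

Multiparametric severity scoring of missense mutations in **SGSH**
(N-sulfoglucosamine sulfohydrolase), the lysosomal sulfatase deficient in
mucopolysaccharidosis type IIIA (Sanfilippo syndrome type A).

MPS-IIIA is genetically heterogeneous: most patient alleles are single
amino-acid substitutions that impair the enzyme through an unknown mix of
biogenesis defects — slowed translation, aggregation, destabilization,
broken secondary structure, lost glycosylation, perturbed catalytic or
quaternary architecture.  `mpsscore` scores each substitution against ten
evidence-based parameters, one point per adverse call (the protein-stability
parameter carries up to two), so a mutation total lies in **[0, 11]**:

| # | parameter | evidence consumed |
|---|-----------|-------------------|
| 1 | translation rate | codon → relative tRNA-abundance table, CDS |
| 2 | aggregation propensity | AGGRESCAN-style a4v profile and hot spots |
| 3 | cellular stability (0–2) | external stability-predictor call |
| 4 | secondary structure | per-residue H/E/C + Chou–Fasman propensities |
| 5 | catalytic-site proximity | structure, heavy-atom minimum distance |
| 6 | N-glycosylation | N-X-[S/T] (X≠P) sequon scan + curated Asn sites |
| 7 | conformational flexibility | Pro/Gly/Cys gained or lost |
| 8 | surface polarity & charge | RSA + hydrophobicity / formal-charge classes |
| 9 | evolutionary conservation | sulfatase multiple alignment column identity |
| 10 | physiological function | Ca²⁺ ligands and homodimer interface |

For a patient genotype the two allele totals combine as a **sum** or — the
default, and the better ordinal predictor of clinical severity — as a
**product**; a product with a zero-score allele is degenerate and excluded
from correlations.

The package bundles the 86-mutation SGSH reference catalogue and reproduces
its published statistical characterization: mean/SD, the 10/70/6 severity
band partition at mean ± 1 SD, skewness/kurtosis with the small-sample
standard errors SES(n) = √(6n(n−1)/((n−2)(n+1)(n+3))) and
SEK(n) = 2·SES(n)·√((n²−1)/((n−3)(n+5))), the D'Agostino–Pearson omnibus
K² normality test, and an amplitude-form Gaussian fit
y = A·exp(−(x−μ)²/2σ²) to the 12-bin score histogram.

## Worked example

```python
>>> from mpsscore import table1_dataset, describe, histogram, fit_gaussian, band
>>> cat = table1_dataset()
>>> len(cat), cat.get("Arg245His").total
(86, 5)
>>> d = describe(cat.totals())
>>> round(d.mean, 4), round(d.sd, 4), round(d.ses, 4), round(d.sek, 4)
(4.4419, 1.5986, 0.2597, 0.5139)
>>> sorted(band(t, d.mean, d.sd) for t in cat.totals()).count("moderate")
70
>>> fit = fit_gaussian(histogram(cat.totals(), 0, 11))
>>> round(fit.mean, 3), round(fit.sd, 3), round(fit.r_squared, 4), fit.degrees_of_freedom
(4.686, 1.682, 0.9355, 9)
```

The 86 totals centre at 4.44 ± 1.60: every catalogued mutation is predicted
to carry some biogenesis burden, 70/86 a moderate one (scores 3–6), with
6 high-scoring (> 6) and 10 low-scoring (< 3) outliers.  The Gaussian fit
(μ = 4.69, σ = 1.68, R² = 0.94 on 9 degrees of freedom) confirms the
near-normal shape of the distribution.

Genotype-level analysis on a synthetic cohort:

```python
>>> from mpsscore import synth_cohort, attach_scores, severity_correlation
>>> patients = synth_cohort(cat, 500, link="multiplicative", seed=1)
>>> rp = severity_correlation(attach_scores(patients, cat, "product"))
>>> rs = severity_correlation(attach_scores(patients, cat, "sum"))
>>> round(rp.rho, 3), round(rs.rho, 3), rp.rho > rs.rho
(0.842, 0.831, True)
```

De-novo scoring of new mutations runs from the command line against an
evidence bundle (`mpsscore score --config config.yaml --out out/`); see
`mpsscore fixtures --out demo/` for a complete self-contained example of
every input file, and `mpsscore stats` / `mpsscore cohort` for the reports.

## Layout

- `src/mpsscore/catalogue.py` — mutation labels, catalogue I/O, pre-selection
- `src/mpsscore/evidence.py` — evidence bundle readers and validation
- `src/mpsscore/aggrescan.py` — aggregation profile and hot-spot scanner
- `src/mpsscore/scorers.py` — the ten parameter scorers
- `src/mpsscore/scoring.py` — totals, bands, compound genotype scores
- `src/mpsscore/stats.py` — distribution summary, K², Gaussian fit, Spearman
- `src/mpsscore/cohort.py` — patient records, correlations, synthetic cohorts
- `src/mpsscore/fixtures.py` — bundled catalogue and synthetic toy bundle
- `src/mpsscore/cli.py` — `mpsscore score|stats|cohort|fixtures`

See `docs/methods.md` for the scientific and numerical conventions.
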