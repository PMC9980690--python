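# hairpinrcp

Analysis of DNA-methylation *maintenance fidelity* from hairpin-bisulfite
sequencing, plus epigenetic-clock age-acceleration comparisons — aimed at
studies that ask whether two groups of individuals differ in how faithfully
methylation states are copied across the two strands of their DNA.

In hairpin bisulfite sequencing, a UMI-barcoded hairpin linker covalently
joins the two strands of each DNA molecule before bisulfite conversion, so a
single read reports the methylation state of **both** cytosines of each CpG
dyad.  Each dyad is fully methylated (M), fully unmethylated (U) or
hemimethylated (H).  With dyad fractions *f<sub>M</sub>*, *f<sub>U</sub>*,
*f<sub>H</sub>* and single-strand methylation level
*m = f<sub>M</sub> + f<sub>H</sub>/2*, the **Ratio of Concordance
Preference** is

```
RCP = fM · fU / (fH / 2)²  =  fU (fU + 2m − 1) / (1 − fU − m)²
```

RCP = 1 when methyl groups are placed independently on the two strands
(no preference), RCP → ∞ when every dyad is concordant (high maintenance
fidelity), RCP = 0 when every dyad is hemimethylated.

The package provides:

- `synthetic_data` — generator for ground-truth dyad populations at a chosen
  (m, RCP), hairpin-read FASTQ emission with realistic bisulfite error
  channels (failed conversion 0.0039, inappropriate conversion 0.017), and
  beta-value matrices with a recoverable age signal;
- `hairpin_fold` — linker location (bisulfite-tolerant, UMI extraction),
  folding and strand realignment with an asymmetric conversion-aware
  substitution matrix, reference-anchored dyad calling, UMI deduplication,
  and conversion-control tallies;
- `rcp_stats` — the RCP statistic, exact inversion of the conversion-error
  channel, and a hierarchical bootstrap (individuals, then molecules, with
  equal per-individual dyad weighting) yielding one- and two-tailed
  p-values for the between-group RCP difference;
- `clock_age` — any linear methylation clock from a coefficient file
  (including the piecewise log-linear age calibration), AgeAccel residuals,
  Welch t-tests, slope/intercept regression comparisons, and a 2-CpG
  cell-fraction model;
- a `hairpinrcp` CLI chaining everything: `simulate`, `fold`, `rcp`,
  `compare`, `clock`, `run-all`.

## Worked example

```bash
hairpinrcp run-all --config examples/demo.yaml --out-dir demo_out
```

simulates two cohorts of 4 individuals × 30 hairpin molecules at the same
methylation level (m = 0.5) but different maintenance fidelity
(target RCP 16 for the "Bangladesh" group vs 2 for "UK"), emits FASTQ with
2% read slippage and the default conversion error rates, folds the reads
back into dyad calls, and runs the bootstrap comparison (B = 2,000) and a
synthetic clock analysis.  `demo_out/rcp_comparison.json` contains:

```
"rcp_point": {"Bangladesh": 14.42, "UK": 2.03},
"p_one_tailed": 0.0,
"p_two_tailed": 0.0
```

i.e. the corrected point estimates recover the simulated fidelity gap and
no bootstrap replicate puts the difference at or below zero.
`demo_out/fold_qc.json` reports all 240 reads folded (`"ok": 240`) and an
empirical failed-conversion rate of 0.0033 estimated from the linker's
known-unmethylated cytosines (truth: 0.0039).  `demo_out/clock_tests.json`
shows the +5-year simulated age offset split across pooled residuals —
group means +1.50 / −1.91 years (n = 14 / 11), Welch t = 4.29,
p = 2.8 × 10⁻⁴ — with parallel slopes (p = 0.11) and separated intercepts
(p = 5.4 × 10⁻⁵).

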