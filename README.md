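# mircorr

Expression-correlation-guided consensus nomination of miRNA targets.

microRNAs repress their target mRNAs, so across a cohort of matched
miRNA/mRNA expression profiles a genuine (miRNA, target) pair tends to show
a *negative* Pearson correlation. `mircorr` implements the screening
pipeline built on that signal, as used to nominate miR-200-family targets
among lung-cancer prognostic marker genes:

1. **Anti-correlation screen.** For every marker probe set *g* and every
   miRNA *m* over *n* matched samples, compute Pearson's *r* and its
   two-sided p-value via the t transform
   *t = r·√(n−2)/√(1−r²)*, df = *n−2*. A pair is significant when
   |*r*| ≥ 0.258 **and** p ≤ 0.05 (the default profile; the thresholds,
   their conjunction, and Benjamini–Hochberg adjusted p-values are all
   configurable).
2. **Consensus with sequence-based predictions.** Prediction tables
   exported from TargetScan, PicTar, miRDB and microRNA.org are normalized
   to one schema; a (miRNA, gene) pair is nominated when ≥1 source
   predicts it *and* ≥1 probe of that gene is significantly negatively
   correlated with the miRNA (genes often carry 1–3 discordant probe
   sets, hence the at-least-one-probe rule).
3. **Annotation.** Experimentally validated interactions (TarBase-style
   catalogue) are flagged, and 3′UTR binding sites are counted after
   filtering on mirSVR score ≤ 0 and PhastCons score ≥ 0 (inclusive).
4. **Bench validation arithmetic.** qPCR fold change by the Livak rule
   *fold = 2^−ΔΔCt* with ΔCt = Ct(target) − Ct(endogenous control),
   western-blot densitometry normalized to a loading control and to the
   scrambled-miRNA reference, tumor-vs-normal fold changes with unpaired
   t-tests, and the confirmation call: a predicted target is *confirmed*
   when its mRNA is significantly downregulated or its protein drops by
   at least 15% relative to the negative control.

A synthetic-cohort generator plants (miRNA, gene) repression at exact
population correlations, simulates per-tool prediction tables with
controlled false-positive/negative rates and synthetic Ct tables, so the
whole pipeline runs and is scored for recovery without any downloads.

Intended users: computational biologists screening matched expression
cohorts for candidate miRNA regulation, and anyone needing tested,
parameterized ΔΔCt/densitometry arithmetic.

## Worked example

```python
from mircorr import (screen_targets, delta_delta_ct, simulate_ct_table,
                     recovery_metrics)
from mircorr.synthetic_data import (SimulationConfig, plant_random_pairs,
                                    simulate_cohort, simulate_prediction_tables)

pairs = plant_random_pairs(n_genes=60, n_mirnas=8, n_pairs=8, target_r=-0.5, seed=11)
cfg = SimulationConfig(seed=11, n_genes=60, n_mirnas=8, planted_pairs=pairs)
cohort, meta, truth = simulate_cohort(cfg)
predictions = simulate_prediction_tables(truth, fp_rate=0.01, fn_rate=0.2, seed=11)

out = screen_targets(cohort, predictions)
print(f"{len(out.screen.results)} pairs screened, {len(out.significant)} significant, "
      f"{len(out.targets)} consensus targets")
m = recovery_metrics(out.targets, truth)
print(f"sensitivity={m.sensitivity:.2f} precision={m.precision:.2f}")

ct = simulate_ct_table(true_fold=0.5, replicate_sd=0.2, n_replicates=3, seed=11)
res = delta_delta_ct(ct, "TARGET", "UBC", "miR-200", "miR-scr")
print(f"ddCt={res.delta_delta_ct:.3f} fold={res.fold:.3f} p={res.p:.4f}")
```

prints

```
944 pairs screened, 71 significant, 10 consensus targets
sensitivity=1.00 precision=0.80
ddCt=0.990 fold=0.504 p=0.0031
```

The screen scored 944 (probe, miRNA) pairs over the 57-sample cohort, 71
passed the |r| ≥ 0.258 & p ≤ 0.05 rule, and intersecting with the four
noisy prediction tables left 10 consensus pairs — all 8 planted
regulations recovered plus 2 false nominations (precision 0.80). The Ct
table was simulated with a true 2-fold repression: the recovered fold of
0.504 and its replicate t-test p = 0.003 show the ΔΔCt chain inverting
the planted effect.

The same steps are available from the shell via
`mircorr simulate | ingest | correlate | consensus | quantify`
(see `mircorr --help`).

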