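"""Run the full pipeline: simulate -> lexicon -> score -> diagnose -> fit.

A single seeded config drives every stage; artifacts (panel, corpus,
lexicon, local coefficients, diagnostics report, manifest) land in the
output directory. The same run is available from the shell as
``hpagtwr run --seed 7 --out scratch/runs/demo``.
"""

import hpagtwr as h

cfg = h.PipelineConfig(seed=7)
cfg.generator.update(n_cities=60, cooccurrence_sentences=600)

result = h.run_pipeline(cfg, "scratch/runs/demo")

print(f"artifacts in {result.run_dir}:")
for out in result.manifest["outputs"]:
    print(f"  {out['path']}")

print(f"\ncurated lexicon: {len(result.lexicon)} words")
print(f"Moran's I on city-mean HPA: {result.report.morans_i:.4f} "
      f"(permutation p = {result.report.morans_p:.3f})")
print(f"GTWR adj R^2 = {result.fit.adj_r2:.3f} vs OLS {result.ols.adj_r2:.3f}")
print(f"GTWR AICc    = {result.fit.aicc:.1f} vs OLS {result.ols.aicc:.1f}")
print("\nperiod-averaged coefficients (pandemic split at 2020):")
print(result.report.period_averages.round(4).to_string())
# Strong positive Moran's I justifies the spatial model; the GTWR/OLS gap
# in AICc and adjusted R^2 mirrors the gain from letting coefficients vary.
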