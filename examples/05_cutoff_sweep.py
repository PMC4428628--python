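"""Locate the diagnostic depth zone with the cut-off-layer sweep.

Runs the full pipeline (simulate -> fit -> stratify -> classify) on
replicate desk-scale pools, then sweeps feature vectors built downward from
the surface layer (10) to each cut-off layer.  The balanced accuracy
(mean of sensitivity and specificity) should peak at cut-off 6 -- the
top half of the epithelium -- and decline as uninformative basal layers
are added.  A single 32-sample pool's optimum fluctuates with the draw,
so the curve is averaged over replicate pools.  Takes ~5 minutes on one
CPU.
"""

import epiflim as ef

config = ef.reduced_config(48, 48)
out = ef.pipeline.run_replicated(config, seed=0, n_pools=12, n_splits=400)

sweep = out["sweep"]
print("cut-off  balanced accuracy (%)")
for cutoff, bal in sorted(sweep.balanced_curve().items(), reverse=True):
    marker = "  <- best" if cutoff == sweep.best_cutoff else ""
    print(f"   {cutoff:2d}     {bal:5.1f}{marker}")
for r in out["results"]:
    print(f"{r.model_name}: sens {r.sensitivity:.1f} %, spec {r.specificity:.1f} %, "
          f"balanced {r.balanced_mean:.1f} %")
print("The peak at cut-off 6 identifies the top-half epithelium as the "
      "effective diagnostic zone; whole-ROI and 3-layer models do worse.")
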