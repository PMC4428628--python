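# epiflim

Layer-resolved fluorescence-lifetime (FLIM) analysis of stratified
epithelium for early cervical-cancer screening, as a tested, fully
synthetic-reproducible Python pipeline.

Cervical precancer (CIN1–3) is graded by how much of the epithelial
thickness is occupied by immature neoplastic cells.  In FLIM images of
H&E-stained sections, the long lifetime component τ₂ of the eosin decay
tracks cellular maturation: in normal epithelium the per-layer mean τ₂
rises steadily from the basal layer to the surface, while CIN shortens it
and flattens the top half.  `epiflim` implements the full analysis chain
that turns this contrast into a diagnosis:

1. **synthetic tissue** — decay cubes (per-pixel TCSPC photon histograms)
   of wavy epithelial bands with calibrated per-layer τ₂ profiles for
   normal/CIN1/CIN2/CIN3 and realistic between-sample variability;
2. **decay fitting** — per-pixel weighted NLLS of the IRF-convolved model
   I(t) = a₁e^(−t/τ₁) + a₂e^(−t/τ₂) (variable projection, 50-photon
   threshold, rising-edge IRF estimate refined on the pooled decay);
3. **layer stratification** — normalized depth d_L/(d_L+d_M) between the
   basement-membrane (L) and surface (M) polylines, divided into k equal
   layers (layer 1 basal, layer k superficial), per-layer μ and σ of τ₂;
4. **ELM classification** — extreme learning machine (random logistic
   hidden layer, output weights β = H⁺T via Moore–Penrose pseudoinverse)
   with 1000× random 16/16 train/test subsampling, reporting sensitivity
   (CIN detection) and specificity (normal clearance);
5. **cut-off-layer sweep** — feature vectors (μ₁₀, …, μ_c) built downward
   from the surface for cut-offs c = 10…1, locating the depth zone that
   maximizes (sensitivity + specificity)/2.

The headline structural result this package reproduces on its calibrated
synthetic pools: the sweep optimum is **cut-off layer 6** — the top half of
the epithelium is the effective diagnostic zone — and the ten-layer model
outranks whole-epithelium and three-layer analysis.

## Worked example

```bash
python examples/03_layer_features.py
```

```
normal: per-layer mean tau2 (ps), basal -> superficial
   690   747   740   797   838   848   905   919   959   997
CIN3: per-layer mean tau2 (ps), basal -> superficial
   680   734   719   770   798   700   734   720   736   749
```

Each number is the mean fitted τ₂ (ps) of one of ten equal-thickness
layers, recovered by the full simulate → fit → stratify chain at desk
scale.  The normal section ramps ~700 → 1000 ps with depth (maturation);
the CIN3 section is shortened and nearly flat across layers 6–10
(maturation arrest) — the contrast the classifier uses.

`examples/` contains one short script per capability (pool simulation,
decay fitting, layer features, ELM classification, the cut-off sweep).
The same stages are scriptable from a shell via the `epiflim` CLI
(`simulate`, `fit`, `layers`, `classify`, `sweep`, `report`, `run-all`).

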