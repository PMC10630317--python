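# fibranet

Quantitative morphometry of fibrous-network micrographs and mesoscale
elasticity from spherical micro-indentation, with synthetic generators that
carry analytic ground truth for every stage.

The package covers the full analysis chain for growth-gradient studies of
layered fiber networks imaged by electron microscopy:

* **segmentation** — Otsu / adaptive-mean / fixed thresholding of grayscale
  micrographs, plus ingestion of externally drawn (manual) masks, with
  provenance tags.
* **network** — skeletonization with junction clustering; fiber radii from
  the Euclidean distance transform sampled along the centerline (junction
  zones excluded); crosslink density ρ_b (μm⁻²); mean segment length l_c
  over a 1–10 μm window with border exclusion; network density ρ (μm/μm²)
  with dangling branches pruned.
* **fiber_typing** — 1-D Gaussian-mixture deconvolution of the radius
  histogram; the number of dominant fiber types is selected by AIC.
* **pores** — complete-pore identification (4-connected background,
  border-touching components flagged), pore-area histograms with dominant-
  and small-pore fractions, porosity, and per-layer table aggregation.
* **indentation** — three-stage (load/dwell/unload) force–indentation
  parsing, pop-in detection, and moduli via the contact-point-free
  derivative form of the Hertz model: fit `dF/du = K·F^n` on a 5–30 μN
  window, gate on `|n − 1/3|`, invert `E* = K^{3/2}(6R)^{-1/2}`.
* **report** — per-layer bundles, percent changes along the gradient,
  validity ratios (R/l_c > 12, r/l_c), and the modulus-vs-crosslink-density
  correlation.
* **synthetic** — capsule-network images and Hertzian indentation curves
  with seeds, noise, contact offsets and pop-in events; every artifact
  ships with exact ground truth (crossing counts, radii, area fraction),
  including a constraint-sampled "sparse" mode where every crossing is
  individually resolvable, and a gradient generator that tunes layers to
  crosslink-density / modulus targets.

Units are μm / μN / kPa throughout (1 μN/μm² = 1 MPa = 1000 kPa, converted
in exactly one place).

## CLI

```sh
# synthetic data with ground-truth sidecars
fibranet simulate network  --seed 3 --out net/
fibranet simulate network  --seed 3 --sparse --out net-sparse/
fibranet simulate indent   --seed 1 --out ind/
fibranet simulate gradient --seed 5 --out grad/

# analysis
fibranet analyze-image net/micrograph.png --pixel-size 0.033 --segmentation otsu --out L-1.json
fibranet analyze-image img.png --pixel-size 0.033 --segmentation mask=manual.png --out L-2.json
fibranet analyze-indent ind/curve.csv --radius-um 92.03 --window 5:30 --poisson 0

# gradient report (CSV + JSON, optional scatter plot)
fibranet report L-1.json L-2.json L-3.json --out report/ --plot
```

Curve CSVs use the header `time_s,depth_um,force_uN`; images are 8-bit
PNG/TIFF with the pixel size passed explicitly.

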