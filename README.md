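# eoseg

Spectral-residual localization of **eosinophils** in multispectral images of
H&E-stained esophagus tissue.

Eosinophil infiltration of the esophagus is the histologic hallmark of
eosinophilic esophagitis, and counting eosinophils on H&E sections is how
pathologists grade it. The catch: eosinophils are eosin-stained pink-red —
essentially the same broadband color as red blood cells and other
connective-tissue structures — so RGB pixel color alone cannot isolate them.
A multispectral acquisition (here, 14 averaged bands spanning 450–720 nm)
retains the narrow-band differences that broadband RGB filters wash out, and
this package exploits them with a simple anomaly-detection scheme:

1. **Transmittance.** Each pixel's spectrum is the ratio of the specimen
   signal to the blank-glass signal per band, `t = i_s / i_g`.
2. **PCA on everything *except* the target.** A principal-component basis
   is fit to the sample covariance `C = (1/(q−1)) Σ (f_k − f̄)(f_k − f̄)ᵀ` of
   labeled transmittance spectra of five tissue classes — nucleus,
   cytoplasm, RBC, fiber, white (tissue-free) area — with eosinophil
   samples deliberately excluded.
3. **Spectral error.** With `m` eigenvectors (m = 5, one per in-model
   class, capturing ≥ 99.99 % of the training variance) every in-model
   pixel reconstructs almost perfectly as
   `f̂ = f̄ + Σᵢ αᵢ vᵢ`, `αᵢ = vᵢᵀ(f − f̄)`, while eosinophil pixels leave a
   structured residual `e = f − f̂`.
4. **Two-band difference.** The mean eosinophil residual has a positive
   peak at band `r` and a negative peak at band `s` (on the 14-band scheme:
   band 10, 630–645 nm, and band 7, 570–585 nm). The scalar map
   `d = e_r − e_s` is high exactly on eosinophils.
5. **Segmentation.** Threshold `d ≥ T` (Otsu by default), morphological
   closing plus small-object removal, and a boundary overlay on an RGB
   rendering.

A k-means (k = 6) clustering of the RGB rendering serves as the baseline it
outperforms: in three broadband channels eosinophils and RBCs fall into the
same cluster.

Because no public multispectral H&E data exist for this task, the package
ships a first-class synthetic phantom generator (`eoseg.synthetic`) built on
Beer–Lambert absorption of the two dyes, with exact ground-truth masks; the
whole pipeline is developed and validated end-to-end against it.

## Worked example

```bash
eoseg simulate --out-dir scene --seed 0 --size 128
eoseg fit --cube scene/cube.tif --sidecar scene/cube.wl \
    --mask scene/truth.png --labels scene/params.yaml --out model.yaml
eoseg segment --cube scene/cube.tif --sidecar scene/cube.wl \
    --model model.yaml --out-dir seg
```

The `fit` step prints

```
  cytoplasm: 10412 samples
  eosinophil: 665 samples
  fiber: 1326 samples
  nucleus: 1314 samples
  rbc: 1010 samples
  white: 1657 samples
explained variance at m=5: 99.9820%
band pair (1-based): r=10 (positive peak), s=7 (negative peak)
```

i.e. five principal components capture 99.98 % of the in-model variance on
this 128×128 scene, and the eosinophil residual peaks land on bands 10 and
7 — the construction bands of the phantom. `eoseg select-bands --model
model.yaml` tabulates the mean residual per band:

```
band    wavelength   mean error
   7    570-585 nm     -0.03309  <- s
  10    630-645 nm      0.07752  <- r
```

The `segment` step reports `threshold=0.01898  foreground px=667` and writes
`mask.png` (the binary eosinophil mask, here recovering the 665 true
eosinophil pixels with a handful of boundary pixels), `overlay.png`
(outlines on the RGB rendering) and the two grey-level error images in
which eosinophils appear as the brightest (band 10) and darkest (band 7)
spots. `eoseg rgb-baseline` writes the RGB rendering and the k-means
cluster map for comparison.

Cubes are multi-page 16-bit TIFFs with a plain-text wavelength sidecar
(one `lo_nm hi_nm` pair per line); `--group 4` averages the native 55-band
5 nm grid down to the 14-band scheme, and `--reference glass.txt` converts
raw counts to transmittance first.

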