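# statedge

Color edge extraction for microscopy images using second-order statistical
features and automatic thresholding.

The package targets stained-cell micrographs — e.g. breast-cancer tissue
sections where immunohistochemistry highlights hormone-receptor-expressing
cells — where clinicians need closed, clean cell boundaries to recognize
and count cells. Plain gradient detectors (Prewitt, Sobel, Canny) produce
broken or over-detected contours on such images and then need costly
post-processing. `statedge` instead detects edges in a *texture* domain:
abrupt changes in the local second-order statistics of each color channel.

## Method

For each primitive color channel `I(x, y)` (gray levels 0–255):

1. **Attribute image.** A `t×t` window slides over every pixel. In each
   window the gray-level co-occurrence matrix `Cooc(i, j)` counts pixel
   pairs at distance `d` for the orientations θ ∈ {0°, 45°, 90°, 135°};
   a scalar feature of the normalized matrix `p(i, j)` is averaged over
   the four orientations and assigned to the center pixel, giving the
   attribute image `Ia(x, y)`. Built-in features:

   | name    | formula                                  | meaning                |
   |---------|------------------------------------------|------------------------|
   | `dm`    | Σ √(½·\|i−j\|·p(i,j))                    | off-diagonal moment    |
   | `direc` | Σᵢ p(i,i)                                | fraction of equal pairs|
   | `ener`  | Σ p(i,j)²                                | uniformity (default)   |
   | `odm`   | Σ p(i,j)/(1+(i−j)²)                      | homogeneity            |
   | `var`   | Σ (i−μ)²·p(i,j)                          | variance (extension)   |

2. **Edge strengths.** Eight 3×3 compass patterns `ES1..ES8` (weighted
   sums over the 8-neighborhood) respond to edges passing through the
   pixel in eight configurations; the local maximum edge strength is
   `LMES(x, y) = max₁≤k≤8 |ESₖ(x, y)|`.

3. **Automatic threshold.** The LMES histogram (bins 0..L, L = 255) is
   split by Otsu's criterion: the threshold `T` maximizes the
   between-class variance `σ_B²(t) = w₁(μ₁−μ_T)² + w₂(μ₂−μ_T)²`.
   A pixel is an edge in that channel iff `LMES(x, y) ≥ T`.

4. **Fusion.** The final map is the logical OR of the three channel maps:
   `E(x, y) = 1` iff at least one of `E_R`, `E_G`, `E_B` is 1. No
   thinning or gap-filling follows.

Evaluation statistics: segmentation sensitivity
`Sen(%) = N_pcc/(N·M)·100` (pixelwise label agreement, both classes), and
the classification probabilities `P_C = N_1C/N_1r` (a true cell/edge pixel
is marked as such) and `P_f = N_1f/N_2r` (a background pixel is falsely
marked), optionally with a pixel tolerance for thin edge references.

A synthetic generator provides ground-truth test material: two-region
images with a known 1-pixel boundary, cell-like blob images, and
salt-and-pepper corruption of density `D` (affecting ≈ `D·M·N` pixels).

## Worked example

```sh
statedge synth --kind two-region --noise 0.0 --seed 0 --out demo
statedge detect demo/image.png --out demo/run
statedge evaluate demo/run/edges_mask.png demo/edges.png --tolerance 2
```

which prints

```
T_R = 0.787441, 1956 edge pixels
T_G = 0.787441, 1956 edge pixels
T_B = 0.787441, 1956 edge pixels
fused edge pixels: 1956
wrote demo/run/edges_mask.png and demo/run/edges_overlay.png
segmentation evaluation
-----------------------
Sen(%)         97.06   (Npcc = 63612)
Pc            1.0000   (N1c = 336 / N1r = 336)
Pf            0.0086   (N1f = 560 / N2r = 65200)
tolerance        2.0   px
```

The three channels select their thresholds independently (they coincide
here because the default energy feature depends only on gray-level
*equality* patterns, which the synthetic two-color geometry makes
identical across channels). Every pixel of the true boundary is matched
within 2 px (`Pc = 1`), 0.9 % of background pixels fall in the detection
band beyond that radius (`Pf`), and 97.06 % of all pixels carry the
correct label — the band is a few pixels wide because the method applies
no thinning.

The same pipeline is available as a library:

```python
from statedge import DetectorConfig, detect_color_edges, evaluate_edge_maps
from statedge import generate_two_region_image

img, region, edges = generate_two_region_image(radius=60, noise=0.0, seed=0)
result = detect_color_edges(img, DetectorConfig(feature="ener", window_size=5))
print(evaluate_edge_maps(result.fused, edges, tolerance=2).summary())
```

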