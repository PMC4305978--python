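# ihcaudit

Image-analysis-assisted stereology marking of immunohistochemistry (IHC)
tissue-microarray spots, and auditing of expert-corrected annotations.

## The problem

Calibrating digital image analysis (DIA) for IHC scoring — here the
proliferation marker Ki67 in breast carcinoma — needs reference data:
thousands of tumour nuclei marked positive or negative by an expert on
unbiased counting frames. Fully manual marking is the bottleneck. A
practical shortcut is to let the DIA produce an initial mark set
(**dD**, "digital data"), overlay it on the spot image together with a
stereology grid, and have the expert *edit* rather than *create* the
marks, yielding the corrected reference set (**cD**). The difference
between dD and cD is then itself informative: every edit grades one
component of the DIA.

`ihcaudit` implements that whole loop on open data structures:

* **markup decoding** — the DIA's multicolor markup raster is turned
  into labeled point marks via the excess-RGB transform
  (`2R−G−B`, `2G−R−B`, `2B−R−G`), fixed thresholds on the excess-red
  (Ki67-positive) and excess-blue (negative) channels,
  8-connected component labeling and centroid extraction;
* **stereology** — systematic uniform random grids of unbiased 2D
  counting frames; a point mark at (x, y) is counted by frame
  `(x0, y0, w, h)` iff `x0 < x ≤ x0+w` and `y0 ≤ y < y0+h` (left and
  bottom edges forbidden), and the grid spacing can be autosized as
  `frame_size / √f` with `f = target/detected` so each spot yields a
  chosen review workload;
* **annotation XML** — an ImageScope-style dialect
  (`Annotations → Annotation → Regions → Region → Vertices → Vertex`)
  carrying point marks per label layer plus the grid as rectangles,
  with lossless, byte-stable round trips;
* **audit** — greedy nearest-neighbour matching of dD against cD,
  classification of every difference (true positive/negative, label
  flips, false detections, under-detections attributed to the
  tissue-mask vs the nuclear-segmentation component via the epithelial
  mask), and per-spot tallies;
* **statistics** — per-series OLS regression of Ki67% (R² = 1 −
  SS_res/SS_tot), Bland–Altman bias and limits of agreement
  (bias ± 1.96·SD of differences), and effort summaries including the
  savings fraction `1 − edits/nuclei`;
* **synthetic data** — a generator of circular TMA spots with
  non-overlapping elliptical nuclear profiles, DIA-style markup masks
  and *logged* injected errors, so the audit can be validated exactly
  against ground truth.

## Worked example

```python
from ihcaudit import (ErrorModel, audit_spot, event_tallies,
                      full_tiling_grid, generate_spot,
                      marks_from_markup, simulate_cd)

em = ErrorModel(p_miss_tissue=0.03, p_miss_nuclear=0.2,
                false_detections_per_spot=30.0,
                p_label_flip_pos=0.01, p_label_flip_neg=0.02, seed=5)
spot = generate_spot(500, 30.0, 896, em, "audit-demo")
dd = marks_from_markup(spot.markup_mask, spot_id="audit-demo")
cd = simulate_cd(spot, dd)
audit = audit_spot(dd, cd, full_tiling_grid(896, 896, 150, 150),
                   spot.tissue_mask)
```

Running this (`python examples/03_audit_pair.py`) prints:

```
dD marks 421, cD marks 500, edits 159
Ki67% dD 28.2 vs cD 28.4
category                      audit  injected
FALSE_POSITIVE_LABEL              4         4
FALSE_NEGATIVE_LABEL              0         0
FALSE_DETECTION                  40        40
UNDETECTED_BY_TISSUE_MASK        12        12
UNDETECTED_BY_NUCLEAR           103       103
```

The machine found 421 of 500 nuclei; the expert made 159 edits, and
every one of them is attributed to the component that caused it — the
audit tallies equal the generator's injected event log exactly, while
the spot-level Ki67% moves only from 28.2% to 28.4%: cell-level errors
largely cancel in the summary index.

The other scripts in `examples/` demonstrate markup decoding
(`01_decode_markup.py`), grid generation and autosizing
(`02_counting_grid.py`) and series-level statistics
(`04_series_statistics.py`).

## Command line

```sh
ihcaudit synth --n-spots 10 --seed 1 --out work/      # synthetic fixtures
ihcaudit wizard work/*.markup.png --target-marks 300 --out work/
ihcaudit audit work/ --out report/                    # CSVs, JSON, plots
```

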