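# respiro

Bright-field image analysis for respiratory organoids: extended-focus
stitching of multi-field z-stacks, organoid segmentation (U-Net or a
classical threshold baseline), watershed instance separation with rich
morphometrics, time-lapse tracking, and dye-free quantification of
forskolin-induced swelling (FIS).

## The scientific problem

Airway organoids — 3D cultures from nasal brushings or iPSC-derived
lung tissue — are the standard personalized readout for CFTR channel
function in cystic fibrosis. In the FIS assay, forskolin activates
CFTR, fluid enters the organoid lumen, and the organoid swells; the
area fold change over ~24 h reports how well the channel works.
Healthy-donor organoids swell strongly, organoids carrying variants
such as F508del swell weakly, and CFTR-modulator drugs shift the
response.

The classical readout needs a fluorescent dye (calcein) and confocal
imaging. This package implements a dye-free alternative on plain
bright-field images, where organoids appear as bright-lumen,
dark-rimmed structures:

1. **EFSI construction** — each well is imaged as a grid of fields,
   each field as a z-stack. Per-pixel variance-of-Laplacian focus
   stacking fuses each stack; the fields are stitched with feathered
   blending and centre-cropped into a single sharp *extended-focus
   stitched image*.
2. **Preprocessing** — 1–99 percentile normalization, CLAHE, resize to
   the network input (2100 px → 512 px, a 4.1× downsample).
3. **Segmentation** — a U-Net (pure-numpy, bit-reproducible, trained
   with a soft-Dice loss) or a minimum-cross-entropy (Li) threshold
   baseline produce organoid/background masks.
4. **Instances & morphometrics** — marker-controlled watershed on the
   distance transform splits touching organoids; per object the package
   measures area (px and µm²), Crofton perimeter, form factor,
   eccentricity, solidity, Feret diameters, Euler number and more, then
   filters artifacts by area and form factor.
5. **Tracking & FIS** — reverse-chronological nearest-centroid matching
   (growing organoids are matched from their final, largest footprint
   backwards), per-track fold change area(t)/area(0 h), the assay
   filter (baseline ≥ 1500 px, fold ≥ 0.8), and per-group
   median/quartile summaries.

A synthetic phantom generator with exact ground truth (including
z-stacks, tile grids, annotator noise and per-organoid growth factors)
makes every stage testable without real data.

## Worked example

Synthesize a two-well FIS experiment (a strong-swelling "healthy" well,
growth factor 1.8, and a weak-swelling "cf" well, 1.4), run the whole
pipeline, and read the recovered swelling table:

```python
from pathlib import Path
import numpy as np
import pandas as pd

from respiro.core import PipelineConfig, tile_filename, write_zstack
from respiro.phantom import advance_time, cut_tiles, generate_scene, render_zstack_tiles
from respiro.pipeline import run_pipeline

root = Path("demo")
raw = root / "raw"

# 1. synthesize raw data: two wells imaged at 0 h and 24 h as 2x2 grids
#    of 3-plane z-stacks
for w, (well, growth) in enumerate([("healthy", 1.8), ("cf", 1.4)]):
    scene, truth = generate_scene(
        n_organoids=4, size_range_px=(24, 34), n_bubbles=1, seed=60 + w,
        canvas_side_px=360, growth_range=(growth, growth),
    )
    for tp, sc in ((0.0, scene), (24.0, advance_time(scene, 1.0))):
        stacks, ref = render_zstack_tiles(sc, n_planes=3, nx=2, ny=2,
                                          well_id=well, timepoint_h=tp)
        d = raw / well / f"{tp:g}"
        d.mkdir(parents=True, exist_ok=True)
        for st in stacks:
            r, c = st.grid_pos
            write_zstack(st, [d / tile_filename(well, tp, r, c, z)
                              for z in range(st.n_planes)])

# 2. configure and run: EFSI -> segment -> instances -> track -> FIS
#    (the tile cutter uses exact integer overlaps; recover them here)
_, ox, oy = cut_tiles(np.zeros((360, 360)), 2, 2, 0.1)
w = (360 + ox) // 2  # tile side for a symmetric 2x2 grid
cfg = PipelineConfig(grid_nx=2, grid_ny=2,
                     overlap_frac_x=ox / w, overlap_frac_y=oy / w,
                     crop_side_px=320, network_side_px=128,
                     backend="threshold", min_area_px=150.0, seed=0)
manifest = run_pipeline(cfg, raw, root / "out", fis_t0_h=0.0, fis_t1_h=24.0)
print("outputs:", ", ".join(manifest["outputs"]))

# 3. read the consolidated swelling table
fis = pd.read_csv(root / "out" / "fis.csv")
print(fis.to_string(index=False))
print()
print(fis.groupby("well_id").fold_change.median().rename("median_fold"))
```

Output (exactly as printed):

```
outputs: cf_0_objects.csv, cf_24_objects.csv, cf_tracks.csv, healthy_0_objects.csv, healthy_24_objects.csv, healthy_tracks.csv, fis.csv, fis_summary.csv
 track_id well_id  area_t0_px  area_t1_px  fold_change
        1      cf        1992        2746     1.378514
        1 healthy        2829        4977     1.759279
        2 healthy        2354        4443     1.887426

well_id
cf         1.378514
healthy    1.823352
Name: median_fold, dtype: float64
```

The pipeline recovers the generator truth well: median fold change
1.823 vs a true growth factor of 1.8 for the healthy-like well, and
1.379 vs 1.4 for the CF-like well, in the correct order. (Tracks whose
baseline is under the 1500 px assay bound are filtered out, which is
why fewer tracks appear than organoids were placed.)

The same flow is available from the command line:

```bash
respiro synth --preset fis-demo --seed 7 --out-dir demo/raw   # phantom fixture set
respiro run --config cfg.yaml --in demo/raw --out demo/out --t0 0 --t1 24
respiro --help                                                # all subcommands
```

Subcommands: `run`, `efsi`, `preprocess`, `segment`, `measure`,
`track`, `fis`, `eval`, `synth`, `train`.

## Training the U-Net

The full-scale profile (depth 5, 32 base filters, 512 px inputs, SGD
momentum 0.9, lr 0.01 halved every 75 epochs, batch 16, 1000 epochs)
is constructible and trainable, but needs real data and long wall
time. The desk-scale profile (depth 3, base 8, 128 px, batch 4, lr
0.03, 60 epochs) trains in ~2 minutes on one CPU and reaches IoU ≥ 0.9
on phantom scenes, comfortably beating the classical baseline (~0.46
on the same scenes, ~0.66 on its best-case scenes):

```bash
respiro train --images imgs/ --masks masks/ --out model.npz --depth 3 --base-filters 8 --epochs 60
respiro segment --backend unet --model model.npz --in efsi.tif --out mask.png
```

Training uses a foreground soft-Dice loss with normalized gradient
steps — see `docs/methods.md` for why this is more stable at small
batch sizes than inverse-volume class weighting.

## Reproduction

```bash
pip install --no-build-isolation -e ".[test]"
pytest                                        # full suite, ~3 min on one CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the release-gate properties (unit
conversions, geometry, split sizes, metric identities, fusion/stitch
oracles, watershed and morphometric oracles, desk-scale training,
end-to-end FIS recovery, byte-level determinism). The acceptance
script re-runs the main computations (~2.5 min, dominated by network
training) and writes the headline quantities — e.g. with `--seed 1`:
`phantom_unet_train_iou` 0.946 vs `phantom_classical_iou` 0.464,
`fis_recovery_max_rel_err` 0.046, `stitch_rmse` ~2e-17,
`determinism_csvs_identical` true.

Everything is deterministic under the configured seed; two identical
runs produce byte-identical CSVs.

## Layout

- `src/respiro/core.py` — shared types, TIFF/PNG/CSV/YAML I/O
- `src/respiro/efsi.py` — focus stacking, stitching, cropping
- `src/respiro/preprocess.py` — normalization, CLAHE, resizing
- `src/respiro/segmentation.py` — numpy U-Net, training, Li baseline
- `src/respiro/objects.py` — watershed, filtering, morphometrics
- `src/respiro/tracking.py` — reverse tracking, fold changes, FIS filter
- `src/respiro/evaluation.py` — metrics, consensus, splits, size R²
- `src/respiro/phantom.py` — synthetic scenes with exact ground truth
- `src/respiro/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — design rationale and known limitations
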