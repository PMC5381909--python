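#!/usr/bin/env python
"""Segment the phantom cohort with both methods and tabulate the metrics.

Runs local fuzzy thresholding and the global rigid baseline on each of the
five phantoms, evaluates DSC / sensitivity / specificity / accuracy for the
core and rim classes against ground truth, and counts the isolated-pixel
artifact of rigid thresholding.  Writes results/metrics_fuzzy.csv,
results/metrics_global.csv and results/isolated_pixels.csv; label previews
go to scratch/segmentation/.
"""

from pathlib import Path

import pandas as pd

from polseg import (PhantomSpec, generate, global_cutoffs, metrics_table,
                    segment_global, segment_local_fuzzy, suggest_rois)
from polseg.io import write_label_preview
from polseg.segmentation import LABEL_RIM, count_isolated_pixels

ROOT = Path(__file__).resolve().parents[1]
SEEDS = (1, 2, 3, 4, 5)

pairs = {"fuzzy": [], "global": []}
iso_rows = []
for seed in SEEDS:
    phantom = generate(PhantomSpec(), seed=seed)
    fuzzy = segment_local_fuzzy(phantom.delta)
    cuts = global_cutoffs(phantom.delta, suggest_rois(phantom.gt))
    rigid = segment_global(phantom.delta, cuts)
    pairs["fuzzy"].append((phantom.gt, fuzzy))
    pairs["global"].append((phantom.gt, rigid))
    outdir = ROOT / "scratch" / "segmentation" / f"sample{seed}"
    write_label_preview(fuzzy, outdir / "fuzzy.png")
    write_label_preview(rigid, outdir / "global.png")
    iso_rows.append({"sample": seed,
                     "isolated_rim_px_fuzzy": count_isolated_pixels(fuzzy, LABEL_RIM),
                     "isolated_rim_px_global": count_isolated_pixels(rigid, LABEL_RIM)})

(ROOT / "results").mkdir(exist_ok=True)
for method, batch in pairs.items():
    df = metrics_table(batch)
    df.to_csv(ROOT / "results" / f"metrics_{method}.csv", index=False,
              float_format="%.4f")
    summary = df[df["sample"].isin(["mean", "sd"])]
    print(f"\n=== {method} thresholding (mean/sd over {len(SEEDS)} samples) ===")
    print(summary[["sample", "class", "dsc", "sensitivity", "specificity",
                   "accuracy"]].to_string(index=False,
                                          float_format=lambda x: f"{x:.3f}"))

iso = pd.DataFrame(iso_rows)
iso.to_csv(ROOT / "results" / "isolated_pixels.csv", index=False)
print("\nisolated single-pixel rim components per sample:")
print(iso.to_string(index=False))
print("\nfuzzy thresholding suppresses the isolated pixels that rigid "
      "cut-offs produce; tables under results/")
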