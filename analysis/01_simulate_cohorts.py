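"""Simulate the two imaging cohorts.

Renders 16 wild-type (WT) and 14 MMP13-knockout (KO) synthetic tumor-boundary
fields of view — three channels each (collagen I IF, backward SHG, forward
SHG) plus one blank-slide acquisition per slide — and writes them as
multi-page TIFF z-stacks under scratch/cohorts/, with a combined manifest at
results/manifest.csv.
"""

from pathlib import Path

import pandas as pd

from tacsquant import make_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

def main() -> None:
    out_dir = ROOT / "scratch" / "cohorts"
    manifests = []
    for group, n_fovs, seed in (("WT", 16, SEED), ("KO", 14, SEED + 1)):
        bundles = make_cohort(group, n_fovs, seed)
        manifests.append(write_cohort(bundles, out_dir, group))
        print(f"{group}: rendered {n_fovs} FOVs "
              f"({bundles[0].if_stack.voxels.shape[2]} px across, "
              f"{bundles[0].if_stack.n_slices} slices)")
    manifest = pd.concat(manifests, ignore_index=True)
    (ROOT / "results").mkdir(exist_ok=True)
    manifest_path = ROOT / "results" / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    print(f"wrote {len(manifest)} manifest rows to {manifest_path}")

if __name__ == "__main__":
    main()
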