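"""MEMRI voxel and region statistics.

Median smoothing, voxelwise homoscedastic t-map, TFCE, permutation
multiple-comparison correction at the 99.9th percentile, cluster
filtering, and region-wise t + FDR tests of manganese enhancement."""

import argparse
import json

import pandas as pd

from rodentfc.pipeline import load_config, run_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default="analysis/config.toml")
    args = ap.parse_args()
    cfg = load_config(args.config)
    out = run_stage("memri", cfg)
    summary = json.loads((out / "memri_summary.json").read_text())
    stats = pd.read_csv(out / "memri_region_stats.tsv", sep="\t")
    n_regions = len(stats)
    print(f"permutation threshold {summary['threshold']:.1f} "
          f"({summary['pipeline']} pipeline, {summary['percentile']}th pct): "
          f"{summary['n_significant_voxels']} significant voxels in "
          f"{summary['n_clusters']} cluster(s)")
    print(f"region tests: {summary['n_significant_regions']} of {n_regions} "
          f"regions enhanced in the epileptic group (q < "
          f"{cfg.get('memri', {}).get('region_alpha', 0.01)})")


if __name__ == "__main__":
    main()
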