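"""Atlas-based volumetry.

Per-region label volumes for every subject and the epileptic-vs-control
group comparison; the cohort plants a one-voxel parcel dilation in two
regions of the epileptic group."""

import argparse

import pandas as pd

from rodentfc.pipeline import load_config, run_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default="analysis/config.toml")
    args = ap.parse_args()
    cfg = load_config(args.config)
    out = run_stage("volumes", cfg)
    comp = pd.read_csv(out / "volume_comparison.tsv", sep="\t")
    regions = comp[comp.region_id != "total"]
    sig = regions[regions.p < 0.05]
    total = comp[comp.region_id == "total"].iloc[0]
    print(f"{len(regions)} regions compared; {len(sig)} differ at p < 0.05: "
          f"{', '.join(str(r) for r in sig.region_id)}")
    print(f"whole-label volume: {total.mean_a_mm3:.1f} vs {total.mean_b_mm3:.1f} mm^3 "
          f"(p = {total.p:.3f})")


if __name__ == "__main__":
    main()
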