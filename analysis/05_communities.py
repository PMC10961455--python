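"""Community structure of the group-mean networks.

Louvain modularity optimisation on each strain/age-group mean matrix
thresholded at k = 6; reports community counts and modularity, the
analog of the three-community split seen in the study networks."""

import argparse

import pandas as pd

from rodentfc.pipeline import load_config, run_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default="analysis/config.toml")
    args = ap.parse_args()
    cfg = load_config(args.config)
    out = run_stage("community", cfg)
    comm = pd.read_csv(out / "communities.tsv", sep="\t")
    for (strain, age), grp in comm.groupby(["strain", "age_group"]):
        print(f"  {strain:>9}/{age:<8}: {grp.community.nunique()} communities, "
              f"modularity {grp.modularity.iloc[0]:.3f}")


if __name__ == "__main__":
    main()
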