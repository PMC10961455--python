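"""Network-based statistic: epileptic vs control.

Edge-wise homoscedastic t-tests over the density-k edge universe,
sign-split connected components, and permutation FWE control (the edge
universe is re-selected inside every permutation).  Run per age group on
subject-level session-averaged z matrices; prints significant components
and where their edges concentrate by functional group."""

import argparse
import json

import pandas as pd

from rodentfc.pipeline import load_config, run_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default="analysis/config.toml")
    args = ap.parse_args()
    cfg = load_config(args.config)
    out = run_stage("nbs", cfg)
    summary = json.loads((out / "nbs_summary.json").read_text())
    for age, info in summary.items():
        sig = [c for c in info["components"] if c["p_fwe"] <= 0.05]
        print(f"  {age}: {len(info['components'])} component(s), {len(sig)} significant")
        for c in sig:
            print(f"    {c['sign']}: {c['n_edges']} edges over {c['n_nodes']} nodes, "
                  f"p_FWE = {c['p_fwe']:.3f}")
        counts = pd.read_csv(out / f"nbs_groupcounts_{age}_stronger.tsv",
                             sep="\t", index_col=0)
        if counts.to_numpy().sum():
            top = counts.stack().idxmax()
            print(f"    stronger edges concentrate in {top[0]} - {top[1]}")


if __name__ == "__main__":
    main()
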