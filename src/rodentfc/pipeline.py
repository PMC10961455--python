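"""Stage runner: configuration handling and the eight pipeline stages.

Each stage is a thin orchestration layer over the library modules; it
reads a TOML config (one file per run), consumes the previous stage's
artifacts from disk, and writes its outputs with deterministic names so
runs are reproducible and diffable.  Every threshold used is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import graph_metrics as gm
from . import io as rio
from . import network_inference as ni
from . import preprocess as pp
from . import synthetic as syn
from . import voxel_stats as vs

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "preprocess", "connect", "graph",
    "nbs", "community", "memri", "volumes",
)

_KNOWN_SECTIONS = {
    "paths", "simulate", "preprocess", "connectivity",
    "graph", "nbs", "community", "memri", "volumes",
}


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    unknown = set(cfg) - _KNOWN_SECTIONS - {"seed"}
    if unknown:
        raise ValueError(f"invalid config section(s): {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("paths", {})
    return cfg


def run_stage(stage: str, config: dict | str | Path, overrides: dict | None = None) -> Path:
    """Run one pipeline stage; returns the stage output directory.

    ``overrides`` (flat {section.key: value}) take precedence over the
    config file, mirroring the CLI flags.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    cfg = load_config(config) if not isinstance(config, dict) else json.loads(json.dumps(config))
    for dotted, value in (overrides or {}).items():
        section, _, key = dotted.partition(".")
        if not key:
            cfg[section] = value
        else:
            cfg.setdefault(section, {})[key] = value
    return _DISPATCH[stage](cfg)


def _dirs(cfg: dict) -> tuple[Path, Path]:
    data = Path(cfg["paths"].get("data_dir", "data"))
    out = Path(cfg["paths"].get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    return data, out


def _manifest(data: Path) -> pd.DataFrame:
    path = data / "manifest.tsv"
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact: {path} (run the simulate stage first)")
    return rio.load_manifest(path)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact: {path}")
    return path


# ---------------------------------------------------------------------------


def stage_simulate(cfg: dict) -> Path:
    data, _ = _dirs(cfg)
    s = cfg.get("simulate", {})
    fields = {f.name for f in dataclasses.fields(syn.CohortConfig)}
    unknown = set(s) - fields
    if unknown:
        raise ValueError(f"invalid [simulate] key(s): {sorted(unknown)}")
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in s.items()}
    config = syn.CohortConfig(**kwargs)
    logger.info("simulating cohort: %d/strain x %d sessions, %d regions, seed %d",
                config.n_per_strain, len(config.sessions), config.n_regions, cfg["seed"])
    syn.simulate_cohort(config, seed=cfg["seed"], out_dir=data)
    return data


def stage_preprocess(cfg: dict) -> Path:
    data, out = _dirs(cfg)
    p = cfg.get("preprocess", {})
    manifest = _manifest(data)
    atlas = rio.read_volume(_require(data / "atlas.nii.gz"))
    mask = np.asarray(atlas.data) > 0
    qc = []
    for row in manifest.itertuples():
        series = rio.read_volume(_require(data / row.bold))
        motion = rio.read_motion_tsv(_require(data / row.motion))
        proc, epoch, tsnr = pp.preprocess_series(
            series, motion, mask,
            window_volumes=p.get("window_volumes"),
            fwhm_mm=p.get("fwhm_mm", 0.6),
            cutoff_hz=p.get("cutoff_hz", 0.1),
        )
        name = f"proc_{row.subject_id}_m{row.session}.nii.gz"
        rio.write_volume(proc, out / name)
        qc.append(dict(subject_id=row.subject_id, session=row.session,
                       epoch_start=epoch.start, epoch_length=epoch.length, tsnr=tsnr))
    logger.info("preprocess: fwhm %.3g mm, cutoff %.3g Hz, order epoch>smooth>lowpass>gsr",
                p.get("fwhm_mm", 0.6), p.get("cutoff_hz", 0.1))
    pd.DataFrame(qc).to_csv(out / "preprocess_qc.tsv", sep="\t", index=False)
    return out


def stage_connect(cfg: dict) -> Path:
    data, out = _dirs(cfg)
    q = cfg.get("connectivity", {}).get("q", 0.05)
    manifest = _manifest(data)
    atlas = rio.read_volume(data / "atlas.nii.gz")
    table = rio.load_region_table(data / "regions.tsv")
    logger.info("connectivity: BY-FDR q=%g per seed map", q)
    for row in manifest.itertuples():
        proc = rio.read_volume(_require(out / f"proc_{row.subject_id}_m{row.session}.nii.gz"))
        mat = conn.build_connectivity_matrix(
            proc, atlas, table, q=q,
            meta=dict(subject=row.subject_id, session=int(row.session)),
        )
        zmat = conn.to_fisher_z(mat)
        rio.write_matrix_tsv(
            zmat.values, zmat.region_ids,
            out / f"zmat_{row.subject_id}_m{row.session}.tsv", metadata=zmat.meta,
        )
    return out


def _subject_age_matrices(cfg: dict) -> dict[tuple[str, str, str], conn.ConnectivityMatrix]:
    """{(strain, age_group, subject): session-averaged z matrix} from the
    connect stage outputs."""
    data, out = _dirs(cfg)
    manifest = _manifest(data)
    result = {}
    for (strain, age, subject), grp in manifest.groupby(["strain", "age_group", "subject_id"]):
        mats = []
        for row in grp.itertuples():
            values, ids = rio.read_matrix_tsv(
                _require(out / f"zmat_{row.subject_id}_m{row.session}.tsv")
            )
            mats.append(conn.ConnectivityMatrix(values, ids, kind="z",
                                                meta={"session": int(row.session)}))
        result[(strain, age, subject)] = conn.average_matrices(mats, group_label=age)
    return result


def stage_graph(cfg: dict) -> Path:
    _, out = _dirs(cfg)
    g = cfg.get("graph", {})
    k = int(g.get("k", 6))
    if k < 1:
        raise ValueError("density k must be >= 1")
    k_min, k_max = g.get("k_range", [2, 20])
    n_random = int(g.get("n_random", 1000))
    subj = _subject_age_matrices(cfg)
    logger.info("graph metrics: k=%d (local), k range %d-%d, %d random nulls",
                k, k_min, k_max, n_random)
    rng = np.random.default_rng(cfg["seed"])
    global_rows, local_tables = [], []
    for (strain, age, subject), mat in sorted(subj.items()):
        for kk in range(k_min, k_max + 1):
            tg = gm.threshold_to_density(mat, kk)
            met = gm.global_metrics(tg, n_random=n_random, seed=int(rng.integers(2**31)))
            global_rows.append(dict(
                subject_id=subject, strain=strain, age_group=age, k=kk,
                gamma=met.gamma, lam=met.lam, sigma=met.sigma,
                n_components=met.n_components,
                raw_clustering=met.raw_clustering, raw_path_length=met.raw_path_length,
            ))
        local = gm.local_metrics(gm.threshold_to_density(mat, k))
        local.insert(0, "age_group", age)
        local.insert(0, "strain", strain)
        local.insert(0, "subject_id", subject)
        local_tables.append(local)
    pd.DataFrame(global_rows).to_csv(out / "global_metrics.tsv", sep="\t", index=False)
    pd.concat(local_tables).to_csv(out / f"local_metrics_k{k}.tsv", sep="\t", index=False)
    return out


def stage_nbs(cfg: dict) -> Path:
    data, out = _dirs(cfg)
    n = cfg.get("nbs", {})
    k = int(n.get("k", 6))
    alpha = float(n.get("alpha", 0.05))
    primary_alpha = float(n.get("primary_alpha", 0.05))
    n_perm = int(n.get("n_perm", 1000))
    logger.info("NBS: k=%d, primary alpha=%g (edge-forming threshold — the key "
                "sensitivity knob), %d permutations, component alpha=%g",
                k, primary_alpha, n_perm, alpha)
    subj = _subject_age_matrices(cfg)
    table = rio.load_region_table(data / "regions.tsv")
    summary = {}
    for age in ("juvenile", "adult"):
        ga = [m for (s, a, _), m in sorted(subj.items()) if s == "epileptic" and a == age]
        gb = [m for (s, a, _), m in sorted(subj.items()) if s == "control" and a == age]
        if not ga or not gb:
            continue
        res = ni.nbs(ga, gb, k=k, primary_alpha=primary_alpha,
                     n_perm=n_perm, seed=cfg["seed"])
        rows = res.edge_table.copy()
        comp_p = {i: c.p_fwe for i, c in enumerate(res.components)}
        rows["component_p"] = rows["component"].map(comp_p).fillna(1.0)
        rows.to_csv(out / f"nbs_edges_{age}.tsv", sep="\t", index=False)
        counts = ni.summarize_by_functional_group(res, table, alpha=alpha)
        summary[age] = {
            "components": [
                dict(sign=c.sign, n_edges=c.n_edges, n_nodes=len(c.nodes), p_fwe=c.p_fwe)
                for c in res.components
            ],
            "significant_stronger_edges": sum(
                c.n_edges for c in res.significant(alpha) if c.sign == "stronger"
            ),
            "significant_weaker_edges": sum(
                c.n_edges for c in res.significant(alpha) if c.sign == "weaker"
            ),
        }
        for sign, mat in counts.items():
            mat.to_csv(out / f"nbs_groupcounts_{age}_{sign}.tsv", sep="\t")
    (out / "nbs_summary.json").write_text(json.dumps(summary, indent=1))
    return out


def stage_community(cfg: dict) -> Path:
    _, out = _dirs(cfg)
    c = cfg.get("community", {})
    k = int(c.get("k", 6))
    resolution = float(c.get("resolution", 1.0))
    subj = _subject_age_matrices(cfg)
    rows = []
    for strain in rio.STRAINS:
        for age in ("juvenile", "adult"):
            mats = [m for (s, a, _), m in sorted(subj.items()) if s == strain and a == age]
            if not mats:
                continue
            mean = conn.average_matrices(mats, group_label=f"{strain}/{age}")
            tg = gm.threshold_to_density(mean, k)
            part = ni.detect_communities(tg, resolution=resolution, seed=cfg["seed"])
            logger.info("community %s/%s: %d communities, modularity %.3f",
                        strain, age, len(set(part.labels.values())), part.modularity)
            for rid, lab in sorted(part.labels.items()):
                rows.append(dict(strain=strain, age_group=age, region_id=rid,
                                 community=lab, modularity=part.modularity))
    pd.DataFrame(rows).to_csv(out / "communities.tsv", sep="\t", index=False)
    return out


def stage_memri(cfg: dict) -> Path:
    data, out = _dirs(cfg)
    m = cfg.get("memri", {})
    kernel = int(m.get("median_kernel", 7))
    n_perm = int(m.get("n_perm", 100))
    percentile = float(m.get("percentile", 99.9))
    min_vox = int(m.get("min_cluster_voxels", 500))
    region_alpha = float(m.get("region_alpha", 0.01))
    pipeline = m.get("pipeline", "tfce")
    logger.info("MEMRI: median %dx%dx%d, %d perms, %.4gth percentile, >%d-voxel "
                "clusters, region FDR q=%g", kernel, kernel, kernel, n_perm,
                percentile, min_vox, region_alpha)
    manifest = _manifest(data)
    atlas = rio.read_volume(data / "atlas.nii.gz")
    mask = np.asarray(atlas.data) > 0
    subjects = manifest.drop_duplicates("subject_id")
    vols = {s: rio.read_volume(_require(data / f"memri_{s}.nii.gz"))
            for s in subjects["subject_id"]}
    ga = [vols[r.subject_id] for r in subjects.itertuples() if r.strain == "epileptic"]
    gb = [vols[r.subject_id] for r in subjects.itertuples() if r.strain == "control"]
    threshold, sig, observed = vs.permutation_threshold(
        ga, gb, mask=mask, n_perm=n_perm, percentile=percentile,
        seed=cfg["seed"], pipeline=pipeline, median_kernel=kernel,
    )
    clusters = vs.cluster_filter(sig, min_voxels=min_vox, value_map=observed)
    clusters.table.to_csv(out / "memri_clusters.tsv", sep="\t", index=False)
    stats = vs.region_intensity_stats(ga, gb, atlas, alpha=region_alpha)
    stats.to_csv(out / "memri_region_stats.tsv", sep="\t", index=False)
    (out / "memri_summary.json").write_text(json.dumps({
        "threshold": threshold, "pipeline": pipeline, "percentile": percentile,
        "n_significant_voxels": int(sig.sum()),
        "n_clusters": int(len(clusters.table)),
        "n_significant_regions": int(stats["significant"].sum()),
    }, indent=1))
    return out


def stage_volumes(cfg: dict) -> Path:
    data, out = _dirs(cfg)
    manifest = _manifest(data)
    subjects = manifest.drop_duplicates("subject_id")
    tables = {
        r.subject_id: vs.region_volumes(
            rio.read_volume(_require(data / f"labels_{r.subject_id}.nii.gz"))
        )
        for r in subjects.itertuples()
    }
    rows = []
    for sid, tab in tables.items():
        t = tab.copy()
        t.insert(0, "subject_id", sid)
        rows.append(t)
    pd.concat(rows).to_csv(out / "region_volumes.tsv", sep="\t", index=False)
    ga = [tables[r.subject_id] for r in subjects.itertuples() if r.strain == "epileptic"]
    gb = [tables[r.subject_id] for r in subjects.itertuples() if r.strain == "control"]
    vs.compare_volumes(ga, gb).to_csv(out / "volume_comparison.tsv", sep="\t", index=False)
    return out


_DISPATCH = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "connect": stage_connect,
    "graph": stage_graph,
    "nbs": stage_nbs,
    "community": stage_community,
    "memri": stage_memri,
    "volumes": stage_volumes,
}
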