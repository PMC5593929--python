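"""End-to-end orchestration: simulate -> prep -> infer -> compare -> associate.

A single :class:`RunConfig` (plain key-value YAML; every key has a default)
drives the whole synthetic analysis: two-condition truths, count tables for
two experiments per condition, filtering and clr, StARS network inference
per condition x experiment, graphlet topology comparison and MDS embedding,
attack robustness and keystone taxa, cross-experiment edge recovery,
multilevel sPLS against simulated sIgA, and IgA-Seq coating indices.

All randomness flows from one master seed through named substreams; a
manifest JSON records every artifact with its stage, parameter hash and the
seed actually used, which is sufficient to re-run any stage in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graphlets, igaseq, prep, recovery, robustness, simulate, spls
from .inference import NeighborhoodNetwork, LambdaPath
from .otu import OtuTable

__all__ = ["RunConfig", "validate_config", "run_pipeline", "substream"]

log = logging.getLogger("micronet")


def substream(master_seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All pipeline parameters; every field has a default."""

    seed: int = 0
    outdir: str = "micronet_out"

    # simulation
    p: int = 40
    shared_edges: int = 30
    unique_edges: int = 12
    n_samples: int = 150
    depth_lo: int = 2_000
    depth_hi: int = 20_000
    conditions: list = field(default_factory=lambda: ["control", "perturbed"])
    experiments: list = field(default_factory=lambda: ["dose", "transfer"])

    # preprocessing
    min_depth: int = 1_000
    min_prevalence: float = 0.2
    min_mean_relabund: float = 0.0001
    pseudocount: float = 1.0

    # inference
    lambda_path_length: int = 30
    lambda_min_ratio: float = 0.01
    stars_subsamples: int = 50
    stars_beta: float = 0.05

    # robustness
    attack_orderings: int = 30
    keystone_k: int = 3

    # sPLS
    spls_support_size: int = 8
    spls_effect_size: float = 1.0
    spls_noise_sd: float = 0.5
    spls_train_subjects: int = 16
    spls_train_timepoints: int = 7
    spls_test_subjects: int = 19
    spls_test_timepoints: int = 4
    spls_components: int = 2
    spls_keep: int = 8
    spls_resamples: int = 100

    # IgA-Seq
    iga_depth: int = 100_000
    iga_samples: int = 10
    iga_affinity_fold: float = 10.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def params_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_RANGES = {
    "stars_beta": (0.0, 0.5),
    "min_prevalence": (0.0, 1.0),
    "min_mean_relabund": (0.0, 1.0),
    "lambda_min_ratio": (1e-6, 1.0),
}
_POSITIVE = {"p", "n_samples", "depth_lo", "depth_hi", "lambda_path_length",
             "stars_subsamples", "attack_orderings", "keystone_k",
             "spls_support_size", "spls_train_subjects", "spls_test_subjects",
             "spls_components", "spls_keep", "spls_resamples", "iga_depth",
             "iga_samples", "pseudocount"}


def validate_config(path_or_dict) -> RunConfig:
    """Build a RunConfig from a YAML file or dict; report all errors at once."""
    if isinstance(path_or_dict, (str, Path)):
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text) or {}
    else:
        raw = dict(path_or_dict or {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    merged = dataclasses.asdict(RunConfig())
    merged.update({k: v for k, v in raw.items() if k in known})
    for key, (lo, hi) in _RANGES.items():
        v = merged[key]
        if not isinstance(v, (int, float)) or not lo <= v <= hi:
            errors.append(f"{key} must lie in [{lo}, {hi}], got {v!r}")
    for key in _POSITIVE:
        v = merged[key]
        if not isinstance(v, (int, float)) or v <= 0:
            errors.append(f"{key} must be positive, got {v!r}")
    if merged["depth_hi"] < merged["depth_lo"]:
        errors.append("depth_hi must be >= depth_lo")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**merged)


class _Manifest:
    def __init__(self, config: RunConfig):
        self.config = config
        self.entries = []

    def add(self, stage: str, path: Path, seed: int | None = None) -> None:
        self.entries.append({
            "stage": stage,
            "file": str(path),
            "params_hash": self.config.params_hash(),
            "seed": seed,
        })

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": dataclasses.asdict(self.config),
                       "artifacts": self.entries}, fh, indent=2, sort_keys=True)


def _stage_dir(outdir: Path, stage: str) -> Path:
    d = outdir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    results: dict = {}

    # ---- simulate ---------------------------------------------------------
    stage = "simulate"
    d = _stage_dir(out, stage)
    seed = substream(config.seed, stage)
    log.info("stage %s (seed %d)", stage, seed)
    control, perturbed = simulate.synth_two_condition(
        p=config.p, shared_edges=config.shared_edges,
        unique_edges_per_condition=config.unique_edges, rng_seed=seed)
    truths = {"control": control, "perturbed": perturbed}
    rng = np.random.default_rng(seed)
    support = rng.choice(np.arange(1, config.p), size=config.spls_support_size,
                         replace=False)
    beta = config.spls_effect_size * np.where(np.arange(config.spls_support_size) % 2, -1.0, 1.0)
    control.spls_support = np.sort(support)
    control.spls_beta = beta
    affinity = np.ones(config.p)
    affinity[int(rng.integers(1, config.p))] = config.iga_affinity_fold
    control.coating_affinity = affinity
    tables: dict[tuple[str, str], OtuTable] = {}
    for cond, truth in truths.items():
        edge_path = d / f"truth_edges_{cond}.tsv"
        truth.edges_to_tsv(edge_path)
        manifest.add(stage, edge_path, seed)
        for exp in config.experiments:
            s = substream(config.seed, f"simulate/{cond}/{exp}")
            tab = simulate.synth_counts(
                truth, n_samples=config.n_samples,
                depth_range=(config.depth_lo, config.depth_hi),
                rng_seed=s, group=cond, experiment=exp,
                sample_prefix=f"{cond[:3]}{exp[:3]}")
            tables[(cond, exp)] = tab
            cpath, mpath = d / f"counts_{cond}_{exp}.tsv", d / f"meta_{cond}_{exp}.tsv"
            tab.to_tsv(cpath, mpath)
            manifest.add(stage, cpath, s)
            manifest.add(stage, mpath, s)
    results["truths"] = truths

    # ---- prep -------------------------------------------------------------
    stage = "prep"
    d = _stage_dir(out, stage)
    clrs = {}
    for key, tab in tables.items():
        filtered = prep.filter_samples_by_depth(tab, config.min_depth)
        filtered = prep.filter_taxa(filtered, min_prevalence=0.0,
                                    min_mean_relabund=config.min_mean_relabund)
        clr = prep.clr_transform(filtered, pseudocount=config.pseudocount)
        clrs[key] = (filtered, clr)
        path = d / f"clr_{key[0]}_{key[1]}.tsv"
        clr.to_tsv(path)
        manifest.add(stage, path)

    # ---- infer ------------------------------------------------------------
    stage = "infer"
    d = _stage_dir(out, stage)
    stars = {}
    networks = {}
    for (cond, exp), (tab, clr) in clrs.items():
        s = substream(config.seed, f"infer/{cond}/{exp}")
        model = NeighborhoodNetwork(clr)
        path = LambdaPath.from_data(model.X, length=config.lambda_path_length,
                                    min_ratio=config.lambda_min_ratio)
        res = model.fit(path=path, n_subsamples=config.stars_subsamples,
                        beta=config.stars_beta, seed=s)
        net = res.network(tab, min_prevalence=config.min_prevalence)
        stars[(cond, exp)] = res
        networks[(cond, exp)] = net
        g_path = d / f"network_{cond}_{exp}.graphml"
        e_path = d / f"edges_{cond}_{exp}.tsv"
        net.to_graphml(g_path)
        net.to_edge_tsv(e_path)
        manifest.add(stage, g_path, s)
        manifest.add(stage, e_path, s)
    results["stars"] = stars
    results["networks"] = networks

    # ---- topology ---------------------------------------------------------
    stage = "topology"
    d = _stage_dir(out, stage)
    keys = sorted(networks)
    labels = [f"{c}/{e}" for c, e in keys]
    gcms = []
    for key in keys:
        orbits = graphlets.count_orbits(networks[key])
        opath = d / f"orbits_{key[0]}_{key[1]}.tsv"
        orbits.to_csv(opath, sep="\t", index_label="taxon")
        manifest.add(stage, opath)
        gcms.append(graphlets.graphlet_correlation_matrix(orbits))
    D = graphlets.pairwise_gcd(gcms)
    dpath = d / "gcd_matrix.tsv"
    pd.DataFrame(D, index=labels, columns=labels).to_csv(dpath, sep="\t")
    manifest.add(stage, dpath)
    if len(gcms) >= 3:
        emb = graphlets.embed_networks(gcms, labels=labels)
        epath = d / "embedding.tsv"
        frame = emb.to_frame()
        frame["condition"] = [l.split("/")[0] for l in labels]
        frame["experiment"] = [l.split("/")[1] for l in labels]
        frame.to_csv(epath, sep="\t", index=False)
        manifest.add(stage, epath)
        results["embedding"] = emb

    # ---- attack + keystones ----------------------------------------------
    stage = "attack"
    d = _stage_dir(out, stage)
    for key in keys:
        s = substream(config.seed, f"attack/{key[0]}/{key[1]}")
        curves = robustness.attack_curves(
            networks[key], n_random_orderings=config.attack_orderings, rng_seed=s)
        cpath = d / f"attack_{key[0]}_{key[1]}.tsv"
        pd.concat([c.to_frame() for c in curves]).to_csv(cpath, sep="\t", index=False)
        manifest.add(stage, cpath, s)
        ranking = robustness.keystone_taxa(networks[key], k=config.keystone_k)
        kpath = d / f"keystones_{key[0]}_{key[1]}.tsv"
        ranking.to_frame().to_csv(kpath, sep="\t", index=False)
        manifest.add(stage, kpath)

    # ---- recovery ---------------------------------------------------------
    stage = "recover"
    d = _stage_dir(out, stage)
    recov = {}
    for cond in config.conditions:
        truth_net = networks[(cond, config.experiments[0])]
        query = stars[(cond, config.experiments[1])]
        common = sorted(set(truth_net.taxa) & set(query.taxa))
        try:
            ranked = recovery.rank_edges(query, taxa_subset=common)
            rec = recovery.recovery_curve(ranked, truth_net, common)
        except ValueError as exc:
            log.warning("recovery skipped for %s: %s", cond, exc)
            continue
        recov[cond] = rec
        cpath = d / f"recovery_{cond}.tsv"
        rec.to_frame().to_csv(cpath, sep="\t", index=False)
        manifest.add(stage, cpath)
        jpath = d / f"recovery_{cond}.json"
        with open(jpath, "w") as fh:
            json.dump(rec.summary_dict(), fh, indent=2)
        manifest.add(stage, jpath)
    results["recovery"] = recov

    # ---- sPLS -------------------------------------------------------------
    stage = "spls"
    d = _stage_dir(out, stage)
    s_train = substream(config.seed, "spls/train")
    s_test = substream(config.seed, "spls/test")
    tp_train = tuple(range(0, 7 * config.spls_train_timepoints, 7))
    tp_test = tuple(range(0, 7 * config.spls_test_timepoints, 7))
    train_tab = simulate.synth_longitudinal_iga(
        control, n_subjects=config.spls_train_subjects, timepoints=tp_train,
        noise_sd=config.spls_noise_sd, rng_seed=s_train, experiment="dose",
        pseudocount=config.pseudocount)
    test_tab = simulate.synth_longitudinal_iga(
        control, n_subjects=config.spls_test_subjects, timepoints=tp_test,
        noise_sd=config.spls_noise_sd, rng_seed=s_test, experiment="transfer",
        pseudocount=config.pseudocount)
    train = spls.LongitudinalDesign.from_table(train_tab, pseudocount=config.pseudocount,
                                               experiment="dose")
    test = spls.LongitudinalDesign.from_table(test_tab, pseudocount=config.pseudocount,
                                              experiment="transfer")
    s_stab = substream(config.seed, "spls/stability")
    scores = spls.stability_select(train, keep_per_component=config.spls_keep,
                                   n_components=config.spls_components,
                                   n_resamples=config.spls_resamples,
                                   rng_seed=s_stab)
    best = spls.iterative_filter(train, test, scores,
                                 n_components=config.spls_components,
                                 keep_per_component=config.spls_keep)
    mpath = d / "spls_model.tsv"
    best.to_frame().to_csv(mpath, sep="\t", index=False)
    manifest.add(stage, mpath, s_stab)
    jpath = d / "spls_summary.json"
    with open(jpath, "w") as fh:
        json.dump({"within_sample_r2": best.within_sample_r2,
                   "oos_r2": best.oos_r2,
                   "n_selected": len(best.selected_taxa),
                   "true_support": [control.taxon_ids[i] for i in control.spls_support]},
                  fh, indent=2)
    manifest.add(stage, jpath)
    results["spls"] = best

    # ---- IgA-Seq ----------------------------------------------------------
    stage = "ici"
    d = _stage_dir(out, stage)
    s = substream(config.seed, "ici")
    pre, pos, neg = simulate.synth_igaseq(control, depth=config.iga_depth,
                                          n_samples=config.iga_samples, rng_seed=s)
    table = igaseq.ici(pos, neg)
    ipath = d / "ici.tsv"
    table.to_frame().to_csv(ipath, sep="\t", index=False)
    manifest.add(stage, ipath, s)
    ranking = igaseq.rank_coated(table)
    rpath = d / "ici_ranking.tsv"
    ranking.to_csv(rpath, sep="\t", index=False)
    manifest.add(stage, rpath)
    results["ici_ranking"] = ranking

    manifest.write(out / "manifest.json")
    results["manifest"] = {"config": dataclasses.asdict(config),
                           "artifacts": manifest.entries}
    return results
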