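"""Config-driven end-to-end analysis run.

Executes the full serial-mtDNA analysis sequence — haplogroup typing,
frequency table, PCA, Ward clustering, Fisher tests, diversity indices,
shared-haplotype analysis, drift continuity tests, and the sequence-level
distance block (ΦST / MDS / AMOVA) — writing one TSV report per stage plus
a machine-readable run manifest.  The global seed deterministically spawns
one independent stream per stochastic stage, so a re-run with the same
config and inputs is bit-for-bit identical.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .continuity import ContinuityConfig, continuity_test
from .core_io import Dataset, GroupDefinition, read_metadata_table, write_metadata_table
from .group_stats import (DEFAULT_SCHEME, build_frequency_table, diversity,
                          fisher_test, pca, ward_cluster)
from .haplogroup_typing import MotifTree, classify_dataset, load_panels
from .seq_distance import amova, mds, pairwise_phist, subsample_groups, tn93_matrix
from .sharing import ancestral_sha, sha_matrix
from .synthetic_data import default_transect_config, generate_transect

STAGES = ["typing", "frequencies", "pca", "cluster", "fisher", "diversity",
          "sha", "continuity", "distance"]

#: Terminal dates (years BCE) used to turn period succession into year gaps.
DEFAULT_TERMINAL_DATES = {"HG": 5700, "EN": 4500, "MLN": 3000, "CHA": 2200,
                          "EBA": 1500}

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": True,
    "metadata": None,
    "fasta": None,
    "groups": None,          # None -> chronological defaults
    "scheme": None,          # None -> 25-category default
    "window": None,
    "ne_values": [1000, 10000],
    "generation_time": 25.0,
    "n_sims": 1000,
    "n_perm": 200,
    "n_boot": 200,
    "subsample_cap": 140,
    "alpha_gamma": 0.117,
    "terminal_dates": None,
    "stages": {s: True for s in STAGES},
}

_DEFAULT_GROUPS = [
    {"label": "HG", "periods": ["HG"], "rank": 0},
    {"label": "EN", "periods": ["EN"], "rank": 1},
    {"label": "MLN", "periods": ["MLN"], "rank": 2},
    {"label": "CHA", "periods": ["CHA"], "rank": 3},
    {"label": "EBA", "periods": ["EBA"], "rank": 4},
]


def group_definitions(specs: list[dict] | None) -> list[GroupDefinition]:
    specs = specs if specs is not None else _DEFAULT_GROUPS
    return [
        GroupDefinition(
            label=s["label"],
            regions=set(s["regions"]) if s.get("regions") else None,
            periods=set(s["periods"]) if s.get("periods") else None,
            member_ids=s.get("member_ids"),
            rank=s.get("rank"),
        )
        for s in specs
    ]


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_dataset(cfg: dict) -> Dataset:
    if cfg.get("metadata"):
        from .core_io import attach_haplotypes, read_fasta
        ds = read_metadata_table(cfg["metadata"])
        if cfg.get("fasta"):
            ds = attach_haplotypes(ds, read_fasta(cfg["fasta"], ds.reference, ds.window))
        return ds
    sim_cfg = default_transect_config(seed=int(cfg.get("seed", 0)))
    return generate_transect(sim_cfg)


def run_pipeline(config: dict | None = None, outdir: str | Path = "paleomt_run") -> dict:
    """Run every enabled stage; returns the manifest (also written as JSON)."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    stages = dict(DEFAULT_CONFIG["stages"])
    stages.update((config or {}).get("stages", {}))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    streams = {s: np.random.default_rng([seed, i]) for i, s in enumerate(STAGES)}
    scheme = cfg["scheme"] or DEFAULT_SCHEME
    tree = MotifTree.default()
    panels = load_panels()

    manifest: dict = {
        "package": "paleomt", "version": __version__, "seed": seed,
        "parameters": {k: v for k, v in cfg.items() if k != "stages"},
        "stages_run": [], "stages_skipped": [], "outputs": {},
    }

    def emit(stage: str, df: pd.DataFrame, path_name: str | None = None):
        path = outdir / f"{path_name or stage}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"][stage] = path.name

    t_all = time.perf_counter()
    dataset = load_dataset(cfg)
    groups = group_definitions(cfg["groups"])
    present = [g for g in groups if g.resolve(dataset)]

    freq_table = None
    for stage in STAGES:
        if not stages.get(stage, True):
            manifest["stages_skipped"].append(stage)
            _log(f"[paleomt] stage {stage}: skipped")
            continue
        t0 = time.perf_counter()
        try:
            if stage == "typing":
                dataset, report = classify_dataset(dataset, tree, panels)
                emit(stage, report)
            elif stage == "frequencies":
                freq_table = build_frequency_table(dataset, present, scheme, tree)
                df = freq_table.counts.reset_index(names="group")
                df.insert(1, "n", freq_table.n.values)
                emit(stage, df)
            elif stage == "pca":
                freq_table = freq_table or build_frequency_table(
                    dataset, present, scheme, tree)
                res = pca(freq_table)
                df = res.scores.reset_index(names="group")
                var = pd.DataFrame({
                    "group": ["<variance_proportion>"],
                    **{c: [res.variance_proportions[i]]
                       for i, c in enumerate(res.scores.columns)},
                })
                emit(stage, pd.concat([df, var], ignore_index=True))
            elif stage == "cluster":
                freq_table = freq_table or build_frequency_table(
                    dataset, present, scheme, tree)
                tree_res = ward_cluster(freq_table, n_boot=int(cfg["n_boot"]),
                                        seed=streams[stage])
                rows = [{"item": "newick", "value": tree_res.newick()}]
                rows += [{"item": "|".join(sorted(s)), "value": f"{sup:.1f}"}
                         for s, sup in tree_res.support.items()]
                emit(stage, pd.DataFrame(rows))
            elif stage == "fisher":
                freq_table = freq_table or build_frequency_table(
                    dataset, present, scheme, tree)
                rows = []
                labs = freq_table.groups
                for a, b in zip(labs, labs[1:]):
                    p = fisher_test(freq_table.counts.loc[a],
                                    freq_table.counts.loc[b],
                                    seed=streams[stage])
                    rows.append({"group_a": a, "group_b": b, "p_value": p})
                emit(stage, pd.DataFrame(rows))
            elif stage == "diversity":
                rows = []
                for g in present:
                    try:
                        d = diversity(dataset, g)
                    except ValueError:
                        continue
                    rows.append({"group": g.label, "n": d.n,
                                 "haplotypes": d.n_haplotypes,
                                 "Hd": d.haplotype_diversity,
                                 "pi": d.nucleotide_diversity,
                                 "S": d.segregating_sites})
                emit(stage, pd.DataFrame(rows))
            elif stage == "sha":
                plain = sha_matrix(dataset, present, tree=tree)
                anc = ancestral_sha(dataset, present, tree=tree)
                rows = [
                    {"panel": panel, "row": r, "col": c, "value": df.loc[r, c]}
                    for panel, df in (("plain", plain), ("ancestral", anc))
                    for r in df.index for c in df.columns
                ]
                emit(stage, pd.DataFrame(rows))
            elif stage == "continuity":
                freq_table = freq_table or build_frequency_table(
                    dataset, present, scheme, tree)
                dates = cfg["terminal_dates"] or DEFAULT_TERMINAL_DATES
                ccfg = ContinuityConfig(
                    ne_values=tuple(cfg["ne_values"]),
                    generation_time=float(cfg["generation_time"]),
                    n_sims=int(cfg["n_sims"]))
                rows = []
                labs = freq_table.groups
                for a, b in zip(labs, labs[1:]):
                    gap = abs(dates.get(a, 0) - dates.get(b, 0))
                    res = continuity_test(freq_table.counts.loc[a],
                                          freq_table.counts.loc[b], gap,
                                          ccfg, rng=streams[stage])
                    for per in res.per_ne:
                        rows.append({"group_a": a, "group_b": b,
                                     "years_gap": gap, "t": res.generations,
                                     "Ne": per.ne, "observed": per.observed,
                                     "p_value": per.p_value})
                emit(stage, pd.DataFrame(rows))
            elif stage == "distance":
                seqs = dataset.sequences()
                members = {
                    g.label: [i.id for i in g.resolve(dataset)
                              if i.haplotype is not None]
                    for g in present
                }
                members = {k: v for k, v in members.items() if len(v) >= 2}
                members = subsample_groups(members, int(cfg["subsample_cap"]),
                                           seed=streams[stage])
                used = [i for ids in members.values() for i in ids]
                dist = tn93_matrix({i: seqs[i] for i in used},
                                   alpha=cfg["alpha_gamma"])
                fst = pairwise_phist(dist, members, n_perm=int(cfg["n_perm"]),
                                     seed=streams[stage])
                rows = [
                    {"section": sec, "row": r, "col": c, "value": df.loc[r, c]}
                    for sec, df in (("phist", fst.phi_st),
                                    ("p", fst.p_values),
                                    ("p_adj", fst.p_adjusted),
                                    ("slatkin", fst.slatkin()))
                    for r in df.index for c in df.columns
                ]
                coords = mds(fst.phi_st, method="classical")
                rows += [{"section": "mds", "row": r, "col": c,
                          "value": coords.coordinates.loc[r, c]}
                         for r in coords.coordinates.index
                         for c in coords.coordinates.columns]
                if len(members) >= 3:
                    labs = list(members)
                    partition = [labs[:1], labs[1:]]
                    am = amova(dist, members, partition,
                               n_perm=int(cfg["n_perm"]), seed=streams[stage])
                    for key, val in (("sigma_among_clusters", am.sigma_among_clusters),
                                     ("sigma_among_pops", am.sigma_among_pops),
                                     ("sigma_within", am.sigma_within),
                                     ("Fct", am.f_ct), ("Fsc", am.f_sc),
                                     ("Fst", am.f_st), ("p_Fct", am.p_ct),
                                     ("p_Fsc", am.p_sc), ("p_Fst", am.p_st)):
                        rows.append({"section": "amova", "row": key, "col": "",
                                     "value": val})
                emit(stage, pd.DataFrame(rows))
        except Exception as exc:  # noqa: BLE001 - abort with stage name + cause
            raise StageError(stage, exc) from exc
        manifest["stages_run"].append(stage)
        _log(f"[paleomt] stage {stage}: {time.perf_counter() - t0:.2f}s")

    if cfg.get("simulate") and not cfg.get("metadata"):
        write_metadata_table(dataset, outdir / "dataset.tsv")
        manifest["outputs"]["dataset"] = "dataset.tsv"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    _log(f"[paleomt] run complete in {time.perf_counter() - t_all:.2f}s")
    return manifest
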