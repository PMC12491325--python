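"""End-to-end pipeline orchestration with deterministic seed fan-out.

A run config lists the stages to execute (simulate -> compare -> enrich ->
cluster, optionally cohort) with their parameters and one global seed.
Every stochastic stage receives a sub-seed derived from the global seed and
a fixed per-stage counter, so adding or removing a stage never reshuffles
the random streams of the others.  A manifest (parameters, seeds, row
counts) is written next to the outputs, enabling bit-identical re-runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as cl
from . import enrichment as enr
from . import simulate as sim
from . import stats as st
from .cohort import cohort_clusters, jsd_matrix, occupancy, pair_separation
from .features import kmer_frequencies, residue_frequencies
from .io import write_clonotypes

#: fixed per-stage counters for seed derivation (never renumber)
STAGE_IDS = {"simulate": 1, "compare": 2, "enrich": 3, "cluster": 4, "cohort": 5}
#: stages run_pipeline executes; the cohort analysis has its own driver
KNOWN_STAGES = ("simulate", "compare", "enrich", "cluster")


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based sub-seed: stable under stage insertion/removal."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(STAGE_IDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    stages: list[str]
    seed: int = 0
    out_dir: str = "thymosig_run"
    chain: str = "TRB"
    n_pre: int = 20000
    n_post: int = 10000
    selection: sim.SelectionSpec = field(default_factory=sim.SelectionSpec.neutral)
    kmer_k: int = 3
    top_n: int = 10000
    kidera_factors: tuple[int, ...] = (2, 4, 6, 8)

    def validate(self) -> None:
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("no stages requested")
        if self.n_post > self.n_pre:
            raise ValueError("n_post cannot exceed n_pre")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "status": "ok"}
    pre = post = None
    records = None
    try:
        if "simulate" in cfg.stages:
            seed = stage_seed(cfg.seed, "simulate")
            params = sim.default_params(cfg.chain)
            pre = sim.generate_pre_selection(params, cfg.n_pre, seed)
            post = sim.generate_post_selection(params, cfg.selection, cfg.n_post,
                                               seed + 1)
            write_clonotypes(pre, out / "pre.tsv")
            write_clonotypes(post, out / "post.tsv")
            manifest["stages"]["simulate"] = {
                "seed": seed, "n_pre": len(pre), "n_post": len(post),
            }
        if "compare" in cfg.stages:
            if pre is None or post is None:
                raise ValueError("compare requires the simulate stage")
            rows = []
            for level, table_fn in (
                ("aa", residue_frequencies),
                ("kmer", lambda r: kmer_frequencies(r, cfg.kmer_k)),
            ):
                comps = st.compare_feature_tables(table_fn(pre), table_fn(post))
                rows += [
                    {"level": level, "feature": c.feature, "freq_pre": c.freq_pre,
                     "freq_post": c.freq_post, "log2_fc": c.log2_fc}
                    for c in comps
                ]
            pd.DataFrame(rows).to_csv(out / "feature_comparison.tsv", sep="\t",
                                      index=False)
            kid_rows = []
            for f in cfg.kidera_factors:
                for e in st.kidera_vj_test(pre, post, f):
                    kid_rows.append({
                        "factor": f, "v_gene": e.v_gene, "j_gene": e.j_gene,
                        "cohen_d": e.cohen_d, "p_value": e.p_value,
                        "p_adj": e.p_adj, "selection_force": e.selection_force,
                    })
            pd.DataFrame(kid_rows).to_csv(out / "kidera_vj.tsv", sep="\t",
                                          index=False)
            manifest["stages"]["compare"] = {"features": len(rows),
                                             "vj_tests": len(kid_rows)}
        if "enrich" in cfg.stages:
            if pre is None or post is None:
                raise ValueError("enrich requires the simulate stage")
            records = {
                "enriched": enr.enrich(post, pre),
                "depleted": enr.deplete(post, pre),
            }
            for name, recs in records.items():
                enr.records_to_frame(recs).to_csv(out / f"{name}.tsv", sep="\t",
                                                  index=False)
            manifest["stages"]["enrich"] = {k: len(v) for k, v in records.items()}
        if "cluster" in cfg.stages:
            if records is None:
                raise ValueError("cluster requires the enrich stage")
            all_clusters = []
            for name, provenance in (("enriched", "enriched_post"),
                                     ("depleted", "depleted_post")):
                top = cl.select_top(records[name], cfg.top_n)
                comps = cl.components(top, provenance=provenance, chain=cfg.chain)
                all_clusters += comps
            cl.export_motif_db(all_clusters, out / "motif_db.tsv")
            manifest["stages"]["cluster"] = {"clusters": len(all_clusters)}
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def twin_masks(chain: str = "TRB", identical: bool = False) -> list[sim.SelectionSpec]:
    """The synthetic twin-cohort selection masks (one per pair).

    All pairs share the same selection backbone — a strong penalty on
    glycine-bearing CDR3s plus knockouts of three common J-germline suffix
    motifs — which is what creates clusters detectable in the pooled cohort
    against a no-selection control.  Each pair additionally disfavors one
    third of the J genes (a stand-in for a shared HLA haplotype), which
    leaves the pooled cluster selection nearly untouched (the tilts cancel
    across pairs) but imprints a pair-specific cluster-occupancy profile.
    With ``identical`` every pair gets the same tilt: the null cohort.
    """
    params = sim.default_params(chain)
    j_names = [s.name for s in params.j_segments]
    thirds = [j_names[0:4], j_names[4:8], j_names[8:12]]
    common = {"G": 0.08, "EAF": 0.08, "EQ": 0.08, "TQY": 0.08}
    masks = []
    for i in range(3):
        subset = thirds[0] if identical else thirds[i]
        masks.append(sim.SelectionSpec(
            motif_penalties=dict(common),
            vj_tilt={("*", j): 0.15 for j in subset},
        ))
    return masks


def run_twin_analysis(
    masks: list[sim.SelectionSpec] | None = None,
    n_per_sample: int = 15000,
    replicates: int = 3,
    bg_size: int = 100000,
    seed: int = 0,
    chain: str = "TRB",
    enr_fc: float = 1.0,
    enr_p: float = 8.0,
    dep_fc: float = 1.0,
    dep_p: float = 8.0,
    min_size: int = 10,
    n_permutations: int = 1000,
) -> dict:
    """Synthetic twin cohort end-to-end: simulate, cluster, occupancy, JSD.

    Defaults are the package's desk-scale study conditions: 3 pairs x 3
    replicates of 15,000 post-selection CDR3s against a 100,000-sequence
    no-selection control, with depth-scaled cluster thresholds (the
    headline thresholds in :func:`thymosig.cohort.cohort_clusters` assume
    ~300k-deep pools).  Three replicates per pair are the minimum for a
    label-permutation p below 0.01 (with 2 replicates the identity orbit
    alone is ~7% of all permutations).  Occupancy of enriched clusters is
    exact-match; depleted clusters — whose member strings are by
    construction rare in the samples — are counted over their Hamming-1
    neighborhood.  Returns per-provenance (within, between, permutation p)
    plus the JSD matrices and cluster counts.
    """
    params = sim.default_params(chain)
    if masks is None:
        masks = twin_masks(chain)
    samples = sim.make_twin_cohort(params, masks, n_per_sample, replicates, seed)
    bg = sim.generate_pre_selection(params, bg_size, stage_seed(seed, "cohort"))
    enriched, depleted = cohort_clusters(samples, bg, enr_fc, enr_p, dep_fc,
                                         dep_p, min_size)
    pair_labels = {s.sample_id: s.meta["pair"] for s in samples}
    result: dict = {"n_enriched_clusters": len(enriched),
                    "n_depleted_clusters": len(depleted)}
    for name, cls_, match in (("enriched", enriched, "exact"),
                              ("depleted", depleted, "hamming1")):
        if not cls_:
            result[name] = None
            continue
        occ = occupancy(cls_, samples, match=match)
        mat = jsd_matrix(occ)
        within, between, p = pair_separation(mat, pair_labels,
                                             n_permutations=n_permutations,
                                             seed=stage_seed(seed, "cohort") + 7)
        result[name] = {"within": within, "between": between,
                        "permutation_p": p, "jsd": mat}
    return result
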