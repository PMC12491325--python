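"""Cohort-level cluster-occupancy divergence (twin / HLA-haplotype analysis).

Workflow: subsample every sample to a common depth, pool, detect CDR3s
enriched in the pool versus a no-selection control (and depleted, via the
swap), cluster each set, then express each sample as a distribution over
clusters ("occupancy") and compare samples by Jensen–Shannon divergence.
Samples sharing a selection environment (e.g. monozygotic twins sharing an
HLA haplotype) should sit closer to each other than to unrelated samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import CdrCluster, components
from .enrichment import NeighborIndex, enrich, records_to_frame
from .io import Repertoire, pool


@dataclass
class OccupancyMatrix:
    """Samples x clusters clonotype counts, with row-normalized distributions."""

    counts: pd.DataFrame  # index = sample ids, columns = cluster ids
    zero_rows: list[str] = field(default_factory=list)

    @property
    def distributions(self) -> pd.DataFrame:
        sums = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = self.counts.div(sums, axis=0)
        return d.fillna(0.0)


def cohort_clusters(
    samples: list[Repertoire],
    bg: Repertoire,
    enr_fc: float = 2.0,
    enr_p: float = 12.0,
    dep_fc: float = 1.0,
    dep_p: float = 12.0,
    min_size: int = 10,
) -> tuple[list[CdrCluster], list[CdrCluster]]:
    """Detect enriched and depleted CDR3 clusters for a pooled cohort.

    Samples (already subsampled to a common depth) are pooled; the pool is
    tested against the no-selection control ``bg`` for enrichment and, with
    the roles swapped, for depletion.  Sequences passing
    (log2_fc > fc AND -log10 p > p) are clustered; only clusters with more
    than ``min_size`` members (strict) are returned.  Default thresholds:
    (2, 12) enriched, (1, 12) depleted, min_size 10.
    """
    pooled = pool(samples, tag_origin=True)
    out = []
    for fg, bg_, fc_thr, p_thr, provenance in (
        (pooled, bg, enr_fc, enr_p, "enriched_post"),
        (bg, pooled, dep_fc, dep_p, "depleted_post"),
    ):
        df = records_to_frame(enrich(fg, bg_))
        passing = df.loc[(df.log2_fc > fc_thr) & (df.neg_log10_p > p_thr), "cdr3_aa"]
        if passing.empty:
            warnings.warn(f"no sequences pass the {provenance} thresholds")
            out.append([])
            continue
        comps = components(set(passing), provenance=provenance,
                           chain=samples[0].chain)
        comps = [c for c in comps if c.size > min_size]
        for i, c in enumerate(comps, start=1):
            c.cluster_id = i
        out.append(comps)
    return out[0], out[1]


def occupancy(
    clusters: list[CdrCluster],
    samples: list[Repertoire],
    match: str = "exact",
) -> OccupancyMatrix:
    """Count, per sample, the clonotypes falling into each cluster.

    ``exact`` counts clonotypes whose CDR3 is a cluster member; ``hamming1``
    also counts single-substitution neighbors of a member.  A clonotype
    matching several clusters counts once in each.  All-zero rows are
    flagged rather than silently normalized.
    """
    if not clusters:
        raise ValueError("no clusters supplied")
    ids = [c.cluster_id for c in clusters]
    indexes = {c.cluster_id: NeighborIndex(c.members) for c in clusters}
    counts = pd.DataFrame(0, index=[s.sample_id for s in samples], columns=ids)
    for s in samples:
        for cdr3 in s.sequences:
            for c in clusters:
                if cdr3 in c.members:
                    counts.loc[s.sample_id, c.cluster_id] += 1
                elif match == "hamming1" and indexes[c.cluster_id].count_neighbors(cdr3) > 0:
                    counts.loc[s.sample_id, c.cluster_id] += 1
    zero_rows = list(counts.index[counts.sum(axis=1) == 0])
    if zero_rows:
        warnings.warn(f"samples with zero cluster occupancy: {zero_rows}")
    return OccupancyMatrix(counts, zero_rows)


def jsd(p: np.ndarray, q: np.ndarray, base: float = 2.0) -> float:
    """Jensen–Shannon divergence between two distributions (0*log0 := 0)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    return (0.5 * kl(p, m) + 0.5 * kl(q, m)) / np.log(base)


def jsd_matrix(m: OccupancyMatrix, base: float = 2.0) -> pd.DataFrame:
    """Pairwise JSD between samples' cluster distributions.

    Zero-occupancy rows are excluded (with the warning raised when the
    matrix was built) rather than smoothed.
    """
    d = m.distributions.drop(index=m.zero_rows)
    if len(d) < 2:
        raise ValueError("need at least 2 samples with non-zero occupancy")
    labels = list(d.index)
    arr = d.to_numpy()
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jsd(arr[i], arr[j], base)
    return pd.DataFrame(out, index=labels, columns=labels)


def pair_separation(
    jsd_df: pd.DataFrame,
    pair_labels: dict[str, object],
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Mean within-pair vs between-pair JSD, with a label-permutation p-value.

    The statistic is (between - within); the p-value is the fraction of
    label permutations with at least as large a gap (add-one corrected).
    """
    labels = np.array([pair_labels[s] for s in jsd_df.index])
    arr = jsd_df.to_numpy()
    iu = np.triu_indices(len(labels), k=1)

    def gap(lab: np.ndarray) -> tuple[float, float, float]:
        same = lab[iu[0]] == lab[iu[1]]
        within = arr[iu][same].mean() if same.any() else np.nan
        between = arr[iu][~same].mean() if (~same).any() else np.nan
        return within, between, between - within

    within, between, observed = gap(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        hits += gap(perm)[2] >= observed
    p = (hits + 1) / (n_permutations + 1)
    return float(within), float(between), float(p)
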