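"""CDR3 motif clusters: connected components of the 1-substitution graph.

Top neighbor-enriched sequences are clustered by connecting any two
sequences that differ by a single amino-acid substitution; components with
at least two members become clusters, numbered by decreasing size.  Each
cluster carries a position-weight matrix over its (same-length) members;
clusters and PWMs round-trip through a plain-TSV motif database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import EnrichmentRecord
from .features import AA_ORDER


@dataclass
class CdrCluster:
    cluster_id: int  # 1 = largest
    members: frozenset[str]
    provenance: str = "enriched_post"
    chain: str = "TRB"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(m) for m in self.members}
        if len(lengths) > 1:
            raise ValueError("cluster members must share one length")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def length(self) -> int:
        return len(next(iter(self.members)))


def select_top(records: list[EnrichmentRecord], n: int) -> set[str]:
    """The ``n`` sequences with the smallest enrichment p-values.

    Ties are broken by larger fold change, then lexicographic CDR3, so the
    selection is deterministic.
    """
    ranked = sorted(records, key=lambda r: (r.p_value, -r.log2_fc, r.cdr3_aa))
    return {r.cdr3_aa for r in ranked[:n]}


def components(seqs: set[str] | list[str], min_size: int = 2,
               provenance: str = "enriched_post", chain: str = "TRB") -> list[CdrCluster]:
    """Connected components under the single-substitution edge.

    Edges exist only between equal-length sequences, so components are
    length-pure by construction.  Components smaller than ``min_size``
    (singletons by default) are discarded; survivors are numbered 1.. by
    decreasing size, ties broken by lexicographic smallest member.
    """
    seqs = sorted(set(seqs))
    g = nx.Graph()
    g.add_nodes_from(seqs)
    buckets: dict[tuple, list[str]] = {}
    for s in seqs:
        for i in range(len(s)):
            buckets.setdefault((i, s[:i], s[i + 1 :]), []).append(s)
    for members in buckets.values():
        # a star within the bucket yields the same connected components
        for other in members[1:]:
            g.add_edge(members[0], other)
    comps = [c for c in nx.connected_components(g) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), min(c)))
    out = []
    for i, c in enumerate(comps, start=1):
        assert len({len(m) for m in c}) == 1, "components must be length-pure"
        out.append(CdrCluster(i, frozenset(c), provenance, chain))
    return out


def cluster_pwm(c: CdrCluster) -> pd.DataFrame:
    """Position x residue probability matrix over the cluster members.

    Column ``j``, residue ``a`` holds count(a at j) / |members|; no
    pseudocount, so each row (position) sums to exactly 1.
    """
    m = np.zeros((c.length, len(AA_ORDER)))
    idx = {aa: i for i, aa in enumerate(AA_ORDER)}
    for s in c.members:
        for j, ch in enumerate(s):
            m[j, idx[ch]] += 1
    return pd.DataFrame(m / c.size, columns=list(AA_ORDER),
                        index=pd.RangeIndex(c.length, name="position"))


def consensus(c: CdrCluster) -> str:
    pwm = cluster_pwm(c)
    return "".join(pwm.columns[j] for j in pwm.to_numpy().argmax(axis=1))


def export_motif_db(clusters: list[CdrCluster], path: str | Path) -> None:
    """Write the motif database: one TSV row per cluster, PWM as JSON."""
    rows = []
    for c in clusters:
        pwm = cluster_pwm(c)
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "provenance": c.provenance,
                "chain": c.chain,
                "size": c.size,
                "length": c.length,
                "members": ",".join(sorted(c.members)),
                "consensus": consensus(c),
                "pwm": json.dumps(pwm.round(9).to_numpy().tolist()),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_motif_db(path: str | Path) -> list[CdrCluster]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        c = CdrCluster(int(row.cluster_id), frozenset(row.members.split(",")),
                       row.provenance, row.chain)
        c.meta["pwm"] = pd.DataFrame(json.loads(row.pwm), columns=list(AA_ORDER))
        out.append(c)
    return out


def plot_logo(c: CdrCluster, ax=None):
    """Minimal sequence-logo rendering: letters stacked by information content.

    A plotting convenience only; the tested artifact is the PWM itself.
    """
    import matplotlib.pyplot as plt
    from matplotlib.textpath import TextPath
    from matplotlib.patches import PathPatch
    from matplotlib.transforms import Affine2D
    from matplotlib.font_manager import FontProperties

    pwm = cluster_pwm(c).to_numpy()
    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * pwm.shape[0], 2.0))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    for j in range(pwm.shape[0]):
        col = pwm[j]
        info = np.log2(20) + np.nansum(np.where(col > 0, col * np.log2(col), 0.0))
        y = 0.0
        for i in np.argsort(col):
            if col[i] == 0:
                continue
            h = col[i] * info
            tp = TextPath((0, 0), AA_ORDER[i], size=1.0, prop=fp)
            bb = tp.get_extents()
            tr = (Affine2D().translate(-bb.x0, -bb.y0)
                  .scale(0.9 / bb.width, h / bb.height).translate(j + 0.05, y))
            ax.add_patch(PathPatch(tp.transformed(tr), lw=0, fc="C0"))
            y += h
    ax.set_xlim(0, pwm.shape[0])
    ax.set_ylim(0, np.log2(20))
    ax.set_xlabel("CDR3 position")
    ax.set_ylabel("bits")
    return ax
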