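"""TCRNET-style Hamming-neighbor enrichment of CDR3 sequences.

A CDR3 of interest sits in a denser region of the sequence-similarity graph
of its repertoire than expected from a control: its number of distinct
Hamming-distance-1 neighbors (same length, exactly one substitution) in the
foreground is compared to the count expected from the background, scaled by
sample sizes, with an exact upper-tail binomial p-value.  Depletion is the
same test with foreground and background swapped.

The index uses masked keys (each sequence hashed once per position with
that position wildcarded), so building and querying are O(N * L), never
all-pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io import Repertoire

_TINY = 5e-324  # smallest positive float; keeps p-values in (0, 1]


@dataclass
class EnrichmentRecord:
    cdr3_aa: str
    v_gene: str
    j_gene: str
    obs_neighbors: int
    ctrl_neighbors: int
    expected: float
    log2_fc: float
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value))


class NeighborIndex:
    """Masked-key index counting distinct Hamming-1 neighbors.

    Two same-length sequences differing in exactly one position share
    exactly one masked key, so summing (bucket size - 1) over a member's
    keys — or bucket sizes for a foreign query, minus the L-fold
    self-matches if the query happens to be present — counts each neighbor
    exactly once.  Built over unique sequences; a sequence is never its own
    neighbor.
    """

    def __init__(self, sequences) -> None:
        self.members = set(sequences)
        self.size = len(self.members)
        self._buckets: Counter = Counter()
        for s in self.members:
            for i in range(len(s)):
                self._buckets[(i, s[:i], s[i + 1 :])] += 1

    def count_neighbors(self, query: str) -> int:
        total = 0
        for i in range(len(query)):
            total += self._buckets.get((i, query[:i], query[i + 1 :]), 0)
        if query in self.members:
            total -= len(query)
        return total


def neighbor_index(r: Repertoire) -> NeighborIndex:
    return NeighborIndex(r.unique_sequences())


def enrich(fg: Repertoire, bg: Repertoire, pseudocount: float = 0.5) -> list[EnrichmentRecord]:
    """Score every unique foreground CDR3 for neighbor enrichment vs background.

    For CDR3 x with d_fg foreground and d_bg background neighbors::

        expected = d_bg * |fg| / |bg|
        log2_fc  = log2((d_fg + psi) / (expected + psi))
        p        = P[X >= d_fg],  X ~ Binomial(|fg|, max(d_bg, 1) / |bg|)

    where |fg|, |bg| are unique-sequence counts.  The binomial tail is
    exact; the pseudocount enters only the fold change.  The control rate
    is floored at one neighbor: a control that showed zero neighbors still
    cannot witness a rate below 1/|bg|, and the plug-in rate d_bg/|bg| = 0
    would otherwise declare every chance foreground neighbor infinitely
    significant (p = 0), destroying calibration under the null.
    """
    fg_unique = fg.unique_sequences()
    if not fg_unique:
        raise ValueError("foreground is empty")
    bg_index = NeighborIndex(bg.unique_sequences())
    if bg_index.size == 0:
        raise ValueError("background is empty")
    fg_index = NeighborIndex(fg_unique)
    n_fg, n_bg = fg_index.size, bg_index.size

    vj: dict[str, tuple[str, str]] = {}
    for c in fg.clonotypes:
        vj.setdefault(c.cdr3_aa, (c.v_gene, c.j_gene))

    d_fg = np.array([fg_index.count_neighbors(s) for s in fg_unique])
    d_bg = np.array([bg_index.count_neighbors(s) for s in fg_unique])
    expected = d_bg * n_fg / n_bg
    log2_fc = np.log2((d_fg + pseudocount) / (expected + pseudocount))
    # sf(k-1) = P[X >= k]; exact tail, no normal approximation
    p = binom.sf(d_fg - 1, n_fg, np.maximum(d_bg, 1) / n_bg)
    p = np.clip(p, _TINY, 1.0)

    return [
        EnrichmentRecord(s, *vj[s], int(o), int(c_), float(e), float(l), float(pv))
        for s, o, c_, e, l, pv in zip(fg_unique, d_fg, d_bg, expected, log2_fc, p)
    ]


def deplete(fg: Repertoire, bg: Repertoire, pseudocount: float = 0.5) -> list[EnrichmentRecord]:
    """Sequences enriched in the background relative to the foreground.

    Swapping foreground and background turns the enrichment test into a
    search for CDR3s over-represented before selection, i.e. depleted by it.
    """
    return enrich(bg, fg, pseudocount)


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "cdr3_aa": [r.cdr3_aa for r in records],
            "v_gene": [r.v_gene for r in records],
            "j_gene": [r.j_gene for r in records],
            "obs": [r.obs_neighbors for r in records],
            "ctrl": [r.ctrl_neighbors for r in records],
            "expected": [r.expected for r in records],
            "log2_fc": [r.log2_fc for r in records],
            "p": [r.p_value for r in records],
        }
    )
    df["neg_log10_p"] = -np.log10(df["p"])
    return df
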