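"""Pre- vs post-selection repertoire comparison statistics.

Per-feature log2 fold changes, per-VJ-pair Kidera-factor tests (Welch t,
Cohen's d, "selection force" = the VJ pair's post/pre fraction ratio),
distribution summaries for charge/length/hydrophobicity with a tail-mass
probe of the winsorizing signature, and V/J usage comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import (FreqTable, mean_hydrophobicity, mean_kidera, net_charge)
from .io import Repertoire

QUANTILES = (0.01, 0.05, 0.25, 0.50, 0.75, 0.95, 0.99)


@dataclass
class FeatureComparison:
    feature: str
    freq_pre: float
    freq_post: float
    log2_fc: float
    p_value: float | None = None


@dataclass
class VjEffect:
    v_gene: str
    j_gene: str
    factor: int
    n_pre: int
    n_post: int
    cohen_d: float
    t_stat: float
    p_value: float | None
    p_adj: float | None
    selection_force: float
    degenerate: bool = False


def compare_feature_tables(
    pre: FreqTable, post: FreqTable, pseudocount: float | None = None
) -> list[FeatureComparison]:
    """Per-feature log2((post+psi)/(pre+psi)) over the feature union.

    The default pseudocount is 1/(number of features in the union), so a
    feature absent from one table gets a finite, size-aware fold change.
    Results are sorted by fold change (most depleted first).
    """
    features = pre.union_features(post)
    if pseudocount is None:
        pseudocount = 1.0 / max(len(features), 1)
    out = []
    for f in features:
        fp = pre.freqs.get(f, 0.0)
        fq = post.freqs.get(f, 0.0)
        lfc = float(np.log2((fq + pseudocount) / (fp + pseudocount)))
        out.append(FeatureComparison(f, fp, fq, lfc))
    out.sort(key=lambda r: (r.log2_fc, r.feature))
    return out


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean(a) - mean(b)) / pooled SD, the classic two-group effect size."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / pooled)


def _group_by_vj(r: Repertoire) -> dict[tuple[str, str], list[str]]:
    groups: dict[tuple[str, str], list[str]] = {}
    for c in r.clonotypes:
        groups.setdefault((c.v_gene, c.j_gene), []).append(c.cdr3_aa)
    return groups


def kidera_vj_test(
    pre: Repertoire, post: Repertoire, factor: int, min_n: int = 30
) -> list[VjEffect]:
    """Per-VJ-pair comparison of mean Kidera-factor values.

    Comparing within each VJ pair removes the bias introduced by shifted
    gene usage.  Per pair: Welch two-sample t-test on per-CDR3 mean factor
    values, Cohen's d (post minus pre, pooled SD), and the selection force
    (pair's clonotype fraction post / fraction pre).  Benjamini–Hochberg
    adjusted p-values are reported alongside the raw ones.
    """
    if not 1 <= factor <= 10:
        raise ValueError("factor index must be 1..10")
    g_pre, g_post = _group_by_vj(pre), _group_by_vj(post)
    n_pre_tot, n_post_tot = len(pre.clonotypes), len(post.clonotypes)
    cache: dict[str, float] = {}

    def values(seqs: list[str]) -> np.ndarray:
        out = np.empty(len(seqs))
        for i, s in enumerate(seqs):
            if s not in cache:
                cache[s] = float(mean_kidera(s)[factor - 1])
            out[i] = cache[s]
        return out

    records = []
    for pair in sorted(set(g_pre) & set(g_post)):
        a, b = g_pre[pair], g_post[pair]
        if len(a) < min_n or len(b) < min_n:
            continue
        va, vb = values(a), values(b)
        force = (len(b) / n_post_tot) / (len(a) / n_pre_tot)
        # ptp == 0 detects constant groups exactly (np.var suffers roundoff)
        degenerate = np.ptp(va) == 0 and np.ptp(vb) == 0
        if degenerate:
            t = p = None
            d = 0.0
        else:
            t, p = sps.ttest_ind(vb, va, equal_var=False)
            t, p = float(t), float(p)
            d = cohens_d(vb, va)
        records.append(
            VjEffect(pair[0], pair[1], factor, len(a), len(b), d,
                     t if t is not None else float("nan"), p, None, force,
                     degenerate)
        )
    testable = [r for r in records if r.p_value is not None]
    if testable:
        adj = multipletests([r.p_value for r in testable], method="fdr_bh")[1]
        for r, pa in zip(testable, adj):
            r.p_adj = float(pa)
    return records


@dataclass
class DistributionSummary:
    property: str
    mean_pre: float
    mean_post: float
    sd_pre: float
    sd_post: float
    quantiles_pre: dict[float, float]
    quantiles_post: dict[float, float]
    tail_mass_pre: float   # fraction of pre outside pre's [5%, 95%] band
    tail_mass_post: float  # fraction of post outside the same (pre) band
    cohen_d: float         # post vs pre


def _property_values(r: Repertoire, prop: str) -> np.ndarray:
    if prop == "charge":
        return np.array([net_charge(s) for s in r.sequences])
    if prop == "length":
        return np.array([len(s) for s in r.sequences], dtype=float)
    if prop == "hydrophobicity":
        return np.array([mean_hydrophobicity(s) for s in r.sequences])
    raise ValueError(f"unknown property {prop!r}")


def distribution_summary(
    pre: Repertoire, post: Repertoire,
    prop: Literal["charge", "length", "hydrophobicity"],
) -> DistributionSummary:
    """Distribution shift summary for one physicochemical property.

    ``tail_mass_post`` is the fraction of post-selection values falling
    outside the pre-selection [5%, 95%] band; its reduction relative to
    ``tail_mass_pre`` (~0.10 by construction; less for discrete properties
    such as length) quantifies the winsorizing of the property after
    selection.
    """
    if not pre.clonotypes or not post.clonotypes:
        raise ValueError("both repertoires must be non-empty")
    va, vb = _property_values(pre, prop), _property_values(post, prop)
    lo, hi = np.quantile(va, [0.05, 0.95])
    return DistributionSummary(
        property=prop,
        mean_pre=float(va.mean()), mean_post=float(vb.mean()),
        sd_pre=float(va.std(ddof=1)), sd_post=float(vb.std(ddof=1)),
        quantiles_pre={q: float(np.quantile(va, q)) for q in QUANTILES},
        quantiles_post={q: float(np.quantile(vb, q)) for q in QUANTILES},
        tail_mass_pre=float(np.mean((va < lo) | (va > hi))),
        tail_mass_post=float(np.mean((vb < lo) | (vb > hi))),
        cohen_d=cohens_d(vb, va),
    )


def vj_usage_comparison(
    pre: Repertoire, post: Repertoire, pseudocount: float | None = None
) -> dict:
    """Gene- and VJ-pair-level usage comparison.

    Returns feature comparisons for V genes, J genes and VJ pairs, plus the
    Pearson correlation of pair log2 fold change with pre-selection pair
    frequency — a probe of whether selection favours already-frequent
    rearrangements ("rich get richer").
    """
    def freq_table(r: Repertoire, key) -> FreqTable:
        counts: dict[str, int] = {}
        for c in r.clonotypes:
            counts[key(c)] = counts.get(key(c), 0) + 1
        total = len(r.clonotypes)
        return FreqTable({k: v / total for k, v in counts.items()}, total,
                         "per_occurrence")

    out: dict = {}
    for level, key in (
        ("v", lambda c: c.v_gene),
        ("j", lambda c: c.j_gene),
        ("vj", lambda c: f"{c.v_gene}|{c.j_gene}"),
    ):
        out[level] = compare_feature_tables(freq_table(pre, key),
                                            freq_table(post, key), pseudocount)
    pairs = out["vj"]
    if len(pairs) >= 3:
        pre_f = np.array([r.freq_pre for r in pairs])
        lfc = np.array([r.log2_fc for r in pairs])
        if np.ptp(lfc) == 0 or np.ptp(pre_f) == 0:
            rho, p = 0.0, 1.0  # no usage shift at all: correlation undefined
        else:
            rho, p = sps.pearsonr(pre_f, lfc)
        out["rich_get_richer"] = {"pearson_r": float(rho), "p_value": float(p)}
    return out
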