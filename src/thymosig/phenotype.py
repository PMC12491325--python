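"""Cluster-phenotype association in phenotype-annotated single-cell data.

Selection-associated CDR3 clusters are intersected with a single-cell
clonotype table (cell barcode -> CDR3 per chain -> phenotype label); for
every (cluster, phenotype) pair a 2x2 contingency table over cells is
tested with the two-tailed Fisher exact test, with multiple-testing
correction across all pairs jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .clusters import CdrCluster
from .enrichment import NeighborIndex


@dataclass
class CellAnnotation:
    cell_id: str
    phenotype: str
    cdr3_aa_tra: str | None = None
    cdr3_aa_trb: str | None = None

    def cdr3(self, chain: str) -> str | None:
        return self.cdr3_aa_tra if chain == "TRA" else self.cdr3_aa_trb


@dataclass
class AssociationRecord:
    cluster_id: int
    phenotype: str
    a: int  # cluster & phenotype
    b: int  # cluster & not phenotype
    c: int  # not cluster & phenotype
    d: int  # not cluster & not phenotype
    odds_ratio: float
    p_raw: float
    p_adj: float | None = None
    flagged: bool = False


def read_cell_table(path: str | Path) -> list[CellAnnotation]:
    """Read a cell annotation TSV (cell_id, cdr3_aa_tra, cdr3_aa_trb, phenotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"cell table requires column {col!r}")
    cells = []
    for row in df.itertuples():
        tra = getattr(row, "cdr3_aa_tra", None)
        trb = getattr(row, "cdr3_aa_trb", None)
        cells.append(CellAnnotation(
            cell_id=row.cell_id, phenotype=row.phenotype,
            cdr3_aa_tra=None if pd.isna(tra) else tra,
            cdr3_aa_trb=None if pd.isna(trb) else trb,
        ))
    if len({c.cell_id for c in cells}) != len(cells):
        raise ValueError("cell_id values must be unique")
    return cells


def match_cells(
    clusters: list[CdrCluster],
    cells: list[CellAnnotation],
    chain: str = "TRB",
    match: str = "exact",
) -> dict[str, set[int]]:
    """Per cell, the set of cluster ids its CDR3 falls into.

    Cells lacking the analysis chain's CDR3 are excluded from the mapping
    (and hence from all contingency totals).
    """
    indexes = {c.cluster_id: NeighborIndex(c.members) for c in clusters}
    out: dict[str, set[int]] = {}
    for cell in cells:
        cdr3 = cell.cdr3(chain)
        if cdr3 is None:
            continue
        matched = set()
        for c in clusters:
            if cdr3 in c.members:
                matched.add(c.cluster_id)
            elif match == "hamming1" and indexes[c.cluster_id].count_neighbors(cdr3) > 0:
                matched.add(c.cluster_id)
        out[cell.cell_id] = matched
    return out


def associate(
    matches: dict[str, set[int]],
    cells: list[CellAnnotation],
    correction: str = "BH",
) -> list[AssociationRecord]:
    """Fisher-exact cluster-phenotype association over all pairs.

    The odds ratio is the sample ad/(bc) with the Haldane 0.5 correction
    when any cell of the table is zero; the p-value is the exact two-tailed
    Fisher probability.  Correction ('BH' or 'bonferroni') is applied
    jointly across all testable (cluster, phenotype) pairs; pairs from an
    empty phenotype stratum are flagged and excluded from correction.
    """
    counted = [c for c in cells if c.cell_id in matches]
    phenotypes = sorted({c.phenotype for c in counted})
    if len(phenotypes) < 2:
        raise ValueError("need at least 2 phenotypes among matched-chain cells")
    cluster_ids = sorted({cid for s in matches.values() for cid in s})
    records = []
    for cid in cluster_ids:
        for ph in phenotypes:
            a = b = c_ = d = 0
            for cell in counted:
                in_cluster = cid in matches[cell.cell_id]
                is_ph = cell.phenotype == ph
                if in_cluster and is_ph:
                    a += 1
                elif in_cluster:
                    b += 1
                elif is_ph:
                    c_ += 1
                else:
                    d += 1
            flagged = (a + c_) == 0  # empty phenotype stratum
            if 0 in (a, b, c_, d):
                or_ = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c_ + 0.5))
            else:
                or_ = (a * d) / (b * c_)
            _, p = fisher_exact([[a, b], [c_, d]], alternative="two-sided")
            records.append(AssociationRecord(cid, ph, a, b, c_, d,
                                             float(or_), float(p), None, flagged))
    testable = [r for r in records if not r.flagged]
    if testable:
        method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[correction]
        adj = multipletests([r.p_raw for r in testable], method=method)[1]
        for r, pa in zip(testable, adj):
            r.p_adj = float(pa)
    return records


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
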