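"""Reading, filtering, subsampling and pooling of clonotype tables.

Supports the common AIRR-seq tabular dialects (AIRR rearrangement TSV,
VDJtools, immunoSEQ) plus the package's own canonical TSV.  A clonotype is
one V(D)J rearrangement identified by its CDR3 amino-acid sequence, the V
and J genes, and a read/UMI count; the nucleotide junction and its
V / NDN / J segmentation are optional but required for somatic-origin
(NDN) attribution of motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: dialect -> (cdr3_aa, cdr3_nt, v, j, count) column names; None = absent
DIALECTS = {
    "airr": ("junction_aa", "junction", "v_call", "j_call", "duplicate_count"),
    "vdjtools": ("cdr3aa", "cdr3nt", "v", "j", "count"),
    "immunoseq": ("amino_acid", "rearrangement", "v_gene", "j_gene", "templates"),
    "canonical": ("cdr3_aa", "cdr3_nt", "v_gene", "j_gene", "count"),
}

_ALLELE_RE = re.compile(r"\*\d+$")


class FormatError(ValueError):
    """A mandatory column is missing or the file is otherwise malformed."""


class EmptyRepertoireError(ValueError):
    """The file contained no (valid) clonotype rows."""


class ChainMismatchError(ValueError):
    """Repertoires of different chains cannot be pooled."""


@dataclass
class Clonotype:
    """One rearrangement: CDR3 amino acids, genes, count, optional junction.

    ``segment_bounds`` are three half-open nucleotide intervals over
    ``cdr3_nt`` — the V-templated part, the somatic NDN part, and the
    J-templated part — tiling the junction exactly.
    """

    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int = 1
    cdr3_nt: str | None = None
    segment_bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if self.cdr3_nt is not None and len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise ValueError(
                f"cdr3_nt length {len(self.cdr3_nt)} != 3*len(cdr3_aa) for {self.cdr3_aa}"
            )
        if self.segment_bounds is not None:
            (v0, v1), (n0, n1), (j0, j1) = self.segment_bounds
            if not (v0 == 0 and v1 == n0 and n1 == j0 and j1 == len(self.cdr3_nt or "")):
                raise ValueError("segment_bounds must tile cdr3_nt exactly")


@dataclass
class Repertoire:
    """A named collection of clonotypes from one chain (TRA or TRB)."""

    sample_id: str
    chain: str
    clonotypes: list[Clonotype]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self):
        return iter(self.clonotypes)

    @property
    def sequences(self) -> list[str]:
        return [c.cdr3_aa for c in self.clonotypes]

    def unique_sequences(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.clonotypes:
            seen.setdefault(c.cdr3_aa)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "chain": self.chain,
                "cdr3_aa": [c.cdr3_aa for c in self.clonotypes],
                "cdr3_nt": [c.cdr3_nt or "" for c in self.clonotypes],
                "v_gene": [c.v_gene for c in self.clonotypes],
                "j_gene": [c.j_gene for c in self.clonotypes],
                "count": [c.count for c in self.clonotypes],
            }
        )


def normalize_gene(name: str) -> str:
    """Strip allele suffix ("*01") and surrounding whitespace from a gene call.

    Ambiguous calls ("TRBV12-3/12-4") and pseudogene names are kept verbatim:
    downstream VJ-pair analyses aggregate at the gene level.
    """
    return _ALLELE_RE.sub("", name.strip())


def _valid_cdr3(seq: str) -> bool:
    return bool(seq) and all(ch in AA_ALPHABET for ch in seq)


def read_clonotypes(
    path: str | Path,
    dialect: str = "airr",
    sample_id: str | None = None,
    chain: str = "TRB",
) -> Repertoire:
    """Read a clonotype TSV into a :class:`Repertoire`.

    Rows whose CDR3 contains a stop codon ('*'), a frameshift marker ('_'),
    or any non-amino-acid character are dropped; the number of dropped rows
    is recorded in ``Repertoire.meta['dropped_rows']``.  Gene allele
    suffixes are stripped.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    aa_col, nt_col, v_col, j_col, count_col = DIALECTS[dialect]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path} is empty") from None
    for col in (aa_col, v_col, j_col, count_col):
        if col not in df.columns:
            raise FormatError(f"dialect {dialect!r} requires column {col!r}; not found in {path}")
    dropped = 0
    clonotypes: list[Clonotype] = []
    has_nt = nt_col in df.columns
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        aa = str(rec[aa_col]).strip()
        if not _valid_cdr3(aa):
            dropped += 1
            continue
        nt = None
        if has_nt:
            nt_val = str(rec[nt_col]).strip().upper()
            if nt_val and nt_val != "NAN" and len(nt_val) == 3 * len(aa):
                nt = nt_val
        try:
            count = int(float(rec[count_col]))
        except (TypeError, ValueError):
            dropped += 1
            continue
        clonotypes.append(
            Clonotype(
                cdr3_aa=aa,
                v_gene=normalize_gene(str(rec[v_col])),
                j_gene=normalize_gene(str(rec[j_col])),
                count=count,
                cdr3_nt=nt,
            )
        )
    if not clonotypes and dropped == 0:
        raise EmptyRepertoireError(f"{path} contains no clonotype rows")
    return Repertoire(
        sample_id=sample_id or path.stem,
        chain=chain,
        clonotypes=clonotypes,
        meta={"dropped_rows": dropped, "source": str(path), "dialect": dialect},
    )


def write_clonotypes(r: Repertoire, path: str | Path, dialect: str = "canonical") -> None:
    """Write a repertoire as a TSV in the requested dialect."""
    aa_col, nt_col, v_col, j_col, count_col = DIALECTS[dialect]
    df = pd.DataFrame(
        {
            aa_col: [c.cdr3_aa for c in r.clonotypes],
            nt_col: [c.cdr3_nt or "" for c in r.clonotypes],
            v_col: [c.v_gene for c in r.clonotypes],
            j_col: [c.j_gene for c in r.clonotypes],
            count_col: [c.count for c in r.clonotypes],
        }
    )
    if dialect == "canonical":
        df.insert(0, "sample_id", r.sample_id)
        df.insert(1, "chain", r.chain)
    df.to_csv(path, sep="\t", index=False)


def filter_singletons(r: Repertoire) -> Repertoire:
    """Keep only count-1 clonotypes (naive-cell proxy), preserving order."""
    kept = [c for c in r.clonotypes if c.count == 1]
    return Repertoire(r.sample_id, r.chain, kept, dict(r.meta, singletons_only=True))


def merge_duplicates(r: Repertoire) -> Repertoire:
    """Sum counts over identical (cdr3_aa, v_gene, j_gene) rows.

    Not applied on read: the clonotype counts reported by upstream pipelines
    would silently change under automatic merging.
    """
    agg: dict[tuple[str, str, str], Clonotype] = {}
    for c in r.clonotypes:
        key = (c.cdr3_aa, c.v_gene, c.j_gene)
        if key in agg:
            agg[key].count += c.count
        else:
            agg[key] = Clonotype(c.cdr3_aa, c.v_gene, c.j_gene, c.count, c.cdr3_nt,
                                 c.segment_bounds, dict(c.meta))
    return Repertoire(r.sample_id, r.chain, list(agg.values()), dict(r.meta))


def deduplicate(r: Repertoire) -> Repertoire:
    """Keep the first clonotype per unique CDR3 amino-acid sequence."""
    seen: set[str] = set()
    kept = []
    for c in r.clonotypes:
        if c.cdr3_aa not in seen:
            seen.add(c.cdr3_aa)
            kept.append(c)
    return Repertoire(r.sample_id, r.chain, kept, dict(r.meta))


def subsample(r: Repertoire, n: int, seed: int) -> Repertoire:
    """Uniform sample of ``n`` clonotypes without replacement, seeded."""
    if n > len(r.clonotypes):
        raise ValueError(f"cannot subsample {n} from {len(r.clonotypes)} clonotypes")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(r.clonotypes), size=n, replace=False)
    kept = [r.clonotypes[i] for i in np.sort(idx)]
    return Repertoire(r.sample_id, r.chain, kept, dict(r.meta, subsampled_to=n))


def pool(rs: Sequence[Repertoire], tag_origin: bool = True,
         sample_id: str = "pool") -> Repertoire:
    """Concatenate repertoires of the same chain.

    With ``tag_origin`` each clonotype records its source sample_id in
    ``meta['origin']`` so the pooled set can be partitioned back.
    """
    if not rs:
        raise ValueError("nothing to pool")
    chains = {r.chain for r in rs}
    if len(chains) > 1:
        raise ChainMismatchError(f"cannot pool mixed chains {sorted(chains)}")
    clonotypes: list[Clonotype] = []
    for r in rs:
        for c in r.clonotypes:
            if tag_origin:
                c = Clonotype(c.cdr3_aa, c.v_gene, c.j_gene, c.count, c.cdr3_nt,
                              c.segment_bounds, dict(c.meta, origin=r.sample_id))
            clonotypes.append(c)
    return Repertoire(sample_id, chains.pop(), clonotypes,
                      {"pooled_from": [r.sample_id for r in rs]})
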