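"""Per-sequence and per-repertoire CDR3 features.

Residue and k-mer frequency tables, N-glycosylation sequon and fixed-motif
scanning with somatic (NDN) region attribution, physicochemical profiles
(Kidera factors, net charge, hydrophobicity, length) and positional
amino-acid log-odds between repertoires.

Constant tables (the 10x20 Kidera matrix, hydrophobicity scales, side-chain
pKa sets) ship as plain-text data files under :mod:`thymosig.data`.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io import AA_ALPHABET, Clonotype, Repertoire

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: motifs of putative tyrosine-sulfation sites screened alongside sequons
SULFATION_MOTIFS = ("DDD", "DDY", "YYY", "EEE")


def _load_table(fname: str) -> pd.DataFrame:
    with resources.files("thymosig.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


_KIDERA_DF = _load_table("kidera_factors.tsv").set_index("aa")
KIDERA: dict[str, np.ndarray] = {
    aa: _KIDERA_DF.loc[aa].to_numpy(dtype=float) for aa in _KIDERA_DF.index
}

_HYDRO_DF = _load_table("hydrophobicity.tsv").set_index("aa")
HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    col: _HYDRO_DF[col].to_dict() for col in _HYDRO_DF.columns
}

_PKA_DF = _load_table("pka_sets.tsv")
PKA_SETS: dict[str, dict[str, tuple[float, int]]] = {
    name: {row.aa: (row.pka, int(row.sign)) for row in grp.itertuples()}
    for name, grp in _PKA_DF.groupby("set")
}


@dataclass
class FreqTable:
    """Feature -> frequency map with its denominator and weighting mode."""

    freqs: dict[str, float]
    total: int
    weighting: Literal["per_occurrence", "per_clonotype_presence"]

    def union_features(self, other: "FreqTable") -> list[str]:
        return sorted(set(self.freqs) | set(other.freqs))


@dataclass
class PhyschemProfile:
    kidera: np.ndarray  # shape (10,)
    charge: float
    hydrophobicity: float
    length: int


@dataclass
class MotifHit:
    pattern: str
    position: int  # 0-based start of the match
    region: str = "unknown"  # V | NDN | J | unknown


def _check_residues(seq: str) -> None:
    for ch in seq:
        if ch not in AA_ALPHABET:
            raise ValueError(f"unknown residue {ch!r} in {seq!r}")


def residue_frequencies(
    r: Repertoire, weighting: str = "per_occurrence"
) -> FreqTable:
    """Single amino-acid frequencies over all CDR3s (clonotype weight 1).

    ``per_occurrence``: every residue occurrence counts once; frequencies
    sum to 1.  ``per_clonotype_presence``: the fraction of clonotypes whose
    CDR3 contains the residue at least once.
    """
    if not r.clonotypes:
        raise ValueError("repertoire is empty")
    if weighting == "per_occurrence":
        counts = Counter()
        for c in r.clonotypes:
            counts.update(c.cdr3_aa)
        total = sum(counts.values())
        freqs = {aa: counts[aa] / total for aa in counts}
    elif weighting == "per_clonotype_presence":
        counts = Counter()
        for c in r.clonotypes:
            counts.update(set(c.cdr3_aa))
        total = len(r.clonotypes)
        freqs = {aa: counts[aa] / total for aa in counts}
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return FreqTable(freqs, total, weighting)  # type: ignore[arg-type]


def kmer_frequencies(r: Repertoire, k: int = 3,
                     weighting: str = "per_occurrence") -> FreqTable:
    """Sliding-window k-mer frequencies over every CDR3 (all positions).

    k-mers are not filtered by their position in the CDR3.  Each clonotype
    contributes once regardless of read count (the all-singletons design
    makes count weighting moot); ``per_clonotype_presence`` counts each
    distinct k-mer once per clonotype.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for c in r.clonotypes:
        seq = c.cdr3_aa
        kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
        if weighting == "per_clonotype_presence":
            kmers = set(kmers)
        counts.update(kmers)
    total = sum(counts.values())
    if total == 0:
        warnings.warn(f"k={k} exceeds every sequence length; empty table")
        return FreqTable({}, 0, weighting)  # type: ignore[arg-type]
    freqs = {km: n / total for km, n in counts.items()}
    return FreqTable(freqs, total, weighting)  # type: ignore[arg-type]


def scan_sequons(seq: str, exclude_proline_x: bool = False) -> list[MotifHit]:
    """All N-X-[S/T] sequon starts in ``seq`` (overlapping hits included).

    With ``exclude_proline_x`` the non-glycosylated N-P-[S/T] variants are
    omitted.
    """
    _check_residues(seq)
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 2] in "ST":
            if exclude_proline_x and seq[i + 1] == "P":
                continue
            hits.append(MotifHit(seq[i : i + 3], i))
    return hits


def scan_fixed_motifs(
    seq: str, motifs: Iterable[str] = SULFATION_MOTIFS
) -> list[MotifHit]:
    """All exact-substring occurrences of ``motifs`` (overlaps allowed)."""
    _check_residues(seq)
    motifs = list(motifs)
    if not motifs:
        raise ValueError("motif list is empty")
    hits = []
    for i in range(len(seq)):
        for m in motifs:
            if seq.startswith(m, i):
                hits.append(MotifHit(m, i))
    return hits


def attribute_region(hit: MotifHit, c: Clonotype) -> str:
    """Map a motif hit's anchor residue to the V / NDN / J nucleotide segment.

    The anchor residue (the 'N' of a sequon, the first residue of a fixed
    motif) occupies one codon; the segment containing the majority (>= 2) of
    its three nucleotides wins.  Without ``segment_bounds`` the region is
    unknown.
    """
    if c.segment_bounds is None:
        return "unknown"
    codon_start = 3 * hit.position
    labels = ("V", "NDN", "J")
    overlaps = []
    for (a, b), label in zip(c.segment_bounds, labels):
        overlaps.append((max(0, min(b, codon_start + 3) - max(a, codon_start)), label))
    best_overlap, best_label = max(overlaps)
    return best_label if best_overlap >= 2 else "unknown"


def mean_kidera(seq: str) -> np.ndarray:
    """Mean (over residues) of the 10 Kidera factors; not z-score normalized."""
    _check_residues(seq)
    return np.mean([KIDERA[ch] for ch in seq], axis=0)


def net_charge(seq: str, ph: float = 7.0, pka_set: str = "lehninger",
               include_termini: bool = False) -> float:
    """Henderson–Hasselbalch net charge over ionizable side chains at ``ph``.

    Termini are excluded by default: the CDR3 is an internal loop of the
    receptor chain, not a free peptide.
    """
    _check_residues(seq)
    pkas = PKA_SETS[pka_set]
    q = 0.0
    residues = list(seq)
    if include_termini:
        residues += ["Nterm", "Cterm"]
    for res in residues:
        if res not in pkas:
            continue
        pka, sign = pkas[res]
        if sign > 0:
            q += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            q -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return q


def mean_hydrophobicity(seq: str, scale: str = "kyte_doolittle") -> float:
    _check_residues(seq)
    table = HYDROPHOBICITY_SCALES[scale]
    return float(np.mean([table[ch] for ch in seq]))


def physchem(seq: str, ph: float = 7.0, pka_set: str = "lehninger",
             hydro_scale: str = "kyte_doolittle",
             include_termini: bool = False) -> PhyschemProfile:
    """Full physicochemical profile of one CDR3."""
    return PhyschemProfile(
        kidera=mean_kidera(seq),
        charge=net_charge(seq, ph, pka_set, include_termini),
        hydrophobicity=mean_hydrophobicity(seq, hydro_scale),
        length=len(seq),
    )


def positional_marginals(
    post: Repertoire, pre: Repertoire, length: int, pseudocount: float = 1e-3
) -> pd.DataFrame:
    """Position x residue log2 odds of post- vs pre-selection occurrence.

    Restricted to CDR3s of exactly ``length`` residues — an empirical
    stand-in for learned positional selection factors.  A residue absent
    from both repertoires at a position has log-odds 0 (symmetric
    pseudocount).
    """
    mats = []
    for rep in (post, pre):
        seqs = [s for s in rep.sequences if len(s) == length]
        if not seqs:
            raise ValueError(f"no sequences of length {length} in {rep.sample_id}")
        m = np.zeros((length, len(AA_ORDER)))
        idx = {aa: i for i, aa in enumerate(AA_ORDER)}
        for s in seqs:
            for pos, ch in enumerate(s):
                m[pos, idx[ch]] += 1
        mats.append(m / len(seqs))
    post_f, pre_f = mats
    lo = np.log2((post_f + pseudocount) / (pre_f + pseudocount))
    return pd.DataFrame(lo, columns=list(AA_ORDER),
                        index=pd.RangeIndex(length, name="position"))
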