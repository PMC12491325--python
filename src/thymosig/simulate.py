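"""Simplified V(D)J rearrangement simulator and thymic-selection filter.

The generator emulates the structure of somatic recombination: a V, (D,) and
J segment are drawn by usage probability, junction-facing ends are trimmed by
geometric deletion lengths, untemplated (N) nucleotides are inserted from a
biased base composition, and the junction is kept only when it is productive
(in frame, no stop codon, starts with the conserved Cys, ends with Phe/Trp).
Rejection sampling mirrors how generative tools emit productive-only
rearrangements.  Segment boundaries are recorded exactly, so the somatic
(NDN) origin of any residue is known ground truth.

Selection is modelled as an independent per-sequence survival draw whose
probability multiplies a base rate with motif penalties, logistic terms on
mean Kidera-factor values and CDR3 length, and V/J-pair tilts.  Because
every knob has a closed-form effect on post/pre frequency ratios, imposed
effects are recoverable by the downstream comparison statistics.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .io import Clonotype, Repertoire

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})

BASES = "ACGT"


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string (standard code, '*' = stop)."""
    if len(nt) % 3:
        raise ValueError("sequence length not a multiple of 3")
    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))


class Segment(NamedTuple):
    name: str
    seq: str  # junction-facing terminal nucleotides
    prob: float


@dataclass
class GenerativeParams:
    """Parameters of the simplified rearrangement model.

    ``trim_p`` holds one geometric parameter per trimmed end (``v3``,
    ``d5``, ``d3``, ``j5``); deletion lengths are ``Geom(p) - 1`` so zero
    deletions have positive mass.  ``insert_p`` likewise controls N-insert
    lengths, with per-base composition ``insert_base_probs``.
    """

    chain: str
    v_segments: list[Segment]
    j_segments: list[Segment]
    d_segments: list[Segment] = field(default_factory=list)
    trim_p: dict[str, float] = field(
        default_factory=lambda: {"v3": 0.45, "d5": 0.35, "d3": 0.35, "j5": 0.35}
    )
    insert_p: float = 0.28
    insert_base_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )

    def __post_init__(self) -> None:
        for segs, label in ((self.v_segments, "V"), (self.j_segments, "J")):
            total = sum(s.prob for s in segs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} usage probabilities sum to {total}, not 1")
        if self.d_segments:
            total = sum(s.prob for s in self.d_segments)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"D usage probabilities sum to {total}, not 1")
        total = sum(self.insert_base_probs.get(b, 0.0) for b in BASES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"insertion base composition sums to {total}, not 1")

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        return cls(
            chain=d["chain"],
            v_segments=[Segment(*s) for s in d["v_segments"]],
            j_segments=[Segment(*s) for s in d["j_segments"]],
            d_segments=[Segment(*s) for s in d.get("d_segments", [])],
            trim_p=dict(d.get("trim_p", {"v3": 0.45, "d5": 0.35, "d3": 0.35, "j5": 0.35})),
            insert_p=float(d.get("insert_p", 0.28)),
            insert_base_probs=dict(d.get("insert_base_probs",
                                         {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerativeParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_params(chain: str = "TRB") -> GenerativeParams:
    """Load the toy parameter set shipped with the package (20 V, 12 J, 2 D)."""
    fname = {"TRB": "toy_trb_params.json", "TRA": "toy_tra_params.json"}[chain]
    text = resources.files("thymosig.data").joinpath(fname).read_text()
    return GenerativeParams.from_dict(json.loads(text))


class UnproductiveModelError(RuntimeError):
    """Rejection sampling failed to produce productive junctions."""


def _geom_lengths(rng: np.random.Generator, p: float, size: int) -> np.ndarray:
    # support {0, 1, 2, ...}; mean (1-p)/p
    return rng.geometric(p, size=size) - 1


def generate_pre_selection(
    p: GenerativeParams,
    n: int,
    seed: int,
    sample_id: str = "pre_sim",
    max_batches: int = 200,
) -> Repertoire:
    """Generate ``n`` productive clonotypes from the rearrangement model.

    Junctions are resampled until ``n`` productive ones (in frame, no stop,
    C...F/W) are collected; each carries exact ``segment_bounds`` splitting
    the junction into V-templated, NDN, and J-templated intervals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    v_probs = np.array([s.prob for s in p.v_segments])
    j_probs = np.array([s.prob for s in p.j_segments])
    d_probs = np.array([s.prob for s in p.d_segments]) if p.d_segments else None
    base_probs = np.array([p.insert_base_probs[b] for b in BASES])
    has_d = bool(p.d_segments)

    out: list[Clonotype] = []
    batch = max(2048, int(n * 1.2))
    for _ in range(max_batches):
        if len(out) >= n:
            break
        vi = rng.choice(len(p.v_segments), size=batch, p=v_probs)
        ji = rng.choice(len(p.j_segments), size=batch, p=j_probs)
        di = rng.choice(len(p.d_segments), size=batch, p=d_probs) if has_d else None
        t_v3 = _geom_lengths(rng, p.trim_p["v3"], batch)
        t_j5 = _geom_lengths(rng, p.trim_p["j5"], batch)
        if has_d:
            t_d5 = _geom_lengths(rng, p.trim_p["d5"], batch)
            t_d3 = _geom_lengths(rng, p.trim_p["d3"], batch)
            n_ins1 = _geom_lengths(rng, p.insert_p, batch)
            n_ins2 = _geom_lengths(rng, p.insert_p, batch)
        else:
            n_ins1 = _geom_lengths(rng, p.insert_p, batch)
        total_ins = int(n_ins1.sum() + (n_ins2.sum() if has_d else 0))
        ins_pool = rng.choice(list(BASES), size=max(total_ins, 1), p=base_probs)
        pos = 0
        for k in range(batch):
            vseq = p.v_segments[vi[k]].seq
            jseq = p.j_segments[ji[k]].seq
            vpart = vseq[: max(len(vseq) - t_v3[k], 0)]
            jpart = jseq[min(t_j5[k], len(jseq)) :]
            ins1 = "".join(ins_pool[pos : pos + n_ins1[k]])
            pos += n_ins1[k]
            if has_d:
                dseq = p.d_segments[di[k]].seq
                dpart = dseq[min(t_d5[k], len(dseq)) : max(len(dseq) - t_d3[k], 0)]
                if len(dpart) < 0:
                    dpart = ""
                ins2 = "".join(ins_pool[pos : pos + n_ins2[k]])
                pos += n_ins2[k]
                ndn = ins1 + dpart + ins2
            else:
                ndn = ins1
            nt = vpart + ndn + jpart
            if len(nt) % 3 or len(nt) < 9:
                continue
            aa = translate(nt)
            if "*" in aa or not aa.startswith("C") or aa[-1] not in "FW":
                continue
            bounds = (
                (0, len(vpart)),
                (len(vpart), len(vpart) + len(ndn)),
                (len(vpart) + len(ndn), len(nt)),
            )
            out.append(
                Clonotype(
                    cdr3_aa=aa,
                    v_gene=p.v_segments[vi[k]].name,
                    j_gene=p.j_segments[ji[k]].name,
                    count=1,
                    cdr3_nt=nt,
                    segment_bounds=bounds,
                )
            )
            if len(out) >= n:
                break
    if len(out) < n:
        raise UnproductiveModelError(
            f"only {len(out)}/{n} productive junctions after {max_batches} batches"
        )
    return Repertoire(sample_id, p.chain, out[:n], {"generator": "thymosig.vdj_sim"})


@dataclass
class SelectionSpec:
    """A configurable per-sequence thymic-survival filter.

    Survival probability of a clonotype is::

        base_rate
        * prod(mult for pattern, mult in motif_penalties if pattern matches)
        * prod(sigmoid(-w * mean_KF_i) for i, w in kidera_shifts)
        * sigmoid(k*(L - lo)) * sigmoid(k*(hi - L))   # if length_window

    optionally multiplied by a V/J-pair tilt.  All multipliers live in
    [0, 1]; a positive Kidera weight therefore *penalizes* sequences with a
    high mean value of that factor, shifting the post-selection mean down.
    """

    motif_penalties: dict[str, float] = field(default_factory=dict)
    kidera_shifts: dict[int, float] = field(default_factory=dict)
    length_window: tuple[float, float, float] | None = None  # (lo, hi, steepness)
    vj_tilt: dict[tuple[str, str], float] = field(default_factory=dict)
    base_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.base_rate <= 1.0):
            raise ValueError("base_rate must be in (0, 1]")
        for pat, m in self.motif_penalties.items():
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"multiplier for {pat!r} outside [0, 1]")
        for key, m in self.vj_tilt.items():
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"vj_tilt for {key} outside [0, 1]")
        self._compiled = [(re.compile(p), m) for p, m in self.motif_penalties.items()]

    @classmethod
    def neutral(cls) -> "SelectionSpec":
        return cls(base_rate=1.0)

    def survival_probability(self, c: Clonotype) -> float:
        from .features import mean_kidera  # local import avoids cycle at module load

        p = self.base_rate
        for rx, mult in self._compiled:
            if rx.search(c.cdr3_aa):
                p *= mult
        if self.kidera_shifts:
            kf = mean_kidera(c.cdr3_aa)
            for idx, w in self.kidera_shifts.items():
                p *= 1.0 / (1.0 + np.exp(w * kf[idx - 1]))
        if self.length_window is not None:
            lo, hi, k = self.length_window
            L = len(c.cdr3_aa)
            p *= 1.0 / (1.0 + np.exp(-k * (L - lo)))
            p *= 1.0 / (1.0 + np.exp(-k * (hi - L)))
        if self.vj_tilt:
            for key in ((c.v_gene, c.j_gene), (c.v_gene, "*"), ("*", c.j_gene)):
                if key in self.vj_tilt:
                    p *= self.vj_tilt[key]
                    break
        return float(p)


def apply_selection(r: Repertoire, s: SelectionSpec, seed: int) -> Repertoire:
    """Draw independent survival for each clonotype; return the survivors."""
    if not r.clonotypes:
        raise ValueError("repertoire is empty")
    rng = np.random.default_rng(seed)
    probs = np.array([s.survival_probability(c) for c in r.clonotypes])
    keep = rng.random(len(probs)) < probs
    survivors = []
    for c, k, p in zip(r.clonotypes, keep, probs):
        if k:
            c = Clonotype(c.cdr3_aa, c.v_gene, c.j_gene, c.count, c.cdr3_nt,
                          c.segment_bounds, dict(c.meta, survival_p=float(p)))
            survivors.append(c)
    meta = dict(r.meta, selected=True, realized_survival=float(keep.mean()))
    return Repertoire(r.sample_id + "_post", r.chain, survivors, meta)


def generate_post_selection(
    p: GenerativeParams,
    s: SelectionSpec,
    n: int,
    seed: int,
    sample_id: str = "post_sim",
    max_rounds: int = 60,
) -> Repertoire:
    """Generate exactly ``n`` post-selection clonotypes (generate-then-filter)."""
    children = np.random.SeedSequence(seed).spawn(2 * max_rounds)
    out: list[Clonotype] = []
    for round_ in range(max_rounds):
        if len(out) >= n:
            break
        g_seed = int(children[2 * round_].generate_state(1)[0] % (2**31))
        s_seed = int(children[2 * round_ + 1].generate_state(1)[0] % (2**31))
        pre = generate_pre_selection(p, max(n, 4096), g_seed, sample_id="tmp")
        post = apply_selection(pre, s, s_seed)
        out.extend(post.clonotypes)
    if len(out) < n:
        raise UnproductiveModelError(f"selection too harsh: {len(out)}/{n} survivors")
    return Repertoire(sample_id, p.chain, out[:n], {"generator": "thymosig.vdj_sim",
                                                    "selected": True})


def make_twin_cohort(
    p: GenerativeParams,
    shared_masks: Sequence[SelectionSpec],
    n_per_sample: int,
    replicates: int,
    seed: int,
) -> list[Repertoire]:
    """Synthetic twin cohort: each pair shares one selection mask.

    For mask ``i`` (a stand-in for a shared HLA haplotype), ``replicates``
    independent post-selection repertoires are generated; ``meta['pair']``
    records the pair label so within/between-pair divergences can be
    compared downstream.
    """
    if len(shared_masks) < 2:
        raise ValueError("need at least 2 masks (pairs)")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(shared_masks) * replicates)
    out: list[Repertoire] = []
    k = 0
    for pair_idx, mask in enumerate(shared_masks, start=1):
        for rep in range(1, replicates + 1):
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            rep_sample = generate_post_selection(
                p, mask, n_per_sample, child_seed,
                sample_id=f"pair{pair_idx}_rep{rep}",
            )
            rep_sample.meta.update(pair=pair_idx, replicate=rep)
            out.append(rep_sample)
    return out


def sequon_knockout_spec(multiplier: float = 0.2) -> SelectionSpec:
    """Selection penalizing N-glycosylation sequons (N-X-[S/T], X != P).

    The default multiplier 0.2 removes 80% of sequon-bearing CDR3s, the
    package's standard condition for motif-depletion recovery studies.
    """
    return SelectionSpec(motif_penalties={"N[^P][ST]": multiplier})


def physchem_selection_spec() -> SelectionSpec:
    """Selection reproducing the directional physicochemical signatures.

    Penalizes high Kidera factor 4 (inverse hydrophobicity; weight 6 shifts
    the post-selection mean down by roughly 0.5 pooled SD), penalizes
    lysine/arginine-bearing CDR3s (multiplier 0.4, lowering net charge) and
    applies a soft length window whose lower edge (5) is below the shortest
    productive junction, so it acts purely on the long-length tail — a
    winsorizing of CDR3 length rather than a shift.
    """
    return SelectionSpec(
        motif_penalties={"[KR]": 0.4},
        kidera_shifts={4: 6.0},
        length_window=(5.0, 16.0, 1.5),
    )
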