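"""Monomer family clustering and consensus construction.

Repeat-unit copies extracted from a tandem region are compared all-vs-all
with unit-cost edit distance normalized by the longer length, clustered
into families by single-linkage at a strict 5% threshold (copies that
differ by *less than* 5% are connected), and each family is summarized by
a column-majority consensus over a star alignment to the family medoid.
Families are labelled m1, m2, m3, ... and can be phase-relabelled so the
dominant within-copy order reads m1 -> m2 -> m3.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from horscope._align import edit_distance, encode


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering threshold; linkage is fixed to single (documented)."""

    threshold: float = 0.05
    linkage: str = "single"

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.linkage != "single":
            raise ValueError("only single linkage is supported")


@dataclass
class DivergenceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]


@dataclass
class MonomerFamily:
    label: str
    members: list[str]
    member_ids: list[int]
    consensus: str | None = None
    max_intra_divergence: float = 0.0


def pairwise_divergence(a: str, b: str) -> float:
    """Unit-cost edit distance divided by the longer sequence length.

    Symmetric, zero iff the sequences are equal; max-length normalization
    penalizes truncations.  N is treated as matching nothing.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return edit_distance(encode(a), encode(b)) / max(len(a), len(b))


def divergence_matrix(copies: list[str], labels: list[str] | None = None) -> DivergenceMatrix:
    if not copies:
        raise ValueError("need at least one copy")
    n = len(copies)
    labels = labels or [f"copy{i}" for i in range(n)]
    enc = [encode(c) for c in copies]
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(enc[i], enc[j]) / max(len(copies[i]), len(copies[j]))
            values[i, j] = values[j, i] = d
    return DivergenceMatrix(labels=list(labels), values=values)


def cluster_families(
    matrix: DivergenceMatrix,
    copies: list[str],
    config: ClusterConfig | None = None,
) -> list[MonomerFamily]:
    """Single-linkage families: connected components of the < threshold graph.

    The threshold is strict — a pair at exactly the threshold is *not*
    connected.  Families are ordered by their first member's input index
    and labelled m1, m2, ... in that order; ``max_intra_divergence``
    reports the largest pairwise divergence inside each component, so a
    chain that exceeds the threshold end-to-end is visible.
    """
    config = config or ClusterConfig()
    n = len(copies)
    adj = csr_matrix((matrix.values < config.threshold).astype(np.int8))
    n_comp, comp = connected_components(adj, directed=False)
    order = []
    seen = set()
    for i in range(n):
        if comp[i] not in seen:
            seen.add(comp[i])
            order.append(comp[i])
    families = []
    for rank, cid in enumerate(order):
        ids = [i for i in range(n) if comp[i] == cid]
        intra = 0.0
        for i, j in itertools.combinations(ids, 2):
            intra = max(intra, matrix.values[i, j])
        families.append(
            MonomerFamily(
                label=f"m{rank + 1}",
                members=[copies[i] for i in ids],
                member_ids=ids,
                max_intra_divergence=intra,
            )
        )
    return families


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 0
_aligner.mismatch_score = -1
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def build_consensus(family: MonomerFamily) -> str:
    """Column-majority consensus over a star alignment to the medoid.

    The medoid (member minimizing summed divergence to the rest) anchors
    the columns.  Every member is globally aligned to it with unit edit
    costs; each medoid column takes the majority base over aligned member
    bases (gap counts as a vote to drop the column), and an insertion
    column is emitted after a medoid position only when a strict majority
    of members insert there, taking the majority inserted base.  Ties are
    broken alphabetically (A < C < G < T, gap loses ties).  Deterministic
    given member order.
    """
    members = family.members
    if len(members) == 1:
        family.consensus = members[0]
        return members[0]
    n = len(members)
    enc = [encode(m) for m in members]
    sums = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(enc[i], enc[j])
            sums[i] += d
            sums[j] += d
    medoid = int(np.argmin(sums))
    anchor = members[medoid]
    L = len(anchor)
    votes = np.zeros((L, 5), dtype=np.int32)  # A C G T gap
    ins_after: list[dict[str, int]] = [dict() for _ in range(L + 1)]
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for mi, mem in enumerate(members):
        if mi == medoid:
            for col, b in enumerate(anchor):
                votes[col, base_idx.get(b, 4)] += 1
            continue
        aln = _aligner.align(anchor, mem)[0]
        ablocks, bblocks = aln.aligned
        prev_a = prev_b = 0
        for (a0, a1), (b0, b1) in zip(ablocks, bblocks):
            for col in range(prev_a, a0):  # deletion in member
                votes[col, 4] += 1
            if b0 > prev_b:  # insertion in member, placed after column a0
                ins = mem[prev_b:b0]
                key_col = a0
                ins_after[key_col][ins] = ins_after[key_col].get(ins, 0) + 1
            for off in range(a1 - a0):
                votes[a0 + off, base_idx.get(mem[b0 + off], 4)] += 1
            prev_a, prev_b = a1, b1
        for col in range(prev_a, L):
            votes[col, 4] += 1
        if len(mem) > prev_b:
            ins = mem[prev_b:]
            ins_after[L][ins] = ins_after[L].get(ins, 0) + 1
    out = []
    for col in range(L + 1):
        if ins_after[col]:
            ins, cnt = max(ins_after[col].items(), key=lambda kv: (kv[1], kv[0]))
            if cnt > n // 2:
                out.append(ins)
        if col < L:
            v = votes[col]
            best = int(np.argmax(v))  # argmax takes first max: A<C<G<T<gap ties
            if best < 4:
                out.append("ACGT"[best])
    consensus = "".join(out)
    family.consensus = consensus
    return consensus


def relabel_by_hor_phase(
    families: list[MonomerFamily], hits_preview: list[str]
) -> list[MonomerFamily]:
    """Rename families so the dominant within-copy order is m1 -> m2 -> m3.

    ``hits_preview`` is the sequence of family labels of a draft scan in
    genomic order.  All bijective relabellings are scored by how many
    consecutive label triples become (m1, m2, m3); the best is applied.
    On a tie no dominant phase exists: positional labels are kept and a
    warning is emitted.
    """
    labels = [f.label for f in families]
    if len(families) <= 1 or len(families) > 6:
        return families
    best_perm, best_score, tie = None, -1, False
    for perm in itertools.permutations(labels):
        mapping = dict(zip(perm, labels))  # perm[i] -> canonical label m{i+1}
        score = 0
        for a, b, c in zip(hits_preview, hits_preview[1:], hits_preview[2:]):
            if (mapping.get(a), mapping.get(b), mapping.get(c)) == ("m1", "m2", "m3"):
                score += 1
        if score > best_score:
            best_perm, best_score, tie = perm, score, False
        elif score == best_score:
            tie = True
    if tie or best_score <= 0:
        if best_score > 0:
            warnings.warn("ambiguous HOR phase; keeping positional family labels")
        return families
    mapping = dict(zip(best_perm, labels))
    for f in families:
        f.label = mapping[f.label]
    families.sort(key=lambda f: f.label)
    return families


def mean_corresponding_divergence(set_a: list[str], set_b: list[str]) -> float:
    """Mean pairwise divergence between corresponding consensus monomers.

    Used to compare consensus sets from two assemblies (e.g. the m1/m2/m3
    consensus monomers of two hominin genomes) monomer-by-monomer.
    """
    if len(set_a) != len(set_b) or not set_a:
        raise ValueError("consensus sets must be non-empty and equal-length")
    return float(np.mean([pairwise_divergence(a, b) for a, b in zip(set_a, set_b)]))
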