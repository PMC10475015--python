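"""Genome-wide consensus-monomer search and assembly-gap mapping.

Each consensus monomer and its reverse complement is searched base-by-base
against the assembly with a semi-global (infix) unit-cost edit-distance
scan: at every text position the best alignment of the whole consensus
ending there is scored.  Local minima under the acceptance threshold
become candidate hits; candidates from all families and both strands are
then accepted greedily by ascending divergence (ties: ascending start,
then family order) under a strict non-overlap rule, so each locus keeps
only its best-fitting family.  Coordinates are always reported on the
forward strand, 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from horscope._align import encode, semiglobal_best_start, semiglobal_end_scores
from horscope.synthetic import revcomp


@dataclass(frozen=True)
class ScanConfig:
    """Acceptance threshold and hit-filtering parameters.

    ``max_divergence`` (default 0.15) comfortably contains intra-family
    drift (< 5%) plus inter-assembly drift while excluding the ~25%
    family-to-family divergence.  ``min_separation`` = 0 means strict
    non-overlap; ``max_n_fraction`` drops hits mostly inside gap runs.
    """

    max_divergence: float = 0.15
    min_separation: int = 0
    max_n_fraction: float = 0.1
    boundary_slack: int = 16

    def __post_init__(self):
        if not 0.0 < self.max_divergence < 0.5:
            raise ValueError("max_divergence must be in (0, 0.5)")
        if self.boundary_slack < 0:
            raise ValueError("boundary_slack must be >= 0")


@dataclass
class MonomerHit:
    chrom: str
    start: int
    end: int
    family: str
    strand: str
    edits: int
    divergence: float

    def overlaps(self, other: "MonomerHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class GapInterval:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _candidate_minima(scores: np.ndarray, thresh: int, radius: int) -> list[int]:
    """End positions that are <= thresh and minimal within +-radius.

    Plateaus keep their leftmost position.  ``radius`` should be about
    half the query length so two adjacent tandem copies survive.
    """
    idx = np.nonzero(scores <= thresh)[0]
    out = []
    for j in idx:
        lo = max(0, j - radius)
        hi = min(len(scores), j + radius + 1)
        w = scores[lo:hi]
        m = w.min()
        if scores[j] == m and (j - lo == int(np.argmin(w))):
            out.append(int(j))
    return out


def scan_monomers(
    seq: str,
    consensus_set: dict[str, str],
    config: ScanConfig | None = None,
    chrom: str = "seq",
) -> list[MonomerHit]:
    """Scan with every consensus (direct + reverse complement).

    Returns accepted, mutually non-overlapping hits sorted by start.
    ``divergence`` is edits / consensus length; the genomic span of a hit
    comes from the alignment itself (indel-aware), not a fixed window.
    """
    config = config or ScanConfig()
    text = encode(seq)
    n_mask = text == 4
    n_cum = np.concatenate(([0], np.cumsum(n_mask.astype(np.int64))))
    candidates = []  # (divergence, start, fam_rank, end, family, strand, edits)
    for fam_rank, (family, cons) in enumerate(consensus_set.items()):
        m = len(cons)
        if m > len(seq):
            warnings.warn(f"consensus {family} longer than sequence; skipped")
            continue
        thresh = int(np.floor(config.max_divergence * m))
        for strand, query in (("+", cons), ("-", revcomp(cons))):
            q = encode(query)
            scores = semiglobal_end_scores(q, text)
            for j in _candidate_minima(scores, thresh, max(1, m // 2)):
                start, edits = semiglobal_best_start(q, text, j)
                end = j + 1
                n_frac = (n_cum[end] - n_cum[start]) / max(1, end - start)
                if n_frac > config.max_n_fraction:
                    continue
                candidates.append(
                    (edits / m, start, fam_rank, end, family, strand, int(edits))
                )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    accepted: list[MonomerHit] = []
    intervals: list[tuple[int, int]] = []
    for div, start, fam_rank, end, family, strand, edits in candidates:
        # Optimal alignments of abutting tandem copies may claim a few
        # bases across the junction; trim within boundary_slack so real
        # neighbors are kept while accepted hits never share a base.
        s = start - config.min_separation
        e = end + config.min_separation
        for a, b in intervals:
            if s < b and a < e:
                if a <= start < b <= end and b - start <= config.boundary_slack:
                    start = b  # clip left edge
                    s = start - config.min_separation
                elif start < a <= end <= b and end - a <= config.boundary_slack:
                    end = a  # clip right edge
                    e = end + config.min_separation
        if start >= end or any(s < b and a < e for a, b in intervals):
            continue
        intervals.append((start, end))
        accepted.append(
            MonomerHit(
                chrom=chrom,
                start=start,
                end=end,
                family=family,
                strand=strand,
                edits=edits,
                divergence=div,
            )
        )
    accepted.sort(key=lambda h: h.start)
    return accepted


def find_assembly_gaps(seq: str, min_len: int = 2000, chrom: str = "seq") -> list[GapInterval]:
    """Maximal runs of N strictly longer than ``min_len``, sorted by start.

    The boundary is strict: a run of exactly ``min_len`` N is not a gap,
    mirroring the "larger than 2000 bp" convention for assembly gap maps.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("N")
    if not arr.any():
        return []
    d = np.diff(arr.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if arr[0]:
        starts.insert(0, 0)
    if arr[-1]:
        ends.append(len(arr))
    return [
        GapInterval(chrom=chrom, start=int(s), end=int(e))
        for s, e in zip(starts, ends)
        if e - s > min_len
    ]
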