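"""Global Repeat Map (GRM): k-string interval spectra of DNA sequences.

The GRM diagram of a sequence is the histogram, over the complete ensemble
of K-length substrings, of the distances between consecutive occurrence
start positions of each K-string.  A tandem repeat of unit length L makes
every K-string inside the unit recur at period L, so the diagram shows a
peak at L — and at multiples of L when the units themselves are organized
into higher-order repeats (HORs).  The mapping is parameter-free apart
from K and needs no prior knowledge of the repeats present.

Coordinates are 0-based half-open.  Windows containing N are excluded
from the ensemble, so assembly gaps cannot create phantom periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from horscope._align import encode


@dataclass(frozen=True)
class GRMConfig:
    """K-string length, noise floor and peak-merging parameters."""

    k: int = 12
    min_count: int = 5
    peak_merge_radius: float = 0.03
    max_length: int = 20_000

    def __post_init__(self):
        if not 4 <= self.k <= 64:
            raise ValueError("k must be in [4, 64]")
        if not 0.0 < self.peak_merge_radius < 0.2:
            raise ValueError("peak_merge_radius must be in (0, 0.2)")
        if self.max_length < 1:
            raise ValueError("max_length must be positive")


@dataclass
class GRMDiagram:
    """Histogram length -> count of consecutive K-string occurrence gaps."""

    histogram: dict[int, int]
    interval: tuple[int, int] = (0, 0)
    k: int = 12

    @property
    def total_mass(self) -> int:
        return sum(self.histogram.values())

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lengths = np.array(sorted(self.histogram), dtype=np.int64)
        counts = np.array([self.histogram[l] for l in lengths], dtype=np.int64)
        return lengths, counts


@dataclass
class GRMPeak:
    length: int
    count: int
    prominence: float = 0.0


@dataclass
class TandemRegion:
    """A maximal region where one K-string recurs at a near-constant period."""

    start: int
    end: int
    unit_length: int
    n_units: int
    key: str


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes of all K-windows plus a validity mask (no N).

    Only k <= 32 fits the packing; larger K falls back to hashing in
    :func:`kstring_interval_histogram`.
    """
    enc = encode(seq).astype(np.uint64)
    n = len(enc) - k + 1
    valid_base = enc < 4
    codes = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        codes = (codes << np.uint64(2)) | (enc[i : i + n] & np.uint64(3))
    # window valid iff all k bases valid: sliding all-true via cumsum
    cs = np.concatenate(([0], np.cumsum(valid_base.astype(np.int64))))
    valid = (cs[k:] - cs[:-k]) == k
    return codes, valid


def kstring_interval_histogram(
    seq: str, config: GRMConfig | None = None, interval: tuple[int, int] | None = None
) -> GRMDiagram:
    """Accumulate consecutive-occurrence distances of every K-string.

    For each K-window (skipping windows that contain N), the start-to-start
    distances between consecutive occurrences of that exact K-string are
    histogrammed, capped at ``max_length``.  Total mass therefore equals
    sum over K-strings w of max(occ(w) - 1, 0), restricted to distances
    <= max_length.
    """
    config = config or GRMConfig()
    k = config.k
    if interval is not None:
        seq = seq[interval[0] : interval[1]]
    else:
        interval = (0, len(seq))
    hist: dict[int, int] = {}
    if len(seq) < k:
        return GRMDiagram(histogram=hist, interval=interval, k=k)
    if k <= 32:
        codes, valid = _kmer_codes(seq, k)
        codes = codes[valid]
        pos = np.nonzero(valid)[0].astype(np.int64)
        order = np.argsort(codes, kind="stable")  # stable keeps position order
        sc, sp = codes[order], pos[order]
        same = sc[1:] == sc[:-1]
        gaps = (sp[1:] - sp[:-1])[same]
        gaps = gaps[gaps <= config.max_length]
        lengths, counts = np.unique(gaps, return_counts=True)
        hist = {int(l): int(c) for l, c in zip(lengths, counts)}
    else:  # rare configuration; string keys, memory bounded by distinct K-strings
        last: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            j = last.get(w)
            if j is not None:
                d = i - j
                if d <= config.max_length:
                    hist[d] = hist.get(d, 0) + 1
            last[w] = i
    return GRMDiagram(histogram=hist, interval=interval, k=k)


def detect_peaks(diagram: GRMDiagram, config: GRMConfig | None = None) -> list[GRMPeak]:
    """Merge nearby bins into peaks and rank them by count.

    Bins are claimed greedily in descending count order; a bin within
    ``peak_merge_radius`` (relative) of an existing peak's modal length
    merges into it, otherwise it seeds a new peak at its own length.
    Peaks below ``min_count`` are dropped; ties sort shorter-length first.
    """
    config = config or GRMConfig()
    items = sorted(diagram.histogram.items(), key=lambda kv: (-kv[1], kv[0]))
    peaks: list[GRMPeak] = []
    for length, count in items:
        merged = False
        for p in peaks:
            if abs(length - p.length) <= config.peak_merge_radius * p.length:
                p.count += count
                merged = True
                break
        if not merged:
            peaks.append(GRMPeak(length=length, count=count))
    peaks = [p for p in peaks if p.count >= config.min_count]
    for p in peaks:
        lo, hi = p.length * 0.8, p.length * 1.2
        bg = [
            c
            for l, c in diagram.histogram.items()
            if lo <= l <= hi and abs(l - p.length) > config.peak_merge_radius * p.length
        ]
        p.prominence = p.count / (1.0 + float(np.median(bg)) if bg else 1.0)
    peaks.sort(key=lambda p: (-p.count, p.length))
    return peaks


def validate_hor_signature(
    diagram: GRMDiagram,
    unit_length: int,
    n: int = 3,
    tol: float = 0.05,
    config: GRMConfig | None = None,
) -> bool:
    """True iff the diagram peaks at the unit length and its first n multiples.

    The HOR signature rule: a candidate monomer of length L belongs to an
    n-mer higher-order structure only if peaks are present near L, 2L, ...
    nL (each within ``tol`` of the multiple).
    """
    if unit_length <= 0 or n < 2:
        raise ValueError("unit_length must be positive and n >= 2")
    peaks = detect_peaks(diagram, config)
    lengths = np.array([p.length for p in peaks], dtype=float)
    if lengths.size == 0:
        return False
    for m in range(1, n + 1):
        target = m * unit_length
        if not np.any(np.abs(lengths - target) <= tol * target):
            return False
    return True


def locate_tandem_regions(
    seq: str,
    config: GRMConfig | None = None,
    min_copies: int = 3,
    unit_range: tuple[int, int] = (100, 10_000),
    max_cv: float = 0.1,
) -> list[TandemRegion]:
    """Find regions where some K-string recurs at a near-constant period.

    For each K-string, runs of consecutive occurrences are split wherever
    the gap exceeds ``max_length`` or 5x the run's median period; a run
    with >= ``min_copies`` occurrences, coefficient of variation of its
    gaps <= ``max_cv`` and modal gap inside ``unit_range`` yields a
    candidate region spanning first occurrence to last occurrence + unit.
    Overlapping candidates with compatible unit lengths are merged.
    """
    config = config or GRMConfig()
    k = config.k
    if len(seq) < k or k > 32:
        return []
    codes, valid = _kmer_codes(seq, k)
    codes = codes[valid]
    pos = np.nonzero(valid)[0].astype(np.int64)
    order = np.argsort(codes, kind="stable")
    sc, sp = codes[order], pos[order]
    boundaries = np.nonzero(sc[1:] != sc[:-1])[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(sc)]))
    candidates: list[TandemRegion] = []
    lo_unit, hi_unit = unit_range
    for s, e in zip(starts, ends):
        if e - s < min_copies:
            continue
        p = sp[s:e]
        gaps = np.diff(p)
        med = float(np.median(gaps))
        split_at = np.nonzero(gaps > min(config.max_length, 5 * max(med, 1.0)))[0]
        run_bounds = np.concatenate(([0], split_at + 1, [len(p)]))
        for rs, re in zip(run_bounds[:-1], run_bounds[1:]):
            if re - rs < min_copies:
                continue
            rp = p[rs:re]
            rgaps = np.diff(rp)
            mean = float(rgaps.mean())
            if mean <= 0:
                continue
            cv = float(rgaps.std()) / mean
            vals, cnts = np.unique(rgaps, return_counts=True)
            unit = int(vals[np.argmax(cnts)])
            if cv <= max_cv and lo_unit <= unit <= hi_unit:
                candidates.append(
                    TandemRegion(
                        start=int(rp[0]),
                        end=int(rp[-1]) + unit,
                        unit_length=unit,
                        n_units=len(rp),
                        key=_decode_kmer(int(sc[s]), k),
                    )
                )
    if not candidates:
        return []
    candidates.sort(key=lambda r: (r.start, r.end))
    merged = [candidates[0]]
    for r in candidates[1:]:
        cur = merged[-1]
        unit = max(cur.unit_length, r.unit_length)
        compatible = abs(r.unit_length - cur.unit_length) <= (
            config.peak_merge_radius * unit
        )
        # near-adjacent compatible runs belong to one array whose key
        # coverage has holes (mutated K-strings); bridge up to two units
        if compatible and r.start <= cur.end + 2 * unit:
            best = r if r.n_units > cur.n_units else cur
            start = min(cur.start, r.start)
            end = max(cur.end, r.end)
            merged[-1] = TandemRegion(
                start=start,
                end=end,
                unit_length=best.unit_length,
                n_units=max(
                    cur.n_units, r.n_units, (end - start) // best.unit_length
                ),
                key=cur.key,  # leftmost key: occurs at the region start
            )
        elif r.start <= cur.end:
            if r.n_units > cur.n_units:  # overlapping, incompatible: keep larger
                merged[-1] = r
        else:
            merged.append(r)
    return merged


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append("ACGT"[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def extract_repeat_copies(seq: str, region: TandemRegion) -> list[str]:
    """Segment a tandem region into unit copies at occurrences of its key.

    Copies are the fragments between successive key start positions; the
    terminal fragment after the last key occurrence is dropped, as are
    fragments shorter than 80% of the unit length (partial copies at
    region edges).
    """
    sub = seq[region.start : region.end]
    starts = []
    i = sub.find(region.key)
    while i != -1:
        starts.append(i)
        i = sub.find(region.key, i + 1)
    if not starts:
        raise ValueError("region key absent from its own region (corrupt region)")
    copies = []
    for a, b in zip(starts, starts[1:]):
        frag = sub[a:b]
        if len(frag) >= 0.8 * region.unit_length:
            copies.append(frag)
    return copies
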