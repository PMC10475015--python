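"""Synthetic genomes with planted monomer families and HOR arrays.

Every downstream stage of the pipeline (spectrum, clustering, scanning,
assembly) is tested against genomes produced here, for which the exact
ground truth is known by construction.  The generator emulates the
architecture of NBPF-like regions: a random background carrying tandem
arrays of higher-order-repeat (HOR) copies built from a small set of
~1.6 kb monomer families, with canonical three-monomer copies, variant
copies of one or two monomers, whole arrays in reverse-complement
orientation, and runs of N emulating assembly gaps.

Divergence regime defaults follow the alpha-satellite HOR prototype:
copy-to-copy divergence within an array (~1%) is an order of magnitude
below family-to-family divergence (~25%).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class ValidationError(ValueError):
    """A spec object violates its invariants."""


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a set of related monomer families.

    n_families: number of families (m1, m2, ...); monomer_length in bases;
    inter_family_divergence: target pairwise edit divergence between family
    base sequences.
    """

    n_families: int = 3
    monomer_length: int = 1600
    inter_family_divergence: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        if self.monomer_length < 20:
            raise ValidationError("monomer_length must be >= 20")
        if not 0.0 <= self.inter_family_divergence <= 0.75:
            raise ValidationError("inter_family_divergence must be in [0, 0.75]")


@dataclass(frozen=True)
class ArrayPlan:
    """One planted tandem array of HOR copies.

    ``rows`` is the ordered list of copies; each row is a tuple of family
    indices (0-based) in strictly increasing order, e.g. (0, 1, 2) for a
    canonical copy, (0, 2) or (1,) for variant copies.  ``position`` is the
    insertion offset in the background sequence.  Arrays on the '-' strand
    are written as the reverse complement of the concatenated rows.
    """

    position: int
    rows: tuple[tuple[int, ...], ...]
    strand: str = "+"
    intra_divergence: float = 0.01
    indel_rate: float = 0.001

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(tuple(r) for r in self.rows))
        if not self.rows:
            raise ValidationError("rows must be non-empty")
        for r in self.rows:
            if not 1 <= len(r) <= 3:
                raise ValidationError("each row must have 1-3 monomers")
            if list(r) != sorted(set(r)):
                raise ValidationError(
                    "row labels must be distinct and in increasing order"
                )
        if self.strand not in "+-":
            raise ValidationError("strand must be '+' or '-'")
        for rate in (self.intra_divergence, self.indel_rate):
            if not 0.0 <= rate <= 0.1:
                raise ValidationError("rates must be in [0, 0.1]")
        if self.position < 0:
            raise ValidationError("position must be >= 0")


@dataclass(frozen=True)
class GenomeSpec:
    background_length: int = 1_000_000
    gc_content: float = 0.5
    families: FamilySpec = field(default_factory=FamilySpec)
    arrays: tuple[ArrayPlan, ...] = ()
    gap_runs: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "arrays", tuple(self.arrays))
        object.__setattr__(
            self, "gap_runs", tuple((int(p), int(l)) for p, l in self.gap_runs)
        )
        if not 0.0 < self.gc_content < 1.0:
            raise ValidationError("gc_content must be in (0, 1)")
        points = [a.position for a in self.arrays] + [p for p, _ in self.gap_runs]
        if len(points) != len(set(points)):
            raise ValidationError("insertion points of arrays/gaps must be distinct")
        for p in points:
            if p > self.background_length:
                raise ValidationError("insertion point beyond background")


@dataclass
class MonomerTruth:
    start: int
    end: int
    family: int  # 0-based family index
    strand: str
    divergence: float  # substitution rate actually applied


@dataclass
class SyntheticTruth:
    """Exact annotation of a simulated genome.

    ``monomers`` are sorted, non-overlapping forward-strand intervals
    (0-based half-open).  ``copies`` and ``arrays`` are index lists that
    partition the monomers and copies respectively.
    """

    monomers: list[MonomerTruth] = field(default_factory=list)
    copies: list[list[int]] = field(default_factory=list)
    arrays: list[list[int]] = field(default_factory=list)

    @property
    def array_copy_counts(self) -> list[int]:
        return [len(a) for a in self.arrays]

    @property
    def array_canonical_counts(self) -> list[int]:
        return [
            sum(1 for ci in arr if len(self.copies[ci]) == 3) for arr in self.arrays
        ]

    @property
    def n_canonical(self) -> int:
        return sum(self.array_canonical_counts)


def random_sequence(length: int, gc_content: float, rng: np.random.Generator) -> str:
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    arr = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return arr.tobytes().decode("ascii")


def mutate(
    seq: str,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    ins_frac: float = 0.5,
) -> str:
    """Apply independent per-base substitutions and single-base indels.

    Substitutions change a base to one of the three alternatives uniformly.
    At each position an indel event occurs with probability ``indel_rate``;
    a fraction ``ins_frac`` of events insert a random base before the
    position, the rest delete it.  Deterministic given the seed.
    """
    for rate in (sub_rate, indel_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValidationError("rates must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[str] = []
    n = len(seq)
    subs = rng.random(n) < sub_rate if sub_rate > 0 else np.zeros(n, dtype=bool)
    indels = rng.random(n) < indel_rate if indel_rate > 0 else np.zeros(n, dtype=bool)
    for i, base in enumerate(seq):
        if subs[i] and base in "ACGT":
            alt = "ACGT".replace(base, "")
            base = alt[rng.integers(3)]
        if indels[i]:
            if rng.random() < ins_frac:
                out.append("ACGT"[rng.integers(4)])
                out.append(base)
            # else: deletion — skip the base
        else:
            out.append(base)
    return "".join(out)


def _measured_divergence(a: str, b: str) -> float:
    from horscope.families import pairwise_divergence

    return pairwise_divergence(a, b)


def make_family_set(spec: FamilySpec) -> list[str]:
    """Generate family base monomers at the requested mutual divergence.

    Families descend from a shared random ancestor by independent
    substitution; the per-branch rate is solved from the expected pairwise
    divergence of two branches, then accepted only if every measured
    pairwise divergence is within 10% (relative) of the target, redrawing
    otherwise.  This keeps the inter-family separation controllable so the
    intra-array (<5%) vs inter-family (~25%) regime holds by construction.
    """
    # distinct stream key so equal seeds in FamilySpec/GenomeSpec cannot make
    # the ancestor collide with the background sequence draws
    rng = np.random.default_rng([1, spec.seed])
    ancestor = random_sequence(spec.monomer_length, 0.5, rng)
    d = spec.inter_family_divergence
    if spec.n_families == 1 or d == 0.0:
        return [ancestor] * spec.n_families
    # expected divergence of two branches at per-base rate p:
    # P(differ) = 2p(1-p) + (2/3)p^2  ->  solve 2p - (4/3)p^2 = d
    a, b, c = -4.0 / 3.0, 2.0, -d
    p = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    for _attempt in range(200):
        fams = [mutate(ancestor, sub_rate=p, seed=rng) for _ in range(spec.n_families)]
        divs = [
            _measured_divergence(fams[i], fams[j])
            for i in range(spec.n_families)
            for j in range(i + 1, spec.n_families)
        ]
        if all(abs(x - d) <= 0.10 * d for x in divs):
            return fams
    raise RuntimeError("could not achieve target inter-family divergence")


def generate_genome(spec: GenomeSpec) -> tuple[str, SyntheticTruth, list[str]]:
    """Build the genome sequence and its exact truth annotation.

    Returns ``(sequence, truth, family_base_monomers)``.  Arrays and N-gap
    runs are spliced into the background at their insertion offsets; truth
    coordinates refer to the final emitted sequence, always on the forward
    strand, with the strand flag marking reverse-complement arrays.
    """
    rng = np.random.default_rng([0, spec.seed])
    background = random_sequence(spec.background_length, spec.gc_content, rng)
    bases = make_family_set(spec.families)

    # Build inserts in background order.
    inserts: list[tuple[int, str, ArrayPlan | None, list]] = []
    for plan in spec.arrays:
        rows_seq: list[str] = []
        rows_meta: list[list[tuple[int, int, int, float]]] = []  # per-row monomers
        offset = 0
        for row in plan.rows:
            row_meta = []
            for fam in row:
                if fam >= spec.families.n_families:
                    raise ValidationError("row references unknown family")
                mono = mutate(
                    bases[fam],
                    sub_rate=plan.intra_divergence,
                    indel_rate=plan.indel_rate,
                    seed=rng,
                )
                row_meta.append((offset, offset + len(mono), fam, plan.intra_divergence))
                rows_seq.append(mono)
                offset += len(mono)
            rows_meta.append(row_meta)
        arr_seq = "".join(rows_seq)
        if plan.strand == "-":
            arr_seq = revcomp(arr_seq)
            total = len(arr_seq)
            rows_meta = [
                [(total - e, total - s, fam, dv) for (s, e, fam, dv) in row]
                for row in rows_meta
            ]
        inserts.append((plan.position, arr_seq, plan, rows_meta))
    for pos, length in spec.gap_runs:
        inserts.append((pos, "N" * length, None, []))
    inserts.sort(key=lambda t: t[0])

    truth = SyntheticTruth()
    pieces: list[str] = []
    cursor = 0
    genome_offset = 0
    for pos, ins_seq, plan, rows_meta in inserts:
        pieces.append(background[cursor:pos])
        genome_offset += pos - cursor
        cursor = pos
        if plan is not None:
            copy_ids_in_array: list[int] = []
            for row_meta in rows_meta:
                monomer_ids = []
                for s, e, fam, dv in row_meta:
                    truth.monomers.append(
                        MonomerTruth(
                            start=genome_offset + s,
                            end=genome_offset + e,
                            family=fam,
                            strand=plan.strand,
                            divergence=dv,
                        )
                    )
                    monomer_ids.append(len(truth.monomers) - 1)
                truth.copies.append(monomer_ids)
                copy_ids_in_array.append(len(truth.copies) - 1)
            truth.arrays.append(copy_ids_in_array)
        pieces.append(ins_seq)
        genome_offset += len(ins_seq)
    pieces.append(background[cursor:])
    genome = "".join(pieces)

    order = sorted(range(len(truth.monomers)), key=lambda i: truth.monomers[i].start)
    remap = {old: new for new, old in enumerate(order)}
    truth.monomers = [truth.monomers[i] for i in order]
    truth.copies = [[remap[i] for i in c] for c in truth.copies]
    for m0, m1 in zip(truth.monomers, truth.monomers[1:]):
        assert m0.end <= m1.start, "planted monomer intervals overlap"
    return genome, truth, bases


def t2t_like_scenario(
    copies_per_array: tuple[int, ...] = (19, 15, 14, 13, 5, 9),
    background_length: int = 2_000_000,
    intra_divergence: float = 0.02,
    indel_rate: float = 0.005,
    seed: int = 0,
    variant_rows: int = 11,
    gap: tuple[int, int] | None | str = "auto",
    mixed_strands: bool = True,
) -> GenomeSpec:
    """Scenario template mirroring a six-array chromosome-1-like layout.

    Plants six tandem arrays with total copy counts (canonical + variant)
    defaulting to (19, 15, 14, 13, 5, 9) — 75 copies, of which 64 are
    canonical once 11 rows are replaced by one- or two-monomer variant
    rows — plus one N-gap run, with some arrays in reverse-complement
    orientation.  Variant rows are spread out so no two are adjacent
    (two adjacent variant rows whose labels happen to continue increasing
    would be indistinguishable from a canonical copy by construction).
    """
    rng = np.random.default_rng(seed)
    if gap == "auto":
        gap = (int(background_length * 0.75) + 1, 2500)  # +1: avoid array collision
    n_arr = len(copies_per_array)
    positions = np.linspace(
        background_length * 0.1, background_length * 0.9, n_arr
    ).astype(int)
    variant_pool = [(0, 1), (0, 2), (1, 2), (0,), (1,), (2,)]
    per_array_variants = [0] * n_arr
    k = 0
    while sum(per_array_variants) < variant_rows:
        i = k % n_arr
        if per_array_variants[i] < (copies_per_array[i] + 1) // 2 - 1:
            per_array_variants[i] += 1
        k += 1
    arrays = []
    for i, n_total in enumerate(copies_per_array):
        rows: list[tuple[int, ...]] = [(0, 1, 2)] * n_total
        nv = per_array_variants[i]
        for j in range(nv):  # evenly spread, never adjacent
            at = int((j + 0.5) * n_total / nv)
            rows[min(at, n_total - 1)] = variant_pool[int(rng.integers(len(variant_pool)))]
        strand = "-" if (mixed_strands and i % 3 == 1) else "+"
        arrays.append(
            ArrayPlan(
                position=int(positions[i]),
                rows=tuple(rows),
                strand=strand,
                intra_divergence=intra_divergence,
                indel_rate=indel_rate,
            )
        )
    return GenomeSpec(
        background_length=background_length,
        arrays=tuple(arrays),
        gap_runs=(gap,) if gap else (),
        families=FamilySpec(seed=seed),
        seed=seed,
    )


def write_truth(truth: SyntheticTruth, bed_path, json_path, chrom: str = "synthetic"):
    """Persist truth as BED6 (0-based half-open) and lossless JSON."""
    bed_path, json_path = Path(bed_path), Path(json_path)
    with open(bed_path, "w") as fh:
        for i, m in enumerate(truth.monomers):
            fh.write(
                f"{chrom}\t{m.start}\t{m.end}\tm{m.family + 1}.{i}\t0\t{m.strand}\n"
            )
    payload = {
        "monomers": [dataclasses.asdict(m) for m in truth.monomers],
        "copies": truth.copies,
        "arrays": truth.arrays,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(json_path) -> SyntheticTruth:
    with open(json_path) as fh:
        payload = json.load(fh)
    return SyntheticTruth(
        monomers=[MonomerTruth(**m) for m in payload["monomers"]],
        copies=[list(c) for c in payload["copies"]],
        arrays=[list(a) for a in payload["arrays"]],
    )
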