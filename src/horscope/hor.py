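"""Assembly of monomer hits into HOR copies, tandem arrays and reports.

A higher-order-repeat (HOR) copy is a row of one to three monomers with
strictly increasing family labels on a common strand: (m1, m2, m3) is a
canonical copy, one- or two-monomer rows are variant copies.  Maximal runs
of copies separated by small genomic gaps form tandem arrays; an array is
"prominent" when it contains at least two neighboring canonical copies in
tandem.  Reports give per-array copy counts (canonical + variant) and
canonical totals; schemes render one row per copy with its 1-based start
position, family-colored boxes and a reverse-complement flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from horscope.scan import MonomerHit

FAMILY_COLORS = {"m1": "#f5a623", "m2": "#9ad6f0", "m3": "#2559a6"}  # Fig-style palette
_FALLBACK_COLOR = "#999999"


@dataclass(frozen=True)
class AssemblyConfig:
    """Gap tolerances quantifying 'adjacent' and 'blank space'.

    ``intra_copy_gap_tol`` (default 400 = 0.25 x monomer length) bounds the
    gap between monomers of one copy; ``array_gap_tol`` (default 10 000,
    about two canonical HOR lengths) separates tandem arrays.
    """

    intra_copy_gap_tol: int = 400
    array_gap_tol: int = 10_000

    def __post_init__(self):
        if self.intra_copy_gap_tol <= 0 or self.array_gap_tol <= 0:
            raise ValueError("gap tolerances must be positive")


@dataclass
class HORCopy:
    monomers: list[MonomerHit]
    strand: str

    @property
    def start(self) -> int:
        """Forward-strand coordinate of the first monomer in gene orientation."""
        return self.monomers[0].start

    @property
    def interval(self) -> tuple[int, int]:
        return (min(m.start for m in self.monomers), max(m.end for m in self.monomers))

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(m.family for m in self.monomers)

    @property
    def canonical(self) -> bool:
        return self.families == ("m1", "m2", "m3")


@dataclass
class HORArray:
    copies: list[HORCopy]

    @property
    def interval(self) -> tuple[int, int]:
        return (
            min(c.interval[0] for c in self.copies),
            max(c.interval[1] for c in self.copies),
        )

    @property
    def n_canonical(self) -> int:
        return sum(1 for c in self.copies if c.canonical)

    @property
    def prominent(self) -> bool:
        return any(
            a.canonical and b.canonical for a, b in zip(self.copies, self.copies[1:])
        )


@dataclass
class AssemblyReport:
    arrays: list[HORArray]
    labels: list[str | None] = field(default_factory=list)

    @property
    def per_array_counts(self) -> list[int]:
        return [len(a.copies) for a in self.arrays]

    @property
    def per_array_canonical(self) -> list[int]:
        return [a.n_canonical for a in self.arrays]

    @property
    def total_copies(self) -> int:
        return sum(self.per_array_counts)

    @property
    def total_canonical(self) -> int:
        return sum(self.per_array_canonical)

    @property
    def prominent_arrays(self) -> list[HORArray]:
        return [a for a in self.arrays if a.prominent]

    @property
    def scattered_arrays(self) -> list[HORArray]:
        return [a for a in self.arrays if not a.prominent]

    def to_dict(self) -> dict:
        rows = []
        for i, a in enumerate(self.arrays):
            rows.append(
                {
                    "array": i,
                    "label": self.labels[i] if i < len(self.labels) else None,
                    "start": a.interval[0],
                    "end": a.interval[1],
                    "copies": len(a.copies),
                    "canonical": a.n_canonical,
                    "prominent": a.prominent,
                    "rows": [
                        {
                            "strand": c.strand,
                            "monomers": [
                                {
                                    "chrom": m.chrom,
                                    "start": m.start,
                                    "end": m.end,
                                    "family": m.family,
                                }
                                for m in c.monomers
                            ],
                        }
                        for c in a.copies
                    ],
                }
            )
        return {
            "arrays": rows,
            "total_copies": self.total_copies,
            "total_canonical": self.total_canonical,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssemblyReport":
        arrays = []
        labels = []
        for arr in d["arrays"]:
            labels.append(arr.get("label"))
            copies = [
                HORCopy(
                    monomers=[
                        MonomerHit(
                            chrom=m["chrom"],
                            start=m["start"],
                            end=m["end"],
                            family=m["family"],
                            strand=row["strand"],
                            edits=0,
                            divergence=0.0,
                        )
                        for m in row["monomers"]
                    ],
                    strand=row["strand"],
                )
                for row in arr.get("rows", [])
            ]
            arrays.append(HORArray(copies=copies))
        return cls(arrays=arrays, labels=labels)


def _label_rank(family: str) -> tuple:
    return (len(family), family)  # m1 < m2 < ... < m10


def group_hits_into_copies(
    hits: list[MonomerHit], config: AssemblyConfig | None = None
) -> list[HORCopy]:
    """Partition sorted non-overlapping hits into HOR-copy rows.

    Hits are walked in genomic order, except that maximal blocks of '-'
    strand hits are walked right-to-left so rows read m1 -> m2 -> m3 in
    gene orientation while coordinates stay on the forward strand.  A new
    row starts when the family label fails to strictly increase, the
    strand changes, or the gap to the previous monomer exceeds
    ``intra_copy_gap_tol``.
    """
    config = config or AssemblyConfig()
    for a, b in zip(hits, hits[1:]):
        if a.end > b.start:
            raise ValueError("input hits overlap or are unsorted")
    # split into maximal same-strand blocks
    blocks: list[list[MonomerHit]] = []
    for h in hits:
        if blocks and blocks[-1][0].strand == h.strand:
            blocks[-1].append(h)
        else:
            blocks.append([h])
    copies: list[HORCopy] = []
    for block in blocks:
        strand = block[0].strand
        walk = block if strand == "+" else block[::-1]
        current: list[MonomerHit] = []
        for h in walk:
            if current:
                prev = current[-1]
                gap = (h.start - prev.end) if strand == "+" else (prev.start - h.end)
                increasing = _label_rank(h.family) > _label_rank(prev.family)
                if not increasing or gap > config.intra_copy_gap_tol or len(current) == 3:
                    copies.append(HORCopy(monomers=current, strand=strand))
                    current = []
            current.append(h)
        if current:
            copies.append(HORCopy(monomers=current, strand=strand))
    copies.sort(key=lambda c: c.interval[0])
    return copies


def group_copies_into_arrays(
    copies: list[HORCopy], config: AssemblyConfig | None = None
) -> list[HORArray]:
    """Maximal runs of copies with inter-copy gap <= ``array_gap_tol``.

    Isolated monomers (single-monomer copies) form single-copy arrays.
    """
    config = config or AssemblyConfig()
    copies = sorted(copies, key=lambda c: c.interval[0])
    arrays: list[HORArray] = []
    for c in copies:
        if arrays and c.interval[0] - arrays[-1].interval[1] <= config.array_gap_tol:
            arrays[-1].copies.append(c)
        else:
            arrays.append(HORArray(copies=[c]))
    return arrays


def count_report(
    arrays: list[HORArray], labels: list[str] | None = None
) -> AssemblyReport:
    """Table-style per-array and total copy counts.

    ``labels`` (e.g. gene names) are user-supplied annotations applied
    positionally to the prominent arrays; on a count mismatch they are
    dropped with a warning, never inferred.
    """
    report = AssemblyReport(arrays=list(arrays), labels=[None] * len(arrays))
    if labels:
        prominent_idx = [i for i, a in enumerate(arrays) if a.prominent]
        if len(labels) == len(arrays):
            report.labels = list(labels)
        elif len(labels) == len(prominent_idx):
            for i, lab in zip(prominent_idx, labels):
                report.labels[i] = lab
        else:
            warnings.warn("label count matches neither arrays nor prominent arrays; dropped")
    return report


def render_scheme(report: AssemblyReport, families: list[str] | None = None) -> str:
    """Aligned text scheme: one row per copy, blank line between arrays.

    Rows print the 1-based start position, one fixed column per family so
    monomers of the same family line up vertically, and a '*' suffix on
    reverse-complement rows.
    """
    families = families or sorted(
        {m.family for a in report.arrays for c in a.copies for m in c.monomers},
        key=_label_rank,
    )
    col = {f: i for i, f in enumerate(families)}
    lines = []
    for ai, arr in enumerate(report.arrays):
        if ai:
            lines.append("")
        label = report.labels[ai] if ai < len(report.labels) else None
        if label:
            lines.append(f"# {label}")
        for c in arr.copies:
            cells = ["  ."] * len(families)
            for m in c.monomers:
                cells[col[m.family]] = f" {m.family:>2}"
            flag = "*" if c.strand == "-" else " "
            lines.append(f"{c.start + 1:>12}{flag}{''.join(cells)}")
    return "\n".join(lines) + ("\n" if lines else "")


def render_scheme_svg(
    report: AssemblyReport,
    families: list[str] | None = None,
    box_w: int = 46,
    box_h: int = 14,
) -> str:
    """Deterministic SVG scheme: colored boxes per monomer, bold start
    positions for reverse-complement rows, vertical blank space between
    arrays."""
    families = families or sorted(
        {m.family for a in report.arrays for c in a.copies for m in c.monomers},
        key=_label_rank,
    )
    col = {f: i for i, f in enumerate(families)}
    rows = sum(len(a.copies) for a in report.arrays) + max(0, len(report.arrays) - 1)
    width = 110 + box_w * len(families) + 10
    height = rows * (box_h + 4) + 20
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">'
    ]
    y = 10
    for ai, arr in enumerate(report.arrays):
        if ai:
            y += box_h + 4  # blank space between arrays
        for c in arr.copies:
            weight = "bold" if c.strand == "-" else "normal"
            parts.append(
                f'<text x="100" y="{y + box_h - 3}" text-anchor="end" '
                f'font-size="10" font-family="monospace" font-weight="{weight}">'
                f"{c.start + 1}</text>"
            )
            for m in c.monomers:
                x = 110 + col[m.family] * box_w
                color = FAMILY_COLORS.get(m.family, _FALLBACK_COLOR)
                parts.append(
                    f'<rect x="{x}" y="{y}" width="{box_w - 4}" height="{box_h}" '
                    f'fill="{color}" stroke="black" stroke-width="0.5"/>'
                )
            y += box_h + 4
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def align_panels(
    reports: list[AssemblyReport],
    anchors: list[list[int]] | None = None,
    panel_titles: list[str] | None = None,
) -> str:
    """Side-by-side text layout with anchor arrays placed on common rows.

    ``anchors[k]`` lists, for report k, the array indices to co-align; all
    reports must supply the same number of anchors.  The first copy of
    anchor j is placed on the same output row across panels, preserving
    intra-array row order.  With zero anchors the schemes are concatenated
    with separators.  Purely presentational.
    """
    panel_titles = panel_titles or [f"panel{i + 1}" for i in range(len(reports))]
    if anchors is None or not any(anchors):
        out = []
        for t, r in zip(panel_titles, reports):
            out.append(f"=== {t} ===")
            out.append(render_scheme(r))
        return "\n".join(out)
    n_anchor = {len(a) for a in anchors}
    if len(n_anchor) != 1:
        raise ValueError("all reports must supply the same number of anchor arrays")
    # build per-panel rows, remembering the row index of each anchor's first copy
    panel_rows: list[list[str]] = []
    anchor_rows: list[list[int]] = []
    for r, anc in zip(reports, anchors):
        anc = sorted(anc)  # anchors co-align in genomic order
        rows: list[str] = []
        a_rows: list[int] = []
        for ai, arr in enumerate(r.arrays):
            if rows:
                rows.append("")
            if ai in anc:
                a_rows.append(len(rows))
            for c in arr.copies:
                flag = "*" if c.strand == "-" else ""
                rows.append(f"{c.start + 1:>11}{flag:<1} {' '.join(c.families)}")
        panel_rows.append(rows)
        anchor_rows.append(a_rows)
    n_anc = len(anchors[0])
    # compute shifts so anchor j lands on a common row in every panel
    shifts = [0] * len(reports)
    padded: list[list[str]] = [list(r) for r in panel_rows]
    for j in range(n_anc):
        target = max(anchor_rows[p][j] + shifts[p] for p in range(len(reports)))
        for p in range(len(reports)):
            need = target - (anchor_rows[p][j] + shifts[p])
            if need > 0:
                at = anchor_rows[p][j] + shifts[p]
                padded[p][at:at] = [""] * need
                shifts[p] += need
    height = max(len(r) for r in padded)
    widths = [max((len(x) for x in r), default=10) + 3 for r in padded]
    lines = ["".join(t.ljust(w) for t, w in zip(panel_titles, widths))]
    for i in range(height):
        lines.append(
            "".join(
                (padded[p][i] if i < len(padded[p]) else "").ljust(widths[p])
                for p in range(len(reports))
            ).rstrip()
        )
    return "\n".join(lines) + "\n"
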