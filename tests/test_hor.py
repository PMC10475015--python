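"""HOR copy/array assembly, count reports and rendered schemes."""

import pytest

from horscope.hor import (
    AssemblyConfig,
    AssemblyReport,
    align_panels,
    count_report,
    group_copies_into_arrays,
    group_hits_into_copies,
    render_scheme,
    render_scheme_svg,
)
from horscope.scan import MonomerHit


def mk_hits(spec, start=0, length=100, gap=0):
    """Build adjacent hits from [(family, strand), ...]."""
    hits = []
    pos = start
    for fam, strand in spec:
        hits.append(
            MonomerHit("chr", pos, pos + length, fam, strand, 0, 0.0)
        )
        pos += length + gap
    return hits


class TestCopies:
    def test_canonical_triple(self):
        copies = group_hits_into_copies(mk_hits([("m1", "+"), ("m2", "+"), ("m3", "+")]))
        assert len(copies) == 1
        assert copies[0].canonical and copies[0].families == ("m1", "m2", "m3")

    def test_two_monomer_variant(self):
        copies = group_hits_into_copies(mk_hits([("m1", "+"), ("m3", "+")]))
        assert len(copies) == 1
        assert not copies[0].canonical and copies[0].families == ("m1", "m3")

    def test_break_on_label_decrease(self):
        copies = group_hits_into_copies(
            mk_hits([("m1", "+"), ("m2", "+"), ("m3", "+")] * 2)
        )
        assert len(copies) == 2 and all(c.canonical for c in copies)

    def test_break_on_large_gap(self):
        hits = mk_hits([("m1", "+")]) + mk_hits([("m2", "+")], start=5_000)
        copies = group_hits_into_copies(hits, AssemblyConfig(intra_copy_gap_tol=400))
        assert len(copies) == 2

    def test_break_on_strand_change(self):
        copies = group_hits_into_copies(mk_hits([("m1", "+"), ("m2", "-")]))
        assert len(copies) == 2

    def test_minus_block_read_in_gene_orientation(self):
        # genomically m3,m2,m1 on '-' strand is one canonical copy
        copies = group_hits_into_copies(mk_hits([("m3", "-"), ("m2", "-"), ("m1", "-")]))
        assert len(copies) == 1
        assert copies[0].canonical and copies[0].strand == "-"
        # first monomer in gene orientation is the genomically last hit
        assert copies[0].start == 200

    def test_overlapping_input_rejected(self):
        hits = [
            MonomerHit("chr", 0, 100, "m1", "+", 0, 0.0),
            MonomerHit("chr", 50, 150, "m2", "+", 0, 0.0),
        ]
        with pytest.raises(ValueError):
            group_hits_into_copies(hits)


class TestArrays:
    def test_back_to_back_canonicals_one_prominent_array(self):
        copies = group_hits_into_copies(
            mk_hits([("m1", "+"), ("m2", "+"), ("m3", "+")] * 5)
        )
        arrays = group_copies_into_arrays(copies)
        assert len(arrays) == 1
        assert len(arrays[0].copies) == 5 and arrays[0].prominent

    def test_distant_copies_split_into_non_prominent_arrays(self):
        hits = mk_hits([("m1", "+"), ("m2", "+"), ("m3", "+")]) + mk_hits(
            [("m1", "+"), ("m2", "+"), ("m3", "+")], start=50_000
        )
        copies = group_hits_into_copies(hits)
        arrays = group_copies_into_arrays(copies, AssemblyConfig(array_gap_tol=10_000))
        assert len(arrays) == 2
        assert not arrays[0].prominent and not arrays[1].prominent

    def test_isolated_monomer_single_copy_array(self):
        arrays = group_copies_into_arrays(
            group_hits_into_copies(mk_hits([("m2", "+")]))
        )
        assert len(arrays) == 1
        assert len(arrays[0].copies) == 1 and not arrays[0].prominent


class TestReport:
    def test_empty(self):
        rep = count_report([])
        assert rep.total_copies == 0 and rep.total_canonical == 0

    def test_totals_are_sums(self, small_scenario):
        from horscope import scan

        genome, truth, bases = small_scenario
        hits = scan.scan_monomers(genome, {f"m{i+1}": b for i, b in enumerate(bases)})
        arrays = group_copies_into_arrays(group_hits_into_copies(hits))
        rep = count_report(arrays)
        assert rep.total_copies == sum(rep.per_array_counts)
        assert rep.total_canonical == sum(rep.per_array_canonical)
        # every hit lands in exactly one copy, every copy in one array
        n_monomers = sum(len(c.monomers) for a in arrays for c in a.copies)
        assert n_monomers == len(hits)
        for a in arrays:
            assert a.n_canonical <= len(a.copies)

    def test_positional_labels_on_prominent_arrays(self):
        hits = mk_hits([("m1", "+"), ("m2", "+"), ("m3", "+")] * 2) + mk_hits(
            [("m2", "+")], start=90_000
        )
        arrays = group_copies_into_arrays(group_hits_into_copies(hits))
        rep = count_report(arrays, labels=["NBPF20"])
        assert rep.labels[0] == "NBPF20" and rep.labels[1] is None

    def test_label_mismatch_warns_and_drops(self):
        arrays = group_copies_into_arrays(
            group_hits_into_copies(mk_hits([("m1", "+")]))
        )
        with pytest.warns(UserWarning):
            rep = count_report(arrays, labels=["a", "b", "c"])
        assert rep.labels == [None]

    def test_round_trip_via_dict(self, small_scenario):
        from horscope import scan

        genome, _, bases = small_scenario
        hits = scan.scan_monomers(genome, {f"m{i+1}": b for i, b in enumerate(bases)})
        rep = count_report(
            group_copies_into_arrays(group_hits_into_copies(hits))
        )
        back = AssemblyReport.from_dict(rep.to_dict())
        assert back.per_array_counts == rep.per_array_counts
        assert back.per_array_canonical == rep.per_array_canonical
        assert render_scheme(back) == render_scheme(rep)


class TestScheme:
    def test_empty_scheme(self):
        assert render_scheme(count_report([])) == ""

    def test_one_based_start_positions(self):
        copies = group_hits_into_copies(
            mk_hits([("m1", "+"), ("m2", "+"), ("m3", "+")], start=999)
        )
        rep = count_report(group_copies_into_arrays(copies))
        scheme = render_scheme(rep)
        assert "1000" in scheme.split("\n")[0]

    def test_reverse_complement_rows_flagged(self):
        copies = group_hits_into_copies(mk_hits([("m3", "-"), ("m2", "-"), ("m1", "-")]))
        rep = count_report(group_copies_into_arrays(copies))
        assert "*" in render_scheme(rep)
        assert 'font-weight="bold"' in render_scheme_svg(rep)

    def test_blank_line_between_arrays(self):
        hits = mk_hits([("m1", "+")]) + mk_hits([("m1", "+")], start=99_000)
        rep = count_report(group_copies_into_arrays(group_hits_into_copies(hits)))
        assert "\n\n" in render_scheme(rep)


class TestAlignPanels:
    def _report(self, starts):
        hits = []
        for s in starts:
            hits.extend(mk_hits([("m1", "+"), ("m2", "+"), ("m3", "+")], start=s))
        return count_report(group_copies_into_arrays(group_hits_into_copies(hits)))

    def test_zero_anchors_concatenates(self):
        r = self._report([0])
        out = align_panels([r, r], None, panel_titles=["a", "b"])
        assert "=== a ===" in out and "=== b ===" in out

    def test_anchor_rows_colinear(self):
        r1 = self._report([0, 50_000])
        r2 = self._report([0, 0 + 300, 90_000])  # extra copy before its anchor
        out = align_panels([r1, r2], [[1], [1]], panel_titles=["p1", "p2"])
        lines = out.split("\n")
        row1 = next(i for i, l in enumerate(lines) if "50001" in l)
        row2 = next(i for i, l in enumerate(lines) if "90001" in l)
        assert row1 == row2

    def test_anchor_count_mismatch_rejected(self):
        r = self._report([0])
        with pytest.raises(ValueError):
            align_panels([r, r], [[0], []])
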