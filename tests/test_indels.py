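"""Read classification, CIGAR in/del extraction, window filtering,
control subtraction, OAS and activity summaries."""

import numpy as np
import pandas as pd
import pysam
import pytest

from guideforge.indels import (
    IndelEvent,
    TargetSite,
    activity_summary,
    call_activity,
    classify_reads,
    compute_oas,
    extract_indels,
    indel_events,
    kendall_tau_b,
    subtract_control,
    window_filter,
)

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1_000_000}]}
)


def _read(cigar="150M", mapq=60, proper=True, dup=False, unmapped=False, pos=100):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = "r"
    if unmapped:
        a.flag = 0x4
        return a
    a.reference_id = 0
    a.reference_start = pos - 1
    a.cigarstring = cigar
    n = sum(ln for op, ln in a.cigartuples if op in (0, 1, 4, 7, 8))
    a.query_sequence = "A" * n
    a.flag = 0x1 | (0x2 if proper else 0) | (0x400 if dup else 0)
    a.mapping_quality = mapq
    return a


class TestClassifyReads:
    @pytest.mark.parametrize(
        "kwargs,kept",
        [
            (dict(cigar="150M", proper=True, mapq=60), False),  # unedited pair
            (dict(cigar="70M5D80M", proper=False, mapq=60), True),
            (dict(cigar="70M5D80M", proper=True, mapq=60), True),  # gapped proper
            (dict(cigar="150M", proper=False, mapq=60), True),
            (dict(cigar="70M5D80M", proper=False, mapq=37), False),  # below MAPQ 38
            (dict(cigar="70M5D80M", proper=False, mapq=38), True),  # at threshold
            (dict(cigar="70M5D80M", proper=False, mapq=60, dup=True), False),
        ],
    )
    def test_truth_table(self, kwargs, kept):
        retained, _ = classify_reads([_read(**kwargs)])
        assert (len(retained) == 1) is kept

    def test_unmapped_skipped_with_count(self):
        retained, stats = classify_reads([_read(unmapped=True)])
        assert retained == [] and stats.n_unmapped == 1

    def test_stats_partition_input(self):
        reads = [
            _read(),  # proper gapless
            _read(cigar="10M2I138M", proper=False),
            _read(cigar="10M2I138M", proper=False, mapq=20),
            _read(cigar="10M2I138M", proper=False, dup=True),
            _read(unmapped=True),
        ]
        retained, s = classify_reads(reads)
        assert s.n_input == 5
        assert (
            s.n_unmapped + s.n_proper_gapless + s.n_duplicate
            + s.n_low_mapq + s.n_retained
        ) == s.n_input
        assert s.n_retained == len(retained) == 1


class TestExtractIndels:
    def test_insertion_position_left_of_insert(self):
        (ev,) = indel_events(100, [("M", 10), ("I", 2), ("M", 8)], "chr1", "r")
        assert (ev.type, ev.length, ev.position) == ("insertion", 2, 109)

    def test_deletion_position_first_deleted_base(self):
        (ev,) = indel_events(50, [("M", 5), ("D", 3), ("M", 15)], "chr1", "r")
        assert (ev.type, ev.length, ev.position) == ("deletion", 3, 55)

    def test_gapless_read_has_no_events(self):
        assert indel_events(10, [("M", 20)]) == []

    def test_softclip_does_not_advance_reference(self):
        (ev,) = indel_events(100, [("S", 5), ("M", 10), ("D", 2), ("M", 5)])
        assert ev.position == 110

    def test_malformed_cigar_names_read(self):
        with pytest.raises(ValueError, match="badread"):
            indel_events(1, [("Q", 5)], "chr1", "badread")

    def test_matches_brute_force_on_random_reads(self):
        """Pipeline extraction equals an independent per-base reference walk
        on 10^4 random CIGARs."""
        rng = np.random.default_rng(42)
        ops_pool = ["M", "I", "D", "S", "N", "=", "X"]

        def brute_force(pos, cigar):
            # re-derive reference spans from scratch: expand op by op,
            # tracking the reference pointer independently
            events, ref = [], pos
            for op, ln in cigar:
                if op == "I":
                    events.append(("insertion", ln, ref - 1))
                elif op == "D":
                    events.append(("deletion", ln, ref))
                if op in ("M", "D", "N", "=", "X"):
                    ref = ref + ln
            return events

        for _ in range(10_000):
            n_ops = int(rng.integers(1, 8))
            cigar = []
            prev = None
            for _ in range(n_ops):
                op = str(rng.choice(ops_pool))
                if op == prev:
                    continue
                cigar.append((op, int(rng.integers(1, 30))))
                prev = op
            pos = int(rng.integers(1, 10_000))
            got = indel_events(pos, cigar, "chr1", "r")
            assert [(e.type, e.length, e.position) for e in got] == brute_force(
                pos, cigar
            )

    def test_extract_from_sam_record(self):
        read = _read(cigar="10M2I138M", proper=False, pos=100)
        (ev,) = extract_indels(read)
        assert (ev.type, ev.position, ev.chrom) == ("insertion", 109, "chr1")


class TestWindowFilter:
    SITE = TargetSite("g", "chr1", 117)  # window 115-120

    def _ev(self, type_, pos, length=1):
        return IndelEvent(type_, length, "chr1", pos, "r")

    def test_window_is_six_bases(self):
        lo, hi = self.SITE.window
        assert (lo, hi) == (115, 120)

    @pytest.mark.parametrize(
        "event,valid",
        [
            (("deletion", 116, 2), True),
            (("insertion", 113, 1), False),
            (("deletion", 110, 10), True),  # span 110-119 intersects
            (("insertion", 115, 3), True),  # boundary in
            (("insertion", 120, 1), True),
            (("insertion", 121, 1), False),
            (("insertion", 114, 1), False),
            (("deletion", 121, 5), False),
            (("deletion", 100, 15), False),  # span 100-114 stops short of 115
            (("deletion", 100, 16), True),  # span 100-115 reaches the window
        ],
    )
    def test_hand_enumerated_cases(self, event, valid):
        type_, pos, length = event
        ev = self._ev(type_, pos, length)
        got = window_filter([ev], self.SITE)
        assert (got == [ev]) is valid

    def test_point_rule_for_deletions(self):
        ev = self._ev("deletion", 110, 10)
        assert window_filter([ev], self.SITE, deletion_rule="point") == []

    def test_other_chromosome_invalid(self):
        ev = IndelEvent("deletion", 2, "chr2", 116, "r")
        assert window_filter([ev], self.SITE) == []


class TestSubtractControl:
    def _ev(self, pos, length, type_="deletion", read="r1"):
        return IndelEvent(type_, length, "chr1", pos, read)

    def test_identical_key_removed(self):
        ev = self._ev(117, 3)
        ctrl = self._ev(117, 3, read="ctrl")
        assert subtract_control([ev], [ctrl]) == []

    def test_different_length_kept(self):
        ev = self._ev(117, 3)
        ctrl = self._ev(117, 4, read="ctrl")
        assert subtract_control([ev], [ctrl]) == [ev]

    def test_empty_control_is_identity(self):
        evs = [self._ev(117, 3), self._ev(200, 1, "insertion")]
        assert subtract_control(evs, []) == evs


class TestOas:
    def test_zero_mu_gives_zero(self):
        assert compute_oas(0.0, 500, 10_000) == 0.0

    def test_worked_values(self):
        assert compute_oas(50, 1_000, 100_000) == pytest.approx(50.0)
        assert compute_oas(10, 2_000, 100_000) == pytest.approx(5.0)

    def test_scale_invariance(self):
        base = compute_oas(12.5, 730, 55_000)
        for k in (2, 10, 1000):
            assert compute_oas(12.5, 730 * k, 55_000 * k) == pytest.approx(base)

    def test_undetected_guide_is_nan(self):
        assert np.isnan(compute_oas(5.0, 0, 10_000))

    def test_equals_mu_when_representation_is_one_percent(self):
        assert compute_oas(7.0, 1_000, 100_000) == pytest.approx(7.0)


class TestKendallTau:
    def test_identical_ranks(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        assert kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 2, 3, 4, 5], [2, 1, 3, 3, 5, 4]),
            ([1, 1, 2, 3], [4, 4, 2, 1]),
            ([3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8], [2, 7, 1, 8, 2, 8, 1, 8, 2, 8, 4, 5]),
        ],
    )
    def test_matches_all_pairs_brute_force_with_ties(self, x, y):
        conc = disc = tx = ty = 0
        n = len(x)
        for i in range(n):
            for j in range(i + 1, n):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx * dy > 0:
                    conc += 1
                elif dx * dy < 0:
                    disc += 1
                elif dx == 0 and dy != 0:
                    tx += 1
                elif dy == 0 and dx != 0:
                    ty += 1
        denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
        expected = (conc - disc) / denom
        assert kendall_tau_b(x, y) == pytest.approx(expected)

    def test_too_few_pairs_absent(self):
        assert np.isnan(kendall_tau_b([1], [2]))


def _write_sam(path, records):
    with pysam.AlignmentFile(str(path), "w", header=HEADER) as fh:
        for r in records:
            fh.write(r)


class TestCallActivity:
    def _records(self, rng, cut, n, rate):
        out = []
        for k in range(n):
            if rng.random() < rate:
                jitter = int(rng.integers(-2, 3))
                ln = int(rng.integers(1, 10))
                pre = (cut + jitter) - (cut - 75)
                r = _read(
                    cigar=f"{pre}M{ln}D{150 - pre}M",
                    proper=False,
                    pos=cut - 75,
                )
            else:
                r = _read(cigar="150M", proper=True, pos=cut - 75)
            r.query_name = f"r{cut}:{k}"
            out.append(r)
        return out

    def test_filter_chain_monotone_and_oracle_counts(self, tmp_path):
        """Per-guide valid-event counts equal an independent re-derivation
        from the SAM text."""
        rng = np.random.default_rng(7)
        sites = [
            TargetSite("gA", "chr1", 5_000),
            TargetSite("gB", "chr1", 40_000),
        ]
        records = self._records(rng, 5_000, 300, 0.4) + self._records(
            rng, 40_000, 300, 0.1
        )
        sam = tmp_path / "e.sam"
        _write_sam(sam, records)
        counts = pd.DataFrame({"guide_id": ["gA", "gB"], "raw_reads": [100, 100]})
        act = call_activity([str(sam)], None, sites, counts)

        # independent oracle: parse the SAM text and re-derive spans
        import re

        expect = {"gA": 0, "gB": 0}
        for line in open(sam):
            if line.startswith("@"):
                continue
            f = line.split("\t")
            flag, pos, mapq, cigar = int(f[1]), int(f[3]), int(f[4]), f[5]
            ops = re.findall(r"(\d+)([MIDNSHP=X])", cigar)
            gapless = not any(op in "ID" for _, op in ops)
            if (flag & 0x2 and gapless) or flag & 0x400 or mapq < 38:
                continue
            ref = pos
            for ln, op in ops:
                ln = int(ln)
                if op == "I":
                    for s in sites:
                        lo, hi = s.window
                        if lo <= ref - 1 <= hi:
                            expect[s.guide_id] += 1
                elif op == "D":
                    for s in sites:
                        lo, hi = s.window
                        if ref <= hi and ref + ln - 1 >= lo:
                            expect[s.guide_id] += 1
                    ref += ln
                elif op in "MN=X":
                    ref += ln
        got = dict(zip(act.table["guide_id"], act.table["indels_rep1"]))
        assert got == expect
        assert got["gA"] > 0

    def test_control_subtraction_and_active_flags(self, tmp_path):
        cut = 5_000
        site = TargetSite("gA", "chr1", cut)
        bg = _read(cigar="73M4D77M", proper=False, pos=cut - 75)  # del at 4998
        edited = _read(cigar="75M2D75M", proper=False, pos=cut - 75)  # del at 5000
        e_sam, c_sam = tmp_path / "e.sam", tmp_path / "c.sam"
        _write_sam(e_sam, [bg, edited])
        _write_sam(c_sam, [bg])
        counts = pd.DataFrame({"guide_id": ["gA"], "raw_reads": [50]})
        act = call_activity([str(e_sam)], str(c_sam), [site], counts).table
        assert act.loc[0, "indels_rep1"] == 1  # background removed
        act_nc = call_activity([str(e_sam)], None, [site], counts).table
        assert act_nc.loc[0, "indels_rep1"] == 2

    def test_undetected_in_pool_not_active(self, tmp_path):
        cut = 5_000
        site = TargetSite("gA", "chr1", cut)
        edited = _read(cigar="75M2D75M", proper=False, pos=cut - 75)
        sam = tmp_path / "e.sam"
        _write_sam(sam, [edited])
        counts = pd.DataFrame(
            {"guide_id": ["gA", "gB"], "raw_reads": [0, 100]}
        )
        act = call_activity([str(sam)], None, [site], counts).table
        assert not act.loc[0, "detected_in_pool"]
        assert not act.loc[0, "active"]
        assert np.isnan(act.loc[0, "oas"])


class TestActivitySummary:
    def test_groupwise_and_gene_level(self):
        activity = pd.DataFrame(
            {
                "guide_id": ["a5", "a6", "b5", "b6"],
                "oas": [1.0, 0.0, 2.0, 3.0],
                "active": [True, False, True, True],
                "detected_in_pool": [True, True, True, True],
            }
        )
        lib = pd.DataFrame(
            {
                "guide_id": ["a5", "a6", "b5", "b6"],
                "gene_id": ["A", "A", "B", "B"],
                "group": [5, 6, 5, 6],
            }
        )
        s = activity_summary(activity, lib)
        assert s["pct_active_overall"] == pytest.approx(75.0)
        assert s["pct_active_by_group"] == {5: 100.0, 6: 50.0}
        assert s["pct_genes_edited"] == pytest.approx(100.0)

    def test_tau_reported_with_predictions(self):
        activity = pd.DataFrame(
            {
                "guide_id": list("abcd"),
                "oas": [1.0, 2.0, 3.0, 4.0],
                "active": [True] * 4,
                "detected_in_pool": [True] * 4,
            }
        )
        pred = pd.DataFrame(
            {"guide_id": list("abcd"), "predicted_activity": [0.1, 0.2, 0.3, 0.4]}
        )
        s = activity_summary(activity, predicted=pred)
        assert s["kendall_tau_b"] == pytest.approx(1.0)

    def test_tau_absent_with_single_pair(self):
        activity = pd.DataFrame(
            {
                "guide_id": ["a"],
                "oas": [1.0],
                "active": [True],
                "detected_in_pool": [True],
            }
        )
        pred = pd.DataFrame({"guide_id": ["a"], "predicted_activity": [0.5]})
        s = activity_summary(activity, predicted=pred)
        assert s["kendall_tau_b"] is None
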