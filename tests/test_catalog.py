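"""RepeatMasker parsing and defragmentation into proviral loci."""

import pytest

from ervscan.catalog import (RepeatHit, RepeatMaskerParseError,
                             catalog_summary, defragment,
                             parse_repeatmasker_out)

HEADER = (
    "   SW  perc perc perc  query  position in query  matching repeat ...\n"
    "score  div. del. ins.  sequence begin end (left) repeat class ...\n"
    "\n"
)


def out_row(chrom, begin_1b, end_1b, name, strand="+", div=1.0):
    return (f" 2000 {div:5.1f}  0.0  0.0  {chrom} {begin_1b} {end_1b} (0) "
            f"{strand} {name} LTR/ERV1 1 {end_1b - begin_1b + 1} (0) 1\n")


def hit(chrom, start, end, name, strand="+", hit_id=0):
    return RepeatHit(chrom=chrom, start=start, end=end, strand=strand,
                     repeat_name=name, repeat_class="LTR/ERV1",
                     divergence_pct=1.0, hit_id=hit_id)


class TestParse:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "one.out"
        p.write_text(HEADER + out_row("chr1", 1001, 1400, "CERV1_LTR"))
        (h,) = parse_repeatmasker_out(p)
        assert (h.start, h.end) == (1000, 1400)
        assert h.strand == "+" and h.repeat_name == "CERV1_LTR"

    def test_minus_strand_marker(self, tmp_path):
        p = tmp_path / "c.out"
        p.write_text(HEADER + out_row("chr1", 11, 20, "CERV1_LTR", strand="C"))
        (h,) = parse_repeatmasker_out(p)
        assert h.strand == "-"

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.out"
        p.write_text(HEADER)
        assert parse_repeatmasker_out(p) == []

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text(HEADER + " 2000 x  0.0  0.0  chr1 10\n")
        with pytest.raises(RepeatMaskerParseError, match="line 4"):
            parse_repeatmasker_out(p)

    def test_name_filter_and_candidate_count(self, tmp_path):
        """A 693-row annotation with a matching name filter yields 693 hits
        (the computationally-predicted candidate count of the original
        screen), with non-matching rows excluded."""
        rows = []
        pos = 1
        for i in range(693):
            name = "PtERV-1c_LTR" if i % 2 else "CERV1_LTR"
            rows.append(out_row("chr1", pos, pos + 99, name))
            pos += 200
        rows.append(out_row("chr1", pos, pos + 99, "AluY"))
        p = tmp_path / "cand.out"
        p.write_text(HEADER + "".join(rows))
        hits = parse_repeatmasker_out(p, name_prefixes=("PtERV", "CERV"))
        assert len(hits) == 693


class TestDefragment:
    def test_ltr_internal_ltr_is_full_length(self):
        hits = [hit("chr1", 0, 400, "CERV1_LTR", hit_id=0),
                hit("chr1", 400, 8000, "CERV1-int", hit_id=1),
                hit("chr1", 8000, 8400, "CERV1_LTR", hit_id=2)]
        loci, ignored = defragment(hits, max_gap_bp=500)
        assert len(loci) == 1 and not ignored
        locus = loci[0]
        assert locus.category == "full_length"
        assert locus.span == (0, 8400)
        assert locus.subfamily == "CERV1"

    def test_isolated_ltr_is_solo(self):
        hits = [hit("chr1", 0, 400, "CERV1_LTR", hit_id=0),
                hit("chr1", 10_000, 10_400, "CERV1_LTR", hit_id=1)]
        loci, _ = defragment(hits, max_gap_bp=500)
        assert [l.category for l in loci] == ["solo_ltr", "solo_ltr"]

    def test_internal_plus_one_ltr_is_truncated(self):
        hits = [hit("chr1", 0, 4000, "CERV1-int", hit_id=0),
                hit("chr1", 4000, 4400, "CERV1_LTR", hit_id=1)]
        loci, _ = defragment(hits, max_gap_bp=500)
        assert loci[0].category == "truncated"

    def test_split_internal_merges_within_gap(self):
        """Two internal fragments 50 bp apart merge into one full-length
        locus; expected span verified by a brute-force interval merge."""
        spans = [(0, 400, "CERV1_LTR"), (400, 4000, "CERV1-int"),
                 (4050, 8000, "CERV1-int"), (8000, 8400, "CERV1_LTR")]
        hits = [hit("chr1", a, b, n, hit_id=i)
                for i, (a, b, n) in enumerate(spans)]
        # oracle: greedy merge of intervals with gap <= 500
        merged = []
        for a, b, _ in sorted(spans):
            if merged and a - merged[-1][1] <= 500:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        assert len(merged) == 1
        loci, _ = defragment(hits, max_gap_bp=500)
        assert len(loci) == 1
        assert loci[0].category == "full_length"
        assert loci[0].span == merged[0]
        assert len(loci[0].internal_spans) == 1

    def test_two_ltrs_without_internal_is_unknown(self):
        hits = [hit("chr1", 0, 400, "CERV1_LTR", hit_id=0),
                hit("chr1", 500, 900, "CERV1_LTR", hit_id=1)]
        loci, _ = defragment(hits, max_gap_bp=1000)
        assert loci[0].category == "unknown"

    def test_mixed_family_proviral_chain_is_unknown(self):
        hits = [hit("chr1", 0, 400, "CERV1_LTR", hit_id=0),
                hit("chr1", 400, 8000, "CERV2-int", hit_id=1),
                hit("chr1", 8000, 8400, "CERV2_LTR", hit_id=2)]
        loci, _ = defragment(hits, max_gap_bp=500)
        assert loci[0].category == "unknown"

    def test_unknown_name_ignored_with_warning(self, caplog):
        hits = [hit("chr1", 0, 400, "CERV1_LTR", hit_id=0),
                hit("chr1", 5000, 5400, "MysteryRepeat", hit_id=1)]
        loci, ignored = defragment(hits, max_gap_bp=500)
        assert ignored == [1]
        assert len(loci) == 1

    def test_no_hit_lost(self):
        hits = [hit("chr1", i * 2000, i * 2000 + 400, "CERV1_LTR", hit_id=i)
                for i in range(10)]
        hits.append(hit("chr1", 100, 300, "CERV1_LTR", hit_id=10))  # nested
        loci, ignored = defragment(hits, max_gap_bp=500)
        seen = sorted(sum((l.member_hit_ids for l in loci), []) + ignored)
        assert seen == sorted(h.hit_id for h in hits)

    def test_idempotent_at_locus_level(self):
        hits = [hit("chr1", 0, 400, "CERV1_LTR", hit_id=0),
                hit("chr1", 450, 4000, "CERV1-int", hit_id=1),
                hit("chr1", 4020, 8000, "CERV1-int", hit_id=2),
                hit("chr1", 8100, 8500, "CERV1_LTR", hit_id=3)]
        loci, _ = defragment(hits, max_gap_bp=500)
        # re-present each locus as merged fragments and defragment again
        rehits = []
        for i, l in enumerate(loci):
            if l.ltr5_span:
                rehits.append(hit(l.chrom, *l.ltr5_span, f"{l.subfamily}_LTR",
                                  l.strand, len(rehits)))
            for span in l.internal_spans:
                rehits.append(hit(l.chrom, *span, f"{l.subfamily}-int",
                                  l.strand, len(rehits)))
            if l.ltr3_span:
                rehits.append(hit(l.chrom, *l.ltr3_span, f"{l.subfamily}_LTR",
                                  l.strand, len(rehits)))
        again, _ = defragment(rehits, max_gap_bp=500)
        assert [(l.span, l.category) for l in again] == \
            [(l.span, l.category) for l in loci]


class TestCatalogSummary:
    def make_loci(self, counts, subfamilies=None):
        from ervscan.catalog import ErvLocus
        loci = []
        i = 0
        for category, n in counts.items():
            for _ in range(n):
                sub = None
                if subfamilies:
                    sub = subfamilies[i % len(subfamilies)]
                loci.append(ErvLocus(
                    locus_id=f"l{i}", chrom="chr1", start=i * 10_000,
                    end=i * 10_000 + 400, strand="+", category=category,
                    ltr5_span=None, ltr3_span=None, internal_spans=[],
                    subfamily=sub, member_hit_ids=[i]))
                i += 1
        return loci

    def test_four_category_counts_sum_to_total(self):
        loci = self.make_loci({"full_length": 121, "solo_ltr": 110,
                               "truncated": 22, "unknown": 3})
        summary = catalog_summary(loci)
        assert summary["by_category"] == {"full_length": 121, "solo_ltr": 110,
                                          "truncated": 22, "unknown": 3}
        assert summary["total"] == 256

    def test_empty_input_all_zeros(self):
        summary = catalog_summary([])
        assert summary["total"] == 0
        assert all(v == 0 for v in summary["by_category"].values())

    def test_family_member_totals(self):
        loci = (self.make_loci({"full_length": 83}, ["CERV1"])
                + self.make_loci({"full_length": 124}, ["PtERV-1c"]))
        summary = catalog_summary(loci)
        assert summary["by_subfamily"]["CERV1"] \
            + summary["by_subfamily"]["PtERV-1c"] == 207
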