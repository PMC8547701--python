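"""Annotation parsing, nesting resolution, autonomy and family summaries."""

import numpy as np
import pandas as pd
import pytest

from te_ecology.annotation import (
    AnnotationError,
    TECopy,
    classify_autonomy,
    family_summary,
    read_te_gff,
    resolve_nesting,
)
from te_ecology.taxonomy import TaxonomyError


def _copy(cid, start, end, parent=None, fam="RLG00001", sf="RLG", chrom="chr1"):
    return TECopy(copy_id=cid, family_id=fam, superfamily=sf, chrom=chrom,
                  start=start, end=end, parent_te=parent)


class TestReadGFF:
    def test_coordinates_converted_to_half_open(self, tmp_path):
        gff = tmp_path / "te.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\ttransposable_element\t101\t200\t.\t+\t.\t"
            "ID=te1;family=RLG00003;superfamily=RLG\n"
        )
        (c,) = read_te_gff(gff)
        assert (c.start, c.end) == (100, 200)
        assert c.end - c.start == 100

    def test_family_prefix_gives_taxonomy(self, tmp_path):
        gff = tmp_path / "te.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\ttransposable_element\t1\t100\t.\t+\t.\t"
            "ID=te1;family=RLG00003;superfamily=RLG\n"
        )
        (c,) = read_te_gff(gff)
        assert (c.superfamily, c.order, c.te_class) == ("RLG", "LTR", "I")

    def test_superfamily_mismatch_rejected(self, tmp_path):
        gff = tmp_path / "te.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\ttransposable_element\t1\t100\t.\t+\t.\t"
            "ID=te1;family=DTM99999;superfamily=RLC\n"
        )
        with pytest.raises(AnnotationError, match="prefix"):
            read_te_gff(gff)

    def test_missing_attribute_reports_line(self, tmp_path):
        gff = tmp_path / "te.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\ttransposable_element\t1\t100\t.\t+\t.\tID=te1;family=RLG00001\n"
        )
        with pytest.raises(AnnotationError, match="superfamily"):
            read_te_gff(gff)


class TestResolveNesting:
    def test_single_nesting(self):
        a = _copy("A", 0, 10_000)
        b = _copy("B", 4000, 5000, parent="A", fam="DTA00002", sf="DTA")
        r = resolve_nesting([a, b])
        assert r.surviving_bp["A"] == 9000
        assert r.segments["A"] == [(0, 4000), (5000, 10_000)]
        assert r.disrupted["A"] and not r.disrupted["B"]
        assert r.within_te["B"] and not r.within_te["A"]
        assert r.surviving_bp["B"] == 1000

    def test_host_below_50bp_dropped(self):
        a = _copy("A", 0, 100)
        b = _copy("B", 10, 80, parent="A", fam="DTA00002", sf="DTA")
        r = resolve_nesting([a, b])
        assert r.surviving_bp["A"] == 30
        assert r.dropped["A"] and not r.dropped["B"]
        assert "A" not in r.kept_ids()

    def test_three_level_chain_ownership(self):
        a = _copy("A", 0, 1000)
        b = _copy("B", 100, 900, parent="A", fam="DTA00002", sf="DTA")
        c = _copy("C", 200, 300, parent="B", fam="DTT00003", sf="DTT")
        r = resolve_nesting([a, b, c])

        def owner_of(base):
            for cid, segs in r.segments.items():
                if any(s <= base < e for s, e in segs):
                    return cid

        assert owner_of(250) == "C"
        assert owner_of(150) == "B"
        assert owner_of(50) == "A"

    def test_idempotent_without_nesting(self):
        copies = [_copy("A", 0, 500), _copy("B", 1000, 1800)]
        r = resolve_nesting(copies)
        for cid in ("A", "B"):
            assert r.segments[cid] == [(r.copies[cid].start, r.copies[cid].end)]
            assert r.surviving_bp[cid] == r.span_bp[cid]
            assert not r.disrupted[cid]

    def test_child_outside_parent_rejected(self):
        a = _copy("A", 0, 1000)
        b = _copy("B", 900, 1200, parent="A", fam="DTA00002", sf="DTA")
        with pytest.raises(AnnotationError, match="contained"):
            resolve_nesting([a, b])

    def test_cyclic_links_rejected(self):
        a = _copy("A", 0, 1000, parent="B")
        b = _copy("B", 100, 900, parent="A", fam="DTA00002", sf="DTA")
        with pytest.raises(AnnotationError):
            resolve_nesting([a, b])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_base_sweep_oracle(self, seed, annotation_factory, ownership_oracle):
        rng = np.random.default_rng(seed)
        copies = annotation_factory(rng, genome_len=30_000, n_copies=25)
        expected = ownership_oracle(copies, genome_len=30_000)
        r = resolve_nesting(copies)
        for cid in expected:
            assert r.segments[cid] == expected[cid]
        # conservation: all owned bp equals union coverage of the annotation
        total = sum(r.surviving_bp.values())
        arr = np.zeros(30_000, dtype=bool)
        for c in copies:
            arr[c.start : c.end] = True
        assert total == int(arr.sum())


class TestAutonomy:
    def _domains(self, rows):
        return pd.DataFrame(rows, columns=["copy_id", "domain"])

    def test_ltr_with_all_five_is_autonomous(self):
        c = _copy("A", 0, 5000)
        hits = self._domains([("A", d) for d in ("GAG", "AP", "RT", "RNaseH", "INT")])
        (call,) = classify_autonomy([c], hits)
        assert call.status == "autonomous_coding"
        assert call.family_has_coding_member

    def test_gag_only_is_partial(self):
        c = _copy("A", 0, 5000)
        (call,) = classify_autonomy([c], self._domains([("A", "GAG")]))
        assert (call.status, call.detail) == ("partial_coding", "GAG_only")

    def test_pol_only_is_partial(self):
        c = _copy("A", 0, 5000)
        hits = self._domains([("A", d) for d in ("AP", "RT", "RNaseH", "INT")])
        (call,) = classify_autonomy([c], hits)
        assert (call.status, call.detail) == ("partial_coding", "POL_only")

    def test_tir_transposase_is_autonomous(self):
        c = _copy("A", 0, 800, fam="DTT00001", sf="DTT")
        (call,) = classify_autonomy([c], self._domains([("A", "TPase")]))
        assert call.status == "autonomous_coding"

    def test_unknown_domain_rejected(self):
        c = _copy("A", 0, 800)
        with pytest.raises(AnnotationError, match="unknown"):
            classify_autonomy([c], self._domains([("A", "KRAB")]))

    def test_family_coding_flag_shared_across_members(self):
        a = _copy("A", 0, 5000)
        b = _copy("B", 6000, 11_000)
        hits = self._domains([("A", d) for d in ("GAG", "AP", "RT", "RNaseH", "INT")])
        calls = {c.copy_id: c for c in classify_autonomy([a, b], hits)}
        assert calls["B"].status == "noncoding"
        assert calls["B"].family_has_coding_member


class TestFamilySummary:
    def test_single_intact_copy(self):
        r = resolve_nesting([_copy("A", 0, 500)])
        df = family_summary(r, {"A": 1e4})
        row = df.iloc[0]
        assert row["copy_number"] == 1 and row["prop_intact"] == 1.0

    def test_activity_flag_and_bins(self):
        r = resolve_nesting([_copy("A", 0, 500), _copy("B", 1000, 1500)])
        df = family_summary(r, {"A": 50e3, "B": 2e5})
        row = df.iloc[0]
        assert row["active_last_100ky"]
        hist = row["age_hist_10ky"]
        assert hist[5] == 1 and hist[20] == 1 and sum(hist) == 2

    def test_reporting_filter_uses_strictly_more_than_threshold(self):
        copies = [_copy(f"A{i}", i * 1000, i * 1000 + 500) for i in range(10)]
        r = resolve_nesting(copies)
        df = family_summary(r, {c.copy_id: 1e5 for c in copies},
                            min_copies_for_reporting=10)
        assert not df.iloc[0]["reporting"]  # exactly 10 copies is excluded

    @pytest.mark.parametrize("seed", range(5))
    def test_medians_match_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        copies = [_copy(f"A{i}", i * 5000, i * 5000 + int(rng.integers(100, 2000)))
                  for i in range(n)]
        ages = {c.copy_id: float(rng.uniform(0, 1e6)) for c in copies}
        r = resolve_nesting(copies)
        df = family_summary(r, ages)
        assert df.iloc[0]["median_age_years"] == pytest.approx(
            float(np.sort(list(ages.values()))[n // 2]) if n % 2
            else float(np.mean(np.sort(list(ages.values()))[n // 2 - 1 : n // 2 + 1]))
        )
        assert df.iloc[0]["median_length_bp"] == pytest.approx(
            float(np.median([c.end - c.start for c in copies]))
        )


def test_invalid_interval_rejected():
    with pytest.raises(AnnotationError):
        _copy("A", 100, 100)


def test_malformed_family_id_rejected():
    with pytest.raises(TaxonomyError):
        TECopy(copy_id="A", family_id="XXX123", superfamily="RLG",
               chrom="chr1", start=0, end=10)
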