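"""Annotation: frame choice, region segmentation, binning, span extraction."""

import random

import pytest

from vdjwell.annotate import (
    AnnotatedChain,
    MotifBackend,
    TableBackend,
    annotate,
    annotate_nt,
    asv_support_filter,
    bin_by_aa,
    extract_reported_nt,
    filter_zero_length_regions,
    get_backend,
    translate_best_frame,
)
from vdjwell.chains import REGION_NAMES
from vdjwell.denoise import Asv
from vdjwell.sim import generate_clone


@pytest.fixture(scope="module")
def clone():
    return generate_clone(seed=42)


@pytest.fixture(scope="module")
def table_backend(clone):
    return TableBackend.from_clones([clone])


class TestTranslateBestFrame:
    def test_clean_orf_in_frame_zero(self, clone):
        aa, frame = translate_best_frame(clone.heavy.insert_nt)
        assert frame == 0
        assert clone.heavy.domain_aa in aa

    def test_shifted_copy_lands_in_frame_one(self, clone):
        aa, frame = translate_best_frame("G" + clone.heavy.insert_nt)
        assert frame == 1
        assert clone.heavy.domain_aa in aa

    def test_all_frames_with_stops_returns_none(self):
        # stops planted every 31 nt cycle through all three frames, so no
        # frame offers a domain-sized stop-free stretch
        nt = list("G" * 400)
        for k in range(0, 397, 31):
            nt[k : k + 3] = "TAA"
        assert translate_best_frame("".join(nt)) is None


class TestBackends:
    def test_table_backend_recovers_truth_regions(self, clone, table_backend):
        ann = annotate_nt(clone.vh_nt, table_backend, "VH")
        assert ann is not None
        assert ann.regions == clone.vh_regions

    def test_table_backend_places_domain_within_insert(self, clone, table_backend):
        ann = annotate_nt(clone.heavy.insert_nt, table_backend, "VH")
        assert ann.domain_start == 10  # 10 aa pad precedes the domain
        assert ann.domain_aa == clone.heavy.domain_aa

    def test_motif_backend_rejects_random_protein(self):
        rng = random.Random(7)
        junk = "".join(rng.choice("ADEGHIKLNPQRSTV") for _ in range(130))  # no C/W/F anchors
        assert MotifBackend().segment(junk, "VH") is None

    def test_motif_backend_segments_simulated_chain(self, clone):
        ann = annotate_nt(clone.heavy.insert_nt, MotifBackend(), "VH")
        assert ann is not None
        assert ann.regions == clone.vh_regions

    def test_tcr_beta_chain_annotated_via_table(self):
        tcr = generate_clone(seed=8, chain_classes=("alpha", "beta"))
        backend = TableBackend.from_clones([tcr])
        ann = annotate_nt(tcr.heavy.insert_nt, backend, "beta")
        assert ann is not None
        assert ann.chain_class == "beta"

    def test_unknown_backend_name_is_hard_error(self):
        with pytest.raises(KeyError, match="unknown annotation backend"):
            get_backend("hmm-numbering")


class TestRegionFilter:
    def test_all_regions_present_kept(self, clone, table_backend):
        ann = annotate_nt(clone.vl_nt, table_backend, "VL")
        assert filter_zero_length_regions(ann)

    @pytest.mark.parametrize("empty_region", ["CDR2", "FR4"])
    def test_zero_length_region_discarded(self, clone, empty_region):
        regions = dict(clone.vh_regions)
        regions[empty_region] = ""
        domain = "".join(regions[r] for r in REGION_NAMES)
        ann = AnnotatedChain(aa_seq=domain, chain_class="VH", regions=regions)
        assert not filter_zero_length_regions(ann)

    def test_reannotation_of_kept_chain_is_idempotent(self, clone, table_backend):
        ann = annotate_nt(clone.vh_nt, table_backend, "VH")
        assert filter_zero_length_regions(ann)
        again = annotate(ann.aa_seq, table_backend, "VH", nt=ann.nt_full, frame=ann.frame)
        assert again.regions == ann.regions


def _ann_for(asv, clone, chain_class, backend):
    return annotate_nt(asv.seq, backend, chain_class)


class TestBinning:
    def test_trailing_nt_difference_collapses_to_one_bin(self, clone, table_backend):
        nt = clone.heavy.insert_nt
        variant = nt[:-3]  # differs only 3' of FR4
        a1 = Asv(seq=nt, count=60, support_fraction=0.6)
        a2 = Asv(seq=variant, count=40, support_fraction=0.4)
        pairs = [(a, annotate_nt(a.seq, table_backend, "VH")) for a in (a1, a2)]
        bins = bin_by_aa(pairs)
        assert len(bins) == 1
        assert bins[0].total_count == 100
        assert bins[0].representative_nt == nt  # most abundant member

    def test_different_cdr3_aa_stay_in_two_bins(self, table_backend):
        c1, c2 = generate_clone(seed=1), generate_clone(seed=2)
        backend = TableBackend.from_clones([c1, c2])
        pairs = []
        for c in (c1, c2):
            a = Asv(seq=c.vh_nt, count=10)
            pairs.append((a, annotate_nt(a.seq, backend, "VH")))
        assert len(bin_by_aa(pairs)) == 2

    def test_single_asv_single_bin(self, clone, table_backend):
        a = Asv(seq=clone.vh_nt, count=7)
        bins = bin_by_aa([(a, annotate_nt(a.seq, table_backend, "VH"))])
        assert len(bins) == 1
        assert bins[0].total_count == 7

    def test_binning_conserves_reads(self, clone, table_backend):
        nt = clone.heavy.insert_nt
        asvs = [Asv(seq=nt, count=50), Asv(seq=nt[:-3], count=30), Asv(seq=nt[:-6], count=20)]
        pairs = [(a, annotate_nt(a.seq, table_backend, "VH")) for a in asvs]
        bins = bin_by_aa(pairs)
        assert sum(b.total_count for b in bins) == 100


class TestSupportFilter:
    def test_ten_percent_minimum(self):
        def mkbin(count):
            a = Asv(seq="A" * 30, count=count)
            ann = AnnotatedChain(
                aa_seq="X", chain_class="VH", regions={r: "X" if r == "FR1" else "" for r in REGION_NAMES}
            )
            b = bin_by_aa([(a, ann)])[0]
            return b

        bins = [mkbin(60), mkbin(30), mkbin(8)]
        kept = asv_support_filter(bins, well_chain_total=100, min_support=0.10)
        assert len(kept) == 2

    def test_exactly_at_threshold_is_retained(self):
        a = Asv(seq="A" * 30, count=10)
        ann = AnnotatedChain(aa_seq="X", chain_class="VH", regions={r: "X" if r == "FR1" else "" for r in REGION_NAMES})
        (b,) = bin_by_aa([(a, ann)])
        assert asv_support_filter([b], well_chain_total=100) == [b]
        assert asv_support_filter([b], well_chain_total=101) == []

    def test_single_full_support_bin_retained(self):
        a = Asv(seq="A" * 30, count=55)
        ann = AnnotatedChain(aa_seq="X", chain_class="VH", regions={r: "X" if r == "FR1" else "" for r in REGION_NAMES})
        (b,) = bin_by_aa([(a, ann)])
        assert asv_support_filter([b], well_chain_total=55) == [b]


class TestReportedSpan:
    def test_light_chain_spans_imgt_1_to_127(self):
        clone = generate_clone(seed=5, cdr3_len={"VL": 21, "VH": 22})
        backend = TableBackend.from_clones([clone])
        ann = annotate_nt(clone.light.insert_nt, backend, "VL")
        assert len(ann.domain_aa) == 127
        assert len(extract_reported_nt(ann)) == 127 * 3

    def test_heavy_chain_spans_imgt_1_to_128(self):
        clone = generate_clone(seed=5, cdr3_len={"VL": 21, "VH": 22})
        backend = TableBackend.from_clones([clone])
        ann = annotate_nt(clone.heavy.insert_nt, backend, "VH")
        assert len(ann.domain_aa) == 128
        assert len(extract_reported_nt(ann)) == 128 * 3

    def test_long_domains_are_clipped_never_padded(self):
        clone = generate_clone(seed=6, cdr3_len={"VH": 25})
        backend = TableBackend.from_clones([clone])
        ann = annotate_nt(clone.heavy.insert_nt, backend, "VH")
        assert len(ann.domain_aa) == 131
        assert len(extract_reported_nt(ann)) == 128 * 3

    def test_truncated_leading_positions_narrow_the_span(self, clone, table_backend):
        ann = annotate_nt(clone.heavy.insert_nt, table_backend, "VH")
        shifted = AnnotatedChain(
            aa_seq=ann.aa_seq,
            chain_class=ann.chain_class,
            regions=ann.regions,
            frame=ann.frame,
            nt_full=ann.nt_full,
            domain_start=ann.domain_start,
            imgt_start=3,
        )
        full = extract_reported_nt(ann)
        narrowed = extract_reported_nt(shifted)
        assert len(narrowed) == len(full) - 2 * 3 if len(ann.domain_aa) >= 128 else True
        assert len(narrowed) == 3 * min(128 - 3 + 1, len(ann.domain_aa))

    def test_reported_nt_translates_back_to_domain_prefix(self, clone, table_backend):
        from vdjwell.sequtil import translate_nt

        ann = annotate_nt(clone.heavy.insert_nt, table_backend, "VH")
        nt = extract_reported_nt(ann)
        assert translate_nt(nt) == ann.domain_aa[: len(nt) // 3]
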