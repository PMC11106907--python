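import numpy as np
import pytest

from isoforge.splice_events import (
    EventType,
    classify_event,
    enumerate_locus_events,
    variant_regions,
)

from conftest import make_model
from oracles import oracle_event_type, oracle_variant_windows


def one_region(a, b):
    regions = variant_regions(a, b)
    assert len(regions) == 1
    return regions[0]


class TestVariantRegions:
    def test_identical_chains_give_no_regions(self):
        a = make_model([(0, 100), (200, 300)], transcript_id="a")
        b = make_model([(10, 100), (200, 290)], transcript_id="b")
        assert variant_regions(a, b) == []

    def test_skipped_exon_region_flanked_by_shared_sites(self):
        # a junctions {(200,300),(500,600)}, b junctions {(200,600)}
        a = make_model([(100, 200), (300, 500), (600, 700)], transcript_id="a")
        b = make_model([(100, 200), (600, 700)], transcript_id="b")
        region = one_region(a, b)
        assert (region.flank_left, region.flank_right) == (200, 600)

    def test_non_overlapping_spans_give_empty_list(self):
        a = make_model([(0, 100), (200, 300)], transcript_id="a")
        b = make_model([(1000, 1100), (1200, 1300)], transcript_id="b")
        assert variant_regions(a, b) == []

    def test_transcript_end_differences_are_not_regions(self):
        # same chain, different start/end exons only
        a = make_model([(0, 100), (200, 300), (400, 500)], transcript_id="a")
        b = make_model([(50, 100), (200, 300), (400, 450)], transcript_id="b")
        assert variant_regions(a, b) == []


def _pad(exons):
    """Surround a variant window with shared flanking exons."""
    return exons


class TestClassifyEvent:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exon_skipping(self, strand):
        a = make_model([(0, 100), (300, 400), (500, 600), (700, 800)], strand=strand, transcript_id="a")
        b = make_model([(0, 100), (500, 600), (700, 800)], strand=strand, transcript_id="b")
        # ES window is (100, 500): b's junctions (100,500) and (600,700) keep
        # flanks 100/500 shared; a carries internal exon (300,400)
        a = make_model([(0, 100), (300, 400), (500, 800)], strand=strand, transcript_id="a")
        b = make_model([(0, 100), (500, 800)], strand=strand, transcript_id="b")
        region = one_region(a, b)
        assert classify_event(region, strand) is EventType.ES

    def test_alt_acceptor_on_plus(self):
        a = make_model([(0, 200), (300, 500), (700, 800)], transcript_id="a")
        b = make_model([(0, 200), (320, 500), (700, 800)], transcript_id="b")
        region = one_region(a, b)
        assert classify_event(region, "+") is EventType.ALT_ACCEPTOR

    def test_alt_donor_on_plus(self):
        # the shifted donor needs an upstream shared junction to bound it
        a = make_model([(0, 50), (100, 200), (300, 500)], transcript_id="a")
        b = make_model([(0, 50), (100, 180), (300, 500)], transcript_id="b")
        region = one_region(a, b)
        assert classify_event(region, "+") is EventType.ALT_DONOR

    def test_strand_flips_donor_acceptor_roles(self):
        a = make_model([(0, 200), (300, 500), (700, 800)], strand="-", transcript_id="a")
        b = make_model([(0, 200), (320, 500), (700, 800)], strand="-", transcript_id="b")
        region = one_region(a, b)
        assert classify_event(region, "-") is EventType.ALT_DONOR

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_intron_retention(self, strand):
        a = make_model(
            [(0, 50), (100, 200), (300, 400), (450, 500)], strand=strand, transcript_id="a"
        )
        b = make_model([(0, 50), (100, 400), (450, 500)], strand=strand, transcript_id="b")
        region = one_region(a, b)
        assert (region.flank_left, region.flank_right) == (100, 400)
        assert classify_event(region, strand) is EventType.INTRON_RETENTION

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_mutually_exclusive_exons(self, strand):
        a = make_model([(0, 100), (300, 400), (600, 700)], strand=strand, transcript_id="a")
        b = make_model([(0, 100), (450, 550), (600, 700)], strand=strand, transcript_id="b")
        region = one_region(a, b)
        assert classify_event(region, strand) is EventType.MXE

    def test_complex_window_is_other(self):
        # donor shift plus skipped exons in one window
        a = make_model(
            [(0, 50), (100, 200), (300, 400), (500, 600), (700, 800)],
            transcript_id="a",
        )
        b = make_model([(0, 50), (100, 180), (700, 800)], transcript_id="b")
        region = one_region(a, b)
        assert classify_event(region, "+") is EventType.OTHER


class TestSymmetryAndStrand:
    def _aa_pair(self, strand="+"):
        a = make_model([(0, 200), (300, 500), (700, 800)], strand=strand, transcript_id="a")
        b = make_model([(0, 200), (320, 500), (700, 800)], strand=strand, transcript_id="b")
        return a, b

    def test_classification_symmetric_under_pair_swap(self):
        a, b = self._aa_pair()
        ra = one_region(a, b)
        rb = one_region(b, a)
        assert classify_event(ra, "+") is classify_event(rb, "+")
        assert {ra.structure_a, ra.structure_b} == {rb.structure_a, rb.structure_b}

    def _mirror(self, model, c=10_000):
        flipped = "-" if model.strand == "+" else "+"
        exons = tuple(sorted((c - e, c - s) for s, e in model.exons))
        return make_model(exons, strand=flipped, transcript_id=model.transcript_id)

    def test_strand_flip_alone_swaps_donor_acceptor(self):
        a, b = self._aa_pair("+")
        am, bm = self._aa_pair("-")
        assert classify_event(one_region(a, b), "+") is EventType.ALT_ACCEPTOR
        assert classify_event(one_region(am, bm), "-") is EventType.ALT_DONOR

    def test_reverse_complement_view_preserves_event_types(self):
        # mirroring coordinates AND flipping strand is the same molecule
        cases = []
        a, b = self._aa_pair()
        cases.append((a, b))
        cases.append(
            (
                make_model([(0, 100), (300, 400), (500, 800)], transcript_id="a"),
                make_model([(0, 100), (500, 800)], transcript_id="b"),
            )
        )
        for a, b in cases:
            t_fwd = classify_event(one_region(a, b), a.strand)
            ma, mb = self._mirror(a), self._mirror(b)
            t_rc = classify_event(one_region(ma, mb), ma.strand)
            assert t_fwd is t_rc


class TestEnumerateLocusEvents:
    def test_two_isoforms_one_skipping_event(self):
        a = make_model([(0, 100), (300, 400), (500, 800)], transcript_id="a")
        b = make_model([(0, 100), (500, 800)], transcript_id="b")
        events = enumerate_locus_events([a, b], "L1")
        assert len(events) == 1 and events[0].type is EventType.ES

    def test_shared_region_deduplicates_across_pairs(self):
        a = make_model([(0, 100), (300, 400), (500, 800)], transcript_id="a")
        b = make_model([(0, 100), (500, 800)], transcript_id="b")
        c = make_model([(0, 100), (500, 790)], transcript_id="c")  # b-like chain, new end
        events = enumerate_locus_events([a, b, c], "L1")
        assert len(events) == 1

    def test_pair_unit_keeps_each_realizing_pair(self):
        a = make_model([(0, 100), (300, 400), (500, 800)], transcript_id="a")
        b = make_model([(0, 100), (500, 800)], transcript_id="b")
        c = make_model([(0, 100), (500, 790)], transcript_id="c")
        events = enumerate_locus_events([a, b, c], "L1", count_unit="pair")
        assert len(events) == 2

    def test_fewer_than_two_isoforms_gives_no_events(self):
        a = make_model([(0, 100), (300, 400)], transcript_id="a")
        assert enumerate_locus_events([a], "L1") == []


def random_exon_chain(rng, n_max=7):
    """Exon chains on a coarse 50-nt grid so shared sites are common."""
    n = int(rng.integers(3, n_max + 1))
    exons = []
    pos = int(rng.integers(0, 3)) * 50
    for _ in range(n):
        elen = int(rng.integers(1, 4)) * 50
        exons.append((pos, pos + elen))
        pos += elen + int(rng.integers(1, 4)) * 50
    return exons


def perturb_chain(exons, rng, n_edits):
    """Random local edits (exon drop, boundary shift, intron retention,
    exon replacement) that keep the rest of the chain shared."""
    ex = [list(e) for e in exons]
    for _ in range(n_edits):
        if len(ex) < 3:
            break
        op = int(rng.integers(0, 5))
        i = int(rng.integers(1, len(ex) - 1))
        if op == 0:
            del ex[i]
        elif op == 1 and ex[i][1] - ex[i][0] > 50:
            ex[i][0] += 50  # shift genomic-left edge
        elif op == 2 and ex[i][1] - ex[i][0] > 50:
            ex[i][1] -= 50  # shift genomic-right edge
        elif op == 3:
            ex[i - 1][1] = ex[i][1]  # retain the intron before exon i
            del ex[i]
        elif op == 4 and ex[i + 1][0] - ex[i][1] > 100:
            ex[i] = [ex[i][1] + 50, min(ex[i][1] + 100, ex[i + 1][0] - 1)]
    out = [tuple(e) for e in ex]
    prev = None
    for s, e in out:
        if e <= s or (prev is not None and s <= prev):
            return None
        prev = e
    return out


class TestOracleAgreement:
    def test_types_match_segment_oracle_on_randomized_pairs(self):
        rng = np.random.default_rng(42)
        checked = 0
        for trial in range(800):
            strand = "+" if trial % 2 == 0 else "-"
            base = random_exon_chain(rng)
            other = perturb_chain(base, rng, int(rng.integers(1, 4)))
            if other is None:
                other = random_exon_chain(rng)
            a = make_model(base, strand=strand, transcript_id="a")
            b = make_model(other, strand=strand, transcript_id="b")
            if min(a.end, b.end) <= max(a.start, b.start):
                continue
            regions = variant_regions(a, b)
            windows = oracle_variant_windows(a, b)
            assert [(r.flank_left, r.flank_right) for r in regions] == windows
            for r in regions:
                got = classify_event(r, strand).value
                want = oracle_event_type(a, b, r.flank_left, r.flank_right, strand)
                assert got == want, (a.exons, b.exons, strand, r)
                checked += 1
        assert checked > 300
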