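import numpy as np
import pytest

from cslkit import csl_design as cd
from cslkit.seqcore import Interval, Sequence, longest_shared_substring, read_fasta, reverse_complement
from conftest import brute_force_lss


def random_target(seed, n, tid="TX"):
    rng = np.random.default_rng(seed)
    return Sequence(tid, "".join(rng.choice(list("ACGT"), size=n)))


class TestTileRegion:
    @pytest.mark.parametrize(
        "region_len,expected_tiles",
        [(76, 2), (38, 1), (100, 2), (760, 20), (37 + 38, 1)],
    )
    def test_tile_count_is_floor_of_region_over_binding_len(
        self, params, region_len, expected_tiles
    ):
        target = random_target(0, 800)
        tiles = cd.tile_region(target, Interval("TX", 0, region_len), params)
        assert len(tiles) == expected_tiles

    def test_alternation_and_contiguity(self, params):
        target = random_target(1, 200)
        tiles = cd.tile_region(target, Interval("TX", 10, 10 + 4 * 38), params)
        strands = [s for _, s in tiles]
        assert strands == ["sense", "antisense", "sense", "antisense"]
        for (iv1, _), (iv2, _) in zip(tiles, tiles[1:]):
            assert iv2.start == iv1.end  # contiguous, non-overlapping
        assert tiles[0][0].start == 10
        assert all(len(iv) == 38 for iv, _ in tiles)

    def test_alternate_off_keeps_start_strand(self, adapter):
        p = cd.DesignParams(adapter_seq=adapter, alternate=False, start_strand="antisense")
        tiles = cd.tile_region(random_target(2, 200), Interval("TX", 0, 190), p)
        assert {s for _, s in tiles} == {"antisense"}

    def test_region_shorter_than_binding_len_errors(self, params):
        with pytest.raises(cd.DesignError):
            cd.tile_region(random_target(3, 100), Interval("TX", 0, 37), params)

    def test_region_beyond_target_errors(self, params):
        with pytest.raises(cd.DesignError):
            cd.tile_region(random_target(4, 50), Interval("TX", 0, 100), params)


class TestBuildCatcher:
    def test_sense_bound_catcher_carries_reverse_complement(self, params):
        target = Sequence("TX", "A" * 38 + "GATTACA")
        catcher = cd.build_catcher(target, (Interval("TX", 0, 38), "sense"), params)
        assert catcher.binding_site.bases == "T" * 38

    def test_antisense_bound_catcher_carries_sense_segment(self, params):
        target = random_target(5, 80)
        iv = Interval("TX", 10, 48)
        catcher = cd.build_catcher(target, (iv, "antisense"), params)
        assert catcher.binding_site.bases == target.bases[10:48]

    def test_full_sequence_is_domain_concatenation(self, params):
        target = random_target(6, 80)
        c = cd.build_catcher(target, (Interval("TX", 0, 38), "sense"), params)
        assert c.full_sequence.bases == (
            c.release_site.bases + c.binding_site.bases + c.adapter.bases
        )
        assert len(c.full_sequence) == 10 + 38 + 22

    def test_release_len_zero_gives_60nt_probe(self, adapter):
        p = cd.DesignParams(adapter_seq=adapter, release_len=0)
        c = cd.build_catcher(random_target(7, 60), (Interval("TX", 0, 38), "sense"), p)
        assert c.release_site is None
        assert len(c.full_sequence) == 38 + 22 == 60

    def test_missing_adapter_errors(self):
        p = cd.DesignParams(adapter_seq=None)
        with pytest.raises(cd.DesignError):
            cd.build_catcher(random_target(8, 60), (Interval("TX", 0, 38), "sense"), p)

    def test_release_site_avoids_target_complementarity(self, params):
        target = random_target(9, 2000)
        c = cd.build_catcher(target, (Interval("TX", 0, 38), "sense"), params)
        m = longest_shared_substring(c.release_site, target, both_strands=True)
        # threshold relaxes deterministically but stays far below the toehold length
        assert m.length <= 7


class TestReleaseStrand:
    def test_sequence_is_revcomp_of_release_plus_binding(self):
        catcher = cd.CatcherStrand(
            name="c1",
            target_interval=Interval("TX", 0, 38),
            bound_strand="sense",
            binding_site=Sequence("b", "G" * 38),
            adapter=Sequence("a", "A" * 22),
            release_site=Sequence("r", "A" * 10),
        )
        rs = cd.design_release_strand(catcher)
        assert rs.sequence.bases == "C" * 38 + "T" * 10
        assert len(rs.sequence) == 48

    def test_base_by_base_complementarity_to_catcher_5prime(self, three_target_csl):
        csl, _ = three_target_csl
        for catcher in csl:
            rs = cd.design_release_strand(catcher)
            duplex = catcher.full_sequence.bases[: len(rs.sequence)]
            assert reverse_complement(rs.sequence.bases) == duplex

    def test_catcher_without_release_site_errors(self, adapter):
        p = cd.DesignParams(adapter_seq=adapter, release_len=0)
        c = cd.build_catcher(random_target(10, 60), (Interval("TX", 0, 38), "sense"), p)
        with pytest.raises(cd.DenaturationOnlyError):
            cd.design_release_strand(c)


class TestDesignCsl:
    def test_full_length_760nt_target_yields_20_alternating_catchers(self, params):
        target = random_target(11, 760)
        csl = cd.design_csl([target], None, params)
        assert len(csl) == 20
        strands = [c.bound_strand for c in csl]
        assert strands == ["sense", "antisense"] * 10
        assert len({c.binding_site.bases for c in csl}) == 20

    def test_empty_region_set_gives_empty_library(self, params):
        csl = cd.design_csl([random_target(12, 500)], [], params)
        assert len(csl) == 0

    def test_identical_targets_raise_uniqueness_error(self, params):
        t1 = random_target(13, 200)
        t2 = Sequence("TX2", t1.bases)
        with pytest.raises(cd.UniquenessError) as exc:
            cd.design_csl([t1, t2], None, params)
        assert exc.value.collisions

    def test_region_naming_unknown_target_errors(self, params):
        with pytest.raises(cd.DesignError):
            cd.design_csl([random_target(14, 200)], [Interval("NOPE", 0, 38)], params)

    def test_deterministic_byte_identical_order_sheets(self, params):
        target = random_target(15, 500)
        sheet1 = cd.order_sheet(cd.design_csl([target], None, params))
        sheet2 = cd.order_sheet(cd.design_csl([target], None, params))
        assert sheet1 == sheet2

    def test_every_binding_site_maps_to_its_own_design_locus(self, params):
        """With k = binding_len and self-exclusion off, each probe hits
        exactly its design interval on its own target."""
        target = random_target(16, 380)
        csl = cd.design_csl([target], None, params)
        hits = cd.screen_offtargets(csl, [target], k=38, exclude_designed=False)
        assert len(hits) == len(csl)
        by_name = {h.catcher_name: h for h in hits}
        for c in csl:
            h = by_name[c.name]
            assert h.transcript_interval.start == c.target_interval.start
            assert h.transcript_interval.end == c.target_interval.end


class TestOfftargetScreen:
    def test_embedded_segment_is_flagged(self, params):
        target = random_target(17, 400)
        segment = target.bases[114:152]  # second tile of the region below
        readthrough = Sequence("RT", random_target(18, 150).bases + segment + random_target(19, 150, "x").bases)
        csl = cd.design_csl([target], [Interval("TX", 76, 190)], params)
        hits = cd.screen_offtargets(csl, [readthrough, target], k=16)
        assert hits, "readthrough embedding a tiled segment must be flagged"
        assert all(h.transcript_id == "RT" for h in hits)  # own target excluded
        assert max(h.shared_len for h in hits) >= 38
        assert [h.shared_len for h in hits] == sorted(
            (h.shared_len for h in hits), reverse=True
        )

    def test_short_shared_stretch_below_k_not_flagged(self, params):
        target = random_target(20, 400)
        decoy = Sequence("DECOY", random_target(21, 100, "d").bases + target.bases[50:60])
        csl = cd.design_csl([target], [Interval("TX", 38, 114)], params)
        hits = [h for h in cd.screen_offtargets(csl, [decoy], k=16) if h.transcript_id == "DECOY"]
        assert hits == []

    def test_empty_library_gives_empty_hit_list(self, params):
        csl = cd.design_csl([random_target(22, 200)], [], params)
        assert cd.screen_offtargets(csl, [random_target(23, 200)], k=16) == []

    def test_k_below_8_rejected(self, three_target_csl):
        csl, _ = three_target_csl
        with pytest.raises(cd.DesignError):
            cd.screen_offtargets(csl, [], k=7)

    def test_shared_len_agrees_with_brute_force(self, params):
        target = random_target(24, 300)
        other = Sequence("OT", random_target(25, 80, "o").bases + target.bases[10:40])
        csl = cd.design_csl([target], [Interval("TX", 0, 76)], params)
        for h in cd.screen_offtargets(csl, [other], k=8):
            catcher = next(c for c in csl if c.name == h.catcher_name)
            exp = max(
                brute_force_lss(catcher.binding_site.bases, other.bases)[0],
                brute_force_lss(
                    catcher.binding_site.bases, reverse_complement(other.bases)
                )[0],
            )
            assert h.shared_len == exp


class TestOrderSheets:
    def test_two_catcher_sheet_has_header_and_two_rows(self, params):
        csl = cd.design_csl([random_target(26, 76)], None, params)
        lines = cd.order_sheet(csl).strip().splitlines()
        assert len(lines) == 3
        assert lines[0].startswith("name\ttarget")

    def test_round_trip_reproduces_all_sequences(self, params, tmp_path):
        csl = cd.design_csl([random_target(27, 300)], None, params)
        text = cd.order_sheet(csl)
        back = cd.read_order_sheet(text)
        assert [c.full_sequence.bases for c in back] == [
            c.full_sequence.bases for c in csl
        ]
        assert [c.release_site.bases for c in back] == [
            c.release_site.bases for c in csl
        ]

    def test_write_library_files(self, params, tmp_path):
        csl = cd.design_csl([random_target(28, 300)], None, params)
        written = cd.write_library(csl, tmp_path / "lib")
        assert len(written) == 4
        fasta = read_fasta(tmp_path / "lib.fasta")
        assert len(fasta) == len(csl)

    def test_release_sheet_without_release_sites_warns_and_is_empty(self, adapter):
        p = cd.DesignParams(adapter_seq=adapter, release_len=0)
        csl = cd.design_csl([random_target(29, 120)], None, p)
        with pytest.warns(UserWarning):
            sheet = cd.release_sheet(csl)
        assert sheet.strip().splitlines() == ["name\tcatcher_name\tsequence"]
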