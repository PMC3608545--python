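"""Minimal-exchange painting: observations, DP vs oracle, tie policies."""

import numpy as np
import pytest

from matpaint.locus import call_polymorphic_sites
from matpaint.painting import (
    ANCHOR_POS,
    PaintingError,
    PanelIndex,
    SomaticHaplotype,
    observe_sites,
    paint_minimal,
    select_painting,
)

from conftest import (
    make_panel,
    mosaic_haplotype,
    oracle_min_exchanges,
    pseudo_compat,
    random_haplotype,
    random_panel,
)


def paint(panel, hap):
    table = call_polymorphic_sites(panel)
    obs = observe_sites(hap, table, panel)
    return obs, paint_minimal(obs, hap.anchor_mt, panel, haplotype_id=hap.id)


class TestObserveSites:
    def test_consensus_haplotype_compatible_with_consensus_carriers(self, toy_panel):
        hap = SomaticHaplotype("h", toy_panel.consensus.sequence, "d1")
        table = call_polymorphic_sites(toy_panel)
        obs = observe_sites(hap, table, toy_panel)
        # at each site the consensus base is carried by the majority donors
        assert [sorted(o.compatible_donors) for o in obs] == [
            ["d2", "d3"], ["d1", "d2"], ["d1", "d3"],
        ]
        assert not any(o.is_novel for o in obs)

    def test_base_in_no_donor_is_novel(self, toy_panel):
        seq = list(toy_panel.consensus.sequence)
        seq[40] = "A"  # donors carry T,T,C there
        hap = SomaticHaplotype("h", "".join(seq), "d1")
        table = call_polymorphic_sites(toy_panel)
        obs = observe_sites(hap, table, toy_panel)
        assert obs[1].is_novel and obs[1].compatible_donors == frozenset()

    def test_truncated_donor_excluded_beyond_valid_range(self):
        # site at column 3; d2's homologous base matches observed but d2
        # ends at column 2 and must not appear in the compatible set
        panel = make_panel(
            [("d1", "AAAG", 4), ("d2", "AAAG", 2), ("d3", "AAAT", 4)],
            consensus="AAAG",
        )
        hap = SomaticHaplotype("h", "AAAG", "d1")
        table = call_polymorphic_sites(panel)
        assert table.positions == [3]
        obs = observe_sites(hap, table, panel)
        assert obs[0].compatible_donors == frozenset({"d1"})

    def test_length_mismatch_rejected(self, toy_panel):
        hap = SomaticHaplotype("h", "ACGT", "d1")
        table = call_polymorphic_sites(toy_panel)
        with pytest.raises(PaintingError, match="length"):
            observe_sites(hap, table, toy_panel)


class TestPaintMinimal:
    def test_toy_two_minimal_paintings(self, toy_panel):
        # observed A,T,A; anchor d1: switch in (10,40] or (40,70]
        seq = list(toy_panel.consensus.sequence)
        seq[10], seq[40], seq[70] = "A", "T", "A"
        hap = SomaticHaplotype("h", "".join(seq), "d1")
        _, paintings = paint(toy_panel, hap)
        assert all(p.n_exchanges == 1 for p in paintings)
        assert all(p.donor_runs == ("d1", "d2") for p in paintings)
        assert sorted(p.switch_intervals[0] for p in paintings) == [(10, 40), (40, 70)]
        assert all(p.tie_class == "ambiguous" for p in paintings)

    def test_haplotype_equal_to_full_length_donor_zero_exchanges(self, toy_panel):
        d2 = toy_panel.donor("d2")
        hap = SomaticHaplotype("h", d2.sequence, "d2")
        _, paintings = paint(toy_panel, hap)
        assert len(paintings) == 1
        assert paintings[0].n_exchanges == 0
        assert paintings[0].donor_runs == ("d2",)

    def test_terminal_anchor_zero_exchanges(self, default_bundle):
        # the terminal gene is complete in the germline: painting its own
        # sequence needs zero exchanges
        panel = default_bundle.panel_a
        term = panel.donor(panel.terminal_mt)
        hap = SomaticHaplotype("h", term.sequence, panel.terminal_mt)
        table = call_polymorphic_sites(panel)
        obs = observe_sites(hap, table, panel)
        paintings = paint_minimal(obs, panel.terminal_mt, panel)
        assert [p.n_exchanges for p in paintings] == [0]

    def test_truncated_anchor_requires_one_exchange_even_without_sites(self):
        # the molecule reaches the 3' end, which the truncated anchor
        # cannot supply: one exchange is structurally necessary
        panel = make_panel(
            [("full", "AAAA", 4), ("tr", "AAAA", 2)], consensus="AAAA"
        )
        hap = SomaticHaplotype("h", "AAAA", "tr")
        _, paintings = paint(panel, hap)
        assert all(p.n_exchanges == 1 for p in paintings)
        assert all(p.donor_runs == ("tr", "full") for p in paintings)

    def test_all_novel_sites_degenerate(self, toy_panel):
        seq = list(toy_panel.consensus.sequence)
        seq[10], seq[40], seq[70] = "T", "A", "T"  # carried by no donor
        hap = SomaticHaplotype("h", "".join(seq), "d1")
        _, paintings = paint(toy_panel, hap)
        assert len(paintings) == 1
        assert paintings[0].degenerate
        assert paintings[0].segments == ()
        assert set(paintings[0].novel_positions) == {10, 40, 70}

    def test_anchor_incompatible_flagged_not_fatal(self, toy_panel):
        # first site shows a base d1 does not carry although d1 is the anchor
        seq = list(toy_panel.consensus.sequence)
        seq[10], seq[40], seq[70] = "G", "T", "A"
        hap = SomaticHaplotype("h", "".join(seq), "d1")
        _, paintings = paint(toy_panel, hap)
        assert all(p.anchor_incompatible for p in paintings)
        assert all(p.donor_runs[0] == "d1" for p in paintings)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        checked = 0
        for i in range(150):
            n_donors = int(rng.integers(2, 7))
            n_sites = int(rng.integers(1, 13))
            panel, positions = random_panel(rng, n_donors, n_sites)
            hap = (
                mosaic_haplotype(rng, panel, positions)
                if i % 2 == 0
                else random_haplotype(rng, panel, positions)
            )
            table = call_polymorphic_sites(panel)
            obs = observe_sites(hap, table, panel)
            informative = [o for o in obs if not o.is_novel]
            if obs and not informative:
                continue  # degenerate all-novel haplotype, no path to check
            expect = oracle_min_exchanges(pseudo_compat(panel, hap.anchor_mt, informative))
            got = paint_minimal(obs, hap.anchor_mt, panel)[0].n_exchanges
            assert got == expect
            checked += 1
        assert checked >= 140

    @pytest.mark.parametrize("seed", [3, 4])
    def test_adding_informative_site_never_decreases_exchanges(self, seed):
        # monotonicity: dropping one informative site can never increase
        # the minimum exchange count
        rng = np.random.default_rng(seed)
        for _ in range(40):
            panel, positions = random_panel(rng, 4, 8)
            hap = mosaic_haplotype(rng, panel, positions)
            table = call_polymorphic_sites(panel)
            obs = observe_sites(hap, table, panel)
            full = paint_minimal(obs, hap.anchor_mt, panel)[0].n_exchanges
            informative = [o for o in obs if not o.is_novel]
            if not informative:
                continue
            drop = int(rng.integers(len(informative)))
            reduced = [o for o in obs if o.is_novel or o is not informative[drop]]
            less = paint_minimal(reduced, hap.anchor_mt, panel)[0].n_exchanges
            assert less <= full


class TestSelectPainting:
    def _toy_minimal(self, toy_panel):
        seq = list(toy_panel.consensus.sequence)
        seq[10], seq[40], seq[70] = "A", "T", "A"
        hap = SomaticHaplotype("h", "".join(seq), "d1")
        _, paintings = paint(toy_panel, hap)
        return paintings

    def test_latest_switch_extends_anchor(self, toy_panel):
        sel = select_painting(self._toy_minimal(toy_panel), "latest_switch")
        assert sel.switch_intervals == ((40, 70),)

    def test_conservative_is_interval_hull(self, toy_panel):
        sel = select_painting(self._toy_minimal(toy_panel), "conservative")
        assert sel.switch_intervals == ((10, 70),)

    def test_unique_minimal_unchanged_under_both_policies(self, toy_panel):
        d2 = toy_panel.donor("d2")
        hap = SomaticHaplotype("h", d2.sequence, "d2")
        _, paintings = paint(toy_panel, hap)
        assert select_painting(paintings, "latest_switch") == paintings[0]
        assert select_painting(paintings, "conservative") == paintings[0]

    def test_empty_list_rejected(self):
        with pytest.raises(PaintingError):
            select_painting([], "latest_switch")


class TestPanelIndex:
    def test_novel_scan_covers_invariant_columns(self, toy_panel):
        idx = PanelIndex(toy_panel)
        seq = list(toy_panel.consensus.sequence)
        seq[5] = "T"  # invariant column, all donors carry C
        assert idx.novel_positions("".join(seq)) == [5]

    def test_anchor_segment_starts_at_attachment_point(self, toy_panel):
        d2 = toy_panel.donor("d2")
        hap = SomaticHaplotype("h", d2.sequence, "d2")
        _, paintings = paint(toy_panel, hap)
        assert paintings[0].segments[0][1][0] == ANCHOR_POS
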