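"""Synthetic locus and cohort generator: structure, truth, determinism."""

import json

import numpy as np
import pytest

from matpaint.locus import call_polymorphic_sites, donor_order
from matpaint.painting import PanelIndex
from matpaint.simulate import (
    REAL_ORDER,
    SimConfig,
    SimulationError,
    generate_cohort,
    make_germline,
    simulate_cohorts,
    simulate_pcr,
    simulate_rearrangement,
)


class TestSimConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(SimulationError, match="unknown config keys"):
            SimConfig.from_dict({"n_pairs": 4, "bogus": 1})

    def test_rate_bounds_enforced(self):
        with pytest.raises(SimulationError):
            SimConfig(pcr_error_rate=1.5)

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(mechanism="teleportation")

    def test_site_count_must_fit(self):
        with pytest.raises(SimulationError):
            make_germline(SimConfig(consensus_length_a=50, n_sites_a=60))


class TestMakeGermline:
    def test_planted_sites_recovered_exactly(self, default_bundle):
        for side, panel in (("A", default_bundle.panel_a), ("B", default_bundle.panel_b)):
            planted = default_bundle.truth["planted_sites"][side]
            table = call_polymorphic_sites(panel)
            assert len(table) == len(planted)
            for site, plan in zip(table, planted):
                assert site.position == plan["position"]
                assert site.unique_to == plan["unique_to"]
                for lab, base in plan["deviants"].items():
                    assert site.donor_bases[lab] == base

    def test_default_site_counts_and_order(self, default_bundle):
        assert len(call_polymorphic_sites(default_bundle.panel_a)) == 59
        assert len(call_polymorphic_sites(default_bundle.panel_b)) == 52
        assert donor_order(default_bundle.panel_a) == list(REAL_ORDER)

    def test_terminal_donors_full_length(self, default_bundle):
        assert default_bundle.panel_a.terminal_mt == "II"
        assert default_bundle.panel_b.terminal_mt == "III"

    def test_single_pair_panel(self):
        cfg = SimConfig(n_pairs=1, n_sites_a=0, n_sites_b=0,
                        n_exconjugants=5, n_mature=0)
        b = simulate_cohorts(cfg)
        assert len(b.panel_a.donors) == 1
        # downstream painting of the sole pair needs zero exchanges
        from matpaint.pipeline import paint_cohort

        table = call_polymorphic_sites(b.panel_a)
        pc = paint_cohort(b.panel_a, table, b.haplotypes[("exconjugant_0fission", "A")])
        assert all(p.n_exchanges == 0 for p in pc.paintings)

    def test_two_seeds_differ_in_placement_not_structure(self):
        pa1, _, t1 = make_germline(SimConfig(seed=1))
        pa2, _, t2 = make_germline(SimConfig(seed=2))
        pos1 = [s["position"] for s in t1["planted_sites"]["A"]]
        pos2 = [s["position"] for s in t2["planted_sites"]["A"]]
        assert pos1 != pos2
        assert len(pos1) == len(pos2) == 59
        assert [d.trunc for d in pa1.donors] == [d.trunc for d in pa2.donors]


class TestSimulateRearrangement:
    def test_single_pair_identity(self):
        cfg = SimConfig(n_pairs=1, n_sites_a=0, n_sites_b=0)
        pa, pb, _ = make_germline(cfg)
        rng = np.random.default_rng(0)
        r = simulate_rearrangement(pa, pb, "coordinated", rng)
        assert r["sequence_a"] == pa.donors[0].sequence
        assert r["sequence_b"] == pb.donors[0].sequence
        assert r["events"] == []

    def test_join_positions_within_homologous_overlap(self, default_bundle):
        pa, pb = default_bundle.panel_a, default_bundle.panel_b
        rng = np.random.default_rng(1)
        for mech in ("coordinated", "independent_ends"):
            for _ in range(50):
                r = simulate_rearrangement(pa, pb, mech, rng)
                for ev in r["events"]:
                    panel = pa if ev["side"] == "A" else pb
                    assert 1 <= ev["join"] <= panel.donor(ev["target"]).trunc

    def test_independent_ends_conserves_pairs(self, default_bundle):
        pa, pb = default_bundle.panel_a, default_bundle.panel_b
        rng = np.random.default_rng(2)
        for _ in range(100):
            r = simulate_rearrangement(pa, pb, "independent_ends", rng)
            excised = [lab for ev in r["events"] for lab in ev["excised"]]
            assert sorted(excised + [r["retained"]]) == sorted(REAL_ORDER)

    def test_painting_recovers_truth_end_to_end(self, default_bundle):
        # any replicate: painting finds the retained type and a switch
        # interval containing the true crossover
        from matpaint.pipeline import paint_cohort

        pa = default_bundle.panel_a
        table = call_polymorphic_sites(pa)
        rng = np.random.default_rng(3)
        from matpaint.painting import SomaticHaplotype

        haps, joins = [], []
        for i in range(40):
            r = simulate_rearrangement(pa, default_bundle.panel_b, "coordinated", rng)
            haps.append(SomaticHaplotype(f"h{i}", r["sequence_a"], r["retained"]))
            joins.append(r["join_a"])
        pc = paint_cohort(pa, table, haps)
        for hap, con, j in zip(haps, pc.conservative, joins):
            if j is None:
                assert con.n_exchanges == 0
            else:
                assert con.n_exchanges == 1
                assert con.donor_runs == (hap.anchor_mt, "II")
                l, r_ = con.switch_intervals[0]
                assert l < j <= r_


class TestSimulatePCR:
    def test_no_artifacts_identity(self):
        rng = np.random.default_rng(0)
        pool = ["ACGT" * 100, "TTTT" * 100]
        inserts, truth = simulate_pcr(pool, 0.0, 0.0, rng)
        assert inserts == pool
        assert all(t["events"] == [] for t in truth)

    def test_empty_pool_rejected(self):
        with pytest.raises(SimulationError):
            simulate_pcr([], 0.0, 0.0, np.random.default_rng(0))

    def test_error_count_binomial(self):
        rng = np.random.default_rng(4)
        pool = ["A" * 2000] * 500  # 1e6 bases
        inserts, truth = simulate_pcr(pool, 2e-5, 0.0, rng)
        n_err = sum(len(t["events"]) for t in truth)
        # 3 SD of Binomial(1e6, 2e-5): 20 +- 13.4
        assert abs(n_err - 20) <= 3 * np.sqrt(20 * (1 - 2e-5))

    def test_template_switch_recorded_and_applied(self):
        rng = np.random.default_rng(5)
        pool = ["A" * 50, "C" * 50]
        inserts, truth = simulate_pcr(pool, 0.0, 1.0, rng)
        for ins, t in zip(inserts, truth):
            (ev,) = t["events"]
            assert ev["type"] == "template_switch"
            p = ev["position"]
            assert ins[:p] == pool[t["template"]][:p]
            assert ins[p:] == pool[ev["partner"]][p:]


class TestCohortGeneration:
    def test_file_bytes_deterministic(self, tmp_path):
        cfg = SimConfig(seed=9, n_exconjugants=8, n_mature=8,
                        consensus_length_a=400, consensus_length_b=400,
                        n_sites_a=15, n_sites_b=15)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        generate_cohort(cfg, d1)
        generate_cohort(cfg, d2)
        for f in sorted(d1.iterdir()):
            assert (d2 / f.name).read_bytes() == f.read_bytes(), f.name

    def test_outputs_parse_and_round_trip(self, tmp_path):
        from matpaint import io as mio

        cfg = SimConfig(seed=10, n_exconjugants=6, n_mature=0,
                        consensus_length_a=400, consensus_length_b=400,
                        n_sites_a=15, n_sites_b=15)
        bundle = generate_cohort(cfg, tmp_path)
        panel = mio.read_panel_fasta(tmp_path / "germline_A.fasta")
        assert [d.sequence for d in panel.donors] == [
            d.sequence for d in bundle.panel_a.donors
        ]
        haps = mio.read_haplotype_fasta(tmp_path / "somatic_0fission_A.fasta")
        assert [h.sequence for h in haps] == [
            h.sequence for h in bundle.haplotypes[("exconjugant_0fission", "A")]
        ]
        json.loads((tmp_path / "truth.json").read_text())

    def test_every_novel_base_is_a_recorded_artifact(self):
        # truth-consistency: novel bases in sampled inserts trace back to a
        # recorded PCR error (no conversions at these settings)
        cfg = SimConfig(seed=12, pcr_error_rate=2e-4, n_exconjugants=40, n_mature=0)
        b = simulate_cohorts(cfg)
        for side, panel in (("A", b.panel_a), ("B", b.panel_b)):
            idx = PanelIndex(panel)
            cells = b.truth["cells"]["exconjugant_0fission"]
            pcr = b.truth["pcr"]["exconjugant_0fission"][side]
            key = "sequence_a" if side == "A" else "sequence_b"
            n_novel_inserts = 0
            for t in pcr:
                seq = list(cells[t["template"]][key])
                recorded = set()
                for ev in t["events"]:
                    assert ev["type"] == "pcr_error"  # no switching configured
                    seq[ev["position"]] = ev["to"]
                    recorded.add(ev["position"])
                novels = set(idx.novel_positions("".join(seq)))
                assert novels <= recorded
                n_novel_inserts += bool(novels)
            assert n_novel_inserts > 0  # rate high enough to exercise the check

    def test_mature_cohort_gains_conversions(self):
        cfg = SimConfig(seed=13, pcr_error_rate=0.0, conversion_rate=0.5,
                        n_exconjugants=40, n_mature=40)
        b = simulate_cohorts(cfg)
        convs = [
            c["conversions"] for c in b.truth["cells"]["mature_120fission"]
        ]
        assert any(c["A"] or c["B"] for c in convs)
        assert all(
            c["conversions"] == {"A": None, "B": None}
            for c in b.truth["cells"]["exconjugant_0fission"]
        )
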