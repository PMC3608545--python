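"""End-to-end orchestration: sites -> paint -> classify -> summarize.

The pipeline either simulates a locus and cohorts or loads FASTA inputs,
then runs the full inference chain and writes TSV tables plus a summary
JSON with four blocks: polymorphic sites, paintings, event classes per
cohort, and the cohort comparison (join-region spans, novel-base rate,
homogeneity chi-square).  Everything is deterministic given the config
seed; each stage logs its counts.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import __version__
from .events import (
    EventRecord,
    aggregate_join_region,
    classify,
    cohort_chi2,
    event_category,
    novel_base_rate,
    summarize_cohort,
)
from .locus import GermlinePanel, PolymorphismTable, call_polymorphic_sites
from .painting import (
    Painting,
    PanelIndex,
    SomaticHaplotype,
    observe_sites,
    paint_minimal,
    select_painting,
)
from .simulate import SimConfig, simulate_cohorts

log = logging.getLogger("matpaint")

COHORTS = ("exconjugant_0fission", "mature_120fission")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PaintedCohort:
    haplotypes: list[SomaticHaplotype]
    paintings: list[Painting]            # selected under the run policy
    conservative: list[Painting]         # hull switch intervals
    records: list[EventRecord]


def paint_cohort(
    panel: GermlinePanel,
    table: PolymorphismTable,
    haplotypes: list[SomaticHaplotype],
    policy: str = "latest_switch",
    index: Optional[PanelIndex] = None,
) -> PaintedCohort:
    """Paint and classify every haplotype of one cohort/side."""
    idx = index if index is not None else PanelIndex(panel)
    terminal = panel.terminal_mt
    selected, conservative, records = [], [], []
    for h in haplotypes:
        obs = observe_sites(h, table, panel)
        novel = idx.novel_positions(h.sequence)
        minimal = paint_minimal(
            obs, h.anchor_mt, panel, novel_positions=novel, haplotype_id=h.id
        )
        sel = select_painting(minimal, policy=policy)
        con = select_painting(minimal, policy="conservative")
        selected.append(sel)
        conservative.append(con)
        records.append(classify(sel, h.anchor_mt, terminal, h.multiplicity))
    return PaintedCohort(haplotypes, selected, conservative, records)


def ungapped_length(sequence: str) -> int:
    return len(sequence) - sequence.count("-")


def cohort_error_rate(cohort: PaintedCohort):
    return novel_base_rate(
        novel_counts=[len(p.novel_positions) for p in cohort.paintings],
        lengths=[ungapped_length(h.sequence) for h in cohort.haplotypes],
        multiplicities=[h.multiplicity for h in cohort.haplotypes],
    )


def analyze(
    panel_a: GermlinePanel,
    panel_b: GermlinePanel,
    haplotypes: dict[tuple[str, str], list[SomaticHaplotype]],
    policy: str = "latest_switch",
) -> dict:
    """Run the whole inference chain over both sides and cohorts.

    Returns a nested result dict (the summary JSON payload) plus the
    intermediate objects under the "objects" key for programmatic use.
    """
    panels = {"A": panel_a, "B": panel_b}
    tables = {s: call_polymorphic_sites(p) for s, p in panels.items()}
    log.info("sites: A=%d B=%d", len(tables["A"]), len(tables["B"]))

    painted: dict[tuple[str, str], PaintedCohort] = {}
    for (cohort, side), haps in sorted(haplotypes.items()):
        pc = paint_cohort(panels[side], tables[side], haps, policy=policy)
        painted[(cohort, side)] = pc
        log.info(
            "paint: %s side %s: %d haplotypes, %d inserts",
            cohort, side, len(haps), sum(h.multiplicity for h in haps),
        )

    summary: dict = {
        "version": __version__,
        "policy": policy,
        "sites": {
            s: {
                "n_sites": len(tables[s]),
                "n_unique": sum(1 for x in tables[s] if x.unique_to),
            }
            for s in panels
        },
        "cohorts": {},
        "join_region": {},
        "error_rate": {},
        "chi2": {},
    }

    for (cohort, side), pc in sorted(painted.items()):
        block = {
            "weighted": summarize_cohort(pc.records, weighted=True),
            "unweighted": summarize_cohort(pc.records, weighted=False),
        }
        summary["cohorts"].setdefault(cohort, {})[side] = block

    for side in ("A", "B"):
        key = ("exconjugant_0fission", side)
        if key in painted:
            pc = painted[key]
            jr = aggregate_join_region(pc.records, pc.conservative, side)
            summary["join_region"][side] = {
                "n_intervals": len(jr.intervals),
                "aggregate_span": list(jr.aggregate_span) if jr.aggregate_span else None,
                "span_length": jr.span_length,
                "span_length_inclusive": jr.span_length_inclusive,
            }

    for cohort in COHORTS:
        pcs = [painted[(cohort, s)] for s in ("A", "B") if (cohort, s) in painted]
        if not pcs:
            continue
        est = novel_base_rate(
            novel_counts=[len(p.novel_positions) for pc in pcs for p in pc.paintings],
            lengths=[ungapped_length(h.sequence) for pc in pcs for h in pc.haplotypes],
            multiplicities=[h.multiplicity for pc in pcs for h in pc.haplotypes],
        )
        summary["error_rate"][cohort] = {
            "novel_bases": est.novel_base_count,
            "total_bases": est.total_sequenced_bases,
            "rate_per_bp": est.rate,
            "bp_per_novel_base": est.reciprocal,
        }

    for side in ("A", "B"):
        k0, k1 = ("exconjugant_0fission", side), ("mature_120fission", side)
        if k0 in painted and k1 in painted:
            cats = ["single_simple_join", "extra_exchange_or_conversion", "multi_donor"]
            c0: dict[str, int] = {}
            c1: dict[str, int] = {}
            for rec in painted[k0].records:
                c0[event_category(rec)] = c0.get(event_category(rec), 0) + rec.multiplicity
            for rec in painted[k1].records:
                c1[event_category(rec)] = c1.get(event_category(rec), 0) + rec.multiplicity
            cmp_ = cohort_chi2(c0, c1, categories=cats)
            summary["chi2"][side] = {
                "categories": list(cmp_.categories),
                "counts_0fission": list(cmp_.counts_0fission),
                "counts_120fission": list(cmp_.counts_120fission),
                "statistic": cmp_.statistic,
                "df": cmp_.df,
                "p_value": cmp_.p_value,
            }

    summary["objects"] = {"tables": tables, "painted": painted, "panels": panels}
    return summary


# ------------------------------------------------------------- config ----

_TOP_KEYS = {"seed", "outdir", "policy", "simulate", "inputs"}


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", cfg.get("seed", 0))
        SimConfig.from_dict(sim)  # raises on unknown keys / bad values
    else:
        need = {"germline_a", "germline_b"}
        unknown = set(cfg["inputs"]) - (need | {"haplotypes"})
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        missing = need - set(cfg["inputs"])
        if missing:
            raise ValueError(f"missing input keys: {sorted(missing)}")
    cfg.setdefault("policy", "latest_switch")
    cfg.setdefault("seed", 0)
    return cfg


def run_pipeline(cfg: dict, outdir: Optional[str | Path] = None) -> dict:
    """Execute the configured pipeline, writing tables and summary JSON.

    Outputs are removed again if any stage fails, so a run directory is
    either complete or absent.
    """
    from . import io as mio

    cfg = validate_config(dict(cfg))
    out = Path(outdir or cfg.get("outdir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log.info("matpaint %s; seed=%s; python=%s", __version__, cfg["seed"],
             sys.version.split()[0])

    def emit(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    try:
        stage = "load"
        if "simulate" in cfg:
            sim = dict(cfg["simulate"])
            sim.setdefault("seed", cfg["seed"])
            bundle = simulate_cohorts(SimConfig.from_dict(sim))
            panel_a, panel_b = bundle.panel_a, bundle.panel_b
            haplotypes = bundle.haplotypes
            emit(out / "truth.json", lambda p: p.write_text(
                json.dumps(bundle.truth, indent=1, sort_keys=True)))
        else:
            inputs = cfg["inputs"]
            panel_a = mio.read_panel_fasta(inputs["germline_a"])
            panel_b = mio.read_panel_fasta(inputs["germline_b"])
            haplotypes = {}
            for path in inputs.get("haplotypes", []):
                for h in mio.read_haplotype_fasta(path):
                    side = "A" if "_A" in Path(path).stem else "B"
                    haplotypes.setdefault((h.cohort, side), []).append(h)

        stage = "analyze"
        summary = analyze(panel_a, panel_b, haplotypes, policy=cfg["policy"])
        objects = summary.pop("objects")

        stage = "write"
        for side, panel in (("A", panel_a), ("B", panel_b)):
            df = mio.sites_table(objects["tables"][side], panel)
            emit(out / f"sites_{side}.tsv",
                 lambda p, df=df: df.to_csv(p, sep="\t", index=False))
        all_paintings = [
            p for pc in objects["painted"].values() for p in pc.paintings
        ]
        all_records = [
            r for pc in objects["painted"].values() for r in pc.records
        ]
        emit(out / "paintings.tsv",
             lambda p: mio.paintings_table(all_paintings).to_csv(p, sep="\t", index=False))
        emit(out / "events.tsv",
             lambda p: mio.events_table(all_records).to_csv(p, sep="\t", index=False))
        for side, panel in (("A", panel_a), ("B", panel_b)):
            haps = [
                h for (cohort, s), hs in sorted(haplotypes.items()) if s == side
                for h in hs
            ]
            doc = mio.write_collapsed(panel, haps)
            emit(out / f"collapsed_{side}.txt", lambda p, doc=doc: p.write_text(doc))
        emit(out / "summary.json", lambda p: p.write_text(
            json.dumps(summary, indent=1, sort_keys=True)))
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise StageError(stage, exc) from exc

    summary["objects"] = objects
    return summary
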