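"""Classify paintings into joining-event categories.

Scores each haplotype against the single-simple-join expectation, counts
gene-conversion signatures (X->Y->X), localizes the aggregate join region
from the conservative switch intervals, and estimates the novel-base rate
per sequenced base pair.
"""

import argparse
from pathlib import Path

from matpaint import io as mio
from matpaint.events import aggregate_join_region, summarize_cohort
from matpaint.locus import call_polymorphic_sites
from matpaint.pipeline import cohort_error_rate, paint_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    all_records = []
    for side in ("A", "B"):
        panel = mio.read_panel_fasta(args.datadir / f"germline_{side}.fasta")
        table = call_polymorphic_sites(panel)
        for tag, cohort in (("0fission", "exconjugant"), ("120fission", "mature")):
            haps = mio.read_haplotype_fasta(
                args.datadir / f"somatic_{tag}_{side}.fasta"
            )
            pc = paint_cohort(panel, table, haps)
            all_records.extend(pc.records)
            w = summarize_cohort(pc.records, weighted=True)
            u = summarize_cohort(pc.records, weighted=False)
            print(
                f"side {side} {cohort}: single simple join "
                f"{100 * w['single_simple_join_fraction']:.1f}% of {w['n']} inserts "
                f"({100 * u['single_simple_join_fraction']:.1f}% of {u['n']} haplotypes)"
            )
            if cohort == "exconjugant":
                jr = aggregate_join_region(pc.records, pc.conservative, side)
                if jr.aggregate_span:
                    print(
                        f"  join region: {len(jr.intervals)} intervals, "
                        f"span {jr.aggregate_span} = {jr.span_length} bp"
                    )
                est = cohort_error_rate(pc)
                recip = f"1 per {est.reciprocal:,.0f} bp" if est.reciprocal else "none seen"
                print(
                    f"  novel bases: {est.novel_base_count} in "
                    f"{est.total_sequenced_bases:,} bp ({recip})"
                )

    out = args.outdir / "events.tsv"
    mio.events_table(all_records).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
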