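"""Call polymorphic sites from the germline panels.

Reads the simulated germline FASTAs, rebuilds the consensus by majority,
tabulates every deviant column (the Tables-S5/S6-style site tables) and
reports how many sites are diagnostic for a single donor — the sites that
make haplotype painting possible.
"""

import argparse
from pathlib import Path

from matpaint import io as mio
from matpaint.locus import call_polymorphic_sites


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for side in ("A", "B"):
        panel = mio.read_panel_fasta(args.datadir / f"germline_{side}.fasta")
        table = call_polymorphic_sites(panel)
        df = mio.sites_table(table, panel)
        out = args.outdir / f"sites_{side}.tsv"
        df.to_csv(out, sep="\t", index=False)
        n_unique = sum(1 for s in table if s.unique_to)
        n_del = sum(1 for s in table if "-" in s.donor_bases.values())
        print(
            f"side {side}: {len(table)} polymorphic sites "
            f"({n_unique} unique to one donor, {n_del} deletions) -> {out}"
        )


if __name__ == "__main__":
    main()
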