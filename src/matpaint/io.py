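"""FASTA dialects, collapsed-alignment text format, tabular output.

The collapsed alignment is a compact plain-text rendering of a donor panel
plus somatic haplotypes against the germline consensus: invariant runs of
columns collapse to a single dot, only deviant columns are written
explicitly, deletions are ``-``, positions beyond a donor's truncation are
blank, and novel bases (present in no germline donor) are written in
lowercase with a ``*`` marker line beneath the row.  Column positions are
1-based and written vertically above the rows.  For the A side the columns
are displayed 3'-to-5' left-to-right, preserving the genomic orientation
of the locus; all internal coordinates stay 5'-to-3' and only the writer
flips.

The format is round-trip exact: expanding a collapsed row against the
consensus reproduces the original sequence byte-for-byte, and re-collapsing
a parsed document is idempotent.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus import (
    ConsensusProfile,
    DonorCopy,
    GermlinePanel,
    LocusModelError,
    build_consensus,
)
from .painting import Painting, PanelIndex, SomaticHaplotype

_WRAP = 60

_COHORT_TOKEN = {"exconjugant_0fission": "0", "mature_120fission": "120"}
_COHORT_FROM_TOKEN = {v: k for k, v in _COHORT_TOKEN.items()}


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- FASTA ---

def _parse_tokens(description: str) -> dict[str, str]:
    tokens = {}
    for part in description.split()[1:]:
        if "=" in part:
            k, v = part.split("=", 1)
            tokens[k.lower()] = v
    return tokens


def write_panel_fasta(panel: GermlinePanel, path: str | Path) -> None:
    """Donor copies with ``mt= side= trunc= full=`` header tokens, wrapped
    at 60 columns."""
    records = []
    for d in panel.donors:
        desc = (
            f"mt={d.mt_label} side={panel.side} trunc={d.trunc} "
            f"full={1 if d.full_length else 0}"
        )
        records.append(
            SeqRecord(Seq(d.sequence), id=d.mt_label, description=desc)
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_WRAP)
        writer.write_file(records)


def read_panel_fasta(path: str | Path) -> GermlinePanel:
    """Load a donor panel; the consensus is rebuilt by per-column majority
    over the covering donors."""
    donors_raw = []
    side = None
    for rec in SeqIO.parse(str(path), "fasta"):
        tok = _parse_tokens(rec.description)
        if not {"mt", "side", "trunc", "full"} <= set(tok):
            raise FormatError(
                f"{path}: record {rec.id!r} missing mt=/side=/trunc=/full= tokens"
            )
        side = side or tok["side"].upper()
        donors_raw.append(
            (tok["mt"], str(rec.seq).upper(), int(tok["trunc"]), tok["full"] == "1")
        )
    if not donors_raw:
        raise FormatError(f"{path}: no donor records")
    seqs = [s for _, s, _, _ in donors_raw]
    ranges = [(0, t) for _, _, t, _ in donors_raw]
    consensus = build_consensus(seqs, ranges)
    donors = [
        DonorCopy(mt_label=m, sequence=s, valid_range=(0, t), full_length=f)
        for m, s, t, f in donors_raw
    ]
    return GermlinePanel(side=side, donors=donors, consensus=consensus)


def write_haplotype_fasta(
    haplotypes: Sequence[SomaticHaplotype], path: str | Path
) -> None:
    records = []
    for h in haplotypes:
        cohort = _COHORT_TOKEN.get(h.cohort, h.cohort)
        desc = f"anchor={h.anchor_mt} n={h.multiplicity} cohort={cohort}"
        records.append(SeqRecord(Seq(h.sequence), id=h.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_WRAP)
        writer.write_file(records)


def read_haplotype_fasta(path: str | Path) -> list[SomaticHaplotype]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tok = _parse_tokens(rec.description)
        if "anchor" not in tok:
            raise FormatError(f"{path}: record {rec.id!r} missing anchor= token")
        cohort = _COHORT_FROM_TOKEN.get(tok.get("cohort", "0"), tok.get("cohort", "0"))
        out.append(
            SomaticHaplotype(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                anchor_mt=tok["anchor"],
                multiplicity=int(tok.get("n", 1)),
                cohort=cohort,
            )
        )
    return out


# --------------------------------------------- collapsed alignment -------

def _display_columns(
    panel: GermlinePanel,
    haplotypes: Sequence[SomaticHaplotype],
) -> list[int]:
    """Columns at which any displayed row deviates from the consensus
    (within coverage); everything else collapses into dot runs."""
    cons = panel.consensus.sequence
    cols: set[int] = set()
    for d in panel.donors:
        lo, hi = d.valid_range
        for p in range(lo, hi):
            if d.sequence[p] != cons[p]:
                cols.add(p)
    for h in haplotypes:
        for p, (a, b) in enumerate(zip(h.sequence, cons)):
            if a != b:
                cols.add(p)
    return sorted(cols)


def _slots(cols: list[int], length: int) -> list[tuple[str, int, int]]:
    """Alternating run/column slots covering [0, length).

    Returns (kind, start, end) with kind 'run' (half-open interval) or
    'col' (single position)."""
    out: list[tuple[str, int, int]] = []
    prev = 0
    for c in cols:
        if c > prev:
            out.append(("run", prev, c))
        out.append(("col", c, c + 1))
        prev = c + 1
    if length > prev:
        out.append(("run", prev, length))
    return out


def _render_row(
    sequence: str,
    cons: str,
    slots: list[tuple[str, int, int]],
    trunc: int,
    novel: frozenset[int] = frozenset(),
) -> str:
    chars = []
    for kind, a, b in slots:
        if kind == "run":
            chars.append("." if trunc >= b else " ")
        else:
            if a >= trunc:
                chars.append(" ")
            elif sequence[a] == cons[a]:
                chars.append(".")
            elif a in novel:
                chars.append(sequence[a].lower())
            else:
                chars.append(sequence[a])
    return "".join(chars)


def _numbering_lines(slots: list[tuple[str, int, int]]) -> list[str]:
    """Vertical 1-based column numbering: one character per slot per line."""
    labels = {
        i: str(a + 1) for i, (kind, a, _) in enumerate(slots) if kind == "col"
    }
    width = max((len(v) for v in labels.values()), default=0)
    lines = []
    for row in range(width):
        line = []
        for i, _ in enumerate(slots):
            lab = labels.get(i)
            if lab is None:
                line.append(" ")
            else:
                padded = lab.rjust(width)
                line.append(padded[row])
        lines.append("".join(line))
    return lines


def write_collapsed(
    panel: GermlinePanel,
    haplotypes: Sequence[SomaticHaplotype] = (),
    paintings: Sequence[Painting] = (),
    index: Optional[PanelIndex] = None,
) -> str:
    """Render a panel plus somatic haplotypes as a collapsed alignment."""
    cons = panel.consensus.sequence
    length = panel.length
    for h in haplotypes:
        if len(h.sequence) != length:
            raise FormatError(f"row {h.id!r} not aligned to consensus length {length}")
    novel_by_id: dict[str, frozenset[int]] = {
        p.haplotype_id: frozenset(p.novel_positions) for p in paintings
    }
    if haplotypes and not novel_by_id:
        idx = index if index is not None else PanelIndex(panel)
        novel_by_id = {
            h.id: frozenset(idx.novel_positions(h.sequence)) for h in haplotypes
        }
    cols = _display_columns(panel, haplotypes)
    slots = _slots(cols, length)
    flip = panel.side == "A"

    def orient(s: str) -> str:
        return s[::-1] if flip else s

    lines = [
        "@collapsed v1",
        f"@side {panel.side}",
        f"@length {length}",
        f"@orientation {'3p-left' if flip else '5p-left'}",
        "@consensus",
    ]
    for i in range(0, length, _WRAP):
        lines.append(cons[i : i + _WRAP])
    lines.append("@columns " + ",".join(str(c + 1) for c in cols))
    lines.append("@rows")
    for num in _numbering_lines(slots):
        lines.append("| " + orient(num))
    lines.append("C\tGerm consensus\t-\t" + orient(_render_row(cons, cons, slots, length)))
    for d in panel.donors:
        row = _render_row(d.sequence, cons, slots, d.trunc)
        lines.append(f"D\tGerm {d.mt_label}\ttrunc={d.trunc}\t" + orient(row))
    for h in haplotypes:
        novel = novel_by_id.get(h.id, frozenset())
        row = _render_row(h.sequence, cons, slots, length, novel)
        meta = (
            f"x {h.multiplicity} anchor={h.anchor_mt} "
            f"cohort={_COHORT_TOKEN.get(h.cohort, h.cohort)}"
        )
        lines.append(f"H\t{h.id}\t{meta}\t" + orient(row))
        if novel:
            stars = "".join(
                "*" if kind == "col" and a in novel else " " for kind, a, _ in slots
            )
            lines.append("N\t\t\t" + orient(stars))
    return "\n".join(lines) + "\n"


def read_collapsed(text: str) -> tuple[Optional[GermlinePanel], list[SomaticHaplotype]]:
    """Parse a collapsed alignment back into a panel and haplotype rows.

    Expansion against the embedded consensus is exact; ``x N``
    multiplicities and truncations are recovered from the row metadata.
    """
    if not text.strip():
        return None, []
    lines = text.splitlines()
    it = iter(enumerate(lines, start=1))
    meta: dict[str, str] = {}
    cons_parts: list[str] = []
    cols: list[int] = []
    rows: list[tuple[int, str, str, str, str]] = []
    mode = "head"
    for ln, line in it:
        if line.startswith("@consensus"):
            mode = "cons"
            continue
        if line.startswith("@columns"):
            payload = line[len("@columns"):].strip()
            try:
                cols = [int(x) - 1 for x in payload.split(",")] if payload else []
            except ValueError as exc:
                raise FormatError(f"line {ln}: bad column numbering: {exc}") from exc
            mode = "head"
            continue
        if line.startswith("@rows"):
            mode = "rows"
            continue
        if line.startswith("@"):
            k, _, v = line[1:].partition(" ")
            meta[k] = v
            continue
        if mode == "cons":
            cons_parts.append(line.strip())
        elif mode == "rows":
            if line.startswith("|"):
                continue  # decorative numbering
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"line {ln}: expected 4 tab-separated fields")
            rows.append((ln, *parts))

    cons = "".join(cons_parts)
    try:
        length = int(meta.get("length", len(cons)))
    except ValueError as exc:
        raise FormatError(f"bad @length: {exc}") from exc
    if len(cons) != length:
        raise FormatError(f"consensus length {len(cons)} != declared {length}")
    side = meta.get("side", "A").upper()
    flip = meta.get("orientation", "5p-left") == "3p-left"
    slots = _slots(cols, length)

    def expand(rendered: str, ln: int) -> tuple[str, int]:
        if flip:
            rendered = rendered[::-1]
        if len(rendered) != len(slots):
            raise FormatError(
                f"line {ln}: row has {len(rendered)} slots, expected {len(slots)}"
            )
        seq = list(cons)
        trunc = length
        for ch, (kind, a, b) in zip(rendered, slots):
            if ch == " ":
                trunc = min(trunc, a)
            elif kind == "col" and ch != ".":
                seq[a] = ch.upper()
        return "".join(seq), trunc

    donors: list[DonorCopy] = []
    haps: list[SomaticHaplotype] = []
    for ln, kind, name, metafield, rendered in rows:
        if kind == "C":
            continue
        seq, trunc_seen = expand(rendered, ln)
        if kind == "D":
            tok = dict(
                p.split("=", 1) for p in metafield.split() if "=" in p
            )
            trunc = int(tok.get("trunc", trunc_seen))
            label = name.removeprefix("Germ ").strip()
            donors.append(
                DonorCopy(
                    mt_label=label,
                    sequence=seq,
                    valid_range=(0, trunc),
                    full_length=trunc == length,
                )
            )
        elif kind == "H":
            mult = 1
            anchor = ""
            cohort = "0"
            parts = metafield.split()
            i = 0
            while i < len(parts):
                if parts[i] == "x" and i + 1 < len(parts):
                    try:
                        mult = int(parts[i + 1])
                    except ValueError as exc:
                        raise FormatError(
                            f"line {ln}: bad multiplicity {parts[i + 1]!r}"
                        ) from exc
                    i += 2
                    continue
                if "=" in parts[i]:
                    k, v = parts[i].split("=", 1)
                    if k == "anchor":
                        anchor = v
                    elif k == "cohort":
                        cohort = v
                i += 1
            haps.append(
                SomaticHaplotype(
                    id=name,
                    sequence=seq,
                    anchor_mt=anchor or "?",
                    multiplicity=mult,
                    cohort=_COHORT_FROM_TOKEN.get(cohort, cohort),
                )
            )
        elif kind == "N":
            continue
        else:
            raise FormatError(f"line {ln}: unknown row kind {kind!r}")

    panel = None
    if donors:
        panel = GermlinePanel(
            side=side, donors=donors, consensus=ConsensusProfile(cons)
        )
    return panel, haps


# -------------------------------------------------------------- tables ---

def sites_table(table, panel: GermlinePanel):
    """Polymorphism table as a DataFrame: 1-based position, consensus
    base, one column per donor, unique_to."""
    import pandas as pd

    order = [d.mt_label for d in panel.donors]
    recs = []
    for s in table:
        row = {
            "position": s.position + 1,
            "consensus_base": s.consensus_base,
        }
        for lab in order:
            row[lab] = s.donor_bases.get(lab, "")
        row["unique_to"] = s.unique_to or ""
        recs.append(row)
    cols = ["position", "consensus_base", *order, "unique_to"]
    return pd.DataFrame(recs, columns=cols)


def paintings_table(paintings: Sequence[Painting]):
    """Painting results as a DataFrame (1-based inclusive intervals)."""
    import pandas as pd

    recs = []
    for p in paintings:
        recs.append(
            {
                "haplotype": p.haplotype_id,
                "segments": ";".join(
                    f"{lab}:{a + 2 if a >= 0 else 1}-{b + 1}" for lab, (a, b) in p.segments
                ),
                "donor_runs": "->".join(p.donor_runs),
                "switch_intervals": ";".join(
                    f"({l + 1},{r + 1}]" for l, r in p.switch_intervals
                ),
                "n_exchanges": p.n_exchanges,
                "novel_positions": ",".join(str(x + 1) for x in p.novel_positions),
                "tie_class": p.tie_class,
                "anchor_incompatible": p.anchor_incompatible,
                "degenerate": p.degenerate,
            }
        )
    return pd.DataFrame(
        recs,
        columns=[
            "haplotype", "segments", "donor_runs", "switch_intervals",
            "n_exchanges", "novel_positions", "tie_class",
            "anchor_incompatible", "degenerate",
        ],
    )


def events_table(records):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "haplotype": r.haplotype_id,
                "multiplicity": r.multiplicity,
                "n_exchanges": r.n_exchanges,
                "n_distinct_donors": r.n_distinct_donors,
                "n_gene_conversions": r.n_gene_conversions,
                "excess_exchanges": r.excess_exchanges,
                "single_simple_join": r.is_single_simple_join,
                "uses_third_donor": r.uses_third_donor,
                "unclassifiable": r.unclassifiable,
            }
            for r in records
        ]
    )
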