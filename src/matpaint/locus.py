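"""Germline donor panel: consensus building and polymorphic-site calling.

The germline *mat* locus of *Tetrahymena thermophila* is a tandem array of
six head-to-head, incomplete mating-type gene pairs.  Each gene carries a
terminal exon encoding a transmembrane domain; only the two terminal genes
of the array (*MTA2* on the left, *MTB3* on the right) carry a full-length
copy of that exon ("TM"), while every other copy is truncated ("tm").  The
near-identical TM/tm copies of one side (A = *MTA* family, B = *MTB*
family) form a *donor panel*: a small set of sequences aligned to a common
consensus, distinguishable only at a few dozen polymorphic sites, most of
which are unique to one donor.

Coordinates are 0-based, half-open, on the consensus.  Human-readable
output adds 1 (the source alignments number from the 5' end starting at 1).
Deletions relative to the consensus are a fifth state ``-`` occupying
explicit columns; a multi-base indel occupies consecutive columns.  A
truncated donor is *undefined* (not "match") beyond its valid range and can
never explain an observed base there.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

GAP = "-"
#: deterministic tie-break order for consensus calls
BASE_ORDER = "ACGT-"


class LocusModelError(ValueError):
    """Raised for structurally invalid panels or unaligned inputs."""


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-column majority sequence over the covering donors."""

    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DonorCopy:
    """One germline TM/tm exon copy, aligned to the consensus.

    ``valid_range`` is the half-open interval [0, trunc) of consensus
    positions the copy actually spans; ``sequence`` is only meaningful
    inside it.  ``full_length`` is equivalent to trunc == consensus length.
    """

    mt_label: str
    sequence: str
    valid_range: tuple[int, int]
    full_length: bool

    @property
    def trunc(self) -> int:
        return self.valid_range[1]

    def covers(self, position: int) -> bool:
        return self.valid_range[0] <= position < self.valid_range[1]

    def base_at(self, position: int) -> Optional[str]:
        """Base at a consensus position, or None beyond the truncation."""
        if not self.covers(position):
            return None
        return self.sequence[position]


@dataclass(frozen=True)
class PolymorphicSite:
    """One consensus column at which at least one covering donor deviates.

    ``donor_bases`` maps every *covering* donor label to its base (``-``
    for a deletion).  ``unique_to`` is set iff exactly one covering donor
    deviates from all the others — such sites are diagnostic for that donor
    and are what makes painting possible.
    """

    position: int
    consensus_base: str
    donor_bases: dict[str, str]
    unique_to: Optional[str]


@dataclass(frozen=True)
class PolymorphismTable:
    sites: tuple[PolymorphicSite, ...]

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]


@dataclass
class GermlinePanel:
    """Ordered donor panel for one side (A or B) of the gene-pair array."""

    side: str  # "A" or "B"
    donors: list[DonorCopy]
    consensus: ConsensusProfile
    locus_features: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.side not in ("A", "B"):
            raise LocusModelError(f"side must be 'A' or 'B', got {self.side!r}")
        labels = [d.mt_label for d in self.donors]
        if len(set(labels)) != len(labels):
            raise LocusModelError("donor mating-type labels must be unique")
        length = self.consensus.length
        for d in self.donors:
            if len(d.sequence) != length:
                raise LocusModelError(
                    f"donor {d.mt_label} not aligned to consensus length {length}"
                )
            if d.full_length != (d.valid_range == (0, length)):
                raise LocusModelError(
                    f"donor {d.mt_label}: full_length flag inconsistent with valid_range"
                )

    @property
    def length(self) -> int:
        return self.consensus.length

    def donor(self, mt_label: str) -> DonorCopy:
        for d in self.donors:
            if d.mt_label == mt_label:
                return d
        raise KeyError(mt_label)

    @property
    def full_length_donors(self) -> list[str]:
        return [d.mt_label for d in self.donors if d.full_length]

    @property
    def terminal_mt(self) -> str:
        """The unique full-length donor (*MTA2* / *MTB3* analogue)."""
        full = self.full_length_donors
        if len(full) != 1:
            raise LocusModelError(
                f"expected exactly one full-length donor on side {self.side}, "
                f"found {full}"
            )
        return full[0]


def donor_order(panel: GermlinePanel) -> list[str]:
    """Mating-type labels in germline array order (II, V, VI, IV, VII, III
    for the real locus); simply the load order, preserved exactly."""
    if not panel.donors:
        raise LocusModelError("empty panel")
    return [d.mt_label for d in panel.donors]


def build_consensus(
    sequences: list[str], valid_ranges: Optional[list[tuple[int, int]]] = None
) -> ConsensusProfile:
    """Per-column majority base over covering donors.

    Ties are broken by fixed base order A < C < G < T < '-' so the call is
    deterministic.  Positions outside a donor's valid range do not vote.
    """
    if not sequences:
        raise LocusModelError("no donors")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise LocusModelError("donor sequences have unequal aligned lengths")
    if len(sequences) < 2:
        raise LocusModelError("need >=2 sequences to build a consensus")
    if valid_ranges is None:
        valid_ranges = [(0, length)] * len(sequences)

    out = []
    for pos in range(length):
        votes = Counter(
            seq[pos]
            for seq, (lo, hi) in zip(sequences, valid_ranges)
            if lo <= pos < hi
        )
        if not votes:
            raise LocusModelError(f"zero-coverage column at position {pos}")
        best = max(votes)  # placeholder, replaced below
        top = max(votes.values())
        best = min(
            (b for b, c in votes.items() if c == top),
            key=lambda b: BASE_ORDER.index(b) if b in BASE_ORDER else len(BASE_ORDER),
        )
        out.append(best)
    return ConsensusProfile("".join(out))


def call_polymorphic_sites(panel: GermlinePanel) -> PolymorphismTable:
    """One site per column where >=1 covering donor deviates from consensus.

    A donor never contributes a base outside its valid range.  ``unique_to``
    is set when exactly one covering donor differs from every other covering
    donor (the classic donor-diagnostic site).
    """
    sites = []
    cons = panel.consensus.sequence
    for pos in range(panel.length):
        covering = {
            d.mt_label: d.sequence[pos] for d in panel.donors if d.covers(pos)
        }
        if not covering:
            continue
        if all(b == cons[pos] for b in covering.values()):
            continue
        deviants = [
            lab
            for lab, b in covering.items()
            if all(b != b2 for lab2, b2 in covering.items() if lab2 != lab)
        ]
        unique_to = deviants[0] if len(deviants) == 1 else None
        sites.append(
            PolymorphicSite(
                position=pos,
                consensus_base=cons[pos],
                donor_bases=dict(covering),
                unique_to=unique_to,
            )
        )
    return PolymorphismTable(tuple(sites))


def apply_table(panel: GermlinePanel, table: PolymorphismTable, mt_label: str) -> str:
    """Reconstruct one donor's sequence (within its valid range) from the
    consensus plus the polymorphism table — the round-trip companion of
    :func:`call_polymorphic_sites`."""
    donor = panel.donor(mt_label)
    seq = list(panel.consensus.sequence)
    for site in table:
        if mt_label in site.donor_bases:
            seq[site.position] = site.donor_bases[mt_label]
    lo, hi = donor.valid_range
    return "".join(seq[lo:hi])
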