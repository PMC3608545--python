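"""Donor painting of somatic TM-exon haplotypes by minimal exchanges.

A sequenced somatic TM exon is explained as a mosaic of germline donor
copies.  At every polymorphic site the observed base restricts which donors
could have contributed that stretch; painting finds the partitions of the
exon into donor segments that require (1) the minimum number of exchanges
(donor changes) and, among those, (2) the minimum number of distinct
donors.  Bases carried by no covering donor are *novel* (PCR or
replication-repair errors) and are recorded but never allowed to force an
exchange.

The 5' end of the exon is physically attached to the mating-type-specific
segment of the anchor donor, so the segment containing position 0 is the
anchor by construction.  This is modelled as a pseudo informative site at
position -1 compatible only with the anchor: a haplotype whose first real
informative site already shows the full-length terminal donor still counts
one exchange, with the join localized anywhere up to that site.  No 3'
constraint is imposed; only full-length donors can cover 3'-terminal sites,
which enforces the terminal join structurally: the sequenced molecule extends to the 3'
end of the exon, which only a full-length copy can contribute, so a second
pseudo-site at position L is compatible with exactly the full-length
donors.  Neither pseudo-site asserts a particular donor beyond what the
molecule's physical extent implies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .locus import GermlinePanel, PolymorphicSite, PolymorphismTable

#: sentinel position of the anchor attachment point, 5' of the exon
ANCHOR_POS = -1

#: safety bound on enumerated exchanges; beyond this a single greedy
#: furthest-reach painting is returned (still minimal — greedy maximal runs
#: are optimal for segment count — but ties are not enumerated)
_MAX_ENUM_EXCHANGES = 6


class PaintingError(ValueError):
    pass


@dataclass(frozen=True)
class SomaticHaplotype:
    """One distinct sequenced somatic TM-exon sequence.

    ``multiplicity`` is the number of sequenced inserts sharing this exact
    sequence (the "x N" counts of the collapsed alignments); ``anchor_mt``
    is the mating type implied by the attached mt-specific segment.
    """

    id: str
    sequence: str
    anchor_mt: str
    multiplicity: int = 1
    cohort: str = "exconjugant_0fission"

    def __post_init__(self):
        if self.multiplicity < 1:
            raise PaintingError(f"{self.id}: multiplicity must be >= 1")


@dataclass(frozen=True)
class SiteObservation:
    site: PolymorphicSite
    observed_base: str
    compatible_donors: frozenset[str]

    @property
    def is_novel(self) -> bool:
        return not self.compatible_donors

    @property
    def position(self) -> int:
        return self.site.position


@dataclass(frozen=True)
class Painting:
    """One minimal-exchange explanation of a haplotype.

    ``segments`` are (donor label, (first, last)) with inclusive informative
    site positions (the anchor segment starts at -1, the attachment point);
    ``switch_intervals`` are half-open ``(left, right]`` intervals bounded
    by the informative sites flanking each exchange.
    """

    haplotype_id: str
    segments: tuple[tuple[str, tuple[int, int]], ...]
    switch_intervals: tuple[tuple[int, int], ...]
    novel_positions: tuple[int, ...]
    tie_class: str  # "unique_minimal" | "ambiguous"
    anchor_incompatible: bool = False
    degenerate: bool = False

    @property
    def n_exchanges(self) -> int:
        return max(len(self.segments) - 1, 0)

    @property
    def donor_runs(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.segments)

    @property
    def n_distinct_donors(self) -> int:
        return len(set(self.donor_runs))


class PanelIndex:
    """Cached numpy view of a panel for fast per-haplotype comparisons."""

    def __init__(self, panel: GermlinePanel):
        self.panel = panel
        L = panel.length
        n = len(panel.donors)
        self.bases = np.zeros((n, L), dtype="S1")
        self.cover = np.zeros((n, L), dtype=bool)
        for i, d in enumerate(panel.donors):
            self.bases[i] = np.frombuffer(d.sequence.encode(), dtype="S1")
            lo, hi = d.valid_range
            self.cover[i, lo:hi] = True

    def novel_positions(self, sequence: str) -> list[int]:
        """Positions where the observed base is carried by no covering donor."""
        if len(sequence) != self.panel.length:
            raise PaintingError(
                f"haplotype length {len(sequence)} != consensus {self.panel.length}"
            )
        obs = np.frombuffer(sequence.encode(), dtype="S1")
        matched = ((self.bases == obs[None, :]) & self.cover).any(axis=0)
        covered = self.cover.any(axis=0)
        return [int(p) for p in np.nonzero(covered & ~matched)[0]]


def observe_sites(
    haplotype: SomaticHaplotype, table: PolymorphismTable, panel: GermlinePanel
) -> list[SiteObservation]:
    """One observation per polymorphic site, with the compatible donor set.

    A donor is compatible when it covers the site and carries the observed
    base there; a truncated donor can never explain a base beyond its valid
    range.  An empty compatible set marks the base as novel.
    """
    if len(haplotype.sequence) != panel.length:
        raise PaintingError(
            f"{haplotype.id}: sequence length {len(haplotype.sequence)} does not "
            f"match consensus length {panel.length}"
        )
    out = []
    for site in table:
        base = haplotype.sequence[site.position]
        compat = frozenset(
            lab for lab, b in site.donor_bases.items() if b == base
        )
        out.append(SiteObservation(site=site, observed_base=base, compatible_donors=compat))
    return out


def _feasible_run_ends(
    labels: Sequence[str],
    compat: dict[str, np.ndarray],
    k: int,
) -> Optional[list[list[int]]]:
    """Per-switch feasible end-site indices for a fixed donor-run sequence.

    Runs must tile sites 0..k-1 in order, each run non-empty and compatible
    throughout.  Returns a list of feasible end indices per run (the last
    run always ends at k-1), or None when the sequence is infeasible.
    """
    m = len(labels)
    # reach[j][s]: furthest e with labels[j] compatible at every site s..e
    reach = []
    for lab in labels:
        c = compat[lab]
        r = np.full(k, -2, dtype=int)
        e = -1
        for s in range(k - 1, -1, -1):
            if not c[s]:
                e = -1
            else:
                e = s if e == -1 else e
                r[s] = e
        reach.append(r)
    # suffix-feasible start sets: A[j] = site indices s from which runs j..m-1
    # can tile s..k-1
    A: list[set[int]] = [set() for _ in range(m + 1)]
    A[m] = {k}
    for j in range(m - 1, -1, -1):
        for s in range(k):
            r = reach[j][s]
            if r < s:
                continue
            if any((e + 1) in A[j + 1] for e in range(s, r + 1)):
                A[j].add(s)
    if 0 not in A[0]:
        return None
    # forward: possible end indices per run given all feasible prefixes
    starts = {0}
    ends_per_run: list[list[int]] = []
    for j in range(m):
        ends = set()
        for s in starts:
            r = reach[j][s]
            if r < s:
                continue
            for e in range(s, r + 1):
                if (e + 1) in A[j + 1]:
                    ends.add(e)
        if not ends:
            return None
        ends_per_run.append(sorted(ends))
        starts = {e + 1 for e in ends if e + 1 <= k - 1} or {k}
    return ends_per_run


def _min_exchanges(compat_sets: list[frozenset[str]]) -> int:
    """Exchange-count DP over informative sites (site 0 is the anchor
    pseudo-site, so its compatible set is a singleton)."""
    prev = {d: 0 for d in compat_sets[0]}
    for C in compat_sets[1:]:
        best_prev = min(prev.values())
        cur = {}
        for d in C:
            stay = prev.get(d, None)
            cur[d] = min(
                stay if stay is not None else best_prev + 1, best_prev + 1
            )
        prev = cur
    return min(prev.values())


def paint_minimal(
    observations: list[SiteObservation],
    anchor_mt: str,
    panel: GermlinePanel,
    novel_positions: Optional[Sequence[int]] = None,
    haplotype_id: str = "",
) -> list[Painting]:
    """All paintings achieving minimum exchanges, then minimum distinct donors.

    Novel sites are excluded from the path constraints but recorded.  When
    every observed site is novel, a degenerate zero-segment painting is
    returned, flagged for downstream handling.
    """
    labels_all = [d.mt_label for d in panel.donors]
    if anchor_mt not in labels_all:
        raise PaintingError(f"anchor {anchor_mt!r} not in panel")
    informative = [o for o in observations if not o.is_novel]
    novel_here = sorted(
        set(o.position for o in observations if o.is_novel)
        | set(novel_positions or ())
    )
    if observations and not informative:  # every site novel: nothing to paint
        return [
            Painting(
                haplotype_id=haplotype_id,
                segments=(),
                switch_intervals=(),
                novel_positions=tuple(novel_here),
                tie_class="unique_minimal",
                degenerate=True,
            )
        ]
    positions = [o.position for o in informative]
    if positions != sorted(positions):
        raise PaintingError("observations must be ordered by position")
    anchor_incompatible = bool(informative) and (
        anchor_mt not in informative[0].compatible_donors
    )

    # pseudo-site at ANCHOR_POS pins the 5' segment to the anchor donor;
    # pseudo-site at L pins the 3' segment to a full-length donor (the
    # molecule reaches the exon end, which no truncated copy can supply)
    full_labels = frozenset(d.mt_label for d in panel.donors if d.full_length)
    if not full_labels:
        raise PaintingError("panel has no full-length donor")
    pos = [ANCHOR_POS] + positions + [panel.length]
    compat_sets = (
        [frozenset([anchor_mt])]
        + [o.compatible_donors for o in informative]
        + [full_labels]
    )
    k = len(pos)
    compat = {
        lab: np.array([lab in C for C in compat_sets], dtype=bool)
        for lab in labels_all
    }

    n_exch = _min_exchanges(compat_sets)
    m = n_exch + 1

    feasible: list[tuple[tuple[str, ...], list[list[int]]]] = []
    if n_exch <= _MAX_ENUM_EXCHANGES:
        for rest in itertools.product(labels_all, repeat=m - 1):
            labels = (anchor_mt,) + rest
            if any(labels[i] == labels[i + 1] for i in range(m - 1)):
                continue
            ends = _feasible_run_ends(labels, compat, k)
            if ends is not None:
                feasible.append((labels, ends))
    enumerated = bool(feasible)
    if not feasible:
        # pathological depth only: greedy furthest-reach path (minimal count)
        labels, ends = _greedy_path(compat_sets, anchor_mt)
        feasible = [(labels, ends)]

    min_distinct = min(len(set(labs)) for labs, _ in feasible)
    feasible = [(labs, ends) for labs, ends in feasible if len(set(labs)) == min_distinct]

    paintings: list[Painting] = []
    for labs, ends_per_run in feasible:
        mm = len(labs)
        # enumerate boundary vectors (ends of runs 0..mm-2); last run ends k-1
        def boundary_vectors(j: int, start: int):
            if j == mm - 1:
                if start <= k - 1 and compat[labs[j]][start:k].all():
                    yield ()
                return
            for e in ends_per_run[j]:
                if e < start:
                    continue
                if not compat[labs[j]][start : e + 1].all():
                    continue
                for tail in boundary_vectors(j + 1, e + 1):
                    yield (e,) + tail

        for bvec in boundary_vectors(0, 0):
            segs = []
            switches = []
            s = 0
            for j in range(mm):
                e = bvec[j] if j < mm - 1 else k - 1
                segs.append((labs[j], (pos[s], pos[e])))
                if j < mm - 1:
                    switches.append((pos[e], pos[e + 1]))
                s = e + 1
            paintings.append(
                Painting(
                    haplotype_id=haplotype_id,
                    segments=tuple(segs),
                    switch_intervals=tuple(switches),
                    novel_positions=tuple(novel_here),
                    tie_class="pending",
                    anchor_incompatible=anchor_incompatible,
                )
            )
    tie = "unique_minimal" if len(paintings) == 1 and enumerated else "ambiguous"
    paintings = [
        Painting(
            haplotype_id=p.haplotype_id,
            segments=p.segments,
            switch_intervals=p.switch_intervals,
            novel_positions=p.novel_positions,
            tie_class=tie,
            anchor_incompatible=p.anchor_incompatible,
        )
        for p in paintings
    ]
    return paintings


def _greedy_path(compat_sets, anchor_mt):
    """Left-to-right greedy maximal-run path; used only beyond the
    enumeration depth guard."""
    k = len(compat_sets)
    labels = [anchor_mt]
    ends = []
    s = 0
    while True:
        cur = labels[-1]
        e = s
        while e < k and cur in compat_sets[e]:
            e += 1
        e -= 1
        if e >= k - 1:
            ends.append([k - 1])
            break
        ends.append([e])
        nxt = e + 1
        # prefer the donor that extends furthest from nxt
        best, best_reach = None, -1
        for d in compat_sets[nxt]:
            r = nxt
            while r < k and d in compat_sets[r]:
                r += 1
            if r - 1 > best_reach:
                best, best_reach = d, r - 1
        labels.append(best)
        s = nxt
    return tuple(labels), ends


def select_painting(paintings: list[Painting], policy: str = "latest_switch") -> Painting:
    """Resolve ties among minimal paintings.

    ``latest_switch`` extends the anchor donor as far 3'-ward as possible,
    then each subsequent donor maximally.  ``conservative`` keeps those
    segments but widens each switch interval to the hull over all minimal
    paintings sharing the same donor-run sequence, so the reported interval
    is guaranteed to contain the true join under the mosaic model.
    """
    if not paintings:
        raise PaintingError("empty painting list")
    if len(paintings) == 1:
        return paintings[0]

    def key(p: Painting):
        lefts = tuple(l for l, _ in p.switch_intervals)
        return (lefts, tuple(r for _, r in p.switch_intervals), p.donor_runs)

    chosen = max(paintings, key=key)
    if policy == "latest_switch":
        return chosen
    if policy == "conservative":
        same = [p for p in paintings if p.donor_runs == chosen.donor_runs]
        widened = tuple(
            (
                min(p.switch_intervals[i][0] for p in same),
                max(p.switch_intervals[i][1] for p in same),
            )
            for i in range(len(chosen.switch_intervals))
        )
        return Painting(
            haplotype_id=chosen.haplotype_id,
            segments=chosen.segments,
            switch_intervals=widened,
            novel_positions=chosen.novel_positions,
            tie_class=chosen.tie_class,
            anchor_incompatible=chosen.anchor_incompatible,
        )
    raise PaintingError(f"unknown policy {policy!r}")


def paint_haplotype(
    haplotype: SomaticHaplotype,
    table: PolymorphismTable,
    panel: GermlinePanel,
    index: Optional[PanelIndex] = None,
    policy: str = "latest_switch",
) -> Painting:
    """Convenience wrapper: observe sites, scan for novel bases genome-wide,
    paint minimally and resolve ties under one policy."""
    idx = index if index is not None else PanelIndex(panel)
    obs = observe_sites(haplotype, table, panel)
    novel = idx.novel_positions(haplotype.sequence)
    minimal = paint_minimal(
        obs, haplotype.anchor_mt, panel, novel_positions=novel,
        haplotype_id=haplotype.id,
    )
    return select_painting(minimal, policy=policy)
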