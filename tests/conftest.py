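"""Shared fixtures and instance generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from matpaint.locus import (
    ConsensusProfile,
    DonorCopy,
    GermlinePanel,
    build_consensus,
)
from matpaint.painting import SomaticHaplotype

BASES = "ACGT"


def make_panel(donor_specs, consensus=None, side="A"):
    """Build a panel from (label, sequence, trunc) specs; consensus defaults
    to per-column majority."""
    L = len(donor_specs[0][1])
    donors = [
        DonorCopy(lab, seq, (0, trunc), trunc == L)
        for lab, seq, trunc in donor_specs
    ]
    if consensus is None:
        consensus = build_consensus(
            [d.sequence for d in donors], [d.valid_range for d in donors]
        )
    elif isinstance(consensus, str):
        consensus = ConsensusProfile(consensus)
    return GermlinePanel(side=side, donors=donors, consensus=consensus)


def toy_three_donor_panel():
    """Three full-length donors, sites at 10/40/70 with bases
    d1={A,T,G}, d2={G,T,A}, d3={G,C,G} over a constant background."""
    L = 100
    back = "C" * L

    def mk(bases):
        s = list(back)
        for p, b in zip((10, 40, 70), bases):
            s[p] = b
        return "".join(s)

    cons = list(back)
    cons[10], cons[40], cons[70] = "G", "T", "G"
    return make_panel(
        [("d1", mk("ATG"), L), ("d2", mk("GTA"), L), ("d3", mk("GCG"), L)],
        consensus="".join(cons),
    )


def random_panel(rng, n_donors, n_sites, alphabet=4, truncated_fraction=0.3):
    """Random panel with majority-consistent consensus for oracle tests."""
    L = n_sites * 4 + 8
    cons0 = "".join(rng.choice(list(BASES), size=L))
    positions = sorted(
        rng.choice(np.arange(1, L - 1), size=n_sites, replace=False).tolist()
    )
    raw = []
    for d in range(n_donors):
        s = list(cons0)
        trunc = (
            L
            if d == 0 or rng.random() > truncated_fraction
            else int(rng.integers(L // 2, L))
        )
        for p in positions:
            if p < trunc:
                s[p] = str(rng.choice(list(BASES[:alphabet])))
        raw.append((f"d{d}", "".join(s), trunc))
    consensus = build_consensus([s for _, s, _ in raw], [(0, t) for _, _, t in raw])
    donors = [
        DonorCopy(m, s, (0, t), t == len(consensus.sequence)) for m, s, t in raw
    ]
    return GermlinePanel("A", donors, consensus), positions


def mosaic_haplotype(rng, panel, positions, switch_prob=0.25, noise_prob=0.05):
    """Observed sequence built as a random donor mosaic plus sparse noise."""
    donors = panel.donors
    hap = list(panel.consensus.sequence)
    cur = int(rng.integers(len(donors)))
    anchor = donors[cur].mt_label
    for p in positions:
        if rng.random() < switch_prob:
            cur = int(rng.integers(len(donors)))
        d = donors[cur]
        hap[p] = d.sequence[p] if d.covers(p) else str(rng.choice(list(BASES)))
        if rng.random() < noise_prob:
            hap[p] = str(rng.choice(list(BASES)))
    return SomaticHaplotype("h", "".join(hap), anchor)


def random_haplotype(rng, panel, positions, alphabet=3):
    """Observed bases drawn independently of the donors (hard instances)."""
    hap = list(panel.consensus.sequence)
    for p in positions:
        hap[p] = str(rng.choice(list(BASES[:alphabet])))
    anchor = panel.donors[int(rng.integers(len(panel.donors)))].mt_label
    return SomaticHaplotype("h", "".join(hap), anchor)


def oracle_min_exchanges(compat_sets):
    """Brute-force minimum donor changes over all per-site assignments.

    Exhaustive depth-first enumeration with cost-bound pruning; entirely
    independent of the dynamic program it checks.
    """
    best = [len(compat_sets) + 1]
    k = len(compat_sets)

    def rec(i, last, cost):
        if cost >= best[0]:
            return
        if i == k:
            best[0] = cost
            return
        for d in compat_sets[i]:
            rec(i + 1, d, cost + (0 if d == last else 1))

    first = compat_sets[0]
    for d in first:
        rec(1, d, 0)
    return best[0]


def pseudo_compat(panel, anchor_mt, informative):
    """The compatibility chain painting operates on: anchor attachment,
    informative sites, full-length 3' terminus."""
    full = frozenset(d.mt_label for d in panel.donors if d.full_length)
    return (
        [frozenset([anchor_mt])]
        + [o.compatible_donors for o in informative]
        + [full]
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition simulation shared across tests (seed 42)."""
    from matpaint.simulate import SimConfig, simulate_cohorts

    return simulate_cohorts(SimConfig(seed=42))


@pytest.fixture(scope="session")
def toy_panel():
    return toy_three_donor_panel()
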