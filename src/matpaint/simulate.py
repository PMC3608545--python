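"""Synthetic germline panels, programmed-rearrangement and PCR simulation.

The generator emulates the architecture of the *T. thermophila* germline
*mat* locus: a tandem array of six head-to-head gene pairs whose TM exons
are near-identical, with ~59 (A side) and ~52 (B side) polymorphic sites,
mostly unique to one donor; only the two terminal copies are full length.
Somatic assembly is simulated under two mechanisms — ``coordinated`` (one
gene pair is selected, its two ends cut, and the full-length terminal TM
exons joined in one step) and ``independent_ends`` (recombination events at
either end excise one or more pairs and are reiterated until a single
complete pair remains).  PCR sequencing adds per-base substitution errors
and optional template switching; mature (120-fission) cohorts additionally
receive gene-conversion tracts modelling secondary somatic recombination.

Every haplotype carries a full ground-truth record (join points, excised
pairs, artifact events) so the painting and classification stages can be
validated end to end.  All randomness flows from a single seed through
named streams, and emitted files are byte-deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .locus import (
    ConsensusProfile,
    DonorCopy,
    GermlinePanel,
    LocusModelError,
    call_polymorphic_sites,
)
from .painting import SomaticHaplotype

#: germline array order of the real mat-2 locus (Fig-3-style architecture)
REAL_ORDER = ("II", "V", "VI", "IV", "VII", "III")

BASES = "ACGT"

_STREAMS = {"germline": 0, "exconjugant": 1, "mature": 2,
            "pcr_exconjugant": 3, "pcr_mature": 4}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic locus and cohorts.

    Site counts default to the real panel values (59 A-side, 52 B-side).
    ``pcr_error_rate`` defaults to 2e-5 substitutions per base.  The
    template-switch and conversion rates are order-of-magnitude
    placeholders (no measured values exist); conversion applies to the
    mature cohort only.
    """

    n_pairs: int = 6
    consensus_length_a: int = 1200
    consensus_length_b: int = 2400
    n_sites_a: int = 59
    n_sites_b: int = 52
    unique_fraction: float = 0.8
    deletion_fraction: float = 0.05
    truncation_fractions: tuple[float, ...] = (0.85, 0.70, 0.90, 0.60, 0.75)
    mechanism: str = "coordinated"
    pcr_error_rate: float = 2e-5
    template_switch_rate: float = 0.0
    conversion_rate: float = 0.2
    n_exconjugants: int = 60
    n_mature: int = 60
    inserts_per_molecule: int = 1
    crossover_beta: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self):
        for name in ("unique_fraction", "deletion_fraction", "pcr_error_rate",
                     "template_switch_rate", "conversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0,1], got {v}")
        if self.mechanism not in ("coordinated", "independent_ends"):
            raise SimulationError(f"unknown mechanism {self.mechanism!r}")
        if self.n_pairs < 1:
            raise SimulationError("n_pairs must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SimulationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "truncation_fractions" in d:
            d["truncation_fractions"] = tuple(d["truncation_fractions"])
        if d.get("crossover_beta") is not None:
            d["crossover_beta"] = tuple(d["crossover_beta"])
        return cls(**d)

    def stream(self, name: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), _STREAMS[name]])


def _labels(n_pairs: int) -> list[str]:
    if n_pairs == 6:
        return list(REAL_ORDER)
    return [f"D{i + 1}" for i in range(n_pairs)]


def _make_side(
    side: str, labels: list[str], length: int, n_sites: int, cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[GermlinePanel, list[dict]]:
    n = len(labels)
    terminal_idx = 0 if side == "A" else n - 1
    cons = "".join(rng.choice(list(BASES), size=length))
    truncs = []
    ti = 0
    for i in range(n):
        if i == terminal_idx:
            truncs.append(length)
        else:
            frac = cfg.truncation_fractions[ti % len(cfg.truncation_fractions)]
            truncs.append(int(frac * length))
            ti += 1
    coverage = np.array([[t > p for t in truncs] for p in range(length)]).sum(axis=1)

    n_unique = int(round(cfg.unique_fraction * n_sites)) if n > 1 else n_sites
    n_shared = n_sites - n_unique if n > 2 else 0
    n_unique = n_sites - n_shared
    elig_unique = np.nonzero(coverage >= min(3, n))[0]
    elig_shared = np.nonzero(coverage >= 5)[0] if n_shared else np.array([], dtype=int)
    if n > 1 and len(elig_unique) < n_sites:
        raise SimulationError(
            f"side {side}: cannot place {n_sites} sites on {len(elig_unique)} "
            f"eligible columns"
        )
    positions = rng.choice(elig_unique, size=n_sites, replace=False)
    positions.sort()
    shared_flags = np.zeros(n_sites, dtype=bool)
    if n_shared:
        ok = [i for i, p in enumerate(positions) if p in set(elig_shared.tolist())]
        pick = rng.choice(ok, size=min(n_shared, len(ok)), replace=False)
        shared_flags[pick] = True

    donor_seqs = [list(cons) for _ in range(n)]
    planted = []
    for i, p in enumerate(positions):
        p = int(p)
        covering = [j for j in range(n) if truncs[j] > p]
        cons_base = cons[p]
        if shared_flags[i] and len(covering) >= 5:
            dev = rng.choice(covering, size=2, replace=False)
            alt = rng.choice([b for b in BASES if b != cons_base])
            for j in dev:
                donor_seqs[j][p] = alt
            planted.append({
                "position": p,
                "deviants": {labels[int(j)]: alt for j in dev},
                "unique_to": None,
            })
        else:
            j = int(rng.choice(covering))
            if rng.random() < cfg.deletion_fraction:
                alt = "-"
            else:
                alt = str(rng.choice([b for b in BASES if b != cons_base]))
            donor_seqs[j][p] = alt
            planted.append({
                "position": p,
                "deviants": {labels[j]: alt},
                "unique_to": labels[j],
            })

    donors = []
    for j, lab in enumerate(labels):
        donors.append(
            DonorCopy(
                mt_label=lab,
                sequence="".join(donor_seqs[j]),
                valid_range=(0, truncs[j]),
                full_length=truncs[j] == length,
            )
        )
    panel = GermlinePanel(side=side, donors=donors, consensus=ConsensusProfile(cons))
    return panel, planted


def make_germline(config: SimConfig) -> tuple[GermlinePanel, GermlinePanel, dict]:
    """Build both donor panels plus the ground-truth site plan."""
    rng = config.stream("germline")
    labels = _labels(config.n_pairs)
    if config.n_sites_a >= config.consensus_length_a or \
            config.n_sites_b >= config.consensus_length_b:
        raise SimulationError("site count exceeds consensus length")
    if config.n_pairs == 1:
        # a single full-length pair: no polymorphism is definable
        panel_a, sites_a = _make_side("A", labels, config.consensus_length_a, 0, config, rng)
        panel_b, sites_b = _make_side("B", labels, config.consensus_length_b, 0, config, rng)
    else:
        panel_a, sites_a = _make_side(
            "A", labels, config.consensus_length_a, config.n_sites_a, config, rng)
        panel_b, sites_b = _make_side(
            "B", labels, config.consensus_length_b, config.n_sites_b, config, rng)
    truth = {
        "seed": config.seed,
        "array_order": labels,
        "planted_sites": {"A": sites_a, "B": sites_b},
    }
    return panel_a, panel_b, truth


def _draw_join(rng: np.random.Generator, trunc: int,
               beta: Optional[tuple[float, float]]) -> int:
    """Crossover point j in [1, trunc]: positions [0, j) come from the
    anchor-side copy, [j, L) from the downstream copy."""
    if beta is None:
        return int(rng.integers(1, trunc + 1))
    a, b = beta
    return 1 + int(rng.beta(a, b) * trunc)


def simulate_rearrangement(
    panel_a: GermlinePanel,
    panel_b: GermlinePanel,
    mechanism: str,
    rng: np.random.Generator,
    crossover_beta: Optional[tuple[float, float]] = None,
) -> dict:
    """Assemble one somatic gene pair; returns sequences plus ground truth.

    ``coordinated``: one retained pair chosen uniformly, one crossover per
    side inside the homologous overlap with the terminal full-length exon.
    ``independent_ends``: events at either end join the current terminal
    exon to a downstream/upstream truncated copy, excising intervening
    pairs, reiterated until one pair remains.
    """
    order = [d.mt_label for d in panel_a.donors]
    n = len(order)
    term_a, term_b = panel_a.donors[0], panel_b.donors[n - 1]
    if not (term_a.full_length and term_b.full_length):
        raise SimulationError("panels must carry terminal full-length donors")

    if mechanism == "coordinated":
        r = int(rng.integers(n))
        lab = order[r]
        events = []
        if r == 0:
            seq_a, join_a = term_a.sequence, None
        else:
            d = panel_a.donors[r]
            join_a = _draw_join(rng, d.trunc, crossover_beta)
            seq_a = d.sequence[:join_a] + term_a.sequence[join_a:]
            events.append({"side": "A", "target": lab, "join": join_a,
                           "excised": order[:r]})
        if r == n - 1:
            seq_b, join_b = term_b.sequence, None
        else:
            d = panel_b.donors[r]
            join_b = _draw_join(rng, d.trunc, crossover_beta)
            seq_b = d.sequence[:join_b] + term_b.sequence[join_b:]
            events.append({"side": "B", "target": lab, "join": join_b,
                           "excised": order[r + 1:]})
        return {
            "retained": lab,
            "sequence_a": seq_a,
            "sequence_b": seq_b,
            "join_a": join_a,
            "join_b": join_b,
            "events": events,
            "mechanism": mechanism,
        }

    # independent_ends
    lo, hi = 0, n - 1
    cur_a, cur_b = term_a.sequence, term_b.sequence
    events: list[dict] = []
    join_a = join_b = None
    while lo < hi:
        if rng.random() < 0.5:
            t = int(rng.integers(lo + 1, hi + 1))
            d = panel_a.donors[t]
            j = _draw_join(rng, d.trunc, crossover_beta)
            cur_a = d.sequence[:j] + cur_a[j:]
            events.append({"side": "A", "target": order[t], "join": j,
                           "excised": order[lo:t]})
            lo, join_a = t, j
        else:
            t = int(rng.integers(lo, hi))
            d = panel_b.donors[t]
            j = _draw_join(rng, d.trunc, crossover_beta)
            cur_b = d.sequence[:j] + cur_b[j:]
            events.append({"side": "B", "target": order[t], "join": j,
                           "excised": order[t + 1:hi + 1]})
            hi, join_b = t, j
    return {
        "retained": order[lo],
        "sequence_a": cur_a,
        "sequence_b": cur_b,
        "join_a": join_a,
        "join_b": join_b,
        "events": events,
        "mechanism": mechanism,
    }


def apply_conversion(
    sequence: str,
    panel: GermlinePanel,
    site_positions: list[int],
    rng: np.random.Generator,
) -> tuple[str, Optional[dict]]:
    """Swap a tract between two random informative sites to another donor —
    the X->Y->X signature of somatic gene conversion."""
    if len(site_positions) < 2:
        return sequence, None
    i, j = sorted(rng.choice(len(site_positions), size=2, replace=False))
    if i == j:
        return sequence, None
    lo, hi = site_positions[i], site_positions[j]  # tract = [lo, hi)
    eligible = [d for d in panel.donors if d.trunc >= hi]
    donor = eligible[int(rng.integers(len(eligible)))]
    new = sequence[:lo] + donor.sequence[lo:hi] + sequence[hi:]
    if new == sequence:
        return sequence, None
    return new, {"tract": [int(lo), int(hi)], "donor": donor.mt_label}


def simulate_pcr(
    pool: list[str],
    pcr_error_rate: float,
    template_switch_rate: float,
    rng: np.random.Generator,
    inserts_per_molecule: int = 1,
) -> tuple[list[str], list[dict]]:
    """Sample sequenced inserts from a molecule pool.

    Each insert independently receives Bernoulli(per-base) substitutions
    (gap columns are never mutated) and, with probability
    ``template_switch_rate``, one switch at a uniform internal position to
    another uniformly chosen pool molecule.  Artifact events are recorded
    per insert.
    """
    if not pool:
        raise SimulationError("empty molecule pool")
    inserts: list[str] = []
    truth: list[dict] = []
    for mi, template in enumerate(pool):
        for _ in range(inserts_per_molecule):
            seq = template
            events: list[dict] = []
            if len(pool) > 1 and rng.random() < template_switch_rate:
                partner = int(rng.integers(len(pool) - 1))
                if partner >= mi:
                    partner += 1
                p = int(rng.integers(1, len(seq)))
                seq = seq[:p] + pool[partner][p:]
                events.append({"type": "template_switch",
                               "position": p, "partner": partner})
            if pcr_error_rate > 0:
                valid = np.frombuffer(seq.encode(), dtype="S1") != b"-"
                n_err = rng.binomial(int(valid.sum()), pcr_error_rate)
                if n_err:
                    idx = rng.choice(np.nonzero(valid)[0], size=n_err, replace=False)
                    chars = list(seq)
                    for p in sorted(int(x) for x in idx):
                        old = chars[p]
                        chars[p] = str(rng.choice([b for b in BASES if b != old]))
                        events.append({"type": "pcr_error", "position": p,
                                       "from": old, "to": chars[p]})
                    seq = "".join(chars)
            inserts.append(seq)
            truth.append({"template": mi, "events": events})
    return inserts, truth


def _collapse(
    seqs: list[str], anchors: list[str], cohort: str, side: str
) -> list[SomaticHaplotype]:
    """Group identical (anchor, sequence) inserts into haplotypes with
    multiplicities, deterministically ordered."""
    counts: dict[tuple[str, str], int] = {}
    for s, a in zip(seqs, anchors):
        counts[(a, s)] = counts.get((a, s), 0) + 1
    out = []
    for i, ((a, s), m) in enumerate(sorted(counts.items())):
        out.append(
            SomaticHaplotype(
                id=f"{side}_{cohort}_{i:04d}",
                sequence=s,
                anchor_mt=a,
                multiplicity=m,
                cohort=cohort,
            )
        )
    return out


@dataclass
class CohortBundle:
    """In-memory result of one full simulation."""

    config: SimConfig
    panel_a: GermlinePanel
    panel_b: GermlinePanel
    haplotypes: dict[tuple[str, str], list[SomaticHaplotype]]  # (cohort, side)
    truth: dict


def simulate_cohorts(config: SimConfig) -> CohortBundle:
    """Generate panels and both cohorts (exconjugant 0-fission, mature
    120-fission) with PCR artifacts and ground truth."""
    panel_a, panel_b, truth = make_germline(config)
    sites_a = [s["position"] for s in truth["planted_sites"]["A"]]
    sites_b = [s["position"] for s in truth["planted_sites"]["B"]]
    haplotypes: dict[tuple[str, str], list[SomaticHaplotype]] = {}
    truth["cells"] = {}
    truth["pcr"] = {}

    for cohort, n_cells in (("exconjugant_0fission", config.n_exconjugants),
                            ("mature_120fission", config.n_mature)):
        stream = "exconjugant" if cohort.startswith("excon") else "mature"
        rng = config.stream(stream)
        cells = []
        for _ in range(n_cells):
            cell = simulate_rearrangement(
                panel_a, panel_b, config.mechanism, rng,
                crossover_beta=config.crossover_beta,
            )
            cell["conversions"] = {"A": None, "B": None}
            if cohort == "mature_120fission" and config.conversion_rate > 0:
                for side, key, sites, panel in (
                    ("A", "sequence_a", sites_a, panel_a),
                    ("B", "sequence_b", sites_b, panel_b),
                ):
                    if rng.random() < config.conversion_rate:
                        newseq, ev = apply_conversion(cell[key], panel, sites, rng)
                        cell[key] = newseq
                        cell["conversions"][side] = ev
            cells.append(cell)
        truth["cells"][cohort] = cells

        prng = config.stream(f"pcr_{stream}")
        truth["pcr"][cohort] = {}
        for side, key, _panel in (("A", "sequence_a", panel_a), ("B", "sequence_b", panel_b)):
            if not cells:
                haplotypes[(cohort, side)] = []
                truth["pcr"][cohort][side] = []
                continue
            pool = [c[key] for c in cells]
            anchors = [c["retained"] for c in cells]
            inserts, pcr_truth = simulate_pcr(
                pool, config.pcr_error_rate, config.template_switch_rate,
                prng, config.inserts_per_molecule,
            )
            ins_anchors = [
                anchors[t["template"]] for t in pcr_truth
            ]
            haplotypes[(cohort, side)] = _collapse(inserts, ins_anchors, cohort, side)
            truth["pcr"][cohort][side] = pcr_truth

    return CohortBundle(
        config=config, panel_a=panel_a, panel_b=panel_b,
        haplotypes=haplotypes, truth=truth,
    )


def generate_cohort(config: SimConfig, outdir: str | Path) -> CohortBundle:
    """Run :func:`simulate_cohorts` and write FASTA files plus truth JSON."""
    from . import io as mio  # local import to avoid a cycle

    bundle = simulate_cohorts(config)
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_panel_fasta(bundle.panel_a, outdir / "germline_A.fasta")
        mio.write_panel_fasta(bundle.panel_b, outdir / "germline_B.fasta")
        for (cohort, side), haps in sorted(bundle.haplotypes.items()):
            short = "0fission" if cohort.startswith("excon") else "120fission"
            mio.write_haplotype_fasta(
                haps, outdir / f"somatic_{short}_{side}.fasta"
            )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    except OSError as exc:
        raise SimulationError(f"failed writing to {outdir}: {exc}") from exc
    return bundle
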