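# Methods

## Background and model

*Tetrahymena thermophila* carries a germline *mat* locus organised as a
tandem array of six head-to-head, incomplete mating-type gene pairs (array
order II–V–VI–IV–VII–III for the *mat-2* allele modelled here). Each gene
ends in a terminal exon encoding a transmembrane domain. Only the two
terminal copies of the array are full length (*MTA2* on the A side, *MTB3*
on the B side); every other copy is 3'-truncated. During differentiation
of a new somatic nucleus, one gene pair is completed by joining its
truncated tm segments to the full-length terminal TM exons, and all other
pairs are deleted.

Because the TM/tm copies are nearly identical, the only evidence for where
joining occurred is the small set of polymorphic sites — mostly unique to
one donor copy — scattered along the exon. `matpaint` turns that evidence
into inference in four stages:

1. **Locus model** (`matpaint.locus`). Donor copies are aligned to a
   common consensus (per-column majority over covering donors). Every
   column where at least one covering donor deviates becomes a
   `PolymorphicSite`; a site is *unique* when exactly one covering donor
   differs from all others. A truncated donor is undefined beyond its
   valid range `[0, trunc)` and never votes or matches there.
2. **Painting** (`matpaint.painting`). A somatic haplotype is explained as
   a mosaic of donor segments with (a) the minimum number of exchanges
   and (b), among those, the minimum number of distinct donors. This is
   the parsimony criterion used throughout; no probabilistic copying model
   is fitted.
3. **Event statistics** (`matpaint.events`). Paintings are classified
   against the single-simple-join expectation, gene conversions are
   counted by the X→Y→X adjacency rule, join regions are aggregated, the
   novel-base rate is estimated, and cohorts are compared by Pearson
   homogeneity chi-square.
4. **Simulation** (`matpaint.simulate`). A generative model of the locus,
   the rearrangement, and the sequencing artifacts provides ground truth
   for every stage.

## Coordinates and encodings

All internal coordinates are 0-based, half-open, on the consensus of the
relevant side; human-readable outputs add 1. Deletions relative to the
consensus are a fifth character state `-` occupying explicit columns; a
multi-base indel occupies consecutive columns. Consensus ties are broken
by fixed base order A < C < G < T < `-`, a convention chosen purely for
determinism.

## Painting algorithm

At each polymorphic site the observed base defines a compatible-donor set
(donors covering the site and carrying that base). Bases carried by no
covering donor are **novel**; novel sites are recorded but excluded from
path constraints, so a painting is never distorted to absorb a sequencing
error. Novel bases are additionally detected at invariant columns by a
genome-wide scan, since substitution errors mostly fall outside the site
table.

Two *pseudo-sites* encode physical constraints that the site table cannot:

* position −1 is compatible only with the **anchor** donor — the
  mating-type-specific segment attached 5' of the exon identifies the
  donor of the 5'-most segment by construction;
* position L is compatible with exactly the **full-length** donors — the
  sequenced molecule extends to the exon's 3' end, which no truncated
  copy can supply.

Neither pseudo-site asserts a specific join partner; they only express the
molecule's physical extent. A consequence is that the "minimum necessary"
exchange count (one for non-terminal mating types, zero for the terminal
genes) emerges from the chain itself rather than being imposed. If the
anchor donor is incompatible with the first real informative site the
haplotype is flagged (`anchor_incompatible`) but painting proceeds.

Minimisation runs in two steps. A dynamic program over informative sites
(state = donor, transition cost 1 per donor change) gives the minimum
exchange count E*. All donor-run label sequences of length E*+1 beginning
with the anchor are then enumerated (at most 5^E* for six donors), each
checked for feasibility by an interval-tiling scan, filtered to the
minimum number of distinct donors, and expanded into every boundary
placement. The result is the complete set of minimal paintings. Beyond
E* = 6 (never reached on data generated by the locus model) a single
greedy furthest-reach painting is returned; greedy maximal runs are
optimal for segment count, so the exchange count is still exact, but tie
enumeration is skipped and the painting is marked ambiguous.

Tie resolution between minimal paintings uses two policies:

* `latest_switch` (default) extends the anchor donor as far 3'-ward as
  possible, then each subsequent donor maximally — the natural analogue of
  drawing the simplest origin;
* `conservative` keeps those segments but widens each switch interval to
  the hull (minimum left bound, maximum right bound) over all minimal
  paintings sharing the same donor-run sequence, so the reported interval
  is guaranteed to contain the true join point under the mosaic model.
  Join-region aggregation always uses the conservative intervals.

Switch intervals are half-open `(left, right]`, bounded by the informative
sites flanking the exchange; the virtual bounds −1 and L appear when the
join is localised only by a pseudo-site (i.e. before the first or after
the last informative site).

## Event classification

`minimum_necessary` is 0 when the anchor is the terminal gene (already
complete in the germline) and 1 otherwise. A haplotype is a **single
simple join** when its excess exchanges are zero, it uses at most two
distinct donors, and it carries no gene-conversion signature. Gene
conversions are counted as adjacent-run patterns X→Y→X; consecutive
exchanges through a third donor (X→Y→Z→X) are not counted, and
overlapping signatures each count. Cohort percentages are weighted by
sequenced-insert multiplicity by default; an unweighted per-haplotype
variant is always computed alongside, since either denominator is
defensible for clone-collapsed data.

The novel-base rate is novel bases per sequenced base pair, per-insert
weighted, with the reciprocal (bp per novel base) reported; gap columns
are excluded from the denominator. Cohort comparisons use the Pearson
homogeneity chi-square without continuity correction
(`scipy.stats.chi2_contingency`); categories with zero total in both
cohorts are dropped with a warning, a single surviving category yields
p = 1 (trivially homogeneous), and p-values are reported unadjusted.

The aggregate join region is the minimal interval containing every
single-join conservative switch interval. Its length is reported under
both endpoint conventions (open span `right − left` and site-inclusive
`right − left + 1`), since either boundary convention is used for spans
of this kind.

## Synthetic data generator

`SimConfig` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_pairs` | 6 | gene pairs in the array, order II–V–VI–IV–VII–III |
| `consensus_length_a/b` | 1200 / 2400 bp | TM exon lengths (the real exons are ~1–3 kb) |
| `n_sites_a/b` | 59 / 52 | planted polymorphic sites per side |
| `unique_fraction` | 0.8 | fraction of sites unique to one donor ("most") |
| `deletion_fraction` | 0.05 | unique sites planted as single-column deletions |
| `truncation_fractions` | 0.85…0.60 | tm truncations as fractions of the exon |
| `mechanism` | `coordinated` | or `independent_ends` |
| `pcr_error_rate` | 2e-5 /bp | per-base substitution rate |
| `template_switch_rate` | 0 | per-molecule chimera probability |
| `conversion_rate` | 0.2 | per-molecule conversion probability, mature cohort only |
| `n_exconjugants`/`n_mature` | 60 / 60 | cells per cohort |

Sites are planted so that the declared consensus is a strict per-column
majority (unique sites need ≥3 covering donors, shared-pair sites ≥5),
which makes site recovery exact by construction and testable. The
`coordinated` mechanism picks one retained pair uniformly and one
crossover per side uniformly within the homologous overlap between the
retained tm and the terminal TM exon; `independent_ends` reiterates
end-wise recombination events, excising intervening pairs, until one pair
remains. Crossovers are uniform because no positional model is measured;
the observed concentration of A-side joins near the exon start in the
real data is an empirical finding, not a model input, so a configurable
Beta positional bias (`crossover_beta`) is provided for sensitivity tests
only. Template-switch and conversion rates are order-of-magnitude
placeholders — the source data quantify neither — and must be treated as
such. Gene conversion is simulated as a donor-swapped tract between two
random informative sites, producing the X→Y→X signature. IES excision is
treated as already complete: somatic sequences are IES-free, consistent
with mating-type determination occurring after IES removal, and painting
operates on IES-free sequence.

What the generator does **not** emulate: the positional clustering of real
A-side joins (hence the simulated join-region span covers most of the
exon rather than a few hundred bp); amitotic chromosome assortment
dynamics (the mature cohort's secondary recombination is a phenomenological
per-molecule rate, not a population model); epigenetic marking; PCR
recombination hotspots; read-level sequencing error profiles. Passing
tests therefore demonstrate correctness of the inference machinery under
the stated generative model, not calibration against real libraries.

Determinism: all randomness flows from the single config seed through
named streams (`germline`, `exconjugant`, `mature`, `pcr_*`), and emitted
files are byte-identical across runs. Identical inserts are collapsed
into haplotypes with "x N" multiplicities in deterministic order.

## Collapsed alignment format

The plain-text rendering follows the collapsed-alignment convention used
for this locus:
invariant column runs collapse to one dot, deviant columns are explicit,
deletions are `-`, positions beyond a truncation are blank, 1-based column
positions are written vertically, and the A side is displayed 3'→5'
left-to-right (the writer alone flips; coordinates stay 5'→3'). Novel
bases are written lowercase with a `*` marker line beneath the row, which
keeps the format round-trip exact: expanding any row against the embedded
consensus reproduces the original sequence byte-for-byte, and
re-collapsing a parsed document is idempotent. Exact visual fidelity to
any particular hand-made alignment layout is not a goal.

## Problem sizes and numerical checks

The test suite validates: painting against a brute-force assignment
oracle (1,000 random instances, ≤12 sites, ≤6 donors); 100% single-simple
classification and true-crossover containment on 500 artifact-free
exconjugants; exact planted-site recovery across seeds; novel-base-rate
recovery within three binomial standard errors at 2e-5 over >1e6
simulated bases; uniform retained-type frequencies for the coordinated
mechanism (100 meta-replicates of 6,000 assemblies on a 300-bp locus);
chi-square null calibration against uniform p-values (1,000 identical
multinomial pairs of n = 300); detection power for a 0.3 conversion rate
(≥90 rejections in 100 replicate cohorts); and byte-exact collapsed
round trips on 100 random cohorts. `scripts/acceptance.py` recomputes the
headline quantities at the default study conditions, with a deeper
700-cell cohort for the novel-base rate (~2.5 M bases).

## Known limitations

* Parsimony cannot distinguish donors that are locally identical; such
  ambiguity is surfaced (`tie_class`, conservative hulls) rather than
  resolved.
* The conservative interval is a hull per switch index over paintings
  with the same donor-run sequence; when several distinct run sequences
  are minimal, intervals from the alternatives are not merged across
  sequences.
* Panels read from FASTA rebuild the consensus by majority; a panel whose
  true consensus is not the covering majority would shift site calls.
* Secondary-recombination attribution (somatic-copy recombination vs
  maturation events) is deliberately out of scope; the package reports
  category counts and homogeneity tests only.
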