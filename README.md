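# matpaint

Donor painting and rearrangement simulation for the *Tetrahymena
thermophila* mating-type (*mat*) locus.

## The problem

*T. thermophila* chooses one of six mating types (II–VII, *mat-2* allele)
by programmed DNA rearrangement: the germline *mat* locus is a tandem
array of six incomplete, head-to-head *MTA*/*MTB* gene pairs, and during
differentiation of a new somatic nucleus exactly one pair is completed —
its truncated transmembrane-exon segments (tm) joined to the single
full-length terminal exons (*MTA2*-TM, *MTB3*-TM) at the ends of the
array — while every other pair is deleted. The TM/tm copies are nearly
identical, so the joining events are only visible through the few dozen
polymorphic sites, mostly unique to one germline copy, carried along the
exon.

`matpaint` is for researchers analysing such gene-segment joining data:
it calls the polymorphic sites from a germline donor panel, *paints* each
sequenced somatic TM exon as a mosaic of germline donors with the minimum
number of exchanges, localises the join sites, classifies haplotypes
(single simple join, extra exchanges, third donors, gene conversions
X→Y→X), estimates the novel-base (PCR/repair error) rate, and compares
exconjugant (0-fission) with mature (120-fission) cohorts by homogeneity
chi-square. A synthetic generator simulates the locus architecture, both
proposed rearrangement mechanisms (coordinated ends vs independently
processed ends), PCR substitution errors and template switching, so the
entire pipeline runs and is validated end-to-end without external data.

## The method in brief

For haplotype *h* with observed base *h(p)* at polymorphic site *p*, the
compatible donor set is C(p) = { d : d covers p and d(p) = h(p) }; empty
C(p) marks a novel base. Painting finds all partitions of the exon into
donor segments minimising first the number of exchanges and then the
number of distinct donors, subject to two structural constraints: the 5'
segment belongs to the anchor donor (identified by the attached
mating-type-specific segment) and the 3' terminus belongs to a
full-length donor (a truncated copy cannot supply the exon end). Each
exchange is localised to the half-open interval between its flanking
informative sites; a conservative policy widens intervals to the hull
over all minimal paintings so the true join is guaranteed to lie inside.
See `docs/methods.md` for the full model.

## Worked example

Simulate the default study conditions (six pairs, 59/52 sites, 60 cells
per cohort, PCR error 2×10⁻⁵) and run the analysis chain:

```
python analysis/01_simulate_locus.py --seed 42
python analysis/02_call_sites.py
python analysis/03_paint_haplotypes.py
python analysis/04_classify_events.py
python analysis/05_compare_cohorts.py
```

which prints, among other lines:

```
array order: II - V - VI - IV - VII - III
side A: 59 polymorphic sites (47 unique to one donor, 6 deletions) -> results/sites_A.tsv
side B: 52 polymorphic sites (42 unique to one donor, 5 deletions) -> results/sites_B.tsv
side A exconjugant: exchanges {0x:13, 1x:47}
side A mature: exchanges {0x:8, 1x:45, 2x:3, 3x:4}
side A exconjugant: single simple join 100.0% of 60 inserts (100.0% of 40 haplotypes)
  novel bases: 1 in 71,941 bp (1 per 71,941 bp)
side A mature: single simple join 88.3% of 60 inserts (84.1% of 44 haplotypes)
side A: chi2=7.43 df=2 p=0.0243 (0-fission [60, 0, 0] vs 120-fission [53, 4, 3])
coordinated mechanism: retained-type GOF p=0.882 over 6000 assemblies
```

Reading this: every exconjugant insert is explained by the minimum
necessary joining events (one exchange, or zero for the terminal genes —
the `0x` entries are *MTA2* haplotypes, already complete in the
germline); the mature cohort, simulated with a 0.2 per-molecule
secondary-recombination rate, shows extra exchanges and third donors,
and the chi-square flags the cohort difference; novel bases appear at
roughly the planted 1-per-50,000 bp error rate; and the coordinated
mechanism retains each mating type uniformly.

The same stages are available as a CLI (`matpaint sites | paint |
classify | simulate | report | run`) and as library functions
(`matpaint.pipeline.analyze` runs everything in memory).

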