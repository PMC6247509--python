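# mycoprimer

A toolkit for evaluating and designing fungi-specific 18S rRNA gene (SSU)
primers. Fungal community surveys and isolate classification both depend on
choosing a primer pair with high fungal coverage, a broad phylum spectrum and
low co-amplification of non-fungal eukaryotes — properties that vary wildly
across the many "fungi-specific" SSU primers in circulation. `mycoprimer`
gives microbial ecologists and mycologists a reproducible, scriptable way to
measure those properties by in silico PCR against taxonomically annotated
reference sequences (SILVA-style FASTA), to screen and rank primer pairs
under explicit criteria, to design new primers, and to design annealing
blocking oligonucleotides that suppress co-amplification.

## What it computes

**Degenerate, mismatch-tolerant matching.** A primer position *mismatches* a
reference position iff their IUPAC base sets are disjoint; primer N (and
inosine) never mismatch. A primer's *coverage* of a taxon group at mismatch
level *m* ("0M", "1M", …) is the fraction of the group's sequences carrying at
least one binding site with ≤ *m* mismatches. A pair covers a record when it
yields a valid amplicon (forward site upstream of the reverse-complement
site) with the allowance applied per primer. *Co-amplification* is the
coverage of the pooled non-fungal eukaryotes by a "fungi-specific" pair.

**Oligo properties** follow the OligoCalc composition formulas: Wallace rule
Tm = 2(nA+nT) + 4(nG+nC) below 14 nt; basic Tm = 64.9 + 41(nGC − 16.4)/N and
salt-adjusted Tm = 100.5 + 41·nGC/N − 820/N + 16.6·log₁₀[Na⁺] for longer
oligos, with nGC the ambiguity-weighted G+C count. Primer names follow the
Gargas & DePriest nomenclature on the *S. cerevisiae* 18S reference
(acc. Z75578), e.g. `nu-SSU-1333-5′`.

**Screening ladder.** Single primers must cover ≥ 50% of fungal sequences at
1M. Pairs form under a strict < 5 °C basic-Tm difference and classify into
amplicon-size groups S (≤ 600 nt), M (600–1000 nt) and L (> 1000 nt).
Biodiversity pairs need ≥ 65% / ≥ 75% fungal coverage at 0M/1M, must target
every major fungal phylum/subphylum, and must co-amplify < 20% at 1M; ranking
is by highest fungal coverage, then lowest co-amplification, then lowest
co-amplification of the problematic marine outgroups (Stramenopiles,
Alveolata, Rhizaria, *Telonema*). Group-specific shortlists (Sanger-size
pairs) keep up to five pairs per group with group coverage > 70%.

**Primer design** finds conserved words (18–21 nt) under three quorums
(strict occurrence, mismatch-tolerant sensitivity, outgroup false-positive
rate), filters candidate pairs (all groups targeted, ≤ 20% co-amplification,
≤ 600 nt amplicon, ≤ 10 °C ΔTm, the more specific primer having the lower
Tm), scores them by barcode coverage Bc (fraction of target species
amplified) and barcode specificity Bs (fraction of amplified species with an
unambiguous insert), and merges matched variants into degenerate consensus
primers.

**Blocking-oligo design** amplifies the database with a pair (primer
footprints kept), splits amplicons by taxonomic group, dereplicates, and
enumerates 18–25-mers overlapping a primer footprint by ≥ 3 nt; the selected
blocker maximizes exact-match coverage of its target group subject to a cap
on cumulative fungal coverage and a Tm within tolerance of the competing
primer. Output annotates the 3′ modification (C3 spacer) that makes the
oligo non-extendable.

A seeded synthetic-database generator plants binding sites with exact
per-record mismatch counts and rejects accidental secondary sites, giving
exact ground truth for every statistic — the test oracle for the whole
toolkit.

## Worked example

Generate a synthetic database in which 60 of 100 fungal records carry an
exact annealing site for each primer of the FF390/FR-1 pair, 30 more carry a
single-substitution site, and 2 of 20 Stramenopiles records carry exact dual
sites — then measure pair coverage:

```python
from mycoprimer import (Oligo, build_pair, pair_coverage,
                        generate_reference_db)
from mycoprimer.simulate import FixtureSpec, GroupSpec, PlantedSite

fwd = Oligo("nu-SSU-1333-5'", "CGATAACGAACGAGACCT", "forward", ref_position=1333)
rev = Oligo("nu-SSU-1647-3'", "AICCATTCAATCGGTAIT", "reverse", ref_position=1647)
spec = FixtureSpec(
    groups=[GroupSpec("Ascomycota", True, 100, subphylum="Pezizomycotina"),
            GroupSpec("Stramenopiles", False, 20)],
    template_length=800,
    planted_sites=[
        PlantedSite(fwd, 101, {"Ascomycota": {0: 60, 1: 30}, "Stramenopiles": {0: 2}}),
        PlantedSite(rev, 401, {"Ascomycota": {0: 60, 1: 30}, "Stramenopiles": {0: 2}}),
    ],
    seed=42,
)
db, truth = generate_reference_db(spec)
report = pair_coverage(build_pair(fwd, rev), db, (0, 1))
print(f"fungal coverage 0M: {100 * report.fungal_coverage(0):.1f}%")
print(f"fungal coverage 1M: {100 * report.fungal_coverage(1):.1f}%")
print(f"co-amplification 0M: {100 * report.co_amplification(0):.1f}%")
```

prints

```
fungal coverage 0M: 60.0%
fungal coverage 1M: 90.0%
co-amplification 0M: 10.0%
```

exactly the planted ground truth: 60/100 fungal records amplify with zero
mismatches, 90/100 when one mismatch per primer is allowed, and 2/20
outgroup records co-amplify.

The same workflow is available from the shell:

```bash
mycoprimer props   --primers primers.tsv --out props.tsv
mycoprimer coverage --primers primers.tsv --db refs.fasta --out coverage.tsv
mycoprimer run     --primers primers.tsv --db refs.fasta --out-dir results/
mycoprimer design-blockers --pair pair.tsv --db refs.fasta \
    --outgroups Stramenopiles,Alveolata --out blockers.tsv
```

## Layout

- `src/mycoprimer/reference.py` — SILVA-style FASTA loading, fungal/outgroup
  classification, taxonomy overrides, dereplication
- `src/mycoprimer/oligo.py` — GC, Tm, degeneracy, reverse complement, naming
- `src/mycoprimer/pcr.py` — matching engine, amplification, coverage reports
- `src/mycoprimer/pairs.py` — pairing rule, size groups, variable regions
- `src/mycoprimer/screening.py` — screens, criteria, shortlists, ranking
- `src/mycoprimer/design.py` — conserved-word design, Bc/Bs, consensus
- `src/mycoprimer/blockers.py` — blocking-oligonucleotide design
- `src/mycoprimer/simulate.py` — synthetic databases with exact ground truth
- `src/mycoprimer/cli.py`, `pipeline.py`, `io.py` — CLI, run config, tables

See `docs/methods.md` for the model, parameter and design details.
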