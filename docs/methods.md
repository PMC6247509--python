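# Methods

## Matching model

The engine treats every IUPAC code as a set of concrete bases and declares a
mismatch at a position iff the primer's and the reference's sets are
disjoint. This is the standard probe-matching convention: a degenerate
primer position (R, Y, N, …) matches any base in its set, and reference
ambiguity codes (common in SILVA-style data) are handled symmetrically
rather than being treated as errors. Consequences worth knowing:

- Primer N and inosine (I) never mismatch anything.
- Reference N never mismatches any primer position. On heavily
  N-contaminated references this inflates coverage; the matching is
  deliberately permissive rather than probabilistic.
- The mismatch count equals the minimum Hamming distance over all concrete
  expansions of both sequences (the property the test suite verifies against
  a brute-force expansion oracle).

Forward primers scan plus-strand windows; reverse primers match windows
whose reverse complement matches the primer, implemented by scanning with
the primer's reverse complement. Internally sequences are encoded as 4-bit
base-set masks and scanned with a vectorized sliding window; all reported
coordinates are 1-based inclusive.

No positional mismatch weighting and no 3′-exclusion zone are applied by
default: the screening criteria are defined on a global per-primer mismatch
count. (The synthetic generator does expose a protected-3′-zone option for
sensitivity analyses.) Amplification requires a forward site strictly
upstream of the reverse-complement site and accepts amplicon lengths of
50–3,000 nt by default — wide enough for the long-read size class (largest
published amplicon 1,615 nt) while excluding degenerate geometries such as
overlapping footprints. A record with several valid amplicons is still
counted once by coverage. Detailed-match mode supports up to 3 mismatches
per primer.

## Oligo properties

Tm uses the OligoCalc composition formulas (the convention the evaluated
primer lists were characterized with): Wallace rule 2(nA+nT)+4(nG+nC) below
14 nt; basic Tm = 64.9 + 41(nGC − 16.4)/N at ≥ 14 nt; salt-adjusted
Tm = 100.5 + 41·nGC/N − 820/N + 16.6·log₁₀[Na⁺] with [Na⁺] defaulting to
0.05 M (for short oligos the Wallace value is rescaled from the 50 mM
reference condition). nGC is the ambiguity-weighted G+C count: each code
contributes the G+C fraction of its base set (S=1, W=0, R/Y/K/M/N=0.5,
B/V=2/3, D/H=1/3). Reported Tm is rounded to 0.1 °C; all comparisons (the
pairing rule, blocker Tm tolerance) use unrounded values.

Three of the four published blocking-oligo Tm values (Alveolata 50.3 °C,
Rhizaria 48.9 °C, Telonema 48.1 °C) are reproduced exactly by the basic
formula; the Stramenopiles entry (48.3 °C printed vs 48.0 °C computed)
matches no OligoCalc variant we could reconcile with its printed sequence
and is left documented rather than special-cased.

Inosine is carried as a distinct letter: it pairs with every base for
matching purposes, contributes 0 to the weighted G+C count (it is a weakly
pairing universal base), counts toward length, and has degeneracy 1 (one
physical base). A known consequence: composition formulas undervalue
inosine-containing primers — FR-1 (two inosines) computes to 41.2 °C basic
Tm, putting the well-established FF390/FR-1 combination 6.8 °C apart, outside
the strict < 5 °C pairing rule. Workflows evaluating inosine-containing
primers should either widen `max_tm_diff` or supply externally computed Tm
values; the pairing rule itself is applied exactly as stated.

Primer naming follows the Gargas & DePriest scheme,
`nu-SSU-<4-digit position>-5′/3′[-length]`, anchored at the supplied
reference position. The stored position is defined as the reference
coordinate of the primer's 5′ terminus in its own sense (leftmost plus-strand
coordinate for forward primers, rightmost for reverse primers), and the
expected amplicon length on the naming reference is
`rev_pos − fwd_pos + 1`. This is a labeling/geometry convention, not a claim
about empirical amplicon lengths, which depend on the actual reference
sequences amplified.

## Reference databases and classification

A record is fungal iff the literal label "Fungi" (configurable) occurs at
any rank of its taxonomy path; the phylum is the next rank and the subphylum
the one after (absent subphylum ⇒ phylum-level counting only). Non-fungal
eukaryotes get an outgroup label: the first rank below the supergroup
containers (Eukaryota, SAR, TSAR, Opisthokonta), so `Eukaryota;SAR;
Stramenopiles;…` labels as Stramenopiles. Prokaryotes are dropped at load
with a logged count — all denominators in this toolkit are eukaryote-only,
because co-amplification is defined over non-fungal *eukaryotes*.
Dereplication collapses exact full-length duplicates within a taxon group,
keeping the first occurrence. Taxonomy overrides (prefix → replacement, e.g.
relabeling zygomycete fungi onto the revised taxonomy) are applied atomically
and re-classify the record; two overrides matching one record is an error.

## Screening thresholds

All thresholds default to the published criteria and keep their quoted
inequality directions exactly (each boundary has a dedicated unit test):

| rule | default | direction |
| --- | --- | --- |
| single-primer screen, fungal coverage at 1M | 0.50 | ≥ (inclusive) |
| biodiversity fungal coverage 0M / 1M | 0.65 / 0.75 | ≥ |
| biodiversity co-amplification at 1M | 0.20 | < (strict) |
| group-specific co-amplification 0M / 1M | 0.20 / 0.30 | < |
| group-specific group coverage | 0.70 | > (strict, "exceeds") |
| shortlist size per group | 5 | ≤ |
| pairing Tm difference | 5 °C | < (strict) |
| size groups | ≤600 / (600,1000] / >1000 | — |

"Major fungal phyla and subphyla" are the phylum/subphylum labels present in
the loaded database with at least `major_group_min_records` records
(default 10) — the published list is database-dependent, so membership is
derived from the data. "Targeting" a group means coverage > 0 at 1M
(configurable to 0M); the historically documented exclusion case was a pair
matching zero sequences of one subphylum. Group-specific shortlist coverage
is evaluated at 0M by default (the stated rule does not fix the level;
configurable). Ranking is the lexicographic formalization of the verbal
rule — (fungal coverage at 0M ↓, co-amplification at 0M ↑, mean
focus-group co-amplification ↑, name) with passing pairs always ahead of
failing ones; no numeric weights are invented.

## Variable-region map

The toolkit ships approximate V1–V9 intervals (no V6 — it does not exist in
the 18S numbering) on the *S. cerevisiae* reference: V1 69–109, V2 134–297,
V3 437–545, V4 620–880, V5 1049–1107, V7 1400–1465, V8 1480–1560,
V9 1727–1786. These are editable configuration (3-column TSV), chosen once
to be consistent with the region annotations of the seven published top
pairs (e.g. the 1333–1647 amplicon covers V7+V8 only and stops short of V9).
A region is "full" when contained in the amplicon interval, "partial" on any
overlap ≥ 1 nt.

## Primer design

Word discovery is exhaustive over the target records (desk-scale databases;
no suffix-structure indexing, though nothing forbids adding one): a word of
permitted length is a candidate when its exact-occurrence rate among targets
is ≥ `strict_quorum`, its mismatch-tolerant occurrence rate is
≥ `sensitivity_quorum`, and its mismatch-tolerant rate on the outgroup
partition does not exceed `false_positive_quorum`. Defaults 0.7 / 0.7 / 0.2
sit inside the published exploration ranges (0.5–0.8, 0.5–0.8, 0.1–0.3) and
are configuration, not claims. The six candidate-pair filters are
conjunctive; "most specific primer with the lowest Tm" is implemented as:
the member with the strictly lower individual outgroup match rate must not
have the higher Tm.

Barcode metrics use "species" = the final taxonomy-path element (SILVA-style
paths terminate at or near species). Bs compares *inserts* (primer
footprints excluded), since variation under the primers is masked by the
primers themselves; a species is unambiguous when its dereplicated insert
set is disjoint from every other amplified species' set. Bc = Bs = 0 when
nothing amplifies. Target-group strategies (fungi-only, fungi+outgroup,
basal-fungi-only databases) are dataset-selection options, not separate
algorithms.

## Blocking-oligo design

The blocker is built in the same sense as the competing primer — it competes
for that primer's annealing site — so amplicons are reverse-complemented
when the competing primer is the reverse one. Candidates are all 18–25-mers
from the target group's dereplicated amplicons whose span overlaps the
primer footprint by ≥ 3 positions. Scoring uses the strictest criterion:
coverage of a record = exact full-length 0-mismatch occurrence (either
strand), consistent with per-group blocker coverages being reported without
a mismatch level. Selection maximizes target-group coverage subject to
cumulative fungal coverage ≤ `fungal_coverage_cap` (default 0.01, a
configurable bound mirroring the ≤ 0.1% ambition for fungal blocking) and
|Tm − primer Tm| ≤ `tm_tolerance` (default ±2.0 °C; the four published
blockers lie within ≈2 °C of each other). Ties break deterministically:
lower fungal coverage, smaller |ΔTm|, lexicographically smallest sequence.
`overlap_nt` is the count of aligned identical positions between blocker and
primer over the footprint (base-set intersection, so inosine counts as
shared); the published Rhizaria blocker reproduces its documented 15 shared
nt with the forward primer under this convention. The 3′ modification
("C3 spacer") is an output annotation — a synthesis instruction — never part
of the matched sequence.

## Synthetic databases and what passing tests show

The generator emulates the *shape* of a curated SSU reference set: taxon
groups of chosen sizes with SILVA-style taxonomy paths, i.i.d. background
composition (default uniform), and annealing sites planted at fixed
positions with an exact number of mutated positions per record. Each
mutation substitutes a base outside the primer's set at that position (a
guaranteed mismatch), mutations never land on positions a primer cannot
mismatch (N/I) nor inside a configured protected 3′ zone, and finished
records are re-scanned to reject accidental secondary sites (bounded
resampling, then a hard error). Ground truth is therefore exact, and the
suite asserts measured coverage equals it at every level — for all fixtures.

What the fixtures do **not** model: rRNA secondary structure, phylogenetic
covariation, length heterogeneity, chimeras, or realistic taxon abundance
distributions. Passing tests demonstrate the *statistics and algorithms* are
correct, not that any particular primer performs well on real databases;
coverage percentages on real SILVA releases are database-version-dependent
and are out of scope here.

Sizes used by default test/acceptance runs: 100 fungal + 20 outgroup records
of 800 nt for coverage recovery; 200 random 150-nt records and 1,000 random
(primer, window) pairs for the matching-engine oracle; a 14-record
three-group fixture for blocker design; a 164-profile panel for the screen.
These were chosen as the smallest sizes at which every planted proportion is
exactly representable.

## Numerical and degenerate-input conventions

- Coverage fractions are exact rational counts (matched/denominator);
  rendered tables show one-decimal percentages.
- Empty fungal partition → error (the denominator of every headline
  statistic); empty candidate sets and groups without amplicons are
  structured errors or empty results as documented per function.
- A primer longer than a record yields no hits (not an error).
- All stochastic draws flow from a single integer seed; identical seed and
  configuration give byte-identical outputs (tested).

## Known limitations

- Composition-formula Tm is crude for inosine/degenerate primers (see
  above); nearest-neighbor thermodynamics, hairpin and dimer screening are
  deliberately out of scope.
- Matching has no positional weighting, so a 3′-terminal mismatch counts the
  same as a 5′ one despite its larger effect on extension.
- The conserved-word search is exhaustive and intended for curated,
  desk-scale target sets, not for multi-gigabase references.
- Blocker efficiency in a real PCR (competition kinetics, co-blocking of
  multiple oligos) is not modeled; the design criteria are purely
  sequence-based.
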