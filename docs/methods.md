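# Methods

## Scope and model

`hemeped` analyses pedigrees of familial malignant blood disorders (MBD)
under the working model that susceptibility segregates non-Mendelianly, with
sex-of-parent-dependent transmission (consistent with parental genomic
imprinting), a birth-order effect restricted to male CLL in paternal lines,
and anticipation.  The package takes no position on mechanism: every
procedure is a descriptive or inferential statistic on the observed pedigree,
and the simulator encodes the *statistical* structure only.

Diagnoses are grouped as lymphoproliferative (LPD: CLL, ALL, other lymphoid
leukemias, MM, MGUS, HL, DLBCL, FL, other lymphomas), myeloproliferative
(MPD: AML, CML, other MPD) and other (leukemia NOS, malignant histiocytosis).
CLL is singled out everywhere because its segregation differs from every
other diagnosis.

## Pair enumeration and lineage

Every affected member acts once as proband crude (Pc).  An affected relative
(AR) is an affected member 1–5 generations *before* the Pc whose connecting
path carries at most 5 unaffected members strictly between the two
(`max_generations` and `max_healthy_intermediates`, both default 5).
Connecting paths ascend through parents and may then descend once (simple
up-then-down paths), so ancestors are reached as well as collaterals such as
uncles and great-aunts.  A pair is *vertical* when a purely ascending path
exists within the caps, *oblique* otherwise; all non-vertical relations are
treated as oblique, and same-generation relatives (siblings, cousins) form no
pair at all — sibling concordance is available as a separate horizontal
operation and never enters the pair table.  When several paths connect the
same Pc/AR through the same first parental edge, the representative is the
shortest cap-satisfying path with the fewest unaffected intermediates; this
choice makes enumeration monotone in both caps (raising either cap never
removes a pair).

Lineage is paternal (PA) when the first ancestral step from the Pc passes
through the father, maternal (MA) through the mother.  In consanguinity
loops an ancestor can be reachable through both parents; `classify_lineage`
then signals ambiguity, and the enumerator emits one pair per distinct first
edge (one PA, one MA), both flagged, so lineage-specific counts remain
complete and a sensitivity analysis can drop or keep them explicitly.

The reported pair table keeps vertical pairs with generation gap ≤ 2
(parent–offspring and grandparent–grandchild).  A grandparent pair may have
an unaffected intermediate parent; the `healthy_intermediates` field is
retained on every pair so the stricter reading (no skipped generation) can
be recovered by filtering.  Percentages of offspring-side members by sex are
rounded half-up to integers; empty strata are reported as undefined (NaN),
never as 0%.

## Co- and contravariation

For a proband diagnosis *P* and AR diagnosis *d* in group *G*, the AR pool
is the number of ARs of group *G* related to probands with *P* (total, male,
female).  The expected count is

    E_d = (p_d / 100) · N_pool,

where *p_d* is the prevalence of *d* within *G* **carried at its 1-decimal
percent** — so HL at 8.7% against a pool of 121 gives 10.53, not the
unrounded 10.497.  This deliberate quantisation mirrors how such expectation
tables are conventionally computed and printed; `exact_prevalence=True`
disables it.  The sex split of the expectation follows the diagnosis' own
sex ratio, summing to the total exactly before display rounding (which is
round-half-up: 10.53 → 11).

The test statistic sums Pearson terms (O−E)²/E over the male and female
cells and is referred to chi-square with df = 2 (the reporting convention
for these tables), without continuity correction, at α = 0.05 and without
multiple-testing adjustment.  When the observed cells arise as a multinomial
classification of a pool much larger than the expectation, the two retained
cells are approximately independent Poisson counts, and the df = 2 reference
is calibrated — the test suite verifies a type-I rate within [0.03, 0.07]
over 10,000 null replicates (pool 500, expected cells 30 and 20).  Each
result row carries both a `direction` (the sign of OBS−EXP, always defined)
and a `call` (direction gated at p < α); published tables of this kind have
used significance conventions that a plain 1- or 2-df Pearson chi-square on
the printed cells does not reproduce, so direction and call are kept
separate rather than tuned to match.  A zero expected cell raises an error
directing the caller to pool diagnoses.

## Birth-order effect

For sibship *j* of size *s* with *m* affected at birth ranks *r₁…r_m*, the
observed contribution is the rank sum; under the null of exchangeable
placement (ranks drawn without replacement) its mean is *m(s+1)/2* and its
variance *m(s−m)(s+1)/12*.  Totals are summed over informative sibships
(those with 0 < m < s and s ≥ 2; singletons and fully affected sibships have
zero null variance and contribute to neither side).  The total is referred
to a normal approximation: `late_excess` if above mean + 1.96·sd,
`early_excess` if below mean − 1.96·sd.  The moments are verified against
exhaustive enumeration for every s ≤ 6, and the empirical type-I rate over
10,000 simulated 30-sibship datasets is checked to lie in [0.03, 0.07].

Ranks are positional within the full sibship (same father AND same mother) —
the only definition under which the null placement is exchangeable.  Stored
birth orders win; when a sibship has only birth years, ranks are derived
ascending with ties broken lexicographically by id (and a warning logged).
An optional restriction (sex, diagnosis, lineage) narrows which affected
members count; unselected members are treated as unaffected for ranking and
for the control test.

The Wilcoxon control scores each selected affected member as (number of
older healthy sibs) − (number of younger healthy sibs) and tests the scores
against symmetry about zero, dropping zeros per the standard convention; if
every score is zero the test is reported as undefined rather than silently
significant.

## Anticipation

Generation strata are founder depths — the longest parent-path from any
founder, the only operational definition that is well defined in looped
pedigrees.  The report gives the affected count and median onset per
stratum (oldest → youngest), a two-sided rank-based trend test (Kendall's
tau of onset against depth; degenerate inputs with constant onset or a
single stratum return a zero statistic or an undefined flag), a
least-squares slope in years/generation as the effect-size estimate, and,
when a registry reference prevalence table is supplied, a df = 1 chi-square
per diagnosis of the familial count against the reference proportion.

## The simulator

What it emulates: susceptibility as a two-state carrier process.  Carriers
transmit to each child independently with probability
`transmit_prob[(parent_sex, child_sex)]` (default 0.5 throughout); carriers
are affected with penetrance 0.6 (default), receive a diagnosis drawn from a
configurable mixture (default: the packaged continental counts in nuclear
mode, the endemic counts in endemic mode, sex-conditional), and an onset age
`onset_median − depth·anticipation_delta + N(0, onset_spread²)` truncated at
1 year (normal noise, sd default 8 y, seed-stable).  Allele-level imprinting
is deliberately not modelled: pair statistics constrain only the
transmission weights, so the carrier process is the minimal sufficient
parameterisation.

`maternal_drive` (default 0.64, the observed maternal pair fraction in the
reference material) shifts segregation toward maternal lines.  In nuclear
mode it is the probability that the founder carrier is the mother, making
the expected MA fraction of vertical pairs equal the drive exactly; in
endemic mode it tilts each transmission by 2·drive (mothers) and 2·(1−drive)
(fathers).  `birth_order_enhancement` β ≥ 1 multiplies the penetrance *odds*
by β^(rank−1), by default only for male offspring of paternal carrier lines
whose prospective diagnosis is CLL (the scope is configurable).  β = 1 and
`anticipation_delta = 0` recover the null model exactly.

Nuclear mode draws sibship sizes as 1 + Poisson(parity − 1) with parity 2.7
(the reference material's mean cases per family is 2.7 and its realized
simulated analogue is reported per run) and ascertains families to contain
at least two affected members, as familial materials are collected.  Endemic
mode grows one connected pedigree from founder couples (one carrier per
couple, alternating sex) over `n_generations`; children marry in-migrating
founders except with probability `loop_rate` (default 0.25) a
within-generation non-sibling, which creates the consanguinity loops of an
isolate.  The loop rate is a free knob, not calibrated to any real isolate.

What it does **not** emulate: real demography (mortality, remarriage,
population growth), HLA haplotypes or microchimerism, incidence (the package
works with prevalences throughout), aunts/uncles in nuclear mode (two
generations only), or genetic linkage between diagnoses.  Passing tests
therefore demonstrate that the *procedures* recover known statistical
structure, not that real registry data satisfy the model.

Because the published registry pedigrees are not deposited, the packaged
fixture pedigrees (`fixtures.continental_pedigree`, `fixtures.
faroese_pedigree`, `fixtures.table2_pedigree`) are synthetic constructions
that realize the printed marginal counts exactly — diagnosis-by-sex counts,
onset medians (offsets placed symmetrically about the median so the median
is exact), family count and the pair-table cells — while ids and the precise
family structure are invented.  They validate arithmetic, not biology.

## Numerical and design choices

- Prevalences are reported and consumed at 1-decimal percent; display
  rounding is always round-half-up; statistical quantities are never
  display-rounded internally.
- Chi-square df defaults to 2 (reporting convention), α = 0.05, no
  continuity correction, no multiplicity adjustment.
- Sex is binary {male, female}: the entire analysis is sex-stratified and
  the source registries record only these.
- Missing parents make founders; pairs are never formed through a parent
  whose record is absent.
- An optional `uncertain` CSV column excludes members whose position in the
  tree is unreliable, severing references to them, without guessing any
  further criteria.
- Monte-Carlo problem sizes in the test suite (10,000 replicates for the
  two type-I calibrations; 2,500 families for drive recovery; 250 replicates
  of 40 families for the full-pipeline null) were chosen to give binomial
  standard errors comfortably inside the asserted bands while keeping the
  default test run short.

## Known limitations

- The oblique class is a catch-all: any relative connected up-then-down
  within the caps that is not a direct ancestor, with no finer taxonomy.
- Endemic-mode simulations produce denser affected clustering than real
  isolates because mortality and out-migration are not modelled.
- The normal approximation of the rank-sum total is poor with very few
  informative sibships; the result object reports
  `n_sibships_informative` so callers can judge.
- The df = 2 convention for the 2-cell chi-square is conservative when the
  observed total is constrained (fixed-pool sampling); use df = 1 in that
  design.
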