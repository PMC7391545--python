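# Methods

## The sib-mating cross-type chain

At one autosomal locus, a haplodiploid line propagated by single-pair
brother–sister mating is fully described by the cross type of its current
mated female: *A* (heterozygous mother, mate shares no allele), *B*
(heterozygous, mate shares one), *C* (homozygous, mate differs), *D*
(homozygous, mate matches). Working out the brood of each type and the
four equiprobable sib pairings gives the linear map

A' = A/2, B' = A/2 + B/2 + C, C' = B/4, D' = B/4 + D,

a four-state Markov chain with D absorbing. The inbreeding coefficient
(probability the female's two alleles are identical by descent) is
f = C + D, and D is the probability the line is already fully inbred at
the locus. Because at most three founder alleles can enter through one
mated female, a single locus never needs more than the x/y/z labelling.

Assumptions: single locus; random sib-mating uniform over an effectively
large brood; a single father per brood (first-male sperm precedence); no
selection or mutation. The default initial state is the most-heterozygotic
founding cross A₀ = 1 — the conservative choice when founder genotypes
are unknown, since any allele sharing only accelerates inbreeding.
Arbitrary valid initial distributions are accepted for known founders.

**Arithmetic.** Every update divides by 2 or 4, so from a dyadic start
the state stays dyadic. The default mode carries `fractions.Fraction`
values and is exact at any horizon; a floating mode exists for long
horizons where speed matters. Input validation accepts a float state
whose frequencies sum to 1 within 1e-12.

**The two f computations and their index offset.** The direct recurrence
f_t = 1/4 + (1/4) f_{t−2} + (1/2) f_{t−1} with f_1 = f_2 = 0 conditions
on where a female's two alleles come from: with probability 1/2 both
descend from the grandmother (then IBD with probability 1/2, else
inheriting her f), and with probability 1/2 one comes from each
grandparent (inheriting the mother's f). Its natural index starts one
later than the chain's: the recurrence value at index t + 1 equals the
chain's f at generation t, and only this alignment yields 95.1% "after
15 generations". The chain indexing (generation 0 = founding cross,
generation t = t completed sib-mating generations) is canonical
throughout the package; the one-index shift is applied explicitly
wherever recurrence output is compared.

**Display.** Percentages are rounded to one decimal for display; stored
values keep full precision (exact rationals in the default mode).

## Gene dropping

The simulator draws transmission directly: a daughter receives one
uniformly chosen maternal allele plus the paternal allele per locus, a
son one uniformly chosen maternal allele; loci segregate independently
(no linkage — recombination maps are out of scope). Each generation one
daughter and one son are drawn independently and mated, which equals
random sib-mating in the large-brood limit.

The Monte-Carlo estimator tracks only the per-line state (female allele
pair, mate allele) in int8 arrays and is vectorised over lines and loci;
the explicit pedigree layer (`Individual`/`MatedPair` with parent ids)
is the reference implementation and the two are cross-checked in the
test suite. With 2×10⁵ lines the full 15-generation run takes well under
a second.

**Random numbers.** The root seed spawns one `SeedSequence` child per
(generation, purpose) pair — daughter picks and son picks use separate
streams — and draws are indexed by line within each stream. Consequence:
results are bit-for-bit reproducible, and enlarging the panel appends
new lines without altering existing ones. The individual-based
single-line simulator instead derives one child stream per line index,
so a line is identical whether simulated alone or within a panel.

**Per-locus versus genome-wide "fully inbred".** The chain's D is a
single-locus quantity, and the estimator reports it per locus (focal
locus = first). A genome-wide summary, the proportion of lines type D at
every simulated locus, is exposed as `genomewide_fully_inbred_prob`; for
unlinked loci it estimates the product of per-locus probabilities and is
an independence-assumption extra, not a chain quantity.

## Line-panel attrition

The panel model mirrors the husbandry protocol: each of n lines
(default 450) is kept on r replicate patches (default 3) per generation
(default horizon 15); each patch fails independently with probability q
per generation, and a line dies only when all r patches fail, i.e. with
probability q^r. Replicates are survival insurance only — the line
continues from one mated female, so there is no genetic branching.
Expected survivors after G generations: n·(1 − q^r)^G.

Per-cause failure rates (female death, null fecundity, no hatching,
single-sex brood) are not separately known, so the optional cause
decomposition is purely a labelling that must sum to the marginal q.
The marginal itself can be calibrated from an observed endpoint by
inverting the closed form with bounded root-finding (`brentq`); the
endpoint 450 → 59 lines over 15 generations with r = 3 gives q ≈ 0.502.
The calibration assumes q constant over generations and lines; real
attrition likely concentrates in early generations (inbreeding
depression) and varies between genotypes, so the simulated trajectory
shape is not evidence about real per-generation loss curves — only the
endpoint is anchored.

What the synthetic panels do not emulate: brood-size demography,
viability selection on genotypes, inbreeding depression feeding back on
failure rates, and non-independence of replicate patches (shared
environment). Passing tests therefore validate the bookkeeping and the
calibrated endpoint, not those biological mechanisms.

## Crossing designs

Combination labels record maternal lineage left-to-right; the first
letter is the population of the mother's maternal line and hence the
mitochondrial origin (the labels' semantics are fixed here explicitly
since letter order is otherwise ambiguous). Matched pairs over four
populations: reciprocal crosses within two fixed pairs, then reciprocal
hybrid × hybrid crosses across pairs — 8 combinations, each founder
mitochondrial origin of exactly 2. Round robin over three populations:
all six reciprocal parental crosses, each F1 female mated to males of
the population absent from her parental cross — 6 combinations, again 2
per founder. Only these two designs are supported; other population
counts are rejected at validation rather than generalized, because male
production (via virgin females, one generation delayed) makes naive
generalizations silently wrong.

The schedule builder materialises the synchronization repeats as
explicit generation blocks: since hybrid males exist only one generation
after the cross that made their mothers, each cross set is repeated one
generation later (including a third parental cohort in the four-population
design) so that every female consumed in block g was produced by a cross
in block g−1 and every male by a virgin-isolation step in block g−1.
Those two provenance rules are re-checked by `CrossSchedule.validate`,
so a hand-edited schedule that drops an isolation step fails loudly.
Founder-population females are stock and exempt from the provenance rule.

The founding census equalizes representation at the minimum available
count per combination (surplus genotypes are discarded by design); the
pass-through rule exists for scarce pools — e.g. keeping all males when
their total is too low to equalize. Screening out an incompatible
population (hybrid breakdown) is handled by the user excluding it before
design construction; it is not detected computationally.

## Effective generations of selection

Transfers source females greedily: current box, then the t−1 backup,
then the base population (modelled as unlimited and at Gen 0 throughout;
its own laboratory evolution is out of scope). The effective number of
generations of selection is the transfer-weighted mean
Gen_{t+1} = 1 + (N_t·Gen_t + N_{t−1}·Gen_{t−1} + N_0·0)/N_total, kept
fractional — it is a mean, not a count. The backup box carries the
regime's value of one step earlier (it is simply the previous
generation's box left until the next transfer); backups older than one
step are not supported. Transfer mortality is not modelled — the user
supplies realized availabilities.

Bounds: the value always lies in [1, chronological generation count],
and a step gains at most one generation over max(Gen_t, Gen_{t−1}). The
simpler-looking bound Gen_{t+1} ≤ Gen_t + 1 fails in one real scenario:
after a full base refill the current box's Gen (1) can be lower than the
backup's, and a backup-heavy next transfer then gains more than one over
the previous value. The property tests assert the correct bound.

## Configuration and reproducibility

Runs are described by flat YAML configs with one parameter block per
subcommand; unknown keys are rejected. Defaults are the protocol values
this toolkit models: horizon 15 generations, 450 lines × 3 replicates,
200 crosses per type, 220 females per transfer. Every stochastic run
records its seed in all outputs; identical config + seed reproduce
byte-identical data artifacts (the run report additionally carries wall
timestamps, so reports from two runs differ only in those fields).

## Problem sizes

The analytic chain is exact and instantaneous at any horizon used here
(≤ 35 generations). Monte-Carlo verification uses 2×10⁵ replicate lines
(binomial SE ≈ 0.05 percentage points on f at generation 15); panel
calibration checks use 10⁴ replicate panels of 450 lines (SE of the mean
survivor count ≈ 0.07 lines). Both finish in seconds on one CPU.

## Known limitations

- Single-father broods only; mixed paternity is not modelled.
- No selection, mutation, linkage, or inbreeding depression anywhere.
- The two supported crossing designs are hard-coded; the schedule is a
  class-level plan (genotype classes and counts), not an individual-level
  assignment.
- Diploid systems are out of scope, though the chain structure would
  differ only in the transition map.
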