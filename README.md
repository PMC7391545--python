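# haplobreed

Planning and simulation toolkit for building the standard breeding
resources of haplodiploid arthropods — outbred laboratory populations,
panels of inbred lines, and serially transferred experimental-evolution
populations. It was written with spider mites (*Tetranychus*) in mind, but
applies to any arrhenotokous haplodiploid: females develop from fertilized
(diploid) eggs, males from unfertilized (haploid) eggs and therefore have
no father.

## What it computes

**Inbreeding under full sib-mating** (`haplobreed.inbreeding`). At a
single locus a sib-mated line is one of four cross types: *A* [xy]×[z],
*B* [xy]×[x], *C* [xx]×[y], *D* [xx]×[x]. One generation of random
sib-mating maps the frequencies linearly:

    A' = A/2        B' = A/2 + B/2 + C
    C' = B/4        D' = B/4 + D

The inbreeding coefficient is f = C + D and D is the probability the line
is fully inbred at the locus (type D is absorbing). The equivalent direct
recurrence f_t = 1/4 + (1/4) f_{t−2} + (1/2) f_{t−1} (f_1 = f_2 = 0) is
also provided; its index t + 1 corresponds to chain generation t. All
updates are halvings and quarterings, so the chain runs in exact
dyadic-rational arithmetic by default.

**Gene dropping** (`haplobreed.genedrop`). A seeded individual-based
simulator of allele transmission through sib-mating lines (one maternal
allele chosen uniformly per locus; daughters add the paternal allele,
sons get nothing else), used as a Monte-Carlo check of the chain, plus a
line-panel attrition model: each line is kept on r replicate patches per
generation and is lost only when all r fail.

**Crossing designs** (`haplobreed.crossing`). Enumeration and scheduling
of the two controlled designs that build a fully hybrid outbred
population with balanced nuclear and mitochondrial representation:
matched pairs over four founder populations (8 combinations) and a round
robin over three (6 combinations), plus founding censuses under the
equal-representation minimum rule.

**Transfer bookkeeping** (`haplobreed.evolution`). The serial-transfer
protocol sources females with priority current box → previous-generation
backup → base population, and the effective number of generations of
selection evolves as

    Gen_{t+1} = 1 + (N_t·Gen_t + N_{t−1}·Gen_{t−1} + N_0·Gen_0) / N_total

with Gen_0 = 0 for the unadapted base.

## Worked example

```python
import haplobreed as hb

# exact inbreeding trajectory from the most-heterozygotic founding cross
traj = hb.iterate_trajectory(hb.CrossTypeDistribution.pure("A"), 15)
point = traj[15]
print(f"f_15 = {float(point.f):.6f} ({100 * float(point.f):.1f}%)")
print(f"D_15 = {float(point.p_fully_inbred):.6f} ({100 * float(point.p_fully_inbred):.1f}%)")

# how hard was the protocol on the lines? calibrate from 450 -> 59 survivors
q = hb.calibrate_failure_prob(450, 59, generations=15, replicates_per_line=3)
print(f"per-replicate failure probability: {q:.3f}")
```

prints

```
f_15 = 0.951263 (95.1%)
D_15 = 0.936218 (93.6%)
per-replicate failure probability: 0.502
```

After 15 generations of sib-mating a line founded by an [xy] female mated
to a [z] male has inbreeding coefficient 95.1% and is fully inbred at the
focal locus with probability 93.6%; keeping 59 of 450 lines over that
horizon with 3 replicate patches per line corresponds to a per-patch,
per-generation failure probability of about 0.50.

The same pipelines are available from the shell:

```
haplobreed inbreeding --generations 15 --out run/
haplobreed design --kind matched-pairs-4 --labels ABCD --out run/
haplobreed panel --calibrate-from-survivors 59 --seed 7 --out run/
haplobreed evolve --history-file history.tsv --target 220 --out run/
```

Every run writes TSV/JSON artifacts plus a `run_report.json` echoing the
configuration and seed, so identical configs reproduce identical results.

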