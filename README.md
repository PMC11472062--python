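# dorqseq

A toolkit for hybridization-probe quantification of tRNA isoacceptor pools
(DORQ-seq style workflows): it designs the quantification oligos, simulates
the capture → index-PCR → sequencing process, turns reads into abundance
tables, and converts relative abundances into absolute masses by spike-in
standard addition.

**Who it is for.** Groups measuring tRNA isoacceptor abundances by
hybridizing dye-labeled DNA oligos (cDOQs) to total tRNA and sequencing the
captured constructs, and anyone who wants a fully synthetic, seeded test bed
for that pipeline's computational steps.

## The method in brief

**Probe design.** For each tRNA family the probe's recognition sequence is
the reverse complement of the last 40 nt of the mature tRNA (the 3′ end,
including the universal CCA). References whose 3′ 40-mers are within a
Levenshtein distance below 6 are collapsed into one family (single-linkage
connected components); the probe construct is

```
P5 (21 nt) + recognition (40 nt) + P3 (26 nt)  =  87 nt
```

dyed 6-FAM for cytosolic and Cy5 for mitochondrial families. The design is
validated by the minimum pairwise Levenshtein distance *d*<sub>min</sub> of
the recognition set; *d*<sub>min</sub> = 6 is 15% of the hybridization
region.

**Quantification.** Reads are trimmed to their first 40 nt and assigned to
the unique probe within edit distance `max_dist`. The default
`max_dist = 2 = ⌊(d_min − 1)/2⌋` makes assignment provably unique by the
triangle inequality. A sample's relative abundances are the per-probe read
fractions; RPM (reads per million total reads) provides a depth-independent
signal.

**Absolute calibration (standard addition).** Known masses *s* of an in
vitro transcript targeting one "anchor" probe are spiked into aliquots of a
pool of total mass *M*; the anchor's RPM is regressed on *s*. The
y-intercept is the endogenous zero-spike signal, converted to mass by

```
ng = (RPM / 10^6) · M          e.g.  37,000 RPM of a 25 ng pool = 0.925 ng
```

and every other family's mass follows from relative abundance.

**Simulation.** The forward model draws reads multinomially from the pool
composition (optionally reweighted by a deterministic per-family PCR
amplification bias `(1 + e_f)^cycles`), emits recognition + adapter
sequences, and applies substitution errors at the Phred rate
`p = 10^(−Q/10)`. At Q = 33.6 that is under one error per 2200 base calls,
so fewer than 2% of 40-nt recognitions carry any error.

## Worked example

```
dorq demo --seed 1 -o demo_out
```

designs probes for 38 synthetic tRNA references, simulates a three-level
spike-in series (0/1/2 ng into a 25 ng pool, 100,000 reads per level at
Q = 33.6), quantifies each level, and fits the standard addition. It prints:

```json
{
  "n_families": 38,
  "min_pairwise_distance": 16,
  "anchor": "AspTGC",
  "true_endogenous_ng": 0.9249999999999999,
  "fit": {
    "slope": 35710.0,
    "intercept": 38116.66666666667,
    "r_squared": 0.9970750630180898,
    "endogenous_ng": 0.9529166666666669
  },
  "mapping_rate_zero_spike": 1.0
}
```

Reading this: the 38 synthetic probes are mutually ≥ 16 edits apart (well
above the design floor of 6); every simulated read mapped; the spike series
is linear (R² = 0.997); and the y-intercept of ≈ 38,100 RPM converts to
0.953 ng of endogenous anchor tRNA, recovering the programmed 0.925 ng
within 3%. Individual steps are available as `dorq design / simulate /
quantify / calibrate / absolute / qc / bias / compare` — see `dorq --help`.

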