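# Methods

## Probe design model

A probe's recognition sequence is the reverse complement of the 3′-terminal
40 nt of the mature tRNA, the region chosen because it differentiates
families well while keeping oligos short, and because the 3′ end of most
tRNAs carries few Watson–Crick-impeding modifications. References are
assumed mature (3′-CCA present); `append_cca=True` adds CCA to genomic
database entries that lack it, since the sequenced molecule carries it.

**Family collapsing.** Two 3′ 40-mers belong to the same family when their
Levenshtein distance is strictly below the collapse threshold (default 6).
Grouping is single-linkage: families are the connected components of the
pairwise "distance < threshold" graph. This is the unique order-independent
realization of collapsing similar sequences into one species; a property
test asserts invariance under input permutation. The family representative
is the most frequent member 40-mer, ties broken lexicographically — a
frequency-weighted choice that maximizes exact-match capture of reads.
Because single linkage is transitive, two members of *different* families
are guaranteed ≥ threshold apart only for directly compared pairs;
validation therefore audits all pairs of final recognitions and reports —
but does not enforce — the minimum.

**Distances in tRNA orientation.** All distances are computed on the 40-mer
regions in tRNA orientation. Levenshtein distance is invariant under jointly
reverse-complementing both arguments, so this equals the distance between
recognitions; the convention is stated for determinism.

**Ambiguity codes are rejected, not expanded.** The distance computations
require concrete sequences; silently expanding an `N` would corrupt every
distance involving it. RNA input (U) is converted to DNA (T) on read —
probes and reads are DNA, and one canonical alphabet avoids mixed
comparisons.

**Adapters.** Defaults are the Illumina-compatible P5
`AGACGTGTGCTCTTCCGATCT` (21 nt) and P3 `GATCGTCGGACTGTAGAACTCTGAAC`
(26 nt), giving 87-nt constructs; both are overridable and construct length
is always `len(p5) + 40 + len(p3)`.

## Read assignment

Reads are trimmed to their first 40 nt (the recognition region; shorter
reads are counted as `too_short`). Assignment tries an exact hash lookup
first, then searches for the unique probe within Levenshtein `max_dist`
(edit-distance computation via edlib with early cutoff). Ties at the minimum
distance are `unassigned`. The default radius is

    max_dist = 2 = floor((d_min − 1) / 2)   with the design floor d_min = 6,

the largest radius for which the triangle inequality guarantees a unique
nearest probe: a read within 2 edits of probe *f* is ≥ 6 − 2 = 4 > 2 edits
from every other probe. Strict mode refuses a radius beyond
`floor((d_min − 1)/2)` computed from the actual probe set. Assignment is
strand-specific (no reverse-complement search) because library orientation
is fixed by the adapter layout.

**Denominators.** Fractions are shares of *mapped* reads (mapping rates run
>98%, so the difference from total reads is sub-percent); RPM uses *total*
reads. Both are reported, which sidesteps the ambiguity between the two
plausible definitions of "relative abundance".

## Simulator

The simulator is the package's synthetic test bed; its defaults are the
study conditions used throughout the tests.

* **Reference generation** draws 76-nt sequences ending in CCA whose 3′
  40-mers are rejection-sampled to mutual Levenshtein distance ≥ 6, with
  round-robin cytosolic/mitochondrial annotation. Random 40-mers are almost
  always ≥ 6 apart, so rejection is rare; a retry budget turns pathological
  parameter choices into a clean `GenerationError`.
* **PCR bias** is deterministic exponential amplification: after *c* cycles
  family *f*'s weight is `fraction_f · (1 + e_f)^c`, renormalized, with
  per-cycle efficiency `e_f ∈ [0, 1]`. A deterministic efficiency captures
  reproducible, sequence-specific bias without a stochastic duplication
  tree; it is a phenomenological stand-in, not a fitted mechanism — real
  cycle-response curves are only constrained at a few cycle counts.
  Capture (hybridization) efficiency is 1 by default.
* **Reads** are drawn as one multinomial over families per simulation and
  emitted grouped by family (read order carries no information; the
  quantifier is permutation-invariant by property test). Each read is the
  recognition followed by P3 adapter bases up to `read_length` (default 66 =
  40 + 26, the full informative template; longer reads are padded with `A`).
* **Errors** are independent per-base substitutions to a uniformly random
  different base at rate `p = 10^(−q/10)`; emitted qualities all equal the
  configured q (rounded to integer Phred). Substitution-only is deliberate:
  the quality argument for short Illumina reads concerns base-calling
  substitutions, and indel rates are negligible at this scale.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: position- and cycle-dependent quality profiles,
reverse-transcription stops and misincorporations at modified nucleosides,
hybridization efficiency differences between probes, adapter dimers and
tRNA-derived fragments, and stochastic PCR duplicate trees. Tests against
the simulator certify the arithmetic of the pipeline, not the wet-lab
behavior of any particular probe set.

## Standard-addition calibration

The calibration series regresses the anchor family's signal (RPM by
default) on the spiked mass via ordinary least squares; R² is the squared
Pearson correlation. The endogenous mass is taken from the **y-intercept**
(the zero-spike signal) converted through the total input mass,
`ng = intercept/10^6 · M` — RPM has an absolute scale here because reads
are proportional to mass across the whole pool. The classical
standard-addition estimate (the magnitude of the x-intercept,
`|intercept/slope|`) is computed alongside; in raw-count mode, where the
signal has no absolute scale, it becomes the estimate. Note that RPM is not
exactly linear in the spike (the spike also grows the denominator pool:
signal ∝ (m₀ + s)/(M + s)); over spikes small relative to M the curvature
is far below counting noise and the fit's R² stays above 0.99.

Degenerate inputs: a series with all spike levels equal raises
`DegenerateSeriesError`; a zero-slope series reports R² = 0 with a
`zero_slope` flag rather than NaN; a negative intercept (possible under
noise for a scarce anchor) is reported with a `negative_mass` flag, never
clipped.

`absolute_pool` scales every family by `anchor_ng / fraction_anchor`, so
mass ratios equal fraction ratios exactly and the anchor maps to its
calibrated mass exactly.

## Bias and QC statistics

Cycle-bias profiles divide each family's fraction at cycle *c* by its
fraction at the baseline cycle (default: the smallest cycle supplied —
bias is conventionally expressed relative to the least-amplified library).
Families absent at baseline are flagged, not divided. Fold changes beyond
|log₂ FC| > 0.5 (≈ 1.4×) are flagged by default. The GC correlation is the
Pearson r between log₂ fold change and recognition GC fraction. Pool
comparisons use the squared Pearson correlation of shared-family fractions
with the one-predictor adjusted form `1 − (1 − R²)(n − 1)/(n − 2)`.

## Default parameters

| Parameter | Default | Why |
|---|---|---|
| recognition length | 40 nt | 3′ region balancing specificity and oligo length |
| collapse threshold | 6 edits | design floor; 15% of the recognition |
| `max_dist` | 2 | `⌊(6−1)/2⌋`, the provable uniqueness radius |
| q score | 33.6 | typical multiplexed Illumina run quality |
| read length | 66 nt | recognition + P3, the informative template |
| PCR cycles / efficiencies | 0 / none | unbiased library unless profiling bias |
| spike levels | 0, 1, 2 ng | three-level series into a 25 ng pool |
| demo pool | 38 families, anchor 3.7% | pool size and anchor share of a realistic tRNA panel |
| reads per level | 100,000 | counting noise ≪ the 5% recovery tolerance |

The test suite runs its stochastic checks at these sizes (200 seeded
simulations of 10⁴ reads for parameter recovery; 10⁵ reads per level for
calibration), which keeps the whole suite under a minute on one CPU while
leaving statistical envelopes comfortably wide.

## Known limitations

* Probe thermodynamics (secondary structure, melting behavior) are not
  modeled; edit distance is the only specificity criterion.
* The exponential PCR-bias model reproduces the phenomenology of
  sequence-specific bias, not measured per-sequence efficiencies.
* Isodecoder family `members` count unique input records; gene-copy
  multiplicity is whatever the input FASTA encodes.
* No modification calling or reverse-transcription signature analysis:
  probe capture reads out abundance only.
* Spike-in purity and length effects are uncorrected; one anchor per
  calibration (no multi-anchor reconciliation).
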