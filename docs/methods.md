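# Methods

This note records the models implemented by `techrono`, the default
parameter values and why they were chosen, what the simulator does and
does not emulate, and the numerical choices and known limitations of the
estimators. All quantitative statements here are properties verified by
the test suite or computed by `scripts/acceptance.py`.

## Divergence model

Sequence divergence is measured with the Kimura 2-parameter (K2P)
distance,

```
K = -1/2 · ln[(1 − 2P − Q) · sqrt(1 − 2Q)]
```

where `P` and `Q` are the proportions of transition and transversion
differences over aligned, ungapped, unambiguous columns. Alignment
columns containing a gap or a non-ACGT symbol are excluded from both the
numerator and denominator. The estimator saturates when either log
argument is ≤ 0; saturated estimates are reported as undefined rather
than clamped, and downstream stages (landscapes, dating tables) carry
them as skips/NaN instead of silently dropping or inventing values.

Alignment is done with `edlib` in two modes:

- **fragment** (infix, free end gaps on the reference) for genomic copy
  vs consensus — genomic copies are typically 5′/3′-truncated fragments;
- **global** for the two terminal repeats of one element, which are
  homologous end to end.

Copy-vs-consensus estimates whose aligned span covers less than 50% of
the copy are flagged low-confidence and excluded from landscapes.

## Divergence landscapes

Each copy with a defined, confident K contributes its genomic length (bp)
to integer bin `floor(100·K)`, capped at bin 50, per TE class. The bin
totals are exactly conservative: summed bin coverage equals the summed
lengths of the contributing copies (checked on every simulated genome).
The peak bin of a burst is a proxy for its age: a pulse whose copies have
drifted to copy–consensus divergence ≈ 0.05 peaks in bins 4–6.

## LTR insertion dating

The two long terminal repeats of an LTR retrotransposon are identical at
insertion and accumulate substitutions independently afterwards, so their
divergence grows at `2r` and the insertion time is

```
T = K / (2r),    r = 2.8e-9 substitutions · site⁻¹ · year⁻¹ (default)
```

`r` is the neutral-rate estimate commonly used for *Fragaria*; it is a
single scale factor, so all downstream times rescale linearly if a
different rate is supplied (`--rate`). Ages are summarised as histograms
with 500,000-year bins anchored at the present (bin i covers
`[i·w, (i+1)·w)`), and as Gaussian kernel densities (Silverman bandwidth,
renormalised to unit trapezoid integral over the evaluation window).

## Removal half-life

Under constant insertion and constant-rate (memoryless) removal, the
count of surviving elements inserted `t` years ago is `N0·exp(−λt)`; the
half-life is `ln2/λ`. The fit minimises the summed distance between the
model evaluated at bin midpoints and the observed bin counts, from bin 0
(optionally bin 1, `--drop-youngest`) through the last non-empty bin.

Numerical choices:

- **L1 loss by default** ("summed distance"; L2 available via
  `--loss squared`). L1 is robust to a single anomalous bin — a recent
  burst or an annotation artefact moves an L2 fit much further than an L1
  fit.
- The L1 objective is non-smooth, so the optimiser is a 200-point
  log-spaced grid over `λ ∈ [1e-9, 1e-5] yr⁻¹` (half-lives ≈ 0.07–700 My)
  with the conditionally optimal `N0` at each grid point (closed form for
  L2; for L1 the optimum is the weighted median of `count/exp(−λt)` with
  weights `exp(−λt)`), followed by Nelder–Mead refinement in
  `(log N0, log λ)`. A fit landing at the grid floor is flagged
  (`at_grid_floor`) rather than trusted.
- At least 3 non-empty bins are required; fewer is an error, not a guess.

The model assumes constant insertion. Families with explicit bursts
violate that assumption, so pipeline code (e.g. the `demo` subcommand)
fits the half-life on constant-rate families and handles burst families
through the profiling stage instead.

## Pan-genome library construction

Candidate consensus sequences are filtered for minimum length (default
80 bp) and for simple repeats: a sequence is discarded when ≥ 80% of its
positions are covered by exact tandem arrays of period ≤ 10 bp spanning
at least `max(2·period, 8)` bp. Redundancy is then removed greedily,
longest sequence first (lexicographic tie-break, so output is independent
of input order): a candidate is redundant when it aligns to an already
retained sequence — on either strand, containment allowed — at ≥ 80%
identity over ≥ 80% of its own length (the 80/80 rule). Identity is
matches over aligned non-gap columns; coverage is aligned columns over
candidate length. The procedure is idempotent, and the output carries a
certificate property: no retained pair still satisfies the redundancy
rule (verified exhaustively in the tests).

## Comparative layers

- **Family profiles**: per species, the percentage of dated insertions
  younger than a window (default 1.0 My) attributed to each family.
  Species with no recent insertions are dropped with a warning. For
  log-scale comparison, zeros are replaced by half the smallest non-zero
  percentage before taking log2.
- **Clustering**: hierarchical clustering (Euclidean distance, average
  linkage by default) of profile rows; the dendrogram is emitted as
  Newick.
- **PIC**: phylogenetically independent contrasts via Felsenstein
  pruning on strictly bifurcating trees with positive branch lengths
  (both enforced at read time). A contrast is
  `(x_l − x_r)/sqrt(b_l + b_r)`; the node value is the
  1/b-weighted average and the parent branch is extended by
  `b_l·b_r/(b_l + b_r)`. The contrast correlation is computed through the
  origin. Correctness is checked against a hand-worked 4-leaf pruning and
  against a GLS oracle built from the phylogenetic covariance matrix
  (equal to 1e-10), and calibration by Brownian simulation (true contrast
  correlation 0.9 recovered within 0.05 over 200 replicates of 50 taxa).
- **Ancestry**: intact-TE consensus sets (LTR/TIR/Helitron by default)
  are intersected between polyploid subgenomes and candidate diploid
  donors; the row-argmax of the shared-count matrix is the donor call.
  Venn region counts are per-element and verified against an
  inclusion–exclusion oracle.

## Simulator

The simulator provides ground truth, not biological realism beyond what
the estimators need:

- **Emulated**: exact K2P substitution (per-branch transition and
  transversion probabilities from the rate `r` and transition/transversion
  parameter `κ`, default 2.0), per-family consensus sequences shared
  across genomes, constant-rate (Poisson) insertion plus Gaussian-jittered
  burst pulses, memoryless removal at a configurable half-life, LTR
  elements whose two terminal repeats start identical and mutate
  independently, optional truncation, strand, non-overlapping placement
  in random background sequence, and ancestry plans assigning family
  subsets to genomes.
- **Not emulated**: indels during divergence (substitutions only),
  nested insertions, solo-LTR formation via recombination, GC bias,
  selection, segmental duplication, or sequence-assembly error. These are
  deliberately out of scope: each estimator is validated on the process
  it inverts, plus the alignment noise the real pipeline introduces.

### Default scales and why

Simulation scenarios in the tests and acceptance script use parameter
scales chosen for realism and statistical resolution, not tuned to the
estimators:

- **LTR length 1.2–2.5 kb, internal region several kb** — typical of
  plant LTR retrotransposons. Length matters: divergence over an LTR of
  length L is quantised in steps of `1/L`, i.e. age steps of `1/(2rL)`.
  Short repeats (a few hundred bp) make that quantum comparable to the
  500-ky bin width and produce aliasing in age histograms; realistic
  kb-scale repeats keep the quantum well below the bin width.
- **Half-life recovery at n ≈ 6,000 elements** — sampling noise on
  ~23 bins at n ≈ 2,000 leaves seed-to-seed spread of the fitted
  half-life near the ±15% validation band; n ≈ 6,000 (a 160-Mb genome at
  1,650 insertions/My) brings the spread comfortably inside it.

## Known limitations

- **Downward half-life bias near the insertion horizon.** Dating noise
  scatters estimated ages of old elements past the oldest true insertion
  time, so the last non-empty bin — which sets the fit range — lies
  beyond the horizon and contains only noise-spilled counts. With a
  10-My horizon, a 3.0-My half-life and kb-scale LTRs this biases the
  fitted half-life low by roughly 5–10%. It is a property of fitting
  through the last non-empty bin under measurement noise, not of the
  optimiser; the noiseless fit recovers the rate to 1e-3 relative.
- **Alignment absorbs a small fraction of substitutions.** Pairwise
  alignment of diverged sequences occasionally explains true
  substitutions as spurious short indels, deflating K slightly; the
  insertion-time regression slope on simulated data is ≈ 0.95 rather
  than 1.0.
- **Saturation ceiling.** K2P is undefined past `1 − 2P − Q ≤ 0`;
  elements older than the saturation age are reported undefined and drop
  out of histograms, so all chronology is effectively limited to the
  unsaturated range.
- **The removal fit assumes constant insertion.** Applying it to a
  family with a strong recent burst conflates insertion history with
  removal; burst families should be profiled, not decay-fitted.
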