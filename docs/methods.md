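# Methods

This note records the models, conventions and design choices behind each
analysis stage, what the synthetic generators do and do not emulate, and
the numerical details a user may need to interpret or override.

## Domain annotation and architecture classification

Inputs are proteome FASTA files (headers `genomeID|proteinID`; a
`complete=0` description token marks proteins lacking a start or stop
codon) and HMMER per-domain tables (`--domtblout` dialect). Coordinates
are 1-based inclusive throughout, following HMMER. The conditional
E-value — HMMER's per-domain significance conditioned on the sequence
being a homolog — is the score used everywhere; the independent E-value
is ignored.

Resolution proceeds per protein:

1. hits covering less than `min_coverage` (default 0.25) of their profile
   HMM are discarded;
2. surviving hits are accepted greedily in order of ascending conditional
   E-value (ties: higher bit score, longer interval, lower start, family
   name — a total order, so results are deterministic); a candidate is
   rejected when it overlaps an accepted domain by more than
   `overlap_threshold` (default 0.50);
3. the overlap fraction is shared residues divided by the **shorter** of
   the two intervals. This is the strictest symmetric reading of an
   "overlap by more than 50%" rule; the denominator choice matters only
   for very unequal interval lengths.

Each accepted region's family is that of its best hit, demoted to the
ambiguous label `Hx` when the best *other* family on the region scores
within `ambiguity_ratio` (default 10) times the winning E-value. This
score-ratio rule is a deliberately simple stand-in for phylogenetic
assignment, which is out of scope here: an E-value ratio below an order
of magnitude is treated as "could not be assigned". The ratio is
configurable; raising it produces more `Hx` calls.

Architectures are the hyphen-joined N-to-C family orders
(e.g. `H2B-H2A-H3-H4`), classed by domain count as
singlet/doublet/triplet/quadruplet (`other` beyond four). Quadruplets
containing each core family exactly once receive a configuration label
(HQA/HQB/HQC) from an order→label table. **The default table is
provisional**: it fixes three distinct full-complement orders that keep
H2A/H2B and H3/H4 in series, which is the observed constraint, but the
exact order↔label correspondence should be overridden
(`classify_architecture(..., quadruplet_table=...)`) when known.

Types seen in fewer than `min_genomes` (default 2) distinct genomes are
flagged non-recurrent — repeated observations within one genome count
once — guarding against single-genome prediction artefacts. Incomplete
proteins are parsed but excluded from architecture statistics unless
requested.

Linkers are the substrings strictly between consecutive resolved domains
(zero length allowed); N- and C-terminal extensions are reported
separately, so domain + linker + tail lengths always partition the
protein. Per-type linker summaries report the per-junction median ± SD
(ddof = 1) across proteins.

## Co-occurrence and complements

The presence matrix is boolean genome × type. The network is directed:
node weight = number of genomes containing the type; edge A→B =
|genomes with both| / |genomes with A|. The directed conditional
proportion is the default because it is what an asymmetric
"co-occurrence proportion" most naturally means; a symmetric Jaccard
variant is available. Genomes with no histones are excluded from the
network but counted under the empty subset in Venn counts, which
partition genomes over all 16 subsets of {H2A, H2B, H3, H4} and
therefore always sum to the number of genomes.

## Alignment statistics

* **Trimming**: columns with non-gap occupancy below `gap_threshold`
  (default 0.20) are removed, then sequences with fewer than
  `min_site_fraction` (default 0.50) non-gap characters over the kept
  columns. Removing sequences can push further columns below threshold,
  so the pair of filters is iterated to a fixed point; the result
  satisfies both criteria simultaneously and the operation is idempotent.
* **Shannon entropy** per column over the 20 residues, gaps excluded by
  default (optionally a 21st state), in bits (log₂; the base is
  configurable). All-gap columns are NaN.
* **Composition χ²** compares each sequence's residue counts with those
  expected under the pooled alignment frequencies; df = non-empty
  categories − 1, P from the asymptotic χ² distribution, flagged at
  P < 0.05. Because the pooled frequencies are estimated from the data,
  the test is slightly conservative for few/short sequences; with ~100
  sequences of ≥300 columns the null flag rate is within sampling error
  of the nominal 5%.
* **Dayhoff recoding** collapses the alphabet to 4 exchange groups,
  default {AGNPST, CHWY, DEKQR, FILMV}, each represented by one of its
  own members so recoding is idempotent. Several 4-bin reductions exist
  in the wild; the scheme is a plain mapping argument and fully
  user-overridable.
* **Length ANOVA** is a one-way fixed-effects ANOVA; with two groups F
  equals the pooled-variance t².

## Gompertz growth fitting

OD₆₀₀ curves are blank-subtracted point-wise, then fit with
y(t) = A·exp(−exp((µe/A)(λ−t) + 1)). This grouping of the exponent is
the standard modified-Gompertz parameterisation in which the parameters
carry their stated meanings exactly: y(λ) = A·e^(−e) ≈ 0.066·A, the
inflection sits at t = λ + A/(µe) with value A/e and slope µ (the
maximum slope), and the tangent there crosses y = 0 at t = λ. λ is
therefore reported as the conventional lag time — the tangent
construction — rather than "the time of maximum slope", which is the
inflection point t_i = λ + A/(µe); both readings are recoverable from
the returned parameters.

Fitting is trust-region least squares with bounds A, µ > 0, at most
10,000 function evaluations and a relative cost tolerance of 1e-5.
Starting values come from the data (A₀ = max y; µ₀ = steepest
finite-difference slope; λ₀ from the tangent at that point), with up to
three seeded log-normal jittered restarts on failure. Degenerate inputs
— fewer than 5 points, all-zero after blank subtraction, monotonically
decreasing — return `converged=False` rather than raising. Noiseless
synthetic curves are recovered to ≲1e-9 relative error; at measurement
noise σ = 0.01 OD the median relative parameter error is well under 5%.

Condition comparisons run Tukey HSD per parameter across strain groups
(converged fits only; groups with <2 converged replicates are excluded
with a warning), then multiply the Tukey-adjusted P values by a
Bonferroni factor for the number of parameters tested (default 3: A, µ,
λ) since three families of pairwise tests are examined. Compact letters
use the insert-and-absorb algorithm; groups sharing a letter are not
significantly different at the chosen α (default 0.01).

## MNase fragment ladders

`detect_peaks` is deliberately simple: moving-average smoothing (window
5 points) then local maxima with prominence ≥ 5% of the trace maximum.
It is adequate for clean, well-separated bands; at low signal-to-noise
(≈10) it also reports noise maxima, and neighbouring bands closer than
about 3 band-widths merge into shoulders that *no* local-maxima rule can
split — with band σ = 5 bp and decaying heights, steps below ~15 bp are
mathematically unimodal. `summarize_ladder` takes the smallest prominent
peak as the primary fragment (the mono-nucleosome band; "most intense"
is available), steps are successive peak differences, and the step ratio
is mean(step)/primary × 100. Batch summaries report the step ratio under
both averaging orders (per-sample mean of ratios, and pooled steps over
mean primary), which differ when samples are heterogeneous.

`fit_ladder` is the quantitative estimator: a Gaussian comb
Σₖ hₖ·N(P + k·s, σ²) + offset with non-negative heights profiled out by
NNLS over a coarse (P, s, σ) grid (P confined near the tallest band,
since heights decay), refined by continuous least squares. The comb is
identified only up to integer tooth shifts when edge teeth carry no
height, so leading/trailing teeth below 5% of the maximum height are
trimmed before reporting; the primary is the first substantive tooth.
Across planted primaries 60–160 bp and step fractions 0.2–1.0 at σ =
5 bp and SNR 10, recovery is within ±2 bp and ±0.03 respectively,
including the merged-shoulder regime. Baseline subtraction
(rolling-minimum) is available but off by default, matching traces whose
background is flat.

## Nucleoid profiles

Cells outside 2–4 µm are excluded (size control). Each transect is
divided by its own maximum, mapped to relative position [0, 1] and
linearly interpolated onto a fixed 100-point grid (no length-warping
beyond the relative mapping); strain summaries are per-grid-point mean ±
SE (SD/√n). Strains are compared with a two-sample KS statistic on the
pooled normalised intensity values (all cells × grid points), the
simple, reproducible choice; an intensity-weighted position comparison
would be the main alternative. Pooled values are strongly dependent
within a cell (shared maximum, smooth profiles), so treating them as
independent in the classical KS P value is anticonservative by an order
of magnitude. The default P value therefore comes from a **cell-label
permutation** null (999 permutations, seeded), which is exact at the
cell level regardless of within-cell dependence; the asymptotic P is
available with `n_permutations=0` for compatibility. Bonferroni
multiplies P by the number of strains compared against the control.

## Synthetic generators

All generators are pure functions of (seed, parameters); each derives
its own stream from the master seed plus a scenario label (CRC32), so
adding scenarios never shifts existing outputs. Ground truth is written
as JSON beside every artifact.

* `synth_proteome` concatenates family segments (fixed per-family HMM
  lengths, 60–80 aa) joined by Poisson linkers (default means 12/56/16,
  the observed quadruplet profile) with Poisson terminal tails, across a
  default type mix of quadruplets, core doublets and singlets. True hits
  get coordinates jittered ≤2 residues and conditional E-values
  log-uniform in [1e-30, 1e-8]; decoys (rate 0.3 per domain) are either
  sub-threshold fragments (coverage < 0.25) or cross-family hits on a
  true domain with E-values 10–10⁶× worse. Sequences are random — the
  generator emulates hit-table *rank structure*, not histone sequence
  evolution, so passing recovery tests says nothing about HMM
  sensitivity on real proteins, only about the resolution logic.
* `synth_growth` adds N(0, 0.01) noise and a media blank (0.04 OD) to
  Gompertz curves sampled every 30 min over 24 h, the plate-reader
  schedule; default truths contrast a control with a long-lag strain.
* `synth_ladder` builds the Gaussian comb (σ = 5 bp, heights 0.7ᵏ,
  3 orders, SNR 10 white noise, clipped at zero) on a 20–700 bp grid.
* `synth_transects` draws cell lengths uniform on 1.5–4.5 µm (so the
  2–4 µm filter is exercised), condensed cells as a central Gaussian
  bump (relative σ 0.1) over a 0.15 baseline, dispersed cells as a flat
  unit profile, both with σ = 0.05 additive noise. Real micrographs have
  cell-to-cell bump asymmetries and correlated noise that these profiles
  do not; the generators are sufficient for testing the normalisation,
  averaging and testing machinery, not for benchmarking segmentation.

## Problem sizes and tolerances used in the checks

The shipped checks use 200 random hit sets (≤12 hits) against an
exhaustive enumeration oracle, 500 planted proteins at decoy rate 0.3,
50 noisy growth replicates, 100 planted ladder traces, and ≥500
replicates per calibration rate (χ² flagging, ANOVA type-I, Tukey
familywise, KS null at 79 permutations); calibration rates are accepted
within three binomial standard errors of the nominal α. These sizes give
stable rates while keeping the whole suite inside a few minutes on one
CPU.

## Known limitations

* Family assignment is score-based, not phylogenetic; `Hx` calls depend
  on the ambiguity ratio, and distinguishing genuinely intermediate
  domains from noisy scores is beyond this surrogate.
* The quadruplet configuration table is provisional (above).
* `detect_peaks` is not reliable below SNR ≈ 20 or for merged bands; use
  `fit_ladder` for quantitative work.
* The KS comparison tests equality of pooled intensity distributions;
  it is sensitive to any distributional difference, not specifically to
  condensation, and the permutation P floor is 1/(n_permutations+1).
* Incomplete-protein handling trusts the upstream completeness
  annotation; no reading-frame checks are performed here.
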