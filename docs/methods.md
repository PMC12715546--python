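# Methods

## The capture model

`rampsim` treats hybridization capture as an equilibrium binding process
followed by conditioned sampling. Candidate bait–target sites come from an
external mapper as SAM alignments; the simulator itself never aligns.
A site is retained only if its alignment has no insertions or deletions
and at most `max_mismatches` (default 40) substitutions; all mapped
records are treated equally, so secondary alignments contribute off-target
sites. Soft/hard-clipped bait ends are excluded from the site span — bases
that did not align are assumed not to hybridize.

**Energy.** Site free energy is the unified nearest-neighbor stack sum
ΔG(T) = Σᵢ (ΔHᵢ − T·ΔSᵢ), evaluated at the configured hybridization
temperature rather than from a fixed-temperature ΔG table, because T is a
tunable input that also enters the Boltzmann factor. Any dinucleotide step
touching a mismatched or ambiguous (N) position contributes 0: a stack
needs both flanking base pairs. A fully mismatched site therefore has
E = 0, and its score degenerates to the genome abundance. Duplex
initiation, terminal-AT and symmetry corrections are excluded by default
(`EnergyModel(include_initiation=True)` enables the per-end initiation
terms): they are near-constant per-duplex offsets that the per-bait
normalization cancels for panels of equal-length baits. The parameter
table ships as a plain-text file (`data/santalucia1998_unified.tsv`,
kcal/mol and cal/(mol·K)); alternative sets can be dropped in by path.
R = 1.987×10⁻³ kcal/(mol·K); the CLI accepts temperature in °C (default
70 °C, a standard capture hybridization temperature) and converts to
Kelvin.

**Occupancy.** For bait p with candidate sites H_p, the score of site
b = (x, g) is S(b, p) = a_g·exp(−E(x,p)/RT) and the occupancy
I(b, p) = S(b, p)/Σ_{b'∈H_p} S(b', p). Occupancies are computed as a
max-shifted softmax of log scores: |E|/RT exceeds 150 for long perfect
duplexes, so naive exponentiation overflows. The stored `score` field is
clipped into the float range for inspection; occupancies never use it.

**Sampling.** The binding process is a family of Poisson rates
(proportional to c_p across baits, to S(b,p) across a bait's sites);
conditioning on totals turns these into the multinomials that are
implemented directly. With user-specified `total_fragments` and
`capture_fraction` f: N = round(f·total) capture events (round-half-even
on ties) and N′ = total − N background fragments. Capture events are
split Mult(N, c/Σc) over baits, then Mult(N_p, I) over each bait's sites.
Each event draws L with ln L ~ Normal(log_mu, log_sigma²), rounded to the
nearest integer and clamped at `min_fragment_length` (default 50), then a
uniform integer center in the window [m − ⌊L/2⌋, m + ⌈L/2⌉) on the site
midpoint m = ⌊(start+end)/2⌋, and yields [center − ⌊L/2⌋, center − ⌊L/2⌋ + L)
clipped to the record bounds. Conventions fixed here (midpoint of even
spans, integer center, start anchor) are arbitrary but deterministic. A
capture fragment is not forced to contain its site: the window rule alone
governs placement. Genomes are linear; clipping can shorten fragments near
ends, and the rare event whose clipped interval is empty is dropped and
reported (conservation: realized capture + dropped = N, background = N′).
Events of baits with no candidate site are likewise dropped with a
warning. Background fragments place their start uniformly over the record,
with per-genome counts Mult(N′, a_g) and, within multi-record organisms,
records chosen in proportion to length (one abundance per organism, shared
by its chromosomes and plasmids). All draws flow through a single
`numpy.random.Generator` in fixed order, so a seed reproduces the fragment
list — and the output FASTA — byte for byte.

## Fitting

`fit_lognormal` is the fixed-location lognormal MLE: log_mu and log_sigma
are the mean and population standard deviation of ln(lengths) (identical
to `scipy.stats.lognorm.fit(x, floc=0)`, which a test verifies). An
all-equal input yields σ̂ = 0 and is clamped to 10⁻⁶ with a warning.

`estimate_capture_fraction` classifies a read as capture when its midpoint
lies within exp(log_mu)/2 — half the *median* fragment length on the
natural scale — of the nearest candidate-site midpoint on the same
genome, mirroring the window used to place capture centers.
Midpoint-to-midpoint distance is the documented choice (edges and overlap
were the alternatives); it matches the center-based placement rule and
makes the estimate monotone in log_mu. Lookup uses sorted midpoints and
binary search, O((R+S) log S). The estimate is biased: fragments longer
than the median can have centers outside the window (downward pressure on
capture reads), while background reads landing near sites are counted as
capture (upward). On sparsely targeted genomes with a tight length
distribution the second effect dominates, so re-fitting simulator output
recovers at least the configured fraction; with a wide length spread the
estimate can fall below it.

## Evaluation

Coverage tracks are per-position fragment depths (difference array,
O(n + L)). For comparison, a track is normalized by its positional sum.
The earth mover's distance rescales positions to [0, 1] (position i at
i/L) so genomes of different lengths are comparable, and computes the 1-D
Wasserstein-1 distance as the mean absolute CDF difference; tests verify
it against `scipy.stats.wasserstein_distance` and an exhaustive
optimal-transport linear program. Absolute EMD values depend on this
normalization choice, so only comparisons (simulated vs uniform against
the same observed track) are meaningful across conventions.

High-coverage labels use a strict median threshold: depth > median, ties
low ("passes the threshold" read as exceeds). Classification metrics take
the observed labels as ground truth; ratios with zero denominators are
reported as 0. The uniform baseline redraws fragments with uniform starts
and the fitted lognormal lengths, with the count chosen so expected mean
coverage matches the observed track: n = round(cov·L / E[length]),
E[length] = exp(log_mu + log_sigma²/2). Metrics over `n_iter` = 100 draws
are summarized as mean ± 1.96·SD/√n_iter (normal-approximation 95% CI).
Species abundances are percentages of assigned reads, with unassigned
reads excluded from the denominator and counted separately. For
multi-record organisms, per-record metrics should be aggregated weighted
by record length.

## Synthetic communities

The `fixtures` module generates i.i.d. uniform-base genomes with planted
bait targets: exact copies at recorded loci (about a quarter on the
reverse strand), plus optional off-target copies carrying an exact number
of substitutions. It writes syntactically valid FASTA/TSV/SAM files with
correct CIGARs, positions and edit distances, and returns the ground
truth. The `zymo-like` preset mirrors a log-distributed 10-organism mock
community standard — abundances spanning 89.1% down to 0.000089% in
decade steps, with the two fungi and one bacterium left untargeted — at
reduced genome sizes (20 kb per organism by default) so whole-pipeline
runs finish in seconds. Uniform random genomes make spurious bait
homology negligible at these scales; the fixtures deliberately do not
model GC skew, repeats, or real genome composition, so passing tests
demonstrate correctness of the sampling machinery and statistics, not
fidelity to any particular organism's sequence biases. Real-data effects
that are out of the model — PCR/GC bias, extraction efficiency,
mismatch-specific energy penalties, salt and dangling-end corrections,
wash stringency, sequencing error — are not simulated; sequencing error is
delegated to downstream read simulators.

## Problem sizes and tolerances

Statistical tests run at sizes where 3-standard-error (multinomial
moments) or α = 0.01 (chi-square uniformity) bounds are comfortably
informative: 10⁵ draws for ratio/abundance/length recovery, 2×10⁴
fragments on 10–30 kb toy genomes for the coverage self-consistency
checks, 100 iterations for the uniform baseline. Occupancy arithmetic is
checked to 10⁻⁹ against an 80-bit extended-precision direct evaluation;
the EMD against the transport LP to 10⁻⁹. Seeds are fixed everywhere;
`scripts/acceptance.py` derives all of its streams from the single
`--seed` argument.

## Known limitations

- Energies use Watson–Crick stack terms only; all mismatches are
  energetically identical (zeroed stacks), so near-homologous off-targets
  are penalized by mismatch count and position, not identity.
- Linear genomes only; no circular wrap of fragments.
- The capture-fraction estimator conflates capture and background reads
  near sites (see above); it is a calibration heuristic, not an unbiased
  estimator.
- Multi-record organisms share one abundance but coverage statistics are
  per record; organism-level aggregation is left to the caller.
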