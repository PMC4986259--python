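# Methods

## The search model

A tandem mass spectrum is identified by comparing it against the
theoretical fragmentation of every database peptide whose neutral
monoisotopic mass lies within a relative window of the observed
precursor mass. The package implements the SEQUEST/ProLuCID lineage of
this comparison and controls errors at the protein level with a
concatenated target-decoy database.

### Index

Proteins are digested fully-tryptically: cleavage C-terminal to K or R,
suppressed when the next residue is proline; semi-tryptic peptides are
not generated. Digestion defaults follow common MudPIT practice:

| parameter | default | unit |
|---|---|---|
| missed cleavages | 2 | sites |
| peptide length | 6–60 | residues |
| peptide mass | 600–6000 | Da |
| static modification | C +57.02146 | Da (carbamidomethyl) |

Decoys are whole-protein sequence reversals appended after the targets
with a `Reversed_` defline prefix. Reversal preserves composition and
(approximately) the tryptic fragment-length spectrum, which is exactly
what makes reversed decoys a usable null model — and also why incorrect
matches are slightly enriched on the reversed twin of the true protein
(see *Calibration* below).

Peptide masses are neutral monoisotopic sums over a published residue
table plus one water (18.0105646863 Da). The MassDB grouping key is the
mass in 0.1 mDa fixed point (`round(mass × 10⁴)`): fine enough that a
10 ppm window at 6 kDa spans hundreds of keys (no retrieval loss),
coarse enough that floating-point noise cannot split one peptide across
keys. Non-canonical residues (B/J/O/U/X/Z) are handled by policy:
`skip` (default) drops the containing peptide and counts it in the
build report, `reject` raises, `map` rewrites U→C and O→K.

The storage contract is deliberately narrow — append, point lookup,
ordered mass-key range scan — and the default backend is one SQLite
file (`:memory:` for transient indexes). The range scan touches only
records whose key lies in the queried window, so per-query cost is
proportional to window content, independent of total database size;
the backend counts records touched so this contract is assertable
without wall clocks.

### Scoring

Observed spectra are binned at 1.0005079 Th (the average peptide-mass
spacing per dalton), intensities square-rooted, the vector split into
10 regions each scaled to a maximum of 50, and peaks within ±1.5 Th of
the precursor removed. The cross-correlation background is subtracted
in closed form: v′[i] = v[i] − mean(v[i−75..i+75] \ v[i]), after which
XCorr is a single sparse dot product with the theoretical spectrum,
scaled by 10⁻⁴. Equivalence with the naive R(0) − mean R(τ≠0)
definition is enforced by test to 10⁻⁶.

Theoretical spectra hold b-ions (prefix + proton) and y-ions (suffix +
water + proton) at fragment charge 1, adding charge 2 when the
precursor charge is ≥3; primary bins weigh 1.0 and ±1-bin flanks 0.25.
Reported XCorr is floored at 0; the raw (possibly negative) values feed
the candidate statistics. All these constants live in one block at the
top of `engine.py` and can be swapped coherently.

Per scan: candidates stream through a bounded top-k buffer (peak memory
O(report_hits), asserted by instrumentation), ties in XCorr break
lexicographically so output is deterministic, and scans without a
charge are scored at 2+ and 3+ with the higher-XCorr interpretation
kept. ΔCn = (XCorr₁ − XCorr₂)/XCorr₁, defined as 0 when XCorr₁ = 0 and
as 1 when only one candidate was scored (no second competitor — the
small-database limit, which is why focused-database ΔCn medians are
high). The Z-score standardizes the top raw XCorr against the
population mean/SD of all candidate raw XCorrs, reported as 0 when
fewer than 3 candidates were scored or the SD is 0.

Note that XCorr magnitudes scale with the number of matched fragment
bins and the normalized intensity ceiling; the synthetic spectra here
(short peptides, sparse peaks) produce values well below the 2–4
typical of instrument data. All comparisons in this package are
relative, so only the ordering matters.

### Filtering

Search is wide (30 ppm) and the precursor accuracy gate is applied at
filter time, strictly: |ppm error| < 10. Gated rank-1 PSMs fan out to
every parent protein; peptides with both target and decoy parents count
toward both sides (the two-peptide rule makes them nearly harmless, and
they are tallied in the report). Loci need ≥2 distinct peptides; the
FDR threshold search then picks the least-strict locus best-XCorr
cutoff with (#decoy loci)/(#target loci) ≤ the ceiling (default 1 %);
the 2d/(t+d) estimator is selectable. The search is exhaustive over
candidate thresholds and is tested against a brute-force scan. Loci
with identical peptide sets are collapsed into one reported row.

## The synthetic study

The generator emulates a clean MudPIT acquisition: uniform random
proteomes (lengths N(300, 100²) truncated at 20, uniform residue
frequencies), tryptic peptides sampled uniformly from the indexable
digest, and per scan the full primary b/y series at constant intensity
100, thinned by 10 % dropout, plus 10 uniform noise peaks in 200–2000 Th
(intensity 10–100) and N(0, 5 ppm) precursor jitter; charges 2 and 3
with probability 0.6/0.4. These are the package's default study
conditions; clean variants (no noise/dropout/jitter) are used where a
property should hold exactly.

What the generator does **not** emulate: realistic fragmentation
intensity structure (HCD/CID propensities), chimeric spectra,
non-tryptic background, empirical residue frequencies, or homology
between proteins. Passing tests therefore demonstrate algorithmic
correctness of index/scoring/filtering, not robustness to instrument
artifacts.

Problem sizes used by the test suite and acceptance script — chosen as
the smallest sizes at which each property is statistically meaningful:
500 random proteins for the digestion oracle; 1,000 random peptides for
the mass oracle; 200 spectrum/peptide pairs for the XCorr oracle; a
1,000-protein build with 1,000 random window queries for index
consistency; a clean 500-scan run for rank-1 self-recovery; 20 noisy
400-scan replicates for FDR calibration; 100 proteins + 50,000
distractors for the database-inflation experiment; 1×/10×/100×
inflations for the access-count scaling contract.

### Calibration design

In the calibration replicates, half of each simulated sample's proteins
are deliberately absent from the index, so those scans can only produce
false matches — giving the decoy estimator a real error rate to
estimate. Two properties are asserted, pooled over 20 replicates:

- the decoy/target ratio on the eligible locus set tracks the
  ground-truth false-locus fraction within a factor of 2 (plus a
  two-locus counting-resolution slack). The estimator runs conservative
  here because incorrect matches are enriched on reversed twins of true
  generators, a known property of reversal decoys;
- the realized false-locus fraction among accepted loci stays within 2×
  of the nominal 1 % ceiling.

At these problem sizes (~60 targets per run) a single decoy locus
already exceeds 1 %, so the chosen threshold typically excludes every
decoy; the eligible-set comparison is where the estimator has countable
signal.

## Design choices on genuinely open points

- The preprocessing/scoring constants (bin width, 10×50 normalization,
  ±75 background, 0.25 flanks, 10⁻⁴ scale) are the lineage conventions;
  they are not derivable from first principles and are isolated for
  replacement.
- The FDR-driving threshold is one-dimensional (locus best XCorr) for
  determinism and testability; ΔCn and per-PSM XCorr floors are exposed
  as optional gates rather than folded into a combined score.
- Idempotent rebuilds deduplicate on (peptide, protein, offset), so
  re-importing the same FASTA cannot inflate occurrence counts.
- Spectra with multiple charge annotations keep the first; unannotated
  spectra try 2+ and 3+.

## Known limitations

- No variable modifications, isotope-error windows, or a/c/x/z ions.
- Monotonicity of the accepted-locus count in the gate parameters
  (stricter ppm, higher peptide minimum) holds on realistic data and is
  tested there, but is not a theorem: removing a decoy locus can loosen
  the FDR threshold and admit more targets in adversarial
  configurations.
- The count symmetry between a protein's and its reversal's digest is
  exact only up to K/R–P adjacency asymmetries; tests bound the
  difference analytically rather than asserting equality.
- Absolute XCorr values are not comparable with instrument-data
  searches (see scoring note above).
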