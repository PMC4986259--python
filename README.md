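# compilite

Desk-scale shotgun-proteomics database search, built the way very-large
metaproteomic search stacks are built: a three-collection peptide/protein
index over a decoy-augmented FASTA, a SEQUEST-style cross-correlation
search engine with streaming mass-window candidate retrieval, and
protein-level target-decoy FDR filtering — plus a synthetic
proteome/spectrum generator so the whole loop can be validated closed-form
with known ground truth, no instrument data required.

## Who this is for

Proteomics tool developers and computational biologists who want a small,
fully testable implementation of the classic search pipeline:

1. **Index** (`compilite.store`) — proteins are read from FASTA, reversed
   decoys are appended (`Reversed_` prefix), and every protein is digested
   in silico with trypsin specificity (cleave after K/R, not before P).
   Three collections result: **ProtDB** (protein records), **SeqDB**
   (distinct peptide → monoisotopic mass + parent occurrences), and
   **MassDB** (peptides grouped under a fixed-point mass key, 0.1 mDa
   resolution). Precursor queries are ordered key-range scans, so query
   cost tracks the number of peptides in the mass window, not the size of
   the database. The default backend is a single SQLite file; the backend
   contract (point lookup + ordered range scan + append) is small enough
   that a document store can be dropped in.
2. **Engine** (`compilite.engine`) — MS2/MGF scans are binned at
   1.0005079 Th, square-root transformed, normalized to a max of 50 in 10
   m/z regions, and background-subtracted over ±75 bins so that the
   SEQUEST cross-correlation

   XCorr = 10⁻⁴ · [R(0) − mean R(τ), τ ∈ [−75, 75], τ ≠ 0]

   reduces to one dot product with the theoretical b/y-ion spectrum.
   Candidates stream from the mass window at 30 ppm; per scan the engine
   reports XCorr (floored at 0), ΔCn = (XCorr₁ − XCorr₂)/XCorr₁, and a
   Z-score of the top hit against all candidate XCorrs. Results are
   written as SQT-dialect text.
3. **Filter** (`compilite.filtering`) — rank-1 PSMs pass a strict
   <10 ppm precursor gate, fan out to parent-protein loci, and loci with
   ≥2 distinct peptides are thresholded on best XCorr at the least-strict
   cutoff with (decoy loci)/(target loci) ≤ 1 %.
4. **Simulate** (`compilite.simulate`) — random proteomes, simulated
   MudPIT-style runs (b/y fragments, charge 2–3, peak dropout, noise
   peaks, ppm jitter) with per-scan ground truth, and the
   small-vs-inflated-database agreement experiment.

## Worked example

```
$ compilite simulate --seed 7 --proteins 200 --spectra 300 --out sim
wrote proteome.fasta, run.ms2, truth.json under sim
$ compilite build --fasta sim/proteome.fasta --out idx
indexed 400 proteins, 26582 distinct peptides, 20611 mass keys
$ compilite search --index idx --spectra sim/run.ms2 --out results.sqt
scored 300 scans with >=1 candidate -> results.sqt
$ compilite filter --sqt results.sqt --index idx --out filtered
82 loci at 0.000% protein FDR -> filtered/filtered_loci.tsv
```

The build indexes the 200 synthetic proteins plus their 200 reversed
decoys (400 records). Of the 300 simulated scans (10 noise peaks, 10 %
fragment dropout, 5 ppm precursor jitter — the generator defaults), 290
rank-1 matches survive the <10 ppm gate, assembling into 82 target loci
with ≥2 distinct peptides and zero decoy loci, so the achieved protein
FDR is 0 % against the 1 % ceiling. The locus table:

```
defline      distinct_peptides  spectral_count  best_xcorr
syn|000079   8                  8               0.4807
syn|000094   5                  7               0.6297
```

`sim/truth.json` holds the generating peptide per scan, so every
identification above can be checked against ground truth.

The same loop is available as library calls (`generate_proteins`,
`build_from_records`, `score_scan`, `filter_results`,
`spike_experiment`); see the module docstrings.

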