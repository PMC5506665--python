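# Methods

## Model and assumptions

The estimator targets the situation where a treatment changes the
*global level* of a histone mark while leaving its spatial distribution
largely intact. Write the expected binned coverage of the treated and
untreated IP libraries as

```
E[u_b] = d_u · s_b                (untreated)
E[t_b] = d_t · r · s_b           (treated, outside artifact bins)
E[t_b] = d_t · a_b               (treated, at artifact bins)
E[u_b] = d_u · a_b               (untreated, at artifact bins)
```

where `s_b` is the true mark signal (background plus enrichment), `a_b`
the artifact pile-up intensity, `d_u`, `d_t` the library depth factors
and `r` the uniform biological change. Per-library normalisation
estimates `d_u`, `d_t` from total coverage, which conflates `d_t` with
`r`. The artifact bins break the degeneracy: their between-library ratio
is `d_t/d_u` exactly, independent of `r`, so

```
f = 1 / median_{b ∈ top-k(u)} (t_b / u_b)  →  d_u / d_t
```

and the rescaled treated track `f·t` estimates `r·s_b` on the untreated
depth scale. The method assumes:

* artifact loci have (near-)identical profiles in IP and input and are
  unaffected by the treatment — checked, not assumed silently, via the
  input-consistency report;
* there are at least `k` such bins and they dominate the top of the
  untreated coverage ranking — checked via the threshold sweep;
* the biological change spares the artifact loci (they are not
  chromatin-derived signal).

The estimator makes *no* assumption about `r` itself; it may be 1.

### Why the median

Per-bin ratios at extreme-coverage bins are approximately
depth-ratio × multiplicative counting noise, occasionally contaminated
by bins that are partly biological. The median of the k ratios is
insensitive to such contamination up to 50% of the set, whereas the mean
is not; the mean is still reported as a diagnostic. Bins with zero
coverage in either library are excluded and counted rather than
pseudocounted — a pseudocount shifts extreme-value ratios
asymmetrically.

### Validation statistics

* **Input consistency**: for the input libraries, total-coverage fold
  change and outlier-bin median fold change both estimate depth alone,
  so they must agree. The default acceptance band is |log2 gap| ≤ 0.1
  (≈ 7% — comfortably above counting noise at these depths, well below
  any biologically meaningful global change); it is a parameter and is
  recorded in the report. The same statistic computed on the IP
  libraries *diverges* exactly when a global change is present — that
  divergence is the finding, not a failure.
* **Threshold sweep**: the factor is recomputed over a range of k
  (default 50–500) and summarised as (max−min)/median.

## Genome representation and coverage

Coordinates are 0-based half-open throughout (BED convention). Each
sequence is tiled with `ceil(L/bin)` bins (default 500 bp); a final
partial bin keeps its true length as the averaging denominator so edge
bins are not inflated. Coverage is mean per-base fragment depth:
fragment bases overlapping the bin divided by bin length, computed
exactly via an integer per-base difference array; the invariant
`Σ value_b · len_b = total fragment bases` holds to float precision and
is tested. Fragments extending past a sequence end are clipped with a
warning; fragments on unknown sequences are an error. No
mappability/blacklist masking is applied — extreme artifact bins are the
method's calibration signal, not noise to remove.

## Promoter and genome-wide comparisons

Promoter windows are TSS ± 2 kb (strand used only to locate the TSS;
window symmetric, clipped at sequence bounds), one window per gene from
a gene-level BED6. Window signal is the overlap-weighted mean of bin
values, i.e. the window mean of the per-base profile as represented on
the grid. Promoter fold change is the ratio of window means (not a mean
of per-bin ratios); promoters with zero untreated signal are flagged,
never dropped. Genome-wide correlation is Pearson r over bins nonzero in
at least one track, on raw values by default with a log2(x+1) option —
the transform is recorded in the result. Note r is invariant under
positive rescaling, so it measures distributional similarity and cannot
detect (or be biased by) the depth correction.

## Domain calling and overlap

H3K9me2-class marks occupy broad domains, so enrichment is called by
threshold-and-merge: mark bins with IP/input ≥ 1.5, merge marked runs
across gaps ≤ 1000 bp, drop runs < 2000 bp. Bins with zero input use the
genome-wide mean input as denominator (keeps artifact bins — which have
high input — while avoiding infinite ratios). The defaults suit
broad-domain marks and are exposed as flags; calling is monotone in the
threshold (tested). Overlap of two region sets is a base-pair three-way
partition plus Jaccard, with region-count overlaps also reported since a
Venn diagram may be drawn in either unit.

## PTM comparison

Input is a validated table of per-replicate relative abundances
(fractions summing to 1 ± 0.01 within each residue site). Condition
comparison reports the log2 ratio of condition means (the mean of
per-replicate ratios is emitted alongside; the two differ only at
second order in the replicate noise), a two-sided Welch t-test across
replicates, and a ranking by |log2 ratio|. No multiple-testing
correction is applied to the primary p-values (per-mark significance
calls); a Benjamini–Hochberg q-value column is included for
transparency. With fewer than two replicates in a condition, p-values
are omitted with a warning and ratios still reported.

## Synthetic data generator

The generator emulates the statistical structure the estimator relies
on, at desk scale so the full pipeline runs in under a second per
experiment. Defaults (all exposed in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| genome | 2 × 5 Mb, 500 bp bins (20,000 bins) | smallest size at which domains, promoters and artifacts coexist at realistic densities |
| background rate | 0.01 fragments/bp | ≈ 2× base coverage at 200 bp fragments, matching a typical 20M-fragment mammalian library per Gb |
| artifact bins | 150, intensities log-uniform over [33×, 300×] background (geometric centre 100×) | isolated single-bin pile-ups; the order-of-magnitude intensity spread mirrors real artifact loci and is what makes top-k selection rank by true intensity rather than by counting noise |
| minor artifact continuum | 1000 bins at 3–20× background | real genomes carry a long tail of mildly artifactual bins; the weak dependence of the factor on k up to 500 rests on this continuum |
| domains | 20, lengths uniform 100–500 kb, 5× enrichment, non-overlapping | LOCK-like broad domains covering ~half the genome |
| promoters | 200 genes, 3× enrichment over TSS ± 2 kb | promoter-localised signal for the fold-change ranking |
| depth factors | IP 1.0 / 1.75, input 1.0 / 1.3 | independent per-library sequencing depths; true factor 1/1.75 ≈ 0.571 |
| reduction r | 0.4 | uniform multiplicative loss of treated IP signal outside artifact bins |
| fragments | fixed 200 bp, counts Poisson (or NB with dispersion 10) per bin, midpoints uniform within the generating bin | spans spread symmetrically into flanking bins like paired-end pile-ups |

Structural choices that matter and why:

* **Artifact rate replaces local signal** at artifact bins and is
  identical in IP and input apart from depth — the defining property of
  an alignment artifact. Artifacts are therefore placed outside enriched
  domains (one-bin margin) and with ≥ 2 free bins between pile-ups (a
  bin flanked by two pile-ups would collect enough spill to rank as an
  outlier itself).
* **r multiplies the whole non-artifact signal** (background +
  enrichment) of the treated IP, modelling a uniform genome-wide loss;
  hence the rescaled per-bin fold-change median outside artifact bins
  estimates r directly.
* **Promoters avoid artifact bins**: artifact loci are not annotated
  promoters, and a window dominated by artifact signal would carry a
  fold change of ≈ 1 by construction, contaminating the promoter
  statistic with non-biology.

The exact expected bin coverage under this process has a closed form
(`expected_coverage`): with per-bp rate ρ constant within a bin and
fragment length L ≤ bin size B, a fragment keeps `L − L²/(4B)` expected
bases in its own bin and leaks `L²/(8B)` to each neighbour (clipped at
sequence ends). Monte-Carlo coverage converges to it (tested), which
pins the generator's law independently of the sampling code path.

**What the generator does not emulate**: GC and fragment-length bias,
mappability structure, read-level errors, duplicate fragments,
antibody-efficiency differences between libraries, non-uniform
(domain-specific) biological change, and >2 conditions. Passing
recovery tests therefore demonstrate correctness of the estimator under
its stated assumptions, not robustness to every real-data pathology; on
real libraries the input-consistency check and threshold sweep are the
guards against assumption failure.

## PTM table generator

Planted tables use fixed baseline compositions for H3K4/K9/K27/K36
(shaped on naïve ES cells), move H3K9me2 from 0.30 to 0.115 in the
treated condition (≈ 2.6-fold, log2 ≈ −1.38) crediting the difference to
unmodified H3K9, add Gaussian noise (σ = 0.01) per entry and renormalise
each site/replicate block. At this noise level the sampling SD of the
triplicate log2 ratio-of-means is ≈ 0.06–0.08, so single-table ratio
estimates scatter visibly around −1.38; tests of the central value
therefore average over 20 independent tables, while ranking and
significance hold in every table.

## Numerical choices

* Top-k ties break by ascending genomic index (determinism).
* Factor estimates are exact reciprocals of the ratio median; applying
  the factor makes the outlier median ratio 1 to 1e-9 (tested).
* Undefined ratios (zero denominators) are NaN-flagged and excluded
  from medians, never imputed.
* Region merging coalesces overlapping *and* abutting intervals, so a
  region set is a canonical form; overlap accounting is integer bp.
* The scaling-factor estimator is scale-equivariant to 1e-12
  (`estimate(c·t, u) = estimate(t, u)/c`) and strictly monotone in the
  treated outlier values.

## Problem sizes

The test suite and `scripts/acceptance.py` run 20-seed batches of the
default 2 × 5 Mb experiment (~1.2M fragments per experiment across four
libraries, ~0.6 s each), 100-instance brute-force oracles for coverage
and overlap on ≤ 100 kb genomes, and 20 planted PTM tables; the whole
suite completes in well under a minute on one CPU.

## Known limitations

* Exactly two conditions; no joint multi-sample normalisation.
* The domain caller is deliberately simple (no significance model, no
  FDR); it characterises broad-domain overlap, not precise boundaries.
* The input-consistency tolerance (0.1 log2) is a calibration choice,
  not a derived detection threshold.
* With fewer than ~50 usable outlier bins the factor's variance grows
  quickly; the sweep makes this visible but cannot repair it.
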