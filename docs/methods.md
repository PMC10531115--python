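# Methods

## Data model

The pipeline consumes the output family of HMM-based local-ancestry
inference (LAI) over a phased, diploid, 3-way admixed cohort. Per
chromosome:

* a **forward–backward file**: one row per variant holding
  `n_haplotypes × K` posterior probabilities, haplotype-major (each
  haplotype's K-vector sums to 1);
* a **Viterbi file**: the most-likely ancestry code (1..K) per variant per
  haplotype;
* a **locations file**: the variant's genetic position in centimorgans, one
  per line;
* a **sample list**: one id per line; haplotype columns are sample-major,
  two per sample (`id.0`, `id.1`).

The exact on-disk dialect of the upstream tool varies by version, so
`rfmix_io` *fixes* this contract and the simulator emits it bit-exactly;
everything downstream depends only on the contract. Posterior rows whose
probabilities sum outside 1 ± 1e-4 are an error by default rather than
silently renormalized (an explicit `renormalize=True` rescales), because a
bad sum usually means upstream corruption. A strict 1e-6 sum tolerance
applies to in-memory tensors. RFMix-v2 table formats are not supported.

## Ancestry search (per-variant cohort summary)

A sample's diploid ancestry vector at a variant is the arithmetic mean of
its two haplotype posteriors; the cohort average weights every included
sample equally. For fully diploid cohorts this equals averaging over
haplotypes, so the choice is benign; it is made explicit because published
descriptions of the procedure say only "average ancestry by variant". The
combined table (`all_chr.anc`) is ordered chromosome-major then by cM, with
the fixed column order rsid, chrom, pos_bp, cM, one `avg_<label>` column per
ancestry, then one column per sample holding its K-vector as
semicolon-joined reals (the published format leaves the cell encoding
unstated; semicolons keep cells atomic in tab-delimited text). Per-sample
cells are serialized at 6 significant digits; averages at 10, so re-reading
a table preserves the averages to ~1e-9 but drops the (rounded) per-sample
tensor rather than pretend the avg-equals-mean invariant still holds.

Lookups of target rsids report found rows and an explicit missing list;
a miss is data, not an error — reference panels routinely lack variants
(in the published study, only 10 of 50 CVD SNPs had inferable ancestry).

## Genetic coordinates

Physical (bp, GRCh37, 1-based) to genetic (cM) conversion uses a monotone
piecewise-linear map: HapMap-style `chrom pos_bp cM` anchors, linear
interpolation between flanking anchors, linear extrapolation at the
terminal inter-anchor rate beyond them, clamped at 0 cM. Interpolation is
exact at anchors and non-decreasing in position. A uniform 1 cM/Mb fallback
map is available for demonstrations and is logged loudly: real analyses
must use the genetic map the upstream LAI actually used. Chromosome labels
are stored as strings with any `chr` prefix stripped (so `X` is
admissible); no liftover and no sex-specific maps.

## Bracket search (proximity)

Two variants are in proximity when they share a chromosome and their
genetic distance is at most the window half-width (default 0.5 cM). The
boundary |Δ| = 0.5 is **included**: reading "±0.5 cM" as a closed interval
is the conservative choice for a co-localization claim. Pairs are
same-chromosome only, since cM coordinates are per-chromosome. Each
unordered qualifying pair is reported once, never self-paired by rsid,
sorted by chromosome then by the cM of its A-side member; when a pair was
generated in both orientations (possible in a self-search) the orientation
with the smaller (cM, rsid) is kept, making the output independent of
generation order. The production search sorts each chromosome by cM and
sweeps a two-pointer window (O(n log n)); the O(|A|·|B|) double loop is
retained as an independent oracle and the two are checked for equality on
hundreds of random instances.

## Random controls and enrichment

Random controls are drawn by seeded Fisher–Yates shuffle (numpy
permutation) of the universe after removing excluded targets, taking the
first *n*; exclusion matches by rsid **or** by (chrom, pos_bp) so renamed
variants are still excluded. Draws are deterministic given the seed, and
each variant's long-run inclusion frequency is uniform (property-tested).

A locus is classified to ancestry *k* when its average proportion is
**strictly** greater than the threshold (default 0.50); strictness makes
classes disjoint for any threshold ≥ 0.5 and is required to reproduce the
published enrichment counts, whose panel contains one locus sitting at
exactly 0.50 (that text describes the rule as "≥50%", but its printed
counts match only the strict reading). Published tables round proportions
to two decimals, so their row sums are validated at ±0.02; computed
summaries keep the 1e-6 tolerance.

Target and control classifications form a 2×C table (one column per
ancestry plus "unclassified"; all-zero columns dropped; a table with a
single surviving column or an empty group is reported as no-association,
p = 1). Test selection under `method="auto"`:

* every expected cell ≥ 5 → Pearson chi-square, no continuity correction;
* otherwise → **mid-p Fisher exact test** by exhaustive conditional
  enumeration (probability ordering over all admissible first rows of the
  multivariate hypergeometric, exact for any 2×C).

The classical two-sided Fisher test (full weight on the equi-probable
class) is implemented and selectable; for 2×2 it matches
`scipy.stats.fisher_exact` and yields the textbook value
p = 2/C(20,10) ≈ 1.0825e-5 for [[10,0],[0,10]]. The *mid-p* variant is the
default for sparse tables because our null-calibration simulations measured
the classical test's attained size at ≈0.027 for the 10-target-versus-60-
control design — the familiar conservatism of exact tests under heavy
discreteness — while mid-p attains ≈0.05; mid-p forgoes the guaranteed
size bound in exchange for calibration, the standard trade-off. No
multiple-testing correction is applied across ancestries: the comparison is
a single omnibus table by design.

## Synthetic cohorts

Each haplotype is an independent single-pulse ancestry mosaic on a
chromosome of genetic length L cM: after g generations, breakpoints follow
a Poisson process of rate g/100 per cM (count ~ Poisson(gL/100), positions
uniform), and each segment draws its ancestry iid from the mixing
proportions. Enrichment spikes force breakpoints at the interval bounds and
boost the focal ancestry's segment probability to b inside, rescaling the
rest proportionally. Posteriors put 1−ε on the true ancestry and ε/(K−1)
elsewhere; Viterbi files carry the true codes, so truth-argmax equals
Viterbi exactly and ε = 0 makes the cohort summary equal the empirical
truth frequencies exactly. SNP grids are evenly spaced in cM at segment
midoffsets ((i+0.5)·L/n), with bp = cM × 1e6 under the uniform fallback
map so the coordinate and proximity stages are exercised consistently. All
randomness flows from one seed through spawned per-chromosome seed
sequences.

Key parameters (defaults in parentheses): ancestry labels (IBS, YRI, NA);
mixing proportions (0.64, 0.21, 0.15 — typical published global-ancestry
estimates for Puerto Rican / Caribbean Hispanic cohorts); generations since
admixture g (10, giving ~10 cM mean tracts, the right scale for post-
colonial admixture); cohort size (500 diploid samples, matching the scale
of the motivating 510-patient cohort); one 100 cM chromosome with 1000
SNPs; posterior noise ε (0.02, a small LAI error rate that keeps argmax on
the truth).

**What the generator does and does not emulate.** It reproduces the
per-locus marginal structure (each locus's haplotype ancestries are draws
from the mix), tract-length scale, and file dialect that the
post-processing consumes. It is *not* a demographic model: haplotypes share
no pedigree, so there is no drift of local ancestry across the cohort, and
segment ancestries carry no LD. Consequently, with a large cohort every
locus's average converges to the global mix — the striking locus-to-locus
spread seen in real published panels (locus averages from 0.10 to 0.94 for
one ancestry) reflects shared genealogy that this generator deliberately
omits. Passing tests therefore validate the *computations* (averaging,
search, counting, testing), not any demographic claim about real cohorts.

**Tract-length estimator.** The mean ancestry-tract length is estimated as
total simulated genetic length divided by total breakpoint count — the MLE
of the Poisson inter-breakpoint mean, expected 100/g cM. The naive mean of
observed segment lengths is biased low by the two edge-censored segments
per chromosome (≈ L/(gL/100 + 1), a 17% shortfall at g = 5 on a 100 cM
chromosome), which is why the MLE is used. Tracts here are
inter-breakpoint segments; merging adjacent same-ancestry segments would
lengthen them by 1/(1 − Σ_k m_k²) and is not done.

## Validation studies (`experiments` module)

* **Parameter recovery**: 500 samples, g = 10, mix (0.20, 0.25, 0.55),
  1000 SNPs on one 100 cM chromosome, ε = 0.02. The genome-wide mean of
  locus averages recovers each mixing proportion within ±0.02: the
  posterior-noise bias on component k is ε(1 − K·m_k)/(K − 1), at most
  0.0065 in magnitude here, and the sampling SE is ~0.005. The
  tract-length MLE lands within 10% of 10 cM.
* **Spike detection (power)**: default mix, 30 samples, 300 SNPs; NA
  boosted to 0.9 over 45–50 cM; the 10 spiked loci versus 60 random
  controls. Detection rate at α = 0.05 over 200 seeded replicates.
* **Null calibration (type-I error)**: identical comparison with no spike
  and targets drawn at random, 1000 replicates. This arm uses mix
  (0.20, 0.25, 0.55) and 20 samples: calibration must be measured where
  locus classification retains sampling variability. Under the
  IBS-dominant default mix, all loci fall into one class for any sizeable
  cohort, the table degenerates, and every test is trivially conservative —
  that measures degeneracy, not calibration. The small cohort keeps the
  per-locus classification probability away from 0/1 so the contingency
  test operates with real resolution.

The small cohorts in the replicate studies are a deliberate scientific
choice for the same reason: in this generator, per-locus spread shrinks as
1/√(haplotypes), so small cohorts are the regime where locus classification
is non-trivial.

## Degenerate inputs and tie-breaks

Empty catalogs, empty queries, and all-missing lookups are valid and return
empty results; an all-zero contingency table and an empty summary for
mixing recovery raise degenerate-input errors. Classification argmax takes
the first maximal ancestry, which cannot matter at thresholds ≥ 0.5 (two
ancestries cannot both strictly exceed 0.5). Proximity output order and
random-control membership are fully deterministic given inputs and seed;
the pipeline writes no timestamps into outputs, so reruns are
byte-identical.

## Known limitations

* The proximity analysis of the published panels covers the 10 CVD loci
  with printed cM coordinates; the full 50-CVD-versus-10-clopidogrel search
  would need an external genetic map to place the remaining variants in cM.
* The simulator emits no genotypes or sequences and cannot drive an actual
  LAI tool; it emulates LAI *output*.
* RFMix-v2 file formats, sex-specific maps, LD-aware proximity (r²), and
  admixture-mapping association frameworks are out of scope.
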