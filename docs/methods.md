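# Methods

## Statistics

**Per-site diversity.** π at a site is the unbiased heterozygosity
2j(n−j)/(n(n−1)) for j alternate alleles among n called alleles — exactly
the fraction of differing pairs among all C(n,2) allele pairs. Sites with
fewer than two called alleles are undefined (NaN, never 0: zero is a
meaningful value and undefined statistics must not be conflated with it;
this convention holds everywhere in the package).

**Window statistics.** Windows tile each chromosome from position 0 in
non-overlapping spans (default 100,000 bp); a trailing partial window is
emitted with its true span and flagged rather than silently truncated.
Within a window and population, π is the mean of per-site π. Two denominator
modes exist and differ by orders of magnitude: `per_site` (default) averages
over variant sites only, matching a compute-per-site-then-average procedure;
`per_bp` divides the same sum by the window span. The mode is surfaced in
the API and output headers rather than resolved silently. Tajima's D uses
the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) with S the segregating
sites in the population's window and the summed site π as the mean pairwise
difference; with missing data the allele count n is the rounded mean of
called alleles over usable sites. Windows with fewer than `min_sites`
(default 10) usable sites are undefined.

**F<sub>ST</sub> and d<sub>xy</sub>.** The default F<sub>ST</sub> is
Hudson (1992) as a window-level ratio of averages:
N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and
D = p₁(1−p₂) + p₂(1−p₁), summed over usable sites before dividing — robust
to unequal sample sizes and with E[N/D] = F under the Balding–Nichols
divergence model, which the recovery tests exploit. Weir & Cockerham's
θ̂ (allele-count form) is available as a flagged alternative.
d<sub>xy</sub> per site is p₁(1−p₂) + p₂(1−p₁), averaged per the chosen
denominator mode.

**Allele sharing.** A site is *shared* if it segregates in ≥2 populations,
*private* to the single population in which it segregates, a *fixed
difference* if all populations are fixed but not for the same allele, and
*monomorphic* otherwise; populations with no called alleles are ignored and
sites with fewer than two informative populations are undefined. The four
classes partition all classified sites, so their percentages sum to 100.

**Sub-genome comparison.** The L-vs-S test is the large-sample two-sample
z-test z = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂) with a two-sided normal p-value;
Welch's t is offered for small window counts since the normal reference is
mildly anti-conservative there (at ~40 windows a side the realised size at
α = 0.05 is ≈ 0.055, inside the calibration band the tests enforce).
Degenerate zero-variance inputs yield p = 1 (equal means) or p = 0.

**Exon-flank windows.** One record per qualifying exon: the first and last
exon of each multi-exon gene and the sole exon of single-exon genes, in
transcription order (strand-aware; the first exon of a minus-strand gene is
its highest-coordinate exon). The window is the exon body plus a 10 kb
flank on each side (`anchor="exon"`); a fixed-width window centred on the
exon midpoint (`anchor="midpoint"`) is provided because either reading of
"20 kb windows centred on the exon" is defensible. Overlapping windows from
adjacent genes are kept independently — no deduplication rule is imposed —
which matters for inference: overlapping records share sites and are
therefore correlated, so significance tests on dense toy layouts need
spacing (the calibration suite spaces single-exon genes beyond the window
width for exactly this reason).

**Effect classification.** For a coding SNP the codon is located through
the CDS segments, phase and strand of the gene model (longest-CDS
transcript per gene), translated with the standard code, and classified:
synonymous → silent/Low, stop gain → nonsense/High, other amino-acid
change → missense/Moderate. Stop-loss and start-loss are High impact with
function class missense — the one deliberate exception to
missense → Moderate, mirroring the usual annotation-tool convention.
Positions outside any CDS (or in out-of-frame leading phase bases) are
noncoding/Modifier; with several covering transcripts the most severe
consequence wins. An exhaustive oracle (all 64 codons × 3 positions × 3
substitutions on both strands, 1,152 cases) pins the implementation to a
hand-written codon table. The ANN parser maps externally annotated VCFs
into the same vocabulary. The derived allele is the non-reference allele;
no ancestral polarisation is attempted, so spectra are non-ref-frequency
spectra.

**Pool-seq F<sub>ST</sub>.** Two estimators on pooled read counts, with the
effective allele count capped at min(C, 2·pool_size) since reads beyond
twice the pool size sample no new chromosomes:

* `classical` (default): (π_total − mean π_within)/π_total with each
  π̂ = 2f(1−f)·C_eff/(C_eff−1), π_total from the unweighted mean of the two
  pool frequencies with the min-coverage correction. This mirrors the
  classical sliding-window pool tooling, and window F<sub>ST</sub> is the
  mean of defined site values. **Caveat:** with only two demes its
  expectation is F/(2−F), not F (≈ 0.176 at F = 0.30; ≈ 0.155 measured with
  depth-30 read noise) — fine for ranking and outlier selection, biased as
  an estimate of the divergence parameter.
* `hudson`: the Hudson numerator/denominator on pool frequencies with the
  read-sampling correction f(1−f)/(C_eff−1), window-level ratio of
  averages. Unbiased for F under the divergence model; this is the variant
  checked against F = 0.30 in the acceptance suite.

**Outliers and candidate genes.** Outlier windows are the top
⌈quantile·N⌉ defined windows by mean F<sub>ST</sub> (default 1%), ties
broken by position. Sub-genome enrichment is an exact two-sided binomial
test of the L count among outliers against the background L proportion —
an extension beyond the proportions themselves. Candidate genes are those
whose interval lies within 10 kb (≤, strand-agnostic, distance 0 inside
the gene) of a SNP with F<sub>ST</sub> ≥ 0.15. In the pipeline the
threshold is applied to SNPs *inside the selected outlier windows*: the
threshold and the top-1% selection describe the same tail, and at desk
scale raw site F<sub>ST</sub> at depth ~30 crosses 0.15 by noise at a few
percent of background sites, which would otherwise flood the gene list
(site-level thresholding over all sites remains available through the
generic function). Homeolog pairing is by the terminal `.L`/`.S`
gene-symbol suffix (duplicate same-tag symbols are ambiguous and excluded);
a retained pair whose two copies both qualify is `both_copies`, one
qualifying copy is `one_copy`, unpaired genes are `single_copy`.

## Filters

The stringent genotype filters are: per-genotype DP < 5 or GQ < 30 → set
missing; per-site mean DP > 20, missingness > 20%, or MAF < 5% → drop the
site; multi-allelic and non-SNP records are dropped with a logged count.
"Maximum average depth" is applied as the per-site mean across samples,
with the per-sample minimum handling low coverage, matching the semantics
of the two flags in standard VCF filtering tools. MAF is computed on the
full cohort by default (a per-population option exists via subsetting).
Setting `min_maf=0` (the "relaxed" configuration) retains every polymorphic
biallelic site. Tightening any single filter field can only reduce the
retained site count (a property the suite verifies). Pool counts are
bounded to coverage 4–50 in every pool with pool size 32; an indel mask is
accepted as a BED input rather than computed.

Coordinates are 0-based half-open internally, converted at the VCF/GFF
boundary (both 1-based inclusive), so window arithmetic is unambiguous.

## The synthetic cohort generator

The generator emulates the data a sub-genome comparison consumes, not the
coalescent process that produced the real data. Per site: ancestral
frequency p ~ Beta(0.5, 0.5) (a U-shaped folded spectrum), deme frequencies
q ~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes Binomial(2, q). Defaults
describe the emulated study conditions: two populations of 10 diploids at
F = 0.30 (the empirical between-population window F<sub>ST</sub> range is
roughly 0.27–0.35), per-genotype depth Poisson(11) and GQ 99 with a 3%
low-GQ rate, 2% missingness, pools of 32 individuals at 32× with background
pool divergence F = 0.05 (the stated pool-scenario condition; the empirical
pool contrast's ≈0.09 is a classical-estimator output, not a model F).
θ is the expected variant-site density per bp; the desk-scale default
(5 × 10⁻³) trades genome length for site count, and problem sizes in tests
(genome sizes from 0.3 to 5 Mb, 10⁵ sites for recovery checks, 200–500
calibration replicates) are chosen so each property is measured with
adequate resolution at interactive runtimes.

Background selection enters as a trough multiplier
m(d) = 1 − depth·exp(−d/decay) (default depth 0.5, decay 5 kb) on distance
d to the nearest exon. It acts twice: variant positions are Poisson-thinned
by m, and the minor-allele frequency is multiplied by m (folding first, so
the deflation strictly reduces heterozygosity on both arms — deflating the
alt-allele frequency directly would *raise* heterozygosity wherever
p > 0.5). Density thinning alone would leave the per-variant-site π
estimator unchanged, so the frequency deflation is what produces the
empirical trough signature under this estimator. Note the two effects
partially offset in exon windows: thinning preferentially removes
low-frequency (near-exon) sites, so the realised exon-window deficit in
mean site π is milder than the depth parameter suggests (≈ 9% at depth 0.5
with the default geometry) though clearly detectable.

Coding variants draw a target function class from `impact_mix`
renormalised over the classes reachable by a single-base change at that
codon position, and the alt base is chosen to realise it — ground truth and
sequence are therefore always mutually consistent, and the annotation
module must reproduce the committed class at every site. Because silent
changes are only reachable at a minority of codon positions, the realised
missense/silent count ratio exceeds the nominal mix (≈3 with defaults) —
the mutation-opportunity ratio, as in real unselected mutation data;
purifying selection is modelled downstream of counts, as per-impact
multiplicative deflation of the ancestral frequency (defaults 1.0 / 0.7 /
0.3 for Low/Moderate/High), which left-shifts the High spectrum. Gene
retention is asymmetric by default (92% on L, 69% on S, matching reported
progenitor gene-loss asymmetry), producing both/L-only/S-only homeolog
groups. CDS sequences are built from non-stop codons (ATG … stop) and
written into an otherwise random reference, so no gene contains premature
stops. Any parameter can be overridden per sub-genome through `asymmetry`,
and `make_null_pair` enforces the fully symmetric null. All randomness
flows through one seeded generator: equal seeds give byte-identical files,
and the seed is recorded in the emitted headers.

What the generator does **not** model — and hence what passing tests do not
establish about real data: linkage and recombination (sites are
independent, so window variances are smaller than with LD), demography
(population-size change, migration, admixture beyond a flag), sequencing
error, indels, multi-allelic sites, reference bias, or correlated
missingness. Calibration results in particular describe the independent-
site regime; on real data, correlated windows make the z-tests
anti-conservative and block-resampling would be the defensible upgrade.

## Numerical conventions

Undefined values are NaN throughout (never 0); F<sub>ST</sub> estimators
may be slightly negative by sampling correction. Outlier ties break
deterministically by (chromosome, start). The window z-test removes NaN
windows before testing and requires two finite values per group. The
enrichment test needs a non-empty outlier set. Effect proportions are
reported with explicit denominators (coding impact tiers vs function
classes) since the two classification axes have different totals.

## Known limitations

The pool estimator caveat and the independence caveat above are the two
substantive ones. Homeolog pairing by name suffix assumes the standard
`.L`/`.S` nomenclature; an explicit pairing table can be supplied where
names deviate. The windows-table column format (`fst_<pop1>_<pop2>`) is
ambiguous when population names themselves contain underscores; the
file-based sub-genome stage therefore treats statistic columns generically
rather than parsing pair names.
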