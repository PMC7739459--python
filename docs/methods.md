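# Methods

`codonuse` implements a multispecies codon-usage analysis for sets of
protein-coding sequences (CDS). This note records the model choices,
parameter conventions and numerical decisions behind each stage, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Input model and quality filtering

The unit of analysis is an in-frame CDS on the coding strand: length a
positive multiple of 3, ATG start, TAA/TAG/TGA stop, no internal stop,
no bases outside {A,C,G,T}. RNA-alphabet input (U) is mapped to T on
read and everything is uppercased. Each failing sequence is rejected
under exactly one reason, the first failing in the fixed precedence

    bad_length → ambiguous_base → no_start → bad_stop → internal_stop

so filter reports are deterministic and satisfy the conservation
identity `n_input = n_retained + Σ rejections`. The multiple-of-3 rule
is a structural necessity (codon indices are undefined otherwise)
rather than a biological filter; there is no minimum-length filter by
default, but a configurable nucleotide floor exists and folds into the
`bad_length` reason so the report schema stays fixed. Duplicate FASTA
ids are disambiguated with a numeric suffix (`id.2`, `id.3`, ...)
instead of failing, because real annotation dumps contain them.

## Codon-level indices

All indices are computed on **sense codons**: the terminal stop codon
of each gene is dropped first, and stop codons never enter any tally.
Overall GC and positional GC1/GC2/GC3 are percentages of G+C among the
scoped bases; a `with-stop` scope is available for the GC fields
because conventions differ between published tables, but sense-only is
the default used everywhere downstream. GC3s restricts the
third-position tally to codons of amino acids with at least two
synonyms (Met/ATG and Trp/TGG excluded).

RSCU follows Sharp & Li: for codon *c* in a synonymous family of size
*k*, `RSCU(c) = k·count(c)/family_total`; the family share is
`count(c)/family_total`. Six-fold families (Leu, Ser, Arg) are treated
as single families of size 6. A family never observed is reported as
missing rather than as a row of zeros — an RSCU of 0 specifically
means "family used, but never via this codon".

ENc is Wright's estimator, which is also what the codonW program
computes. Per amino acid with family size ≥ 2 and n ≥ 2 codons
observed, the codon homozygosity is

    F̂ = (n·Σp̂² − 1)/(n − 1)

with p̂ the within-family codon frequencies. F̂ is averaged over the
degeneracy classes of the standard code (9 two-fold amino acids, Ile
alone in the three-fold class, 5 four-fold, 3 six-fold) and combined
as

    ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ ,

capped at 61. Amino acids with n ≤ 1 or F̂ ≤ 0 are excluded from class
means; a missing three-fold mean (Ile unobserved) is replaced by
(F̄₂+F̄₄)/2; any other empty class leaves ENc undefined for that gene,
and such genes are excluded (and counted) in downstream plots. At one
codon per amino acid every F̂ is exactly 1 and ENc = 2+9+1+5+3 = 20;
uniform usage drives it toward 61.

Species summaries pool GC fields over the concatenated sense codons of
all genes and report ENc as the unweighted mean of defined per-gene
values. Pooled GC is the default because per-species tables in the
literature rarely state their convention; a `gene_mean` switch
averages the per-gene values instead.

High-frequency codons are those with RSCU strictly above 1.5 **or** a
family share strictly above 60%. The share rule matters for two-fold
families, where a 61% share only reaches RSCU 1.22.

## Neutrality plot and ENc plot

The neutrality plot regresses per-gene GC12 = (GC1+GC2)/2 on GC3 by
ordinary least squares (delegated to `scipy.stats.linregress`), with
the two-sided t-test p-value for zero slope. GC3 (not GC3s) is the
default x-variable, with a flag to switch. Degenerate inputs are
handled explicitly: fewer than 3 genes is an error, zero GC3 variance
leaves the slope undefined and flagged, and a constant response
returns slope 0 with r² = 0 rather than NaN.

The expected ENc under pure GC3s composition is

    ENc_exp(F) = 2 + F + 29/(F² + (1−F)²),   F = GC3s fraction ∈ [0,1],

giving 60.5 at F = 0.5 and 31/32 at the endpoints. The per-gene
relative deviation `d = (ENc_exp − ENc_obs)/ENc_exp` is binned at
width 0.05 over [−1, 1] (left-closed bins; genuine ENc values cannot
leave this range, but the end bins absorb anything synthetic that
does), and the mass in [0, 0.1) is reported separately because it is
the diagnostic band: composition-driven usage concentrates near 0,
while selected usage shifts the mass positive.

## Codon pairs (RSCPU)

Ordered adjacent codon pairs are tallied within each gene with a step
of one codon, after dropping the terminal stop; no pair spans a gene
boundary, so a gene with s sense codons contributes s − 1 of the
3,721 = 61 × 61 possible pair types. Synonymous codon-pair families
are defined as all pairs encoding the same ordered amino-acid pair
(dipeptide), so the family size is `n_i = deg(a)·deg(b)` with
singleton factors allowed for Met and Trp. RSCPU is the pair count
divided by the family mean, `RSCPU_i = x_i·n_i/Σ_family x`, and the
high-frequency rules are the same strict 1.5/60% pair of thresholds
used for single codons. The dipeptide reading of "synonymous codon
pair" is a deliberate disambiguation: it is the only definition under
which the family-mean normalisation is internally consistent.

## Dinucleotide signatures

Per species, a one-base sliding window over each filtered CDS yields
the dinucleotide frequencies `f_xy = count(xy)/Σ(L_i − 1)` and base
frequencies `f_x = count(x)/ΣL_i`; windows never cross sequence
boundaries. The species signature is the 16-vector
`p_xy = f_xy/(f_x·f_y)` in fixed lexicographic order — an odds-ratio
profile that is 1 everywhere for an i.i.d. base stream and invariant
under duplicating the whole collection. Signatures are pooled per
species (not averaged over genes); a zero base frequency yields
`p_xy = 0` with a flag rather than an error, to tolerate degenerate
synthetic input. Species similarity is the Pearson correlation of
signatures, computed in the raw-moment form with N = 16 and verified
to machine precision against the covariance form.

## Comparison and clustering

The clustering feature space is the 59-codon RSCU vector (61 sense
codons minus ATG and TGG), with a fixed column order — amino acids
alphabetical by one-letter code, codons alphabetical within each
family — since no heat-map tool ordering is canonical. Missing
families are imputed as 0 with a per-cell mask. Agglomerative
clustering uses Euclidean distance and average linkage (UPGMA) via
`scipy.cluster.hierarchy`; rows and columns are clustered
independently for the biclustered layout. Rows are not standardized
before clustering. Ties in agglomeration resolve deterministically to
the smallest cluster indices. Dendrograms serialize to Newick with
ultrametric branch lengths (parent height minus child height), so
leaf-to-node path length reproduces the merge height.

## Workflow outputs

`run_workflow` executes the stages in order — preprocessing, GC
content, neutrality/ENc plots, high-frequency codons, codon pairs,
comparison and clustering, dinucleotide statistics — and writes a TSV
per product plus two Newick dendrograms. Every output starts with
comment lines carrying the package version, a configuration hash and
the seed, and reruns with identical configuration are byte-identical.
A stage failure aborts the run, names the stage and species, and
removes partial outputs.

## Synthetic data generator

The generator emulates what the pipeline consumes: multi-gene CDS sets
with controllable synonymous-codon preferences. Amino-acid composition
is uniform over the 20 amino acids by default (a `cycle` mode
guarantees coverage for small collections); per-family codon choice
follows explicit weights, or weights drawn once per family from a
symmetric Dirichlet whose concentration sets the bias strength (≈0.3
gives strongly biased, selection-like usage; large values approach
uniform). Defaults of 100 genes of 100–400 codons sit in the range of
typical plant CDS catalogues at test scale. A GC3 target, when set,
overrides third-position choice: each controllable position picks a
GC-ending synonym with probability q = (target − p_forced)/(1 −
p_forced), where p_forced is the probability of drawing Met or Trp
(which force G); realized GC3 then concentrates binomially around the
target. Quality defects (missing start, bad stop, internal stop,
ambiguous base, frame-breaking length) are injected per gene at
configurable, mutually exclusive rates, and every gene carries its
injected defect label — an exact oracle for the filter report.

Each gene draws from `default_rng([seed, gene_index])`, so collections
are reproducible byte-for-byte and adding or removing genes does not
shift the others. `generate_biased_pair` produces two collections
whose weight models are geometrically interpolated in log-weight
space: divergence 0 means identical models, 1 means the second spec's
model, larger values extrapolate — giving monotone control of
signature correlation and RSCU distance for separation tests.

What the generator does **not** emulate: real gene-length and
amino-acid composition distributions, intra-genome heterogeneity
(expression-correlated bias), isochore structure, or annotation noise
beyond the five defect classes. Passing tests therefore demonstrate
the correctness of the computations and the qualitative behaviour of
the diagnostics, not quantitative agreement with any real genome.

## Problem sizes

The test suite and the acceptance script run on generated collections
of tens to hundreds of genes (10³–10⁵ codons per species). These sizes
were chosen so that stochastic checks (share convergence at 10⁵
codons within 0.02, GC3 targeting within 0.03, signature correlation
of same-model replicates above 0.999) sit comfortably inside their
binomial tolerances; all computations scale linearly in total codons
and handle genome-scale inputs.

## Known limitations

- ENc for very short genes (a few codons) is frequently undefined
  because degeneracy classes lack usable amino acids; such genes are
  excluded and counted rather than imputed.
- The aggregate GC convention (pooled vs gene-averaged) changes
  species summaries when gene lengths vary; both are implemented, and
  comparisons across studies must match conventions.
- Pearson correlation on 16-dimensional signatures is a similarity
  heuristic, not a phylogenetic distance; the dendrogram is a
  descriptive clustering, not a tree-inference result.
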