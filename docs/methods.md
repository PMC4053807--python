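# Methods

This note documents the models implemented in `areclip`, the parameter
choices behind the synthetic study, the numerical conventions, and the
limits of what the synthetic conditions demonstrate.

## Coordinates, alphabets, conventions

All in-memory coordinates are genomic, 0-based, half-open. BED input is
taken as-is; the cluster-CSV dialect and GTF are 1-based closed and
converted on read. All sequences are held in the RNA alphabet (A/C/G/U),
strand-resolved (written 5′→3′ in transcript orientation); DNA input (T)
is normalized to U on ingest. A site's representative point is its
interval midpoint — the center nucleotide, left-of-center for even
lengths — which is symmetric and does not privilege either cluster edge.

## Region annotation

A site is assigned to the gene with the largest total strand-aware overlap
(an exact tie between genes → `unannotated`, which avoids double counting
in gene summaries), and within that gene to the segment label with the
majority of the overlap; label ties are broken by the precedence
3′UTR > 5′UTR > CDS > intron. The precedence produces mutually exclusive
region labels from a single rule; annotation is deterministic and
invariant to input row order. Gene summaries keep one transcript per gene
and measure `utr3_length` from its (longest) annotated 3′UTR.

## Motif enrichment (SNR)

SNR(m) = (occurrences of m per nucleotide of site sequence) /
(occurrences per nucleotide of background sequence), with the background
being the longest annotated 3′UTR per gene across the whole provided
annotation (not only expressed genes — a deliberate, configurable choice:
callers can pass any background sequence set). Occurrences are counted at
every start position (overlapping mode) because tandem AREs overlap;
"instances per nucleotide" implies positional scanning. Occurrences are
counted within site boundaries only; flanking context is not scanned. No
pseudocounts anywhere: a motif absent from the background has an undefined
SNR, carried as NaN and flagged, never as infinity.

## Affinity calibration

K_d = a·(1/SNR)^b is fitted by ordinary least squares of log₁₀K_d on
log₁₀(1/SNR) — a power curve with multiplicative error, the standard
assumption when the error model is unstated. `r_log` is the Pearson
correlation of the log-transformed quantities. Probes whose sequence never
occurs in the site set have no defined SNR and are excluded from fitting;
nonpositive K_d or SNR values are excluded with a warning. Duplicated
probe rows act as weights (they change the fit) — deliberate, since a
probe measured twice is twice the evidence. The spacer scan builds
UAUU⟨spacer⟩UAUU variants for spacer lengths 0–4: length 0 is exactly the
intact octamer UAUUUAUU; spacers are runs of U (uridylate) or of a single
non-uridylate V ∈ {A, C, G}, with the V row reported as the mean over the
three bases.

## Spearman partial correlation

Ranks (average ranks for ties) are computed once per column; all further
machinery is Pearson on ranks. Three routes are implemented and must
agree:

1. **residual** — regress the rank-transformed x and y on the
   rank-transformed controls plus an intercept; correlate the residuals
   with the product-moment estimator in its summation form.
2. **recursive** — reduce the order-n coefficient via
   ρ_XY·Z = (ρ_XY·Z′ − ρ_XZ₀·Z′ ρ_Z₀Y·Z′) /
   √((1 − ρ²_XZ₀·Z′)(1 − ρ²_Z₀Y·Z′)), Z′ = Z∖{Z₀}, with memoization;
   controls are eliminated in the order given (the result is
   order-invariant, asserted by test).
3. **matrix** — invert the Spearman correlation matrix of {x, y} ∪ Z and
   read −P₁₂/√(P₁₁P₂₂) off the precision matrix (the oracle route).

The three agree to 1e-10 on nondegenerate data (asserted over 200 random
datasets). Degeneracies raise typed errors: a control that fully explains
x or y (zero residual variance, detected with a relative tolerance of
1e-16 on the rank variance), and collinear control sets (condition number
above 1e12). Rows with missing values are dropped listwise, with the count
reported — the standard choice when no imputation policy is stated.
The null 99% band helper uses the Fisher z approximation,
tanh(z₀.₉₉₅/√(n − |Z| − 3)).

Library-size differences between site sets are handled by depth matching —
taking the top-n sites by read count, ties broken by coordinate — rather
than by rate scaling, mirroring how a deeper library is reduced to a
comparable subset.

## Hotelling T²

Two-sample T² with pooled covariance on 2-D points (joint response to two
perturbations), p from the exact transform
F = (n₁+n₂−p−1)/(p(n₁+n₂−2))·T² ~ F(p, n₁+n₂−p−1). Bonferroni correction
across gene categories is applied by the caller. The implementation is
validated against an independent multivariate-test implementation
(pingouin) in the test suite.

## Spatial permutation statistics

One permutation scheme throughout: each site keeps its host segment and
the segment its length; only the position is redrawn uniformly over the
valid placements of a site of that length, repeated `n_perm` times
(default 100 for density bands, 1000 for enrichment tests). Because
redrawing whole sites matches how observed sites occupy a segment, the
null is exactly calibrated; redrawing bare midpoints would be biased near
segment ends by half a site length. Positional densities use a Gaussian
kernel with Silverman bandwidth on a 512-point grid — a conventional
default, since the original plotting tools' settings are unknowable.
Terminal enrichment reports ratio = observed/mean-permuted counts in the
last 100 nt and p = (1 + #{perm ≥ obs})/(1 + n_perm); an analytic uniform
background (sum of per-site Bernoulli probabilities, normal
approximation) is available behind a flag. Cross-RBP proximity uses the
edge-to-edge gap (0 for overlapping intervals) rather than
midpoint-to-midpoint: with heavily overlapping site sets a midpoint metric
would report spurious distances.

## The synthetic study

The generator's defaults are the study conditions under which the package
is validated:

| parameter | default | rationale |
| --- | --- | --- |
| genes / sites | 2,000 / 3,000 | a few thousand genes with ~1.5 sites each, the scale of a single PAR-CLIP library |
| segment lengths | log-normal; 3′UTR mean 800 nt (CV 0.7), 5′UTR 200, coding exon 400, intron 1,500; 2 introns | human-like magnitudes, kept modest so simulation stays desk-scale |
| region probabilities | 3′UTR 0.70, intron 0.25, CDS 0.03, 5′UTR 0.02 | the regional binding profile of a 3′UTR-biased regulator |
| site length | log-normal, mean 25 nt (CV 0.25), clipped to [12, 60] | typical cluster lengths |
| motif planting | nonamer 0.08, octamer 0.06, pentamer 0.25, half-site 0.45 per site | AU-rich element frequencies of the right order for this protein class |
| base composition | A/U 0.3 each, C/G 0.2 each | mildly AU-rich 3′UTR-like background |
| read counts | negative binomial, mean 40, size 1.2 | overdispersed cluster depths |
| conversions | per read: T-to-C with p = 0.7; non-T-to-C among the rest with p = 0.05 | high conversion specificity of a good library |
| expression | log2FC = −0.5·(3′UTR sites) − 0.3·(3′UTR kb) + N(0, 0.5²); 5 + 5 replicates with SD 0.2 around a N(8, 1.5²) baseline | both a direct binding effect and a transcript-length effect, with noise that leaves them recoverable but not trivial |
| probe panel | 50 probes, SNR log-uniform over 10⁻¹–10^1.5, log-noise 0.1 | spans depleted (non-binding controls) to strongly enriched sequences; keeps the fitted intercept within the design |

Segments are drawn per gene; sites choose a segment with probability
proportional to segment length (uniform per nucleotide), so longer 3′UTRs
host more sites — reproducing the site-count/UTR-length confound that the
partial-correlation analyses exist to untangle. Planted motifs are written
into the segment sequence, so FASTA output, background sequences and site
sequences stay mutually consistent (overlapping sites may overwrite one
another's plants; each site's recorded sequence reflects its own plant).
All generating parameters are recorded in a JSON manifest next to the
output files. A fixed seed yields bit-identical output; each generator
stage draws from its own child stream, so outputs do not depend on which
other stages run.

### What the synthetic conditions do not show

The generator emulates structure, not biology: sequences are i.i.d.
letters plus planted motifs (no real 3′UTR composition gradients, repeats
or secondary structure), one isoform per gene (no alternative 3′UTR
ends), site placement is independent across sites (no real multimerization
beyond what the proximity tests plant explicitly), and the expression
model is exactly linear with Gaussian noise. Passing tests therefore
demonstrate that the estimators recover what the model puts in — exact
formula agreement, calibration of permutation nulls, sign and magnitude
recovery — not that real libraries satisfy the model. In the same vein,
the synthetic expression model has no secondary-upregulation mechanism —
essentially every perturbed gene goes down — so the 2×2 down-regulation
contingency is computed over all measured genes (where sampling noise
provides the "up" margin) rather than over significantly changed genes
only, and its value reflects the generator's structure, not a calibrated
biological effect size.

## Problem sizes

Validation runs use 2,000-gene studies for recovery checks (100 seeds),
300-gene studies for permutation calibration (100 seeds × 300
permutations), 200 random datasets for the three-route agreement check,
and 1,000 random sequences for the counting oracle — sizes at which every
distributional claim in the test suite has comfortable statistical power
while the whole suite stays desk-scale.
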