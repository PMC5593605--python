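# Methods

## Methylation quantification

The unit of analysis is the CpG dinucleotide, represented by its plus-strand
cytosine position (counts are assumed strand-merged by the aligner, as in
Bismark coverage output; file coordinates are 1-based inclusive, internal
coordinates 0-based half-open). The level of a CpG is `M/(M+U)`; single-CpG
levels require coverage ≥ `min_cov` (default 5×). Tiles are fixed, non-sliding
windows `[100k, 100(k+1))` anchored at position 0 of each chromosome. A tile
pools the raw counts of its covered CpGs, so its level equals the
coverage-weighted mean of the per-CpG levels — an identity the tests assert
against a brute-force oracle. A tile is retained iff ≥1 CpG contributes. The
coverage rule is applied inclusively (≥5×) for both CpGs and tile
contributions and is a single configurable knob.

Stage methylomes average replicate tile levels arithmetically (no coverage
weighting) over the intersection of replicate tile sets; a sample's global
level is the unweighted mean over its tiles. Local CpG density of a CpG is
the count of CpGs within ±50 bp (self included, computed over all CpGs in
the input, not only covered ones); a tile's density is the mean over its
contributing CpGs. Methylation status bins are low < 0.20, high > 0.80,
boundaries inclusive to intermediate.

## Gene models and regional summaries

Genes are loaded from GTF (gffutils; transcripts collapsed to the longest
isoform) or BED12. The TSS is the strand-respecting 5′ end; the promoter is
TSS ± 1 kb (width exactly 2,000 bp). Gene-body summaries exclude the
promoter window: promoter and body multipliers are generated independently
in the simulator, and without the exclusion the two regional signals share
up to 1 kb of sequence and their across-gene means correlate at r ≈ 0.9,
which makes opposite-signed couplings unrecoverable. For TSS meta-profiles,
tiles are assigned to contiguous 100-bp bins by the offset of their midpoint
from the TSS (±5 kb), orientation flipped for minus-strand genes; values are
averaged within a gene first, then across genes. "Distal" lncRNAs for
class comparisons lie ≥1 kb from every coding gene body. Distribution
comparisons between classes use the two-sided two-sample Kolmogorov–Smirnov
test with asymptotic p-values.

## Gamete-specific DMRs

Tiles covered in every sperm and oocyte replicate are tested. The direction
rule acts on replicate-mean levels: sperm-specific iff mean_sperm > 0.75 and
mean_oocyte < 0.25 (and symmetrically). Significance is a per-tile
two-sample pooled-variance t-test with Benjamini–Hochberg correction across
all tested tiles; calls require q < 0.05.

The t-test observation unit is configurable. The default (`method='cpg'`)
treats every (CpG, replicate) level within the tile as an observation,
giving df = n_sperm + n_oocyte − 2 per tile. The alternative
(`method='replicates'`) tests the replicate tile means; with two replicates
per gamete it has df = 2, which floors the attainable p near `1/(2t²)` —
after BH correction over thousands of tiles such tests rarely reach
q < 0.05 no matter how clean the separation, so the replicate-level variant
is retained for designs with more replicates but is not the default. With
either method the level thresholds carry most of the selection.

DMR trajectories (stage-level matrix, missing stages imputed by the stage
mean over DMRs) are clustered by k-means with k = 6, seeded and relabelled
in decreasing cluster-size order. Annotation enrichment of a DMR set in
promoter/exon/intron/CGI labels is the hypergeometric upper tail
P(X ≥ k) on the tested-tile universe, BH-corrected across labels. Parental
bias compares the sperm/oocyte composition of DMR-hosting genes between
classes in a 2×2 Pearson chi-square without continuity correction; a DMR
overlapping genes of both classes counts once per class and is flagged
ambiguous. Promoter and gene-body assignments are tallied separately.

## Developmental-specific DMRs

A tile's stage vector m is converted to pseudo-probabilities
`p_s = (m_s+ε)/Σ(m_t+ε)` (ε = 10⁻³ guards log 0; all-zero vectors score as
maximum entropy and are never called) and scored by `H = −Σ p_s log₂ p_s`.
Because hypomethylation in one stage is also specificity, H is additionally
computed on the reflected vector `m′ = (max m + min m) − m` and the minimum
of the two orientations is reported, with the minimizing orientation as the
direction (hyper/hypo). This makes H exactly symmetric under reflection and
invariant under scaling of m as ε → 0.

Entropy ranges over [0, log₂S]; the reference threshold of 4.22 bits
belongs to a 32-sample design (range 5 bits) and is rescaled as
`4.22·log₂(S)/5` for other sample counts, with a warning. The threshold is
treated as an opaque configuration value. Calling requires coverage in
every stage; tiles missing a stage are excluded and counted.

## Methylation–expression correlation

Expression is an FPKM genes × samples matrix with a sample → stage map.
Stage expression is the mean FPKM over the stage's cells transformed as
log₂(mean + 1); the pseudocount of 1 is a choice, documented here because
the transform's zero-handling is not standardized. Pearson r is computed
across genes within each stage between regional methylation (promoter, or
promoter-excluded gene body) and the transformed expression; stages with a
constant vector or fewer than 3 complete genes are reported missing with a
reason rather than as r = 0.

## Coding–noncoding network

Gene filtering keeps genes with max FPKM > 5 and log-scale variance at or
above the 25th percentile of all genes ("top 75% most variable"; the
stricter top-25% reading is available via `var_keep_fraction=0.25`).
All-pairs Pearson correlations are computed across all expression samples
(cells, not stage means — the sample count enters the test), with two-sided
p from `t = r√(n−2)/√(1−r²)` on df = n−2; |r| = 1 maps to p = 0. Edges
require |r| > 0.8 AND raw p < 0.05 (the p-gate is not FDR-corrected; with
the |r| gate at realistic n it is never binding) AND at least one endpoint
among the seed genes — genes whose promoter overlaps a called D-DMR.
Topology reports degrees, connected components, and hubs (top 5% by
degree). Gene-set enrichment of network members is the upper-tail
hypergeometric test per term with BH across terms and fold enrichment
(k/n)/(K/N); BH is applied per term family when families are analyzed
separately.

## Synthetic-data generator

The generator is the package's study stand-in, not a fixture dump: it
emulates the statistical shape of an RRBS developmental series plus a
single-cell expression matrix, with every planted feature recorded for
recovery scoring.

**Genome and annotation.** Default: two chromosomes totalling 1.2 Mb,
120 coding + 80 lncRNA genes placed in non-overlapping slots (bodies
1.5–3 kb, 2–4 exons, both strands). CpG sites are Bernoulli-placed with
piecewise rates: background 0.005/bp, gene bodies 0.010, coding promoters
0.030–0.050, lncRNA promoters 0.010–0.022, CpG islands (TSS ± 400 bp at
60% of coding and 20% of lncRNA promoters) 0.08 — so coding promoters are
systematically CpG-richer, as in real annotation.

**Methylation model.** Each stage has a baseline level (sperm 0.80,
oocyte 0.55, zygote 0.45, 2-cell 0.25, rising to 0.75 post-implantation)
encoding the demethylation wave; the wave's exact depth is a qualitative
choice, not a reproduction of any measured series. Regions modulate the
baseline: per-gene body propensity U(0.40, 1.00); promoter propensity
U(0.05, 0.60) for coding and U(0.25, 0.90) for lncRNA (lncRNA promoters
hotter, matching the class contrast the analysis must detect); CGIs ×0.3.
Promoters additionally retain a residual floor through the wave
(`prom = mult·(0.35 + 0.65·baseline)`): biologically, promoter methylation
does not track the global erasure proportionally, and statistically this
keeps across-gene promoter variance — hence the detectable expression
coupling — from collapsing at the 2-cell nadir. Planted regions override
absolutely: G-DMRs (3 tiles, 0.95 in their gamete / 0.03 in the other;
sperm-specific regions decay by the 2-cell stage and re-methylate
post-implantation, oocyte-specific regions persist imprint-like near 0.5);
D-DMRs (0.90 in exactly one embryonic stage, 0.05 elsewhere; one in four
planted as hypomethylation dips). Counts are beta-binomial: coverage
Poisson(30) truncated at zero, per-CpG success probability
Beta(mκ, (1−m)κ) with κ = 1/beta_dispersion = 100 — modest overdispersion
appropriate for homogeneous simulated regions, and the margin calculations
for the planted thresholds (0.95 vs 0.75 at tile-level sd ≈ 0.045) assume
it. Planted regions are disjoint, tile-aligned, and guaranteed ≥1 CpG.

**Expression model.** log₂ expression = baseline N(4, 0.5) +
(−2)·promoter methylation + 1.5·(promoter-excluded) body methylation +
module factor + N(0, 0.5) noise per cell; FPKM = 2^log₂expr > 0. Nine
stages × 8 cells. Each of 3 planted modules has 8 genes sharing a
per-cell latent factor of weight 2.0 (pairwise |r| ≈ 0.9); the first two
members of each module are lncRNAs whose promoters receive planted
D-DMRs, so modules are reachable through the network's seed rule.
Remaining D-DMRs go 2/3 to promoters (64% lncRNA) and 1/3 to gene bodies;
G-DMR hosts are 67% lncRNA (sperm) and 49% (oocyte), mirroring the kind of
class bias the analysis reports.

**What the fixture does not emulate.** Read-level artifacts (conversion
errors, M-bias), non-CpG methylation, allele/parent-of-origin resolution,
genomic repeat structure, isoform complexity, expression dropout and
library-size variation of real single-cell data, and genome-scale tile
counts. Passing recovery tests therefore demonstrates that the
implementations are correct and calibrated under the stated statistical
model — not that real-data effect sizes would be recovered at these rates.

## Numerical and design choices

- Degenerate t-tests (zero variance in both groups) map to p = 1 for equal
  means and p = 0 otherwise.
- BH q-values come from statsmodels (`fdr_bh`); q is monotone in p and
  every reported call satisfies its q-gate.
- k-means uses scikit-learn with `n_init=10` and an explicit seed; repeated
  runs with one seed are identical.
- K-S p-values are asymptotic; chi-square tests are Pearson without Yates
  correction (matching the direct formula).
- The D-DMR background false-call rate is measured against constant
  background: planted gamete-specific regions are excluded from the
  background set because their stage trajectories are genuinely specific
  (H ≈ 2.3 bits, below the 9-stage threshold of 2.675).
- Problem sizes (1.2 Mb genome, ~21 k CpGs, ~7.4 k tested tiles, 200
  genes) were chosen so the complete pipeline runs in seconds while every
  statistic operates far from small-sample degeneracy.

## Known limitations

- The entropy score is a plain relative-entropy specificity with a
  reflection correction; it does not reproduce any particular legacy tool's
  internal weighting, and the 4.22-bit reference threshold is adopted as an
  opaque constant rather than re-derived.
- With 2 replicates per stage the replicate-level t-test variant is
  documented as underpowered rather than "fixed"; the per-CpG default
  changes the observation unit, which modestly overstates independence when
  neighboring CpGs co-vary.
- Parental-bias and class-ratio chi-squares treat (DMR, class) assignments
  as independent observations; overlapping gene models violate this mildly
  (flagged ambiguous).
- The pipeline's resume logic is file-presence based; it re-runs all
  downstream stages after any recomputed stage but does not hash inputs.
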