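# Methods

## Problem and model

`chillregnet` reconstructs a phase-structured transcriptional regulatory
network from two parallel two-channel expression experiments on rice
seedlings: a chilling (10 °C) time course sampled at 0.5, 2, 4, 6, 12, 18,
24, 36, 48 and 96 h, and an exogenous-H₂O₂ "oxidative mimic" series
sampled at 1, 3 and 6 h. The underlying biological model is that a
transient oxidative burst during the first 6–12 h of chilling acts as the
primary signal for an early-response regulon: clusters of co-expressed
genes whose promoters are enriched for cis-element classes bound by
specific transcription-factor (TF) families (bZIP on as1/ocs/TGA and ABRE
elements, ERF/DREB/RAV on GCC-box/JAre and DRE/CRT/rav1 elements, R2R3-
and R1-MYB on MYB2-box and GARE/pyrimidine-box elements, WRKY on W boxes,
bHLH on MYC2 boxes).

The inference chain is:

1. **Induction calling.** A gene is induced at a time point when its
   log₂(treated/control) ratio is ≥ 1.8 with a per-cell p < 0.05
   (two-sided one-sample t-test over the biological replicates).
   Upregulated genes must be induced at ≥ 2 *consecutive sampled* time
   points in the chilling series (≥ 1 for H₂O₂) and never significantly
   repressed. Downregulated genes need one significant point at ≤ −1.8
   and no ratio anywhere reaching +1.8 (the up-crossing exclusion looks at
   the ratio alone; both guards are config switches). "Consecutive" means
   adjacent samples, not adjacent clock hours — the sampling grid is
   non-uniform by design.
2. **Waves and phases.** Maximal runs of consecutive induced samples form
   induction waves (duration = last − first hour); more than one wave
   flags an interrupted, multiphasic profile. The earliest induced hour
   assigns the phase: ≤ 6 h → phase-1, (6, 24] h → phase-2, > 24 h →
   phase-3 (upper bounds inclusive).
3. **Co-expression clustering.** Upregulated non-TF genes are clustered
   by k-means (default k = 18) on the raw log₂ profile vectors, Euclidean
   distance (Pearson distance by flag), best of 8 restarts by
   within-cluster SSE, k-means++ seeding, farthest-point re-seeding of
   emptied clusters, and an in-loop assertion that the SSE never
   increases. k = 18 is a design constant, not selected by any model
   criterion; no model-selection step is implemented. Each cluster gets a
   binary consensus (centroid ≥ 1.8), a phase (consensus onset), and the
   fraction of members also called H₂O₂-responsive.
4. **Motif discovery.** Promoter windows are [−1000, +200) around the TSS
   (strand-aware, clipped and flagged at contig ends). Per cluster, up to
   30 motifs of width 8–10 nt are discovered by an iterative
   seed–EM–mask procedure: the most frequent unexplored w-mer seeds a
   PWM (match probability 0.7, pseudocount 0.25 per base per column);
   a ZOOPS-style EM (zero-or-one site per sequence, order-0 background
   from the observed base composition, both strands) refines it; sites
   are called where the PWM log-odds reaches 0.875 of the maximal
   achievable score; called sites are masked before the next slot. The
   site threshold interpretation (fraction of the maximal log-odds) and
   the ZOOPS site model are **reconstructions**: the original study used
   a proprietary EM tool whose internals its text does not specify, and
   this implementation reproduces the tool's role (top-30 thresholded
   motifs of 8–10 nt), not its bit-exact output. Motifs are discarded
   when either their uniform-background total information content (TIC,
   Σⱼ(2 − Hⱼ) bits) or their composition-relative information (minimum
   over the two orientations) falls below 6 bits; the orientation-minimum
   guard exists because on skewed backgrounds the EM can converge to the
   complement of a low-complexity background word, which is formally
   "surprising" but biologically vacuous.
5. **Background subtraction.** Each motif's per-sequence site probability
   is estimated on promoters of non-stress genes; the e-value is a
   Bonferroni-scaled one-sided binomial tail for the foreground
   site-carrying count, and motifs with e > 10⁻³ (the magnitude of the
   published tables) or no excess over background are removed. The
   printed e-values of the original study are not exactly reconstructable
   (their definition is not given); any monotone enrichment statistic
   with the same accept/reject behaviour on the binomial oracle is
   acceptable, and this one is deliberately simple.
6. **Element classes and scores.** Motif consensi are matched to a
   packaged catalog of cis-element classes by ungapped IUPAC-aware
   alignment on both strands (compatibility ≥ 0.75 over the shorter
   string; ties by similarity then catalog order; a motif matching two
   classes — the classic W-box/as1 ambiguity — is assigned to the better
   one and dual-reported). Fine classes pool into broad scoring
   categories (e.g. DRE/CRT + rav1 → "DRE/CRT/rav1-like"; MYB1/MYB2/MCB
   species pool into the R2R3-MYB target category). A cluster's **total
   enrichment score** per category is the sum of occurrence percentages
   of all motif species of that category present in ≥ 50 % of the
   cluster's promoters.
7. **Network edges.** A TF class → cluster edge requires the category to
   be enriched in the cluster and ≥ 1 upregulated TF of the class's
   family with phase ≤ the cluster's phase (temporal
   precedence/coincidence operationalizes "coordinate expression"; a
   correlation-based alternative is out of scope). The top three
   candidates by total score are ranked primary/secondary/tertiary;
   further candidates stay unranked; clusters with no candidate carry a
   no-regulator flag. Mediation labels follow the H₂O₂-responsive member
   fraction: ≥ 50 % oxidative, 25–50 % mixed, < 25 % independent
   (left-inclusive; the 0.50/0.25 bounds are reconstructed from the
   published fraction ranges and are config-exposed).
8. **QTL co-localization.** A gene is QTL-associated when its interval
   shares ≥ 1 bp with a QTL interval on the same chromosome (multi-QTL
   genes yield multiple records). Enrichment of upregulated TFs is a
   one-sided ("greater") Fisher exact test on the 2×2 table subset/rest ×
   associated/not, deliberately permissive at p < 0.25 for candidate
   screening, with the flag additionally requiring subset ratio >
   genome-wide ratio. Traits are pooled by default (per-trait mode
   available); no multiple-testing correction is applied across traits,
   matching the screening character of the analysis.

## Synthetic data

The generator emulates the *statistical structure* of the study, not its
raw arrays. Defaults are the study conditions: 3,600 genes (≈ 5.7 % TFs
from the six families; 72.3 % up-truth ≈ 2,604 genes, 14 % down-truth),
the ten chilling and three H₂O₂ hours, two biological replicates, a
71/22/7 % phase mixture over non-TF genes, 18 clusters split 12/5/1 over
phases with distinct template profiles (onset/offset/amplitude
combinations, amplitudes 2.4–3.4 log₂ units), per-cluster H₂O₂ fractions
mirroring the published spread (two low phase-1 clusters at 39 %/16 %, ten
in the 50–79 % band, slower clusters at 12–49 %), 1,200-nt promoters with
one planted cis-element class per cluster at rate 0.7 on a uniform order-0
background, and a 12-chromosome genome with 14 QTL intervals over seven
trait symbols (COLDTL, SDLVIG, OSADJCAP, SALTSN, CHLCN, LFRL, GERMSP) and
a planted 3× enrichment of up-TFs inside QTL (factor 1 leaves positions
untouched — an exact null used for calibration).

Replicate noise is Gaussian on the log-ratio scale (σ = 0.2 by default;
the noise law of real two-channel arrays is not known here, so the
distribution is a config choice), and per-cell p-values come from the
same two-replicate t-test the calling rules assume, so significance is
honest with df = 1. With σ = 0 every replicate equals the truth and
p-values degenerate to 0/1, giving the noise-free identity used in tests.
The H₂O₂ "recovery" sample of the original design is not simulated: it
contributes nothing to the single-time-point induction rule.

What the generator does **not** emulate: dye bias, spatial artifacts,
correlated noise between genes, promoter composition heterogeneity
(GC-rich proximal regions, TATA structure), overlapping/nested regulons,
or repressor logic for the downregulated transcriptome. Passing recovery
tests therefore demonstrates correctness of the inference chain under the
declared generative model, not performance on real arrays.

## Numerical choices

* EM convergence: relative objective change < 10⁻⁵ or 50 iterations; the
  tracked objective includes the Dirichlet pseudocount term, which is the
  quantity the pseudocounted M-step actually maximizes, and is asserted
  non-decreasing (tolerance 10⁻⁶ relative).
* Scanning background composition uses add-one smoothing so log-odds stay
  finite on degenerate input.
* k-means ties and empty clusters: farthest-point re-seeding; cluster
  labels are assigned deterministically by consensus onset, then size.
* IUPAC consensus: per column, bases in descending probability until 80 %
  mass, stopping at bases below 20 %.
* Seeds: a single seed fans out through `numpy` seed sequences, so every
  stage (and every per-cluster discovery) is independently reproducible;
  fixed seed ⇒ byte-identical bundles and reports (timestamps excluded
  from manifests).
* Problem sizes in the recovery analyses (discovery on a 40-promoter
  subsample per cluster with 3 motif slots of width 8, occurrence then
  scored on all members; 20 seeds for network recovery; 500 seeds at 800
  genes for null calibration) were chosen as the smallest sizes at which
  the planted effects are comfortably detectable; the subsample-then-
  score-all pattern is standard practice for EM motif discovery on large
  promoter sets.

## Known limitations

* The published motif tables list only a subset of the motif species
  behind the published per-category score graphs; recomputing category
  scores from the printed rows therefore reproduces most but not all of
  the score ranges quoted in the running text (the discrepant cells are
  asserted as printed and left failing, documented in the test ids).
* Cluster labels (C01…C18) are arbitrary; the original C78…C100A labels
  come from an unstated prior numbering and are not reproduced.
* Exactly one regulator class is planted per synthetic cluster;
  combinatorial (multi-class) promoter architectures are representable in
  the config but not part of the default conditions.
* The downregulated network and genome-scale promoter extraction from a
  real assembly are out of scope.
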