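# Methods

## Scope and model

`cernet` implements the computational core of a small paired
case–control transcriptomics study that integrates mRNA, lncRNA,
circRNA and miRNA expression into competing-endogenous-RNA (ceRNA)
networks. The ceRNA hypothesis: a lncRNA or circRNA ("sponge") that
shares miRNA binding sites with an mRNA can sequester that miRNA and
derepress the mRNA, so sponge and mRNA should co-vary positively while
the miRNA opposes both. The pipeline operationalizes this as
DE calling → thresholded coexpression → shared-miRNA triplet assembly,
with target relations supplied as input tables (no binding-site
prediction is performed).

## Differential expression

* **Test.** Two-sided paired t-test on log2(x + c), pairing patient
  sample i with control sample i via the metadata pair id; df = n − 1
  pairs. Working on the log scale makes the simulator's multiplicative
  (log-normal) noise additive, so the test is exactly calibrated under
  the null; an unpaired Welch option (`method="welch"`) covers designs
  without true pairing.
* **Effect size.** log2FC = log2((mean_A + c)/(mean_H + c)) on the
  normalized scale as supplied, pseudocount c = 0.01 (configurable)
  guarding zero means. Inputs are assumed pre-normalized; no
  re-normalization is attempted.
* **Call.** `passes ⇔ |log2FC| ≥ 1 ∧ p < 0.05`. The fold-change bounds
  FC ≥ 2 or FC ≤ 0.5 are exactly |log2FC| ≥ 1. BH q-values are always
  reported; `use_fdr_for_call=True` swaps q for p in the gate (the
  stricter variant). Features with zero-variance paired differences
  have no defined t statistic; they are flagged `degenerate`, carry NaN
  statistics, never pass, and are excluded from the BH adjustment
  (NaNs pass through `bh_adjust` positionally).

## Coexpression

Pearson r between every passing DE ncRNA and DE mRNA across all
samples of both groups, computed on log2(x + c). The test p-value uses
the exact Student-t CDF via the t-transform with df = n − 2; at n = 6
this is what reproduces published seven-significant-figure p-values —
a normal approximation is off by orders of magnitude in the far tail.
The selection rule is |r| ≥ 0.8 and p < 0.05 with the sign retained:
downstream ceRNA assembly uses only positively correlated sponge–mRNA
pairs, but negative pairs are reported. Output is sorted by p with
lexicographic (ncRNA, mRNA) tie-breaks so results are byte-stable.

Recomputing a p-value from a correlation printed to 9 decimals is
ill-conditioned near |r| = 1 (d ln p/dr ≈ 4r/(1 − r²) for df = 4, so
±5e-10 on r moves p by up to ~2.5e-5 relative). Reproduction tests
therefore compare at the precision the printed inputs support (≥ 5
significant figures, plus interval containment under the propagated
rounding) rather than at the full printed precision of p.

## Expression filters and triplet assembly

A feature survives filtering when (group-A mean > 0.5 OR group-H mean
> 0.5) AND it is expressed in ≥ 2/3 of all samples. "Expressed" means
strictly > 0 by default (`expressed_threshold` configurable) — no
detection floor is imposed because normalized units vary between
platforms. The filter is monotone in `min_group_mean` by construction.

A triplet (sponge s, miRNA m, mRNA g) is emitted iff s and g pass DE
and filters, (s, g) is a surviving coexpression pair with r > 0, and
the target map contains both (m, s) and (m, g). miRNA DE status is
*not* required: miRNAs absent from the DE results are annotated
`unknown`, matching the practice of displaying non-DE hub miRNAs in
published networks. `strict_mirna_de=True` additionally requires the
miRNA to be DE in the direction opposite to its sponge. A numerical
miRNA–target anti-correlation check is deliberately not part of the
default rule. Ordering is lexicographic (miRNA, sponge, mRNA).

The network is the union graph of triplet edges (miRNA–sponge,
miRNA–mRNA, sponge–mRNA coexpression) with node attributes kind and
direction; exports: SIF, GraphML, and node/edge TSVs whose re-import
reproduces the graph exactly. An optional whitelist filter restricts
triplets to a set of key mRNAs, mirroring the common practice of
pruning dense networks around genes of interest.

## Over-representation analysis

Hypergeometric upper tail P(X ≥ k) with universe N = expressed genes ∩
annotated genes (standard ORA practice when the assay does not cover
the genome), term size K within the universe, DE set size n, overlap k.
Terms not intersecting the universe are skipped; BH q over tested
terms; ranking by raw p then term id for reproducibility. GMT files
carry the category (BP/CC/MF/pathway) in the description field as
`category|name`; round-trip identity holds for files the package
writes.

## qPCR quantification

Relative expression per sample is 2^−ΔCt, ΔCt = mean Ct(target) −
mean Ct(reference), technical replicates averaged on the Ct scale
before the transform (averaging after the transform would bias the
geometric structure of Ct data). Groups are compared on the 2^−ΔCt
values with a two-tailed equal-variance Student's t-test (Welch
optional). Identical constant groups return t = 0, p = 1; constant
groups with unequal means raise a degenerate-test error rather than
fabricating an infinite statistic.

## Synthetic-data generator

The generator emulates the study design the pipeline targets:

* **Design.** Two groups of `n_per_group = 3` samples, sample i of A
  paired with sample i of H. Feature counts per class default to
  mRNA 400, lncRNA 300, circRNA 150, miRNA 100 — a desk-scale set
  preserving the class ordering of real transcriptomes while keeping
  the full pipeline under a second per run.
* **Expression.** log2 values: per-feature baseline ~
  N(3, 1.5²) (so typical normalized expression ~8 with a wide dynamic
  range), i.i.d. per-sample noise sd `noise_log2_sd = 0.25`, planted DE
  features (fraction 0.1, alternating up/down) shifted by
  ±`effect_log2fc = 3` in group A. Output is 2^log2, hence strictly
  positive.
* **Triplets.** `n_triplets = 5` triplets draw their sponge (alternating
  lncRNA/circRNA) and mRNA from the planted-up features and their miRNA
  from the planted-down miRNAs. Coupling uses a shared per-sample latent
  factor z via a variance decomposition of the stated noise: member
  noise = ±σ√r·z + σ√(1−r)·ε with r = `coupling_r = 0.9`. The marginal
  noise sd stays exactly σ (the stated study condition) while the noise
  correlation between members is ±r; the group-A shift adds further
  between-group covariance, so realized sponge–mRNA sample correlations
  are strongly positive and miRNA–partner correlations negative.
* **Target map.** All planted miRNA→sponge and miRNA→mRNA edges, plus
  decoy edges between null miRNAs and null targets drawn i.i.d.
  Bernoulli(`decoy_edge_fraction = 0.05`).
* **Annotation.** `n_terms = 20` random sets of 10–40 mRNAs plus one
  planted term with ≥ 80% DE members (id `TERM_ENRICHED`).
* **qPCR.** Ct is generated from the planted truth directly: base Ct ~
  U(22, 28) per gene, group-A shift −log2FC, reference gene ACTB at
  Ct 18, replicate noise sd `noise_log2_sd` cycles. With zero noise the
  group difference in ΔCt equals −log2FC exactly.

Determinism: every generator draws from `numpy.random.default_rng`
seeded with `[seed, stream]` (streams 0–3 for expression, targets,
annotation, qPCR), so each artifact is reproducible independently and
the whole run is byte-identical under a fixed seed.

**What the generator does not emulate:** count noise (sequencing depth,
negative-binomial dispersion), batch effects, correlated null features,
library-size normalization artifacts, circRNA back-splice ambiguity,
or realistic miRNA target-site structure. Passing recovery tests on
this generator demonstrates the pipeline's logic and calibration under
its stated noise model, not performance on real sequencing data.

## Pipeline and numerical choices

* Stages consume the *persisted* TSV artifacts (written with `%.10g`
  floats), so a full run and a stage-at-a-time run produce identical
  reports and files.
* All orderings (DE tables, pairs, triplets, network exports) have
  deterministic lexicographic tie-breaks.
* Problem sizes in tests and examples are the generator defaults above;
  the calibration and recovery studies use 20 seeds × the default
  configuration and a 2000-feature null run, which complete in seconds.
* Degenerate inputs are handled by explicit errors (`DesignError`,
  `DegenerateTestError`, `UndefinedCorrelationError`,
  `MissingReferenceError`, `ParseError` with line numbers) rather than
  NaN propagation, except where exclusion is the documented behavior
  (degenerate features within a DE table).

## Known limitations

* The paired t-test at n = 3 pairs (df = 2) has little power for
  moderate effects; the default planted effect (|log2FC| = 3) is
  detectable, but real effects near the |log2FC| = 1 threshold would
  often be missed at this sample size.
* ceRNA triplet inference is correlational; no causal claim, no
  conditional/partial correlation, and no binding-energy evidence.
* ORA treats genes as exchangeable; gene-length or expression-level
  bias corrections are out of scope.
* The miRNA direction annotation depends entirely on the supplied DE
  table; miRNAs measured on a different platform must be harmonized
  upstream.
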