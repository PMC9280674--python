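# Methods

This note documents the models, conventions and numerical choices behind
`sslmap`, in the order the pipeline runs.

## Coordinates and segment inference

All positions are 1-based physical base pairs; interval lengths are
coordinate differences (`end − start`), matching the Mb arithmetic usual in
substitution-line work. A line's marker calls (recipient-homozygous,
donor-homozygous, heterozygous, missing) are scanned per chromosome:
maximal runs of consecutive equal non-recipient calls become segments.
Missing calls *bridge* runs rather than break them — SSSL libraries are
curated so that isolated genotyping failures inside a donor block are far
more likely than double recombination within one marker interval — and
each bridge is logged.

Two bounds are kept per segment:

* **core** — the span of the run's outermost non-recipient markers; donor
  genotype is proven here;
* **estimated** — each core bound extended to the midpoint between that
  marker and the nearest flanking recipient-typed marker (the standard
  graphical-genotype convention for the expected recombination
  breakpoint). With no flanking recipient marker on a side, the estimated
  bound stays at the core bound.

`boundary_rule="core-only"` disables the extension. Heterozygous runs are
retained as separate segments with their own zygosity; they are excluded
from localization, which the mapping design performs with homozygous
material only.

## Line classification

Lines are compared with the recipient by Dunnett's many-to-one procedure:
pooled error variance across all groups, adjusted p-values from the
equicoordinate k-variate t distribution (`scipy.stats.dunnett`). The
quasi-Monte-Carlo quadrature inside scipy's multivariate-t CDF is run with
a fixed generator so reports are reproducible (p-value error ~1e-4), and
the mathematically exact constraint p_adjusted ≥ p_raw is enforced against
that quadrature noise. Raw p-values use the same pooled-variance t
statistic, so the pair is coherent.

Percentage traits are arcsine-square-root transformed (θ = arcsin√(p/100))
before every group-separation test; group means are reported untransformed.
The transform stabilizes binomial-like sampling variance, which for
chalkiness percentages shrinks strongly toward 0 and 100.

The multiple-range test behind the compact letter displays is the
Student–Newman–Keuls stepwise studentized-range procedure: ordered means,
range of p means declared significant when it exceeds
q(α; p, df)·√(MSE/n_h) (n_h the harmonic mean group size), non-significant
ranges never subdivided. With two groups it reduces exactly to the pooled
t test. Ties order stably by group label, making letter assignment
deterministic.

## Localization

The candidate region for one trait on one chromosome is

    ⋂ (estimated segments of divergent lines) − ⋃ (core segments of ns lines).

Divergent lines contribute estimated bounds because the QTL may sit
anywhere donor chromatin could extend; non-significant lines exclude only
their core bounds because absence of effect is asserted only where donor
genotype is proven (`exclusion_rule="estimated"` is available for
sensitivity analysis). An empty intersection raises an
"inconsistent divergent set" error (two or more QTLs, or misclassification);
a candidate fully erased by exclusions raises a "contradictory exclusion"
error; multiple surviving disjoint intervals are reported as ambiguous, not
resolved. Flanking markers are the nearest mapped markers at or outside
each candidate bound, with explicit chromosome-end sentinels.

## Effects

The **additive effect** reported for an SSSL/NIL is the full line-minus-
recipient mean difference on the percent scale — the operational definition
in substitution-line studies, where the two lines differ by one homozygous
segment. This is twice the classical a of quantitative genetics;
`dominance_from_f2` reports the classical a = (mean(P2/P2) − mean(P1/P1))/2
alongside, and uses it for degree = d/|a|. The standard error is the pooled
two-sample formula; the p-value comes from the pooled t test on the
transformed scale.

**Dominance** at a QTL is classified from F2 genotype-class values. The
heterozygote-vs-midparent contrast is evaluated on the percent scale,
where d is defined — the arcsine transform is nonlinear, so the
transformed-scale midparent is a different null and would mislabel a
heterozygote sitting exactly at the percent midpoint. Group separation
(which homozygote the heterozygote differs from) uses the transformed-scale
letter display. Decision order: no significant d → additive; separated
from both homozygotes → incomplete dominance if strictly between them,
overdominance if outside; separated from exactly one → complete dominance;
otherwise degree thresholds (|degree| < 0.2 additive, ≤ 0.8 incomplete,
≤ 1.2 complete, else over) break the tie. The classification is invariant
under relabelling the homozygote classes (a flips sign).

**Season (G×E) contrast.** Δ = a_FCS − a_SCS, with p from the t test of
the 2×2 interaction contrast (line − control) in FCS minus (line − control)
in SCS on the percent scale, Welch-type cell variances and Satterthwaite
degrees of freedom; plants across years are the replicates. The contrast
is taken on the percent scale deliberately: the additive effect itself is
defined there, and a QTL with equal percent-scale effects in both seasons
(the natural "insensitive" null) has a nonzero arcsine-scale interaction
whenever the seasonal baselines differ — a transformed-scale test would
brand every such QTL season-sensitive. Cells are heteroscedastic on the
percent scale (variance shrinks with the mean), hence Welch rather than a
pooled MSE. Classification: non-significant → insensitive; otherwise
enhanced or suppressed by high temperature according to whether |a| is
larger or smaller in the hot season.

## Segregation tests

Pearson chi-square against arbitrary positive ratio weights, df = classes
− 1, no continuity correction (a two-class device; F2 class counts here are
≥ ~25). Both the exact p-value and the critical-value decision at α ∈
{0.05, 0.01} are reported.

## Synthetic studies

The generator emulates the reference design: recipient baseline PGC 25.8%
in the hot first cropping season and 16.6% in the cooler second; two SSSLs
whose QTLs have per-season effects (−18.6, −12.3) and (−21.6, −13.1)
percentage points; eight NILs tiling the chromosome-5 segment (five
carrying the QTL, three not); 10 plants per line per season over three
years. Marker genotypes follow deterministically from prescribed segment
spans on a 1 Mb grid — no meiosis is simulated.

Per plant, the transformed trait is θ = arcsin√(baseline/100) plus, for
each carried QTL, the transformed-scale shift that moves the seasonal
baseline by the target percent-scale effect, plus N(0, σ_θ) noise with
σ_θ = 0.05 rad. Injecting effects on the θ scale keeps noise homoscedastic
there, matching the analysis transform; σ_θ = 0.05 is a calibration choice
(plant-level chalkiness variance is rarely published; 0.05 rad corresponds
to ≈ 4.4 points of PGC at a 25.8% mean and ≈ 2 points at 5%). PCA is drawn
as N(40, 5) clipped to [1, 100] — the conditional chalky-area percentage
among chalky grains — and PCG is derived so PGC = PCG × PCA / 100 holds
exactly; when a plant's PGC exceeds its drawn PCA, PCG is capped at 100 and
PCA raised to PGC (logged). The F2 simulator draws genotype classes
multinomially at (¼, ½, ¼) and class phenotypes around (m − a, m + d,
m + a) on the percent scale.

What the generator does **not** emulate: recombination within segments,
linked or epistatic QTLs, year effects beyond independent replication,
plot/field structure, and any trait other than the chalkiness triplet.
Passing recovery tests therefore shows the inference is correct under the
stated generative model, not that real studies are free of those
complications.

## Simulation sizes and tolerances

* Parameter recovery and G×E operating characteristics: 200 seeded
  replicates of the reference design; the true position must fall inside
  the mapped interval in ≥ 95% of studies, and the mean absolute
  per-season effect error stays below one percentage point.
* Type-I error of the t and chi-square tests: 10 000 null replicates at
  α = 0.05, checked to ± 0.01.
* Dunnett family-wise error at k = 5: 2 000 simulated null families
  (each family costs a multivariate-t CDF evaluation, ~30 ms; 2 000 keeps
  the Monte-Carlo standard error at 0.005 against the α + 0.01 bound).
* Determinism: every simulation seed is explicit; the fixed internal seed
  for scipy's Dunnett quadrature is the only other randomness source.

## Known limitations

* One trait, one chromosome per localization call; linked-QTL
  decomposition is out of scope and surfaces as the inconsistent-divergent-
  set error.
* The Dunnett procedure assumes a common error variance; strongly
  heteroscedastic groups (very low-chalk lines vs the recipient on the raw
  scale) are mitigated, not eliminated, by the arcsine transform.
* Estimated segment bounds depend on marker density; with sparse markers
  the midpoint rule can substantially overstate donor length, which is why
  exclusion uses core bounds by default.
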