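# Methods

This note records the statistical model behind `sgascore`, the choices made
where the procedure admits more than one reading, and what the synthetic
validation does and does not establish.

## The screen and its observable

An arrayed double-mutant screen pins each library deletion as *r* replicate
spots (4 or 12 in practice) at fixed grid positions on paired plates: a
control plate without double-mutant selection and a test plate with it, at
matching positions. The observable is colony area in arbitrary units
("size"); a size of 0 means the spot produced no colony. The analysis asks,
per gene, whether double mutants grow systematically worse (synthetic sick)
or better (synthetic rescue, the pattern sought at a temperature where the
query allele alone barely grows) than the matched single mutants.

## Normalization

Two multiplicative artifacts dominate arrayed colony data: an **edge
effect** (outermost colonies grow larger through nutrient access) and
**plate effects** (whole-plate differences in growth conditions). The
correction is per plate *p*:

1. *edge step* — edge spots (outermost two rows and two columns; a grid
   therefore needs at least 5 rows and columns) are multiplied by
   *f_p = m_p / e_p*, where *m_p* and *e_p* are the middle and edge means;
2. *plate step* — all spots are multiplied by *g_p = M / m_p*, with
   *M* = median over plates of *m_p*.

After both steps every normalizable plate's middle mean equals *M* exactly;
the transform is idempotent and scale-equivariant, and middle spots are only
ever touched by the plate step. The edge factor is one number per plate
(`per_ring=True` instead fits one factor per ring for the two outer rings —
a robustness option, off by default, since the single-factor reading is the
simplest one consistent with correcting "the outermost two rows and two
columns to the plate middle mean").

Zeros are handled by origin:

- a **dead spot of a library gene** is a real observation and stays in
  *m_p* / *e_p* (a dead middle colony legitimately lowers the plate's growth
  estimate);
- a **never-spotted position** (sentinel gene `EMPTY`, present only when a
  plate is partially filled) is structural and is excluded from the plate
  statistics, while still receiving the plate's factors;
- a plate whose middle spots are all zero cannot be normalized: it is
  excluded from *M* and its spots are marked unnormalizable (NaN) rather
  than silently scaled.

`middle_stat="median"` replaces the mean with the median in *m_p*/*e_p* as a
robustness option; the procedure is defined on the mean and the mean is the
default.

## Per-gene statistics

Control and test spots are paired by matched grid position — the generator
guarantees identical layouts, and real tables must carry a replicate index
with the same meaning. A **valid pair has both spots alive**: a size-0 spot
is a failed or dead pinning, not a measurement of growth, and keeping dead
test spots as zeros would turn a single dropout into an outlier difference
that dominates the gene's variance estimate. The per-gene counts
`n_dead_control` / `n_dead_test` are reported so that fully lethal double
mutants — which lose their pairs by construction — remain visible for
follow-up rather than disappearing; with the planted effect sizes used here
(0.5×) this situation does not arise. Genes with fewer than 2 valid pairs
are reported with `insufficient_data` status, never dropped.

Per gene and experiment, with differences *d_i = control_i − test_i* on
normalized sizes:

- *t = d̄ / (s_d/√n)*, *p* from Student's *t* with *n−1* df (two-sided by
  default; the paired test's sidedness is not dictated by the screen design,
  and the sick/rescue direction is enforced at call time through the sign of
  *d̄*);
- all-identical differences give a degenerate flag with *p* = 1 if *d̄* = 0
  and *p* = 0 otherwise (no variance estimate exists).

Across experiments, p-values are combined by Fisher's method,
*X² = −2Σ ln p_i ~ χ²_{2k}* (a single experiment passes through unchanged;
*p* = 0 is clamped to the smallest positive float with a warning). Genes
whose per-experiment *t* statistics disagree in sign are never called: two
opposite-direction experiments can otherwise combine into a spurious hit.
Reported `diff`, `mean_control` and `mean_test` are weighted across
experiments by pair count; `t_stat`/`p_raw` mirror the first experiment
(exact per-experiment values live in the per-experiment table).

## Linkage exclusion

Genes physically near the query locus or a selection-marker locus cannot
recombine away from the query during the cross, so their double-mutant
recovery is biased regardless of interaction. Every gene on a window's
chromosome whose interval lies within 500 kb (inclusive) of the window
center is flagged; distance is measured from the center to the nearest base
of the gene interval, so long genes cannot escape on a technicality.
Flagged genes keep their statistics for audit but are removed from the
multiple-testing universe and can never be called. Genes without
coordinates are likewise excluded from the universe, with a warning.

## Calling

Benjamini–Hochberg adjustment (the conventional choice where the adjustment
method is not otherwise fixed; Bonferroni by flag) is applied to combined
p-values over the post-linkage universe. Calls use the dual threshold:
**sick** requires adjusted *p* < 0.05 and *d̄* > 25 normalized area units
(strictly greater); **rescue** is symmetric with *d̄* < −25. The size
threshold is in the same units as the normalization target (baseline 100),
i.e. a 25% growth change; both thresholds are configurable. Rescue uses the
same machinery as sick — the screen supplies no separate quantitative
rescue criterion, so symmetry is the stated choice.

## Enrichment and phenotype statistics

Hit lists are tested for gene-set overrepresentation with the
hypergeometric upper tail *P(X ≥ k)*, *X ~ Hypergeom(N, K, n)*, BH-adjusted
across sets; sets with fewer than 3 members in the universe are skipped.
The universe is the set of scored, unlinked genes — what could have been a
hit — not the genome.

Follow-up 2×2 counts (e.g. anaphases with lagging chromosomes out of
anaphases scored, per strain) are compared with Fisher's exact test
(two-sided by the minimum-likelihood convention; one-sided variants
available) and summarized as percentages with exact Clopper–Pearson 95%
intervals.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
screen images:

    size = baseline · effect(gene | test plate) · plate · edge · noise

with lognormal noise of mean 1 and coefficient of variation `noise_cv`
(sizes are positive and effects compound, so multiplicative lognormal noise
is the natural model), a lognormal per-plate multiplier (sd
`plate_effect_sd` on the log scale), `edge_boost` on the outermost two
rows/columns, planted effects `sick_effect` (< 1) / `rescue_effect` (> 1)
on test plates, and a `missing_rate` of spots zeroed at random. Defaults:
baseline 100, noise CV 0.1 (typical colony-area repeatability), plate sd
0.1 (plates rarely differ by more than ±20%), edge boost 1.3, 5% sick at
0.5×, 2% rescue at 1.5×, 1% missing. Replicate blocks are laid out
contiguously row-major; a partially filled final plate is padded with
`EMPTY` positions of size 0 so grids stay complete. Genes are placed
uniformly on a three-chromosome genome (5.58/4.54/2.45 Mb, fission-yeast
scale) with one gene forced into each query window; planted interactors are
drawn only from unlinked genes, because genes inside a linkage window are
structurally undetectable by the screen and planting an effect there would
be unobservable by construction. A catalog of 25 gene sets of 30 accompanies
each screen; one set receives half of the planted sick genes, the rest are
random decoys.

What passing the synthetic suite shows: the normalization exactly restores
its contract under the artifacts it models; the test statistics match
independent closed forms; type-I error and FDR are controlled, and planted
effects of realistic size are recovered, under multiplicative lognormal
noise with position-paired spots. What it does not show: robustness to
spatially smooth gradients within the plate middle, row/column streaks,
neighbor competition, non-multiplicative artifacts, or mispaired layouts —
real screens need the t-statistic normality QC (`qc_tstat_normality`) and
the normalization report as sanity checks.

## Numerical and scale choices

Validation simulations use 500-gene screens (12 replicate spots, one or two
experiments) and 10–20 generator seeds — large enough that Monte-Carlo
error on a 5% rate is a fraction of a percentage point, small enough to
keep the suite fast. Normalization contracts are asserted to 1e-9 relative
tolerance, closed-form oracle agreement to 1e-12. TSV output uses a fixed
`%.10g` float format and stable sort orders, so a fixed seed reproduces
every table byte-identically. All randomness flows from
`numpy.random.SeedSequence` spawns of a single integer seed.

## Known limitations

- The normalization models exactly two artifacts (edge, plate); no spatial
  trend surfaces or competition corrections.
- Fully lethal interactions (all test spots dead) yield no valid pairs and
  surface only through the dead-spot counts, not as calls.
- Fisher combination assumes experiments are independent; replicates within
  an experiment that share a plate violate independence only through the
  plate factor, which the normalization removes in expectation.
- The rescue criterion is the mirror image of the sick criterion by choice;
  screens with a dedicated rescue readout (e.g. growth at the restrictive
  temperature only) should score those tables separately.
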