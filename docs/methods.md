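# Methods

This note records the model, the defaults and the numerical choices behind
`mirsea`, and what the synthetic studies used in testing do and do not
establish about real data.

## Model and assumptions

The method treats a pathway as *regulated* in a two-class design when the
miRNAs tied to it concentrate at one extreme of the differential-expression
ranking.  Three ingredients make that operational:

**Hypergeometric pathway weighting.**  The association between miRNA *i*
and pathway *j* is scored by how surprising their target/gene overlap is
under random sampling from a gene universe of size *m*:
`W_ij = 1 − P(X ≥ r)` with `X ~ Hypergeom(m, t_j, n_i)`.  The tail includes
the observed overlap (`x = r … min(n, t)`), evaluated through the
survival function `sf(r−1)` so extreme tails do not underflow.  Overlaps
are counted after restricting both target sets and pathway gene sets to
the universe, keeping `m, t, n, r` mutually consistent.  The universe
itself is not a law of nature: the default is the union of all target and
pathway genes, with `targets_only` and `fixed_count(m)` modes for matching
an externally chosen genome size.  Weights therefore depend on the
interaction tables supplied, and two databases of different depth yield
different weights for the same miRNA.

**Weight-boosted ranking.**  `miRScore_i = (1 + W_i) · DE_i` doubles, at
most, the differential-expression statistic of a pathway-linked miRNA and
never changes its sign; miRNAs measured but absent from the interaction
tables keep `W = 0` and simply dilute the ranking, as non-member genes do
in GSEA.  `DE` is the signal-to-noise ratio with sample (ddof = 1) class
standard deviations.  A GSEA-style variance floor
(`sd ← max(sd, 0.2·|mean|, 1e-8)`) is available but **off** by default:
the plain ratio is the documented metric, and the floor is only needed for
near-constant rows, which error out explicitly otherwise.  The ranking
metric is deliberately pluggable in principle; the signal-to-noise ratio
is the only built-in.

**Weighted KS running sum.**  Over the ranked list, members contribute
`|miRScore|^q / N_R` and non-members `−1/N_miss`; the signed maximum
deviation from zero is `miRES`, and `q = 1` is the default (with `q = 0`
the statistic reduces to the classic unweighted KS form — a property the
tests exploit).  Core miRNAs are the members at/before the peak (at/after,
for negative scores).  A `miRES` of exactly 0 — possible only for
degenerate constant data — is given an empty core and p = 1.

## Significance

Permutation is by phenotype relabelling, preserving class sizes and the
miRNA–miRNA correlation structure; each relabelling recomputes the whole
pipeline (one shared DE vector per relabelling, reused across pathways).
Relabellings are drawn with replacement; a warning notes when fewer
distinct labelings exist than were requested (e.g. 2v2 designs).

**Empirical p-value.**  The observed score is compared against the
permuted scores on its own side, and by default is divided by the number
of *same-sign* permuted scores.  A variant dividing by the full
permutation count is available (`p_denominator="all"`), but it is not the
default because the score chooses its sign first: under an exchangeable
null that reading rejects at twice the nominal rate (P(p ≤ α) = 2α), which
the calibration test demonstrates empirically, and the Benjamini–Hochberg
adjustment downstream assumes calibrated inputs.  Counting is strict
(`perm > obs`), so p = 0 can occur; add-one smoothing `(M+1)/(N+1)` is
optional and off by default.

**FDR and normalisation.**  BH is applied separately within the
positive-score (down-regulated) and negative-score (up-regulated) groups,
matching how two-sided enrichment lists are usually reported; a pooled
mode is a flag.  `NmiRES` divides the observed score by the mean same-sign
permuted score of the *same pathway* (no cross-pathway pooling), so a
null-like score lands near ±1.  Each pathway's p-value and normalisation
use its own permutation distribution.

## Numerical choices

- **Tie-breaks.**  Ranking ties resolve by miRNA id ascending; running-sum
  peak ties resolve to the earliest position.  Both are conventions for
  determinism; with continuous expression data neither is ever exercised.
- **Label-swap antisymmetry by construction.**  Swapping the two classes
  must negate every miRES/NmiRES exactly, not just approximately.  Two
  implementation details guarantee this: (1) permutation masks are the
  dataset's own label vector pushed through index permutations that depend
  only on the sample count and seed, so the swapped contrast sees exactly
  complementary relabelings; (2) the KS walk canonicalises its orientation
  (by the sign of the id-order score sum) and maps the result back, so a
  profile and its mirror run through bit-identical float operations.  The
  guarantee holds whenever the extremum magnitude is uniquely attained,
  which is always the case for tie-free scores.
- **Reductions.**  `N_R` is accumulated over the zero-padded member vector
  in ranked order in both the scalar and the vectorised scorer, so the two
  agree bit-for-bit.
- **Degenerate inputs.**  Constant expression rows (zero variance in both
  classes without the floor), pathways covering the whole measured panel
  (`N_miss = 0`), all-zero member scores (`N_R = 0`) and constant matrices
  are hard errors, not silent NaNs.  Converted pathways with no measured
  member are dropped before scoring, and the reported pathway size is the
  post-intersection member count.

## Synthetic studies

The generator (`mirsea.simulate`) emulates a two-class miRNA profiling
experiment: Gaussian intensities (baseline 8, unit noise SD — an
array-intensity scale), a panel of 300 miRNAs over 10 samples per class,
40 pathways of 30–60 genes, and 15–30 validated targets per miRNA over a
5,600-gene universe.  The universe size is chosen so that a converted
pathway captures roughly 16% of the measured panel, the density observed
in real interaction databases (~47 targets/miRNA over ~16k genes, with
converted pathways of ~10–180 of ~880 measured miRNAs).  Planted signal is
*joint*, because the method requires both ingredients: planted miRNAs are
shifted by `delta` noise-SDs in the reference class **and** carry 14 of
their targets inside the planted pathway (giving them weights near 1
there).  The planted pathway's genes are exclusive to it; background
pathways draw from the rest of the genome and may overlap each other.
Without that exclusivity the ground truth is ill-posed — a background
pathway sharing planted-module genes inherits most planted miRNAs as
members and is partially a true positive itself.

Two presets define the tested regimes: `null` (delta = 0, fully
exchangeable — what the permutation test assumes) and `planted`
(delta = 1.5, 15 planted miRNAs).  Test problem sizes — 10 null replicates
at 200 permutations for calibration, 20 planted replicates at 1000
permutations for recovery — keep the full suite in the low minutes while
giving the binomial checks adequate resolution.

What passing these tests shows: the statistic is computed exactly, the
null is calibrated when exchangeability holds, and a strong joint signal
is recovered.  What they do not show: behaviour under miRNA–miRNA
co-expression (the generator draws rows independently; real profiles are
correlated, which the phenotype permutation handles but the generator does
not stress), array-specific noise, batch structure, annotation errors in
the interaction tables, or power at realistic effect sizes smaller than
the planted delta.

## Known limitations

- No moderated statistics, paired designs or >2-class contrasts.
- No predicted (non-validated) target sources and no miRNA-id
  harmonisation across miRBase versions; identifier hygiene is the
  caller's responsibility.
- Per-pathway nulls only; a GSEA-style pooled-null FDR is a possible
  extension.
- Empirical p-value resolution is 1/N_same-sign; pathways far in the tail
  all report p = 0 and tie at the smallest FDR, where ordering falls back
  to |NmiRES|.
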