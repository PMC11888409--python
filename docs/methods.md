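# Methods

## The selection model behind the synthetic data

The generator emulates a pooled selection experiment on a tiled ORF. A
library of clones carries a Poisson-distributed number of codon
substitutions per clone (`clone_lambda`, default 0.64 for the
activity-assay preset and 0.83 for the abundance preset), assigned
uniformly over the NNK-reachable amino-acid outcomes of each codon
(21 outcomes per position: 19 missense, 1 synonymous, 1 nonsense, since
every amino acid and the TAG stop are NNK-encodable). The ORF is split
into 5 equal tiles; a variant is observed only through reads of its own
tile.

Each variant has a latent **true effect** *e* on the unit scale
(1 = wild-type-like, 0 = null). Missense effects are drawn from a
two-mode Gaussian mixture — damaged mode N(0, `mode_sd`) with weight
`deleterious_fraction` (defaults 0.08 and 0.15/0.18), tolerated mode
N(1, `mode_sd`) — matching the strongly bimodal missense score
distributions these assays produce. The within-mode Gaussian shape is a
modeling stand-in: nothing in the data constrains it, and any unimodal
spread with comparable width behaves equivalently downstream.

Selection multiplies a clone frequency by the survival function

    s(e) = floor + (1 − floor) · clamp(e, 0, 1),      floor = 0.05

so null variants retain 5% residual survival, and post-selection
frequencies are renormalized within each tile (the untouched wild-type
remainder survives with s = 1). Sequencing error adds a per-variant
frequency drawn from Gamma(shape 1.5, scale 2e-6) — a long-tailed
positive distribution with mean 3 ppm, well below the 10 cpm
"well-measured" threshold — **identically** in library and wild-type
control samples, so WT subtraction is exactly unbiased in expectation.
Observed counts are multinomial over (variants in tile + WT remainder) at
`depth` reads (default 1.3e6 per tile per condition), independently per
replicate (default 2) and condition (pre, post, wt_pre, wt_post).

What the generator does **not** model: read-level artifacts (PCR
jackpotting, base-call errors at the read level), linkage between
co-occurring variants within a clone (tiles observe marginals anyway),
bottleneck drift between replicates, and fitness epistasis between
substitutions in multi-variant clones. Passing tests therefore
demonstrate correctness of the analysis chain under idealized sampling
noise, not robustness to those real-data pathologies.

Randomness: one root seed; each stage (ORF, truth, counts, reference
sets) draws from a hash-derived `SeedSequence` substream, recorded in the
run manifest. Identical config ⇒ byte-identical outputs.

## Scoring chain

1. **Frequencies**: freq = count/depth, cpm = 1e6·freq.
2. **Filters**, per replicate, from pre-selection data: raw count < 10
   (`low_count`); cpm < 10 (`not_well_measured`, threshold inclusive so
   exactly 10 cpm passes); frequency ≤ the 90th percentile of the
   WT-control frequency distribution *across variants within the same
   tile* (`below_wt_p90`). A variant is excluded only if it carries at
   least one flag in **every** replicate — the lenient union-of-evidence
   reading that maximizes coverage. The percentile is taken over
   variants (not over positions or control replicates); this is the
   interpretation that makes the filter a per-tile error-floor estimate.
3. **Correction/enrichment**: corrected frequencies f′ = f_lib − f_WT per
   condition; φ = f′_post/f′_pre. Non-positive f′_pre makes φ meaningless
   (flagged); non-positive f′_post is floored at one pseudo-read
   (1/depth) so fully depleted variants — most nonsense variants at high
   depth — remain scoreable.
4. **Error regularization**: the empirical sd of log2 φ across replicates
   is shrunk toward a log-log linear trend fitted against pre-selection
   cpm over all variants with replicate pairs (≥30 required):
   se² = (m·sd_model² + (n−1)·sd_emp²)/(m+n−1), pseudo-weight m = 2,
   df = m+n−1. m = 2 treats the trend as worth two extra observations —
   enough to stabilize the many variants whose two replicates agree by
   chance, without masking genuine irreproducibility.
5. **Combination**: inverse-variance weighted mean of log2 φ, combined
   se = (Σ w)^(−1/2), Welch–Satterthwaite df = (Σw)²/Σ(w²/df_i).
   Single-replicate variants pass through, flagged.
6. **Rescaling**: noise is symmetric in log space, so steps 4–5 operate
   on log2 φ; the final score is linear in φ,
   score = (φ − med φ_non)/(med φ_syn − med φ_non), with the se mapped by
   the delta method (se_φ = φ ln2 · se_log). The linear scale makes the
   score an unbiased estimate of clamp(e) under the survival model above
   (the normalization constant cancels), keeps both anchor medians exact
   by construction, and reproduces the canonical bimodal score shape with
   the density valley near the mode midpoint. A log-scale score would
   stretch the damaged mode's upper tail (ln(1+19e) for floor 0.05)
   across the valley and displace the density minimum far from the
   midpoint.

## Map assembly

Cells are damaging below the map threshold, "hyper" above 1 + 2·se (a
pragmatic rule — the assay literature shows above-WT cells but no
published cutoff), tolerated otherwise. The data-driven threshold is the
minimum of a Gaussian KDE (Scott bandwidth, 2048-point grid) between the
two highest modes of the missense score distribution, falling back to the
configured default (0.5 activity / −0.4 abundance) with a warning when
the estimate is unimodal. Group contrasts use two-sided Mann–Whitney U —
exact permutation null for group sizes ≤ 8 (ties handled by enumeration),
tie-corrected normal approximation otherwise — with Benjamini–Hochberg
adjustment within each declared family. ΔΔG discordance defaults to
"destabilizing below −0.5" with the sign convention configurable, window
width 10 positions (step 1) for the moving-window tracks; both numbers are
conventions, not fits. Multi-study phenotype values are collapsed by
sample-size-weighted mean before Spearman correlation. Spearman on
constant input is reported as undefined (None), never NaN-propagated.

## Clinical calibration

Balanced precision re-weights the reference sets 50/50:
bp = recall/(recall + FPR), equal to ordinary precision whenever
|P| = |N|. Thresholds sweep the observed scores with ties called
pathogenic-side (orientation: lower score = more pathogenic). AUBPRC
integrates by trapezoid over recall, keeping the maximum bp per distinct
recall and extending the leftmost bp to recall 0; R90BP is the largest
recall at bp ≥ 0.90, 0 if never reached.

Densities use the Epanechnikov kernel K(u) = ¾(1−u²) with the
Sheather–Jones solve-the-equation bandwidth. SJ is computed for the
Gaussian kernel (pilot bandwidths 1.24·λ·n^(−1/7), 1.23·λ·n^(−1/9) with
λ = min(sd, IQR/1.349); fixed point by Brent bracketing, normal-reference
fallback if bracketing fails) and converted through the canonical-kernel
ratio (15^(1/5)/(2√π)^(−1/5) ≈ 2.214); it matches R's `bw.SJ` reference
implementation to <2%. LLRp(s) = ln f_P(s) − ln f_B(s), computed as a
difference of logs so that swapping the sets negates every value exactly.
Queries outside the union of the two kernel supports are clamped to the
nearest edge, and each density is floored at 1e-6 of its maximum before
the ratio, keeping LLRp finite with compact-support kernels.

Confidence intervals are 95% percentile case-resampling bootstraps
(default 500 resamples), resampling each reference set independently and
refitting both densities (bandwidth included) per resample; degenerate
(constant) resamples are dropped and counted. Evidence strengths follow
the Tavtigian odds-of-pathogenicity ladder with op = 350: thresholds
ln(op^(1/8)) … ln(op) on the pathogenic side, mirrored for benign.
By default a non-indeterminate call additionally requires the CI to
exclude 0 on the opposite side — a conservative gate against over-calling
from sparse reference sets (the published calibrations do not state their
gating; ours is explicit and can be disabled).

## Structure and trajectory

RSA = Shrake–Rupley ASA (heavy atoms only, probe 1.4 Å, 960 sphere
points) divided by the theoretical Gly-X-Gly maximum per residue type
(Tien et al. 2013 values), so rsa can exceed 1 in extended conformations.
Core < 0.20, surface > 0.35, intermediate between. The ASA context
(monomer vs complex) is whatever structure the caller passes; both are
legitimate and the annotation table records the chain used. Interfaces:
any heavy-atom pair across two chains within 5.0 Å marks both residues.
Metal-binding positions default to {47, 49, 64, 72, 81, 84} and the
disulfide pair to {58, 147}; both configurable.

Trajectory statistics read multi-model PDB (dependency-light, text-only).
MSF is measured against frame 0 ("relative to the initial structure"),
with rigid-body Kabsch superposition over Cα on by default — without it,
global tumbling counts as fluctuation. Hydrogen bonds use the
donor–acceptor heavy-atom distance ≤ 3.4 Å and the D–H···A angle
(vertex at H, 180° = linear) ≥ 120°, boundaries inclusive; hydrogens must
be present (no implicit-H inference). Pair-distance sd is the population
sd over frames.

## Problem sizes

The default study conditions — 153-residue ORF (3213 variants), depth
1.3e6 × 5 tiles × 2 replicates × 4 conditions — run in a few seconds, so
tests and the acceptance script use them directly; unit tests use a
40-residue / 2e5-depth configuration, and bootstrap checks use 200
resamples.

## Known limitations

- The two-mode Gaussian truth model has no intermediate (hypomorphic)
  shoulder; threshold recovery on real maps with filled valleys will be
  less crisp than the tests suggest.
- The error model regresses log sd on log pre-selection cpm only;
  condition-specific overdispersion (e.g. selection bottlenecks) is not
  modeled.
- Evidence strengths use the op = 350 ladder without a disease-specific
  prior; calibrating the prior is left to the caller.
- The balanced-PRC curve treats score ties at a threshold as
  pathogenic-side calls; with heavily quantized scores this choice is
  visible in the curve.
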