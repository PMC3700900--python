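# Methods

This note documents the statistical model behind duocall, the defaults
that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Signal model

At a marker, sample *i* yields intensities `(a_i, b_i)`, modelled as
channel sensitivities times half the per-allele dose plus noise:

    a_i ≈ s_A · d_A(i)/2 + ε,    b_i ≈ s_B · d_B(i)/2 + ε,

where `d_A`, `d_B` are the copy counts of alleles A and B (0–2 per
channel for the diploid range) and `s_A`, `s_B` are unknown per-marker,
per-channel sensitivities. A diploid homozygote therefore sits at the
full-dose level `s`, a heterozygote at `s/2` per channel, a hemizygous
deletion at `s/2` on its single informative channel, and a homozygous
deletion at noise level on both. Duplications add dose but fluorescence
saturates, so doses above 2 are compressed; duocall treats all
amplifications as one pooled state (CN3+) and never stratifies them.

## Normalization

Scales are estimated from candidate homozygotes selected by provisional
BAF bands on the raw data (≤ 0.25 → candidate AA, ≥ 0.75 → candidate
BB, the open middle band → candidate heterozygotes), excluding samples
whose total intensity is below 5 % of the marker median (they carry no
band information). The per-channel scale is the *weighted mode* of the
candidate intensities: a Gaussian KDE is weighted by `w(x) = x` and the
scale is the highest-intensity local maximum of the weighted curve whose
height reaches `mode_frac = 0.1` of the curve maximum.

Two points deserve justification:

- **Why a mode and not a centroid.** At markers inside deletions, the
  candidate-homozygote pool mixes full-dose and half-dose clusters; a
  centroid lands between them and mis-scales the channel. The mode locks
  onto one cluster.
- **Why the highest qualifying mode and not the global weighted
  maximum.** When the deletion allele is common, the half-dose cluster
  outweighs the full-dose cluster by more than the factor-two intensity
  weight can compensate, so the *global* maximum of any mildly
  increasing weight still picks the wrong mode. Selecting the
  highest-intensity mode above a relative height floor is the monotone
  weighting taken to its limit, and is scale-equivariant, so
  normalization remains invariant under global rescaling of the raw
  data.
- **Bandwidth.** Silverman's rule with a robust sigma
  `min(SD, IQR/1.349)`: the plain rule oversmooths bimodal candidate
  pools and erases a minor full-dose mode entirely (the low-MAF
  deletion-marker case).

Channels without enough homozygote candidates (`min_candidates = 5`)
fall back to the heterozygote arm, dividing its weighted mode by
`het_target = 0.5`; channels with neither are passed through unscaled
and flagged.

A residual failure mode remains: when a channel has *no* full-dose
homozygotes at all (rare allele, common deletion), the homozygote arm
can only see the half-dose cluster and the scale halves. The CNV stage
detects this downstream (see cross-arm consistency below).

## SNP genotyping

BAF is the two-channel angle `(2/π)·atan2(b, a)` — monotone, bounded in
[0, 1], and requiring no cluster file; absolute intensity is `a + b`.

**Zero-copy detection.** Sorted absolute intensities are scanned for a
gap whose lower value lies in the expected threshold range [0, 0.5] (on
the normalized sum scale a hemizygous deletion sits near 0.5, so a
zero cluster must separate below that). The gap must exceed
`zero_gap_factor = 10` times the median of the remaining consecutive
differences; the candidate gap is excluded from its own null scale so
the rule behaves at small n. The threshold is the gap midpoint.

**Peak search.** The BAF PDF is a scaled histogram (`n_bins = 50` below
500 samples, else `⌈n/10⌉`), smoothed with a 3-bin moving average to
suppress single-bin sampling noise. Peaks are accepted greedily by
height among local maxima that (i) reach `min_peak_frac = 1 %` of the
curve maximum, (ii) carry at least one sample within the smoothing
window, (iii) lie `min_separation = 0.12` BAF units from every accepted
peak, and (iv) claim a genotype anchor in {0, ½, 1} not already claimed
— wide hemizygous-deletion clusters otherwise put shoulder bumps next
to a homozygote peak that steal the heterozygote slot. The search stops
at three peaks.

**Limits and refinement.** Boundaries sit at the density minimum
between consecutive centres; among tied minimal bins (an empty
plateau), at the midpoint of the longest minimal run — an isolated
empty bin inside a cluster tail is not a boundary, and a symmetric
empty valley splits at its centre. With fewer than three peaks, each
genotype interval is re-histogrammed at `refine_factor = 4` times the
bin density and re-searched (anchor rule off, sub-peaks need ≥ 2
samples), which recovers clusters merged by channel imbalance.

**Assignment and quality.** Three peaks map ascending to AA/AB/BB;
fewer map to anchors by total distance with ties broken toward
homozygotes. Samples are genotyped by interval; zero-masked samples are
ZERO; only missing data yields NOCALL — confidence is carried by the
scores, and filtering is left to the user. The global score is the mean
within-cluster BAF SD (proportionality constant 1); the per-call score
is the distance to the assigned centre divided by the distance to the
nearest adjacent centre (1 for single-centre markers).

## CNV genotyping

Each SNP genotype cluster is analyzed on its informative channel only:
arms AA-on-A, BB-on-B, AB-on-A, AB-on-B. Zero-copy samples are already
resolved and enter no arm. Arms below `min_arm_size = 10` samples are
skipped and score at the diploid default.

**Fits.** The one-component model is the closed-form Gaussian (variance
floored at `1e-4`). The two-component model is a univariate EM, best of
nine deterministic quantile-split starts (splits at quantiles 0.5,
0.25, 0.75, 0.1, 0.9, 0.35, 0.65, 0.15, 0.85; additional restarts, if
configured, are seeded random two-point starts), tolerance `1e-6`
relative log-likelihood, 200 iterations max. Quantile splits cover
minor-component weights on either flank and make the default fit fully
deterministic; on arm-geometry instances they match a 200-restart
brute-force search.

**Selection.** The two-component model is kept only if all hold:
`BIC₂ < BIC₁ − 10` (2 vs 5 free parameters), minimum weight ≥ 0.03,
mean separation ≥ 2.5 pooled within-component SDs, EM converged.
These quantify a requirements-all-met rule; each is in config.

**Labeling.** For a homozygote arm, components (mean-ascending) get
total-copy doses: if the high component is the frequent one, high =
diploid (2) and low = hemizygous deletion (1); if the high component is
minor but zero-copy samples were seen at the marker, the same (a
segregating deletion allele explains a large low cluster, consistent
with Hardy–Weinberg); if the high component is minor and no zero-copy
samples exist, high = amplification (3) over diploid (2). One-component
arms default to diploid. Heterozygote arms use per-allele doses and can
never carry an allele deletion (an AB call implies one copy of each
allele): a minor high component is an allele amplification (2 vs 1);
with a majority high component both are labelled normal — deviations
are captured as outliers instead.

**Cross-arm consistency.** A one-component homozygote arm at a marker
where deletions segregate (zero-copy samples present) is re-checked
against the heterozygote per-allele signal on the same channel: if the
arm mean sits below 1.5× that reference (i.e. near 1× rather than the
2× a true homozygote implies), the whole cluster carries one allele
copy — every called "homozygote" is hemizygous, the low-MAF case — and
the component is labelled as a deletion cluster. This also rescues
markers whose channel scale halved during normalization, since the
ratio between arms is scale-free.

**Outliers and scoring.** Samples beyond `z_cut = 4` SDs of their
maximum-posterior component are low/high outliers and score at the
capped value (1/3 on homozygote arms; per-channel dose 0/2 for
heterozygotes). Otherwise `S` is the posterior-weighted dose, summed
over the two channels for heterozygotes, clamped to [0, 3]; zero-masked
samples score 0. Categories are fixed bins of S — CN0 < 0.5 ≤ CN1 < 1.5
≤ CN2 < 2.5 ≤ CN3+ — right-closed on the left edge (S = 1.5 → CN2). The
per-marker non-diploid frequency (share of non-CN2 categories) is the
downstream CNV-marker filter (> 1 %).

## Evaluation layer

- `genotype_r2`: squared Pearson correlation of paired integer
  copy-number vectors (discrete calls, not continuous S, matching how
  external call sets are published); zero variance on either side is
  undefined and treated as 0 under maximization.
- `best_marker_per_locus`: loci are 1-based inclusive intervals; the
  reported r² is the max over markers inside, with an r²-stratification
  summary (> 0.9 / 0.8–0.9 / < 0.8 / undetected / uncovered).
- `population_association`: chi-square test of category × population
  without continuity correction; empty categories dropped, categories
  with expected count < 1 pooled into a neighbour; degenerate tables
  give p = 1.
- `pvalue_ratio_metric`: per locus `log10(p_method)/log10(p_ref)` over
  reference-significant loci (p < 0.05); the summary is the percentage
  inside [0.9, 1.1] plus the percentage of loci the method misses
  (method p > 0.05). Method p per locus is the minimum over the locus's
  markers.
- `ld_pair_candidates` / `cnv_locus_builder`: the mining filters
  (≤ 50 kb SNP–CNV distance, r² > 0.7 in any population, gene within
  100 kb or TF-interval overlap; chains of ≥ 3 markers ≤ 5 kb apart
  with **all pairwise** r² > 0.7 near a gene ≤ 15 kb away, best locus
  per gene by mean pairwise r²). All-pairs rather than adjacent-pairs
  r² was chosen for locus membership (configurable); it is the stricter
  reading and keeps loci internally consistent.

## Synthetic data

`simulate_marker` draws two haplotypes per sample — deletion with
probability `del_freq`, duplicated allele with `amp_freq`, otherwise a
single allele (B with probability `maf`) — so genotype and copy-number
states follow Hardy–Weinberg exactly. Channel means follow the signal
model; per-channel doses above 2 are compressed as
`2 + (dose − 2)·0.3`, capped at `saturation_level = 2.6`, encoding the
premise that amplifications barely move the signal. Noise is Gaussian
truncated at zero (clipping keeps the analytic cluster means simple;
the noise model is a single function and pluggable). Marker classes
(plain / deletion / amplification / monomorphic / channel-imbalanced)
and their mixture are configurable; per-population frequency overrides
and shared-event blocks (perfect within-block LD) support association
and locus tests. All draws derive from integer seed sequences, never
process state.

What the generator does **not** emulate: inter-marker LD beyond shared
CNV events, plate/batch effects, GC waves, intensity heteroscedasticity
and the long-tailed noise of real arrays, or cluster-position shifts
between cohorts. Passing tests therefore demonstrate the algorithmic
properties of the method under its own signal model, not performance on
any particular real platform.

## Study conditions used by tests and the acceptance script

Problem sizes are chosen so the whole suite runs on a laptop-class
single core: SNP recovery on 500 markers × 200 samples (channel noise
0.03, MAF ≥ 0.05); zero-detection on 100 constructed gap fixtures and
100 no-gap fixtures (n = 100 each); EM-vs-oracle on 50 instances of
n = 60; model-selection rates on 200 + 200 arms of n = 300;
hemizygous-deletion recovery on 50 replicate markers (deletion allele
0.3, n = 300, noise 0.07); association power on 100 two-population
deletion loci (deletion allele 0.4 vs 0.1, 100 samples per population);
chi-square calibration on 1000 null loci.

## Known limitations

- Single-marker calling only: no HMM segmentation across consecutive
  markers, so short multi-marker events gain nothing from their
  neighbours (the locus builder groups calls post hoc instead).
- Amplifications are detected mainly via minor-high components and
  high outliers; under strong saturation they are expected to be
  missed, and the tests only require that they produce no false
  deletions.
- Chromosome X and other non-diploid baselines are out of scope; all
  markers are treated as autosomal.
- When a marker has neither full-dose homozygotes nor enough
  heterozygotes on a channel, its scale is unidentifiable; such markers
  are flagged rather than repaired.
- NOCALL is reserved for missing data; quality-based filtering is the
  caller's responsibility via the global and per-call scores.
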