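# Methods

## The outcome model

One simulated *integration* is a cell that received the heteroduplex vector
with a single replication-blocking lesion on one strand. The model assumes
the replicative discontinuity picture of damage tolerance: the fork
re-primes downstream of the lesion, replication of both strands completes,
and a single-stranded daughter-strand gap is left opposite the lesion. The
first division then separates the two chromatids:

- the daughter inheriting the lesion-containing chromatid lives iff its gap
  was resolved — by homology-directed gap repair (probability `h`) or by
  translesion synthesis (probability `t`), independent per gap;
- the daughter inheriting the other chromatid lives iff *that* strand's own
  gaps are all resolved. Endogenous blocking lesions on the opposite strand
  are Poisson with mean `lambda_opp`; in the clustered-UV mode an additional
  Poisson load `lambda_uv` is present. Each such gap resolves independently
  with the same per-gap probability `r = h + t`.

There is no division checkpoint: cells divide regardless of unrepaired gaps.
Writing `lam = lambda_opp + lambda_uv`, Poisson thinning gives the closed
forms implemented in `survival_closed_form` (survival
`S = r + (1-r)·exp(-lam(1-r))`, chromatid loss `(1-r)·exp(-lam(1-r))`,
HDGR `h`, TLS `t`), all as fractions of integrations with the lesion-free
control defined as 1. Endogenous lesions are modelled only on the strand
opposite the introduced lesion and the control arm survives with probability
1: the assay normalizes every number to the lesion-free control, so attrition
shared by both arms cancels and only the differential term is informative.

Marker transmission follows the construct geometry: the gap-repaired
daughter carries C+B (upstream damaged-strand marker plus the opposite-strand
allele patched in at the gap), a TLS daughter C+D, the undamaged daughter
A+B; on the six-marker layout downstream E/F markers follow the strand of
origin (C+B+F, C+D+F, A+B+E). Each surviving daughter's B/D heteroduplex
locus then converts with probability `c` per locus, which is what mixes HDGR
and TLS counts in raw data. Orientation (leading/lagging) is metadata only;
the parameters are orientation-independent, consistent with the observation
that gap filling behaves identically on both strands.

## Parameters and calibration

Defaults (per strain × lesion, `CALIBRATIONS`): `lambda_opp = 0.8`
everywhere and `c = 0.05`, with per-gap probabilities

| strain   | lesion  | h     | t     |
|----------|---------|-------|-------|
| parental | UV      | 0.895 | 0.002 |
| parental | G-AAF   | 0.88  | 0.02  |
| recA     | any     | 0.05  | 0.01  |
| recF     | UV      | 0.46  | 0.002 |
| recF     | G-AAF   | 0.42  | 0.08  |
| recB     | UV      | 0.72  | 0.002 |
| sulA     | UV      | = parental |   |

These reproduce the published partitioning as emergent Monte-Carlo output:
parental HDGR ≈ 90% with ≈ 10% white colonies; recA-null survival ≈ 50%
(`0.06 + 0.94·e^(-0.752) ≈ 0.503`) with ≈ 88% of survivors white and ≈ 10%
sectored (the residual `h = 0.05` stands for RecA-independent exchange);
recF-null survival ≈ 81% with HDGR ≈ 46%; the four-fold G-AAF TLS rise in
recF; the ~20% HDGR drop in recB; sulA identical to parental. `lambda_opp =
0.8` makes the recA-null survival ≈ 50% and is consistent with "half of
cells carry at least one opposite-strand lesion" (`1 - e^{-0.8·0.94} ≈
0.53`). The clustered mode uses `lambda_uv = 2.56`, fixed by the measured
7.73% zero class (`e^{-2.56} = 0.0773`), within the stated 2–3 lesions per
strand. The calibration grid search (`calibrate_params`) is deterministic:
h, t on a 0.005 grid, lambda on a 0.05 grid up to 2, minimax objective on
tolerance-normalized residuals with an L2 tie-break, since published targets
are band claims rather than point data.

## Construct fixtures

Full vector sequences are not published, so fixtures are synthetic: backbone
filler is drawn from a fixed per-layout seed, then rejected and redrawn until
no stray primer match or diagnostic restriction site exists on any daughter
duplex. Constrained features are real: primer pairs VP56/VP215, VP210/VP215
and VP56/GM1 embedded so B-carrying daughters yield 506, 1100 and 2283 bp
products; lesion contexts GCAAGTTAACACG (TT lesions, HincII site) and
ATCACCGGCGCCACA (G-AAF, NarI site) inside the D allele; marker alleles
engineered so exactly one allele per locus carries its diagnostic site (SspI,
PvuII, EcoRI, NheI or BglII per layout). Which allele carries the site is not
documented; here the undamaged-strand alleles (A, B, E) carry them. D is a
+2-nt insertion allele and B a +4-nt insertion; the backbone is taken to sit
at frame offset −4 relative to functional *lacZ* so that B-carrying daughters
are in frame and C+B alone (no stop codon) is *lacZ+*. Frame arithmetic is
asserted as bookkeeping, not translated. Coordinates are 1-based;
upstream/downstream follow fork direction.

## Molecular readout

PCR is exact-match with both primers required to bind the duplex exactly once
convergently. Digestion cuts the amplicon wherever a recognition motif (or
its reverse complement) matches the primer-bearing strand, at a fixed blunt
offset; overhang chemistry is irrelevant to fragment lengths. Gel resolution
is treated as perfect and fragment order is discarded (a pattern is the
multiset of lengths), matching qualitative agarose readout. The decoder
forward-simulates all 2^loci daughters and inverts the pattern map; layout
generation guarantees injectivity, and the decoder raises distinct errors
for unknown patterns (corrupt input) versus ambiguous maps (design error).
Pure-blue colonies (only the gap-repaired daughter grew) are classified HDGR
but tallied separately (`n_pure_blue`). A colony whose phenotype contradicts
its decoded genotype raises a discordance error rather than being silently
classified; the pipeline counts these.

## Quantification and inference

Tolerance percentages are ratio-of-ratios:
`100·(class/std_lesion)/(control/std_free)`. Class CIs are Wilson intervals
on the lesion-arm multinomial scaled by the normalization ratio; the survival
CI uses a log-normal delta method over the four counts; a seeded Poisson
percentile bootstrap (2000 resamples) is available for the full
ratio-of-ratios. Marker conversion is undone by inverting the symmetric 2×2
confusion matrix `[[1-c, c], [c, 1-c]]` on (HDGR, TLS) — the exact arithmetic
of the wet protocol's "taken into account" is unstated, so the explicit
inverse is this package's choice; corrected counts below zero are clipped
with a warning (`c ≥ 0.5` is rejected as non-invertible in the intended
regime). The clustered-mode correction inverts the mixture
`S_obs = f0·S_single + (1−f0)·S_clustered` with `f0 = e^{-lambda_uv}`.
`estimate_opposite_burden` inverts the survival law in closed form,
`lam = -ln((S-r)/(1-r))/(1-r)`, defined for `r < S ≤ 1`; survival below `r`
is inadmissible under the model and raises. The conversion-rate estimator
counts, per decoded sector of lesion-free colonies, B/D alleles discordant
with the parent strand identified by the A/C marker; generator and estimator
agree on a per-sector basis.

## Synthetic data: what it does and does not emulate

The generator emulates per-integration outcome sampling, genotype-dependent
per-gap probabilities, the Poisson opposite-strand burden, the clustered-UV
load, B/D marker conversion, plating of a lesion-free control arm, and
internal-standard counts (Poisson, mean 30 000 per arm, the precision of
automated spiral-plater counting; this choice sets the normalization noise
floor). It does not emulate: SOS induction dynamics, sector-size variation
within colonies, partial digestion or gel artefacts, mismatch-repair-active
strains, or any lesion-position dependence. Passing tests therefore
demonstrate internal consistency of model + readout + statistics under these
idealizations, not wet-lab accuracy beyond the published class frequencies.

In the clustered mode the model retains the recA-null residual per-gap
resolution (h = 0.05) for every gap, which predicts a few percent survival,
whereas essentially none was observed experimentally; whether
RecA-independent exchange fails on multi-gap chromatids is unknown, so no
quantitative claim is made for clustered survival. Likewise, whether the
published "7–13% of tolerance events" in the recA-null strain denominates
survivors or all integrations is ambiguous; the sectored share among
survivors (~10%) and among integrations (~5–6%) are both derivable from the
emitted tables and both are consistent with the model.

## Numerical and design notes

- One seeded `numpy` generator per experiment; the vectorized experiment
  path and the scalar `simulate_integration` implement the same law and are
  cross-checked against the closed form (20-point grid, 3 SE) in the tests.
- Pipeline runs derive per-section seeds from the root seed via
  `SeedSequence.spawn`, making reruns byte-identical; for that reason the
  run log records parameters, seeds and versions but not wall-clock runtime
  (which goes to stderr logging instead).
- Desk-scale problem sizes: 20 000 integrations per simulated condition and
  10 000 lesion-free colonies for conversion estimation, chosen so sampling
  error (≲ 0.5 pp) is negligible against the published bands.
- Degenerate inputs: zero lesion-arm colonies yield a 0% partition with
  degenerate CIs; `n ~ Poisson(0)` and `r = 1` short-circuit exactly;
  internal-standard draws of zero are impossible at the default mean but
  bootstrap resamples clip them to 1.
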