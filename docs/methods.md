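# Methods

## Model

Every observed intensity in a multiplexed proteomics run is modeled as a
product of the true amount and multiplicative nuisance terms:

```
I(feature, sample) = amount × E(sample)^[pre-extraction] × L(batch) × R(sample) × ε
```

where `E ∈ (0, 1]` is the per-sample extraction efficiency (applied only
to material present before protein extraction: the pre-extraction spike
tier and the endogenous proteins), `L` is the per-batch labeling
multiplier, `R` the per-sample instrument/ionization response (which
absorbs the arbitrary intensity scale), and `ε` multiplicative
measurement noise.

Anchoring any feature to the BSA carrier digest of known amount `B`,

```
µg-eq(x) = I(x) · B / I(BSA),
```

cancels `L·R` exactly because the carrier is observed in the same channel.
Hence for a pre-extraction standard of spiked amount `A_pre`,
`µg-eq = A_pre · E`, while a post-extraction standard gives `A_post`.
Tier summaries are unweighted means of µg-equivalents over each tier's
standards (the standards are normalized individually; the mean is the
aggregation choice, made here because no weighting information exists at
the abundance level). The per-sample correction factor

```
CF = mean µg-eq(pre-tier) / mean µg-eq(post-tier) = (A_pre/A_post) · E
```

identifies `E = CF / CF*` against the ideal factor `CF* = A_pre/A_post`,
and the protein multiplier `1/E = CF*/CF` restores protein µg-equivalents
to their pre-extraction amounts. In the noise-free limit this chain is
exact for *any* batch/instrument multipliers — that identifiability is
asserted at 1e-9 relative tolerance in the test suite and is the core
claim the two-tier design rests on.

**Orientation of the correction factor.** The factor is pre/post, the
ideal is the spiked-amount ratio, and the multiplier is ideal/factor, so
100% extraction means a multiplier of 1. The inverted convention
(post/pre, i.e. multiplying by the raw tier ratio) differs only by the
constant ideal factor and is available as multiplier mode `literal`; it
rescales every sample identically and therefore changes no relative
statement, only the µg scale.

**Ideal factor and units.** `CF*` is computed from configured per-standard
amounts (mean over the tier). The default configuration assigns amounts
proportional to the spiked concentrations (36 µM pre, 54 µM post, equal
volumes) in a common nominal unit, giving `CF* = 36/54 = 0.667`; because
only ratios of like quantities enter the chain, the nominal unit cancels.
The BSA carrier amount is configuration (default 100 pmol = 6.65 µg at
66,463 g/mol); amounts are config-driven rather than hard-coded because
carrier preparations vary.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bsa_amount_ug` | 6.65 | carrier digest amount (µg); 100 pmol BSA |
| `min_replicates` (k) | 2 | a protein must be observed in ≥ k replicates of *some single* condition |
| `alpha` | 0.05 | significance level of the per-protein Welch t-test |
| `fdr` | off | Benjamini–Hochberg adjustment of group-test p-values |
| `multiplier` | efficiency | `efficiency` (ideal/CF) or `literal` (1/CF) |
| `rel_tol` | 0.05 | relative change below which a condition difference is "flat" for trend labels |
| `p_threshold`, `fc_threshold` | 0.05, 2.0 | volcano gates for analyte significance |
| `merge_rule` | mean | duplicate-analyte consolidation (mean; `sum` for additive adducts) |

Choices that were genuinely open:

- **Welch, two-sided, uncorrected by default** for the group test: with
  n = 6 per group, equal variances cannot be assumed, and the correction
  choice is surfaced as a flag rather than silently imposed. The
  convention used is recorded in the run manifest.
- **Replicate filter counts within a single condition**: a protein seen
  twice in one condition is quantifiable there even if absent elsewhere;
  counting across conditions would pass proteins that are never twice
  measurable in any comparable state.
- **Missing abundances are explicit and excluded from means, never
  zero-imputed** — zero-imputation would bias tier summaries downward and
  fabricate extraction loss.
- **Zeros entering log10 are masked, not offset**; a pseudo-count would
  manufacture fold changes at the detection limit. A half-minimum offset
  is deliberately not the default.
- **Trend tolerance 5%**: small enough to keep the worked anchor example
  (6.1 → 1.0 → 4.1 µg) unambiguous, large enough not to label replicate
  noise as change.
- **Normativity is reported per condition** from condition-mean analyte
  levels and condition-mean anchor amounts (levels are presented
  condition-wise; per-replicate ratios would propagate anchor noise into
  every analyte).
- The lipid volcano p-threshold default is 0.05; a threshold of 0.5 would
  accept half of all null features and is treated as a configuration to
  opt into explicitly, never a default.

## Synthetic experiments

`simulate_experiment` emulates the reference design: 3 batches × 12
channels, 6 conditions (control; crush; regeneration at days 7/14/21/28)
× 6 replicates, pre-extraction standards at 36 amount-units, post at 54,
one BSA carrier observation per channel. Defaults chosen where no value
was prescribed: labeling sd 0.25 and response sd 0.25 on the log scale
(visible but not dominant batch/run variation), biological CV 20%,
protein baselines log-uniform on 0.5–10 µg, total protein ≈ 70 µg per
sample (CV 10%), measurement CV 10%. Analytes are tied to one anchor
protein each through a fixed normative ratio (e.g. citrate ↔ P001 at
2,500 units/µg). Measurement noise is mean-one log-normal (σ² = ln(1+CV²)
with a −σ²/2 log-mean offset), so noise adds no systematic bias and the
Monte-Carlo bias of the efficiency estimator stays below 2% at CV = 0.1
(the residual ~0.5% comes from the convexity of the ratio of noisy tier
means, not from the noise model). Per-sample extraction efficiencies can
be drawn from a mean/sd-matched Beta distribution (`efficiency_sd > 0`);
a fixed global value is the default.

What the simulator does *not* emulate — and therefore what passing tests
do not establish about real data: reporter-ion interference and impurity
cross-talk between channels, ratio compression from co-isolation,
peptide-to-protein roll-up, missingness that depends on abundance
(the simulator's tables are complete), retention-time drift, and matrix
effects that couple analytes to each other. The identifiability results
say the arithmetic of the chain is right, not that real extractions obey
a single multiplicative loss factor.

## Numerical notes

- Tier summaries with every standard missing, a missing/non-positive BSA
  reference, or an undefined correction factor make the *sample* NaN with
  a logged warning; downstream stages drop such samples, never impute.
- Zero-variance groups in the Welch test: equal means → t = 0, p = 1;
  unequal means → p = 0 (the statistic's limit), instead of scipy's NaN.
- Intersection outputs are ordered lexicographically (combination names
  and pathway ids) so reruns are byte-identical.
- Table writing uses `%.12g`, which round-trips decimal values of ≤ 12
  significant digits exactly.
- Problem sizes in the test suite: identifiability runs at 36 samples × 8
  proteins; the Monte-Carlo bias study uses 200 replicates of the
  36-sample design with spikes only, since the efficiency estimator never
  touches protein rows.

## Known limitations

- The pipeline consumes protein-level (or standard-level) abundances as
  exported by search software; no spectral or peptide-level processing.
- Pathway maps are offline files; counts depend on the annotation version
  supplied, so no canonical pathway counts are built in.
- The generator links each analyte to exactly one anchor; multi-anchor
  normativity (mean of several anchor proteins) is supported in the
  analysis but not simulated.
- With only one standard in a tier, the tier "mean" is that standard, and
  a single aberrant measurement propagates directly into the correction
  factor; multiple standards per tier is the intended operating point.
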