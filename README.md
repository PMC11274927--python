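# regennorm

Two-tier spike-in normalization for multiplexed (TMT) quantitative
proteomics, and proteome-anchored ("normative") quantification of
metabolites and lipids.

## The problem

Isobaric labeling (TMT) gives clean *relative* quantification of up to 18
samples within one plex, but nothing ties one plex — or one experiment, or
one model organism — to another: extraction losses, labeling efficiency
and instrument response all drift between runs. And for small molecules
(metabolites, lipids), no panel of internal standards can normalize across
the mass range at all, because instrument response is non-linear even over
narrow m/z windows.

`regennorm` implements a two-tier spike-in scheme that addresses both:

1. **Pre-extraction spike peptides** (doped into the tissue lysis buffer,
   amount $A_{pre}$ per standard) experience the extraction loss;
   **post-extraction spike peptides** (doped after labeling, amount
   $A_{post}$) do not. A **carrier digest** (trypsin-digested BSA, known
   amount $B$ µg) anchors every intensity to micrograms:

   $$\mathrm{\mu g\text{-}eq}(x) = \frac{I_x \cdot B}{I_{BSA}}$$

   Per sample, the **correction factor** is the ratio of tier summaries
   $CF = \overline{\mathrm{\mu g\text{-}eq}}_{pre} / \overline{\mathrm{\mu g\text{-}eq}}_{post}$.
   At 100% extraction it equals the **ideal factor**
   $CF^\* = A_{pre}/A_{post}$ (≈ 0.66 for the default 36 µM pre / 54 µM
   post tiers); the **extraction efficiency** is $E = CF/CF^\*$, and
   protein µg-equivalents are corrected by $1/E$. Because the BSA anchor
   shares every channel's labeling and response terms, batch and
   instrument effects cancel exactly.

2. **Normativity**: instead of normalizing an analyte by total protein,
   express it per µg of a *normalized anchor protein* from a relevant
   pathway — e.g. citrate per µg of aconitate hydratase. Since anchor
   amounts change with biological state (control vs optic-nerve crush vs
   axon regeneration), the normative level can show a different condition
   trend than the total-protein-normalized level; that contrast is the
   scientific signal.

The package also intersects per-ome pathway sets (proteome × metabolome ×
lipidome) and ships a synthetic-experiment simulator with known ground
truth, so the whole chain is testable without any instrument data.

## Worked example

Generate a synthetic 3-batch experiment (36 samples, 6 conditions × 6
replicates, true extraction efficiency 0.757, 10% measurement CV) and run
the full pipeline on its output tables:

```bash
regennorm simulate --seed 7 --out-dir demo
regennorm run --abundances demo/abundances.tsv --design demo/design.tsv \
    --spikes demo/spikes.tsv --analytes demo/analytes.tsv \
    --anchor P001 --out-dir demo_out
```

`demo_out/report.md` then contains (output from this exact invocation):

```
batch_id  correction_factor  extraction_efficiency
  batch1             0.5340                 0.8010
  batch2             0.5163                 0.7744
  batch3             0.4948                 0.7421

Mean correction factor: 0.5150 (ideal 0.6667); mean extraction efficiency: 77.3%.
Proteins retained by the replicate filter: 40.
```

The mean correction factor sits near the ideal 0.667 × the true 0.757 ≈
0.505, and the recovered efficiency near the simulated 75.7%; the
remaining spread is the injected 10% measurement noise. The same chain is
available as a library:

```python
>>> from regennorm import (regen_v_default, ideal_correction_factor,
...                        extraction_efficiency, simulate_experiment,
...                        recover_efficiency)
>>> ideal_correction_factor(regen_v_default())
0.6666666666666666
>>> extraction_efficiency(0.5, 0.66)          # the printed worked example
0.7575757575757576
>>> sim = simulate_experiment(seed=1)         # defaults: eff 0.757, cv 0.1
>>> recover_efficiency(sim)[1]["mean_estimated_efficiency"]
0.7540959451558841
```

`0.754` against a truth of `0.757`: the estimator is unbiased up to the
noise floor (the test suite checks < 2% bias over 200 replicates).

Outputs per run: `correction_sets.tsv` (one row per sample: tier
summaries, correction factor, ideal factor, efficiency, multiplier),
`normalized_proteins.tsv` (consensus µg-equivalents), `protein_tests.tsv`
(Welch t-tests between regenerative and non-regenerative groups),
`normativity.tsv` (per-condition normative levels with trend labels),
`pathway_intersections.tsv` (when an annotation map is supplied),
`manifest.json` and `report.md`.

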