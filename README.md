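# ddrcyto

Mass-cytometry (CyTOF) analysis of the DNA damage response (DDR) in
peripheral-blood lymphocyte subsets.

After ionizing radiation (IR, 2 Gy) or UVC exposure (100 mJ/m²), lymphocytes
phosphorylate a cascade of DDR proteins — γH2AX (Ser139), p-ATM (Ser1981),
p-CHK2 (Thr68) and p53 — with kinetics and magnitudes that differ sharply
between T, NK and B cells and between naïve and memory compartments.
Quantifying those differences from a barcoded CyTOF experiment requires a
chain of event-level steps, each of which this package implements as a
tested, reusable stage:

1. **FCS I/O** — a purpose-built reader/writer for FCS 3.0/3.1 list-mode
   files (`$DATATYPE` F and I), carrying the panel (channel ↔ metal ↔
   marker ↔ role) and acquisition metadata through the pipeline.
2. **Preprocessing** — arcsinh transform (x ↦ asinh(x/5)), singlet
   discrimination on the Ir191/Ir193 DNA intercalator channels
   (mode ± 3·MAD band), and cisplatin viability gating (density-valley
   threshold).
3. **Debarcoding** — single-cell separation deconvolution of the 20-key,
   3-of-6 palladium barcode scheme (Pd102–Pd110): per-channel robust
   rescaling, top-3 assignment, and rejection of events whose separation
   (3rd − 4th highest rescaled intensity) falls below a cutoff.
4. **Gating** — a declarative, hierarchical population tree covering ~30
   subsets of CD45⁺ lymphocytes (naïve/CM/EM CD4 and CD8 T cells,
   CD56^bright/dim × CD16 × CD57 NK subsets, and the full B-cell taxonomy
   down to plasmablasts and transitional B), with per-marker thresholds
   estimated from density valleys; plus ki67/IdU cell-cycle classification
   (G0/G1/S and the ki67⁻IdU⁺ arrest class).
5. **DDR quantification** — per-population geometric mean intensities
   (geometric MFI, raw scale, positives only), fold induction
   `fold(t) = geoMFI(t) / geoMFI(untreated)` normalised within donor,
   survival composition (% of viable CD45⁺), and ki67± stratified kinetics.
6. **Statistics** — two-way ANOVA with Tukey HSD comparisons between
   populations within time points, Šídák-adjusted paired comparisons,
   Student's t-test, and star coding (\*p ≤ 0.05 … \*\*\*\*p ≤ 0.0001).
7. **Synthetic experiments** — a seeded generator that emits pooled,
   barcoded event files with ground-truth sidecars: subset-specific
   zero-inflated lognormal expression, pulse-shaped DDR kinetics
   `fold(t) = 1 + A·(t/t_p)·e^(1−t/t_p)`, B-cell death by 24 h, injected
   doublets and dead cells, and ATM-deficient (ataxia telangiectasia, AT)
   donor profiles with abrogated induction. Every pipeline stage is
   verified against this ground truth.

The intended users are cytometry bioinformaticians who want a scriptable,
auditable replacement for manual FlowJo/Cytobank workflows when studying
DDR kinetics in immune subsets, including AT-patient discrimination.

## Worked example

Simulate a 2-donor IR experiment (5 time points × 5,000 events pooled per
donor) and run the full pipeline:

```bash
$ ddrcyto simulate --out sim --donors 2 --events 5000 --seed 1
wrote 2 pooled donor files to sim
$ printf 'input_dir: sim\noutput_dir: out\n' > demo.yaml
$ ddrcyto run --config demo.yaml
pipeline complete: 6 output files in out
```

`out/kinetics.csv` then contains one row per (donor, population, marker,
time point). Averaging the γH2AX fold inductions over donors:

```
timepoint_h        0     1     4     8     24
population
CD19+CD20+ B      1.0  1.51  1.09  1.04  0.97
CD3+ T            1.0  2.37  1.28  1.01  1.00
CD56dim CD16+ NK  1.0  3.63  1.59  0.95  1.04
```

γH2AX peaks 1 h after IR and is strongest in CD56^dim CD16⁺ NK cells,
intermediate in T cells and weakest in B cells, then decays back toward
baseline as damage is repaired. `out/comparisons_kinetics.csv` holds the
Tukey comparisons behind the per-time-point significance display:

```
                      comparison  statistic  p_adjusted stars
          CD19+CD20+ B vs CD3+ T     6.2232      0.0023    **
CD19+CD20+ B vs CD56dim CD16+ NK    15.3365      0.0000  ****
      CD3+ T vs CD56dim CD16+ NK     9.1133      0.0001  ****
```

(at 1 h, γH2AX; the statistic is the studentized range q with the two-way
ANOVA residual as pooled error). `out/survival.csv` tracks each
population's share of viable CD45⁺ cells over time — with the default
generator the B-cell share roughly halves by 24 h — and
`out/comparisons_survival.csv` applies Šídák-adjusted paired t-tests to
those shares (with only 2 donors the demo has 1 degree of freedom, so
nothing reaches significance; the reproduction script below runs cohorts
of 8–26 donors).

The same stages are available as library functions
(`ddrcyto.analyze_donor`, `ddrcyto.fold_induction_table`, …) for use on
real debarcoding-ready FCS directories: point `input_dir` at a directory
with `<donor>_pooled.fcs`, `<donor>_codebook.csv`, `manifest.csv` and
`panel.csv`.

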