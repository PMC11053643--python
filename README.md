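# pfas-bcbcr

Screening-level risk prioritization for per- and polyfluoroalkyl substances
(PFAS) by comparing measured human blood concentrations with the
concentrations at which bioactivity is seen in vitro.

Many PFAS have human half-lives of months to years, so their blood
concentrations are stable enough that a single biomonitoring measurement is a
meaningful exposure surrogate. For such chemicals one can form the **Bioactive
Concentration to Blood Concentration Ratio**

```
BCBCR = POD_chemical (ng/mL) / c_plasma (ng/mL)
```

where `POD_chemical` is the chemical-level in vitro point of departure — the
minimum over assay-technology set-level PODs, `POD_set` — and `c_plasma` is a
population summary statistic (percentile, mean, median, extreme) of the
plasma concentration. The BCBCR is a margin-of-exposure-style statistic:
values below 1 mean blood levels reach bioactive concentrations; given the
method's stacked uncertainties, values below 100–1000 already mark a chemical
for closer study. The package is written for computational toxicologists and
risk assessors who have biomonitoring extracts and high-throughput assay
results and want a reproducible, auditable ranking.

## What the pipeline does

1. **Biomonitoring harmonization** (`pfas_bcbcr.biomonitoring`) — long-format
   summary records in whole blood, serum, plasma, cord matrices or blood
   spots are normalized to ng/mL and converted to plasma equivalents:
   serum/plasma pass through (`c_plasma = c_serum`); blood-like matrices are
   divided by the chemical's blood-to-plasma ratio `Rb2p` (measured in vivo if
   available, else an in vitro-derived prediction, else a default of 0.5).
   Metric labels are normalized (all mean flavors collapse to "mean") and
   grouped into High / 75th / 50th / 25th / Low strata. Plasma values above
   100 ng/mL are flagged for manual QC review; nothing is dropped or
   deduplicated.
2. **POD aggregation** (`pfas_bcbcr.pod`) — endpoint-level potencies (AC50 /
   BMC / LEL, μM) collapse per assay set to the lower 5th percentile of
   active potencies (or the minimum, for technologies defined that way), with
   a 1000 μM censoring sentinel for all-inactive sets and curve-quality
   filters for the developmental-neurotoxicity battery. The chemical-level
   POD is the minimum over sets, converted to ng/mL via the molecular weight
   (1 μM = MW ng/mL).
3. **BCBCR and ranking** (`pfas_bcbcr.bcbcr`) — one ratio per chemical ×
   population × metric, banded at strict thresholds (<1, <100, <1000,
   <10000), and a per-chemical ranking by minimum BCBCR.
4. **In vivo anchor** (`pfas_bcbcr.invivo`) — set-level PODs are compared with
   the plasma concentrations measured at the lowest effect level in a packaged
   28-day rat gavage study (seven PFAS, nine phenotypes, both sexes).
5. **Synthetic data** (`pfas_bcbcr.synthetic_data`) — log-normal population
   and assay-endpoint generators with known ground truth, so the whole
   pipeline is testable without any external download.

A 31-chemical roster (identity, formula, structure, half-life class) and the
rat-study table ship as packaged CSV fixtures.

## Worked example

Generate a three-chemical synthetic study and run the screen:

```sh
pfas-bcbcr simulate --seed 1 --out-dir demo_in
pfas-bcbcr compute --roster demo_in/roster.csv \
    --biomonitoring demo_in/biomonitoring.csv \
    --assays demo_in/assay_results.csv --out-dir demo_out
```

which prints the ranking:

```
 rank        dtxsid abbreviation     min_bcbcr driving_snaid driving_population driving_metric      band  pod_censored  n_<1  n_<100  n_<1000  n_<10000  n_above_max
    1 DTXSID8031865         PFOA      0.032668  SYN_PFOA_EXP            exposed        maximum        <1         False    11       5        8         2            0
    2 DTXSID3031864         PFOS      0.099754  SYN_PFOS_EXP            exposed        maximum        <1         False     7      15        4         0            0
    3 DTXSID5030030         PFBS 105651.446455  SYN_PFBS_GEN            general        maximum above_max          True     0       0        0         0           13
```

Reading this: the scenario gives PFOA an exposed population whose plasma
levels exceed its in vitro POD, so its minimum BCBCR (0.033, at the exposed
population's maximum metric) lands in the "<1" band — the prioritization
signal. PFBS was simulated inactive in every assay set, so its POD is the
1000 μM censoring sentinel (`pod_censored`): its enormous ratios are a
statement about absent bioactivity up to the tested range, not a measured
margin. `demo_out/` also contains the per-record BCBCR table, set-level PODs,
QC flags, the in vitro/in vivo comparison, and four diagnostic figures
(log-scale concentration axes; exposed populations orange, general blue).

The same run is available programmatically via
`pfas_bcbcr.pipeline.run_pipeline(RunConfig(...))`, and `pfas-bcbcr report
--config run.cfg` drives it from a plain `key = value` file.

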