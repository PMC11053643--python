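# Methods

## The statistic

For a chemical with stable blood levels, the screen compares two
concentrations on a common ng/mL plasma scale:

* `c_plasma` — a population summary statistic of the measured plasma
  concentration (one of thirteen metrics: 5th–99th percentiles, minimum,
  maximum, mean, median), taken from biomonitoring studies of exposed or
  general populations;
* `POD_chemical` — the chemical-level in vitro point of departure, the
  minimum over assay-technology set-level PODs converted from μM with
  `c[ng/mL] = c[μM] × MW[g/mol]`.

`BCBCR = POD_chemical / c_plasma`. The statistic is computed per chemical ×
study population × metric; chemicals are ranked by their minimum. It is
strictly increasing in the POD, strictly decreasing in the plasma value, and
invariant under common rescaling — the test suite asserts all three.

The core assumption is toxicokinetic steadiness: a spot measurement is
representative only when the chemical's human half-life is long (months or
more). Each result therefore carries a `halflife_applicable` flag derived
from a QSAR half-life class consumed as an input annotation; by default the
flag annotates rather than filters (a CLI switch enables filtering), since
short-half-life results are still informative as likely *underestimates* of
peak exposure.

## Matrix harmonization

Serum and plasma (including cord variants) are treated as equivalent. Whole
blood, cord blood and dried blood spots are divided by the blood-to-plasma
concentration ratio `Rb2p`, with precedence: in vivo measured ratio →
in vitro-derived prediction → default 0.5. The default reflects that most
measured/predicted PFAS ratios cluster between 0.5 and 0.6 (red-cell
exclusion of highly protein-bound anions); `Rb2p` prediction itself is out of
scope — ratios are inputs. Measured totals (not free fractions) are assumed
on both sides of the ratio. Records are never deduplicated and censored
("<LOD") entries are rejected at ingest rather than imputed; LOD/LOQ travel
with the record for annotation only.

QC: plasma-equivalent values strictly above 100 ng/mL are flagged for manual
review against source documents (the threshold at which transcription errors
matter, since almost all in vitro PODs exceed it). Flagging copies records;
nothing is mutated or dropped.

## POD aggregation

Within one chemical × assay set, active endpoint potencies collapse by
policy:

* **P5** (default; multiplexed transcription-factor panels, primary-cell
  systems, transcriptomics per cell type, DNT, thyroid enzymatic assays):
  lower 5th percentile of active potencies, linear interpolation between
  order statistics (numpy's default "linear"/type-7 convention; the
  convention is configurable because the source analyses do not state one).
* **MIN** (impedance-based proliferation pair, phenotypic-profiling category
  BMCs per cell type, zebrafish endpoint BMCs): minimum active potency.

All-inactive sets receive a censoring sentinel of 1000 μM (configurable) with
`censored=True`; censored PODs propagate so downstream ratios are labelled
"POD censored at max tested concentration" rather than silently treated as
potencies. Censored chemicals are retained in the ranking. Maximum tested
concentrations (100 μM generally; 150–300 μM for some technologies) are
stored as metadata only.

DNT endpoints pass a curve-quality filter first; a curve is demoted to
inactive when (1) it carries ≥3 caution flags, (2) it is active with model
top ≤ 1.2 × cutoff and a fitted potency below the lowest tested
concentration, or (3) its hitcall is undetermined (−1, series shorter than
four concentrations). The filter is idempotent and applies only to DNT sets.

Chemical-level PODs take the minimum over sets with a deterministic
lexicographic tie-break on the assay-set name. Each distinct cell type of the
transcriptomic and phenotypic-profiling technologies is its own assay set
(separate `POD_set`), and within a primary-cell system LELs aggregate under
the default P5 policy — both points where the source analyses are silent; the
choices are recorded in `PodConfig`.

## Chain length

"Fully fluorinated carbon" is implemented as a carbon bearing at least one
fluorine and no hydrogens — i.e. every hydrogen position fluorinated; bonds
to backbone heteroatoms (sulfonate sulfur, ether oxygen) do not disqualify.
This reproduces the conventional counts (7 for an 8-carbon perfluoro
carboxylic acid, whose carboxyl carbon has no fluorine; 8 for an 8-carbon
perfluoro sulfonic acid). A stricter rule requiring *all* non-carbon
neighbors to be fluorine was rejected because it undercounts perfluoroalkane
sulfonic acids. Consequence: perfluoroether carbons qualify, so an
ether-linked acid contributes its longest carbon-only segment (3 for the
propoxy branch of the C6 ether acid). The chain length is the longest simple
path in the qualifying-carbon adjacency graph (exhaustive DFS; PFAS skeletons
are tiny). Chemicals without structures get a missing marker, never 0, so
they are excluded rather than misplaced in chain-length analyses.

Molecular weights use 2021 IUPAC standard atomic weights embedded as
constants; the test suite cross-checks every roster chemical against rdkit's
independent values to within 0.05 g/mol.

## Classification and ranking

Band thresholds default to (1, 100, 1000, 10000), strict `<` at every
boundary (a ratio of exactly 1.0 is "<100"). The minimum BCBCR per chemical
can only decrease as populations accumulate — a monotone screening property
the tests assert directly.

## In vivo comparison

The packaged 28-day rat study table lists, per chemical and sex, lowest
effect levels (mg/kg-day) for nine phenotypes and the plasma concentration at
the lowest LEL. The per-row minimum over non-missing LELs is the in vivo POD;
the male/female plasma values span a closed interval (a POD equal to a
boundary counts as overlapping — the convention is ours, the source being
silent) against which each in vitro set-level POD is flagged below / in /
above range. Plasma-at-LEL values are consumed as given, never recomputed
from dose.

## Synthetic data

The generator emulates the *reporting process*, not the biology: plasma
concentrations in a population are log-normal (the standard working model for
biomonitoring of chemicals with stable blood levels) with chosen geometric
mean and geometric standard deviation; a blood-matrix population is converted
subject-wise with a true `Rb2p` before summarizing, so the pipeline's inverse
conversion must recover the plasma summaries exactly. Assay endpoints scatter
log-normally with the aggregation statistic pinned to a true POD: for P5 sets
the distribution's 5th percentile equals the truth (sample P5 is unbiased in
the large-endpoint limit); for MIN sets potencies are drawn at or above the
truth, so the sample minimum is exact at zero noise and converges from above
otherwise. DNT sets receive decoy curves triggering each filter criterion at
one tenth of the true potency, making the filter load-bearing in end-to-end
tests. One global seed fans out to per-block seeds by CRC32 hashing, so
adding a population does not perturb existing draws.

What this does **not** emulate: sampling variability of real cohorts beyond
log-normality (age/sex structure, mixture co-occurrence), time-varying
exposure, assay-specific artifact structure, or inter-study analytical bias.
Passing recovery tests therefore demonstrates the pipeline's arithmetic and
plumbing, not the field validity of the log-normal exposure model.

Default demonstration conditions: three chemicals; exposed populations with
geometric means 5000 and 800 ng/mL (gsd 2.5) against general populations at
4–15 ng/mL (gsd 2.0), sizes 150–500 — order-of-magnitude patterns typical of
occupational versus background PFAS serum studies; endpoint noise 0.2 on the
log scale (endpoint potencies within a technology commonly spread several
fold). Recovery checks use 10,000 subjects and 20 replicates, at which the
sample median of a gsd-2 log-normal is within ~3% of the geometric mean with
high probability, comfortably inside the 5% assertion.

## Numerical choices and degenerate inputs

* Percentile interpolation: linear (type 7), configurable.
* Ties in the chemical-level minimum: lexicographic assay-set order.
* Zero plasma concentrations make the ratio undefined: single computation
  raises; batch computation skips the record with a logged warning.
* A missing molecular weight leaves the μM POD usable but the ng/mL value
  (and hence BCBCR) absent.
* Tables are written with `%.10g` formatting, making pipeline reruns
  byte-identical.

## Limitations

* Nominal-concentration comparison: no tissue partitioning, in vitro
  disposition, or placental-transfer corrections — deliberately, because such
  corrections are highly uncertain for this chemistry.
* The screen inherits whatever assay battery it is fed; adding technologies
  can only lower PODs (and BCBCRs).
* Half-life classes and blood-to-plasma ratios are inputs; the package does
  not predict either.
* The packaged roster carries no blood-to-plasma ratios, so blood-matrix
  conversions with it fall back to the 0.5 default unless the user supplies
  ratios.
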