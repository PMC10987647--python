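# Methods

## The model

`panelvar` treats the knowledge available to a diagnostic laboratory as two
monthly time series joined per month:

* **Gene–disease knowledge**: a versioned virtual gene panel. Each version
  is a set of entries with an ordinal confidence rating 0–3; rating 3
  ("Green") marks a gene as diagnostic grade. The representative snapshot
  for a calendar month is the latest version whose timestamp is at or
  before 23:59:59 on the last day of the month, in UTC. Months with no new
  version inherit the previous snapshot — a panel always has a defined
  state, which is what a laboratory actually experiences.
* **Variant–disease knowledge**: monthly per-gene summary files from a
  variant knowledgebase, giving each gene's total allele count and its
  count of Pathogenic / Likely Pathogenic (P/LP) alleles, keyed by NCBI
  Gene ID.

The joined quantity of interest for month *m* is the number of P/LP
variants in that month's diagnostic genes,
`PLP(m) = Σ_{g ∈ diag(m)} plp(g, m)`. Its month-over-month percent change
is the signal proposed for triggering re-analysis: steady low growth
suggests calendar-based review intervals are adequate; bursts suggest
re-analysing when they occur.

## Identity and change classification

Genes are tracked across panel versions by Ensembl stable ID when present,
falling back to symbol, so a symbol rename with a stable ID is not a
change event. Transitions between consecutive monthly snapshots fall into
six pairwise-disjoint categories (added/removed × diagnostic/
non-diagnostic, upgraded, downgraded) satisfying the conservation
identity; this identity is asserted property-style over randomly generated
snapshot pairs in the test suite. A gene removed and later re-added counts
as a fresh addition — re-entry has no special status. Entries that are not
genes (repeat expansions, CNV regions) are parsed and retained in
snapshots but excluded from every count.

## Missing vs zero

A gene absent from a month's summary file is *missing*, never zero: the
knowledgebase omits genes with no submissions, so absence cannot be
distinguished from schema drift or a failed join, and silently zeroing it
would corrupt the series. All sums skip missing cells and report how many
requested genes were missing; joined outputs report matched and total gene
counts separately ("29 (30)").

## ID resolution

The Ensembl→NCBI map is resolved once per gene (not per month) to avoid
identity flapping, with precedence: manual override → unique candidate →
largest allele count. The "largest count" comparison is made at the latest
month the matrix-present candidates share; if they share none, each is
scored at its own latest sighting; candidates absent from the matrix
entirely fall through to the numerically smaller NCBI ID. The tie-breaks
exist purely for determinism — resolution is a pure function and repeated
calls agree. The chosen ID is fixed, but a gene only contributes to a
month's sums when present in that month's matrix column. The map covers
every Ensembl ID that ever appears on the panel, so months before a
downgrade or removal still resolve their genes.

## Month assignment for summary files

Summary files carry a date in the filename (`YYYY-MM` prefix by default; a
full date is honoured when present). Each panel month maps to the file
dated nearest the month's end; a month-only name anchors to the end of its
month, so identically named months map to themselves. Ties break to the
earlier file, and a month with no file within 45 days is an error rather
than a silent gap. The 45-day tolerance and the tie-break are conventions
of this package, chosen so that a missing monthly archive is caught
loudly while a few days' publication jitter is absorbed.

## Change metrics

Percent change is `100·(end − start)/start`; a zero start yields an
undefined marker (`None`), never a division error, and undefined months
are excluded from summary statistics with a warning count. Internal values
are never rounded; the reporting layer applies round-half-away-from-zero
to integer percent (a truncating mode is available as a display option).
The monthly mean is the arithmetic mean of the per-month percent changes,
matching the "average per month" reading; compounding the per-month
changes reconstructs the series exactly, which is asserted in tests.
Burst detection flags months whose change strictly exceeds a threshold —
5.0%/month by default, a conventional illustrative value, not a derived
constant — comparing signed change by default with a two-sided option for
large declines. Correlation between series is the Pearson product-moment
coefficient (scipy), undefined for constant input.

## The synthetic-data generator

The generator emulates all three inputs from a seed and an explicit event
schedule, and writes the realised events to `event_log.json`. Defaults: 50
genes, 24 months, ~55% of genes diagnostic at launch, per-gene P/LP counts
starting at 5–120 alleles and growing geometrically at a mean 1.8% per
month (noise sd 0.6%, clipped to [0%, 4.5%]). The mean growth echoes the
observed pace of curated gene cohorts in public variant databases; the
clip keeps baseline aggregate growth below the 5% burst threshold, which
is what makes "burst detection flags exactly the injected months" a
well-posed check. Injected event kinds cover panel changes (add / upgrade
/ downgrade / remove), count changes (P/LP step and decline, floored at
zero), and join pathologies (a gene absent from the ID table; an Ensembl
ID mapping to a decoy NCBI gene with deliberately small counts).

What the generator does **not** emulate: submission-level dynamics, review
status, symbol renames in the summary files, genuinely non-monotone
baseline drift, and panel renames/merges. Passing tests therefore
demonstrate that the bookkeeping, joins and metrics are correct given
well-formed inputs of the documented dialects — not that five years of
real archives are free of surprises; the parser's legacy-column mapping
and the loud failure modes (missing columns, out-of-tolerance months,
duplicate IDs) are the defence for those.

## Problem sizes and determinism

The standard test fixture is 50 genes × 24 months with one event of every
kind — large enough that every code path (carry-forward, re-resolution,
missing cells, bursts) is exercised, small enough that the full pipeline
runs in well under a second. The acceptance script uses the same scale.
Identical spec + seed regenerate byte-identical files (sorted iteration,
integer counts, seeded numpy generator), and a full CLI re-run over the
same inputs produces a byte-identical bundle; the run log records a
content digest per stage so any reported cell can be traced to its
artefact.

## Known limitations

* The P/LP column of the summary dialect excludes variants overlapping
  other genes while the total-allele column does not, so P/LP-to-total
  ratios are approximate; both are stored as published.
* Variant-level reclassification (why a gene's P/LP count fell) is out of
  scope — the matrix sees net counts only.
* "Number of variants in all genes" sums matched genes only; the
  matched/total gap is always reported alongside.
* Live API fetching is a convenience (`panelvar fetch`); the library and
  tests are file-based by design.
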