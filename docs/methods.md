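# Methods

## Overview

`barcodeaudit` implements the analytical core of DNA barcode
reference-library construction: compliance filtering of COI-5P records,
pairwise divergence estimation, BIN-style OTU assignment, reconciliation
of specimen names against a fixed checklist, and a concordance audit that
partitions both bins and species into interpretable classes. This note
records the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Distance model

Barcodes are compared only when equal in length. COI-5P is effectively
indel-free within an insect order, so the toolkit treats unequal lengths
as an input error rather than silently re-aligning; callers who need
alignment should align upstream (e.g., with mafft) before computing
distances. Sites where either sequence carries a gap or any non-ACGT
code are excluded from the comparable set for that pair (*pairwise*
deletion). Complete deletion — dropping a site from every pair if any
sequence is ambiguous there — is the main alternative; platforms differ
and often do not document which they use, so pairwise deletion (the common
choice in barcode practice, retaining the most signal per pair) is used
throughout and noted here as a potential source of small discrepancies
against platform-reported distances.

The uncorrected distance is p = (transitions + transversions) /
comparable sites. The Kimura two-parameter distance corrects for multiple
hits with separate transition and transversion rates:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition (A↔G, C↔T) and transversion fractions. The
correction satisfies d ≥ p, with equality only at p = 0, and d/p → 1 as
divergence → 0 — both are enforced as property tests. When the log
argument is non-positive (saturation, P + Q near 1) the distance is
reported as an explicit error, never as infinity, so downstream summaries
cannot silently average an unbounded value; within-species summaries drop
such pairs with a warning.

Intraspecific divergence per species is summarized over all n(n−1)/2
within-species pairs: mean, SE, min, max. The SE treats pairwise
distances as observations (SD/√n_pairs); pairs sharing a specimen are not
independent, so this understates uncertainty — it is a descriptive
summary in the style of library reports, not an inferential quantity.
With exactly one pair the sample SD is undefined and the SE is reported
as 0. Species with mean divergence strictly above 2% are flagged as
potential cryptic complexes; the 2% operator is strict, as is the QC
boundary ("longer than 500 bp" admits 501, "less than 1% Ns" rejects
exactly 1%).

## OTU assignment

Stage one is threshold single linkage on uncorrected distances: two
sequences share a cluster when a chain of pairs, each at distance ≤ t,
connects them. The default t = 0.022 (2.2%) is the published seed
threshold of the BIN (RESL) system; it is exposed everywhere as a
parameter. Single linkage deliberately over-merges — chains of borderline
pairs can link distinct tight groups.

Stage two refines each initial cluster of size ≥ 3 with Markov clustering
on a similarity graph with edge weights max(0, 1 − d/t): expansion power
2, inflation 2.0, self-loops at the maximum similarity, iterated to
convergence (max-norm change < 1e-8) or 100 iterations, with attractors
interpreted as sub-clusters. Clusters of size < 3 pass through; a
non-converged cluster is kept unsplit with a warning. Refinement is
**split-only**: merging across initial clusters is a plausible extension
(the chaining argument runs both ways) but is not guessed into the
default path — over-splitting is recoverable by lowering inflation,
whereas silent merges would corrupt the concordance audit. Inflation and
the size-3 guard are implementation choices; no published parameterization
exists to match.

All iteration orders are fixed by input order and nothing is randomized,
so partitions are bit-reproducible. Labels are `SYN:NNNN` (ordinal of the
cluster's first member) and never imitate real BOLD BIN URIs; input
`bin_label` fields are kept separate and comparable via a Rand index.

## Name reconciliation

Names are normalized before matching: whitespace collapsed, subgenus
parentheticals and parenthesized author/year strings removed, the first
alphabetic token after the genus taken as the epithet (even when wrongly
capitalized — case-agreement errors are a target of this step, which
means a genus followed immediately by a bare author surname would be
mis-read; such strings do not occur in species fields in practice),
trinomials truncated to the binomial, and placeholder epithets (sp., cf.,
nr., aff.) treated as genus-only, i.e. unidentified.

Resolution order: exact checklist match → local synonym table (synonym /
declared spelling variant / post-checklist description) → fuzzy spelling
match → tentative new. The fuzzy stage is restricted to the **same
genus** and accepts either Levenshtein distance ≤ 2 on the epithet or a
Latin gender-suffix swap (-us/-a/-um, -is/-e) on an identical stem;
gender swaps outrank edit-distance candidates, then smaller distance,
then checklist order. Restricting to congeners is conservative by
design: cross-genus fuzzy matches would auto-merge legitimate congeners.
Same-epithet/different-genus cases (changes of generic combination) are
surfaced as tentative-new with a hint in the evidence text — they need a
human. Checklist lookups are local files; no network service is
consulted, so a run is reproducible against a pinned checklist and
synonym table.

## Concordance audit and library assembly

Bin status uses named members only: one accepted species name →
concordant, several → discordant, none → unnamed. Unidentified specimens
therefore never create discordance; fully unnamed bins are reported
separately as possible new species records (optionally filtered to bins
with at least one record from a given country). A singleton bin is one
with exactly one specimen. Species status follows from the bins a
species touches: identifiable (all concordant), sharing (any discordant,
with partners listed), unplaced (no bin). Both classifications are
exhaustive partitions, asserted as identities in tests.

Species are always counted by **accepted** (post-reconciliation) name, so
a synonym pair collapses before concordance rather than fabricating a
two-name bin. Library inclusion = QC pass ∧ name resolving into the
checklist (match, synonym, or spelling variant) ∧ bin assignment; every
exclusion carries its full reason list, and rebuilding from the library's
own records is a fixed point. Only sequence-compliant records (length and
ambiguity, not naming) enter the distance matrix, mirroring the practice
of assigning OTUs only to standard-length barcodes; records excluded
there surface downstream with a NO_BIN reason.

The suborder roll-up buckets each record by the checklist suborder of its
accepted species; a record whose own higher taxonomy contradicts the
checklist placement goes to a `Not.assigned` row (a deliberate workflow
flag, not an error), as do unresolvable records whose claimed suborder is
unknown to the checklist. The totals row equals the column sums by
construction and is re-asserted in tests. Checklist rows lacking a genus
or epithet are skipped with a logged line number rather than aborting the
read: checklist files are hand-maintained and a single bad row should not
block an audit (the warning preserves the audit trail).

## Synthetic data generator

The generator emulates what the audit needs to be true of real barcode
data: each species' specimens form a tight haplotype cluster
(intraspecific p-distance ≈ 0.5% by default) and species are separated by
a floor (≥ 6%) comfortably astride the 2.2% threshold. Interspecific
divergence is guaranteed structurally — each cluster gets a private block
of diagnostic sites mutated away from a shared root — while intraspecific
variation accumulates at the remaining sites with transition bias
κ = ti/tv = 3, typical of insect mitochondrial COI. Realized extremes are
recorded in the truth ledger and asserted, not assumed. Defaults: 20
species, 3–8 specimens each, 658 bp, 10% unidentified specimens, 2
synonym pairs, 2 misspellings, 3 non-compliant sequences (one short, one
ambiguity-rich, one missing).

Artifact targets are drawn without overlap, and species in forced
sharing groups are excluded from the artifact pool: each planted fact
must have exactly one expected detector for the closed-loop ledger test
to be meaningful. One species is always blanked in full (when any
unidentified fraction is requested) so that an unnamed bin exists by
construction.

What the generator does **not** emulate: coalescent genealogy within
species, rate variation across sites or lineages, indels, contamination,
misidentification noise, or geographic structure. Passing tests on this
data show the machinery is correct under the separations the method
assumes; they do not show that real faunas satisfy those separations —
on real data, species violating the barcode gap will (correctly) surface
as sharing or high-divergence flags rather than being recovered.

## Problem sizes and runtime choices

The bundled study conditions run ~20 species / ~110 specimens / 658 bp,
chosen so the whole suite and the acceptance script complete in seconds
while still exercising every stage and artifact class; distance
computation is O(n²·L) and has been run comfortably at a few thousand
sequences. Full-scale checks against published data-release totals
require the corresponding public BOLD datasets to be downloaded locally
(`data/bold_releases/`); the toolkit itself never touches the network.

## Known limitations

- No internal aligner; equal-length input is a hard requirement.
- The MCL refinement never merges initial clusters (documented extension
  point).
- SE of intraspecific divergence ignores pair non-independence.
- Fuzzy name matching cannot see changes of generic combination; these
  remain tentative-new by design.
- Pairwise deletion may differ from platform-reported K2P values computed
  under other deletion schemes.
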