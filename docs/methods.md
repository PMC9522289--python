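# Methods

This note records the models, conventions, parameter defaults and known
limitations behind `coregscan`, in the spirit of a statistical-methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and sequence handling

All sequences are uppercase RNA over `{A, C, G, U, N}`; DNA input is
normalised (`T → U`).  Internal coordinates are 1-based inclusive, with
position 1 the first nucleotide after the stop codon — the convention used
in figure-style UTR maps.  BED6 export converts to 0-based half-open
(`start − 1`, `end` unchanged).  The ambiguity code `N` never matches any
motif position: scanning is deliberately conservative.  Scanning is
single-strand 5'→3' only, because the substrate is mRNA.

## PRE model

The canonical element is `UGUA·x·AUA` (8 nt).  The optimal human element
has `x ∈ {A, U}`, but published annotation practice also admits `C`; the
default position-5 alphabet is therefore `{A, U, C}`, with the narrow
reading selectable (`PREMotifConfig(canonical_pos5_alphabet={"A","U"})`).
Both readings genuinely circulate, so the choice is a config knob rather
than a constant.

"Non-canonical PRE" has no single operational definition in the
literature: the consensus ingredients are an intact `UGUA` core and an
AU-rich (or `AUA`-containing) region just downstream.  The default rule is
a 4-nt window immediately after the core with ≥ 3 of `{A, U}`; the
stricter "window must contain `AUA`" reading is available via
`noncanonical_require_AUA`.  Window length, AU minimum and the AUA switch
are all exposed because published non-canonical counts cannot be assumed
reproducible under any single parameterisation.  A canonical anchor is
never double-reported as non-canonical (canonical precedence at the same
anchor), but overlapping matches at different anchors are all reported.
An anchor whose downstream window would run past the 3' end is not
called.

Conservation profiling takes positionally aligned per-species motif
windows (gap character `-`), reports the fraction of species whose
degapped window still contains an intact canonical or non-canonical
element, and per-column modal-character identity among non-gap entries
(all-gap columns score 0).

## miR seed sites

The seed is mature positions 2–7 (extended 2–8).  Site types follow the
standard taxonomy: 8mer (complement of 2–8 plus an A anchor), 7mer-m8
(complement of 2–8), 7mer-A1 (complement of 2–7 plus an A anchor), 6mer
(complement of 2–7; detection exists but is off by default, matching the
practice of excluding 2–7-only matches from site maps).  Two conventions
are fixed deliberately: the A1 anchor is an A in the *target* regardless
of the miR's position-1 base, and G:U wobble is not allowed (perfect
complementarity).  Each seed-match locus yields one call under the
precedence 8mer > 7mer-m8 > 7mer-A1 > 6mer; `report_all_types=True`
drops the negative conditions and reports every matching pattern.

Site-inclusion criteria: 8mer and 7mer-m8 sites are kept for all families;
7mer-A1 sites only for families broadly conserved among vertebrates;
6mers are always removed.

## Expression and differential analysis

TPM is count / per-sample column total × 10⁶.  The column total is the sum
of miR counts in the matrix — the only total recoverable from a count
table.  The expression call is inclusive: TPM ≥ 10 in ≥ 2 reference (WT)
samples.  "Present" means ≥ 1 raw read in ≥ 1 sample of a condition.

Size factors are median-of-ratios: for each sample, the median over
all-nonzero rows of count / row geometric mean, computed on the natural
scale.  Rows containing any zero are excluded from estimation (standard
practice; a zero would annihilate the geometric mean).  Note that factors
are meaningful up to a common scale: scaling one sample's counts by *c*
multiplies its factor *relative to the others* by *c*, not the absolute
factor, because the row geometric means absorb part of the change.

The differential stage is a deliberately simple NB-Wald test, not a
DESeq2 re-implementation (no dispersion shrinkage, no Cook's outlier
filtering):

1. normalise counts by size factors;
2. estimate per-miR dispersion by method of moments from the pooled
   within-group variance, `α = (s² − μ) / μ²`;
3. stabilise as `max(α_miR, α_trend)` where `α_trend` is the median
   method-of-moments dispersion over miRs with normalized mean > 5, with
   a floor of 1e-8.  The maximum guards the Wald statistic against the
   severe underestimation of α that 3+3 replicates produce about half the
   time; with purely per-miR moments the test is anticonservative
   (empirical type-I error ≈ 0.11 at nominal 0.05 in our null
   simulations), while the stabilised version calibrates to ≈ 0.05–0.07.
   This mirrors the classic mean–variance-trend approach to dispersion
   estimation;
4. log2FC = log2((m_KD + ½) / (m_WT + ½)); the half-count pseudocount
   keeps all-zero groups finite and is negligible at moderate counts;
5. Wald z = log2FC / SE with a delta-method SE and a normal reference;
   two-sided p-values; BH adjustment over tested miRs only.  MiRs with
   overall normalized mean < 1 are excluded before testing and from the
   BH denominator.

BH adjustment itself is delegated to `statsmodels` (step-up with enforced
monotonicity, capped at 1).

## Co-regulation analyses

MiR name matching between expression sets and prediction lists is
case-insensitive with the `hsa-` prefix stripped, since the same miR
appears under both spellings in real tables.  The PRE–site gap is the
number of nucleotides strictly between the two intervals (overlap or
abutment → 0); "proximal" means gap ≤ 50 nt by default.  Edge-to-edge
distance is the most literal reading of "within 50 nt" — centre-to-centre
is not offered.  Pathway richness is |targets ∩ pathway| / |pathway| with
an upper-tail hypergeometric p-value and BH q-values across pathways; the
annotation table is user-supplied (GMT), never fetched live, because
database-version drift makes such counts irreproducible.

The bundled table `data/pum_kd_dem_table.tsv` is a published reference
dataset: DESeq results and host-gene/PRE annotations for the 21 miRs
differentially expressed on PUM1/PUM2 knockdown in SH-SY5Y neuronal cells
plus six non-differential controls.  It is treated as an input (desk
checks recount its rows); its DESeq-internal fold changes and p-values are
not recomputed here.

## qPCR

Technical replicates are averaged per (condition, biological replicate,
assay) before any biological statistics.  ΔCT = CT(target) −
CT(reference) per biological replicate; ΔΔCT per treated replicate is
measured against the mean control ΔCT; the reported fold change is the
mean over treated replicates of 2^−ΔΔCT with SEM across those replicates.
The construction makes the result invariant to any uniform CT shift and
anti-symmetric under swapping treated/control.

Reference stability is scored as `w₁·SD(CT across biological replicates)
+ w₂·|mean CT difference between conditions|` with default weights (1, 1),
ranked ascending.  The verbal criterion it operationalises ("most stable
across replicates, least variation between treatments") does not pin down
a unique formula; the weights are configurable for that reason.

## Synthetic data

`gen_utr` draws an i.i.d. background at a given GC content, plants motifs
at fixed coordinates, then *redraws* any background positions that create
accidental PREs or seed sites of the planted miRs (rejection sampling).
Truth sets are therefore exact and scanner tests can assert equality, not
containment.  Planted non-canonical windows are chosen to satisfy both the
AU-fraction and contained-AUA readings.  `gen_ortholog_set` applies i.i.d.
substitutions per species (species 1 is the unmutated base), optionally
protecting motif columns; alignments are positional with no indels.
`gen_counts` draws NB counts with variance μ + αμ² (the (mean, dispersion)
parameterisation, stated to avoid the (n, p) ambiguity), baseline means
log10-uniform over (0.5, 3.5) — roughly 3–3000 counts, a realistic miR
dynamic range — and planted effects with alternating sign, emulating a
mixture of up- and down-regulated miRs.  Defaults follow the study design:
3 replicates per condition, dispersion 0.1, 10% differential miRs at
|log2FC| = 1.5.

What the generators do *not* emulate: read-level artefacts (adapter
content, mapping multi-hits), miR-family cross-mapping, correlated library
composition effects, overdispersion heterogeneity across miRs, and indels
in ortholog alignments.  Passing tests therefore demonstrate correctness
of the implemented statistics under the stated model, not robustness to
those real-data complications.

## Problem sizes and numerical choices

Scanner–oracle equivalence is checked exhaustively over all 4⁸ = 65,536
8-mers (the complete motif space) and over seeded random sequences up to
500 nt; null calibration uses one simulation of 2,000 miRs (binomial SE
≈ 0.005 on the rejection rate); recovery checks use 2,000 miRs at the
design point.  Ties in BED output are broken by class name; ties in
stability ranking by assay name; dispersion floors at 1e-8; TPM requires
strictly positive library totals and errors on zero-total samples naming
the sample.

## Known limitations

* The non-canonical PRE rule is a parameterised convention; counts under
  different parameterisations can differ on real UTRs.
* The DE stage approximates, but does not reproduce, DESeq2 output;
  published per-miR fold changes/p-values from shrinkage-based pipelines
  will not match exactly.
* 3'-compensatory and wobble-containing miR sites are out of scope, as are
  context scores and binding-energy models.
* Pathway enrichment q-values depend on the supplied annotation table and
  target universe; only the richness ratio is database-version-free.
* Amplification-efficiency correction (Pfaffl) is not implemented; 2^−ΔΔCT
  assumes ~100% efficiency for target and reference.
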