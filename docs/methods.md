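# Methods

This note documents the models, defaults and design choices behind
`seedsafe`, and what the synthetic fixtures do and do not establish about
real data.

## Coordinates and alphabets

All local coordinates in reports and in-memory objects are 1-based
inclusive, matching how seed positions and UTR site positions are written in
the field; genomic intervals are BED-convention 0-based half-open, and
conversion happens only at the report boundary. DNA input is accepted
everywhere and normalized to RNA (uppercase, T→U), because UTR FASTA files
are DNA-alphabet. Minus-strand UTRs are stored in spliced-transcript
orientation; their genomic coordinates are retained solely for
deduplicating sites shared between transcript isoforms. Gene ids are
compared after stripping a trailing ".N" version suffix, since RefSeq and
Ensembl accession versions drift between annotation snapshots. Non-NM
(non-protein-coding) transcript ids are flagged in the log rather than
rejected; restriction to protein-coding sets is the caller's choice.

## Site discovery

The canonical scanner walks every A1 anchor (the target position opposite
guide position 1) and reports the single strongest applicable type at that
anchor, precedence 8mer > 7mer-m8 > 7mer-A1 > 6mer. This prevents one
physical site from being counted as three types. The A of the A1 anchor is
required to be a literal A regardless of the guide's first nucleotide, the
standard convention for A1-type sites. 6mer sites are excluded from
profiles by default (an `include_6mer` flag exposes them); 7–8mer types are
what standard canonical predictions report.

The relaxed scanner takes independent G:U and mismatch budgets per seed
length in the `"len;count,len;count"` mini-language, default
`6;0,7;1,8;1` for both. Seed length L uses guide positions 2..L+1. An
optional switch additionally forbids any defect at the anchor-adjacent
position 2; it is off by default because the positional restrictions of the
relaxed matchers this emulates are not precisely documented. Both scanners
do literal string matching on the transcript strand only.

## Energy model

Parameters are the published Turner 2004 37 °C nearest-neighbor set,
shipped as versioned TSV tables (`seedsafe/data/*turner2004.tsv`): the 6×6
stack matrix over {CG, GC, GU, UG, AU, UA} (so G:U wobbles stack), loop-size
initiation penalties for hairpin/bulge/internal loops with Jacobson–
Stockmayer extrapolation above size 30, NINIO asymmetry, affine multiloop
terms, duplex initiation (+4.10 kcal/mol) and the terminal-AU/GU penalty
(+0.50 kcal/mol).

**ΔGduplex** is a two-strand dynamic program over guide×window pairings:
stacks for adjacent pairs, a flat +1.0 kcal/mol penalty per 1×1 internal
mismatch (configurable `thermo.mismatch_penalty`), size/asymmetry penalties
for internal loops up to 3×3, and no multiloops — guide:target hybrids are
short. The duplex-initiation constant is excluded from reported values by
default because it cancels in every ΔΔG comparison; `include_init=True`
restores it, and with it the implementation reproduces ViennaRNA's
`duplexfold` (dangles off) exactly on perfectly complementary hybrids.
Values are clipped at 0 ("no stable hybrid"), which also covers the
degenerate single-nucleotide case.

**ΔGopen** is computed from a simplified Zuker fold of the local window
(site ± `thermo.flank`, default 50 nt): stacks, loop-size penalties,
multiloops, hard constraints to force site nucleotides unpaired. The fold
deliberately omits terminal-mismatch, dangle and special-hairpin terms;
this keeps the model monotone and transparent at the cost of absolute
accuracy, so the ViennaRNA cross-check for folding is directional
(sign/ordering) rather than quantitative, while the quantitative 0.5
kcal/mol oracle agreement is asserted on hybridization energies where the
two models coincide. dg_open = (unconstrained − constrained) MFE ≤ 0, with
0 meaning a fully accessible site.

**Sign conventions.** ΔΔG = ΔGduplex − ΔGopen, so burying a site in
structure makes its ΔΔG less negative (weaker), and lower ΔΔG means a
stronger site. Sites with ΔΔG below `thermo.threshold` (default −10
kcal/mol) are flagged likely functional; for an overexpressed guide the
effective threshold may be higher, which is why the flag is a label, not a
filter. The flank width is the knob to tune when calibrating against other
accessibility implementations.

**Loading asymmetry** sums the stacking energies of the `thermo.k_terminal`
(default 4) terminal pairs at each duplex end; a positive score (guide 5′
end less stable) predicts guide-strand RISC loading.

## Profile pipeline

Per guide and UTRome, in order: canonical scan → relaxed scan → drop
relaxed evidence not overlapping (≥1 shared nt) a canonical site — overlap
rather than identical spans, because the two matchers report different
window widths → ΔΔG and context-like scoring of the surviving canonical
sites → genomic deduplication (key: chrom, start, end, strand, site type;
representative keeps the smallest transcript id) → gene aggregation with
per-gene minima → expression marking from an externally supplied gene list
(no expression-threshold logic lives in the tool) → ranking ascending by
min ΔΔG with (min context score, gene id) as deterministic tie-breaks.

The context-like score is deliberately a simplified stand-in that preserves
ranking semantics, not a reimplementation of any published regression: a
site-type baseline (8mer −0.31 < 7mer-m8 −0.16 < 7mer-A1 −0.10 < 6mer
−0.04), a local-AU term over 30-nt flanks, a 3′-supplementary term for the
longest complementary run of guide positions 13–16 against the upstream
flank, and a position term rewarding proximity to either UTR end.
Coefficients are configurable.

Cross-species conservation consumes precomputed two-column ortholog tables;
a gene is conserved if any ortholog's UTR carries ≥1 site for the same
guide. The headline fraction divides by all off-target genes of the query
species, with unmapped genes counted separately (both directions are
reported). Summaries report both gene- and transcript-granularity counts so
either reading of a gene-level or transcript-level total can be recomputed.

## Variant design

Exclusions are annotations, never hard drops, so the full per-variant table
can always be produced. Position-8 variants are flagged because 7mer-A1 and
6mer recognition depends only on positions 2–7 — every such parent site
survives the mutation, which is the mechanism behind their extensively
overlapping profiles. CG-disruption is flagged when the substitution
removes a CG dinucleotide anywhere in the extended seed; on CpG-depleted
3′UTRs a CG-containing seed has systematically fewer matches, so losing the
CG inflates the off-target count.

`mean_ddg_shift` rescores the variant guide on the parent's own site
windows (variant − parent; the window-bound accessibility term cancels), so
a positive shift is off-target relief. Wobble-creating variants can shift
by ~0: G:U is a stacking pair in the energy model, which mirrors why
wobble variants retain silencing and detoxify poorly.

The ranking rule table is shipped as editable JSON
(`seedsafe/data/retention_rules.json`) because it encodes empirical
findings that may not generalize to every guide: position tiers 5–6 (best
retention) > 3/4/8 > 2/7 (disruptive), retention class order G:U wobble >
pyr:pyr > pur:pyr > pur:pur, and the reverse order as the detox key
(purine:purine discriminates best). Final ordering: non-excluded first,
then (retention rank, off-target count, shared fraction, name).

## Retargeting

The hexamer seed is scanned with G:U counted against the mismatch budget
(conservative — the wobble's class is recorded so ranking can still prefer
it). Region classification is majority-overlap with a CDS tie-break;
junction flags fire when an exon boundary lies strictly inside the window.
Assembled guides put U at position 1 (the conventional loading-biased 5′
nucleotide; configurable), the parent seed at 2–7 unchanged, and full
reverse-complementarity to the target flank at 8..L.

## Synthetic fixtures

The generator emulates mammalian 3′UTR collections: configurable length
distribution (default 300–1200 nt), GC fraction (default 0.45) and CpG
depletion (default 0.8, implemented as a first-order suppression of G after
C with the removed mass moved to C, preserving GC in expectation). All
randomness flows through one integer-only numpy Generator per fixture, so
output is byte-identical across platforms for a given seed. Site planting
rejection-samples the background and then verifies by brute rescan that the
canonical scan sees exactly the planted sites (guard nucleotides prevent a
planted weaker type from upgrading, e.g. a 7mer-m8 followed by A becoming an
8mer); fixtures that cannot be scrubbed cleanly are deterministically
resampled. Transcript-model fixtures give the same exact-truth guarantee
for ≤1-mismatch retarget windows.

What the fixtures do not emulate: real 3′UTR composition beyond first-order
GC/CpG statistics (no repeats, no conserved motif families, no isoform
structure), expression levels (the expression set is a random subset), and
orthology complexity (maps are 1:1 by construction unless specified).
Passing the planted-truth tests therefore demonstrates algorithmic
correctness — exact site discovery, scoring identities, pipeline plumbing —
not predictive accuracy on biological annotations, which depends on the
annotation snapshot and on calibration of the accessibility window.

## Acceptance-scale choices

The acceptance screen uses a 700-gene UTRome (250–600 nt) with 40 planted
off-target genes and a parent whose seed carries a CG dinucleotide at
positions 3–4 — the regime of a siSPOTR-style low-off-target trigger, where
both parent and variant profiles are sparse and the shared-off-target
fraction of retained variants concentrates well below 10%. Oracle
equivalence runs on 1000 random instances, planted recovery on 100
fixtures, and the CpG match-count comparison on 100 fixtures; these sizes
keep the whole screen under a minute on one CPU while leaving the binomial
margins wide.

## Known limitations

* The accessibility fold is MFE-based, not ensemble-based; partition-
  function accessibilities would be smoother and are out of scope.
* No temperature dependence or salt correction; all energies are 37 °C.
* The flat mismatch penalty makes all non-wobble mismatches equally costly
  in ΔGduplex; class-dependent penalties would refine variant relief
  estimates but would need calibration data.
* Antisense-strand matches, centered sites, bulged seed sites and
  3′-supplementary-only sites are not searched.
* Reported ΔΔG values depend on the window/flank convention; comparisons
  against other accessibility tools require matching those defaults.
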