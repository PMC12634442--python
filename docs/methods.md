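# Methods

## Scope and model

`leukotype` models the *evidence-integration* layer of a pediatric AML
molecular diagnostics workflow built on integrated whole-genome and
whole-transcriptome sequencing (iWGS-WTS). Upstream read alignment and
primary variant/fusion calling are out of scope: inputs are call-level
records (small variants with per-platform VAFs, breakpoint pairs with
gene/exon annotation, copy-number segments, ISCN karyotype strings,
normalized expression values). The package answers three questions per
case: *which findings are valid for reporting*, *what molecular
subtype defines the case*, and *how would other modalities have
performed on the same truth*.

A deliberate modeling choice throughout is that platform evidence is
three-valued: a numeric VAF, absence (the platform did not assay the
locus), or the distinct state `"insufficient"` (the platform looked but
lacked coverage/support to call either way). Several rules depend on
that distinction — an ITD with strong DNA evidence and *insufficient*
RNA coverage is reportable, while strong RNA evidence with a negative
(not merely uncovered) genome is only borderline.

## Reportability rules and their parameters

All thresholds live in `RuleConfig`; defaults are the clinical rule
set the package models.

| parameter | default | units | role |
|---|---|---|---|
| `wgs_vaf_min` | 0.05 | fraction | somatic P/LP reporting floor on the genome |
| `wts_rescue_vaf` | 0.25 (strict >) | fraction | RNA rescue of sub-floor AML drivers |
| `focal_cnv_max_bp` | 5 Mb (strict <) | bp | focal vs large-scale CNV split |
| `cnloh_min_bp` | 10 Mb | bp | copy-neutral LOH reporting floor |
| `sub50kb_bp` | 50 kb | bp | intragenic-review flag; PTD gain ceiling |
| `enhancer_window_bp` | 500 kb per side | bp | hijack candidate search window |
| `cyto_visible_min_bp` | 9 Mb | bp | G-band visibility at 400-band resolution |
| `subclonal_cnv_min_fraction` | 0.35 | fraction | clone-fraction floor for CNV detection |
| `complex_karyotype_min` | 3 | lesions | complex-karyotype rule |
| `overexpression_z` | 2.0 | SD | hijack-target overexpression call |
| `ase_skew_threshold` | 0.30 | fraction | DNA/RNA VAF skew for ASE calls |

Choices where the underlying practice gives a range, not a number:

- **RNA rescue is restricted to annotated AML drivers** and is strict
  (`> 0.25`), a literal reading of "exceeding 25 %". Evidence from
  exome sequencing never rescues: the rule set is defined over the
  genome + transcriptome pair.
- **Enhancer window 500 kb per side.** Observed hijack breakpoints
  cluster from a few kb to ~300 kb upstream and ~80–150 kb downstream
  of the target oncogene; 500 kb covers that range with margin while
  staying within a typical topologically associating domain scale. The
  window is configurable, and an in-frame exon junction always takes
  precedence over window logic. When several oncogenes qualify
  (HOXA-cluster genes overlap each other's windows) the candidate is
  attributed to the nearest locus.
- **Overexpression as z ≥ 2 on log1p.** Clinical practice judges
  expression plots qualitatively; a z-score against a reference that
  *excludes structurally rearranged cases* is the simplest monotone
  operationalization. log1p rather than log keeps zero-expression
  references finite; the call is invariant to uniform library-size
  rescaling up to the log1p offset.
- **ASE skew 0.30** makes the canonical (0.35 DNA, 0.97 RNA) example
  decisively mutant-skewed while keeping binomial VAF noise at typical
  depths well below the threshold.
- **Complex karyotype = ≥ 3 distinct clonal abnormalities**, the
  standard convention.
- **Biallelic TP53** = two P/LP hits: two variants, or one variant plus
  a 17p loss, or one variant plus cnLOH over the TP53 locus.

### ITD decision table

The FLT3-ITD combiner is total over the 4 × 4 (WGS × WTS) strength
grid: strong DNA ⇒ reportable regardless of RNA; strong RNA with
weak/absent/insufficient DNA ⇒ borderline; weak/weak ⇒ borderline;
every remaining cell (at most one weak signal) ⇒ not reportable by
sequencing. Borderline is an action state — it routes the finding to
orthogonal PCR fragment-analysis confirmation — not a soft negative;
the weak/weak and RNA-only cells are distinguished by rationale codes
because they have different failure modes (low clonal fraction vs
genome mappability of the duplicated repeat).

### KMT2A-PTD

A PTD call requires an intragenic gain < 50 kb in KMT2A; an in-frame
chimeric junction splicing exon 7/8 back upstream of exon 2/3/4
makes it reportable, otherwise the call is emitted as borderline
(mirroring the ITD logic: RNA coverage over the duplication may simply
be insufficient).

## Classification

Tiers are evaluated in fixed priority (DS-AML → WHO fusions → WHO
mutations → proposed class → AML-MR → rare/novel fusions → NOS); the
first match defines the case and everything else reportable becomes a
secondary driver. Two design points deserve note:

- **AML-MR is a diagnosis of exclusion.** It fires only when *no*
  driver-eligible fusion of any tier exists — a rare in-frame fusion in
  a complex-karyotype case defines the case, not the karyotype.
  Cooperating point mutations in non-class-defining genes (KIT, FLT3,
  CBL, ...) do not block AML-MR, matching how class-defining status is
  assigned in practice.
- **Refuted enhancer-hijack candidates never define.** A candidate
  whose target shows baseline expression is excluded from every tier;
  an *unvalidated* candidate (no expression data available) remains
  eligible on DNA evidence alone.
- Within a tier, ties break by pattern-list order, then alphabetically
  by 5′ partner — a determinism guarantee, not a clinical claim.

Pattern content (fusion pairs, wildcard rearrangements such as
`KMT2A::*` and `MECOM-r`, mutation patterns, MR gene/lesion lists)
ships in `data/classification_rules.yaml`. Tier membership of recently
described lesions is editable data; the engine only requires the tiers
to be disjoint.

Karyotype/CNV lesions are compared at chromosome-arm resolution using
a packaged table of approximate GRCh38 centromere positions; a loss
covering ≥ 80 % of a chromosome counts as a numerical change
(monosomy). Arm-level matching is the natural common resolution of
band-level karyotypes and bp-level segments.

## Synthetic cohorts and platform models

The generator emulates the study conditions the analysis assumes: a
~150-case cohort with subtype frequencies fixed at the published
breakdown (86:26:21:5:6:4:5 over 153), blast counts ~N(63, 20) clipped
to [5, 96] %, driver VAFs uniform on [0.20, 0.50], FLT3-ITD in ~12 % of
cases with strata drawn at the published proportions, cooperating
driver mutations in 60 % of cases, and ≥ 1 large-scale CNV in ~54 %.
Enhancer-hijacked oncogenes draw expression from a log-normal shifted
by +4 SD (log scale) over a baseline with σ_log = 0.5, so the default
z ≥ 2 call separates cleanly (a ~2 % tail of hijack cases is refuted by
its own draw — deliberate, honest noise).

Platform observation degrades truth independently per case:

- *cytogenetics*: CNVs require ≥ 9 Mb and clone fraction ≥ 0.35;
  each fusion type is missed with its published cryptic-miss
  probability (e.g. NUP98::NSD1 1.0, MECOM-r 0.67, RUNX1::RUNX1T1 0.0).
- *WGS*: variants require underlying VAF ≥ 0.05 and are re-observed as
  binomial draws at 60× (matching the study's ~61× genomes); CNVs
  require clone_fraction × purity ≥ 0.35 — which is what makes the
  dilution series (100 %/40 %/30 % purity) monotone and reliable at
  40 % but not below.
- *WTS*: fusion transcripts are seen with a 2 % miss rate; hijack
  rearrangements never produce one.

What the generator does **not** emulate: sequence-level reads,
breakpoint microhomology, clonal phylogenies, inter-lesion
co-occurrence structure beyond independent rates, and real expression
covariance across genes. Passing recovery tests therefore demonstrate
that the *rules and statistics* are implemented correctly under the
assumed sensitivity models — not that those models capture every
failure mode of real platforms.

## Numerical and I/O choices

- VAFs are fractions in [0, 1] internally; percent appears only in
  printed outputs. Bundle files carry VAFs at 4-decimal precision
  (below any clinical distinction; VCF float32 round-trips exactly).
- Coordinates are 1-based inclusive internally; BEDPE converts from
  0-based half-open on read. Readers reject malformed coordinates with
  file/line/rule errors rather than coercing.
- Indels are reduced to minimal representation on read and can be
  left-aligned through repeat tracts when a reference accessor is
  supplied; cross-platform matching uses the normalized key
  (case, chrom, pos, ref, alt).
- Detection tables follow the truth-denominator convention: `total`
  counts events established by the reference analysis; events seen only
  by the comparison platform are tallied separately and excluded from
  the denominator. Agreement rates use the symmetric union denominator
  and round to the nearest integer; diagnostic yield reports one
  decimal.
- Pearson r / OLS slope come from `scipy.stats.linregress`; constant
  inputs and n < 3 are errors, not NaNs.
- The ISCN parser covers an explicit grammar subset (numerical changes,
  del/add/t/i, markers, clone structure with metaphase counts,
  idem/sl); unsupported tokens degrade to `other` lesions with a logged
  warning, because heterogeneous clinical strings must not abort a
  cohort run, and only lesion classes — not exotic token syntax —
  feed the comparisons.

## Problem sizes

Statistical properties run at sizes chosen to make the assertions
sharp: miss-rate recovery uses a 1 200-case cohort (≈ 900 fusion
events, ≥ 30 per checked category) against exact binomial 95 % bounds;
the subtype-frequency check uses 10 000 cases against a 3-SD binomial
envelope; everything fixture-based is exact and instant. The whole
suite completes in a few seconds on one CPU.

## Known limitations

- Pathogenicity (P/LP/VUS) is consumed as input annotation; the package
  never re-curates variants.
- The classification pattern file covers the lesions named in the
  modeled study, not the full WHO 5th-edition rule content; it is data,
  intended to be extended.
- Germline analysis is limited to panel filtering; the 220-gene panel
  content is site configuration, not shipped.
- Gene loci and centromeres are approximate GRCh38 spans; adequate for
  500 kb windows and arm-level matching, not for bp-precise annotation.
- Relapse/post-cytotoxic context is carried on the case but does not
  alter any rule — no published rule depends on it.
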