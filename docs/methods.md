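# Methods

This note records the model this package implements, the conventions and
numerical choices behind it, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Coordinates and alleles

Positions are 1-based inclusive GRCh37 chromosome-6 coordinates, and the
telomere→centromere direction of the MHC class II region coincides with
increasing position, so no orientation switch is implemented anywhere.
Every distance is a plain subtraction `pos_b − pos_a` with no +1
adjustment; this is the convention under which the NCF worked example's
21,096-base sub-region reproduces exactly. Alleles are opaque categorical
tokens — single nucleotides for SNPs, arbitrary strings for
deletion-insertion polymorphisms (DIPs) — compared by exact string
equality, with no sequence normalization: DIP alleles are treated
categorically throughout. A missing call (`MISSING`, Python `None`) is
distinct from every token and is never coerced to one by any reader.

The marker map validates strictly increasing positions (duplicates are an
error naming both markers, never silently reordered) and requires each
amplicon's markers to form a contiguous run. Sub-region boundaries are
derived as the centromeric-most (maximum) marker position per sub-region;
the map records both marker membership and that boundary point, and the
NCF layer consumes the boundary points.

## Segregation phasing

Phasing is purely logical, two-layered:

1. **Per-marker transmission.** For each child and marker, every ordering
   of the child's unordered genotype consistent with both parents'
   genotypes is enumerated (MISSING is a wildcard). No consistent ordering
   is a Mendelian violation: the marker is excised for that family (set
   MISSING in its haplotypes) and flagged — families are retained, not
   aborted — with an additional silent-allele suspicion flag when a
   homozygous parent shares no allele with a fully typed child. When all
   consistent orderings agree on what a parent transmitted, that
   transmission is determined.
2. **Phase linkage.** Per parent, heterozygous markers are linked through
   children's gametes under a greedy minimum-switch rule. Orientation
   evidence lives in *components*: stretches linked by at least one child
   with determined transmissions at both ends. A link can arrive
   retrospectively, in which case the earlier component is merged —
   physically swapping its block when the joining parity is inverted, by
   majority vote when several children join at once (the minority are the
   recombinants). Surviving switches are reported as intra-family
   crossovers with the bounding marker interval; a gamete with more than
   one switch flags the family for review. Founder haplotypes come only
   from the parents, so child recombinants never enter the founder list.
   Components never linked to the main track are surfaced as
   linkage-ambiguous blocks — with a single child, or when every linking
   subject is heterozygous at both markers, no amount of processing can
   orient them, and guessing silently would fabricate phase.

**Residual ambiguity** (per-marker: every informative subject
heterozygous; or whole blocks) is resolved in a separate, explicitly
flagged step. The context rule assigns the allele of the group's dominant
sequence to the haplotype that follows that dominant sequence at the
nearest unambiguous flanking markers. The relevant dominant sequence is
chosen by overall agreement (≥90% across informative markers); a
haplotype that no longer matches any dominant globally — it crossed over —
falls back to the sequence it follows locally (the nearest three
informative markers on each side). "Flanking" has no distance cap. With no
usable context the assignment is deterministic (lexically smaller allele
to the lower haplotype id) and still flagged. Unrelated subjects
homozygous at every typed marker contribute one haplotype; heterozygous
unrelateds surface all heterozygous sites as ambiguities. Statistical
(likelihood/imputation) phasing is a non-goal.

## Dominant sequences, microvariation and fixity

The dominant sequence of a group is computed by a single
telomere→centromere sweep from the anchor (the centromeric end of the core
region, where all members are assumed to carry the group sequence). At
each marker the dominant allele is the modal allele among retained members
with non-missing calls. A retained member deviates where its non-missing
allele differs; the deviation is *isolated* iff the member matches the
dominant allele at its nearest non-missing informative marker on each side
(window of 1 — the minimal reading of "isolated"; configurable via
`isolation_window`). Isolated deviations are recorded as private
variation and do not cost retention; two or more consecutive deviations
are therefore always a crossover, and the member is removed at the first
of them, permanently — no re-admission after back-recombination, a
fidelity assumption since no such case is handled upstream. MISSING spans
never remove a member (identity is assumed across unsequenced intervals);
a member whose first non-missing marker after a gap deviates non-isolatedly
is removed at that marker, and the break-point layer widens its interval
accordingly. A marker where every retained member is missing carries an
UNDEFINED dominant allele and is excluded from all comparisons.

A modal tie forks the track into co-dominant branches, one per tied
allele, each swept independently over its member subset; members missing
or deviating at the fork join the branch they agree with at their next
non-missing marker, else the largest branch. The merged track reports
UNDEFINED wherever branches disagree and the sum of branch retained
counts. Fixity divides retained count by the *full original* group size,
so curves start at 1 and are non-increasing; a single tie-break in member
labeling aside, results are independent of input order.

## Break points, representation, tags and privates

A crossed member's interval runs from the position of its last non-missing
marker matching its (branch) dominant track to its first non-isolated
deviation; a member deviating at the anchor itself gets the configured
anchor boundary as its last-match position. Reference representation runs
the same scan against an external haplotype, tolerating isolated reference
mismatches (a cell line's private mutation) and following the matching
branch through co-dominant splits; it ends at the first non-isolated
mismatch or at a split matching neither continuation, and is declared
unresolvable when the reference is missing at more than half the analyzed
markers. A tag marker is an allele carried by every *retained* member with
a call and by no haplotype outside the retained set — the retained set,
not the full group, because crossed-over members sit on the non-carrying
side of the partition. Private variants are isolated deviations whose
allele occurs on exactly one haplotype in the cohort.

## NCF

`NCF_r = (crossovers_r / remaining_r) × (1e6 / distance_r)` per sub-region,
with `remaining_1` equal to the full group size (all members carry the
dominant sequence at the anchor) and `remaining_{r+1} = remaining_r −
crossovers_r`. A crossover is assigned to the sub-region whose interval
`(previous boundary, boundary]` contains its first-mismatch position, so
crossovers deduced in inter-region gaps count in the centromeric region; a
wide interval is assigned by its first-mismatch end, with the width
reported so localization uncertainty stays visible. The first sub-region's
telomeric boundary (anchor position) is a configuration value. The area
identity `ncf × distance / 1e6 = crossovers / remaining` holds exactly
before display rounding; tables carry full precision plus one-decimal
display values, and the plot draws bars on a to-scale axis so areas, not
heights, are compared. Rates in cM/Mb are out of scope: the number of
meioses behind any population recombinant is unknown.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes: ancestral
group sequences distinguished by unique core-marker patterns, erosion by a
single crossover per haplotype (the analysis tracks only the first loss of
the dominant sequence) placed uniformly over base positions strictly
between a sub-region's flanking analyzed points, donors drawn uniformly
from the background pool plus other groups' ancestors, isolated private
mutations (on the conserved segment, never at core markers, never adjacent
to a crossover or to each other, unique at the site cohort-wide),
amplicon-level missingness (sequencing fails by amplicon, not by marker;
the serologically typed core is exempt), and nuclear-family transmission
with optional intra-family crossovers. Everything derives from one seed.

Two deliberate idealizations matter for interpreting test results. First,
the donor at a planted crossover is required to differ from the ancestor at
the two markers immediately centromeric to the breakpoint, so every planted
crossover is observable exactly at its landing marker; this is what makes
the exact oracle equivalences (retained set = truth survivors; pipeline NCF
= truth-ledger NCF) provable rather than approximate. Real crossovers onto
locally identical sequence are detected late or not at all — the package
handles this (intervals widen; fixity is conservative) but exactness
claims then no longer apply, which is precisely the localization caveat of
the break-point layer. Second, the generator is not a coalescent: allele
frequencies, mutation ages and hotspot fine structure are not modeled, so
passing tests demonstrate correctness of the inference rules, not realism
of any particular population history.

Default conditions: four groups of 30/23/18/16 members plus a 40-haplotype
background pool (~160 chromosomes), eleven sub-regions of 10 markers each
over ~450 kb, per-sub-region crossover probabilities of 3%, and zero
mutation/missingness unless a scenario sets them — sized so the full test
battery (including a 50-configuration property sweep and n=500 parameter
recovery) runs in seconds. Exact per-sub-region crossover counts
(`crossovers_exact`) reproduce fixed scenarios such as the 3-of-16 /
21,096-base worked example deterministically.

## Known limitations

* Pedigrees are nuclear; multi-generation phase propagation is not
  implemented (each couple is phased from its own children).
* With two children a detected intra-family switch cannot be attributed to
  a specific child (the minimum-recombinant solution is not unique); the
  interval is still correct and the tie is broken deterministically.
* Co-dominant forks recurse but the merged track's UNDEFINED markers make
  downstream comparisons conservative near a split.
* Multi-reference triangulation of a break point across several external
  cell-line sequences is not formalized and left out.
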