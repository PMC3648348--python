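# Methods

This note documents the models and procedures implemented in `mpscaffold`,
the defaults and why they were chosen, and what the synthetic data do and do
not establish about real sequencing libraries.

## Synthetic genomes and repeat landscapes

`simulate_genome` draws an i.i.d. nucleotide background (default GC 0.42,
a mammalian-like composition) and superimposes interspersed repeats.
Repeats are organized in *families*: each family has a consensus sequence
whose length is drawn from the class's size range, and every copy is the
consensus with independent substitutions at the per-copy divergence rate.
Copies are placed uniformly at random without overlap (rejection sampling,
largest families first); the annotation therefore contains non-overlapping,
sorted intervals, and the per-class bp tally from the annotation is exact by
construction.

The default landscape (`MAMMALIAN_REPEAT_CONFIG`) emulates a rat-like
genome: ~49 % repetitive overall, with LINEs the dominant class at 18.9 % of
the genome and element sizes up to 8 kb, LTRs next, then SINE/DNA/other
classes filling the remainder. Class fractions are genome fractions;
element counts are derived as `fraction × G / mean_length`, so the realized
repeat fraction lands within a few percent of the target on any genome
size.

**Mappability model.** Real pipelines keep only tags with a single best
hit. The stand-in here is deterministic: a tag is non-unique iff it lies
entirely inside a repeat copy whose family has at least two copies *and*
whose divergence leaves less than one expected mismatch over the tag
(`divergence × read_length < 1`), i.e. the copies are indistinguishable at
tag resolution. With the default divergence of 2 % and 50 bp tags, repeat
copies are (just) distinguishable; configuring a family with divergence 0
creates genuinely unmappable regions, which is how the repeat-desert
behaviour is exercised. This binary rule ignores partial overlaps, paralog
mosaicism and mapping-quality subtleties.

## Contig layouts

`fragment_into_contigs` cuts the genome into `n` contigs separated by
exponential gaps (default mean 500 bp, minimum 1 bp) with a minimum contig
length (default 1 kb); contig bp + gap bp equals the genome length exactly,
and the true order/orientation is recorded as an AGP-like table. Gap
positions are uniform, independent of the repeat annotation — real
assemblies break preferentially *at* repeats, so synthetic contigs are, if
anything, harder to anchor than real ones of the same size.

For the scaffolding evaluation the layout uses contigs of at least 4 kb
(5000 contigs on 50 Mb, i.e. 4–15 kb pieces, the kilobase-range contig
sizes typical of NGS drafts) and short intra-scaffold gaps (exponential,
mean 200 bp). Contigs much smaller than ~2 kb capture too few tags for any
library to anchor them at the default link threshold, and a scaffolder can
then only leave them out or leapfrog them; that regime is a property of the
input assembly, not of the libraries under comparison, so the evaluation
excludes it by construction.

## Libraries and artifact classes

`simulate_library` emits exactly `n_pairs` mapped pairs. Outer spans follow
a truncated normal (default) or lognormal distribution parameterized by the
median and a spread, truncated to [2·read_length, 100 kb]; a spread of zero
gives fixed-size inserts for geometry tests. Tags face inward
(forward/reverse) after the mate-pair circularization convention is
normalized, so PE and MP libraries share one consistency rule. Artifacts:

- *duplicates* — exact coordinate clones of previously emitted pairs (PCR
  model; never near-duplicates),
- *remote* pairs — one tag repositioned uniformly ≥ 100 kb away, strands
  kept in the expected facing-in pattern (a chimeric junction joins two
  fragments in proper orientation),
- *inverted* / *everted* pairs — one or both tags flipped.

The seven study profiles (`paper_library_specs`) use median inserts of
170 bp and 3/5/8/15/20/25 kb, per-insert duplicate levels spanning 5–96 %
(pooling duplicate library preparations of one insert size), 10 % remote
and ~0.5 %/0.4 % inverted/everted pairs among non-duplicates, 50 bp tags,
and a spread of 10 % of the median — the study reports only medians, so the
spread is an explicit, configurable choice. `n_pairs` is scaled so the
qualifying subset reaches the requested physical coverage with a 25 %
margin.

## Classification and clustering

Classes are assigned with strict precedence: clonal (identical coordinate
signature of both tags; exactly one representative survives per signature),
then ambiguous (any non-unique tag — excluded from everything downstream),
then by geometry: facing-in pairs within the insert bounds on one
chromosome are consistent; facing-in pairs violating span or chromosome are
remote; one flipped tag is inverted; facing-out (wrong tag order) is
everted. Insert bounds default to the 1st–99th percentile of the library's
own span distribution, estimated from facing-in, same-chromosome, non-clonal
pairs under 100 kb. Inconsistent pairs cluster by single linkage requiring
both breakpoint sides to agree within `max_gap` (default: the insert
median); clusters below `min_support = 2` are dropped, separating recurrent
signals from single-pair chimeras.

## Coverage, complexity, normalization

Physical coverage sums outer spans of consistent pairs with spans inside
the library's p1–p99 band and divides by the genome length. The ~2 % tail
trim means a library's measured coverage sits slightly below `n·insert/G`;
this is intentional and matches the percentile-skipping convention.
`normalize_to_coverage` adds random qualifying pairs until the cumulative
span first reaches the target, so the subset overshoots by at most one pair
span and is deterministic under its seed.

The complexity curve subsamples pairs without replacement at each grid
depth (default 3 replicates, reporting Monte-Carlo SE) and counts distinct
coordinate signatures. `estimate_max_unique` fits `C(1 − e^(−n/C))` by
least squares with `C` bounded below by the observed unique count; if the
deepest point is within 10 % of the fitted plateau the library is called
saturated and `C` is returned, otherwise the observed count is returned as
a lower bound. The exponential-saturation form is a one-parameter choice
(equivalent to Poisson sampling of equally abundant molecules); libraries
with strongly skewed molecule abundances would saturate more slowly than
the fit assumes.

Expected coverage uses the *nominal* insert (170 bp, 3 kb, …) and a
configurable effective genome length. The default constant is 2.47 Gb, the
mappable chromosome-anchored fraction of a 2.51 Gb rat-like assembly; both
constants are exposed because repeat accounting uses the full assembly
length while coverage arithmetic uses the mappable fraction. The printed
per-insert coverage values these reproduce are internally consistent only
to about one unit in their last digit (the rows imply mappable lengths
between 2.469 and 2.475 Gb), which bounds the precision any single constant
can achieve.

## Repeat bridging

An element is bridged iff some qualifying pair (consistent class, span not
above the 99th percentile) has its left tag ending at or before the element
start and its right tag starting at or after the element end — full
containment with both tags in flanking sequence. This strict reading is
deliberate: only it explains why short-insert libraries bridge essentially
none of the long elements even at equal physical coverage. The
implementation sorts pairs by left-tag end and keeps a running maximum of
right-tag starts, answering each element in O(log n). Elements are binned
by their own annotated length in 500 bp windows per class. The closed-form
check `1 − exp(−n·max(0, I − L − 2r + 1)/G)` treats fragment starts as
uniform, which the simulator satisfies up to an O(span/G) edge correction.

## Scaffolding

`build_link_graph` turns inter-contig pairs (non-clonal, unambiguous) into
weighted links between contig ends: a forward-strand tag points out of its
contig's right end, a reverse-strand tag out of the left end; the per-pair
gap estimate is `insert_median − d_a − d_b` with `d` the tag-to-end
distances, and the edge keeps the median (floored at 1 bp for output, raw
value retained). Links below `min_support = 5` never make a join but are
retained for conflict detection, the way SSPACE evaluates its link-ratio on
raw tallies before applying the min-links threshold.

`greedy_scaffold` processes libraries from the smallest to the largest
insert; within a library, edges by descending support with lexicographic
tie-breaks (fully deterministic). A candidate edge joins two chains iff
both ends are free outer ends of different chains and no competing link at
either end — leading to a different partner — has raw support
≥ 0.7 × the candidate's (the best/second-best ambiguity rule; default ratio
0.7 and min-links 5 are the SSPACE-like defaults). Competing tallies are
aggregated over the current and all smaller-insert libraries. This
aggregation is the one deliberate extension beyond a per-library rule: when
contigs are much shorter than the insert, a large-insert library's
strongest links legitimately connect non-adjacent contigs, and only the
small-insert libraries' (individually weak) adjacency links identify the
contig in between; pooling raw tallies lets several libraries that agree
weakly veto a leapfrogging link that any single library would accept.
Smallest-first processing then fills junctions before long-range links can
claim their ends.

`evaluate_against_truth` partitions made joins into correct (adjacent in
truth with compatible traversal orientation), orientation errors (adjacent,
wrong orientation) and misjoins (everything else, including joins that skip
a contig); missed joins are unrealized true adjacencies. A globally
mirrored scaffold counts as correct.

`combination_sweep` normalizes every library once (seeded per library),
then scaffolds each requested combination independently from the same
contig set; `coverage_escalation` scaffolds one library at rising coverage
targets for the coverage-versus-combination comparison.

## Restriction maps and windowed comparisons

`in_silico_digest` cuts at the center of every occurrence of the
recognition site on either strand (SwaI, `ATTTAAAT`, palindromic, blunt:
cut index = site start + 4); `N` runs never match, and fragment lengths sum
to the sequence length exactly. The optical-map noise model — cut retained
with probability 1 − miss_rate (default 0.10), Poisson false cuts per bp
(default 0), multiplicative Normal(1, 0.05) sizing error, fragments below
2 kb unresolved — is a stated stand-in; no published error model accompanies
the maps it emulates.

`align_maps` is a global dynamic program over ordered fragment lists: a
block matches k ≤ max_merge fragments of A against m ≤ max_merge of B iff
the summed lengths agree within 5 % of the larger (merges absorb
missed/false cuts); skipped fragments cost 0.5 × their length on either
side. The reported `concordant_fraction` is matched A-bp over total A-bp,
so aligning a sub-scaffold against a whole-genome map is not penalized for
the genome it does not cover. Complexity is O(n·m·max_merge²), adequate to
a few thousand fragments.

`window_inconsistency` compares two scaffold arrangements of the same
contigs. Arrangement A is laid end to end as the reference frame; every
junction of arrangement B is consistent iff its two contigs are adjacent in
A with the same relative orientation and order (mirrored traversal is
consistent). Inconsistent links are counted once per contig pair,
attributed to the 100 kb reference window containing the midpoint of the
two facing contig ends, and split by whether both contigs share one
A-scaffold (*within*) or not (*between*) — so a B-junction that connects
two A-scaffolds is a between-scaffold change, and a reordering inside one
A-scaffold is a within-scaffold change.

## Problem sizes used in the checks

The bundled checks run at simulation scale chosen for completeness of the
phenomena rather than for realism of absolute numbers: bridging theory is
checked on a 10 Mb genome with 50 isolated elements per size across inserts
of 3/8/20 kb; the scaffolding comparison uses a 50 Mb genome, ~49 %
repetitive, 5000 contigs and all seven library profiles normalized to
8.5×; complexity recovery plants 10⁴ molecules sequenced to 10⁵ pairs;
map-concordance checks use ~1–1.5 Mb sequences (~60–75 SwaI fragments).
Qualitative orderings (which insert sizes bridge which element sizes; the
combination outperforming singles; PE joining almost nothing) reproduce at
this scale; absolute N50s do not transfer to any real genome.

## What passing tests do not show

The generator has no base-calling errors, no coverage biases (GC,
chimera-hotspots), no segmental duplications or nested repeat structures,
and mappability is binary. Real libraries' insert distributions are
skewed and sometimes multimodal, where the simulator is unimodal. The
scaffolder is a documented simplification of production tools: no
iterative re-estimation, no contig sequence overlap merging, no gap
closing. Cluster-level results (fractions of inconsistent pairs forming
clusters) depend on the unmodelled genome context and are reported as
measurements, not validated against external truth.
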