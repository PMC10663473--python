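# Methods

`rilforge` constructs and interrogates genetic maps from recombinant inbred
line (RIL) populations — near-homozygous lines produced by repeated selfing
from an F2, each a mosaic of the two parental genomes.  This note records
the models, the numerical choices, and the limits of what the built-in
simulator can demonstrate.

## The observable and the distance calculus

For a pair of markers the raw observable is **R**, the fraction of inbred
lines whose alleles at the two markers derive from different parents.  R is
computed over lines where both calls are homozygous; heterozygous and
missing calls are excluded pair by pair (residual heterozygosity in an F6
is only ~3%, and R is defined on fixed parental alleles).

Repeated meioses during inbreeding inflate R relative to the per-meiosis
recombination rate r ("map expansion").  For extensively selfed lines the
Haldane–Waddington relationship

    r = R / (2 (1 − R))

inverts the expansion; its fixed-point limit is R = 2r/(1 + 2r).  Distances
come from Haldane's mapping function under no interference,

    d = −50 ln(1 − 2r)   [cM]

For small values r ≈ R/2 and d ≈ 100 r.  The exact relative deviation of d
from the linear 100·R/2 is (1 + R)(1 + r) − 1 ≈ 1.5 R, i.e. ~1.5% at
R = 0.01, vanishing linearly as R → 0.  A population of ~500 lines
resolves at best R = 1/500, hence r ≈ 0.001 and d ≈ 0.1 cM — the
resolution floor reported by `scripts/acceptance.py`.

Maps are assembled by accumulating adjacent-interval distances along a
given order (no multipoint smoothing).  Intervals with R ≥ 0.5 (unlinked
or mis-ordered neighbors) are flagged and capped at `max_interval_cM`
(default 100) rather than clamped silently; intervals scored in fewer
than `min_informative` lines (default 20) are flagged `low_info`.

## Crossover counting

Along an ordered map, a change between the two homozygous classes counts
one event and a change between homozygosity and heterozygosity counts ½,
so a line's total estimates the crossover count per transmitted gamete.
Missing calls are skipped and the flanking informative calls compared —
the minimum-event count at marker resolution; two exchanges inside one
marker interval are invisible and counted once.  A run of H contributes
only its flanking half-events (A…H…B totals 1).

Matched early/late generation lines are compared breakpoint by
breakpoint.  A breakpoint between two homozygous flanks is fixed and must
reappear in the descendant.  A breakpoint against a heterozygous flank
follows Mendelian resolution of that flank: retained heterozygous with
probability ½, resolved to the non-recombinant or recombinant homozygous
configuration with probability ¼ each — independent of map distances,
because the resolution is a single-locus event.

## The single-seed-descent simulator

The simulator is the test substrate for every other module.  Meiosis has
no interference and no obligate chiasma: per gamete the crossover count on
a group of length L cM is Poisson(L/100), positions are i.i.d. uniform,
and the starting homolog is a fair coin.  Lineages advance from a fully
heterozygous F1 by one selfed offspring per generation.  Defaults used
across the test suite mirror the study populations: F6–F7 readout,
200–400 lines (2,000 where breakpoint-class frequencies are estimated),
7 linkage groups, genotyping error 1%, missing data 2% where noise is
modeled.  Genotyping error replaces a call with a uniformly chosen
different state among A/B/H; missingness is applied first and
independently.

Segregation distortion is modeled as per-locus viability weights
(w_A, w_H, w_B): each generation an offspring survives with probability
equal to the product of the weights at its genotypes, rejected offspring
being redrawn from the same parent.  This is a stand-in mechanism chosen
to produce signed-χ² signatures, not a claim about the biology of RIL
attrition.

Two properties of the model worth stating plainly:

* **Junction counts are only approximately Poisson.**  The per-line count
  of visible crossovers accumulates over generations, and the time a
  region stays heterozygous (hence exposed to *visible* recombination)
  correlates across intervals and generations.  At F6 on a 120 cM group
  (mean ≈ 2.2 events/line) the variance/mean ratio is ≈ 1.10 and the
  non-recombinant fraction exceeds e^−μ by ≈ 0.02.  At a few hundred
  lines this is indistinguishable from Poisson; at 5,000 lines it is
  resolvable.  The simulator was cross-validated against the independent
  Haldane–Waddington closed form (R → 2r/(1+2r) at g = 20), so the
  dispersion is model truth, not an implementation artifact.
* **Seed hygiene.**  Advancing a stored population one generation
  (`self_once`) requires an RNG stream independent of the one that built
  it; re-seeding with the same value replays the first generation's
  meiosis draws and spuriously preserves every heterozygous site.

### Translocation signatures

`inject_translocation` changes only the *claimed* chromosome labels of a
distal segment; simulated transmission always follows the linkage group.
The bundled study genome (`translocation_demo_genome`) additionally places
a recombination-suppressed block (markers at essentially identical cM) at
the junction, because around a real translocation breakpoint recombinant
gametes are unbalanced and not recovered — that suppression is precisely
what makes cross-chromosome marker pairs show R = 0.  The translocated
tip's physical coordinates are placed at the start of the partner
chromosome, as a real moved segment's would be, so genetic-vs-physical
collinearity visibly degrades for the affected group.

## Principal-component marker ordering

Markers encoded +1/−1/0 (parent-1, parent-2, het-or-missing) across the
lines are projected by SVD of the markers-by-lines matrix — smaller and
faster than a marker-distance matrix.  Each line (column) is centered to
remove allele-frequency offset; no scaling, since ±1 is already a common
scale.  Component signs follow a fixed convention (largest-magnitude score
positive) so repeated runs are bit-identical.  Default k = 3 components
for the interactive display.

Linkage groups are single-linkage connected components of the graph
joining reliably scored pairs with R below `link_threshold` (default 0.2,
uncorrected), labeled largest-first.  Within a group, ordering is
deterministic seriation: a minimum spanning tree over corrected cM
distances (Euclidean coordinate distance, scaled by 10⁻⁶, breaks ties;
pairs with R ≥ 0.5 get a 300 cM stand-in; a uniform 10⁻⁹ offset keeps
zero-distance edges in the sparse MST), whose diameter path is the
backbone; off-path markers are inserted beside their nearest backbone
neighbor on the side adding the least path length, nearest first.  The
orientation of a group is fixed by correlation with physical positions
when annotation exists, else lexicographically.  The off-curve distance of
an interior marker — its distance to the segment through its two ordered
neighbors — is the marker-quality readout: error-laden markers drift off
the thread.  This seriation is a deliberate, parameter-free replacement
for iterative principal-curve fitting and is documented as replaceable.

The 3-D export is a single self-contained HTML file (inline data and
viewer code, no network fetches) with one trace per chromosome label and
marker ids on hover; label subsets support pairwise linkage-group views.

## Physical-scaffold map construction

The second mapping route seeds the order from assembly coordinates, flags
markers whose position is inconsistent with the minimum number of
recombination events, builds a scaffold map without them, and reinserts
each at the event-minimizing gap, scanning all groups genome-wide so
markers from misassembled scaffolds can change chromosome.  The
inconsistency score ("excess") is the drop in total events when the
marker is removed; the default flag threshold is an excess above 2 events
— one genuine double crossover is possible, recurrent ones concentrated
on one marker are not.  Placement scoring uses homozygous calls only: a
residual het between identical homozygous flanks would otherwise charge a
spurious double-event to a correctly placed marker.  Ties at reinsertion
break by claimed physical proximity, then smallest index.  The
flag/reinsert loop runs to an order fixed point, at most 5 rounds.

## Distortion scan and pseudolinkage blocks

Per marker, the two homozygote counts n1, n2 are tested against 1:1:
χ² = (n1 − n2)²/(n1 + n2), carrying the sign of n1 − n2 (positive =
parent-1 excess).  Heterozygotes are excluded — the populations of
interest are near-fully inbred.  The 1% critical value at 1 df is 6.635;
no multiple-testing correction is applied to the scan (the marker count
is reported so users can apply their own).

Pseudolinkage detection collects, per chromosome pair, the markers
participating in at least one reliably scored cross-chromosome pair with
R ≤ R_max (default 0), forms maximal runs tolerating one interrupting
marker, and reports block extents, the qualifying-pair count, and the
minimum cross-R, largest block first.  Independent chromosomes sit at
R ≈ 0.5, so with ≥ 200 lines a zero-R cross pair essentially never arises
by chance.

## Trait placement

A two-state Mendelian trait is scanned as a pseudo-marker: per mapped
marker, the fraction of informative lines whose phenotype-implied allele
disagrees with the call.  With dominance on, heterozygous genotypes score
concordant with the dominant class; off, they are skipped.  The scan
minimum marks the determinant; the interval runs to the nearest flanking
markers with discordance above the minimum, markers tied at the minimum
co-segregate, and a minimum at a group end yields a flagged one-sided
interval.  Genotype/phenotype generation offset (e.g. genotyped F7,
phenotyped F8) is not modeled; the mis-scoring rate absorbs it, and
`discordant_lines` lists candidate mis-scorings at the chosen marker.

## What the simulations do not show

The generator emulates Poisson meiosis, selfing, uniform error/missing
rates, viability distortion and label-level structural conflicts.  It
does not model crossover interference, segmental duplications or paralog
cross-hybridization, batch- or plate-structured error, allele-specific
call failure, residual outcrossing, or real assembly misjoins beyond
relocated labels.  Passing tests therefore certify the algorithms under
the stated model, not performance on any particular array dataset.
Problem sizes in the suite (hundreds of markers, hundreds of lines) are
chosen as the smallest giving the statistical power each check needs;
real populations with 15,000–18,000 markers run through the same code
paths, with the pairwise-R matrix (O(M²)) the main memory consumer.
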