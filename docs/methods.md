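# Methods

## The inference model

A homologous gene quartet is the unit of inference: a duplicated gene pair
(p1, p2) born at an old polyploidy event, plus each copy's ortholog (o1, o2)
in a second genome or parental diploid, born at a later divergence.  Under
no conversion the additive tree is ((p1,o1),(p2,o2)) and the four-point
condition — the pairing with the smallest sum of pairwise distances names
the unrooted topology — returns the orthologous grouping.  Gene conversion
overwrites one paralog with the other, shrinking d(p1,p2) below the
orthologous distances and flipping the four-point call to the paralogous
grouping.  With four taxa the four-point condition coincides with
neighbor-joining on additive distances, and unlike a tree build it can be
recomputed exactly under bootstrap resampling, which is why the detectors
use it directly.

Ties in the four-point comparison resolve to the orthologous (no-conversion)
topology: every tie-break in the package is chosen so that noise pushes
toward *not* calling conversion.

## Detectors

**WCV-I** computes raw NG86 synonymous distances (below) for all six pairs,
requires the point-estimate topology to group the paralogs, then resamples
codon columns of the four-way alignment with replacement (default 1000
replicates) and re-derives the topology from per-column NG86 contributions.
A call needs bootstrap support ≥ 0.95 (configurable).  Synonymous distances
are used because synonymous sites are the least selectively distorted record
of when two sequences last shared history.

**WCV-II** uses amino-acid identities over shared non-gap columns: the
paralog pair must be *strictly* more similar than both role-matched ortholog
pairs, and the four-point topology on amino-acid p-distances must also group
the paralogs.  It is deterministic and, because closely related genomes keep
ortholog identities very high, stricter than WCV-I in practice; the suite
checks the call-count ordering on the reference simulation.

**PCV** classifies each nucleotide column of the quartet alignment as
*supporting* (paralogs share a state that breaks the orthologous pattern:
p1 = p2 while p1 ≠ o1 or p2 ≠ o2), *opposing* (p1 = o1, p2 = o2, p1 ≠ p2) or
*neutral* (everything else, including gaps), scores them +1 / −2 / 0, and
finds maximal-sum segments by a linear max-subarray scan with recursive
masking so several disjoint tracts can be reported.  A segment is reported
if it spans > 10 nt, contains ≥ 3 supporting sites, and its score beats a
permutation null (column scores shuffled, default 1000 rounds, α = 0.05;
the null maximum is computed once per quartet and shared by its segments).

Kadane endpoints necessarily sit on supporting columns, which biases raw
segment bounds inward and lets isolated background-identity columns attach
outward, so boundaries are refined in two steps: (i) a log-likelihood
changepoint pass over four column classes (supporting / opposing /
paralog-mismatch / neutral) whose inside/outside frequencies are estimated
from the candidate tract itself versus the rest of the alignment; (ii) the
final boundary is the midpoint of the uninformative gap between the
outermost supporting site and the first paralog-mismatch site beyond it —
the maximum-entropy estimate of where the tract edge lies in that gap.  On
the reference simulation this places ~90 % of both boundaries within ±6 nt
of the planted tract edge, close to the information-theoretic limit set by
the informative-site spacing (~2–3 nt at the reference divergences).

**Donor assignment** uses the allotetraploid pattern's diploid outgroups:
the acceptor is the tetraploid copy lying closer (nucleotide p-distance,
restricted to the converted segment for PCV) to the *other* subgenome's
diploid than to its own; the donor is the other copy.  If neither or both
copies satisfy the criterion the call is ambiguous, and within-genome (LCT)
quartets are always ambiguous absent an explicit outgroup.

## NG86 rates and Jukes–Cantor correction

Synonymous site counts follow Nei–Gojobori (1986): each position of a codon
contributes (number of synonymous single-nucleotide changes)/3, with changes
to stop codons never counted as synonymous; differences between codons are
averaged over all minimal single-step pathways, skipping pathways through
stop codons and re-admitting them only if every pathway is blocked.  Gapped
or ambiguous codon columns are dropped pairwise.  Raw proportions Ks = Sd/S
and Ka = Nd/N are corrected with the one-parameter Jukes–Cantor formula
−(3/4)·ln(1 − 4p/3); p ≥ 0.75 is reported as NaN with a saturation flag,
never an exception.  The implementation is validated against an independent
brute-force enumeration oracle to 1e-9 on random codon alignments.

Block dating uses the *corrected* Ps by default: raw NG86 Ks is bounded by
the p-distance scale (< 0.75), so old-polyploidy blocks — whose corrected
median synonymous distance is around 0.8–0.9 — are only separable from the
recent-divergence mode on the corrected scale.  Both metrics are emitted and
the choice is configurable.  Default event windows (corrected scale):
recent divergence [0, 0.35), old duplication [0.5, 1.2]; these are
config-level values a user should review against their own Ks distribution.
Block medians use the lower of the two middle values at even counts, a
deterministic tie rule.

## Chaining and overlap resolution

Filtered hits are deduplicated to unique anchor points per chromosome pair
and chained by a dynamic program maximizing anchor count under strict
monotonicity (either sign on the second genome) and a per-step gap cap of
50 intervening genes on both chromosomes.  Competing chains are resolved
greedily: accept the best chain, remove its anchors, re-chain the remainder,
stopping below 4 anchors.  "Best" is ordered by anchor count, then smaller
total gap, then the lexicographically smallest chain of *sorted gene-id
pairs* — a key chosen to be invariant under swapping the two genomes, so
detection is exactly symmetric — then parallel before inverted.  An
exhaustive enumeration oracle reproduces the output on random 20×20
instances.  A block score (sum of −log10 e-values) is reported but never
used for filtering; block significance is the ≥ 4-anchor rule.

## The simulator and its reference conditions

Sequences evolve by a Poisson process of substitution attempts (rate 1 per
site per time unit) along the quartet tree; an attempt picks one of the
three alternative bases uniformly, attempts that would create a stop codon
are redirected uniformly to a non-stop alternative, and amino-acid-changing
attempts are accepted with probability `omega`.  `omega = 1` (the default)
is a pure Jukes–Cantor nucleotide process; `omega < 1` switches on the codon
model with purifying selection, and `omega_predup` can relax constraint on
the pre-divergence (post-duplication) branches for studying Pn/Ps-ratio
contrasts.  Conversion is an instantaneous unidirectional overwrite — the
donor is never altered — either of the whole CDS or of a window whose
length is drawn from 30–300 nt and snapped to codon boundaries so a chimeric
boundary codon can never introduce a stop.  No indels are simulated, so
emitted quartet sequences are mutually aligned as-is; the genome-set
simulator adds colinear gene order, gene losses, segmental inversions,
spurious homology hits and inflated gene families, with e-values/bit scores
computed deterministically from simulated identity (no search is run).

Reference conditions (the generator defaults): per-lineage depths of 0.4
expected substitutions/site to the duplication and 0.1 to the divergence
(pairwise synonymous divergences ≈ 0.8 and 0.2 — an old-polyploidy-scale
paralog pair against a moderately diverged congeneric ortholog pair), gene
lengths 300–600 codons, conversion at 75 % of the post-divergence interval
(observable conversions in extant genomes are biased recent, since older
ones re-diverge), and a 0.8/0.2 whole/partial mix at planted fraction 0.2.
These were fixed from an analytic margin calculation: at these depths the
four-point margin of a converted quartet is ≈ 2·0.75·0.1 = 0.15
substitutions/site, roughly 4 standard errors of the summed distance
estimates at the median gene length, which is what makes a 0.95-support
bootstrap call reachable at ≥ 0.90 sensitivity while the null stays below
the 0.05 call rate.

End-to-end runs (and the pipeline examples) set `omega = 0.3`: under strict
neutrality, paralogs at the deep-duplication depth fall to ~35 % amino-acid
identity and the 40 % identity filter correctly removes every quartet, which
would make an end-to-end test vacuous; with purifying selection — the
regime real proteomes occupy — the same quartets retain ~60 % identity and
pass, as their real counterparts do.

What passing these simulations does *not* show: the generator has no indels
(so alignment-error robustness is exercised only by the filter thresholds),
no rate heterogeneity across sites or lineages, no tandem duplications, no
pericentromeric structure, and uniform conversion placement (so the
terminal-bin fold test is validated for calibration, not for power on a
planted spatial gradient).

## Positional and functional statistics

Duplicated genes are binned by distance from their chromosome-arm terminus
(default 1 Mb bins); absent a centromere table, arms are approximated by the
chromosome midpoint and results are flagged `approx_arms`.  The fold
increase is the mean conversion rate of the first k occupied bins (default
1) over the mean of the rest; significance comes from uniformly permuting
per-bin rates (default 10^6 rounds) with the +1/(N+1) correction, which
keeps the p-value valid and strictly positive.  Note a structural floor: an
exchangeable series of B bins cannot yield p below ~1/B for a first-bin
statistic, whatever the effect size — with 20 bins a 3× first bin settles
at p ≈ 0.05, and the calibration suite asserts exactly that exchangeability
value.  Homogeneity across chromosomes and per-category functional
enrichment both use the Pearson chi-square without continuity correction
(scipy), with low-count categories flagged (default: fewer than 5 annotated
duplicated genes) and a Benjamini–Hochberg column emitted alongside the raw
p-values, which remain primary.

## Problem sizes used in validation

The reference benchmarks use 100 planted whole conversions against 400 null
quartets (WCV), 200 planted partial conversions against 200 null (PCV), 200
allotetraploid-pattern conversions (donor assignment), 500 null bin series
at 10^4 permutation rounds (calibration), and a two-genome set of 2×200
genes at planted fraction 0.2 run through the complete pipeline twice to
check byte-identical manifests; together they run in about a minute on one
CPU.  These sizes give binomial standard errors comfortably inside the
asserted margins (e.g. ±0.03 on a 0.9 sensitivity at n = 100).

## Known limitations

* NG86 with pathway averaging overestimates deep synonymous distances
  (corrected Ps > 1 is possible); dating windows are calibrated on the same
  scale, so this is consistent within the pipeline but not comparable to
  maximum-likelihood (codeml-style) estimates.
* PCV boundary precision is limited by informative-site spacing; at low
  paralog divergence (< ~0.25 mismatches/nt) ±6 nt recovery is
  information-theoretically out of reach regardless of scoring.
* Donor assignment needs diploid outgroup orthologs; within-genome
  duplication quartets stay "ambiguous" by design.
* The two-genome pipeline layout covers the within-genome duplication
  pattern end to end; the allotetraploid pattern is supported at the API
  level (quartet assembly, detection, donor assignment, simulation) but the
  genome-set orchestrator does not lay out a four-genome tetraploid dataset.
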