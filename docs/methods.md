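# Methods

## Capture model

A random-shear library is modeled as N independent inserts of fixed length I
whose starts are uniform over the S = G − I + 1 placeable positions of a
linear genome of length G (multi-chromosome genomes: the chromosome is chosen
proportional to its own placeable count, then the start uniform within it).
An interior cluster [a, a+L) is contained by an insert starting at s iff
a + L − I ≤ s ≤ a, giving w = max(0, I − L + 1) favorable starts and the
binomial capture probability p = 1 − (1 − w/S)^N, evaluated with `log1p` /
`expm1` so tiny w/S at large N stay accurate. Edge effects — clusters within
I bp of a chromosome end have fewer favorable starts — are deliberately not
modeled in the closed form; the Monte-Carlo estimator (`monte_carlo_capture`)
uses the very same placement rule as the library simulator (a shared internal
draws both) and is the reference when edge effects or variable insert sizes
matter. `clones_for_capture` inverts the closed form as
ceil(ln(1−p)/ln(1−w/S)) with an integer boundary check, so the returned N is
exactly minimal.

Assumptions: uniform shearing (no cloning bias), fixed insert length in the
analytic layer, independence across inserts and across clusters. Expected
captured clusters is therefore a sum of per-cluster probabilities — exact in
expectation, though cluster counts are not independent events.

## Insert inference and candidate ranking

End reads are treated as interval evidence only: a clone maps (BOTH_ENDS)
when its two surviving end alignments share a chromosome, lie on opposite
strands facing inward, and imply a span inside a plausibility window,
default 20–300 kb — the upper bound reflecting how large random-shear BAC
inserts can get. The insert is then [leftmost start, rightmost end). When
repeats produce more than one alignment per end, the highest identity wins,
then the longest alignment, then the leftmost position; a clone with one
mapped end is ONE_END_ONLY, a clone with none UNMAPPED, and everything else
DISCORDANT. Coordinates are 0-based half-open internally; the 12-column
alignment dialect on disk is 1-based inclusive with minus-strand hits encoded
by reversed subject coordinates.

Containment is strict interval inclusion. Candidates for an intact cluster
are ranked by min(left flank, right flank) descending with clone-id
tie-breaks: a capture-ready clone should carry the cluster plus context on
its weaker side, since regulatory elements flank the biosynthetic genes.
Clusters touched only partially are reported PARTIAL_ONLY with clones ordered
by overlap.

## Componentization and the screen

Component detection is greedy and seed-driven: repeatedly take the globally
most intense unassigned feature at or above the 5×10⁶ threshold as a seed and
absorb every unassigned feature within 10 ppm of the seed m/z and 2.5 min of
the seed RT, from any sample and at any intensity. Two interpretation choices
are worth making explicit. First, the 2.5 min retention-time window is read
as a maximum deviation from the seed, not a full width, matching the
single-number style of the ppm criterion. Second, the intensity threshold
gates seeding and presence but not membership, so weak signal in a control
sample still joins a component and can defeat "uniqueness" — the conservative
direction for a discovery screen. Ties in seed order break by (lower m/z,
earlier RT, sample id), making the clustering order-deterministic; each run
asserts feature conservation (assigned + discarded = input) and that member
spreads respect both tolerances.

TIC normalization scales each sample by (mean TIC)/(sample TIC), which
preserves within-sample ratios exactly; presence calls are made on raw
intensities, requiring every replicate of a strain (biological and technical
pooled) to clear the threshold — the strictest replicate rule, chosen because
a compound genuinely unique to one strain should survive it while sporadic
noise should not. The uniqueness filter keeps components present in the
target and absent in all controls; the empty-vector strain and the other FAC
strains are weighted identically as controls. The decoy FDR reruns the
filter once per control strain as pseudo-target against the remaining
controls, excluding the real target so a genuine unique compound cannot
inflate the null; the estimate is mean pseudo count / max(1, target count),
the max guarding the empty-result division. The known-compound monitor
reports per-compound detection fraction and the coefficient of variation
(sample SD over mean, ddof = 1, the replicate-measurement convention) of
TIC-normalized intensity, flagging CV > 0.5 or non-detection.

## Dereplication

Formulas are parsed as plain Hill notation (no parentheses or isotopes);
monoisotopic masses sum the most-abundant-isotope atomic masses from the NIST
table shipped with pyteomics, the package's sourced and versioned mass table.
Adducts default to the positive-electrospray set [M+H]+, [M+Na]+, [M+NH4]+,
[M+K]+ with shifts computed as full cation masses (electron deficit
included). The ppm error is signed and referenced to the theoretical m/z —
the convention under which a reported "0.3 ppm" match is measured against a
theoretical exact mass — making it exactly reversible. Database matching at
tolerance t is monotone by construction (a hit at t is a hit at any t' > t).
MS2 confirmation pairs observed and predicted fragment m/z greedily by
ascending |ppm error|, one-to-one, scoring matched/predicted; fragment
*prediction* (bond-breaking enumeration) is out of scope — predicted masses
are an input list.

## Synthetic-data generator

The generator's defaults are the reference study conditions. Genome: one
30 Mb chromosome (a configuration choice — a mid-sized Aspergillus assembly —
not a measured value) carrying 56 non-overlapping clusters with lengths
uniform on 30–80 kb and ≥10 kb gaps, placed by drawing uniform slack offsets;
a capacity precheck (n·(max size + gap) ≤ G) rejects infeasible requests.
Library: 7,680 clones of fixed 100 kb; end reads are exact 800 bp edge reads
at 100.0 identity (no sequencing-error model — the pipeline under test is
interval logic, not alignment quality), with one-end dropout producing the
"one end only" class downstream.

Metabolome: 15 strains (one empty-vector control + 14 FAC strains), 3
biological × 2 technical replicates, 12 background compounds shared by all
strains and planted unique compounds per designated strain. Planted compounds
take real molecular formulas from a built-in fungal-metabolite table and are
observed as [M+H]+ ions, so the dereplication stage has genuine masses to
recover; background beyond the table gets synthetic masses uniform on the
m/z 200–1500 acquisition range. Observed m/z is the true value times
(1 + ε), ε ~ N(0, 1 ppm) — consistent with sub-ppm mass accuracy at 35,000
resolution; RT is uniform on 2–45 min with N(0, 0.2 min) jitter, small
against the 2.5 min window. Intensities are a per-compound base level,
log-normal with median 8×10⁷ and log-scale 0.5, times a per-measurement
log-normal factor (σ = 0.2): the generator emulates compounds that are
reliably detected and quantified — as the planted compound and the dozen
consistent known compounds were — so base levels sit an order of magnitude
above the 5×10⁶ componentization threshold. Dropout, when enabled, removes a
compound for a whole biological replicate (both technical injections
together), since technical replicates re-measure the same extract.

What the generator does not emulate — and what green tests therefore do not
show about real data: chromatographic peak shapes and RT drift beyond iid
jitter, isotope envelopes and in-source fragments (each compound is a single
feature), ionization suppression and cross-sample intensity correlation,
cloning bias and repeat-induced mis-mapping, and incomplete telomeric
assembly (unplaced clones surface only as UNMAPPED).

## Problem sizes and numerical choices

The acceptance computation uses 20 replicates of the full-scale design
(30 Mb, 56 clusters, 7,680 clones) and reports the median captured-cluster
count; containment is evaluated by binary search over sorted insert starts.
Monte-Carlo cross-checks use 10,000 libraries at full scale (vectorized,
chunked placement draws) and 3-standard-error agreement bands; brute-force
oracle comparisons run on 100 random instances of ≤100 clones / ≤20 clusters
and ≤60 features, where exhaustive enumeration is cheap and exact equality is
asserted. Seeds are fixed everywhere; identical seeds give bit-identical
outputs, which the CLI exploits to make reruns byte-identical (configuration
hash and seed are stamped in every output header, results are computed fully
in memory before any file is written).

## Known limitations

The closed-form capture model ignores insert-size variability and edge
effects (use the Monte-Carlo path for those); the screen has no RT alignment
across runs beyond the window, no isotope-envelope deconvolution, and no
fold-change statistics (the filter is strictly presence/absence); the decoy
FDR is an empirical mean over as many pseudo-targets as there are controls,
so its resolution is limited by the control count; dereplication assumes
singly-charged positive-mode ions and cannot distinguish isomers sharing a
formula.
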