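# Methods

## Break geometry and coordinate conventions

The package models an enzyme that cleaves duplex DNA leaving a 2-nt 5′
overhang whose midpoint is a twofold rotational symmetry axis (the dyad
axis). Coordinates are 0-based internally. A cleavage event is anchored at
`dyad_left`, the coordinate of dyad-relative position −1; the axis lies
between `dyad_left` and `dyad_left + 1`. User-facing dyad-relative positions
are numbered …,−2,−1,+1,+2,… with no position 0: −k maps to
`dyad_left − k + 1` and +k to `dyad_left + k`.

Library chemistry is modeled after end-capture protocols in which the 5′
overhang is filled in, an adaptor is ligated, and the read is assigned to
the nucleotide immediately next to the adaptor. A DSB at `dyad_left = p`
therefore yields a top-strand read at `p` and a bottom-strand read at
`p + 1`. This operational convention is what produces the +1
strand-to-strand cross-correlation offset that the polarity test checks;
the underlying fill-in geometry could also be described as a 2-position
overlap, but the read-assignment convention above is the one the analysis
chain is built on, and we do not attempt to re-derive the wording.

## Synthetic library generator

`BiasModel` holds strictly positive multiplicative preference factors over
dyad positions −W..−1,+1..+W × {A,C,G,T} plus a global exponent `strength`;
a site's weight is `(∏_p w(p, base_p))^strength`. A model is *rotationally
symmetric* when `w(p, b) = w(−p, complement(b))`; `BiasModel.symmetric_gnatnc()`
builds the canonical symmetric 6-bp signature (G at −3, A at −1 / T at +1,
C at +3, ×10 per matching base). Events are drawn with replacement with
probability proportional to site weight; each event is a nick with
probability `p_nick` (split evenly between strands by default — no strand
preference is assumed for nicks).

Read multiplicity per cleaved end is Poisson with mean `reads_per_event`,
with a single draw shared by the two ends of a DSB so that pure-DSB
libraries are exactly strand-balanced. Incomplete fill-in is modeled as a
one-nucleotide inward shift applied independently per read with probability
`f_partial` (top p→p+1, bottom p+1→p); this is the simplest mechanism that
creates false enrichment immediately adjacent to true positions. Background
is Poisson per position per strand at `background_rate`, emulating the flat
map of a catalytically dead control.

Dataclass defaults are neutral (`p_nick=0, f_partial=0, background_rate=0,
reads_per_event=1`); study conditions are always set explicitly. The test
and acceptance conditions use: a 10-kb circular reference at 50% GC (a
plasmid-scale substrate with no external sequence needed), 1,000 events for
the polarity check with background at 1% of the per-position signal density
(0.001 reads/position/strand), 3,000 events with the ×10 strength-2
symmetric signature for composition recovery, and `f_partial = 0.3` for the
artifact-filter check — a deliberately harsh misassignment rate, well above
what a mostly complete fill-in reaction produces. These sizes keep the full
suite in seconds while leaving sampling noise far below the asserted
margins.

What the generator does *not* emulate: sequencing errors, fragment-length
and adaptor effects, mappability, chromatin or protein cofactors, and any
nick/DSB kinetic interconversion. Passing tests therefore demonstrate that
the analysis chain recovers what the generative model embeds — polarity,
composition bias, artifact geometry — not that real libraries are free of
other confounders.

## Strand maps

Raw maps count read 5′ ends per strand per position. RPM normalization
multiplies by 10⁶ / total mapped reads, where the denominator is the
library total on both strands *before masking* — the standard reading of
"per million mapped reads"; masking excludes positions from statistics
without changing the denominator, so masking and normalization commute.
Masked positions are serialized as absent bedGraph intervals, keeping
"no signal" distinct from "excluded".

Smoothing uses the symmetric Hann taper `w(n) = 0.5(1 − cos(2πn/(M−1)))`,
M = 21 by default, normalized to unit sum; circular topology wraps (and
conserves the track total exactly), linear topology truncates the kernel at
the edges and renormalizes. Smoothing is display-only: polarity, peaks and
composition always run on unsmoothed values.

## Polarity test

The cross-correlogram entry at lag k is the Pearson correlation between
`top[i]` and `bottom[i+k]` over all unmasked pairs (wrap-around on circular
references, overlapping segment on linear ones); raw cross-covariance is
available as an option. The polarity offset is the argmax over lags
−10..+10, with exact ties broken toward the smallest |lag| and then the
positive sign. Masking applies to this test exactly as to every other
statistic; the correlation window is the whole (unmasked) reference.

## Peak calling and artifact filtering

Peaks are strand-specific threshold exceedances — every unmasked position
whose strand value strictly exceeds the RPM threshold — matching how
nucleotide-resolution break maps are scored at plasmid (>3,000 RPM) and
genomic (>10, >15 RPM) scales. The fill-in artifact filter removes a
top-strand candidate at x when `top[x] < top[x−1]` and a bottom-strand
candidate when `bottom[x] < bottom[x+1]`: the inward-shifted artifact always
sits next to a stronger true position as long as misassignment stays below
50%. The comparison direction is isolated in one predicate so the opposite
reading can be swapped in if a different library chemistry shifts reads
outward. "Top 50 peaks" selection is by score with ties broken by position;
we assume score ranking rather than hand curation.

## Composition, logos, symmetry, motifs

Bottom-strand peaks are reoriented (reverse complement, adaptor-adjacent
base at −1) before pooling, so the two windows of one DSB are exact reverse
complements and a fully symmetric detection yields an exactly symmetric
matrix. The logo statistic is background relative entropy: with a
background determined by a single G+C fraction
(`q_A = q_T = (1−gc)/2, q_C = q_G = gc/2`), per-position information is
`R = Σ_b f_b log₂(f_b / q_b)` (with 0·log 0 = 0) and letter height is
`f_b · R`. The GC fraction can be a genome average or a local override
around the mapped sites when the two differ substantially. This choice of
correction is ours; only the background-GC idea is inherited from the
experimental convention. The symmetry score is the mean absolute deviation
from `f(p, b) = f(−p, complement(b))` over p > 0 — 0 for perfect rotational
symmetry, and also 0 for a featureless uniform matrix (it measures
asymmetry, not signal strength).

Motif scanning is exact degenerate IUPAC matching on the top strand, all
overlapping matches reported, wrap-around included for circular references;
an option also scans the reverse complement, which is moot for
self-reverse-complementary patterns such as GNATNC/CNTANG. Anchored
profiles average strand-specific signal in windows centered on anchor
positions and return the per-anchor matrix for heat-map rendering.

In simulation, increasing substrate complexity (longer references, fewer
events per site) sharpens the recovered information at determinate
positions, qualitatively matching the observation that sequence signatures
strengthen with more complex substrates.

## Binding and kinetics

Equilibrium occupancy of one monomer site is the hyperbola θ = P/(K_d+P);
a cleavable site with two independent monomer sites is dimer-bound with
probability θ². K_d fitting uses this hyperbola by default — the "apparent
K_d" convention for band-shift titrations — with the ligand-depletion
quadratic available because probe concentrations (~0.1 nM) are not far
below sub-nanomolar K_d values.

Two-phase association fits, `Y(t) = A₁(1−e^{−k₁t}) + A₂(1−e^{−k₂t})`, are
multi-start least squares with k₁ ≥ k₂ by convention and a degeneracy flag
when the phases are not separable (rate ratio < 3 or either amplitude < 2%
of the total). They are descriptive summaries of biphasic trends, not
estimators of mechanistic rate constants.

The kinetic-trap simulator is the minimal mass-action embodiment of
dispersed high-affinity monomer binding limiting dimer assembly:

    S + P  → SP      2·k_on·S·P          SP  → S + P    k_off·SP
    SP + P → SP₂     boost·k_on·SP·P     SP₂ → SP + P   2·k_off·SP₂
    SP₂    → cleaved k_cut·SP₂ (t ≥ 0)
    D + P ⇌ DP       k_on / k_off

The statistical factors (2·k_on first binding, 2·k_off losing one of two
protomers) make the k_cut = 0 equilibrium coincide exactly with the
independent-two-site closed form, which the tests verify to 1e−6. Cleaved
product keeps both protomers covalently attached, so committed protein is
not recycled. Substrate pools carry an `add_time`; negative times are a
pre-equilibration phase (assembly on ice) during which k_cut is forced to
0, and positive times inject substrate mid-course for order-of-addition
experiments. With k_cut ≫ k_off and decoys in excess, the first-added
substrate shows a fast phase (pre-assembled dimers firing) followed by a
slow exchange-limited phase, and outruns a later-added competitor; raising
the second-binding on-rate (`dimer_boost`, the artificial-dimerization
analog) increases the fast-phase amplitude. Whether dimer assembly proceeds
by capture from solution or one-dimensional sliding is not modeled — the
scheme is agnostic. Integration is LSODA with rtol 1e−10 / atol 1e−12,
piecewise between addition breakpoints; protein and DNA pools are conserved
to ~1e−8 relative. Stochastic per-molecule simulation, religation and
supercoil relaxation are out of scope.

Units throughout: concentrations nM, time minutes, k_on /nM/min, k_off and
k_cut /min; break-yield arithmetic uses 1 nM × 1 µL = 1 fmol.

## Numerical and degenerate-input conventions

- Strand maps reject negative unmasked values; RPM normalization of an
  already normalized map is an error, as is a zero-read library.
- The polarity test requires nonzero variance on both strands; nick-only
  libraries raise rather than returning an arbitrary lag.
- K_d fits with all-zero fractions and two-phase fits with fewer than five
  points are rejected; non-convergence raises instead of silently
  defaulting.
- Logo backgrounds of GC 0 or 1 are rejected (infinite relative entropy).
- Hann windows must be odd and ≥ 3.
- Integration failure or negative concentrations raise, never clamp.

## Known limitations

Peak scoring has no width, merging or FDR machinery by design. The
composition analysis assumes independent flanking bases when comparing
recovered fractions to generator weights; on real genomes, k-mer
correlations and chromatin context break this. The kinetic scheme is the
simplest that yields biphasic kinetics and order-of-addition asymmetry —
real reactions include nick intermediates, religation and possibly
topoisomerase-like turnover that it deliberately omits.
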