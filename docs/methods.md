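# Methods

## The system being modeled

A methanol-responsive polyacrylamide-based graft copolymer carries short
"anchor" oligonucleotides along its backbone. Programming the polymer with
**catcher strands** — probes whose 3′ adapter domain is complementary to
the anchor — turns it into a sequence-selective macroligand: targets
hybridize to the probes' binding sites in homogeneous solution, methanol
addition precipitates the polymer together with the bound (and
matrix-encapsulated) targets, and redispersing the pellet in clean buffer
allows targets to be released either non-selectively (denaturation) or
selectively by **toehold-mediated strand displacement (TMSD)**: a release
strand nucleates at the probe's single-stranded release site (toehold) and
branch-migrates through the binding site, evicting the target while
remaining on the probe. Capture selects for the binding-site sequence;
TMSD release selects a second, independent time for the release-site
sequence. This *dual selection* is why the released pool is essentially
free of nonspecifically adsorbed molecules: they fail the second
selection and stay in the pellet.

`cslkit` implements the computational side of this workflow: probe/library
design, off-target screening, a stochastic model of the catch-and-release
statistics, depletion-experiment evaluation, and the polymer conformation
arithmetic. Wet-lab concerns (synthesis, precipitation conditions,
fractionation instrument operation, sequencing library prep and alignment)
are out of scope; sequencing data enter as coverage tracks and count
tables.

## Library design (`csl_design`)

**Tiling.** A target region is tiled with contiguous, non-overlapping
windows of exactly `binding_len` (default 38 nt, the published probe
architecture); a trailing remainder shorter than one window is dropped, so
every binding site has uniform length and hence comparable hybridization
behavior. The bound strand alternates window-to-window
(sense, antisense, …) so that for a denatured duplex target both strands
are captured and sense–antisense re-hybridization is sterically blocked;
`alternate=False` and `start_strand` cover single-stranded use cases. A
`step` parameter permits gapped or overlapped tiling; the default is
contiguous. The starting strand is sense-binding by default — an arbitrary
but fixed convention, exposed as a parameter.

**Domain order.** Catchers are written 5′-`[release][binding][adapter]`-3′:
the adapter at the 3′ end hybridizes the polymer-grafted anchor, leaving
the release toehold at the free 5′ end, maximally accessible to the
release strand.

**Binding-site orientation.** A *sense-bound* catcher carries the reverse
complement of the sense segment (it hybridizes the sense strand); an
*antisense-bound* catcher carries the sense segment verbatim (the
complement of the antisense strand). Coordinates are 0-based half-open on
the sense strand throughout (BED convention).

**Release sites.** Toeholds must stay single-stranded in the reaction, so
candidate sites are drawn from a seeded generator and rejection-sampled
against every design target: a candidate is accepted when its longest
shared substring with each target, on either strand, is at most 3 nt. For
realistic targets this bound is usually unsatisfiable — a transcript of a
few hundred nucleotides already contains nearly all 256 possible 4-mers on
its two strands — so the threshold relaxes by one after a fixed number of
failed draws (200). The procedure is deterministic given the design seed
(each catcher derives its own generator stream from the seed and the
catcher name, so inserting or removing one catcher does not reshuffle the
others) and in practice settles at 5–7 nt of maximal complementarity for
a 10-nt toehold against kilobase targets, well below the length needed for
stable pairing under stringent annealing. Default `release_len` is 10 nt
(typical TMSD toeholds are 6–10 nt); `release_len=0` omits the domain, and
such libraries can only be recovered by denaturation — asking for their
release strands is an error.

**Uniqueness.** Binding sites must be pairwise distinct across the whole
library ("unique binding site" is a library property, not a per-probe
one); collisions are a hard error listing the offending pairs, since two
identical probes silently halve the effective library and confound release
selectivity. Design output order is deterministic (target id, then
coordinate), so order sheets are byte-identical across runs.

**Off-target screen.** Every binding site is compared against every
background transcript with an exact longest-shared-substring search on
both strands; transcripts sharing at least `k` contiguous bases
(default 16) are flagged, excluding each catcher's own design target. The
default k reflects that shorter shared stretches are unlikely to survive
stringent annealing; it is a parameter, not a melting-temperature model.
The canonical hit this screen exists for is a readthrough transcript that
embeds a targeted gene's sequence and is therefore co-captured.

## Shared-substring search (`seqcore`)

The longest exact shared substring is found by binary search over the
match length with exact k-mer set membership (the k-mer set is built on
the shorter sequence; actual substrings are stored, so there are no hash
collisions), O((|a|+|b|)·log min(|a|,|b|)). Ties resolve to the smallest
start in the first sequence, then in the second; when both strands are
searched, the forward strand wins exact ties and minus-strand positions
are reported in forward coordinates. The implementation is verified in the
test suite against a quadratic dynamic-programming oracle (including
tie-breaks) on sequences up to 200 nt.

Sequences are strict A/C/G/T; degenerate IUPAC codes are rejected at
construction because designed sequences end up on synthesis order sheets,
where ambiguity is a silent error.

## Pulldown simulation (`pulldown_sim`)

Capture and release are modeled as independent Bernoulli events per
molecule (binomial sampling per member): the experiments being emulated
report ensemble efficiencies, not kinetics, so no rate equations are
fitted. Defaults are those measured efficiencies:

| parameter | default | meaning |
|---|---|---|
| `e_capture` | 0.88 | per-molecule capture probability, ssDNA targets |
| `e_capture_ds` | 0.898 | capture probability for duplex members |
| `e_release` | 0.90 | TMSD release probability per captured molecule |
| `p_nonspecific` | 0.02 | nonspecific pellet retention of non-targets |
| `p_nonspecific_release` | 0.0 | release probability of nonspecifically captured molecules |
| `min_match` | 20 nt | contiguous complementarity required to call a member targeted |

ssDNA and duplex capture efficiencies are kept as separate parameters even
though they are statistically compatible, because they come from different
experiments; duplex members are single entries with the duplex
probability — sense/antisense re-hybridization competition is folded into
that number, not modeled mechanistically. `p_nonspecific_release = 0`
encodes the observed purity of the released pool (99.8 ± 0.5% free of
non-targets); it is exposed for sensitivity analysis. Members known to
adsorb above the average (the published mixture had one such strand) can
be given per-member overrides via `p_nonspecific_overrides`; no default
override is set because no quantitative level was reported.

A member is *targeted* when either orientation of its sequence shares at
least `min_match` contiguous bases with some binding site; the best match
decides which catcher captures it, which in turn decides whether a
supplied release-strand subset frees it. Closed-form expectations
(`expected_fractions`) accompany the sampler: depletion = e_capture,
non-target retention = 1 − p_nonspecific, end-to-end yield =
e_capture·e_release = 0.792 at defaults, and released-pool purity as a
function of the relative abundances. Monte-Carlo pooled fractions converge
to these within binomial standard errors (tested at 10⁵ molecules per
member over 20 seeds).

All randomness flows through explicit integer seeds; capture and release
consume distinct, independently derived generator streams, so a fixed seed
gives byte-identical reports.

## Depletion evaluation (`depletion_eval`)

**Relative base count.** r_i = (treated_i/N_t)/(control_i/N_c) per base,
where the library-size factors N are total depths summed over *untargeted*
transcripts only — removing a few very abundant genes changes the total
read count, and normalizing on the untouched remainder is what keeps
untargeted profiles at r ≈ 1. Positions with control depth below
`min_cov` (default 10) are masked as missing rather than produced as
infinities or noise-dominated ratios. An optional centered moving-average
window smooths the trace (default 1 = off; the exact published smoothing
is not specified). Per-transcript efficiency is 1 − mean(r_i) over a
chosen interval, clipped to [0, 1].

**TPM efficiencies.** TPM_g = 10⁶·(count_g/length_g)/Σ rates. Because a
TPM column always sums to 10⁶, depleting abundant targets inflates every
other gene's TPM; the per-target efficiency estimator therefore first
rescales the treated column by the median treated/control ratio over a
reference set of untargeted genes, then reports 1 − rescaled ratio,
clipped to [0, 1]. On multinomially resampled synthetic libraries at 10⁶
reads the estimator recovers the simulated depletion fraction within 0.02.

**Supporting statistics.** Expressed-gene counts use a strict `> 1 TPM`
threshold. Correlation QC computes Spearman and Pearson coefficients on
log10(TPM + 1) (pseudocount configurable), excluding the depleted targets
so the intended signal does not dominate the agreement measure. The
two-sample t-test is the pooled-variance (Student) form — not Welch — so
that n = 3 + 3 gives df = 4, matching how such comparisons are
conventionally reported; zero-pooled-variance input returns t = 0, p = 1
for equal means and a signed infinite t for unequal means.

Coverage I/O is bedGraph (0-based half-open) with dense per-base arrays
internally.

## Polymer calculations (`polymer_calc`)

V_app,h = (4/3)·π·R_h³ and ρ_app,h = M_w/(V_app,h·N_A), with nm / µm³ /
g·cm⁻³ as canonical units and explicit conversions (source data mix nm,
µm³ and MDa; the unit-audit test computes the water fraction for both
published polymer variants and any conversion slip moves it by orders of
magnitude). Note the volume is cubic in R_h as dimensional analysis
requires — some printed forms of the relation omit the exponent — and the
implementation is consistent with the published V_app,h and plausible
coil radii. The coil water fraction is 100·(1 − ρ_app,h/ρ_solution) with
ρ_solution = 1.0 g/cm³.

The conformation exponent ν of R_g = K·M^ν is fitted by ordinary least
squares on log R_g vs log M over a fractionation series (≥ 3 points,
strictly increasing masses), returning ν with its standard error; ν ≈ 0.33
indicates a hard sphere, 0.5 a statistical chain in a theta solvent, with
branched compact coils in between. Instrument-level fits of raw
light-scattering data are out of scope; published ν values are treated as
reference numbers, since the underlying series are not redistributable.

Anchor capacity is plain stoichiometry: o anchors per chain of mass M
(g/mol) give (o/M)·10⁶ nmol hybridization sites per mg polymer;
utilization is measured/theoretical × 100. The nominal 20 nmol/mg for a
~100-anchor chain and the fractionation-derived ≈ 15.3 nmol/mg
(o ≈ 130, M_w = 8.47 MDa) are genuinely different computations — nominal
synthesis stoichiometry vs measured chain composition — and both are
exposed without forcing a reconciliation.

## Synthetic fixtures (`fixtures`)

The generators emulate the *structure* of the real inputs, not their
biology: uniform-composition random transcripts (the design and evaluation
logic is composition-agnostic, so GC/codon realism would add nothing the
tests could detect), a 10-member ssDNA mixture with lengths uniform in
20–190 nt and pairwise shared substrings capped at 15 nt so membership
classification cannot cross-react, fragment libraries with lengths uniform
in 150–700 nt (the size range of sheared cDNA libraries) and an abundance
model in which 3 "dominant" genes jointly hold 50% of the molecule mass —
a few high-abundance transcripts consuming a large share of reads, the
regime targeted depletion exists for. The exact dominant share is not a
published number; 50% across three genes was fixed once as a realistic
value. Fragment length is clipped to the transcript and the start drawn
uniformly from the admissible range, so long transcripts get uniform
pileups and short ones whole-length fragments.

`simulate_depleted_coverage` removes each fragment overlapping a
binding-site interval by ≥ `min_match` (20 nt, the simulator's
classification threshold) with probability e, giving matched
control/treated coverage pairs. Because fragments extend up to one
fragment length beyond a targeted region, per-base depletion is ≈ e at the
region center, decays with distance from the region, and vanishes beyond
the maximum fragment length — the distance-decay signature of fragment-
level capture. Default 10⁵ fragments per fixture keeps every simulation in
seconds while leaving Monte-Carlo errors far below the tested tolerances.

What passing these tests does *not* show about real data: no sequencing
error, mappability, PCR or fragment-GC bias, no isoform structure, no
partial-hybridization efficiency gradient across a fragment. The fixtures
validate the estimators' arithmetic and the simulator's selection logic,
not the wet-lab efficiencies themselves, which enter as parameters.

## Problem sizes and determinism

The default verification workloads — 10 members × 10⁵ molecules × 20
seeds for the dual-selection statistics, 10⁵ fragments over two 4-kb genes
for the coverage profiles, 10⁶ multinomial reads for the TPM recovery —
were chosen so the full suite and the reproduction script each run in
about a minute on one CPU while keeping sampling error an order of
magnitude below the tolerances being checked. Every stochastic component
takes an explicit integer seed and derives independent named substreams
(design vs capture vs release vs fixtures), so all outputs are
reproducible byte-for-byte.

## Known limitations

* No hybridization thermodynamics: binding is a length threshold, not a
  melting model; probes are not Tm-optimized.
* No TMSD kinetics: release is a probability, not a toehold-length → rate
  curve.
* Off-target screening is exact-match only (no mismatches/gaps); a
  near-complementary off-target with no 16-nt exact stretch is invisible.
* The per-base profile treats fragments as the unit of capture; within-
  fragment position effects are not modeled.
* Read alignment and transcript quantification are consumed as tables,
  never computed.
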