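# Methods

This note documents the models, parameter choices and numerical decisions
behind `scnpair`, in the order the pipeline runs them.

## Pairwise alignment

Global alignment uses the three-state Gotoh recurrence (match/mismatch,
gap-in-query, gap-in-reference) under affine gap costs: a gap of length L
costs `gap_open + (L−1)·gap_extend`, i.e. the opening penalty covers the
first gapped column. Defaults are BLOSUM62 with gap open 10 and extend 1 —
conventional protein-alignment settings; the original analysis named only
the alignment programs, not their parameters, and reported that identity
scores were robust to the program choice, so moderate parameter sensitivity
is expected and the scheme is fully configurable (including loading any
NCBI-format matrix).

The dynamic program is vectorised row-wise in numpy: the match and
gap-in-query states depend only on the previous row, and the
gap-in-reference state, whose recurrence runs along the row, is rewritten as
a prefix maximum (`T[j] = Iy[j] + j·gap_extend` turns the decayed running
maximum into `np.maximum.accumulate`). Traceback recomputes the attaining
predecessor at each cell; ties are broken deterministically in the order
match/mismatch → gap in query → gap in reference, so identical inputs
always produce identical alignments. Equality tests in the traceback are
exact floating-point comparisons, which is sound because all intermediate
values are sums of matrix entries and gap penalties; integer or dyadic
penalties (the defaults) keep those sums exactly representable.

Correctness is established two independent ways in the test suite: against
a brute-force enumeration of *all* global alignments for short sequences
over a reduced alphabet with random scoring schemes, and against an
independently implemented affine-gap aligner on longer random protein
pairs.

**Percent identity.** A column counts as identical only if both rows carry
the same canonical residue (X never matches). The denominator is the number
of *reference* residues in the scored span — conservation is measured over
the reference protein, so paralog gaps and insertions count against
identity but reference gaps cannot occur inside a projected span.
Alternative denominators (all columns; shorter sequence) are available as
options. A span whose reference residues all align to nothing (possible
only for hand-built alignments, not projected domains) yields an undefined
identity, reported as missing rather than 0 and excluded from flagging.

## Domain conservation scan

Domain annotations are 1-based inclusive spans on the reference, validated
for bounds, overlap and duplicate labels. Each span is projected to
alignment columns independently in the two paralog alignments via the
reference coordinate map, scored for identity, and the difference
`delta = identity_b − identity_a` is flagged when `|delta| > 20` percentage
points, *strictly* — a delta of exactly 20.0 is not flagged. The threshold
is configurable. Spans shorter than 5 residues are annotated as short
peptides (they are still scored, but identity over so few residues is
noisy; the annotation mirrors the asterisk convention of channel-domain
figures). The sign convention (positive = paralog B better conserved)
matches the usual presentation where scn1lab is the better-conserved
paralog.

## Knockout-allele model

The model operates on the spliced CDS; exon structure is metadata only, and
splice-site effects are deliberately out of scope. A deletion of L bp is a
frameshift iff `L mod 3 ≠ 0`, independent of position. Translation uses the
standard nuclear genetic code, stops at the first stop codon, ignores a
trailing partial codon, and renders N-containing codons as X. The
premature-stop rule compares codon indices in the edited frame: a wild-type
stop at codon `s` corresponds to edited codon `s − ⌊L/3⌋`, and any stop
strictly earlier is premature. (No published rule exists for this
comparison; this operationalization is the natural one and is documented
here because other conventions — e.g. comparing protein lengths — differ by
one codon in edge cases.) Predicted loss of function is frameshift OR
premature stop; this is a sequence-level prediction only, with no
nonsense-mediated-decay or truncated-protein modelling.

## LFP analysis

**Filtering.** A 50 Hz biquad notch (−3 dB width 2 Hz, Q = 25) followed by
a 4th-order Butterworth band-pass at 2.5–100 Hz, both applied
forward-backward (zero phase) so event onsets are not delayed. Filter
family and order are design choices — chosen for a flat pass band and no
phase distortion — and are configurable. Filtering is idempotent for
pass-band interior content (a second application changes the RMS of 10–30 Hz
tones by <1%) but not for broadband noise, whose band-edge content the
rolloff attenuates on every pass. For real 13-minute recordings the first
60 s (electrode placement) can be trimmed after filtering; the trim is off
by default for synthetic traces.

**Spectra.** One-sided magnitude-squared FFT of a 40-s window, linearly
detrended and Hann-tapered, normalised as `|X_k|²/N` with interior bins
doubled so that the total power equals the energy of the tapered window
(Parseval, exact to rounding). Frequency resolution is 1/40 Hz. Band
summaries integrate 2.5–20 Hz ("low") and 40–100 Hz ("high").

**Spike detection.** The published observations report epileptiform events
but define no detector, so the detector here is a declared
operationalization validated against synthetic truth: events are excursions
of |signal| above `k` times a robust SD estimate (1.4826 × median absolute
deviation of the whole preprocessed trace — insensitive to the events
themselves), with `k = 5` by default; excursions closer than 100 ms are
merged into one event (a biphasic spike crosses zero between its lobes and
must not count twice); excursions starting within 50 ms of either trace
boundary are discarded because zero-phase filtering leaves transients
there. A zero-variance trace returns an empty event list with a warning.
Detected amplitude is reported in robust-SD units; polarity is the sign at
the peak.

**Stimulus locking.** Each event is assigned to the most recent stimulus if
its onset falls within 0.5 s after it ("directly after" made concrete;
configurable); the response fraction is the share of stimuli with at least
one assigned event. With no stimuli the fraction is undefined (None), not
zero.

## Locomotor analysis

Tracks are per-animal binned series (distance per bin, peak velocity per
bin); the standard assay is 90 min in 10-min bins with the first 30 min
discarded. Activity is the summed distance over the remaining bins. Burst
movements are contiguous runs of bins with peak velocity strictly above
50 mm/s, counted once per run so a single movement spanning a bin boundary
is not double-counted. Run counting is monotone in the cut-off only when
excursions are isolated (raising the cut-off can split a dense run in two);
isolated single-bin excursions are what both the simulator and real burst
movements produce.

**Mann–Whitney U.** U is computed from midrank sums. For
`min(n1, n2) ≤ 12` the two-sided p is exact: midranks are doubled to
integers and the full permutation distribution of the group-A rank sum over
all `C(n1+n2, n1)` labelings is built by a subset-counting recursion
(counts fit exactly in double precision; C(24,12) ≈ 2.7·10⁶), which handles
ties exactly — this is the reason the test is implemented here rather than
delegated, since standard exact implementations fall back to the asymptotic
formula under ties. The two-sided p doubles the smaller tail, capped at 1.
Above the exact regime a normal approximation with tie correction and
continuity correction is used. Significance is `p ≤ 0.01` (the complement
of "p above 0.01 is not significant"). The exact p agrees with an
independent implementation on tie-free data and with the normal
approximation to within 0.02 at n = 12 per group.

## Synthetic data: what it emulates, and what it does not

The generators replace three real input sources and are first-class,
tested code; all randomness flows through `numpy.random.SeedSequence`
children of one integer seed, so identical specs reproduce byte-identical
artifacts.

**Paralog families.** The reference is uniform over the 20 canonical
residues; each paralog mutates each site independently with its local
divergence probability, replacing the residue by a uniformly chosen
*different* one — so expected identity is exactly `1 − d` and recovery
tests are analytic (binomial). Divergence is piecewise constant: one rate
per annotated domain per paralog, one background rate between domains
(default 0.05). Truth flags domains with `|d_a − d_b| > 0.20`. Optional
1–3-residue indels (default off) are placed only outside annotated domains
so per-domain truth stays well-defined. This is deliberately not a
phylogenetic model: no substitution-rate matrix, no tree, no selection —
realized identity, not evolutionary realism, is what downstream scoring
consumes. A channel-like layout helper (4 homologous domains × 6
transmembrane segments plus termini/linkers) provides realistic geometry.

**LFP.** Baseline noise is white Gaussian or 1/f (default white, SD 1 in
arbitrary units); an optional 50 Hz sinusoid models mains pickup. Events
are one positive then one negative half-sine lobe of 30 ms each — a
parametric stand-in for biphasic epileptiform spikes — with default peak
amplitude 10× the noise SD (large interictal spikes are typically several-
to tens-fold above baseline). Spontaneous events follow a homogeneous
Poisson process (default 6/min for event-bearing recordings); stimulus-
locked events occur with a set probability at a uniform 0.02–0.4 s latency
after each flash. The photic protocol default mirrors the assay: flashes
every 30 s over 5 min. Real baselines' noise statistics are not published
for this preparation, so these defaults are declared placeholders exposed
as simulation parameters; passing tests therefore demonstrate correct *pipeline
behaviour* under a plausible signal model, not detector performance on real
recordings.

**Cohorts.** 12 animals per group, 90 min in 10-min bins. Per-bin distance
is zero-truncated Gaussian with mean 1200 mm per 10-min bin for controls
(a typical dark-phase larval travel rate of ~2 mm/s) and CV 0.2; group B's
mean is multiplied by the hyperactivity factor (1 = null). Burst counts per
recording are Poisson (defaults 0); each burst occupies one bin, placed in
non-adjacent bins so run counting recovers the injected count exactly, with
peak velocity 20 mm/s above the 50 mm/s cut-off; non-burst bins stay below
45 mm/s. The "scn1lab-like" contrast used in analyses is a 2.5× activity
effect with ~15 bursts/recording versus ~0.2; the "scn1laa-like" contrast
is the null. What the simulator does not model: within-bin movement
kinematics, habituation trends over time (trimming is still applied, as in
the real assay), inter-animal correlation, and any drug or light-phase
effects.

## Problem sizes

The test suite and the acceptance script size their simulations for exact
or well-margined checks at interactive runtimes: 200 brute-force aligner
comparisons at length ≤ 6; 100 families of six ≥150-residue domains
(differential divergence 0.45 vs 0.05, background 0.05) for flag recovery;
50 paired 40-s traces for band-power elevation; 200 photic recordings for
response-fraction calibration; 500 null cohorts for type-I control and 100
strong-effect cohorts for power. Real-scale inputs (2000-residue channel
proteins, 13-min traces) run in seconds through the same code paths.

## Known limitations

* The 58-domain partition of the real reference protein is
  annotation-version-sensitive; reproducing the published "12 of 58
  flagged" requires the UniProt feature set as of the original access date,
  so real-data domain counts are treated as an external benchmark, not a
  unit test.
* Whether published protein-wide identities derive from one three-way MSA
  or from reference-anchored pairwise alignments is not stated; this
  package uses pairwise alignments (each paralog vs the reference), which
  the robustness of those identity scores across alignment programs
  suggests is immaterial at the whole-protein level but is a choice, not a
  given.
* The spike detector and the burst statistic are operationalizations of
  qualitative descriptions; both are validated against synthetic truth
  only.
* No local alignment, no >2-sequence MSA, no CRISPR efficiency/off-target
  modelling, no NMD prediction, no seizure staging.
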