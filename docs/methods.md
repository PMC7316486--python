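# Methods

## The analysis in outline

The package reconstructs how a type II-A CRISPR-Cas system's PAM is
inferred from adaptation data. Survivor colonies (BIMs) of a phage
challenge are screened by amplifying the CRISPR locus; each amplicon is
parsed into repeats and spacers; new spacers are called by diffing against
the wild-type array; spacers are mapped back onto the phage genome as
protospacers; and the 10 bp flanking each protospacer are tabulated to
find the motif enriched on one side. A separate, pluggable acceptance rule
— fit to plasmid interference assays rather than to acquisition counts —
predicts whether a given construct is cleaved.

## Array model and parsing

An array is modelled as R s₁ R s₂ … R sₙ R′: n spacers between n+1
repeats, index 1 leader-proximal. Repeat matching is substitution-only
(Hamming), because the only repeat variant observed in this system is a
single terminal substitution and because Hamming matching makes the parser
exactly invertible against the simulator. Internal repeats tolerate 2
mismatches by default and terminal repeats 3 (both configurable; the
terminal budget may never be smaller). The parser scans every window at
the terminal budget, requires candidates not to overlap (overlap is an
error naming the offsets, since spacer extraction would be ambiguous),
chains consecutive candidates whose gaps fall in the spacer-length window
(default 20–45 bp, generously bracketing the observed 28–32), and keeps
the longest chain, leftmost on ties. If no window matches, the reverse
complement is tried and the parsed array flagged `is_reverse`; if neither
matches, an empty array is returned with a warning rather than an
exception, because repeat-free amplicons are an expected screening
outcome.

Event calling aligns the native spacer list as an ordered subsequence of
the BIM list, greedily leftmost. Unmatched BIM spacers become events; an
event's insertion index is the number of native spacers 5′ of it, so index
0 is polar and index i ≥ 1 ectopic. Two conventions are ours rather than
observed facts: events are reported 5′→3′, and an insertion 3′ of the last
native spacer (index n) — never generated by the simulator and not seen in
the real data — is classified ectopic. When a new spacer duplicates a
native one the leftmost backbone placement is taken and the event flagged
`ambiguous`.

## Mapping

`find_hits` is an exhaustive sliding-window Hamming scan of both strands
(vectorised over byte arrays), returning *all* placements within the
budget, sorted by mismatches, then leftmost coordinate, then strand.
Coordinates are 1-based inclusive with start > end on the minus strand,
the convention in which targeted phage positions are conventionally
reported. Flanks are returned in spacer orientation and truncated (and
flagged) at linear genome ends; in circular mode the sequence is scanned
doubled, wrapped duplicates are dropped, flanks wrap, and hits crossing
the origin keep coordinates extending past the genome length so the
strand/coordinate encoding stays intact. Ambiguity (two or more placements
tied at the minimal mismatch count) is flagged but does not exclude a
spacer from PAM inference: the best hit is used, matching the practice of
counting every mappable protospacer. The default mapping budget is 2
mismatches, the maximum observed among mapped spacers; non-ACGT symbols
count as mismatches to everything. Indels are deliberately out of scope.

## PAM inference

`build_pam_table` counts the k-mer (default k = 5) at offset 1 — the first
base beyond the protospacer — on the chosen side; on the upstream side the
offset counts leftward from the base abutting the protospacer. Hits whose
flank is too short are excluded and tallied separately so table total +
excluded always equals the number of input hits. `motif_fraction`
evaluates IUPAC patterns (N = any base) anchored at a k-mer position,
weighting by counts; it is monotone under wildcard relaxation.
`build_pfm` gives per-position base frequencies and information content
IC(p) = 2 + Σ_b f_b log₂ f_b ∈ [0, 2] bits; only hits covering the full
width contribute, so all positions share one denominator. Consensus calls
a base where its frequency reaches 0.75 (configurable), a threshold chosen
so the published downstream frequencies yield `NAA`/`NAAA` while
genome-composition fluctuations upstream do not call anything.
`count_genome_motif` counts forward-strand occurrences with overlaps
(`AAAA` contains `AA` three times); single-strand overlapping counting is
an assumption, stated here because the convention behind published genome
background counts is not recorded.

Both flanks are always computable so the upstream side serves as a
negative control: on PAM-simulated data no upstream position should exceed
the composition-plus-noise baseline (~0.07 bits at 35% GC), and the
upstream consensus should be all N.

## Interference rule

The P42S rule over the 3′ 5-mer: accept iff position 3 is A and (position
2 is A, or position 2 is G and position 4 is A). This is exactly
NAANN ∪ NGAAN — 64 + 16 = 80 of the 1024 5-mers — and positions 1 and 5
(and 4, when position 2 is A) can never flip the outcome. The rule is a
plain predicate object so other strains' rules (an NGG preset is included)
can be swapped in. `scan_construct` treats plasmids as circular by default
and demands a full-length spacer match at 0 mismatches plus an accepted
PAM; mismatch tolerance of interference was not probed experimentally, so
0 is the honest default and the budget is exposed as a parameter.

## Simulator: what it emulates and what it does not

`SimulationConfig` defaults are the study conditions: genome length 30,664
at 35% GC (i.i.d. bases — no genes, no codon structure, no repeats);
spacer lengths {30: 0.68, 31: 0.27, 32: 0.03, 29: 0.01, 28: 0.01};
mismatch rate 0.10 (1 or 2 substitutions, equiprobable); non-phage rate
0.02 (modelled as random sequences verified absent from either genome
strand — no host genome is simulated); PAM obedience 0.93; five native
spacers of 29–31 bp drawn independently of the genome. Protospacer sites
are drawn uniformly over positions and strands and rejection-sampled so
that the downstream 5-mer satisfies (or, with probability 1 − obedience,
violates) the rule; uniformity is an assumption — no positional hotspots
are modelled. "Obedience" is defined against the full acceptance rule, and
parameter recovery measures the rule-accepted fraction of mapped hits;
the `NAA`-pattern fraction is systematically a few points lower because
accepted sites include `NGAA`. Spacers-per-BIM defaults to
{1: 0.45, 2: 0.25, 3: 0.12, 4: 0.08, 5: 0.05, 6: 0.03, 7: 0.02} — chosen
once to make one or two acquisitions typical and seven possible, matching
the qualitative report; the ectopic rate defaults to 0.14 (≈ 23 of 165
mapped protospacers came from ectopic insertions). Every BIM in the
emitted cohort carries at least one new spacer, i.e. the cohort models the
screened spacer-positive colonies, not the raw survival rate; UV-enriched
acquisition is reproduced by choosing `n_bims`, not mechanistically.

All randomness flows from `numpy.random.default_rng` seeded from
`config.seed` (distinct fixed sub-streams per operation), so a fixed seed
fixes every output byte.

Passing tests on this generator demonstrate correct bookkeeping —
coordinates, strands, flanks, event indices, calibrated fractions — under
the stated statistical model. They do not demonstrate robustness to
features of real data the generator omits: sequencing errors, chimeric
amplicons, repeat polymorphisms beyond the terminal variant, indel
variation in protospacers, or non-uniform protospacer sampling.

## Problem sizes and numerical choices

Cohort-level tests use 40–300 BIMs on genomes of 8–30.7 kb, sizes at which
binomial 95% intervals are tight enough to detect miscalibration while the
whole suite stays fast. Calibration checks compare recovered fractions to
the configured rates within 1.96·√(p(1−p)/n). Tie-breaks are deterministic
everywhere: hit sorting (mismatches, leftmost, '+' first), k-mer tables
(count descending, then lexicographic), PFM consensus (alphabetical
argmax), anti-repeat search (matches, longer window, smaller offset, '+'
strand). Degenerate inputs have defined behaviour: empty hit lists yield
`(None, False)` from `best_hit`; an empty BIM file yields a zero-event
summary with exit 0; a repeat-free sequence parses to an empty array with
a warning.

## Known limitations

- Hamming-only matching throughout; an indel in a repeat or protospacer
  shifts the frame and the element is missed or mis-scored.
- Arrays and phage genomes are linear; only constructs are circular.
- The anti-repeat search is exhaustive enumeration (fine for ~200-nt
  regions against a 36-mer; not meant for genome-scale scans).
- The published acquired-PAM table is reproduced as counts only; per-BIM
  provenance of the 165 protospacers is not modelled, so acquisition-mode
  subsets (5′-only vs ectopic-only PAM preferences) are validated on
  simulated cohorts instead.
- Interference predictions are binary targeted/untargeted; transformation
  efficiencies are not modelled.
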