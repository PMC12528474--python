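# Methods

`ighrep` models the formation and developmental selection of the mouse
immunoglobulin heavy-chain (IgH) repertoire across the pro-B to small
pre-B ("pre-B") transition, and the detection of VH-replacement (VHR)
excision circles in framework-3 run-off sequencing libraries.  Everything
runs on synthetic data produced by the package's own generative model, so
every downstream statistic can be checked against planted ground truth.

## The toy germline locus

`locus_model.build_toy_locus` emits a deterministic locus of `n_v` ordered
V segments (rank 1 = most D-proximal), `n_d` D and `n_j` J segments.  The
V segments are 294-nt stop-free open reading frames with a fixed internal
geometry chosen to reproduce the features the analysis depends on:

* the invariant Cys96 codon at nt 285–288, with the cryptic RSS heptamer
  `TACTGTG` overlapping Tyr95/Cys96 (nt 282–289) in a configurable fraction
  of V (default 0.8; V without a cRSS carry `TATTGTG` instead);
* V coding ends five bases after the cRSS, so 3'-exonucleolytic trimming
  can remodel CDR3 positions 97–98 and occasionally removes Cys96
  entirely, in which case the CDR3 is reported unresolved — as in real
  data;
* codon 97 begins with the final `G` of the cRSS: the default completion
  encodes Ala97, and the VH1-11 analogue encodes Gly97; alternate VH2
  members encode Ser/Lys98; three V end in `TA`, the first two bases of a
  stop codon;
* each V carries a conventional RSS heptamer (`CACA[GAT]TG`, degenerate
  fifth position) and 120 nt of unique 3' intergenic sequence — the
  donor-side signature of a replacement circle.

D segments (17 nt) are searched so that reading frame 2 (Ichihara
numbering) always contains the Dmu ATG and never a stop, frame 1 is
glycine/tyrosine-rich, frame 2 threonine/valine-rich, and at least one D
carries a stop in frame 3.  J segments contribute 6 (JH1/JH4) or 4
(JH2/JH3) codons to the CDR3 before the conserved Trp.

All synthetic background sequence is scrubbed of both RSS heptamer motifs.
In germline reads the cRSS sits 5 nt upstream of the conventional
heptamer, outside the 0–4 nt insertion window of a signal joint, so
planted circles are the only junction strings in a library.  This margin
is deliberate and the detector's insertion bounds must stay below it.

## Junctional diversity

Per junction end: geometric trimming (`trim_p` 0.25, capped at 10 nt),
Poisson non-templated additions (mean 3, capped at 15 nt) and up to 2
palindromic nucleotides on untrimmed V 3' / J 5' ends.  These defaults
give a net CDR3 gain of roughly 0–3 amino acids and an in-frame fraction
of about one third before stop-codon loss.  Trimming that would consume a
D segment entirely is redrawn (at least 1 nt of D always remains).

## Developmental selection model

Cells carry two alleles; both D–J join first.  V choice happens in two
waves: wave 1 with weights exp(−(rank−1)/τ1), τ1 = 2 ranks (recombination
before locus contraction, hence the strong proximal bias), wave 2 uniform.
Events per cell, in order:

1. **Dmu arrest** — before wave-2 recombination, a cell with a
   reading-frame-2 DJ allele arrests with probability 0.9 (never in muMT
   mode, where membrane mu cannot signal).
2. **Productivity** — in-frame, stop-free VDJ are "productive".
3. **SLC pairing** — a productive mu chain pairs per step with probability
   `base_pair_p` (0.5: about half of new mu chains fail to pair) scaled by
   a per-V multiplier (0.05 for the VH5-2 analogue, 0.3–0.6 for other
   proximal VH5/VH2/VH3, ≥1 for distal VH1/VH14), by 0.3 for VH2/3/5
   paired with the short JH2/JH3, and by CDR3-residue multipliers
   (G97 0.25, S/K98 0.5, H99 2.0, Y101 1.8, T/V at 100–102 0.55–0.7 — the
   RF2-typical residues).  The product is clipped to [0, 1].
4. **Stalling and VHR** — a productive non-pairing allele stalls the cell
   for `n_steps` (3) steps; per step a V with a cRSS is replaced with
   probability `vhr_rate` (0.3) by a donor drawn uniformly from
   strictly-distal V, excising a circle with a 0–4 nt signal-joint
   insertion.  Non-productive alleles attempt VHR once at 0.25 × the rate
   (nonsense-mediated decay shortcut) before the second allele recombines.
   The 0.3/step rate is an order-of-magnitude choice giving stalled cells
   a ~2/3 chance of rescue over the stall window; it is what makes the
   wild-type pro-B productive repertoire visibly diverge from the
   non-productive one while the muMT repertoire stays flat.
5. **Allelic exclusion** — a pairing allele ends recombination; the cell
   proceeds through large to small pre-B.  No surviving cell carries two
   pairing productive alleles.
6. **muMT mode** — no arrest, no pairing-dependent transitions (cells stay
   pro-B), both alleles recombine, VHR at 0.4 × rate (a calibration so a
   wild-type : muMT circle-count excess around 2.5 is attainable, not a
   mechanism claim).

The **pro-B pool** is each cell's VDJ allele state at the moment it leaves
the pro-B compartment (progression, arrest, death or simulation end);
replaced alleles are gone from it and replacement products are in it.  The
**pre-B pool** is the allele set of cells that reached small pre-B.

The VHR footprint retains up to 7 nt of recipient sequence 3' of the cRSS
cut in the new junction.  Mechanistically the retained DNA lies 3' of the
cut (between cRSS and V end); the length cap is configurable and the D–J
junction nucleotides are preserved verbatim.  Replaced alleles do not
undergo a second replacement by default (supported via
`allow_second_replacement`).

## Read emitters

VDJseq-like libraries: one molecule per sampled allele (default sampling
5–10%), J-anchored fragments starting 150 nt into the V, 12-nt UMIs in the
read title (`UMI:<seq>`), optional PCR duplicates sharing the UMI, uniform
substitution errors only (no indels — the detector's tolerances are
specified against substitutions).  RCseq-like libraries: dominant germline
background from the primer-panel V (FR3 run-off through the RSS into
intergenic sequence) plus reads across each circle whose recipient is in
the panel.

## Annotation

Merging is best ungapped overlap (≥20 nt, ≤10% mismatch, higher quality
base wins); deduplication keys on (UMI, sequence length) with the
highest-mean-quality read as representative.  V and J are assigned by
anchored ungapped matching (40-nt V anchor ending at the cRSS, 30-nt J
anchor past the trim zone, ≤2 mismatches; tied V take the lower locus rank
and set an ambiguity flag); D by the best ≥6-nt exact match inside the
junction.  With geometric trimming a substantial minority of D remnants
are shorter than 6 nt and genuinely unidentifiable; accuracy targets are
therefore stated over identifiable remnants.  Productivity requires frame
shift 0 and no stop between Cys96 and the conserved J Trp (if the Trp
codon is degraded the stop scan ends at the junction and the row is
flagged).  The D reading frame is reported in Ichihara numbering; the
IMGT-to-Ichihara transposition (1→2, 2→3, 3→1) is provided for imported
annotations.

## Statistics

Frequency tables keep pooled rare keys in the denominator; fold changes
with zero baseline are undefined rather than infinite; positional
statistics use only rows whose CDR3 resolves the position; CDR3-length
comparisons can be restricted to RF1 rows.  Net charge counts R/K − D/E
and ignores His by default (configurable); GRAVY is mean Kyte–Doolittle
hydropathy; aliphatic index 100·(fA + 2.9 fV + 3.9 (fI+fL)).  These are
the standard definitions, used because the repertoire literature rarely
spells out alternatives.  Inference uses simple linear regression R² and
Welch's unequal-variance t test with Satterthwaite degrees of freedom;
Benjamini–Hochberg q-values are available but off by default.

## Circle detection

The main search requires, per molecule: 60 nt of a V's framework-3 (≤2
mismatches), a 10–120 nt gap containing `TACTGTG`, a 0–4 nt insertion and
a `CACA[GAT]TG` heptamer, then 60 nt of a *different* V's 3' intergenic
sequence (≤2 mismatches); one best candidate per molecule.  The fallback
greps for the back-to-back heptamers with ≤3 nt insertions and identifies
segments with 20-nt anchors, rescuing molecules too short for the donor
anchor.  Automated curation enforces: junction pattern present, anchors of
at least 20 nt at ≤3.4% mismatch, donor ≠ recipient, donor strictly
locus-distal.  Rejections are labelled (`no_junction`, `weak_anchor`,
`self_match`, `donor_not_distal`).  Only the exact cRSS heptamer and the
single-degenerate conventional heptamer are accepted; degenerate cRSS
variants are not searched.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the real assays (UMI
duplicates, molecular sampling, junctional diversity, germline-dominated
RCseq background, donor-distal circles) but not sequencing indels, primer
chemistry, real locus copy numbers, or inter-mouse variability.  Passing
tests therefore demonstrate that the pipeline recovers planted truths and
that the statistics move in the directions the selection model encodes at
realistic effect sizes — not that the specific default multipliers are
quantitatively those of the mouse.

## Problem sizes

Cohort-level checks use 5×10⁴ cells (≈10⁵ alleles); detector specificity
uses ≥10⁵ background molecules; the reproducibility figure in
`scripts/acceptance.py` simulates 1.3×10⁵ cells (>2×10⁵ pro-B VDJ
alleles) and reports the median R² of five pairs of independent 5%
molecular samples.  These sizes give the statistics comfortable power
while keeping a full run on one CPU in minutes.

## Known limitations

Light-chain editing, somatic hypermutation, cRSS sites other than the 3'
one, cell-cycle timing and absolute developmental rates are out of scope.
Stall duration and the absolute VHR rate are not quantified by available
data; they are exposed parameters with order-of-magnitude defaults.  The
two-wave V-choice model is the simplest scheme that reproduces the early
proximal bias; continuous developmental time is not modelled.
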