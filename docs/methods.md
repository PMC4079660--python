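# Methods

## Problem setting and model

`ervscan` targets the comparative-genomics recipe for cataloguing
lineage-specific endogenous retrovirus insertions. The biological model is
the standard LTR-retroelement life cycle: integration plants
`5'LTR–gag–pro–pol–env–3'LTR` flanked by a 2–5 bp target-site duplication
(TSD); the two LTRs are identical at time zero and then diverge neutrally,
so the K2P-corrected LTR-pair distance d estimates 2·r·T for neutral rate r
and age T; LTR–LTR homologous recombination leaves solitary LTRs; and a
minority of insertions arrive through double-strand-break repair rather than
integrase chemistry — these non-classical insertions (NCPIs) lack a TSD,
delete host sequence at the insertion point, and often show 2–3 bp of
junction microhomology.

An insertion is *ingroup-specific* when the orthologous position in every
informative outgroup genome lacks the element. We test this positionally:
both 2-kb flanks of the locus are located in the outgroup and the
inter-flank interval is inspected. Three outcomes per outgroup:

* gap ≤ 50 bp (`absence_threshold`) → `element_absent`;
* gap ≥ 0.5 × element length (`presence_margin`) *and* the gap sequence
  aligns to the element at ≥ 0.85 identity → `element_present`;
* a larger gap that does **not** align to the element is *deleted host
  sequence* and is likewise `element_absent` — this is the NCPI signature
  and the gap size is retained for deletion sizing. Only an element-like gap
  that is too short to clear the presence margin is left ambiguous
  (`unmapped`). Without this rule, deletion-associated insertions could
  never be called ingroup-specific.

Final call: `ingroup_specific` iff ≥ 1 outgroup mapped and every mapped
outgroup is `element_absent`; `shared` iff any outgroup is
`element_present`; `unresolved` otherwise.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `flank_bp` | 2000 | flank length used for orthologous mapping; the census protocol's choice |
| `kmer` | 16 | exact seed length for flank location; at 2% outgroup divergence a 16-mer survives with p ≈ 0.72, giving ~17 clean seeds per flank |
| `min_identity` | 0.85 | flank and gap-vs-element alignment identity floor |
| `absence_threshold` | 50 bp | inter-flank gap below which the site is empty |
| `presence_margin` | 0.5 | fraction of the element length the orthologous gap must reach to count as the element being present |
| `max_gap_bp` | 1000 | defragmentation radius; above simulated fragment splits, below the 5-kb event spacing |
| `tsd` search | 2–6 bp | classical TSDs are 2–5 bp; the ceiling is 6 so over-long duplications are observed rather than capped |
| `intact_fraction` | 0.95 | stop-free ORF coverage of the consensus gene length required to call a gene intact (the source protocol gives no quantitative rule; this is our stand-in) |
| rates | 0.26 / 0.20 %/site/myr | the two published neutral calibrations; `age = d / 2r`, bounds ratio fixed at 1.3 |

Both-flank consistency (same outgroup chromosome, same orientation, within
10 × element length) is required before any presence/absence call — a guard
against paralogous flank hits that substitutes for the manual-inspection
step of the original screen. One outgroup is permitted (reduced stringency);
the study design uses three.

## NCPI calling

A locus is an NCPI candidate iff no 2–5 bp TSD was detected **and** at least
one outgroup mapped. TSD absence alone is never sufficient: a spurious 2-bp
duplication arises by chance at roughly 1/16 per junction offset, so the
orthologous interval is always consulted. The deletion size per outgroup is
the orthologous inter-flank span minus the residual ingroup inter-flank span
(zero when flanks directly abut the element); the consensus is the median
across outgroups, flagged when the spread exceeds 10% of the consensus and
marked low-confidence with a single outgroup. A TSD-absent locus whose
orthologous gap is below the absence threshold is retained as an
insertion-only NCPI with deletion size 0. Junction microhomology is the
longest exact overlap (≤ 10 bp scanned) between the element terminus and
the retained flank at each breakpoint.

## Dating

K2P distances exclude alignment columns containing a gap **or** an ambiguity
code from both the substitution counts and the site total (the conservative
"without INDEL" convention). Subfamily assignment global-aligns the LTR
(edlib) to each consensus and takes the minimal K2P distance, breaking ties
lexicographically with a flag. Subfamily-level distance is the mean over all
unordered LTR pairs; the age interval is computed from that mean. Saturated
pairs (log argument ≤ 0) raise rather than return a number.

For parameter-recovery evaluation a *replicate* is a simulated subfamily of
100 LTR pairs whose mean distance is dated — the same quantity the pipeline
dates. A single 400-bp pair at d ≈ 0.009 carries only ~3.7 expected
differences, so per-pair age intervals are dominated by Poisson noise and no
estimator could bracket the truth reliably; the subfamily mean is the
meaningful unit.

## Synthetic data: what it emulates and what it does not

The generator builds an i.i.d. random ancestor (GC 0.41 by default),
derives each outgroup by independent per-site substitution at the configured
divergence (observed mismatch fraction equals the parameter), and plants
events into the ingroup copy. LTR aging uses a per-site Poisson substitution
process with a 2:1 transition:transversion ratio, so P ≠ Q and the K2P
multiple-hit correction is genuinely exercised; `d ≈ 2·r·T` holds by
construction. Event placement enforces ≥ 5 kb spacing between event
footprints (flanks never overlap another event) and rejects sites with
non-unique flanks. Planted hallmark signatures are validated locally at
planting time and re-sampled on chance collisions (a spurious TSD at an
NCPI junction, a chance extension of a planted TSD or microhomology), so
the truth ledger is an exact oracle for the detectors. Decoy elements
planted before outgroup derivation are shared by all genomes and exercise
false-positive rejection.

Deliberate simplifications, and hence the limits of what green tests show:

* **No indels** in flanks or during divergence — flank mapping coordinates
  are exact on synthetic data, so deletion sizes are recovered exactly; on
  real genomes indel drift would blur sizes by the local alignment
  ambiguity (the median-across-outgroups rule is the mitigation).
* **Internal regions carry no random drift.** Retrotransposition-competent
  elements keep a pristine internal region; non-competent ones get premature
  stop codons injected mid-gene. The ledger's `orf_intact` flags are thereby
  constructed truth, not re-derived by the screening code — avoiding a
  circular oracle — but the screen is only exercised against clean
  intact/disrupted/missing cases, not marginal 94–96% coverage calls.
* **Microhomology convention.** At NCPI junctions the ≤ 3 retained flank
  bases on the ingroup copy are set equal to the element terminus at
  planting time (outgroups keep ancestral bases). Detector and generator
  therefore agree on the definition "flank terminus equals element
  terminus"; real breakpoint junctions admit more assignment ambiguity.
* **The consensus library is synthetic.** Six subfamilies in two families
  with the published LTR lengths (409/379/544/586/491/603 bp), a shorter
  env in the second family, and ~12% LTR divergence between within-family
  siblings. Real subfamily boundaries are fuzzier; the ≥ 99% assignment
  accuracy measured at ≤ 5% mutation is specific to this geometry.
* **No nested insertions, no recombination maps, uniform chromosomes.**

## Numerical and implementation choices

* Flank location: exact-16-mer diagonal voting, ambiguous when the runner-up
  diagonal reaches 80% of the winner's votes; identity verified by edlib
  infix alignment over the full flank. The winning diagonal (not alignment
  endpoints) supplies coordinates, which is exact under substitution-only
  divergence.
* Defragmentation keeps the longer of two nested hits (deterministic
  tie-break: earlier start, then lower id); a locus with two LTRs but no
  internal sequence is `unknown`, not solo; mixed-family LTR–internal–LTR
  chains are `unknown`; the locus subfamily is the majority member label,
  ties unassigned.
* Multiple alignment for consensus construction is delegated to `mafft`
  (`--auto`); the column consensus is majority-rule with IUPAC codes on
  ties, all-gap columns dropped, gaps never outvoting bases.
* Percentages are rounded half-up to one decimal (`Decimal`), matching how
  census tables conventionally print 45.9 / 62.5 / 20.9 / 22.2.
* Problem sizes: the test-suite property run uses a 10-Mb ingroup, two
  chromosomes, 97 events and three outgroups at 1% divergence (~40 s
  end-to-end); the dating study uses 100 replicates × 100 pairs × 400 bp.
  These sizes give exact-recovery statistics with zero slack at ordinary
  desktop cost.

## Known limitations

* The flank mapper does not search the reverse strand of outgroups; it
  assumes outgroups are colinear with the ancestor (true for the simulator,
  usually true locally for closely related primates; inversions would
  surface as `unmapped`).
* `element_present` requires the gap to align to the element at
  ≥ `min_identity`; a shared element older than ~15% divergence would be
  missed (reported `element_absent`), overstating specificity for very old
  insertions.
* Ages assume the neutral two-rate calibration; selection on LTRs or rate
  variation between subfamilies is not modelled, and the two published
  calibrations bound but do not quantify that uncertainty.
* The polymorphism module summarises whatever genotype matrix it is given;
  it does not model relatedness of panel individuals, so rates from small
  related panels underestimate population polymorphism.
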