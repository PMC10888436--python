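# Methods

This note documents the models, parameter choices and numerical conventions
behind `circbact`, and what the synthetic validation does and does not show.

## Mass model

Peptide masses are residue sums over the standard monoisotopic and average
residue-mass tables shipped with pyteomics. A linear peptide carries one
water (terminal H and OH); a head-to-tail cyclized peptide does not, because
the closing amide bond is a condensation:

* `M(linear) = Σ m(residue) + m(H2O)`; `M(circular) = Σ m(residue)`.
* Water: 18.010565 Da monoisotopic, 18.01528 Da average.
* Proton: **1.007276 Da** (the physical proton, not atomic hydrogen at
  1.00794). This choice is required to reproduce 4-decimal MH⁺ values;
  using atomic H inflates every charge state by ~0.5 mDa per charge.
* Met oxidation: +15.994915 Da, a variable modification; at most one per
  peptide by default in matching (configurable). It is required to
  reproduce the oxidized-Met fragment identifications; it is off for plain
  mass calls.
* Ambiguity codes (B, J, O, U, X, Z) are rejected with the offending
  position, never averaged: downstream mass targets are exact.
* Masses are carried at full double precision and rounded only at
  presentation (4 decimals).

Isoleucine and leucine are isobaric; nothing downstream can or does
distinguish them by mass (property-tested).

## Intact-mass (dehydration) check

Linear-mode MALDI-TOF of intact peptides in this mass range reports
average-mass, singly-protonated species. The check therefore compares the
peak list against

* cyclic hypothesis: `deduced_linear_average − 18.0153 + 1.0073`,
* linear hypothesis: `deduced_linear_average + 1.0073`,

with a ±1.5 Da tolerance (default). The colloquial "18 Da loss" is the
water of condensation; note that a *deduced-minus-observed* difference of
~17.0 Da is exactly what the cyclic [M+H]⁺ hypothesis predicts
(−18.015 + 1.007), which is why the comparison is made against the
protonated species rather than against a bare 18 Da offset. The 1.5 Da
tolerance absorbs linear-mode MALDI calibration drift of a few tenths of a
Dalton on ~7 kDa species.

## Circular digestion

A protease rule is `cleave after residues in A unless the next residue is
in B` (trypsin: A = {K, R}, B = {P}); on a circular parent, "next" wraps
from position n to 1. Digestion of a circle is enumerated over the doubled
sequence restricted to fragments of length ≤ n starting in the first copy
— O(n·sites) and transparent. An independent all-rotations brute-force
oracle lives in the test suite; the two must agree on 500 random cores per
run (and on every hypothesis-generated case).

Degenerate/edge conventions:

* No cleavage sites: the cycle is trypsin-resistant and is returned as a
  single undigestible record, junction-flagged, linearized at position 1.
  (Consequently the "report" of a permuted-then-digested site-free core is
  a rotation of the original's, not an identical string.)
* A cleavage site at position n cuts the head-to-tail bond itself, so no
  0-missed fragment spans the junction in that case; otherwise exactly one
  does. Real mature cores end in W/Y/F, so the exception never applies to
  them.
* Repeats: fragments with identical sequence but different start are kept
  as distinct records; de-duplication is a reporting-layer helper.
* Missed cleavages default to 2 — enough to cover the observed
  one-missed-cleavage identification with margin.
* Semi-specific expansion (default minimum length 6) enumerates prefixes
  and suffixes of fully-specific peptides, as de-novo search stages report;
  the junction flag is recomputed from the truncated coordinates, never
  inherited, because a truncation can lose the wrap.
* Reporting note: the one-missed-cleavage identification of the 70-residue
  bacteriocin is sometimes quoted as "YLNEIK" in running text; the tabulated
  (and mass-consistent) form is `YLKNEIK`, which is what the toolkit
  reproduces.

## Fragment matching and the circularity verdict

Matching is tolerance-window search (±20 ppm default) of theoretical
[M+zH]z+ (z ∈ {1, 2} default) against the sorted peak list; every
peptide/modification/charge/peak combination within tolerance is reported,
so one peak may support several peptides — ambiguity is preserved, never
silently resolved. Match sets are monotone in the tolerance
(property-tested).

Verdict rule: `circular_supported` iff the intact cyclic hypothesis matched
AND at least one junction-spanning fragment matched; `linear_only` iff the
intact linear hypothesis matched and circular support is absent;
`insufficient` otherwise. Intact evidence alone is deliberately
insufficient: a −18 Da offset can have other causes, while a junction
peptide is structurally specific.

## Mining

* Coordinates are 1-based inclusive (GenBank dialect) everywhere; 0-based
  arithmetic exists only inside alignment internals.
* Role cascade: curated annotation keywords (spoiim/duf95, abc/atp-binding,
  immunity) take precedence over sequence heuristics, because GenBank
  products are curated. Heuristics: Walker A `[AG]x4GK[ST]` plus a
  hydrophobic-block Walker B for ABC ATP-binding proteins; Kyte–Doolittle
  hydropathy (window 19, threshold 1.6, segments ≥ 17 residues, gaps < 5
  merged — standard textbook settings, configurable in code) for
  membrane-like architecture; ≥ 4 TM segments at 150–400 residues with no
  annotation is a low-confidence SpoIIM/DUF95 call.
* Precursor anchoring: Smith–Waterman, BLOSUM62, gap open 10 / extend 1
  (fixed but overridable; identity-computation parameters are a package
  choice), hit threshold 30% identity over ≥ 50% of the panel core.
  Identity is identical columns over alignment columns (gaps included for
  global alignments, excluded for local). The leader/core boundary snaps
  the N-terminus to L/V/W within ±3 of the aligned start; the C-terminus
  must be W/Y/F at (or within 3 residues of) the protein's end. With
  `strict_termini` (default) candidates failing the snap are dropped;
  otherwise they are emitted flagged low-confidence.
* The bundled reference panel is **synthetic**: family-patterned stand-in
  cores (realistic length, composition and terminal residues), clearly
  labelled in the FASTA. It makes the homology machinery fully testable
  offline; for real mining, supply a curated panel of published mature
  cores. Closticin-type linear matches (≥ 40% identity, ≥ 50% coverage)
  are reported as `linear_like` calls and never receive a cyclization
  model, since their maturation is a different, unresolved process.
* Cluster span: all features within 6,000 bp of the precursor gene;
  completeness counts distinct context roles among SpoIIM/DUF95, ABC
  ATP-binding and membrane (0–3).

## Designer

* Split positions are numbered on the mature core's own 1-based scale.
  `circular_permute(core, k)` makes residue k the new N-terminus; the new
  C-terminus is residue k−1 (wrapping) — the pair the intein chemistry must
  re-ligate. Permutation is a bijection and composing split k with split
  n−k+2 restores the original order (brute-force-verified for all splits,
  lengths 2–10).
* Part order is IntC – permuted core – IntN – tag by default, configurable,
  because both arrangements exist in practice. The shipped IntC/IntN and
  the default SsrA-style tag are placeholders/configuration inputs — the
  intein YAML is where curated sequences go; all tests use short synthetic
  fragments.
* Reverse translation: `max_frequency` (deterministic, alphabetical
  tie-break) or `weighted` (seeded numpy PCG64). Round-trip
  translate(reverse_translate(p)) = p is property-tested for both. The
  bundled E. coli K-12 usage table carries approximate, commonly tabulated
  relative frequencies (noted in its header); only relative ranking matters
  for `max_frequency`.
* The expression cassette prepends ATG and appends TAA when absent, flanks
  with the T7 promoter/terminator constant regions used in the linear PCR
  templates, and refuses coding sequences with internal in-frame stops,
  reporting the codon index.

## Synthetic data: what it emulates and what it does not

`gen_cluster` emits a contig whose mature core is a **mutated descendant of
a panel core** (default 25% point-mutation rate, terminal 3 residues at
each end protected, middle indels to reach the target length — default 65
residues with a 49-residue leader including the start Met). This is the
realistic regime for family mining — new members are homologs — and it is
what makes recall measurable. Context genes: an ABC gene with embedded
Walker A/B, a K-free polar membrane protein with two hydrophobic 21-mers
(K-free so no spurious Walker A), an annotated SpoIIM/DUF95 gene, random
spacers of 150–400 bp.

`gen_peaklists` simulates fragment peaks as [M+2H]²⁺ of the full tryptic
digest (missed ≤ 2) with Gaussian ppm error (σ = 5 ppm default), a 30%
decoy fraction uniform over the observed m/z range but ≥ 50 ppm away from
every true peak (closer "decoys" would be indistinguishable from shifted
true peaks and would make the recovery target meaningless), and one intact
peak with σ = 0.3 Da. Linear-truth mode digests the unclosed chain and
emits the non-dehydrated intact species.

Not emulated: isotope envelopes, intensity/chromatography models, charge
states beyond 2+, co-purifying contaminant peptides, homology between the
leader and anything. Passing the synthetic loop therefore demonstrates the
*logic* (digestion, tolerance search, verdict rules) under calibrated
noise, not performance on real spectra, where search-engine-level scoring
(explicitly out of scope) would be needed.

All randomness uses numpy's seeded PCG64 (`default_rng(seed)`); identical
seeds reproduce byte-identical outputs.

## Problem sizes used in validation

The test suite validates the digest against its brute-force oracle on 500
random cores (lengths 10–80, 0–2 missed cleavages), the verdict loop on
200 seeded clusters at 5 ppm noise / 30% decoys (pass bar ≥ 95% correct;
zero-noise runs must be 100%), and the reverse-translation round trip on
1,000 random proteins. These sizes give stable pass/fail behaviour at
sub-minute runtimes.

## Known limitations

* The miner is a transparent homology-plus-architecture scanner, not a
  profile-HMM tool: sensitivity to remote homologs is traded for
  determinism and offline testability.
* Leader-boundary prediction is homology-plus-snap; where a genome's true
  leader boundary is not homology-resolvable the model is flagged rather
  than guessed (one defensible reading among several).
* Semi-specific expansion covers one ragged end only; doubly-non-specific
  fragments are not enumerated.
* Intact-mass interpretation assumes singly-protonated species; adducts
  (Na⁺, K⁺) are not modelled and must be absorbed by the Da tolerance.
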