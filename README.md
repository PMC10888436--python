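# circbact

Toolkit for discovering and verifying **head-to-tail circular bacteriocins**
— ribosomally synthesized antimicrobial peptides whose N- and C-termini are
joined by a backbone amide bond, with the loss of one water relative to the
linear chain.

It is aimed at microbiologists and proteomics analysts who have (i) a
bacterial genome suspected to encode circular bacteriocins and (ii) mass
spectra of purified culture supernatants, and who want to go from sequence
to a defensible *"this peptide is circular"* verdict, and on to an
expression construct.

## What it computes

**Cyclization mass accounting.** For a mature core of residues
$r_1 \dots r_n$, the neutral masses are

$$M_\text{linear} = \sum_i m(r_i) + m(\mathrm{H_2O}), \qquad
  M_\text{circular} = \sum_i m(r_i)$$

so circularization is a −18.011 Da (monoisotopic) event. Charge states
follow $[M+z\mathrm{H}]^{z+} = (M + z \cdot 1.007276)/z$. Intact masses from
linear-mode MALDI-TOF are compared on the average-mass scale (±1.5 Da);
high-resolution LC-MS/MS fragments on the monoisotopic scale (±20 ppm).

**Circular in-silico digestion.** Trypsin cuts after K/R except before P;
on a cycle, position $n$ is adjacent to position 1. The digest is
enumerated over the doubled sequence; with $s \ge 1$ cleavage sites and no
missed cleavages it yields exactly $s$ fragments, exactly one of which
spans the head-to-tail junction (unless the junction itself is a cleavage
site). Detecting that junction-spanning fragment in a spectrum is direct
evidence of circularity, because no linear form of the molecule can
produce it. Semi-specific prefixes/suffixes (one ragged end) are optionally
enumerated to mirror de-novo identifications.

**Cluster mining.** Protein-coding features (GenBank CDS, or six-frame ORF
calling on FASTA) are role-classified — annotation keywords first, then
Walker A/B motifs for ABC ATP-binding proteins and Kyte–Doolittle
transmembrane segments for membrane/SpoIIM-DUF95 candidates. Precursors are
anchored by Smith–Waterman homology (BLOSUM62, gap 10/1) to a panel of
mature cores, and the leader/core boundary is snapped to the family's
terminal-residue rule (core starts L/V/W, ends W/Y/F). The bundled panel is
**synthetic** (family-patterned stand-ins); point `--panel` at a curated
FASTA of real mature cores for production use.

**SIML construct design.** A chosen split position opens the cycle
(circular permutation); the permuted core is sandwiched as
IntC–core–IntN(–SsrA tag), reverse-translated with an E. coli codon-usage
table, and emitted as an annotated T7 expression cassette, or as a linear
T7 PCR template with flanking primers.

**Synthetic data.** A seeded generator produces toy genomes with known
cluster ground truth and simulated fragment/intact peak lists (ppm-scale
Gaussian error, uniform decoys), closing the loop for validation.

## Worked example

```bash
$ circbact mass --seq YAAEWLATNLGISR --charge 1
1564.8118
$ circbact mass --seq YAAEWLATNLGISR --charge 2
782.9095
$ circbact digest --seq LATNLGISRKGTGAKYAAEW --circular --missed 0
sequence        start   length  missed  junction        specificity     mh_plus
K       10      1       0       0       full    147.1128
GTGAK   11      5       0       0       full    433.2405
YAAEWLATNLGISR  16      14      0       1       full    1564.8118
```

The 20-residue circular core ends `...YAAEW` and begins `LATNLGISR...`;
the digest's junction-spanning fragment (`junction = 1`) reads straight
across the W→L closure, and its MH⁺ of 1564.8118 Da is what a targeted
LC-MS/MS run should detect (at z = 2: m/z 782.91).

The full pipeline on a synthetic fixture:

```bash
$ circbact simulate --seed 7 --out-dir fixtures/
$ cat > run.yaml <<EOF
genome: fixtures/genome.gbk
fragment_peaks: fixtures/fragments.txt
intact_peaks: fixtures/intact.txt
out_dir: out/
EOF
$ circbact run --config run.yaml
report -> out/report.json
```

`out/report.json` then contains one circular cluster call with
completeness 3 (SpoIIM/DUF95 + ABC + membrane context genes found), the
49-residue leader / 65-residue core precursor model, and
`"verdict": "circular_supported"` backed by matched junction fragments and
the −18 Da intact-mass check.

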