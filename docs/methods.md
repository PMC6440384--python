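# Methods

## Problem and scope

γδ T cells recognise antigen without MHC restriction; in adult blood the
compartment is dominated by Vγ9Vδ2 cells carrying a public canonical
Vγ9-JγP γ chain, while tumor-infiltrating γδ T cells can be enriched for
non-canonical Vγ9-Jγ2 rearrangements. `gdrep` implements the complete
analysis needed to establish such a contrast from amplicon sequencing:
segment-level read annotation, CDR3 junction extraction, clonotype
diversity and divergence statistics, canonical-vs-non-canonical
classification, and a k-mer screen that estimates γδ vs αβ T-cell
abundance from bulk RNA-seq. Because patient repertoire data of this
kind is controlled-access, the package pairs the pipeline with a V(D)J
recombination simulator that provides per-read ground truth, and every
claim the package makes is validated against that truth or against
independent brute-force oracles.

## Germline reference

Segments carry explicit junction anchors: `cys_anchor` is the 0-based
offset of the conserved 2nd-CYS codon on V segments; `fw_anchor` the
offset of the Phe/Trp codon of the J `[FW]-G-X-G` motif. All coordinates
are 0-based half-open, and anchors always point at codon starts — one
convention throughout prevents off-by-one junction bugs. Loading
validates structure loudly: 14 TRGV segments, TRDV1-3, the five shared
TRDV/TRAV segments, both TRGC exon groups, constant genes for all four
chains, anchors that actually translate to C and F/W on functional
segments.

The bundled reference is synthetic: real IMGT flat files are not
redistributed here, so sequences are generated with the locus's
*structure* — IMGT segment names (TRGV1-TRGV11, TRGV5P, TRGVA, TRGVB
reach the 14-count, with the six functional members flagged), correct
anchor motifs, near-identical TRGJ1/TRGJ2 (as in the real locus, with
enough differences inside the amplicon window to keep them separable),
highly similar TRGC1/TRGC2 and TRBC1/TRBC2 paralog pairs, and a TRGV9
3' end plus TRGJP 5' end that are germline-compatible with the public
canonical junction `C-ALWEVQELGKKIKV-F`. Constant genes carry the
IMGT/LIGM-DB accessions of their real counterparts as provenance notes.
Whether the 14-Vγ count includes pseudogenes is resolved here by fixing
the count at 14 and flagging functionality per segment. Any real
reference can be substituted as FASTA + metadata TSV and passes the same
validation.

## Simulator

Per clonotype: V and J (TRD: plus one D, chosen uniformly from TRDD1-3)
are drawn from configurable usage maps; each joined end is trimmed by a
Geometric(mean = `trim_mean`, support 0,1,2,…) number of nucleotides;
N regions have Poisson(`n_insert_mean`) length with uniform base
composition (one N region for TRG, two flanking the D for TRD). The
geometric/Poisson choices are minimal standard models for exonuclease
nibbling and TdT addition — the phenomena, not their exact
distributions, are what matters downstream. Clonotype frequencies come
from a symmetric Dirichlet whose concentration controls clonality
(small → oligoclonal). `canonical_spike` forces a fraction of reads to
the zero-trim, zero-insert Vγ9-JγP clonotype, emulating blood dominance
of the public sequence. Out-of-frame rearrangements arise at the rate
junction arithmetic implies and are flagged, not discarded, so artifact
filtering is testable.

Reads cover an amplicon window: the final 60 nt of the (trimmed) V
through the first 40 nt of the (trimmed) J. This is a declared
approximation of CDR3-centric amplicon designs; the real vendor primer
positions are proprietary. Sequencing error is per-base substitution
(no indels); qualities are constant Q30 — both documented
simplifications. Defaults (`trim_mean=2`, `n_insert_mean=4`,
`error_rate≈0.002` in scenarios) are typical of V(D)J junctions and
Illumina amplicon data.

Scenario builders define the study conditions: a blood-like sample
(canonical spike 0.35, JγP-heavy J usage, ~200 clonotypes,
concentration 2), a tumor-like sample (Jγ2-heavy usage, 80 clonotypes,
concentration 0.3, the three highest-frequency clonotypes forced to
Vγ9-Jγ2 with non-empty N regions and junctions disjoint from blood),
and an oligoclonal pair (one clonotype at 96% of blood reads,
error-free, clonotype sets forced disjoint so the divergence bound is
exactly attained). Determinism is strict: one `numpy` Generator seeded
from the config; identical config + seed gives byte-identical FASTQ.

What the simulator does not emulate — PCR amplification bias, UMI
structure, indel errors, paired-end artifacts, allele-level germline
variation — bounds what passing tests show about real data: they
validate the *algorithms* (annotation recovers the generating
rearrangement; statistics match their definitions), not platform-
specific error handling.

## Annotation

Smith-Waterman local alignment with affine gaps, implemented as a
numba-jitted DP. Scoring defaults: match +2, mismatch −3, gap open 5,
gap extend 2; a gap of length L costs `open + (L−1)·extend`; N never
matches. Minimum accepted scores are 40 for V and 20 for J (J segments
are short). Score ties are broken by smallest read start, then smallest
reference start; tie candidates are enumerated from all maximal cells
and resolved after traceback. Reads are scanned on both strands; the
orientation with the larger summed V+J score wins, ties going to the
given strand. The J is aligned to the read suffix after the V hit,
which enforces non-overlapping V/J intervals by construction.

Junction extraction is anchor-based, not alignment-end-based: the
junction runs from the read position *aligned to* the V cys anchor
through the last base of the J [FW] codon. This makes extraction immune
to chance extension of the local alignment into N-region bases. If an
anchor is outside the aligned region or falls in a gap the read is kept
with `pass_qc=False` and a reason code. Productivity = in-frame (length
divisible by 3) and stop-free. Reported `cdr3_aa` excludes the
flanking C and F/W; the stored junction includes them (AIRR
convention).

Artifact filtering removes no-calls, anchor failures, sub-threshold
hits and junctions outside 5-35 aa; the QC report counts every removal
by reason, making the filter auditable (published pipelines do not
disclose their artifact criteria, so this filter is a declared
stand-in). Base qualities are ignored by design.

## Repertoire statistics

Clonotypes are keyed by junction nucleotides + V call + J call;
amino-acid collapsing happens only in reporting, because treemap-style
repertoire views are of nucleotide sequences. Shannon index and JSD use
base-2 logarithms so that H is in bits and JSD is bounded by 1 with
equality exactly at disjoint supports; the base is a parameter of
`shannon_index` for users who prefer nats. JSD is reported as the
divergence, not its square root (the JS distance). JSD is computed over
the union support with absent keys at probability zero; the
implementation is cross-checked in tests against
`scipy.spatial.distance.jensenshannon` squared.

Top-10 tables report amino-acid-collapsed clonotypes per V-J pair with
two percentages: share within the (productive) reads of that V-J pair,
and share of all clean same-chain reads — the total-share denominator
is all clean reads of the chain, a documented choice where the source
convention is ambiguous. Ties rank lexicographically by CDR3 for
determinism. The treemap layout is the standard squarified algorithm;
areas equal frequencies to 1e-9 and tile the unit square.

Canonical classification: TRGV9+TRGJP → canonical (Cγ1 inferred);
TRGV9+TRGJ2 → non-canonical (Cγ2 inferred); anything else → other. The
constant-gene call is an inference from locus order (JγP1/JγP/Jγ1
precede Cγ1; JγP2/Jγ2 precede Cγ2) and is labelled inferred — amplicons
rarely reach the constant exon. The JγP lysine anchor is tested as a
CDR3 suffix motif (`KIKV`), a deliberate simplification of IMGT
position-109 numbering: J 5' trimming consumes the J's junction-proximal
end, so a surviving germline JγP tail always ends in KIKV.

## Bulk constant-gene quantification

The screen follows the BBDuk contaminant-matching semantics: a read
matches a gene if any k-window (default k=25, both strands) is within
Levenshtein distance 2 of any gene k-mer. "Edit distance" is full
Levenshtein, implemented as a banded DP (band = max distance) with a
Hamming fast path taken when no indel can change the decision — results
are identical to the plain definition, which the tests enforce against
an exhaustive edlib oracle. Multi-gene hits go to the minimum-distance
gene; exact ties split the count fractionally, which matters for the
TRBC1/TRBC2 paralogs. RPKM uses all input reads in the denominator by
default (configurable to evaluable reads ≥ k nt), since this screen has
no genome mapping step. The γδ/αβ ratio is
RPKM(TRDC)/(RPKM(TRBC1)+RPKM(TRBC2)), undefined (flagged, not zero)
when the denominator is empty.

## Numerical and design notes

* Frequencies are renormalised before entropy computation; `0·log 0`
  is 0 by mask; JSD is clamped to [0, 1] against rounding at the
  boundary.
* Evenness is H/log₂(richness), defined as 0 for a single clonotype.
* Segment-score ties during V/J selection resolve to the first segment
  in reference order (deterministic).
* Shared Vδ/Vα segments are addressable by compound id
  (`TRDV5/TRAV29`) or TRDV alias; lookup is case-insensitive.
* The demo cohort holds four synthetic patients — two diverse
  blood/tumor pairs, one oligoclonal pair, one canonical-rich-in-both
  pair — at 1,500 reads per compartment by default; tests and the
  acceptance script use 120-10,000 reads per step, sizes chosen so each
  statistical check has the power it needs (binomial/chi-square margins
  at 3σ) while the whole suite stays quick on a laptop.
* Reproducibility: every CLI artifact embeds version, seed, config and
  config hash, and contains no timestamps, so identical invocations are
  byte-identical.

## Known limitations

* The bundled reference is synthetic; absolute alignment scores against
  real reads require a real IMGT reference (drop-in via FASTA + TSV).
* No D-segment calling for TRD reads (np1/np2 decomposition exists only
  in simulator truth); no UMI deduplication; no indel sequencing-error
  model; no allele (\*01/\*02) resolution.
* Shannon/JSD values from heavily sequenced real samples depend on
  sequencing depth; no rarefaction or Hill-number framework is
  included.
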