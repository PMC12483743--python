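# Methods

This note documents the models, heuristics, parameters and numerical
choices behind `cathmine`, and what the synthetic-data tests do and do not
establish about behaviour on real assemblies.

## Locus detection (`locus_search`)

The search engine is a Gotoh affine-gap local aligner (numba-compiled DP,
deterministic traceback preferring diagonal > up > left) applied to the
164-residue cathelin consensus probe against all six reading frames of the
genome in 50 kb windows with 1 kb overlap. Windowed scanning keeps memory
linear in window size; the overlap exceeds the probe's coding footprint
(164 aa ≈ 492 nt), so no hit can be lost at a window boundary.

Defaults: BLOSUM62, gap open 11 / extend 1 (a gap of length L costs
11 + (L−1)·1) — the conventional choices for translated protein-vs-genome
search. Translation renders stops as `*` and N-containing codons as `X`;
`X` scores 0 against everything so N-filled scaffolds neither attract nor
repel alignments.

**Score threshold.** There is no E-value machinery; instead the reporting
threshold is calibrated per genome as mean + 5 SD of the best local scores
obtained on dinucleotide-shuffled (Altschul–Erickson) windows of the same
size as the scan window, with a floor of max(null sample) + 5. The floor
matters: with eight null samples the SD estimate occasionally collapses
while the true null max distribution has a long right tail. A locus is
confirmed only if one of its HSPs shows ≥ 55% identity over ≥ 25 aligned
residues; near-threshold random-sequence alignments run at ~30% identity,
whereas genuine cathelin hits in the use-case regime (within-order
conservation) are far above. Identity is computed over substitution
columns only — the probe legitimately aligns *across* whole introns with
multi-hundred-column gaps, and a gap-inclusive ratio would veto true loci.
HSPs within 5 kb merge into one locus, padded by 10 kb flanks.

## Exon assembly (`gene_assembly`)

All work happens on the locus sequence in gene orientation (reverse
complement for minus-strand loci); coordinates are mapped back to the
forward strand only when the model is emitted. Internal coordinates are
0-based half-open; GFF3 output converts to 1-based inclusive at the
boundary.

**Core exons.** Exon 2 (108 bp) and exon 3 (72 bp) are exhaustively
enumerated as segments with an AG immediately upstream (intron acceptor)
and GT immediately downstream (next intron's donor), whose best-frame
translation aligns to the probe with score ≥ 60 / ≥ 40. Three guards keep
the enumeration honest: the probe-alignment start must fall in the
mid-region window implied by the architecture (residues 40–95 for exon 2,
70–130 for exon 3, derived from the 150–260 nt exon-1 range), nearly the
whole segment must align (≥ exon length/3 − 2 residues), and exon 2 must
sit one intron-2 length (100–400 nt) upstream of exon 3 — if the best
scorer violates the spacing it is re-searched inside the window exon 3
pins down. Without these, 108-bp "shadows" inside exon 1 or exon 4 with
chance AG..GT flanks occasionally out-score the true exon.

**Exon 1** is an ATG..GT segment 200–1500 nt upstream of exon 2, length
150–260 nt, frame-compatible with exon 2, whose first 20 translated
residues match the probe start at ≥ 50% identity. Candidates score by
probe alignment plus a +6 bonus for GTGAG/GTAAG donors, minus 4 per
residue of deviation from the probe-implied exon-1 length (exon 2's
probe-alignment start tells us where exon 1 must end; without the penalty,
local alignment happily extends exon 1 in-frame into intron 1 whenever a
few intron-translated residues score positively). No signal-peptide
predictor is used: the signal span is fixed at residues 1–29 (the probe's
pre-cathelin region), overridable by the caller.

**Exon-4 repair.** Every acceptor (AG) 300–1500 nt downstream of exon 3
opens a candidate: the reading frame is carried across the junction (the
split codon's leftover bases prepended) and translated to the first stop,
capped at 700 nt. Candidates are scored

    total = domain_tail_score + acceptor_bonus − intron_len_penalty

with acceptor_bonus = 5 for CAG/TAG and penalty = 0.01/nt outside the
500–600 bp intron-3 band. The domain-tail score compares the first 12
residues of the candidate translation against the probe residues
immediately following exon 3's alignment end — the conserved domain
extends a few residues into exon 4, and this is the only sequence signal
that distinguishes the true acceptor. It is a *position-anchored* ungapped
score (±1 residue slack for the junction codon), not a local alignment: a
local score lets an acceptor shifted by whole codons clip its
out-of-register prefix and mimic the truth. An in-frame stop is a hard
constraint ranked above any soft score. A relaxed scan over every position
in the window (no AG required) runs alongside; if its best candidate is
non-canonical and beats the best AG-gated candidate by > 8 score units,
the intron is flagged `anomalous_acceptor` and the final triplet recorded
— this recovers genes whose acceptor has mutated (e.g. AG→GG). An AATAAA
within 1 kb downstream of the stop is recorded as a polyadenylation hint.

**Status mapping.** `missing_exon2`, `premature_stop` and
`anomalous_acceptor` ⇒ nonfunctional; `truncated_scaffold` and `n_gap`
(N-run ≥ 10 in the modelled span) ⇒ incomplete; four exons and no flags ⇒
complete. Premature stops are detected on the spliced translation, and
attributed to the exon containing the stop codon.

## Peptides (`peptide_derivation`)

Maturation follows the neutrophil-elastase rule: cleave immediately after
the first valine of the exon-4 translation (residues are assigned to the
exon containing their codon's first base). A translation whose exon-4
start is itself the only valine yields an empty propiece; one with no
valine raises a no-cleavage-site error and is reported unprocessed.

Names are `<Genus initial><two epithet letters>_<first two residues><length>`;
repeats within a run get `-2`, `-3`, … Peptides from defective genes keep
the same grammar but carry a `psi-` prefix in tables.

**CAP18.** The CAP18 (LPS-binding, helix-prone) region is modelled as a
log-odds profile built from a small shipped file of *synthetic* aligned
exemplars (`data/cap18_synthetic.fasta`, user-replaceable — the motif is
data, not code). Columns where every exemplar holds I/L/F/V are anchor
columns. Scoring slides the profile ungapped along the peptide (25%
overhang allowed); status is `present` if all anchors sit on I/L/F/V and
the score reaches 60% of the profile's self-consensus score, `similar`
at 40%, else `absent`. The 40% threshold was fixed by a shuffle
calibration: composition-preserving shuffles of the consensus reach it in
≤ 5% of 200 trials (enforced by a test).

**Secondary structure** is a Chou–Fasman-style heuristic: per-residue
helix/sheet/turn propensities averaged over a 5-residue window, state =
argmax if ≥ 1.0 else coil, then runs shorter than 4 (H), 3 (E) or 2 (T)
demoted to coil. A caller-supplied string overrides the heuristic verbatim
— typing never depends on a structure-prediction dependency.

**Eight types**, first match wins: T8 = exactly two cysteines (potential
intra- or inter-molecular disulphide); T6 = Pro ≥ 0.15 and Arg ≥ 0.20;
T7 = Arg ≥ 0.20 and Pro < 0.05 (the richness cut-offs are config values —
the source material says "rich"/"lacking" without numbers); then, crossing
CAP18 (present/similar vs absent) with structure: one helix and no strand
⇒ T1/T3; two helices joined by ≥ 1 turn ⇒ T2/T5; helix + strand ⇒ T4;
anything else is `unclassified`. CAP18 `similar` routes with `present` for
typing but is reported separately in tables.

## Comparative (`comparative`)

Progressive MSA: pairwise global (Gotoh) alignments give p-distances, a
UPGMA guide tree (lexicographic tie-breaks) orders profile–profile global
alignments (sum-of-pairs expected BLOSUM62 score, gap symbol −4).
Per-cent identity counts gap-containing columns as non-identical over all
columns and rounds half-up to two decimals, matching printed conventions;
how terminal gaps are treated in unequal-length comparisons follows the
same uniform all-columns rule. The consensus uses the display conventions
uppercase = unanimous residue, lowercase = dominant residue, `+` = exact
tie among ≥ 2 modal residues, `-` = strictly dominant gap; dominance is
the modal fraction.

Distances are p-distances with Kimura's correction d = −ln(1 − p − 0.2p²),
gap columns excluded pairwise, capped at 10 when the argument is
non-positive. Trees are neighbor-joining (standard Q criterion,
lexicographic tie-breaks) rather than maximum likelihood — a deliberate
simplification: the tree's role here is descriptive clustering of highly
conserved domains, and on additive matrices NJ reproduces the generating
metric exactly (tested to 1e-9). Bootstrap resamples columns with
replacement under a caller seed; supports are bipartition frequencies.

## Synthetic data (`synthetic_data`)

The generator emulates the gene architecture the assembler assumes: the
probe (or a user template) is reverse-translated with uniform codon usage
(validity, not codon-bias realism, is the goal), split at a sampled exon-1
length (uniform 150–260 nt) into exons of 108/72 bp and a remainder exon 4
ending in a stop, with AATAAA placed 30–300 nt downstream. Intron lengths:
triangular(270, 603, 1200) for intron 1 (typical value 603 with the
observed occasional extremes), uniform 134–160 for intron 2 and 500–600
for intron 3; donors and acceptors draw GTGAG/GTAAG and CAG/TAG at
75%/25%. Background is i.i.d. DNA at GC 0.42 (no repeat model), 100 kb by
default; the gene block sits between two short marker-ORF stubs in the
opposite orientation, mimicking the kinase/phosphatase neighbourhood of
real loci. Defect directives (delete_exon2, premature_stop,
acceptor_to_GG, insert_Ns, duplicate_exon4) are applied at construction
time with exact coordinate bookkeeping; `inject_defect` re-simulates from
the stored config with the directive appended, so results are
deterministic per seed.

What passing these tests shows: the assembler recovers exact exon
coordinates and calls lesion classes correctly whenever the architecture
assumptions hold and the gene is close to the probe. What they do not
show: robustness to repeats, paralogous pseudogene fragments, diverged
species at < ~60% probe identity, codon bias, indel-rich drafts, or
assembly chimeras — real-genome use should treat the defaults as starting
points and inspect the ranked exon-4 candidates in the report.

## Problem sizes and determinism

The round-trip property is evaluated on 200 seeded replicates of the
default 100 kb genome (≈ 1 s each on one core, numba-compiled), and defect
calling on 20 replicates per lesion class; unit tests use 25–30 kb
backgrounds, which changes nothing but the flank padding available. Every
stochastic step (simulation, shuffle calibration, bootstrap) takes an
explicit seed; identical seeds give byte-identical artifacts, a property
the CLI tests assert.
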