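# Methods

This note records the models implemented in phagecharm, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter when reading its output.

## Coordinates and data model

Internally every feature is 0-based, half-open, with an explicit strand;
conversion to GenBank's 1-based inclusive convention (and GFF3's on export)
happens only in the readers and writers. G+C content is computed over
unambiguous bases: `N` counts toward genome length but enters neither the
numerator nor the denominator. Coding fraction is the length of the **union**
of CDS intervals divided by genome length — overlapping genes, common in
phages, are counted once. Published coding-capacity figures computed from
summed gene lengths can therefore differ from this union-based value by a few
tenths of a percent; the union convention is used throughout and not
reconciled against any particular printed rounding.

## Gene calling

An ORF candidate is an allowed start codon (ATG, GTG, CTG, TTG) with at
least 30 further codons before the first in-frame stop (TAA/TAG/TGA,
translation table 11), on either strand. ORFs running off the sequence end
are excluded; for circularly permuted chromosomes, rotate to an intergenic
origin first (`rotate_origin` refuses to cut through a feature rather than
emit wrapped coordinates).

The ribosome-binding-site rule — "an upstream sequence resembling GGAGGT" —
is operationalized as the best ungapped match of the hexamer whose 3′ end
falls 4–16 bp upstream of the start codon, gated at ≥ 4 of 6 matching
positions. No published threshold exists for this style of screen; 4/6 within
canonical Shine–Dalgarno spacing is the weakest rule that still discriminates
at all on random sequence, and both the window and the gate are arguments.
Consequences of the weak gate are visible in the README example: on random
DNA it admits many chance ORFs, so recall of true genes is high while
precision is deliberately left to curation, matching how manually finished
phage annotations are actually produced. Within one stop-anchored frame the
longest qualifying start is kept (one gene per locus); `all_starts=True`
emits every candidate. Overlapping genes in different frames are allowed and
never resolved.

## Regulatory-element scanning

All scanners run both strands and report every placement within the mismatch
budget; hits identical in (pattern, position) on opposite strands — which
happens exactly for palindromic motifs — are both reported, with an optional
collapse. σ70 promoters are a −35 box TTGACA and −10 box TATAAT separated by
a 15–18 bp spacer with a *summed* mismatch budget; per anchor only the
fewest-mismatch placement is kept, ties to the shorter spacer. Degenerate
(IUPAC) patterns count mismatches only at constraining columns — an `N`
column is free.

`build_consensus` regenerates logo-style consensus patterns from aligned
sites: a column becomes a base at ≥ 80% frequency, a two-base IUPAC code when
the top two bases jointly reach 80% with ≥ 25% each, otherwise `N`. The rule
is a reconstruction — published consensus strings of this shape (conserved
anchors in a sea of N) never state the rule that produced them — and both
thresholds are arguments.

Genome-wide counts of short-motif hits are dominated by chance matches
(binomial expectation ≈ `2(L−w+1) · Σ_{k≤m} C(w,k) 3^k 4^{−w}`), so such
counts are validated here against brute-force oracles and closed-form
expectations, not against any published tally, and context filters
(`assign_upstream`, intergenic gating) are separate, composable steps.

## Terminator thermodynamics

Rho-independent terminators are called where a hairpin sits immediately
upstream (≤ 8 bp, strand-aware) of a run of ≥ 4 T's, with stems of 4–20 bp,
loops of 3–10 nt and at most one internal mismatch, and a free energy below
−10 kcal/mol. The energy model is a transparent additive nearest-neighbor
sum: unified DNA stack parameters (ΔG°37, 1 M NaCl) over consecutive
Watson–Crick pairs, plus a hairpin-loop initiation penalty tabulated by loop
length (log-extrapolated beyond 30 nt), plus a fixed +1.0 kcal/mol per
internal mismatched pair, which also breaks stacking on both sides. This is
deliberately not a full folding engine — no suboptimal structures, bulges,
dangling ends or pseudoknots — but it is monotone in stem strength, exact on
the bundled tables (tests hand-sum toy hairpins), and every reported call is
re-checked by an independent validator function. "Intergenic" means no
overlap with any CDS interval on either strand.

## Codon usage

"Frequency" is the within-synonymous-family relative frequency — the only
reading under which a 30% threshold is meaningful across 2–6-codon families;
a per-1000-codons measure is available separately. Stops are excluded from
family normalization; unobserved families report `None`, not zero. The
overrepresentation rule (family frequency ≥ 30% and ≥ 1.5-fold over host)
flags a codon with zero host usage as fold = ∞. Decoding uses standard
wobble at the codon third position (anticodon 5′ G reads C/T, T reads A/G,
A reads T, C reads G); positions 1–2 require Watson–Crick pairing. The host
codon table may be built from any CDS collection the user supplies; flagged
sets depend on that choice and are not fixed targets.

## Protein properties and the holin screen

Molecular weights are sums of **average** residue masses plus one water,
matching how predicted masses are compared to SDS-PAGE bands and intact-mass
measurements (monoisotopic masses behind a flag; N-terminal Met retained; no
PTMs). Isoelectric points solve the Henderson–Hasselbalch net-charge equation
(termini + D, E, C, Y, H, K, R; EMBOSS pKa values) by bisection until the
charge at the returned pH is within 0.001 of zero — note that different
published pKa sets shift pI by a few tenths of a unit; values are comparable
only within one set. Band assignment is nearest-neighbor within a tolerance
(default 8 kDa, wide enough for gel error but narrow enough that a compact
refolded protein running ~50 kDa light is flagged anomalous rather than
misassigned); several bands may legitimately map to one protein. Peptide
coverage is the union of exact-substring placements, each residue counted
once. The holin screen marks residues whose centered 19-residue mean
Kyte–Doolittle hydropathy is ≥ 1.6, merges runs separated by < 5 residues,
and calls a protein holin-like at ≤ 130 aa with 2–3 segments — a physics
screen, not a topology predictor.

## Host-range phenotyping

Detection time is the first (linearly interpolated) time OD reaches
baseline + 0.3, with baseline the minimum of the first 3 readings — the
reference OD for "+0.3" is never defined in microplate protocols, so it is a
documented, configurable choice. Replicate detection times are averaged per
arm before differencing. Categories: C when the phage arm never detects
within the run; D+ at a delay ≥ 5 h (closed boundary — exactly 5.0 h is D+);
D above the no-effect band; N within ±0.5 h (the band width is a choice — no
numeric width for "no delay" is ever stated — and a phage arm detecting
*earlier* than control also reports N). One-step growth parameters come from
a slope threshold on log10 titer (default 0.02 /min) splitting the curve into
pre-burst plateau, rise, and post-burst plateau; latent = last pre-rise time,
rise = span of the rising phase, burst = ratio of plateau means. This mirrors
reading the parameters off a plotted curve and avoids committing to a
parametric burst model.

## Proteome comparison

Homologs are reciprocal best hits under local alignment with BLOSUM62 and
affine gaps costing 11 + k for a gap of length k, thresholded on raw score
(default 75, mirroring classic BLASTP-score stringency screens). Because
alignment engines and versions differ, shared-homolog *counts* against
external proteomes are configuration-dependent and are not treated as fixed
values; the procedure is what is tested — against an exhaustive
dynamic-programming oracle for scores, and against planted homolog pairs for
recovery. A shared-4-mer prefilter skips pairs with no exact 4-mer in common;
on diverged-but-real homologs (≥ ~60% identity) it is lossless, verified
against the exhaustive mode in tests, and `exhaustive=True` disables it.
Identity is reported over aligned columns (gaps included) of the best local
alignment; for short chance alignments between unrelated proteins this can be
high even though scores stay far below the homolog threshold, so identity is
informative only for pairs that pass the score gate.

## Synthetic data: what it does and does not emulate

The generator lays planted genes left to right with background gaps of
i.i.d. bases at the requested G+C; gene bodies are sampled per amino acid
with GC-matched codon weights (optionally forced to a target within-family
fraction for bias experiments), so whole-genome G+C tracks the request to
within a point at ≥ 50 kb. Each gene carries a Shine–Dalgarno hexamer of
specified quality at 4–16 bp spacing; promoters (exact σ70 or late boxes) and
designed GC-stem terminators with T8 tails are planted only in intergenic
gaps. Growth-curve plates are logistic (baseline 0.1 OD, capacity 1.2, rate
1.0 /h, control midpoint 6 h) with category-determined delays (N: 0 h, D:
uniform 1–4 h, D+: uniform 5–10 h, C: held at baseline), triplicate wells,
additive Gaussian noise, 24 h at 20-min reads. Proteome pairs diverge
homologs by uniform point substitution at rate 1 − identity.

Deliberately absent: overlapping genes (planted genes never overlap so
recovery is unambiguous; real phage genomes overlap heavily), sequencing
error, operon structure, genuinely degenerate promoters, non-logistic growth,
indels in homologs, and compositional heterogeneity along the genome.
Passing recovery tests therefore demonstrates correctness of the procedures
under their own assumptions, not annotation accuracy on real genomes — that
is what the deposited-record validation surface (`phagecharm.validation`,
network-dependent) is for. A single integer seed drives one explicit
generator instance through all sampling; identical spec + seed is
byte-identical.

## Problem sizes and numerical conventions

Recovery runs use a 40 kb genome with 20 genes, 20 promoters and 10
terminators, 50+50-protein proteomes with 30 planted homologs at 60%
identity, and 24-strain plates shaped like the published host-range table
(11 C / 8 D+ / 1 D / 4 N) — large enough for stable rates, small enough that
the whole suite and the acceptance script each run in seconds. GC-skew
windows with no G or C report skew 0 flagged undefined, keeping profile
length fixed. Hairpin ΔG values are rounded to 0.01 kcal/mol; pI to 0.001 pH;
percentages to one decimal, matching how such tables are printed.
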