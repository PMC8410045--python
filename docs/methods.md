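# Methods

This note documents the models and procedures implemented in `neoforge`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Personalized proteogenomic database (`proteodb`)

A sample's search database contains two sequence sets, both gated by
expression of the source transcript (strictly TPM > 0):

1. **Canonical set** — the translation of every expressed coding
   transcript, standard genetic code, stopping at the first stop codon.
2. **Variant set** — one window per somatic variant on an expressed
   transcript. Missense: the mutant protein's residues
   [max(1, r−30), min(L, r+30)] around the substituted residue
   r = ⌈cds_pos/3⌉ (61-mer in the interior, substitution at window
   position 31). Frameshift: the indel is applied to the CDS, the mutant
   is retranslated from codon 1, and the window runs from 30 residues
   upstream of the first residue that differs from wild type through the
   residue before the novel stop; the whole novel region is marked
   mutated.

Coordinates are 1-based throughout (HGVS-style c./p. semantics). Variant
records use anchored replacement semantics (the reference bases at the
given CDS position are replaced by the alternate bases), which makes
missense SNVs and VCF-style indels uniform and lets every consequence be
re-verified by retranslation. Start-loss, stop-loss, nonsense and
synonymous inputs are rejected: they are not the missense/frameshift
events this analysis handles. Frameshifts whose shifted frame stops
immediately contribute no mutation-specific sequence and are dropped;
frames that never reach a stop are truncated at the last complete codon
and flagged `no_stop`. The choice to anchor the frameshift's upstream
context on the first *altered* residue (rather than the indel codon) keeps
the two window rules symmetric; for indels inside homopolymer runs the
first altered residue can lie downstream of the indel codon, so the two
conventions genuinely differ.

Exact duplicate sequences are collapsed with merged provenance; a window
identical to a canonical sequence is therefore not counted as
mutation-specific evidence downstream. The build is order-independent and
idempotent, and an all-silent sample (every TPM = 0) is a hard error
rather than an empty file.

## Binding percentile rank (`mhcrank`)

Binding prediction is a pluggable contract — anything exposing
`score(peptide) -> float` (higher = stronger) for lengths 8–11 — so an
external predictor can be wrapped unchanged. The bundled default is a
seeded per-length position-weight matrix with strong anchor weights at P2
(Y +3.0, F +2.5) and the C-terminal position (F/L/I/W +3.0/2.5/2.2/2.0)
over N(0, 0.3) background weights, emulating an HLA-A24-like motif. The
matrices are a pure function of the scorer seed and a version constant, so
scores are stable across runs.

%rank converts scores to a percentile against a background of random
peptides: for a query p of length L,
%rank = 100 · |{b in pool_L : s(b) ≥ s(p)}| / N with N ≥ 10,000 per
length. Ties count against the query (≥, not >), which inflates the rank
of tie-heavy scorers instead of promoting binders by tie luck. The pool is
drawn once per model from supplied amino-acid frequencies — the pipeline
passes the frequencies of the database being searched, so the background
mimics "random natural peptides" of that proteome rather than a uniform
alphabet.

Candidate enumeration takes every 8–11-mer substring of a variant entry
overlapping the mutated region by at least one residue (an interior
single-residue substitution yields 8+9+10+11 = 38 placements), collapses
duplicate peptide strings with the union of their mutated positions, and
filters at %rank < 2.0 (strict inequality) and source TPM > 0. For
frameshift entries any overlap with the novel region counts as mutated;
junction-spanning peptides are enumerated like any other overlap.

## MS/MS identification (`msident`)

Masses are monoisotopic: residue masses from the standard table, water
18.010565, proton 1.007276, Met oxidation +15.994915 (at most 2 variable
oxidations per peptide, bounding the modification combinatorics; the
positions are enumerated exactly). Fragments are singly protonated b/y
ladders; the identity b_k + y_{L−k} = M + 2·proton holds for every ladder
and is property-tested.

The no-enzyme index holds every distinct 8–11-mer substring of every
entry, keyed by neutral mass, with all source entries retained per
peptide. Decoys are whole-entry sequence reversals (preserving length and
composition spectra) searched concatenated with targets; a peptide string
occurring on both sides is assigned to the target side, the standard
concatenated-TDC convention.

Search matches candidates within ±10 ppm on the *neutral* mass (the
tolerance is then charge-independent) and fragments within ±0.02 Da, each
theoretical ion claiming at most its nearest observed peak. The score is a
log-hyperscore, log(Σ matched intensities) + log(n_b!) + log(n_y!), with
log-factorials via lgamma to avoid overflow. The best candidate per
spectrum is kept; exact score ties break toward the target, then the
lexicographically smallest peptide, for determinism. Spectra with no
candidate or no matched ion are unidentified, not errors.

q-values: for threshold s, FDR(s) = #decoys ≥ s / max(1, #targets ≥ s),
monotonized by taking the running minimum from the low-score end, so q is
nonincreasing in score. Acceptance is PSM-level q ≤ α (default 0.01)
reported at best-PSM-per-peptide; an accepted peptide is classified a
neoantigen iff every source entry is a mutation-altered window and the
peptide overlaps its mutated region. Whether peptide-level or PSM-level
q-values are "correct" here is underdetermined; both views are exposed
(`filter_fdr(..., peptide_level=...)`) without asserting one.

## Ligandome comparison (`ligandome`)

Ligandomes are peptide sets (8–11-mers, set semantics). The overlap
summary reports union size, peptides present in ≥2 samples, and per-sample
private counts; the tumor/normal partition calls a tumor peptide
"shared/normal" iff it occurs in *any* normal set, and the partition is
exact: shared + tumor-only = tumor set size. TAA selection keeps tumor-only
peptides with fold = tumor_TPM / max(normal_TPM, ε) strictly above the
threshold (default 20), using the maximal fold over a multi-gene peptide's
source genes. ε = 0.1 TPM is a pseudocount guarding zero normal
expression — such candidates are selected but flagged `normal_zero`, and ε
is a parameter, not a constant, because the right value depends on the
quantification pipeline's noise floor. Motif summaries are per-length
counts plus a 20×L column-stochastic position-frequency matrix.

## Assays (`assays`)

- **ΔMFI** — plain difference, negative values reported as-is.
- **4PL EC50** — least-squares fit of
  r(x) = bottom + (top − bottom)/(1 + (EC50/x)^hill), parameterized in
  log10 EC50, Levenberg–Marquardt with quantile-based initial values and
  8 seeded jittered restarts; negative-hill solutions are reflected into
  the canonical orientation. A warning is raised when responses do not
  span the asymptotes. On a noiseless 8-dose curve the EC50 is recovered
  within 1%. Information analysis shaped the generator default here: with
  8 *single* measurements at noise of 5% of range, the Fisher information
  bound on log10 EC50 is ≈0.098 (a ~15% median relative error floor, no
  estimator can do better), whereas triplicate wells — the standard
  dose-response plate layout — bring the floor to ≈0.056 (~9% median).
  The generator therefore simulates triplicate wells by default.
- **LDH lysis** — 100 · (experimental − effector_spontaneous −
  target_minimal)/(target_maximal − target_minimal), clipped to [0, 100]
  with a flag (round-off at the limits is not flagged). The exact algebra
  of the published equation is not visible in the extracted text; this
  form follows the stated definitions of spontaneous/minimal/maximal
  release and is the standard LDH correction — flagged as an assumption.
- **VAF** — alt/depth with 0 ≤ alt ≤ depth, depth > 0.

## Repertoire (`repertoire`)

Frequencies are count shares with a stable ordering (count desc, CDR3
lexicographic). Expansion is strictly greater than the threshold (default
2%): a clone at exactly 2.0% is excluded, matching the "over 2%" reading.
Clone matching requires equality on CDR3 (amino-acid level; a nucleotide
CDR3 column is honored when both sides carry it), V and J, and on D/C only
when both records report them — D and C calls are frequently absent from
short-read clonotyping, so requiring them unconditionally would discard
true matches.

## Synthetic data (`synthdata`)

One integer seed drives everything; each stage derives a child generator
from seed + CRC32(stage name), so stages rerun independently and all
outputs (FASTA/TSV/MGF) are byte-identical per seed.

What is emulated, with defaults chosen as realistic desk-scale analogues
of the study conditions: coding transcripts (default 50, CDS 300–900 nt)
with correlated tumor/normal log-normal TPM (log-mean 3, log-sd 1.5) and
an exact fraction (default 10%) silent; missense:frameshift variants at
roughly the hypermutated-tumor ratio (default 30:6, mirroring a 3367:600
class balance) with binomial read support at depths 100–600; ligandomes
realized with *exact* sharing counts and planted TAA peptides whose source
genes get an exact configured fold (default 25); spectra with fragment
jitter sd 0.004 Da (below a third of the 0.02 Da matching tolerance),
precursor jitter 2 ppm, 10 uniform noise peaks, charges 1–3, and foreign
spectra built by shuffling true peptides' interiors until absent from the
database — composition-preserving, so they compete for the same precursor
windows and keep the decoy comparison honest; 4PL titrations in triplicate
wells; clonotype tables as one multinomial draw over planted frequencies
plus a power-law background.

Not emulated (hence not demonstrated by passing tests): chromatographic
retention, isotope envelopes and co-isolation chimeras, peptide-level
detectability bias (real immunopeptidomics loses low-abundance and
low-affinity peptides), splice isoforms and germline phasing, sequencing
error in read counts, and V(D)J recombination statistics beyond gene-name
sampling. Results on real data will degrade in proportion to how much
these matter.

## Pipeline and interfaces

`run_pipeline` composes the stages file-to-file (the only inter-stage
contract) and writes a report whose every count is re-derivable from the
stage outputs; it is deterministic per seed. The same stages are exposed
as `neoforge` subcommands and as the numbered drivers in `analysis/`. All
thresholds (%rank 2.0/0.5, FDR 0.01, 10 ppm/0.02 Da, 20-fold, 2%) are
config keys defaulted to the analysis' operating points.

## Known limitations

- The bundled PWM scorer is a motif emulator for testing the %rank
  machinery, not a trained binding predictor; wrap a real predictor for
  real HLA work.
- The hyperscore search has no rescoring layer (no retention-time or
  intensity-prediction features); its FDR calibration is demonstrated on
  synthetic spectra only.
- Entry-level reversal decoys can underestimate FDR for heavily
  palindromic databases (not the case for natural proteins).
- The expression gate is transcript-level TPM of the searched sample;
  isoform-aware or allele-specific expression is out of scope.
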