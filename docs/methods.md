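# Methods

## Virtual tag extraction

SAGE library construction digests cDNA with NlaIII (site `CATG`) and
sequences the fragment downstream of the 3′-most site of each
transcript. The database builder therefore emits, per transcript, the
3′-most `CATG` on the sense strand plus the following `tag_length − 4`
bases. Tag length is configurable; the default of 27 (anchor + 23 nt) is
the scale of SOLiD-era SAGE tags and is recorded in the database
metadata. A transcript whose 3′-most anchor leaves too little downstream
sequence contributes no tag by default — that mirrors the physical
protocol, where only the 3′-most restriction fragment is captured; an
opt-in fallback walks to earlier anchors instead. Tag windows containing
`N` are suppressed (indeterminate sequence cannot be matched reliably).
Ambiguity is defined at the gene level: a tag shared by several
transcripts of one gene is a single unambiguous entry, a tag shared
across genes is flagged ambiguous and is never counted downstream.
Coordinates are 0-based internally.

## Tag assignment and TPM

Assignment is exact-first (hash lookup), with a Hamming search over the
whole database only on an exact miss — equivalent to a full scan because
distance 0 always beats any positive distance. Within the mismatch
allowance (default 2), only minimal-distance hits vote on gene identity;
if they span more than one gene the tag is discarded as ambiguous. This
tie rule is the standard read-mapping convention; discarding new
ambiguity created by the mismatch search is a deliberate choice in
keeping with the unambiguous-mapping rule for exact hits. The search
packs tags into 64-bit words (2 bits/base, tags ≤ 32 nt) and computes
whole query batches by XOR + popcount; longer tags fall back to a
byte-matrix comparison. Iteration order is lexicographic so outputs are
byte-stable.

TPM uses only assigned (uniquely mapped) tags in its denominator, which
is why a library of several million raw reads can have a noticeably
smaller TPM denominator. ΣTPM = 10⁶ holds for every non-empty profile
and is asserted in the tests. Base-call qualities are ignored; an
optional minimum-count-per-tag filter exists but is off by default.

## Differential expression

Fold change is stored as treated/control with direction derived from it;
the selection criterion is two-sided, `max(FC, 1/FC) ≥ fc_min`, so up-
and down-regulation are treated symmetrically. The abundance filter is
`TPM > tpm_min` in at least one library (default 10, strictly greater; a
flag makes it inclusive, and another makes the FC comparison strict).
A zero TPM on one side is replaced by the TPM of a single tag computed
from *that library's own total* — the familiar 0.2 figure is just the
single-tag TPM of a ~5-million-tag library, not a constant. Genes at
zero in both libraries have no defined ratio and are skipped. No
p-values are attached: with one pooled library per condition there is no
within-group variance to estimate, and the design intentionally ranks by
measured effect size only.

Abundance profiles bin expressed genes by TPM (default edges at powers
of ten from 0.2 up, chosen to span the observable range down to the
single-tag TPM) and report, per bin and cumulatively, the number of gene
entries and the fraction of all tags they carry, plus threshold queries
of the form "entries above t TPM and their tag share".

## Enrichment

Fold enrichment is (m/n)/(M/N) on the harmonised (case-folded) gene
universe; the p-value is the exact hypergeometric upper tail
P(X ≥ m). A flag applies the conservative EASE-style jackknife
(evaluating the tail at m − 1), and Benjamini–Hochberg adjustment is
optional; the default is the plain exact test at raw α = 0.05 because
that is the usual screening configuration for this kind of desk
analysis. The background is always user-supplied — there is no built-in
genome size. DE genes absent from the background are dropped with a
logged count rather than silently.

## qPCR arm

Technical replicates are averaged on the Ct scale before anything else
(standard plate practice). Amplification efficiency is fixed at 2, so
relative quantity is 2^(−Ct); per-gene efficiency calibration is out of
scope. geNorm's classic M is implemented: the mean, over partner
candidates, of the SD across samples of the pairwise log2 ratio —
computed directly on Ct differences since log2(2^(−Ctj)/2^(−Ctk)) =
Ct_k − Ct_j. The normalisation factor is the geometric mean of the
reference genes' relative quantities, and −ΔΔCt baselines the target's
ΔCt against the mean ΔCt of the control group, yielding a log2 fold
change per treated individual.

Panel validation (≥ 2-fold in ≥ 5 individuals) is a configurable default
rather than a universal standard; the threshold is recorded in the
outputs. Dose dependence is a strict inequality on mean log2 FC between
doses with no significance test attached — it is a qualitative call.
Group comparisons use the equal-variance Student's t-test; groups with
zero pooled variance get the limiting convention p = 1 (equal means) or
p = 0. Clustering is agglomerative with Pearson-correlation or Euclidean
distance (average linkage by default, matching common heatmap-viewer
defaults); note that correlation distance is blind to magnitude, so
questions like "does the uniformly up-regulated treatment separate from
the rest" are Euclidean questions. Trees are serialised as Newick with
branch lengths derived from merge heights.

## Synthetic data

The generator reproduces the *shape* of the study, not its biology:

- **Abundances** are log-normal on the TPM scale, renormalised to 10⁶,
  with a cap at 150,000 TPM (no transcript above ~15% of the library,
  matching the dynamic range seen in real SAGE libraries). The default
  σ = 3.5 (natural log) at 2,000 genes puts roughly a tenth of gene
  entries above 100 TPM while they carry the overwhelming majority of
  tags — the defining skew of these libraries.
- **Planted effects** default to 100 genes at 4×, 100 at 0.25×, 50 at 2×
  and 50 at 0.5×; the treated condition renormalises to 10⁶, so realised
  TPM ratios differ from planted effects by a common factor near 1 (both
  are recorded in the truth table).
- **Libraries** are multinomial draws (default 2×10⁶ tags each — large
  enough for stable TPM at the filter boundary, small enough to run the
  whole study in seconds; the full 13.6-million-tag depth is a manifest
  parameter away). Sequencing errors are independent per-base
  substitutions (default 0.5%); no indels, since the matcher is
  Hamming-based, and no quality model.
- **Ct tables** place gene baselines uniformly in 18–26 cycles, shift
  treated samples down by the true log2 FC (optionally jittered per
  individual to mimic biological variability), and add Gaussian
  technical noise (default SD 0.25 cycles) per replicate. The analytic
  standard error used to check recovery combines replicate averaging,
  reference averaging, and the shared control baseline.

Every generator is a pure function of the manifest and seed
(`numpy.random.default_rng` seeded per stream), so outputs are
bit-reproducible and truth tables always join generated data on gene and
sample identifiers.

What passing these benchmarks does **not** show: the generator has no
3′-bias, no PCR duplication, no transcript-length effects, no isoform
structure, no correlated errors, and its null genes are exactly null —
real libraries violate all of these, so recovery rates here are upper
bounds on real-data performance, and the matcher's ambiguity handling is
exercised only lightly (random 27-mers rarely collide).

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| tag length | 27 nt | SOLiD-SAGE scale; configurable, recorded in metadata |
| mismatch allowance | 2 | bounded-error tag mapping convention |
| TPM filter | > 10 | ~3 transcripts/cell; physiologically meaningful abundance |
| FC filter | ≥ 2 | effect-size selection without replicates |
| enrichment α | 0.05 | raw screening cutoff; BH optional |
| references | geometric mean of 3 genes | geNorm-selected stable trio |
| validation rule | ≥2-fold in ≥5/9 fish | per-individual robustness call |
| simulation | 2,000 genes, 2×10⁶ tags | minutes-scale, stable statistics |

## Known limitations

Transcript-space mapping only (no intron-aware genome mapping, no
antisense tags); NlaIII only (the anchor string is configurable but no
other enzyme logic is modelled); no replicate-aware DE statistics by
design; no ortholog mapping in enrichment (case-insensitive string match
only); no primer design, melt-curve QC or absolute quantification in the
qPCR arm.
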