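# Methods

This note documents the models behind each simulation stage, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
fixtures do and do not establish about real data.

## Count model

Counts are Gamma–Poisson: X<sub>fc</sub> | s<sub>c</sub> ~
Poisson(s<sub>c</sub> λ<sub>fc</sub>) with λ<sub>fc</sub> ~ Gamma(mean
μ<sub>f</sub>, variance φ<sub>f</sub>μ<sub>f</sub>²), i.e. a negative
binomial with Var = μ + φμ² per unit size factor. φ = 0 degenerates to
Poisson. Size factors are log-normal; at simulation time s<sub>c</sub> =
exp(σ·z) so the median factor is exactly 1 and μ<sub>f</sub> is directly
"UMIs per median cell". This is a deliberate simplification of richer
count simulators (gene–gene correlation, batch structure and
multivariate-hypergeometric library-size conditioning are not modelled);
its defence is that the marginal mean–variance behaviour, sparsity and
library-size spread — the properties that matter for read-level
simulation — are matched and fully testable.

Estimation is by method of moments. Size factor = cell total / median cell
total. With y = x/s, E[y] = μ and Var(y) = μ·E[1/s] + φμ², so
φ̂ = (v̂ − μ̂·mean(1/s)) / μ̂², floored at 0 for under-dispersed features.
Empty cells (zero total) are excluded rather than given an undefined size
factor. Tests recover μ within 5 % and φ within 20 % at 2000 cells, which
is about the Fisher-information limit for moment estimators at that sample
size.

## Read structure and transcript choice

The perfect-read layout is `adapter · CB · UMI · (dT)₂₀ · cDNA · TSO`.
Defaults follow 10x Chromium 3′ v3 geometry: 16 nt barcode, 12 nt UMI,
20 nt oligo(dT). The default adapter is the partial read-1 primer sequence
and the TSO the usual template-switch oligo; both are plain configuration
values, not protocol constants, and can be overridden. Barcodes come from
a user whitelist (drawn without replacement), are used verbatim when the
matrix columns already are valid barcodes, or are generated as random
distinct 16-mers and written out as the ground-truth whitelist.

For gene-level matrices the isoform is drawn with weight exp(−L/τ). A
single-parameter exponential prior is monotone in length, bounded, and
reduces to uniform as τ → ∞; τ defaults to 2000 nt, which at typical
isoform length differences of 1–3 kb gives the short isoform a 70–90 %
share — the qualitative behaviour seen in dT-primed long-read libraries
where shorter cDNAs amplify and sequence preferentially. UMIs are i.i.d.
uniform 4-letter strings; collisions are allowed, as in reality.

Intron retention is a per-molecule Bernoulli event (default probability 0,
i.e. off). The unspliced sequence is the full genomic span from first exon
start to last exon end on the annotated strand; it requires a GTF and
genome and raises a clear error otherwise.

## Truncation

cDNA truncation is modelled by the joint empirical distribution of relative
alignment endpoints (t<sub>start</sub>/L<sub>t</sub>,
t<sub>end</sub>/L<sub>t</sub>) over primary PAF alignments, binned on a
50×50 grid by default. Sampling picks a bin by mass, then a uniform point
inside it; drawn endpoints are floored/ceiled to integer coordinates with a
minimum retained length of 1 nt and start < end enforced. Bin edges may
have zero width, in which case sampling returns the boundary exactly — the
"no truncation" default is the degenerate model with start fixed at 0 and
end at 1, so full-length molecules are reproduced byte-exactly rather than
merely "within a bin width". The grid resolution trades smoothness against
sample-size noise; 50 bins needs a few thousand alignments to populate
sensibly.

## PCR branching process

Each cycle, every pool molecule independently spawns one copy with
probability P_dup (default 0.9), so E[|pool|] = N(1+P_dup)^cycles and the
exact pool-size variance follows the recursion v′ = (1+p)²v + p(1−p)m,
which the tests use as their oracle. Copies are made from the current
template, so substitutions accumulate down lineages — this heritability is
the point of the stage, since it produces UMI-duplicate families with
shared errors that barcode/UMI collapsing tools must handle.

Mutations are substitution-only with per-base probability P_error (default
3.5×10⁻⁵). Indels during PCR are not modelled; polymerase errors are
overwhelmingly substitutions and a fixed-length model keeps the process
simple (a documented limitation). The per-copy mutation count is drawn
Binomial(L, P_error) and positions sampled without replacement —
distributionally identical to per-base Bernoulli but ~10⁴× fewer RNG calls
at realistic rates. `N` bases are never mutated. An overflow guard rejects
runs whose expected pool exceeds 2×10⁸ molecules. Unmutated copies share
their template's string object, so memory grows with the number of
*mutated* copies, not the pool size times read length. Subsampling (after
all cycles) is uniform without replacement with randomized order.

## Sequencing-error model

Per-read accuracy is beta distributed. Identities are computed from PAF
alignments under three definitions — gap-included (matches / all alignment
columns, using the PAF block length), gap-excluded (matches / M=X columns),
gap-compressed (each indel run counts one column) — the standard triple for
long-read identity. Values are clamped to [10⁻⁶, 1−10⁻⁶] before fitting
(the beta likelihood diverges at the boundary); the fit is method of
moments refined by maximum likelihood, falling back to the moment estimate
if the MLE mean drifts more than 10⁻³ from the sample mean (moment matching
is part of the contract). Fits need ≥ 10 values with non-degenerate
variance; a constant identity should be run as a fixed value instead.

Error injection places `round(L·(1−identity))` events at uniform distinct
positions; each event is a substitution, insertion or deletion per the
error profile (default ⅓ each). The deterministic event count keeps the
realized-vs-target calibration tight (|realized − target| ≤ 0.02 for
L ≥ 500, verified against an independent edit-distance realignment with
edlib in the tests). This is intentionally simpler than k-mer-trained
basecaller error models: no homopolymer enrichment, no adapter hot-spots,
no quality–error correlation along the read. Per-base quality is
Q = −10·log₁₀(max(error rate, 10⁻⁴)) plus integer jitter in [−3, 3],
clamped to [2, 40] — a stand-in whose only contract is that implied error
probabilities track the realized error rate within a factor of two.

## Pipeline and determinism

The `all` command chains counts → templates → (optional) PCR → errors →
QC in one process. Stage RNGs are spawned from the single global seed via
`SeedSequence`, every intermediate is written, and a manifest records
config, per-stage seeds and SHA-256 checksums; the HTML report contains no
timestamps, so identical config + seed reproduce identical bytes end to
end (asserted in the tests).

## Synthetic fixtures and their limits

The toy reference is one chromosome with multi-exon genes on alternating
strands; extra isoforms skip one internal exon each, so isoforms share
sequence but differ in length, exercising the length prior, splicing and
intron retention. Splicing correctness is oracle-checked by re-extracting
exons from the genome. Constructed PAF files realise exact truncation
endpoints and identities by building the coordinates and CIGAR backwards
from the requested values.

These fixtures validate the machinery, not biological realism: toy genes
are a few hundred nt (real transcripts are kilobases), expression is
homogeneous across cells (no cell types, no differential expression), and
constructed alignments have no mapping ambiguity. Passing tests show the
estimators and generators are correct and calibrated under known truth;
fidelity to a specific real dataset comes from feeding the package a real
matrix and real alignments.

Test and acceptance problem sizes (10⁴ molecules for growth-rate recovery,
10⁶ duplicated kilobases for mutation-rate recovery, 10⁴ draws for
distribution fits) were chosen so Monte-Carlo standard errors sit several
times below the asserted tolerances.
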