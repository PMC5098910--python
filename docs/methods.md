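# Methods

`idrscape` characterizes intrinsically disordered, acidic, repetitive
proteins from primary sequence alone. This note records the models
implemented, the parameters that matter, the numerical choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real data.

## Charge model and isoelectric point

Each chain is modelled as a set of independent ionizable groups with fixed
pK values: exactly one free N-terminal amino group and one free C-terminal
carboxyl group, plus one group per K, R, H (basic) and per D, E, C, Y
(acidic) side chain. At pH `x` a basic group of constant `pK` contributes
`+1/(1+10^(x-pK))` elementary charges and an acidic group
`-1/(1+10^(pK-x))` (Henderson–Hasselbalch). The default pK set is the
EMBOSS table:

| group | Amino | Carboxyl | C | D | E | H | K | R | Y |
|-------|-------|----------|---|---|---|---|---|---|---|
| pK    | 8.6   | 3.6      | 8.5 | 3.9 | 4.1 | 6.5 | 10.8 | 12.5 | 10.1 |

Users may supply any nine-group pK table as JSON. Post-translational
modifications are not modelled, and masked `X` residues carry no charge.

Every chain has at least one basic and one acidic group (the termini), and
each summand is strictly decreasing in pH, so the net charge has exactly one
root in (0, 14). `isoelectric_point` brackets it by plain bisection to a
tolerance of 1e-4 pH units (≈47 iterations; robust, and fast enough that a
fancier root finder buys nothing). Reported pI values are rounded to two
decimals (round-half-away) in human-facing output; the full-precision root
is used internally. Acidity percentiles use a strict inequality — "more
acidic than P% of the proteome" counts proteome proteins whose pI is
strictly greater — so ties count against the query.

## Charge–hydropathy (Uversky-plane) classification

Per-residue hydropathy uses the Kyte–Doolittle scale rescaled affinely to
[0, 1] via `(kd + 4.5)/9` (the published scale spans [-4.5, +4.5]), averaged
over a centred window of 5 residues. At the termini the window shrinks
(truncates) rather than padding, so the profile always has one value per
residue and the mean is a true per-residue mean. `<H>` is the mean of that
profile; `<R>` is `|net charge at pH 7.0| / length`, computed with the full
Henderson–Hasselbalch model above rather than the integer `K+R-D-E` count
(the count shortcut is available behind `approximate=True`). A chain is
called **disordered** iff

    <H> < (<R> + 1.151) / 2.785

the empirical boundary between natively unfolded and folded proteins in
this plane. Points exactly on the boundary are called folded — "disordered"
is deliberately the strict-inequality side. The classifier takes pre-cut
IDR sequences; delimiting IDRs within full-length proteins (disorder
prediction) is the caller's responsibility.

## Composition enrichment and bootstrap errors

Enrichment of residue x in a query dataset against an ordered reference is
`(C_x - C_order)/C_order`, with frequencies pooled over all residues of the
dataset. Residues absent from the reference have undefined enrichment and
are reported as NaN, never ±inf. Error bars are the SD over bootstrap
replicates in which both datasets are resampled with replacement at their
original sizes and the enrichment recomputed; the resampling unit is the
residue (implemented as multinomial draws over the 20 frequencies, which is
exactly residue-with-replacement resampling), with a per-sequence mode
behind `unit="sequence"`. Default `n_boot=10000`; results are reproducible
bit-for-bit given a seed. The weighted sum Σ C_order,x · enrichment_x equals
Σ C_x − Σ C_order = 0, a conservation identity asserted to 1e-9 in tests.

The bundled `ordered_like` / `disordered_like` reference tables are
synthetic package constants mirroring the qualitative enrichment directions
of ordered versus disordered datasets (disordered: up D/E/S/T/P/K/G/Q, down
W/C/F/I/Y/V/L/M); real analyses should supply their own reference FASTA or
frequency table.

## Motif scanning and track smoothing

The SUMO-interacting-motif pattern is the ELM-style regular expression
`[DEST]{0,5}.[VILPTM][VIL][DESTVILMA][VIL].{0,1}[DEST]{1,10}` — a
hydrophobic core flanked by acidic/phosphorylatable residues. Because the
flanks are variable-length, matches can overlap; the default reports the
maximal non-overlapping set scanning left to right with each match
leftmost-greedy (discrete "bar" semantics), and `overlapping=True`
enumerates a greedy match from every start position. The murine tandem
repeat is counted as non-overlapping occurrences of `GE[PMS]E[ST]EAK`.
All coordinates are 0-based half-open; only human-facing reports convert
to 1-based.

Score tracks are smoothed by simple exponential smoothing with the
*damping-factor* convention used by spreadsheet tools: with damping `d`
(default 0.9), `s_1 = x_1` and `s_t = (1-d)·x_t + d·s_{t-1}` — i.e. the
smoothing constant is `1-d`. Smoothed values never leave `[min(x), max(x)]`.

## Ortholog triage

From per-domain HMM-search hit tables (HMMER3 `--domtblout` or a simple
TSV), the rules are: keep hits with full-sequence E-value **strictly** below
1e-5 (a hit at exactly the threshold is removed); per gene keep the longest
isoform (gene tag when present, else the id root before the isoform
delimiter `-`; ties to the lexicographically smallest id); per species keep
a single strain — the one contributing the longest protein (untagged
entries unaffected; the representative-strain rule is a documented
assumption, as only "one strain per species" is specified by the
procedure); collapse identity components (from reciprocal-search output or
exact equality) to the longest member. A surviving protein is a **full**
family member iff all three domains (protease, zinc finger, HMG box) have
significant hits, **partial** iff protease + zinc finger but not all three,
else **none**. The per-domain conditional E-values of domtbl rows are
ignored; significance is whole-protein.

## HMM-similarity clustering

Directed match probabilities p_ij from HMM–HMM comparison are converted to
dissimilarities D_ij = −ln p'_ij with a floor p' = max(p, 0.001). The floor
is applied to every probability below 0.001, not only exact zeros, so that
D remains monotone in p (a zeros-only mode exists for strict fidelity to
the substitute-zeros convention). The natural log is used; any other base
rescales all heights uniformly and cannot change the topology. Directed
pairs are symmetrized by the arithmetic mean of the two −log values
(elementwise strongest-evidence mode behind `symmetrize="max"`), and the
diagonal forced to zero. Agglomeration is average linkage (UPGMA-style) via
`scipy.cluster.hierarchy.linkage`; the test suite checks its merge
sequences and heights against an independent O(n³) brute-force agglomerator
on random matrices (ties have probability zero there; SciPy's own
tie-breaking applies on degenerate inputs). Matrix readers auto-detect
percentage-scaled inputs (any value > 1) and rescale by 1/100, logging the
decision. Newick export sets branch lengths to parent-height minus
child-height with leaves at height zero.

## Synthetic data

The generators are pure functions of a `GeneratorSpec` whose seed feeds
fixed-label child streams (`[seed, crc32(label)]`), so adding a generator
never perturbs existing outputs. They emulate: i.i.d.-residue proteomes
from ordered-like/disordered-like/uniform composition profiles; sequences
with literal motifs or tandem repeat blocks spliced at recorded offsets;
hit tables with known full/partial/none architectures (significant E-values
log-uniform on [1e-12, 1e-6], decoys on [1e-4, 1]); block-structured
probability matrices (within-block Beta with mean 0.9, between-block mean
0.01, unit diagonal); and step-function disorder tracks (levels 0.2/0.8,
Gaussian noise σ = 0.1).

What passing the synthetic suites shows: the *computations* are correct —
scans find what was planted, triage recovers known architectures,
clustering recovers planted blocks, estimators match independent oracles.
What it does not show: performance on real proteins. i.i.d. residues have
no local sequence structure, real IDR/ordered compositions are less cleanly
separated than the synthetic profiles, real E-value distributions are not
log-uniform, and real HMM–HMM probabilities are not Beta block models. The
bundled stand-in transcript likewise exercises the full
translate→characterize pipeline with known ground truth (25 planted repeat
units, an acidic repeat-dominated composition giving pI ≈ 4.20) but is a
constructed sequence, not biological data.

## Problem sizes and degenerate inputs

Test and acceptance runs use deliberately modest sizes — 100 random
sequences for the pI oracle comparison (grid step 1e-4), 200 sequences of
length 300 per class for charge–hydropathy separation, 200 proteins for
triage recovery, 100 random matrices of n ≤ 8 for the clustering oracle,
2000 bootstrap replicates — chosen so the whole suite completes in well
under a minute while keeping every statistical margin wide (the separation
and recovery rates sit at ≈100% against 90% thresholds). Degenerate inputs
are rejected with specific errors: empty sequences and FASTA files,
non-standard residues (strict mode) or masked to X (permissive), even
smoothing windows, non-consecutive track positions, non-square or
asymmetric matrices, NaN dissimilarities, empty proteomes. Translation
without an in-frame stop emits a dedicated warning and returns the full
read-through product.
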