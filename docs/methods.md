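# Methods

This note records the models, conventions and design choices behind
`irscreen`, in the order a user meets them.

## The screen: identity ratios over a species panel

Each gene is represented by one protein per species — the longest annotated
isoform, with equal-length ties broken by the lexicographically smallest
accession so the choice is reproducible. All unordered species pairs are
aligned globally and the percent identity collected into a symmetric matrix.

**Alignment.** Needleman–Wunsch with affine gaps; BLOSUM62, gap open 11,
gap extend 1 (protein-BLAST defaults), where a gap of length *k* costs
`open + k·extend`. Global alignment is deliberate: the acceleration
statistics compare whole orthologs, so terminal gaps are divergence and must
be penalised, unlike in local search. The engine is Biopython's
`PairwiseAligner`; when several tracebacks are co-optimal the engine's first
traceback is used, which is deterministic for fixed inputs (the identity
count, not the traceback, is what the downstream statistics consume; the
optimal *score* is verified against an independent brute-force recursion in
the tests). The ambiguity letter X scores 0 against every residue and never
counts as an identity.

**Percent identity.** Identical columns divided by total alignment columns,
×100 — the BLAST reporting convention. Because published screens do not
always state their denominator, `denominator="shorter"` (identities over the
shorter ungapped length) is available everywhere, and the RefSeq
reproduction example reports both. Identities are kept at full precision
internally; reports round to 2 decimals.

**IR and EIR.** With matrix *M* and species roles (reference, focal,
baseline; default human, house mouse, bovine):

    IR  = M[ref, focal] / M[ref, base]
    EIR = (Σ_t M[focal, t]) / (Σ_{t<u} M[t, u]),  trio default {human, bovine, rabbit}

Both are scale-free (invariant to uniform rescaling of the matrix) and the
EIR denominator is symmetric in the trio. IR compares the focal lineage's
divergence from the reference with the baseline's; EIR pools three
reference lineages and is the more stringent statistic, so the screen ranks
and fences on EIR by default (IR is always reported alongside).

**Outlier fencing.** Over the screened panel the chosen ratio's median, Q1
and Q3 are computed with linear interpolation between order statistics (the
most common quantile convention; fixed here so goldens are stable), and
genes below the Tukey lower fence `Q1 − 1.5·IQR` are flagged. The phrase
"lower 1.5 interquartile" in screen write-ups is read as exactly this fence.
At least four complete gene panels are required — below that the fence is
meaningless. Genes missing a panel species are skipped, logged and counted
in the report, never silently dropped.

## Exon-partition selection-site rates

Selection-site calls are consumed as TSV (1-based residue position, class
`positive`/`negative`, calling method) from external MEME/FEL/FUBAR-class
analyses; this package does not run codon-model site inference. Exon
partitions are ordered, non-overlapping 1-based inclusive residue intervals;
a call maps to at most one partition and otherwise counts as unassigned
(conservation: per-partition counts plus unassigned equals total calls).
Calls from different methods are never merged silently — mixed call sets
require an explicit method choice. Rates are `100·count/length` reported to
1 decimal.

Two partitions' rates are compared with the pooled two-proportion z test,
two-tailed, no continuity correction:

    p* = (x1+x2)/(n1+n2),  z = (x1/n1 − x2/n2) / sqrt(p*(1−p*)(1/n1+1/n2))

A pooled proportion of exactly 0 or 1 has zero variance and is rejected as
degenerate rather than reported as z = 0. The test treats residues as
independent trials, which selection-site calls only approximately are; the
test is used here as the conventional screen-level significance summary.

## The ω (dN/dS) estimator

Gene-level ω is estimated with the Nei–Gojobori (1986) counting method on a
gap-free pairwise codon alignment (standard genetic code only):

- Per codon, each of the nine single-nucleotide neighbours contributes 1/3
  of a site, classified synonymous or nonsynonymous; mutations creating a
  stop codon count as nonsynonymous. Site totals are averaged over the two
  sequences, so N + S = 3 × codons.
- Codon differences at 2–3 positions are averaged over all minimal
  mutational paths; paths through stop-codon intermediates are excluded
  (the standard NG86 choice). If every path is blocked — possible only for
  rare codon pairs — all paths are used as a fallback.
- pN = Nd/N and pS = Sd/S are corrected for multiple hits with Jukes–Cantor,
  `d = −(3/4)·ln(1 − 4p/3)`; p ≥ 3/4 makes the correction diverge and the
  result is flagged rather than forced. ω = dN/dS, undefined (flagged) when
  dS = 0.

This is a transparent desk-scale estimator, not a maximum-likelihood codon
model: it ignores transition/transversion bias and codon frequencies, and
with strong transition bias it is biased downward because synonymous sites
are undercounted. Published ω values from likelihood tools on curated
alignments are therefore not expected to be matched numerically; the
estimator is validated instead by calibration on simulations with known ω
(see below).

## The simulator

**Protein families.** A root sequence is drawn uniformly over the 20 amino
acids and evolved down a Newick species tree. Along a branch of length *d*
(expected substitutions per site, optionally scaled by a per-branch rate
multiplier), each site receives Poisson(*d*) substitution events, each
replacing the residue uniformly among the other 19. This uniform-replacement
model was chosen over an empirical matrix because it admits a closed form:
two leaves at total path distance *d* match at a site with probability

    E[identity] = 1/20 + (19/20)·exp(−20d/19)

which the tests use as an exact oracle (binomial 3-SE bands at d = 0.05,
0.2, 0.5). Lineage acceleration is a rate multiplier on the focal terminal
branch; branches are addressed by leaf name or by the `+`-joined sorted leaf
set of their clade.

**Default tree.** `((human:0.09,(rabbit:0.10,house_mouse:0.12):0.02):0.02,bovine:0.16)`
— a Glires-consistent toy topology in which the house mouse groups with
human and rabbit against bovine *and* the human–mouse path (0.23) is shorter
than the human–bovine path (0.27), so the equal-rate IR expectation exceeds
1 as the statistic's phylogenetic argument requires. Branch lengths are
illustrative, not inferred; the screen's conclusions depend only on the
ordering of path lengths.

**Codon families.** Root codons are uniform over the 61 sense codons; each
codon site draws an ω class once at the root and keeps it. Along a branch of
length *d*, a codon receives Poisson(3d) mutation proposals: a uniform
position, a target nucleotide with transition weight κ versus 1 per
transversion (default κ = 2, a typical mammalian transition bias), stop
proposals rejected, and nonsynonymous proposals accepted with probability
min(1, ω). Acceptance–rejection makes ω the ground-truth
nonsynonymous/synonymous rate ratio at each site. Estimator calibrations are
run at κ = 1 so the counting estimator's mutational assumptions match the
generator exactly and deviations measure implementation error, not model
mismatch; the κ-bias of NG86 is a documented property, not a defect under
test. Neutral calibration (100 pairs × 500 codons) requires the mean
estimated ω within [0.9, 1.1]; observed means are ≈ 0.95–0.96, the small
deficit being the stop-rejection edge effect shared by any NG86-style
count.

**Screen-scale datasets.** `generate_screen_dataset` simulates *n* gene
families (default length 300 aa — a mid-sized protein, large enough that
per-gene identity noise does not swamp a 2× acceleration), an accelerated
subset drawn without replacement, and emits per-gene FASTA, a truth TSV and
a flat key-value manifest (tree, parameters, seed). The recovery experiment
of record: 200 genes, 20% accelerated 2× on the focal branch — accelerated
genes show a lower median EIR than background in ≥ 95% of 20 seeded runs
(observed: 20/20), and under equal rates the fence flags < 5% of genes.

**What the simulator does not emulate.** Indels (alignments of simulated
proteins are effectively gap-free), rate heterogeneity across protein sites,
empirical amino-acid exchangeabilities, codon-usage bias, isoform structure
and recombination. Passing recovery tests therefore demonstrate the
statistics' behaviour under controlled divergence, not performance on real
proteomes, where alignment quality and annotation (isoform choice) dominate.

## Numerical and interface conventions

- Coordinates 1-based inclusive everywhere, matching amino-acid numbering.
- Gene symbols uppercased for matching; no alias mapping.
- FASTA headers `accession|gene_symbol|species`, with a plain-accession
  dialect plus a sidecar metadata TSV for database downloads; sequences
  uppercased, one terminal `*` stripped; 60-column wrapping on write.
- TSV readers ignore undeclared columns with a warning, and reject missing
  required ones.
- Ratios and percent identities: full precision internally, 2 decimals in
  reports; partition rates 1 decimal; p-values 2 decimals in reports.
- Seeds are explicit in every stochastic entry point; identical seeds give
  byte-identical outputs.

## Known limitations

- The RefSeq reproduction of the published FAM161A numbers requires a
  manual download (documented in `examples/refseq_fam161a.py`); the package
  never fetches from NCBI, and the exact printed values also depend on the
  original tool's undocumented alignment settings, which is why both
  identity denominators are reported.
- The two-proportion z test's independence assumption is optimistic for
  clustered selection sites.
- NG86 ω is pairwise; no tree-aware or branch-specific ω is computed.
- Only genetic code table 1 is supported.
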