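# Methods

## Reference-anchored residue typing

The pipeline's central operation is reading the residue at a fixed
reference coordinate — AtDFR position 133 for DFR, AtFLS1 position 132 for
FLS — off an arbitrary homolog. Rather than building a multiple sequence
alignment, each candidate is aligned pairwise to the family reference with
a Needleman–Wunsch/Gotoh dynamic program (optimal global alignment, affine
gaps) and the reference coordinate is projected through the gaps. This is
deterministic, dependency-free, and sufficient for position anchoring; an
externally computed MSA in aligned FASTA is accepted as an alternative
input wherever an alignment is consumed.

Scoring defaults: BLOSUM62, gap open 10, gap extend 1, with a gap of
length L costing `open + (L−1)·extend`. These are conventional defaults
and are exposed in `ScoringScheme`, not hard-coded. `X` (ambiguity from
N-containing codons) and `*` (internal stop retained by translation) score
0 against every residue: ambiguity is neutral, and pseudogene candidates
must remain alignable so they can be reported as non-functional "-like"
sequences rather than dropped. Ties are broken deterministically —
match/mismatch over gap-in-candidate over gap-in-reference — so repeated
runs are bit-identical.

All protein coordinates are 1-based; codon extraction uses the half-open
nucleotide interval `[3(p−1), 3p)`. Translation uses the standard genetic
code; a single trailing stop is stripped silently, an internal stop is
kept as `*` and flagged; any codon containing N becomes X even where the
code would be unambiguous (e.g. GCN), a conservative choice since X never
satisfies a residue rule. CDS records whose length is not a multiple of
three are rejected rather than frame-guessed.

### Classification table

The anchor residue maps to a type and substrate set (DHK/DHQ/DHM =
dihydrokaempferol/-quercetin/-myricetin):

| family | residue | type | substrates | confidence |
|---|---|---|---|---|
| DFR | N | DFR_N | DHK, DHQ, DHM | reported |
| DFR | D | DFR_D | DHQ, DHM | reported |
| DFR | A | DFR_A | DHK | reported |
| DFR | L | DFR_other (noted) | DHK | reported |
| DFR | other | DFR_other | — | none |
| FLS | H | FLS_H | DHK, DHQ | hypothesized |
| FLS | F | FLS_F | DHK | hypothesized |
| FLS | Y | FLS_Y | DHQ | hypothesized |
| FLS | other | FLS_other | — | none |
| either | deleted | absent | — | none |

A deletion spanning the anchor is typed `absent`, never `other`: a missing
column is evidence of a different kind than a substitution. The table is
config-loadable; the shipped default is the one above.

### Functionality screening

FLS candidates are screened for the published required residues (G68, H75,
P207, G261 for the 2-ODD fold; H132/F134/K202/F293/E295 for DHQ binding,
with position 132 admitting the three type residues H/F/Y) and for the
motifs `PxxxIRxxxEQP`, `SxxTxLVP`, the ferrous-iron motif
`Hx(D/E)x{40,150}H`, and `RxS` scanned in the C-terminal half. A motif
counts as a failed check only when it has no match anywhere in the
sequence. The iron-motif gap bounds (40–150) are deliberately wide — the
spacer length varies across 2-ODD proteins and no canonical bound exists —
to avoid false negatives; the `RxS` positional restriction to the
C-terminal half likewise reflects that the 2-oxoglutarate-binding residues
sit in the C-terminal part of the fold without a fixed coordinate. For DFR
the per-position requirements beyond the anchor are not fully enumerated
in the literature, so the shipped DFR rule set checks presence of the 26-residue substrate-binding region (reference
positions anchor−2 … anchor+23) with at most 30% gaps; users can supply a
curated rule TSV. `functional` is true iff no check failed; typing is
independent of the functional flag.

## Phylogenetics

Distances are protein p-distances with pairwise deletion (gapped columns
skipped per pair). Maximum-likelihood inference and codon models are out
of scope by design; NJ over p-distance is the self-contained stand-in and
external newick trees can be imported instead. Neighbor joining follows
Saitou–Nei with two numerical conventions fixed for reproducibility: ties
in the Q matrix go to the smallest (i, j) index pair, and a negative
branch-length estimate is clamped to zero with the deficit transferred to
the sister edge (the pairwise path length is preserved). The final three
lineages are resolved in closed form at an unresolved root, giving the
conventional unrooted NJ tree. Bootstrap resamples alignment columns with
replacement, rebuilds the NJ tree, and reports the percentage of
replicates containing each internal bipartition of the full-data tree;
everything is driven by one integer seed. Annotation clones the tree (the
topology and branch lengths of the input are never modified), suffixes
leaf labels with their type, and writes an iTOL COLORSTRIP dataset with an
injective color map over the nine type labels plus `untyped`.

## Expression analysis

Only TPM drives pairing and the index (counts are carried through and
summed, but cross-sample comparison needs the length/depth normalization);
the detection floor defaults to 1 TPM, a conventional threshold, and is
config-exposed. "Close paralogs" is operationalized as protein identity
≥ 0.8 (global-alignment identical columns over alignment length) together
with an identical anchor residue; merging is by connected components so
the rule is order-independent, and genes with different anchor residues
are never merged regardless of identity. The exclusivity index
(median |F−D|/(F+D) over retained samples) is an artifact-defined summary
of the qualitative "one or the other, almost never both" expression
pattern and is labeled as such in every output; it is invariant to gene
relabeling and to a common positive rescaling of all TPM values. The
density grid bins log10(TPM+1) on both axes over a shared range so the
grid total equals the retained-pair count; rendering log-scales the color
with a pseudocount of 1.

## Synthetic data

The generator exists so that every stage has ground truth. The packaged
reference proteins are **synthetic**: random sequences of length 310 (FLS)
and 330 (DFR) with the required residues and motifs planted at the real
reference coordinates, generated once from a fixed internal seed. They
carry the coordinate system and the screening targets, not the real
Arabidopsis sequences; any real reference can be supplied instead.

Families diverge from the reference iid (star topology): per-site
substitutions at rate 0.10 by default, indels at rate 0.02 with
geometric(0.5) lengths (mean 2), the anchor residue drawn from a
configurable distribution and back-translated to a uniformly chosen
synonymous codon (no codon-usage table — codon identity is only exercised
by codon extraction). Indels avoid the terminal 3 columns to prevent
end-gap ties. `protect_anchor` keeps indels out of a ±3-column window
around the anchor: a gap placed at the anchor's flank can slide over the
anchor column at equal or better alignment score whenever neighboring
residues repeat, so admitting adjacent indels would make "recovery of the
planted residue" ill-defined rather than merely hard. Even so, recovery is
not information-theoretically guaranteed at 10% substitution divergence —
a substituted neighborhood can occasionally imitate a gapped alignment
that scores higher than the true one (roughly one sequence per thousand in
our runs) — which is why recovery rates are quoted at fixed seeds.

The expression generator emulates the cross-species sample structure: per
sample, with probability ρ exactly one of FLS/DFR is "on" (TPM lognormal
with ln-scale μ = 3, σ = 1, i.e. median ≈ 20 TPM; the other gene uniform
on [0, 0.01] TPM), otherwise both are on; each family's total is split
over its paralogs by a Dirichlet draw, and a few noise genes pad the gene
universe. Defaults are 10 species × 50 samples and ρ = 0.9, a level
consistent with "almost never both". What passing tests on this generator
do **not** show: robustness to mislabeled samples, batch effects, isoform
ambiguity in quantification, or the cell-type mixing that makes bulk
RNA-seq co-expression an upper bound on single-cell co-expression — none
of which the generator emulates.

## Problem sizes and known limitations

The shipped tests and the acceptance script use 200-sequence families,
500-sample expression studies, 6-taxon NJ oracles and 100-replicate
bootstraps — sizes chosen so the whole suite completes in well under a
minute while every statistic is far from its noise floor. The aligner is
O(nm) per pair and comfortably handles thousands of candidates against a
~350-residue reference; the NJ implementation is O(n³) and intended for
the hundreds-of-leaves regime, not tens of thousands. Monophyly verdicts
are exact-set checks and therefore sensitive to a single mislabeled leaf.
The pairwise-anchoring strategy can misplace an anchor when divergence
approaches the twilight zone; for such data an externally computed MSA
should be supplied instead.
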