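# flavotype

Substrate-preference typing of the competing flavonoid enzymes **FLS**
(flavonol synthase) and **DFR** (dihydroflavonol 4-reductase), with
neighbor-joining phylogenetics and cross-species expression analysis.

## The problem

Dihydroflavonols (DHK, DHQ, DHM — differing in B-ring hydroxylation) sit at
a branch point of flavonoid biosynthesis: FLS oxidizes them to colorless
flavonols while DFR reduces them toward colored anthocyanins and
proanthocyanidins, so the two enzymes compete for the same substrate pool.
Which dihydroflavonols each enzyme accepts is strongly associated with a
single substrate-preference determining residue, expressed in Arabidopsis
reference numbering: position 133 of AtDFR and position 132 of AtFLS1.

* DFR: **N**133 accepts all three dihydroflavonols; **D**133 prefers
  DHQ/DHM; **A**133 prefers DHK; L restricts to DHK.
* FLS: **H**132 (DHK and DHQ), **F**132 (DHK), **Y**132 (DHQ) — these
  associations are hypothesized from DHQ-binding-site mutagenesis.

`flavotype` turns this residue logic into a reproducible pipeline for any
set of coding sequences:

1. **Anchoring** — each candidate protein is globally aligned to the family
   reference (Needleman–Wunsch/Gotoh, BLOSUM62, affine gaps) and reference
   coordinates are mapped through the gaps, so "position 133" can be read
   off any homolog.
2. **Typing & screening** — the anchor residue assigns the type
   (DFR_N/D/A, FLS_H/F/Y, `…_other`, or `absent` for a deletion); the
   residues and motifs required for catalysis (2-ODD fold residues
   G68/H75/P207/G261, DHQ-binding H132/F134/K202/F293/E295, the
   iron-binding motif `Hx(D/E)x{n}H`, 2-oxoglutarate-binding `RxS`, the
   FLS-specific motifs `PxxxIRxxxEQP` and `SxxTxLVP`, and the 26-residue
   DFR substrate-binding region) decide a functional flag.
3. **Phylogenetics** — p-distance + Saitou–Nei neighbor joining with
   column-bootstrap support, leaf annotation by type, and iTOL color-strip
   export.
4. **Expression** — kallisto `abundance.tsv` tables are merged per the
   sample metadata, close paralogs (same anchor residue, protein identity
   ≥ 0.8) are summed, and per sample the pair (F, D) of total functional
   FLS and DFR TPM is scored with the **exclusivity index**

   index = median over samples of |F − D| / (F + D),  F + D ≥ 1 TPM,

   an artifact-defined statistic where 1 means every sample expresses only
   one of the two genes and 0 means perfectly balanced co-expression, plus
   the standard 2D density grid over log10(TPM+1) with marginal histograms.

A fully deterministic synthetic-data module generates diverged CDS families
with planted anchor residues and per-sample abundance tables with a tunable
exclusivity parameter ρ, so every stage is testable without downloads.

## Worked example

The `report` subcommand runs the full simulate → type → expression chain
and scores the pipeline against the generator's truth tables:

```bash
flavotype report --out demo --seed 1 --n-sequences 60
```

prints

```json
{
  "anchor_residue_accuracy": 1.0,
  "type_label_accuracy": 1.0,
  "type_confusion": {
    "DFR_A->DFR_A": 18,
    "DFR_D->DFR_D": 21,
    "DFR_N->DFR_N": 21
  },
  "expressed_call_accuracy": 1.0,
  "n_samples_scored": 500,
  "exclusivity_index": 0.9995217589559697,
  "n_samples_used": 500,
  "seed": 1
}
```

All 60 simulated DFR homologs (10% substitution, 2% indel divergence) are
re-typed to their planted N/D/A residues; across 500 simulated samples with
exclusivity ρ = 0.9 the expressed gene is called correctly in every sample
and the exclusivity index is ≈ 1, i.e. the generator's near-mutually
exclusive FLS/DFR expression is recovered.

The individual stages are available as `flavotype simulate|type|tree|
expression` (see `--help`), and the underlying functions are importable
from `flavotype` for scripted use.

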