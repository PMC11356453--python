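"""Sequence and table I/O for the FLS/DFR typing pipeline.

Reads and writes the plain-text formats the pipeline touches — FASTA,
newick, and the kallisto ``abundance.tsv`` dialect — and translates coding
sequences.  All protein coordinates in this package are 1-based; codon
extraction uses half-open nucleotide intervals so that protein position
``p`` corresponds to CDS slice ``[3*(p-1), 3*p)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "TranslationFlags",
    "FastaFormatError",
    "FrameError",
    "DialectError",
    "read_fasta",
    "write_fasta",
    "translate_cds",
    "codon_at",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_newick",
    "write_newick",
    "ABUNDANCE_COLUMNS",
]

CDS_ALPHABET = set("ACGTN")

#: exact kallisto abundance.tsv header, in order
ABUNDANCE_COLUMNS = ("target_id", "length", "eff_length", "est_counts", "tpm")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty file, duplicate ids)."""


class FrameError(ValueError):
    """Raised when a CDS length is not a multiple of three."""


class DialectError(ValueError):
    """Raised when an abundance table does not match the kallisto dialect."""


@dataclass
class SequenceRecord:
    """A named sequence, either coding DNA ('cds') or protein.

    CDS residues are upper-cased on load and restricted to A/C/G/T/N;
    protein residues are upper-case letters plus '*' (stop) and '-' (gap,
    only in aligned contexts).
    """

    id: str
    residues: str
    molecule: str = "cds"  # 'cds' | 'protein'
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.molecule not in ("cds", "protein"):
            raise ValueError(f"unknown molecule type {self.molecule!r}")
        self.residues = self.residues.upper()
        if self.molecule == "cds":
            bad = set(self.residues) - CDS_ALPHABET
            if bad:
                raise ValueError(
                    f"CDS {self.id!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TranslationFlags:
    internal_stop: bool = False
    trailing_stop_stripped: bool = False


def _infer_molecule(residues: str) -> str:
    return "cds" if set(residues.upper()) <= CDS_ALPHABET else "protein"


def read_fasta(path: str | Path, molecule: str | None = None,
               species: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Multi-line bodies are concatenated and record order is preserved.
    ``molecule`` may be forced; by default it is inferred per file (a file
    whose residues are all A/C/G/T/N is taken as CDS).  Duplicate ids and
    empty files raise :class:`FastaFormatError`.
    """
    path = Path(path)
    parsed = list(_BioSeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FastaFormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    residues = [str(r.seq).upper() for r in parsed]
    if molecule is None:
        mol = "cds" if all(set(s) <= CDS_ALPHABET for s in residues) else "protein"
    else:
        mol = molecule
    records = []
    for rec, seq in zip(parsed, residues):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=seq, molecule=mol,
                                      species=species))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="")
           for r in records]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# translation

_FORWARD = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _FORWARD[_stop] = "*"


def _translate_codon(codon: str) -> str:
    # any N-containing codon is conservatively ambiguous, even where the
    # genetic code would be unambiguous (e.g. GCN)
    if "N" in codon:
        return "X"
    return _FORWARD[codon]


def translate_cds(record: SequenceRecord) -> tuple[SequenceRecord, TranslationFlags]:
    """Translate a CDS record with the standard genetic code.

    A single trailing stop codon is stripped silently; an internal stop is
    kept as ``*`` and flagged, because pseudogene candidates must remain
    typeable downstream.  A length not divisible by 3 raises
    :class:`FrameError`.
    """
    if record.molecule != "cds":
        raise ValueError(f"{record.id}: translate_cds expects a CDS record")
    n = len(record.residues)
    if n % 3 != 0:
        raise FrameError(f"{record.id}: CDS length {n} is not a multiple of 3")
    aa = [_translate_codon(record.residues[i:i + 3]) for i in range(0, n, 3)]
    flags = TranslationFlags()
    if aa and aa[-1] == "*":
        aa.pop()
        flags.trailing_stop_stripped = True
    if "*" in aa:
        flags.internal_stop = True
    protein = SequenceRecord(id=record.id, residues="".join(aa),
                             molecule="protein", species=record.species)
    return protein, flags


def codon_at(record: SequenceRecord, protein_position: int) -> str:
    """Codon coding for 1-based protein position ``p``: cds[3(p-1) .. 3p)."""
    if record.molecule != "cds":
        raise ValueError(f"{record.id}: codon_at expects a CDS record")
    n_codons = len(record.residues) // 3
    if not 1 <= protein_position <= n_codons:
        raise IndexError(
            f"{record.id}: protein position {protein_position} outside 1..{n_codons}"
        )
    i = 3 * (protein_position - 1)
    return record.residues[i:i + 3]


# ---------------------------------------------------------------------------
# kallisto abundance dialect

def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    """Read one kallisto ``abundance.tsv`` file.

    The header must be exactly ``target_id length eff_length est_counts
    tpm`` (tab-separated).  Returns a DataFrame indexed by ``target_id``.
    Negative counts or TPM raise ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != ABUNDANCE_COLUMNS:
        raise DialectError(
            f"{path}: expected columns {list(ABUNDANCE_COLUMNS)}, "
            f"found {list(df.columns)}"
        )
    if df["target_id"].duplicated().any():
        dup = df["target_id"][df["target_id"].duplicated()].iloc[0]
        raise DialectError(f"{path}: duplicate target_id {dup!r}")
    for col in ("est_counts", "tpm"):
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0, "target_id"].iloc[0]
            raise ValueError(f"{path}: negative {col} for {bad!r}")
    return df.set_index("target_id")


def write_abundance_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index() if df.index.name == "target_id" else df.copy()
    if tuple(out.columns) != ABUNDANCE_COLUMNS:
        raise DialectError(
            f"cannot write abundance table with columns {list(out.columns)}"
        )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# newick

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; branch lengths and internal support labels kept."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: newick parse error: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)


def newick_string(tree: dendropy.Tree) -> str:
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return buf.getvalue().strip()
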