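"""Aligned protein-family container with per-sequence metadata.

The :class:`AlignedFamily` is the substrate of every sequence-level stage:
linker delimitation, the per-column co-segregation screen, and distance-based
phylogenetics.  Sequences are stored as aligned strings over the 20 standard
amino acids plus the gap character ``-`` and the ambiguity code ``X``;
metadata (taxon, optional class label) travels alongside in a DataFrame
indexed by sequence id.

Coordinates are 1-based throughout the public API: alignment columns are
numbered ``1..alignment_length`` and residue positions are 1-based on the
ungapped sequence, matching the conventional residue numbering of motifs such
as the p-loop lysine K14.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AMBIGUOUS = "X"
ALPHABET = frozenset(AMINO_ACIDS) | {GAP, AMBIGUOUS}


@dataclass
class AlignedFamily:
    """An immutable-ish multiple sequence alignment plus metadata.

    Parameters
    ----------
    ids
        Unique sequence identifiers, in alignment order.
    seqs
        Aligned sequences (equal length, alphabet: amino acids, ``-``, ``X``).
    meta
        DataFrame indexed by id with at least a ``taxon`` column; a ``class``
        column carries group labels when present.  Built automatically when
        omitted.
    """

    ids: list[str]
    seqs: list[str]
    meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("sequence ids must be unique")
        if not self.seqs:
            raise AlignmentError("family must contain at least one sequence")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"aligned sequences differ in length: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]
        bad = set("".join(self.seqs)) - ALPHABET
        if bad:
            raise AlignmentError(f"illegal alignment characters: {sorted(bad)}")
        if self.meta is None:
            self.meta = pd.DataFrame({"taxon": self.ids}, index=pd.Index(self.ids, name="id"))
        else:
            missing = set(self.ids) - set(self.meta.index)
            if missing:
                raise AlignmentError(f"metadata missing for ids: {sorted(missing)[:5]}")
            self.meta = self.meta.loc[self.ids]

    # -- basic geometry -------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def alignment_length(self) -> int:
        return len(self.seqs[0])

    def to_matrix(self) -> np.ndarray:
        """Alignment as an ``(n_sequences, alignment_length)`` char array."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def column(self, col: int) -> np.ndarray:
        """Symbols of 1-based alignment column ``col``."""
        if not 1 <= col <= self.alignment_length:
            raise AlignmentError(f"column {col} outside 1..{self.alignment_length}")
        return np.array([s[col - 1] for s in self.seqs], dtype="U1")

    def sequence(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise AlignmentError(f"unknown sequence id {seq_id!r}") from None

    def ungapped(self, seq_id: str) -> str:
        return self.sequence(seq_id).replace(GAP, "")

    # -- coordinate mapping ---------------------------------------------

    def column_of_residue(self, seq_id: str, residue: int) -> int:
        """Alignment column (1-based) holding 1-based ungapped ``residue``."""
        seq = self.sequence(seq_id)
        n = 0
        for j, ch in enumerate(seq, start=1):
            if ch != GAP:
                n += 1
                if n == residue:
                    return j
        raise AlignmentError(
            f"{seq_id!r} has only {n} residues; residue {residue} does not exist"
        )

    def residue_at_column(self, seq_id: str, col: int) -> int | None:
        """1-based ungapped residue number at column ``col``, None on a gap."""
        seq = self.sequence(seq_id)
        if seq[col - 1] == GAP:
            return None
        return sum(1 for ch in seq[:col] if ch != GAP)

    # -- I/O -------------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_meta(self, path: str | Path) -> None:
        self.meta.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_fasta(cls, path: str | Path, meta_path: str | Path | None = None) -> "AlignedFamily":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        ids = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("id")
        return cls(ids=ids, seqs=seqs, meta=meta)

    def subset(self, keep_ids: list[str]) -> "AlignedFamily":
        idx = {i: k for k, i in enumerate(self.ids)}
        seqs = [self.seqs[idx[i]] for i in keep_ids]
        return AlignedFamily(ids=list(keep_ids), seqs=seqs, meta=self.meta.loc[keep_ids])

    def labels(self, column: str = "class") -> np.ndarray:
        if column not in self.meta.columns:
            raise AlignmentError(f"metadata has no {column!r} column")
        return self.meta[column].to_numpy()
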