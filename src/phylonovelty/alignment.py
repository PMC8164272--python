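"""Alignment columns with missing-data semantics.

Gap characters ('-', '.'), '?' and the usual ambiguity codes ('N' plus the
IUPAC nucleotide ambiguities; 'X'/'B'/'Z'/'J' for amino acids) are coerced
to *missing*.  A missing entry contributes a flat partial likelihood and a
weight of zero to every character count, the standard phylogenetic
treatment of gaps as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .models import RateModel

MISSING = -1

_DNA_MISSING = set("-.?NRYSWKMBDHV")
_PROTEIN_MISSING = set("-.?XBZJUO*")


class AlignmentError(ValueError):
    """Ragged alignments, unknown characters, empty input."""


def _encode_char(ch: str, states: tuple[str, ...], state_pos: dict[str, int]) -> int:
    up = ch.upper()
    if up in state_pos:
        return state_pos[up]
    if len(states) == 4:
        if up == "U":
            return state_pos["T"]
        if up in _DNA_MISSING:
            return MISSING
    else:
        if up in _PROTEIN_MISSING:
            return MISSING
    raise AlignmentError(
        f"character {ch!r} is not in the model alphabet {''.join(states)} "
        "and is not a recognised gap/ambiguity code"
    )


@dataclass(frozen=True)
class AlignmentColumn:
    """One alignment column: tip label -> observed character (or missing)."""

    labels: tuple[str, ...]
    codes: np.ndarray  # int, MISSING (-1) for unobserved
    states: tuple[str, ...]
    index: int | None = None

    def __getitem__(self, label: str) -> str | None:
        code = int(self.codes[self.labels.index(label)])
        return None if code == MISSING else self.states[code]

    @property
    def n_observed(self) -> int:
        return int(np.sum(self.codes != MISSING))

    @property
    def is_empty(self) -> bool:
        return self.n_observed == 0

    def code_for(self, label: str) -> int:
        return int(self.codes[self.labels.index(label)])

    @classmethod
    def from_mapping(cls, mapping, states, index=None) -> "AlignmentColumn":
        """Build a column from ``{label: character-or-None}``."""
        states = tuple(states)
        pos = {s: i for i, s in enumerate(states)}
        labels = tuple(mapping)
        codes = np.array(
            [
                MISSING if mapping[lab] is None else _encode_char(mapping[lab], states, pos)
                for lab in labels
            ],
            dtype=np.int64,
        )
        return cls(labels=labels, codes=codes, states=states, index=index)


def empty_column(labels, states) -> AlignmentColumn:
    """An uninformative column (all entries missing): conditioning on it is a no-op."""
    return AlignmentColumn.from_mapping({lab: None for lab in labels}, states)


class Alignment:
    """A list of :class:`AlignmentColumn` sharing row labels."""

    def __init__(self, labels, codes: np.ndarray, states):
        self.labels = tuple(labels)
        self.codes = np.asarray(codes, dtype=np.int64)
        self.states = tuple(states)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.labels):
            raise AlignmentError("codes must be (n_sequences, n_columns)")
        if len(set(self.labels)) != len(self.labels):
            raise AlignmentError("duplicate sequence names")

    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    def column(self, k: int) -> AlignmentColumn:
        return AlignmentColumn(
            labels=self.labels, codes=self.codes[:, k], states=self.states, index=k
        )

    def __iter__(self):
        return (self.column(k) for k in range(self.n_columns))

    def to_fasta(self) -> str:
        rows = []
        for i, lab in enumerate(self.labels):
            seq = "".join(
                "-" if c == MISSING else self.states[c] for c in self.codes[i]
            )
            rows.append(f">{lab}\n{seq}")
        return "\n".join(rows) + "\n"


def read_fasta_alignment(source, model: RateModel) -> Alignment:
    """Read a FASTA alignment and encode it against the model alphabet.

    ``source`` is a path or an open text handle.  Sequences must be of
    equal length; names must be unique and should match the tree tips
    (checked where tree and alignment meet, at weight time).
    """
    states = tuple(model.states)
    pos = {s: i for i, s in enumerate(states)}
    if hasattr(source, "read"):
        records = list(SeqIO.parse(source, "fasta"))
    else:
        with open(source) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise AlignmentError("empty alignment")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    labels = [r.id for r in records]
    codes = np.array(
        [[_encode_char(ch, states, pos) for ch in str(r.seq)] for r in records],
        dtype=np.int64,
    )
    return Alignment(labels, codes, states)
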