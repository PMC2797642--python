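"""Amino-acid alignments as integer state matrices.

States are encoded 0..19 in the fixed residue order A R N D C Q E G H I L K
M F P S T W Y V; anything else (gaps, X, B, Z, J, U, O, ?) is MISSING.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

RESIDUES = "ARNDCQEGHILKMFPSTWYV"
MISSING = 20

_CODE = {aa: i for i, aa in enumerate(RESIDUES)}


def encode_sequence(seq: str) -> np.ndarray:
    """Map a one-letter amino-acid string to integer states (MISSING for
    gaps and ambiguity codes)."""
    return np.array([_CODE.get(c.upper(), MISSING) for c in seq], dtype=np.int8)


def decode_states(states: np.ndarray, missing_char: str = "-") -> str:
    return "".join(RESIDUES[s] if s < MISSING else missing_char for s in states)


@dataclass
class AminoAlignment:
    """Taxa-by-sites matrix of amino-acid states.

    Parameters
    ----------
    labels : list of str
        Unique taxon names, one per row.
    states : ndarray of shape (ntaxa, nsites)
        Integer codes in ``{0..19}`` plus ``MISSING`` (20).
    """

    labels: list[str]
    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D taxa x sites matrix")
        if len(self.labels) != self.states.shape[0]:
            raise ValueError("label count does not match state matrix rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        if self.states.shape[0] < 2:
            raise ValueError("alignment needs at least 2 taxa")
        if self.states.shape[1] < 1:
            raise ValueError("alignment needs at least 1 site")
        if self.states.min() < 0 or self.states.max() > MISSING:
            raise ValueError("state codes outside 0..20")

    @property
    def ntaxa(self) -> int:
        return self.states.shape[0]

    @property
    def nsites(self) -> int:
        return self.states.shape[1]

    def row(self, label: str) -> np.ndarray:
        try:
            return self.states[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"taxon {label!r} not in alignment") from None

    def subset(self, labels: list[str]) -> "AminoAlignment":
        idx = [self.labels.index(l) for l in labels]
        return AminoAlignment(list(labels), self.states[idx].copy())

    def empirical_frequencies(self, pseudocount: float = 1e-6) -> np.ndarray:
        """Observed residue proportions with a small pseudocount per residue
        ("+F" frequencies); MISSING cells are ignored."""
        counts = np.bincount(
            self.states[self.states < MISSING].ravel(), minlength=20
        ).astype(float)
        counts += pseudocount
        return counts / counts.sum()

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_sequences(cls, records: list[tuple[str, str]]) -> "AminoAlignment":
        labels = [name for name, _ in records]
        states = np.vstack([encode_sequence(s) for _, s in records])
        return cls(labels, states)

    @classmethod
    def read_fasta(cls, path) -> "AminoAlignment":
        recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not recs:
            raise ValueError(f"no FASTA records in {path}")
        return cls.from_sequences(recs)

    @classmethod
    def read_phylip(cls, path) -> "AminoAlignment":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        return cls.from_sequences([(r.id, str(r.seq)) for r in aln])

    @classmethod
    def read(cls, path) -> "AminoAlignment":
        """Sniff FASTA vs relaxed PHYLIP from the first character."""
        with open(path) as fh:
            first = fh.read(1)
        return cls.read_fasta(path) if first == ">" else cls.read_phylip(path)

    def to_fasta(self) -> str:
        buf = io.StringIO()
        for label, row in zip(self.labels, self.states):
            buf.write(f">{label}\n{decode_states(row)}\n")
        return buf.getvalue()

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())
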