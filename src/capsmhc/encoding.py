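"""Substitution-matrix encodings of peptide and MHC sequences.

Every peptide is encoded as a fixed 23 x 15 real matrix and every MHC
molecule as a 23 x 385 matrix: column ``c`` is the substitution-matrix
column of residue ``c`` of the sequence, and columns past the true
sequence length hold a padding vector (all zeros by default).  The 23-row
alphabet is the 20 standard amino acids in the conventional BLOSUM
publication order followed by the ambiguity codes B, Z and X; the stop
(``*``) row of published 24-column BLOSUM tables is dropped.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .records import BindingRecord, PEPTIDE_MAX_LEN

#: Fixed row/column ordering of all encodings (20 standard residues in
#: BLOSUM publication order, then B, Z, X).
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"

#: Residues rejected by default and mapped to X in permissive mode.
AMBIGUOUS_RESIDUES = frozenset("UOJ*")

MHC_LEN = 385

_SUPPORTED_MATRICES = ("BLOSUM62", "BLOSUM80")


class UnsupportedSchemeError(ValueError):
    """Requested substitution-matrix scheme is not available."""


class InvalidResidueError(ValueError):
    """A sequence contains a symbol outside the supported alphabet."""


class PeptideLengthError(ValueError):
    """A peptide exceeds the fixed 15-residue encoding width."""


class AlleleNotFoundError(KeyError):
    """An allele name cannot be resolved in the allele table."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 23 x 23 amino-acid substitution score table."""

    name: str
    alphabet: str
    values: np.ndarray
    _index: Dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (23, 23):
            raise ValueError(f"expected a 23x23 table, got {values.shape}")
        if len(self.alphabet) != 23 or len(set(self.alphabet)) != 23:
            raise ValueError("alphabet must hold exactly 23 distinct symbols")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.alphabet)})

    def column(self, residue: str) -> np.ndarray:
        """23-vector encoding of a single residue."""
        try:
            return self.values[:, self._index[residue]]
        except KeyError:
            raise InvalidResidueError(
                f"residue {residue!r} not in alphabet {self.alphabet}"
            ) from None

    def __contains__(self, residue: str) -> bool:
        return residue in self._index


@dataclass(frozen=True)
class EncodedSequence:
    """Fixed-width encoding of one sequence (peptide or MHC)."""

    matrix: np.ndarray
    true_length: int
    role: str  # "peptide" | "mhc"


def load_substitution_matrix(
    name: str = "blosum62", normalized: bool = False
) -> SubstitutionMatrix:
    """Load a supported substitution matrix with the fixed 23-symbol alphabet.

    Parameters
    ----------
    name
        ``"blosum62"`` (default) or ``"blosum80"``, case-insensitive.
    normalized
        If true, min-max rescale all entries to [0, 1].
    """
    key = name.upper().replace("-", "").replace("_", "")
    if key not in _SUPPORTED_MATRICES:
        raise UnsupportedSchemeError(
            f"unsupported substitution matrix {name!r}; supported: "
            + ", ".join(m.lower() for m in _SUPPORTED_MATRICES)
        )
    published = substitution_matrices.load(key)
    src_alpha = str(published.alphabet)
    idx = [src_alpha.index(a) for a in ALPHABET]
    values = np.asarray(published, dtype=float)[np.ix_(idx, idx)]
    label = key.lower()
    if normalized:
        lo, hi = values.min(), values.max()
        values = (values - lo) / (hi - lo)
        label += "-normalized"
    return SubstitutionMatrix(name=label, alphabet=ALPHABET, values=values)


def read_matrix_file(path, name: str | None = None) -> SubstitutionMatrix:
    """Read a substitution matrix in the standard NCBI text layout.

    Rows/columns are reordered to the fixed 23-symbol alphabet; any extra
    symbols (such as ``*``) are dropped.
    """
    rows: Dict[str, Dict[str, float]] = {}
    header: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if not header:
                header = parts
                continue
            rows[parts[0]] = dict(zip(header, (float(v) for v in parts[1:])))
    missing = [a for a in ALPHABET if a not in rows]
    if missing:
        raise ValueError(f"matrix file lacks required symbols: {missing}")
    values = np.array([[rows[a][b] for b in ALPHABET] for a in ALPHABET])
    return SubstitutionMatrix(
        name=name or str(path), alphabet=ALPHABET, values=values
    )


_HLA_RE = re.compile(r"^(?:HLA-?)?([A-Z]+[0-9]*)\*?(\d{2,3})[:._-]?(\d{2,3})$")


def normalize_allele_name(name: str) -> str:
    """Canonicalize an HLA allele name to the ``HLA-A*01:01`` style.

    Case-folded; the ``HLA-`` prefix is enforced and separators normalized.
    Names that do not look like two-field HLA identifiers are returned
    upper-cased and otherwise untouched.
    """
    raw = name.strip().upper()
    m = _HLA_RE.match(raw)
    if m:
        gene, f1, f2 = m.groups()
        return f"HLA-{gene}*{f1}:{f2}"
    return raw


class AlleleTable:
    """Mapping from normalized allele names to MHC amino-acid sequences."""

    def __init__(self, entries: Dict[str, str]):
        self._entries: Dict[str, str] = {}
        for name, seq in entries.items():
            seq = seq.strip().upper()
            bad = set(seq) - set(ALPHABET)
            if bad:
                raise InvalidResidueError(
                    f"allele {name!r} sequence contains unsupported symbols {sorted(bad)}"
                )
            self._entries[normalize_allele_name(name)] = seq

    @classmethod
    def from_fasta(cls, path) -> "AlleleTable":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    @classmethod
    def from_tsv(cls, path) -> "AlleleTable":
        entries: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, seq = line.split("\t")[:2]
                entries[name] = seq
        return cls(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, allele: str) -> bool:
        return normalize_allele_name(allele) in self._entries

    def names(self) -> List[str]:
        return sorted(self._entries)

    def sequence(self, allele: str) -> str:
        key = normalize_allele_name(allele)
        try:
            return self._entries[key]
        except KeyError:
            near = difflib.get_close_matches(key, self._entries, n=3)
            hint = f"; nearest matches: {', '.join(near)}" if near else ""
            raise AlleleNotFoundError(f"allele {allele!r} not in table{hint}") from None


def _encode(
    sequence: str,
    matrix: SubstitutionMatrix,
    width: int,
    role: str,
    pad: str,
    permissive: bool,
) -> EncodedSequence:
    seq = sequence.strip().upper()
    if permissive:
        seq = "".join("X" if c in AMBIGUOUS_RESIDUES else c for c in seq)
    out = np.zeros((23, width))
    if pad == "x":
        out[:] = matrix.column("X")[:, None]
    for i, residue in enumerate(seq[:width]):
        out[:, i] = matrix.column(residue)
    return EncodedSequence(matrix=out, true_length=min(len(seq), width), role=role)


def encode_peptide(
    sequence: str,
    matrix: SubstitutionMatrix,
    pad: str = "zero",
    permissive: bool = False,
) -> EncodedSequence:
    """Encode a peptide (1-15 residues) as a 23 x 15 matrix.

    Columns beyond the peptide length hold the padding vector: all zeros
    (``pad="zero"``, default) or the matrix column of X (``pad="x"``).
    """
    seq = sequence.strip().upper()
    if len(seq) == 0:
        raise PeptideLengthError("empty peptide")
    if len(seq) > PEPTIDE_MAX_LEN:
        raise PeptideLengthError(
            f"peptide {seq!r} has {len(seq)} residues; the encoder is capped at "
            f"{PEPTIDE_MAX_LEN}"
        )
    return _encode(seq, matrix, PEPTIDE_MAX_LEN, "peptide", pad, permissive)


def encode_mhc(
    allele: str,
    table: AlleleTable,
    matrix: SubstitutionMatrix,
    length: int = MHC_LEN,
    pad: str = "zero",
    permissive: bool = False,
) -> EncodedSequence:
    """Encode the MHC sequence of ``allele`` as a 23 x 385 matrix.

    Sequences longer than ``length`` are truncated at the C-terminus;
    shorter ones are padded.
    """
    seq = table.sequence(allele)
    return _encode(seq, matrix, length, "mhc", pad, permissive)


def encode_batch(
    records: Sequence[BindingRecord],
    table: AlleleTable,
    matrix: SubstitutionMatrix,
    batch_size: int = 100,
    pad: str = "zero",
    permissive: bool = False,
) -> Iterator[Tuple[np.ndarray, np.ndarray]]:
    """Yield (B x 23 x 15, B x 23 x 385) array pairs in record order.

    The final batch may be smaller; encoding errors carry the offending
    record index.
    """
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    # MHC encodings repeat heavily across records; cache per allele.
    mhc_cache: Dict[str, np.ndarray] = {}
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        peps = np.empty((len(chunk), 23, PEPTIDE_MAX_LEN))
        mhcs = np.empty((len(chunk), 23, MHC_LEN))
        for j, rec in enumerate(chunk):
            try:
                peps[j] = encode_peptide(rec.peptide, matrix, pad, permissive).matrix
                key = normalize_allele_name(rec.allele)
                if key not in mhc_cache:
                    mhc_cache[key] = encode_mhc(
                        rec.allele, table, matrix, pad=pad, permissive=permissive
                    ).matrix
                mhcs[j] = mhc_cache[key]
            except (InvalidResidueError, PeptideLengthError, AlleleNotFoundError) as e:
                raise type(e)(f"record {start + j}: {e}") from e
        yield peps, mhcs
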