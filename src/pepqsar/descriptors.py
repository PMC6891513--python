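"""Amino-acid descriptor scales and fixed-length encoding of peptides.

Variable-length peptide sequences are mapped to fixed-length numeric
vectors by a *two-terminal position numbering* scheme: the first ``k_n``
residues counted from the N-terminus and the first ``k_c`` residues
counted from the C-terminus are each replaced by the d-dimensional
property vector of the residue, and the blocks are concatenated.
Positions beyond the peptide length receive ``fill_value``; for peptides
shorter than ``k_n + k_c`` the two windows overlap and residues are used
by both windows.  The result always has length ``(k_n + k_c) * d``, so
peptides of any length share one design-matrix layout.

The bundled default scale is the five-dimensional z-scale of Sandberg et
al. (z5), a principal-component summary of 26 measured physicochemical
properties (lipophilicity, size/polarisability, electronic/NMR
properties) of the 20 coded amino acids.  Custom scales can be loaded
from tabular files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(STANDARD_AMINO_ACIDS)

#: Name of the scale used when none is specified.
DEFAULT_SCALE = "z5"


class SequenceError(ValueError):
    """A peptide string is empty or contains a non-standard residue."""


def validate_sequence(raw: str) -> str:
    """Canonicalise a peptide string.

    Strips whitespace and upper-cases; every remaining character must be
    one of the 20 standard one-letter codes (B, J, O, U, X and Z are
    rejected along with anything else non-standard).

    Parameters
    ----------
    raw : str
        The sequence as read from user input or a file.

    Returns
    -------
    str
        The canonical upper-case sequence.

    Raises
    ------
    SequenceError
        If the stripped sequence is empty or contains an invalid
        character (the message names the character and its 1-based
        position).
    """
    if raw is None:
        raise SequenceError("sequence is None")
    seq = "".join(raw.split()).upper()
    if not seq:
        raise SequenceError("empty peptide sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_SET:
            raise SequenceError(
                f"invalid residue {ch!r} at position {pos} in sequence {seq!r}"
            )
    return seq


@dataclass(frozen=True)
class DescriptorScale:
    """An immutable per-residue property table.

    Attributes
    ----------
    name : str
        Label of the scale (e.g. ``"z5"``).
    dims : int
        Number of descriptor dimensions d.
    values : mapping
        One d-vector (tuple of floats) per standard residue.
    """

    name: str
    dims: int
    values: Mapping[str, tuple[float, ...]] = field(repr=False)

    def __post_init__(self):
        missing = _AA_SET - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")
        extra = set(self.values) - _AA_SET
        if extra:
            raise ValueError(f"scale {self.name!r} has non-standard rows: {sorted(extra)}")
        for aa, vec in self.values.items():
            if len(vec) != self.dims:
                raise ValueError(
                    f"scale {self.name!r}: residue {aa} has {len(vec)} values, expected {self.dims}"
                )
            if not all(np.isfinite(v) for v in vec):
                raise ValueError(f"scale {self.name!r}: non-finite value for residue {aa}")
        # freeze the mapping
        object.__setattr__(self, "values", {aa: tuple(map(float, v)) for aa, v in self.values.items()})

    def vector(self, residue: str) -> np.ndarray:
        return np.asarray(self.values[residue], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Return the scale as a residue-indexed DataFrame."""
        df = pd.DataFrame.from_dict(dict(self.values), orient="index")
        df.index.name = "residue"
        df.columns = [f"d{i+1}" for i in range(self.dims)]
        return df.sort_index()


@dataclass(frozen=True)
class EncodingSpec:
    """Two-terminal encoding configuration.

    ``k_n`` N-terminal and ``k_c`` C-terminal positions are encoded;
    ``fill_value`` pads positions past the end of short peptides (filled
    before any downstream autoscaling, so under column autoscaling the
    fill effectively becomes a shift to the column mean).
    """

    k_n: int = 5
    k_c: int = 5
    fill_value: float = 0.0
    scale_ref: str = DEFAULT_SCALE

    def __post_init__(self):
        if self.k_n < 1:
            raise ValueError("k_n must be >= 1")
        if self.k_c < 0:
            raise ValueError("k_c must be >= 0")
        if not np.isfinite(self.fill_value):
            raise ValueError("fill_value must be finite")

    @property
    def n_positions(self) -> int:
        return self.k_n + self.k_c

    def with_scale(self, name: str) -> "EncodingSpec":
        return replace(self, scale_ref=name)


def _bundled_scale_path(name: str) -> Path | None:
    ref = resources.files("pepqsar") / "data" / "scales" / f"{name}.tsv"
    try:
        with resources.as_file(ref) as p:
            return p if p.exists() else None
    except FileNotFoundError:
        return None


def load_scale(source: str | Path = DEFAULT_SCALE) -> DescriptorScale:
    """Load a descriptor scale from a bundled name or a tabular file.

    The file format is delimited text (tab or comma) with a header row;
    column 1 holds the residue letter and the remaining d columns hold
    numeric property values, one row per residue, 20 rows total.

    Parameters
    ----------
    source : str or Path
        Either the name of a bundled scale (e.g. ``"z5"``) or a path to
        a scale table.

    Raises
    ------
    ValueError
        On missing residues, duplicate residue rows, or non-numeric
        cells.
    FileNotFoundError
        If neither a bundled scale nor a file matches ``source``.
    """
    path = Path(source)
    name = path.stem
    if not path.exists():
        bundled = _bundled_scale_path(str(source))
        if bundled is None:
            raise FileNotFoundError(f"no bundled scale or readable file named {source!r}")
        path, name = bundled, str(source)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"scale table {path} needs a residue column plus >=1 numeric column")
    residues = df.iloc[:, 0].str.strip().str.upper()
    dup = residues[residues.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate residue rows in {path}: {sorted(dup.unique())}")
    try:
        numeric = df.iloc[:, 1:].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in scale table {path}: {exc}") from exc
    values = {aa: tuple(row) for aa, row in zip(residues, numeric.to_numpy())}
    return DescriptorScale(name=name, dims=numeric.shape[1], values=values)


@dataclass(frozen=True)
class EncodedPeptide:
    """A sequence together with its fixed-length feature vector."""

    sequence: str
    features: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))


def encode_peptide(
    seq: str, spec: EncodingSpec | None = None, scale: DescriptorScale | None = None
) -> np.ndarray:
    """Encode one canonical peptide to a ``(k_n + k_c) * d`` vector.

    Layout: ``[N-pos 1 .. N-pos k_n, C-pos 1 .. C-pos k_c]`` where N-pos
    i is the descriptor vector of residue i from the N-terminus and
    C-pos j that of residue j from the C-terminus.  Positions past the
    peptide length get ``spec.fill_value`` in every dimension; short
    peptides are covered by both windows (overlap, no truncation).
    """
    if spec is None:
        spec = EncodingSpec()
    if scale is None:
        scale = load_scale(spec.scale_ref)
    seq = validate_sequence(seq)
    n = len(seq)
    d = scale.dims
    out = np.full(spec.n_positions * d, spec.fill_value, dtype=float)
    for i in range(spec.k_n):
        if i < n:
            out[i * d : (i + 1) * d] = scale.vector(seq[i])
    for j in range(spec.k_c):
        if j < n:
            block = spec.k_n + j
            out[block * d : (block + 1) * d] = scale.vector(seq[n - 1 - j])
    return out


def encode_set(
    peptides: list[str],
    spec: EncodingSpec | None = None,
    scale: DescriptorScale | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Encode a list of peptides into an ``N x p`` design matrix.

    Row order is preserved and duplicates are kept.  Per-sequence errors
    are re-raised with the offending row number.

    Returns
    -------
    (ndarray, list of str)
        The feature matrix and the canonical sequences (row index).
    """
    if spec is None:
        spec = EncodingSpec()
    if scale is None:
        scale = load_scale(spec.scale_ref)
    if not peptides:
        raise ValueError("cannot encode an empty peptide list")
    rows, index = [], []
    for i, raw in enumerate(peptides):
        try:
            seq = validate_sequence(raw)
        except SequenceError as exc:
            raise SequenceError(f"row {i + 1}: {exc}") from exc
        rows.append(encode_peptide(seq, spec, scale))
        index.append(seq)
    return np.vstack(rows), index
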