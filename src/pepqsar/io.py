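"""Readers and writers for the project's tabular and sequence formats.

Activity tables and composition tables are delimited text (comma or tab,
auto-detected); peptide lists arrive as FASTA or one-sequence-per-line
text; reports go out as TSV with the run configuration embedded as
``#``-prefixed header comments so outputs are self-describing and
byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .assays import DoseResponse
from .descriptors import SequenceError, validate_sequence
from .qsar import PeptideRecord, ValidationReport
from .simulate import FluorescenceExperiment

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (fully serialisable)."""

    scale: str = "z5"
    k_n: int = 5
    k_c: int = 5
    fill_value: float = 0.0
    components: str | int = "auto"
    ratio: tuple[int, int] = (2, 1)
    seed: int = 0
    inputs: tuple[str, ...] = ()
    output: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str, sort_keys=True)

    def header_lines(self) -> list[str]:
        return [f"# config: {self.to_json()}", f"# seed: {self.seed}"]


def _data_path(name: str) -> Path:
    with resources.as_file(resources.files("pepqsar") / "data" / name) as p:
        return p


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read delimited text, sniffing comma vs tab from the header."""
    return pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)


def read_activity_table(path: str | Path) -> list[PeptideRecord]:
    """Read a (sequence, activity) table into validated records.

    The file must contain ``sequence`` and ``activity`` columns (case
    insensitive); an optional ``no`` row-number column is preserved in
    the file format for subsetting but not required.  Row order is kept.
    """
    df = _read_table(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    cols = {c.strip().lower(): c for c in df.columns}
    if "sequence" not in cols or "activity" not in cols:
        raise ValueError(f"{path}: need 'sequence' and 'activity' columns, found {list(df.columns)}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            seq = validate_sequence(str(row[cols["sequence"]]))
        except SequenceError as exc:
            raise SequenceError(f"{path}, line {line}: {exc}") from exc
        try:
            act = float(row[cols["activity"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: bad activity {row[cols['activity']]!r}") from exc
        if not np.isfinite(act):
            raise ValueError(f"{path}, line {line}: non-finite activity")
        records.append(PeptideRecord(seq, act))
    return records


def write_activity_table(records: list[PeptideRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {"no": np.arange(1, len(records) + 1),
         "sequence": [r.sequence for r in records],
         "activity": [r.activity for r in records]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_peptide_list(path: str | Path) -> list[str]:
    """Read candidate peptides from FASTA or one-per-line plain text.

    Order is preserved and duplicates kept; every sequence is validated
    and canonicalised.  Invalid residues are reported with the record id
    (FASTA) or line number (plain text).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty peptide list")
    seqs: list[str] = []
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(path, "fasta"):
            try:
                seqs.append(validate_sequence(str(rec.seq)))
            except SequenceError as exc:
                raise SequenceError(f"{path}, record {rec.id!r}: {exc}") from exc
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                seqs.append(validate_sequence(line))
            except SequenceError as exc:
                raise SequenceError(f"{path}, line {lineno}: {exc}") from exc
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    return seqs


def read_composition_table(path: str | Path, column: str | None = None) -> dict[str, float]:
    """Read a (residue, amount) table; 'ND' (not detected) counts as 0.

    ``column`` picks the amount column when the file has several (e.g.
    total vs free); default is the second column.  Aggregate rows
    (HAA/NCAA/AAA/Sum) are skipped if present.
    """
    df = _read_table(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    amount_col = column if column is not None else df.columns[1]
    if amount_col not in df.columns:
        raise ValueError(f"{path}: no column {amount_col!r}; have {list(df.columns)}")
    skip = {"HAA", "HAAS", "NCAA", "NCAAS", "AAA", "AAAS", "SUM", "TOTAL"}
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        name = str(row[df.columns[0]]).strip()
        if name.upper() in skip:
            continue
        raw = str(row[amount_col]).strip()
        out[name] = 0.0 if raw.upper() in {"ND", "NA", "NAN", ""} else float(raw)
    return out


def read_fluorescence_curves(path: str | Path) -> FluorescenceExperiment:
    """Read kinetic curves: columns ``time``, ``control``, one per dose (header = mg/mL)."""
    df = _read_table(path).astype(float)
    cols = {c.strip().lower(): c for c in df.columns}
    if "time" not in cols or "control" not in cols:
        raise ValueError(f"{path}: need 'time' and 'control' columns")
    dose_cols = [c for c in df.columns if c not in (cols["time"], cols["control"])]
    if not dose_cols:
        raise ValueError(f"{path}: no dose columns")
    return FluorescenceExperiment(
        times=tuple(df[cols["time"]]),
        control_curve=tuple(df[cols["control"]]),
        sample_curves={float(c): tuple(df[c]) for c in dose_cols},
    )


def load_orac_table() -> list[PeptideRecord]:
    """The bundled ORAC peptide activity database (26 records)."""
    return read_activity_table(_data_path("orac_peptides.tsv"))


def load_composition_table(column: str = "total_nmol_per_mg") -> dict[str, float]:
    """The bundled hydrolysate amino-acid composition (nmol/mg).

    ``column`` is ``"total_nmol_per_mg"`` (default) or
    ``"free_nmol_per_mg"`` for the free amino-acid fraction.
    """
    return read_composition_table(_data_path("amino_acid_composition.tsv"), column=column)


def write_report(obj, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a results object as TSV with config/seed header comments.

    Accepts a :class:`ValidationReport`, a ranking DataFrame (from
    ``QSARResults.rank``), or a :class:`DoseResponse`.  Column order and
    float formatting are fixed so repeated runs are byte-identical.
    """
    if isinstance(obj, ValidationReport):
        df = obj.to_frame()
    elif isinstance(obj, DoseResponse):
        df = obj.to_frame()
        df["slope"] = obj.slope
        df["intercept"] = obj.intercept
        df["ec50"] = obj.ec50
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    lines = config.header_lines() if config is not None else []
    body = df.to_csv(sep="\t", index=False, float_format=FLOAT_FMT)
    Path(path).write_text("".join(l + "\n" for l in lines) + body)
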