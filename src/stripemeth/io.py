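"""Tabular and FASTA input/output.

Ct tables are plain TSV with a header line::

    sample  fragment  treatment  replicate  ct

plus an optional ``digestion`` column (defaults to 1).  Treatment tokens
are ``mcrbc``/``mock``, case-insensitive, surrounding whitespace ignored.
A missing Ct is written as ``NA``; a "no amplification" Ct is written as
``inf`` and read back as ``float('inf')``.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Sentinel Ct meaning the reaction never crossed threshold.
NO_AMPLIFICATION = math.inf

CT_COLUMNS = ["sample", "fragment", "treatment", "digestion", "replicate", "ct"]
TREATMENTS = ("mcrbc", "mock")


class TableFormatError(ValueError):
    """Malformed tabular input; message carries the offending line number."""


def _parse_ct(token: str, lineno: int) -> float:
    token = token.strip()
    if token in ("", "NA", "NaN", "nan", "na", "."):
        return math.nan
    if token.lower() in ("inf", "+inf", "infinity"):
        return NO_AMPLIFICATION
    try:
        return float(token)
    except ValueError:
        raise TableFormatError(f"line {lineno}: cannot parse Ct value {token!r}") from None


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a Ct TSV into a DataFrame with :data:`CT_COLUMNS`."""
    path = Path(path)
    rows = []
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if header is None:
                header = [f.lower() for f in fields]
                required = {"sample", "fragment", "treatment", "replicate", "ct"}
                missing = required - set(header)
                if missing:
                    raise TableFormatError(
                        f"line {lineno}: header missing column(s) {sorted(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise TableFormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rec = dict(zip(header, fields))
            treatment = rec["treatment"].strip().lower()
            if treatment not in TREATMENTS:
                raise TableFormatError(
                    f"line {lineno}: unknown treatment {rec['treatment']!r} "
                    f"(expected one of {TREATMENTS})"
                )
            try:
                replicate = int(rec["replicate"])
                digestion = int(rec.get("digestion", "1") or "1")
            except ValueError:
                raise TableFormatError(
                    f"line {lineno}: replicate/digestion must be integers"
                ) from None
            rows.append(
                {
                    "sample": rec["sample"],
                    "fragment": rec["fragment"],
                    "treatment": treatment,
                    "digestion": digestion,
                    "replicate": replicate,
                    "ct": _parse_ct(rec["ct"], lineno),
                    "_line": lineno,
                }
            )
    if header is None:
        raise TableFormatError("empty Ct table")
    df = pd.DataFrame(rows, columns=CT_COLUMNS + ["_line"])
    key = ["sample", "fragment", "treatment", "digestion", "replicate"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        lines = df.loc[dup, "_line"].tolist()
        raise TableFormatError(f"duplicate measurement keys at lines {lines}")
    return df.drop(columns="_line").reset_index(drop=True)


def _format_ct(value: float) -> str:
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    if value == NO_AMPLIFICATION:
        return "inf"
    return format(value, "g")


def write_ct_table(path: str | Path, table: pd.DataFrame,
                   provenance: Mapping[str, object] | None = None) -> None:
    table = table.copy()
    table["ct"] = [_format_ct(v) for v in table["ct"]]
    write_results(path, table[CT_COLUMNS], provenance=provenance)


def write_results(path: str | Path, records, columns: Sequence[str] | None = None,
                  provenance: Mapping[str, object] | None = None) -> None:
    """Write records (DataFrame or iterable of dicts) as TSV with a provenance header."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records), columns=columns)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        if provenance:
            items = " ".join(f"{k}={v}" for k, v in provenance.items())
            fh.write(f"# stripemeth {items}\n")
        records.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` with uppercase sequences."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def config_digest(config: Mapping[str, object]) -> str:
    """Stable short hash of a config mapping, for provenance headers."""
    canon = repr(sorted(_flatten(config))).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def _flatten(obj, prefix=""):
    if isinstance(obj, Mapping):
        for k in sorted(obj):
            yield from _flatten(obj[k], f"{prefix}{k}.")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            yield from _flatten(v, f"{prefix}{i}.")
    else:
        yield (prefix.rstrip("."), repr(obj))
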