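"""Table I/O and canonical formula-string handling.

Formula strings use a fixed Hill-like CHNOS element order with counts
greater than one printed (``C6H6O``); printing and parsing are exact
inverses over valid compositions.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .formula import ElementVector, Peak

__all__ = ["formula_string", "parse_formula", "read_peaklist", "write_peaklist",
           "read_formula_table", "write_formula_table"]

_ELEMENT_ORDER = ("C", "H", "N", "O", "S")
_TOKEN_RE = re.compile(r"([CHNOS])(\d*)")


def formula_string(ev: ElementVector) -> str:
    """Canonical text form of a composition, fixed C,H,N,O,S order."""
    parts = []
    for sym, cnt in zip(_ELEMENT_ORDER, ev.as_tuple()):
        if cnt == 0:
            continue
        parts.append(sym if cnt == 1 else f"{sym}{cnt}")
    return "".join(parts)


def parse_formula(text: str) -> ElementVector:
    """Inverse of :func:`formula_string`."""
    counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula string: {text!r}")
        sym, digits = m.groups()
        if counts[sym]:
            raise ValueError(f"repeated element {sym} in {text!r}")
        counts[sym] = int(digits) if digits else 1
        pos = m.end()
    if pos != len(text) or pos == 0:
        raise ValueError(f"malformed formula string: {text!r}")
    return ElementVector(counts["C"], counts["H"], counts["N"], counts["O"], counts["S"])


def read_peaklist(path: str | Path) -> list[Peak]:
    """Read a peak list CSV/TSV with ``mz`` and ``intensity`` columns.

    Row order is preserved; lines starting with ``#`` are skipped.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    for col in ("mz", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    peaks = []
    for idx, row in df.iterrows():
        mz, inten = row["mz"], row["intensity"]
        try:
            mz = float(mz)
            inten = float(inten)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric value in row {idx}") from exc
        if inten < 0:
            raise ValueError(f"{path}: negative intensity in row {idx}")
        peaks.append(Peak(mz=mz, intensity=inten))
    return peaks


def write_peaklist(peaks: list[Peak], path: str | Path) -> None:
    pd.DataFrame(
        {"mz": [p.mz for p in peaks], "intensity": [p.intensity for p in peaks]}
    ).to_csv(path, index=False)


def read_formula_table(path: str | Path) -> pd.DataFrame:
    """Read a pre-assigned formula table (columns c,h,n,o,s,mz,intensity[,ppm_error])."""
    df = pd.read_csv(path, comment="#")
    required = {"c", "h", "n", "o", "s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_formula_table(records, path: str | Path) -> None:
    """Write assignment results; unassigned peaks get empty formula fields."""
    rows = []
    for rec in records:
        ev = rec.primary
        rows.append(
            {
                "mz": rec.peak.mz,
                "intensity": rec.peak.intensity,
                "c": ev.c if ev else "",
                "h": ev.h if ev else "",
                "n": ev.n if ev else "",
                "o": ev.o if ev else "",
                "s": ev.s if ev else "",
                "formula": formula_string(ev) if ev else "",
                "ppm_error": rec.primary_ppm_error if ev else "",
                "n_candidates": len(rec.candidates),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
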