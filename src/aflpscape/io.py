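"""Reading and writing the pipeline's table formats.

Band matrices are CSV with individuals as rows.  Two dialects are
supported:

``plain01``
    Columns ``individual, population[, replicate_of], <locus...>``;
    entries 0/1 with missing coded as ``-9`` (default) or empty.

``genalex``
    Same body preceded by two GenAlEx-style header rows (counts row and
    title row), as produced by common dominant-marker exporters.

Site and phenotype tables are ordinary CSV handled through pandas; the
simulation ground truth travels as JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING_CODE, BandMatrix

__all__ = [
    "read_band_matrix",
    "write_band_matrix",
    "read_table",
    "write_table",
    "read_truth",
    "write_truth",
]


class BandMatrixParseError(ValueError):
    """Raised with a file position when a band-matrix file is malformed."""


def _parse_cell(token: str, missing_codes: tuple[str, ...], line: int, col: str) -> float:
    tok = token.strip()
    if tok in missing_codes or tok == "":
        return np.nan
    if tok in ("0", "0.0"):
        return 0.0
    if tok in ("1", "1.0"):
        return 1.0
    raise BandMatrixParseError(
        f"line {line}: unknown band code {tok!r} in column {col!r}"
    )


def read_band_matrix(
    path,
    dialect: str = "plain01",
    missing_codes: tuple[str, ...] = (MISSING_CODE,),
) -> BandMatrix:
    """Parse a band-matrix CSV; see the module docstring for dialects."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    offset = 0
    if dialect == "genalex":
        if len(rows) < 3:
            raise BandMatrixParseError("genalex dialect needs two header rows")
        offset = 2
    elif dialect != "plain01":
        raise ValueError(f"unknown dialect {dialect!r}")
    header = [h.strip() for h in rows[offset]]
    if header[:2] != ["individual", "population"]:
        raise BandMatrixParseError(
            f"line {offset + 1}: expected columns 'individual,population', got {header[:2]}"
        )
    has_rep = len(header) > 2 and header[2] == "replicate_of"
    first_locus = 3 if has_rep else 2
    loci = header[first_locus:]
    ids: list[str] = []
    pops: list[str] = []
    reps: list[str | None] = []
    vals: list[list[float]] = []
    for k, row in enumerate(rows[offset + 1:], start=offset + 2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise BandMatrixParseError(
                f"line {k}: ragged row ({len(row)} fields, header has {len(header)})"
            )
        ind = row[0].strip()
        if ind in ids:
            raise BandMatrixParseError(f"line {k}: duplicate individual id {ind!r}")
        ids.append(ind)
        pops.append(row[1].strip())
        reps.append(row[2].strip() or None if has_rep else None)
        vals.append(
            [_parse_cell(c, missing_codes, k, loci[j]) for j, c in enumerate(row[first_locus:])]
        )
    return BandMatrix(np.array(vals), ids, pops, loci, reps)


def write_band_matrix(m: BandMatrix, path, dialect: str = "plain01") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    has_rep = any(r is not None for r in m.replicate_of)
    header = ["individual", "population"] + (["replicate_of"] if has_rep else []) + list(m.locus_names)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        if dialect == "genalex":
            w.writerow([m.n_loci, m.n_individuals, len(m.populations())])
            w.writerow(["aflpscape band matrix"])
        elif dialect != "plain01":
            raise ValueError(f"unknown dialect {dialect!r}")
        w.writerow(header)
        for i in range(m.n_individuals):
            row = [m.individual_ids[i], m.population_ids[i]]
            if has_rep:
                row.append(m.replicate_of[i] or "")
            row += [
                MISSING_CODE if np.isnan(v) else str(int(v)) for v in m.values[i]
            ]
            w.writerow(row)


def read_table(path) -> pd.DataFrame:
    """Read a site or phenotype CSV (one row per population)."""
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_truth(truth: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
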