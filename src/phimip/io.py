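"""Delimited-text I/O for matrices and time series."""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError


def _sniff_delimiter(path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if "," in first:
        return ","
    if "\t" in first:
        return "\t"
    return None  # whitespace


def read_matrix(path, delimiter: str | None = None) -> np.ndarray:
    """Read a numeric matrix from delimited text (CSV, TSV or whitespace).

    A single header line of non-numeric column names is tolerated.
    """
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    for skip in (0, 1):
        try:
            m = np.genfromtxt(path, delimiter=delimiter, skip_header=skip)
        except (ValueError, OSError) as exc:
            raise ValidationError(f"cannot read matrix from {path}: {exc}") from exc
        m = np.atleast_2d(m)
        if m.size and not np.isnan(m).any():
            return m
    raise ValidationError(f"non-numeric entries in {path}")


def write_matrix(path, matrix: np.ndarray, delimiter: str = ",") -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter=delimiter)


def read_series(path, delimiter: str | None = None) -> np.ndarray:
    """Read a (T, N) time series: rows are samples, columns are channels."""
    series = read_matrix(path, delimiter=delimiter)
    if series.ndim != 2:
        raise ValidationError(f"{path} is not a 2-D series")
    return series
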