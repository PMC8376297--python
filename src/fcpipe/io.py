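"""Delimited-text readers and writers for matrices, series and phenotypes.

All on-disk formats are plain text: connectivity matrices and ROI time
series as tab- or comma-separated tables (delimiter sniffed, optional
header row of region labels), phenotype tables as TSV with ``subject_id``,
``group``, ``session``, ``NCT`` and ``DST`` columns, and results as JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import ConnectivityMatrix, EdgeVector, RoiTimeSeries

__all__ = [
    "read_table",
    "read_matrix",
    "read_timeseries",
    "read_phenotype",
    "write_matrix",
    "write_timeseries",
    "write_edge_vector",
    "read_cohort_dir",
]

PHENOTYPE_COLUMNS = ("subject_id", "group", "session", "NCT", "DST")


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,; ").delimiter
    except csv.Error:
        return "\t"


def read_table(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited numeric table; return (values, header labels or None)."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    first = path.read_text().splitlines()[0].split(delim)

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(tok) for tok in first if tok.strip())
    df = pd.read_csv(path, sep=delim, header=0 if has_header else None)
    labels = [str(c) for c in df.columns] if has_header else None
    values = df.to_numpy(dtype=float)
    return values, labels


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    values, labels = read_table(path)
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: expected a square connectivity matrix, got {values.shape}"
        )
    if not np.allclose(values, values.T, atol=1e-8, rtol=0.0):
        raise ValueError(f"{path}: connectivity matrix is not symmetric")
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix((values + values.T) / 2.0, labels)


def read_timeseries(path: str | Path, sampling_interval: float = 2.5) -> RoiTimeSeries:
    values, labels = read_table(path)
    return RoiTimeSeries(values, sampling_interval, labels)


def read_phenotype(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype table missing column(s) {missing}")
    return df


def write_matrix(path: str | Path, m: ConnectivityMatrix) -> None:
    np.savetxt(
        path, m.z, delimiter="\t", header="\t".join(m.region_labels), comments=""
    )


def write_timeseries(path: str | Path, ts: RoiTimeSeries) -> None:
    np.savetxt(
        path, ts.values, delimiter="\t", header="\t".join(ts.region_labels), comments=""
    )


def write_edge_vector(path: str | Path, v: EdgeVector) -> None:
    """Two-column TSV: edge label ``ROI_i--ROI_j`` and Fisher-z value."""
    with open(path, "w") as fh:
        fh.write("edge\tz\n")
        for k in range(v.n_edges):
            fh.write(f"{v.edge_label(k)}\t{v.values[k]:.10g}\n")


def read_cohort_dir(path: str | Path, sampling_interval: float = 2.5):
    """Load a cohort directory written by :func:`fcpipe.synthetic.write_cohort`.

    Matrix files become :class:`ConnectivityMatrix`; non-square tables are
    treated as ROI time series.  Returns a :class:`fcpipe.synthetic.Cohort`.
    """
    from .synthetic import Cohort, Subject  # local import avoids a cycle

    path = Path(path)
    pheno = read_phenotype(path / "phenotype.tsv")
    if "file" not in pheno.columns:
        raise ValueError("phenotype.tsv must carry a 'file' column")
    truth_file = path / "truth.json"
    truth = json.loads(truth_file.read_text()) if truth_file.exists() else {}
    subjects = []
    n_regions = None
    for row in pheno.itertuples(index=False):
        values, labels = read_table(path / row.file)
        if values.shape[0] == values.shape[1]:
            np.fill_diagonal(values, 0.0)
            subj = Subject(
                subject_id=str(row.subject_id),
                group=str(row.group),
                session=str(row.session),
                matrix=ConnectivityMatrix((values + values.T) / 2.0, labels),
            )
            n_regions = values.shape[0]
        else:
            subj = Subject(
                subject_id=str(row.subject_id),
                group=str(row.group),
                session=str(row.session),
                timeseries=RoiTimeSeries(values, sampling_interval, labels),
            )
            n_regions = values.shape[1]
        subj.nct = None if pd.isna(row.NCT) else float(row.NCT)
        subj.dst = None if pd.isna(row.DST) else float(row.DST)
        subjects.append(subj)
    return Cohort(subjects=subjects, truth=truth, n_regions=int(n_regions))
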