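"""Reading, writing and validation of the trial dataset CSV schema.

The layout follows pharmacometric conventions: one dose row per subject
(EVID=1, CMT=1, AMT in nmol) and observation rows (EVID=0) keyed by an
analyte compartment code, with DV in nM (empty when the observation is below
the quantification limit, BLQ=1), the limit itself in LLOQ, and the subject's
covariates repeated on every row.  Doses are stored in nmol so that the
dataset is unit-consistent with DV; the mg-to-nmol conversion happens at the
design/config level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ANALYTE_CODES = {"SV": 2, "SVA": 3, "HMSV": 4, "HMSVA": 5, "DHSV": 6}
CODE_ANALYTES = {v: k for k, v in ANALYTE_CODES.items()}

SNP_COLUMNS = ("RS4149056", "RS4149015", "RS2306283",
               "RS15524", "RS776746", "RS10264272")

COLUMNS = ("ID", "TIME", "AMT", "EVID", "CMT", "DV", "MDV", "BLQ", "LLOQ",
           "AGE", "WT", "HT", "SEX") + SNP_COLUMNS


class DatasetError(ValueError):
    """Schema or invariant violation, with row numbers where applicable."""


def _fail(msg: str) -> None:
    raise DatasetError(msg)


def validate_dataset(df: pd.DataFrame) -> None:
    """Check schema invariants; raises :class:`DatasetError` naming the
    offending column or 1-based data rows."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        _fail(f"missing column(s): {', '.join(missing)}")
    obs = df["EVID"] == 0
    rows = df.index + 1

    bad = obs & (df["BLQ"] == 1) & df["DV"].notna()
    if bad.any():
        _fail(f"BLQ=1 rows must have empty DV (rows "
              f"{list(rows[bad])[:5]})")
    bad = obs & (df["BLQ"] == 0) & df["DV"].isna()
    if bad.any():
        _fail(f"non-BLQ observation rows must have DV (rows "
              f"{list(rows[bad])[:5]})")
    for col in SNP_COLUMNS:
        bad = ~df[col].isin((0, 1, 2))
        if bad.any():
            _fail(f"{col} allele counts must be 0/1/2 (rows "
                  f"{list(rows[bad])[:5]})")
        if (df.groupby("ID")[col].nunique() > 1).any():
            _fail(f"{col} must be constant within subject")
    bad = obs & (df["LLOQ"].isna() | (df["LLOQ"] <= 0))
    if bad.any():
        _fail(f"observation rows need a positive LLOQ (rows "
              f"{list(rows[bad])[:5]})")
    for sid, g in df[obs].groupby("ID"):
        for code, gc in g.groupby("CMT"):
            if np.any(np.diff(gc["TIME"].to_numpy()) < 0):
                _fail(f"TIME not monotone within subject {sid}, CMT {code}")
    n_dose = df[df["EVID"] == 1].groupby("ID").size()
    if not (n_dose == 1).all():
        _fail("each subject must have exactly one dose row")
    bad_cmt = obs & ~df["CMT"].isin(tuple(CODE_ANALYTES))
    if bad_cmt.any():
        _fail(f"unknown observation CMT code (rows "
              f"{list(rows[bad_cmt])[:5]})")


def write_dataset(dataset, path) -> None:
    """Write a trial dataset to CSV (comma separated, UTF-8, header)."""
    df = dataset.df if hasattr(dataset, "df") else dataset
    df = df[list(COLUMNS)]
    df.to_csv(path, index=False, float_format="%.10g")


def read_dataset(path):
    """Read and validate a trial dataset CSV; returns a
    :class:`~svmetpk.simulate.TrialDataset`."""
    from .simulate import TrialDataset

    df = pd.read_csv(path)
    df.columns = [c.upper() for c in df.columns]
    validate_dataset(df)
    df = df[list(COLUMNS)]
    for col in ("ID", "EVID", "CMT", "MDV", "BLQ") + SNP_COLUMNS:
        df[col] = df[col].astype(int)
    for col in ("TIME", "AMT", "DV", "LLOQ", "AGE", "WT", "HT"):
        df[col] = df[col].astype(float)
    return TrialDataset(df.reset_index(drop=True))
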