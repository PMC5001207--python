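"""Indirect evaluation of PAM50 predictions through ER/PR status.

True intrinsic-subtype labels are rarely available for a new cohort, but
immunohistochemical ER (estrogen receptor) and PR (progesterone receptor)
status usually is. From a large cohort in which both PAM50 subtype and
ER/PR status were recorded, one can tabulate the empirical conditional
probability P(PAM50 subtype | ER, PR). The Indirect Summed Evaluation
Probability (ISEP) of a prediction is then the sum, over samples with
known ER/PR status, of the conditional probability of the *predicted*
subtype given that sample's status: predictions compatible with the
receptor biology score higher.

ISEP values are comparable only within one dataset — cohorts differ in
their subtype mix, so the report always carries the number of samples
included and the per-status-row composition alongside the score.

The default count table ships with a caveat: only its ER+/PR+ row is
unambiguous in the source material (246 LumA of 539, i.e. 45.64 %); the
other rows admit more than one reading and can be overridden with any
user-supplied count table. HER2 status is deliberately not part of the
default table (it is less commonly documented), but the row set is
arbitrary, so an extended status table works unchanged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import DataError, PAM50_SUBTYPES

STATUS_ROWS = ["ER+/PR+", "ER+/PR-", "ER-/PR+", "ER-/PR-"]

# Cohort tally of PAM50 subtype by ER/PR status (rows: STATUS_ROWS, cols:
# PAM50_SUBTYPES). Row 1 is corroborated by the worked value 246/539 =
# 45.64 %; rows 2-4 are a best-effort reading of ambiguously typeset
# counts — override via build_conditional_table(counts) where it matters.
DEFAULT_COUNTS = pd.DataFrame(
    [
        [246, 188, 78, 4, 23],
        [125, 13, 3, 3, 36],
        [15, 5, 3, 4, 1],
        [4, 17, 60, 59, 28],
    ],
    index=STATUS_ROWS,
    columns=PAM50_SUBTYPES,
)


@dataclass
class ErPrPam50Table:
    """Counts and row-normalised conditional probabilities P(subtype | ER, PR)."""

    counts: pd.DataFrame
    probs: pd.DataFrame

    def prob(self, status_row: str, subtype: str) -> float:
        return float(self.probs.loc[status_row, subtype])


@dataclass
class IsepReport:
    """An ISEP score with the context needed to interpret it."""

    isep: float
    n_included: int
    n_excluded: int
    row_composition: dict[str, int]  # included samples per ER/PR status row

    def to_dict(self) -> dict:
        return {
            "isep": self.isep,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "row_composition": dict(self.row_composition),
        }


def build_conditional_table(counts: pd.DataFrame | None = None) -> ErPrPam50Table:
    """Row-normalise a status x subtype count table into conditional probabilities.

    An all-zero row carries no information and becomes uniform (with a
    warning); negative counts are an error.
    """
    if counts is None:
        counts = DEFAULT_COUNTS
    counts = pd.DataFrame(counts).astype(float)
    if (counts.to_numpy() < 0).any():
        raise DataError("negative count in the status/subtype table")
    rowsum = counts.sum(axis=1)
    probs = counts.div(rowsum.replace(0, np.nan), axis=0)
    zero_rows = rowsum.index[rowsum == 0].tolist()
    if zero_rows:
        warnings.warn(f"all-zero status row(s) {zero_rows}: using a uniform distribution")
        probs.loc[zero_rows] = 1.0 / counts.shape[1]
    return ErPrPam50Table(counts=counts, probs=probs)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a count table: header row of subtype names, first column status strings."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return df.astype(float)
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric count: {exc}") from exc


def status_row(er: str, pr: str) -> str:
    return f"ER{er}/PR{pr}"


def isep(
    predicted_labels: pd.Series,
    status: pd.DataFrame,
    table: ErPrPam50Table | None = None,
) -> IsepReport:
    """Sum the conditional probability of each predicted subtype given ER/PR.

    ``predicted_labels`` maps sample id to predicted subtype; ``status`` is
    a frame with ER and PR columns coded ``+``/``-``. Samples missing from
    the status table (or lacking either marker) are excluded and counted in
    ``n_excluded``. A predicted label outside the table's subtype columns
    is an error.
    """
    if table is None:
        table = build_conditional_table()
    predicted_labels = pd.Series(predicted_labels)
    known = set(table.probs.columns)
    bad = sorted(set(predicted_labels.unique()) - known)
    if bad:
        raise DataError(f"predicted class(es) outside the table's subtypes: {bad}")

    total = 0.0
    composition: dict[str, int] = {}
    n_included = 0
    for sample, label in predicted_labels.items():
        if sample not in status.index or status.loc[sample].isna().any():
            continue
        row = status_row(status.loc[sample, "ER"], status.loc[sample, "PR"])
        if row not in table.probs.index:
            raise DataError(f"status row {row!r} absent from the conditional table")
        total += table.prob(row, label)
        composition[row] = composition.get(row, 0) + 1
        n_included += 1
    return IsepReport(
        isep=float(total),
        n_included=n_included,
        n_excluded=len(predicted_labels) - n_included,
        row_composition=composition,
    )
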