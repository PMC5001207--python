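"""Reading, writing and harmonisation of expression data and annotations.

Conventions
-----------
An *expression matrix* is a :class:`pandas.DataFrame` with gene symbols as
the row index and sample identifiers as columns; values are log-scale
expression. On disk it is a UTF-8 tab-separated table whose header row
holds the sample IDs and whose first column holds the gene symbols.

Gene symbols are matched case-insensitively throughout: symbol-case drift
between platforms is common, and the downstream statistics only ever key
on the symbol. Duplicate symbols within one file (typically multiple
probes mapping to one gene) are collapsed by arithmetic mean.

By default each dataset is gene-wise median-centered at load time (each
gene row minus its own median within that dataset). The signature filters
and the target-cluster call reason about *absolute* average expression
around zero, which presumes centered log expression; pass ``center=False``
to keep raw values.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .signature_selection import SignatureModel

SCHEMA_VERSION = 1

PAM50_SUBTYPES = ["LumA", "LumB", "Her2", "Basal", "Normal"]

_STATUS_ALIASES = {
    "+": "+", "-": "-",
    "pos": "+", "neg": "-",
    "positive": "+", "negative": "-",
    "1": "+", "0": "-",
}


class DataError(ValueError):
    """An input file or in-memory table violates the format contract."""


def _casefold(index) -> pd.Index:
    return pd.Index([str(g).casefold() for g in index])


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene row's median, gene-wise, within this dataset."""
    return matrix.sub(matrix.median(axis=1), axis=0)


def read_expression_tsv(path, *, center: bool = True) -> pd.DataFrame:
    """Load a genes x samples expression TSV.

    Duplicate gene symbols (case-insensitive) are collapsed by mean with a
    warning; all-missing gene rows are dropped with a warning; rows with
    any remaining missing cell are dropped so that downstream statistics
    always see complete rows. With ``center=True`` (default) the matrix is
    gene-wise median-centered after loading.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = pd.Index(header[1:])
    if len(sample_ids) == 0:
        raise DataError(f"{path}: no sample columns found (is the header tab-separated?)")
    if sample_ids.duplicated().any():
        dups = sample_ids[sample_ids.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate sample IDs {dups}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise DataError(f"{path}: cannot parse expression table: {exc}") from exc
    raw.columns = sample_ids.astype(str)

    mat = raw.apply(pd.to_numeric, errors="coerce")
    bad = mat.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} for gene "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r} (line {r + 2})"
        )
    mat.index = mat.index.astype(str)

    empty = mat.isna().all(axis=1)
    if empty.any():
        warnings.warn(f"{path.name}: dropped {int(empty.sum())} all-missing gene row(s)")
        mat = mat.loc[~empty]

    folded = _casefold(mat.index)
    if folded.duplicated().any():
        dup_names = sorted(set(folded[folded.duplicated()]))
        warnings.warn(
            f"{path.name}: collapsed {len(dup_names)} duplicate gene symbol(s) "
            f"by mean (e.g. {dup_names[:5]})"
        )
        first_name: dict[str, str] = {}
        for orig, f in zip(mat.index, folded):
            first_name.setdefault(f, orig)
        mat = mat.groupby(folded, sort=False).mean()
        mat.index = pd.Index([first_name[f] for f in mat.index])

    partial = mat.isna().any(axis=1)
    if partial.any():
        warnings.warn(f"{path.name}: dropped {int(partial.sum())} gene row(s) with missing values")
        mat = mat.loc[~partial]
    if mat.shape[0] == 0:
        raise DataError(f"{path}: no usable gene rows")
    if center:
        mat = median_center(mat)
    mat.index.name = None
    return mat


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


@dataclass
class LabeledDataset:
    """An expression matrix plus one class label per sample.

    ``class_names`` fixes a deterministic class order (sorted by default);
    all tie-breaks of the form "lowest class index" refer to this order.
    """

    matrix: pd.DataFrame
    labels: pd.Series
    class_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        labels = self.labels.reindex(self.matrix.columns)
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise DataError(f"samples without a class label: {missing[:5]}")
        self.labels = labels.astype(str)
        if self.class_names is None:
            self.class_names = sorted(self.labels.unique())
        else:
            extra = set(self.labels.unique()) - set(self.class_names)
            if extra:
                raise DataError(f"labels outside the declared classes: {sorted(extra)}")
            self.class_names = list(self.class_names)
        if len(self.class_names) < 2:
            raise DataError("need at least two classes")
        counts = self.labels.value_counts()
        small = [c for c in self.class_names if counts.get(c, 0) < 2]
        if small:
            raise DataError(f"every class needs >= 2 samples; too small: {small}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def samples_of(self, class_name: str) -> pd.Index:
        return self.labels.index[self.labels == class_name]

    def subset(self, sample_ids) -> "LabeledDataset":
        """Restrict to a sample subset (e.g. one cross-validation fold)."""
        sample_ids = list(sample_ids)
        return LabeledDataset(self.matrix[sample_ids], self.labels.loc[sample_ids])


def read_labels_tsv(path) -> pd.Series:
    """Read a two-column ``sample_id<TAB>class`` table (header optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    if df.iloc[0, 0].strip().lower() in {"sample_id", "sample", "id"}:
        df = df.iloc[1:]
    labels = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class")
    if labels.index.duplicated().any():
        dups = labels.index[labels.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate sample IDs {dups[:5]}")
    return labels.astype(str)


def write_labels_tsv(labels: pd.Series, path, status: pd.Series | None = None) -> None:
    out = labels.rename("label").to_frame()
    if status is not None:
        out["status"] = status
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_erpr_tsv(path) -> pd.DataFrame:
    """Read a ``sample_id<TAB>ER<TAB>PR`` status table.

    Status values ``+``/``-`` with aliases ``pos/neg``, ``positive/negative``
    and ``1/0``. Samples missing either marker are dropped with a warning —
    the indirect evaluation needs both.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 3:
        raise DataError(f"{path}: expected three tab-separated columns (sample, ER, PR)")
    df = df.iloc[:, :3]
    if df.iloc[0, 1].strip().upper() in {"ER"}:
        df = df.iloc[1:]
    df.columns = ["sample_id", "ER", "PR"]
    df = df.set_index("sample_id")

    def _norm(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return _STATUS_ALIASES.get(str(v).strip().lower())

    out = df.map(_norm)
    bad_tokens = df[(out.isna()) & df.notna()].stack().unique().tolist()
    unknown = [t for t in bad_tokens if str(t).strip().lower() not in {"na", "nan", ""}]
    if unknown:
        raise DataError(f"{path}: unrecognised ER/PR status value(s) {unknown[:5]}")
    incomplete = out.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{path.name}: dropped {int(incomplete.sum())} sample(s) lacking ER or PR status"
        )
        out = out.loc[~incomplete]
    return out


def harmonize_genes(
    reference: pd.DataFrame, prediction: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to their common genes, in reference row order.

    Matching is case-insensitive; the returned prediction matrix adopts the
    reference's symbol spelling so that later lookups never miss on case.
    """
    ref_fold = _casefold(reference.index)
    pred_fold = _casefold(prediction.index)
    pred_pos = {f: i for i, f in enumerate(pred_fold)}
    keep = [i for i, f in enumerate(ref_fold) if f in pred_pos]
    if not keep:
        raise DataError("no common genes between reference and prediction datasets")
    ref_out = reference.iloc[keep].copy()
    pred_out = prediction.iloc[[pred_pos[ref_fold[i]] for i in keep]].copy()
    pred_out.index = ref_out.index.copy()
    return ref_out, pred_out


def write_signature_model(model: "SignatureModel", path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **model.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_signature_model(path) -> "SignatureModel":
    from .signature_selection import SignatureModel

    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise DataError(f"{path}: not a valid signature-model JSON document: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise DataError(f"{path}: missing schema_version; not a signature model file")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise DataError(
            f"{path}: schema version {payload['schema_version']} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )
    try:
        return SignatureModel.from_dict(payload)
    except (KeyError, TypeError) as exc:
        raise DataError(f"{path}: malformed signature model: {exc}") from exc
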