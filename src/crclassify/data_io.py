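"""Reading and writing labeled expression matrices.

The package-internal orientation is **features x samples**: columns of the
value matrix are samples, so the training matrix can be used directly as a
column-sample dictionary.  Files on disk may be oriented either way; the
orientation is purely an I/O concern and is resolved at load time.

Two dialects are supported:

* delimited text (TSV/CSV, auto-detected by extension) with a header row,
  carrying labels either in a column (samples-as-rows layout) or in a
  separate side file (features-as-rows layout);
* a GCT v1.2-style matrix (two header lines, ``Name``/``Description``
  columns) paired with a CLS-style label file, the format in which the
  classic leukemia benchmark is distributed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledExpressionSet",
    "DataFormatError",
    "read_expression_table",
    "write_expression_table",
    "read_cls_labels",
    "write_cls_labels",
]


class DataFormatError(ValueError):
    """A file does not conform to the expected expression-table dialect."""


def _ordered_unique(items: Sequence[str]) -> list[str]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(x, None)
    return list(seen)


@dataclasses.dataclass
class LabeledExpressionSet:
    """A labeled expression matrix in features x samples orientation.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_features, n_samples)``; expression units
        are whatever the source provides (raw intensities, log2(RPKM+1), ...).
    feature_ids, sample_ids
        Row and column identifiers.
    labels
        One class label per sample, kept verbatim as strings.

    Class identity is positional: class ``i`` everywhere in the package means
    position ``i`` in :attr:`class_names`, which orders labels by first
    appearance in ``labels``.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (features x samples)")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        nf, ns = self.values.shape
        if len(self.feature_ids) != nf:
            raise ValueError(
                f"{len(self.feature_ids)} feature_ids for {nf} matrix rows"
            )
        if len(self.sample_ids) != ns or len(self.labels) != ns:
            raise ValueError(
                f"sample_ids ({len(self.sample_ids)}) and labels "
                f"({len(self.labels)}) must both match {ns} matrix columns"
            )
        dup = [s for s in _ordered_unique(self.sample_ids)
               if self.sample_ids.count(s) > 1]
        if dup:
            raise DataFormatError(f"duplicate sample identifiers: {dup}")
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("values contain non-finite entries")

    # -- basic geometry -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def class_names(self) -> list[str]:
        return _ordered_unique(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_indices(self) -> np.ndarray:
        """Per-sample integer class index into :attr:`class_names`."""
        pos = {c: i for i, c in enumerate(self.class_names)}
        return np.array([pos[l] for l in self.labels], dtype=int)

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, idx: Sequence[int]) -> "LabeledExpressionSet":
        idx = np.asarray(idx, dtype=int)
        return LabeledExpressionSet(
            self.values[:, idx],
            list(self.feature_ids),
            [self.sample_ids[i] for i in idx],
            [self.labels[i] for i in idx],
        )

    def subset_features(self, idx: Sequence[int]) -> "LabeledExpressionSet":
        idx = np.asarray(idx, dtype=int)
        return LabeledExpressionSet(
            self.values[idx, :],
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            list(self.labels),
        )

    def equals(self, other: "LabeledExpressionSet") -> bool:
        return (
            np.array_equal(self.values, other.values)
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.labels == other.labels
        )


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_numeric(df: pd.DataFrame, path: Path) -> np.ndarray:
    """Coerce a frame to float, naming the offending cell on failure."""
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise DataFormatError(
                    f"{path}: non-numeric value {df.at[row, col]!r} "
                    f"at row {row!r}, column {col!r}"
                ) from None
        raise


def _handle_missing(values: np.ndarray, path: Path, impute_missing: bool) -> np.ndarray:
    if not np.isnan(values).any():
        return values
    if not impute_missing:
        r, c = np.argwhere(np.isnan(values))[0]
        raise DataFormatError(
            f"{path}: missing value at matrix position ({r}, {c}); "
            "pass impute_missing=True to mean-impute per feature"
        )
    # per-feature (row) mean imputation
    row_means = np.nanmean(values, axis=1, keepdims=True)
    if np.isnan(row_means).any():
        raise DataFormatError(f"{path}: a feature is entirely missing")
    return np.where(np.isnan(values), row_means, values)


def read_cls_labels(path: str | Path) -> list[str]:
    """Read a CLS-style label file or a plain one-label-per-line file.

    CLS layout: header ``<n> <k> 1``, a ``#``-prefixed line of class names,
    then one line of space-separated labels (names or integer codes).
    """
    path = Path(path)
    lines = [l.strip() for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise DataFormatError(f"{path}: empty label file")
    if path.suffix.lower() == ".cls" or (len(lines) >= 3 and lines[1].startswith("#")):
        if len(lines) < 3:
            raise DataFormatError(f"{path}: CLS file needs 3 non-empty lines")
        names = lines[1].lstrip("#").split()
        toks = lines[2].split()
        if all(t.lstrip("-").isdigit() for t in toks):
            codes = [int(t) for t in toks]
            order = _ordered_unique([str(c) for c in codes])
            if len(names) != len(order):
                raise DataFormatError(
                    f"{path}: {len(names)} class names for {len(order)} codes"
                )
            mapping = {int(c): n for c, n in zip(order, names)}
            return [mapping[c] for c in codes]
        return toks
    # plain: one label per line
    return lines


def write_cls_labels(labels: Sequence[str], path: str | Path) -> None:
    labels = [str(l) for l in labels]
    names = _ordered_unique(labels)
    pos = {c: i for i, c in enumerate(names)}
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(names)} 1\n")
        fh.write("# " + " ".join(names) + "\n")
        fh.write(" ".join(str(pos[l]) for l in labels) + "\n")


def _read_delimited(
    path: Path,
    orientation: str,
    label_source: str | Path,
    impute_missing: bool,
) -> LabeledExpressionSet:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    if orientation == "samples_as_rows":
        label_col = str(label_source)
        if label_col in df.columns:
            labels_ser = df[label_col]
            mat = df.drop(columns=[label_col])
            missing = labels_ser.isna()
            if missing.any():
                sample = labels_ser.index[missing.to_numpy().nonzero()[0][0]]
                raise DataFormatError(f"{path}: missing label for sample {sample!r}")
            labels = [str(l) for l in labels_ser]
        elif Path(label_source).exists():
            labels = read_cls_labels(Path(label_source))
            mat = df
        else:
            raise DataFormatError(
                f"{path}: label source {label_source!r} is neither a column "
                "of the table nor an existing file"
            )
        sample_ids = [str(s) for s in mat.index]
        feature_ids = [str(f) for f in mat.columns]
        values = _check_numeric(mat, path).T
    elif orientation == "features_as_rows":
        labels = read_cls_labels(Path(label_source))
        sample_ids = [str(s) for s in df.columns]
        feature_ids = [str(f) for f in df.index]
        values = _check_numeric(df, path)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if len(labels) != len(sample_ids):
        raise DataFormatError(
            f"{path}: {len(labels)} labels for {len(sample_ids)} samples"
        )
    values = _handle_missing(values, path, impute_missing)
    return LabeledExpressionSet(values, feature_ids, sample_ids, labels)


# ---------------------------------------------------------------------------
# GCT
# ---------------------------------------------------------------------------

def _read_gct(path: Path, label_source: str | Path, impute_missing: bool) -> LabeledExpressionSet:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise DataFormatError(f"{path}: missing GCT version line, got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise DataFormatError(f"{path}: malformed GCT dimensions line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0,
                         float_precision="round_trip")
    if "Description" not in df.columns:
        raise DataFormatError(f"{path}: GCT table lacks a Description column")
    mat = df.drop(columns=["Description"])
    if mat.shape != (n_rows, n_cols):
        raise DataFormatError(
            f"{path}: header announces {n_rows}x{n_cols} but table is "
            f"{mat.shape[0]}x{mat.shape[1]}"
        )
    if label_source is None:
        raise DataFormatError("GCT carries no labels; a CLS side file is required")
    labels = read_cls_labels(Path(label_source))
    if len(labels) != n_cols:
        raise DataFormatError(
            f"{label_source}: {len(labels)} labels for {n_cols} GCT samples"
        )
    values = _handle_missing(_check_numeric(mat, path), path, impute_missing)
    return LabeledExpressionSet(
        values, [str(f) for f in mat.index], [str(s) for s in mat.columns], labels
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path,
    format: str = "delimited",
    orientation: str = "samples_as_rows",
    label_source: str | Path = "Label",
    impute_missing: bool = False,
) -> LabeledExpressionSet:
    """Load a labeled expression matrix into the internal orientation.

    Parameters
    ----------
    path
        Input file. For delimited input, ``.csv`` means comma-separated and
        anything else tab-separated.
    format
        ``"delimited"`` or ``"gct"``.
    orientation
        How samples are laid out in a *delimited* file; GCT is always
        features-as-rows.
    label_source
        For samples-as-rows input, the name of the label column (default
        ``"Label"``). Otherwise the path of a CLS-style or one-label-per-line
        side file.
    impute_missing
        Replace missing cells by the per-feature mean instead of erroring.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        return _read_delimited(path, orientation, label_source, impute_missing)
    if format == "gct":
        return _read_gct(path, label_source, impute_missing)
    raise ValueError(f"unknown format {format!r}")


def write_expression_table(
    data: LabeledExpressionSet,
    path: str | Path,
    format: str = "delimited",
    orientation: str = "samples_as_rows",
    label_column: str = "Label",
) -> None:
    """Write ``data`` so that :func:`read_expression_table` round-trips it.

    Values are printed with 17 significant digits, enough to reproduce any
    double exactly.  The GCT dialect writes a ``.cls`` label file next to the
    matrix (same stem).
    """
    if data.n_samples == 0 or data.n_features == 0:
        raise ValueError("refusing to write an empty expression set")
    path = Path(path)
    if format == "delimited":
        if orientation == "samples_as_rows":
            df = pd.DataFrame(
                data.values.T, index=data.sample_ids, columns=data.feature_ids
            )
            df[label_column] = data.labels
            df.to_csv(path, sep=_sep_for(path), index_label="sample_id",
                      float_format="%.17g")
        elif orientation == "features_as_rows":
            df = pd.DataFrame(
                data.values, index=data.feature_ids, columns=data.sample_ids
            )
            df.to_csv(path, sep=_sep_for(path), index_label="feature_id",
                      float_format="%.17g")
            write_cls_labels(data.labels, path.with_suffix(".cls"))
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{data.n_features}\t{data.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(data.sample_ids) + "\n")
            for i, fid in enumerate(data.feature_ids):
                row = "\t".join(format_float(v) for v in data.values[i])
                fh.write(f"{fid}\tna\t{row}\n")
        write_cls_labels(data.labels, path.with_suffix(".cls"))
    else:
        raise ValueError(f"unknown format {format!r}")


def format_float(v: float) -> str:
    return "%.17g" % v
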