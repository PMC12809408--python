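"""Readers and writers for the external formats the toolkit touches.

Counts come in as dense TSV/CSV tables (genes in rows, header row of sample
IDs) or as a 10x-style MatrixMarket directory (``matrix.mtx`` plus
``features.tsv``/``genes.tsv`` and ``barcodes.tsv`` sidecars, 1-based
indices per the MatrixMarket standard). Gene sets use the GMT dialect.
Trained scoring models round-trip through a versioned JSON document so the
feature list and calibration parameters stay auditable.

Gene identifiers are upper-cased on ingest so that human and mouse symbols
(``SLPI`` vs ``Slpi``) match; duplicate gene rows arising from the
normalization (or from multi-mapped annotation rows) are collapsed by
summation, which preserves total counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

MODEL_SCHEMA = "senescore-sid-model/1"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CountMatrix:
    """Non-negative integer counts, genes x samples.

    ``values`` is a dense ``int64`` array or a scipy sparse matrix; ``layout``
    records which. Gene identifiers are unique after upper-casing; sample
    identifiers are unique as given.
    """

    values: object  # np.ndarray or scipy.sparse matrix, genes x samples
    gene_ids: list[str]
    sample_ids: list[str]
    layout: str = "dense"  # "dense" | "sparse"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.layout not in ("dense", "sparse"):
            raise FormatError(f"unknown layout {self.layout!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene identifiers not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("sample identifiers not unique")
        data = self.values.data if sp.issparse(self.values) else self.values
        data = np.asarray(data)
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise FormatError("counts must be finite and non-negative")

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.int64)
        return np.asarray(self.values, dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets with a provenance record (source path)."""

    sets: list[tuple[str, str, list[str]]]  # (name, description, genes)
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.sets]
        if len(set(names)) != len(names):
            raise FormatError("gene set names not unique")
        for name, _, genes in self.sets:
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.sets]

    def genes(self, name: str) -> list[str]:
        for set_name, _, genes in self.sets:
            if set_name == name:
                return list(genes)
        raise KeyError(name)


def normalize_gene_ids(gene_ids) -> list[str]:
    """Upper-case gene symbols; idempotent."""
    return [str(g).strip().upper() for g in gene_ids]


def _collapse_duplicate_genes(values, gene_ids: list[str]):
    """Sum rows sharing a (normalized) gene id, preserving first-seen order."""
    order: dict[str, int] = {}
    for g in gene_ids:
        if g not in order:
            order[g] = len(order)
    if len(order) == len(gene_ids):
        return values, gene_ids
    if len(order) == 1 and len(gene_ids) > 1:
        logger.warning("all %d gene rows share one identifier", len(gene_ids))
    dupes = len(gene_ids) - len(order)
    logger.warning("collapsing %d duplicate gene row(s) by summation", dupes)
    rows = np.fromiter((order[g] for g in gene_ids), dtype=np.int64, count=len(gene_ids))
    n_unique = len(order)
    # grouping matrix G (unique x original): collapsed = G @ values
    group = sp.csr_matrix(
        (np.ones(len(gene_ids), dtype=np.int64), (rows, np.arange(len(gene_ids)))),
        shape=(n_unique, len(gene_ids)),
    )
    collapsed = group @ values
    if sp.issparse(values):
        collapsed = sp.csr_matrix(collapsed)
    else:
        collapsed = np.asarray(collapsed)
    return collapsed, list(order)


def _check_integer_counts(arr: np.ndarray, source: str) -> np.ndarray:
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{source}: non-finite count entries")
    if np.any(arr < 0):
        raise FormatError(f"{source}: negative count entries")
    rounded = np.rint(arr)
    if not np.array_equal(arr, rounded):
        raise FormatError(f"{source}: non-integer count entries")
    return rounded.astype(np.int64)


def read_counts(path, format: str | None = None) -> CountMatrix:
    """Read a counts matrix from dense TSV/CSV or a MatrixMarket directory.

    Parameters
    ----------
    path : path-like
        File (tsv/csv) or directory (mtx_dir).
    format : {"tsv", "csv", "mtx_dir"}, optional
        Inferred from the path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix.lower() == ".csv":
            format = "csv"
        else:
            format = "tsv"
    if format == "mtx_dir":
        return _read_counts_mtx_dir(path)
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown counts format {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric entries") from exc
    values = _check_integer_counts(arr, str(path))
    gene_ids = normalize_gene_ids(df.index)
    values, gene_ids = _collapse_duplicate_genes(values, gene_ids)
    return CountMatrix(values, gene_ids, [str(c) for c in df.columns], layout="dense")


def _find_sidecar(path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        p = path / stem
        if p.exists():
            return p
    raise FileNotFoundError(f"{path}: none of {stems} found")


def _read_counts_mtx_dir(path: Path) -> CountMatrix:
    mtx = _find_sidecar(path, ("matrix.mtx",))
    features = _find_sidecar(path, ("features.tsv", "genes.tsv"))
    barcodes = _find_sidecar(path, ("barcodes.tsv",))
    mat = mmread(str(mtx))
    feats = pd.read_csv(features, sep="\t", header=None)
    codes = pd.read_csv(barcodes, sep="\t", header=None)
    gene_ids = normalize_gene_ids(feats.iloc[:, 0])
    sample_ids = [str(b) for b in codes.iloc[:, 0]]
    if mat.shape != (len(gene_ids), len(sample_ids)):
        raise FormatError(
            f"{path}: matrix shape {mat.shape} does not match "
            f"{len(gene_ids)} features x {len(sample_ids)} barcodes"
        )
    values = sp.csr_matrix(mat)
    values = sp.csr_matrix(_check_sparse_integer(values, str(mtx)))
    values, gene_ids = _collapse_duplicate_genes(values, gene_ids)
    return CountMatrix(values, gene_ids, sample_ids, layout="sparse")


def _check_sparse_integer(mat: sp.csr_matrix, source: str) -> sp.csr_matrix:
    data = np.asarray(mat.data, dtype=float)
    checked = _check_integer_counts(data, source)
    out = mat.copy()
    out.data = checked
    return out.astype(np.int64)


def write_counts(matrix: CountMatrix, path, format: str | None = None) -> None:
    """Write counts back to dense TSV/CSV or a MatrixMarket directory."""
    path = Path(path)
    if format is None:
        if path.suffix.lower() == ".csv":
            format = "csv"
        elif path.suffix.lower() in (".tsv", ".txt"):
            format = "tsv"
        else:
            format = "mtx_dir"
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        coo = sp.coo_matrix(matrix.values)
        mmwrite(str(path / "matrix.mtx"), coo, field="integer")
        (path / "features.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{s}\n" for s in matrix.sample_ids))
        return
    sep = "\t" if format == "tsv" else ","
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file: name, description, then gene symbols.

    Blank gene tokens (e.g. trailing empty fields) are dropped; lines with
    fewer than three columns or duplicated set names are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sets: list[tuple[str, str, list[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            name, desc = fields[0], fields[1]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            genes = normalize_gene_ids([g for g in fields[2:] if g.strip()])
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append((name, desc, genes))
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in collection.sets:
            fh.write("\t".join([name, desc, *genes]) + "\n")


def save_model(model, path) -> None:
    """Serialize a trained SID model to a versioned JSON document.

    Floating-point fields use Python's shortest round-trip representation,
    so a load reproduces bit-identical scoring behaviour.
    """
    doc = {
        "schema": MODEL_SCHEMA,
        "mode_id": int(model.mode_id),
        "feature_genes": list(model.feature_genes),
        "weights": [float(w) for w in model.weights],
        "bias": float(model.bias),
        "alpha": float(model.alpha),
        "beta": float(model.beta),
        "train_meta": model.train_meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path):
    """Load a SID model written by :func:`save_model`."""
    from .sid import SidModel

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: corrupted or truncated model document") from exc
    if not isinstance(doc, dict) or doc.get("schema") != MODEL_SCHEMA:
        raise FormatError(
            f"{path}: unknown model schema {doc.get('schema')!r} "
            f"(expected {MODEL_SCHEMA!r})"
        )
    required = {"mode_id", "feature_genes", "weights", "bias", "alpha", "beta"}
    missing = required - doc.keys()
    if missing:
        raise FormatError(f"{path}: model document missing fields {sorted(missing)}")
    return SidModel(
        mode_id=int(doc["mode_id"]),
        feature_genes=[str(g) for g in doc["feature_genes"]],
        weights=np.asarray(doc["weights"], dtype=np.float64),
        bias=float(doc["bias"]),
        alpha=float(doc["alpha"]),
        beta=float(doc["beta"]),
        train_meta=doc.get("train_meta", {}),
    )


@dataclass
class SampleMetadata:
    """Per-sample annotations aligned to a CountMatrix."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns:
            raise FormatError("metadata requires a 'sample_id' column")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in metadata")
        if "label" in self.table.columns:
            labels = self.table["label"].dropna()
            if not set(np.unique(labels.astype(int))) <= {0, 1}:
                raise FormatError("labels must be binary (0/1)")

    def column(self, name: str, sample_ids: list[str]) -> np.ndarray:
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise FormatError(f"metadata missing samples: {missing[:5]}")
        return t.loc[sample_ids, name].to_numpy()


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))
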