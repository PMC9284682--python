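"""Shared data model and readers/writers for counts, sample metadata and config.

Counts live on disk as genes x samples (the bioinformatics convention for
bulk expression tables); statistics modules operate on samples x features
and the transpose happens exactly once, at this boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml


class ValidationError(ValueError):
    """An input violates a data-model invariant (negative count, bad p_low...)."""


class SchemaError(ValueError):
    """A table is missing a required column."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


REQUIRED_SAMPLE_COLUMNS = ("sample_id", "group", "batch", "p_low")


@dataclass
class CountMatrix:
    """Raw gene x sample counts with unique string identifiers.

    ``counts`` is an integer ndarray of shape (n_genes, n_samples); every
    entry is a finite nonnegative integer.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.issubdtype(counts.dtype, np.integer):
            as_float = counts.astype(float)
            if not np.all(np.isfinite(as_float)):
                raise ValidationError("counts contain non-finite entries")
            if not np.all(as_float == np.round(as_float)):
                raise ValidationError("counts contain non-integer entries")
            counts = as_float.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts contain negative entries")
        self.counts = counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        """Return a copy restricted to ``sample_ids`` in the given order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx].copy())


@dataclass
class SampleTable:
    """Per-sample metadata: biological group, batch label and p_low.

    ``p_low`` is the probability that a sample is of low quality, in [0, 1].
    Extra columns from the input file are preserved in ``annotations``.
    """

    data: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"sample table missing required column(s): {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        plow = df["p_low"]
        finite = plow.notna()
        if finite.any():
            vals = plow[finite].astype(float)
            if (vals < 0).any() or (vals > 1).any():
                bad = df.loc[finite & ((plow < 0) | (plow > 1)), "sample_id"].tolist()
                raise ValidationError(f"p_low outside [0, 1] for sample(s): {bad}")
        df["p_low"] = plow.astype(float)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def groups(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    @property
    def batches(self) -> np.ndarray:
        return self.data["batch"].to_numpy()

    @property
    def p_low(self) -> np.ndarray:
        return self.data["p_low"].to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def require_p_low(self) -> np.ndarray:
        """p_low values, erroring when any is missing (quality ops need all)."""
        p = self.p_low
        if np.isnan(p).any():
            bad = [s for s, v in zip(self.sample_ids, p) if np.isnan(v)]
            raise ValidationError(f"p_low missing for sample(s): {bad}")
        return p

    def aligned_to(self, sample_ids: list[str]) -> "SampleTable":
        """Reorder/subset rows to match ``sample_ids``; bijection or hard error."""
        have = set(self.sample_ids)
        want = list(sample_ids)
        missing = [s for s in want if s not in have]
        if missing:
            raise ValidationError(f"sample table lacks sample(s): {missing}")
        df = self.data.set_index("sample_id").loc[want].reset_index()
        ann = None
        if self.annotations is not None:
            ann = self.annotations.set_index(self.data["sample_id"]).loc[want].reset_index(drop=True)
        return SampleTable(df, ann)

    def subset(self, keep: list[str]) -> "SampleTable":
        return self.aligned_to(keep)


@dataclass
class PipelineConfig:
    """Tunable parameters of the end-to-end workflow."""

    pseudocount: float = 1.0
    de_alpha: float = 0.05
    n_components: int = 2
    lambda_grid: tuple[float, ...] = tuple(np.linspace(0.0, 20.0, 41))
    penalty_tol: float = 0.05
    outlier_min_gap: float = 0.3
    outlier_threshold: float | None = None
    compute_de: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if not 0 < self.de_alpha < 1:
            raise ValidationError("de_alpha must be in (0, 1)")
        if self.n_components < 1:
            raise ValidationError("n_components must be a positive integer")
        grid = tuple(float(x) for x in self.lambda_grid)
        if len(grid) == 0 or grid[0] != 0.0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError("lambda_grid must be strictly increasing and start at 0")
        if any(x < 0 for x in grid):
            raise ValidationError("lambda_grid values must be nonnegative")
        self.lambda_grid = grid
        if not 0 < self.penalty_tol < 1:
            raise ValidationError("penalty_tol must be in (0, 1)")
        if not 0 < self.outlier_min_gap <= 1:
            raise ValidationError("outlier_min_gap must be in (0, 1]")
        if self.outlier_threshold is not None and not 0 <= self.outlier_threshold <= 1:
            raise ValidationError("outlier_threshold must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
        if raw is None:
            raw = {}
        if "lambda_grid" in raw:
            raw["lambda_grid"] = tuple(raw["lambda_grid"])
        return cls(**raw)


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a gene x sample count matrix.

    ``tsv``: first column gene ids, header row sample ids.
    ``mtx``: MatrixMarket file with ``genes.tsv`` / ``samples.tsv`` id
    sidecars next to it (one id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"cannot parse count TSV {path}: {exc}") from exc
        values = df.to_numpy()
        if values.dtype == object or not np.issubdtype(values.dtype, np.number):
            for i, row in enumerate(df.itertuples(index=False), start=2):
                for v in row:
                    try:
                        float(v)
                    except (TypeError, ValueError):
                        raise ParseError(f"{path}: non-numeric count on line {i}: {v!r}") from None
        return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        genes = _read_id_sidecar(path.parent / "genes.tsv")
        samples = _read_id_sidecar(path.parent / "samples.tsv")
        dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        return CountMatrix(genes, samples, dense)
    raise ValueError(f"unknown count format: {format!r}")


def _read_id_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing id sidecar {path}")
    return [line.strip().split("\t")[0] for line in path.read_text().splitlines() if line.strip()]


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
        df.index.name = "gene"
        df.to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
        (path.parent / "genes.tsv").write_text("\n".join(cm.gene_ids) + "\n")
        (path.parent / "samples.tsv").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown count format: {format!r}")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a per-sample metadata TSV with columns sample_id, group, batch, p_low.

    Extra columns are preserved as opaque annotations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse sample table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_SAMPLE_COLUMNS]
    annotations = df[extra].copy() if extra else None
    return SampleTable(df[list(REQUIRED_SAMPLE_COLUMNS)].copy(), annotations)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    df = table.data.copy()
    if table.annotations is not None:
        df = pd.concat([df, table.annotations.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def join_counts_samples(cm: CountMatrix, table: SampleTable) -> SampleTable:
    """Align the sample table to the count matrix column order (bijection or error)."""
    aligned = table.aligned_to(cm.sample_ids)
    extra = set(table.sample_ids) - set(cm.sample_ids)
    if extra:
        raise ValidationError(f"sample table has sample(s) absent from counts: {sorted(extra)}")
    return aligned
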