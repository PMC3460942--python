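"""Typed tables for expression, composition and clinical data, plus cross-platform helpers.

All on-disk formats are plain TSV (tab-separated, UTF-8, header row, ``NA`` for
missing). Expression values are assumed to already be on the log2 scale; no
background correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("ccprog")

_SUM_TOL = 1e-6


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    Rows containing any missing/non-finite value must be dropped before
    construction (the readers do this and log the count).
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.sample_ids, self.values[rows])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            cols = [idx[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"unknown sample on alignment: {e.args[0]!r}") from None
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, cols])


@dataclass
class CompositionTable:
    """Per-sample cell-type fractions (tumor epithelium, stroma, optionally more)."""

    sample_ids: list
    cell_types: list
    fractions: np.ndarray  # samples x cell types

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.cell_types = list(self.cell_types)
        self.fractions = np.asarray(self.fractions, dtype=float)
        _check_unique(self.sample_ids, "sample")
        if self.fractions.shape != (len(self.sample_ids), len(self.cell_types)):
            raise ValueError("fractions shape does not match sample/cell-type lists")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            bad = np.argwhere((self.fractions < 0) | (self.fractions > 1))[0]
            raise ValueError(
                f"fraction outside [0,1] for sample {self.sample_ids[bad[0]]!r}, "
                f"cell type {self.cell_types[bad[1]]!r}"
            )
        sums = self.fractions.sum(axis=1)
        if np.any(sums > 1 + _SUM_TOL):
            i = int(np.argmax(sums))
            raise ValueError(
                f"cell-type fractions for sample {self.sample_ids[i]!r} sum to "
                f"{sums[i]:.6f} > 1"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.sample_ids, columns=self.cell_types)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    def align(self, sample_ids) -> "CompositionTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [idx[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"unknown sample on alignment: {e.args[0]!r}") from None
        return CompositionTable(list(sample_ids), self.cell_types, self.fractions[rows])

    def fraction_of(self, cell_type: str) -> np.ndarray:
        if cell_type not in self.cell_types:
            raise KeyError(f"cell type {cell_type!r} not in composition table")
        return self.fractions[:, self.cell_types.index(cell_type)]


@dataclass
class ClinicalTable:
    """Per-sample outcome data: biochemical relapse status, follow-up, Gleason sum.

    ``relapse`` is the observed biochemical relapse label used by the screen;
    ``months``/``event`` are the follow-up time and event indicator used by the
    survival module. Missing values are NaN.
    """

    sample_ids: list
    relapse: np.ndarray = None
    months: np.ndarray = None
    event: np.ndarray = None
    gleason: np.ndarray = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        for name in ("relapse", "months", "event", "gleason"):
            v = getattr(self, name)
            v = np.full(n, np.nan) if v is None else np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} length does not match sample count")
            setattr(self, name, v)
        for name in ("relapse", "event"):
            v = getattr(self, name)
            ok = np.isnan(v) | (v == 0) | (v == 1)
            if not np.all(ok):
                i = int(np.argmin(ok))
                raise ValueError(
                    f"{name} must be 0/1 where present; sample "
                    f"{self.sample_ids[i]!r} has {v[i]!r}"
                )
        bad = ~np.isnan(self.months) & (self.months < 0)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"months must be >= 0; sample {self.sample_ids[i]!r} has {self.months[i]}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relapse": self.relapse,
                "months": self.months,
                "event": self.event,
                "gleason": self.gleason,
            },
            index=self.sample_ids,
        )

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    def align(self, sample_ids) -> "ClinicalTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [idx[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"unknown sample on alignment: {e.args[0]!r}") from None
        return ClinicalTable(
            list(sample_ids),
            self.relapse[rows],
            self.months[rows],
            self.event[rows],
            self.gleason[rows],
        )


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=True)
    return df


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header row sample ids).

    Rows with any missing value are dropped (count logged). Duplicate gene or
    sample ids and non-numeric cells raise with the offending location.
    """
    df = _read_tsv(path)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifier: {dup[0]!r}")
    dupc = df.columns[df.columns.duplicated()]
    if len(dupc):
        raise ValueError(f"duplicate sample identifier: {dupc[0]!r}")
    for col in df.columns:
        if df[col].dtype == object:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValueError(
                    f"non-numeric expression value at gene {row!r}, sample {col!r}: "
                    f"{df.loc[row, col]!r}"
                )
            df[col] = converted
    keep = df.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_expression: dropped %d gene row(s) with missing values", n_dropped)
    return ExpressionMatrix.from_dataframe(df.loc[keep])


def read_composition(path) -> CompositionTable:
    """Read a samples x cell-types fraction TSV keyed by sample_id."""
    df = _read_tsv(path)
    return CompositionTable(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with columns relapse, months, event, gleason (NA allowed)."""
    df = _read_tsv(path)
    def col(name):
        return df[name].to_numpy(dtype=float) if name in df.columns else None
    return ClinicalTable(
        list(df.index), col("relapse"), col("months"), col("event"), col("gleason")
    )


def intersect_probes(a: ExpressionMatrix, b: ExpressionMatrix):
    """Restrict two matrices to their common probes, in a's row order.

    Used before cross-platform normalization, where one platform's probe set is
    (approximately) a subset of the other's.
    """
    in_b = set(b.gene_ids)
    common = [g for g in a.gene_ids if g in in_b]
    if not common:
        raise ValueError("empty probe intersection between the two matrices")
    return a.subset_genes(common), b.subset_genes(common)


def reference_quantile_vector(reference: ExpressionMatrix) -> np.ndarray:
    """Per-rank mean of the sorted reference samples (the normalization target)."""
    return np.sort(reference.values, axis=0).mean(axis=1)


def reference_quantile_normalize(
    test: ExpressionMatrix, reference: ExpressionMatrix
) -> ExpressionMatrix:
    """Quantile-normalize each test sample against a fixed reference distribution.

    Every test sample's values are replaced rank-for-rank by the reference
    quantile vector (per-rank mean over sorted reference samples), so the
    within-sample ordering is preserved while the marginal distribution becomes
    exactly the reference's. Tied test values receive the mean of the reference
    quantiles of their tied ranks. Idempotent for a fixed reference.
    """
    if test.gene_ids != reference.gene_ids:
        raise ValueError(
            "test and reference must share identical gene ids (apply intersect_probes first)"
        )
    q = reference_quantile_vector(reference)
    out = np.empty_like(test.values)
    for j in range(test.n_samples):
        x = test.values[:, j]
        order = np.argsort(x, kind="mergesort")
        col = np.empty_like(x)
        col[order] = q
        xs = x[order]
        # average reference quantiles over runs of tied input values
        ties = np.flatnonzero(xs[1:] == xs[:-1])
        if ties.size:
            i = 0
            while i < len(xs):
                k = i
                while k + 1 < len(xs) and xs[k + 1] == xs[i]:
                    k += 1
                if k > i:
                    col[order[i : k + 1]] = q[i : k + 1].mean()
                i = k + 1
        out[:, j] = col
    return ExpressionMatrix(test.gene_ids, test.sample_ids, out)
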