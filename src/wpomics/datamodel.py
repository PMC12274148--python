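"""Core data containers for integrative multi-omics analysis with block-missing
expression data.

The data consist of a phenotype vector ``Y`` (length *n*), an optional covariate
matrix ``X`` (*n* x *r*), a methylation matrix ``M`` (*n* x *q* CpG sites) and a
standardized gene-expression matrix ``G`` observed only on a subset of *n1*
samples (*n1* x *d* genes).  Missingness is sample-level: a subject either has
its entire expression profile or none of it.  The sample split induced by that
pattern — a complete set ``Z1`` carrying (M, Y, X, G) and an incomplete set
``Z2`` carrying (M, Y, X) — is the structural backbone of the whole method.

Sample identifiers are the join key across files; row order on disk carries no
meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    InsufficientSamplesError,
    ValidationError,
    ZeroVarianceError,
)

__all__ = [
    "OmicsMatrixSet",
    "CompleteSet",
    "IncompleteSet",
    "SplitOmicsDataset",
    "load_dataset",
    "write_dataset",
    "standardize_expression",
    "split_dataset",
]


def _check_no_nan(frame: pd.DataFrame | pd.Series, name: str) -> None:
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(
            f"matrix {name!r} contains NaN entries; within-matrix missingness "
            "is unsupported (missingness must be whole-sample absence from G)"
        )


@dataclass
class OmicsMatrixSet:
    """Row-aligned phenotype, covariates, methylation and (partial) expression.

    Parameters
    ----------
    y
        Phenotypic outcome, indexed by sample id (length *n*).
    M
        Methylation matrix, samples x CpG sites (*n* x *q*).
    G
        Expression matrix over the expressed subset of samples (*n1* x *d*).
        Its index must be a subset of ``y``'s.
    X
        Optional covariate matrix (*n* x *r*); ``None`` means *r* = 0.
    """

    y: pd.Series
    M: pd.DataFrame
    G: pd.DataFrame
    X: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        sample_ids = self.y.index
        if sample_ids.has_duplicates:
            dupes = sample_ids[sample_ids.duplicated()].tolist()
            raise AlignmentError(f"duplicate sample ids in outcome: {dupes}")

        for name, frame in (("M", self.M), ("X", self.X)):
            if frame is None:
                continue
            missing = sample_ids.difference(frame.index)
            extra = frame.index.difference(sample_ids)
            if len(missing) or len(extra):
                raise AlignmentError(
                    f"sample ids of {name} do not match outcome; "
                    f"missing={missing.tolist()[:5]}, extra={extra.tolist()[:5]}"
                )

        extra_g = self.G.index.difference(sample_ids)
        if len(extra_g):
            raise AlignmentError(
                "expression matrix contains sample ids absent from the outcome: "
                f"{extra_g.tolist()[:5]}"
            )

        # Row-align everything to the outcome's sample order.
        self.M = self.M.loc[sample_ids]
        if self.X is not None:
            self.X = self.X.loc[sample_ids]
        self.G = self.G.loc[[s for s in sample_ids if s in set(self.G.index)]]

        _check_no_nan(self.y, "Y")
        _check_no_nan(self.M, "M")
        _check_no_nan(self.G, "G")
        if self.X is not None:
            _check_no_nan(self.X, "X")

    # -- dimensions ---------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.y.index

    @property
    def expressed_ids(self) -> pd.Index:
        return self.G.index

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n1(self) -> int:
        return len(self.G)

    @property
    def n2(self) -> int:
        return self.n - self.n1

    @property
    def q(self) -> int:
        return self.M.shape[1]

    @property
    def d(self) -> int:
        return self.G.shape[1]

    @property
    def r(self) -> int:
        return 0 if self.X is None else self.X.shape[1]


@dataclass
class CompleteSet:
    """View of the complete set Z1: samples with an observed expression profile."""

    y: pd.Series
    M: pd.DataFrame
    G: pd.DataFrame
    X: Optional[pd.DataFrame] = None

    @property
    def n1(self) -> int:
        return len(self.y)

    @property
    def r(self) -> int:
        return 0 if self.X is None else self.X.shape[1]


@dataclass
class IncompleteSet:
    """View of the incomplete set Z2: samples whose expression is missing."""

    y: pd.Series
    M: pd.DataFrame
    X: Optional[pd.DataFrame] = None

    @property
    def n2(self) -> int:
        return len(self.y)


@dataclass
class SplitOmicsDataset:
    """Partition of an :class:`OmicsMatrixSet` into complete/incomplete sets."""

    data: OmicsMatrixSet
    z1: CompleteSet = field(init=False)
    z2: IncompleteSet = field(init=False)

    def __post_init__(self) -> None:
        data = self.data
        complete = data.expressed_ids
        incomplete = data.sample_ids.difference(complete, sort=False)
        X1 = data.X.loc[complete] if data.X is not None else None
        X2 = data.X.loc[incomplete] if data.X is not None else None
        self.z1 = CompleteSet(
            y=data.y.loc[complete], M=data.M.loc[complete], G=data.G, X=X1
        )
        self.z2 = IncompleteSet(
            y=data.y.loc[incomplete], M=data.M.loc[incomplete], X=X2
        )

    @property
    def missing_rate(self) -> float:
        """Fraction of samples whose expression profile is absent (n2/n)."""
        return self.data.n2 / self.data.n

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def n1(self) -> int:
        return self.data.n1

    @property
    def n2(self) -> int:
        return self.data.n2


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path, delimiter: Optional[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(
        path,
        sep=_sep_for(path, delimiter),
        index_col=0,
        float_precision="round_trip",
    )
    frame.index = frame.index.astype(str)
    return frame


def load_dataset(
    y_path: str | Path,
    m_path: str | Path,
    g_path: str | Path,
    x_path: str | Path | None = None,
    delimiter: str | None = None,
) -> OmicsMatrixSet:
    """Load a dataset from delimited text files (TSV default, CSV by extension).

    Each file has sample ids in the first column and feature ids in the header.
    ``Y``/``X``/``M`` must share an identical sample-id set; ``G``'s ids must be
    a subset.  Omitting ``x_path`` yields a covariate-free dataset (r = 0).
    """
    y_frame = _read_table(Path(y_path), delimiter)
    if y_frame.shape[1] != 1:
        raise ValidationError(
            f"outcome file must have exactly one value column, got {y_frame.shape[1]}"
        )
    y = y_frame.iloc[:, 0].astype(float)
    M = _read_table(Path(m_path), delimiter).astype(float)
    G = _read_table(Path(g_path), delimiter).astype(float)
    X = None
    if x_path is not None:
        X = _read_table(Path(x_path), delimiter).astype(float)
    return OmicsMatrixSet(y=y, M=M, G=G, X=X)


def write_dataset(data: OmicsMatrixSet, directory: str | Path) -> dict[str, Path]:
    """Write a dataset as TSV files ``Y.tsv``, ``M.tsv``, ``G.tsv`` (and ``X.tsv``).

    Values are written with full ``repr`` precision so a write/load round trip
    reproduces finite inputs bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    y_frame = data.y.to_frame(name=data.y.name or "Y")
    for name, frame in (
        ("Y", y_frame),
        ("M", data.M),
        ("G", data.G),
        ("X", data.X),
    ):
        if frame is None:
            continue
        path = directory / f"{name}.tsv"
        out = frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def standardize_expression(G: pd.DataFrame) -> pd.DataFrame:
    """Column-standardize expression to sample mean 0 and sd 1 (ddof = 1).

    Statistics are computed on the rows given — by construction the complete
    set, the only samples for which expression exists.
    """
    values = G.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [str(G.columns[i]) for i in zero[:5]]
        raise ZeroVarianceError(f"zero-variance gene columns: {names}")
    return pd.DataFrame(
        (values - mean) / sd, index=G.index, columns=G.columns
    )


def split_dataset(
    data: OmicsMatrixSet,
    d_effective: int | None = None,
    standardize: bool = False,
) -> SplitOmicsDataset:
    """Partition samples into the complete set Z1 and the incomplete set Z2.

    Parameters
    ----------
    d_effective
        Number of expression regressors the downstream outcome model will use
        (d, or k after factor reduction).  When given, an identifiability check
        requires ``n1 >= r + d_effective + 2``.
    standardize
        Standardize ``G`` over the complete set before splitting.
    """
    if d_effective is not None and data.n1 < data.r + d_effective + 2:
        raise InsufficientSamplesError(
            f"complete set has n1={data.n1} samples, too few for a model with "
            f"{d_effective} expression regressors and {data.r} covariates "
            f"(need n1 >= {data.r + d_effective + 2})"
        )
    if standardize:
        data = OmicsMatrixSet(
            y=data.y, M=data.M, G=standardize_expression(data.G), X=data.X
        )
    return SplitOmicsDataset(data=data)
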