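"""Gene filtering, per-gene z-scaling, and mean temporal profiles.

The test statistic downstream is defined on complete, z-scaled temporal
profiles: each gene's expression across the M time points is centred to mean
zero and scaled to standard deviation one (sample sd, denominator M-1, by
default). Genes with missing values or zero temporal variance cannot be
scaled and are removed first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ContractError, EmptyMatrixError
from .io_formats import ExpressionMatrix, GeneSet, normalize_gene_id

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterLog:
    """Counts of genes removed by :func:`filter_genes`, per reason."""

    n_missing: int
    n_constant: int

    @property
    def n_removed(self) -> int:
        return self.n_missing + self.n_constant


@dataclass(frozen=True)
class ScaledMatrix:
    """A complete genes x time matrix with every row at mean 0, sd 1."""

    gene_ids: tuple[str, ...]
    time_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_labels)


@dataclass(frozen=True)
class Profile:
    """A mean temporal profile over ``n_genes`` scaled genes."""

    time_labels: tuple[str, ...]
    values: np.ndarray
    n_genes: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.time_labels),):
            raise ContractError("profile length does not match time labels")


def filter_genes(
    matrix: ExpressionMatrix,
    drop_missing: bool = True,
    drop_constant: bool = True,
) -> tuple[ExpressionMatrix, FilterLog]:
    """Remove genes that cannot be z-scaled.

    Default policy removes genes with any missing value and genes that are
    constant across the time course (zero variance). Returns the filtered
    matrix and a per-reason removal log; counts are also emitted on the
    logging channel so the decision is auditable.

    Raises
    ------
    EmptyMatrixError
        If no gene survives filtering.
    """
    values = matrix.values
    missing = np.zeros(matrix.n_genes, dtype=bool)
    constant = np.zeros(matrix.n_genes, dtype=bool)
    if drop_missing:
        missing = np.isnan(values).any(axis=1)
    if drop_constant:
        # ptp, not sd: float round-off can give a constant row a tiny nonzero sd
        with np.errstate(invalid="ignore"):
            span = np.nanmax(values, axis=1) - np.nanmin(values, axis=1)
        constant = ~missing & (span == 0.0)
    keep = ~(missing | constant)
    log = FilterLog(n_missing=int(missing.sum()), n_constant=int(constant.sum()))
    if log.n_removed:
        logger.info(
            "filter_genes removed %d genes (%d with missing values, %d constant)",
            log.n_removed, log.n_missing, log.n_constant,
        )
    if not keep.any():
        raise EmptyMatrixError("all genes removed by filtering")
    if keep.all():
        return matrix, log
    filtered = ExpressionMatrix(
        gene_ids=tuple(g for g, k in zip(matrix.gene_ids, keep) if k),
        time_labels=matrix.time_labels,
        values=values[keep],
    )
    return filtered, log


class GeneProfileScaler(TransformerMixin, BaseEstimator):
    """Scale each gene's temporal profile to mean 0, standard deviation 1.

    In the sklearn orientation used here the genes are the samples (rows) and
    the time points the features (columns), so this is a per-row transform;
    it is stateless and ``fit`` only validates input.

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom of the standard deviation. 1 gives the
        sample sd (denominator M-1); 0 the population sd.

    Notes
    -----
    The transform is idempotent up to floating tolerance and invariant to
    per-gene affine maps ``a*x + b`` with ``a > 0``.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        self._validate(X)
        self.n_features_in_ = np.asarray(X, dtype=float).shape[1]
        return self

    def transform(self, X):
        values, index = self._validate(X)
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=self.ddof, keepdims=True)
        out = (values - mean) / sd
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def _validate(self, X):
        index = X.index if isinstance(X, pd.DataFrame) else None
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ContractError("expected a 2-D genes x time array")
        if values.shape[1] <= self.ddof:
            raise ContractError(
                f"need more than ddof={self.ddof} time points to scale"
            )
        if np.isnan(values).any():
            raise ContractError("missing values present; run filter_genes first")
        flat = np.flatnonzero(np.ptp(values, axis=1) == 0.0)
        if flat.size:
            name = index[flat[0]] if index is not None else f"row {flat[0]}"
            raise ContractError(
                f"constant gene profile cannot be scaled: {name}"
            )
        return values, index


def scale_rows(matrix: ExpressionMatrix, ddof: int = 1) -> ScaledMatrix:
    """Z-scale every gene's profile (see :class:`GeneProfileScaler`)."""
    frame = matrix.to_frame()
    scaled = GeneProfileScaler(ddof=ddof).fit_transform(frame)
    return ScaledMatrix(matrix.gene_ids, matrix.time_labels, scaled.to_numpy())


def background_profile(scaled: ScaledMatrix) -> Profile:
    """Column-wise mean over all genes — the background every set is compared to."""
    return Profile(
        time_labels=scaled.time_labels,
        values=scaled.values.mean(axis=0),
        n_genes=scaled.n_genes,
    )


def match_members(
    scaled: ScaledMatrix,
    gene_set: GeneSet | frozenset | set | tuple | list,
    case_insensitive: bool = True,
) -> np.ndarray:
    """Row indices of ``scaled`` whose gene ids appear in the set.

    Matching normalizes both sides (whitespace trim, optional case-fold).
    Indices come back in matrix order.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else gene_set
    wanted = {normalize_gene_id(m, case_insensitive) for m in members}
    idx = [
        i
        for i, g in enumerate(scaled.gene_ids)
        if normalize_gene_id(g, case_insensitive) in wanted
    ]
    return np.asarray(idx, dtype=np.intp)


def set_profile(
    scaled: ScaledMatrix,
    gene_set: GeneSet | frozenset | set | tuple | list,
    min_overlap: int = 3,
    case_insensitive: bool = True,
) -> Profile | None:
    """Mean scaled profile over the set members present in the matrix.

    Returns ``None`` (a "not testable" signal, logged — not an error) when
    fewer than ``min_overlap`` members are present.
    """
    idx = match_members(scaled, gene_set, case_insensitive)
    if idx.size < min_overlap:
        name = gene_set.name if isinstance(gene_set, GeneSet) else "<anonymous>"
        logger.info(
            "set %s not testable: overlap %d < min_overlap %d",
            name, idx.size, min_overlap,
        )
        return None
    return Profile(
        time_labels=scaled.time_labels,
        values=scaled.values[idx].mean(axis=0),
        n_genes=int(idx.size),
    )
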