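"""Genotype quality control, {-1,0,1} coding and genomic covariate structures.

Three covariate structures can be fed to a prediction model:

* ``X`` — the coded marker matrix itself (n individuals x m markers),
* ``G`` — the standardized genomic relationship matrix
  ``G = W W^T / (2 * sum_j q_j (1 - q_j))`` where ``W`` is ``X`` with each
  column centred by its expected value ``2 q_j - 1`` (VanRaden-style
  construction under the -1/0/1 parameterization),
* ``UD`` — principal-component scores from the singular value decomposition
  ``X = U D V^T``; the n-dimensional re-expression ``UD`` preserves
  ``X X^T`` exactly.

``G`` and ``UD`` are min-max scaled to [-1, 1] before entering a network;
``X`` already lives on that scale through its coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyPanelError, ValidationError

__all__ = [
    "RawGenotypeTable",
    "CodedGenotypeMatrix",
    "GenomicRelationship",
    "PCScores",
    "ScaledInputMatrix",
    "qc_filter",
    "allele_frequencies",
    "code_genotypes",
    "compute_G",
    "compute_UD",
    "minmax_scale",
    "inverse_minmax",
    "build_input",
    "INPUT_KINDS",
]

INPUT_KINDS = ("X", "G", "UD")


@dataclass
class RawGenotypeTable:
    """Allele-count genotypes: entries in {0, 1, 2}, NaN marks a missing call."""

    sample_ids: list[str]
    marker_ids: list[str]
    counts: np.ndarray  # float (n, m); values 0/1/2 or NaN

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array (individuals x markers)")
        n, m = self.counts.shape
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise ValidationError(
                f"id lists ({len(self.sample_ids)} samples, {len(self.marker_ids)} "
                f"markers) do not match counts shape {self.counts.shape}"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        observed = self.counts[~np.isnan(self.counts)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise ValidationError(f"genotype entries must be 0/1/2 or missing; found {bad}")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def missing_rate(self) -> float:
        return float(np.isnan(self.counts).mean()) if self.counts.size else 0.0


@dataclass
class CodedGenotypeMatrix:
    """Marker matrix coded -1/0/1 with mean-imputed missing calls.

    ``q`` holds, per marker, the frequency of the allele coded +1 (the major
    allele after orientation, so q >= 0.5 up to ties).
    """

    X: np.ndarray  # float (n, m); in [-1, 1] after imputation
    q: np.ndarray  # float (m,); frequency of the +1-coded allele, in (0, 1)
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if np.isnan(self.X).any():
            raise ValidationError("coded matrix must not contain missing values")
        if ((self.q <= 0) | (self.q >= 1)).any():
            raise ValidationError("allele frequencies of retained markers must lie in (0,1)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class GenomicRelationship:
    """Standardized genomic relationship matrix and its scalar denominator."""

    G: np.ndarray  # (n, n) symmetric
    denominator: float  # 2 * sum_j q_j (1 - q_j)


@dataclass
class PCScores:
    """Principal-component scores UD of the coded marker matrix.

    ``UD @ UD.T`` equals ``X @ X.T`` up to floating error; columns are ordered
    by descending singular value, padded with zero columns when m < n.
    """

    UD: np.ndarray  # (n, n)
    singular_values: np.ndarray  # (n,), descending, zero-padded


@dataclass
class ScaledInputMatrix:
    """A covariate matrix min-max scaled to [-1, 1] with its scaling state."""

    values: np.ndarray
    kind: str  # one of INPUT_KINDS (or "raw" for ad-hoc use)
    lo: np.ndarray  # per-column minima (or a single value when per_column=False)
    hi: np.ndarray
    per_column: bool = True
    source_shape: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.source_shape is None:
            self.source_shape = tuple(self.values.shape)


def _nonmissing_counts(table: RawGenotypeTable) -> np.ndarray:
    return (~np.isnan(table.counts)).sum(axis=0)


def allele_frequencies(table: RawGenotypeTable) -> np.ndarray:
    """Frequency of the counted allele per marker, over non-missing calls.

    q_j = (sum of allele counts) / (2 * number of non-missing samples).
    """
    n_obs = _nonmissing_counts(table)
    if (n_obs == 0).any():
        j = int(np.argmax(n_obs == 0))
        raise ValidationError(
            f"marker {table.marker_ids[j]!r} has no non-missing genotype calls"
        )
    return np.nansum(table.counts, axis=0) / (2.0 * n_obs)


def qc_filter(
    table: RawGenotypeTable,
    maf_min: float = 0.05,
    missing_max: float = 0.95,
) -> tuple[RawGenotypeTable, pd.DataFrame]:
    """Drop markers with minor allele frequency below ``maf_min`` or missing
    fraction above ``missing_max``; marker order is preserved.

    Returns the filtered table and a removal log (marker_id, reason, value).
    Raises :class:`EmptyPanelError` if nothing survives.
    """
    if table.m == 0:
        raise EmptyPanelError("empty marker panel: input table has no markers")
    n_obs = _nonmissing_counts(table)
    miss_frac = 1.0 - n_obs / table.n
    # markers with zero calls get MAF 0 and fall to the MAF filter
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n_obs > 0, np.nansum(table.counts, axis=0) / (2.0 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(q, 1.0 - q)

    removals: list[dict] = []
    keep = np.ones(table.m, dtype=bool)
    for j in range(table.m):
        if miss_frac[j] > missing_max:
            keep[j] = False
            removals.append(
                {"marker_id": table.marker_ids[j], "reason": "missing_rate", "value": miss_frac[j]}
            )
        elif maf[j] < maf_min:
            keep[j] = False
            removals.append(
                {"marker_id": table.marker_ids[j], "reason": "maf", "value": maf[j]}
            )
    log = pd.DataFrame(removals, columns=["marker_id", "reason", "value"])
    if not keep.any():
        raise EmptyPanelError("empty marker panel: every marker failed quality control")
    filtered = RawGenotypeTable(
        sample_ids=list(table.sample_ids),
        marker_ids=[mid for mid, k in zip(table.marker_ids, keep) if k],
        counts=table.counts[:, keep].copy(),
    )
    return filtered, log


def code_genotypes(table: RawGenotypeTable) -> CodedGenotypeMatrix:
    """Code counts to -1/0/1 and mean-impute missing calls.

    Orientation: -1 is the homozygote for the minor allele and +1 the
    homozygote for the other (major) allele. Raw tables may count either
    allele, so columns whose counted-allele frequency is below 0.5 are
    flipped (c -> 2 - c) before the shift c -> c - 1.
    """
    q_counted = allele_frequencies(table)
    counts = table.counts.copy()
    flip = q_counted < 0.5
    counts[:, flip] = 2.0 - counts[:, flip]
    q = np.where(flip, 1.0 - q_counted, q_counted)
    X = counts - 1.0
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    return CodedGenotypeMatrix(
        X=X, q=q, sample_ids=list(table.sample_ids), marker_ids=list(table.marker_ids)
    )


def compute_G(coded: CodedGenotypeMatrix) -> GenomicRelationship:
    """Standardized genomic relationship matrix.

    Columns of X are centred by their expectation 2 q_j - 1 and the Gram
    matrix is divided by 2 * sum_j q_j (1 - q_j).
    """
    if coded.m < 1:
        raise ValidationError("need at least one marker")
    denom = float(2.0 * np.sum(coded.q * (1.0 - coded.q)))
    if denom == 0.0:
        raise ValidationError("G denominator is zero: all markers are monomorphic")
    W = coded.X - (2.0 * coded.q - 1.0)
    G = W @ W.T / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return GenomicRelationship(G=G, denominator=denom)


def compute_UD(coded: CodedGenotypeMatrix) -> PCScores:
    """Principal-component scores from the SVD X = U D V^T.

    Signs are pinned so the largest-magnitude element of each right-singular
    vector is positive; trailing components are zero-padded so UD is n x n.
    """
    X = coded.X
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least two individuals for the SVD")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(len(s)):
        row = Vt[i]
        pivot = int(np.argmax(np.abs(row)))
        if row[pivot] < 0:
            Vt[i] = -row
            U[:, i] = -U[:, i]
    UD = U * s  # column-wise scaling
    if UD.shape[1] < n:
        pad = n - UD.shape[1]
        UD = np.hstack([UD, np.zeros((n, pad))])
        s = np.concatenate([s, np.zeros(pad)])
    return PCScores(UD=UD, singular_values=s[:n])


def minmax_scale(
    matrix: np.ndarray, per_column: bool = True, kind: str = "raw"
) -> ScaledInputMatrix:
    """Linearly map entries to [-1, 1]: x -> 2 (x - min) / (max - min) - 1.

    Per column by default; constant columns map to 0. The (min, max) pairs
    are retained so :func:`inverse_minmax` can reproduce the source exactly.
    """
    M = np.asarray(matrix, dtype=float)
    if not np.isfinite(M).all():
        raise ValidationError("matrix must be finite for min-max scaling")
    if per_column:
        lo = M.min(axis=0)
        hi = M.max(axis=0)
    else:
        lo = np.array([M.min()])
        hi = np.array([M.max()])
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    values = 2.0 * (M - lo) / safe - 1.0
    if per_column:
        values[:, span == 0] = 0.0
    elif span[0] == 0:
        values[:] = 0.0
    return ScaledInputMatrix(values=values, kind=kind, lo=lo, hi=hi, per_column=per_column)


def inverse_minmax(scaled: ScaledInputMatrix) -> np.ndarray:
    """Undo :func:`minmax_scale`; constant columns are restored from lo."""
    span = scaled.hi - scaled.lo
    safe = np.where(span == 0, 1.0, span)
    M = (scaled.values + 1.0) / 2.0 * safe + scaled.lo
    if scaled.per_column:
        M[:, span == 0] = scaled.lo[span == 0]
    elif span[0] == 0:
        M[:] = scaled.lo[0]
    return M


def build_input(coded: CodedGenotypeMatrix, kind: str) -> ScaledInputMatrix:
    """Assemble one of the three network input structures.

    ``X`` is used as coded (already in [-1, 1]); ``G`` and ``UD`` are min-max
    scaled per column.
    """
    if kind not in INPUT_KINDS:
        raise ValidationError(f"input kind must be one of {INPUT_KINDS}, got {kind!r}")
    if kind == "X":
        lo = np.full(coded.m, -1.0)
        hi = np.full(coded.m, 1.0)
        return ScaledInputMatrix(values=coded.X.copy(), kind="X", lo=lo, hi=hi)
    if kind == "G":
        return minmax_scale(compute_G(coded).G, kind="G")
    # UD is scaled as a whole matrix: per-column scaling would blow every
    # trailing component up to the amplitude of the leading ones, discarding
    # exactly the variance ordering that makes principal-component scores
    # useful as inputs.
    return minmax_scale(compute_UD(coded).UD, kind="UD", per_column=False)
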