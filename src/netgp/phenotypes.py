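"""Phenotype normalization to the network's working scale.

Networks with tanh hidden units expect responses roughly in [-1, 1]. The
working transform is

    y* = (y - mu_y) / max_y,

with mu_y the sample mean and max_y the sample maximum of the raw trait.
Dividing by the raw maximum only guarantees the range approximately (traits
with large negative deviations can fall below -1); a strict variant dividing
by max|y - mu_y| is available via ``strict=True``. The transform is affine,
so Pearson correlations between predictions and observations are identical
on either scale, and it is exactly invertible from the stored (mu_y, max_y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "PhenotypeRecord",
    "NormalizedPhenotype",
    "normalize_phenotype",
    "denormalize_phenotype",
    "apply_normalization",
    "invert_normalization",
]


@dataclass
class PhenotypeRecord:
    sample_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.sample_ids) != len(self.y):
            raise ValidationError("sample_ids and y must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in phenotype record")
        if not np.isfinite(self.y).all():
            raise ValidationError("phenotypes must be finite")


@dataclass
class NormalizedPhenotype:
    """Normalized trait with the statistics needed for exact back-transform."""

    sample_ids: list[str]
    y_star: np.ndarray
    mu_y: float
    max_y: float


def apply_normalization(y, mu_y: float, max_y: float):
    """The forward transform y -> (y - mu_y) / max_y with given statistics."""
    if max_y == 0:
        raise ValidationError("normalization denominator max_y is zero")
    return (np.asarray(y, dtype=float) - mu_y) / max_y


def invert_normalization(y_star, mu_y: float, max_y: float):
    """Exact inverse: y = y* * max_y + mu_y."""
    return np.asarray(y_star, dtype=float) * max_y + mu_y


def normalize_phenotype(rec: PhenotypeRecord, strict: bool = False) -> NormalizedPhenotype:
    """Centre by the sample mean and divide by the sample maximum.

    ``strict=True`` divides by max|y - mu_y| instead, guaranteeing [-1, 1].
    Constant traits are rejected as untrainable, as is a zero or negative
    denominator (a trait whose maximum is <= 0 is refused rather than
    silently sign-flipped).
    """
    y = rec.y
    if len(y) < 2:
        raise ValidationError("need at least two phenotype records")
    if np.ptp(y) == 0:
        raise ValidationError("constant phenotype cannot be normalized (untrainable)")
    mu = float(y.mean())
    denom = float(np.max(np.abs(y - mu))) if strict else float(y.max())
    if denom <= 0:
        raise ValidationError(
            f"normalization denominator must be positive, got {denom}; "
            "use strict=True for traits with non-positive maxima"
        )
    return NormalizedPhenotype(
        sample_ids=list(rec.sample_ids),
        y_star=apply_normalization(y, mu, denom),
        mu_y=mu,
        max_y=denom,
    )


def denormalize_phenotype(norm: NormalizedPhenotype) -> PhenotypeRecord:
    """Recover the raw-scale record from a normalized one."""
    return PhenotypeRecord(
        sample_ids=list(norm.sample_ids),
        y=invert_normalization(norm.y_star, norm.mu_y, norm.max_y),
    )
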