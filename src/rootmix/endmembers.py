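"""Endmember estimation for the two-pool delta13C mixing model.

The recent-crop (maize, C4) root endmember is estimated from the upper tail
of the coarse-root delta13C distribution: coarse samples are the least
contaminated stream, and the isotopically heaviest of them are taken to be
pure recent root biomass. The extraneous-organic-matter (EOM, C3-derived)
endmember is the plain mean of a prior-year ley fine-root reference set,
whose material is assumed to resemble the EOM recovered with the current
crop's roots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .study_data import (
    DegenerateEndmemberError,
    DegenerateSelectionError,
    GroupingError,
    InsufficientDataError,
)

log = logging.getLogger("rootmix")

#: Minimum root-EOM separation (per mil) for a usable mixing denominator.
DEFAULT_MIN_SEPARATION = 2.0
DEFAULT_QUANTILE = 0.8


@dataclass(frozen=True)
class EndmemberEstimate:
    """A source signature: mean and SD in per mil, with selection provenance."""

    mean: float
    sd: float
    n: int
    source_label: str  # "root" | "eom"
    rule: str

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("endmember estimate needs n >= 1")
        if self.sd < 0:
            raise ValueError("endmember SD must be >= 0")


@dataclass(frozen=True)
class EndmemberPair:
    """The two source signatures; root must be isotopically heavier than EOM."""

    root: EndmemberEstimate
    eom: EndmemberEstimate
    min_separation: float = DEFAULT_MIN_SEPARATION

    def __post_init__(self):
        if not (self.root.mean > self.eom.mean):
            raise DegenerateEndmemberError(
                f"root endmember ({self.root.mean}) must exceed EOM "
                f"endmember ({self.eom.mean})")
        if self.separation < self.min_separation:
            raise DegenerateEndmemberError(
                f"endmember separation {self.separation:.3f} per mil below "
                f"minimum {self.min_separation}")

    @property
    def separation(self) -> float:
        return self.root.mean - self.eom.mean


def pair_from_values(root_mean: float, root_sd: float, eom_mean: float,
                     eom_sd: float, n_root: int = 1, n_eom: int = 1,
                     min_separation: float = DEFAULT_MIN_SEPARATION
                     ) -> EndmemberPair:
    """Convenience constructor from plain numbers (e.g. literature values)."""
    return EndmemberPair(
        EndmemberEstimate(root_mean, root_sd, n_root, "root", "supplied"),
        EndmemberEstimate(eom_mean, eom_sd, n_eom, "eom", "supplied"),
        min_separation,
    )


def estimate_root_endmember(coarse_values, q: float = DEFAULT_QUANTILE
                            ) -> EndmemberEstimate:
    """Estimate the recent-root endmember from coarse-root delta13C values.

    The empirical *q*-quantile is computed by linear interpolation at rank
    ``1 + q*(n-1)`` on the sorted values (numpy's default); the estimate is
    the mean and SD of the values **strictly greater** than that quantile —
    values tied with the quantile are excluded.

    Raises
    ------
    InsufficientDataError
        With fewer than 5 input values.
    DegenerateSelectionError
        If no value exceeds the quantile (all values tied at the maximum).
    """
    values = np.asarray(coarse_values, dtype=float)
    if values.ndim != 1 or values.size < 5:
        raise InsufficientDataError(
            f"root endmember needs >= 5 coarse values, got {values.size}")
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile q must be in (0, 1), got {q}")
    cut = float(np.quantile(values, q, method="linear"))
    selected = values[values > cut]
    if selected.size == 0:
        raise DegenerateSelectionError(
            f"no value strictly exceeds the {q} quantile ({cut:.3f}); "
            "input values are tied at the maximum")
    sd = float(np.std(selected, ddof=1)) if selected.size > 1 else 0.0
    rule = (f"mean of values strictly above the empirical {q} quantile "
            f"(linear interpolation at rank 1+q(n-1)) of "
            f"{values.size} coarse values; cut={cut:.3f}")
    return EndmemberEstimate(float(np.mean(selected)), sd,
                             int(selected.size), "root", rule)


def estimate_eom_endmember(reference_values) -> EndmemberEstimate:
    """Estimate the EOM endmember as the mean of the ley reference values."""
    values = np.asarray(reference_values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise InsufficientDataError(
            f"EOM endmember needs >= 2 reference values, got {values.size}")
    return EndmemberEstimate(
        float(np.mean(values)), float(np.std(values, ddof=1)),
        int(values.size), "eom",
        f"mean of all {values.size} ley fine-root reference values")


def estimate_pair(coarse_values, reference_values,
                  q: float = DEFAULT_QUANTILE,
                  min_separation: float = DEFAULT_MIN_SEPARATION
                  ) -> EndmemberPair:
    """Estimate both endmembers from study data and bundle them."""
    return EndmemberPair(
        estimate_root_endmember(coarse_values, q=q),
        estimate_eom_endmember(reference_values),
        min_separation,
    )


def group_invariance_check(values, labels, B: int = 999, seed: int = 0
                           ) -> float:
    """Permutation p-value for between-group differences in endmember inputs.

    Used to check that candidate endmember values do not differ by treatment
    or depth before pooling them. The statistic is the between-group mean
    square of the group means; labels are permuted freely. A significant
    result is advisory (logged), never fatal: the caller decides.

    Returns ``p = (1 + #{permuted stat >= observed}) / (B + 1)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise GroupingError("values and labels must be parallel")
    if B < 99:
        raise ValueError(f"need B >= 99 permutations, got {B}")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise GroupingError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise GroupingError("every group needs at least 2 values")

    def stat(v: np.ndarray) -> float:
        sums = np.bincount(codes, weights=v)
        means = sums / counts
        grand = v.mean()
        return float((counts * (means - grand) ** 2).sum() / (uniq.size - 1))

    observed = stat(values)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        if stat(rng.permutation(values)) >= observed:
            hits += 1
    p = (1 + hits) / (B + 1)
    if p < 0.05:
        log.warning(
            "endmember inputs differ between groups (permutation p=%.4g); "
            "pooling may be inappropriate", p)
    return p
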