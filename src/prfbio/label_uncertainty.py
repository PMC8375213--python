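"""Soft class labels from potency values via a cumulative-normal conversion.

A compound's measured pActivity carries experimental error.  Instead of a
hard active/inactive call at a potency threshold, each measurement is mapped
to the probability Δy that its true potency lies on the active side of the
threshold, assuming homoscedastic Gaussian measurement error with standard
deviation σ (in log units):

    Δy = ½ [1 + erf((p_activity − p_threshold) / (σ √2))]

i.e. the normal CDF with mean ``p_threshold`` and sd ``σ`` evaluated at the
measurement.  σ = 0 degenerates to the classical step-function label.
Putative inactives — compounds assumed inactive without any measured potency
— are pinned at Δy = 0 for every σ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

from .activity_data import ActivityRecord, FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelConfig:
    """Threshold and assumed measurement error for the label conversion.

    ``p_threshold`` is in −log10 molar units (5 ↔ 10 µM, 6 ↔ 1 µM, 7 ↔ 0.1 µM);
    ``sigma`` is the homoscedastic measurement sd in the same log units and
    must be ≥ 0.  σ = 0 selects the degenerate step-function case.
    """

    p_threshold: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.p_threshold):
            raise ValueError("p_threshold must be finite")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def delta_y(p_activity, p_threshold: float, sigma: float):
    """Probability of the active class given a potency measurement.

    Normal CDF of ``p_activity`` under mean ``p_threshold`` and sd ``sigma``;
    with ``sigma = 0`` the step function (ties at the threshold map to 1,
    matching the usual "pActivity ≥ threshold ⇒ active" convention).
    Accepts scalars or arrays; returns the matching shape in float64.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    p = np.asarray(p_activity, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("p_activity values must be finite")
    if sigma == 0:
        out = (p >= p_threshold).astype(float)
    else:
        out = 0.5 * (1.0 + erf((p - p_threshold) / (sigma * np.sqrt(2.0))))
    return float(out) if np.isscalar(p_activity) else out


@dataclass
class SoftLabelDataset:
    """Binary features paired with soft (Δy) and hard activity labels.

    Rows of ``features`` align positionally with ``delta_y``, ``hard_label``
    and ``is_putative_inactive``.  For measured samples ``hard_label`` is the
    step-function call at the configured threshold; putative inactives have
    Δy = 0 and hard label 0 at every σ.
    """

    features: FeatureMatrix
    delta_y: np.ndarray
    hard_label: np.ndarray
    config: LabelConfig
    is_putative_inactive: np.ndarray

    def __post_init__(self) -> None:
        self.delta_y = np.asarray(self.delta_y, dtype=float)
        self.hard_label = np.asarray(self.hard_label, dtype=int)
        self.is_putative_inactive = np.asarray(self.is_putative_inactive, dtype=bool)
        n = self.features.n_samples
        for name, arr in (
            ("delta_y", self.delta_y),
            ("hard_label", self.hard_label),
            ("is_putative_inactive", self.is_putative_inactive),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
        if ((self.delta_y < 0) | (self.delta_y > 1)).any():
            raise ValueError("delta_y values must lie in [0, 1]")
        if not np.isin(self.hard_label, (0, 1)).all():
            raise ValueError("hard_label values must be 0 or 1")
        if (self.delta_y[self.is_putative_inactive] != 0).any():
            raise ValueError("putative inactives must have delta_y = 0")

    @property
    def n_samples(self) -> int:
        return self.features.n_samples


def label_dataset(
    records: Iterable[ActivityRecord],
    features: FeatureMatrix,
    config: LabelConfig,
    putative_inactive_ids: Sequence[str] = (),
    putative_overrides_measured: bool = False,
) -> SoftLabelDataset:
    """Join measurements with feature rows and attach soft/hard labels.

    Measured compounds get Δy from the cumulative-normal conversion and a
    hard label from the threshold; compounds in ``putative_inactive_ids``
    get (Δy, hard) = (0, 0).  Replicate measurements for one compound are
    averaged (with a warning) before conversion.  Feature rows with neither
    a measurement nor a putative-inactive flag are excluded with a warning
    count.  A compound id appearing in both the records and the putative set
    is an error unless ``putative_overrides_measured`` is set.
    """
    records = list(records)
    row_index = features.row_index()
    putative = set(putative_inactive_ids)

    by_compound: dict[str, list[float]] = {}
    for rec in records:
        if rec.compound_id not in row_index:
            raise ValueError(
                f"compound {rec.compound_id!r} has a measurement but no feature row"
            )
        by_compound.setdefault(rec.compound_id, []).append(rec.p_activity)

    overlap = putative & by_compound.keys()
    if overlap:
        if not putative_overrides_measured:
            raise ValueError(
                f"{len(overlap)} compound(s) are both measured and flagged "
                "putative inactive; pass putative_overrides_measured=True to "
                "force the putative (delta_y = 0) labelling"
            )
        for cid in overlap:
            del by_compound[cid]

    n_replicated = sum(1 for v in by_compound.values() if len(v) > 1)
    if n_replicated:
        logger.warning(
            "%d compound(s) have replicate measurements; using the mean "
            "pActivity per compound",
            n_replicated,
        )

    keep: list[int] = []
    dy: list[float] = []
    hard: list[int] = []
    flag: list[bool] = []
    n_excluded = 0
    for i, cid in enumerate(features.row_ids):
        if cid in by_compound:
            p = float(np.mean(by_compound[cid]))
            keep.append(i)
            dy.append(delta_y(p, config.p_threshold, config.sigma))
            hard.append(int(p >= config.p_threshold))
            flag.append(False)
        elif cid in putative:
            keep.append(i)
            dy.append(0.0)
            hard.append(0)
            flag.append(True)
        else:
            n_excluded += 1
    if n_excluded:
        logger.warning(
            "excluded %d feature row(s) with neither a measurement nor a "
            "putative-inactive flag",
            n_excluded,
        )
    return SoftLabelDataset(
        features=features.subset_rows(keep),
        delta_y=np.array(dy, dtype=float),
        hard_label=np.array(hard, dtype=int),
        config=config,
        is_putative_inactive=np.array(flag, dtype=bool),
    )
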