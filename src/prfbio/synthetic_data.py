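"""Synthetic bioactivity datasets with controllable label uncertainty.

The generator emulates the statistical structure of a per-target bioactivity
modelling set:

* sparse binary, fingerprint-like features;
* a latent (true) pActivity per measured compound, actives above and
  measured inactives below the potency threshold, with a configurable mass
  of near-threshold ("marginal") compounds;
* an observed pActivity = latent + Gaussian experimental noise of sd
  ``sigma_experimental`` — the label noise the probabilistic forest is
  designed to absorb;
* informative feature bits whose Bernoulli rate rises monotonically with
  latent potency, so features carry a learnable but — near the threshold —
  genuinely ambiguous signal;
* putative inactives: background compounds with no measured potency,
  accepted only if their Jaccard (Tanimoto) similarity to every active is
  below a sphere-exclusion cutoff (default 0.4).

Class imbalance defaults to the active:inactive ratio of 0.4 that is
typical of curated per-target sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit

from .activity_data import ActivityRecord, FeatureMatrix
from .label_uncertainty import LabelConfig, delta_y

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset realisation.

    Counts: ``n_active`` + ``n_measured_inactive`` measured compounds plus
    ``n_putative_inactive`` sphere-excluded background compounds; defaults
    give the 0.4 active:inactive ratio.  ``near_threshold_weight`` is the
    fraction of measured compounds whose latent potency sits within about
    ``near_threshold_scale`` log units of the threshold (the marginal
    regime); the rest are drawn uniformly over the remainder of
    ``potency_range``.  Informative bits interpolate between
    ``inactive_bit_rate`` and ``active_bit_rate`` through a logistic ramp of
    width ``feature_scale`` (log units) centred on the threshold.
    """

    n_active: int = 160
    n_measured_inactive: int = 300
    n_putative_inactive: int = 100
    n_features: int = 64
    n_informative: int = 16
    sigma_experimental: float = 0.3
    p_threshold: float = 5.0
    potency_range: tuple[float, float] = (3.0, 8.0)
    near_threshold_weight: float = 0.2
    near_threshold_scale: float = 0.35
    active_bit_rate: float = 0.65
    inactive_bit_rate: float = 0.15
    background_bit_rate: float = 0.08
    feature_scale: float = 0.5
    se_similarity_cutoff: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_active, self.n_measured_inactive, self.n_putative_inactive) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError("need 0 < n_informative <= n_features")
        if self.sigma_experimental < 0:
            raise ValueError("sigma_experimental must be >= 0")
        if not 0 < self.se_similarity_cutoff <= 1:
            raise ValueError("se_similarity_cutoff must lie in (0, 1]")
        lo, hi = self.potency_range
        if not lo < self.p_threshold < hi:
            raise ValueError("p_threshold must lie inside potency_range")
        if not 0 <= self.near_threshold_weight <= 1:
            raise ValueError("near_threshold_weight must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """One generated dataset; putative rows have NaN latent/observed potency."""

    features: FeatureMatrix
    latent_p_activity: np.ndarray
    observed_p_activity: np.ndarray
    is_putative_inactive: np.ndarray
    spec: SyntheticSpec

    @property
    def measured_mask(self) -> np.ndarray:
        return ~self.is_putative_inactive

    def to_activity_records(self, target_id: str = "T1") -> list[ActivityRecord]:
        """Activity-table rows for the measured compounds."""
        out = []
        for i in np.flatnonzero(self.measured_mask):
            out.append(
                ActivityRecord(
                    compound_id=self.features.row_ids[i],
                    target_id=target_id,
                    p_activity=float(self.observed_p_activity[i]),
                    source="synthetic",
                )
            )
        return out

    def putative_ids(self) -> list[str]:
        return [
            self.features.row_ids[i]
            for i in np.flatnonzero(self.is_putative_inactive)
        ]


def jaccard_similarity(row_a: Sequence[int], row_b: Sequence[int]) -> float:
    """|a ∩ b| / |a ∪ b| for binary rows (Tanimoto on fingerprints).

    Two all-zero rows are defined as similarity 0.
    """
    a = np.asarray(row_a)
    b = np.asarray(row_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rows must be 1-d and of equal length")
    inter = int(np.count_nonzero((a > 0) & (b > 0)))
    union = int(np.count_nonzero((a > 0) | (b > 0)))
    return 0.0 if union == 0 else inter / union


def _max_jaccard_to_set(rows: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Max Jaccard similarity of each candidate row against a row set."""
    rows = rows.astype(np.int64)
    candidates = candidates.astype(np.int64)
    inter = candidates @ rows.T
    union = (
        candidates.sum(axis=1)[:, None] + rows.sum(axis=1)[None, :] - inter
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim.max(axis=1) if rows.shape[0] else np.zeros(candidates.shape[0])


def _latent_potencies(rng, n, side, spec: SyntheticSpec) -> np.ndarray:
    """Latent potencies on one side of the threshold.

    ``side`` is +1 (actives) or −1 (measured inactives).  A
    ``near_threshold_weight`` fraction sits just off the threshold
    (half-normal offsets of scale ``near_threshold_scale``); the rest spread
    uniformly over the far part of the potency range.
    """
    lo, hi = spec.potency_range
    far_span = (hi - spec.p_threshold) if side > 0 else (spec.p_threshold - lo)
    near = rng.random(n) < spec.near_threshold_weight
    offsets = np.empty(n)
    offsets[near] = np.abs(rng.normal(0.0, spec.near_threshold_scale, near.sum()))
    far_lo = min(2 * spec.near_threshold_scale, 0.5 * far_span)
    offsets[~near] = rng.uniform(far_lo, far_span, (~near).sum())
    latent = spec.p_threshold + side * offsets
    return np.clip(latent, lo, hi)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; identical specs (including seed) give identical data."""
    rng = np.random.default_rng(spec.seed)
    n_meas = spec.n_active + spec.n_measured_inactive

    latent = np.concatenate(
        [
            _latent_potencies(rng, spec.n_active, +1, spec),
            _latent_potencies(rng, spec.n_measured_inactive, -1, spec),
        ]
    )
    noise = rng.normal(0.0, spec.sigma_experimental, n_meas) if n_meas else np.empty(0)
    observed = latent + noise

    # Informative bits: Bernoulli rate ramps with latent potency so that
    # far-from-threshold compounds look typed and marginal ones ambiguous.
    ramp = expit((latent - spec.p_threshold) / spec.feature_scale)
    rate = spec.inactive_bit_rate + (
        spec.active_bit_rate - spec.inactive_bit_rate
    ) * ramp
    X_meas = np.empty((n_meas, spec.n_features), dtype=np.int8)
    X_meas[:, : spec.n_informative] = (
        rng.random((n_meas, spec.n_informative)) < rate[:, None]
    )
    X_meas[:, spec.n_informative :] = (
        rng.random((n_meas, spec.n_features - spec.n_informative))
        < spec.background_bit_rate
    )

    actives = X_meas[: spec.n_active]
    putative_rows: list[np.ndarray] = []
    budget = max(1000, 200 * spec.n_putative_inactive)
    drawn = 0
    while len(putative_rows) < spec.n_putative_inactive and drawn < budget:
        batch = min(256, budget - drawn)
        drawn += batch
        cand = (
            rng.random((batch, spec.n_features)) < spec.background_bit_rate
        ).astype(np.int8)
        ok = _max_jaccard_to_set(actives, cand) < spec.se_similarity_cutoff
        for row in cand[ok]:
            if len(putative_rows) < spec.n_putative_inactive:
                putative_rows.append(row)
    if len(putative_rows) < spec.n_putative_inactive:
        raise RuntimeError(
            "sphere-exclusion rejection sampling exhausted its attempt budget "
            f"({budget} draws for {spec.n_putative_inactive} rows); loosen "
            "se_similarity_cutoff, lower background_bit_rate or add features"
        )
    X_put = (
        np.stack(putative_rows)
        if putative_rows
        else np.empty((0, spec.n_features), dtype=np.int8)
    )

    X = np.vstack([X_meas, X_put])
    row_ids = (
        [f"ACT{i:05d}" for i in range(spec.n_active)]
        + [f"INA{i:05d}" for i in range(spec.n_measured_inactive)]
        + [f"PUT{i:05d}" for i in range(spec.n_putative_inactive)]
    )
    feature_ids = [f"F{j:04d}" for j in range(spec.n_features)]
    nan_pad = np.full(spec.n_putative_inactive, np.nan)
    return SyntheticDataset(
        features=FeatureMatrix(X, row_ids, feature_ids),
        latent_p_activity=np.concatenate([latent, nan_pad]),
        observed_p_activity=np.concatenate([observed, nan_pad]),
        is_putative_inactive=np.concatenate(
            [np.zeros(n_meas, dtype=bool), np.ones(spec.n_putative_inactive, bool)]
        ),
        spec=spec,
    )


def near_threshold_fraction(
    dataset: SyntheticDataset, config: LabelConfig, lo: float, hi: float
) -> float:
    """Fraction of measured samples whose Δy under ``config`` falls in [lo, hi]."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    mask = dataset.measured_mask
    if not mask.any():
        return 0.0
    dy = delta_y(
        dataset.observed_p_activity[mask], config.p_threshold, config.sigma
    )
    return float(((dy >= lo) & (dy <= hi)).mean())


def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["potency_range"] = list(d["potency_range"])
    return d


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    if "potency_range" in d:
        d["potency_range"] = tuple(d["potency_range"])
    return SyntheticSpec(**d)
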