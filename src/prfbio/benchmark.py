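"""Comparison statistics for probabilistic vs classical random forests.

Both classifiers are scored against the *ideal label*: the soft label Δy the
test-set measurements receive under the test-time uncertainty assumption
(threshold, σ_test).  For a sample with ideal label y and predicted
probability p the signed *error margin* is y − p.  Two derived quantities
compare the classifiers:

* ``margin_delta`` — (y − p_RF) − (y − p_PRF), which algebraically equals
  p_PRF − p_RF; negative values in a region mean the probabilistic forest
  sits closer to the ideal there (when its margin is the smaller one).
* ``relative score`` — the percentage of the worse classifier's absolute
  error removed by the better one: 100·(|e_worse| − |e_better|)/|e_worse|.
  An improvement from 0.75 to 0.70 against an ideal of 0.65 scores 50%,
  from 0.85 to 0.80 scores 25% — the same absolute gain matters more close
  to the optimum.

Summaries are reported per cell of a (σ_train, σ_test, ideal-label bin)
grid; distributions of margins are compared with a KS normality check
followed by Welch's unequal-variance t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .label_uncertainty import LabelConfig, delta_y
from .prf_core import ProbabilisticRandomForestClassifier

logger = logging.getLogger(__name__)

#: Default ideal-label bins: five equal ranges, half-open except the last.
DEFAULT_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def error_margin(y_ideal, prob):
    """Signed distance of a prediction from the ideal label: y − p."""
    return np.asarray(y_ideal, dtype=float) - np.asarray(prob, dtype=float)


def relative_score(y_ideal: float, prob_worse: float, prob_better: float) -> float:
    """Percentage of the worse classifier's absolute error removed.

    100 · (|e_worse| − |e_better|) / |e_worse| with e = y_ideal − prob.  The
    denominator is always the larger absolute error regardless of argument
    order, and both-perfect (zero error) cases are defined as 0.
    """
    e_a = abs(float(y_ideal) - float(prob_worse))
    e_b = abs(float(y_ideal) - float(prob_better))
    worse = max(e_a, e_b)
    if worse == 0.0:
        return 0.0
    return 100.0 * abs(e_a - e_b) / worse


@dataclass
class ComparisonRecord:
    """Per-sample comparison of the two classifiers against the ideal label.

    ``margin_delta`` is the RF margin minus the PRF margin and is therefore
    identically ``prf_prob − rf_prob``.
    """

    sample_id: str
    y_ideal: float
    rf_prob: float
    prf_prob: float
    rf_margin: float
    prf_margin: float
    margin_delta: float
    relative_score_pct: float
    better: str  # "PRF", "RF" or "tie"


def compare_predictions(
    sample_ids: Sequence[str],
    y_ideal: np.ndarray,
    rf_prob: np.ndarray,
    prf_prob: np.ndarray,
) -> pd.DataFrame:
    """Tabulate per-sample margins, margin deltas and relative scores."""
    y_ideal = np.asarray(y_ideal, dtype=float)
    rf_prob = np.asarray(rf_prob, dtype=float)
    prf_prob = np.asarray(prf_prob, dtype=float)
    rf_m = error_margin(y_ideal, rf_prob)
    prf_m = error_margin(y_ideal, prf_prob)
    delta = rf_m - prf_m
    assert np.allclose(delta, prf_prob - rf_prob, atol=1e-12)
    rows = []
    for i, sid in enumerate(sample_ids):
        abs_rf, abs_prf = abs(rf_m[i]), abs(prf_m[i])
        if abs_rf > abs_prf:
            better = "PRF"
        elif abs_prf > abs_rf:
            better = "RF"
        else:
            better = "tie"
        rows.append(
            ComparisonRecord(
                sample_id=str(sid),
                y_ideal=float(y_ideal[i]),
                rf_prob=float(rf_prob[i]),
                prf_prob=float(prf_prob[i]),
                rf_margin=float(rf_m[i]),
                prf_margin=float(prf_m[i]),
                margin_delta=float(delta[i]),
                relative_score_pct=relative_score(
                    y_ideal[i], rf_prob[i], prf_prob[i]
                ),
                better=better,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def bin_index(values: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """Assign each value to a half-open bin [lo, hi); the last bin is closed."""
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    return idx


@dataclass
class GridCell:
    """Summary of one (σ_train, σ_test, ideal-label bin) cell."""

    sigma_train: float
    sigma_test: float
    bin_lo: float
    bin_hi: float
    n_samples: int
    mean_margin_delta: float | None = None
    median_margin_delta: float | None = None
    mean_relative_score: float | None = None
    mean_abs_margin_rf: float | None = None
    mean_abs_margin_prf: float | None = None
    better_algorithm: str | None = None


@dataclass
class TrainTestData:
    """Feature/potency arrays for one train/test realisation.

    ``p_*`` entries for rows flagged putative are ignored (those samples are
    pinned at Δy = 0 for every σ).
    """

    X_train: np.ndarray
    p_train: np.ndarray
    putative_train: np.ndarray
    X_test: np.ndarray
    p_test: np.ndarray
    putative_test: np.ndarray


def _labels(p, putative, threshold, sigma):
    dy = delta_y(np.asarray(p, dtype=float), threshold, sigma)
    dy = np.where(putative, 0.0, dy)
    hard = np.where(putative, 0.0, (np.asarray(p) >= threshold).astype(float))
    return dy, hard


def run_sigma_grid(
    dataset_factory: Callable[[], TrainTestData],
    sigma_train_list: Sequence[float],
    sigma_test_list: Sequence[float],
    model_config: dict,
    bins: Sequence[float] = DEFAULT_BINS,
    counters: dict | None = None,
    return_records: bool = False,
):
    """Train and score both forests over a σ_train × σ_test grid.

    For every σ_train one probabilistic forest (soft labels) and one
    classical forest (hard labels) are trained on the factory's data with
    identical hyperparameters and seed; for every σ_test the ideal labels of
    the test set are recomputed and per-bin summaries collected.

    ``model_config`` must contain ``p_threshold``; remaining keys are passed
    to :class:`ProbabilisticRandomForestClassifier`.  ``counters`` (optional
    dict) is incremented under ``prf_fits`` / ``rf_fits`` / ``evaluations``.
    Returns the list of :class:`GridCell`; with ``return_records=True`` also
    a long-format per-sample DataFrame.
    """
    if not sigma_train_list or not sigma_test_list:
        raise ValueError("sigma_train_list and sigma_test_list must be non-empty")
    model_config = dict(model_config)
    threshold = model_config.pop("p_threshold")
    data = dataset_factory()
    cells: list[GridCell] = []
    frames: list[pd.DataFrame] = []
    for s_train in sigma_train_list:
        dy_train, hard_train = _labels(
            data.p_train, data.putative_train, threshold, s_train
        )
        prf = ProbabilisticRandomForestClassifier(**model_config)
        prf.fit(data.X_train, dy_train)
        rf = ProbabilisticRandomForestClassifier(**model_config)
        rf.fit(data.X_train, hard_train)
        if counters is not None:
            counters["prf_fits"] = counters.get("prf_fits", 0) + 1
            counters["rf_fits"] = counters.get("rf_fits", 0) + 1
        prf_prob = prf.predict_proba(data.X_test)[:, 1]
        rf_prob = rf.predict_proba(data.X_test)[:, 1]
        for s_test in sigma_test_list:
            if counters is not None:
                counters["evaluations"] = counters.get("evaluations", 0) + 1
            y_ideal, _ = _labels(
                data.p_test, data.putative_test, threshold, s_test
            )
            df = compare_predictions(
                [str(i) for i in range(len(y_ideal))], y_ideal, rf_prob, prf_prob
            )
            df["sigma_train"] = s_train
            df["sigma_test"] = s_test
            df["bin"] = bin_index(y_ideal, bins)
            if return_records:
                frames.append(df)
            for b in range(len(bins) - 1):
                sub = df[df["bin"] == b]
                cell = GridCell(
                    sigma_train=s_train,
                    sigma_test=s_test,
                    bin_lo=float(bins[b]),
                    bin_hi=float(bins[b + 1]),
                    n_samples=len(sub),
                )
                if len(sub):
                    mar_rf = sub["rf_margin"].abs().mean()
                    mar_prf = sub["prf_margin"].abs().mean()
                    cell.mean_margin_delta = float(sub["margin_delta"].mean())
                    cell.median_margin_delta = float(sub["margin_delta"].median())
                    cell.mean_relative_score = float(
                        sub["relative_score_pct"].mean()
                    )
                    cell.mean_abs_margin_rf = float(mar_rf)
                    cell.mean_abs_margin_prf = float(mar_prf)
                    if mar_prf < mar_rf:
                        cell.better_algorithm = "PRF"
                    elif mar_rf < mar_prf:
                        cell.better_algorithm = "RF"
                    else:
                        cell.better_algorithm = "tie"
                cells.append(cell)
    if return_records:
        records = pd.concat(frames, ignore_index=True)
        return cells, records
    return cells


def cells_to_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    """One row per grid cell, in grid order."""
    return pd.DataFrame([c.__dict__ for c in cells])


def compare_margin_distributions(
    margins_a: Sequence[float], margins_b: Sequence[float]
) -> dict:
    """Normality check plus Welch's t-test between two margin collections.

    Each collection is first checked against a normal with its own mean/sd
    via a one-sample KS test (reported, not used as a gate); the two are
    then compared with an unpaired t-test without the equal-variance
    assumption.  Returns a dict with ``normality`` (per collection),
    ``t_statistic``, ``p_value``, ``significant_at_0_05`` and ``undefined``
    (True when both collections have zero variance, in which case the test
    statistics are None).
    """
    a = np.asarray(margins_a, dtype=float)
    b = np.asarray(margins_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each collection needs at least 3 values")

    def _ks(x: np.ndarray):
        sd = x.std(ddof=1)
        if sd == 0:
            return {"statistic": None, "p_value": None}
        res = stats.kstest(x, "norm", args=(x.mean(), sd))
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}

    normality = [_ks(a), _ks(b)]
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return {
            "normality": normality,
            "t_statistic": None,
            "p_value": None,
            "significant_at_0_05": None,
            "undefined": True,
        }
    t_res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "normality": normality,
        "t_statistic": float(t_res.statistic),
        "p_value": float(t_res.pvalue),
        "significant_at_0_05": bool(t_res.pvalue < 0.05),
        "undefined": False,
    }
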