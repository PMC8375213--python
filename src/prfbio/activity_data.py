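"""Activity tables, binary feature matrices and replicate-variability audits.

Bioactivity repositories report potency as pActivity (−log10 of a molar
IC50/EC50/Ki/Kd).  The same compound–target pair is frequently measured more
than once, in different assays, by different labs, or with different readout
types; the spread across those replicates is the experimental uncertainty
that the probabilistic forest propagates into its labels.  This module reads
and writes activity tables and fingerprint-style feature matrices and
computes the replicate standard-deviation audit under user-defined
aggregation schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASUREMENT_TYPES = frozenset({"IC50", "EC50", "Ki", "Kd"})

#: Canonical column names understood by read/write helpers.
REQUIRED_COLUMNS = ("compound_id", "target_id", "p_activity")
OPTIONAL_COLUMNS = ("assay_id", "measurement_type", "source")


class ConfigurationError(ValueError):
    """Raised when a table or mapping does not declare a required column."""


@dataclass
class ActivityRecord:
    """One experimental potency measurement for a compound–target pair.

    ``p_activity`` is −log10 of the molar potency (dimensionless log units);
    e.g. 10 µM ↔ 5.0.  Values outside 0–15 are kept but flagged with a
    warning, since they almost always indicate a unit mix-up upstream.
    Replicates (repeated compound–target pairs) are expected and preserved.
    """

    compound_id: str
    target_id: str
    p_activity: float
    assay_id: str | None = None
    measurement_type: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.p_activity = float(self.p_activity)
        if not math.isfinite(self.p_activity):
            raise ValueError(
                f"p_activity must be finite, got {self.p_activity!r} "
                f"for compound {self.compound_id!r}"
            )
        if not 0.0 <= self.p_activity <= 15.0:
            logger.warning(
                "p_activity %.4g for compound %r is outside the plausible "
                "0-15 log-unit range; check units upstream",
                self.p_activity,
                self.compound_id,
            )
        if (
            self.measurement_type is not None
            and self.measurement_type not in MEASUREMENT_TYPES
        ):
            raise ValueError(
                f"measurement_type must be one of {sorted(MEASUREMENT_TYPES)}, "
                f"got {self.measurement_type!r}"
            )


def read_activity_table(
    path: str | Path,
    column_map: Mapping[str, str],
    delimiter: str | None = None,
) -> list[ActivityRecord]:
    """Read an activity table from CSV/TSV into :class:`ActivityRecord` rows.

    Parameters
    ----------
    path:
        CSV/TSV file with a header row.
    column_map:
        Maps canonical names (``compound_id``, ``target_id``, ``p_activity``
        and optionally ``assay_id``, ``measurement_type``, ``source``) to the
        column names used in the file.
    delimiter:
        Field delimiter; sniffed from the file when ``None``.

    Rows whose pActivity is missing or non-numeric are skipped; the skip
    count is reported through the module logger.  Records come back in file
    order.
    """
    path = Path(path)
    for canonical in REQUIRED_COLUMNS:
        if canonical not in column_map:
            raise ConfigurationError(
                f"column_map must name the {canonical!r} column"
            )
    df = pd.read_csv(
        path, sep=delimiter, engine="python" if delimiter is None else "c", dtype=str
    )
    missing = [col for col in column_map.values() if col not in df.columns]
    if missing:
        raise ConfigurationError(
            f"columns {missing} named in column_map are absent from {path.name} "
            f"(found: {list(df.columns)})"
        )

    records: list[ActivityRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        raw = row[column_map["p_activity"]]
        p_act = pd.to_numeric(raw, errors="coerce")
        if pd.isna(p_act):
            n_skipped += 1
            continue
        kwargs = {}
        for canonical in OPTIONAL_COLUMNS:
            if canonical in column_map:
                value = row[column_map[canonical]]
                kwargs[canonical] = None if pd.isna(value) else str(value)
        records.append(
            ActivityRecord(
                compound_id=str(row[column_map["compound_id"]]),
                target_id=str(row[column_map["target_id"]]),
                p_activity=float(p_act),
                **kwargs,
            )
        )
    if n_skipped:
        logger.warning(
            "skipped %d row(s) with missing/non-numeric pActivity in %s",
            n_skipped,
            path.name,
        )
    return records


def write_activity_table(
    records: Iterable[ActivityRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records to CSV/TSV using the canonical column names."""
    df = records_to_frame(records)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.6g")


def records_to_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    """Tabulate records with the canonical column order."""
    rows = [
        {
            "compound_id": r.compound_id,
            "target_id": r.target_id,
            "p_activity": r.p_activity,
            "assay_id": r.assay_id,
            "measurement_type": r.measurement_type,
            "source": r.source,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS)


@dataclass(frozen=True)
class AggregationScheme:
    """A named set of grouping keys defining what counts as a replicate.

    ``compound_id`` and ``target_id`` are always included: replicates are by
    definition repeated measurements of the same compound–target pair.
    Adding further keys (assay, readout type, source) makes the grouping
    finer and isolates narrower sources of variability.
    """

    name: str
    grouping_keys: tuple[str, ...]

    def __post_init__(self) -> None:
        allowed = set(REQUIRED_COLUMNS[:2]) | set(OPTIONAL_COLUMNS)
        unknown = set(self.grouping_keys) - allowed
        if unknown:
            raise ValueError(f"unknown grouping keys: {sorted(unknown)}")
        for key in ("compound_id", "target_id"):
            if key not in self.grouping_keys:
                raise ValueError(
                    f"grouping_keys must include {key!r}; replicates are "
                    "per compound-target pair"
                )


#: Reconstructable named schemes: within one assay, across all assays, and
#: within one readout type.
PRESET_SCHEMES: dict[str, AggregationScheme] = {
    "intra_assay": AggregationScheme(
        "intra_assay", ("compound_id", "target_id", "assay_id")
    ),
    "cross_assay": AggregationScheme("cross_assay", ("compound_id", "target_id")),
    "intra_measurement_type": AggregationScheme(
        "intra_measurement_type", ("compound_id", "target_id", "measurement_type")
    ),
}


def replicate_sd(
    records: Iterable[ActivityRecord],
    scheme: AggregationScheme | str,
    min_replicates: int = 2,
    population: bool = False,
) -> tuple[pd.DataFrame, float | None]:
    """Per-group replicate standard deviations plus their median.

    Groups records by ``scheme.grouping_keys`` and, for every group with at
    least ``min_replicates`` measurements, reports the standard deviation of
    its pActivity values.  The sample convention (n−1 denominator) is the
    default; ``population=True`` switches to the n denominator.

    Returns ``(table, median_sd)`` where ``table`` has one row per qualifying
    group (grouping keys, ``n_replicates``, ``sd``) and ``median_sd`` is the
    median of the per-group sds, or ``None`` when no group qualifies.
    """
    if isinstance(scheme, str):
        scheme = PRESET_SCHEMES[scheme]
    if min_replicates < 2:
        raise ValueError("min_replicates must be >= 2")
    df = records_to_frame(records)
    keys = list(scheme.grouping_keys)
    ddof = 0 if population else 1
    if df.empty:
        grouped = pd.DataFrame(columns=keys + ["n_replicates", "sd"])
    else:
        grouped = (
            df.groupby(keys, dropna=False, sort=True)["p_activity"]
            .agg(n_replicates="size", sd=lambda s: s.std(ddof=ddof))
            .reset_index()
        )
        grouped = grouped[grouped["n_replicates"] >= min_replicates].reset_index(
            drop=True
        )
    if grouped.empty:
        logger.warning(
            "no group under scheme %r has >= %d replicates; median sd undefined",
            scheme.name,
            min_replicates,
        )
        return grouped, None
    return grouped, float(grouped["sd"].median())


@dataclass
class FeatureMatrix:
    """A binary (fingerprint-like) feature matrix with row and column ids.

    Entries must be exactly 0 or 1.  All-zero feature columns are legal but
    flagged with a warning — they carry no signal yet silently dropping them
    would desynchronise feature ids between training and prediction.
    """

    values: np.ndarray
    row_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if self.values.shape != (len(self.row_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.feature_ids)} feature ids"
            )
        if not np.isin(self.values, (0, 1)).all():
            bad = np.unique(self.values[~np.isin(self.values, (0, 1))])
            raise ValueError(f"feature entries must be 0 or 1; found {bad[:5]}")
        self.values = self.values.astype(np.int8)
        if self.values.shape[0] and not self.values.any(axis=0).all():
            n_empty = int((~self.values.any(axis=0)).sum())
            logger.warning(
                "%d all-zero feature column(s) present; kept as-is", n_empty
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def row_index(self) -> dict[str, int]:
        return {rid: i for i, rid in enumerate(self.row_ids)}

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            self.values[idx], [self.row_ids[i] for i in idx], list(self.feature_ids)
        )

    @classmethod
    def read_dense_csv(
        cls, path: str | Path, delimiter: str | None = None
    ) -> "FeatureMatrix":
        """Read a dense matrix: first column compound id, remaining columns bits."""
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            index_col=0,
        )
        return cls(
            df.to_numpy(),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
        )

    @classmethod
    def read_triplet_csv(
        cls, path: str | Path, delimiter: str | None = None
    ) -> "FeatureMatrix":
        """Read a sparse triplet file with columns (row_id, feature_id, value).

        Absent pairs are 0; listed pairs must have value 1.  Row and feature
        orderings follow first appearance in the file.
        """
        df = pd.read_csv(
            path, sep=delimiter, engine="python" if delimiter is None else "c",
            dtype=str,
        )
        if df.shape[1] < 3:
            raise ConfigurationError(
                "triplet format needs three columns: row_id, feature_id, value"
            )
        rows = list(dict.fromkeys(df.iloc[:, 0]))
        feats = list(dict.fromkeys(df.iloc[:, 1]))
        ridx = {r: i for i, r in enumerate(rows)}
        fidx = {f: j for j, f in enumerate(feats)}
        values = np.zeros((len(rows), len(feats)), dtype=np.int8)
        for r, f, v in df.itertuples(index=False):
            values[ridx[r], fidx[f]] = int(float(v))
        return cls(values, rows, feats)

    def write_dense_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_ids)
        df.index.name = "compound_id"
        df.to_csv(path)
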