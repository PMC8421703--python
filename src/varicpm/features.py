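"""Behavioral scoring and per-node predictor features.

Scoring follows the study's instruments: recovery is the first-screen BDI
minus the 3-month score (positive = less depressive); interdependence is the
interdependent-subscale mean minus the independent-subscale mean of the
Self-Construal Scale; participants with baseline BDI >= 14 form the
high-depression group, <= 4 the low group.

The predictor of the self-construal-dependent models is the per-node
interaction X_k = z(V_k) * z(I): the elementwise product of variability and
interdependence after z-scoring each across participants.  The normalization
scope is configurable — ``training_fold`` (default; the statistics come from
the training participants of each LOOCV fold and are applied unchanged to
the held-out one, which is leakage-safe) or ``global`` (cohort-wide, the
reading suggested by normalizing "before the prediction analysis").  The
self-referential models use raw condition-contrast variability, no
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variability import VariabilityProfile

__all__ = [
    "BehavioralRecord",
    "FeatureMatrix",
    "score_behavior",
    "interaction_features",
    "contrast_features",
    "zscore",
]

SCOPES = ("global", "training_fold")
KINDS = ("interaction", "contrast", "raw_variability")


def zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """z-score with the unbiased (n-1) standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=axis, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(np.atleast_1d(sd) == 0) + 1
        raise ValueError(f"zero variance (node(s) {bad.tolist()}); cannot z-score")
    return (x - x.mean(axis=axis)) / sd


@dataclass(frozen=True)
class BehavioralRecord:
    """One participant's scored behavior."""

    participant_id: str
    bdi_t1: float
    bdi_t2: float
    recovery: float
    interdep_mean: float
    indep_mean: float
    interdependence: float
    group: str  # high / low / none


def score_behavior(raw: pd.DataFrame, *, strict: bool = True) -> pd.DataFrame:
    """Derive recovery, interdependence and group from a raw table.

    Required columns: participant_id, bdi_t1, bdi_t2, interdep_mean,
    indep_mean.  ``strict`` enforces the instruments' ranges (BDI totals
    0-63, subscale means 1-7) — turn it off for synthetic tables whose
    real-valued second-screen scores may stray past the integer floor.
    """
    need = {"participant_id", "bdi_t1", "bdi_t2", "interdep_mean", "indep_mean"}
    missing = need - set(raw.columns)
    if missing:
        raise ValueError(f"behavior table lacks column(s) {sorted(missing)}")
    df = raw.copy()
    if strict:
        for col, lo, hi in (
            ("bdi_t1", 0, 63),
            ("bdi_t2", 0, 63),
            ("interdep_mean", 1, 7),
            ("indep_mean", 1, 7),
        ):
            bad = df.index[(df[col] < lo) | (df[col] > hi)].tolist()
            if bad:
                ids = df.loc[bad, "participant_id"].tolist()
                raise ValueError(
                    f"{col} outside [{lo}, {hi}] for participant(s) {ids}"
                )
    df["recovery"] = df["bdi_t1"] - df["bdi_t2"]
    df["interdependence"] = df["interdep_mean"] - df["indep_mean"]
    df["group"] = np.select(
        [df["bdi_t1"] >= 14, df["bdi_t1"] <= 4], ["high", "low"], default="none"
    )
    return df


@dataclass
class FeatureMatrix:
    """Participants×nodes predictor features.

    For ``kind="interaction"`` with ``normalization_scope="training_fold"``
    the raw variability matrix and interdependence vector are carried along
    (``raw_v``, ``raw_i``) so the prediction engine can re-normalize inside
    each fold; ``values`` then holds the cohort-wide-normalized features for
    inspection.  Contrast features are raw differences and are used as-is.
    """

    kind: str
    values: np.ndarray
    normalization_scope: str = "training_fold"
    participant_ids: Sequence[str] | None = None
    node_ids: np.ndarray | None = None
    raw_v: np.ndarray | None = None
    raw_i: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.normalization_scope not in SCOPES:
            raise ValueError(f"normalization_scope must be one of {SCOPES}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be participants×nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features contain missing entries")
        if self.node_ids is None:
            self.node_ids = np.arange(1, self.values.shape[1] + 1)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        """Row-subset (e.g. one depression group), preserving kind/scope."""
        pids = (
            [self.participant_ids[i] for i in np.flatnonzero(rows)]
            if self.participant_ids is not None and np.asarray(rows).dtype == bool
            else None
        )
        return FeatureMatrix(
            kind=self.kind,
            values=self.values[rows],
            normalization_scope=self.normalization_scope,
            participant_ids=pids,
            node_ids=self.node_ids,
            raw_v=None if self.raw_v is None else self.raw_v[rows],
            raw_i=None if self.raw_i is None else self.raw_i[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(i) for i in self.node_ids])
        if self.participant_ids is not None:
            df.insert(0, "participant_id", list(self.participant_ids))
        return df


def interaction_features(
    v: np.ndarray,
    interdependence: np.ndarray,
    scope: str = "training_fold",
    *,
    participant_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """X_k = z(V_k) * z(I): the self-construal × variability interaction.

    Rows of ``v`` must align with ``interdependence``.  Under
    ``scope="global"`` the z-statistics are cohort-wide and final; under
    ``scope="training_fold"`` the stored values are the same cohort-wide
    product (for inspection) but the prediction engine recomputes the
    statistics per training fold from the carried raw arrays.
    """
    v = np.asarray(v, dtype=float)
    i = np.asarray(interdependence, dtype=float)
    if v.ndim != 2 or i.ndim != 1 or v.shape[0] != i.size:
        raise ValueError("v must be participants×nodes aligned with interdependence")
    values = zscore(v) * zscore(i)[:, None]
    return FeatureMatrix(
        kind="interaction",
        values=values,
        normalization_scope=scope,
        participant_ids=participant_ids,
        raw_v=v.copy(),
        raw_i=i.copy(),
    )


def contrast_features(
    profiles: Mapping[str, VariabilityProfile] | Sequence[VariabilityProfile],
    *,
    participant_order: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Stack per-participant contrast profiles into participants×nodes.

    ``profiles`` maps participant_id to a contrast
    :class:`~varicpm.variability.VariabilityProfile` (or is a sequence of
    them); ``participant_order`` fixes the row order (defaults to the
    mapping/sequence order).  No normalization is applied.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.participant_id: p for p in profiles}
    order = list(participant_order) if participant_order is not None else list(profiles)
    missing = [p for p in order if p not in profiles]
    if missing:
        raise ValueError(f"missing contrast profile(s) for participant(s) {missing}")
    conds = {profiles[p].condition for p in order}
    if len(conds) != 1:
        raise ValueError(f"profiles mix contrasts {sorted(conds)}")
    values = np.vstack([profiles[p].v for p in order])
    return FeatureMatrix(
        kind="contrast",
        values=values,
        normalization_scope="global",
        participant_ids=order,
    )
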