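"""Temporal variability of regional functional connectivity.

The quantity computed here is the per-node temporal variability

    V_k = 1 - mean_{i<j} corr(F_{i,k}, F_{j,k})

where ``F_{i,k}`` is node *k*'s connectivity profile in window (or scan) *i*:
the vector of Pearson correlations between node *k* and every other node,
with the self-correlation entry removed.  ``V_k`` lies in ``[0, 2]``; it is 0
exactly when the node's connectivity pattern is perfectly stable across
windows and approaches 2 when consecutive profiles anti-correlate.

Two estimation routes are provided:

* :func:`rest_variability` — split a resting scan into non-overlapping
  windows (the study design: nine 30-s windows on a 5-min scan at TR 2 s
  after discarding the first five volumes) and compare windowed FC matrices.
* :func:`condition_variability` — compare whole-segment FC matrices of the
  same task condition across repeated scans.

Condition contrasts (self minus other, self minus font control, ...) are
formed by :func:`contrast_variability`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NodeTimeSeries

__all__ = [
    "WindowScheme",
    "VariabilityProfile",
    "windowed_fc",
    "node_variability",
    "rest_variability",
    "condition_variability",
    "contrast_variability",
    "CONTRASTS",
]


@dataclass(frozen=True)
class WindowScheme:
    """Non-overlapping windowing of a resting scan.

    Defaults reproduce the study design: 30-s windows, nine of them.
    Windows are taken consecutively from the first available sample; any
    trailing remainder is discarded (145 post-discard samples at TR 2 s
    hold exactly nine 15-sample windows, with 10 samples left over).
    """

    window_seconds: float = 30.0
    n_windows: int = 9

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.n_windows < 1:
            raise ValueError("n_windows must be a positive integer")

    def window_samples(self, tr_seconds: float) -> int:
        ws = int(round(self.window_seconds / tr_seconds))
        if ws < 3:
            raise ValueError(
                f"window of {self.window_seconds} s at TR {tr_seconds} s has "
                f"{ws} samples; at least 3 are required for a correlation"
            )
        return ws


@dataclass
class VariabilityProfile:
    """Per-node temporal variability for one participant and condition.

    ``condition`` is ``"rest"``, a task-condition label, or a contrast name;
    ``n_comparisons`` is the number of window/scan pairs averaged
    (``C(m, 2)`` for *m* windows or scans; for a contrast, the smallest pair
    count among the profiles entering it).
    """

    participant_id: str
    condition: str
    v: np.ndarray
    n_comparisons: int

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 1:
            raise ValueError("v must be a 1-D per-node vector")

    @property
    def n_nodes(self) -> int:
        return self.v.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "condition": self.condition,
                "node_id": np.arange(1, self.n_nodes + 1),
                "v": self.v,
                "n_comparisons": self.n_comparisons,
            }
        )


def windowed_fc(ts: NodeTimeSeries, scheme: WindowScheme) -> list[np.ndarray]:
    """Pearson FC matrix within each non-overlapping window.

    Returns one symmetric node×node correlation matrix with unit diagonal
    per window.  A node that is constant within a window makes its
    correlations undefined and is a hard error naming node and window.
    """
    ws = scheme.window_samples(ts.tr_seconds)
    needed = scheme.n_windows * ws
    if needed > ts.n_samples:
        raise ValueError(
            f"scheme needs {scheme.n_windows}×{ws}={needed} samples but the "
            f"series has only {ts.n_samples}"
        )
    mats = []
    for w in range(scheme.n_windows):
        seg = ts.data[:, w * ws : (w + 1) * ws]
        sd = seg.std(axis=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0) + 1
            raise ValueError(
                f"constant signal in window {w} for node(s) {bad.tolist()}; "
                "correlation is undefined"
            )
        mats.append(np.corrcoef(seg))
    return mats


def node_variability(fc_list: Sequence[np.ndarray]) -> np.ndarray:
    """V_k from an ordered collection of FC matrices.

    For each node its connectivity profile (matrix row with the diagonal
    self-entry removed) is correlated between every unordered pair of
    matrices; ``V_k`` is one minus the mean of those coefficients.  The
    result does not depend on the order of the matrices.
    """
    mats = [np.asarray(m, dtype=float) for m in fc_list]
    m = len(mats)
    if m < 2:
        raise ValueError("at least 2 FC matrices are required")
    n = mats[0].shape[0]
    for a in mats:
        if a.shape != (n, n):
            raise ValueError("FC matrices must share one square shape")
    off = ~np.eye(n, dtype=bool)
    # profiles[k, i, :] = node k's off-diagonal row in matrix i
    profiles = np.empty((n, m, n - 1))
    for i, a in enumerate(mats):
        profiles[:, i, :] = a[off].reshape(n, n - 1)
    profiles = profiles - profiles.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(profiles, axis=2)
    if np.any(norms == 0):
        bad = sorted(set((np.argwhere(norms == 0)[:, 0] + 1).tolist()))
        raise ValueError(
            f"constant connectivity profile for node(s) {bad}; "
            "profile correlation is undefined"
        )
    profiles /= norms[:, :, None]
    corr = np.einsum("kie,kje->kij", profiles, profiles)
    iu, ju = np.triu_indices(m, k=1)
    return 1.0 - corr[:, iu, ju].mean(axis=1)


def _maybe_fisher(mats: Iterable[np.ndarray], fisher_z: bool) -> list[np.ndarray]:
    if not fisher_z:
        return list(mats)
    out = []
    for a in mats:
        z = np.arctanh(np.clip(a, -0.999999, 0.999999))
        out.append(z)
    return out


def rest_variability(
    ts: NodeTimeSeries,
    scheme: WindowScheme | None = None,
    *,
    discard_initial: int = 0,
    fisher_z: bool = False,
) -> VariabilityProfile:
    """General (resting-state) variability of one participant.

    ``discard_initial`` drops that many leading volumes before windowing —
    the study removed the first five volumes of the 150-volume scan.
    ``fisher_z`` applies arctanh to FC entries before profile comparison
    (sensitivity option; off by default, the canonical formula uses raw
    coefficients).
    """
    scheme = scheme or WindowScheme()
    if discard_initial:
        ts = ts.drop_initial(discard_initial)
    mats = _maybe_fisher(windowed_fc(ts, scheme), fisher_z)
    v = node_variability(mats)
    return VariabilityProfile(
        participant_id=ts.participant_id,
        condition="rest",
        v=v,
        n_comparisons=scheme.n_windows * (scheme.n_windows - 1) // 2,
    )


def condition_variability(
    scans: Sequence[NodeTimeSeries], *, fisher_z: bool = False
) -> VariabilityProfile:
    """Variability of one task condition across repeated scans.

    One FC matrix is computed from each scan's whole condition segment (no
    sub-windowing); profiles are then compared across the ``m`` scans,
    giving ``C(m, 2)`` pairwise comparisons per node.
    """
    if len(scans) < 2:
        raise ValueError("at least 2 scans of the condition are required")
    pids = {s.participant_id for s in scans}
    conds = {s.condition for s in scans}
    if len(pids) != 1:
        raise ValueError(f"scans mix participants {sorted(pids)}")
    if len(conds) != 1:
        raise ValueError(f"scans mix conditions {sorted(conds)}")
    mats = []
    for s in scans:
        sd = s.data.std(axis=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0) + 1
            raise ValueError(
                f"constant signal in scan {s.scan_id} for node(s) {bad.tolist()}"
            )
        mats.append(np.corrcoef(s.data))
    v = node_variability(_maybe_fisher(mats, fisher_z))
    m = len(scans)
    return VariabilityProfile(
        participant_id=next(iter(pids)),
        condition=next(iter(conds)),
        v=v,
        n_comparisons=m * (m - 1) // 2,
    )


#: contrast name -> (conditions averaged with +, conditions averaged with -)
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "self_minus_other": (
        ("self_mental", "self_physical", "self_social"),
        ("other_mental", "other_physical", "other_social"),
    ),
    "self_minus_font": (("self_mental", "self_physical", "self_social"), ("font",)),
    "other_minus_font": (("other_mental", "other_physical", "other_social"), ("font",)),
    "self_minus_other_mental": (("self_mental",), ("other_mental",)),
    "self_minus_other_physical": (("self_physical",), ("other_physical",)),
    "self_minus_other_social": (("self_social",), ("other_social",)),
}


def contrast_variability(
    profiles: Mapping[str, VariabilityProfile], contrast: str
) -> VariabilityProfile:
    """Condition contrast of variability profiles for one participant.

    ``self_minus_other`` subtracts the mean variability of the three
    other-related conditions from the mean of the three self-related ones;
    font contrasts and single-domain (mental / physical / social) variants
    use the corresponding condition subsets.
    """
    try:
        plus, minus = CONTRASTS[contrast]
    except KeyError:
        raise ValueError(
            f"unknown contrast {contrast!r}; known: {sorted(CONTRASTS)}"
        ) from None
    missing = [c for c in plus + minus if c not in profiles]
    if missing:
        raise ValueError(f"missing condition profile(s) {missing} for {contrast!r}")
    used = [profiles[c] for c in plus + minus]
    pids = {p.participant_id for p in used}
    if len(pids) != 1:
        raise ValueError(f"contrast mixes participants {sorted(pids)}")
    v = np.mean([profiles[c].v for c in plus], axis=0) - np.mean(
        [profiles[c].v for c in minus], axis=0
    )
    return VariabilityProfile(
        participant_id=next(iter(pids)),
        condition=contrast,
        v=v,
        n_comparisons=min(p.n_comparisons for p in used),
    )


def profiles_to_frame(profiles: Iterable[VariabilityProfile]) -> pd.DataFrame:
    """Long-format TSV-ready table of variability profiles."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
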