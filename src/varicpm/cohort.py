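"""Synthetic cohort generator with plantable ground-truth effects.

Emulates the study design — 60 participants, a 5-min resting scan at TR 2 s
(150 volumes, first 5 treated as equilibration), six task scans each holding
one block per condition (three self-related, three other-related, one font
control), 264 nodes — and plants node-level couplings between

* recovery and the variability × interdependence interaction, and
* recovery and the self-minus-other variability contrast,

so that every downstream stage (variability estimation, feature building,
LOOCV prediction, permutation inference, moderation) can be validated
against known generating parameters without any real data.

Mechanism.  Signals are zero-mean multivariate normal.  Each window / task
block draws its covariance as a per-node convex mixture of a fixed base
correlation matrix ``C0`` (one per participant) and a fresh random
correlation matrix ``R``:

    C_w[k, l] = sqrt((1-w_k)(1-w_l)) * C0[k, l] + sqrt(w_k w_l) * R_w[k, l]

where ``w_k`` is node *k*'s variability target in ``[0, 1)``.  ``C_w`` stays
a valid correlation matrix; target 0 pins the node to the stable base
pattern (measured variability ~ estimation noise only) and larger targets
hand the node over to the window-specific pattern, so measured V_k is
monotone in the target in expectation.

Randomness: one master seed; ``SeedSequence(seed).spawn(3)`` yields the
target stream (0), the time-series stream (1) and the behavior stream (2).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NodeTimeSeries, write_timeseries_tsv

__all__ = [
    "DEFAULT_CONDITIONS",
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "draw_variability_targets",
    "generate_timeseries",
    "generate_behavior",
    "simulate_cohort",
    "write_cohort",
]

DEFAULT_CONDITIONS = (
    "self_mental",
    "self_physical",
    "self_social",
    "other_mental",
    "other_physical",
    "other_social",
    "font",
)

SELF_CONDITIONS = ("self_mental", "self_physical", "self_social")
OTHER_CONDITIONS = ("other_mental", "other_physical", "other_social")


def _zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=axis, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance; cannot z-score")
    return (x - x.mean(axis=axis)) / sd


@dataclass(frozen=True)
class CohortSpec:
    """Design constants and planted-effect parameters of a synthetic cohort.

    Defaults reproduce the study design: 60 participants, 264 nodes,
    TR 2 s, 150 resting volumes of which the first 5 are discarded by the
    analysis, 6 task scans with one ~24-s block (12 volumes) per condition.

    ``effect_nodes`` (1-based node ids) carry the planted effects;
    ``effect_size_interaction`` is the recovery slope (BDI points) on the
    mean standardized variability×interdependence product over those nodes,
    ``effect_size_self_other`` the slope on the mean standardized
    self-minus-other variability.  ``effect_node_correlation`` is the
    common-factor correlation of effect-node variability across
    participants (planted effects are subnetwork-coherent).  ``noise_sd``
    is the behavioral residual SD in BDI points.
    """

    n_participants: int = 60
    n_nodes: int = 264
    tr_seconds: float = 2.0
    rest_volumes: int = 150
    rest_discard: int = 5
    task_scans: int = 6
    block_volumes: int = 12
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    effect_nodes: tuple[int, ...] = ()
    effect_size_interaction: float = 0.0
    effect_size_self_other: float = 0.0
    effect_node_correlation: float = 0.9
    noise_sd: float = 2.0
    window_seconds: float = 30.0
    n_high: int | None = None
    couple_groups_to_effect: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_nodes", "rest_volumes", "block_volumes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.tr_seconds <= 0 or self.noise_sd < 0 or self.window_seconds <= 0:
            raise ValueError("tr_seconds/window_seconds must be positive, noise_sd >= 0")
        if self.task_scans < 0:
            raise ValueError("task_scans must be non-negative")
        if not 0 <= self.rest_discard < self.rest_volumes:
            raise ValueError("rest_discard must lie in [0, rest_volumes)")
        if not 0 <= self.effect_node_correlation < 1:
            raise ValueError("effect_node_correlation must lie in [0, 1)")
        bad = [k for k in self.effect_nodes if not 1 <= k <= self.n_nodes]
        if bad:
            raise ValueError(f"effect_nodes outside 1..{self.n_nodes}: {bad}")
        if self.task_scans > 0:
            has_self = any(c.startswith("self_") for c in self.conditions)
            has_other = any(c.startswith("other_") for c in self.conditions)
            if not (has_self and has_other):
                raise ValueError(
                    "conditions need at least one self_* and one other_* label"
                )
        if self.n_high is not None and not 0 <= self.n_high <= self.n_participants:
            raise ValueError("n_high out of range")

    @property
    def effect_index(self) -> np.ndarray:
        """0-based column indices of the effect nodes."""
        return np.asarray(self.effect_nodes, dtype=int) - 1

    @property
    def window_samples(self) -> int:
        return int(round(self.window_seconds / self.tr_seconds))

    def streams(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return [np.random.default_rng(c) for c in children]


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the planted recovery exactly."""

    targets: np.ndarray  # participants×nodes variability level fed downstream
    interdependence: np.ndarray
    recovery: np.ndarray
    noise: np.ndarray
    interaction_term: np.ndarray
    self_other_term: np.ndarray
    effect_nodes: tuple[int, ...]
    coefficients: tuple[float, float]  # (effect_size_interaction, effect_size_self_other)

    def reconstruct_recovery(self) -> np.ndarray:
        b1, b2 = self.coefficients
        return b1 * self.interaction_term + b2 * self.self_other_term + self.noise

    def to_json(self) -> str:
        d = {
            "effect_nodes": list(self.effect_nodes),
            "coefficients": list(self.coefficients),
            **{
                k: np.asarray(getattr(self, k)).tolist()
                for k in (
                    "targets",
                    "interdependence",
                    "recovery",
                    "noise",
                    "interaction_term",
                    "self_other_term",
                )
            },
        }
        return json.dumps(d)


@dataclass
class TargetSet:
    """Per-node variability targets for rest and each task condition."""

    rest: np.ndarray  # participants×nodes
    task: dict[str, np.ndarray]
    self_other: np.ndarray  # participants×nodes planted contrast (task target scale)


def draw_variability_targets(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> TargetSet:
    """Draw participant×node variability targets with planted structure.

    Rest targets sit around 0.45 with SD 0.15 — wide enough that
    between-participant differences in *measured* V clearly exceed the
    windowed-FC estimation floor (individual differences in connectivity
    variability are reliable traits; a narrower spread would drown them in
    estimation noise).  Effect nodes share a participant-level common
    factor (correlation ``effect_node_correlation`` across participants).
    Task-condition targets equal the rest targets shifted by ±half of a
    planted self-minus-other offset at effect nodes.  Everything is
    clipped to [0.02, 0.9].
    """
    rng = rng or spec.streams()[0]
    n, p = spec.n_participants, spec.n_nodes
    c = spec.effect_node_correlation
    x = rng.standard_normal((n, p))
    eff = spec.effect_index
    if eff.size:
        u = rng.standard_normal(n)
        x[:, eff] = np.sqrt(c) * u[:, None] + np.sqrt(1 - c) * x[:, eff]
    rest = np.clip(0.45 + 0.15 * x, 0.02, 0.9)

    d = rng.standard_normal((n, p)) * 0.02
    if eff.size:
        w = rng.standard_normal(n)
        d[:, eff] = 0.12 * (np.sqrt(c) * w[:, None] + np.sqrt(1 - c) * rng.standard_normal((n, eff.size)))
    task: dict[str, np.ndarray] = {}
    for cond in spec.conditions:
        if cond.startswith("self_"):
            task[cond] = np.clip(rest + d / 2, 0.02, 0.9)
        elif cond.startswith("other_"):
            task[cond] = np.clip(rest - d / 2, 0.02, 0.9)
        else:
            task[cond] = rest.copy()
    return TargetSet(rest=rest, task=task, self_other=d)


def _random_correlation(
    rng: np.random.Generator, n: int, rank: int = 14, idio: float = 0.25
) -> np.ndarray:
    """Random low-rank-plus-diagonal correlation matrix.

    Functional connectomes are dominated by a handful of network-level
    components, so connectivity patterns are drawn from ``rank`` latent
    factors (default 14, the network count of the parcellation) plus an
    idiosyncratic diagonal share ``idio``.  Off-diagonals then sit around
    ``(1-idio)/sqrt(rank)`` ~ 0.2 at any matrix size — comparable to real
    FC — so windowed-FC estimates carry pattern signal well above their
    sampling noise.  (A full-rank draw would shrink off-diagonals like
    1/sqrt(n), leaving nothing measurable at 264 nodes.)
    """
    a = rng.standard_normal((n, max(3, min(rank, n))))
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    return (1.0 - idio) * (a @ a.T) + idio * np.eye(n)


def _mixture_cov(
    base: np.ndarray, perturb: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    s1 = np.sqrt(1.0 - weights)
    s2 = np.sqrt(weights)
    return np.outer(s1, s1) * base + np.outer(s2, s2) * perturb


def _sample_segment(
    rng: np.random.Generator, cov: np.ndarray, n_samples: int
) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-9 * np.eye(cov.shape[0]))
    return chol @ rng.standard_normal((cov.shape[0], n_samples))


def generate_timeseries(
    spec: CohortSpec,
    targets: np.ndarray,
    *,
    task_targets: Mapping[str, np.ndarray] | None = None,
    base_cov: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[NodeTimeSeries]:
    """Simulate every scan of the cohort from variability targets.

    ``targets`` (participants×nodes, values in [0, 1)) drive the resting
    scan; ``task_targets`` maps each condition to its own matrix (defaults
    to the rest targets).  Each participant gets one resting scan of
    ``rest_volumes`` samples segmented as [discard | n complete analysis
    windows | remainder], with a fresh mixture covariance per segment, plus
    ``task_scans`` scans holding one ``block_volumes`` block per condition.
    Deterministic under a fixed seed.
    """
    rng = rng or spec.streams()[1]
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (spec.n_participants, spec.n_nodes):
        raise ValueError(
            f"targets shape {targets.shape} != "
            f"({spec.n_participants}, {spec.n_nodes})"
        )
    all_t = [targets] + [np.asarray(v, float) for v in (task_targets or {}).values()]
    for t in all_t:
        if np.any((t < 0) | (t >= 1)):
            raise ValueError("variability targets must lie in [0, 1)")
    if base_cov is not None:
        base_cov = np.asarray(base_cov, dtype=float)
        try:
            np.linalg.cholesky(base_cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                "base covariance is not positive definite; provide a valid "
                "SPD correlation matrix"
            ) from None

    ws = spec.window_samples
    avail = spec.rest_volumes - spec.rest_discard
    n_win = avail // ws
    remainder = avail - n_win * ws
    segments = [spec.rest_discard] + [ws] * n_win + [remainder]
    segments = [s for s in segments if s > 0]

    out: list[NodeTimeSeries] = []
    for pi in range(spec.n_participants):
        pid = f"sub-{pi + 1:03d}"
        c0 = base_cov if base_cov is not None else _random_correlation(rng, spec.n_nodes)
        w = targets[pi]
        chunks = []
        for seg in segments:
            cov = _mixture_cov(c0, _random_correlation(rng, spec.n_nodes), w)
            chunks.append(_sample_segment(rng, cov, seg))
        out.append(
            NodeTimeSeries(
                pid, "rest", "rest", np.concatenate(chunks, axis=1), spec.tr_seconds
            )
        )
        for s in range(spec.task_scans):
            sid = f"task-{s + 1}"
            for cond in spec.conditions:
                wt = (task_targets or {}).get(cond, targets)[pi]
                cov = _mixture_cov(c0, _random_correlation(rng, spec.n_nodes), wt)
                out.append(
                    NodeTimeSeries(
                        pid,
                        sid,
                        cond,
                        _sample_segment(rng, cov, spec.block_volumes),
                        spec.tr_seconds,
                    )
                )
    return out


def generate_behavior(
    spec: CohortSpec,
    variability: np.ndarray,
    *,
    self_other: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Behavioral table with recovery planted on the supplied variability.

    ``variability`` is a participants×nodes matrix — either the generator's
    targets or measured V from the variability module.  Recovery is

        b_int * mean_{k in effect} z(V_k) z(I)
        + b_so * mean_{k in effect} z(D_k)  + noise

    with ``I`` interdependence ~ N(0, 1) on the subscale-difference scale
    and ``D`` the self-minus-other contrast (``self_other`` argument,
    required when ``effect_size_self_other`` is nonzero).  Baseline BDI is
    assigned so that ~28/60 of the cohort is high-depression (score >= 14)
    and the rest low (<= 4); group membership is independent of the planted
    effect unless ``couple_groups_to_effect``.  Second-screen BDI is the
    exact real-valued difference ``bdi_t1 - recovery`` so the planted
    linear model reconstructs recovery bit-exactly.
    """
    rng = rng or spec.streams()[2]
    v = np.asarray(variability, dtype=float)
    n = spec.n_participants
    if v.shape != (n, spec.n_nodes):
        raise ValueError(f"variability shape {v.shape} != ({n}, {spec.n_nodes})")
    interdep = rng.standard_normal(n)
    eff = spec.effect_index
    if eff.size:
        interaction_term = (_zscore(v[:, eff]) * _zscore(interdep)[:, None]).mean(axis=1)
    else:
        interaction_term = np.zeros(n)
    if spec.effect_size_self_other != 0.0:
        if self_other is None:
            raise ValueError(
                "effect_size_self_other is nonzero but no self_other contrast "
                "matrix was supplied"
            )
        d = np.asarray(self_other, dtype=float)
        if d.shape != (n, spec.n_nodes):
            raise ValueError(f"self_other shape {d.shape} != ({n}, {spec.n_nodes})")
        self_other_term = _zscore(d[:, eff]).mean(axis=1) if eff.size else np.zeros(n)
    else:
        self_other_term = np.zeros(n)
    noise = rng.standard_normal(n) * spec.noise_sd
    recovery = (
        spec.effect_size_interaction * interaction_term
        + spec.effect_size_self_other * self_other_term
        + noise
    )

    n_high = spec.n_high if spec.n_high is not None else int(round(n * 28 / 60))
    if spec.couple_groups_to_effect:
        order = np.argsort(-recovery, kind="stable")
    else:
        order = rng.permutation(n)
    is_high = np.zeros(n, dtype=bool)
    is_high[order[:n_high]] = True
    bdi_t1 = np.where(
        is_high,
        np.clip(np.round(rng.normal(19.21, 2.19, n)), 14, 28),
        np.clip(np.round(rng.normal(2.25, 1.44, n)), 0, 4),
    ).astype(float)
    bdi_t2 = bdi_t1 - recovery

    df = pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "bdi_t1": bdi_t1,
            "bdi_t2": bdi_t2,
            "recovery": recovery,
            "interdep_mean": 4.0 + interdep / 2.0,
            "indep_mean": 4.0 - interdep / 2.0,
            "interdependence": interdep,
            "group": np.where(is_high, "high", "low"),
        }
    )
    gt = GroundTruth(
        targets=v,
        interdependence=interdep,
        recovery=recovery,
        noise=noise,
        interaction_term=interaction_term,
        self_other_term=self_other_term,
        effect_nodes=spec.effect_nodes,
        coefficients=(spec.effect_size_interaction, spec.effect_size_self_other),
    )
    return df, gt


@dataclass
class Cohort:
    spec: CohortSpec
    targets: TargetSet
    timeseries: list[NodeTimeSeries]
    behavior: pd.DataFrame
    ground_truth: GroundTruth


def simulate_cohort(spec: CohortSpec, *, timeseries: bool = True) -> Cohort:
    """One-call cohort: targets, (optionally) signals, behavior, truth.

    Behavior is planted on the *target* variability matrix, so the cohort
    is self-contained; pipelines that want the planted effect expressed on
    *measured* variability instead can call :func:`generate_timeseries`,
    estimate V, and pass it to :func:`generate_behavior` themselves.
    """
    t_rng, ts_rng, b_rng = spec.streams()
    targets = draw_variability_targets(spec, t_rng)
    ts = (
        generate_timeseries(spec, targets.rest, task_targets=targets.task, rng=ts_rng)
        if timeseries
        else []
    )
    behavior, gt = generate_behavior(
        spec, targets.rest, self_other=targets.self_other, rng=b_rng
    )
    return Cohort(spec=spec, targets=targets, timeseries=ts, behavior=behavior, ground_truth=gt)


def write_cohort(cohort: Cohort, outdir: str | os.PathLike) -> Path:
    """Write TSV time series + manifest + behavior + ground-truth JSON."""
    out = Path(outdir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in cohort.timeseries:
        rel = Path("timeseries") / f"{ts.participant_id}_{ts.scan_id}_{ts.condition}.tsv"
        write_timeseries_tsv(ts, out / rel)
        rows.append(
            {
                "participant_id": ts.participant_id,
                "scan_id": ts.scan_id,
                "condition": ts.condition,
                "path": str(rel),
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    cohort.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False, float_format="%.17e")
    (out / "ground_truth.json").write_text(cohort.ground_truth.to_json())
    return out
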