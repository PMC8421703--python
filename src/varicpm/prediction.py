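"""Leave-one-out cross-validated CPM-style prediction with permutation tests.

The four-stage procedure, per LOOCV fold (one participant held out):

1. *Feature selection* — two-sided Pearson test of each node's feature
   against recovery over the training rows; nodes with p < alpha split by
   correlation sign into positive and negative sets.
2. *Model establishment* — positive features are averaged into the positive
   strength, negated negative features into the negative strength, and the
   two (where defined) are averaged into the total strength; each strength
   is regressed on recovery by ordinary least squares.
3. *Prediction* — the held-out participant's strengths (computed with the
   training fold's node sets, and with the training fold's normalization
   statistics when the features are fold-normalized interactions) are
   substituted into the fitted lines.
4. *Evaluation* — predictive power is the Pearson correlation between
   LOOCV-predicted and observed recovery; a model is invalid when any fold
   selected no feature for it.  Nodes selected in more than 95% of
   iterations are the "important nodes".

Permutation inference reruns the whole procedure on shuffled recovery;
permutations in which a model goes invalid are excluded from its valid null
(but counted), and the empirical P uses the add-one estimator
``(1 + #{null >= observed}) / (1 + #valid)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix
from .io import Atlas

__all__ = [
    "MODELS",
    "ModelConfig",
    "PredictionResult",
    "PermutationResult",
    "select_features",
    "feature_strengths",
    "loocv_predict",
    "permutation_test",
    "important_nodes",
    "network_breakdown",
    "subgroup_fixed_feature_predict",
]

MODELS = ("total", "positive", "negative")


@dataclass(frozen=True)
class ModelConfig:
    """Tunables of the predictive procedure.

    ``selection_alpha`` is the two-sided p threshold of the feature
    selection stage (0.05; 0.01 as a robustness setting);
    ``importance_threshold`` the strict selection-frequency cutoff for
    important nodes; ``total_strategy`` chooses between averaging the two
    strengths (``"average"``, default) and pooling all signed features into
    one mean (``"pooled"``).
    """

    selection_alpha: float = 0.05
    n_permutations: int = 1000
    permutation_seed: int = 0
    importance_threshold: float = 0.95
    total_strategy: str = "average"

    def __post_init__(self) -> None:
        if not 0 < self.selection_alpha < 1:
            raise ValueError("selection_alpha must lie in (0, 1)")
        if not 0 < self.importance_threshold < 1:
            raise ValueError("importance_threshold must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.total_strategy not in ("average", "pooled"):
            raise ValueError("total_strategy must be 'average' or 'pooled'")


def _critical_r(alpha: float, df: int) -> float:
    """|r| above which the two-sided correlation test has p < alpha."""
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(df + t * t))


def select_features(
    features: np.ndarray, outcome: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Positive / negative node sets by two-sided Pearson test (p < alpha).

    Returns 0-based column indices.  Strict inequality: a node whose p
    equals alpha exactly is not selected.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.size:
        raise ValueError("features must be participants×nodes aligned with outcome")
    n = y.size
    if n < 4:
        raise ValueError("at least 4 training participants are required")
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise ValueError("outcome has zero variance; correlations undefined")
    xc = x - x.mean(axis=0)
    xnorm = np.linalg.norm(xc, axis=0)
    if np.any(xnorm == 0):
        bad = (np.flatnonzero(xnorm == 0) + 1).tolist()
        raise ValueError(f"zero feature variance at node(s) {bad}")
    r = (xc.T @ yc) / (xnorm * ynorm)
    rc = _critical_r(alpha, n - 2)
    return np.flatnonzero(r > rc), np.flatnonzero(r < -rc)


def feature_strengths(
    row: np.ndarray,
    positive: np.ndarray,
    negative: np.ndarray,
    *,
    total_strategy: str = "average",
) -> tuple[float | None, float | None, float | None]:
    """(S_pos, S_neg, S_tot) for one participant's feature vector.

    S_pos averages the positive-set features; S_neg averages the *negated*
    negative-set features; S_tot averages the defined strengths (or pools
    all signed features when ``total_strategy="pooled"``).  Undefined
    strengths are ``None``, never silently zero; both sets empty is the
    "no feature" signal (all three ``None``).
    """
    row = np.asarray(row, dtype=float)
    positive = np.asarray(positive, dtype=int)
    negative = np.asarray(negative, dtype=int)
    s_pos = float(row[positive].mean()) if positive.size else None
    s_neg = float(-row[negative].mean()) if negative.size else None
    if s_pos is None and s_neg is None:
        return None, None, None
    if total_strategy == "pooled":
        pooled = np.concatenate([row[positive], -row[negative]])
        s_tot = float(pooled.mean())
    elif s_pos is not None and s_neg is not None:
        s_tot = (s_pos + s_neg) / 2.0
    else:
        s_tot = s_pos if s_pos is not None else s_neg
    return s_pos, s_neg, s_tot


# ---------------------------------------------------------------------------
# fold machinery (shared by the observed run and the permutation null)


@dataclass
class _Fold:
    test: int
    train: np.ndarray  # row indices
    xtr: np.ndarray  # training features (fold-normalized if applicable)
    xc: np.ndarray  # column-centered xtr
    xnorm: np.ndarray  # column norms of xc
    xtest: np.ndarray  # held-out feature row


def _build_folds(fm: FeatureMatrix) -> list[_Fold]:
    n = fm.n_participants
    if n < 5:
        raise ValueError("LOOCV needs at least 5 participants")
    fold_normalize = fm.kind == "interaction" and fm.normalization_scope == "training_fold"
    if fold_normalize and (fm.raw_v is None or fm.raw_i is None):
        raise ValueError(
            "training_fold scope requires the raw variability and "
            "interdependence carried on the FeatureMatrix"
        )
    folds: list[_Fold] = []
    idx = np.arange(n)
    for i in range(n):
        train = idx[idx != i]
        if fold_normalize:
            vtr = fm.raw_v[train]
            mu, sd = vtr.mean(axis=0), vtr.std(axis=0, ddof=1)
            if np.any(sd == 0):
                bad = (np.flatnonzero(sd == 0) + 1).tolist()
                raise ValueError(f"zero training-fold variance at node(s) {bad}")
            itr = fm.raw_i[train]
            imu, isd = itr.mean(), itr.std(ddof=1)
            if isd == 0:
                raise ValueError("zero training-fold variance in interdependence")
            zi = (itr - imu) / isd
            xtr = ((vtr - mu) / sd) * zi[:, None]
            xtest = ((fm.raw_v[i] - mu) / sd) * ((fm.raw_i[i] - imu) / isd)
        else:
            xtr = fm.values[train]
            xtest = fm.values[i]
        xc = xtr - xtr.mean(axis=0)
        xnorm = np.linalg.norm(xc, axis=0)
        if np.any(xnorm == 0):
            bad = (np.flatnonzero(xnorm == 0) + 1).tolist()
            raise ValueError(f"zero feature variance at node(s) {bad} in fold {i}")
        folds.append(_Fold(i, train, xtr, xc, xnorm, xtest))
    return folds


def _fold_models(
    fold: _Fold, y: np.ndarray, rc: float, total_strategy: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float]]:
    """Selection + fits + held-out prediction for one fold.

    Returns (pos, neg, r_per_node, predictions dict model->float or nan).
    """
    ytr = y[fold.train]
    yc = ytr - ytr.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise ValueError("outcome has zero variance in a training fold")
    r = (fold.xc.T @ yc) / (fold.xnorm * ynorm)
    pos = np.flatnonzero(r > rc)
    neg = np.flatnonzero(r < -rc)
    preds: dict[str, float] = {}
    s_pos_tr = fold.xtr[:, pos].mean(axis=1) if pos.size else None
    s_neg_tr = -fold.xtr[:, neg].mean(axis=1) if neg.size else None
    if total_strategy == "pooled" and (pos.size or neg.size):
        k = pos.size + neg.size
        s_tot_tr = (
            (fold.xtr[:, pos].sum(axis=1) if pos.size else 0.0)
            - (fold.xtr[:, neg].sum(axis=1) if neg.size else 0.0)
        ) / k
    elif s_pos_tr is not None and s_neg_tr is not None:
        s_tot_tr = (s_pos_tr + s_neg_tr) / 2.0
    else:
        s_tot_tr = s_pos_tr if s_pos_tr is not None else s_neg_tr
    s_pos_te, s_neg_te, s_tot_te = feature_strengths(
        fold.xtest, pos, neg, total_strategy=total_strategy
    )
    for name, s_tr, s_te in (
        ("total", s_tot_tr, s_tot_te),
        ("positive", s_pos_tr, s_pos_te),
        ("negative", s_neg_tr, s_neg_te),
    ):
        if s_tr is None:
            preds[name] = np.nan
            continue
        sc = s_tr - s_tr.mean()
        denom = float(sc @ sc)
        if denom == 0:
            preds[name] = np.nan
            continue
        slope = float(sc @ yc) / denom
        intercept = float(ytr.mean() - slope * s_tr.mean())
        preds[name] = slope * s_te + intercept
    return pos, neg, r, preds


def _power(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float] | None:
    """Pearson predictive power and parametric two-sided p, or None if degenerate."""
    if np.any(~np.isfinite(pred)) or np.std(pred) == 0 or np.std(obs) == 0:
        return None
    r, p = stats.pearsonr(pred, obs)
    return float(r), float(p)


@dataclass
class PredictionResult:
    """Full LOOCV bookkeeping for the three models."""

    n_iterations: int
    predicted: dict[str, np.ndarray]
    observed: np.ndarray
    r: dict[str, float | None]
    p_parametric: dict[str, float | None]
    valid: dict[str, bool]
    invalid_reason: dict[str, str | None]
    selection_frequency: np.ndarray  # per node, either sign
    pos_counts: np.ndarray
    neg_counts: np.ndarray
    mean_selected_r: np.ndarray  # mean training r over folds where selected
    iteration_sets: list[tuple[np.ndarray, np.ndarray]]

    def significant(self, model: str, alpha: float = 0.05) -> bool:
        """The study's success rule: significant *positive* predictive power."""
        r, p = self.r.get(model), self.p_parametric.get(model)
        return r is not None and r > 0 and p < alpha

    def to_node_table(self, atlas: Atlas | None = None, threshold: float = 0.95) -> pd.DataFrame:
        n = self.selection_frequency.size
        df = pd.DataFrame(
            {
                "node_id": np.arange(1, n + 1),
                "selection_frequency": self.selection_frequency,
                "sign": np.where(
                    self.pos_counts + self.neg_counts == 0,
                    "",
                    np.where(self.mean_selected_r >= 0, "positive", "negative"),
                ),
                "important": self.selection_frequency > threshold,
            }
        )
        if atlas is not None:
            df = df.merge(atlas.table, on="node_id", how="left")
        return df


def loocv_predict(
    features: FeatureMatrix, outcome: np.ndarray, config: ModelConfig | None = None
) -> PredictionResult:
    """Run the full LOOCV predictive procedure on one cohort."""
    config = config or ModelConfig()
    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or y.size != features.n_participants:
        raise ValueError("outcome must align with the feature rows")
    folds = _build_folds(features)
    n = len(folds)
    rc = _critical_r(config.selection_alpha, n - 3)  # n-1 training rows, df = n-3
    pred = {m: np.full(n, np.nan) for m in MODELS}
    pos_counts = np.zeros(features.n_nodes)
    neg_counts = np.zeros(features.n_nodes)
    r_sums = np.zeros(features.n_nodes)
    iteration_sets: list[tuple[np.ndarray, np.ndarray]] = []
    for fold in folds:
        pos, neg, r_nodes, preds = _fold_models(fold, y, rc, config.total_strategy)
        iteration_sets.append((pos, neg))
        pos_counts[pos] += 1
        neg_counts[neg] += 1
        sel = np.concatenate([pos, neg])
        r_sums[sel] += r_nodes[sel]
        for m in MODELS:
            pred[m][fold.test] = preds[m]
    counts = pos_counts + neg_counts
    with np.errstate(invalid="ignore"):
        mean_r = np.where(counts > 0, r_sums / np.maximum(counts, 1), 0.0)
    r_out: dict[str, float | None] = {}
    p_out: dict[str, float | None] = {}
    valid: dict[str, bool] = {}
    reason: dict[str, str | None] = {}
    for m in MODELS:
        n_missing = int(np.sum(~np.isfinite(pred[m])))
        if n_missing > 0:
            valid[m] = False
            reason[m] = f"no feature selected in {n_missing} iteration(s)"
            r_out[m] = p_out[m] = None
            continue
        rp = _power(pred[m], y)
        if rp is None:
            valid[m] = False
            reason[m] = "predicted values are constant; power undefined"
            r_out[m] = p_out[m] = None
            continue
        valid[m] = True
        reason[m] = None
        r_out[m], p_out[m] = rp
    return PredictionResult(
        n_iterations=n,
        predicted=pred,
        observed=y,
        r=r_out,
        p_parametric=p_out,
        valid=valid,
        invalid_reason=reason,
        selection_frequency=counts / n,
        pos_counts=pos_counts,
        neg_counts=neg_counts,
        mean_selected_r=mean_r,
        iteration_sets=iteration_sets,
    )


def _null_r(
    folds: list[_Fold], y: np.ndarray, rc: float, total_strategy: str
) -> dict[str, float | None]:
    """Light LOOCV pass: predictive power per model, None where invalid."""
    n = len(folds)
    pred = {m: np.full(n, np.nan) for m in MODELS}
    for fold in folds:
        _, _, _, preds = _fold_models(fold, y, rc, total_strategy)
        for m in MODELS:
            pred[m][fold.test] = preds[m]
    out: dict[str, float | None] = {}
    for m in MODELS:
        rp = _power(pred[m], y) if np.all(np.isfinite(pred[m])) else None
        out[m] = None if rp is None else rp[0]
    return out


def _null_r_batch(
    folds: list[_Fold], ys: np.ndarray, rc: float, total_strategy: str
) -> dict[str, np.ndarray]:
    """Predictive power per model for a batch of outcome vectors.

    ``ys`` is (B, n); returns per model an array of length B with NaN where
    that model was invalid (a no-feature or degenerate-fit fold, or
    constant predictions).  Semantically identical to running
    :func:`_null_r` on each row; vectorized across permutations.
    """
    B, n = ys.shape
    F = len(folds)
    train = np.stack([f.train for f in folds])  # (F, n-1)
    xtr = np.stack([f.xtr for f in folds])  # (F, n-1, N)
    xc = np.stack([f.xc for f in folds])
    xnorm = np.stack([f.xnorm for f in folds])  # (F, N)
    xtest = np.stack([f.xtest for f in folds])  # (F, N)
    test_idx = np.asarray([f.test for f in folds])

    yt = ys[:, train]  # (B, F, n-1)
    ytm = yt.mean(axis=2)
    yc = yt - ytm[..., None]
    ynorm = np.linalg.norm(yc, axis=2)
    if np.any(ynorm == 0):
        raise ValueError("outcome has zero variance in a training fold")
    r = np.einsum("fin,bfi->bfn", xc, yc) / (xnorm[None] * ynorm[..., None])
    posm = (r > rc).astype(float)
    negm = (r < -rc).astype(float)
    pcnt = posm.sum(axis=2)  # (B, F)
    ncnt = negm.sum(axis=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        s_pos = np.einsum("fin,bfn->bfi", xtr, posm) / pcnt[..., None]
        s_neg = -np.einsum("fin,bfn->bfi", xtr, negm) / ncnt[..., None]
        t_pos = np.einsum("fn,bfn->bf", xtest, posm) / pcnt
        t_neg = -np.einsum("fn,bfn->bf", xtest, negm) / ncnt
        if total_strategy == "pooled":
            k = pcnt + ncnt
            s_tot = (
                np.einsum("fin,bfn->bfi", xtr, posm)
                - np.einsum("fin,bfn->bfi", xtr, negm)
            ) / k[..., None]
            t_tot = (
                np.einsum("fn,bfn->bf", xtest, posm)
                - np.einsum("fn,bfn->bf", xtest, negm)
            ) / k
        else:
            s_tot = np.where(
                (pcnt > 0)[..., None] & (ncnt > 0)[..., None],
                (s_pos + s_neg) / 2.0,
                np.where((pcnt > 0)[..., None], s_pos, s_neg),
            )
            t_tot = np.where(
                (pcnt > 0) & (ncnt > 0), (t_pos + t_neg) / 2.0,
                np.where(pcnt > 0, t_pos, t_neg),
            )

    out: dict[str, np.ndarray] = {}
    for name, s_tr, s_te, defined in (
        ("total", s_tot, t_tot, (pcnt + ncnt) > 0),
        ("positive", s_pos, t_pos, pcnt > 0),
        ("negative", s_neg, t_neg, ncnt > 0),
    ):
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = s_tr.mean(axis=2)
            sc = s_tr - sm[..., None]
            denom = np.einsum("bfi,bfi->bf", sc, sc)
            slope = np.einsum("bfi,bfi->bf", sc, yc) / denom
            pred_f = slope * s_te + (ytm - slope * sm)  # (B, F)
        ok = defined.all(axis=1) & (denom > 0).all(axis=1)
        pred = np.empty((B, n))
        pred[:, test_idx] = pred_f
        rs = np.full(B, np.nan)
        if ok.any():
            p = pred[ok]
            y_ok = ys[ok]
            pc = p - p.mean(axis=1, keepdims=True)
            yc2 = y_ok - y_ok.mean(axis=1, keepdims=True)
            pn = np.linalg.norm(pc, axis=1)
            yn = np.linalg.norm(yc2, axis=1)
            good = (pn > 0) & (yn > 0)
            vals = np.full(ok.sum(), np.nan)
            vals[good] = np.einsum("bi,bi->b", pc, yc2)[good] / (pn * yn)[good]
            rs[ok] = vals
        out[name] = rs
    return out


@dataclass
class PermutationResult:
    """Null distribution of predictive power per model."""

    observed_r: dict[str, float]
    null_r: dict[str, np.ndarray]
    n_permutations: int
    n_invalid_permutations: dict[str, int]
    empirical_p: dict[str, float]


def permutation_test(
    features: FeatureMatrix,
    outcome: np.ndarray,
    config: ModelConfig | None = None,
    observed: PredictionResult | None = None,
) -> PermutationResult:
    """Permutation inference: shuffle recovery, rerun the full LOOCV.

    Only models valid in the observed result are tested.  A permutation in
    which a model has a no-feature iteration (or degenerate predictions) is
    counted in ``n_invalid_permutations`` for that model and excluded from
    its valid null.  ``empirical_p = (1 + #{valid null_r >= observed_r}) /
    (1 + #valid)`` — never exactly zero.
    """
    config = config or ModelConfig()
    y = np.asarray(outcome, dtype=float)
    observed = observed if observed is not None else loocv_predict(features, y, config)
    models = [m for m in MODELS if observed.valid[m]]
    if not models:
        raise ValueError("no valid observed model; nothing to permute")
    folds = _build_folds(features)
    rc = _critical_r(config.selection_alpha, len(folds) - 3)
    rng = np.random.default_rng(config.permutation_seed)
    null: dict[str, list[float]] = {m: [] for m in models}
    invalid = {m: 0 for m in models}
    chunk = 50
    done = 0
    while done < config.n_permutations:
        b = min(chunk, config.n_permutations - done)
        ys = np.stack([rng.permutation(y) for _ in range(b)])
        rs = _null_r_batch(folds, ys, rc, config.total_strategy)
        for m in models:
            vals = rs[m]
            bad = int(np.sum(~np.isfinite(vals)))
            invalid[m] += bad
            null[m].extend(vals[np.isfinite(vals)].tolist())
        done += b
    emp: dict[str, float] = {}
    null_arr: dict[str, np.ndarray] = {}
    for m in models:
        arr = np.asarray(null[m])
        if arr.size == 0:
            raise ValueError(f"zero valid permutations for the {m} model")
        null_arr[m] = arr
        emp[m] = float((1 + np.sum(arr >= observed.r[m])) / (1 + arr.size))
    return PermutationResult(
        observed_r={m: observed.r[m] for m in models},
        null_r=null_arr,
        n_permutations=config.n_permutations,
        n_invalid_permutations=invalid,
        empirical_p=emp,
    )


def important_nodes(
    result: PredictionResult, threshold: float = 0.95
) -> pd.DataFrame:
    """Nodes selected in strictly more than ``threshold`` of iterations.

    Returns a table (node_id, selection_frequency, sign); sign is the sign
    of the node's mean training-set correlation across the iterations in
    which it was selected.
    """
    freq = result.selection_frequency
    keep = np.flatnonzero(freq > threshold)
    return pd.DataFrame(
        {
            "node_id": keep + 1,
            "selection_frequency": freq[keep],
            "sign": np.where(result.mean_selected_r[keep] >= 0, "positive", "negative"),
        }
    )


def network_breakdown(nodes: Sequence[int], atlas: Atlas) -> pd.DataFrame:
    """Count of nodes per atlas network, descending.

    ``nodes`` are 1-based node ids; an id outside the atlas is an error.
    Networks with zero members are included so counts always total the set
    size over an exhaustive partition listing.
    """
    nodes = list(nodes)
    bad = [k for k in nodes if not 1 <= k <= atlas.n_nodes]
    if bad:
        raise ValueError(f"node id(s) {bad} not in the atlas")
    labels = [atlas.network_of(k) for k in nodes]
    all_networks = atlas.table["network"].unique().tolist()
    counts = pd.Series(labels, dtype=object).value_counts()
    out = pd.DataFrame(
        {
            "network": all_networks,
            "count": [int(counts.get(n, 0)) for n in all_networks],
        }
    ).sort_values(["count", "network"], ascending=[False, True], ignore_index=True)
    return out


def subgroup_fixed_feature_predict(
    features: FeatureMatrix,
    outcome: np.ndarray,
    groups: Sequence[str],
    positive_nodes: Sequence[int],
    negative_nodes: Sequence[int],
    config: ModelConfig | None = None,
) -> dict[str, dict[str, float | None]]:
    """Robustness check: LOOCV within each group with a fixed node set.

    The feature-selection stage is replaced by the given positive/negative
    node sets (1-based ids, e.g. the important nodes of the full-cohort
    analysis); the regression is refit per fold within the group.  Each
    group needs at least 5 members.  Returns per-group
    ``{"r": ..., "p": ..., "n": ...}`` for the total model.
    """
    config = config or ModelConfig()
    y = np.asarray(outcome, dtype=float)
    groups = np.asarray(groups)
    pos = np.asarray(positive_nodes, dtype=int) - 1
    neg = np.asarray(negative_nodes, dtype=int) - 1
    if pos.size + neg.size == 0:
        raise ValueError("fixed node set is empty")
    out: dict[str, dict[str, float | None]] = {}
    for g in [g for g in pd.unique(groups) if g != "none"]:
        rows = groups == g
        ng = int(rows.sum())
        if ng < 5:
            raise ValueError(f"group {g!r} has {ng} members; at least 5 required")
        fg = features.subset(rows)
        yg = y[rows]
        folds = _build_folds(fg)
        pred = np.full(ng, np.nan)
        for fold in folds:
            ytr = yg[fold.train]
            s_tr = feature_strengths_matrix(fold.xtr, pos, neg, config.total_strategy)
            s_te = feature_strengths(fold.xtest, pos, neg, total_strategy=config.total_strategy)[2]
            sc = s_tr - s_tr.mean()
            denom = float(sc @ sc)
            if denom == 0:
                continue
            slope = float(sc @ (ytr - ytr.mean())) / denom
            pred[fold.test] = slope * s_te + (ytr.mean() - slope * s_tr.mean())
        rp = _power(pred, yg) if np.all(np.isfinite(pred)) else None
        out[str(g)] = {
            "r": None if rp is None else rp[0],
            "p": None if rp is None else rp[1],
            "n": ng,
        }
    return out


def feature_strengths_matrix(
    x: np.ndarray, positive: np.ndarray, negative: np.ndarray, total_strategy: str = "average"
) -> np.ndarray:
    """Total strength for every row of a feature matrix (vectorized)."""
    positive = np.asarray(positive, dtype=int)
    negative = np.asarray(negative, dtype=int)
    s_pos = x[:, positive].mean(axis=1) if positive.size else None
    s_neg = -x[:, negative].mean(axis=1) if negative.size else None
    if s_pos is None and s_neg is None:
        raise ValueError("both node sets empty")
    if total_strategy == "pooled":
        k = positive.size + negative.size
        return (
            (x[:, positive].sum(axis=1) if positive.size else 0.0)
            - (x[:, negative].sum(axis=1) if negative.size else 0.0)
        ) / k
    if s_pos is not None and s_neg is not None:
        return (s_pos + s_neg) / 2.0
    return s_pos if s_pos is not None else s_neg
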