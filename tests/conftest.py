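"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (nested loops, scipy.stats calls
per pair) and share no code with the package; they exist so the vectorized
implementations can be checked against a direct transcription of the
definitions.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import varicpm as v


# ---------------------------------------------------------------------------
# oracles


def brute_force_variability(fc_list):
    """V_k by explicit loops over matrix pairs and per-pair pearsonr."""
    m = len(fc_list)
    n = fc_list[0].shape[0]
    out = np.empty(n)
    for k in range(n):
        coeffs = []
        for i in range(m):
            for j in range(i + 1, m):
                pi = np.delete(fc_list[i][k], k)
                pj = np.delete(fc_list[j][k], k)
                coeffs.append(stats.pearsonr(pi, pj)[0])
        out[k] = 1.0 - np.mean(coeffs)
    return out


def naive_loocv(x, y, alpha=0.05, total_strategy="average"):
    """Direct reimplementation of the LOOCV procedure on a plain feature
    matrix (no fold re-normalization): per fold, per-node pearsonr test,
    strength averaging, np.polyfit line, held-out prediction."""
    n, p = x.shape
    preds = {m: np.full(n, np.nan) for m in ("total", "positive", "negative")}
    for i in range(n):
        tr = [j for j in range(n) if j != i]
        xt, yt = x[tr], y[tr]
        pos, neg = [], []
        for k in range(p):
            r, pv = stats.pearsonr(xt[:, k], yt)
            if pv < alpha and r > 0:
                pos.append(k)
            elif pv < alpha and r < 0:
                neg.append(k)

        def strength(row):
            sp = np.mean([row[k] for k in pos]) if pos else None
            sn = np.mean([-row[k] for k in neg]) if neg else None
            if sp is None and sn is None:
                return None, None, None
            if total_strategy == "pooled":
                st = np.mean([row[k] for k in pos] + [-row[k] for k in neg])
            elif sp is not None and sn is not None:
                st = (sp + sn) / 2
            else:
                st = sp if sp is not None else sn
            return sp, sn, st

        tr_strengths = [strength(xt[j]) for j in range(n - 1)]
        te = strength(x[i])
        for name, idx in (("positive", 0), ("negative", 1), ("total", 2)):
            s_tr = [s[idx] for s in tr_strengths]
            if any(s is None for s in s_tr) or te[idx] is None:
                continue
            slope, intercept = np.polyfit(np.asarray(s_tr), yt, 1)
            preds[name][i] = slope * te[idx] + intercept
    out = {}
    for name, pr in preds.items():
        if np.all(np.isfinite(pr)):
            out[name] = (pr, stats.pearsonr(pr, y)[0])
        else:
            out[name] = (pr, None)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny simulated cohort reused by several test modules."""
    spec = v.CohortSpec(
        n_participants=8, n_nodes=12, task_scans=2, block_volumes=12, seed=11
    )
    return v.simulate_cohort(spec)
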