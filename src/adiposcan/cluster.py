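"""Embedding subphenotyping: Gower distances, PAM, stability, outcomes.

The 128-dimensional embeddings are all-continuous, so the Gower distance
reduces to the mean over dimensions of range-normalized absolute
differences (ranges computed on the clustered sample); the matrix is
symmetric with zero diagonal and values in [0, 1].  Partitioning around
medoids runs the classic BUILD + SWAP algorithm, the cluster count is
selected by maximal average silhouette width over a candidate range, and
cluster robustness is measured by bootstrap Jaccard stability.  Outcome
analysis compares clusters on incident diabetes and microalbuminuria with
Kaplan-Meier curves, log-rank tests and adjusted proportional-hazards
models (lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score


@dataclass
class ClusterResult:
    assignments: np.ndarray
    medoids: np.ndarray
    k: int
    silhouette: dict[int, float] = field(default_factory=dict)
    jaccard: np.ndarray | None = None


def gower_matrix(X: np.ndarray) -> np.ndarray:
    """Gower distances for all-continuous features.

    ``d(i, j) = mean_f |x_if - x_jf| / range_f``; zero-range dimensions are
    dropped with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x p matrix with n >= 2")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing or non-finite values are not supported")
    rng_ = X.max(axis=0) - X.min(axis=0)
    keep = rng_ > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} zero-range dimension(s)", stacklevel=2)
    if not np.any(keep):
        return np.zeros((X.shape[0], X.shape[0]))
    Xs = X[:, keep] / rng_[keep]
    D = np.abs(Xs[:, None, :] - Xs[None, :, :]).mean(axis=2)
    np.fill_diagonal(D, 0.0)
    return D


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        # gain of adding candidate c: total reduction in nearest-medoid distance
        gains = np.clip(dmin[None, :] - D, 0, None).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int = 200) -> list[int]:
    n = D.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        dmed = D[:, medoids]
        nearest = np.argmin(dmed, axis=1)
        d1 = dmed[np.arange(n), nearest]
        cost = d1.sum()
        best_delta, best_swap = 0.0, None
        others = [h for h in range(n) if h not in medoids]
        for mi in range(len(medoids)):
            rest = [m for j, m in enumerate(medoids) if j != mi]
            d_rest = D[:, rest].min(axis=1) if rest else np.full(n, np.inf)
            for h in others:
                new_d = np.minimum(d_rest, D[:, h])
                delta = new_d.sum() - cost
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    return medoids


def pam(D: np.ndarray, k: int, seed: int = 0, restarts: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids (BUILD + SWAP) on a distance matrix.

    The SWAP phase only ever accepts cost-decreasing exchanges, so the total
    distance to medoids is non-increasing.  Extra seeded random restarts
    guard against poor BUILD starts; the lowest-cost solution wins.
    Returns ``(assignments, medoid indices)``.
    """
    n = D.shape[0]
    if not (2 <= k <= n - 1):
        raise ValueError(f"k={k} outside [2, n-1]")
    rng = np.random.default_rng(seed)
    best_cost, best = np.inf, None
    starts = [_pam_build(D, k)] + [list(rng.choice(n, size=k, replace=False)) for _ in range(restarts - 1)]
    for start in starts:
        medoids = _pam_swap(D, start)
        cost = D[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, medoids
    medoids = np.array(sorted(best))
    assignments = np.argmin(D[:, medoids], axis=1)
    return assignments, medoids


def pam_silhouette(D: np.ndarray, k_range=range(2, 9), seed: int = 0) -> ClusterResult:
    """Run PAM per candidate k; select k by maximal average silhouette width."""
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    widths: dict[int, float] = {}
    solutions: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in k_range:
        if k > n - 1:
            continue
        assignments, medoids = pam(D, k, seed=seed)
        solutions[k] = (assignments, medoids)
        if len(np.unique(assignments)) < 2:
            widths[k] = -1.0
        else:
            widths[k] = float(silhouette_score(D, assignments, metric="precomputed"))
    best_k = max(widths, key=lambda k: (widths[k], -k))
    assignments, medoids = solutions[best_k]
    return ClusterResult(assignments=assignments, medoids=medoids, k=best_k, silhouette=widths)


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.intersect1d(a, b).size
    union = np.union1d(a, b).size
    return inter / union if union else 0.0


def bootstrap_stability(
    D: np.ndarray, result: ClusterResult, B: int = 100, seed: int = 0
) -> np.ndarray:
    """Clusterwise bootstrap Jaccard stability.

    Each bootstrap resample is re-clustered at the original k; every
    original cluster is matched to its maximum-Jaccard counterpart
    (computed on the unique resampled points) and the per-cluster mean over
    resamples is returned.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    k = result.k
    sums = np.zeros(k)
    counts = np.zeros(k)
    for _ in range(B):
        idx = np.unique(rng.integers(0, n, size=n))
        if idx.size <= k + 1:
            continue
        sub = D[np.ix_(idx, idx)]
        sub_assign, _ = pam(sub, k, seed=int(rng.integers(2**31)))
        for c in range(k):
            orig = idx[result.assignments[idx] == c]
            if orig.size == 0:
                continue
            best = max(_jaccard(orig, idx[sub_assign == cb]) for cb in range(k))
            sums[c] += best
            counts[c] += 1
    return sums / np.maximum(counts, 1)


def outcome_analysis(
    assignments: np.ndarray,
    followup: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    event_specs=(
        ("time_to_diabetes", "diabetes_event"),
        ("time_to_microalbuminuria", "microalbuminuria_event"),
    ),
) -> dict:
    """Kaplan-Meier curves per cluster, log-rank tests, adjusted Cox models.

    ``covariates`` columns (e.g. sex, age, bmi, hba1c_pct, baseline_uacr)
    are added to the proportional-hazards model alongside cluster indicator
    variables.  Returns a report dict with, per endpoint: the KM survival
    tables, the multivariate log-rank statistic and p-value, the fitted
    hazard ratios, and scaled Schoenfeld-style residuals for the
    proportionality diagnostic.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    assignments = np.asarray(assignments)
    if len(assignments) != len(followup):
        raise ValueError("assignments and follow-up table are not aligned")
    report: dict = {}
    for time_col, event_col in event_specs:
        times = followup[time_col].to_numpy(dtype=float)
        events = followup[event_col].to_numpy(dtype=int)
        if events.sum() == 0:
            report[time_col] = {"error": "no events observed"}
            continue
        km_tables = {}
        for c in np.unique(assignments):
            sel = assignments == c
            kmf = KaplanMeierFitter()
            kmf.fit(times[sel], events[sel], label=f"cluster_{c}")
            km_tables[int(c)] = kmf.survival_function_
        lr = multivariate_logrank_test(times, assignments, events)
        entry: dict = {
            "km": km_tables,
            "logrank_stat": float(lr.test_statistic),
            "logrank_p": float(lr.p_value),
        }
        df = pd.DataFrame({"time": times, "event": events})
        for c in np.unique(assignments)[1:]:
            df[f"cluster_{c}"] = (assignments == c).astype(int)
        if covariates is not None:
            for col in covariates.columns:
                df[col] = covariates[col].to_numpy(dtype=float)
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            entry["cox_summary"] = cph.summary
            entry["hazard_ratios"] = cph.hazard_ratios_.to_dict()
            entry["schoenfeld"] = cph.compute_residuals(df, kind="scaled_schoenfeld")
        except Exception as exc:  # degenerate designs on tiny cohorts
            entry["cox_error"] = str(exc)
        report[time_col] = entry
    return report
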