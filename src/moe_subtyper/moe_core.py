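"""Semi-supervised mixture of max-margin experts with fuzzy C-means coupling.

The estimator fits K linear experts (w_k, b_k) that each separate one AD
subgroup from the shared CN "anchor" class, jointly with fuzzy memberships
m_ik of AD subjects to experts and FCM centroids d_k, by minimizing

    sum_k [ 1/2 ||w_k||_1
            + C sum_i s_i m_ik (1 - y_i (w_k.x_i + b_k))^2
            + t sum_{i in AD} m_ik^2 ||x_i - d_k||^2 ]

subject to sum_k m_ik = 1, m_ik >= 0 for every AD subject i. CN subjects
(y = -1) enter every expert's classification loss with fixed unit
membership and carry no membership variables; s_i is the class weight
(rho for AD, 1 for CN). The squared loss (1 - y f)^2 equals (y - f)^2 for
y in {-1, +1}, so each expert update is an exact sample-weighted
L1-penalized least-squares fit. Block coordinate descent over (experts,
centroids, memberships) is monotone because each block is solved to its
global optimum: the expert subproblem is a convex lasso, the centroid
d_k = sum m^2 x / sum m^2 minimizes the quadratic FCM term, and the
membership rows solve a simplex-constrained diagonal QP in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold

_DEAD_WEIGHT_EPS = 1e-8
_DIST_FLOOR = 1e-12


class DeadExpertError(RuntimeError):
    """An expert lost all membership mass and could not be revived."""


class DimensionError(ValueError):
    """Model and data dimensions disagree."""


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

def default_grid() -> tuple[float, ...]:
    """Powers-of-two search grid 2^-3 ... 2^10 for C and t."""
    return tuple(float(2.0**e) for e in range(-3, 11))


@dataclass(frozen=True)
class MOEConfig:
    K: int = 3
    C: float = 8.0
    t: float = 0.125
    alpha: float = 2.0
    class_weight_ratio: float = 1.0     # AD:CN weight rho >= 1
    squared_hinge: bool = False         # truncated loss max(0, 1-yf)^2 variant
    fit_intercept: bool = True
    cv_folds: int = 10
    max_iter: int = 100
    tol: float = 1e-4
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.C <= 0 or self.t <= 0:
            raise ValueError("C and t must be > 0")
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if self.class_weight_ratio < 1:
            raise ValueError("class_weight_ratio must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class LabeledDataset:
    """Residualized features with CN = -1 (anchor) and AD = +1 labels."""

    X: np.ndarray
    y: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, float)
        y = np.asarray(self.y, int)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise DimensionError("X must be 2-D with one label per row")
        if not np.all(np.isin(y, (-1, 1))):
            raise ValueError("labels must be -1 (CN) or +1 (AD)")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite (no missing values)")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @classmethod
    def from_frames(cls, residuals: pd.DataFrame, subjects: pd.DataFrame) -> "LabeledDataset":
        sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
        mask = sub.loc[residuals.index, "diagnosis"].isin(["CN", "AD"])
        ids = residuals.index[mask]
        y = np.where(sub.loc[ids, "diagnosis"] == "AD", 1, -1)
        return cls(X=residuals.loc[ids].to_numpy(float), y=y, ids=tuple(map(str, ids)))

    @property
    def ad_mask(self) -> np.ndarray:
        return self.y == 1

    @property
    def n_ad(self) -> int:
        return int(self.ad_mask.sum())


@dataclass
class ExpertModel:
    """One linear expert: hyperplane (w, b) plus its FCM centroid d."""

    w: np.ndarray
    b: float
    d: np.ndarray

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b


@dataclass
class MOEModel:
    experts: list[ExpertModel]
    memberships: np.ndarray          # AD subjects x K, rows sum to 1
    objective_trace: list[float]
    converged: bool
    config: MOEConfig
    ad_ids: tuple[str, ...] = ()

    @property
    def K(self) -> int:
        return len(self.experts)

    @property
    def centroids(self) -> np.ndarray:
        return np.vstack([e.d for e in self.experts])


@dataclass
class ModelSelectionReport:
    """Grid-search record: one row per (C, t, rho) with Acc, W_r and BPC."""

    table: pd.DataFrame
    selected: dict
    rule: str = "max Acc, then min W_r, then max BPC, then smallest C, t, rho"

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _losses(data: LabeledDataset, experts: Sequence[ExpertModel], config: MOEConfig) -> np.ndarray:
    """Classification loss per subject x expert: (1 - y f)^2, optionally truncated."""
    F = np.column_stack([e.decision(data.X) for e in experts])
    margin = 1.0 - data.y[:, None] * F
    if config.squared_hinge:
        margin = np.maximum(margin, 0.0)
    return margin**2


def moe_objective(
    data: LabeledDataset,
    experts: Sequence[ExpertModel],
    memberships: np.ndarray,
    config: MOEConfig,
) -> float:
    """Value of the joint objective at the given blocks."""
    memberships = np.asarray(memberships, float)
    K = len(experts)
    ad = data.ad_mask
    if memberships.shape != (int(ad.sum()), K):
        raise DimensionError(
            f"memberships shape {memberships.shape} does not match "
            f"(n_ad={int(ad.sum())}, K={K})"
        )
    L = _losses(data, experts, config)
    rho = config.class_weight_ratio
    total = 0.0
    X_ad = data.X[ad]
    for k, e in enumerate(experts):
        total += 0.5 * float(np.abs(e.w).sum())
        total += config.C * rho * float(memberships[:, k] @ L[ad, k])
        total += config.C * float(L[~ad, k].sum())      # CN anchors, unit weight
        dist2 = ((X_ad - e.d[None, :]) ** 2).sum(axis=1)
        total += config.t * float((memberships[:, k] ** 2) @ dist2)
    return total


# ---------------------------------------------------------------------------
# Block updates
# ---------------------------------------------------------------------------

def update_experts(
    data: LabeledDataset, memberships: np.ndarray, config: MOEConfig
) -> list[tuple[np.ndarray, float]]:
    """Solve each expert's weighted L1 least-squares subproblem exactly.

    Per expert k the sample weight is rho*m_ik for AD subjects and 1 for CN;
    with y in {-1, +1} the loss (1 - y f)^2 equals (y - f)^2, so the
    subproblem is a lasso with weight-rescaled penalty. Returns (w, b) pairs.
    """
    ad = data.ad_mask
    K = memberships.shape[1]
    out: list[tuple[np.ndarray, float]] = []
    for k in range(K):
        sw = np.ones(len(data.y))
        sw[ad] = config.class_weight_ratio * memberships[:, k]
        ad_weight = float(sw[ad].sum())
        if ad_weight < _DEAD_WEIGHT_EPS:
            raise DeadExpertError(f"expert {k} has total AD weight {ad_weight:.3g}")
        out.append(_weighted_l1_fit(data.X, data.y.astype(float), sw, config))
    return out


def _weighted_l1_fit(
    X: np.ndarray, y: np.ndarray, sw: np.ndarray, config: MOEConfig
) -> tuple[np.ndarray, float]:
    if config.squared_hinge:
        return _weighted_l1_fit_hinge(X, y, sw, config)
    # scikit-learn rescales sample weights to sum to n; its objective is then
    # (1/(2 W)) sum sw_i (y - f)^2 + alpha ||w||_1 with W = sum(sw), which is
    # proportional to ours exactly when alpha = 1 / (4 C W).
    keep = sw > 0
    W = float(sw.sum())
    alpha = 1.0 / (4.0 * config.C * W)
    lasso = Lasso(
        alpha=alpha, fit_intercept=config.fit_intercept, max_iter=100_000, tol=1e-12
    )
    lasso.fit(X[keep], y[keep], sample_weight=sw[keep])
    return lasso.coef_.copy(), float(lasso.intercept_) if config.fit_intercept else 0.0


def _weighted_l1_fit_hinge(
    X: np.ndarray, y: np.ndarray, sw: np.ndarray, config: MOEConfig
) -> tuple[np.ndarray, float]:
    """Squared-hinge variant via smooth bound-constrained optimization."""
    from scipy.optimize import minimize

    n, p = X.shape
    nb = 1 if config.fit_intercept else 0

    def fun(z):
        wp, wm = z[:p], z[p : 2 * p]
        b = z[-1] if nb else 0.0
        w = wp - wm
        r = np.maximum(1.0 - y * (X @ w + b), 0.0)
        val = 0.5 * (wp.sum() + wm.sum()) + config.C * float(sw @ r**2)
        g_f = -2.0 * config.C * sw * r * y
        gw = X.T @ g_f
        grad = np.concatenate([gw + 0.5, -gw + 0.5, [g_f.sum()] if nb else []])
        return val, grad

    z0 = np.zeros(2 * p + nb)
    bounds = [(0, None)] * (2 * p) + ([(None, None)] if nb else [])
    res = minimize(fun, z0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    w = res.x[:p] - res.x[p : 2 * p]
    b = float(res.x[-1]) if nb else 0.0
    return w, b


def update_centroids(
    data: LabeledDataset, memberships: np.ndarray, alpha: float = 2.0
) -> np.ndarray:
    """FCM centroids d_k = sum_i m_ik^a x_i / sum_i m_ik^a over AD subjects."""
    X_ad = data.X[data.ad_mask]
    M = np.asarray(memberships, float) ** alpha
    denom = M.sum(axis=0)
    dead = np.flatnonzero(denom <= _DEAD_WEIGHT_EPS)
    if dead.size:
        raise DeadExpertError(f"expert {dead[0]} has zero membership mass")
    return (M.T @ X_ad) / denom[:, None]


def update_memberships(
    data: LabeledDataset, experts: Sequence[ExpertModel], config: MOEConfig
) -> np.ndarray:
    """Exact per-subject simplex QP via KKT water-filling.

    For AD subject i minimize sum_k [ C rho m_k L_ik + t m_k^2 D_ik ] over the
    probability simplex; the KKT stationarity condition gives
    m_k = max(0, (lam - C rho L_ik) / (2 t D_ik)) with lam chosen so the row
    sums to one. D_ik is floored at 1e-12 to avoid division by zero.
    """
    ad = data.ad_mask
    L = _losses(data, experts, config)[ad]
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite classification loss in membership update")
    X_ad = data.X[ad]
    D = np.stack(
        [((X_ad - e.d[None, :]) ** 2).sum(axis=1) for e in experts], axis=1
    )
    a = config.C * config.class_weight_ratio * L      # linear cost
    c = 2.0 * config.t * np.maximum(D, _DIST_FLOOR)   # quadratic curvature
    return _simplex_qp_rows(a, c)


def _simplex_qp_rows(a: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Row-wise minimize a.m + (c/2).m^2 on the simplex; c > 0 elementwise."""
    n, K = a.shape
    order = np.argsort(a, axis=1)
    a_s = np.take_along_axis(a, order, axis=1)
    c_s = np.take_along_axis(c, order, axis=1)
    inv_c = 1.0 / c_s
    num = np.cumsum(a_s * inv_c, axis=1) + 1.0      # lam numerator for prefix j
    den = np.cumsum(inv_c, axis=1)
    lam_j = num / den
    # active set = largest prefix j with lam_j > a_s[:, j-1]
    feasible = lam_j > a_s - 1e-15
    j_star = feasible.shape[1] - 1 - np.argmax(feasible[:, ::-1], axis=1)
    lam = lam_j[np.arange(n), j_star]
    m_s = np.maximum(0.0, (lam[:, None] - a_s) * inv_c)
    m_s[np.arange(K)[None, :] > j_star[:, None]] = 0.0
    m = np.empty_like(m_s)
    np.put_along_axis(m, order, m_s, axis=1)
    m /= m.sum(axis=1, keepdims=True)
    return m


# ---------------------------------------------------------------------------
# Initialization: plain fuzzy C-means on the AD rows
# ---------------------------------------------------------------------------

def _fcm_memberships(X: np.ndarray, centroids: np.ndarray, alpha: float) -> np.ndarray:
    D = np.maximum(
        ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2), _DIST_FLOOR
    )
    power = 1.0 / (alpha - 1.0)
    inv = (1.0 / D) ** power
    return inv / inv.sum(axis=1, keepdims=True)


def init_memberships(
    data: LabeledDataset, K: int, seed: int, alpha: float = 2.0,
    max_iter: int = 300, tol: float = 1e-7,
) -> np.ndarray:
    """Standard FCM on the AD rows, run to convergence from seeded centroids."""
    X = data.X[data.ad_mask]
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of AD subjects ({n})")
    if K == 1:
        return np.ones((n, 1))
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=K, replace=False)]
    m = _fcm_memberships(X, centroids, alpha)
    for _ in range(max_iter):
        Ma = m**alpha
        centroids = (Ma.T @ X) / Ma.sum(axis=0)[:, None]
        m_new = _fcm_memberships(X, centroids, alpha)
        if np.abs(m_new - m).max() < tol:
            return m_new
        m = m_new
    return m


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------

def _as_experts(
    wb: list[tuple[np.ndarray, float]], centroids: np.ndarray
) -> list[ExpertModel]:
    return [ExpertModel(w=w, b=b, d=d) for (w, b), d in zip(wb, centroids)]


def fit_moe(data: LabeledDataset, config: MOEConfig) -> MOEModel:
    """Alternating optimization from FCM initialization, best of n restarts.

    Each sweep runs experts -> centroids -> memberships; every block attains
    its conditional optimum, so the recorded objective trace is
    non-increasing. Convergence is declared when the largest membership
    change falls below ``config.tol``. A dead expert (zero membership mass)
    is re-seeded at the worst-fit AD point up to three times before raising.
    """
    ss = np.random.SeedSequence(config.seed)
    restart_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max(1, config.n_restarts))]
    best: MOEModel | None = None
    first_err: DeadExpertError | None = None
    for rs in restart_seeds:
        try:
            model = _fit_once(data, config, rs)
        except DeadExpertError as err:
            first_err = first_err or err
            continue
        if best is None or model.objective_trace[-1] < best.objective_trace[-1]:
            best = model
    if best is None:
        raise first_err or DeadExpertError("all restarts failed")
    return best


def _fit_once(data: LabeledDataset, config: MOEConfig, seed: int) -> MOEModel:
    m = init_memberships(data, config.K, seed, alpha=config.alpha)
    X_ad = data.X[data.ad_mask]
    trace: list[float] = []
    converged = False
    revive_budget = 3
    experts: list[ExpertModel] = []
    for _ in range(config.max_iter):
        while True:
            try:
                wb = update_experts(data, m, config)
                centroids = update_centroids(data, m, config.alpha)
                break
            except DeadExpertError:
                if revive_budget == 0:
                    raise
                revive_budget -= 1
                m = _revive_dead(data, m, config)
        experts = _as_experts(wb, centroids)
        m_new = update_memberships(data, experts, config)
        trace.append(moe_objective(data, experts, m_new, config))
        delta = np.abs(m_new - m).max()
        m = m_new
        if delta < config.tol:
            converged = True
            break
    if not experts:  # max_iter = 0 degenerate config
        raise ValueError("max_iter must be >= 1")
    return MOEModel(
        experts=experts, memberships=m, objective_trace=trace,
        converged=converged, config=config,
        ad_ids=tuple(np.array(data.ids)[data.ad_mask]),
    )


def _revive_dead(data: LabeledDataset, m: np.ndarray, config: MOEConfig) -> np.ndarray:
    """Re-seed dead experts' centroids at the worst-fit AD points."""
    X_ad = data.X[data.ad_mask]
    mass = m.sum(axis=0)
    dead = np.flatnonzero(mass <= _DEAD_WEIGHT_EPS)
    alive = np.flatnonzero(mass > _DEAD_WEIGHT_EPS)
    if alive.size == 0:
        raise DeadExpertError("no expert retains membership mass")
    Ma = m[:, alive] ** config.alpha
    centroids = np.zeros((m.shape[1], X_ad.shape[1]))
    centroids[alive] = (Ma.T @ X_ad) / Ma.sum(axis=0)[:, None]
    # worst-fit = largest distance to its best current centroid
    best_d = ((X_ad[:, None, :] - centroids[None, alive, :]) ** 2).sum(axis=2).min(axis=1)
    worst = np.argsort(-best_d)
    for j, k in enumerate(dead):
        centroids[k] = X_ad[worst[j % len(worst)]]
    D = np.maximum(
        ((X_ad[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2), _DIST_FLOOR
    )
    inv = 1.0 / D
    return inv / inv.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Prediction and validity indices
# ---------------------------------------------------------------------------

def predict_label(model: MOEModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each row to its nearest-centroid expert, label by its sign.

    A decision value of exactly zero maps to +1; argmin ties resolve to the
    lowest expert index. Returns (labels, expert_indices).
    """
    X = np.atleast_2d(np.asarray(X, float))
    D = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    k_star = D.argmin(axis=1)
    F = np.column_stack([e.decision(X) for e in model.experts])
    vals = F[np.arange(len(X)), k_star]
    labels = np.where(vals >= 0.0, 1, -1)
    return labels, k_star


def cross_validate(
    data: LabeledDataset, config: MOEConfig
) -> tuple[float, float, np.ndarray]:
    """Stratified k-fold accuracy of the full MOE fit; seeded fold split."""
    counts = {c: int((data.y == c).sum()) for c in (-1, 1)}
    if min(counts.values()) < config.cv_folds:
        raise ValueError(
            f"cv_folds={config.cv_folds} exceeds the minority class size {min(counts.values())}"
        )
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(data.X, data.y)):
        if len(np.unique(data.y[te])) < 2 or len(np.unique(data.y[tr])) < 2:
            raise ValueError(f"fold {fold} lacks a class")
        sub = LabeledDataset(
            X=data.X[tr], y=data.y[tr], ids=tuple(np.array(data.ids)[tr])
        )
        fold_cfg = replace(config, seed=config.seed + 1000 + fold)
        model = fit_moe(sub, fold_cfg)
        pred, _ = predict_label(model, data.X[te])
        accs.append(float((pred == data.y[te]).mean()))
    accs = np.array(accs)
    return float(accs.mean()), float(accs.std(ddof=1)), accs


def bezdek_pc(memberships: np.ndarray) -> float:
    """Bezdek partition coefficient (1/N) sum_ik m_ik^2; 1 = crisp, 1/K = fuzzy."""
    m = np.asarray(memberships, float)
    return float((m**2).sum() / m.shape[0])


def pairwise_wr(experts: Sequence[ExpertModel]) -> float:
    """Maximum pairwise inner product of unit-normalized expert weights.

    Returns NaN for a single expert (undefined). Raises for a zero weight
    vector, which signals a degenerate expert.
    """
    if len(experts) < 2:
        return float("nan")
    W = np.vstack([e.w for e in experts])
    norms = np.linalg.norm(W, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"expert {int(np.flatnonzero(norms == 0)[0])} has zero weight vector")
    U = W / norms[:, None]
    G = U @ U.T
    iu = np.triu_indices(len(experts), k=1)
    return float(G[iu].max())


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def grid_search_select(
    data: LabeledDataset,
    config: MOEConfig,
    C_grid: Sequence[float] | None = None,
    t_grid: Sequence[float] | None = None,
    rho_grid: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
) -> ModelSelectionReport:
    """Evaluate Acc, W_r and BPC on the (C, t, rho) grid and select a point.

    Selection is lexicographic: maximum cross-validated accuracy, ties broken
    by minimum W_r, then maximum BPC, then smallest C, t and rho. The full
    table is returned so users can re-select under a different rule.
    """
    C_grid = tuple(C_grid) if C_grid is not None else default_grid()
    t_grid = tuple(t_grid) if t_grid is not None else default_grid()
    if not C_grid or not t_grid or not rho_grid:
        raise ValueError("grid must be non-empty")
    rows = []
    for C in C_grid:
        for t in t_grid:
            for rho in rho_grid:
                cfg = replace(config, C=float(C), t=float(t), class_weight_ratio=float(rho))
                acc_mean, acc_sd, _ = cross_validate(data, cfg)
                model = fit_moe(data, cfg)
                rows.append({
                    "C": float(C), "t": float(t), "rho": float(rho),
                    "acc_mean": acc_mean, "acc_sd": acc_sd,
                    "wr": pairwise_wr(model.experts),
                    "bpc": bezdek_pc(model.memberships),
                })
    table = pd.DataFrame(rows)
    wr_key = table["wr"].fillna(-np.inf)  # K = 1: W_r undefined, never a tie-breaker
    order = np.lexsort((
        table["rho"].values, table["t"].values, table["C"].values,
        -table["bpc"].values, wr_key.values, -table["acc_mean"].values,
    ))
    sel = int(order[0])
    table["selected"] = False
    table.loc[sel, "selected"] = True
    return ModelSelectionReport(table=table, selected=table.loc[sel].to_dict())


# ---------------------------------------------------------------------------
# Model serialization (plain JSON + TSV membership table)
# ---------------------------------------------------------------------------

def save_model(model: MOEModel, path, roi_names: Sequence[str] | None = None) -> None:
    import json
    from dataclasses import asdict

    p = model.experts[0].w.size
    names = list(roi_names) if roi_names is not None else [f"f{i}" for i in range(p)]
    payload = {
        "config": asdict(model.config),
        "converged": model.converged,
        "objective_trace": model.objective_trace,
        "feature_names": names,
        "experts": [
            {"w": e.w.tolist(), "b": e.b, "d": e.d.tolist()} for e in model.experts
        ],
        "ad_ids": list(model.ad_ids),
        "memberships": model.memberships.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> MOEModel:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    experts = [
        ExpertModel(w=np.array(e["w"]), b=float(e["b"]), d=np.array(e["d"]))
        for e in payload["experts"]
    ]
    return MOEModel(
        experts=experts,
        memberships=np.array(payload["memberships"]),
        objective_trace=list(payload["objective_trace"]),
        converged=bool(payload["converged"]),
        config=MOEConfig(**payload["config"]),
        ad_ids=tuple(payload["ad_ids"]),
    )
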