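"""Global sensitivity analysis: LHS perturbation designs and OPLSR.

Parameter sets are drawn by Latin hypercube sampling from the calibrated
ranges, the forward model is run per draw, and an orthogonalized partial
least squares regression (OPLSR) maps the perturbation matrix X
(n x p, z-scored) to a scalar outcome y.  The regression is a univariate
two-latent-variable PLS (NIPALS) followed by a post-hoc rotation of the
two-dimensional score space so that the first latent variable carries
the full explained-y direction; the rotation leaves the fitted subspace
— and hence all predictions — unchanged.

Per-parameter importance is summarized by VIP (variable importance in
projection) scores, normalized so that sum(VIP^2) = p and signed by each
parameter's loading on the rotated LV1 (a presentation convention:
positive VIP means the parameter increases the outcome).  Predictive
power Q^2 = 1 - PRESS/TSS is estimated by 5-fold cross-validation, and
model significance by comparing the cross-validated MSE against models
refit to label-permuted outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .parameters import ParameterRange, ParameterSet, default_parameters, default_ranges
from .placenta import simulate, subclass_entropy

__all__ = [
    "PerturbationDesign",
    "OplsrModel",
    "lhs_design",
    "fit_oplsr",
    "sensitivity_experiment",
    "OUTCOMES",
]

OUTCOMES = ("total_igg", "entropy", "optimal_tvax")


@dataclass(frozen=True)
class PerturbationDesign:
    """LHS draws (n x p) with the ranges and seed that produced them."""

    X: np.ndarray
    names: tuple[str, ...]
    ranges: ParameterRange
    seed: int


def lhs_design(ranges: ParameterRange, n: int, seed: int) -> PerturbationDesign:
    """Uniform stratified Latin hypercube draws over the given ranges.

    Each column's n draws occupy every one of the n equal-probability bins
    exactly once; pairing across columns is random but fully determined by
    ``seed``.
    """
    names = ranges.names
    if n < len(names):
        raise ValueError("need at least as many samples as parameters")
    lo, hi = ranges.as_arrays()
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    X = lo + unit * (hi - lo)
    return PerturbationDesign(X=X, names=names, ranges=ranges, seed=seed)


def _zscore(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (a - mu) / sd, mu, sd


def _pls1(X: np.ndarray, y: np.ndarray, n_lv: int = 2):
    """NIPALS PLS1 on centered/scaled data.

    Returns weights W (p x a), scores T (n x a), X-loadings P (p x a) and
    y-loadings q (a,).
    """
    n, p = X.shape
    Xa = X.copy()
    W = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = Xa.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = Xa @ w
        tt = t @ t
        if tt == 0:
            break
        W[:, a] = w
        T[:, a] = t
        P[:, a] = Xa.T @ t / tt
        q[a] = y @ t / tt
        Xa = Xa - np.outer(t, P[:, a])
    return W, T, P, q


@dataclass
class OplsrModel:
    """Fitted two-latent-variable OPLSR model with importance diagnostics."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    weights: np.ndarray          # rotated W (p x 2)
    scores: np.ndarray           # rotated T (n x 2)
    loadings: np.ndarray         # rotated P (p x 2)
    y_loadings: np.ndarray       # rotated q (2,)
    coef: np.ndarray             # regression vector in z-space (p,)
    vip: np.ndarray              # signed VIP per parameter (p,)
    names: tuple[str, ...]
    q2: float | None = None
    permutation_p: float | None = None
    cv_mse: float | None = None
    n_permutations: int = 0
    y_variance_lv1: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return self.y_mean + self.y_std * (Z @ self.coef)

    def top_vip(self, k: int = 3) -> list[str]:
        order = np.argsort(-np.abs(self.vip))
        return [self.names[i] for i in order[:k]]


def _fit_core(Z: np.ndarray, z_y: np.ndarray):
    """Fit 2-LV PLS1 and rotate so LV1 spans the explained-y direction."""
    W, T, P, q = _pls1(Z, z_y, n_lv=2)
    # Regression vector of the unrotated model (identical after rotation).
    coef = W @ np.linalg.pinv(P.T @ W) @ q
    # Rotate the 2-D latent space so the first rotated component carries
    # all of the explained y variance: first rotated axis ~ q direction.
    qn = np.linalg.norm(q)
    if qn > 0:
        g1 = q / qn
        G = np.column_stack([g1, np.array([-g1[1], g1[0]])])
    else:
        G = np.eye(2)
    return W @ G, T @ G, P @ G, G.T @ q, coef, (W, T, P, q)


def _vip(W: np.ndarray, T: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Standard VIP over the (unrotated) latent variables."""
    p = W.shape[0]
    ss = q**2 * (T * T).sum(axis=0)  # y-variance explained per LV
    wnorm2 = (W * W).sum(axis=0)
    wnorm2 = np.where(wnorm2 > 0, wnorm2, 1.0)
    contrib = (W * W) / wnorm2
    denom = ss.sum()
    if denom == 0:
        return np.zeros(p)
    return np.sqrt(p * (contrib @ ss) / denom)


def _cv_press(X, y, folds, n_lv=2):
    """Held-out squared errors for the printed Q^2 formula."""
    press = 0.0
    for train, test in folds:
        Z, mu, sd = _zscore(X[train])
        ym, ys = y[train].mean(), y[train].std(ddof=1)
        ys = ys if ys > 0 else 1.0
        W, T, P, q = _pls1(Z, (y[train] - ym) / ys, n_lv)
        coef = W @ np.linalg.pinv(P.T @ W) @ q
        pred = ym + ys * (((X[test] - mu) / sd) @ coef)
        press += ((y[test] - pred) ** 2).sum()
    return press


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return [
        (np.setdiff1d(perm, fold, assume_unique=True), fold)
        for fold in np.array_split(perm, k)
    ]


def fit_oplsr(
    X: np.ndarray,
    y: np.ndarray,
    names: tuple[str, ...] | None = None,
    n_lv: int = 2,
    cv_folds: int = 5,
    n_permutations: int = 1000,
    seed: int = 0,
) -> OplsrModel:
    """Fit the 2-LV OPLSR model with cross-validated Q^2 and permutation p.

    Q^2 = 1 - sum_i (y_i - f'(x_i))^2 / sum_i (y_i - y_bar)^2 over held-out
    5-fold predictions.  The permutation p-value is the fraction of models
    refit to shuffled outcomes whose cross-validated MSE is at most the
    real model's (ties count against the model).  Fully deterministic
    given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, p) and y (n,)")
    if np.ptp(y) == 0:
        raise ValueError("outcome vector is constant")
    names = tuple(names) if names is not None else tuple(
        f"x{j}" for j in range(X.shape[1])
    )

    Z, mu, sd = _zscore(X)
    ym, ys = y.mean(), y.std(ddof=1)
    z_y = (y - ym) / ys
    Wr, Tr, Pr, qr, coef, (W, T, P, q) = _fit_core(Z, z_y)

    vip = _vip(W, T, q)
    # Presentation sign: orient each VIP along the parameter's LV1 loading.
    sign = np.sign(Pr[:, 0] * np.sign(qr[0] if qr[0] != 0 else 1.0))
    vip_signed = vip * np.where(sign == 0, 1.0, sign)

    ss_y = (z_y @ z_y)
    y_var_lv1 = float((qr[0] ** 2) * (Tr[:, 0] @ Tr[:, 0]) / ss_y) if ss_y > 0 else None

    rng = np.random.default_rng(seed)
    folds = _kfold_indices(X.shape[0], cv_folds, rng)
    press = _cv_press(X, y, folds, n_lv)
    tss = ((y - y.mean()) ** 2).sum()
    q2 = 1.0 - press / tss
    cv_mse = press / X.shape[0]

    perm_p = None
    if n_permutations > 0:
        hits = 0
        for _ in range(n_permutations):
            y_perm = rng.permutation(y)
            perm_folds = _kfold_indices(X.shape[0], cv_folds, rng)
            perm_mse = _cv_press(X, y_perm, perm_folds, n_lv) / X.shape[0]
            if perm_mse <= cv_mse:
                hits += 1
        perm_p = hits / n_permutations

    return OplsrModel(
        x_mean=mu, x_std=sd, y_mean=ym, y_std=ys,
        weights=Wr, scores=Tr, loadings=Pr, y_loadings=qr, coef=coef,
        vip=vip_signed, names=names, q2=q2, permutation_p=perm_p,
        cv_mse=cv_mse, n_permutations=n_permutations,
        y_variance_lv1=y_var_lv1,
    )


def _outcome_total_igg(p: ParameterSet, rtol: float) -> float:
    return float(simulate(p, rtol=rtol).total_fetal()[-1])


def _outcome_entropy(p: ParameterSet, rtol: float) -> float:
    return subclass_entropy(simulate(p, rtol=rtol).fetal_at_end())


def _outcome_optimal_tvax(p: ParameterSet, rtol: float) -> float:
    from .vaccine import optimize_tvax
    return optimize_tvax(p_placenta=p, rtol=rtol)["optimal_tvax"]


_OUTCOME_FN = {
    "total_igg": _outcome_total_igg,
    "entropy": _outcome_entropy,
    "optimal_tvax": _outcome_optimal_tvax,
}


def sensitivity_experiment(
    outcome: str = "total_igg",
    ranges: ParameterRange | None = None,
    n: int = 1000,
    seed: int = 0,
    base: ParameterSet | None = None,
    n_permutations: int = 1000,
    rtol: float = 1e-8,
    max_failed_fraction: float = 0.05,
    design: PerturbationDesign | None = None,
    outcomes_vector: np.ndarray | None = None,
) -> dict:
    """LHS-perturb the free parameters, run the forward model, fit OPLSR.

    Rows whose simulation fails (or yields a non-finite outcome) are
    dropped pairwise from X and y; more than ``max_failed_fraction``
    failures aborts the experiment.  A precomputed ``design`` (and
    optionally its ``outcomes_vector``) can be supplied to share one set
    of forward runs across several outcome models.
    """
    if outcome not in _OUTCOME_FN:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    ranges = default_ranges() if ranges is None else ranges
    base = default_parameters() if base is None else base
    if design is None:
        design = lhs_design(ranges, n, seed)
    fn = _OUTCOME_FN[outcome]

    if outcomes_vector is None:
        ys = np.full(design.X.shape[0], np.nan)
        for i, row in enumerate(design.X):
            p = base.with_free_values(dict(zip(design.names, row)))
            try:
                ys[i] = fn(p, rtol)
            except Exception:
                pass
    else:
        ys = np.asarray(outcomes_vector, dtype=float)

    ok = np.isfinite(ys)
    n_failed = int((~ok).sum())
    if n_failed > max_failed_fraction * ys.size:
        raise RuntimeError(f"{n_failed} of {ys.size} forward runs failed")
    model = fit_oplsr(
        design.X[ok], ys[ok], names=design.names,
        n_permutations=n_permutations, seed=design.seed,
    )
    return {
        "outcome": outcome,
        "design": design,
        "y": ys,
        "model": model,
        "n_effective": int(ok.sum()),
        "n_failed": n_failed,
    }
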