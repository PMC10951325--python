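"""Penalized-spline additive modeling with REML smoothness selection.

This is the numerical engine behind the bias surface and the seasonal
detrender.  It implements Gaussian penalized least squares

    min_beta ||y - X beta||^2 + sum_j lambda_j beta' S_j beta

over a design assembled from unpenalized blocks (intercept, categorical
dummies) and smooth blocks: cubic B-spline bases with second-order
difference penalties (P-splines), their cyclic counterparts, and an
isotropically penalized tensor product of two marginal bases.  Smoothing
parameters are chosen by maximizing the Gaussian restricted likelihood
(REML), profiled over the error variance.

Every smooth block carries a sum-to-zero constraint (its fitted values
average to zero over the training data), which makes the intercept and the
partial effects identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space


# ---------------------------------------------------------------------------
# Bases and penalties
# ---------------------------------------------------------------------------

def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _cyclic_difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.zeros((k, k))
    for i in range(k):
        d[i, i] = 1.0
        d[i, (i + 1) % k] = -2.0
        d[i, (i + 2) % k] = 1.0
    return d.T @ d


def bspline_design(x: np.ndarray, k: int, lo: float, hi: float,
                   degree: int = 3) -> np.ndarray:
    """Open (clamped) uniform B-spline basis with ``k`` functions on [lo, hi]."""
    if k < degree + 1:
        raise ValueError(f"need at least {degree + 1} basis functions")
    if hi <= lo:
        raise ValueError("upper bound must exceed lower bound")
    inner = np.linspace(lo, hi, k - degree + 1)
    t = np.concatenate([[lo] * degree, inner, [hi] * degree])
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    # keep x strictly inside the last knot so the end basis evaluates
    x = np.minimum(x, hi - 1e-10 * max(1.0, abs(hi)))
    return BSpline.design_matrix(x, t, degree).toarray()


def cyclic_bspline_design(x: np.ndarray, k: int, x0: float,
                          period: float) -> np.ndarray:
    """Periodic cubic B-spline basis: ``k`` wrapped uniform B-splines.

    f(x) built on this basis satisfies f(x0) = f(x0 + period) with continuous
    first and second derivatives across the wrap point.
    """
    if k < 4:
        raise ValueError("cyclic basis needs k >= 4")
    h = period / k
    t = x0 + h * np.arange(-3, k + 4)
    u = np.mod(np.asarray(x, dtype=float) - x0, period) + x0
    u = np.minimum(u, x0 + period - 1e-9 * period)
    b = BSpline.design_matrix(u, t, 3).toarray()  # k + 3 columns
    out = b[:, :k].copy()
    out[:, :3] += b[:, k:k + 3]
    return out


@dataclass
class SmoothSpec:
    """Recipe for one smooth block: basis builder + penalty + constraint."""

    name: str
    kind: str                       # "bs" | "cyclic" | "tensor"
    k: int | tuple[int, int]
    bounds: tuple                   # (lo, hi) or ((lo1, hi1), (lo2, hi2))
    period: Optional[float] = None  # cyclic only
    # filled in at build time:
    constraint: np.ndarray = field(default=None, repr=False)
    Z: np.ndarray = field(default=None, repr=False)
    S: np.ndarray = field(default=None, repr=False)
    rank: int = 0
    log_pdet: float = 0.0

    def raw_basis(self, *cols) -> np.ndarray:
        if self.kind == "bs":
            return bspline_design(cols[0], self.k, *self.bounds)
        if self.kind == "cyclic":
            return cyclic_bspline_design(cols[0], self.k, self.bounds[0], self.period)
        if self.kind == "tensor":
            (k1, k2) = self.k
            b1 = bspline_design(cols[0], k1, *self.bounds[0])
            b2 = bspline_design(cols[1], k2, *self.bounds[1])
            return (b1[:, :, None] * b2[:, None, :]).reshape(len(b1), k1 * k2)
        raise ValueError(self.kind)

    def raw_penalty(self) -> np.ndarray:
        if self.kind == "bs":
            return _difference_penalty(self.k)
        if self.kind == "cyclic":
            return _cyclic_difference_penalty(self.k)
        if self.kind == "tensor":
            (k1, k2) = self.k
            s1, s2 = _difference_penalty(k1), _difference_penalty(k2)
            # isotropic: both directions share one smoothing parameter
            return np.kron(s1, np.eye(k2)) + np.kron(np.eye(k1), s2)
        raise ValueError(self.kind)

    def build(self, *cols) -> np.ndarray:
        """Constrained training basis; caches constraint and penalty."""
        b = self.raw_basis(*cols)
        c = b.mean(axis=0)
        self.constraint = c
        self.Z = null_space(c[None, :])
        x = b @ self.Z
        s = self.Z.T @ self.raw_penalty() @ self.Z
        s = 0.5 * (s + s.T)
        eig = np.linalg.eigvalsh(s)
        tol = max(eig.max(), 1.0) * 1e-10
        pos = eig[eig > tol]
        self.S = s
        self.rank = len(pos)
        self.log_pdet = float(np.sum(np.log(pos)))
        return x

    def predict_basis(self, *cols) -> np.ndarray:
        """Constrained basis at new points (training constraint reapplied)."""
        if self.Z is None:
            raise RuntimeError("build() must run before predict_basis()")
        return self.raw_basis(*cols) @ self.Z


# ---------------------------------------------------------------------------
# The additive model
# ---------------------------------------------------------------------------

@dataclass
class FittedAdditiveModel:
    """Penalized least-squares fit with REML-selected smoothing parameters."""

    beta: np.ndarray
    cov: np.ndarray                    # Bayesian posterior covariance of beta
    sigma2: float
    lambdas: dict
    blocks: dict                       # name -> (start, stop) slice bounds
    smooths: dict                      # name -> SmoothSpec
    edf: dict
    rss: float
    deviance_explained: float
    n: int
    reml: float
    term_p_values: dict = field(default_factory=dict)

    def block_beta(self, name: str) -> np.ndarray:
        i, j = self.blocks[name]
        return self.beta[i:j]

    def block_cov(self, name: str) -> np.ndarray:
        i, j = self.blocks[name]
        return self.cov[i:j, i:j]

    def smooth_values(self, name: str, *cols,
                      with_ci: bool = False):
        """Centered partial contribution of one smooth at new points."""
        xg = self.smooths[name].predict_basis(*cols)
        f = xg @ self.block_beta(name)
        if not with_ci:
            return f
        v = np.einsum("ij,jk,ik->i", xg, self.block_cov(name), xg)
        half = 1.96 * np.sqrt(np.maximum(v, 0.0))
        return f, f - half, f + half


def fit_additive_model(
    y: np.ndarray,
    linear_blocks: Sequence[tuple[str, np.ndarray]],
    smooth_blocks: Sequence[tuple[SmoothSpec, tuple]],
    max_iter: int = 400,
) -> FittedAdditiveModel:
    """Fit y ~ linear blocks + constrained smooths, REML smoothing selection.

    ``linear_blocks`` are (name, design) pairs fitted without penalty (pass
    the intercept explicitly).  ``smooth_blocks`` are (spec, columns) pairs
    where columns are the raw predictor vectors the spec's basis consumes.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    parts, blocks, smooths = [], {}, {}
    pos = 0
    for name, xb in linear_blocks:
        xb = np.atleast_2d(np.asarray(xb, dtype=float))
        if xb.shape[0] != n:
            xb = xb.T
        parts.append(xb)
        blocks[name] = (pos, pos + xb.shape[1])
        pos += xb.shape[1]
    pen_embeds, pen_meta = [], []
    for spec, cols in smooth_blocks:
        xb = spec.build(*cols)
        parts.append(xb)
        blocks[spec.name] = (pos, pos + xb.shape[1])
        smooths[spec.name] = spec
        pen_meta.append((spec.name, pos, pos + xb.shape[1], spec))
        pos += xb.shape[1]
    X = np.hstack(parts)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"n = {n} too small for {p} coefficients")
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    for name, i, j, spec in pen_meta:
        emb = np.zeros((p, p))
        # tiny proportional ridge keeps the system well-posed when the data
        # cannot identify the penalty's null space (e.g. near-collinear sites
        # under the tensor surface); negligible at 1e-7 of the penalty scale
        eig_max = max(np.linalg.eigvalsh(spec.S).max(), 1e-12)
        emb[i:j, i:j] = spec.S + 1e-7 * eig_max * np.eye(j - i)
        pen_embeds.append(emb)

    total_rank = sum(spec.rank for _, _, _, spec in pen_meta)
    mp = p - total_rank  # dimension of the unpenalized coefficient space

    def solve_for(log_lams):
        lams = np.exp(np.clip(log_lams, -18.0, 25.0))
        A = XtX.copy()
        for lam, emb in zip(lams, pen_embeds):
            A += lam * emb
        jitter = 1e-10 * np.trace(XtX) / p
        for _ in range(12):
            try:
                c, low = cho_factor(A)
                break
            except np.linalg.LinAlgError:
                A = A + jitter * np.eye(p)
                jitter *= 10.0
        else:
            raise np.linalg.LinAlgError("design is rank deficient")
        beta = cho_solve((c, low), Xty)
        rss = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
        rss = max(rss, 1e-300)
        pen = 0.0
        for lam, emb in zip(lams, pen_embeds):
            pen += lam * (beta @ emb @ beta)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
        return lams, (c, low), beta, rss, pen, logdet_A

    def neg2_reml(log_lams):
        lams, _, beta, rss, pen, logdet_A = solve_for(log_lams)
        logdet_S = sum(
            spec.rank * np.log(lam) + spec.log_pdet
            for lam, (_, _, _, spec) in zip(lams, pen_meta)
        )
        sigma2 = (rss + pen) / (n - mp)
        return ((n - mp) * (np.log(2.0 * np.pi * sigma2) + 1.0)
                + logdet_A - logdet_S)

    if pen_meta:
        x0 = np.zeros(len(pen_meta))
        res = optimize.minimize(neg2_reml, x0, method="Nelder-Mead",
                                options={"maxiter": max_iter, "xatol": 1e-3,
                                         "fatol": 1e-6})
        log_lams = res.x
        reml_val = float(res.fun)
    else:
        log_lams = np.zeros(0)
        reml_val = float("nan")

    lams, chol, beta, rss, pen, _ = solve_for(log_lams)
    sigma2 = (rss + pen) / (n - mp)
    Ainv_XtX = cho_solve(chol, XtX)
    Ainv = cho_solve(chol, np.eye(p))
    cov = sigma2 * 0.5 * (Ainv + Ainv.T)
    edf = {name: float(np.trace(Ainv_XtX[i:j, i:j]))
           for name, (i, j) in blocks.items()}
    ybar = y.mean()
    tss = float(np.sum((y - ybar) ** 2))
    dev_expl = 1.0 - rss / tss if tss > 0 else 0.0
    lambdas = {name: float(lam) for lam, (name, _, _, _) in zip(lams, pen_meta)}

    # Approximate Wald tests per block (reference distribution chi^2 with
    # rounded edf); reported for orientation only.
    p_values = {}
    for name, (i, j) in blocks.items():
        b = beta[i:j]
        v = cov[i:j, i:j]
        vinv = np.linalg.pinv(v, rcond=1e-10)
        statv = float(b @ vinv @ b)
        df = max(1.0, round(edf[name]))
        p_values[name] = float(stats.chi2.sf(statv, df))

    return FittedAdditiveModel(
        beta=beta, cov=cov, sigma2=float(sigma2), lambdas=lambdas,
        blocks=blocks, smooths=smooths, edf=edf, rss=float(rss),
        deviance_explained=float(np.clip(dev_expl, 0.0, 1.0)), n=n,
        reml=reml_val, term_p_values=p_values,
    )


def fit_cyclic_smooth(x: np.ndarray, y: np.ndarray, k: int = 10,
                      x0: float = 1.0, period: float = 365.0):
    """Convenience: intercept + one cyclic smooth of x (e.g. day of year).

    Returns (fitted model, predict function f(x_new) -> fitted values).
    """
    x = np.asarray(x, dtype=float)
    spec = SmoothSpec(name="cycle", kind="cyclic", k=k,
                      bounds=(x0, x0 + period), period=period)
    fit = fit_additive_model(
        y,
        linear_blocks=[("intercept", np.ones((len(x), 1)))],
        smooth_blocks=[(spec, (x,))],
    )

    def predict(x_new):
        x_new = np.asarray(x_new, dtype=float)
        return (fit.block_beta("intercept")[0]
                + fit.smooth_values("cycle", x_new))

    return fit, predict
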