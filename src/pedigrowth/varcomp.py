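"""Maximum-likelihood variance decomposition on pedigrees.

The phenotypic covariance among colony members is modelled as

    Omega = 2*Phi*sigma2_g + H*sigma2_c + I*sigma2_e

where Phi is the kinship matrix (so 2*Phi scales the additive polygenic
component), H is the 0/1 maternal-household matrix (common maternal
environment, c2) and I the identity (individual environment).  Narrow-sense
heritability is h2 = sigma2_g / (sigma2_g + sigma2_c + sigma2_e) and the
maternal share c2 = sigma2_c / total.  Fixed covariate effects beta are
profiled out by generalised least squares at every trial point, and the
residual variance sigma2_e is profiled analytically, leaving a low-
dimensional optimisation over variance ratios.  Variance components are
constrained non-negative; estimates on the zero boundary are flagged, and
the likelihood-ratio test for a single variance component uses the
half-and-half chi2_0/chi2_1 boundary mixture.

A probit liability-threshold model for binary traits (chronic obesity) is
provided via a Laplace approximation over the latent polygenic vector, with
the residual liability variance fixed to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "VarianceComponentModel",
    "VarianceComponentResults",
    "PolygenicModel",
    "LiabilityThresholdModel",
    "CovariateDesign",
    "lrt_variance_component",
    "screen_covariates",
]

_RATIO_MAX = 1e4  # upper bound on sigma2_k / sigma2_e during optimisation
_BOUNDARY_TOL = 1e-6


def _as_2d(X, n):
    if X is None:
        return np.ones((n, 1)), ["const"]
    if isinstance(X, CovariateDesign):
        return X.X.to_numpy(dtype=float), list(X.X.columns)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


class VarianceComponentModel:
    """Linear mixed model y = X beta + sum_k u_k + e with cov(u_k) = sigma2_k K_k.

    Parameters
    ----------
    y : (n,) response (continuous; inverse-normal transform upstream).
    X : (n, p) fixed-effect design (default: intercept only).
    kernels : mapping of component name -> (n, n) PSD covariance kernel,
        e.g. ``{"additive": 2*phi, "household": H}``.
    """

    def __init__(self, y, X=None, kernels=None, ids=None, eig=None):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        self.X, self.xnames = _as_2d(X, n)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix X is rank deficient")
        self.kernels = dict(kernels or {})
        for name, K in self.kernels.items():
            K = np.asarray(K, dtype=float)
            if K.shape != (n, n):
                raise ValueError(f"kernel {name!r} has shape {K.shape}, expected {(n, n)}")
            self.kernels[name] = K
        self.ids = list(ids) if ids is not None else None
        self.nobs = n
        # (w, U) eigendecomposition of the single kernel may be supplied to
        # amortise the O(n^3) factorisation across many fits (e.g. replicate
        # simulations on a fixed pedigree)
        if eig is not None and len(self.kernels) == 1:
            w, U = eig
            self._eig = (np.clip(np.asarray(w, float), 0.0, None),
                         U.T @ self.y, U.T @ self.X)
        else:
            self._eig = None

    # -- likelihood --------------------------------------------------------

    def _profiled(self, V):
        """GLS beta, ML sigma2_e and loglik for V = I + sum r_k K_k."""
        n = self.nobs
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Xi = linalg.cho_solve((c, low), self.X, check_finite=False)
        yi = linalg.cho_solve((c, low), self.y, check_finite=False)
        XtVX = self.X.T @ Xi
        beta = np.linalg.solve(XtVX, Xi.T @ self.y)
        resid = self.y - self.X @ beta
        rss = float(resid @ linalg.cho_solve((c, low), resid, check_finite=False))
        sigma2_e = max(rss / n, 1e-12)
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2_e) + logdet + n)
        return beta, sigma2_e, ll, XtVX

    def _neg_ll_ratios(self, r):
        V = np.eye(self.nobs)
        for rk, K in zip(r, self.kernels.values()):
            V += rk * K
        try:
            return -self._profiled(V)[2]
        except np.linalg.LinAlgError:
            return 1e12

    def loglik(self, variances: dict, sigma2_e: float, beta=None):
        """Exact multivariate-normal log-likelihood at given variances.

        Used directly by grid-search oracles; ``beta`` defaults to the GLS
        estimate at these variances.
        """
        n = self.nobs
        Omega = sigma2_e * np.eye(n)
        for name, s2 in variances.items():
            Omega += s2 * self.kernels[name]
        c, low = linalg.cho_factor(Omega, lower=True, check_finite=False)
        if beta is None:
            Xi = linalg.cho_solve((c, low), self.X, check_finite=False)
            beta = np.linalg.solve(self.X.T @ Xi, Xi.T @ self.y)
        resid = self.y - self.X @ beta
        quad = float(resid @ linalg.cho_solve((c, low), resid, check_finite=False))
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)

    # -- fitting -----------------------------------------------------------

    def fit(self, start=None) -> "VarianceComponentResults":
        names = list(self.kernels)
        if not names:
            beta, s2e, ll, XtVX = self._profiled(np.eye(self.nobs))
            return self._results({}, s2e, beta, ll, XtVX, converged=True)
        if len(names) == 1:
            r = self._fit_single_kernel()
            converged = True
        else:
            r, converged = self._fit_multi(start)
        V = np.eye(self.nobs)
        for rk, K in zip(r, self.kernels.values()):
            V += rk * K
        beta, s2e, ll, XtVX = self._profiled(V)
        variances = {name: float(rk * s2e) for name, rk in zip(names, r)}
        return self._results(variances, s2e, beta, ll, XtVX, converged)

    def _fit_single_kernel(self):
        # eigen-rotation: V = I + r K has eigenvalues 1 + r w in the basis of K
        if self._eig is None:
            K = next(iter(self.kernels.values()))
            w, U = np.linalg.eigh(K)
            self._eig = (np.clip(w, 0.0, None), U.T @ self.y, U.T @ self.X)
        w, yt, Xt = self._eig
        n = self.nobs

        def neg_ll_t(t):
            r = t / (1.0 - t) if t < 1.0 else _RATIO_MAX
            d = 1.0 + r * w
            Xd = Xt / d[:, None]
            XtVX = Xt.T @ Xd
            try:
                beta = np.linalg.solve(XtVX, Xd.T @ yt)
            except np.linalg.LinAlgError:
                return 1e12
            resid = yt - Xt @ beta
            rss = float(resid @ (resid / d))
            s2e = max(rss / n, 1e-300)
            return 0.5 * (n * np.log(2 * np.pi * s2e) + np.sum(np.log(d)) + n)

        grid = np.linspace(0.0, 0.999, 41)
        vals = [neg_ll_t(t) for t in grid]
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(neg_ll_t, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        t = res.x if res.fun <= vals[i] else grid[i]
        return [t / (1.0 - t)]

    def _fit_multi(self, start):
        k = len(self.kernels)
        if start is not None:
            # a warm start (e.g. from the nested null fit) makes the extra
            # cold restart redundant
            starts = [np.asarray(start, dtype=float), np.full(k, 0.5)]
        else:
            starts = [np.full(k, 0.5), np.full(k, 0.05)]
        best = None
        for s0 in starts:
            res = optimize.minimize(
                self._neg_ll_ratios,
                np.clip(s0, 0.0, _RATIO_MAX),
                method="L-BFGS-B",
                bounds=[(0.0, _RATIO_MAX)] * k,
                options={"ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        return best.x, bool(best.success)

    def _results(self, variances, sigma2_e, beta, ll, XtVX, converged):
        beta_cov = sigma2_e * np.linalg.inv(XtVX)
        return VarianceComponentResults(
            model=self,
            variances=variances,
            sigma2_e=float(sigma2_e),
            beta=np.asarray(beta, dtype=float),
            beta_cov=beta_cov,
            loglik=float(ll),
            converged=converged,
        )


@dataclass
class VarianceComponentResults:
    """ML estimates of a pedigree variance-component model."""

    model: VarianceComponentModel
    variances: dict
    sigma2_e: float
    beta: np.ndarray
    beta_cov: np.ndarray
    loglik: float
    converged: bool
    _vc_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def total_variance(self) -> float:
        return self.sigma2_e + sum(self.variances.values())

    def share(self, name: str) -> float:
        return self.variances.get(name, 0.0) / self.total_variance

    @property
    def h2(self) -> float:
        """Narrow-sense heritability (share of the 'additive' component)."""
        return self.share("additive")

    @property
    def c2(self) -> float:
        """Maternal-household share of the phenotypic variance."""
        return self.share("household")

    def boundary(self, name: str) -> bool:
        return self.variances.get(name, 0.0) <= _BOUNDARY_TOL * self.total_variance

    @property
    def identifiable(self) -> bool:
        """False when a genetic kernel is (near-)identity, so the split of
        sigma2_g vs sigma2_e carries no information."""
        for K in self.model.kernels.values():
            off = K - np.diag(np.diag(K))
            if np.abs(off).max() < 1e-10:
                return False
        return True

    # -- uncertainty -------------------------------------------------------

    def _vc_covariance(self) -> np.ndarray:
        """Observed-information covariance of (sigma2_k..., sigma2_e)."""
        if self._vc_cov is not None:
            return self._vc_cov
        names = list(self.variances)
        theta = np.array([self.variances[n] for n in names] + [self.sigma2_e])
        scale = max(self.total_variance, 1e-8)

        def ll_at(th):
            var = {n: max(v, 0.0) for n, v in zip(names, th[:-1])}
            return self.model.loglik(var, max(th[-1], 1e-10))

        m = theta.size
        H = np.zeros((m, m))
        h = np.maximum(1e-4 * scale, 1e-3 * np.abs(theta))
        f0 = ll_at(theta)
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = h[i]
                ej = np.zeros(m); ej[j] = h[j]
                try:
                    if i == j:
                        H[i, i] = (ll_at(theta + ei) - 2 * f0 + ll_at(theta - ei)) / h[i] ** 2
                    else:
                        H[i, j] = H[j, i] = (
                            ll_at(theta + ei + ej) - ll_at(theta + ei - ej)
                            - ll_at(theta - ei + ej) + ll_at(theta - ei - ej)
                        ) / (4 * h[i] * h[j])
                except np.linalg.LinAlgError:
                    H[i, j] = H[j, i] = np.nan
        try:
            cov = np.linalg.pinv(-H)
        except np.linalg.LinAlgError:
            cov = np.full((m, m), np.nan)
        self._vc_cov = cov
        return cov

    def se_share(self, name: str) -> float:
        """Delta-method SE of a variance share (h2 or c2)."""
        names = list(self.variances)
        if name not in names:
            return np.nan
        cov = self._vc_covariance()
        theta = np.array([self.variances[n] for n in names] + [self.sigma2_e])
        tot = theta.sum()
        i = names.index(name)
        grad = np.full(theta.size, -theta[i] / tot**2)
        grad[i] += 1.0 / tot
        var = float(grad @ cov @ grad)
        return np.sqrt(var) if var > 0 else np.nan

    @property
    def se_h2(self) -> float:
        return self.se_share("additive")

    @property
    def se_c2(self) -> float:
        return self.se_share("household")

    def wald_beta(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.beta_cov))
        z = self.beta / se
        return pd.DataFrame(
            {"coef": self.beta, "se": se, "z": z, "p": 2 * stats.norm.sf(np.abs(z))},
            index=self.model.xnames,
        )

    def summary(self) -> str:
        lines = [
            "Variance-component model (ML)",
            f"  n obs: {self.nobs}    loglik: {self.loglik:.4f}    converged: {self.converged}",
            f"  sigma2_e: {self.sigma2_e:.5f}",
        ]
        for name, v in self.variances.items():
            flag = "  [boundary]" if self.boundary(name) else ""
            lines.append(
                f"  sigma2_{name}: {v:.5f}  share: {self.share(name):.4f}"
                f" (SE {self.se_share(name):.4f}){flag}"
            )
        lines.append("  Fixed effects:")
        lines.append(self.wald_beta().to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def PolygenicModel(y, X=None, phi=None, hmat=None, ids=None) -> VarianceComponentModel:
    """Polygenic model with kinship Phi and optional maternal-household matrix.

    Builds ``VarianceComponentModel`` with kernels additive=2*Phi and, when
    ``hmat`` is given, household=H.
    """
    if phi is None:
        raise ValueError("phi (kinship matrix) is required")
    kernels = {"additive": 2.0 * np.asarray(phi, dtype=float)}
    if hmat is not None:
        kernels["household"] = np.asarray(hmat, dtype=float)
    return VarianceComponentModel(y, X, kernels, ids=ids)


def lrt_variance_component(fit_full, fit_reduced, component: str | None = None) -> float:
    """Boundary LRT p-value for one variance component fixed at zero.

    p = 0.5 * P(chi2_1 >= Lambda), the half-half chi2_0/chi2_1 mixture for a
    variance tested on its boundary; Lambda < 0 is clipped to 0 (p = 0.5).
    """
    if component is not None and component in getattr(fit_reduced, "variances", {}):
        raise ValueError(f"reduced fit still contains component {component!r}; not nested")
    lam = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    return float(0.5 * stats.chi2.sf(lam, 1))


# ---------------------------------------------------------------------------
# covariate design and screening


class CovariateDesign:
    """Named fixed-effect design with intercept, factors and interactions.

    ``terms`` maps a term name to its column block; interaction terms
    ("a*b") are elementwise products of their parents' columns.
    """

    def __init__(self, X: pd.DataFrame, terms: dict[str, list[str]]):
        self.X = X
        self.terms = terms

    @property
    def names(self) -> list[str]:
        return [t for t in self.terms if t != "const"]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, main: list[str], interactions: list[str] = (),
                       categorical: list[str] = ()) -> "CovariateDesign":
        cols = {"const": pd.Series(1.0, index=df.index, name="const")}
        terms: dict[str, list[str]] = {"const": ["const"]}
        blocks: dict[str, pd.DataFrame] = {}
        for name in main:
            if name in categorical:
                dummies = pd.get_dummies(df[name].astype("category"), prefix=name,
                                         drop_first=True, dtype=float)
            else:
                dummies = df[[name]].astype(float)
            blocks[name] = dummies
            terms[name] = list(dummies.columns)
            for c in dummies.columns:
                cols[c] = dummies[c]
        for inter in interactions:
            a, b = inter.split("*")
            prod_cols = []
            for ca in terms[a]:
                for cb in terms[b]:
                    name = f"{ca}*{cb}"
                    cols[name] = cols[ca] * cols[cb]
                    prod_cols.append(name)
            terms[inter] = prod_cols
        X = pd.DataFrame(cols)
        # drop exactly-collinear columns (keep first occurrence)
        keep = _independent_columns(X.to_numpy(dtype=float))
        kept = [c for i, c in enumerate(X.columns) if i in keep]
        X = X[kept]
        terms = {t: [c for c in cs if c in X.columns] for t, cs in terms.items()}
        terms = {t: cs for t, cs in terms.items() if cs}
        return cls(X, terms)

    def drop_term(self, name: str) -> "CovariateDesign":
        cols = self.terms[name]
        X = self.X.drop(columns=cols)
        terms = {t: c for t, c in self.terms.items() if t != name}
        return CovariateDesign(X, terms)


def _independent_columns(A: np.ndarray, tol: float = 1e-8) -> set[int]:
    keep: list[int] = []
    for j in range(A.shape[1]):
        cand = A[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol) == len(keep) + 1:
            keep.append(j)
    return set(keep)


def screen_covariates(y, design: CovariateDesign, phi, hmat=None, alpha: float = 0.05):
    """Backward elimination of covariate terms under the polygenic model.

    Repeatedly drops the candidate term with the largest Wald p-value above
    ``alpha``; main effects are retained while any of their interactions
    survive (hierarchy rule).  Exact p ties drop the later-listed term.
    Returns the reduced CovariateDesign.
    """
    current = design
    while True:
        fit = PolygenicModel(y, current, phi=phi, hmat=hmat).fit()
        pvals = _term_wald_p(fit, current)
        droppable = [
            t for t in current.names
            if not any("*" in o and t in o.split("*") for o in current.names)
        ]
        worst, worst_p = None, alpha
        for t in droppable:  # later-listed wins ties via >=
            if pvals[t] >= worst_p:
                worst, worst_p = t, pvals[t]
        if worst is None:
            return current
        current = current.drop_term(worst)


def _term_wald_p(fit: VarianceComponentResults, design: CovariateDesign) -> dict[str, float]:
    cols = list(design.X.columns)
    out = {}
    for term, tcols in design.terms.items():
        if term == "const":
            continue
        idx = [cols.index(c) for c in tcols]
        b = fit.beta[idx]
        C = fit.beta_cov[np.ix_(idx, idx)]
        try:
            w = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError:
            w = 0.0
        out[term] = float(stats.chi2.sf(w, len(idx)))
    return out


# ---------------------------------------------------------------------------
# liability-threshold model for binary traits


class LiabilityThresholdModel:
    """Probit liability model with a polygenic random effect.

    Latent liability l = X beta + g + e with g ~ N(0, 2*Phi*sigma2_g) and
    e ~ N(0, 1); the observed trait is y = 1 iff l > 0 (the intercept plays
    the role of the prevalence threshold).  The marginal likelihood is
    approximated by a Laplace approximation over the latent polygenic
    vector; heritability is reported on the liability scale,
    h2 = sigma2_g / (sigma2_g + 1).
    """

    def __init__(self, y, X=None, phi=None, ids=None):
        self.y = np.asarray(y, dtype=float)
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        if self.y.min() == self.y.max():
            raise ValueError("both classes must be present")
        n = self.y.size
        self.X, self.xnames = _as_2d(X, n)
        if phi is None:
            raise ValueError("phi (kinship matrix) is required")
        self.A = 2.0 * np.asarray(phi, dtype=float)
        off = self.A - np.diag(np.diag(self.A))
        self.identifiable = bool(np.abs(off).max() > 1e-10)
        self.ids = list(ids) if ids is not None else None
        self.nobs = n
        # A may be numerically semi-definite; ridge for the inverse
        self._Ainv = np.linalg.inv(self.A + 1e-8 * np.eye(n))
        self._s = 2.0 * self.y - 1.0

    # Laplace log-likelihood for given beta, sigma2_g (residual var fixed 1)
    def _laplace_ll(self, beta, sigma2_g, g0=None):
        n = self.nobs
        s = self._s
        xb = self.X @ beta
        if sigma2_g < 1e-8:
            return float(np.sum(stats.norm.logcdf(s * xb))), np.zeros(n)
        Sinv = self._Ainv / sigma2_g
        g = np.zeros(n) if g0 is None else g0.copy()
        for _ in range(50):
            eta = xb + g
            z = s * eta
            lam = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
            grad = s * lam - Sinv @ g
            W = lam * (lam + z)  # -d2/deta2 log Phi(s eta), >= 0
            Hess = Sinv + np.diag(W)
            try:
                step = np.linalg.solve(Hess, grad)
            except np.linalg.LinAlgError:
                return -1e12, g
            g_new = g + step
            if np.max(np.abs(step)) < 1e-8:
                g = g_new
                break
            g = g_new
        eta = xb + g
        z = s * eta
        lam = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
        W = lam * (lam + z)
        M = np.eye(n) + (self.A * sigma2_g) * W[None, :]
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return -1e12, g
        ll = float(np.sum(stats.norm.logcdf(z)) - 0.5 * g @ (Sinv @ g) - 0.5 * logdet)
        return ll, g

    def fit(self, maxiter: int = 300) -> "LiabilityResults":
        from scipy.optimize import minimize

        # initialise beta at the plain probit solution
        res0 = minimize(
            lambda b: -float(np.sum(stats.norm.logcdf(self._s * (self.X @ b)))),
            np.zeros(self.X.shape[1]),
            method="BFGS",
        )
        beta0 = res0.x
        ll_null = -res0.fun
        state = {"g": None}

        def neg_ll(params):
            beta, zeta = params[:-1], params[-1]
            sigma2_g = float(np.exp(np.clip(zeta, -12.0, 6.0)))
            ll, g = self._laplace_ll(beta, sigma2_g, state["g"])
            state["g"] = g
            return -ll

        p0 = np.concatenate([beta0, [0.0]])  # sigma2_g starts at 1 (h2 = 0.5)
        res = minimize(neg_ll, p0, method="Nelder-Mead",
                       options={"maxiter": maxiter * (len(p0)), "xatol": 1e-5, "fatol": 1e-7})
        beta = res.x[:-1]
        sigma2_g = float(np.exp(np.clip(res.x[-1], -12.0, 6.0)))
        ll = -res.fun
        lam = max(0.0, 2.0 * (ll - ll_null))
        p_h2 = float(0.5 * stats.chi2.sf(lam, 1))
        h2 = sigma2_g / (sigma2_g + 1.0)
        # profile-likelihood SE on the zeta scale, delta method to h2
        zeta = np.log(max(sigma2_g, 1e-12))
        hstep = 0.3
        llp = -neg_ll(np.concatenate([beta, [zeta + hstep]]))
        llm = -neg_ll(np.concatenate([beta, [zeta - hstep]]))
        d2 = (llp - 2 * ll + llm) / hstep**2
        if d2 < 0:
            se_zeta = np.sqrt(-1.0 / d2)
            se_h2 = se_zeta * sigma2_g / (sigma2_g + 1.0) ** 2
        else:
            se_h2 = np.nan
        boundary = sigma2_g < 1e-4 or not self.identifiable
        return LiabilityResults(
            model=self, beta=beta, sigma2_g=sigma2_g, h2=h2, se_h2=se_h2,
            loglik=ll, loglik_null=ll_null, p_h2=p_h2,
            converged=bool(res.success), boundary=boundary,
        )


@dataclass
class LiabilityResults:
    model: LiabilityThresholdModel
    beta: np.ndarray
    sigma2_g: float
    h2: float
    se_h2: float
    loglik: float
    loglik_null: float
    p_h2: float
    converged: bool
    boundary: bool

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def summary(self) -> str:
        return (
            "Liability-threshold model (Laplace ML)\n"
            f"  n obs: {self.nobs}    prevalence: {self.model.y.mean():.3f}\n"
            f"  h2 (liability): {self.h2:.4f} (SE {self.se_h2:.4f})  p = {self.p_h2:.4g}\n"
            f"  loglik: {self.loglik:.4f}  (null probit: {self.loglik_null:.4f})\n"
            f"  boundary: {self.boundary}   converged: {self.converged}"
        )
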