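"""Logistic growth curves and nonlinear mixed-effects (NLME) estimation.

Size at age t follows the three-parameter logistic

    S(t) = theta1 / (1 + exp(-(theta2 + theta3 * t)))

where theta1 is the adult asymptote (trait units), theta3 the growth-rate
constant (1/years) and theta2 a dimensionless offset such that half of adult
size is reached at the midpoint -theta2/theta3 (years); biologically valid
fits have theta2 < 0.  Growth groups (sex x heavy/light cluster) are fitted
independently; within a group every subject carries a random deviation b_i on
all three parameters,

    y_ij = S(t_ij; theta + b_i) + e_ij,   b_i ~ N(0, Sigma_b),  e ~ N(0, s2),

estimated by maximising the Laplace-approximated marginal likelihood with a
nested scheme: an inner penalised Gauss-Newton solve for each subject's mode
b_i (vectorised across subjects) and an outer derivative-free search over the
fixed effects and (log) variance parameters, initialised from a two-stage
per-subject nonlinear least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

__all__ = [
    "GrowthParams",
    "logistic_size",
    "LogisticGrowthME",
    "GrowthResults",
    "fit_quality",
]


@dataclass(frozen=True)
class GrowthParams:
    """theta1: asymptote (trait units); theta2: offset; theta3: rate (1/yr)."""

    theta1: float
    theta2: float
    theta3: float

    @property
    def midpoint(self) -> float:
        """Age at which half of adult size is reached, -theta2/theta3 (years)."""
        return -self.theta2 / self.theta3

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3], dtype=float)


def logistic_size(t, p: GrowthParams | np.ndarray):
    """S(t) = theta1 * expit(theta2 + theta3 * t); overflow-safe."""
    th = p.as_array() if isinstance(p, GrowthParams) else np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    return th[0] * expit(th[1] + th[2] * t)


def _logistic_jac(t, th):
    """Jacobian of S wrt (theta1, theta2, theta3); rows match t."""
    u = expit(th[1] + th[2] * t)
    dudeta = u * (1.0 - u)
    return np.column_stack([u, th[0] * dudeta, th[0] * dudeta * t])


def _subject_nls(t, y, init):
    """Per-subject nonlinear least squares; falls back to init on failure."""
    def resid(th):
        return logistic_size(t, th) - y

    try:
        res = optimize.least_squares(
            resid, init, bounds=([1e-3, -50.0, 1e-3], [np.inf, 5.0, 50.0]),
            method="trf", max_nfev=200,
        )
        return res.x
    except Exception:
        return np.asarray(init, dtype=float)


class LogisticGrowthME:
    """NLME logistic growth model for one (sex, cluster) group.

    Parameters
    ----------
    data : DataFrame with columns ``id``, ``age`` (years) and ``value``
        (trait units); unmatched/missing ages across subjects are allowed.
    group : optional label, e.g. ``("F", "heavy")``.
    min_measures : subjects with fewer observations are rejected.
    """

    def __init__(self, data: pd.DataFrame, group=None, min_measures: int = 6):
        df = data.dropna(subset=["age", "value"]).copy()
        counts = df.groupby("id")["age"].count()
        bad = counts[counts < min_measures]
        if len(bad):
            raise ValueError(
                f"{len(bad)} subject(s) have fewer than {min_measures} measures: "
                f"{list(bad.index[:5])}"
            )
        df = df.sort_values(["id", "age"])
        self.group = group
        self.ids = list(counts.index)
        self.sub_idx = df["id"].map({s: i for i, s in enumerate(self.ids)}).to_numpy()
        self.t = df["age"].to_numpy(dtype=float)
        self.y = df["value"].to_numpy(dtype=float)
        self.n_subjects = len(self.ids)
        self.nobs = self.t.size

    # -- initial values ----------------------------------------------------

    def _default_init(self) -> np.ndarray:
        theta1 = float(np.percentile(self.y, 95))
        half = theta1 / 2.0
        # age at which the pooled data first crosses half of adult size
        order = np.argsort(self.t)
        above = self.y[order] >= half
        mid = float(self.t[order][above][0]) if above.any() else float(np.median(self.t))
        mid = max(mid, 0.1)
        theta3 = 1.5
        return np.array([theta1, -mid * theta3, theta3])

    def _two_stage(self, init):
        per = np.empty((self.n_subjects, 3))
        for i in range(self.n_subjects):
            m = self.sub_idx == i
            per[i] = _subject_nls(self.t[m], self.y[m], init)
        fixed0 = np.median(per, axis=0)
        sd0 = np.maximum(np.std(per, axis=0), 1e-3 * np.maximum(np.abs(fixed0), 1.0))
        resid = self._resid_from_subject(per)
        s0 = max(float(np.std(resid)), 1e-4)
        return fixed0, sd0, s0, per

    def _resid_from_subject(self, per):
        th = per[self.sub_idx]
        pred = th[:, 0] * expit(th[:, 1] + th[:, 2] * self.t)
        return self.y - pred

    # -- Laplace machinery -------------------------------------------------

    def _inner_modes(self, theta, sd_b, sigma2, b, n_iter=25):
        """Penalised Gauss-Newton for all subjects' modes, vectorised.

        Returns (b, penalised objective per subject, logdet of the Laplace
        Hessian per subject).
        """
        m = self.n_subjects
        prec = 1.0 / sd_b**2  # diagonal Sigma_b^-1
        lam = np.full(m, 1e-3)  # Levenberg damping per subject
        f = self._penalised(theta, prec, sigma2, b)
        for _ in range(n_iter):
            th = theta[None, :] + b
            ths = th[self.sub_idx]
            u = expit(ths[:, 1] + ths[:, 2] * self.t)
            pred = ths[:, 0] * u
            r = self.y - pred
            du = ths[:, 0] * u * (1 - u)
            J = np.column_stack([u, du, du * self.t])  # (N, 3)
            # accumulate J'J and J'r per subject
            JTJ = np.zeros((m, 3, 3))
            JTr = np.zeros((m, 3))
            JJ = J[:, :, None] * J[:, None, :]
            np.add.at(JTJ, self.sub_idx, JJ)
            np.add.at(JTr, self.sub_idx, J * r[:, None])
            grad = JTr / sigma2 - prec[None, :] * b
            H = JTJ / sigma2
            H[:, np.arange(3), np.arange(3)] += prec[None, :] * (1.0 + lam[:, None])
            try:
                step = np.linalg.solve(H, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                H[:, np.arange(3), np.arange(3)] += 1e-6
                step = np.linalg.solve(H, grad[..., None])[..., 0]
            b_new = b + step
            f_new = self._penalised(theta, prec, sigma2, b_new)
            improved = f_new <= f + 1e-12
            b = np.where(improved[:, None], b_new, b)
            f = np.where(improved, f_new, f)
            lam = np.where(improved, lam * 0.5, lam * 4.0)
            if not improved.any() or np.max(np.abs(step[improved])) < 1e-10:
                break
        # Laplace Hessian (Gauss-Newton) at the modes, undamped
        th = theta[None, :] + b
        ths = th[self.sub_idx]
        u = expit(ths[:, 1] + ths[:, 2] * self.t)
        du = ths[:, 0] * u * (1 - u)
        J = np.column_stack([u, du, du * self.t])
        JTJ = np.zeros((m, 3, 3))
        np.add.at(JTJ, self.sub_idx, J[:, :, None] * J[:, None, :])
        H = JTJ / sigma2
        H[:, np.arange(3), np.arange(3)] += prec[None, :]
        sign, logdet = np.linalg.slogdet(H)
        logdet = np.where(sign > 0, logdet, np.inf)
        return b, f, logdet

    def _penalised(self, theta, prec, sigma2, b):
        th = theta[None, :] + b
        ths = th[self.sub_idx]
        pred = ths[:, 0] * expit(ths[:, 1] + ths[:, 2] * self.t)
        r = self.y - pred
        rss = np.zeros(self.n_subjects)
        np.add.at(rss, self.sub_idx, r * r)
        return rss / (2.0 * sigma2) + 0.5 * np.sum(prec[None, :] * b**2, axis=1)

    def _laplace_ll(self, params, state):
        theta = params[:3]
        sd_b = np.exp(np.clip(params[3:6], -12.0, 8.0))
        sigma2 = float(np.exp(np.clip(2.0 * params[6], -24.0, 16.0)))
        if theta[0] <= 0 or theta[2] <= 0:
            return -1e12
        b, f, logdet = self._inner_modes(theta, sd_b, sigma2, state["b"])
        state["b"] = b
        n_i = np.bincount(self.sub_idx, minlength=self.n_subjects)
        ll = np.sum(
            -0.5 * n_i * np.log(2 * np.pi * sigma2)
            - np.sum(np.log(sd_b))
            - f
            - 0.5 * logdet
        )
        return float(ll) if np.isfinite(ll) else -1e12

    # -- fitting -----------------------------------------------------------

    def fit(self, init: GrowthParams | None = None, maxiter: int = 2000,
            seed: int | None = None) -> "GrowthResults":
        """Maximise the Laplace-approximated marginal likelihood."""
        init0 = init.as_array() if init is not None else self._default_init()
        fixed0, sd0, s0, per = self._two_stage(init0)
        state = {"b": np.clip(per - fixed0[None, :], -5 * sd0, 5 * sd0)}
        p0 = np.concatenate([fixed0, np.log(sd0), [np.log(s0)]])

        def neg(params):
            return -self._laplace_ll(params, state)

        res = optimize.minimize(
            neg, p0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8, "adaptive": True},
        )
        theta = res.x[:3]
        sd_b = np.exp(np.clip(res.x[3:6], -12.0, 8.0))
        sigma2 = float(np.exp(2.0 * res.x[6]))
        b, _, _ = self._inner_modes(theta, sd_b, sigma2, state["b"], n_iter=50)
        subject_params = {
            sid: GrowthParams(*(theta + b[i])) for i, sid in enumerate(self.ids)
        }
        boundary = bool(np.any(sd_b < 1e-5 * np.maximum(np.abs(theta), 1.0)))
        return GrowthResults(
            model=self,
            group=self.group,
            fixed=GrowthParams(*theta),
            re_cov=np.diag(sd_b**2),
            resid_var=sigma2,
            subject_effects={sid: b[i].copy() for i, sid in enumerate(self.ids)},
            subject_params=subject_params,
            loglik=-res.fun,
            converged=bool(res.success),
            boundary=boundary,
        )


@dataclass
class GrowthResults:
    """Fitted NLME logistic growth model for one group."""

    model: LogisticGrowthME
    group: object
    fixed: GrowthParams
    re_cov: np.ndarray
    resid_var: float
    subject_effects: dict
    subject_params: dict
    loglik: float
    converged: bool
    boundary: bool

    def extract_subject_params(self) -> dict:
        """Per-subject growth parameters: fixed effects + predicted b_i."""
        return dict(self.subject_params)

    def predict(self, ids, ages) -> np.ndarray:
        out = np.empty(len(ages), dtype=float)
        ages = np.asarray(ages, dtype=float)
        for k, (sid, t) in enumerate(zip(ids, ages)):
            out[k] = logistic_size(t, self.subject_params[sid])
        return out

    def subject_table(self) -> pd.DataFrame:
        rows = []
        for sid, p in self.subject_params.items():
            rows.append({
                "id": sid, "theta1": p.theta1, "theta2": p.theta2,
                "theta3": p.theta3, "midpoint": p.midpoint,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        f = self.fixed
        sds = np.sqrt(np.diag(self.re_cov))
        return (
            f"Logistic growth NLME{f' [{self.group}]' if self.group else ''}\n"
            f"  subjects: {self.model.n_subjects}   observations: {self.model.nobs}\n"
            f"  fixed: theta1={f.theta1:.4f}  theta2={f.theta2:.4f}  "
            f"theta3={f.theta3:.4f}  midpoint={f.midpoint:.4f} yr\n"
            f"  random-effect SD: ({sds[0]:.4f}, {sds[1]:.4f}, {sds[2]:.4f})  "
            f"resid SD: {np.sqrt(self.resid_var):.4f}\n"
            f"  loglik: {self.loglik:.4f}   converged: {self.converged}"
            f"{'   [variance boundary]' if self.boundary else ''}"
        )

    def to_json_dict(self) -> dict:
        return {
            "group": list(self.group) if isinstance(self.group, tuple) else self.group,
            "fixed": {"theta1": self.fixed.theta1, "theta2": self.fixed.theta2,
                      "theta3": self.fixed.theta3, "midpoint": self.fixed.midpoint},
            "re_cov": self.re_cov.tolist(),
            "resid_var": self.resid_var,
            "loglik": self.loglik,
            "converged": self.converged,
            "subjects": {str(k): [p.theta1, p.theta2, p.theta3]
                         for k, p in self.subject_params.items()},
        }


def fit_quality(fit: GrowthResults, data: pd.DataFrame | None = None) -> tuple[float, float]:
    """Pearson r between observed and subject-predicted values.

    ``r_dev`` is restricted to the developmental window (ages below the
    group midpoint + 2/theta3); ``r_life`` covers all ages.
    """
    model = fit.model
    if data is None:
        ids = [model.ids[i] for i in model.sub_idx]
        t, y = model.t, model.y
    else:
        d = data.dropna(subset=["age", "value"])
        ids, t, y = list(d["id"]), d["age"].to_numpy(float), d["value"].to_numpy(float)
    pred = fit.predict(ids, t)
    cutoff = fit.fixed.midpoint + 2.0 / fit.fixed.theta3
    dev = t <= cutoff
    if dev.sum() < 3 or len(t) < 3:
        raise ValueError("fewer than 3 points in a correlation window")
    r_dev = float(np.corrcoef(y[dev], pred[dev])[0, 1])
    r_life = float(np.corrcoef(y, pred)[0, 1])
    return r_dev, r_life
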