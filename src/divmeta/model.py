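"""Multilevel random-effects meta-regression fitted by REML.

The marginal model for a vector of effects y (SMD or lnCVR) is

    y = X beta + u_study + u_genus + u_experiment + e,   e ~ N(0, V)

with V the sampling variance-covariance matrix (shared-control blocks),
exchangeable random intercepts for study and host genus, and a
compound-symmetry experiment level: comparisons from the same experiment share
correlation rho within an experiment-level variance tau2_experiment.  The
marginal covariance is

    Sigma = V + tau2_s Z_s Z_s' + tau2_g Z_g Z_g'
              + tau2_e [(1 - rho) I + rho Z_e Z_e']

Variance components are estimated by maximising the restricted log-likelihood

    l_R = -1/2 [ ln|Sigma| + ln|X' Sigma^-1 X| + r' Sigma^-1 r + (k-p) ln 2 pi ]

with r = y - X beta_GLS, beta_GLS = (X' Sigma^-1 X)^-1 X' Sigma^-1 y, using a
bounded quasi-Newton search on the log-variance scale with dispersed starts.
Wald (z) inference is the default, matching standard meta-analytic practice.

The estimator follows scikit-learn conventions (``fit``, ``get_params``,
fitted attributes with trailing underscores); :func:`fit_reml` and friends are
thin functional wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import ComparisonRecord, EffectSize, MODERATOR_LEVELS, ValidationError
from .effects import SamplingCovariance, build_vcv

_Z975 = scipy.stats.norm.ppf(0.975)
_RANDOM_LEVELS = ("study", "genus", "experiment")
_TAU2_FLOOR = 1e-10


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge after multi-start."""


# ---------------------------------------------------------------------------
# model specification and fit container


@dataclass
class ModelSpec:
    """What to fit: effect kind, fixed moderator terms, random structure."""

    effect_kind: str = "SMD"
    fixed_terms: tuple[str, ...] = ()
    random_levels: tuple[str, ...] = ("study", "genus", "experiment")
    vcv_mode: str = "fixed_r"
    vcv_r: float = 0.5

    def __post_init__(self) -> None:
        self.fixed_terms = tuple(self.fixed_terms)
        self.random_levels = tuple(self.random_levels)
        for lvl in self.random_levels:
            if lvl not in _RANDOM_LEVELS:
                raise ValidationError(f"unknown random level {lvl!r}")
        for term in self.fixed_terms:
            for name in term.split(":"):
                if name not in MODERATOR_LEVELS:
                    raise ValidationError(f"unknown moderator {name!r} in fixed term")


@dataclass
class MetaFit:
    """A fitted multilevel meta-regression."""

    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    coef_names: list[str]
    tau2: dict[str, float]
    rho_exp: float
    k: int
    loglik_reml: float
    ci: np.ndarray  # (p, 2) 95% Wald intervals
    prediction_intervals: np.ndarray  # (p, 2)
    i2: dict[str, float]  # per level, percent, plus "total"
    i2_alternative: dict[str, float]  # share of summed tau2 only
    typical_sampling_variance: float
    converged: bool
    grad_norm: float
    spec: Optional[ModelSpec] = None
    zval: np.ndarray = field(default=None)  # type: ignore[assignment]
    pval: np.ndarray = field(default=None)  # type: ignore[assignment]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "z": self.zval,
                "p": self.pval,
                "ci.lb": self.ci[:, 0],
                "ci.ub": self.ci[:, 1],
                "pi.lb": self.prediction_intervals[:, 0],
                "pi.ub": self.prediction_intervals[:, 1],
            },
            index=self.coef_names,
        )


@dataclass
class ContrastResult:
    estimate: float
    se: float
    z: float
    p: float
    contrast_vector: np.ndarray
    p_holm: Optional[float] = None
    name: str = ""


# ---------------------------------------------------------------------------
# design matrix


def _effects_to_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    rows = []
    for e in effects:
        row = {
            "comparison_id": e.comparison_id,
            "study_id": e.study_id,
            "experiment_id": e.experiment_id,
            "host_genus": e.host_genus,
            "value": e.value,
            "variance": e.variance,
            "shared_control_key": e.shared_control_key,
        }
        row.update(e.moderators)
        rows.append(row)
    return pd.DataFrame(rows)


def build_design(data: pd.DataFrame, fixed_terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Cell-means design: the first term gets a dummy per observed level
    (no intercept, as in subgroup/orchard parameterisations); subsequent terms
    are treatment-coded against their first observed level."""
    k = len(data)
    if not fixed_terms:
        return np.ones((k, 1)), ["intercept"]

    def term_levels(term: str) -> tuple[pd.Series, list[str]]:
        names = term.split(":")
        for nm in names:
            if nm not in data.columns:
                raise ValidationError(f"moderator column {nm!r} missing from data")
        if len(names) == 1:
            col = data[names[0]].astype(str)
            known = [l for l in MODERATOR_LEVELS[names[0]] if l in set(col)]
            labels = [f"{names[0]}={l}" for l in known]
            return col.map({l: f"{names[0]}={l}" for l in known}), labels
        combo = data[names[0]].astype(str)
        lab = names[0] + "="
        combined = lab + combo
        for nm in names[1:]:
            combined = combined + ":" + nm + "=" + data[nm].astype(str)
        order: list[str] = []
        for lev0 in MODERATOR_LEVELS[names[0]]:
            for rest in sorted(set(combined[combo == lev0])):
                if rest not in order:
                    order.append(rest)
        return combined, order

    cols: list[np.ndarray] = []
    names_out: list[str] = []
    for t, term in enumerate(fixed_terms):
        assigned, labels = term_levels(term)
        use = labels if t == 0 else labels[1:]
        for lab in use:
            cols.append((assigned == lab).to_numpy(dtype=float))
            names_out.append(lab)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        aliased = [names_out[i] for i in piv[rank:]]
        raise ValidationError(f"rank-deficient design; aliased columns: {aliased}")
    return X, names_out


# ---------------------------------------------------------------------------
# REML machinery (block-diagonal aware)


class _Structure:
    """Precomputed pieces for fast repeated evaluation of the REML objective."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        V: np.ndarray,
        groups: dict[str, np.ndarray],
        levels: tuple[str, ...],
    ) -> None:
        self.y, self.X, self.V = y, X, V
        self.k, self.p = X.shape
        self.levels = levels
        self.groups = groups
        # connected components of "possibly correlated" -> block diagonal Sigma
        adj = np.abs(V) > 0
        for lvl in levels:
            g = groups[lvl]
            adj = adj | (g[:, None] == g[None, :])
        self.blocks = self._components(adj)
        sizes = sorted({len(b) for b in self.blocks})
        self.dense = len(self.blocks) == 1 or max(sizes) > 64
        if not self.dense:
            self.batches = []
            for s in sizes:
                idx = np.array([b for b in self.blocks if len(b) == s])  # (B, s)
                Vb = V[idx[:, :, None], idx[:, None, :]]
                masks = {
                    lvl: (groups[lvl][idx][:, :, None] == groups[lvl][idx][:, None, :]).astype(float)
                    for lvl in levels
                }
                self.batches.append(
                    dict(idx=idx, V=Vb, masks=masks, X=X[idx], y=y[idx], I=np.eye(s))
                )
        # masks for the dense path
        self.masks_dense = {
            lvl: (groups[lvl][:, None] == groups[lvl][None, :]).astype(float) for lvl in levels
        }

    @staticmethod
    def _components(adj: np.ndarray) -> list[list[int]]:
        n = adj.shape[0]
        seen = np.zeros(n, dtype=bool)
        comps = []
        for i in range(n):
            if seen[i]:
                continue
            stack, comp = [i], []
            seen[i] = True
            while stack:
                j = stack.pop()
                comp.append(j)
                nbrs = np.nonzero(adj[j] & ~seen)[0]
                seen[nbrs] = True
                stack.extend(nbrs.tolist())
            comps.append(sorted(comp))
        return comps

    def sigma_dense(self, tau2: dict[str, float], rho: float) -> np.ndarray:
        S = self.V.copy()
        for lvl in self.levels:
            t = tau2.get(lvl, 0.0)
            if lvl == "experiment":
                S += t * ((1.0 - rho) * np.eye(self.k) + rho * self.masks_dense[lvl])
            else:
                S += t * self.masks_dense[lvl]
        return S

    def reml_nll(self, tau2: dict[str, float], rho: float) -> tuple[float, np.ndarray, np.ndarray]:
        """Negative restricted log-likelihood; also returns beta and cov_beta."""
        p = self.p
        if self.dense:
            S = self.sigma_dense(tau2, rho)
            try:
                L = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                return np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            Xs = scipy.linalg.solve_triangular(L, self.X, lower=True)
            ys = scipy.linalg.solve_triangular(L, self.y, lower=True)
            XtSiX = Xs.T @ Xs
            XtSiy = Xs.T @ ys
            yty = ys @ ys
        else:
            logdet = 0.0
            XtSiX = np.zeros((p, p))
            XtSiy = np.zeros(p)
            yty = 0.0
            for b in self.batches:
                S = b["V"].copy()
                for lvl in self.levels:
                    t = tau2.get(lvl, 0.0)
                    if lvl == "experiment":
                        S += t * ((1.0 - rho) * b["I"] + rho * b["masks"][lvl])
                    else:
                        S += t * b["masks"][lvl]
                try:
                    Lb = np.linalg.cholesky(S)
                except np.linalg.LinAlgError:
                    return np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
                logdet += 2.0 * np.log(np.diagonal(Lb, axis1=1, axis2=2)).sum()
                Sx = np.linalg.solve(S, b["X"])
                Sy = np.linalg.solve(S, b["y"][..., None])[..., 0]
                XtSiX += np.einsum("bij,bik->jk", b["X"], Sx)
                XtSiy += np.einsum("bij,bi->j", b["X"], Sy)
                yty += float(np.einsum("bi,bi->", b["y"], Sy))
        sign, logdet2 = np.linalg.slogdet(XtSiX)
        if sign <= 0:
            return np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
        cov_beta = np.linalg.inv(XtSiX)
        beta = cov_beta @ XtSiy
        quad = yty - XtSiy @ beta
        ll = -0.5 * (logdet + logdet2 + quad + (self.k - p) * math.log(2.0 * math.pi))
        return -ll, beta, cov_beta


def _typical_sampling_variance(variances: Sequence[float]) -> float:
    """Higgins-Thompson 'typical' within-study variance used in I^2."""
    v = np.asarray(variances, dtype=float)
    k = v.size
    if k < 2:
        raise ValidationError("typical sampling variance needs k >= 2")
    w = 1.0 / v
    return float((k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))


# ---------------------------------------------------------------------------
# estimator


class MultilevelMetaRegression(BaseEstimator):
    """Three-level random-effects meta-regression (REML, Wald-z inference).

    Parameters
    ----------
    fixed_terms : tuple of str
        Moderator terms.  Empty fits an intercept-only (overall-effect) model;
        a single name fits level means for that moderator (no intercept); a
        colon term like ``"parasite_genetic_diversity:host_range"`` fits cell
        means of the interaction.
    random_levels : tuple of str
        Any of ``"study"``, ``"genus"``, ``"experiment"``.
    estimate_rho : bool
        Estimate the within-experiment correlation (compound symmetry).  Only
        meaningful when the experiment level is active and some experiment
        carries more than one comparison; otherwise rho is held at 0.
    fix_tau2 : dict or None
        Map level -> fixed variance value (e.g. ``{"study": 0.0}``) excluded
        from estimation.
    fix_rho : float or None
        Hold rho at a fixed value.
    n_starts : int
        Number of dispersed starting points for the bounded quasi-Newton
        search on the log-variance scale.
    vcv_mode, vcv_r : str, float
        How to build the sampling VCV when one is not supplied to ``fit``.
    """

    def __init__(
        self,
        fixed_terms: tuple[str, ...] = (),
        random_levels: tuple[str, ...] = ("study", "genus", "experiment"),
        estimate_rho: bool = True,
        fix_tau2: Optional[dict[str, float]] = None,
        fix_rho: Optional[float] = None,
        n_starts: int = 5,
        polish: bool = True,
        vcv_mode: str = "fixed_r",
        vcv_r: float = 0.5,
    ) -> None:
        self.fixed_terms = fixed_terms
        self.random_levels = random_levels
        self.estimate_rho = estimate_rho
        self.fix_tau2 = fix_tau2
        self.fix_rho = fix_rho
        self.n_starts = n_starts
        self.polish = polish
        self.vcv_mode = vcv_mode
        self.vcv_r = vcv_r

    # -- data marshalling ---------------------------------------------------

    def _marshal(
        self,
        X: Union[Sequence[EffectSize], pd.DataFrame],
        vcv: Optional[SamplingCovariance],
    ) -> tuple[pd.DataFrame, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            data = X.reset_index(drop=True).copy()
            if vcv is None:
                V = np.diag(data["variance"].to_numpy(dtype=float))
            else:
                V = vcv.matrix
        else:
            effects = list(X)
            data = _effects_to_frame(effects)
            if vcv is None:
                has_shared = any(e.shared_control_key is not None for e in effects)
                if has_shared:
                    vcv = build_vcv(effects, mode=self.vcv_mode, r=self.vcv_r)
                    V = vcv.matrix
                else:
                    V = np.diag(data["variance"].to_numpy(dtype=float))
            else:
                V = vcv.matrix
        if vcv is not None and list(vcv.ordering) and "comparison_id" in data:
            want = list(data["comparison_id"].astype(str))
            if list(map(str, vcv.ordering)) != want:
                V = vcv.reorder(want).matrix
        if V.shape[0] != len(data):
            raise ValidationError("VCV dimension does not match number of effects")
        return data, V

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, vcv: Optional[SamplingCovariance] = None):
        data, V = self._marshal(X, vcv)
        yv = data["value"].to_numpy(dtype=float)
        Xd, names = build_design(data, list(self.fixed_terms))
        k, p = Xd.shape
        fixed_all = set(self.fix_tau2 or {}) >= set(self.random_levels)
        min_k = p if fixed_all or not self.random_levels else p + 1
        if k < min_k:
            raise ValidationError(
                f"k={k} effects cannot identify {p} coefficients"
                + ("" if min_k == p else " plus heterogeneity")
            )

        group_cols = {"study": "study_id", "genus": "host_genus", "experiment": "experiment_id"}
        groups = {}
        for lvl in self.random_levels:
            col = group_cols[lvl]
            if col not in data:
                raise ValidationError(f"column {col!r} required for random level {lvl!r}")
            groups[lvl] = pd.factorize(data[col].astype(str))[0]

        fixed = dict(self.fix_tau2 or {})
        free_levels = [lvl for lvl in self.random_levels if lvl not in fixed]
        # rho identifiable only with a multi-comparison experiment
        rho_active = (
            "experiment" in self.random_levels
            and self.fix_rho is None
            and self.estimate_rho
            and "experiment" in groups
            and np.unique(groups["experiment"]).size < k
            and "experiment" not in fixed
        )
        rho_fixed = 0.0 if self.fix_rho is None else float(self.fix_rho)

        struct = _Structure(yv, Xd, V, groups, tuple(self.random_levels))

        s2 = max(float(np.var(yv)), float(np.mean(np.diag(V))), 1e-6)
        ub = max(10.0 * s2, 1.0)
        lo, hi = math.log(_TAU2_FLOOR), math.log(ub)

        def unpack(params: np.ndarray) -> tuple[dict[str, float], float]:
            tau2 = dict(fixed)
            for i, lvl in enumerate(free_levels):
                tau2[lvl] = math.exp(params[i])
            rho = params[len(free_levels)] if rho_active else rho_fixed
            return tau2, float(rho)

        def nll(params: np.ndarray) -> float:
            tau2, rho = unpack(params)
            return struct.reml_nll(tau2, rho)[0]

        n_free = len(free_levels) + (1 if rho_active else 0)
        if n_free == 0:
            tau2, rho = dict(fixed), rho_fixed
            f, beta, cov_beta = struct.reml_nll(tau2, rho)
            best_x = np.empty(0)
            converged, grad_norm = True, 0.0
        else:
            bounds = [(lo, hi)] * len(free_levels) + ([(0.0, 0.999)] if rho_active else [])
            fracs = [0.3, 0.02, 1.0, 0.1, 3.0]
            starts = []
            for f0 in fracs[: max(1, self.n_starts)]:
                x0 = np.full(len(free_levels), math.log(max(f0 * s2, 1e-8)))
                if rho_active:
                    x0 = np.append(x0, 0.5)
                starts.append(np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]))
            best = None
            for x0 in starts:
                res = scipy.optimize.minimize(
                    nll, x0, method="L-BFGS-B", bounds=bounds,
                    options=dict(ftol=1e-13, gtol=1e-9, maxiter=500),
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
            assert best is not None
            if not np.isfinite(best.fun):
                raise ConvergenceError("REML objective not finite at any candidate optimum")
            best_x = best.x
            if self.polish:
                # coordinate-wise Brent refinement: tightens the optimum past
                # the quasi-Newton stopping rule on flat likelihood surfaces
                cur = float(best.fun)
                for _ in range(2):
                    for i in range(n_free):
                        blo, bhi = bounds[i]
                        span = 0.5 if i < len(free_levels) else 0.25

                        def f1(xi: float, i=i) -> float:
                            xt = best_x.copy()
                            xt[i] = xi
                            return nll(xt)

                        res1 = scipy.optimize.minimize_scalar(
                            f1,
                            bounds=(max(blo, best_x[i] - span), min(bhi, best_x[i] + span)),
                            method="bounded",
                            options=dict(xatol=1e-10),
                        )
                        if res1.fun <= cur:
                            best_x[i] = float(res1.x)
                            cur = float(res1.fun)
            tau2, rho = unpack(best_x)
            f, beta, cov_beta = struct.reml_nll(tau2, rho)
            grad_norm = float(np.linalg.norm(best.jac)) if best.jac is not None else np.nan
            converged = bool(best.success)

        tau2 = {lvl: (0.0 if t < 10 * _TAU2_FLOOR else float(t)) for lvl, t in tau2.items()}
        se = np.sqrt(np.diag(cov_beta))
        zval = beta / se
        pval = 2.0 * scipy.stats.norm.sf(np.abs(zval))
        ci = np.column_stack([beta - _Z975 * se, beta + _Z975 * se])
        tau2_sum = float(sum(tau2.values()))
        pi_half = _Z975 * np.sqrt(se**2 + tau2_sum)
        pis = np.column_stack([beta - pi_half, beta + pi_half])

        vdiag = np.diag(V)
        if k >= 2:
            vbar = _typical_sampling_variance(vdiag)
            denom = tau2_sum + vbar
            i2 = {lvl: 100.0 * tau2[lvl] / denom if denom > 0 else 0.0 for lvl in tau2}
            i2["total"] = float(sum(v for l, v in i2.items() if l != "total"))
            alt = {
                lvl: (100.0 * tau2[lvl] / tau2_sum if tau2_sum > 0 else 0.0) for lvl in tau2
            }
        else:
            vbar = float("nan")
            i2 = {lvl: float("nan") for lvl in tau2}
            i2["total"] = float("nan")
            alt = dict(i2)

        self.data_ = data
        self.X_ = Xd
        self.coef_names_ = names
        self.beta_ = beta
        self.se_ = se
        self.cov_beta_ = cov_beta
        self.tau2_ = tau2
        self.rho_ = rho
        self.k_ = k
        self.loglik_ = float(-f)
        self.converged_ = converged
        self.result_ = MetaFit(
            beta=beta,
            se=se,
            cov_beta=cov_beta,
            coef_names=names,
            tau2=tau2,
            rho_exp=rho,
            k=k,
            loglik_reml=float(-f),
            ci=ci,
            prediction_intervals=pis,
            i2=i2,
            i2_alternative=alt,
            typical_sampling_variance=vbar,
            converged=converged,
            grad_norm=grad_norm,
            spec=ModelSpec(
                fixed_terms=tuple(self.fixed_terms), random_levels=tuple(self.random_levels)
            ),
            zval=zval,
            pval=pval,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Model-implied mean effect for rows of moderator values."""
        if not hasattr(self, "beta_"):
            raise ValidationError("estimator is not fitted")
        if not self.fixed_terms:
            return np.full(len(X), self.beta_[0])
        Xd, names = build_design(pd.DataFrame(X), list(self.fixed_terms))
        aligned = np.zeros((Xd.shape[0], len(self.coef_names_)))
        for j, nm in enumerate(names):
            if nm not in self.coef_names_:
                raise ValidationError(f"unseen design column {nm!r}")
            aligned[:, self.coef_names_.index(nm)] = Xd[:, j]
        return aligned @ self.beta_


# ---------------------------------------------------------------------------
# functional surface


def fit_reml(
    effects: Union[Sequence[EffectSize], pd.DataFrame],
    vcv: Optional[SamplingCovariance] = None,
    spec: Optional[ModelSpec] = None,
    **kwargs,
) -> MetaFit:
    """Fit the multilevel meta-regression and return the :class:`MetaFit`."""
    spec = spec or ModelSpec()
    est = MultilevelMetaRegression(
        fixed_terms=tuple(spec.fixed_terms),
        random_levels=tuple(spec.random_levels),
        vcv_mode=spec.vcv_mode,
        vcv_r=spec.vcv_r,
        **kwargs,
    )
    est.fit(effects, vcv=vcv)
    return est.result_


def i2_decompose(fit: MetaFit, variances: Sequence[float]) -> dict[str, float]:
    """Multilevel I^2: share of total variance (heterogeneity + typical
    sampling variance) attributed to each random level, in percent."""
    v = np.asarray(variances, dtype=float)
    if v.size < 2:
        raise ValidationError("I^2 decomposition needs k >= 2")
    vbar = _typical_sampling_variance(v)
    tau2_sum = float(sum(fit.tau2.values()))
    denom = tau2_sum + vbar
    out = {lvl: 100.0 * t / denom if denom > 0 else 0.0 for lvl, t in fit.tau2.items()}
    out["total"] = float(sum(out.values()))
    return out


def qm_test(
    fit: MetaFit,
    coefficients: Optional[Sequence[int]] = None,
    L: Optional[np.ndarray] = None,
) -> tuple[float, int, float]:
    """Omnibus Wald chi-square (QM) test of a coefficient subset or contrast
    matrix L; returns (QM, df, p)."""
    if L is None:
        if coefficients is None:
            raise ValidationError("provide coefficient indices or a contrast matrix")
        idx = list(coefficients)
        if any(i < 0 or i >= len(fit.beta) for i in idx):
            raise ValidationError(f"coefficient index out of range: {idx}")
        L = np.zeros((len(idx), len(fit.beta)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if np.linalg.matrix_rank(L) < L.shape[0]:
        raise ValidationError("contrast matrix is rank deficient")
    b = L @ fit.beta
    C = L @ fit.cov_beta @ L.T
    try:
        sol = np.linalg.solve(C, b)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular contrast covariance") from exc
    qm = float(b @ sol)
    df = L.shape[0]
    p = float(scipy.stats.chi2.sf(qm, df))
    return qm, df, p


def contrast(fit: MetaFit, L: Sequence[float], name: str = "") -> ContrastResult:
    """General linear hypothesis L' beta = 0 with Wald-z inference."""
    Lv = np.asarray(L, dtype=float)
    if Lv.shape != (len(fit.beta),):
        raise ValidationError(
            f"contrast length {Lv.shape} does not match {len(fit.beta)} coefficients"
        )
    est = float(Lv @ fit.beta)
    var = float(Lv @ fit.cov_beta @ Lv)
    if var <= 0:
        raise ValidationError("zero-variance contrast")
    se = math.sqrt(var)
    z = est / se
    p = float(2.0 * scipy.stats.norm.sf(abs(z)))
    return ContrastResult(estimate=est, se=se, z=z, p=p, contrast_vector=Lv, name=name)


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (order-preserving with the input)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def prediction_interval(fit: MetaFit, coefficient: int = 0) -> tuple[float, float]:
    """95% prediction interval for a new true effect at one coefficient:
    beta +/- z_. 975 sqrt(SE^2 + sum tau^2)."""
    b = fit.beta[coefficient]
    half = _Z975 * math.sqrt(fit.se[coefficient] ** 2 + sum(fit.tau2.values()))
    return (float(b - half), float(b + half))


@dataclass
class CrossTab:
    counts: pd.DataFrame
    row_percent: pd.DataFrame  # integer-rounded within-row percentages


def collinearity_crosstab(
    records: Sequence[Union[ComparisonRecord, EffectSize]], a: str, b: str
) -> CrossTab:
    """Contingency table of effect counts for two moderators with integer
    within-row percentages (collinearity diagnostic)."""
    for name in (a, b):
        if name not in MODERATOR_LEVELS:
            raise ValidationError(f"unknown moderator {name!r}")
    va = [r.moderators[a] for r in records]
    vb = [r.moderators[b] for r in records]
    counts = pd.crosstab(pd.Series(va, name=a), pd.Series(vb, name=b))
    counts = counts.reindex(
        index=[l for l in MODERATOR_LEVELS[a] if l in counts.index],
        columns=[l for l in MODERATOR_LEVELS[b] if l in counts.columns],
    )
    totals = counts.sum(axis=1)
    pct = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    pct = pct.fillna(0.0).round(0).astype(int)
    return CrossTab(counts=counts, row_percent=pct)
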