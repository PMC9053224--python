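"""Bifactor liability-threshold models for per-medication endorsements.

For one side effect, the ten per-medication binary endorsement columns are
modelled as dichotomised liabilities driven by a general factor plus
orthogonal SSRI/SNRI class factors:

    y_j = 1  iff  lam_g[j] * F + lam_c[j] * C_class(j) + e_j > tau_j,

with unit total liability variance.  The marginal likelihood integrates the
factors out per participant over the manifests that participant actually
observed (medications taken), evaluated by Gauss-Hermite quadrature.  Because
the class factors act on disjoint manifest blocks given the general factor,
the (up to) three-dimensional integral factorises into nested one-dimensional
quadratures.

Internally the optimiser works in the unconstrained probit slope/intercept
parametrisation (P(y=1|f,c) = Phi(alpha + b_g f + b_c c)), which is a
bijection with (loadings, thresholds) and keeps the residual variance
positive by construction; results are reported on the loading scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri, roots_hermitenorm
from scipy.stats import chi2

from .cohort import CohortTable
from .constants import CHECKLIST_EFFECTS, DRUG_CLASS, DRUGS
from .errors import ConfigError

logger = logging.getLogger(__name__)

MODEL_CLASSES = ("full", "ssri_only", "snri_only", "common_only")

_LOG_TINY = np.log(np.finfo(float).tiny)


def _quadrature(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal Gauss-Hermite nodes and probability weights."""
    x, w = roots_hermitenorm(nodes)
    return x, w / np.sqrt(2.0 * np.pi)


def _class_factors(model_class: str) -> frozenset[str]:
    if model_class == "full":
        return frozenset({"SSRI", "SNRI"})
    if model_class == "ssri_only":
        return frozenset({"SSRI"})
    if model_class == "snri_only":
        return frozenset({"SNRI"})
    if model_class == "common_only":
        return frozenset()
    raise ConfigError(f"unknown model class {model_class!r}")


# ---------------------------------------------------------------------------
# Specs and fits
# ---------------------------------------------------------------------------


@dataclass
class BifactorSpec:
    """Loadings/threshold parametrisation of one model."""

    manifests: list[str]
    classes: list[str]  # per-manifest drug class ("SSRI" | "SNRI" | "other")
    model_class: str
    general_loading: np.ndarray
    class_loading: np.ndarray  # 0 where the manifest has no free class loading
    threshold: np.ndarray

    def __post_init__(self) -> None:
        J = len(self.manifests)
        for name in ("general_loading", "class_loading", "threshold"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (J,):
                raise ConfigError(f"{name} must have length {J}")
            setattr(self, name, arr)
        active = _class_factors(self.model_class)
        free = np.array([c in active for c in self.classes])
        if np.any(self.class_loading[~free] != 0):
            raise ConfigError(
                f"class loadings fixed at 0 under {self.model_class!r} must be 0"
            )
        resvar = 1.0 - self.general_loading**2 - self.class_loading**2
        if np.any(resvar < -1e-12):
            raise ConfigError("residual liability variance below 0")

    @property
    def k_params(self) -> int:
        active = _class_factors(self.model_class)
        n_class = sum(c in active for c in self.classes)
        return 2 * len(self.manifests) + n_class

    def free_class_mask(self) -> np.ndarray:
        active = _class_factors(self.model_class)
        return np.array([c in active for c in self.classes])

    # -- parametrisation bridge --------------------------------------------

    def to_slopes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        resvar = np.clip(1.0 - self.general_loading**2 - self.class_loading**2, 1e-10, None)
        sd = np.sqrt(resvar)
        return (-self.threshold / sd, self.general_loading / sd, self.class_loading / sd)

    @classmethod
    def from_slopes(
        cls,
        manifests: list[str],
        classes: list[str],
        model_class: str,
        alpha: np.ndarray,
        b_g: np.ndarray,
        b_c: np.ndarray,
    ) -> "BifactorSpec":
        s = np.sqrt(1.0 + b_g**2 + b_c**2)
        return cls(
            manifests=list(manifests),
            classes=list(classes),
            model_class=model_class,
            general_loading=b_g / s,
            class_loading=b_c / s,
            threshold=-alpha / s,
        )


@dataclass
class ModelFit:
    spec: BifactorSpec
    loglik: float
    k_params: int
    aic: float
    converged: bool
    gradient_norm: float
    n_obs: int = 0


@dataclass
class ModelComparison:
    full: ModelFit
    reduced: ModelFit
    delta_aic: float
    lrt_stat: float
    df: int
    pvalue: float


# ---------------------------------------------------------------------------
# Pattern aggregation
# ---------------------------------------------------------------------------


@dataclass
class _Patterns:
    """Unique response patterns with counts; codes 0/1 observed, 2 missing."""

    codes: np.ndarray  # (P, J) int8
    counts: np.ndarray  # (P,)
    n_obs: int

    @classmethod
    def from_data(cls, data: np.ndarray) -> "_Patterns":
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ConfigError("data must be a participants x manifests matrix")
        codes = np.where(np.isnan(data), 2, data).astype(np.int8)
        if not np.all(np.isin(codes, [0, 1, 2])):
            raise ConfigError("manifest values must be 0, 1 or missing")
        keep = (codes != 2).any(axis=1)
        codes = codes[keep]
        uniq, counts = np.unique(codes, axis=0, return_counts=True)
        return cls(codes=uniq, counts=counts.astype(float), n_obs=int(keep.sum()))


def _logsumexp_weighted(logx: np.ndarray, w: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(logx, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    s = np.sum(w * np.exp(logx - m), axis=axis)
    return np.squeeze(m, axis=axis) + np.log(np.clip(s, np.finfo(float).tiny, None))


class _Likelihood:
    """Marginal log-likelihood (and gradient) evaluator for one dataset."""

    def __init__(
        self,
        patterns: _Patterns,
        classes: list[str],
        model_class: str,
        nodes: int = 21,
    ) -> None:
        self.pat = patterns
        self.classes = list(classes)
        self.model_class = model_class
        self.active = sorted(_class_factors(model_class))
        self.f_nodes, self.f_w = _quadrature(nodes)
        self.c_nodes, self.c_w = _quadrature(nodes)
        J = len(classes)
        in_class = {
            cls_name: np.flatnonzero([c == cls_name for c in classes])
            for cls_name in self.active
        }
        covered = set().union(*[set(v) for v in in_class.values()]) if in_class else set()
        self.groups = {k: v for k, v in in_class.items()}
        self.solo = np.array(sorted(set(range(J)) - covered), dtype=int)
        self.J = J
        # free-parameter layout: alpha (J), b_g (J), b_c for class manifests
        self.class_param_idx = np.concatenate(
            [self.groups[c] for c in self.active]
        ) if self.active else np.array([], dtype=int)
        self.n_params = 2 * J + len(self.class_param_idx)
        self.I1 = (patterns.codes == 1).astype(float)
        self.I0 = (patterns.codes == 0).astype(float)

    # parameter vector <-> slope arrays
    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        J = self.J
        alpha = theta[:J]
        b_g = theta[J : 2 * J]
        b_c = np.zeros(J)
        b_c[self.class_param_idx] = theta[2 * J :]
        return alpha, b_g, b_c

    def pack(self, alpha: np.ndarray, b_g: np.ndarray, b_c: np.ndarray) -> np.ndarray:
        return np.concatenate([alpha, b_g, b_c[self.class_param_idx]])

    def loglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        alpha, b_g, b_c = self.unpack(theta)
        P = self.pat.codes.shape[0]
        Q = self.f_nodes.size
        f = self.f_nodes

        # -- solo manifests: depend on the general factor only
        logA = np.zeros((P, Q))
        solo_cache = None
        if self.solo.size:
            js = self.solo
            arg = alpha[js][None, :] + np.outer(f, b_g[js])  # (Q, Js)
            p1 = np.clip(ndtr(arg), 1e-300, 1.0)
            p0 = np.clip(1.0 - p1, 1e-300, 1.0)
            logA = self.I1[:, js] @ np.log(p1).T + self.I0[:, js] @ np.log(p0).T
            phi = np.exp(-0.5 * arg**2) / np.sqrt(2 * np.pi)
            # G[p, q, j] = phi * (I1/p1 - I0/p0), assembled lazily in gradient
            solo_cache = (js, p1, p0, phi)

        # -- class blocks: nested quadrature over the class factor
        block_cache = {}
        logL_q = logA.copy()  # (P, Q), accumulates log of per-factor-block terms
        for cls_name in self.active:
            js = self.groups[cls_name]
            c = self.c_nodes
            # arg (Q, R, Jc)
            arg = (
                alpha[js][None, None, :]
                + f[:, None, None] * b_g[js][None, None, :]
                + c[None, :, None] * b_c[js][None, None, :]
            )
            p1 = np.clip(ndtr(arg), 1e-300, 1.0)
            p0 = np.clip(1.0 - p1, 1e-300, 1.0)
            # log prod over the block's observed manifests: (P, Q, R)
            logprod = np.tensordot(self.I1[:, js], np.log(p1), axes=([1], [2])) + np.tensordot(
                self.I0[:, js], np.log(p0), axes=([1], [2])
            )
            logB = _logsumexp_weighted(logprod, self.c_w[None, None, :], axis=2)  # (P, Q)
            logL_q += logB
            phi = np.exp(-0.5 * arg**2) / np.sqrt(2 * np.pi)
            block_cache[cls_name] = (js, p1, p0, phi, logprod, logB)

        logL = _logsumexp_weighted(logL_q, self.f_w[None, :], axis=1)  # (P,)
        total = float(np.dot(self.pat.counts, logL))

        # -- gradient
        grad = np.zeros(self.n_params)
        # posterior weight over f-nodes: W[p, q] = w_q exp(logL_q - logL)
        W = self.f_w[None, :] * np.exp(np.clip(logL_q - logL[:, None], _LOG_TINY, 700.0))
        cW = self.pat.counts[:, None] * W  # (P, Q)

        if solo_cache is not None:
            js, p1, p0, phi = solo_cache
            # G[p, q, j] for solo manifests
            # ratio terms depend on pattern only through I1/I0 indicators
            r1 = phi / p1  # (Q, Js)
            r0 = phi / p0
            # d ll / d alpha_j = sum_pq cW * (I1*r1 - I0*r0)
            T1 = cW.T @ self.I1[:, js]  # (Q, Js)
            T0 = cW.T @ self.I0[:, js]
            galpha = np.sum(T1 * r1 - T0 * r0, axis=0)
            gbg = np.sum((T1 * r1 - T0 * r0) * f[:, None], axis=0)
            grad[js] += galpha
            grad[self.J + js] += gbg

        for cls_name in self.active:
            js, p1, p0, phi, logprod, logB = block_cache[cls_name]
            # W2[p, q, r] = cW[p, q] * v_r exp(logprod - logB)
            inner = self.c_w[None, None, :] * np.exp(
                np.clip(logprod - logB[:, :, None], _LOG_TINY, 700.0)
            )
            W2 = cW[:, :, None] * inner  # (P, Q, R)
            r1 = phi / p1  # (Q, R, Jc)
            r0 = phi / p0
            # T1[q, r, j] = sum_p W2 * I1[p, j]
            T1 = np.tensordot(W2, self.I1[:, js], axes=([0], [0]))  # (Q, R, Jc)
            T0 = np.tensordot(W2, self.I0[:, js], axes=([0], [0]))
            G = T1 * r1 - T0 * r0  # (Q, R, Jc)
            galpha = G.sum(axis=(0, 1))
            gbg = (G * f[:, None, None]).sum(axis=(0, 1))
            gbc = (G * self.c_nodes[None, :, None]).sum(axis=(0, 1))
            grad[js] += galpha
            grad[self.J + js] += gbg
            # b_c slots follow the class_param_idx ordering
            offsets = {j: 2 * self.J + k for k, j in enumerate(self.class_param_idx)}
            for local, j in enumerate(js):
                grad[offsets[j]] += gbc[local]

        return total, grad


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def marginal_loglik(spec: BifactorSpec, data: np.ndarray, nodes: int = 21) -> float:
    """Marginal log-likelihood of ``data`` (NaN = unobserved manifest) under
    the given loadings and thresholds."""
    pat = _Patterns.from_data(data)
    lik = _Likelihood(pat, spec.classes, spec.model_class, nodes=nodes)
    alpha, b_g, b_c = spec.to_slopes()
    theta = lik.pack(alpha, b_g, b_c)
    ll, _ = lik.loglik_grad(theta)
    return ll


def fit(
    data: np.ndarray,
    model_class: str,
    classes: list[str] | None = None,
    manifests: list[str] | None = None,
    nodes: int = 21,
    starts: int = 5,
    seed: int = 0,
) -> ModelFit:
    """Maximise the marginal likelihood over free loadings and thresholds.

    Multi-start L-BFGS with jittered initial values; the best log-likelihood
    is retained and ties break by the lowest start index.  Factor signs are
    identified post hoc by making each factor's first free loading positive.
    """
    data = np.asarray(data, dtype=float)
    J = data.shape[1]
    if classes is None:
        if J != len(DRUGS):
            raise ConfigError("classes must be given when manifests are not the 10 drugs")
        classes = [DRUG_CLASS[d] for d in DRUGS]
    if manifests is None:
        manifests = list(DRUGS) if J == len(DRUGS) else [f"m{j}" for j in range(J)]
    pat = _Patterns.from_data(data)
    lik = _Likelihood(pat, classes, model_class, nodes=nodes)

    # moment-based starting thresholds from marginal prevalences
    with np.errstate(invalid="ignore"):
        prev = np.nanmean(np.where(np.isnan(data), np.nan, data), axis=0)
    prev = np.clip(np.nan_to_num(prev, nan=0.5), 0.02, 0.98)
    alpha0 = ndtri(prev) * 1.2
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, object] | None = None
    for s in range(starts):
        jitter = 0.0 if s == 0 else 0.3
        alpha = alpha0 + jitter * rng.normal(size=J)
        b_g = 0.6 + jitter * rng.normal(size=J)
        b_c = np.zeros(J)
        b_c[lik.class_param_idx] = 0.4 + jitter * rng.normal(size=lik.class_param_idx.size)
        theta0 = lik.pack(alpha, b_g, b_c)

        def negloglik(theta: np.ndarray):
            ll, g = lik.loglik_grad(theta)
            return -ll, -g

        res = optimize.minimize(
            negloglik,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or -res.fun > best[0] + 1e-9:
            best = (-res.fun, res.x, res)

    ll, theta, res = best
    alpha, b_g, b_c = lik.unpack(theta)
    # sign identification: first free loading of each factor positive
    if b_g[0] < 0:
        b_g = -b_g
    for cls_name in lik.active:
        js = lik.groups[cls_name]
        if js.size and b_c[js[0]] < 0:
            b_c[js] = -b_c[js]
    theta_id = lik.pack(alpha, b_g, b_c)
    _, grad = lik.loglik_grad(theta_id)
    gnorm = float(np.max(np.abs(grad)))
    # gradient tolerance scaled by the number of observations
    converged = bool(res.success) and gnorm < 1e-4 * max(pat.n_obs, 1)

    spec = BifactorSpec.from_slopes(manifests, classes, model_class, alpha, b_g, b_c)
    k = spec.k_params
    return ModelFit(
        spec=spec,
        loglik=float(ll),
        k_params=k,
        aic=2.0 * k - 2.0 * float(ll),
        converged=converged,
        gradient_norm=gnorm,
        n_obs=pat.n_obs,
    )


def compare(full: ModelFit, reduced: ModelFit) -> ModelComparison:
    """AIC difference and likelihood-ratio test of a nested reduction."""
    df = full.k_params - reduced.k_params
    if df < 1:
        raise ConfigError("reduced model must have fewer parameters than the full model")
    lrt = 2.0 * (full.loglik - reduced.loglik)
    if lrt < 0:
        if lrt < -1e-3 * max(full.n_obs, 1):
            logger.warning("LRT statistic %.5f < 0 beyond optimizer tolerance", lrt)
        else:
            logger.info("clamping slightly negative LRT statistic %.3g to 0", lrt)
        lrt = 0.0
    return ModelComparison(
        full=full,
        reduced=reduced,
        delta_aic=reduced.aic - full.aic,
        lrt_stat=float(lrt),
        df=int(df),
        pvalue=float(chi2.sf(lrt, df)),
    )


def run_all_side_effects(
    cohort: CohortTable,
    effects: tuple[str, ...] = CHECKLIST_EFFECTS,
    nodes: int = 21,
    starts: int = 5,
    seed: int = 0,
):
    """Fit the four model classes per side effect; returns (comparisons,
    loadings) DataFrames."""
    import pandas as pd

    classes = [DRUG_CLASS[d] for d in DRUGS]
    comp_rows, load_rows = [], []
    for k_eff, eff in enumerate(effects):
        data = np.column_stack([cohort.endorsement(d, eff) for d in DRUGS])
        observed_per_row = (~np.isnan(data)).sum(axis=1)
        if not np.any(observed_per_row >= 2):
            logger.warning("side effect %s: no participant observed on >= 2 drugs; skipped", eff)
            comp_rows.append(
                {"side_effect": eff, "reduction": "unidentifiable", "delta_aic": np.nan,
                 "lrt_stat": np.nan, "df": 0, "pvalue": np.nan,
                 "full_converged": False, "reduced_converged": False}
            )
            continue
        fits = {
            mc: fit(
                data, mc, classes=classes, manifests=list(DRUGS),
                nodes=nodes, starts=starts, seed=seed + 1000 * k_eff,
            )
            for mc in MODEL_CLASSES
        }
        for mc in ("ssri_only", "snri_only", "common_only"):
            c = compare(fits["full"], fits[mc])
            comp_rows.append(
                {
                    "side_effect": eff,
                    "reduction": mc,
                    "full_loglik": c.full.loglik,
                    "reduced_loglik": c.reduced.loglik,
                    "delta_aic": c.delta_aic,
                    "lrt_stat": c.lrt_stat,
                    "df": c.df,
                    "pvalue": c.pvalue,
                    "full_converged": c.full.converged,
                    "reduced_converged": c.reduced.converged,
                }
            )
        for mc, f_ in fits.items():
            for j, d in enumerate(DRUGS):
                load_rows.append(
                    {
                        "side_effect": eff,
                        "model_class": mc,
                        "medication": d,
                        "drug_class": classes[j],
                        "general_loading": f_.spec.general_loading[j],
                        "class_loading": f_.spec.class_loading[j],
                        "threshold": f_.spec.threshold[j],
                        "loglik": f_.loglik,
                        "aic": f_.aic,
                        "converged": f_.converged,
                    }
                )
    return pd.DataFrame(comp_rows), pd.DataFrame(load_rows)
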