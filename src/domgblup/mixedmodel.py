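"""GBLUP repeatability models with additive and dominance effects.

Two univariate models are fitted to repeated records y on genotyped
animals, both with a single fixed mean:

  additive (A):            y = 1*mu + W u + W pe + e
  additive+dominance (A+D): y = 1*mu + W u + W d + W pe + e

with u ~ N(0, G*sigma_a2), d ~ N(0, D*sigma_d2), pe ~ N(0, I*sigma_pe2),
e ~ N(0, I*sigma_e2) and W the record->animal incidence.  Variance
components are estimated by REML (EM warm-up followed by average-
information updates, components floored at zero), genetic values by the
mixed-model/GLS solution at the estimates, and the two models are
compared with a likelihood-ratio test against the 50:50 mixture of
chi-square(0) and chi-square(1) appropriate for a variance tested on the
boundary of its parameter space.

Computationally the record-level restricted likelihood is reduced
exactly to (i) within-animal contrasts, which depend on sigma_e2 alone,
and (ii) animal means with covariance
sigma_a2*G + sigma_d2*D + sigma_pe2*I + sigma_e2*diag(1/r_i),
so every iteration costs one factorisation of an n_animals-sized matrix
rather than an n_records-sized one.  The reduction is an algebraic
identity for this model class (all random effects enter through W); the
test suite checks it against a dense record-level implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import PhenotypeRecords
from .grm import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "Incidence",
    "VarianceComponents",
    "GeneticValues",
    "DerivedRatios",
    "LRTResult",
    "build_incidence",
    "reml_fit",
    "reml_loglik",
    "solve_blup",
    "mixture_lrt",
    "variance_ratios",
    "fit_both_models",
]

logger = logging.getLogger("domgblup")

_LN2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Model choice and REML convergence settings.

    ``em_iterations`` EM steps are taken first (monotone in likelihood,
    safe far from the optimum), then average-information steps with
    step-halving.  A component stepping below zero is floored at zero and,
    once held there for ``pin_after`` consecutive iterations, fixed at the
    boundary for the rest of the fit (no standard error is reported for a
    boundary-fixed component).
    """

    include_dominance: bool = False
    max_iter: int = 200
    tol_loglik: float = 1e-8
    tol_components: float = 1e-6
    em_iterations: int = 5
    pin_after: int = 3
    ridge: float = 1e-8


@dataclass
class Incidence:
    """Record -> animal incidence: each record maps to exactly one animal."""

    animal_ids: list[str]
    record_animal_idx: np.ndarray  # position of each record's animal

    @property
    def n_records(self) -> int:
        return self.record_animal_idx.size

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n_records, self.n_animals))
        W[np.arange(self.n_records), self.record_animal_idx] = 1.0
        return W

    def counts(self) -> np.ndarray:
        return np.bincount(self.record_animal_idx, minlength=self.n_animals)


def build_incidence(
    records: PhenotypeRecords, animal_order: list[str]
) -> Incidence:
    pos = {a: i for i, a in enumerate(animal_order)}
    idx = np.empty(len(records), dtype=np.int64)
    for k, a in enumerate(records.animal_ids):
        if a not in pos:
            raise ValueError(f"record animal {a!r} not in the animal order")
        idx[k] = pos[a]
    return Incidence(list(animal_order), idx)


@dataclass
class VarianceComponents:
    """REML estimates for one model fit.

    ``sigma_d2`` is None for the additive-only model.  ``se`` maps
    component names ('a', 'd', 'pe', 'e') to standard errors from the
    inverse average-information matrix; boundary-fixed components have no
    entry.  ``pinned`` lists components fixed at zero.
    """

    sigma_a2: float
    sigma_d2: float | None
    sigma_pe2: float
    sigma_e2: float
    mu: float = 0.0
    loglik: float = float("nan")
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_iterations: int = 0
    pinned: tuple[str, ...] = ()
    message: str = ""

    @property
    def include_dominance(self) -> bool:
        return self.sigma_d2 is not None

    def total(self) -> float:
        """Total phenotypic variance: sum of all fitted components."""
        d = self.sigma_d2 or 0.0
        return self.sigma_a2 + d + self.sigma_pe2 + self.sigma_e2

    def as_dict(self) -> dict[str, float]:
        out = {"sigma_a2": self.sigma_a2, "sigma_pe2": self.sigma_pe2,
               "sigma_e2": self.sigma_e2}
        if self.sigma_d2 is not None:
            out["sigma_d2"] = self.sigma_d2
        return out


@dataclass
class GeneticValues:
    """Per-animal solutions: breeding value, dominance deviation, their sum
    (total genetic value) and the permanent-environment solution."""

    table: pd.DataFrame  # index animal_id; columns bv, dv, tgv, pe

    @property
    def bv(self) -> pd.Series:
        return self.table["bv"]

    @property
    def dv(self) -> pd.Series:
        return self.table["dv"]

    @property
    def tgv(self) -> pd.Series:
        return self.table["tgv"]

    @property
    def pe(self) -> pd.Series:
        return self.table["pe"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass
class DerivedRatios:
    h_a2: float
    h_d2: float
    dominance_share: float  # sigma_d2 / (sigma_a2 + sigma_d2)
    repeatability: float  # (sigma_a2 + sigma_d2 + sigma_pe2) / sigma_p2
    sigma_p2: float


@dataclass
class LRTResult:
    statistic: float
    p_value: float


# ---------------------------------------------------------------- reduction
class _Reduced:
    """Animal-level sufficient statistics of the repeatability model."""

    def __init__(self, y: np.ndarray, incidence: Incidence) -> None:
        y = np.asarray(y, dtype=float)
        if y.size != incidence.n_records:
            raise ValueError("y length must match the incidence")
        counts = incidence.counts()
        self.obs = np.flatnonzero(counts > 0)  # animals with records, G order
        self.r = counts[self.obs].astype(float)
        # map records onto the observed-animal compression
        comp = -np.ones(incidence.n_animals, dtype=np.int64)
        comp[self.obs] = np.arange(self.obs.size)
        rec = comp[incidence.record_animal_idx]
        sums = np.bincount(rec, weights=y, minlength=self.obs.size)
        self.ybar = sums / self.r
        self.ssw = float(np.sum((y - self.ybar[rec]) ** 2))
        self.n_records = int(y.size)
        self.n_obs = int(self.obs.size)
        self.nu = self.n_records - self.n_obs  # within-animal contrast dof
        self.log_r_sum = float(np.log(self.r).sum())
        self.rinv = 1.0 / self.r


class _Workspace:
    """All per-iterate REML quantities at one set of components.

    Components are ordered (a[, d], pe, e); ``mats`` holds the mean-level
    covariance derivative for the effect components (G, D, I).
    """

    def __init__(
        self,
        red: _Reduced,
        mats: list[np.ndarray],
        theta: np.ndarray,
        ridge: float = 1e-8,
    ) -> None:
        self.red = red
        self.theta = np.asarray(theta, dtype=float)
        n = red.n_obs
        s_e = self.theta[-1]
        V = np.zeros((n, n))
        for sig, A in zip(self.theta[:-1], mats):
            if sig != 0.0:
                V += sig * A
        V[np.diag_indices(n)] += s_e * red.rinv
        try:
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            logger.info("covariance factorisation failed; adding ridge %.1e", ridge)
            V[np.diag_indices(n)] += ridge
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
        self.logdet = 2.0 * float(np.log(np.diag(cf[0])).sum())
        self.Vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
        self.u1 = self.Vinv.sum(axis=1)
        self.s11 = float(self.u1.sum())
        u1y = float(self.u1 @ red.ybar)
        self.mu = u1y / self.s11
        self.t = self.Vinv @ red.ybar - self.u1 * (u1y / self.s11)

        if s_e <= 0.0 and (red.nu > 0 or red.ssw > 0):
            self.loglik = -np.inf
        else:
            within = red.nu * np.log(s_e) + red.ssw / s_e if red.nu > 0 else (
                0.0 if red.ssw == 0 else red.ssw / s_e
            )
            self.loglik = -0.5 * (
                (red.n_records - 1) * _LN2PI
                + within
                + self.logdet
                + red.log_r_sum
                + np.log(self.s11)
                + float(red.ybar @ self.t)
            )

        # per-component helper vectors g_k = V_dot_k @ t (mean level)
        self.g = [A @ self.t for A in mats]
        self.g.append(red.rinv * self.t)  # residual derivative is diag(1/r)
        self.mats = mats

    def apply_P(self, v: np.ndarray) -> np.ndarray:
        return self.Vinv @ v - self.u1 * float(self.u1 @ v) / self.s11

    def trace_P(self, A: np.ndarray) -> float:
        return float((self.Vinv * A).sum() - (self.u1 @ A @ self.u1) / self.s11)

    def trace_P_R(self) -> float:
        rinv = self.red.rinv
        return float(
            (np.diag(self.Vinv) * rinv).sum() - ((self.u1**2) * rinv).sum() / self.s11
        )

    def scores(self) -> np.ndarray:
        """Restricted-likelihood gradient, record scale, components order."""
        red, t = self.red, self.t
        s = []
        for A in self.mats:
            s.append(0.5 * (float(t @ (A @ t)) - self.trace_P(A)))
        s_e = self.theta[-1]
        quad_e = red.ssw / s_e**2 + float(t @ (red.rinv * t))
        tr_e = red.nu / s_e + self.trace_P_R()
        s.append(0.5 * (quad_e - tr_e))
        return np.asarray(s)

    def ai_matrix(self) -> np.ndarray:
        """Average-information matrix over all components."""
        k = len(self.g)
        Pg = [self.apply_P(g) for g in self.g]
        ai = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * float(self.g[i] @ Pg[j])
        ai[k - 1, k - 1] += 0.5 * self.red.ssw / self.theta[-1] ** 3
        return ai

    def em_update(self) -> np.ndarray:
        """One EM-REML step; keeps every component non-negative and the
        likelihood non-decreasing."""
        red, t = self.red, self.t
        theta = self.theta
        new = np.empty_like(theta)
        for i, A in enumerate(self.mats):
            quad = float(t @ (A @ t))
            new[i] = theta[i] + theta[i] ** 2 / red.n_obs * (quad - self.trace_P(A))
        s_e = theta[-1]
        quad_e = red.ssw / s_e**2 + float(t @ (red.rinv * t))
        tr_e = red.nu / s_e + self.trace_P_R()
        new[-1] = s_e + s_e**2 / red.n_records * (quad_e - tr_e)
        return np.maximum(new, 0.0)


def _component_names(include_dominance: bool) -> list[str]:
    return ["a", "d", "pe", "e"] if include_dominance else ["a", "pe", "e"]


def _mean_level_mats(
    red: _Reduced, G: RelationshipMatrix, D: RelationshipMatrix | None,
    include_dominance: bool,
) -> list[np.ndarray]:
    obs = red.obs
    mats = [np.ascontiguousarray(G.values[np.ix_(obs, obs)])]
    if include_dominance:
        assert D is not None
        mats.append(np.ascontiguousarray(D.values[np.ix_(obs, obs)]))
    mats.append(np.eye(obs.size))
    return mats


def _check_model_inputs(
    incidence: Incidence, G: RelationshipMatrix, D: RelationshipMatrix | None,
    include_dominance: bool,
) -> None:
    if list(G.animal_ids) != list(incidence.animal_ids):
        raise ValueError("G animal order must match the incidence animal order")
    if include_dominance:
        if D is None:
            raise ValueError("dominance model requested but no D supplied")
        if list(D.animal_ids) != list(G.animal_ids):
            raise ValueError("D animal order must match G")


def reml_fit(
    y,
    incidence: Incidence,
    G: RelationshipMatrix,
    D: RelationshipMatrix | None = None,
    spec: ModelSpec | None = None,
) -> VarianceComponents:
    """Estimate variance components by REML for model A or A+D.

    EM warm-up then average-information steps; step-halving protects the
    likelihood, components are floored at zero and pinned at the boundary
    when they keep returning there.  Standard errors come from the inverse
    average-information matrix at the optimum.
    """
    spec = spec or ModelSpec()
    _check_model_inputs(incidence, G, D, spec.include_dominance)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector must be finite")
    names = _component_names(spec.include_dominance)
    k = len(names)

    var_y = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
    if var_y == 0.0:
        return _pack(names, np.zeros(k), {}, mu=float(y.mean()),
                     loglik=float("nan"), converged=True, n_iter=0,
                     pinned=tuple(names),
                     message="degenerate: zero phenotypic variance")

    red = _Reduced(y, incidence)
    mats = _mean_level_mats(red, G, D, spec.include_dominance)

    theta = np.full(k, var_y / k)
    floor = 1e-10 * var_y
    pin_count = np.zeros(k, dtype=int)
    pinned = np.zeros(k, dtype=bool)
    ws = _Workspace(red, mats, theta, spec.ridge)
    converged = False
    message = "max iterations reached"
    it = 0
    for it in range(1, spec.max_iter + 1):
        if it <= spec.em_iterations:
            theta_new = ws.em_update()
            theta_new[pinned] = 0.0
            ws_new = _Workspace(red, mats, theta_new, spec.ridge)
        else:
            theta_new, ws_new = _ai_step(red, mats, ws, pinned, floor, spec)

        # boundary bookkeeping
        at_floor = theta_new <= floor
        at_floor[-1] = False  # residual variance is never pinned
        pin_count = np.where(at_floor, pin_count + 1, 0)
        newly = (~pinned) & (pin_count >= spec.pin_after)
        if newly.any():
            pinned |= newly
            theta_new[pinned] = 0.0
            ws_new = _Workspace(red, mats, theta_new, spec.ridge)
            logger.info("pinned components at zero: %s",
                        [names[i] for i in np.flatnonzero(pinned)])

        d_loglik = abs(ws_new.loglik - ws.loglik)
        d_comp = np.max(np.abs(theta_new - ws.theta)) / var_y
        ws = ws_new
        if (
            it > spec.em_iterations
            and d_loglik <= spec.tol_loglik * (1.0 + abs(ws.loglik))
            and d_comp <= spec.tol_components
        ):
            converged = True
            message = "converged"
            break

    se = _standard_errors(ws, names, pinned)
    return _pack(names, ws.theta, se, mu=ws.mu, loglik=float(ws.loglik),
                 converged=converged, n_iter=it,
                 pinned=tuple(n for n, p in zip(names, pinned) if p),
                 message=message)


def _ai_step(red, mats, ws, pinned, floor, spec):
    """AI update on the free components with step-halving; falls back to an
    EM step if no AI step improves the likelihood."""
    free = np.flatnonzero(~pinned)
    s = ws.scores()[free]
    ai = ws.ai_matrix()[np.ix_(free, free)]
    try:
        delta = np.linalg.solve(ai, s)
    except np.linalg.LinAlgError:
        delta = np.linalg.lstsq(ai, s, rcond=None)[0]
    step = delta.copy()
    for _ in range(25):
        cand = ws.theta.copy()
        cand[free] = ws.theta[free] + step
        if (cand[free] < 0.0).any():
            neg = cand[free] < 0.0
            # fully collapse the step for strongly negative proposals
            if (cand[free][neg] < -0.5 * ws.theta[free][neg] - floor).any():
                step = step / 2.0
                continue
            cand[free] = np.maximum(cand[free], 0.0)
        ws_new = _Workspace(red, mats, cand, spec.ridge)
        if ws_new.loglik >= ws.loglik - 1e-10 * (1.0 + abs(ws.loglik)):
            return cand, ws_new
        step = step / 2.0
    cand = ws.em_update()
    cand[pinned] = 0.0
    return cand, _Workspace(red, mats, cand, spec.ridge)


def _standard_errors(ws, names, pinned) -> dict[str, float]:
    free = np.flatnonzero(~pinned)
    if free.size == 0:
        return {}
    ai = ws.ai_matrix()[np.ix_(free, free)]
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
    out: dict[str, float] = {}
    for j, i in enumerate(free):
        v = cov[j, j]
        out[names[i]] = float(np.sqrt(v)) if v > 0 else float("nan")
    return out


def _pack(names, theta, se, mu, loglik, converged, n_iter, pinned, message):
    vals = dict(zip(names, theta))
    return VarianceComponents(
        sigma_a2=float(vals["a"]),
        sigma_d2=float(vals["d"]) if "d" in vals else None,
        sigma_pe2=float(vals["pe"]),
        sigma_e2=float(vals["e"]),
        mu=float(mu),
        loglik=loglik,
        se=se,
        converged=converged,
        n_iterations=n_iter,
        pinned=pinned,
        message=message,
    )


def reml_loglik(
    y,
    incidence: Incidence,
    G: RelationshipMatrix,
    D: RelationshipMatrix | None,
    components: VarianceComponents,
) -> float:
    """Restricted log-likelihood at the supplied components (constants
    included, so it matches a dense record-level evaluation exactly)."""
    include_d = components.sigma_d2 is not None
    _check_model_inputs(incidence, G, D, include_d)
    theta = [components.sigma_a2]
    if include_d:
        theta.append(components.sigma_d2)
    theta += [components.sigma_pe2, components.sigma_e2]
    theta = np.asarray(theta, dtype=float)
    if (theta < 0).any():
        raise ValueError("variance components must be >= 0")
    if theta.sum() == 0.0:
        raise ValueError("all variance components are zero: covariance singular")
    red = _Reduced(np.asarray(y, dtype=float), incidence)
    if components.sigma_e2 == 0.0 and (red.nu > 0 or red.ssw > 0):
        raise ValueError("zero residual variance with repeated records: singular")
    mats = _mean_level_mats(red, G, D, include_d)
    ws = _Workspace(red, mats, theta)
    if not np.isfinite(ws.loglik):
        raise ValueError("restricted likelihood is not finite at these components")
    return float(ws.loglik)


def solve_blup(
    components: VarianceComponents,
    y,
    incidence: Incidence,
    G: RelationshipMatrix,
    D: RelationshipMatrix | None = None,
) -> GeneticValues:
    """Mixed-model (GLS) solutions for u, d and pe at fixed components.

    Animals present in G/D but without records receive predictions through
    their genomic covariances with the phenotyped animals; their
    permanent-environment solution is zero.
    """
    include_d = components.sigma_d2 is not None
    _check_model_inputs(incidence, G, D, include_d)
    y = np.asarray(y, dtype=float)
    red = _Reduced(y, incidence)
    if components.sigma_e2 == 0.0 and red.nu > 0:
        raise ValueError("zero residual variance with repeated records: singular")
    theta = [components.sigma_a2]
    if include_d:
        theta.append(components.sigma_d2)
    theta += [components.sigma_pe2, components.sigma_e2]
    mats = _mean_level_mats(red, G, D, include_d)
    ws = _Workspace(red, mats, np.asarray(theta, dtype=float))
    t = ws.t
    obs = red.obs
    n_all = incidence.n_animals
    bv = components.sigma_a2 * (G.values[:, obs] @ t)
    if include_d:
        dv = components.sigma_d2 * (D.values[:, obs] @ t)
    else:
        dv = np.zeros(n_all)
    pe = np.zeros(n_all)
    pe[obs] = components.sigma_pe2 * t
    table = pd.DataFrame(
        {"bv": bv, "dv": dv, "tgv": bv + dv, "pe": pe},
        index=pd.Index(incidence.animal_ids, name="animal_id"),
    )
    return GeneticValues(table)


def mixture_lrt(logl_A: float, logl_AD: float) -> LRTResult:
    """Likelihood-ratio test of the dominance variance on the boundary.

    statistic = max(0, 2*(logL_{A+D} - logL_A)); under the null the
    statistic is distributed as a 50:50 mixture of a point mass at zero and
    chi-square(1), so p = 0.5 * Pr(chi2_1 >= statistic) for a positive
    statistic and 1 at zero.
    """
    stat = max(0.0, 2.0 * (float(logl_AD) - float(logl_A)))
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return LRTResult(statistic=stat, p_value=p)


def variance_ratios(components: VarianceComponents) -> DerivedRatios:
    """Heritabilities, dominance share of genetic variance and repeatability
    from fitted (or externally supplied) components."""
    sigma_d2 = components.sigma_d2 or 0.0
    sigma_p2 = components.total()
    if sigma_p2 <= 0.0:
        raise ValueError("total phenotypic variance must be positive")
    genetic = components.sigma_a2 + sigma_d2
    return DerivedRatios(
        h_a2=components.sigma_a2 / sigma_p2,
        h_d2=sigma_d2 / sigma_p2,
        dominance_share=(sigma_d2 / genetic) if genetic > 0 else 0.0,
        repeatability=(genetic + components.sigma_pe2) / sigma_p2,
        sigma_p2=sigma_p2,
    )


def fit_both_models(
    records: PhenotypeRecords,
    G: RelationshipMatrix,
    D: RelationshipMatrix,
    spec_a: ModelSpec | None = None,
    spec_ad: ModelSpec | None = None,
) -> tuple[VarianceComponents, VarianceComponents, LRTResult]:
    """Fit model A and model A+D on the same records and compare them."""
    incidence = build_incidence(records, list(G.animal_ids))
    y = records.values
    fit_a = reml_fit(y, incidence, G, None, spec_a or ModelSpec(include_dominance=False))
    fit_ad = reml_fit(y, incidence, G, D, spec_ad or ModelSpec(include_dominance=True))
    return fit_a, fit_ad, mixture_lrt(fit_a.loglik, fit_ad.loglik)
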