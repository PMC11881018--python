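"""Maximum-likelihood structural equation modelling with latent variables.

The engine fits covariance-structure models in a RAM-style parameterisation:
directed paths (factor loadings and regressions) in a matrix A, residual
variances and covariances in a symmetric matrix S, giving the model-implied
covariance  Sigma(theta) = (I - A)^-1 S (I - A)^-T  restricted to the
observed variables.  Estimation minimises the normal-theory discrepancy

    F_ML(theta) = ln|Sigma| + tr(S_sample Sigma^-1) - ln|S_sample| - p

so that chi2 = (n - 1) * F_min.  Latent scales are identified by
fixed-marker scaling (one indicator loading per latent fixed to 1), and
observed exogenous variables have their variances/covariances fixed to the
sample values.  Fit is summarised with chi2, CFI, TLI, RMSEA and SRMR, plus
the adjusted R-squared of the designated outcome; uncertainty comes from the
inverse information (numerical Hessian) and from subsample bootstrap
replication of RMSEA and path estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SemModelSpec",
    "SemFit",
    "BootstrapResult",
    "sem_fit",
    "fit_indices",
    "bootstrap_rmsea",
    "build_paper_models",
]


@dataclass(frozen=True)
class SemModelSpec:
    """Latent/indicator/path structure of one covariance-structure model.

    ``latents`` maps each latent name to its indicators as
    ``(indicator, is_scaling)`` pairs; exactly one indicator per latent must
    be the scaling variable (loading fixed to 1).  ``regressions`` are
    directed ``(outcome, predictor)`` paths; ``covariances`` are free
    residual covariances; ``exogenous`` lists observed variables whose
    (co)variances are fixed to the sample values.
    """

    name: str
    latents: dict[str, tuple[tuple[str, bool], ...]] = field(default_factory=dict)
    regressions: tuple[tuple[str, str], ...] = ()
    covariances: tuple[tuple[str, str], ...] = ()
    exogenous: tuple[str, ...] = ()
    primary_outcome: str | None = None

    def __post_init__(self) -> None:
        for lat, inds in self.latents.items():
            if sum(1 for _, fixed in inds if fixed) != 1:
                raise ValueError(f"latent {lat!r} needs exactly one scaling indicator")
        # regressions must be acyclic
        edges = set(self.regressions)
        remaining = set(n for e in edges for n in e)
        while remaining:
            free = {n for n in remaining
                    if not any(pred in remaining and out == n for out, pred in edges)}
            if not free:
                raise ValueError("regression graph contains a cycle")
            remaining -= free

    def scaling_indicator(self, latent: str) -> str:
        return next(ind for ind, fixed in self.latents[latent] if fixed)

    def observed_vars(self) -> tuple[str, ...]:
        seen: list[str] = []
        for inds in self.latents.values():
            for ind, _ in inds:
                if ind not in seen:
                    seen.append(ind)
        for out, pred in self.regressions:
            for v in (out, pred):
                if v not in self.latents and v not in seen:
                    seen.append(v)
        for v in self.exogenous:
            if v not in seen:
                seen.append(v)
        return tuple(seen)

    def node_names(self) -> tuple[str, ...]:
        return tuple(self.latents) + self.observed_vars()

    def with_scaling(self, latent: str, indicator: str) -> "SemModelSpec":
        """Same model with a different scaling indicator for ``latent``."""
        inds = tuple((ind, ind == indicator) for ind, _ in self.latents[latent])
        if not any(fixed for _, fixed in inds):
            raise ValueError(f"{indicator!r} is not an indicator of {latent!r}")
        new_lat = dict(self.latents)
        new_lat[latent] = inds
        return replace(self, latents=new_lat)


# ---------------------------------------------------------------------------
# parameter bookkeeping


class _ParamTable:
    """Free-parameter layout for a spec: names, start values, bounds."""

    def __init__(self, spec: SemModelSpec, S_samp: np.ndarray, obs: tuple[str, ...]):
        self.spec = spec
        self.nodes = spec.node_names()
        self.idx = {n: i for i, n in enumerate(self.nodes)}
        self.obs = obs
        self.obs_idx = [self.idx[v] for v in obs]
        si = {v: i for i, v in enumerate(obs)}

        endogenous = {out for out, _ in spec.regressions}
        entries: list[tuple[str, tuple]] = []   # (name, ('A'|'S', i, j))
        start: list[float] = []
        lb: list[float] = []

        def sd(v: str) -> float:
            return math.sqrt(S_samp[si[v], si[v]]) if v in si else 1.0

        def proxy(v: str) -> str:
            """Observed stand-in for a node: itself, or a latent's marker."""
            return spec.scaling_indicator(v) if v in spec.latents else v

        def r(u: str, v: str) -> float:
            du, dv = sd(u), sd(v)
            return float(S_samp[si[u], si[v]] / (du * dv)) if du * dv > 0 else 0.0

        for lat, inds in spec.latents.items():
            marker = spec.scaling_indicator(lat)
            for ind, fixed in inds:
                if fixed:
                    continue
                entries.append((f"{lat}=~{ind}", ("A", self.idx[ind], self.idx[lat])))
                # start from the indicator-marker association so weakly
                # related indicators do not pull the fit into local minima
                start.append(r(ind, marker) * sd(ind) / max(sd(marker), 1e-8))
                lb.append(-np.inf)
        for out, pred in spec.regressions:
            entries.append((f"{out}~{pred}", ("A", self.idx[out], self.idx[pred])))
            start.append(0.0)
            lb.append(-np.inf)
        for a, b in spec.covariances:
            entries.append((f"{a}~~{b}", ("S", self.idx[a], self.idx[b])))
            if a in spec.latents and b in spec.latents:
                start.append(r(proxy(a), proxy(b)) * sd(proxy(a)) * sd(proxy(b)))
            else:
                start.append(0.0)
            lb.append(-np.inf)
        # residual variances: every node except fixed-exogenous observed
        for node in self.nodes:
            if node in spec.exogenous:
                continue
            entries.append((f"var({node})", ("S", self.idx[node], self.idx[node])))
            if node in spec.latents:
                m = spec.scaling_indicator(node)
                start.append(0.5 * sd(m) ** 2)
            else:
                start.append(0.5 * sd(node) ** 2)
            lb.append(1e-10)

        self.names = [e[0] for e in entries]
        self.slots = [e[1] for e in entries]
        self.start = np.array(start)
        self.lower = np.array(lb)
        self.n_free = len(entries)

        # fixed structure
        n = len(self.nodes)
        self.A0 = np.zeros((n, n))
        self.S0 = np.zeros((n, n))
        for lat in spec.latents:
            marker = spec.scaling_indicator(lat)
            self.A0[self.idx[marker], self.idx[lat]] = 1.0
        for i, a in enumerate(spec.exogenous):
            for b in spec.exogenous[i:]:
                ia, ib = self.idx[a], self.idx[b]
                self.S0[ia, ib] = self.S0[ib, ia] = S_samp[si[a], si[b]]

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A, S = self.A0.copy(), self.S0.copy()
        for val, (kind, i, j) in zip(theta, self.slots):
            if kind == "A":
                A[i, j] = val
            else:
                S[i, j] = val
                S[j, i] = val
        return A, S

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(Sigma over observed variables, Sigma over all nodes)."""
        A, S = self.matrices(theta)
        ib = np.linalg.inv(np.eye(len(self.nodes)) - A)
        full = ib @ S @ ib.T
        return full[np.ix_(self.obs_idx, self.obs_idx)], full

    def value_and_grad(self, theta: np.ndarray, s_samp: np.ndarray,
                       logdet_s: float) -> tuple[float, np.ndarray]:
        """F_ML and its analytic gradient.

        With C = (I-A)^-1 and W = C S C^T, the derivative of F_ML along a
        path parameter A[i,j] is 2 (C^T M W)[i,j] and along a (co)variance
        S[i,j] is (C^T M C)[i,j] (doubled off-diagonal), where
        M = Sigma^-1 - Sigma^-1 S_sample Sigma^-1 embedded in node space.
        """
        A, S = self.matrices(theta)
        n = len(self.nodes)
        C = np.linalg.inv(np.eye(n) - A)
        W = C @ S @ C.T
        sigma = W[np.ix_(self.obs_idx, self.obs_idx)]
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf, np.zeros_like(theta)
        sig_inv = np.linalg.inv(sigma)
        f = logdet + float(np.trace(sig_inv @ s_samp)) - logdet_s - sigma.shape[0]
        m_obs = sig_inv - sig_inv @ s_samp @ sig_inv
        m_full = np.zeros((n, n))
        m_full[np.ix_(self.obs_idx, self.obs_idx)] = m_obs
        ga = 2.0 * C.T @ m_full @ W
        gs = C.T @ m_full @ C
        grad = np.empty_like(theta)
        for k, (kind, i, j) in enumerate(self.slots):
            if kind == "A":
                grad[k] = ga[i, j]
            elif i == j:
                grad[k] = gs[i, i]
            else:
                grad[k] = 2.0 * gs[i, j]
        return f, grad


def _projected_grad(x: np.ndarray, g: np.ndarray, lower: np.ndarray) -> float:
    pg = g.copy()
    at_bound = (x <= lower + 1e-12) & (g > 0)
    pg[at_bound] = 0.0
    return float(np.max(np.abs(pg))) if pg.size else 0.0


def _minimize_robust(value_and_grad, x0: np.ndarray, lower: np.ndarray,
                     gtol: float, max_outer: int = 30):
    """L-BFGS-B with cliff recovery.

    The ML discrepancy is +inf outside the positive-definite region; the
    line search can stall against that cliff with a large gradient left.
    When that happens a manual backtracking (Armijo) step along the negative
    gradient restarts the quasi-Newton iteration from inside the basin.
    """
    bounds = [(lo if np.isfinite(lo) else None, None) for lo in lower]
    x = x0.copy()
    best = None
    for _ in range(max_outer):
        res = optimize.minimize(value_and_grad, x, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options=dict(maxiter=5000, maxfun=50000,
                                             ftol=1e-14, gtol=gtol))
        if best is None or res.fun < best.fun:
            best = res
        f, g = value_and_grad(res.x)
        if not np.isfinite(f):
            break
        if _projected_grad(res.x, g, lower) < max(gtol, 1e-7):
            best = res
            best.success = True
            return best
        # Armijo backtracking along -g from the stall point
        t, moved = 0.25, False
        for _ in range(40):
            x_new = np.maximum(res.x - t * g, lower)
            f_new, _ = value_and_grad(x_new)
            if np.isfinite(f_new) and f_new < f - 1e-4 * t * float(g @ g):
                x, moved = x_new, True
                break
            t *= 0.5
        if not moved:
            return best  # genuine stationary-ish point or bound solution
    return best


def _f_ml(sigma: np.ndarray, s_samp: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        trace = float(np.trace(np.linalg.solve(sigma, s_samp)))
    except np.linalg.LinAlgError:
        return np.inf
    return logdet + trace - logdet_s - s_samp.shape[0]


# ---------------------------------------------------------------------------
# fit result containers


@dataclass
class SemFit:
    """Estimates, standardized solution and fit indices of one model."""

    spec: SemModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    standardized: dict[str, float]
    chi2: float
    df: int
    p_value: float
    cfi: float
    tli: float | None
    rmsea: float
    srmr: float
    adj_r2: float | None
    r2: float | None
    converged: bool
    heywood: bool
    n: int
    n_free: int
    fmin: float
    sample_cov: pd.DataFrame
    implied_cov: pd.DataFrame
    node_sd: dict[str, float]
    baseline_chi2: float
    baseline_df: int
    notes: tuple[str, ...] = ()


@dataclass
class BootstrapResult:
    rmsea: np.ndarray
    path_ci: dict[str, tuple[float, float, float]]  # (mean, lo, hi)
    path_sd: dict[str, float]
    n_failed: int
    reps: int


def fit_indices(chi2: float, df: int, chi2_baseline: float, df_baseline: int,
                n: int, S: np.ndarray, Sigma: np.ndarray):
    """CFI, TLI, RMSEA, SRMR from chi-squares and covariance matrices.

    CFI   = 1 - max(chi2-df, 0) / max(chi2_b-df_b, chi2-df, 0)
    TLI   = ((chi2_b/df_b) - (chi2/df)) / ((chi2_b/df_b) - 1)   (None if df=0)
    RMSEA = sqrt(max(chi2-df, 0) / (df * (n-1)))                (0 if df=0)
    SRMR  = RMS of residual correlations between S and Sigma, including the
            standardized variance residuals on the diagonal.
    """
    num = max(chi2 - df, 0.0)
    den = max(chi2_baseline - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if df > 0:
        ratio_b = chi2_baseline / df_baseline
        tli = (ratio_b - chi2 / df) / (ratio_b - 1.0)
        rmsea = math.sqrt(num / (df * (n - 1)))
    else:
        tli = None
        rmsea = 0.0
    s_sd = np.sqrt(np.diag(S))
    m_sd = np.sqrt(np.diag(Sigma))
    r_s = S / np.outer(s_sd, s_sd)
    r_m = Sigma / np.outer(m_sd, m_sd)
    p = S.shape[0]
    resid = []
    for i in range(p):
        for j in range(i, p):
            if i == j:
                resid.append((S[i, i] - Sigma[i, i]) / S[i, i])
            else:
                resid.append(r_s[i, j] - r_m[i, j])
    srmr = math.sqrt(float(np.mean(np.square(resid))))
    return cfi, tli, rmsea, srmr


def _baseline_chi2(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-model chi-square (diagonal Sigma, ML closed form)."""
    p = S.shape[0]
    corr_logdet = np.linalg.slogdet(S)[1] - float(np.sum(np.log(np.diag(S))))
    return float(-(n - 1) * corr_logdet), p * (p - 1) // 2


def sem_fit(
    spec: SemModelSpec,
    table: pd.DataFrame,
    flip: tuple[str, ...] = (),
    n_starts: int = 5,
    gtol: float = 1e-8,
    rng: np.random.Generator | None = None,
) -> SemFit:
    """Fit a model to a participant table by maximum likelihood.

    Columns named in ``flip`` are multiplied by -1 before fitting (used for
    the word score, recorded as proportion correct but modelled on the
    worse-is-higher convention of the threshold measures).  Listwise-complete
    rows are used.  On non-convergence the optimiser is restarted from up to
    ``n_starts`` jittered starting points; a still-unconverged fit is
    returned flagged rather than raised.
    """
    obs = spec.observed_vars()
    missing = [v for v in obs if v not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    data = table.loc[:, list(obs)].dropna().astype(float)
    n = len(data)
    if n <= len(obs):
        raise ValueError("need more rows than observed variables")
    for v in flip:
        if v in data.columns:
            data[v] = -data[v]
    S_raw = np.cov(data.to_numpy(), rowvar=False, ddof=1)
    # fit on sd-scaled variables: F_ML and all fit indices are invariant under
    # diagonal rescaling of a fixed-marker model, and the optimisation is far
    # better conditioned; estimates are mapped back to the raw scale below.
    obs_sd = np.sqrt(np.diag(S_raw))
    if np.any(obs_sd <= 0):
        raise ValueError("constant observed variable")
    S_samp = S_raw / np.outer(obs_sd, obs_sd)
    logdet_s = float(np.linalg.slogdet(S_samp)[1])

    tab = _ParamTable(spec, S_samp, obs)

    def objective(theta: np.ndarray) -> float:
        sigma, _ = tab.implied(theta)
        return _f_ml(sigma, S_samp, logdet_s)

    def objective_grad(theta: np.ndarray):
        return tab.value_and_grad(theta, S_samp, logdet_s)

    rng = rng or np.random.default_rng(0)
    best = best_ok = None
    notes: list[str] = []
    if tab.n_free == 0:  # fully constrained (e.g. saturated all-exogenous)
        theta0 = np.empty(0)
        best = optimize.OptimizeResult(
            x=theta0, fun=objective(theta0), success=True, message="no free parameters")
        best_ok = best
    for attempt in range(n_starts if tab.n_free else 0):
        x0 = tab.start if attempt == 0 else tab.start * rng.uniform(0.5, 1.5, tab.n_free)
        res = _minimize_robust(objective_grad, x0, tab.lower, gtol)
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            if best_ok is None or res.fun < best_ok.fun:
                best_ok = res
            break
    if best_ok is not None:
        best = best_ok
    theta = best.x
    converged = best_ok is not None
    if not converged:
        notes.append(f"optimizer did not converge: {best.message}")

    sigma, full = tab.implied(theta)
    fmin = float(best.fun)
    chi2 = max((n - 1) * fmin, 0.0)
    # degrees of freedom: observed moments minus free parameters minus the
    # exogenous moments fixed to their sample values (which the model always
    # reproduces exactly); a saturated model therefore has df = 0
    n_exo = len(spec.exogenous)
    df = len(obs) * (len(obs) + 1) // 2 - tab.n_free - n_exo * (n_exo + 1) // 2
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    chi2_b, df_b = _baseline_chi2(S_samp, n)
    cfi, tli, rmsea, srmr = fit_indices(chi2, df, chi2_b, df_b, n, S_samp, sigma)

    # map estimates back to the raw variable scales (latents take the scale
    # of their marker indicator under fixed-marker identification)
    sd_of = dict(zip(obs, obs_sd))
    node_scale = {node: (sd_of[spec.scaling_indicator(node)] if node in spec.latents
                         else sd_of[node])
                  for node in tab.nodes}
    theta_raw = np.empty_like(theta)
    for k, (kind, i, j) in enumerate(tab.slots):
        si, sj = node_scale[tab.nodes[i]], node_scale[tab.nodes[j]]
        theta_raw[k] = theta[k] * (si / sj if kind == "A" else si * sj)
    estimates = dict(zip(tab.names, theta_raw))
    scaled_estimates = dict(zip(tab.names, theta))
    heywood = any(name.startswith("var(") and val < 1e-6
                  for name, val in scaled_estimates.items())
    if heywood:
        notes.append("Heywood case: residual variance at/below zero")
        warnings.warn(f"{spec.name}: Heywood case (near-zero residual variance)")

    # standard errors from the inverse information (numerical Hessian of the
    # log-likelihood-scaled discrepancy)
    se = dict.fromkeys(tab.names, float("nan"))
    if converged:
        hess = _numerical_hessian(objective, theta)
        try:
            cov_theta = np.linalg.pinv((n - 1) / 2.0 * hess)
            diag = np.diag(cov_theta)
            se = {}
            for name, v, (kind, i, j) in zip(tab.names, diag, tab.slots):
                si, sj = node_scale[tab.nodes[i]], node_scale[tab.nodes[j]]
                factor = si / sj if kind == "A" else si * sj
                se[name] = math.sqrt(v) * factor if v > 0 else float("nan")
        except np.linalg.LinAlgError:
            notes.append("information matrix not invertible; SEs unavailable")

    node_sd = {node: math.sqrt(max(full[tab.idx[node], tab.idx[node]], 0.0))
               for node in tab.nodes}
    standardized = {}
    for name, slot, val in zip(tab.names, tab.slots, theta):
        kind, i, j = slot
        ni, nj = tab.nodes[i], tab.nodes[j]
        if kind == "A":  # path j -> i
            standardized[name] = val * node_sd[nj] / node_sd[ni] if node_sd[ni] > 0 else float("nan")
        elif i == j:
            standardized[name] = val / node_sd[ni] ** 2 if node_sd[ni] > 0 else float("nan")
        else:
            denom = node_sd[ni] * node_sd[nj]
            standardized[name] = val / denom if denom > 0 else float("nan")
    # scaling loadings (fixed to 1) standardized for completeness
    for lat in spec.latents:
        marker = spec.scaling_indicator(lat)
        if node_sd[marker] > 0:
            standardized[f"{lat}=~{marker}"] = node_sd[lat] / node_sd[marker]

    r2 = adj_r2 = None
    if spec.primary_outcome is not None:
        out = spec.primary_outcome
        total = full[tab.idx[out], tab.idx[out]]
        resid = scaled_estimates.get(f"var({out})", 0.0)
        if total > 0:
            r2 = float(1.0 - resid / total)
            k = sum(1 for o, _ in spec.regressions if o == out)
            adj_r2 = float(1.0 - (1.0 - r2) * (n - 1) / (n - k - 1))

    obs_list = list(obs)
    return SemFit(
        spec=spec, estimates=estimates, se=se, standardized=standardized,
        chi2=float(chi2), df=int(df), p_value=p_value, cfi=cfi, tli=tli,
        rmsea=rmsea, srmr=srmr, adj_r2=adj_r2, r2=r2, converged=converged,
        heywood=heywood, n=n, n_free=tab.n_free, fmin=fmin,
        sample_cov=pd.DataFrame(S_raw, index=obs_list, columns=obs_list),
        implied_cov=pd.DataFrame(sigma * np.outer(obs_sd, obs_sd),
                                 index=obs_list, columns=obs_list),
        node_sd=node_sd, baseline_chi2=chi2_b, baseline_df=df_b,
        notes=tuple(notes),
    )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian; adequate for the smooth ML discrepancy."""
    k = x.size
    h = np.maximum(np.abs(x), 1.0) * eps
    hess = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def bootstrap_rmsea(
    spec: SemModelSpec,
    table: pd.DataFrame,
    frac: float = 0.95,
    reps: int = 100,
    rng: np.random.Generator | None = None,
    flip: tuple[str, ...] = (),
) -> BootstrapResult:
    """Subsample bootstrap of RMSEA and path estimates.

    Each replicate refits the model on ``floor(frac * n)`` rows drawn
    without replacement.  Path confidence intervals are mean +/- 1.96 sd of
    the replicate estimates; non-convergent replicates are dropped and
    counted.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = rng or np.random.default_rng()
    obs = spec.observed_vars()
    data = table.loc[:, list(obs)].dropna()
    n = len(data)
    m = int(math.floor(frac * n))
    rmseas, est_rows = [], []
    n_failed = n_heywood = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Heywood flags aggregated below
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
            fit = sem_fit(spec, data.iloc[idx], flip=flip, n_starts=3)
            if not fit.converged:
                n_failed += 1
                continue
            n_heywood += fit.heywood
            rmseas.append(fit.rmsea)
            est_rows.append(fit.estimates)
    if n_heywood:
        warnings.warn(f"{spec.name}: {n_heywood}/{reps} bootstrap replicates "
                      "hit a variance boundary (Heywood)")
    path_ci, path_sd = {}, {}
    if est_rows:
        frame = pd.DataFrame(est_rows)
        for name in frame.columns:
            mu, sd = float(frame[name].mean()), float(frame[name].std(ddof=1))
            if not np.isfinite(sd):
                sd = 0.0
            path_ci[name] = (mu, mu - 1.96 * sd, mu + 1.96 * sd)
            path_sd[name] = sd
    return BootstrapResult(np.array(rmseas), path_ci, path_sd, n_failed, reps)


# ---------------------------------------------------------------------------
# the battery's model set


def build_paper_models() -> dict[str, SemModelSpec]:
    """The three structural models and the measurement-model CFA.

    * model1 - word score (WiN, sign-flipped at fit time) regressed on the
      latent AFG (indicators: fixed task [scaling], low, high, with a
      low/high residual covariance), PTA and age.
    * model2 - the same structure with the sentence score (SiB).
    * model3 - latent SIN (indicators WiN [scaling] and SiB) regressed on
      AFG, PTA and age; no self-report indicator (it showed no measurable
      link to the speech scores).
    * cfa    - two-factor measurement model of SIN (WiN, SiB, SSQ) and AFG
      with a free latent covariance.

    Age and PTA enter as exogenous variables with their sample covariance
    fixed, carrying the age -> PTA association.
    """
    afg = ("AFG", (("AFG_fixed", True), ("AFG_low", False), ("AFG_high", False)))

    def structural(outcome: str, name: str) -> SemModelSpec:
        return SemModelSpec(
            name=name,
            latents=dict([afg]),
            regressions=(
                (outcome, "AFG"), (outcome, "PTA"), (outcome, "age"),
                ("AFG", "PTA"), ("AFG", "age"),
            ),
            covariances=(("AFG_low", "AFG_high"),),
            exogenous=("PTA", "age"),
            primary_outcome=outcome,
        )

    model1 = structural("WiN", "model1")
    model2 = structural("SiB", "model2")
    model3 = SemModelSpec(
        name="model3",
        latents=dict([afg, ("SIN", (("WiN", True), ("SiB", False)))]),
        regressions=(
            ("SIN", "AFG"), ("SIN", "PTA"), ("SIN", "age"),
            ("AFG", "PTA"), ("AFG", "age"),
        ),
        covariances=(("AFG_low", "AFG_high"),),
        exogenous=("PTA", "age"),
        primary_outcome="SIN",
    )
    cfa = SemModelSpec(
        name="cfa",
        latents=dict([
            ("SIN", (("WiN", True), ("SiB", False), ("SSQ", False))),
            afg,
        ]),
        covariances=(("SIN", "AFG"), ("AFG_low", "AFG_high")),
        primary_outcome=None,
    )
    return {"model1": model1, "model2": model2, "model3": model3, "cfa": cfa}
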