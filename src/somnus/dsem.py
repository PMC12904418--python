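"""Two-level dynamic structural equation models for person-day panels.

The model couples, per outcome variable, a within-person regression on
lag-1 and same-day deviations with a between-person regression on person
means, plus a person random intercept and Gaussian residuals:

    z_v(i,t) = a_v + sum_p beta^w_vp x^w_p(i,t) + sum_p beta^b_vp x^b_p(i)
               + u_v(i) + eps_v(i,t)

where x^w are standardized within-person deviations (own lag plus cross
paths at their specified timing), x^b the matching standardized person
means, u_v(i) ~ N(0, tau_v^2) and eps ~ N(0, sigma_v^2). Same-day
("current") paths follow the recursive order TSU -> SUiB -> sleep, so the
system is acyclic and each outcome equation can be estimated as a
regression. Estimation is Bayesian via a blocked Gibbs sampler with
conjugate normal updates for coefficients and intercepts; the
half-Student-t priors on the two scales are handled through their
inverse-gamma scale-mixture representation. Posterior draws from multiply
imputed panels are pooled by concatenation, the Bayesian analogue of
combining analyses across completed datasets.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .panel import DecomposedPanel, ImputationSet

MODEL1_VARIABLES = ["tsu", "suib", "sleep_total"]
MODEL2_VARIABLES = ["tsu", "suib", "core", "deep", "rem"]
#: variables receiving same-day (current) paths from smartphone use
_SLEEP_VARS = {"sleep_total", "core", "deep", "rem"}


@dataclass
class Priors:
    """Weakly-informative defaults standing in for "uninformative".

    Truly flat priors hurt sampling; normal(0, 10) on standardized
    coefficients and half-Student-t(3, 0, 2.5) on scales are effectively
    flat over the plausible range of standardized betas.
    """

    coef_sd: float = 10.0
    scale_df: float = 3.0
    scale_scale: float = 2.5


@dataclass
class ModelSpec:
    """Outcomes, path timings, priors and sampler settings for one model."""

    outcomes: list[str]
    paths: dict[str, list[tuple[str, str]]]  # outcome -> [(predictor, timing)]
    priors: Priors = field(default_factory=Priors)
    chains: int = 2
    iterations: int = 5000  # total per chain; first half is warmup
    seed: int = 0

    def __post_init__(self):
        for out, plist in self.paths.items():
            cur = [p for p, t in plist if t == "current"]
            order = {v: i for i, v in enumerate(self.outcomes)}
            for p in cur:
                if p in order and out in order and order[p] >= order[out]:
                    raise ValueError(
                        f"current path {p}->{out} violates the recursive order"
                    )

    @classmethod
    def from_variables(cls, variables: Sequence[str], **kw) -> "ModelSpec":
        """Path map from the timing rule: autoregressive paths lagged;
        TSU and SUiB to every sleep outcome current, TSU to SUiB current;
        all remaining cross paths lagged."""
        variables = list(variables)
        paths: dict[str, list[tuple[str, str]]] = {}
        for out in variables:
            plist = []
            for pred in variables:
                if pred == out:
                    timing = "lagged"  # autoregression
                elif pred == "tsu" and (out in _SLEEP_VARS or out == "suib"):
                    timing = "current"
                elif pred == "suib" and out in _SLEEP_VARS:
                    timing = "current"
                else:
                    timing = "lagged"
                plist.append((pred, timing))
            paths[out] = plist
        order = [v for v in ("tsu", "suib") if v in variables]
        order += [v for v in variables if v not in order]
        return cls(outcomes=order, paths=paths, **kw)

    @classmethod
    def model1(cls, **kw) -> "ModelSpec":
        return cls.from_variables(MODEL1_VARIABLES, **kw)

    @classmethod
    def model2(cls, **kw) -> "ModelSpec":
        return cls.from_variables(MODEL2_VARIABLES, **kw)


@dataclass
class PathEstimate:
    """One standardized coefficient with credible interval and diagnostics."""

    predictor: str
    outcome: str
    level: str  # within | between
    timing: str  # current | lagged
    beta: float
    ci_low: float
    ci_high: float
    significant: bool
    rhat: float


def significance(draws: np.ndarray) -> bool:
    """True iff the empirical 95% credible interval excludes zero."""
    lo, hi = np.percentile(np.asarray(draws, dtype=float), [2.5, 97.5])
    return bool(lo > 0 or hi < 0)


def rhat(chain_draws: np.ndarray) -> float:
    """Split rank-normalized R-hat for one parameter.

    ``chain_draws`` has shape (chains, draws). A degenerate input (a
    constant chain) has no defined scale-reduction factor and returns NaN.
    """
    arr = np.asarray(chain_draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    if np.allclose(arr.var(axis=1), 0, atol=1e-300):
        return float("nan")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        val = az.rhat(az.convert_to_dataset(arr[None] if arr.ndim == 1 else arr))
    return float(np.asarray(val["x"]))


def vif(X: np.ndarray, flag_cap: float = 1e6) -> np.ndarray:
    """Variance inflation factor 1/(1-R^2) per design column."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    Xc = X - X.mean(axis=0)
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        y = Xc[:, j]
        Z = np.delete(Xc, j, axis=1)
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        tss = float(y @ y)
        r2 = 0.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
        out[j] = flag_cap if r2 >= 1 - 1 / flag_cap else 1.0 / (1.0 - r2)
    return out


def build_design(
    spec: ModelSpec, dp: DecomposedPanel, outcome: str
) -> tuple[np.ndarray, np.ndarray, list[dict], np.ndarray, pd.DataFrame]:
    """Design quantities for one outcome equation.

    Returns ``(y, X, columns, pid_codes, rows)``. The response is the sum
    of the outcome's standardized within and between components; columns
    are the within deviations at their specified timing followed by the
    matching between person-mean columns. Rows with any missing required
    cell (post-imputation, only day-1 rows) are dropped.
    """
    if outcome not in dp.data.columns.str.replace("w_", "", regex=False).tolist() and \
       f"w_{outcome}" not in dp.data.columns:
        raise ValueError(f"outcome {outcome} not in decomposed panel")
    d = dp.data
    cols: list[dict] = []
    mats = []
    for pred, timing in spec.paths[outcome]:
        wcol = f"w_{pred}" if timing == "current" else f"w_{pred}_lag"
        if wcol not in d.columns:
            raise ValueError(f"predictor {pred} absent from panel")
        mats.append(d[wcol].to_numpy(dtype=float))
        cols.append({"predictor": pred, "timing": timing, "level": "within"})
    for pred, timing in spec.paths[outcome]:
        bcol = f"b_{pred}" if timing == "current" else f"b_{pred}_lag"
        mats.append(d[bcol].to_numpy(dtype=float))
        cols.append({"predictor": pred, "timing": timing, "level": "between"})
    X = np.column_stack(mats)
    y = d[f"w_{outcome}"].to_numpy(dtype=float) + d[f"b_{outcome}"].to_numpy(dtype=float)
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    rows = d.loc[keep, ["participant_id", "day_index"]].reset_index(drop=True)
    pids, pid_codes = np.unique(rows["participant_id"].to_numpy(), return_inverse=True)
    return y[keep], X[keep], cols, pid_codes, rows


def _gibbs(
    y: np.ndarray,
    X: np.ndarray,
    pid_codes: np.ndarray,
    iterations: int,
    priors: Priors,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One chain of the blocked Gibbs sampler; returns post-warmup draws."""
    n, p = X.shape
    J = int(pid_codes.max()) + 1
    warmup = iterations // 2
    keep = iterations - warmup
    Xi = np.hstack([np.ones((n, 1)), X])  # leading intercept column
    q = p + 1
    XtX = Xi.T @ Xi
    nj = np.bincount(pid_codes, minlength=J).astype(float)
    nu, s = priors.scale_df, priors.scale_scale
    prior_prec = np.full(q, 1.0 / priors.coef_sd**2)
    prior_prec[0] = 1e-6  # effectively flat intercept

    beta = np.zeros(q)
    u = np.zeros(J)
    sigma2, tau2 = 1.0, 0.5
    a_sig = a_tau = 1.0
    out_beta = np.empty((keep, q))
    out_u = np.empty((keep, J))
    out_sigma = np.empty(keep)
    out_tau = np.empty(keep)
    for it in range(iterations):
        # coefficients | u, sigma2
        prec = XtX / sigma2 + np.diag(prior_prec)
        rhs = Xi.T @ (y - u[pid_codes]) / sigma2
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        z = rng.standard_normal(q)
        beta = mean + np.linalg.solve(L.T, z)
        # random intercepts | beta, scales
        r = y - Xi @ beta
        rsum = np.bincount(pid_codes, weights=r, minlength=J)
        var_j = 1.0 / (nj / sigma2 + 1.0 / tau2)
        u = var_j * rsum / sigma2 + np.sqrt(var_j) * rng.standard_normal(J)
        # residual scale (half-t via inverse-gamma mixture)
        resid = r - u[pid_codes]
        ssr = float(resid @ resid)
        sigma2 = 1.0 / rng.gamma((n + nu) / 2.0, 1.0 / (ssr / 2.0 + nu / a_sig))
        a_sig = 1.0 / rng.gamma((nu + 1) / 2.0, 1.0 / (nu / sigma2 + 1.0 / s**2))
        # random-intercept scale
        ssu = float(u @ u)
        tau2 = 1.0 / rng.gamma((J + nu) / 2.0, 1.0 / (ssu / 2.0 + nu / a_tau))
        a_tau = 1.0 / rng.gamma((nu + 1) / 2.0, 1.0 / (nu / tau2 + 1.0 / s**2))
        if it >= warmup:
            k = it - warmup
            out_beta[k] = beta
            out_u[k] = u
            out_sigma[k] = np.sqrt(sigma2)
            out_tau[k] = np.sqrt(tau2)
    return {"beta": out_beta, "u": out_u, "sigma": out_sigma, "tau": out_tau}


def _spec_matrices(spec: ModelSpec, theta: dict[str, dict[int, float]]):
    """Structural (lag, current) matrices over the spec's outcome order from
    per-outcome within coefficients keyed by column position."""
    vars_ = spec.outcomes
    k = len(vars_)
    idx = {v: i for i, v in enumerate(vars_)}
    A = np.zeros((k, k))
    C = np.zeros((k, k))
    for out in vars_:
        for pos, (pred, timing) in enumerate(spec.paths[out]):
            b = theta[out].get(pos, 0.0)
            if timing == "lagged":
                A[idx[out], idx[pred]] = b
            else:
                C[idx[out], idx[pred]] = b
    return A, C


def centering_bias(
    spec: ModelSpec,
    theta: dict[str, dict[int, float]],
    n_participants: int,
    n_days: int,
    n_reps: int = 40,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Finite-horizon bias of the within-level regression under observed
    person-mean centering, by parametric bootstrap.

    Centering each variable at its observed person mean over a short
    series (here T of order 14) makes the centered lag correlate
    negatively with the innovation — the classic dynamic-panel small-T
    bias, roughly -(1 + beta)/(T - 1) on autoregressive paths. Person
    constants cancel exactly in the centering, so the bias depends only
    on the within dynamics: simulate the fitted standardized within
    process, re-apply the identical centering + standardization +
    regression mirror, and return the mean shift per within column.
    """
    from .synth import _unit_variance_noise  # local: avoids eager import

    vars_ = spec.outcomes
    k = len(vars_)
    idx = {v: i for i, v in enumerate(vars_)}
    A, C = _spec_matrices(spec, theta)
    B = np.linalg.inv(np.eye(k) - C)
    if np.max(np.abs(np.linalg.eigvals(B @ A))) >= 0.999:
        _warnings.warn("fitted within dynamics near non-stationary; "
                       "bias correction skipped")
        return {o: np.zeros(len(spec.paths[o])) for o in vars_}
    d = _unit_variance_noise(A, C)
    sd_e = np.sqrt(d)
    rng = np.random.default_rng(seed)
    n, T = n_participants, n_days
    burn = 30
    acc = {o: np.zeros(len(spec.paths[o])) for o in vars_}
    for _ in range(n_reps):
        w = np.zeros((n, k))
        ws = np.empty((n, T, k))
        for t in range(burn + T):
            e = rng.standard_normal((n, k)) * sd_e
            w = (A @ w.T + e.T).T @ B.T
            if t >= burn:
                ws[:, t - burn] = w
        wc = ws - ws.mean(axis=1, keepdims=True)  # person-mean centering
        for out in vars_:
            cols = []
            for pred, timing in spec.paths[out]:
                j = idx[pred]
                x = wc[:, 1:, j] if timing == "current" else wc[:, :-1, j]
                cols.append(x.reshape(-1))
            y = wc[:, 1:, idx[out]].reshape(-1)
            X = np.column_stack(cols)
            X = X / X.std(axis=0, ddof=1)
            y = y / y.std(ddof=1)
            coef, *_ = np.linalg.lstsq(
                np.hstack([np.ones((len(y), 1)), X]), y, rcond=None)
            truth = np.array([theta[out].get(p, 0.0)
                              for p in range(len(spec.paths[out]))])
            acc[out] += coef[1:] - truth
    return {o: acc[o] / n_reps for o in vars_}


@dataclass
class OutcomeFit:
    """Per-outcome designs and draws across imputations and chains."""

    outcome: str
    columns: list[dict]
    designs: list[dict]  # per imputation: y, X, pid_codes, rows
    beta: np.ndarray  # (m, chains, draws, 1 + p); column 0 is the intercept
    u: np.ndarray  # (m, chains, draws, J)
    sigma: np.ndarray  # (m, chains, draws)
    tau: np.ndarray
    #: per-imputation between-SD / total-SD ratio of the outcome; between
    #: coefficients are reported per total outcome SD (see methods note)
    b_factor: np.ndarray | None = None

    def pooled_beta(self, col: int) -> np.ndarray:
        draws = self.beta[..., col + 1]
        if self.b_factor is not None and self.columns[col]["level"] == "between":
            draws = draws * self.b_factor[:, None, None]
        return draws.reshape(-1)

    def rhat_of(self, col: int) -> float:
        vals = [rhat(self.beta[m, :, :, col + 1]) for m in range(self.beta.shape[0])]
        return float(np.nanmax(vals)) if vals else float("nan")


@dataclass
class FitResult:
    """Pooled estimates, draws and convergence summary for one model."""

    spec: ModelSpec
    outcome_fits: dict[str, OutcomeFit]
    paths: list[PathEstimate]
    m: int
    converged: bool
    within_bias: dict[str, np.ndarray] | None = None

    def path_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.paths])

    def get_path(self, predictor: str, outcome: str, level: str = "within") -> PathEstimate:
        for p in self.paths:
            if p.predictor == predictor and p.outcome == outcome and p.level == level:
                return p
        raise KeyError(f"no path {predictor}->{outcome} ({level})")

    def residual_sd(self) -> dict[str, float]:
        return {o: float(f.sigma.mean()) for o, f in self.outcome_fits.items()}

    def intercept_sd(self) -> dict[str, float]:
        return {o: float(f.tau.mean()) for o, f in self.outcome_fits.items()}


def fit(
    spec: ModelSpec,
    imputations: ImputationSet | DecomposedPanel,
    rhat_threshold: float = 1.01,
    debias: bool = True,
    debias_reps: int = 40,
) -> FitResult:
    """Fit every outcome equation on every completed panel and pool draws.

    Draws are pooled by concatenation across imputations; R-hat is
    computed within each imputation (across its chains) and the worst
    value is reported per path. Non-convergence is flagged on the result,
    never raised. With ``debias`` (default) the within-level coefficient
    draws are shifted by the parametric-bootstrap estimate of the
    person-mean-centering small-T bias (see :func:`centering_bias`).
    """
    if isinstance(imputations, DecomposedPanel):
        imputations = ImputationSet([], [imputations], seed=spec.seed)
    panels = imputations.decomposed
    m = len(panels)
    outcome_fits: dict[str, OutcomeFit] = {}
    for oi, outcome in enumerate(spec.outcomes):
        designs = []
        beta_all, u_all, sig_all, tau_all = [], [], [], []
        b_factors = []
        for mi, dp in enumerate(panels):
            b_factors.append(dp.between_sd[outcome] / dp.total_sd[outcome])
            y, X, cols, pid_codes, rows = build_design(spec, dp, outcome)
            designs.append({"y": y, "X": X, "pid_codes": pid_codes, "rows": rows})
            b_chains, u_chains, s_chains, t_chains = [], [], [], []
            for c in range(spec.chains):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=spec.seed,
                                           spawn_key=(oi, mi, c)))
                d = _gibbs(y, X, pid_codes, spec.iterations, spec.priors, rng)
                b_chains.append(d["beta"])
                u_chains.append(d["u"])
                s_chains.append(d["sigma"])
                t_chains.append(d["tau"])
            beta_all.append(np.stack(b_chains))
            u_all.append(np.stack(u_chains))
            sig_all.append(np.stack(s_chains))
            tau_all.append(np.stack(t_chains))
        outcome_fits[outcome] = OutcomeFit(
            outcome=outcome,
            columns=cols,
            designs=designs,
            beta=np.stack(beta_all),
            u=np.stack(u_all),
            sigma=np.stack(sig_all),
            tau=np.stack(tau_all),
            b_factor=np.asarray(b_factors),
        )

    bias: dict[str, np.ndarray] | None = None
    if debias:
        theta = {
            o: {j: float(of.pooled_beta(j).mean())
                for j, c in enumerate(of.columns) if c["level"] == "within"}
            for o, of in outcome_fits.items()
        }
        des0 = next(iter(outcome_fits.values())).designs[0]
        n_part = int(des0["pid_codes"].max()) + 1
        n_days = int(round(len(des0["y"]) / n_part)) + 1
        bias = centering_bias(spec, theta, n_part, n_days,
                              n_reps=debias_reps, seed=spec.seed + 7919)
        for o, of in outcome_fits.items():
            for j, c in enumerate(of.columns):
                if c["level"] == "within":
                    of.beta[..., j + 1] -= bias[o][j]

    paths: list[PathEstimate] = []
    converged = True
    for outcome, of in outcome_fits.items():
        for j, col in enumerate(of.columns):
            draws = of.pooled_beta(j)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rh = of.rhat_of(j)
            if not np.isfinite(rh) or rh >= rhat_threshold:
                converged = False
            paths.append(
                PathEstimate(
                    predictor=col["predictor"],
                    outcome=outcome,
                    level=col["level"],
                    timing=col["timing"],
                    beta=float(draws.mean()),
                    ci_low=float(lo),
                    ci_high=float(hi),
                    significant=significance(draws),
                    rhat=rh,
                )
            )
    return FitResult(spec=spec, outcome_fits=outcome_fits, paths=paths,
                     m=m, converged=converged, within_bias=bias)


def ppc_mean(result: FitResult, max_draws: int = 1000, seed: int = 0) -> dict[str, float]:
    """Posterior predictive p-value for the mean of each outcome.

    For each imputed dataset and each retained posterior draw, a
    replicated dataset is simulated from the fitted equation and the
    proportion of replications whose mean exceeds the observed mean is
    reported (pooled across imputations). Values near 0.5 mean the
    observed mean is typical under the model.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for outcome, of in result.outcome_fits.items():
        m, chains, keep, q = of.beta.shape
        exceed = total = 0
        for mi in range(m):
            des = of.designs[mi]
            Xi = np.hstack([np.ones((len(des["y"]), 1)), des["X"]])
            obs_mean = des["y"].mean()
            flat_beta = of.beta[mi].reshape(-1, q)
            flat_u = of.u[mi].reshape(-1, of.u.shape[-1])
            flat_sig = of.sigma[mi].reshape(-1)
            n_d = min(max_draws, flat_beta.shape[0])
            idx = rng.choice(flat_beta.shape[0], size=n_d, replace=False)
            for k in idx:
                mu = Xi @ flat_beta[k] + flat_u[k][des["pid_codes"]]
                y_rep = mu + flat_sig[k] * rng.standard_normal(len(mu))
                exceed += y_rep.mean() > obs_mean
                total += 1
        out[outcome] = exceed / total
    return out


def _pointwise_loglik(result: FitResult, max_draws: int = 1000, seed: int = 0):
    """Pointwise log-likelihood summed over outcomes, per person-day row.

    Returns (ids, array of shape (chains=1, draws, n_obs)). Rows are
    aligned on (participant, day); imputations are treated as additional
    draws (pooled posterior).
    """
    rng = np.random.default_rng(seed)
    ids = None
    per_outcome = []
    for outcome, of in result.outcome_fits.items():
        m, chains, keep, q = of.beta.shape
        rows0 = of.designs[0]["rows"]
        key = list(zip(rows0["participant_id"], rows0["day_index"]))
        if ids is None:
            ids = key
        elif key != ids:
            raise ValueError("outcome observation sets are not aligned")
        flat_beta = of.beta.reshape(-1, q)
        flat_u = of.u.reshape(-1, of.u.shape[-1])
        flat_sig = of.sigma.reshape(-1)
        n_d = min(max_draws, flat_beta.shape[0])
        idx = rng.choice(flat_beta.shape[0], size=n_d, replace=False)
        # map each pooled draw back to its imputation's design
        draws_per_imp = chains * keep
        ll = np.empty((n_d, len(ids)))
        for row_k, k in enumerate(idx):
            mi = k // draws_per_imp
            des = of.designs[mi]
            Xi = np.hstack([np.ones((len(des["y"]), 1)), des["X"]])
            mu = Xi @ flat_beta[k] + flat_u[k][des["pid_codes"]]
            sig = flat_sig[k]
            ll[row_k] = -0.5 * np.log(2 * np.pi * sig**2) - (des["y"] - mu) ** 2 / (
                2 * sig**2
            )
        per_outcome.append(ll)
    total_ll = np.sum(per_outcome, axis=0)
    return ids, total_ll[None, :, :]


def loo(result: FitResult, max_draws: int = 1000, seed: int = 0):
    """PSIS-LOO expected log pointwise predictive density (ELPD)."""
    ids, ll = _pointwise_loglik(result, max_draws=max_draws, seed=seed)
    idata = az.from_dict(log_likelihood={"y": ll})
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        # draws are pooled/subsampled across imputations and chains, so no
        # per-chain ESS is available; use relative efficiency 1
        res = az.loo(idata, pointwise=True, reff=1.0)
    return ids, res


def loo_compare(result_a: FitResult, result_b: FitResult,
                max_draws: int = 1000, seed: int = 0) -> tuple[float, float]:
    """ELPD difference (a minus b) and its SE; negative favours ``b``.

    Both fits must cover the same person-day observation set.
    """
    ids_a, loo_a = loo(result_a, max_draws=max_draws, seed=seed)
    ids_b, loo_b = loo(result_b, max_draws=max_draws, seed=seed)
    if set(ids_a) != set(ids_b):
        raise ValueError("fits cover different observation sets")
    pw_a = np.asarray(loo_a.loo_i)
    order = {k: i for i, k in enumerate(ids_b)}
    perm = [order[k] for k in ids_a]
    pw_b = np.asarray(loo_b.loo_i)[perm]
    diff = pw_a - pw_b
    return float(diff.sum()), float(np.sqrt(len(diff) * diff.var(ddof=1)))


class DsemModel(BaseEstimator):
    """Scikit-learn-style front end for the two-level DSEM.

    Parameters
    ----------
    model : 1 | 2
        1 = total sleep, TSU, SUiB; 2 = TSU, SUiB and the three sleep
        stages. Ignored when ``spec`` is given.
    chains, iterations, seed : sampler settings (half of ``iterations``
        is warmup).

    After ``fit`` the instance exposes ``result_`` (the full
    :class:`FitResult`), ``paths_`` (tidy coefficient table),
    ``converged_``, ``vif_`` and ``ppc_``.
    """

    def __init__(self, model: int = 1, chains: int = 2, iterations: int = 5000,
                 seed: int = 0, coef_prior_sd: float = 10.0,
                 scale_prior_df: float = 3.0, scale_prior_scale: float = 2.5,
                 debias: bool = True, spec: ModelSpec | None = None):
        self.model = model
        self.chains = chains
        self.iterations = iterations
        self.seed = seed
        self.coef_prior_sd = coef_prior_sd
        self.scale_prior_df = scale_prior_df
        self.scale_prior_scale = scale_prior_scale
        self.debias = debias
        self.spec = spec

    def _build_spec(self) -> ModelSpec:
        if self.spec is not None:
            return self.spec
        factory = ModelSpec.model1 if self.model == 1 else ModelSpec.model2
        return factory(
            priors=Priors(self.coef_prior_sd, self.scale_prior_df,
                          self.scale_prior_scale),
            chains=self.chains, iterations=self.iterations, seed=self.seed,
        )

    def fit(self, X: ImputationSet | DecomposedPanel, y=None):
        spec = self._build_spec()
        self.spec_ = spec
        self.result_ = fit(spec, X, debias=self.debias)
        self.paths_ = self.result_.path_table()
        self.converged_ = self.result_.converged
        first = next(iter(self.result_.outcome_fits.values()))
        n_within = sum(c["level"] == "within" for c in first.columns)
        self.vif_ = {
            o: vif(of.designs[0]["X"][:, :sum(c["level"] == "within"
                                              for c in of.columns)])
            for o, of in self.result_.outcome_fits.items()
        }
        self.ppc_ = ppc_mean(self.result_, seed=spec.seed)
        return self

    def predict(self, outcome: str, imputation: int = 0) -> np.ndarray:
        """Posterior-mean fitted values for one outcome equation."""
        of = self.result_.outcome_fits[outcome]
        des = of.designs[imputation]
        Xi = np.hstack([np.ones((len(des["y"]), 1)), des["X"]])
        q = of.beta.shape[-1]
        beta_mean = of.beta[imputation].reshape(-1, q).mean(axis=0)
        u_mean = of.u[imputation].reshape(-1, of.u.shape[-1]).mean(axis=0)
        return Xi @ beta_mean + u_mean[des["pid_codes"]]
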