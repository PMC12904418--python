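"""Synthetic study generator: the exact generative mirror of the DSEM.

Two fidelities are produced. ``simulate_panel`` draws person-day panels
from the model the estimator assumes: per participant a trait vector
(between level), then a lag-1 structural vector autoregression for the
within-person deviations, with same-day paths solved in the recursive
order TSU -> SUiB -> sleep. Within innovations are scaled so every
within component has unit stationary variance, which makes the generating
coefficients standardized betas directly. Latent values are mapped to
non-negative seconds through a softplus transform whose location and
scale are calibrated by quadrature so simulated means and SDs match the
configured study anchors; a hard floor would truncate the distribution
and bias parameter recovery, the softplus does not.

``simulate_raw`` renders a panel back into raw streams (step-count XML,
sleep-stage XML, hourly usage CSV) that round-trip through the in-bed
detector and panel builder to the same person-day numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Mapping
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.linalg import solve_discrete_lyapunov
from scipy.optimize import brentq, least_squares

from .io_ingest import DEFAULT_TIMEZONE

#: study-scale anchors in hours (mean, SD) per variable
STUDY_ANCHORS: dict[str, tuple[float, float]] = {
    "tsu": (3.85, 2.34),
    "suib": (0.54, 0.73),
    "sleep_total": (7.30, 1.38),
    "core": (4.98, 1.16),
    "deep": (0.73, 0.35),
    "rem": (1.55, 0.57),
}

MODEL1_VARIABLES = ["tsu", "suib", "sleep_total"]
MODEL2_VARIABLES = ["tsu", "suib", "core", "deep", "rem"]

#: within-person lag-1 coefficients, outcome -> {predictor: beta}
MODEL1_WITHIN_LAG = {
    "tsu": {"tsu": -0.00, "suib": 0.10, "sleep_total": -0.05},
    "suib": {"suib": 0.01, "sleep_total": 0.01},
    "sleep_total": {"sleep_total": -0.16},
}
#: within-person same-day coefficients (recursive order tsu -> suib -> sleep)
MODEL1_WITHIN_CURRENT = {
    "suib": {"tsu": 0.25},
    "sleep_total": {"tsu": -0.02, "suib": 0.08},
}
#: between-person stability targets (person-mean on lagged person-mean)
MODEL1_BETWEEN_STABILITY = {"tsu": 0.82, "suib": 0.63, "sleep_total": 0.53}

MODEL2_WITHIN_LAG = {
    "tsu": {"tsu": -0.00, "suib": 0.10, "core": -0.05, "deep": 0.00, "rem": -0.01},
    "suib": {"suib": 0.01, "core": -0.02, "deep": 0.03, "rem": -0.04},
    "core": {"core": -0.05, "deep": -0.03, "rem": -0.03},
    "deep": {"core": -0.07, "deep": -0.15, "rem": 0.01},
    "rem": {"core": -0.10, "deep": -0.02, "rem": -0.06},
}
MODEL2_WITHIN_CURRENT = {
    "suib": {"tsu": 0.25},
    "core": {"tsu": -0.03, "suib": 0.06},
    "deep": {"tsu": 0.01, "suib": 0.03},
    "rem": {"tsu": 0.02, "suib": 0.04},
}
MODEL2_BETWEEN_STABILITY = {
    "tsu": 0.82, "suib": 0.63, "core": 0.58, "deep": 0.56, "rem": 0.56,
}

#: average share of each stage in total sleep, from the stage anchors
_STAGE_SHARES = np.array([4.98, 0.73, 1.55]) / (4.98 + 0.73 + 1.55)  # core, deep, rem


class CalibrationError(ValueError):
    """Raised when a between-level target cannot be reached."""

    def __init__(self, msg: str, floor: float | None = None):
        super().__init__(msg)
        self.floor = floor


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the study conditions.

    ``lag`` and ``current`` map outcome -> {predictor: coefficient} on the
    standardized within scale; ``current`` must be acyclic in the order of
    ``variables``. ``trait_var`` is the between (trait) variance per
    variable on that same scale, so ICC = trait_var / (1 + trait_var).
    """

    variables: list[str] = field(default_factory=lambda: list(MODEL1_VARIABLES))
    n_participants: int = 68
    n_days: int = 14
    lag: dict = field(default_factory=lambda: {k: dict(v) for k, v in MODEL1_WITHIN_LAG.items()})
    current: dict = field(default_factory=lambda: {k: dict(v) for k, v in MODEL1_WITHIN_CURRENT.items()})
    trait_var: dict = field(default_factory=lambda: {v: 1.0 for v in MODEL1_VARIABLES})
    anchors: dict = field(default_factory=lambda: {k: STUDY_ANCHORS[k] for k in MODEL1_VARIABLES})
    softness_factor: float = 1.0  # softplus softness as a multiple of the anchor SD
    missing_rate: float = 0.05
    seed: int = 0
    start_date: date = date(2024, 3, 4)

    def __post_init__(self):
        k = len(self.variables)
        order = {v: i for i, v in enumerate(self.variables)}
        for out, preds in self.current.items():
            for p in preds:
                if order[p] >= order[out]:
                    raise ValueError(f"current path {p}->{out} is not acyclic")
        A, C = self.matrices()
        B = np.linalg.inv(np.eye(k) - C)
        if np.max(np.abs(np.linalg.eigvals(B @ A))) >= 1:
            raise ValueError("within dynamics are non-stationary")
        for v, tv in self.trait_var.items():
            if tv < 0:
                raise ValueError(f"negative trait variance for {v}")
        for v, (m, s) in self.anchors.items():
            if s <= 0:
                raise ValueError(f"non-positive anchor SD for {v}")

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, C): lag and current coefficient matrices, rows = outcomes."""
        k = len(self.variables)
        idx = {v: i for i, v in enumerate(self.variables)}
        A = np.zeros((k, k))
        C = np.zeros((k, k))
        for out, preds in self.lag.items():
            for p, b in preds.items():
                A[idx[out], idx[p]] = b
        for out, preds in self.current.items():
            for p, b in preds.items():
                C[idx[out], idx[p]] = b
        return A, C

    @classmethod
    def model1(cls, **kw) -> "SynthConfig":
        return cls(**kw)

    @classmethod
    def model2(cls, **kw) -> "SynthConfig":
        kw.setdefault("variables", list(MODEL2_VARIABLES))
        kw.setdefault("lag", {k: dict(v) for k, v in MODEL2_WITHIN_LAG.items()})
        kw.setdefault("current", {k: dict(v) for k, v in MODEL2_WITHIN_CURRENT.items()})
        kw.setdefault("trait_var", {v: 1.0 for v in MODEL2_VARIABLES})
        kw.setdefault("anchors", {k: STUDY_ANCHORS[k] for k in MODEL2_VARIABLES})
        return cls(**kw)


def _unit_variance_noise(A: np.ndarray, C: np.ndarray,
                         tol: float = 1e-12, max_iter: int = 500) -> np.ndarray:
    """Innovation variances making every within component unit-variance.

    Fixed-point on the diagonal of the stationary covariance of the
    reduced-form VAR(1).
    """
    k = A.shape[0]
    B = np.linalg.inv(np.eye(k) - C)
    Ared = B @ A
    d = np.ones(k)
    for _ in range(max_iter):
        S = B @ np.diag(d) @ B.T
        Sigma = solve_discrete_lyapunov(Ared, S)
        dg = np.diag(Sigma)
        if np.max(np.abs(dg - 1)) < tol:
            break
        d = d / dg
    return d


def _stationary_cov(A: np.ndarray, C: np.ndarray, d: np.ndarray) -> np.ndarray:
    k = A.shape[0]
    B = np.linalg.inv(np.eye(k) - C)
    return solve_discrete_lyapunov(B @ A, B @ np.diag(d) @ B.T)


_GH_X, _GH_W = hermegauss(64)
_GH_W = _GH_W / _GH_W.sum()


def _softplus(x: np.ndarray, soft: float) -> np.ndarray:
    return soft * np.logaddexp(0.0, x / soft)


def _calibrate_transform(mean: float, sd: float, soft: float) -> tuple[float, float]:
    """Location/scale of the latent normal so that the softplus output has
    the requested mean and SD (Gauss-Hermite moment matching)."""

    def resid(p):
        m, s = p
        y = _softplus(m + abs(s) * _GH_X, soft)
        mu = float(y @ _GH_W)
        var = float(((y - mu) ** 2) @ _GH_W)
        return [mu - mean, np.sqrt(var) - sd]

    sol = least_squares(resid, x0=[mean, sd], xtol=1e-12, ftol=1e-12)
    m, s = sol.x
    return float(m), float(abs(s))


_GH2_X, _GH2_W = hermegauss(32)
_GH2_W = _GH2_W / _GH2_W.sum()


def _calibrate_capped_transform(
    mean: float, sd: float, soft: float,
    other: tuple[float, float, float], rho: float,
) -> tuple[float, float]:
    """Like :func:`_calibrate_transform` but matching the moments of the
    capped value min(g(x), g_other(x_other)) for correlated latents."""
    lo, so, soft_o = other
    zt = _GH2_X[:, None]
    eta = _GH2_X[None, :]
    w2 = _GH2_W[:, None] * _GH2_W[None, :]
    z_s = rho * zt + np.sqrt(max(1 - rho**2, 0.0)) * eta
    g_other = _softplus(lo + so * zt, soft_o)

    def resid(p):
        m, s = p
        y = np.minimum(_softplus(m + abs(s) * z_s, soft), g_other)
        mu = float((y * w2).sum())
        var = float((((y - mu) ** 2) * w2).sum())
        return [mu - mean, np.sqrt(var) - sd]

    sol = least_squares(resid, x0=[mean, sd], xtol=1e-12, ftol=1e-12)
    m, s = sol.x
    return float(m), float(abs(s))


@dataclass
class TruthRecord:
    """Generating parameters and bookkeeping for one simulated study."""

    config: SynthConfig
    noise_var: np.ndarray
    transform: dict[str, tuple[float, float, float]]  # var -> (loc, scale, soft)
    clip_suib_days: int = 0
    n_missing_cells: int = 0

    def clip_fraction(self, n_days_total: int) -> float:
        return self.clip_suib_days / max(n_days_total, 1)


def simulate_panel(
    config: SynthConfig, seed: int | None = None
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw one study panel from the generative model.

    Returns the tidy panel (seconds, NaN for missing cells) and the truth
    record with every generating parameter. For the three-variable
    configuration the sleep stages are carved out of total sleep with
    near-constant shares so the panel satisfies the stage-sum identity.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    vars_ = config.variables
    k = len(vars_)
    n, T = config.n_participants, config.n_days
    A, C = config.matrices()
    d = _unit_variance_noise(A, C)
    Sigma0 = _stationary_cov(A, C, d)
    B = np.linalg.inv(np.eye(k) - C)
    tv = np.array([config.trait_var[v] for v in vars_])

    traits = rng.standard_normal((n, k)) * np.sqrt(tv)
    w = np.empty((n, T, k))
    L0 = np.linalg.cholesky(Sigma0 + 1e-12 * np.eye(k))
    w[:, 0] = rng.standard_normal((n, k)) @ L0.T
    sd_e = np.sqrt(d)
    for t in range(1, T):
        e = rng.standard_normal((n, k)) * sd_e
        w[:, t] = (A @ w[:, t - 1].T + e.T).T @ B.T

    latent = traits[:, None, :] + w  # total variance 1 + trait_var
    z = latent / np.sqrt(1.0 + tv)

    transform: dict[str, tuple[float, float, float]] = {}
    hours = np.empty_like(z)
    for j, v in enumerate(vars_):
        m_a, s_a = config.anchors[v]
        soft = config.softness_factor * s_a
        if v == "suib" and "tsu" in vars_:
            # the SUiB <= TSU cap shaves the upper tail; match the capped
            # moments so anchors hold on the emitted panel
            jt = vars_.index("tsu")
            rho = float(Sigma0[j, jt] + 0.0) / np.sqrt((1 + tv[j]) * (1 + tv[jt]))
            loc, scale = _calibrate_capped_transform(
                m_a, s_a, soft, transform["tsu"], rho)
        else:
            loc, scale = _calibrate_transform(m_a, s_a, soft)
        transform[v] = (loc, scale, soft)
        hours[:, :, j] = _softplus(loc + scale * z[:, :, j], soft)

    seconds = hours * 3600.0
    cols = {v: seconds[:, :, j] for j, v in enumerate(vars_)}
    truth = TruthRecord(config=config, noise_var=d, transform=transform)

    if "tsu" in cols and "suib" in cols:
        clip = cols["suib"] > cols["tsu"]
        truth.clip_suib_days = int(clip.sum())
        cols["suib"] = np.minimum(cols["suib"], cols["tsu"])

    if "sleep_total" in cols and "core" not in cols:
        # carve stages out of total sleep with lightly jittered shares
        shares = rng.dirichlet(_STAGE_SHARES * 60.0, size=(n, T))
        for j, stage in enumerate(["core", "deep", "rem"]):
            cols[stage] = cols["sleep_total"] * shares[:, :, j]
    elif "core" in cols and "sleep_total" not in cols:
        cols["sleep_total"] = cols["core"] + cols["deep"] + cols["rem"]

    # source-level MCAR missingness: the watch block and the screenshot
    # block drop independently; SUiB needs both
    miss_sleep = rng.random((n, T)) < config.missing_rate
    miss_st = rng.random((n, T)) < config.missing_rate
    for v in ("sleep_total", "core", "deep", "rem"):
        cols[v] = np.where(miss_sleep, np.nan, cols[v])
    cols["tsu"] = np.where(miss_st, np.nan, cols["tsu"])
    cols["suib"] = np.where(miss_sleep | miss_st, np.nan, cols["suib"])
    truth.n_missing_cells = int(miss_sleep.sum() + miss_st.sum())

    rows = []
    for i in range(n):
        pid = f"sim{i + 1:03d}"
        for t in range(T):
            rows.append({
                "participant_id": pid,
                "day_index": t + 1,
                "date": config.start_date + timedelta(days=t),
                "tsu_s": cols["tsu"][i, t],
                "suib_s": cols["suib"][i, t],
                "sleep_total_s": cols["sleep_total"][i, t],
                "rem_s": cols["rem"][i, t],
                "core_s": cols["core"][i, t],
                "deep_s": cols["deep"][i, t],
            })
    panel = pd.DataFrame(rows)
    return panel, truth


def _between_betas(config: SynthConfig, n_check: int, seed: int) -> dict[str, float]:
    """Observed-scale between-level stability coefficients at large n.

    Simulates a complete panel, decomposes it, and regresses each
    variable's standardized current-series person mean on the lagged-series
    person means of that variable's predictors (jointly), returning the
    own-variable coefficient.
    """
    from .panel import decompose

    big = replace(config, n_participants=n_check, missing_rate=0.0)
    panel, _ = simulate_panel(big, seed=seed)
    dp = decompose(panel, variables=config.variables)
    first = dp.data.groupby("participant_id").first()
    out: dict[str, float] = {}
    for v in config.variables:
        preds = [p for p in config.variables]
        Xb = np.column_stack([first[f"b_{p}_lag"].to_numpy() for p in preds])
        yb = first[f"b_{v}"].to_numpy()
        coef, *_ = np.linalg.lstsq(
            np.hstack([np.ones((len(yb), 1)), Xb]), yb, rcond=None
        )
        # reported scale: per between-SD of the predictor and total
        # day-level SD of the outcome
        out[v] = float(coef[1 + preds.index(v)]) * dp.between_sd[v] / dp.total_sd[v]
    return out


def calibrate_between(
    config: SynthConfig,
    target_betas: Mapping[str, float] | None = None,
    tol: float = 0.03,
    n_check: int = 4000,
    max_rounds: int = 6,
    seed: int = 2024,
) -> SynthConfig:
    """Tune per-variable trait variances to hit between-level stabilities.

    The stability coefficient rises monotonically in the trait variance
    from a positive floor (overlapping 13-day person means share almost
    all their within noise, so even zero trait variance leaves a strong
    spurious stability) toward 1. Targets at or above 1 are infeasible by
    construction; targets below the floor raise with the measured floor.
    Search is Monte-Carlo: a large-n panel is simulated each round and the
    trait variances updated by inverting the map
    beta(v) = (v + c) / sqrt((v + psi)(1 + v)), with the shared-noise
    parameters (c, psi) refit from the current round and the floor.
    """
    targets = dict(target_betas) if target_betas is not None else (
        dict(MODEL1_BETWEEN_STABILITY) if set(config.variables) == set(MODEL1_VARIABLES)
        else dict(MODEL2_BETWEEN_STABILITY)
    )
    for v, t in targets.items():
        if t >= 1.0:
            raise CalibrationError(f"target stability {t} for {v} is >= 1 (infeasible)")

    floor_cfg = replace(config, trait_var={v: 1e-8 for v in config.variables})
    floors = _between_betas(floor_cfg, n_check, seed)
    for v, t in targets.items():
        if t < floors[v] - tol:
            raise CalibrationError(
                f"target {t} for {v} is below the feasible floor {floors[v]:.3f} "
                "(overlapping person means share within noise)",
                floor=floors[v],
            )

    tv = {v: max(config.trait_var.get(v, 1.0), 1e-6) for v in config.variables}
    cfg = replace(config, trait_var=dict(tv))
    for rnd in range(max_rounds):
        betas = _between_betas(cfg, n_check, seed + rnd)
        done = all(abs(betas[v] - targets[v]) <= tol * 0.75 for v in targets)
        if done:
            break
        new_tv = dict(tv)
        for v, t in targets.items():
            b, vv, f = betas[v], tv[v], float(np.clip(floors[v], 1e-3, 0.98))

            # beta(v) = (v + c)/sqrt((v + psi)(1 + v)); f = c/sqrt(psi)
            def _psi_resid(psi, b=b, vv=vv, f=f):
                c = f * np.sqrt(psi)
                return (vv + c) / np.sqrt((vv + psi) * (1 + vv)) - b

            try:
                psi = brentq(_psi_resid, 1e-5, 5.0)
            except ValueError:
                psi = 0.077  # white-noise overlap value
            c = f * np.sqrt(psi)

            def _beta_of(x, c=c, psi=psi):
                return (x + c) / np.sqrt((x + psi) * (1 + x)) - t

            try:
                new_v = brentq(_beta_of, 1e-8, 1e4)
            except ValueError:
                new_v = vv * (t / max(b, 1e-3)) ** 2
            new_tv[v] = float(np.clip(new_v, 1e-6, 100.0))
        tv = new_tv
        cfg = replace(cfg, trait_var=dict(tv))
    return cfg


# ---------------------------------------------------------------------------
# raw-stream rendering


@dataclass
class RawStreams:
    """Text renderings of one panel as raw study inputs."""

    steps_xml: str
    sleep_xml: str
    usage_csv: str


def _fmt_hk(ts: datetime) -> str:
    return ts.strftime("%Y-%m-%d %H:%M:%S %z")


def simulate_raw(
    panel: pd.DataFrame,
    config: SynthConfig | None = None,
    timezone: str = DEFAULT_TIMEZONE,
    seed: int = 0,
) -> RawStreams:
    """Render a panel into step XML, sleep XML and an hourly usage CSV.

    Each observed night gets a 10-minute-aligned in-bed interval starting
    near 23:00 with zero recorded steps inside and active step records
    outside; sleep-stage records partition total sleep inside the
    interval in short cycles; in-bed screen time is placed in clock hours
    fully contained in the interval (spilling into boundary hours with a
    proration-compensated amount when full hours run out) and the rest of
    the daily total goes to daytime hours. Pushing the streams back
    through the detector and the panel builder recovers the input panel
    up to hourly-proration rounding.
    """
    tz = ZoneInfo(timezone)
    rng = np.random.default_rng(seed)
    bad = panel.dropna(subset=["tsu_s", "suib_s"])
    if (bad["suib_s"] > bad["tsu_s"] + 1e-6).any():
        raise ValueError("panel has suib_s > tsu_s")

    steps_parts = ["<HealthData>"]
    sleep_parts = ["<HealthData>"]
    usage_rows = ["participant,date,hour,seconds"]

    def step_rec(pid, t0, t1, n):
        steps_parts.append(
            f'  <Record type="HKQuantityTypeIdentifierStepCount" value="{n}"'
            f' sourceName="{pid}" startDate="{_fmt_hk(t0)}" endDate="{_fmt_hk(t1)}"/>'
        )

    def sleep_rec(pid, stage, t0, t1):
        val = {"core": "AsleepCore", "deep": "AsleepDeep", "rem": "AsleepREM",
               "awake": "Awake"}[stage]
        sleep_parts.append(
            f'  <Record type="HKCategoryTypeIdentifierSleepAnalysis"'
            f' value="HKCategoryValueSleepAnalysis{val}" sourceName="{pid}"'
            f' startDate="{_fmt_hk(t0)}" endDate="{_fmt_hk(t1)}"/>'
        )

    def active_steps(pid, t0, t1):
        """10-min step records with clearly active counts over [t0, t1)."""
        cur = t0
        while cur < t1:
            nxt = min(cur + timedelta(minutes=10), t1)
            step_rec(pid, cur, nxt, int(rng.integers(20, 80)))
            cur = nxt

    usage_alloc: dict[tuple[str, date, int], float] = {}

    def add_usage(pid, d, hour, sec):
        key = (pid, d, hour)
        usage_alloc[key] = usage_alloc.get(key, 0.0) + sec

    for pid, grp in panel.groupby("participant_id", sort=True):
        grp = grp.sort_values("day_index")
        prev_exit: datetime | None = None
        for _, row in grp.iterrows():
            day_free_start: datetime | None = None
            day: date = row["date"] if isinstance(row["date"], date) else pd.Timestamp(row["date"]).date()
            sleep_s = row["sleep_total_s"]
            have_sleep = np.isfinite(sleep_s) and sleep_s > 0
            noon = datetime.combine(day, time(12, 0), tzinfo=tz)
            win_open = datetime.combine(day, time(20, 0), tzinfo=tz)

            if have_sleep:
                dur_epochs = int(np.ceil(sleep_s / 600.0)) + 2  # sleep + margin
                dur = timedelta(seconds=600 * max(dur_epochs, 19))  # >= 3h10
                enter = datetime.combine(day, time(23, 0), tzinfo=tz)
                latest_exit = datetime.combine(day + timedelta(days=1),
                                               time(11, 50), tzinfo=tz)
                if enter + dur > latest_exit:
                    enter = latest_exit - dur
                enter = max(enter, win_open + timedelta(minutes=10))
                exit_ = enter + dur

                # daytime + evening activity; none on missing nights
                day_start = prev_exit if prev_exit is not None else noon - timedelta(hours=4)
                day_free_start = day_start
                day_free_end = enter
                active_steps(pid, day_start, enter)
                prev_exit = exit_

                # stage records: short cycles filling sleep_s from enter
                stages = [("core", row["core_s"]), ("deep", row["deep_s"]),
                          ("rem", row["rem_s"])]
                cur = enter
                n_cycles = 4
                for ci in range(n_cycles):
                    for stage, total in stages:
                        if not np.isfinite(total) or total <= 0:
                            continue
                        chunk = total / n_cycles
                        sleep_rec(pid, stage, cur, cur + timedelta(seconds=chunk))
                        cur = cur + timedelta(seconds=chunk)

                # in-bed usage: fill fully-contained clock hours first
                suib = float(row["suib_s"]) if np.isfinite(row["suib_s"]) else 0.0
                first_full = enter.replace(minute=0, second=0, microsecond=0)
                if first_full < enter:
                    first_full += timedelta(hours=1)
                full_hours = []
                h = first_full
                while h + timedelta(hours=1) <= exit_:
                    full_hours.append(h)
                    h += timedelta(hours=1)
                remaining = suib
                if full_hours:
                    per = min(3600.0, remaining / len(full_hours))
                    for h in full_hours:
                        amt = min(per, remaining)
                        if amt > 0:
                            add_usage(pid, h.date(), h.hour, amt)
                        remaining -= amt
                if remaining > 1e-9:
                    # boundary hours, compensated for uniform proration
                    for h, frac in _boundary_hours(enter, exit_):
                        cap = 3600.0 * frac
                        amt = min(remaining, cap)
                        if amt > 0:
                            add_usage(pid, h.date(), h.hour, amt / frac)
                            remaining -= amt
                        if remaining <= 1e-9:
                            break
            else:
                # watch off for the night: no step coverage from the window
                # open until next noon, so the night is flagged missing
                day_start = prev_exit if prev_exit is not None else noon - timedelta(hours=4)
                day_free_start = day_start
                day_free_end = win_open
                active_steps(pid, day_start, win_open)
                prev_exit = datetime.combine(day + timedelta(days=1),
                                             time(12, 0), tzinfo=tz)

            # daytime usage goes only to clock hours fully outside every
            # in-bed interval (between the morning exit and tonight's
            # entry); overflow beyond that capacity is dropped — TSU is
            # recovered from the daily-total row, not from hourly rows
            tsu = float(row["tsu_s"]) if np.isfinite(row["tsu_s"]) else np.nan
            if np.isfinite(tsu):
                suib_day = float(row["suib_s"]) if np.isfinite(row["suib_s"]) else 0.0
                outside = max(tsu - suib_day, 0.0)
                h = day_free_start.replace(minute=0, second=0, microsecond=0)
                if h < day_free_start:
                    h += timedelta(hours=1)
                while outside > 0 and h + timedelta(hours=1) <= day_free_end:
                    amt = min(outside, 3600.0)
                    add_usage(pid, h.date(), h.hour, amt)
                    outside -= amt
                    h += timedelta(hours=1)
                usage_rows.append(f"{pid},{day.isoformat()},daily,{tsu:.0f}")
        if prev_exit is not None:  # morning after the last night
            active_steps(pid, prev_exit, prev_exit.replace(hour=12, minute=0))

    for (pid, d, hour), sec in sorted(usage_alloc.items()):
        usage_rows.append(f"{pid},{d.isoformat()},{hour},{min(sec, 3600.0):.3f}")

    steps_parts.append("</HealthData>")
    sleep_parts.append("</HealthData>")
    return RawStreams(
        steps_xml="\n".join(steps_parts),
        sleep_xml="\n".join(sleep_parts),
        usage_csv="\n".join(usage_rows) + "\n",
    )


def _boundary_hours(enter: datetime, exit_: datetime):
    """Partially-overlapped clock hours of an interval with their overlap
    fraction, widest overlap first."""
    out = []
    h = enter.replace(minute=0, second=0, microsecond=0)
    while h < exit_:
        frac = (min(exit_, h + timedelta(hours=1)) - max(enter, h)).total_seconds() / 3600.0
        if 0 < frac < 1:
            out.append((h, frac))
        h += timedelta(hours=1)
    return sorted(out, key=lambda t: -t[1])
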