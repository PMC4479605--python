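"""Foci kinetics: control-decay correction, half-life fits, GMM focus
classification and linear-programming mass-balance conversion rates.

The conversion-rate estimator treats the five protein pools (diffuse nuclear
background, class 0, plus four focus classes) as compartments. Between
consecutive frames the class intensity vector obeys mass balance

    I_k(t) = I_k(t - dt) + P_k - R_k,
    P_k = sum_{j != k} C_jk I_j(t - dt),     (inflow to k)
    R_k = sum_{j != k} C_kj I_k(t - dt),     (outflow from k)

where C_jk in [0, 1] is the fraction of class j's intensity converting to
class k over the interval. The system is underdetermined (20 unknown
off-diagonal rates, 5 balance equations), so the sparsest transport is chosen
by minimising the sum of the conversion rates subject to the balance
constraints — a linear program. Additive slack with a large penalty absorbs
violations of total-intensity conservation that measurement noise introduces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, linprog
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

N_CLASSES = 5  # background pool 0 + focus classes 1..4


class FitError(RuntimeError):
    """A curve fit failed to converge or the data violate its assumptions."""


# --------------------------------------------------------------------------
# decay fitting


@dataclass
class DecayFit:
    """Exponential settling of spontaneous foci: A*exp(-rate*t) + plateau."""

    amplitude: float
    rate_per_h: float
    plateau: float
    window_h: tuple[float, float] = (0.0, math.inf)

    @property
    def half_life_h(self) -> float:
        return math.inf if self.rate_per_h == 0 else math.log(2.0) / self.rate_per_h

    def predict(self, times_h: np.ndarray) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        return self.amplitude * np.exp(-self.rate_per_h * t) + self.plateau


def fit_control_decay(times_h: np.ndarray, counts: np.ndarray) -> DecayFit:
    """Least-squares fit of A*exp(-rate*t) + plateau to control foci counts.

    Times are hours from the start of acquisition. A constant series returns
    the degenerate fit (A=0, rate=0, plateau=mean).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    t0 = t - t[0]
    if np.ptp(y) < 1e-12:
        return DecayFit(0.0, 0.0, float(y.mean()), (float(t[0]), float(t[-1])))
    p0 = (max(y[0] - y.min(), 1e-3), 0.1, float(y.min()))
    try:
        popt, _ = curve_fit(
            lambda tt, a, r, c: a * np.exp(-r * tt) + c,
            t0, y, p0=p0, bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise FitError(f"control decay fit did not converge: {err}") from err
    # report relative to t[0] = start of acquisition
    return DecayFit(float(popt[0]), float(popt[1]), float(popt[2]),
                    (float(t[0]), float(t[-1])))


def subtract_control(
    times_h: np.ndarray,
    series: np.ndarray,
    control_fit: DecayFit,
    control_t0_h: float | None = None,
) -> np.ndarray:
    """Subtract the fitted (idealised) control curve, never the raw counts."""
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(series, dtype=float)
    if t.shape != y.shape:
        raise ValueError("timeline and series lengths differ")
    t0 = t[0] if control_t0_h is None else control_t0_h
    return y - control_fit.predict(t - t0)


def fit_half_life(
    times_h: np.ndarray, series: np.ndarray, window_h: float = 20.0
) -> float:
    """Half-life (h) of the post-peak exponential decay within a window.

    Fits A*exp(-rate*(t - t_peak)) from the series maximum over the next
    ``window_h`` hours and returns ln(2)/rate.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(series, dtype=float)
    peak = int(np.argmax(y))
    sel = (t >= t[peak]) & (t <= t[peak] + window_h)
    ts, ys = t[sel] - t[peak], y[sel]
    if len(ts) < 3:
        raise FitError("too few points after the peak to fit a decay")
    if ys[-1] >= ys[0]:
        raise FitError("series does not decay after its peak")
    p0 = (max(ys[0], 1e-3), 0.1)
    popt, _ = curve_fit(
        lambda tt, a, r: a * np.exp(-r * tt), ts, ys, p0=p0,
        bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=20000,
    )
    return math.log(2.0) / float(popt[1])


# --------------------------------------------------------------------------
# focus classification


@dataclass
class FociClassModel:
    """GMM over (log area, log mean intensity) with size-ordered classes.

    ``order`` maps fitted component index -> class label 1..K so class 1 is
    the smallest/dimmest (lowest mean log area + log intensity) and class K
    the largest/brightest.
    """

    n_classes: int
    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    order: np.ndarray                    # component index -> class label
    rep_selections: list[int] = field(default_factory=list)
    seed: int | None = None
    _gmm: GaussianMixture | None = None

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "weights": self.weights.tolist(),
            "order": self.order.tolist(),
            "rep_selections": list(self.rep_selections),
            "seed": self.seed,
        }


def _features_to_log(features: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        X = features[["area_um2", "mean_intensity"]].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if np.any(X <= 0):
        raise ValueError("areas and intensities must be positive for log features")
    return np.log(X)


def fit_foci_classes(
    features: pd.DataFrame | np.ndarray,
    n_subsample: int = 10_000,
    n_reps: int = 10,
    k_max: int = 5,
    random_state: int = 0,
) -> FociClassModel:
    """Select K and fit the focus-class mixture the stability-protocol way.

    For each of ``n_reps`` repetitions a random subsample of ``n_subsample``
    points is drawn and mixtures with 1..k_max components are fitted; the
    component count minimising BIC is recorded. The final K is the modal
    selection across repetitions and the final model is refit on one
    subsample. Classes are relabelled by ascending mean(log area + log
    intensity), i.e. small/dim first.
    """
    X = _features_to_log(features)
    rng = np.random.default_rng(random_state)
    if len(X) < n_subsample:
        log.warning(
            "only %d feature rows (< %d); using all rows per repetition",
            len(X), n_subsample,
        )
    selections = []
    first_subsample = None
    for rep in range(n_reps):
        if len(X) > n_subsample:
            idx = rng.choice(len(X), n_subsample, replace=False)
            S = X[idx]
        else:
            S = X
        if first_subsample is None:
            first_subsample = S
        bics = []
        for k in range(1, k_max + 1):
            gm = GaussianMixture(
                n_components=k, n_init=3, reg_covar=1e-6,
                random_state=random_state + rep,
            ).fit(S)
            bics.append(gm.bic(S))
        selections.append(int(np.argmin(bics)) + 1)
    values, counts = np.unique(selections, return_counts=True)
    K = int(values[np.argmax(counts)])
    final = GaussianMixture(
        n_components=K, n_init=5, reg_covar=1e-6, random_state=random_state
    ).fit(first_subsample)
    size_key = final.means_.sum(axis=1)  # log area + log intensity
    comp_rank = np.argsort(np.argsort(size_key, kind="stable"), kind="stable")
    order = comp_rank + 1  # component index -> class label
    return FociClassModel(
        n_classes=K,
        means=final.means_.copy(),
        covariances=final.covariances_.copy(),
        weights=final.weights_.copy(),
        order=order,
        rep_selections=selections,
        seed=random_state,
        _gmm=final,
    )


def assign_class(
    features: pd.DataFrame | np.ndarray, model: FociClassModel
) -> np.ndarray:
    """Maximum-posterior class labels 1..K; ties break to the lower class."""
    X = _features_to_log(features)
    if model._gmm is not None:
        resp = model._gmm.predict_proba(X)
    else:  # rebuild from stored parameters
        gm = GaussianMixture(n_components=model.n_classes)
        gm.means_ = model.means
        gm.covariances_ = model.covariances
        gm.weights_ = model.weights
        gm.precisions_cholesky_ = np.linalg.cholesky(
            np.linalg.inv(model.covariances)
        ).transpose(0, 2, 1)
        resp = gm.predict_proba(X)
    # reorder columns into class order; argmax picks the lower class on ties
    by_class = np.zeros_like(resp)
    for comp, cls in enumerate(model.order):
        by_class[:, cls - 1] = resp[:, comp]
    return np.argmax(by_class, axis=1) + 1


def class_intensity_series(
    foci: pd.DataFrame,
    nuclear: pd.DataFrame,
    n_focus_classes: int = 4,
) -> pd.DataFrame:
    """Per-frame class intensity vector I_0..I_K, normalised per nucleus.

    ``foci`` needs frame, total_intensity, class_label; ``nuclear`` needs
    frame, I_nuclear, I_foci (one row per nucleus per frame). Class 0 is the
    protein not in any focus, so sum_k I_k equals the mean nuclear intensity
    at every frame.
    """
    frames = sorted(nuclear.frame.unique())
    rows = []
    for f in frames:
        nsub = nuclear[nuclear.frame == f]
        n_nuc = max(len(nsub), 1)
        row = {"frame": f, "I0": float((nsub.I_nuclear - nsub.I_foci).sum()) / n_nuc}
        fsub = foci[foci.frame == f] if len(foci) else foci
        for k in range(1, n_focus_classes + 1):
            tot = float(fsub[fsub.class_label == k].total_intensity.sum()) if len(fsub) else 0.0
            row[f"I{k}"] = tot / n_nuc
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# conversion-rate linear program


@dataclass
class ConversionStep:
    """One frame pair's estimated rate matrix and diagnostics."""

    time_min: float
    dt_min: float
    I_prev: np.ndarray
    I_curr: np.ndarray
    rates: np.ndarray            # (K, K), zero diagonal
    slack: np.ndarray            # signed per-class slack
    objective: float

    @property
    def flows(self) -> np.ndarray:
        """Protein amount moved j -> k over the step: C_jk * I_j(t - dt)."""
        return self.rates * self.I_prev[:, None]

    @property
    def predicted_curr(self) -> np.ndarray:
        inflow = self.rates.T @ self.I_prev
        outflow = self.rates.sum(axis=1) * self.I_prev
        return self.I_prev + inflow - outflow


class LPError(RuntimeError):
    def __init__(self, message: str, lp_dump: dict | None = None):
        super().__init__(message)
        self.lp_dump = lp_dump or {}


def estimate_conversion_rates(
    I_prev: np.ndarray,
    I_curr: np.ndarray,
    dt_min: float,
    time_min: float = 0.0,
    slack_weight: float = 1e3,
) -> ConversionStep:
    """Minimal-sum conversion rates between protein pools via linear
    programming.

    Minimises sum(C_jk) + W * sum(|slack_k|) subject to per-class mass balance
    with additive slack, 0 <= C_jk <= 1, per-class outflow row sums <= 1, and
    C_jk fixed to 0 whenever class j held no intensity at the previous frame.
    """
    I_prev = np.asarray(I_prev, dtype=float)
    I_curr = np.asarray(I_curr, dtype=float)
    K = len(I_prev)
    if len(I_curr) != K:
        raise ValueError("I_prev and I_curr lengths differ")
    if np.any(I_prev < 0) or np.any(I_curr < 0):
        raise ValueError("intensities must be non-negative")
    pairs = [(j, k) for j in range(K) for k in range(K) if j != k]
    nvar = len(pairs)
    c = np.concatenate([np.ones(nvar), slack_weight * np.ones(2 * K)])
    A_eq = np.zeros((K, nvar + 2 * K))
    b_eq = I_curr - I_prev
    for col, (j, k) in enumerate(pairs):
        A_eq[k, col] += I_prev[j]   # inflow to k
        A_eq[j, col] -= I_prev[j]   # outflow from j
    for k in range(K):
        A_eq[k, nvar + k] = 1.0          # slack+
        A_eq[k, nvar + K + k] = -1.0     # slack-
    A_ub = np.zeros((K, nvar + 2 * K))
    for col, (j, k) in enumerate(pairs):
        A_ub[j, col] = 1.0
    b_ub = np.ones(K)
    bounds = [
        (0.0, 0.0) if I_prev[j] == 0 else (0.0, 1.0) for (j, k) in pairs
    ] + [(0.0, None)] * (2 * K)
    res = linprog(
        c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise LPError(
            f"conversion-rate LP failed: {res.message}",
            {"I_prev": I_prev.tolist(), "I_curr": I_curr.tolist(),
             "dt_min": dt_min, "status": res.status},
        )
    rates = np.zeros((K, K))
    for col, (j, k) in enumerate(pairs):
        rates[j, k] = res.x[col]
    slack = res.x[nvar:nvar + K] - res.x[nvar + K:]
    return ConversionStep(
        time_min=time_min, dt_min=dt_min, I_prev=I_prev, I_curr=I_curr,
        rates=rates, slack=slack, objective=float(res.fun),
    )


def estimate_rate_series(series: pd.DataFrame) -> list[ConversionStep]:
    """Run the LP on every consecutive frame pair of an I_0..I_4 table.

    ``series`` needs columns time_min and I0..I{K-1}; rates are estimated
    independently per pair with the actual (possibly non-uniform) dt.
    """
    cols = [c for c in series.columns if c.startswith("I")]
    I = series[cols].to_numpy(dtype=float)
    t = series["time_min"].to_numpy(dtype=float)
    steps = []
    for i in range(1, len(series)):
        steps.append(
            estimate_conversion_rates(
                np.clip(I[i - 1], 0, None), np.clip(I[i], 0, None),
                dt_min=t[i] - t[i - 1], time_min=t[i],
            )
        )
    return steps


# --------------------------------------------------------------------------
# cumulative flows


@dataclass
class FlowCurves:
    """Cumulative protein flows per family, optionally sham-normalised.

    Each table is indexed by time (min) with one column per (from, to) pair,
    named ``f{j}_t{k}``.
    """

    induction: pd.DataFrame
    resolving: pd.DataFrame
    merging: pd.DataFrame

    @staticmethod
    def _family_columns(K: int) -> dict[str, list[tuple[int, int]]]:
        return {
            "induction": [(0, k) for k in range(1, K)],
            "resolving": [(k, 0) for k in range(1, K)],
            "merging": [(j, k) for j in range(1, K) for k in range(j + 1, K)],
        }


def cumulative_flows(
    steps: list[ConversionStep],
    sham_steps: list[ConversionStep] | None = None,
) -> FlowCurves:
    """Cumulative induction / resolving / merging protein amounts over time.

    Sham normalisation subtracts the sham cumulative curve pointwise and
    clips at zero (values below sham are set to zero).
    """
    if not steps:
        raise ValueError("no conversion steps")
    K = len(steps[0].I_prev)
    fams = FlowCurves._family_columns(K)
    times = np.array([s.time_min for s in steps])

    def family_table(step_list: list[ConversionStep], pairs) -> pd.DataFrame:
        data = {}
        for j, k in pairs:
            per_step = np.array([s.flows[j, k] for s in step_list])
            data[f"f{j}_t{k}"] = np.cumsum(per_step)
        return pd.DataFrame(data, index=times)

    out = {}
    for name, pairs in fams.items():
        table = family_table(steps, pairs)
        if sham_steps is not None:
            sham_times = np.array([s.time_min for s in sham_steps])
            if len(sham_times) != len(times) or not np.allclose(sham_times, times):
                raise ValueError("sham timeline does not match dose timeline")
            sham = family_table(sham_steps, pairs)
            table = (table - sham).clip(lower=0.0)
        out[name] = table
    return FlowCurves(**out)
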