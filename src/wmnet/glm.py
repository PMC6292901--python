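"""First-level parametric GLM on ROI timeseries.

Each run of the alphabetization task is modelled with separate
HRF-convolved event regressors for array presentation (3 s), the delay
period (5 s) and the response (duration = reaction time), plus two
*concurrent* parametric modulators carried by the delay period: relative
set size (maintenance demand, coded 1-4) and sorting steps (manipulation
demand, raw 0-7 counts).  Modulator weights are mean-centred across the
run's correct trials before convolution and the convolved columns are
residualised against the unmodulated delay regressor, so each modulator
captures demand-driven variance above the shared delay response.
Incorrect and non-response trials are modelled by duplicate event
regressors and excluded from the parametric columns.

Per-ROI ordinary least squares is fitted per run; runs are combined by
fixed-effects (inverse-variance) averaging and subjects by a one-sample
random-effects t converted to z.  Variance inflation factors of the
parametric columns, computed against all other task regressors and
averaged across runs, diagnose the collinearity between the two demand
codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignError",
    "HRFModel",
    "convolve_events",
    "build_design",
    "fit_glm",
    "combine_runs",
    "group_parametric_map",
    "compute_vif",
    "average_vif",
    "Z_CAP",
]

#: z statistics are capped at +/-38 (the float64 normal-quantile limit
#: region) so zero-variance synthetic cases stay finite.
Z_CAP = 38.0

RUN_DURATION = 508.0
TR = 2.0
N_VOLUMES = 254


class DesignError(ValueError):
    """Raised for invalid event timing or rank-deficient designs."""


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma haemodynamic response function.

    ``kernel`` evaluates the difference of two gamma densities on a
    microtime grid: a positive lobe peaking a few seconds after
    stimulus onset and a late undershoot scaled by
    ``undershoot_ratio``.  The kernel is normalised to unit peak.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0
    dt: float = 0.1

    def kernel(self) -> np.ndarray:
        t = np.arange(0.0, self.length, self.dt)
        h = (stats.gamma.pdf(t, self.peak_delay)
             - self.undershoot_ratio * stats.gamma.pdf(t, self.undershoot_delay))
        peak = np.max(np.abs(h))
        if peak <= 0:
            raise DesignError("degenerate HRF kernel")
        return h / peak


def convolve_events(
    onsets: Sequence[float],
    durations: Sequence[float] | float,
    hrf: HRFModel,
    amplitudes: Sequence[float] | float = 1.0,
    run_duration: float = RUN_DURATION,
    tr: float = TR,
    n_volumes: int = N_VOLUMES,
) -> np.ndarray:
    """HRF-convolved event regressor sampled at volume acquisition times.

    Events are placed as boxcars on the microtime grid (``hrf.dt``),
    convolved with the double-gamma kernel and read out at t = k * TR.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), onsets.shape)
    if np.any(onsets < 0) or np.any(onsets + durations > run_duration + 1e-9):
        raise DesignError("event extends beyond the run duration")
    dt = hrf.dt
    n_micro = int(np.ceil(run_duration / dt)) + 1
    box = np.zeros(n_micro)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))
        box[i0:i1] += amp
    # dt factor approximates the continuous-time convolution integral,
    # so a unit-amplitude event keeps an O(1) regressor peak
    conv = np.convolve(box, hrf.kernel())[:n_micro] * dt
    idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[idx]


def _orthogonalize(column: np.ndarray, against: np.ndarray) -> np.ndarray:
    """Residual of ``column`` after regressing on [1, against]."""
    X = np.column_stack([np.ones_like(against), against])
    beta, *_ = np.linalg.lstsq(X, column, rcond=None)
    return column - X @ beta


def build_design(
    table_run: pd.DataFrame,
    hrf: HRFModel | None = None,
    confounds: pd.DataFrame | None = None,
    run_duration: float = RUN_DURATION,
    tr: float = TR,
    n_volumes: int = N_VOLUMES,
    modulators: Sequence[str] = ("set_size", "steps"),
) -> pd.DataFrame:
    """First-level design matrix for one run's trial table.

    ``table_run`` needs columns ``onset_array``, ``onset_delay``,
    ``onset_probe``, ``level``, ``steps``, ``correct``, ``responded``
    and ``rt_ms``.  Returns a volumes x regressors DataFrame whose
    ``attrs`` record ``task_columns``, ``modulator_columns`` and any
    ``degenerate`` (dropped) modulators.
    """
    hrf = hrf or HRFModel()
    t = table_run
    ok = (t["correct"].fillna(False) & t["responded"]).to_numpy(bool)
    err = ~ok
    cols: dict[str, np.ndarray] = {}
    degenerate: list[str] = []

    def conv(mask, onset_col, dur, amp=1.0):
        return convolve_events(
            t.loc[mask, onset_col], dur, hrf, amplitudes=amp,
            run_duration=run_duration, tr=tr, n_volumes=n_volumes)

    if not ok.any():
        raise DesignError("run has no correct trials to model")
    rt_s = (t["rt_ms"].to_numpy(float) / 1000.0)
    cols["array"] = conv(ok, "onset_array", 3.0)
    delay = conv(ok, "onset_delay", 5.0)
    cols["delay"] = delay

    mod_values = {"set_size": t["level"].to_numpy(float),
                  "steps": t["steps"].to_numpy(float)}
    mod_names: list[str] = []
    for mod in modulators:
        vals = mod_values[mod][ok]
        centred = vals - vals.mean()
        name = f"delay_x_{mod}"
        if np.allclose(centred, 0.0):
            degenerate.append(name)
            warnings.warn(f"modulator {name} is constant; dropped as degenerate")
            continue
        col = conv(ok, "onset_delay", 5.0, amp=centred)
        cols[name] = _orthogonalize(col, delay)
        mod_names.append(name)

    cols["response"] = conv(ok, "onset_probe", np.clip(rt_s[ok], 0.2, 4.0))
    if err.any():
        cols["err_array"] = conv(err, "onset_array", 3.0)
        cols["err_delay"] = conv(err, "onset_delay", 5.0)
        err_dur = np.where(t["responded"].to_numpy(bool)[err],
                           np.clip(rt_s[err], 0.2, 4.0), 4.0)
        cols["err_response"] = conv(err, "onset_probe", err_dur)

    design = pd.DataFrame(cols)
    design.attrs["task_columns"] = list(cols)
    design.attrs["modulator_columns"] = mod_names
    design.attrs["degenerate"] = degenerate
    design.attrs["tr"] = tr
    if confounds is not None:
        if len(confounds) != n_volumes:
            raise DesignError("confound table does not match volume count")
        for c in confounds.columns:
            design[c] = np.asarray(confounds[c], dtype=float)
    return design


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    names = ["intercept"] + list(design.columns)
    return X, names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-10
    return [names[i] for i in np.nonzero(diag < tol)[0]]


def fit_glm(signal: np.ndarray, design: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI OLS of one run; returns tidy (roi, column, beta, se, ...).

    ``signal`` is volumes x ROIs.  Raises on rank deficiency, naming
    the collinear columns.
    """
    Y = np.asarray(signal, dtype=float)
    if Y.ndim != 2 or len(Y) != len(design):
        raise DesignError("signal and design must share the volume count")
    X, names = _design_matrix(design)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise DesignError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = len(Y) - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    n_roi = Y.shape[1]
    out = pd.DataFrame({
        "roi": np.repeat(np.arange(n_roi), len(names)),
        "column": np.tile(names, n_roi),
        "beta": beta.T.ravel(),
        "se": se.T.ravel(),
    })
    out.attrs["dof"] = dof
    return out


def combine_runs(run_fits: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects combination across runs (inverse-variance weights)."""
    frames = list(run_fits)
    if not frames:
        raise DesignError("no run fits to combine")
    cat = pd.concat(frames, ignore_index=True)
    w = 1.0 / np.maximum(cat["se"] ** 2, 1e-300)
    cat = cat.assign(_w=w, _wb=w * cat["beta"])
    g = cat.groupby(["roi", "column"], sort=False)
    combined = g[["_w", "_wb"]].sum()
    out = combined.reset_index()
    out["beta"] = out["_wb"] / out["_w"]
    out["se"] = np.sqrt(1.0 / out["_w"])
    return out[["roi", "column", "beta", "se"]]


def group_parametric_map(
    subject_betas: np.ndarray | Sequence[Sequence[float]],
    roi_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """One-sample random-effects t across subjects, converted to z.

    ``subject_betas`` is subjects x ROIs for a single parametric
    effect.  Returns (roi, t, z); z is the normal quantile of the
    two-sided t p-value with the sign of t, capped at +/-38.
    """
    B = np.asarray(subject_betas, dtype=float)
    if B.ndim != 2 or B.shape[0] < 3:
        raise DesignError("group map needs betas from at least 3 subjects")
    n = B.shape[0]
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    denom = sd / np.sqrt(n)
    safe = np.where(denom > 0, denom, 1.0)
    # zero-variance cases: +/-inf for a nonzero mean, 0 when degenerate
    with np.errstate(invalid="ignore"):
        tval = np.where(denom > 0, mean / safe,
                        np.where(mean == 0, 0.0, np.sign(mean) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(tval), df=n - 1)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(np.clip(p / 2.0, 1e-320, 1.0)) * np.sign(tval)
    z = np.clip(np.nan_to_num(z, nan=0.0), -Z_CAP, Z_CAP)
    roi = np.arange(B.shape[1]) if roi_ids is None else np.asarray(roi_ids)
    return pd.DataFrame({"roi": roi, "t": tval, "z": z})


def compute_vif(design: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factors of design columns within one run.

    Each requested column is regressed on all *other* task columns
    (plus an intercept); VIF = 1 / (1 - R^2).  Perfect collinearity is
    reported as ``inf`` with a warning.
    """
    task = design.attrs.get("task_columns", list(design.columns))
    columns = list(columns) if columns is not None else design.attrs.get(
        "modulator_columns", task)
    missing = [c for c in columns if c not in design.columns]
    if missing:
        raise DesignError(f"columns not in design: {missing}")
    X_all = design[task].to_numpy(float)
    out = {}
    for col in columns:
        j = task.index(col)
        y = X_all[:, j]
        others = np.column_stack(
            [np.ones(len(design))] + [X_all[:, k] for k in range(len(task)) if k != j])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"column {col} is perfectly collinear; VIF = inf")
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def average_vif(designs: Iterable[pd.DataFrame],
                columns: Sequence[str] | None = None) -> pd.Series:
    """Mean VIF across runs (the per-subject collinearity summary).

    Runs where a column is perfectly collinear (infinite VIF — e.g. a
    run with so few correct trials that the two demand modulators
    coincide) are excluded from that column's average with a warning.
    """
    frame = pd.concat([compute_vif(d, columns) for d in designs], axis=1)
    finite = frame.replace(np.inf, np.nan)
    if finite.isna().any().any():
        warnings.warn("runs with infinite VIF excluded from the average")
    return finite.mean(axis=1)
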