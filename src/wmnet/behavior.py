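"""Trial-level mixed-effects models of accuracy and reaction time.

Accuracy is analysed with a binomial logistic mixed model over all
responded trials and RT with a linear mixed model over correct trials,
both with relative set size (1-4), sorting steps and their interaction
as fixed effects, and by-subject random intercepts plus uncorrelated
random slopes for the two demand codes.  Each fixed effect is tested by
a likelihood-ratio chi-square of the full model against the model
without that term (maximum-likelihood refits).

Fitting is delegated to R's lme4 (glmer / lmer) through an Rscript
subprocess; a statsmodels MixedLM backend is available for the linear
model as an in-process alternative.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehaviorStatsError",
    "ModelReport",
    "prepare_trials",
    "fit_accuracy_model",
    "fit_rt_model",
    "rt_residual_diagnostics",
]

TERMS = ("intercept", "set_size", "steps", "interaction")

_R_SCRIPT = r"""
suppressMessages({library(lme4); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
dat <- read.delim(args[1])
model <- args[2]
out_path <- args[3]
covars <- if (length(args) >= 4 && nzchar(args[4])) strsplit(args[4], ",")[[1]] else character(0)
dat$subject <- factor(dat$subject)

re <- "(1 | subject) + (0 + level | subject) + (0 + steps | subject)"
cov_rhs <- if (length(covars)) paste("+", paste(covars, collapse = " + ")) else ""
fixed <- list(
  full = paste("level + steps + level:steps", cov_rhs),
  set_size = paste("steps + level:steps", cov_rhs),
  steps = paste("level + level:steps", cov_rhs),
  interaction = paste("level + steps", cov_rhs)
)

fit_one <- function(rhs) {
  f <- as.formula(paste(resp, "~", rhs, "+", re))
  if (model == "accuracy") {
    suppressWarnings(glmer(f, data = dat, family = binomial,
                           control = glmerControl(calc.derivs = FALSE)))
  } else {
    suppressWarnings(lmer(f, data = dat, REML = (rhs == fixed$full)))
  }
}

resp <- if (model == "accuracy") "correct" else "rt_ms"
full <- fit_one(fixed$full)
cf <- summary(full)$coefficients
name_map <- c("(Intercept)" = "intercept", "level" = "set_size",
              "steps" = "steps", "level:steps" = "interaction")
est <- list(); se <- list()
for (rn in rownames(cf)) {
  key <- if (rn %in% names(name_map)) name_map[[rn]] else rn
  est[[key]] <- unname(cf[rn, "Estimate"])
  se[[key]] <- unname(cf[rn, "Std. Error"])
}
lrt <- list()
for (term in c("set_size", "steps", "interaction")) {
  red <- fit_one(fixed[[term]])
  a <- suppressMessages(anova(red, full))  # refits lmer with ML
  lrt[[term]] <- list(chi2 = unname(a$Chisq[2]), df = unname(a$Df[2]),
                      p = unname(a$`Pr(>Chisq)`[2]))
}
msgs <- unlist(summary(full)$optinfo$conv$lme4$messages)
report <- list(estimates = est, std_errors = se, lrt = lrt,
               converged = is.null(msgs),
               messages = if (is.null(msgs)) list() else as.list(msgs),
               n_obs = nrow(dat), n_subjects = nlevels(dat$subject),
               loglik = as.numeric(logLik(full)))
write(toJSON(report, auto_unbox = TRUE, digits = 12), out_path)
"""


class BehaviorStatsError(RuntimeError):
    """Raised for degenerate inputs or failed model fits."""


@dataclass
class ModelReport:
    """Fixed-effect estimates, standard errors and per-term LRTs."""

    model: str
    estimates: dict[str, float]
    std_errors: dict[str, float]
    lrt: dict[str, dict]
    converged: bool
    n_obs: int
    n_subjects: int
    backend: str = "lme4"
    messages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"model": self.model, "estimates": self.estimates,
                "std_errors": self.std_errors, "lrt": self.lrt,
                "converged": self.converged, "n_obs": self.n_obs,
                "n_subjects": self.n_subjects, "backend": self.backend,
                "messages": list(self.messages)}

    def summary(self) -> str:
        lines = [f"{self.model} mixed model "
                 f"({self.n_obs} trials, {self.n_subjects} subjects)"]
        for term in TERMS:
            if term not in self.estimates:
                continue
            row = f"  {term:<12} {self.estimates[term]:>10.3f}"
            row += f" (SE {self.std_errors[term]:.3f})"
            if term in self.lrt:
                row += (f"  chi2={self.lrt[term]['chi2']:.2f}"
                        f" p={self.lrt[term]['p']:.2g}")
            lines.append(row)
        return "\n".join(lines)


def prepare_trials(cohort_table: pd.DataFrame, model: str,
                   covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Select and validate the trials entering a behaviour model.

    Non-response trials are always excluded; the RT model additionally
    keeps correct trials only.  ``covariates`` names extra subject-level
    columns (e.g. gender, starting set size) to carry through; they are
    accepted as fixed-effect controls and otherwise uninterpreted.
    """
    need = {"subject", "level", "steps", "correct", "responded", "rt_ms"}
    need |= set(covariates)
    if not need.issubset(cohort_table.columns):
        raise BehaviorStatsError(f"trial table needs columns {sorted(need)}")
    t = cohort_table[cohort_table["responded"].astype(bool)].copy()
    if model == "rt":
        t = t[t["correct"].astype(bool)]
    if t["subject"].nunique() < 2:
        raise BehaviorStatsError("mixed models need at least 2 subjects")
    t["correct"] = t["correct"].astype(int)
    return t[["subject", "level", "steps", "correct", "rt_ms",
              *covariates]]


def _run_lme4(table: pd.DataFrame, model: str,
              covariates: tuple[str, ...] = ()) -> dict:
    rscript = shutil.which("Rscript")
    if rscript is None:
        raise BehaviorStatsError("Rscript not found on PATH; lme4 backend "
                                 "unavailable")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        data_path = tmp / "trials.tsv"
        script_path = tmp / "fit.R"
        out_path = tmp / "report.json"
        table.to_csv(data_path, sep="\t", index=False)
        script_path.write_text(_R_SCRIPT)
        proc = subprocess.run(
            [rscript, "--vanilla", str(script_path), str(data_path),
             model, str(out_path), ",".join(covariates)],
            capture_output=True, text=True, timeout=600)
        if proc.returncode != 0 or not out_path.exists():
            raise BehaviorStatsError(
                f"lme4 fit failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}")
        return json.loads(out_path.read_text())


def _report_from_lme4(raw: dict, model: str) -> ModelReport:
    return ModelReport(
        model=model,
        estimates={k: float(v) for k, v in raw["estimates"].items()},
        std_errors={k: float(v) for k, v in raw["std_errors"].items()},
        lrt={k: {kk: float(vv) for kk, vv in v.items()}
             for k, v in raw["lrt"].items()},
        converged=bool(raw["converged"]),
        n_obs=int(raw["n_obs"]), n_subjects=int(raw["n_subjects"]),
        messages=list(raw.get("messages", [])))


def fit_accuracy_model(cohort_table: pd.DataFrame,
                       covariates: tuple[str, ...] = ()) -> ModelReport:
    """Binomial logistic mixed model of trial accuracy (lme4 glmer)."""
    t = prepare_trials(cohort_table, "accuracy", covariates)
    return _report_from_lme4(_run_lme4(t, "accuracy", covariates), "accuracy")


def fit_rt_model(cohort_table: pd.DataFrame,
                 backend: str = "lme4",
                 covariates: tuple[str, ...] = ()) -> ModelReport:
    """Linear mixed model of correct-trial RTs.

    ``backend="lme4"`` fits by REML with ML-refit likelihood-ratio
    tests; ``backend="statsmodels"`` uses MixedLM with a subject random
    intercept (no random slopes) as an in-process alternative.
    """
    t = prepare_trials(cohort_table, "rt", covariates)
    if backend == "lme4":
        return _report_from_lme4(_run_lme4(t, "rt", covariates), "rt")
    if backend != "statsmodels":
        raise BehaviorStatsError(f"unknown backend {backend!r}")
    from statsmodels.regression.mixed_linear_model import MixedLM

    X = pd.DataFrame({
        "intercept": 1.0,
        "set_size": t["level"].astype(float),
        "steps": t["steps"].astype(float),
        "interaction": (t["level"] * t["steps"]).astype(float)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = MixedLM(t["rt_ms"].to_numpy(float), X.to_numpy(),
                       t["subject"].to_numpy()).fit(reml=False)
        est = dict(zip(X.columns, full.fe_params))
        se = dict(zip(X.columns, full.bse_fe))
    lrt = {}
    for i, term in enumerate(X.columns):
        if term == "intercept":
            continue
        X_red = X.drop(columns=[term])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            red = MixedLM(t["rt_ms"].to_numpy(float), X_red.to_numpy(),
                          t["subject"].to_numpy()).fit(reml=False)
        chi2 = max(0.0, 2.0 * (full.llf - red.llf))
        lrt[term] = {"chi2": float(chi2), "df": 1.0,
                     "p": float(stats.chi2.sf(chi2, 1))}
    return ModelReport("rt", {k: float(v) for k, v in est.items()},
                       {k: float(v) for k, v in se.items()}, lrt,
                       bool(full.converged), len(t), t["subject"].nunique(),
                       backend="statsmodels")


def rt_residual_diagnostics(cohort_table: pd.DataFrame) -> dict:
    """Levene and Shapiro-Wilk checks on RT fixed-effect residuals.

    Residuals come from a per-subject OLS of the fixed-effect structure
    (absorbing subject differences); Levene tests homoscedasticity
    across difficulty levels and Shapiro-Wilk tests normality.
    """
    t = prepare_trials(cohort_table, "rt")
    resid = np.empty(len(t))
    pos = 0
    for _, g in t.groupby("subject"):
        X = np.column_stack([np.ones(len(g)), g["level"], g["steps"],
                             g["level"] * g["steps"]])
        y = g["rt_ms"].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid[pos:pos + len(g)] = y - X @ beta
        pos += len(g)
    levels = t["level"].to_numpy()
    lev_stat, lev_p = stats.levene(
        *[resid[levels == lv] for lv in np.unique(levels)])
    sample = resid if len(resid) <= 5000 else resid[:: len(resid) // 5000 + 1]
    sw_stat, sw_p = stats.shapiro(sample)
    return {"levene_F": float(lev_stat), "levene_p": float(lev_p),
            "shapiro_W": float(sw_stat), "shapiro_p": float(sw_p),
            "heteroscedastic": bool(lev_p < 0.05)}
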