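"""Synthetic cohorts for the alphabetization working-memory experiment.

Generates desk-scale analogues of a 41-subject scanning cohort: per-run
trial tables with the task's timing (3 s array, 5 s delay, 4 s probe,
~5 s mean jittered ITI; 30 trials per run, 4 runs of 254 volumes at
TR = 2 s), trial-level behaviour from a mixed logistic/linear model with
the published coefficient structure, ROI timeseries with a planted
two-community network ground truth, nuisance confounds, and structural
(fractional anisotropy) matrices.

The timeseries generative model, per run and ROI::

    y = sum_trials a(node, trial) * x_trial + AR(1) noise + confound mix

where ``x_trial`` is the HRF-convolved delay-period regressor of one
trial and the amplitude ``a`` carries three parts: a node-specific
unmodulated delay response; a demand-scaled response (maintenance nodes
scale with relative set size, manipulation nodes with sorting steps);
and a network-level latent amplitude shared by all nodes of a community,
weighted ``w``.  The two communities' latent amplitudes are drawn per
trial from a bivariate normal whose correlation declines with the
trial's difficulty level,

    rho(level) = rho0 - delta * gain_s * level,

so within-network coupling is positive and stable while between-network
coupling grows more negative with demand; the subject-specific
``gain_s`` ties the strength of that reconfiguration to working-memory
ability (Criterion).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.special import expit

from . import sorting
from .glm import HRFModel, convolve_events, RUN_DURATION, TR, N_VOLUMES

__all__ = [
    "BehaviorParams",
    "GroundTruth",
    "SubjectSpec",
    "CohortConfig",
    "Subject",
    "Cohort",
    "STARTING_SIZE_PRIOR",
    "draw_subject_spec",
    "generate_trial_table",
    "simulate_behavior",
    "simulate_timeseries",
    "generate_structural_matrix",
    "generate_cohort",
    "load_cohort",
    "trials_to_events",
    "stage_rng",
]

#: Empirical starting-set-size distribution of the cohort the generator
#: emulates: 12/19/9/1 subjects over sizes 3-6.
STARTING_SIZE_PRIOR = {3: 12 / 41, 4: 19 / 41, 5: 9 / 41, 6: 1 / 41}

NON_RESPONSE_RATE = 0.016
RT_DEADLINE_MS = 4000.0
ITI_MEAN, ITI_LO, ITI_HI = 5.0, 2.0, 10.0

ARRAY_DUR, DELAY_DUR, PROBE_DUR = 3.0, 5.0, 4.0
TRIAL_FIXED = ARRAY_DUR + DELAY_DUR + PROBE_DUR  # 12 s before the ITI


@dataclass(frozen=True)
class BehaviorParams:
    """Fixed effects, random-effect SDs and residual noise of behaviour.

    Defaults are the published mixed-model estimates: a logistic model
    for accuracy and a linear model for RT (ms), both with relative set
    size (1-4, uncentred), raw sorting steps and their interaction.
    """

    acc_intercept: float = 4.10
    acc_set_size: float = -0.94
    acc_steps: float = -0.49
    acc_interaction: float = 0.11
    rt_intercept: float = 1129.17
    rt_set_size: float = 284.36
    rt_steps: float = 89.22
    rt_interaction: float = -29.14
    rt_resid_sd: float = 300.0
    acc_re_sd: tuple[float, float, float] = (0.60, 0.25, 0.15)
    rt_re_sd: tuple[float, float, float] = (180.0, 40.0, 20.0)


@dataclass
class SubjectSpec:
    """Per-subject ground truth: titration outcome and random effects."""

    subject_id: int
    starting_set_size: int
    criterion_set_size: float
    acc_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rt_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    reconfiguration_gain: float = 1.0

    def __post_init__(self):
        if not 3 <= self.starting_set_size <= 6:
            raise ValueError("starting_set_size outside [3, 6]")
        if self.reconfiguration_gain < 0:
            raise ValueError("reconfiguration_gain must be >= 0")


@dataclass
class GroundTruth:
    """Planted network structure for the timeseries generator."""

    n_rois: int = 471
    maintenance_nodes: np.ndarray = None  # type: ignore[assignment]
    manipulation_nodes: np.ndarray = None  # type: ignore[assignment]
    base_amp: np.ndarray = None  # type: ignore[assignment]
    amp_set: np.ndarray = None  # per maintenance node, per unit level
    amp_steps: np.ndarray = None  # per manipulation node, per unit step
    w_maint: float = 0.19
    w_manip: float = 0.115
    rho0: float = -0.15
    delta: float = 0.12
    static_sd: float = 0.12
    recon_sd: float = 0.12
    noise_sd: float = 1.0
    ar1: float = 0.3
    confound_mix_sd: float = 0.08
    fa_within_margin: float = 0.05

    def __post_init__(self):
        m, n = self.maintenance_nodes, self.manipulation_nodes
        if m is None or n is None:
            raise ValueError("ground truth needs both node communities")
        self.maintenance_nodes = np.asarray(m, dtype=int)
        self.manipulation_nodes = np.asarray(n, dtype=int)
        if np.intersect1d(self.maintenance_nodes, self.manipulation_nodes).size:
            raise ValueError("ground-truth communities must be disjoint")
        for level in (1, 2, 3, 4):
            if not -1 < self.rho0 - self.delta * level < 1:
                raise ValueError("rho(level) outside (-1, 1)")

    @classmethod
    def default(cls, rng: np.random.Generator, n_rois: int = 471,
                nodes_per_network: int = 23, **overrides) -> "GroundTruth":
        """Draw a random disjoint 23+23 community layout and amplitudes."""
        nodes = rng.choice(n_rois, size=2 * nodes_per_network, replace=False)
        maint, manip = nodes[:nodes_per_network], nodes[nodes_per_network:]
        fields = dict(
            n_rois=n_rois,
            maintenance_nodes=np.sort(maint),
            manipulation_nodes=np.sort(manip),
            base_amp=rng.uniform(0.012, 0.036, size=n_rois),
            amp_set=rng.uniform(0.030, 0.066, size=nodes_per_network),
            amp_steps=rng.uniform(0.018, 0.042, size=nodes_per_network),
        )
        fields.update(overrides)
        return cls(**fields)

    def rho(self, level: int, gain: float = 1.0) -> float:
        return float(np.clip(self.rho0 - self.delta * gain * level, -0.95, 0.95))


def stage_rng(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Deterministic sub-stream for (master seed, stage, index)."""
    stage_code = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "big")
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), stage_code, int(index)]))


def draw_subject_spec(
    subject_id: int,
    rng: np.random.Generator,
    params: BehaviorParams | None = None,
    starting_prior: dict[int, float] = STARTING_SIZE_PRIOR,
    gain_slope: float = 0.5,
    gain_noise_sd: float = 0.2,
) -> SubjectSpec:
    """Draw one subject: titrated levels, random effects, coupling gain.

    Criterion is uniform within (start+1, start+2), the interval that
    the level-derivation rule maps back to that starting size; the
    reconfiguration gain increases with Criterion (slope 0.5 per set
    size) so network flexibility tracks ability.
    """
    params = params or BehaviorParams()
    sizes = np.array(sorted(starting_prior))
    probs = np.array([starting_prior[s] for s in sizes], dtype=float)
    start = int(rng.choice(sizes, p=probs / probs.sum()))
    criterion = start + 1 + float(rng.uniform())
    mean_crit = float(np.sum((sizes + 1.5) * probs / probs.sum()))
    gain = max(0.0, 1.0 + gain_slope * (criterion - mean_crit)
               + float(rng.normal(0.0, gain_noise_sd)))
    acc_u = tuple(rng.normal(0.0, sd) for sd in params.acc_re_sd)
    rt_u = tuple(rng.normal(0.0, sd) for sd in params.rt_re_sd)
    return SubjectSpec(subject_id, start, criterion,
                       acc_effects=acc_u, rt_effects=rt_u,
                       reconfiguration_gain=gain)


# truncated-exponential ITI: scale solving for the 5 s mean on [2, 10]
def _iti_scale() -> float:
    span = ITI_HI - ITI_LO

    def mean_err(beta):
        q = np.exp(-span / beta)
        return ITI_LO + beta - span * q / (1 - q) - ITI_MEAN

    return brentq(mean_err, 0.5, 200.0)


_ITI_SCALE = None


def _draw_itis(n: int, rng: np.random.Generator, budget: float) -> np.ndarray:
    """ITIs with 5 s mean on [2, 10] s whose first n-1 fit the run budget."""
    global _ITI_SCALE
    if _ITI_SCALE is None:
        _ITI_SCALE = _iti_scale()
    beta, span = _ITI_SCALE, ITI_HI - ITI_LO
    for _ in range(1000):
        u = rng.uniform(size=n)
        itis = ITI_LO - beta * np.log1p(-u * (1 - np.exp(-span / beta)))
        if itis[:-1].sum() <= budget:
            return itis
    # pathological budget: compress proportionally toward the floor
    excess = itis[:-1] - ITI_LO
    itis[:-1] = ITI_LO + excess * (budget - ITI_LO * (n - 1)) / excess.sum()
    return itis


def _deal_levels(n_runs: int, trials_per_run: int) -> list[np.ndarray]:
    """Per-run level lists with exactly equal counts per level overall."""
    total = n_runs * trials_per_run
    if total % 4:
        raise ValueError("total trial count must be divisible by 4 levels")
    base, rem = divmod(trials_per_run, 4)
    runs = []
    extra_ptr = 0
    for _ in range(n_runs):
        counts = [base] * 4
        for _ in range(rem):
            counts[extra_ptr % 4] += 1
            extra_ptr += 1
        runs.append(np.repeat(np.arange(1, 5), counts))
    return runs


def generate_trial_table(
    spec: SubjectSpec,
    rng: np.random.Generator,
    n_runs: int = 4,
    trials_per_run: int = 30,
    run_duration: float = RUN_DURATION,
) -> pd.DataFrame:
    """Trial design for one subject: timing, stimuli and demand codes.

    Levels are balanced within and across runs; probe types are 40%
    valid / 40% invalid / 20% new within each run; sorting steps are
    computed from the generated consonant arrays at generation time.
    """
    n_valid = int(round(0.4 * trials_per_run))
    n_new = trials_per_run - 2 * n_valid
    probe_pool = ["valid"] * n_valid + ["invalid"] * n_valid + ["new"] * n_new
    level_lists = _deal_levels(n_runs, trials_per_run)
    budget = run_duration - TRIAL_FIXED * trials_per_run
    rows = []
    for run in range(1, n_runs + 1):
        levels = rng.permutation(level_lists[run - 1])
        probes = rng.permutation(probe_pool)
        itis = _draw_itis(trials_per_run, rng, budget)
        onset = 0.0
        for i in range(trials_per_run):
            level = int(levels[i])
            size = spec.starting_set_size + level - 1
            letters = sorting.generate_array(size, rng)
            rows.append({
                "subject": spec.subject_id, "run": run, "trial": i + 1,
                "level": level, "abs_set_size": size, "letters": letters,
                "steps": sorting.min_sorting_steps(letters),
                "probe_type": probes[i],
                "onset_array": onset,
                "onset_delay": onset + ARRAY_DUR,
                "onset_probe": onset + ARRAY_DUR + DELAY_DUR,
                "iti": float(itis[i]),
            })
            onset += TRIAL_FIXED + float(itis[i])
    table = pd.DataFrame(rows)
    table["trial_index"] = np.arange(len(table))
    return table


def simulate_behavior(
    table: pd.DataFrame,
    params: BehaviorParams,
    spec: SubjectSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Add correct / rt_ms / responded columns from the mixed model."""
    t = table.copy()
    u0, u1, u2 = spec.acc_effects
    v0, v1, v2 = spec.rt_effects
    level = t["level"].to_numpy(float)
    steps = t["steps"].to_numpy(float)
    eta = ((params.acc_intercept + u0)
           + (params.acc_set_size + u1) * level
           + (params.acc_steps + u2) * steps
           + params.acc_interaction * level * steps)
    if np.any(np.abs(eta) > 30):
        warnings.warn("logit clamped to +/-30 for extreme parameters")
        eta = np.clip(eta, -30, 30)
    t["correct"] = rng.uniform(size=len(t)) < expit(eta)
    rt = ((params.rt_intercept + v0)
          + (params.rt_set_size + v1) * level
          + (params.rt_steps + v2) * steps
          + params.rt_interaction * level * steps
          + rng.normal(0.0, params.rt_resid_sd, size=len(t)))
    t["rt_ms"] = np.clip(rt, 150.0, RT_DEADLINE_MS)
    t["responded"] = rng.uniform(size=len(t)) >= NON_RESPONSE_RATE
    t.loc[~t["responded"], "rt_ms"] = np.nan
    t.loc[~t["responded"], "correct"] = False
    return t


def _confound_table(rng: np.random.Generator, n_volumes: int) -> pd.DataFrame:
    """Six motion traces plus WM and CSF signals as smooth random walks."""
    names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
             "wm", "csf"]
    walks = np.cumsum(rng.normal(0.0, 1.0, size=(n_volumes, len(names))), axis=0)
    walks -= walks.mean(axis=0)
    walks /= np.maximum(walks.std(axis=0), 1e-12)
    return pd.DataFrame(walks, columns=names)


def simulate_timeseries(
    table: pd.DataFrame,
    truth: GroundTruth,
    spec: SubjectSpec,
    rng: np.random.Generator,
    hrf: HRFModel | None = None,
    tr: float = TR,
    n_volumes: int = N_VOLUMES,
) -> dict[int, dict]:
    """ROI timeseries bundle for one subject, keyed by run number.

    Each run entry holds ``signal`` (volumes x ROIs), ``confounds``
    (volumes x 8) and the per-trial latent amplitudes under
    ``latents`` for diagnostics.
    """
    hrf = hrf or HRFModel()
    bundle: dict[int, dict] = {}
    maint, manip = truth.maintenance_nodes, truth.manipulation_nodes
    run_duration = n_volumes * tr
    # level-specific node loadings on a shared per-trial latent: the
    # rank-one edge pattern they imprint differs across difficulty
    # levels, and its magnitude scales with the subject's
    # reconfiguration gain, so state-to-state dissimilarity of the
    # connectivity profile tracks working-memory ability
    g = spec.reconfiguration_gain
    c_load = rng.normal(0.0, truth.recon_sd * g, size=(len(maint), 4))
    d_load = rng.normal(0.0, truth.recon_sd * g, size=(len(manip), 4))
    # static zero-mean loadings on a second shared latent: a stable
    # (level-independent) edge pattern that anchors state similarity
    e_load = rng.normal(0.0, truth.static_sd, size=len(maint))
    f_load = rng.normal(0.0, truth.static_sd, size=len(manip))
    for run, t_run in table.groupby("run"):
        n_trials = len(t_run)
        X = np.empty((n_volumes, n_trials))
        for j, onset in enumerate(t_run["onset_delay"].to_numpy(float)):
            X[:, j] = convolve_events(
                [onset], DELAY_DUR, hrf, run_duration=run_duration,
                tr=tr, n_volumes=n_volumes)
        level = t_run["level"].to_numpy(float)
        steps = t_run["steps"].to_numpy(float)
        # per-trial bivariate latent amplitudes with difficulty-scaled corr
        z = rng.normal(size=(2, n_trials))
        rho = np.array([truth.rho(lv, spec.reconfiguration_gain) for lv in level])
        lam_m = z[0]
        lam_n = rho * z[0] + np.sqrt(1.0 - rho ** 2) * z[1]
        A = np.tile(truth.base_amp[:, None], (1, n_trials)).astype(float)
        A[maint] += truth.amp_set[:, None] * level[None, :]
        A[manip] += truth.amp_steps[:, None] * steps[None, :]
        A[maint] += truth.w_maint * lam_m[None, :]
        A[manip] += truth.w_manip * lam_n[None, :]
        s_t = rng.normal(size=n_trials)
        u_t = rng.normal(size=n_trials)
        lv_idx = level.astype(int) - 1
        A[maint] += c_load[:, lv_idx] * s_t[None, :] + e_load[:, None] * u_t[None, :]
        A[manip] += d_load[:, lv_idx] * s_t[None, :] + f_load[:, None] * u_t[None, :]
        signal = X @ A.T
        innov_sd = truth.noise_sd * np.sqrt(1.0 - truth.ar1 ** 2)
        noise = lfilter([1.0], [1.0, -truth.ar1],
                        rng.normal(0.0, innov_sd, size=(n_volumes, truth.n_rois)),
                        axis=0)
        conf = _confound_table(rng, n_volumes)
        mix = rng.normal(0.0, truth.confound_mix_sd, size=(conf.shape[1], truth.n_rois))
        signal = signal + noise + conf.to_numpy() @ mix
        bundle[int(run)] = {
            "signal": signal,
            "confounds": conf,
            "latents": pd.DataFrame({
                "trial": t_run["trial"].to_numpy(), "level": level,
                "rho": rho, "lam_maint": lam_m, "lam_manip": lam_n}),
        }
    return bundle


def generate_structural_matrix(
    truth: GroundTruth,
    rng: np.random.Generator,
    margin: float | None = None,
    base_fa: float = 0.40,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Symmetric FA matrix over the 46 network nodes for one subject.

    Node order is maintenance nodes then manipulation nodes.  Within-
    network blocks sit ``margin`` above the between-network baseline,
    plus edgewise noise; values are clipped to [0, 1].
    """
    margin = truth.fa_within_margin if margin is None else margin
    k = len(truth.maintenance_nodes)
    n = k + len(truth.manipulation_nodes)
    mean = np.full((n, n), base_fa)
    mean[:k, :k] += margin
    mean[k:, k:] += margin
    fa = mean + rng.normal(0.0, noise_sd, size=(n, n))
    fa = (fa + fa.T) / 2.0
    np.fill_diagonal(fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


@dataclass
class CohortConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_subjects: int = 41
    n_runs: int = 4
    trials_per_run: int = 30
    n_rois: int = 471
    nodes_per_network: int = 23
    include_timeseries: bool = True
    include_structural: bool = True
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    truth_overrides: dict = field(default_factory=dict)
    gain_slope: float = 0.5
    gain_noise_sd: float = 0.2

    @classmethod
    def behavior_only(cls, **kw) -> "CohortConfig":
        return cls(include_timeseries=False, include_structural=False, **kw)


@dataclass
class Subject:
    spec: SubjectSpec
    trials: pd.DataFrame
    bundle: dict | None = None
    fa: np.ndarray | None = None


@dataclass
class Cohort:
    config: CohortConfig
    truth: GroundTruth
    subjects: list[Subject]
    master_seed: int

    @property
    def trial_table(self) -> pd.DataFrame:
        return pd.concat([s.trials for s in self.subjects], ignore_index=True)

    def write(self, path: str | Path) -> Path:
        """Write trial tables, truth and a manifest; timeseries on demand."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.trial_table.to_csv(path / "trials.tsv", sep="\t", index=False)
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in asdict(self.truth).items()}
        (path / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        manifest = {
            "master_seed": self.master_seed,
            "n_subjects": self.config.n_subjects,
            "config": {k: v for k, v in asdict(self.config).items()
                       if not isinstance(v, (dict, BehaviorParams))},
            "subjects": [
                {**asdict(s.spec), "n_trials": len(s.trials),
                 "has_timeseries": s.bundle is not None,
                 "has_structural": s.fa is not None}
                for s in self.subjects],
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for s in self.subjects:
            sub = f"sub-{s.spec.subject_id:02d}"
            if s.fa is not None:
                np.savetxt(path / f"{sub}.fa.tsv", s.fa, delimiter="\t")
            if s.bundle is not None:
                for run, entry in s.bundle.items():
                    stem = path / f"{sub}_run-{run}"
                    np.savetxt(f"{stem}.signal.tsv", entry["signal"],
                               delimiter="\t")
                    entry["confounds"].to_csv(
                        f"{stem}.confounds.tsv", sep="\t", index=False)
                    sidecar = {"tr_s": TR, "n_volumes": int(len(entry["signal"])),
                               "n_rois": int(entry["signal"].shape[1])}
                    Path(f"{stem}.json").write_text(json.dumps(sidecar))
        return path


def trials_to_events(table: pd.DataFrame) -> pd.DataFrame:
    """Flatten a trial table into a BIDS-style events frame.

    One row per task event (array, delay, probe) with ``onset``,
    ``duration``, ``trial_type`` and the trial's demand modulators.
    Response durations use the recorded RT where available.
    """
    frames = []
    for trial_type, onset_col, dur in (("array", "onset_array", ARRAY_DUR),
                                       ("delay", "onset_delay", DELAY_DUR),
                                       ("probe", "onset_probe", PROBE_DUR)):
        f = pd.DataFrame({
            "onset": table[onset_col].to_numpy(float),
            "duration": dur,
            "trial_type": trial_type,
            "run": table["run"].to_numpy(),
            "set_size": table["level"].to_numpy(),
            "steps": table["steps"].to_numpy(),
        })
        if trial_type == "probe" and "rt_ms" in table.columns:
            rt = table["rt_ms"].to_numpy(float) / 1000.0
            f["duration"] = np.where(np.isfinite(rt), rt, PROBE_DUR)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["run", "onset"], kind="mergesort",
                           ignore_index=True)


def load_cohort(path: str | Path) -> Cohort:
    """Reload a cohort written by :meth:`Cohort.write`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    truth_raw = json.loads((path / "ground_truth.json").read_text())
    truth = GroundTruth(**{
        k: (np.asarray(v) if isinstance(v, list) else v)
        for k, v in truth_raw.items()})
    config = CohortConfig(**manifest.get("config", {}))
    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    subjects = []
    for entry in manifest["subjects"]:
        spec = SubjectSpec(
            subject_id=entry["subject_id"],
            starting_set_size=entry["starting_set_size"],
            criterion_set_size=entry["criterion_set_size"],
            acc_effects=tuple(entry["acc_effects"]),
            rt_effects=tuple(entry["rt_effects"]),
            reconfiguration_gain=entry["reconfiguration_gain"])
        t = trials[trials["subject"] == spec.subject_id].reset_index(drop=True)
        sub = f"sub-{spec.subject_id:02d}"
        bundle = None
        if entry.get("has_timeseries"):
            bundle = {}
            for run in sorted(t["run"].unique()):
                stem = path / f"{sub}_run-{run}"
                bundle[int(run)] = {
                    "signal": np.loadtxt(f"{stem}.signal.tsv", delimiter="\t"),
                    "confounds": pd.read_csv(f"{stem}.confounds.tsv", sep="\t"),
                }
        fa = None
        if entry.get("has_structural"):
            fa = np.loadtxt(path / f"{sub}.fa.tsv", delimiter="\t")
        subjects.append(Subject(spec, t, bundle, fa))
    return Cohort(config, truth, subjects, manifest["master_seed"])


def generate_cohort(config: CohortConfig | None = None,
                    master_seed: int = 0) -> Cohort:
    """Generate a full cohort with deterministic per-stage sub-seeds."""
    config = config or CohortConfig()
    truth = GroundTruth.default(
        stage_rng(master_seed, "truth"), n_rois=config.n_rois,
        nodes_per_network=config.nodes_per_network, **config.truth_overrides)
    subjects = []
    for i in range(config.n_subjects):
        spec = draw_subject_spec(
            i + 1, stage_rng(master_seed, "spec", i), config.behavior,
            gain_slope=config.gain_slope, gain_noise_sd=config.gain_noise_sd)
        trials = generate_trial_table(
            spec, stage_rng(master_seed, "design", i),
            n_runs=config.n_runs, trials_per_run=config.trials_per_run)
        trials = simulate_behavior(
            trials, config.behavior, spec, stage_rng(master_seed, "behav", i))
        bundle = fa = None
        if config.include_timeseries:
            bundle = simulate_timeseries(
                trials, truth, spec, stage_rng(master_seed, "bold", i))
        if config.include_structural:
            fa = generate_structural_matrix(
                truth, stage_rng(master_seed, "struct", i))
        subjects.append(Subject(spec, trials, bundle, fa))
    return Cohort(config, truth, subjects, master_seed)
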