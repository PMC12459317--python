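"""Synthetic panel cohorts with the structure the multistate analysis assumes.

Each subject carries a latent three-state continuous-time Markov chain
(normoglycemia <-> prediabetes -> diabetes) simulated by Gillespie sampling
from a generator matrix, observed only on a biennial visit schedule with
imperfect retention.  At attended visits, biomarkers (FPG, 2h-PG, HbA1c,
fasting insulin, medication flag) are drawn from truncated normals confined
to the defining region of the latent state, so classification recovers the
latent state exactly.  Baseline covariates and history flags (prior diabetes,
cardiovascular disease, cancer, missing baseline measurements) are included
so the exclusion cascade has realistic work to do.

The default generator matrices are the principal matrix logarithms of annual
transition-probability matrices in the range reported for middle-aged East
Asian community cohorts; they are the reference study conditions for the
package's recovery tests, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from . import states as st
from .ctmc import generator_from_annual, validate_generator

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "ANNUAL_P_IIFG", "ANNUAL_P_IGT",
    "default_generator",
    "sample_trajectory",
    "observe_panel",
    "emit_biomarkers",
    "generate_cohort",
    "write_cohort",
]

# Reference annual transition-probability matrices (percent/100) over
# (NORMO, PRE, DM) used as default study conditions for each pathway.
ANNUAL_P_IIFG = np.array([
    [0.948, 0.042, 0.010],
    [0.252, 0.671, 0.077],
    [0.0, 0.0, 1.0],
])
ANNUAL_P_IGT = np.array([
    [0.893, 0.102, 0.005],
    [0.226, 0.705, 0.069],
    [0.0, 0.0, 1.0],
])

# Baseline prevalence of the prediabetes phenotype among non-diabetic
# subjects: iIFG is rare (~3.5% of NORMO+iIFG), IGT common (~23%).
BASELINE_PRE_PROB = {"iifg": 0.035, "igt": 0.235}

# Biomarker emission: (mean, sd, lower, upper) of truncated normals per
# state.  Means/SDs loosely follow published baseline tables for such
# cohorts; only the truncation region is contract-bearing.
_EMISSION = {
    st.NORMO: {"fpg": (82.6, 7.2, 40.0, 99.99), "pg2h": (104.8, 20.7, 30.0, 139.99),
               "hba1c": (5.3, 0.3, 3.5, 6.49)},
    st.IIFG: {"fpg": (105.9, 5.4, 100.0, 125.99), "pg2h": (110.1, 21.1, 30.0, 139.99),
              "hba1c": (5.5, 0.4, 3.5, 6.49)},
    st.IGT: {"fpg": (87.8, 9.8, 40.0, 125.99), "pg2h": (161.2, 16.0, 140.0, 199.99),
             "hba1c": (5.5, 0.4, 3.5, 6.49)},
}
_DM_EMISSION = {
    "fpg": (150.0, 20.0, 126.0, 400.0),
    "pg2h": (240.0, 35.0, 200.0, 500.0),
    "hba1c": (7.3, 0.8, 6.5, 15.0),
}
_INSULIN = (24.4, 19.3, 1.0, 150.0)
DM_CRITERIA = ("fpg", "pg2h", "hba1c", "med")


def default_generator(pathway: str) -> np.ndarray:
    """Reference generator matrix for a pathway ('iifg' or 'igt')."""
    p1 = {"iifg": ANNUAL_P_IIFG, "igt": ANNUAL_P_IGT}[pathway]
    return generator_from_annual(p1)


def default_retention(n_waves: int) -> np.ndarray:
    """Per-wave attendance probability: declining 0.95 -> 0.60 over 10 waves."""
    base = np.linspace(0.95, 0.60, 10)
    if n_waves <= 10:
        return base[:n_waves]
    return np.concatenate([base, np.full(n_waves - 10, 0.60)])


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a community cohort of ~10,000 adults aged 40-69 observed
    biennially over 20 years, with declining retention and with the exclusion
    strata (prior diabetes, cardiovascular disease, cancer, missing baseline
    data) at the rates such cohorts report.
    """

    n_subjects: int = 10_000
    pathway: str = "igt"
    visit_interval: float = 2.0
    horizon: float = 20.0
    q_true: np.ndarray | None = None          # over (NORMO, PRE, DM); default per pathway
    baseline_pre_prob: float | None = None    # P(prediabetes | non-DM baseline)
    retention: float | list[float] | None = None  # scalar or per-wave schedule
    age_range: tuple[float, float] = (40.0, 69.0)
    male_prob: float = 0.469
    bmi_mean: float = 24.5
    bmi_sd: float = 3.1
    frac_baseline_dm: float = 0.202
    frac_cvd: float = 0.0177
    frac_cancer: float = 0.0073
    frac_missing_baseline: float = 0.007
    frac_no_followup: float = 0.0013
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pathway not in ("iifg", "igt"):
            raise ValueError(f"unknown pathway {self.pathway!r}")
        n_waves = self.horizon / self.visit_interval
        if abs(n_waves - round(n_waves)) > 1e-9:
            raise ValueError("horizon must be a multiple of visit_interval")
        for name in ("male_prob", "frac_baseline_dm", "frac_cvd", "frac_cancer",
                     "frac_missing_baseline", "frac_no_followup"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    @property
    def n_waves(self) -> int:
        return int(round(self.horizon / self.visit_interval))

    @property
    def schedule(self) -> np.ndarray:
        return np.arange(self.n_waves + 1) * self.visit_interval

    def resolved_q(self) -> np.ndarray:
        q = self.q_true if self.q_true is not None else default_generator(self.pathway)
        return validate_generator(np.asarray(q, dtype=float), absorbing=[2])

    def resolved_retention(self) -> np.ndarray:
        if self.retention is None:
            return default_retention(self.n_waves)
        if np.isscalar(self.retention):
            return np.full(self.n_waves, float(self.retention))
        r = np.asarray(self.retention, dtype=float)
        if len(r) != self.n_waves:
            raise ValueError(f"retention schedule must have {self.n_waves} entries")
        return r

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "q_true" in raw and raw["q_true"] is not None:
            raw["q_true"] = np.asarray(raw["q_true"], dtype=float)
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        if seed is not None:
            raw["seed"] = seed
        return cls(**raw)


@dataclass
class Trajectory:
    """Latent state path: jump times (years) and states, baseline to absorption/horizon."""

    subject_id: object
    times: list[float] = field(default_factory=list)
    states: list[int] = field(default_factory=list)

    def state_at(self, t: float) -> int:
        k = int(np.searchsorted(np.asarray(self.times), t, side="right")) - 1
        return self.states[k]


def sample_trajectory(
    q: np.ndarray,
    initial_state: int,
    horizon: float,
    rng: np.random.Generator,
    subject_id: object = None,
) -> Trajectory:
    """Gillespie-sample one latent path from generator ``q``.

    Holding time in state i is Exponential(rate -q_ii); the next state is
    drawn with probability q_ij / (-q_ii).  Stops at absorption or horizon.
    """
    q = np.asarray(q, dtype=float)
    traj = Trajectory(subject_id=subject_id, times=[0.0], states=[int(initial_state)])
    t, s = 0.0, int(initial_state)
    while True:
        rate = -q[s, s]
        if rate <= 0:
            return traj  # absorbing (or frozen) state
        t = t + rng.exponential(1.0 / rate)
        if t >= horizon:
            return traj
        probs = q[s].copy()
        probs[s] = 0.0
        probs = probs / rate
        s = int(rng.choice(len(probs), p=probs))
        traj.times.append(t)
        traj.states.append(s)


def observe_panel(
    trajectory: Trajectory,
    schedule: np.ndarray,
    retention: np.ndarray | float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Panel observation: latent state at each scheduled time plus attendance.

    Baseline is always attended; wave k > 0 is attended with probability
    ``retention[k-1]``.  Missed visits are flagged, never fabricated.
    Returns (states, attended) arrays aligned with ``schedule``.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("empty visit schedule")
    latent = np.array([trajectory.state_at(t) for t in schedule])
    if np.isscalar(retention):
        retention = np.full(schedule.size - 1, float(retention))
    attended = np.ones(schedule.size, dtype=bool)
    if schedule.size > 1:
        attended[1:] = rng.random(schedule.size - 1) < np.asarray(retention)
    return latent, attended


def _trunc_draw(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    """Truncated-normal draw by inverse-CDF (exact, cheap for scalar calls)."""
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    u = rng.random(size) if size is not None else rng.random()
    return mean + sd * ndtri(a + u * (b - a))


def emit_biomarkers(
    state: str,
    rng: np.random.Generator,
    med_already: bool = False,
) -> tuple[float, float, float, bool]:
    """Draw (fpg, pg2h, hba1c, on_dm_med) consistent with a glycemic state.

    Non-DM states draw every biomarker inside the state's defining region, so
    the classifier maps the emission back to ``state`` with certainty.  DM
    satisfies one criterion chosen uniformly among FPG, 2h-PG, HbA1c and
    medication (the others stay sub-threshold); a medication flag, once set,
    persists (``med_already``).
    """
    if state != st.DM:
        spec = _EMISSION[state]
        fpg = _trunc_draw(rng, *spec["fpg"])
        pg2h = _trunc_draw(rng, *spec["pg2h"])
        hba1c = _trunc_draw(rng, *spec["hba1c"])
        return float(fpg), float(pg2h), float(hba1c), False
    criterion = DM_CRITERIA[rng.integers(len(DM_CRITERIA))]
    # start from sub-threshold draws, then push the chosen criterion over
    fpg = _trunc_draw(rng, *_EMISSION[st.NORMO]["fpg"])
    pg2h = _trunc_draw(rng, *_EMISSION[st.NORMO]["pg2h"])
    hba1c = _trunc_draw(rng, *_EMISSION[st.NORMO]["hba1c"])
    med = bool(med_already)
    if criterion == "fpg":
        fpg = _trunc_draw(rng, *_DM_EMISSION["fpg"])
    elif criterion == "pg2h":
        pg2h = _trunc_draw(rng, *_DM_EMISSION["pg2h"])
    elif criterion == "hba1c":
        hba1c = _trunc_draw(rng, *_DM_EMISSION["hba1c"])
    else:
        med = True
    return float(fpg), float(pg2h), float(hba1c), med


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (baseline, visits) DataFrames.

    The latent state space is (NORMO, PRE, DM) with PRE the configured
    pathway's phenotype.  Subjects in the prior-diabetes stratum start (and
    stay) in DM; subjects in the missing-baseline stratum have their baseline
    FPG blanked; the no-follow-up stratum attends only the baseline visit.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    q = config.resolved_q()
    retention = config.resolved_retention()
    schedule = config.schedule
    pre_label = st.IIFG if config.pathway == "iifg" else st.IGT
    labels = (st.NORMO, pre_label, st.DM)
    p_pre = (config.baseline_pre_prob if config.baseline_pre_prob is not None
             else BASELINE_PRE_PROB[config.pathway])

    n = config.n_subjects
    hist_dm = rng.random(n) < config.frac_baseline_dm
    hist_cvd = rng.random(n) < config.frac_cvd
    hist_cancer = rng.random(n) < config.frac_cancer
    missing_base = rng.random(n) < config.frac_missing_baseline
    no_follow = rng.random(n) < config.frac_no_followup
    age0 = rng.uniform(*config.age_range, size=n)
    sex = np.where(rng.random(n) < config.male_prob, "male", "female")
    bmi0 = rng.normal(config.bmi_mean, config.bmi_sd, size=n)

    base_rows = []
    visit_rows = []
    for i in range(n):
        sid = f"S{i:06d}"
        base_rows.append({
            "subject_id": sid, "age0": round(float(age0[i]), 1), "sex": sex[i],
            "bmi0": round(float(bmi0[i]), 1), "hist_dm": bool(hist_dm[i]),
            "hist_cvd": bool(hist_cvd[i]), "hist_cancer": bool(hist_cancer[i]),
        })
        if hist_dm[i]:
            s0 = 2  # established diabetes: absorbing from baseline
        else:
            s0 = 1 if rng.random() < p_pre else 0
        traj = sample_trajectory(q, s0, config.horizon, rng, subject_id=sid)
        latent, attended = observe_panel(traj, schedule, retention, rng)
        if no_follow[i]:
            attended[1:] = False
        med = False
        for k, t in enumerate(schedule):
            if not attended[k]:
                visit_rows.append({
                    "subject_id": sid, "t_years": float(t), "fpg": np.nan,
                    "pg2h": np.nan, "hba1c": np.nan, "insulin": np.nan,
                    "on_dm_med": False, "attended": False,
                })
                continue
            state_label = labels[latent[k]]
            fpg, pg2h, hba1c, med_now = emit_biomarkers(state_label, rng,
                                                        med_already=med)
            med = med or med_now
            insulin = float(_trunc_draw(rng, *_INSULIN))
            if k == 0 and missing_base[i]:
                fpg = np.nan
            visit_rows.append({
                "subject_id": sid, "t_years": float(t), "fpg": fpg,
                "pg2h": pg2h, "hba1c": hba1c, "insulin": insulin,
                "on_dm_med": med, "attended": True,
            })
    baseline = pd.DataFrame(base_rows, columns=st.BASELINE_COLUMNS)
    visits = pd.DataFrame(visit_rows, columns=st.VISIT_COLUMNS)
    return baseline, visits


def write_cohort(baseline: pd.DataFrame, visits: pd.DataFrame, outdir) -> tuple[Path, Path]:
    """Write the two-CSV cohort dialect; returns (baseline_path, visits_path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bpath = outdir / "baseline.csv"
    vpath = outdir / "visits.csv"
    baseline.to_csv(bpath, index=False, float_format="%.6g")
    visits.to_csv(vpath, index=False, float_format="%.6g")
    return bpath, vpath
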