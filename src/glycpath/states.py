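"""Glycemic-state classification and cohort assembly for panel OGTT data.

Visits carry fasting plasma glucose (FPG, mg/dL), 2-h post-load glucose from
a 75 g OGTT (2h-PG, mg/dL), HbA1c (%) and an anti-diabetic-medication flag.
Each visit is classified into one of four states:

* ``DM``    — FPG >= 126, or 2h-PG >= 200, or HbA1c >= 6.5, or on medication;
* ``IGT``   — otherwise, 2h-PG in [140, 199] (combined IFG+IGT counts as IGT);
* ``IIFG``  — otherwise, FPG in [100, 125] with 2h-PG < 140;
* ``NORMO`` — otherwise.

Downstream multistate models collapse these onto a three-state pathway
(``NORMO`` <-> prediabetes -> ``DM``), with the phenotype not represented by
the pathway handled by a configurable off-state policy.  The module also
implements the exclusion cascade used to assemble the analysis cohort,
last-observation-carried-forward (LOCF) filling of the biennial visit grid,
reduction of subject histories to aggregated transition intervals, the
Matthews HOMA indices, and descriptive baseline summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import CtmcStructure, IntervalCounts

__all__ = [
    "NORMO", "IIFG", "IGT", "DM", "STATES",
    "ModelVariant", "ExclusionTally",
    "classify_state", "classify_visits",
    "assemble_cohort", "locf_fill", "build_intervals",
    "homa_ir", "homa_beta", "baseline_summary", "pct",
    "read_visits", "read_baseline",
]

NORMO = "NORMO"
IIFG = "IIFG"
IGT = "IGT"
DM = "DM"
STATES = (NORMO, IIFG, IGT, DM)

# Diagnostic thresholds (ADA criteria), mg/dL except HbA1c in %
FPG_DM = 126.0
FPG_IFG_LO = 100.0
PG2H_DM = 200.0
PG2H_IGT_LO = 140.0
HBA1C_DM = 6.5

VISIT_COLUMNS = ["subject_id", "t_years", "fpg", "pg2h", "hba1c",
                 "insulin", "on_dm_med", "attended"]
BASELINE_COLUMNS = ["subject_id", "age0", "sex", "bmi0",
                    "hist_dm", "hist_cvd", "hist_cancer"]


class ClassificationError(ValueError):
    """Raised when a visit cannot be classified (missing/invalid biomarkers)."""


@dataclass(frozen=True)
class ModelVariant:
    """One pathway model: which prediabetes phenotype, which transitions.

    ``pathway`` selects the prediabetes state (``"iifg"`` or ``"igt"``);
    ``directionality`` is ``"bi"`` (regression to normoglycemia allowed, the
    base case) or ``"uni"`` (no regression, the sensitivity variant);
    ``offstate_policy`` controls visits classified as the *other* phenotype:
    ``"merge"`` maps them to NORMO (not prediabetic in this model),
    ``"censor"`` splits the history at such visits.
    """

    pathway: str = "iifg"
    directionality: str = "bi"
    offstate_policy: str = "merge"

    def __post_init__(self) -> None:
        if self.pathway not in ("iifg", "igt"):
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.directionality not in ("bi", "uni"):
            raise ValueError(f"unknown directionality {self.directionality!r}")
        if self.offstate_policy not in ("merge", "censor"):
            raise ValueError(f"unknown offstate_policy {self.offstate_policy!r}")

    @property
    def pre_state(self) -> str:
        return IIFG if self.pathway == "iifg" else IGT

    @property
    def off_state(self) -> str:
        return IGT if self.pathway == "iifg" else IIFG

    @property
    def structure(self) -> CtmcStructure:
        states = (NORMO, self.pre_state, DM)
        allowed = [(0, 1), (0, 2), (1, 2)]
        if self.directionality == "bi":
            allowed.insert(2, (1, 0))
        return CtmcStructure(states=states, absorbing=frozenset({DM}),
                             allowed=tuple(allowed))


@dataclass
class ExclusionTally:
    """Counts of subjects removed at each step of the exclusion cascade."""

    missing_baseline: int = 0
    no_followup: int = 0
    baseline_dm: int = 0
    cvd: int = 0
    cancer: int = 0

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.missing_baseline, self.no_followup, self.baseline_dm,
                self.cvd, self.cancer)

    def to_dict(self) -> dict[str, int]:
        return {
            "missing_baseline": self.missing_baseline,
            "no_followup": self.no_followup,
            "baseline_dm": self.baseline_dm,
            "cvd": self.cvd,
            "cancer": self.cancer,
            "total_excluded": sum(self.as_tuple()),
        }


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_state(fpg, pg2h=None, hba1c=None, on_dm_med: bool = False,
                   strict: bool = False) -> str:
    """Classify one visit's biomarkers into NORMO / IIFG / IGT / DM.

    FPG is required.  Missing 2h-PG or HbA1c skip their clauses (so the visit
    is classified on the remaining criteria), unless ``strict=True`` in which
    case a missing 2h-PG raises.
    """
    if _missing(fpg):
        raise ClassificationError("fasting plasma glucose is required")
    if fpg <= 0:
        raise ClassificationError(f"fasting plasma glucose must be positive, got {fpg}")
    for name, v in (("pg2h", pg2h), ("hba1c", hba1c)):
        if not _missing(v) and v < 0:
            raise ClassificationError(f"{name} must be non-negative, got {v}")
    if strict and _missing(pg2h):
        raise ClassificationError("2h-PG missing and strict classification requested")

    if on_dm_med or fpg >= FPG_DM:
        return DM
    if not _missing(pg2h) and pg2h >= PG2H_DM:
        return DM
    if not _missing(hba1c) and hba1c >= HBA1C_DM:
        return DM
    if not _missing(pg2h) and PG2H_IGT_LO <= pg2h < PG2H_DM:
        return IGT
    if FPG_IFG_LO <= fpg < FPG_DM:
        return IIFG
    return NORMO


def classify_visits(visits: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Add a ``state`` column to a visit table (vectorised).

    Unattended visits — and attended visits whose FPG is missing, which the
    exclusion cascade deals with downstream — get a missing state.
    """
    df = visits.copy()
    fpg = df["fpg"].to_numpy(dtype=float)
    pg2h = df["pg2h"].to_numpy(dtype=float) if "pg2h" in df else np.full(len(df), np.nan)
    hba1c = df["hba1c"].to_numpy(dtype=float) if "hba1c" in df else np.full(len(df), np.nan)
    med = df["on_dm_med"].fillna(False).astype(bool).to_numpy()
    attended = df["attended"].fillna(True).astype(bool).to_numpy() if "attended" in df \
        else np.ones(len(df), dtype=bool)

    usable = attended & ~np.isnan(fpg)
    if strict and np.any(usable & np.isnan(pg2h)):
        raise ClassificationError("attended visit with missing 2h-PG in strict mode")
    with np.errstate(invalid="ignore"):
        if np.any(usable & (fpg <= 0)) or np.any(usable & (pg2h < 0)) \
                or np.any(usable & (hba1c < 0)):
            raise ClassificationError("negative or non-positive biomarker value")

    state = np.full(len(df), NORMO, dtype=object)
    with np.errstate(invalid="ignore"):
        is_dm = med | (fpg >= FPG_DM) | (pg2h >= PG2H_DM) | (hba1c >= HBA1C_DM)
        is_igt = ~is_dm & (pg2h >= PG2H_IGT_LO) & (pg2h < PG2H_DM)
        is_iifg = ~is_dm & ~is_igt & (fpg >= FPG_IFG_LO) & (fpg < FPG_DM)
    state[is_igt] = IGT
    state[is_iifg] = IIFG
    state[is_dm] = DM
    state[~usable] = None
    df["state"] = state
    return df


def assemble_cohort(
    visits: pd.DataFrame,
    baseline: pd.DataFrame,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionTally]:
    """Apply the exclusion cascade and return (visits, baseline, tally).

    Steps, in order, each subject tallied at the first step it fails:

    1. missing baseline demographics (age/sex/BMI) or baseline labs (no
       attended baseline visit at t = 0, or its FPG missing);
    2. no follow-up glycemic assessment (no attended visit with t > 0 and
       FPG present);
    3. history of diabetes or diabetes at the baseline visit;
    4. history of cardiovascular disease;
    5. history of cancer.
    """
    if baseline["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in baseline table")
    tally = ExclusionTally()
    visits = visits.sort_values(["subject_id", "t_years"], kind="stable")
    by_subject = dict(tuple(visits.groupby("subject_id", sort=False)))
    included: list = []
    for row in baseline.itertuples(index=False):
        sid = row.subject_id
        sv = by_subject.get(sid)
        base_visit = None
        if sv is not None:
            att = sv[(sv["t_years"] == 0) & sv["attended"].astype(bool)]
            if len(att):
                base_visit = att.iloc[0]
        if (
            _missing(row.age0) or _missing(row.bmi0) or _missing(row.sex)
            or (isinstance(row.sex, float) and math.isnan(row.sex))
            or base_visit is None or _missing(base_visit["fpg"])
        ):
            tally.missing_baseline += 1
            continue
        followup = sv[(sv["t_years"] > 0) & sv["attended"].astype(bool)
                      & sv["fpg"].notna()]
        if not len(followup):
            tally.no_followup += 1
            continue
        if "state" in base_visit.index and isinstance(base_visit["state"], str):
            base_state = base_visit["state"]
        else:
            base_state = classify_state(
                base_visit["fpg"], base_visit.get("pg2h"), base_visit.get("hba1c"),
                bool(base_visit.get("on_dm_med", False)), strict=strict,
            )
        if bool(row.hist_dm) or base_state == DM:
            tally.baseline_dm += 1
            continue
        if bool(row.hist_cvd):
            tally.cvd += 1
            continue
        if bool(row.hist_cancer):
            tally.cancer += 1
            continue
        included.append(sid)
    inc = set(included)
    return (
        visits[visits["subject_id"].isin(inc)].reset_index(drop=True),
        baseline[baseline["subject_id"].isin(inc)].reset_index(drop=True),
        tally,
    )


def locf_fill(times: list[float], states: list[str | None],
              interval: float = 2.0) -> tuple[list[float], list[str]]:
    """Fill a subject's visit grid by last observation carried forward.

    ``times``/``states`` are aligned on the scheduled grid (baseline first);
    missed visits have state ``None``.  Returns the filled grid truncated at
    the last attended visit, and at the first DM observation (DM is absorbing
    downstream, so later times contribute no further intervals).
    """
    if not times or times[0] != 0 or states[0] is None:
        raise ValueError("baseline state at t = 0 is required")
    last_attended = max(i for i, s in enumerate(states) if s is not None)
    out_t: list[float] = []
    out_s: list[str] = []
    current = states[0]
    for i in range(last_attended + 1):
        expected = i * interval
        if not math.isclose(times[i], expected, abs_tol=1e-9):
            raise ValueError(f"grid time {times[i]} != scheduled {expected}")
        if states[i] is not None:
            current = states[i]
        out_t.append(times[i])
        out_s.append(current)
        if current == DM:
            break
    return out_t, out_s


def _map_state(state: str, model: ModelVariant) -> str | None:
    """Project a four-way label onto the model's {NORMO, PRE, DM} space.

    Returns None when the visit must censor the history (off-state under the
    ``censor`` policy).
    """
    if state == model.off_state:
        return NORMO if model.offstate_policy == "merge" else None
    return state


def build_intervals(
    histories: dict[object, tuple[list[float], list[str]]],
    model: ModelVariant,
) -> tuple[IntervalCounts, int]:
    """Aggregate consecutive visit pairs into panel transition counts.

    ``histories`` maps subject_id to its LOCF-filled (times, states).  Pairs
    after the first DM are dropped; off-model states are merged to NORMO or
    censor the history per ``model.offstate_policy``.  Under a unidirectional
    model, observed regressions from prediabetes to normoglycemia are
    inadmissible (their model probability is exactly zero) and are dropped;
    the second return value counts them.
    """
    counts = IntervalCounts()
    n_dropped = 0
    for _sid, (times, states) in histories.items():
        mapped = [_map_state(s, model) for s in states]
        for k in range(len(mapped) - 1):
            a, b = mapped[k], mapped[k + 1]
            if a is None or b is None:
                continue  # censored at an off-model visit
            if a == DM:
                break
            dt = times[k + 1] - times[k]
            if dt <= 0:
                raise ValueError(f"non-increasing visit times for subject {_sid}")
            if model.directionality == "uni" and a == model.pre_state and b == NORMO:
                n_dropped += 1
                continue
            counts.add(a, b, dt)
    return counts, n_dropped


def histories_from_visits(
    classified: pd.DataFrame,
    interval: float = 2.0,
    grid: str = "locf",
) -> dict[object, tuple[list[float], list[str]]]:
    """Per-subject state histories from a classified visit table.

    ``grid="locf"`` snaps to the scheduled grid with LOCF filling (the base
    case); ``grid="raw"`` keeps only attended visits at their actual times,
    so consecutive pairs may span multiple visit intervals.
    """
    if grid not in ("locf", "raw"):
        raise ValueError(f"unknown grid mode {grid!r}")
    histories: dict[object, tuple[list[float], list[str]]] = {}
    for sid, sv in classified.groupby("subject_id", sort=True):
        sv = sv.sort_values("t_years")
        times = sv["t_years"].tolist()
        states = [s if isinstance(s, str) else None for s in sv["state"]]
        if grid == "locf":
            # reindex onto the scheduled grid; absent rows count as missed
            n_slots = int(round(max(times) / interval)) + 1
            slot_t = [k * interval for k in range(n_slots)]
            slot_s: list[str | None] = [None] * n_slots
            for t, s in zip(times, states):
                k = round(t / interval)
                if not math.isclose(t, k * interval, abs_tol=1e-9):
                    raise ValueError(f"visit time {t} is off the {interval}-year grid")
                slot_s[k] = s
            histories[sid] = locf_fill(slot_t, slot_s, interval=interval)
        else:
            t_obs = [t for t, s in zip(times, states) if s is not None]
            s_obs = [s for s in states if s is not None]
            if DM in s_obs:
                cut = s_obs.index(DM) + 1
                t_obs, s_obs = t_obs[:cut], s_obs[:cut]
            histories[sid] = (t_obs, s_obs)
    return histories


def homa_ir(fpg: float, insulin: float) -> float:
    """HOMA insulin-resistance index: FPG [mg/dL] x insulin [mU/L] / 405."""
    return fpg * insulin / 405.0


def homa_beta(fpg: float, insulin: float) -> float:
    """HOMA beta-cell-function index: 360 x insulin / (FPG - 63), FPG > 63 mg/dL."""
    if insulin == 0:
        return 0.0
    if fpg <= 63:
        raise ValueError(f"HOMA-beta requires FPG > 63 mg/dL, got {fpg}")
    return 360.0 * insulin / (fpg - 63.0)


def pct(part: float, whole: float, digits: int = 1) -> float:
    """Percentage share rounded to the printed precision."""
    return round(100.0 * part / whole, digits)


CONTINUOUS_COVARIATES = ["age0", "bmi0", "fpg", "pg2h", "hba1c", "insulin"]
CATEGORICAL_COVARIATES = ["sex", "hist_cvd", "hist_cancer"]


def baseline_summary(baseline: pd.DataFrame, classified: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table by baseline glycemic state.

    Per group: n, % of cohort, mean +/- SD of continuous covariates and n (%)
    of categorical ones.  Group shares sum to 100% over the non-DM states
    present at baseline.
    """
    if baseline.empty:
        raise ValueError("empty cohort")
    base = classified[classified["t_years"] == 0][["subject_id", "state",
                                                   "fpg", "pg2h", "hba1c", "insulin"]]
    merged = baseline.merge(base, on="subject_id", how="inner")
    total = len(merged)
    rows = []
    for state, grp in merged.groupby("state", sort=True):
        row: dict[str, object] = {"state": state, "n": len(grp),
                                  "pct": pct(len(grp), total)}
        for cov in CONTINUOUS_COVARIATES:
            if cov in grp:
                vals = grp[cov].astype(float)
                row[f"{cov}_mean"] = vals.mean()
                row[f"{cov}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        for cov in CATEGORICAL_COVARIATES:
            if cov in grp:
                if cov == "sex":
                    k = int((grp[cov] == "male").sum())
                else:
                    k = int(grp[cov].astype(bool).sum())
                row[f"{cov}_n"] = k
                row[f"{cov}_pct"] = pct(k, len(grp))
        rows.append(row)
    return pd.DataFrame(rows)


def read_visits(path) -> pd.DataFrame:
    """Read the long-format visit CSV (one row per scheduled visit)."""
    df = pd.read_csv(path)
    missing = set(VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"visit table missing columns: {sorted(missing)}")
    df["on_dm_med"] = df["on_dm_med"].fillna(False).astype(bool)
    df["attended"] = df["attended"].fillna(True).astype(bool)
    return df.sort_values(["subject_id", "t_years"], kind="stable").reset_index(drop=True)


def read_baseline(path) -> pd.DataFrame:
    """Read the baseline covariate CSV (one row per subject)."""
    df = pd.read_csv(path)
    missing = set(BASELINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"baseline table missing columns: {sorted(missing)}")
    for col in ("hist_dm", "hist_cvd", "hist_cancer"):
        df[col] = df[col].fillna(False).astype(bool)
    return df
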