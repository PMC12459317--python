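"""End-to-end study orchestration.

``run_study`` takes a cohort (simulated or ingested from the two-CSV
dialect), classifies visits, applies the exclusion cascade, fills the visit
grid by LOCF, and — for every requested (pathway, directionality, stratum)
combination — builds interval counts, fits the multistate model by maximum
likelihood, and derives annual transition probabilities, mean sojourn times
and total length of residence with simulation confidence intervals.
``render_report`` writes the tables as CSV and Markdown.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import states as st
from .ctmc import (FitResult, annual_transitions, fit_ctmc, mean_sojourn,
                   residence_estimate)
from .simulate import SimulationConfig, generate_cohort

__all__ = ["StudyConfig", "StudyReport", "run_study", "stratify", "render_report"]

log = logging.getLogger("glycpath")

AGE_EDGE = 60.0
BMI_EDGES = (23.0, 25.0)
STRATA_FACTORS = ("age", "sex", "bmi")


@dataclass
class StudyConfig:
    """What to run: input source, model variants, strata, CI draws, seed."""

    simulation: SimulationConfig | None = None
    visits_csv: str | None = None
    baseline_csv: str | None = None
    pathways: tuple[str, ...] = ("iifg", "igt")
    directions: tuple[str, ...] = ("bi", "uni")
    strata: tuple[str, ...] = ()
    offstate_policy: str = "merge"
    grid: str = "locf"
    visit_interval: float = 2.0
    b_draws: int = 1000
    start_state: str = st.NORMO
    seed: int = 0
    drop_missing_stratum: bool = True

    def __post_init__(self) -> None:
        if self.simulation is None and (self.visits_csv is None or self.baseline_csv is None):
            raise ValueError("either a simulation config or CSV paths are required")
        if not self.pathways:
            raise ValueError("at least one pathway is required")
        for f in self.strata:
            if f not in STRATA_FACTORS:
                raise ValueError(f"unknown stratification factor {f!r}")


@dataclass
class StudyReport:
    """Fits and derived tables per (pathway, direction, stratum, level)."""

    exclusion_tally: st.ExclusionTally
    n_included: int
    baseline_table: pd.DataFrame
    results: dict[tuple[str, str, str, str], dict] = field(default_factory=dict)

    def key_frame(self) -> pd.DataFrame:
        rows = [{"pathway": p, "direction": d, "stratum": s, "level": l}
                for (p, d, s, l) in self.results]
        return pd.DataFrame(rows)


def stratify(baseline: pd.DataFrame, factor: str,
             drop_missing: bool = True) -> dict[str, pd.DataFrame]:
    """Partition the cohort by a baseline factor.

    Levels: age ``<=60`` / ``>60`` years at baseline; sex ``male``/``female``;
    BMI ``<23``, ``23-<25`` (left-closed), ``>=25`` kg/m^2.
    """
    if factor == "age":
        vals = baseline["age0"].astype(float)
        levels = {"age<=60": vals <= AGE_EDGE, "age>60": vals > AGE_EDGE}
    elif factor == "sex":
        levels = {"male": baseline["sex"] == "male",
                  "female": baseline["sex"] == "female"}
    elif factor == "bmi":
        vals = baseline["bmi0"].astype(float)
        levels = {
            "bmi<23": vals < BMI_EDGES[0],
            "bmi23-25": (vals >= BMI_EDGES[0]) & (vals < BMI_EDGES[1]),
            "bmi>=25": vals >= BMI_EDGES[1],
        }
    else:
        raise ValueError(f"unknown stratification factor {factor!r}")
    covered = np.zeros(len(baseline), dtype=bool)
    out = {}
    for name, mask in levels.items():
        mask = mask.fillna(False).to_numpy(dtype=bool)
        covered |= mask
        out[name] = baseline[mask]
    n_missing = int((~covered).sum())
    if n_missing:
        if not drop_missing:
            raise ValueError(f"{n_missing} subjects lack the {factor} covariate")
        log.warning("%d subjects dropped from %s strata (missing covariate)",
                    n_missing, factor)
    return out


def _fit_one(
    histories: dict,
    model: st.ModelVariant,
    b_draws: int,
    start_state: str,
    rng: np.random.Generator,
) -> dict:
    counts, n_dropped = st.build_intervals(histories, model)
    entry: dict = {"model": model, "n_intervals": counts.total, "n_dropped": n_dropped}
    try:
        fit = fit_ctmc(model.structure, counts)
        fit.n_dropped = n_dropped
    except ValueError as exc:
        entry.update(fit=None, flagged=True, error=str(exc))
        log.warning("fit skipped (%s %s): %s", model.pathway, model.directionality, exc)
        return entry
    entry["fit"] = fit
    entry["flagged"] = not fit.converged
    entry["atp"] = annual_transitions(fit, b=b_draws, rng=rng)
    absorbing_idx = [fit.structure.index(s) for s in fit.structure.absorbing]
    entry["sojourn"] = {
        s: y for s, y in zip(fit.structure.states,
                             mean_sojourn(fit.q_hat, absorbing_idx))
    }
    entry["residence"] = residence_estimate(fit, start_state=start_state,
                                            b=b_draws, rng=rng)
    return entry


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline and return the assembled report."""
    t0 = time.perf_counter()
    if config.simulation is not None:
        log.info("simulating cohort: n=%d pathway=%s seed=%d",
                 config.simulation.n_subjects, config.simulation.pathway,
                 config.simulation.seed)
        baseline, visits = generate_cohort(config.simulation)
    else:
        visits = st.read_visits(config.visits_csv)
        baseline = st.read_baseline(config.baseline_csv)
    log.info("cohort loaded in %.1fs: %d subjects", time.perf_counter() - t0,
             len(baseline))

    classified = st.classify_visits(visits)
    visits_inc, baseline_inc, tally = st.assemble_cohort(classified, baseline)
    log.info("exclusion cascade: %s; %d included", tally.to_dict(), len(baseline_inc))
    if baseline_inc.empty:
        raise ValueError("no subjects left after the exclusion cascade")
    baseline_table = st.baseline_summary(baseline_inc, visits_inc)

    histories = st.histories_from_visits(visits_inc, interval=config.visit_interval,
                                         grid=config.grid)
    rng = np.random.default_rng(config.seed)
    report = StudyReport(exclusion_tally=tally, n_included=len(baseline_inc),
                         baseline_table=baseline_table)
    strata_sets: list[tuple[str, str, set]] = [("overall", "overall",
                                                set(baseline_inc["subject_id"]))]
    for factor in config.strata:
        for level, sub in stratify(baseline_inc, factor,
                                   config.drop_missing_stratum).items():
            strata_sets.append((factor, level, set(sub["subject_id"])))

    for pathway in config.pathways:
        for direction in config.directions:
            model = st.ModelVariant(pathway=pathway, directionality=direction,
                                    offstate_policy=config.offstate_policy)
            for factor, level, ids in strata_sets:
                sub_hist = {sid: h for sid, h in histories.items() if sid in ids}
                t1 = time.perf_counter()
                entry = _fit_one(sub_hist, model, config.b_draws,
                                 config.start_state, rng)
                log.info("fit %s/%s/%s: %.1fs, %s intervals%s",
                         pathway, direction, level, time.perf_counter() - t1,
                         entry["n_intervals"],
                         " [flagged]" if entry.get("flagged") else "")
                report.results[(pathway, direction, factor, level)] = entry
    return report


def _atp_csv(entry: dict) -> pd.DataFrame:
    atp = entry["atp"].copy()
    return atp[["from", "to", "n", "atp_pct", "ci_lo", "ci_hi"]]


def _fig_summary(pathway: str, entry: dict) -> str:
    """Fig.-style text summary: states, ATP arrows, residence times."""
    lines = [f"Pathway model: NORMO <-> {entry['model'].pre_state} -> DM"
             if entry["model"].directionality == "bi"
             else f"Pathway model: NORMO -> {entry['model'].pre_state} -> DM"]
    if entry.get("fit") is None:
        lines.append("  fit unavailable: " + entry.get("error", "unknown"))
        return "\n".join(lines) + "\n"
    for row in entry["atp"].itertuples(index=False):
        if row[0] != row[1] and row.atp_pct > 0:
            lines.append(f"  {row[0]:>6} -> {row[1]:<6} {row.atp_pct:5.1f}% "
                         f"({row.ci_lo:.1f}, {row.ci_hi:.1f})")
    for row in entry["residence"].itertuples(index=False):
        lines.append(f"  total residence in {row.state}: {row.years:.1f} y "
                     f"({row.ci_lo:.1f}, {row.ci_hi:.1f}), from {row.start_state}")
    return "\n".join(lines) + "\n"


def _markdown_table(df: pd.DataFrame) -> str:
    def fmt(v) -> str:
        if isinstance(v, float):
            return f"{v:.4f}"
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    rule = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, rule, *body]) + "\n"


def render_report(report: StudyReport, outdir, format: str = "csv") -> list[Path]:
    """Write the report tables; returns the files written (deterministic names)."""
    if format not in ("csv", "md"):
        raise ValueError(f"unknown format {format!r}; supported: csv, md")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, stem: str) -> None:
        if format == "csv":
            path = outdir / f"{stem}.csv"
            df.to_csv(path, index=False, float_format="%.4f")
        else:
            path = outdir / f"{stem}.md"
            path.write_text(_markdown_table(df))
        written.append(path)

    tally_df = pd.DataFrame([report.exclusion_tally.to_dict()
                             | {"n_included": report.n_included}])
    _write(tally_df, "cohort_flow")
    _write(report.baseline_table, "baseline_summary")

    fig_lines: list[str] = []
    for (pathway, direction, factor, level), entry in sorted(report.results.items()):
        stem = f"atp_{pathway}_{direction}_{factor}_{level}".replace("<", "lt").replace(
            ">", "gt").replace("=", "e")
        if entry.get("fit") is None:
            _write(pd.DataFrame([{"error": entry.get("error", "fit unavailable"),
                                  "n_intervals": entry["n_intervals"]}]), stem)
            continue
        _write(_atp_csv(entry), stem)
        _write(entry["residence"], stem.replace("atp_", "residence_"))
        (outdir / f"fit_{pathway}_{direction}_{factor}_{level}.json".replace(
            "<", "lt").replace(">", "gt").replace("=", "e")).write_text(
            entry["fit"].to_json())
        if factor == "overall":
            fig_lines.append(f"== {pathway} / {direction} ==")
            fig_lines.append(_fig_summary(pathway, entry))
    fig_path = outdir / "figure_summary.txt"
    fig_path.write_text("\n".join(fig_lines))
    written.append(fig_path)
    return written
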