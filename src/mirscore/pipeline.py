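"""End-to-end orchestration: simulate -> compare -> select -> cut-offs ->
score -> stratify -> survival tests, with a deterministic run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from . import __version__
from .cohort import AGE, MARKERS, CohortRecord
from .errors import DegenerateInputError
from .io import write_cohort
from .scoring import (
    HIGH_SCORES,
    ScoreDefinition,
    apply_score_cohort,
    build_score,
    compare_markers,
    default_grouping,
    select_markers,
    stratum_mortality,
)
from .stats import HIGH, LOW, mann_whitney_u, youden_cutpoint
from .survival import km_fit, logrank_test
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger("mirscore")

#: (manifest key, outcome flag, time attribute) for the two endpoints
ENDPOINTS = (
    ("icu", "icu_death", "icu_los"),
    ("overall", "overall_event", "followup_time"),
)


@dataclass
class RunManifest:
    """Everything a run produced; JSON-stable and timestamp-free."""

    version: str
    seed: int | None
    config_hash: str | None
    n_patients: int
    alpha: float
    group_tests: list = field(default_factory=list)
    cutpoints: dict = field(default_factory=dict)
    score_definitions: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)
    strata: dict = field(default_factory=dict)
    logrank: dict = field(default_factory=dict)
    km: dict = field(default_factory=dict)
    sepsis_contingency: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_patients": self.n_patients,
            "alpha": self.alpha,
            "group_tests": self.group_tests,
            "cutpoints": self.cutpoints,
            "score_definitions": self.score_definitions,
            "scores": self.scores,
            "strata": self.strata,
            "logrank": self.logrank,
            "km": self.km,
            "sepsis_contingency": self.sepsis_contingency,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def config_hash(config: SimulationConfig) -> str:
    return hashlib.sha256(config.to_json().encode("utf-8")).hexdigest()


def _test_row(contrast: str, marker: str, test) -> dict:
    return {
        "contrast": contrast,
        "marker": marker,
        "n1": test.n1,
        "n2": test.n2,
        "u": test.statistic_u,
        "p": test.p_value,
        "median1": test.median1,
        "median2": test.median2,
        "direction": test.direction,
    }


def sepsis_contingency(
    cohort: Sequence[CohortRecord], scores: Sequence[int], grouping
) -> dict:
    """Stratified score-by-sepsis contingency report with a chi-square test.

    Strata with zero patients are dropped before testing; degenerate tables
    (fewer than two non-empty rows or columns) report chi2 = 0, p = 1.
    """
    table = stratum_mortality(scores, [r.sepsis for r in cohort], grouping)
    counts = []
    labels = []
    for lab, n, d in zip(table.labels, table.n, table.deaths):
        if n > 0:
            counts.append([d, n - d])  # [sepsis, non-sepsis]
            labels.append(lab)
    arr = np.array(counts, dtype=float)
    report = {
        "strata": labels,
        "sepsis": [int(c[0]) for c in counts],
        "non_sepsis": [int(c[1]) for c in counts],
    }
    if arr.shape[0] < 2 or np.any(arr.sum(axis=0) == 0):
        report.update({"chi_square": 0.0, "df": 0, "p_value": 1.0})
        return report
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    report.update({"chi_square": float(chi2), "df": int(dof),
                   "p_value": float(p)})
    return report


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    logger.info("stage %s done in %.3fs", name, time.perf_counter() - t0)


def run_pipeline(
    config: SimulationConfig | None,
    cohort: Sequence[CohortRecord] | None = None,
    alpha: float = 0.05,
    grouping=None,
    controls: Sequence[dict] | None = None,
) -> RunManifest:
    """Execute all stages for both endpoints, with and without the age item.

    If ``cohort`` is None it is simulated from ``config``.  ``grouping``
    optionally overrides the default {0} / middle / {max} stratum pooling of
    every score.  A control panel enables the patients-vs-control contrast.
    """
    if cohort is None:
        if config is None:
            raise DegenerateInputError("need a config or a cohort")
        t0 = _stage("simulate")
        cohort = simulate_cohort(config)
        _done("simulate", t0)

    manifest = RunManifest(
        version=__version__,
        seed=config.seed if config is not None else None,
        config_hash=config_hash(config) if config is not None else None,
        n_patients=len(cohort),
        alpha=alpha,
    )

    t0 = _stage("compare")
    for key, outcome, _ in ENDPOINTS:
        try:
            tests = compare_markers(cohort, outcome, alpha)
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"stage compare[{key}]: {exc}; supply a cohort with both "
                f"{outcome} classes"
            ) from exc
        manifest.group_tests.extend(
            _test_row(outcome, m, t) for m, t in tests.items()
        )
    # sepsis vs non-sepsis contrast
    sepsis_flags = np.array([r.sepsis for r in cohort], dtype=bool)
    if sepsis_flags.any() and not sepsis_flags.all():
        for m in MARKERS:
            values = np.array([r.markers[m] for r in cohort])
            test = mann_whitney_u(values[~sepsis_flags], values[sepsis_flags],
                                  alpha=alpha)
            manifest.group_tests.append(
                _test_row("sepsis_vs_nonsepsis", m, test)
            )
    if controls:
        for m in MARKERS:
            ctrl = [row[m] for row in controls]
            pats = [r.markers[m] for r in cohort]
            test = mann_whitney_u(ctrl, pats, alpha=alpha)
            manifest.group_tests.append(
                _test_row("patients_vs_control", m, test)
            )
    _done("compare", t0)

    for key, outcome, time_attr in ENDPOINTS:
        t0 = _stage(f"select[{key}]")
        try:
            selected = select_markers(cohort, outcome, alpha)
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"stage select_markers[{key}]: {exc}"
            ) from exc
        if not selected:
            raise DegenerateInputError(
                f"stage select_markers[{key}]: no marker reached p < {alpha}; "
                "lower alpha or supply a larger cohort"
            )
        logger.info("selected for %s: %s", outcome, selected)
        _done(f"select[{key}]", t0)

        flags = np.array([getattr(r, outcome) for r in cohort], dtype=bool)
        manifest.cutpoints[key] = {}
        for marker, direction in selected:
            values = np.array([r.markers[marker] for r in cohort])
            roc_dir = HIGH if direction == HIGH_SCORES else LOW
            cp = youden_cutpoint(values, flags, roc_dir, marker=marker)
            manifest.cutpoints[key][marker] = cp.to_dict()
        ages = np.array([r.age for r in cohort])
        manifest.cutpoints[key][AGE] = youden_cutpoint(
            ages, flags, HIGH, marker=AGE
        ).to_dict()

        for include_age in (False, True):
            t0 = _stage(f"score[{key}, age={include_age}]")
            definition = build_score(cohort, selected, outcome, include_age)
            scores = apply_score_cohort(definition, cohort)
            strata_sets = (
                grouping
                if grouping is not None
                else default_grouping(definition.max_score)
            )
            table = stratum_mortality(scores, flags, strata_sets)
            skey = definition.name
            manifest.score_definitions[skey] = definition.to_dict()
            manifest.scores[skey] = scores
            manifest.strata[skey] = table.to_rows()

            times = np.array([getattr(r, time_attr) for r in cohort])
            labels = np.array(
                [table.labels[_stratum_index(table, s)] for s in scores]
            )
            if len(set(labels)) >= 2:
                lr = logrank_test(times, flags, labels)
                manifest.logrank[skey] = lr.to_dict()
            else:
                manifest.logrank[skey] = None
            manifest.km[skey] = {}
            for lab in table.labels:
                mask = labels == lab
                if mask.any():
                    curve = km_fit(times[mask], flags[mask])
                    manifest.km[skey][lab] = curve.to_table()
            manifest.sepsis_contingency[skey] = sepsis_contingency(
                cohort, scores, strata_sets
            )
            _done(f"score[{key}, age={include_age}]", t0)

    return manifest


def _stratum_index(table, score: int) -> int:
    for i, g in enumerate(table.grouping):
        if score in g:
            return i
    raise DegenerateInputError(f"score {score} outside grouping")


# ---------------------------------------------------------------------------
# artifact writing
# ---------------------------------------------------------------------------

def write_artifacts(
    manifest: RunManifest,
    out_dir: str | Path,
    cohort: Sequence[CohortRecord] | None = None,
) -> None:
    """Write manifest JSON plus per-table CSVs and a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(manifest.to_json() + "\n",
                                       encoding="utf-8")
    if cohort is not None:
        write_cohort(cohort, out / "cohort.csv")

    with (out / "group_tests.csv").open("w", encoding="utf-8") as fh:
        fh.write("contrast,marker,n1,n2,u,p,median1,median2,direction\n")
        for row in manifest.group_tests:
            fh.write(
                f"{row['contrast']},{row['marker']},{row['n1']},{row['n2']},"
                f"{row['u']!r},{row['p']!r},{row['median1']!r},"
                f"{row['median2']!r},{row['direction']}\n"
            )

    for skey, rows in manifest.strata.items():
        with (out / f"strata_{skey}.csv").open("w", encoding="utf-8") as fh:
            fh.write("stratum,n,deaths,mortality_percent\n")
            for r in rows:
                fh.write(
                    f"{r['stratum']},{r['n']},{r['deaths']},"
                    f"{r['mortality_percent']}\n"
                )

    for skey, curves in manifest.km.items():
        with (out / f"km_{skey}.csv").open("w", encoding="utf-8") as fh:
            fh.write("stratum,time,at_risk,events,survival,greenwood_var\n")
            for lab, rows in curves.items():
                fh.write(f"{lab},0.0,,,1.0,\n")
                for r in rows:
                    fh.write(
                        f"{lab},{r['time']!r},{r['at_risk']},{r['events']},"
                        f"{r['survival']!r},{r['greenwood_var']!r}\n"
                    )

    lines = [f"mirscore {manifest.version}  (n={manifest.n_patients}, "
             f"alpha={manifest.alpha})"]
    for skey, rows in manifest.strata.items():
        lines.append("")
        lines.append(f"[{skey}]")
        for r in rows:
            lines.append(
                f"  score {r['stratum']:>4}: n={r['n']:<4} "
                f"deaths={r['deaths']:<4} mortality={r['mortality_percent']}%"
            )
        lr = manifest.logrank.get(skey)
        if lr:
            lines.append(
                f"  log-rank chi2={lr['chi_square']:.3f} df={lr['df']} "
                f"p={lr['p_value']:.4g}"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
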