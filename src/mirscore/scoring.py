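"""Additive dichotomized risk scores and stratified mortality tables.

A score definition is an ordered list of items (marker or AGE, cut-off,
direction); a patient collects one point per item satisfied with strict
inequality (value > cut-off for ``high_scores``, value < cut-off for
``low_scores``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import AGE, MARKERS, CohortRecord
from .errors import DegenerateInputError, InputError
from .stats import HIGH, LOW, TwoGroupTest, mann_whitney_u, youden_cutpoint

HIGH_SCORES = "high_scores"
LOW_SCORES = "low_scores"

OUTCOMES = ("icu_death", "overall_event")


@dataclass(frozen=True)
class ScoreItem:
    marker: str  # panel marker name, or the literal token AGE
    cutoff: float
    direction: str  # high_scores | low_scores

    def __post_init__(self) -> None:
        if self.direction not in (HIGH_SCORES, LOW_SCORES):
            raise InputError(f"unknown item direction {self.direction!r}")
        if not np.isfinite(self.cutoff):
            raise InputError("item cutoff must be finite")


@dataclass(frozen=True)
class ScoreDefinition:
    name: str
    items: tuple[ScoreItem, ...]

    @property
    def includes_age(self) -> bool:
        return any(item.marker == AGE for item in self.items)

    @property
    def max_score(self) -> int:
        return len(self.items)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "items": [
                {"marker": i.marker, "cutoff": i.cutoff, "direction": i.direction}
                for i in self.items
            ],
            "includes_age": self.includes_age,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreDefinition":
        items = tuple(
            ScoreItem(i["marker"], float(i["cutoff"]), i["direction"])
            for i in d["items"]
        )
        return cls(name=d["name"], items=items)

    @classmethod
    def from_json(cls, text: str) -> "ScoreDefinition":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def filter_significant(
    results: Mapping[str, TwoGroupTest], alpha: float
) -> list[tuple[str, str]]:
    """Keep markers with p < alpha, tagged by the non-survivor median shift.

    ``results`` maps marker -> rank-sum test with group a = survivors and
    group b = non-survivors, so direction "up" means elevated in
    non-survivors (-> high_scores item).
    """
    selected = []
    for marker, test in results.items():
        if test.p_value < alpha and test.direction == "up":
            selected.append((marker, HIGH_SCORES))
        elif test.p_value < alpha and test.direction == "down":
            selected.append((marker, LOW_SCORES))
    return selected


def _outcome_flags(cohort: Sequence[CohortRecord], outcome: str) -> np.ndarray:
    if outcome not in OUTCOMES:
        raise InputError(f"unknown outcome {outcome!r}")
    return np.array([getattr(r, outcome) for r in cohort], dtype=bool)


def compare_markers(
    cohort: Sequence[CohortRecord], outcome: str, alpha: float = 0.05
) -> dict[str, TwoGroupTest]:
    """Per-marker rank-sum comparison of survivors vs non-survivors."""
    flags = _outcome_flags(cohort, outcome)
    if flags.all() or not flags.any():
        raise DegenerateInputError(
            f"cohort has a single {outcome} class; cannot compare groups"
        )
    out = {}
    for m in MARKERS:
        values = np.array([r.markers[m] for r in cohort])
        out[m] = mann_whitney_u(values[~flags], values[flags], alpha=alpha)
    return out


def select_markers(
    cohort: Sequence[CohortRecord], outcome: str, alpha: float = 0.05
) -> list[tuple[str, str]]:
    """Markers significantly dysregulated in non-survivors, with direction."""
    return filter_significant(compare_markers(cohort, outcome, alpha), alpha)


# ---------------------------------------------------------------------------
# score construction and application
# ---------------------------------------------------------------------------

def build_score(
    cohort: Sequence[CohortRecord],
    selected: Sequence[tuple[str, str]],
    outcome: str,
    include_age: bool,
    name: str | None = None,
) -> ScoreDefinition:
    """Derive per-item Youden cut-offs on the given outcome.

    Cut-offs are derived on the same cohort the score is later applied to
    (no train/test split), mirroring the derivation-cohort design; an AGE
    item, when requested, always scores high ages.
    """
    if not selected:
        raise InputError("build_score: empty marker selection")
    flags = _outcome_flags(cohort, outcome)
    items = []
    for marker, direction in selected:
        values = np.array([r.markers[marker] for r in cohort])
        roc_dir = HIGH if direction == HIGH_SCORES else LOW
        cp = youden_cutpoint(values, flags, roc_dir, marker=marker)
        items.append(ScoreItem(marker, cp.cutoff, direction))
    if include_age:
        ages = np.array([r.age for r in cohort])
        cp = youden_cutpoint(ages, flags, HIGH, marker=AGE)
        items.append(ScoreItem(AGE, cp.cutoff, HIGH_SCORES))
    if name is None:
        base = "icu_survival" if outcome == "icu_death" else "overall_survival"
        name = base + ("_age" if include_age else "")
    return ScoreDefinition(name=name, items=tuple(items))


def apply_score(definition: ScoreDefinition, record: CohortRecord) -> int:
    """Integer score: one point per item satisfied with strict inequality."""
    score = 0
    for item in definition.items:
        if item.marker == AGE:
            value = record.age
        else:
            try:
                value = record.markers[item.marker]
            except KeyError:
                raise InputError(
                    f"{record.patient_id}: missing marker {item.marker}"
                ) from None
        if item.direction == HIGH_SCORES:
            score += int(value > item.cutoff)
        else:
            score += int(value < item.cutoff)
    return score


def apply_score_cohort(
    definition: ScoreDefinition, cohort: Sequence[CohortRecord]
) -> list[int]:
    return [apply_score(definition, r) for r in cohort]


# ---------------------------------------------------------------------------
# stratified mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumTable:
    grouping: tuple[frozenset, ...]
    labels: tuple[str, ...]
    n: tuple[int, ...]
    deaths: tuple[int, ...]
    mortality_percent: tuple[float, ...]

    def to_rows(self) -> list[dict]:
        return [
            {
                "stratum": lab,
                "n": n,
                "deaths": d,
                "mortality_percent": m,
            }
            for lab, n, d, m in zip(
                self.labels, self.n, self.deaths, self.mortality_percent
            )
        ]

    def to_text(self) -> str:
        rows = self.to_rows()
        widths = [10, 6, 8, 10]
        header = ["stratum", "n", "deaths", "mortality%"]
        lines = ["".join(h.ljust(w) for h, w in zip(header, widths))]
        for r in rows:
            lines.append(
                "".join(
                    str(v).ljust(w)
                    for v, w in zip(
                        [r["stratum"], r["n"], r["deaths"],
                         r["mortality_percent"]],
                        widths,
                    )
                )
            )
        return "\n".join(lines)


def _stratum_label(values: frozenset) -> str:
    vals = sorted(values)
    if len(vals) == 1:
        return str(vals[0])
    if vals == list(range(vals[0], vals[-1] + 1)):
        return f"{vals[0]}-{vals[-1]}"
    return ",".join(str(v) for v in vals)


def round_half_up_percent(deaths: int, n: int) -> float:
    """100 * deaths / n, rounded half-up to one decimal (exact integer math)."""
    tenths = (1000 * deaths * 2 + n) // (2 * n)
    return tenths / 10.0


def stratum_mortality(
    scores: Sequence[int],
    deaths: Sequence[bool],
    grouping: Iterable[Iterable[int]],
) -> StratumTable:
    """Per-stratum n, death count and mortality percent (one decimal)."""
    s = list(scores)
    d = list(deaths)
    if len(s) != len(d):
        raise InputError("scores and deaths must be aligned")
    strata = tuple(frozenset(g) for g in grouping)
    for i, g1 in enumerate(strata):
        for g2 in strata[i + 1 :]:
            if g1 & g2:
                raise InputError("strata must be disjoint")
    covered = frozenset().union(*strata) if strata else frozenset()
    for value in s:
        if value not in covered:
            raise InputError(f"score {value} not covered by any stratum")
    ns, ds, ms, labels = [], [], [], []
    for g in strata:
        idx = [i for i, v in enumerate(s) if v in g]
        n_g = len(idx)
        d_g = sum(1 for i in idx if d[i])
        ns.append(n_g)
        ds.append(d_g)
        ms.append(round_half_up_percent(d_g, n_g) if n_g else 0.0)
        labels.append(_stratum_label(g))
    return StratumTable(
        grouping=strata,
        labels=tuple(labels),
        n=tuple(ns),
        deaths=tuple(ds),
        mortality_percent=tuple(ms),
    )


def default_grouping(max_score: int) -> list[set[int]]:
    """{0}, {1..max-1}, {max} pooling of an additive score's range."""
    if max_score < 1:
        raise InputError("max_score must be >= 1")
    if max_score == 1:
        return [{0}, {1}]
    return [{0}, set(range(1, max_score)), {max_score}]


# ---------------------------------------------------------------------------
# reference (printed) definitions
# ---------------------------------------------------------------------------

def reference_overall_definition(include_age: bool = True) -> ScoreDefinition:
    """Overall-survival score with the printed cut-offs.

    miR-133a > 4.3 AU and miR-150 < 22.7 AU each score one point; the age
    item scores ages above 68.5 years.
    """
    items = [
        ScoreItem("miR-133a", 4.3, HIGH_SCORES),
        ScoreItem("miR-150", 22.7, LOW_SCORES),
    ]
    if include_age:
        items.append(ScoreItem(AGE, 68.5, HIGH_SCORES))
    return ScoreDefinition(
        name="overall_survival" + ("_age" if include_age else ""),
        items=tuple(items),
    )


def reference_icu_definition(
    marker_cutoffs: Mapping[str, float], include_age: bool = True
) -> ScoreDefinition:
    """ICU-survival score: miR-133a high, miR-143 and miR-223 low.

    The three miRNA cut-offs are only reported graphically in the source
    analysis and must therefore be supplied (e.g. derived by
    :func:`build_score` on a cohort); the age item cut-off is the printed
    72.5 years.
    """
    try:
        items = [
            ScoreItem("miR-133a", float(marker_cutoffs["miR-133a"]), HIGH_SCORES),
            ScoreItem("miR-143", float(marker_cutoffs["miR-143"]), LOW_SCORES),
            ScoreItem("miR-223", float(marker_cutoffs["miR-223"]), LOW_SCORES),
        ]
    except KeyError as exc:
        raise InputError(f"missing ICU cut-off for {exc.args[0]}") from None
    if include_age:
        items.append(ScoreItem(AGE, 72.5, HIGH_SCORES))
    return ScoreDefinition(
        name="icu_survival" + ("_age" if include_age else ""),
        items=tuple(items),
    )
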