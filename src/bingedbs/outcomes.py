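"""Binge-size normalization, responder rules and response-profile counts.

Intake from each limited-access session is expressed as percent change
from the animal's average baseline binge size.  Pooled baseline percent
changes define the meaningful-change threshold (2 pooled SDs, ~26 % when
the session-to-session CV is 13 %).  An animal is a responder to a
stimulation target when every one of its stimulation sessions at that
target shows a reduction strictly beyond the threshold; all-session
increases beyond the threshold are flagged separately and never count as
response.  The optimal target is the responding target with the larger
mean reduction; animals responding to neither target are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: fallback meaningful-change threshold (percent), the 2-SD rule at CV 13 %
DEFAULT_THRESHOLD_PCT = 26.0

SESSION_TYPES = ("baseline", "stimulation", "post")
TARGETS = ("core", "shell")


@dataclass(frozen=True)
class BingeSessionRecord:
    """One limited-access session's intake."""

    animal_id: str
    session_index: int
    session_type: str  # baseline | stimulation | post
    target: str  # core | shell | none
    intake_kcal: float

    def __post_init__(self) -> None:
        if self.session_type not in SESSION_TYPES:
            raise ValueError(f"unknown session type {self.session_type!r}")
        if self.intake_kcal < 0:
            raise ValueError("intake must be non-negative")
        if self.session_type in ("stimulation", "post") and self.target not in TARGETS:
            raise ValueError(
                f"{self.session_type} session must carry a target, got {self.target!r}"
            )


@dataclass(frozen=True)
class NormalFit:
    """Normal fit to pooled baseline percent changes."""

    mean: float
    sd: float
    r2: float
    n: int
    bin_rule: str = "fd"


@dataclass(frozen=True)
class ResponseCall:
    status: str  # responder | non-responder
    paradoxical_increase: bool = False

    @property
    def is_responder(self) -> bool:
        return self.status == "responder"


@dataclass(frozen=True)
class OutcomeLabel:
    animal_id: str
    status: Mapping[str, str]  # target -> responder | non-responder
    mean_change: Mapping[str, float]  # target -> mean % change over stim sessions
    optimal_target: str  # core | shell | excluded


def percent_change_from_baseline(intake: float | np.ndarray, baseline_mean: float):
    """Percent change of a session's intake from the baseline average."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean intake must be positive")
    return 100.0 * (np.asarray(intake, dtype=float) - baseline_mean) / baseline_mean


def fit_baseline_distribution(
    pct_changes: Sequence[float], n_animals: int | None = None
) -> NormalFit:
    """Fit a normal to pooled baseline percent changes.

    Returns the mean/SD and the R^2 between the fitted normal density and
    the Freedman-Diaconis-binned empirical density.  When ``n_animals`` is
    given, the SD uses ``N - n_animals`` degrees of freedom: each
    observation is centered on its own animal's observed baseline average,
    which consumes one degree of freedom per animal and would otherwise
    shrink the pooled SD by sqrt((s-1)/s) for s sessions per animal.
    """
    x = np.asarray(list(pct_changes), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 baseline observations")
    mean = float(np.mean(x))
    if n_animals is not None:
        dof = x.size - n_animals
        if dof < 1:
            raise ValueError("need more observations than animals for the pooled SD")
        sd = float(np.sqrt(np.sum((x - mean) ** 2) / dof))
    else:
        sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("baseline percent changes are constant; SD undefined for the rule")
    density, edges = np.histogram(x, bins="fd", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    predicted = stats.norm.pdf(centers, loc=mean, scale=sd)
    ss_res = float(np.sum((density - predicted) ** 2))
    ss_tot = float(np.sum((density - density.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return NormalFit(mean=mean, sd=sd, r2=r2, n=int(x.size))


def classify_response(
    stim_pct_changes: Sequence[float],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    n_required: int = 3,
) -> ResponseCall:
    """Responder call for one target from its stimulation-session changes.

    Responder iff *every* session's reduction is strictly beyond the
    threshold (change < -threshold).  Sessions with increases beyond
    +threshold in every session are flagged as a paradoxical increase but
    never labelled responder.
    """
    x = np.asarray(list(stim_pct_changes), dtype=float)
    if x.size != n_required:
        raise ValueError(f"expected {n_required} stimulation sessions, got {x.size}")
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    responder = bool(np.all(x < -threshold_pct))
    paradoxical = bool(np.all(x > threshold_pct))
    return ResponseCall(
        status="responder" if responder else "non-responder",
        paradoxical_increase=paradoxical,
    )


def assign_optimal_target(
    mean_changes: Mapping[str, float], statuses: Mapping[str, str]
) -> str:
    """Pick the responding target with the larger mean reduction.

    Returns ``"excluded"`` when no target reached responder status.  Exact
    ties (not expected with continuous intake) break toward the first
    target in canonical order, with a logged warning.
    """
    missing = [t for t in TARGETS if t not in statuses or t not in mean_changes]
    if missing:
        raise ValueError(f"both targets must be evaluated; missing {missing}")
    responding = [t for t in TARGETS if statuses[t] == "responder"]
    if not responding:
        return "excluded"
    best = min(responding, key=lambda t: (mean_changes[t], TARGETS.index(t)))
    ties = [t for t in responding if mean_changes[t] == mean_changes[best] and t != best]
    if ties:
        logger.warning(
            "optimal-target tie between %s; broken toward %s", [best] + ties, best
        )
    return best


def compute_outcomes(
    records: Iterable[BingeSessionRecord],
    threshold_pct: float | None = None,
    n_required: int = 3,
) -> list[OutcomeLabel]:
    """Label every animal's per-target response and optimal target.

    When ``threshold_pct`` is None the threshold is recomputed as 2x the
    SD of the pooled baseline percent changes (each session normalized to
    its own animal's baseline average), falling back to 26 % when fewer
    than two baseline observations exist.
    """
    records = list(records)
    by_animal: dict[str, list[BingeSessionRecord]] = {}
    for rec in records:
        by_animal.setdefault(rec.animal_id, []).append(rec)

    baseline_means: dict[str, float] = {}
    pooled: list[float] = []
    for animal, recs in by_animal.items():
        base = [r.intake_kcal for r in recs if r.session_type == "baseline"]
        if not base:
            raise ValueError(f"animal {animal!r} has no baseline sessions")
        baseline_means[animal] = float(np.mean(base))
        pooled.extend(percent_change_from_baseline(np.array(base), baseline_means[animal]))

    if threshold_pct is None:
        try:
            fit = fit_baseline_distribution(pooled, n_animals=len(by_animal))
            threshold_pct = 2.0 * fit.sd
        except ValueError:
            threshold_pct = DEFAULT_THRESHOLD_PCT
            logger.warning("insufficient baseline data; using fallback threshold 26%%")

    labels: list[OutcomeLabel] = []
    for animal, recs in sorted(by_animal.items()):
        statuses: dict[str, str] = {}
        means: dict[str, float] = {}
        for target in TARGETS:
            stim = sorted(
                (r for r in recs if r.session_type == "stimulation" and r.target == target),
                key=lambda r: r.session_index,
            )
            changes = percent_change_from_baseline(
                np.array([r.intake_kcal for r in stim]), baseline_means[animal]
            )
            call = classify_response(changes, threshold_pct, n_required=n_required)
            statuses[target] = call.status
            means[target] = float(np.mean(changes))
        labels.append(
            OutcomeLabel(
                animal_id=animal,
                status=statuses,
                mean_change=means,
                optimal_target=assign_optimal_target(means, statuses),
            )
        )
    return labels


def summarize_response_profiles(labels: Iterable[OutcomeLabel]) -> dict[str, int]:
    """Mutually exclusive response-profile counts over a cohort.

    Returns counts for core-only, shell-only, both and neither responders,
    plus the single-target total and cohort size.
    """
    counts = {"core_only": 0, "shell_only": 0, "both": 0, "neither": 0}
    n = 0
    for label in labels:
        missing = [t for t in TARGETS if t not in label.status]
        if missing:
            raise ValueError(f"animal {label.animal_id!r} missing target label {missing}")
        core = label.status["core"] == "responder"
        shell = label.status["shell"] == "responder"
        key = {
            (True, False): "core_only",
            (False, True): "shell_only",
            (True, True): "both",
            (False, False): "neither",
        }[(core, shell)]
        counts[key] += 1
        n += 1
    counts["single_target"] = counts["core_only"] + counts["shell_only"]
    counts["n"] = n
    return counts
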