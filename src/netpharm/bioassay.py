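"""Bioassay analysis: MTT inhibition, IC50 fitting, qPCR fold change,
flow-cytometry quadrant statistics and JC-1 depolarization.

These are the quantitative reductions applied to the wet-lab readouts of
a cytotoxicity/apoptosis study on a leukemia cell line:

* MTT viability plates -> per-dose growth-inhibition percentages
  (``100 * (A_control - A_treated) / A_control`` on 490 nm absorbances)
  and a 4-parameter log-logistic dose-response fit with IC50;
* qRT-PCR cycle thresholds -> relative expression fold changes by the
  2^-ddCt method against a reference gene (default GAPDH) and a control
  group;
* Annexin V-FITC / propidium iodide two-channel events -> quadrant
  population fractions (viable, early/late apoptotic, necrotic);
* JC-1 monomer/aggregate events -> fraction of depolarized cells;
* a seeded permutation test for dose-dependent trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import UndefinedRatioError, ValidationError

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")  # A+/PI+, A-/PI+, A-/PI-, A+/PI-


# --------------------------------------------------------------------------
# MTT / dose-response


@dataclass(frozen=True)
class DoseResponseDataset:
    """Plate readings for one timepoint.

    ``readings`` maps dose (ug/mL; 0 = untreated control) to the
    replicate absorbances (optical density at 490 nm).
    """

    readings: Mapping[float, Tuple[float, ...]]
    timepoint: float = 24.0

    def __post_init__(self) -> None:
        readings = {
            float(d): tuple(float(a) for a in reps)
            for d, reps in self.readings.items()
        }
        for d, reps in readings.items():
            if d < 0:
                raise ValidationError(f"negative dose {d}")
            if not reps:
                raise ValidationError(f"dose {d} has no replicates")
        object.__setattr__(self, "readings", readings)

    @property
    def doses(self) -> Tuple[float, ...]:
        return tuple(sorted(self.readings))

    @property
    def positive_doses(self) -> Tuple[float, ...]:
        return tuple(d for d in self.doses if d > 0)

    def control_mean(self) -> float:
        if 0.0 not in self.readings:
            raise ValidationError("no control (dose 0) wells present")
        return float(np.mean(self.readings[0.0]))


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4-parameter log-logistic curve.

    ``y = bottom + (top - bottom) / (1 + (dose/ic50)^(-hill))`` with the
    response in % inhibition. ``bottom <= top`` is normalized (the curve
    is invariant under swapping asymptotes and negating the slope).
    """

    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        return four_parameter_logistic(dose, self.ic50, self.hill, self.top, self.bottom)


def inhibition_rate(a_control: float, a_treated: float) -> float:
    """Growth-inhibition percentage from mean absorbances.

    ``100 * (a_control - a_treated) / a_control``; negative values mean
    growth promotion.
    """
    a_control = float(a_control)
    if a_control <= 0:
        raise UndefinedRatioError("control absorbance must be > 0")
    return 100.0 * (a_control - float(a_treated)) / a_control


def inhibition_profile(
    dataset: DoseResponseDataset, per_replicate: bool = False
) -> Dict[float, object]:
    """Inhibition rate at every positive dose, against the mean control.

    With ``per_replicate`` each dose maps to a tuple of per-well rates
    (for dispersion reporting); otherwise to the rate of the replicate
    mean.
    """
    a0 = dataset.control_mean()
    out: Dict[float, object] = {}
    for dose in dataset.positive_doses:
        reps = dataset.readings[dose]
        if per_replicate:
            out[dose] = tuple(inhibition_rate(a0, a) for a in reps)
        else:
            out[dose] = inhibition_rate(a0, float(np.mean(reps)))
    return out


def four_parameter_logistic(dose, ic50, hill, top, bottom):
    """4PL response; defined for dose > 0."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + (dose / ic50) ** (-hill))


def _fit_4pl_points(doses: np.ndarray, responses: np.ndarray) -> DoseResponseFit:
    span = float(np.ptp(responses))
    if span < 1e-9:
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"),
            top=float(responses[0]), bottom=float(responses[0]),
            rss=0.0, converged=False,
        )

    logd = np.log(doses)

    def model(ld, log_ic50, hill, top, bottom):
        return bottom + (top - bottom) / (1.0 + np.exp(-hill * (ld - log_ic50)))

    lo, hi = float(responses.min()), float(responses.max())
    geomean = float(np.mean(logd))
    starts = [
        (geomean, h, hi, lo)
        for h in (1.0, 2.0, 0.5, -1.0)
    ] + [(float(logd.min()), 1.0, hi, lo), (float(logd.max()), 1.0, hi, lo)]

    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                model, logd, responses, p0=p0, maxfev=20000,
                bounds=(
                    [logd.min() - 10.0, -20.0, lo - 2 * span, lo - 2 * span],
                    [logd.max() + 10.0, 20.0, hi + 2 * span, hi + 2 * span],
                ),
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(logd, *popt) - responses) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"), top=float("nan"),
            bottom=float("nan"), rss=float("nan"), converged=False,
        )
    (log_ic50, hill, top, bottom), rss = best
    if bottom > top:  # same curve with asymptotes swapped and slope negated
        top, bottom, hill = bottom, top, -hill
    ic50 = float(np.exp(log_ic50))
    converged = bool(
        np.isfinite(ic50)
        and ic50 > 0
        and logd.min() - 9.0 < log_ic50 < logd.max() + 9.0
        and abs(hill) > 1e-8
    )
    return DoseResponseFit(
        ic50=ic50, hill=float(hill), top=float(top), bottom=float(bottom),
        rss=rss, converged=converged,
    )


def fit_dose_response(dataset: DoseResponseDataset) -> DoseResponseFit:
    """Least-squares 4PL fit of per-replicate inhibition rates vs dose.

    Responses are computed with :func:`inhibition_rate` against the mean
    control well. The optimizer is multi-started (IC50 seeded at the
    geometric mean dose and at the dose range ends); ``converged`` is
    False for constant responses or when no start converges.
    """
    positive = dataset.positive_doses
    if len(positive) < 2:
        raise ValidationError("need at least 2 distinct positive doses")
    profile = inhibition_profile(dataset, per_replicate=True)
    doses, responses = [], []
    for d in positive:
        for y in profile[d]:
            doses.append(d)
            responses.append(y)
    return _fit_4pl_points(np.asarray(doses), np.asarray(responses))


def fit_dose_response_points(
    doses: Sequence[float], responses: Sequence[float]
) -> DoseResponseFit:
    """4PL fit of already-computed responses at positive doses."""
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValidationError("doses and responses must align")
    if np.any(doses <= 0):
        raise ValidationError("doses must be strictly positive")
    if len(np.unique(doses)) < 2:
        raise ValidationError("need at least 2 distinct positive doses")
    return _fit_4pl_points(doses, responses)


# --------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrAssay:
    """Cycle-threshold table: (gene, group, replicate) -> Ct."""

    ct: Mapping[Tuple[str, str, int], float]
    reference_gene: str = "GAPDH"
    control_group: str = "control"

    def __post_init__(self) -> None:
        ct = {k: float(v) for k, v in self.ct.items()}
        for key, v in ct.items():
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"Ct for {key!r} must be finite and > 0")
        object.__setattr__(self, "ct", ct)

    def mean_ct(self, gene: str, group: str) -> float:
        values = [v for (g, grp, _), v in self.ct.items() if g == gene and grp == group]
        if not values:
            raise ValidationError(f"no Ct values for gene {gene!r} in group {group!r}")
        return float(np.mean(values))

    @property
    def genes(self) -> Tuple[str, ...]:
        return tuple(sorted({g for (g, _, _) in self.ct}))

    @property
    def groups(self) -> Tuple[str, ...]:
        return tuple(sorted({grp for (_, grp, _) in self.ct}))


def fold_change_ddct(assay: QpcrAssay, gene: str, group: str) -> float:
    """Relative expression by the 2^-ddCt method on replicate-mean Cts.

    ddCt = (Ct_gene,group - Ct_ref,group) - (Ct_gene,control - Ct_ref,control).
    """
    d_treated = assay.mean_ct(gene, group) - assay.mean_ct(assay.reference_gene, group)
    d_control = assay.mean_ct(gene, assay.control_group) - assay.mean_ct(
        assay.reference_gene, assay.control_group
    )
    return float(2.0 ** -(d_treated - d_control))


# --------------------------------------------------------------------------
# Flow cytometry


@dataclass(frozen=True)
class FlowEventTable:
    """Per-event two-channel intensities with per-channel gate values.

    Channel 1 is Annexin V-FITC (or the JC-1 monomer signal), channel 2
    is PI (or the JC-1 aggregate signal).
    """

    events: np.ndarray
    thresholds: Tuple[float, float]

    def __post_init__(self) -> None:
        events = np.asarray(self.events, dtype=float)
        if events.ndim != 2 or events.shape[1] != 2:
            raise ValidationError("events must be an (n, 2) array")
        if np.any(events < 0):
            raise ValidationError("intensities must be non-negative")
        t1, t2 = (float(t) for t in self.thresholds)
        if t1 <= 0 or t2 <= 0:
            raise ValidationError("thresholds must be strictly positive")
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "thresholds", (t1, t2))

    @property
    def n_events(self) -> int:
        return int(self.events.shape[0])


@dataclass(frozen=True)
class QuadrantSummary:
    """Gated population fractions.

    Q1 = A+/PI+ (late apoptotic), Q2 = A-/PI+ (necrotic),
    Q3 = A-/PI- (viable), Q4 = A+/PI- (early apoptotic).
    """

    fractions: Mapping[str, float]
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fractions = {q: float(self.fractions[q]) for q in QUADRANTS}
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"fractions sum to {total!r}, expected 1")
        for q, f in fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"{q} fraction {f!r} outside [0, 1]")
        object.__setattr__(self, "fractions", fractions)


def classify_quadrants(table: FlowEventTable) -> QuadrantSummary:
    """Assign each event to a quadrant by its two gate comparisons.

    Positivity is strict (> threshold); an intensity exactly at the gate
    counts as negative.
    """
    if table.n_events == 0:
        raise UndefinedRatioError("no events to classify")
    t1, t2 = table.thresholds
    pos1 = table.events[:, 0] > t1
    pos2 = table.events[:, 1] > t2
    counts = {
        "Q1": int(np.sum(pos1 & pos2)),
        "Q2": int(np.sum(~pos1 & pos2)),
        "Q3": int(np.sum(~pos1 & ~pos2)),
        "Q4": int(np.sum(pos1 & ~pos2)),
    }
    n = table.n_events
    return QuadrantSummary(
        fractions={q: c / n for q, c in counts.items()}, counts=counts
    )


def apoptotic_fraction(summary: QuadrantSummary, mode: str = "total") -> float:
    """Apoptotic proportion: ``early`` = Q4; ``total`` = Q1 + Q4."""
    if mode == "early":
        return summary.fractions["Q4"]
    if mode == "total":
        return summary.fractions["Q1"] + summary.fractions["Q4"]
    raise ValidationError(f"unknown mode {mode!r}")


def jc1_depolarized_fraction(
    table: FlowEventTable, ratio_threshold: float = 1.0
) -> float:
    """Fraction of events with aggregate/monomer ratio below threshold.

    Channel 1 is the monomer signal, channel 2 the aggregate signal; a
    low aggregate:monomer ratio marks a depolarized (monomeric JC-1)
    cell. Events with zero monomer signal are excluded; their count is
    available via :func:`jc1_excluded_events`.
    """
    if ratio_threshold <= 0:
        raise ValidationError("ratio_threshold must be > 0")
    monomer = table.events[:, 0]
    aggregate = table.events[:, 1]
    usable = monomer > 0
    n_usable = int(np.sum(usable))
    if n_usable == 0:
        raise UndefinedRatioError("no events with nonzero monomer signal")
    ratio = aggregate[usable] / monomer[usable]
    return float(np.sum(ratio < ratio_threshold) / n_usable)


def jc1_excluded_events(table: FlowEventTable) -> int:
    """Number of events dropped from the JC-1 ratio for zero monomer."""
    return int(np.sum(table.events[:, 0] <= 0))


# --------------------------------------------------------------------------
# Trend and group-comparison statistics


@dataclass(frozen=True)
class TrendTestResult:
    statistic: float  # Spearman rank correlation of dose vs response
    p_value: float
    n_permutations: int


def dose_trend_test(
    values_by_dose: Mapping[float, Sequence[float]],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> TrendTestResult:
    """Permutation test for a monotone dose-response trend.

    The statistic is the Spearman rank correlation between dose and
    response over all replicate wells. The two-sided p-value compares
    |rho| against ``n_permutations`` random permutations of the
    responses, with the add-one convention
    ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_permutations)``.
    """
    doses_levels = sorted(values_by_dose)
    if len(doses_levels) < 3:
        raise ValidationError("need at least 3 dose levels")
    doses, responses = [], []
    for d in doses_levels:
        reps = list(values_by_dose[d])
        if len(reps) < 2:
            raise ValidationError(f"dose {d} has fewer than 2 replicates")
        doses.extend([float(d)] * len(reps))
        responses.extend(float(v) for v in reps)
    dose_ranks = stats.rankdata(doses)
    resp_ranks = stats.rankdata(responses)

    dr = dose_ranks - dose_ranks.mean()
    rr = resp_ranks - resp_ranks.mean()
    denom = math.sqrt(float(dr @ dr) * float(rr @ rr))
    if denom == 0.0:  # constant responses (or a single tied dose rank)
        return TrendTestResult(0.0, 1.0, n_permutations)
    rho = float(dr @ rr) / denom

    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.tile(rr, (n_permutations, 1)), axis=1
    )
    rho_null = (perms @ dr) / denom
    exceed = int(np.sum(np.abs(rho_null) >= abs(rho) - 1e-12))
    p = (1 + exceed) / (1 + n_permutations)
    return TrendTestResult(rho, float(p), n_permutations)


def compare_groups(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Welch's t-test between two replicate groups (no multiplicity
    correction); presentation-level utility."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)
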