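"""Seeded generators for every input the pipeline consumes.

Each generator plants a known ground truth (pass counts, hub ids, IC50,
fold changes, quadrant probabilities) and returns it alongside the
dataset, so downstream recovery tests never have to re-derive it. All
randomness flows from ``SimulationConfig.seed``; each generator draws
from its own seed substream, so identical configs give bit-identical
output regardless of call order.

Defaults mirror the screening study the pipeline was built around: a
981-compound herb library of which 121 are absorbable, a 118-compound x
141-target interaction network with 46 hub targets, an MTT dose range
of 0.5-128 ug/mL with a true IC50 of 13.61 ug/mL at 24 h, Bcl-2-family
expression shifts (Bad and Bax up, Bcl-2 and Bcl-xL down) and an
apoptosis-skewed quadrant mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .admet import CompoundADMETRecord
from .bioassay import (
    DoseResponseDataset,
    FlowEventTable,
    QpcrAssay,
    four_parameter_logistic,
)
from .errors import ValidationError

HERBS = (
    "Rheum palmatum",
    "Reynoutria japonica",
    "Moutan officinalis",
    "Paeonia anomala",
    "Smilax china",
    "Smilax glabra",
    "Notopterygium incisum",
    "Morus alba",
    "Eucommia ulmoides",
    "Stemona sessilifolia",
    "Ginkgo biloba",
)

# Seed-substream tags, one per generator.
_TAG_LIBRARY = 1
_TAG_NETWORK = 2
_TAG_PLATE = 3
_TAG_QPCR = 4
_TAG_FLOW = 5
_TAG_JC1 = 6


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic generators, with study-scale defaults."""

    seed: int = 0
    # ADMET library
    n_library: int = 981
    pass_fraction: float = 121 / 981
    # compound-target network
    n_compounds: int = 118
    n_targets: int = 141
    hub_count: int = 46
    hub_degree_range: Tuple[int, int] = (10, 30)
    background_degree_range: Tuple[int, int] = (0, 3)
    # disease layer
    n_diseases: int = 139
    n_groups: int = 24
    # MTT plate
    doses: Tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)
    n_replicates: int = 3
    ic50: float = 13.61
    hill: float = 1.5
    top: float = 100.0
    bottom: float = 0.0
    noise_sd: float = 3.0  # percentage points, on the inhibition scale
    control_absorbance: float = 0.8
    timepoint: float = 24.0
    # qPCR
    planted_folds: Mapping[str, float] = field(
        default_factory=lambda: {"Bad": 2.5, "Bax": 1.5, "Bcl-2": 0.7, "Bcl-xL": 0.4}
    )
    ct_noise_sd: float = 0.1
    reference_ct: float = 18.0
    # flow cytometry
    n_events: int = 10_000
    quadrant_probs: Tuple[float, float, float, float] = (0.05, 0.03, 0.80, 0.12)
    flow_thresholds: Tuple[float, float] = (100.0, 100.0)
    depolarized_fraction: float = 0.30
    ratio_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pass_fraction <= 1.0:
            raise ValidationError("pass_fraction must lie in [0, 1]")
        for name in ("n_library", "n_compounds", "n_targets", "n_diseases",
                     "n_groups", "n_events", "n_replicates", "hub_count"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if abs(sum(self.quadrant_probs) - 1.0) > 1e-9:
            raise ValidationError("quadrant_probs must sum to 1")
        if any(p < 0 for p in self.quadrant_probs):
            raise ValidationError("quadrant_probs must be non-negative")
        if not 0.0 <= self.depolarized_fraction <= 1.0:
            raise ValidationError("depolarized_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        for f in self.planted_folds.values():
            if f <= 0:
                raise ValidationError("planted fold changes must be > 0")


@dataclass(frozen=True)
class Simulated:
    """A generated dataset together with its planted ground truth."""

    data: object
    truth: Dict


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def simulate_compound_library(config: SimulationConfig) -> Simulated:
    """ADMET profiles with an exact planted number of screen passers.

    Exactly ``round(pass_fraction * n_library)`` records pass both the
    absorption rule and the composite-score rule: passers get positive
    HIA/Caco-2 and all-positive CYP entries; every other record has at
    least one negative absorption endpoint. Magnitudes are uniform on
    [0.5, 1], mimicking classifier confidence.
    """
    rng = _rng(config, _TAG_LIBRARY)
    n = config.n_library
    k = round(config.pass_fraction * n)
    pass_flags = np.zeros(n, dtype=bool)
    pass_flags[rng.choice(n, size=k, replace=False)] = True

    records = []
    for i in range(n):
        mag = rng.uniform(0.5, 1.0, size=7)
        herb = HERBS[int(rng.integers(len(HERBS)))]
        if pass_flags[i]:
            hia, caco2 = mag[0], mag[1]
            cyp = tuple(mag[2:7])
        else:
            # fail absorption: flip at least one endpoint negative
            which = int(rng.integers(3))  # 0: hia, 1: caco2, 2: both
            hia = -mag[0] if which in (0, 2) else mag[0]
            caco2 = -mag[1] if which in (1, 2) else mag[1]
            signs = rng.choice([-1.0, 1.0], size=5)
            cyp = tuple(signs * mag[2:7])
        records.append(
            CompoundADMETRecord(
                compound_id=f"CMPD{i + 1:04d}", herb=herb,
                hia=float(hia), caco2=float(caco2), cyp=cyp,
            )
        )
    passing_ids = [r.compound_id for r, f in zip(records, pass_flags) if f]
    return Simulated(
        data=tuple(records),
        truth={"n_passing": int(k), "passing_ids": passing_ids},
    )


def simulate_bipartite_edges(config: SimulationConfig) -> Simulated:
    """Compound-target edge set with planted hub targets.

    ``hub_count`` targets get degrees drawn from ``hub_degree_range``
    (>= 10); all others get background degrees in
    ``background_degree_range`` (<= 3), so degree-10 hub extraction
    recovers exactly the planted ids.
    """
    rng = _rng(config, _TAG_NETWORK)
    if config.hub_count > config.n_targets:
        raise ValidationError("hub_count exceeds n_targets")
    hub_lo, hub_hi = config.hub_degree_range
    bg_lo, bg_hi = config.background_degree_range
    hub_hi = min(hub_hi, config.n_compounds)
    if hub_lo > config.n_compounds:
        raise ValidationError(
            f"hub degree {hub_lo} infeasible with {config.n_compounds} compounds"
        )
    compounds = [f"C{i + 1:04d}" for i in range(config.n_compounds)]
    targets = [f"T{i + 1:04d}" for i in range(config.n_targets)]
    hub_idx = rng.choice(config.n_targets, size=config.hub_count, replace=False)
    is_hub = np.zeros(config.n_targets, dtype=bool)
    is_hub[hub_idx] = True

    edges = []
    for j, target in enumerate(targets):
        if is_hub[j]:
            deg = int(rng.integers(hub_lo, hub_hi + 1))
        else:
            deg = int(rng.integers(bg_lo, bg_hi + 1))
        deg = min(deg, config.n_compounds)
        for c in rng.choice(config.n_compounds, size=deg, replace=False):
            edges.append((compounds[int(c)], target))
    return Simulated(
        data=(tuple(compounds), tuple(targets), tuple(edges)),
        truth={"hub_targets": sorted(targets[int(j)] for j in hub_idx)},
    )


def simulate_disease_annotations(config: SimulationConfig) -> Simulated:
    """Target-disease pairs plus a disease-to-group (MeSH-style) mapping.

    Every disease gets one or two C-code groups (two with probability
    0.2, mirroring diseases that sit in both a neoplasm and a systemic
    category); each disease is linked to 1-5 targets.
    """
    rng = _rng(config, _TAG_NETWORK + 100)
    targets = [f"T{i + 1:04d}" for i in range(config.n_targets)]
    diseases = [f"D{i + 1:03d}" for i in range(config.n_diseases)]
    groups = [f"C{i + 1:02d}" for i in range(config.n_groups)]
    pairs = []
    for d in diseases:
        for t in rng.choice(config.n_targets, size=int(rng.integers(1, 6)),
                            replace=False):
            pairs.append((targets[int(t)], d))
    mapping = {}
    for d in diseases:
        n_groups = 2 if (config.n_groups >= 2 and rng.random() < 0.2) else 1
        chosen = rng.choice(config.n_groups, size=n_groups, replace=False)
        mapping[d] = [groups[int(g)] for g in chosen]
    return Simulated(
        data=(tuple(pairs), mapping),
        truth={"n_diseases": len(diseases), "n_groups_available": len(groups)},
    )


def simulate_dose_response(config: SimulationConfig) -> Simulated:
    """MTT plate whose noiseless inhibition profile is exactly the 4PL.

    Treated-well absorbances are ``A0 * (1 - (y + eps)/100)`` with ``y``
    the 4PL response and ``eps ~ N(0, noise_sd)`` per replicate; control
    wells read exactly ``A0``, so at ``noise_sd=0`` the inhibition rate
    reproduces the curve to machine precision.
    """
    rng = _rng(config, _TAG_PLATE)
    positive = [d for d in config.doses if d > 0]
    if len(positive) < 2:
        raise ValidationError("need at least 2 positive doses")
    a0 = config.control_absorbance
    readings: Dict[float, Tuple[float, ...]] = {
        0.0: tuple([a0] * config.n_replicates)
    }
    for d in positive:
        y = float(
            four_parameter_logistic(d, config.ic50, config.hill, config.top, config.bottom)
        )
        eps = rng.normal(0.0, config.noise_sd, size=config.n_replicates) \
            if config.noise_sd > 0 else np.zeros(config.n_replicates)
        readings[d] = tuple(a0 * (1.0 - (y + e) / 100.0) for e in eps)
    dataset = DoseResponseDataset(readings=readings, timepoint=config.timepoint)
    return Simulated(
        data=dataset,
        truth={
            "ic50": config.ic50, "hill": config.hill,
            "top": config.top, "bottom": config.bottom,
        },
    )


def simulate_ct_table(config: SimulationConfig) -> Simulated:
    """Ct table with planted per-gene fold changes (treated vs control).

    The reference gene (GAPDH) is constant across groups up to noise;
    each assayed gene's treated-group Ct is shifted by ``-log2(fold)``
    so the 2^-ddCt method inverts the planted fold exactly at zero
    noise.
    """
    rng = _rng(config, _TAG_QPCR)
    ct: Dict[Tuple[str, str, int], float] = {}
    groups = ("control", "treated")

    def noise() -> float:
        return float(rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd > 0 else 0.0

    for grp in groups:
        for rep in range(1, config.n_replicates + 1):
            ct[("GAPDH", grp, rep)] = config.reference_ct + noise()
    for gene, fold in config.planted_folds.items():
        if fold <= 0:
            raise ValidationError(f"fold change for {gene!r} must be > 0")
        base = float(rng.uniform(22.0, 28.0))
        shift = -math.log2(fold)
        for grp in groups:
            for rep in range(1, config.n_replicates + 1):
                value = base + (shift if grp == "treated" else 0.0) + noise()
                ct[(gene, grp, rep)] = value
    assay = QpcrAssay(ct=ct, reference_gene="GAPDH", control_group="control")
    return Simulated(data=assay, truth={"folds": dict(config.planted_folds)})


def _sided_intensities(
    rng: np.random.Generator, threshold: float, above: np.ndarray
) -> np.ndarray:
    """Log-normal-style intensities strictly on the requested side of a gate."""
    spread = np.abs(rng.normal(0.8, 0.4, size=above.shape[0]))
    return threshold * np.exp(np.where(above, spread, -spread))


def simulate_flow_events(config: SimulationConfig) -> Simulated:
    """Annexin/PI events from a multinomial mixture over the quadrants.

    Quadrant counts are multinomial in ``quadrant_probs`` (order Q1
    A+/PI+, Q2 A-/PI+, Q3 A-/PI-, Q4 A+/PI-); intensities are drawn
    from log-normal components strictly on the correct side of each
    gate, then the events are shuffled.
    """
    rng = _rng(config, _TAG_FLOW)
    counts = rng.multinomial(config.n_events, config.quadrant_probs)
    sides = {  # (channel1 above gate?, channel2 above gate?)
        "Q1": (True, True), "Q2": (False, True),
        "Q3": (False, False), "Q4": (True, False),
    }
    t1, t2 = config.flow_thresholds
    chunks = []
    for quadrant, n_q in zip(("Q1", "Q2", "Q3", "Q4"), counts):
        s1, s2 = sides[quadrant]
        above1 = np.full(n_q, s1)
        above2 = np.full(n_q, s2)
        chunks.append(
            np.column_stack([
                _sided_intensities(rng, t1, above1),
                _sided_intensities(rng, t2, above2),
            ])
        )
    events = np.concatenate(chunks) if chunks else np.empty((0, 2))
    rng.shuffle(events, axis=0)
    table = FlowEventTable(events=events, thresholds=config.flow_thresholds)
    return Simulated(
        data=table,
        truth={
            "quadrant_probs": dict(zip(("Q1", "Q2", "Q3", "Q4"),
                                       config.quadrant_probs)),
            "counts": dict(zip(("Q1", "Q2", "Q3", "Q4"), (int(c) for c in counts))),
        },
    )


def simulate_jc1_events(config: SimulationConfig) -> Simulated:
    """JC-1 monomer/aggregate events with a planted depolarized fraction.

    A binomial share of events is depolarized (aggregate:monomer ratio
    strictly below ``ratio_threshold``); the rest are polarized (ratio
    strictly above). Monomer intensities are log-normal around the
    channel-1 gate scale.
    """
    rng = _rng(config, _TAG_JC1)
    n = config.n_events
    n_depol = int(rng.binomial(n, config.depolarized_fraction))
    monomer = config.flow_thresholds[0] * np.exp(rng.normal(0.0, 0.5, size=n))
    spread = np.abs(rng.normal(0.5, 0.3, size=n)) + 1e-6
    depol = np.arange(n) < n_depol
    ratio = config.ratio_threshold * np.exp(np.where(depol, -spread, spread))
    events = np.column_stack([monomer, ratio * monomer])
    order = rng.permutation(n)
    table = FlowEventTable(events=events[order], thresholds=config.flow_thresholds)
    return Simulated(
        data=table,
        truth={
            "depolarized_fraction": config.depolarized_fraction,
            "n_depolarized": n_depol,
        },
    )
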