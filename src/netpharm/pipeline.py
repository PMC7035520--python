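"""End-to-end pipeline driver: screen -> network -> disease map -> bioassay.

A :class:`PipelineConfig` (loadable from YAML) names the input files,
thresholds and seed; :func:`run_pipeline` executes the enabled stages in
order, writes per-stage tables under the output directory, and returns a
summary report that is a pure function of (inputs, config) — the report
file contains no timestamps, so identical runs are byte-identical. A
plain-text log with ISO-8601 timestamps is written alongside.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from . import __version__, admet, bioassay, networks, synthetic
from . import io as npio
from .errors import NetpharmError, ValidationError

ALL_STAGES = ("screen", "network", "diseasemap", "doseresponse", "qpcr", "flow")

logger = logging.getLogger("netpharm")


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative pipeline configuration.

    ``admet_table=None`` falls back to the bundled 32-compound reference
    table. Stage names are a subset of :data:`ALL_STAGES`; stages whose
    inputs are not configured raise a stage-level error naming the file.
    """

    stages: Tuple[str, ...] = ALL_STAGES
    seed: int = 0
    out_dir: str = "netpharm_results"
    # inputs
    admet_table: Optional[str] = None
    edges: Optional[str] = None
    disease_annotations: Optional[str] = None
    compound_subset: Tuple[str, ...] = ()
    plate: Optional[str] = None
    ct_table: Optional[str] = None
    flow_events: Optional[str] = None
    jc1_events: Optional[str] = None
    # thresholds / parameters
    cyp_weights: Tuple[float, ...] = admet.DEFAULT_CYP_ACCURACIES
    score_floor: float = 0.0
    hub_min_degree: int = 10
    flow_thresholds: Tuple[float, float] = (100.0, 100.0)
    ratio_threshold: float = 1.0
    trend_permutations: int = 10_000
    report_precision: int = 8
    reference_gene: str = "GAPDH"
    control_group: str = "control"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)!r}")
        for key in ("stages", "cyp_weights", "flow_thresholds", "compound_subset"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(path: Optional[str], stage: str, what: str) -> Path:
    if path is None:
        raise NetpharmError(f"stage {stage!r}: no {what} file configured")
    p = Path(path)
    if not p.exists():
        raise NetpharmError(f"stage {stage!r}: missing {what} file: {p}")
    return p


def simulate_inputs(config: PipelineConfig) -> PipelineConfig:
    """Generate every pipeline input from the config seed.

    Writes the dataset files plus a ``truth.json`` manifest under
    ``out_dir/inputs`` and returns a config whose paths point at them.
    """
    out = Path(config.out_dir) / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    sim = synthetic.SimulationConfig(
        seed=config.seed,
        flow_thresholds=config.flow_thresholds,
        ratio_threshold=config.ratio_threshold,
    )
    truth: Dict[str, Dict] = {}

    library = synthetic.simulate_compound_library(sim)
    npio.write_admet_table(library.data, out / "admet.csv")
    truth["library"] = library.truth

    network = synthetic.simulate_bipartite_edges(sim)
    compounds, targets, edges = network.data
    npio.write_edges(compounds, targets, edges, out / "edges.csv")
    truth["network"] = network.truth

    annotations = synthetic.simulate_disease_annotations(sim)
    pairs, mapping = annotations.data
    npio.write_disease_annotations(pairs, mapping, out / "disease_annotations.csv")
    truth["diseases"] = annotations.truth

    plate = synthetic.simulate_dose_response(sim)
    npio.write_plate_table(plate.data, out / "plate.csv")
    truth["dose_response"] = plate.truth

    qpcr = synthetic.simulate_ct_table(sim)
    npio.write_ct_table(qpcr.data, out / "ct.csv")
    truth["qpcr"] = qpcr.truth

    flow = synthetic.simulate_flow_events(sim)
    npio.write_flow_events(flow.data, out / "flow.csv")
    truth["flow"] = flow.truth

    jc1 = synthetic.simulate_jc1_events(sim)
    npio.write_flow_events(jc1.data, out / "jc1.csv")
    truth["jc1"] = jc1.truth

    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return replace(
        config,
        admet_table=str(out / "admet.csv"),
        edges=str(out / "edges.csv"),
        disease_annotations=str(out / "disease_annotations.csv"),
        plate=str(out / "plate.csv"),
        ct_table=str(out / "ct.csv"),
        flow_events=str(out / "flow.csv"),
        jc1_events=str(out / "jc1.csv"),
    )


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the configured stages in order and write the summary.

    Returns the report dict; also writes ``summary.json`` (deterministic)
    and ``pipeline.log`` (timestamped) under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S%z")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    prec = config.report_precision
    report: Dict = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": {},
    }
    hub_targets: Tuple[str, ...] = ()
    try:
        logger.info("pipeline start: stages=%s digest=%s",
                    ",".join(config.stages), config.digest())
        if "screen" in config.stages:
            path = config.admet_table or npio.candidate_table_path()
            records = npio.read_admet_table(_require(str(path), "screen", "ADMET table"))
            result = admet.screen_library(
                records,
                weights=admet.CypWeights(config.cyp_weights),
                score_floor=config.score_floor,
            )
            ranked = admet.rank_compounds(result)
            npio.write_screen_result(
                admet.ScreenResult(ranked, result.discarded, result.rules_applied),
                out / "screen_retained.csv", out / "screen_discarded.csv",
            )
            report["stages"]["screen"] = {
                "n_input": result.n_input,
                "n_retained": len(result.retained),
                "n_discarded": len(result.discarded),
                "top_compound": ranked[0].compound_id if ranked else None,
                "scores": {
                    r.compound_id: round(r.score, prec) for r in ranked
                },
            }
            logger.info("screen: retained %d of %d", len(result.retained), result.n_input)

        if "network" in config.stages:
            compounds, targets, edges = npio.read_edges(
                _require(config.edges, "network", "edge list")
            )
            net = networks.build_bipartite_network(compounds, targets, edges)
            hubs = networks.hub_nodes(net, networks.ROLE_TARGET, config.hub_min_degree)
            hub_targets = tuple(sorted(hubs))
            npio.write_sif(net, out / "network.sif")
            npio.write_graphml(net, out / "network.graphml")
            stage = {
                "n_nodes": net.n_nodes,
                "n_compounds": len(net.compounds),
                "n_targets": len(net.targets),
                "n_edges": len(net.edges),
                "hub_min_degree": config.hub_min_degree,
                "n_hub_targets": len(hubs),
                "hub_targets": list(hub_targets),
                "hub_target_percent": round(
                    networks.role_fraction(net, hubs, networks.ROLE_TARGET), prec
                ) if net.targets else None,
            }
            if config.compound_subset:
                sub = networks.subnetwork_by_compounds(
                    net, config.compound_subset, keep_isolated_targets=True
                )
                npio.write_sif(sub, out / "subnetwork.sif")
                stage["subnetwork_n_nodes"] = sub.n_nodes
            report["stages"]["network"] = stage
            logger.info("network: %d nodes, %d edges, %d hubs",
                        net.n_nodes, len(net.edges), len(hubs))

        if "diseasemap" in config.stages:
            pairs, mapping = npio.read_disease_annotations(
                _require(config.disease_annotations, "diseasemap", "disease annotation")
            )
            td = networks.build_target_disease_network(pairs, mapping)
            npio.write_sif(td, out / "target_disease.sif")
            annotated = {t for t, _ in pairs}
            cml_targets = networks.intersect_targets(
                hub_targets or annotated, annotated
            )
            report["stages"]["diseasemap"] = {
                "n_nodes": td.n_nodes,
                "n_targets": len(td.nodes_with_role(networks.ROLE_TARGET)),
                "n_diseases": len(td.nodes_with_role(networks.ROLE_DISEASE)),
                "n_groups": len(td.nodes_with_role(networks.ROLE_GROUP)),
                "n_hub_targets_with_disease": len(cml_targets),
            }
            logger.info("diseasemap: %d nodes", td.n_nodes)

        if "doseresponse" in config.stages:
            dataset = npio.read_plate_table(
                _require(config.plate, "doseresponse", "plate table")
            )
            fit = bioassay.fit_dose_response(dataset)
            profile = bioassay.inhibition_profile(dataset)
            trend = bioassay.dose_trend_test(
                {d: bioassay.inhibition_profile(dataset, per_replicate=True)[d]
                 for d in dataset.positive_doses},
                n_permutations=config.trend_permutations,
                seed=config.seed,
            )
            report["stages"]["doseresponse"] = {
                "timepoint_h": dataset.timepoint,
                "inhibition_percent": {str(d): round(v, prec) for d, v in profile.items()},
                "ic50": round(fit.ic50, prec) if fit.converged else None,
                "hill": round(fit.hill, prec) if fit.converged else None,
                "converged": fit.converged,
                "trend_statistic": round(trend.statistic, prec),
                "trend_p_value": trend.p_value,
            }
            logger.info("doseresponse: ic50=%s converged=%s", fit.ic50, fit.converged)

        if "qpcr" in config.stages:
            assay = npio.read_ct_table(
                _require(config.ct_table, "qpcr", "Ct table"),
                reference_gene=config.reference_gene,
                control_group=config.control_group,
            )
            folds = {}
            for gene in assay.genes:
                if gene == assay.reference_gene:
                    continue
                for group in assay.groups:
                    if group == assay.control_group:
                        continue
                    folds[f"{gene}:{group}"] = round(
                        bioassay.fold_change_ddct(assay, gene, group), prec
                    )
            report["stages"]["qpcr"] = {"fold_changes": folds}
            logger.info("qpcr: %d fold changes", len(folds))

        if "flow" in config.stages:
            stage: Dict = {}
            if config.flow_events:
                table = npio.read_flow_events(
                    _require(config.flow_events, "flow", "flow event"),
                    thresholds=config.flow_thresholds,
                )
                summary = bioassay.classify_quadrants(table)
                stage["quadrant_fractions"] = {
                    q: round(f, prec) for q, f in summary.fractions.items()
                }
                stage["early_apoptotic"] = round(
                    bioassay.apoptotic_fraction(summary, "early"), prec
                )
                stage["total_apoptotic"] = round(
                    bioassay.apoptotic_fraction(summary, "total"), prec
                )
            if config.jc1_events:
                jc1 = npio.read_flow_events(
                    _require(config.jc1_events, "flow", "JC-1 event"),
                    thresholds=config.flow_thresholds,
                )
                stage["jc1_depolarized"] = round(
                    bioassay.jc1_depolarized_fraction(jc1, config.ratio_threshold), prec
                )
                stage["jc1_excluded_events"] = bioassay.jc1_excluded_events(jc1)
            if not stage:
                raise NetpharmError("stage 'flow': no flow_events or jc1_events configured")
            report["stages"]["flow"] = stage
            logger.info("flow: %s", sorted(stage))

        (out / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        logger.info("pipeline done")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report
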