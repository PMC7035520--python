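"""Readers and writers for the pipeline's tabular and network formats.

All tables are plain CSV/TSV (the delimiter is inferred from the file
extension: ``.tsv`` -> tab, anything else -> comma) with strict header
validation; the Unicode minus U+2212 is normalized to an ASCII hyphen
on read. Networks are written as Cytoscape-compatible SIF (interaction
types ``ct``, ``td``, ``dg``) or as GraphML with role and degree
attributes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .admet import CompoundADMETRecord, ScreenResult
from .bioassay import DoseResponseDataset, FlowEventTable, QpcrAssay
from .errors import FormatError
from .networks import (
    ROLE_COMPOUND,
    ROLE_TARGET,
    BipartiteNetwork,
    TargetDiseaseNetwork,
    build_bipartite_network,
    build_target_disease_network,
    to_networkx,
)

ADMET_COLUMNS = [
    "compound_id", "herb", "smiles", "hia", "caco2",
    "cyp_1a2", "cyp_2c9", "cyp_2d6", "cyp_2c19", "cyp_3a4",
]
_CYP_COLUMNS = ADMET_COLUMNS[5:]

MINUS_SIGN = "−"


def _sep(path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    # float() is correctly rounded, so repr-written values round-trip exactly
    raw = df[column].str.replace(MINUS_SIGN, "-", regex=False).str.strip()
    values = np.empty(len(raw))
    for i, text in enumerate(raw):
        if text == "":
            values[i] = np.nan
            continue
        try:
            values[i] = float(text)
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric value {text!r} in column {column!r} "
                f"at line {i + 2}"  # 1-based, counting the header
            ) from None
    return values


# --------------------------------------------------------------------------
# ADMET tables


def read_admet_table(path) -> Tuple[CompoundADMETRecord, ...]:
    """Read a compound ADMET table (extra columns are ignored)."""
    df = _read_table(path, required=ADMET_COLUMNS)
    numeric = {c: _numeric(df, c, path) for c in ADMET_COLUMNS[3:]}
    records = []
    for i in range(len(df)):
        records.append(
            CompoundADMETRecord(
                compound_id=df["compound_id"].iloc[i],
                herb=df["herb"].iloc[i] or None,
                smiles=df["smiles"].iloc[i] or None,
                hia=numeric["hia"][i],
                caco2=numeric["caco2"][i],
                cyp=tuple(numeric[c][i] for c in _CYP_COLUMNS),
            )
        )
    return tuple(records)


def write_admet_table(records: Sequence[CompoundADMETRecord], path) -> None:
    """Write records in the same dialect, with a score column when present."""
    rows = []
    for r in records:
        row = {
            "compound_id": r.compound_id, "herb": r.herb or "",
            "smiles": r.smiles or "", "hia": r.hia, "caco2": r.caco2,
        }
        row.update(dict(zip(_CYP_COLUMNS, r.cyp)))
        if r.score is not None:
            row["score"] = f"{r.score:.8f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def write_screen_result(result: ScreenResult, retained_path, discard_path) -> None:
    """Write the retained table and a discard log (id, reason)."""
    write_admet_table(result.retained, retained_path)
    pd.DataFrame(
        [(r.compound_id, reason) for r, reason in result.discarded],
        columns=["compound_id", "reason"],
    ).to_csv(discard_path, sep=_sep(discard_path), index=False)


def load_candidate_table() -> Tuple[CompoundADMETRecord, ...]:
    """The bundled 32-compound reference ADMET table."""
    return read_admet_table(candidate_table_path())


def candidate_table_path() -> Path:
    return Path(resources.files("netpharm.data") / "admet_candidates.csv")


# --------------------------------------------------------------------------
# Edge lists and annotations


def read_edges(path) -> Tuple[Tuple[str, ...], Tuple[str, ...], Tuple[Tuple[str, str], ...]]:
    """Read a two-column compound-target edge list.

    The header row names the roles (``compound``, ``target``). Node
    declarations are taken from the columns; compounds or targets that
    should exist without edges can be declared with an empty partner
    cell.
    """
    df = _read_table(path, required=["compound", "target"])
    compounds, targets, edges = [], [], []
    seen_c, seen_t = set(), set()
    for c, t in zip(df["compound"], df["target"]):
        if c and c not in seen_c:
            seen_c.add(c)
            compounds.append(c)
        if t and t not in seen_t:
            seen_t.add(t)
            targets.append(t)
        if c and t:
            edges.append((c, t))
    return tuple(compounds), tuple(targets), tuple(edges)


def write_edges(
    compounds: Sequence[str], targets: Sequence[str],
    edges: Sequence[Tuple[str, str]], path,
) -> None:
    rows = [{"compound": c, "target": t} for c, t in edges]
    linked_c = {c for c, _ in edges}
    linked_t = {t for _, t in edges}
    rows += [{"compound": c, "target": ""} for c in compounds if c not in linked_c]
    rows += [{"compound": "", "target": t} for t in targets if t not in linked_t]
    pd.DataFrame(rows, columns=["compound", "target"]).to_csv(
        path, sep=_sep(path), index=False
    )


def read_disease_annotations(path) -> Tuple[Tuple[Tuple[str, str], ...], Dict[str, List[str]]]:
    """Read target-disease-group rows into pairs + disease->groups map."""
    df = _read_table(path, required=["target", "disease", "group"])
    pairs = []
    mapping: Dict[str, List[str]] = {}
    for t, d, g in zip(df["target"], df["disease"], df["group"]):
        if t and d:
            pair = (t, d)
            if pair not in pairs:
                pairs.append(pair)
        if d and g and g not in mapping.setdefault(d, []):
            mapping[d].append(g)
    return tuple(pairs), mapping


def write_disease_annotations(
    pairs: Sequence[Tuple[str, str]], disease_to_groups: Mapping[str, Sequence[str]],
    path,
) -> None:
    rows = []
    for t, d in pairs:
        for g in disease_to_groups.get(d, [""]):
            rows.append({"target": t, "disease": d, "group": g})
    pd.DataFrame(rows, columns=["target", "disease", "group"]).to_csv(
        path, sep=_sep(path), index=False
    )


# --------------------------------------------------------------------------
# Network serialization


def write_sif(network, path) -> None:
    """Cytoscape SIF: ``source<TAB>interaction<TAB>target`` lines, one
    per edge; isolated nodes are written as single-token lines."""
    lines = []
    if isinstance(network, BipartiteNetwork):
        linked = set()
        for c, t in sorted(network.edges):
            lines.append(f"{c}\tct\t{t}")
            linked.update((c, t))
        for node in sorted(set(network.roles) - linked):
            lines.append(node)
    else:
        linked = set()
        for t, d in sorted(network.td_edges):
            lines.append(f"{t}\ttd\t{d}")
            linked.update((t, d))
        for d, g in sorted(network.dg_edges):
            lines.append(f"{d}\tdg\t{g}")
            linked.update((d, g))
        for node in sorted(set(network.roles) - linked):
            lines.append(node)
    Path(path).write_text("\n".join(lines) + "\n")


def read_sif(path, isolated_role: str = ROLE_TARGET) -> BipartiteNetwork:
    """Read a compound-target SIF written by :func:`write_sif`.

    Roles are inferred from edge direction (source of a ``ct`` edge =
    compound). SIF cannot carry a role for isolated nodes, so they are
    assigned ``isolated_role`` (default target; compounds are never
    isolated in this pipeline's networks).
    """
    compounds, targets, edges = [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            (targets if isolated_role == ROLE_TARGET else compounds).append(parts[0])
        elif len(parts) == 3 and parts[1] == "ct":
            c, _, t = parts
            if c not in compounds:
                compounds.append(c)
            if t not in targets:
                targets.append(t)
            edges.append((c, t))
        else:
            raise FormatError(f"{path}: unrecognized SIF line {line!r}")
    return build_bipartite_network(compounds, targets, edges)


def write_graphml(network, path) -> None:
    """GraphML export with role, degree and annotation node attributes."""
    nx.write_graphml(to_networkx(network), path)


def read_graphml(path):
    """Read a GraphML file written by :func:`write_graphml` back into the
    matching network type (full role/annotation fidelity)."""
    g = nx.read_graphml(path)
    roles = nx.get_node_attributes(g, "role")
    if any(r not in (ROLE_COMPOUND, ROLE_TARGET) for r in roles.values()):
        td = [(u, v) for u, v, a in g.edges(data=True) if a.get("interaction") == "td"]
        dg = [(u, v) for u, v, a in g.edges(data=True) if a.get("interaction") == "dg"]
        td = [(u, v) if roles[u] == ROLE_TARGET else (v, u) for u, v in td]
        dg = [(u, v) if roles[u] == "disease" else (v, u) for u, v in dg]
        pairs = td
        mapping: Dict[str, List[str]] = {}
        for d, grp in dg:
            mapping.setdefault(d, []).append(grp)
        return build_target_disease_network(pairs, mapping, strict=False)
    compounds = [n for n, r in roles.items() if r == ROLE_COMPOUND]
    targets = [n for n, r in roles.items() if r == ROLE_TARGET]
    edges = [
        (u, v) if roles[u] == ROLE_COMPOUND else (v, u) for u, v in g.edges()
    ]
    metadata = {}
    for n, attrs in g.nodes(data=True):
        extra = {k: v for k, v in attrs.items() if k not in ("role", "degree")}
        if extra:
            metadata[n] = extra
    return build_bipartite_network(compounds, targets, edges, metadata=metadata)


# --------------------------------------------------------------------------
# Bioassay tables


def read_plate_table(path) -> DoseResponseDataset:
    """Long-format plate CSV: dose, replicate, absorbance[, timepoint]."""
    df = _read_table(path, required=["dose", "replicate", "absorbance"])
    dose = _numeric(df, "dose", path)
    absorbance = _numeric(df, "absorbance", path)
    timepoint = 24.0
    if "timepoint" in df.columns and len(df):
        timepoint = float(_numeric(df, "timepoint", path)[0])
    readings: Dict[float, List[float]] = {}
    for d, a in zip(dose, absorbance):
        readings.setdefault(float(d), []).append(float(a))
    return DoseResponseDataset(
        readings={d: tuple(v) for d, v in readings.items()}, timepoint=timepoint
    )


def write_plate_table(dataset: DoseResponseDataset, path) -> None:
    rows = []
    for d in dataset.doses:
        for i, a in enumerate(dataset.readings[d], start=1):
            rows.append({
                "dose": d, "replicate": i, "absorbance": repr(a),
                "timepoint": dataset.timepoint,
            })
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_ct_table(
    path, reference_gene: str = "GAPDH", control_group: str = "control"
) -> QpcrAssay:
    """Long-format Ct CSV: gene, group, replicate, ct."""
    df = _read_table(path, required=["gene", "group", "replicate", "ct"])
    ct_values = _numeric(df, "ct", path)
    replicate = _numeric(df, "replicate", path)
    ct = {
        (g, grp, int(r)): float(v)
        for g, grp, r, v in zip(df["gene"], df["group"], replicate, ct_values)
    }
    return QpcrAssay(ct=ct, reference_gene=reference_gene, control_group=control_group)


def write_ct_table(assay: QpcrAssay, path) -> None:
    rows = [
        {"gene": g, "group": grp, "replicate": rep, "ct": repr(v)}
        for (g, grp, rep), v in sorted(assay.ct.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_flow_events(path, thresholds: Tuple[float, float]) -> FlowEventTable:
    """Two-column per-event CSV: channel1, channel2."""
    df = _read_table(path, required=["channel1", "channel2"])
    events = np.column_stack([
        _numeric(df, "channel1", path), _numeric(df, "channel2", path)
    ]) if len(df) else np.empty((0, 2))
    return FlowEventTable(events=events, thresholds=thresholds)


def write_flow_events(table: FlowEventTable, path) -> None:
    pd.DataFrame({
        "channel1": [repr(float(v)) for v in table.events[:, 0]],
        "channel2": [repr(float(v)) for v in table.events[:, 1]],
    }).to_csv(path, sep=_sep(path), index=False)
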