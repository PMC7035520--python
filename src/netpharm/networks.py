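"""Compound-target and target-disease network construction and analysis.

Two network shapes are used. The compound-target (cC-cT) network is a
simple bipartite graph whose node degree — the number of incident edges
— measures how promiscuously a compound acts or how widely a target is
hit; targets with degree >= 10 are treated as hubs. The target-disease
(T-D) network is a three-role graph linking candidate targets to the
diseases they are annotated with, and diseases to MeSH-style disease
group codes (e.g. C04 neoplasms); a disease may belong to several
groups.

Only degree-based analysis is provided; no layout and no centralities
beyond degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Sequence, Set, Tuple

import networkx as nx

from .errors import UndefinedRatioError, ValidationError

ROLE_COMPOUND = "compound"
ROLE_TARGET = "target"
ROLE_DISEASE = "disease"
ROLE_GROUP = "disease_group"


@dataclass(frozen=True)
class BipartiteNetwork:
    """Simple bipartite compound-target graph.

    ``roles`` maps every node id to ``"compound"`` or ``"target"``;
    ``edges`` are (compound_id, target_id) pairs with duplicates
    collapsed; ``metadata`` carries free-form per-node annotations such
    as a chemical family; ``duplicates_collapsed`` counts input edges
    dropped as repeats.
    """

    roles: Mapping[str, str]
    edges: FrozenSet[Tuple[str, str]]
    metadata: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    duplicates_collapsed: int = 0

    @property
    def compounds(self) -> Tuple[str, ...]:
        return tuple(sorted(n for n, r in self.roles.items() if r == ROLE_COMPOUND))

    @property
    def targets(self) -> Tuple[str, ...]:
        return tuple(sorted(n for n, r in self.roles.items() if r == ROLE_TARGET))

    @property
    def n_nodes(self) -> int:
        return len(self.roles)


@dataclass(frozen=True)
class TargetDiseaseNetwork:
    """Three-role target-disease-group graph.

    ``td_edges`` link targets to diseases; ``dg_edges`` link diseases to
    group codes. No other edge kind exists.
    """

    roles: Mapping[str, str]
    td_edges: FrozenSet[Tuple[str, str]]
    dg_edges: FrozenSet[Tuple[str, str]]

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    def nodes_with_role(self, role: str) -> Tuple[str, ...]:
        return tuple(sorted(n for n, r in self.roles.items() if r == role))


def build_bipartite_network(
    compounds: Sequence[str],
    targets: Sequence[str],
    edges: Iterable[Tuple[str, str]],
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> BipartiteNetwork:
    """Assemble and validate a compound-target network.

    Node ids must be unique within a role and no id may carry both
    roles; every edge endpoint must be declared. Duplicate edges are
    collapsed, with the number of repeats recorded on the result.
    """
    compounds = list(compounds)
    targets = list(targets)
    if len(set(compounds)) != len(compounds):
        raise ValidationError("duplicate compound ids")
    if len(set(targets)) != len(targets):
        raise ValidationError("duplicate target ids")
    overlap = set(compounds) & set(targets)
    if overlap:
        raise ValidationError(f"ids appear in both roles: {sorted(overlap)!r}")
    roles: Dict[str, str] = {c: ROLE_COMPOUND for c in compounds}
    roles.update({t: ROLE_TARGET for t in targets})

    cset, tset = set(compounds), set(targets)
    seen: Set[Tuple[str, str]] = set()
    duplicates = 0
    for a, b in edges:
        if a in cset and b in tset:
            edge = (a, b)
        elif b in cset and a in tset:
            edge = (b, a)
        else:
            raise ValidationError(f"edge ({a!r}, {b!r}) has an undeclared endpoint")
        if edge in seen:
            duplicates += 1
        else:
            seen.add(edge)
    return BipartiteNetwork(
        roles=roles,
        edges=frozenset(seen),
        metadata=dict(metadata or {}),
        duplicates_collapsed=duplicates,
    )


def degree_map(network: BipartiteNetwork) -> Dict[str, int]:
    """Degree of every node, including isolated ones (degree 0)."""
    degrees = {node: 0 for node in network.roles}
    for c, t in network.edges:
        degrees[c] += 1
        degrees[t] += 1
    return degrees


def hub_nodes(network: BipartiteNetwork, role: str, min_degree: int) -> Set[str]:
    """Ids of the given role with degree >= min_degree (inclusive)."""
    if role not in (ROLE_COMPOUND, ROLE_TARGET):
        raise ValidationError(f"unknown role {role!r}")
    if min_degree < 0:
        raise ValidationError("min_degree must be >= 0")
    degrees = degree_map(network)
    return {
        n
        for n, r in network.roles.items()
        if r == role and degrees[n] >= min_degree
    }


def role_fraction(network: BipartiteNetwork, subset: Set[str], role: str) -> float:
    """Percentage of a role's nodes falling in ``subset`` (full precision)."""
    if role not in (ROLE_COMPOUND, ROLE_TARGET):
        raise ValidationError(f"unknown role {role!r}")
    population = [n for n, r in network.roles.items() if r == role]
    if not population:
        raise UndefinedRatioError(f"no nodes with role {role!r}")
    stray = set(subset) - set(population)
    if stray:
        raise ValidationError(f"subset ids outside role {role!r}: {sorted(stray)!r}")
    return 100.0 * len(subset) / len(population)


def intersect_targets(
    candidate_targets: Iterable[str], disease_targets: Iterable[str]
) -> Tuple[str, ...]:
    """Sorted intersection of a candidate-target and a disease-target set."""
    return tuple(sorted(set(candidate_targets) & set(disease_targets)))


def build_target_disease_network(
    target_disease_pairs: Iterable[Tuple[str, str]],
    disease_to_groups: Mapping[str, Iterable[str]],
    strict: bool = True,
) -> TargetDiseaseNetwork:
    """Assemble the three-role target-disease-group network.

    Every disease appearing in the pairs must have at least one group
    code in ``disease_to_groups``; with ``strict=False`` unannotated
    diseases are placed in an ``"unclassified"`` group instead of
    raising.
    """
    td = set()
    targets: Set[str] = set()
    diseases: Set[str] = set()
    for target, disease in target_disease_pairs:
        td.add((target, disease))
        targets.add(target)
        diseases.add(disease)
    dg = set()
    groups: Set[str] = set()
    for disease in sorted(diseases):
        disease_groups = list(disease_to_groups.get(disease, ()))
        if not disease_groups:
            if strict:
                raise ValidationError(f"disease {disease!r} has no group code")
            disease_groups = ["unclassified"]
        for g in disease_groups:
            dg.add((disease, g))
            groups.add(g)
    clashes = (targets & diseases) | (targets & groups) | (diseases & groups)
    if clashes:
        raise ValidationError(f"ids appear in multiple roles: {sorted(clashes)!r}")
    roles: Dict[str, str] = {t: ROLE_TARGET for t in targets}
    roles.update({d: ROLE_DISEASE for d in diseases})
    roles.update({g: ROLE_GROUP for g in groups})
    return TargetDiseaseNetwork(
        roles=roles, td_edges=frozenset(td), dg_edges=frozenset(dg)
    )


def subnetwork_by_compounds(
    network: BipartiteNetwork,
    compound_subset: Iterable[str],
    keep_isolated_targets: bool = True,
) -> BipartiteNetwork:
    """Restrict the network to a compound subset (e.g. one chemical family).

    With ``keep_isolated_targets`` (the default) every target node is
    retained even if it loses all its edges, so the node count is
    ``|subset| + |targets|``; otherwise targets left without edges are
    dropped.
    """
    subset = set(compound_subset)
    compounds = set(network.compounds)
    unknown = subset - compounds
    if unknown:
        raise ValidationError(f"unknown compound ids: {sorted(unknown)!r}")
    edges = {(c, t) for c, t in network.edges if c in subset}
    if keep_isolated_targets:
        targets = set(network.targets)
    else:
        targets = {t for _, t in edges}
    roles = {c: ROLE_COMPOUND for c in subset}
    roles.update({t: ROLE_TARGET for t in targets})
    metadata = {n: m for n, m in network.metadata.items() if n in roles}
    return BipartiteNetwork(
        roles=roles, edges=frozenset(edges), metadata=metadata
    )


def to_networkx(network: BipartiteNetwork | TargetDiseaseNetwork) -> nx.Graph:
    """Convert to a networkx graph with role/degree node attributes."""
    g = nx.Graph()
    for node, role in network.roles.items():
        g.add_node(node, role=role)
    if isinstance(network, BipartiteNetwork):
        for node, meta in network.metadata.items():
            g.nodes[node].update(meta)
        for c, t in network.edges:
            g.add_edge(c, t, interaction="ct")
    else:
        for t, d in network.td_edges:
            g.add_edge(t, d, interaction="td")
        for d, grp in network.dg_edges:
            g.add_edge(d, grp, interaction="dg")
    degrees = dict(g.degree())
    nx.set_node_attributes(g, degrees, "degree")
    return g
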