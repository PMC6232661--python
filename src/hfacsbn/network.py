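"""HFACS variable catalog, layered network structure, and CPT container.

The model follows the Human Factors Analysis and Classification System
(HFACS): four causal levels, organizational influences (level 4) acting on
unsafe supervision (level 3), acting on preconditions for unsafe acts
(level 2), acting on the outcome (level 1) — here the occurrence of a
needlestick or sharps injury (NSI) in the previous three months. Two
structural assumptions define the graph: variables within a level are
independent (no within-level edges), and every variable in a level is a
direct parent of every variable in the level immediately below.

Parent configurations are enumerated in a canonical mixed-radix order over
the ordered parent list with the LAST parent varying fastest; all CPT rows,
serialized tables and learning counts use this order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence
from xml.etree import ElementTree as ET

import networkx as nx
import numpy as np

__all__ = [
    "VariableSpec",
    "NetworkStructure",
    "CPTSet",
    "BayesianNetworkModel",
    "LEVEL_NAMES",
    "build_variable_catalog",
    "build_hfacs_structure",
    "build_layered_structure",
    "joint_probability",
    "validate_model",
    "uniform_cpts",
    "random_cpts",
    "model_to_json",
    "model_from_json",
    "model_to_xmlbif",
]

#: Human-readable HFACS level names, indexed by level number.
LEVEL_NAMES = {
    4: "organizational influences",
    3: "unsafe supervision",
    2: "preconditions for unsafe acts",
    1: "outcome",
}

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class VariableSpec:
    """One node of the HFACS network.

    Parameters
    ----------
    name
        Identifier used in datasets, CSV columns and serialized models.
    hfacs_level
        4 = organizational influences, 3 = unsafe supervision,
        2 = preconditions for unsafe acts, 1 = outcome.
    states
        Ordered state labels (order is part of the model contract).
    measurement
        ``("multi_item_scale", k)`` for a k-item Likert scale averaged to a
        1-5 score, ``("direct_numeric", None)`` or ``("direct_binary", None)``
        for single direct questions.
    discretization_rule
        Name of the rule in :mod:`hfacsbn.questionnaire` that maps raw
        answers onto ``states``.
    """

    name: str
    hfacs_level: int
    states: tuple[str, ...]
    measurement: tuple[str, int | None]
    discretization_rule: str

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(
                f"{label!r} is not a state of {self.name!r}; "
                f"legal states: {self.states}"
            ) from None


def _scale(name, level, states, k, rule="scale_score_terciles"):
    return VariableSpec(name, level, tuple(states), ("multi_item_scale", k), rule)


def build_variable_catalog() -> list[VariableSpec]:
    """Return the 12 study variables in canonical (table) order.

    Level 4 holds the organizational variables (management commitment to
    safety, staffing, availability of safe work procedures), level 3 the
    supervision/scheduling variables (night shifts per month, working hours
    per week, supervisors' attitude toward safety, safety training), level 2
    the preconditions (fatigue, teamwork, physical environment, safety
    motivation) and level 1 the single binary NSI outcome. All scale-based
    variables have three ordered states; the two yes/no questions
    (availability of procedures, NSI) have two.
    """
    pmg = ("poor", "moderate", "good")
    return [
        _scale("management_commitment", 4, pmg, 5),
        _scale("staffing", 4, pmg, 4),
        VariableSpec(
            "safe_procedures", 4, ("yes", "no"), ("direct_binary", None), "binary_passthrough"
        ),
        VariableSpec(
            "night_shifts", 3, ("normal", "high", "very_high"),
            ("direct_numeric", None), "night_shift_intervals",
        ),
        VariableSpec(
            "working_hours", 3, ("normal", "high", "very_high"),
            ("direct_numeric", None), "working_hour_intervals",
        ),
        _scale("supervisor_attitude", 3, pmg, 4),
        _scale("safety_training", 3, pmg, 4),
        _scale("fatigue", 2, ("low", "moderate", "high"), 4),
        _scale("teamwork", 2, pmg, 4),
        _scale("physical_environment", 2, pmg, 4),
        _scale("safety_motivation", 2, pmg, 4),
        VariableSpec("nsi", 1, ("yes", "no"), ("direct_binary", None), "binary_passthrough"),
    ]


@dataclass(frozen=True)
class NetworkStructure:
    """A layered DAG over a variable catalog.

    ``parents`` maps each node name to its ordered parent tuple (catalog
    order within the parent level). The structure is validated on creation:
    acyclicity, legal node names, and — for HFACS-layered structures built
    by :func:`build_hfacs_structure` — the two layering assumptions.
    """

    variables: tuple[VariableSpec, ...]
    parents: Mapping[str, tuple[str, ...]]
    _by_name: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_by_name", {v.name: v for v in self.variables})
        if len(self._by_name) != len(self.variables):
            raise ValueError("duplicate variable names")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structure contains a cycle")

    def __getitem__(self, name: str) -> VariableSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for child, pars in self.parents.items():
            for p in pars:
                if p not in self._by_name or child not in self._by_name:
                    raise ValueError(f"edge {p}->{child} references unknown variable")
                g.add_edge(p, child)
        return g

    @property
    def n_edges(self) -> int:
        return sum(len(p) for p in self.parents.values())

    def cpt_shape(self, name: str) -> tuple[int, int]:
        """(number of parent configurations, number of child states)."""
        child = self[name]
        n_cfg = math.prod(self[p].n_states for p in self.parents[name])
        return n_cfg, child.n_states

    def cpt_size(self, name: str) -> int:
        n_cfg, n_states = self.cpt_shape(name)
        return n_cfg * n_states

    def parent_config_index(self, name: str, parent_states: Sequence[int]) -> int:
        """Mixed-radix index of a parent state assignment, last parent fastest."""
        idx = 0
        for p, s in zip(self.parents[name], parent_states, strict=True):
            idx = idx * self[p].n_states + s
        return idx

    def parent_config_states(self, name: str, index: int) -> tuple[int, ...]:
        """Inverse of :meth:`parent_config_index`."""
        radices = [self[p].n_states for p in self.parents[name]]
        out = []
        for r in reversed(radices):
            out.append(index % r)
            index //= r
        if index:
            raise IndexError("parent configuration index out of range")
        return tuple(reversed(out))


def build_hfacs_structure(catalog: Sequence[VariableSpec]) -> NetworkStructure:
    """Build the layered-complete HFACS network over ``catalog``.

    Every level-(L+1) variable is a parent of every level-L variable and
    levels share no internal edges, so the 12-variable catalog yields
    3x4 + 4x4 + 4x1 = 32 edges and a largest CPT of 3^4 x 3 = 243 entries.
    """
    levels: dict[int, list[str]] = {}
    for v in catalog:
        levels.setdefault(v.hfacs_level, []).append(v.name)
    missing = {4, 3, 2, 1} - set(levels)
    if missing:
        raise ValueError(f"catalog is missing HFACS levels: {sorted(missing)}")
    parents = {
        v.name: tuple(levels.get(v.hfacs_level + 1, ()))
        for v in catalog
    }
    return NetworkStructure(tuple(catalog), parents)


def build_layered_structure(
    catalog: Sequence[VariableSpec], parents: Mapping[str, Sequence[str]]
) -> NetworkStructure:
    """Generic constructor for user-defined topologies (untested against the
    study's layered-complete pattern; provided for experimentation)."""
    return NetworkStructure(tuple(catalog), {k: tuple(v) for k, v in parents.items()})


class CPTSet(dict):
    """Mapping node name -> conditional probability table.

    Each table is a float array of shape ``(n_parent_configs, n_states)``;
    row ``i`` is P(child | parents in configuration ``i``) with
    configurations in canonical mixed-radix order (last parent fastest).
    """

    def __init__(self, structure: NetworkStructure, tables: Mapping[str, np.ndarray]):
        super().__init__()
        self.structure = structure
        for name in structure.names:
            tab = np.asarray(tables[name], dtype=float)
            expected = structure.cpt_shape(name)
            if tab.shape != expected:
                raise ValueError(
                    f"CPT for {name!r} has shape {tab.shape}, expected {expected}"
                )
            self[name] = tab

    def copy(self) -> "CPTSet":
        return CPTSet(self.structure, {k: v.copy() for k, v in self.items()})

    @property
    def n_parameters(self) -> int:
        return sum(t.size for t in self.values())


@dataclass(frozen=True)
class BayesianNetworkModel:
    """A fully specified discrete Bayesian network: structure + CPTs."""

    structure: NetworkStructure
    cpts: CPTSet

    def __post_init__(self):
        report = validate_model(self.structure, self.cpts)
        if report:
            raise ValueError("invalid CPTs:\n" + "\n".join(report))


def uniform_cpts(structure: NetworkStructure) -> CPTSet:
    tables = {}
    for name in structure.names:
        n_cfg, n_states = structure.cpt_shape(name)
        tables[name] = np.full((n_cfg, n_states), 1.0 / n_states)
    return CPTSet(structure, tables)


def random_cpts(structure: NetworkStructure, rng: np.random.Generator,
                concentration: float = 1.0) -> CPTSet:
    """Row-wise Dirichlet(concentration) CPTs, for fixtures and oracles."""
    tables = {}
    for name in structure.names:
        n_cfg, n_states = structure.cpt_shape(name)
        tables[name] = rng.dirichlet(np.full(n_states, concentration), size=n_cfg)
    return CPTSet(structure, tables)


def joint_probability(
    structure: NetworkStructure,
    cpts: CPTSet,
    assignment: Mapping[str, str],
) -> float:
    """Chain-rule probability of one full state assignment.

    P(x_1..x_12) = prod over nodes of P(x_i | parents(x_i)); a deliberately
    simple lookup-and-multiply used as a ground-truth primitive by the
    inference oracles.
    """
    missing = set(structure.names) - set(assignment)
    if missing:
        raise KeyError(f"assignment is missing variables: {sorted(missing)}")
    p = 1.0
    for v in structure.variables:
        parent_states = [structure[q].state_index(assignment[q]) for q in structure.parents[v.name]]
        cfg = structure.parent_config_index(v.name, parent_states)
        p *= cpts[v.name][cfg, v.state_index(assignment[v.name])]
    return p


def validate_model(structure: NetworkStructure, cpts: Mapping[str, np.ndarray]) -> list[str]:
    """Report-only CPT validity check.

    Returns one message per violation (size mismatch, entry outside [0, 1],
    row not summing to 1 within 1e-9); an empty list means the CPT set
    satisfies every invariant.
    """
    problems: list[str] = []
    for name in structure.names:
        if name not in cpts:
            problems.append(f"{name}: missing CPT")
            continue
        tab = np.asarray(cpts[name], dtype=float)
        expected = structure.cpt_shape(name)
        if tab.shape != expected:
            problems.append(f"{name}: shape {tab.shape} != expected {expected}")
            continue
        bad = np.argwhere((tab < 0) | (tab > 1))
        for cfg, state in bad:
            problems.append(
                f"{name}: entry out of [0,1] at parent config "
                f"{structure.parent_config_states(name, int(cfg))}, "
                f"state {structure[name].states[int(state)]} ({tab[cfg, state]:g})"
            )
        sums = tab.sum(axis=1)
        for cfg in np.nonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]:
            problems.append(
                f"{name}: row for parent config "
                f"{structure.parent_config_states(name, int(cfg))} sums to {sums[cfg]:.6g}"
            )
    return problems


# ---------------------------------------------------------------------------
# Serialization


def model_to_json(model: BayesianNetworkModel, *, indent: int | None = 2) -> str:
    """Serialize a model to the package's documented JSON schema.

    Schema: ``{"variables": [{name, hfacs_level, states, measurement,
    discretization_rule}], "parents": {node: [...]}, "cpts": {node: [[row
    in canonical parent-config order] ...]}}``.
    """
    st = model.structure
    doc = {
        "format": "hfacsbn-model",
        "version": 1,
        "variables": [
            {
                "name": v.name,
                "hfacs_level": v.hfacs_level,
                "states": list(v.states),
                "measurement": list(v.measurement),
                "discretization_rule": v.discretization_rule,
            }
            for v in st.variables
        ],
        "parents": {name: list(st.parents[name]) for name in st.names},
        "cpts": {name: model.cpts[name].tolist() for name in st.names},
    }
    return json.dumps(doc, indent=indent)


def model_from_json(text: str) -> BayesianNetworkModel:
    doc = json.loads(text)
    if doc.get("format") != "hfacsbn-model":
        raise ValueError("not an hfacsbn model document")
    catalog = [
        VariableSpec(
            d["name"], d["hfacs_level"], tuple(d["states"]),
            (d["measurement"][0], d["measurement"][1]), d["discretization_rule"],
        )
        for d in doc["variables"]
    ]
    structure = NetworkStructure(
        tuple(catalog), {k: tuple(v) for k, v in doc["parents"].items()}
    )
    cpts = CPTSet(structure, {k: np.asarray(v) for k, v in doc["cpts"].items()})
    return BayesianNetworkModel(structure, cpts)


def model_to_xmlbif(model: BayesianNetworkModel, network_name: str = "hfacs_nsi") -> str:
    """Export to XMLBIF 0.3 for interchange with standard BN tools.

    XMLBIF lists a DEFINITION per node whose TABLE is row-major over parent
    configurations with the last parent fastest — the same canonical order
    used internally, so tables are emitted verbatim.
    """
    st = model.structure
    root = ET.Element("BIF", VERSION="0.3")
    net = ET.SubElement(root, "NETWORK")
    ET.SubElement(net, "NAME").text = network_name
    for v in st.variables:
        var = ET.SubElement(net, "VARIABLE", TYPE="nature")
        ET.SubElement(var, "NAME").text = v.name
        for s in v.states:
            ET.SubElement(var, "OUTCOME").text = s
    for v in st.variables:
        d = ET.SubElement(net, "DEFINITION")
        ET.SubElement(d, "FOR").text = v.name
        for p in st.parents[v.name]:
            ET.SubElement(d, "GIVEN").text = p
        ET.SubElement(d, "TABLE").text = " ".join(
            f"{x:.12g}" for x in model.cpts[v.name].ravel()
        )
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
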