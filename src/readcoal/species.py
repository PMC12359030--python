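"""Species networks: a rooted species tree with divergence times, population
sizes, and optional gene flow (discrete introgression events or continuous
migration bands).

Units follow the multispecies-coalescent convention used throughout the
package: divergence times tau and population-size parameters theta (= 4*N*mu)
are both measured in expected substitutions per site, so the pairwise
coalescent rate inside a population is 2/theta per unit time.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "IntrogressionEvent",
    "MigrationBand",
    "SpeciesNetwork",
    "validate_network",
    "build_preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class IntrogressionEvent:
    """A discrete introgression (hybridization) event.

    Forward in time, a proportion ``phi`` of the recipient population's genes
    at time ``time`` originate from the donor population.  Backwards in time a
    lineage found in the recipient at ``time`` jumps to the donor branch with
    probability ``phi``.
    """

    donor: str
    recipient: str
    time: float
    phi: float


@dataclass(frozen=True)
class MigrationBand:
    """Continuous migration from ``source`` into ``dest`` (forward in time).

    ``rate`` is the population migration rate M = N_dest * m, the expected
    number of source->dest migrants per generation.  The band is active only
    while both populations exist.
    """

    source: str
    dest: str
    rate: float


class _Node:
    __slots__ = ("name", "parent", "children", "tau", "theta")

    def __init__(self, name: str, tau: float = 0.0, theta: float = 0.0):
        self.name = name
        self.parent: _Node | None = None
        self.children: list[_Node] = []
        self.tau = tau
        self.theta = theta

    @property
    def is_tip(self) -> bool:
        return not self.children


class SpeciesNetwork:
    """A rooted binary species tree plus optional gene-flow specification.

    Every node (tip or internal) names one population: the branch between the
    node and its parent.  ``tau`` maps node names to divergence times (tips are
    at time 0) and ``theta`` maps node names to population-size parameters.
    """

    def __init__(
        self,
        newick: str,
        tau: dict[str, float],
        theta: float | dict[str, float],
        introgressions: tuple[IntrogressionEvent, ...] | list[IntrogressionEvent] = (),
        migrations: tuple[MigrationBand, ...] | list[MigrationBand] = (),
    ):
        self._nodes: dict[str, _Node] = {}
        self.root = self._parse_newick(newick)
        for name, t in tau.items():
            if name not in self._nodes:
                raise ValueError(f"tau given for unknown node {name!r}")
            self._nodes[name].tau = float(t)
        if isinstance(theta, dict):
            for name, th in theta.items():
                if name not in self._nodes:
                    raise ValueError(f"theta given for unknown node {name!r}")
                self._nodes[name].theta = float(th)
        else:
            for node in self._nodes.values():
                node.theta = float(theta)
        self.introgressions = tuple(introgressions)
        self.migrations = tuple(migrations)

    # -- construction -----------------------------------------------------

    def _parse_newick(self, newick: str) -> _Node:
        tree = dendropy.Tree.get(data=newick, schema="newick")
        counter = [0]

        def build(dnode) -> _Node:
            if dnode.is_leaf():
                name = dnode.taxon.label
            else:
                name = dnode.label
                if name is None:
                    counter[0] += 1
                    name = f"n{counter[0]}"
            if name in self._nodes:
                raise ValueError(f"duplicate node label {name!r}")
            node = _Node(name)
            self._nodes[name] = node
            for child in dnode.child_nodes():
                cn = build(child)
                cn.parent = node
                node.children.append(cn)
            return node

        return build(tree.seed_node)

    # -- queries -----------------------------------------------------------

    @property
    def species(self) -> list[str]:
        """Extant species names, in a stable (alphabetical) order."""
        return sorted(n.name for n in self._nodes.values() if n.is_tip)

    @property
    def node_names(self) -> list[str]:
        return list(self._nodes)

    def node(self, name: str) -> _Node:
        return self._nodes[name]

    def tau(self, name: str) -> float:
        return self._nodes[name].tau

    def theta(self, name: str) -> float:
        return self._nodes[name].theta

    def parent(self, name: str) -> str | None:
        p = self._nodes[name].parent
        return None if p is None else p.name

    def children(self, name: str) -> list[str]:
        return [c.name for c in self._nodes[name].children]

    def lifespan(self, name: str) -> tuple[float, float]:
        """Time interval [tau_node, tau_parent) during which the population
        exists; the root population extends to infinity."""
        node = self._nodes[name]
        upper = math.inf if node.parent is None else node.parent.tau
        return node.tau, upper

    def to_newick(self, annotate: bool = False) -> str:
        """Newick string; with ``annotate=True`` internal labels carry
        ``#tau=...,theta=...`` comments in the BPP annotation spirit."""

        def fmt(node: _Node) -> str:
            if node.is_tip:
                label = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner}){node.name}"
            if annotate:
                label += f"[&tau={node.tau:.8g},theta={node.theta:.8g}]"
            return label

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SpeciesNetwork({self.to_newick()!r})"


def validate_network(net: SpeciesNetwork) -> list[str]:
    """Return a list of invariant violations (empty when the network is valid).

    Checks time-ordering of divergence times, positivity of theta, the ranges
    and placement of gene-flow events, and that introgression events and
    migration bands are not mixed in one network.
    """
    violations: list[str] = []
    for name in net.node_names:
        node = net.node(name)
        if node.is_tip and node.tau != 0.0:
            violations.append(f"tip {name!r} has nonzero tau {node.tau}")
        for child in node.children:
            if child.tau >= node.tau:
                violations.append(
                    f"node {name!r} (tau={node.tau}) not older than child "
                    f"{child.name!r} (tau={child.tau})"
                )
        if not node.theta > 0.0:
            violations.append(f"population {name!r} has nonpositive theta {node.theta}")

    for ev in net.introgressions:
        if not 0.0 <= ev.phi <= 1.0:
            violations.append(
                f"introgression {ev.donor}->{ev.recipient}: phi={ev.phi} outside [0, 1]"
            )
        for role, pop in (("donor", ev.donor), ("recipient", ev.recipient)):
            if pop not in net.node_names:
                violations.append(f"introgression {role} {pop!r} is not a population")
                continue
            lo, hi = net.lifespan(pop)
            if not lo <= ev.time < hi:
                violations.append(
                    f"introgression time {ev.time} outside lifespan "
                    f"[{lo}, {hi}) of {role} {pop!r}"
                )

    for band in net.migrations:
        if band.rate < 0.0:
            violations.append(
                f"migration {band.source}->{band.dest}: negative rate {band.rate}"
            )
        missing = [p for p in (band.source, band.dest) if p not in net.node_names]
        for pop in missing:
            violations.append(f"migration population {pop!r} is not a population")
        if not missing:
            lo_s, hi_s = net.lifespan(band.source)
            lo_d, hi_d = net.lifespan(band.dest)
            if min(hi_s, hi_d) <= max(lo_s, lo_d):
                violations.append(
                    f"migration {band.source}->{band.dest}: populations never coexist"
                )

    if net.introgressions and net.migrations:
        violations.append(
            "network mixes introgression events and migration bands; use one"
        )
    return violations


# ---------------------------------------------------------------------------
# Simulation presets: five-species trees B and U, without gene flow (species
# tree estimation design) and with two gene-flow events b->c and d->e (the
# parameter-estimation design).  All tau are proportional to theta so that
# theta acts as an overall mutation-rate scale.
# ---------------------------------------------------------------------------

_TOPOLOGY_B = "(((A,B)t,C)s,(D,E)u)r;"
_TOPOLOGY_U = "((((A,B)u,C)t,D)s,E)r;"

# tau multipliers (times theta)
_TAU_B = {"r": 5.0, "s": 4.8, "t": 4.7, "u": 4.8}
_TAU_U = {"r": 5.0, "s": 4.8, "t": 4.6, "u": 4.4}
_TAU_B_FLOW = {"r": 5.0, "s": 4.0, "t": 3.0, "u": 4.5}
_TAU_U_FLOW = {"r": 5.0, "s": 4.0, "t": 3.0, "u": 2.5}

PRESET_NAMES = ("B", "U", "B-IM", "U-IM", "B-MIG", "U-MIG")


def build_preset(name: str, theta: float) -> SpeciesNetwork:
    """Construct one of the standard five-species simulation designs.

    ``B``/``U``: balanced / unbalanced species trees without gene flow.
    ``*-IM``: the same shapes with two introgression events, B->C at time
    theta with phi = 0.3 and D->E at time theta with phi = 0.2.
    ``*-MIG``: continuous migration bands B->C with M = 0.3 and D->E with
    M = 0.2.  All divergence times scale linearly with ``theta``.
    """
    if theta <= 0.0:
        raise ValueError("theta must be positive")
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    base = name.split("-")[0]
    flow = name.partition("-")[2]  # "", "IM" or "MIG"
    if flow:
        topo = _TOPOLOGY_B if base == "B" else _TOPOLOGY_U
        mult = _TAU_B_FLOW if base == "B" else _TAU_U_FLOW
    else:
        topo = _TOPOLOGY_B if base == "B" else _TOPOLOGY_U
        mult = _TAU_B if base == "B" else _TAU_U

    tau = {k: v * theta for k, v in mult.items()}
    intro: list[IntrogressionEvent] = []
    mig: list[MigrationBand] = []
    if flow == "IM":
        intro = [
            IntrogressionEvent(donor="B", recipient="C", time=theta, phi=0.3),
            IntrogressionEvent(donor="D", recipient="E", time=theta, phi=0.2),
        ]
    elif flow == "MIG":
        mig = [
            MigrationBand(source="B", dest="C", rate=0.3),
            MigrationBand(source="D", dest="E", rate=0.2),
        ]
    net = SpeciesNetwork(topo, tau=tau, theta=theta, introgressions=intro, migrations=mig)
    problems = validate_network(net)
    if problems:  # pragma: no cover - presets are valid by construction
        raise AssertionError(f"preset {name} invalid: {problems}")
    return net
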