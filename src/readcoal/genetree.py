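"""Gene-tree simulation under the multispecies coalescent, with optional
discrete introgression (MSC-I) or continuous migration (MSC-M).

Time runs backwards from the tips (time 0) in units of expected substitutions
per site.  Within a population with size parameter theta each pair of lineages
coalesces at rate 2/theta.  Backwards in time, a lineage in the recipient of a
migration band source->dest (forward direction) jumps to the source population
at rate 4*M/theta_dest, the standard conversion for M = N*m and theta = 4*N*mu.
At an introgression event, each lineage present in the recipient takes the
donor path with probability phi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import SpeciesNetwork, validate_network

__all__ = ["GeneTreeNode", "GeneTree", "simulate_gene_tree"]


class GeneTreeNode:
    __slots__ = ("time", "children", "label", "species", "individual", "allele", "population")

    def __init__(self, time=0.0, children=(), label=None, species=None,
                 individual=None, allele=None, population=None):
        self.time = time
        self.children = list(children)
        self.label = label
        self.species = species          # tip: species of origin
        self.individual = individual    # tip: diploid individual index (1-based)
        self.allele = allele            # tip: allele index 1 or 2
        self.population = population    # population in which this node lives/coalesced

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class GeneTree:
    """A rooted genealogy with node times in substitutions per site."""

    root: GeneTreeNode

    def tips(self) -> list[GeneTreeNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_tip:
                out.append(node)
            else:
                stack.extend(node.children)
        out.sort(key=lambda n: n.label)
        return out

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def root_time(self) -> float:
        return self.root.time

    def newick(self, precision: int = 10) -> str:
        def fmt(node: GeneTreeNode, parent_time: float) -> str:
            bl = parent_time - node.time
            if node.is_tip:
                return f"{node.label}:{bl:.{precision}g}"
            inner = ",".join(fmt(c, node.time) for c in node.children)
            return f"({inner}):{bl:.{precision}g}"

        inner = ",".join(fmt(c, self.root.time) for c in self.root.children)
        return f"({inner});"

    def coalescent_times(self) -> list[float]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_tip:
                out.append(node.time)
                stack.extend(node.children)
        return sorted(out)


def _make_tips(samples: dict[str, int]) -> dict[str, list[GeneTreeNode]]:
    lineages: dict[str, list[GeneTreeNode]] = {}
    for sp in sorted(samples):
        count = samples[sp]
        if count < 0:
            raise ValueError("allele counts must be >= 0")
        nodes = []
        for idx in range(count):
            ind = idx // 2 + 1
            allele = idx % 2 + 1
            nodes.append(
                GeneTreeNode(
                    time=0.0,
                    label=f"{sp}_{ind}_{allele}",
                    species=sp,
                    individual=ind,
                    allele=allele,
                    population=sp,
                )
            )
        lineages[sp] = nodes
    return lineages


def simulate_gene_tree(
    net: SpeciesNetwork,
    samples: dict[str, int],
    rng: np.random.Generator,
) -> GeneTree:
    """Draw one gene tree for the given per-species allele counts.

    ``samples`` maps species name to the number of sampled alleles (a diploid
    individual contributes two; allele indices in the tip labels
    ``species_individual_allele`` make the diploid pairing deterministic).
    """
    problems = validate_network(net)
    if problems:
        raise ValueError("invalid species network: " + "; ".join(problems))
    unknown = set(samples) - set(net.species)
    if unknown:
        raise ValueError(f"samples given for unknown species {sorted(unknown)}")
    total = sum(samples.values())
    if total < 2:
        raise ValueError("need at least 2 sampled alleles in total")

    lineages = _make_tips({sp: samples.get(sp, 0) for sp in net.species})
    alive = set(lineages)

    # Scheduled (deterministic) events: population merges at each internal tau
    # and introgression routing points, processed in time order.  Introgression
    # events sort before a merge at the same instant so that routing happens
    # while both branches still exist.
    events: list[tuple[float, int, str, object]] = []
    for name in net.node_names:
        node = net.node(name)
        if not node.is_tip:
            events.append((node.tau, 1, name, None))
    for ev in net.introgressions:
        events.append((ev.time, 0, ev.recipient, ev))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    t = 0.0
    for ev_time, _, ev_name, payload in events:
        t = _evolve_epoch(t, ev_time, lineages, alive, net, rng)
        if payload is None:
            # speciation: merge child populations into the ancestral one
            merged: list[GeneTreeNode] = []
            for child in net.children(ev_name):
                merged.extend(lineages.pop(child, ()))
                alive.discard(child)
            for lin in merged:
                lin.population = ev_name
            lineages[ev_name] = merged
            alive.add(ev_name)
        else:
            intro = payload
            stay, move = [], []
            for lin in lineages.get(intro.recipient, ()):
                (move if rng.random() < intro.phi else stay).append(lin)
            if intro.recipient in lineages:
                lineages[intro.recipient] = stay
                for lin in move:
                    lin.population = intro.donor
                lineages.setdefault(intro.donor, []).extend(move)

    # root population: run until a single lineage remains
    _evolve_epoch(t, np.inf, lineages, alive, net, rng)
    remaining = [lin for pop in lineages.values() for lin in pop]
    assert len(remaining) == 1
    return GeneTree(root=remaining[0])


def _evolve_epoch(
    t: float,
    t_end: float,
    lineages: dict[str, list[GeneTreeNode]],
    alive: set[str],
    net: SpeciesNetwork,
    rng: np.random.Generator,
) -> float:
    """Competing-exponentials simulation within one inter-event epoch."""
    n_left = sum(len(v) for v in lineages.values())
    while True:
        if n_left <= 1 and np.isinf(t_end):
            return t
        # category rates: coalescence per population, then migration per band
        cats: list[tuple[float, str, object]] = []
        total = 0.0
        for pop, lins in lineages.items():
            k = len(lins)
            if k >= 2:
                rate = k * (k - 1) / net.theta(pop)
                cats.append((rate, "coal", pop))
                total += rate
        for band in net.migrations:
            if band.rate > 0.0 and band.source in alive and band.dest in alive:
                n_dest = len(lineages.get(band.dest, ()))
                if n_dest:
                    rate = n_dest * 4.0 * band.rate / net.theta(band.dest)
                    cats.append((rate, "mig", band))
                    total += rate
        if total == 0.0:
            return t_end
        dt = rng.exponential(1.0 / total)
        if t + dt >= t_end:
            return t_end
        t += dt
        u = rng.random() * total
        for rate, kind, obj in cats:
            if u < rate:
                break
            u -= rate
        if kind == "coal":
            lins = lineages[obj]
            k = len(lins)
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            a, b = (lins[i], lins[j]) if i < j else (lins[j], lins[i])
            parent = GeneTreeNode(time=t, children=[a, b], population=obj)
            lins[:] = [l for l in lins if l is not a and l is not b]
            lins.append(parent)
            n_left -= 1
        else:
            band = obj
            lins = lineages[band.dest]
            i = int(rng.integers(len(lins)))
            lin = lins.pop(i)
            lin.population = band.source
            lineages.setdefault(band.source, []).append(lin)
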