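"""End-to-end dataset generation: gene trees -> JC sequences -> diploid truth
-> depth tracks -> reads and ML genotype calls -> IUPAC-coded alignments, with
reproducible seeding, writers for the BPP multilocus dialect, and summary
reporting of observed versus analytic genotyping-error rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .depth import sample_depth_track, sample_species_mean, unscale_depth
from .genetree import GeneTree, simulate_gene_tree
from .genotype import _LEDGER_COLUMNS, analytic_error_rate, corrupt_alignment
from .seqevolve import DiploidAlignment, HaploidAlignment, diploid_from_haploid, evolve_jc
from .species import (
    IntrogressionEvent,
    MigrationBand,
    SpeciesNetwork,
    validate_network,
)

__all__ = [
    "LocusData",
    "ReplicateDataset",
    "AmbiguityView",
    "simulate_dataset",
    "regenerate",
    "to_ambiguity_view",
    "report_error_rates",
    "write_phylip",
    "write_imap",
    "write_fasta",
    "write_outputs",
]


@dataclass
class LocusData:
    """Everything simulated at one locus."""

    index: int
    gene_tree: GeneTree
    haploid: HaploidAlignment
    truth: DiploidAlignment
    called: DiploidAlignment
    depths: np.ndarray  # (n_individuals, n_sites) integer read depths
    ledger: pd.DataFrame


@dataclass
class ReplicateDataset:
    """One replicate dataset plus the manifest needed to regenerate it."""

    config: SimulationConfig
    network: SpeciesNetwork
    species_mean_depths: dict[str, float]
    loci: list[LocusData]
    manifest: dict

    @property
    def ledger(self) -> pd.DataFrame:
        frames = [l.ledger for l in self.loci if len(l.ledger)]
        if not frames:
            return pd.DataFrame(columns=_LEDGER_COLUMNS)
        return pd.concat(frames, ignore_index=True)

    def true_site_counts(self) -> dict[str, int]:
        """Counts of truly homozygous / heterozygous genotype sites."""
        het = sum(int(l.truth.heterozygous().sum()) for l in self.loci)
        total = sum(l.truth.n_individuals * l.truth.n_sites for l in self.loci)
        return {"homozygote": total - het, "heterozygote": het}


def _network_manifest(net: SpeciesNetwork) -> dict:
    return {
        "newick": net.to_newick(),
        "tau": {n: net.tau(n) for n in net.node_names},
        "theta": {n: net.theta(n) for n in net.node_names},
        "introgressions": [
            {"donor": e.donor, "recipient": e.recipient, "time": e.time, "phi": e.phi}
            for e in net.introgressions
        ],
        "migrations": [
            {"source": b.source, "dest": b.dest, "rate": b.rate}
            for b in net.migrations
        ],
    }


def simulate_dataset(
    config: SimulationConfig,
    net: SpeciesNetwork,
    seed: int | None = None,
) -> ReplicateDataset:
    """Simulate one replicate dataset.

    The master seed (argument overrides ``config.seed``) is split into one
    stream for the per-species mean depths and one independent stream per
    locus, so loci are reproducible in isolation and datasets with different
    ``error_mode`` but the same seed share all reads, depths and gene trees.
    """
    config.validate()
    problems = validate_network(net)
    if problems:
        raise ValueError("invalid species network: " + "; ".join(problems))
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a master seed is required (config.seed or seed=)")
    seed = int(seed)

    params = config.depth_params()
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(config.loci + 1)
    species_rng = np.random.default_rng(streams[0])

    species = net.species
    xbar_s = {sp: sample_species_mean(params, species_rng) for sp in species}
    mean_depths = {sp: float(unscale_depth(x, params)) for sp, x in xbar_s.items()}

    samples = {sp: 2 * config.samples_per_species for sp in species}
    loci: list[LocusData] = []
    for l in range(config.loci):
        rng = np.random.default_rng(streams[l + 1])
        tree = simulate_gene_tree(net, samples, rng)
        hap = evolve_jc(tree, config.sites, rng)
        truth = diploid_from_haploid(hap, tree.tips())
        tracks = np.stack([
            sample_depth_track(xbar_s[sp], config.sites, params, rng)
            for sp, _tok in truth.individuals
        ])
        called, ledger = corrupt_alignment(
            truth, tracks, config.error_rate, config.error_mode, rng, locus=l
        )
        loci.append(LocusData(
            index=l, gene_tree=tree, haploid=hap, truth=truth,
            called=called, depths=tracks, ledger=ledger,
        ))

    manifest = {
        "format": "readcoal-manifest",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "network": _network_manifest(net),
        "species_mean_depths": mean_depths,
    }
    return ReplicateDataset(
        config=config, network=net, species_mean_depths=mean_depths,
        loci=loci, manifest=manifest,
    )


def regenerate(manifest: dict) -> ReplicateDataset:
    """Rebuild a dataset bit-identically from its manifest."""
    cfg_dict = dict(manifest["config"])
    config = SimulationConfig(**cfg_dict)
    netm = manifest["network"]
    net = SpeciesNetwork(
        netm["newick"],
        tau=netm["tau"],
        theta=netm["theta"],
        introgressions=[IntrogressionEvent(**e) for e in netm["introgressions"]],
        migrations=[MigrationBand(**b) for b in netm["migrations"]],
    )
    return simulate_dataset(config, net, seed=manifest["seed"])


# ---------------------------------------------------------------------------
# Views and reports
# ---------------------------------------------------------------------------

@dataclass
class AmbiguityView:
    """Annotation for the heterozygote-as-ambiguity analysis convention.

    The alignment content is unchanged; the flag marks that downstream
    analyses should read each IUPAC ambiguity as an undetermined nucleotide in
    a haploid sequence.  ``masked_per_locus`` counts the heterozygous (hence
    masked) genotype calls per locus.
    """

    dataset: ReplicateDataset
    masked_per_locus: list[int]
    ambiguity_is_missing: bool = True

    @property
    def total_masked(self) -> int:
        return sum(self.masked_per_locus)


def to_ambiguity_view(dataset: ReplicateDataset) -> AmbiguityView:
    masked = [int(l.called.heterozygous().sum()) for l in dataset.loci]
    return AmbiguityView(dataset=dataset, masked_per_locus=masked)


def report_error_rates(datasets) -> pd.DataFrame:
    """Observed genotyping-error rates per (mean depth, eps, genotype class).

    For each dataset the observed miscall frequency of each class (miscalled
    sites of the class over true sites of the class, taken from the simulated
    calls before mode filtering) is reported with its binomial Monte-Carlo
    standard error, next to the analytic error rate at the fixed nominal
    depth for comparison.
    """
    rows = []
    for ds in datasets:
        counts = ds.true_site_counts()
        ledger = ds.ledger
        d_nom = ds.config.mean_depth
        eps = ds.config.error_rate
        for cls, classes in (
            ("homozygote", ("hom-as-het", "hom-as-other-hom")),
            ("heterozygote", ("het-as-hom", "het-as-other-het")),
        ):
            n_true = counts[cls]
            n_err = int(ledger["error_class"].isin(classes).sum()) if len(ledger) else 0
            rate = n_err / n_true if n_true else float("nan")
            se = (
                float(np.sqrt(rate * (1.0 - rate) / n_true)) if n_true else float("nan")
            )
            rows.append({
                "mean_depth": d_nom,
                "error_rate": eps,
                "genotype_class": cls,
                "n_sites": n_true,
                "n_miscalled": n_err,
                "observed_rate": rate,
                "mc_se": se,
                "analytic_at_mean_depth": analytic_error_rate(
                    cls, int(round(d_nom)), eps
                ),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _phylip_text(dataset: ReplicateDataset, which: str = "called") -> str:
    chunks = []
    for locus in dataset.loci:
        aln = getattr(locus, which)
        names = aln.sequence_names()
        width = max(len(n) for n in names) + 2
        lines = [f" {aln.n_individuals} {aln.n_sites}"]
        for i, name in enumerate(names):
            lines.append(f"{name:<{width}}{aln.iupac(i)}")
        chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + "\n"


def write_phylip(dataset: ReplicateDataset, path: str | Path, which: str = "called") -> None:
    """Write the multilocus alignment in the BPP PHYLIP dialect (per-locus
    ``n_seq n_sites`` headers, sequence names ``individual^species``, IUPAC
    heterozygotes).  ``which`` selects 'called' or 'truth'."""
    Path(path).write_text(_phylip_text(dataset, which))


def write_imap(dataset: ReplicateDataset, path: str | Path) -> None:
    """Two-column individual -> species map matching the PHYLIP names."""
    pairs = dataset.loci[0].truth.individuals
    lines = [f"{tok} {sp}" for sp, tok in pairs]
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(dataset: ReplicateDataset, out_dir: str | Path, which: str = "haploid") -> None:
    """Per-locus FASTA files of the true haploid sequences."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for locus in dataset.loci:
        locus.haploid.to_fasta(out / f"locus_{locus.index:04d}.fasta")


def write_outputs(dataset: ReplicateDataset, out_dir: str | Path) -> None:
    """Standard output layout: alignments, truth, Imap, ledger and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_phylip(dataset, out / "alignments.phy", which="called")
    write_phylip(dataset, out / "alignments_true.phy", which="truth")
    write_imap(dataset, out / "Imap.txt")
    dataset.ledger.to_csv(out / "error_ledger.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(dataset.manifest, indent=2) + "\n")
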