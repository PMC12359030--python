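"""Sequence evolution along gene trees under the Jukes-Cantor model, and
merging of haploid allele pairs into unphased diploid genotypes coded with
IUPAC ambiguity letters.

Bases are held as uint8 codes 0..3 for A, C, G, T.  Under JC the probability
that the base at the end of a branch of length t differs from the base at the
start is (3/4) * (1 - exp(-4 t / 3)), and a changed base is uniform over the
other three; sites evolve independently, so substitutions are sampled directly
from the per-branch transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetree import GeneTree

__all__ = [
    "BASES",
    "IUPAC_PAIR",
    "HaploidAlignment",
    "DiploidAlignment",
    "evolve_jc",
    "jc_diff_probability",
    "merge_diploid",
    "diploid_from_haploid",
]

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

# IUPAC code for each unordered base pair (indexable by two base codes)
IUPAC_PAIR = np.array(
    [
        ["A", "M", "R", "W"],
        ["M", "C", "S", "Y"],
        ["R", "S", "G", "K"],
        ["W", "Y", "K", "T"],
    ]
)


def jc_diff_probability(t: float) -> float:
    """JC probability that two bases separated by total distance t differ."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


@dataclass
class HaploidAlignment:
    """True (error-free) haploid sequences at one locus, one row per tip."""

    labels: list[str]
    seqs: np.ndarray  # (n_tips, n_sites) uint8 codes 0..3

    def __post_init__(self):
        self.seqs = np.asarray(self.seqs, dtype=np.uint8)
        if self.seqs.ndim != 2 or len(self.labels) != self.seqs.shape[0]:
            raise ValueError("labels and sequence rows must match")
        if self.seqs.size and self.seqs.max() > 3:
            raise ValueError("alphabet restricted to ACGT")

    @property
    def n_sites(self) -> int:
        return self.seqs.shape[1]

    def sequence(self, i: int) -> str:
        return "".join(BASES[c] for c in self.seqs[i])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(i)), id=label, description="")
            for i, label in enumerate(self.labels)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class DiploidAlignment:
    """Unphased diploid sequences: two base codes per individual per site.

    ``individuals`` holds (species, individual_token) pairs; ``alleles`` has
    shape (n_individuals, n_sites, 2).  ``phased_truth`` distinguishes the
    true simulated genotypes from genotypes called from reads.
    """

    individuals: list[tuple[str, str]]
    alleles: np.ndarray
    phased_truth: bool = True

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_sites, 2)")
        if len(self.individuals) != self.alleles.shape[0]:
            raise ValueError("individuals and allele rows must match")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def heterozygous(self) -> np.ndarray:
        """Boolean mask (n_individuals, n_sites) of heterozygous genotypes."""
        return self.alleles[:, :, 0] != self.alleles[:, :, 1]

    def iupac(self, i: int) -> str:
        """IUPAC-coded sequence of individual i (ambiguity = heterozygote)."""
        a = self.alleles[i]
        return "".join(IUPAC_PAIR[a[:, 0], a[:, 1]])

    def sequence_names(self) -> list[str]:
        """BPP-style names ``individual^species``."""
        return [f"{tok}^{sp}" for sp, tok in self.individuals]


def evolve_jc(tree: GeneTree, sites: int, rng: np.random.Generator) -> HaploidAlignment:
    """Evolve one locus of ``sites`` sites along the gene tree under JC.

    The root sequence is uniform over ACGT per site; each branch applies the
    JC transition matrix site-independently.
    """
    if sites < 1:
        raise ValueError("sites must be >= 1")
    labels: list[str] = []
    rows: list[np.ndarray] = []
    root_seq = rng.integers(0, 4, size=sites).astype(np.uint8)
    stack = [(tree.root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_tip:
            labels.append(node.label)
            rows.append(seq)
            continue
        for child in node.children:
            t = node.time - child.time
            child_seq = seq
            if t > 0.0:
                p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
                mask = rng.random(sites) < p_change
                child_seq = seq.copy()
                n_mut = int(mask.sum())
                if n_mut:
                    child_seq[mask] = (
                        child_seq[mask] + rng.integers(1, 4, size=n_mut).astype(np.uint8)
                    ) % 4
            else:
                child_seq = seq.copy()
            stack.append((child, child_seq))
    order = np.argsort(labels)
    return HaploidAlignment(
        labels=[labels[i] for i in order],
        seqs=np.stack([rows[i] for i in order]),
    )


def _to_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        try:
            return np.array([_BASE_CODE[b] for b in seq.upper()], dtype=np.uint8)
        except KeyError as exc:
            raise ValueError(f"non-ACGT base {exc.args[0]!r}") from None
    arr = np.asarray(seq, dtype=np.uint8)
    if arr.size and arr.max() > 3:
        raise ValueError("non-ACGT base code")
    return arr


def merge_diploid(seq_allele1, seq_allele2) -> str:
    """Merge two haploid sequences into one unphased IUPAC-coded sequence.

    Equal bases give the base itself; unequal bases give the unique two-base
    ambiguity code (Y for T/C, and so on).  Order-insensitive.
    """
    a = _to_codes(seq_allele1)
    b = _to_codes(seq_allele2)
    if a.shape != b.shape:
        raise ValueError("allele sequences must have equal length")
    return "".join(IUPAC_PAIR[a, b])


def diploid_from_haploid(hap: HaploidAlignment, tips) -> DiploidAlignment:
    """Pair haploid tip sequences into diploid individuals by tip metadata.

    ``tips`` is the gene tree's tip list; alleles 1 and 2 of the same
    (species, individual) become one diploid row, ordered by species then
    individual index.
    """
    index = {label: i for i, label in enumerate(hap.labels)}
    by_ind: dict[tuple[str, int], dict[int, int]] = {}
    for tip in tips:
        by_ind.setdefault((tip.species, tip.individual), {})[tip.allele] = index[tip.label]
    individuals: list[tuple[str, str]] = []
    pairs: list[np.ndarray] = []
    for (sp, ind), alleles in sorted(by_ind.items()):
        if set(alleles) != {1, 2}:
            raise ValueError(f"individual {sp}/{ind} lacks a full allele pair")
        individuals.append((sp, f"{sp.lower()}{ind}"))
        pairs.append(np.stack([hap.seqs[alleles[1]], hap.seqs[alleles[2]]], axis=1))
    return DiploidAlignment(
        individuals=individuals, alleles=np.stack(pairs), phased_truth=True
    )
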