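"""Read simulation and maximum-likelihood genotype calling.

At a site covered by n reads, each read copies one of the two alleles of the
true genotype (uniformly for a heterozygote) and is read correctly with
probability 1 - eps; on error the read shows one of the three other bases
uniformly.  Sites where more than two distinct bases occur are resampled
wholesale.  Calling reduces the reads to counts of two alleles, k copies of
allele "1" among n, and maximizes the three binomial likelihoods

    L(00 | k) = C(n, k) (1 - eps)^(n-k) eps^k
    L(01 | k) = C(n, k) (1/2)^n
    L(11 | k) = C(n, k) (1 - eps)^k eps^(n-k)

over genotypes 00, 01, 11.  Miscalls fall into two main classes: a true
homozygote called heterozygote (hom-err) and a true heterozygote called
homozygote (het-err); these can be committed selectively to study each class
in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .seqevolve import BASES, DiploidAlignment, IUPAC_PAIR

__all__ = [
    "HOMOZYGOTE",
    "HETEROZYGOTE",
    "ERROR_CLASSES",
    "SiteReads",
    "GenotypeCall",
    "AliasTable",
    "read_count_sampler",
    "ml_decision_table",
    "ml_call_exact",
    "simulate_reads",
    "call_genotype_ml",
    "analytic_error_rate",
    "classify_call",
    "corrupt_alignment",
]

HOMOZYGOTE = "homozygote"
HETEROZYGOTE = "heterozygote"

ERROR_CLASSES = (
    "none",
    "hom-as-het",
    "het-as-hom",
    "hom-as-other-hom",
    "het-as-other-het",
)

# genotype codes used by the likelihood machinery
_GT00, _GT01, _GT11 = 0, 1, 2


# ---------------------------------------------------------------------------
# ML decision rule
# ---------------------------------------------------------------------------

def _ml_call_scalar(n: int, k: int, eps: float) -> int:
    """Genotype code maximizing the binomial likelihoods for k 1s in n reads.

    Ties are broken toward the homozygote of the majority allele (and toward
    allele 0 when k == n - k); ties only arise at contrived eps values.
    """
    if eps == 0.0:
        if k == 0:
            return _GT00
        if k == n:
            return _GT11
        return _GT01
    log_e = math.log(eps)
    log_1e = math.log1p(-eps)
    l00 = (n - k) * log_1e + k * log_e
    l01 = n * math.log(0.5)
    l11 = k * log_1e + (n - k) * log_e
    best_hom, hom_code = (l00, _GT00) if l00 >= l11 else (l11, _GT11)
    if l00 == l11:
        hom_code = _GT11 if k > n - k else _GT00
    if l01 > best_hom:
        return _GT01
    return hom_code


_DECISION_CACHE: dict[tuple[int, float], np.ndarray] = {}


def ml_decision_table(n: int, eps: float) -> np.ndarray:
    """Array of length n + 1 giving the ML genotype code for each k."""
    key = (int(n), float(eps))
    table = _DECISION_CACHE.get(key)
    if table is None:
        table = np.array([_ml_call_scalar(n, k, eps) for k in range(n + 1)], dtype=np.int8)
        table.setflags(write=False)
        _DECISION_CACHE[key] = table
    return table


def ml_call_exact(n: int, k: int, eps: Fraction) -> int:
    """Arbitrary-precision reference: maximize the likelihoods with exact
    rational arithmetic.  Shares the float path's tie-break rule."""
    one = Fraction(1)
    l00 = (one - eps) ** (n - k) * eps**k
    l01 = Fraction(1, 2) ** n
    l11 = (one - eps) ** k * eps ** (n - k)
    best_hom, hom_code = (l00, _GT00) if l00 >= l11 else (l11, _GT11)
    if l00 == l11:
        hom_code = _GT11 if k > n - k else _GT00
    return _GT01 if l01 > best_hom else hom_code


# ---------------------------------------------------------------------------
# Alias-method multinomial sampling of allele counts
# ---------------------------------------------------------------------------

class AliasTable:
    """Walker alias sampler for a finite discrete distribution.

    One uniform draw (plus one integer draw) yields one sample regardless of
    the number of categories, which makes per-site allele-count sampling cost
    independent of read depth.
    """

    def __init__(self, probs):
        p = np.asarray(probs, dtype=float)
        if p.ndim != 1 or p.size == 0 or np.any(p < 0):
            raise ValueError("probs must be a nonnegative vector")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("probs must sum to 1")
        k = p.size
        scaled = p * k / total
        self.prob = np.ones(k)
        self.alias = np.arange(k)
        small = [i for i in range(k) if scaled[i] < 1.0]
        large = [i for i in range(k) if scaled[i] >= 1.0]
        scaled = scaled.copy()
        while small and large:
            s = small.pop()
            l = large.pop()
            self.prob[s] = scaled[s]
            self.alias[s] = l
            scaled[l] = scaled[l] - (1.0 - scaled[s])
            (small if scaled[l] < 1.0 else large).append(l)

    def sample(self, rng: np.random.Generator, size=None):
        idx = rng.integers(0, self.prob.size, size=size)
        accept = rng.random(size=size) < self.prob[idx]
        out = np.where(accept, idx, self.alias[idx])
        return int(out) if size is None else out


_SAMPLER_CACHE: dict[tuple[int, str, float], AliasTable] = {}


def read_count_sampler(n: int, genotype_class: str, eps: float) -> AliasTable:
    """Cached alias table for k | (n, genotype class, eps).

    For a homozygote k ~ Binomial(n, eps) (count of error reads); for a
    heterozygote k ~ Binomial(n, 1/2) independently of eps.
    """
    if genotype_class not in (HOMOZYGOTE, HETEROZYGOTE):
        raise ValueError("genotype_class must be 'homozygote' or 'heterozygote'")
    key = (int(n), genotype_class, float(eps))
    table = _SAMPLER_CACHE.get(key)
    if table is None:
        p = eps if genotype_class == HOMOZYGOTE else 0.5
        table = AliasTable(stats.binom.pmf(np.arange(n + 1), n, p))
        _SAMPLER_CACHE[key] = table
    return table


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SiteReads:
    """Reads at one site reduced to per-base counts.

    ``allele0``/``allele1`` are the base codes playing the roles of alleles 0
    and 1 in the likelihoods: allele 0 is the true base (homozygote) or the
    first true allele (heterozygote) whenever it is observed; allele 1 is the
    other observed base (None when only one base occurs).  ``k`` counts reads
    of allele 1.
    """

    depth: int
    counts: np.ndarray  # length-4 base counts
    allele0: int
    allele1: int | None

    @property
    def k(self) -> int:
        return 0 if self.allele1 is None else int(self.counts[self.allele1])


def _assign_alleles(counts: np.ndarray, true_genotype: tuple[int, int]) -> tuple[int, int | None]:
    observed = np.flatnonzero(counts)
    for base in true_genotype:
        if counts[base] > 0:
            a0 = int(base)
            break
    else:
        a0 = int(observed[0])
    others = [int(b) for b in observed if b != a0]
    return a0, (others[0] if others else None)


def simulate_reads(
    true_genotype,
    depth: int,
    eps: float,
    rng: np.random.Generator,
    model: str = "full",
    max_attempts: int = 10_000,
) -> SiteReads:
    """Simulate the reads covering one site.

    ``true_genotype`` is a pair of bases (codes 0..3 or characters).  With
    ``model='full'`` every read is simulated individually, error bases are
    drawn uniformly from the three alternatives, and the whole site is
    resampled if more than two distinct bases occur (capped at
    ``max_attempts``).  With ``model='two-allele'`` the allele count k is
    drawn directly from its binomial law via the cached alias table — the
    reduced two-allele model that the analytic error rates describe.
    """
    g0, g1 = (_base_code(b) for b in true_genotype)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must lie in [0, 1)")
    het = g0 != g1

    if model == "two-allele":
        sampler = read_count_sampler(depth, HETEROZYGOTE if het else HOMOZYGOTE, eps)
        k = sampler.sample(rng)
        if het:
            a1 = g1
        else:
            a1 = (g0 + int(rng.integers(1, 4))) % 4 if k > 0 else None
        counts = np.zeros(4, dtype=np.int64)
        counts[g0] = depth - k
        if a1 is not None:
            counts[a1] += k
        return SiteReads(depth=depth, counts=counts,
                         allele0=g0, allele1=a1 if k > 0 else None)
    if model != "full":
        raise ValueError("model must be 'full' or 'two-allele'")

    for _ in range(max_attempts):
        if het:
            templates = np.where(rng.random(depth) < 0.5, g0, g1).astype(np.int64)
        else:
            templates = np.full(depth, g0, dtype=np.int64)
        bases = templates.copy()
        errors = rng.random(depth) < eps
        n_err = int(errors.sum())
        if n_err:
            bases[errors] = (bases[errors] + rng.integers(1, 4, size=n_err)) % 4
        counts = np.bincount(bases, minlength=4)
        if int((counts > 0).sum()) <= 2:
            a0, a1 = _assign_alleles(counts, (g0, g1))
            return SiteReads(depth=depth, counts=counts, allele0=a0, allele1=a1)
    raise RuntimeError("site resampling cap reached; more than two alleles persist")


def _base_code(b) -> int:
    if isinstance(b, str):
        try:
            return BASES.index(b.upper())
        except ValueError:
            raise ValueError(f"non-ACGT base {b!r}") from None
    code = int(b)
    if not 0 <= code <= 3:
        raise ValueError(f"base code {code} outside 0..3")
    return code


# ---------------------------------------------------------------------------
# Genotype calling and error classification
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCall:
    """Outcome of ML calling at one site (unordered genotype semantics)."""

    true: tuple[int, int]
    called: tuple[int, int]
    error_class: str


def classify_call(true_pair, called_pair) -> str:
    """Name the error class of a (true, called) genotype pair."""
    t = frozenset(_base_code(b) for b in true_pair)
    c = frozenset(_base_code(b) for b in called_pair)
    if t == c:
        return "none"
    true_hom = len(t) == 1
    called_hom = len(c) == 1
    if true_hom and not called_hom:
        return "hom-as-het"
    if not true_hom and called_hom:
        return "het-as-hom"
    if true_hom and called_hom:
        return "hom-as-other-hom"
    return "het-as-other-het"


def call_genotype_ml(reads: SiteReads, eps: float,
                     true_genotype=None) -> GenotypeCall:
    """ML genotype from the reads at one site.

    When ``true_genotype`` is omitted it is taken as homozygous for
    ``reads.allele0`` only for classification purposes.
    """
    table = ml_decision_table(reads.depth, eps)
    code = int(table[reads.k])
    a0 = reads.allele0
    a1 = reads.allele1 if reads.allele1 is not None else a0
    called = {
        _GT00: (a0, a0),
        _GT01: tuple(sorted((a0, a1))),
        _GT11: (a1, a1),
    }[code]
    if true_genotype is None:
        true = (a0, a0)
    else:
        true = tuple(sorted(_base_code(b) for b in true_genotype))
    return GenotypeCall(true=true, called=called,
                        error_class=classify_call(true, called))


def analytic_error_rate_exact(genotype_class: str, depth: int, eps) -> Fraction:
    """Exact-rational version of :func:`analytic_error_rate`.

    ``eps`` is coerced to a Fraction (pass a string or Fraction to avoid
    binary-float noise); the result is an exact rational probability.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    eps = Fraction(eps)
    if genotype_class == HOMOZYGOTE:
        p, truth = eps, _GT00
    elif genotype_class == HETEROZYGOTE:
        p, truth = Fraction(1, 2), _GT01
    else:
        raise ValueError("genotype_class must be 'homozygote' or 'heterozygote'")
    total = Fraction(0)
    for k in range(depth + 1):
        if ml_call_exact(depth, k, eps) != truth:
            total += math.comb(depth, k) * p**k * (1 - p) ** (depth - k)
    return total


def analytic_error_rate(genotype_class: str, depth: int, eps: float) -> float:
    """Exact genotyping-error probability under the two-allele binomial model.

    Enumerates k = 0..depth with k ~ Binomial(depth, eps) for a homozygote or
    Binomial(depth, 1/2) for a heterozygote and sums the probability of every
    k whose ML call differs from the truth.  At eps = 0 this gives 0 for
    homozygotes and (1/2)^(depth-1) for heterozygotes.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    table = ml_decision_table(depth, eps)
    k = np.arange(depth + 1)
    if genotype_class == HOMOZYGOTE:
        pmf = stats.binom.pmf(k, depth, eps)
        wrong = table != _GT00
    elif genotype_class == HETEROZYGOTE:
        pmf = stats.binom.pmf(k, depth, 0.5)
        wrong = table != _GT01
    else:
        raise ValueError("genotype_class must be 'homozygote' or 'heterozygote'")
    return float(pmf[wrong].sum())


# ---------------------------------------------------------------------------
# Alignment corruption with selectable error modes
# ---------------------------------------------------------------------------

_LEDGER_COLUMNS = [
    "locus", "sequence", "site", "depth",
    "true_gt", "called_gt", "error_class", "committed",
]


def _gt_string(pair) -> str:
    i, j = sorted(pair)
    return BASES[i] + BASES[j]


def _commit(error_class: str, error_mode: str) -> bool:
    if error_mode == "both-err":
        return True
    if error_mode == "no-err":
        return False
    true_hom = error_class in ("hom-as-het", "hom-as-other-hom")
    return true_hom if error_mode == "hom-err" else not true_hom


def corrupt_alignment(
    truth: DiploidAlignment,
    tracks: np.ndarray,
    eps: float,
    error_mode: str,
    rng: np.random.Generator,
    locus: int = 0,
) -> tuple[DiploidAlignment, pd.DataFrame]:
    """Simulate reads and ML calls for every site of a true diploid alignment.

    ``tracks`` holds one integer depth per sequence and site, shape
    (n_individuals, n_sites).  Reads are always simulated for every site; the
    ``error_mode`` only decides which miscalls are committed to the returned
    alignment (hom-err keeps errors at truly homozygous sites, het-err the
    converse, both-err all, no-err none), so datasets generated from the same
    seed under different modes share reads, depths and suppressed calls.  The
    ledger records every miscall with its commit status (sites are 1-based).
    """
    if error_mode not in ("no-err", "hom-err", "het-err", "both-err"):
        raise ValueError(f"unknown error_mode {error_mode!r}")
    tracks = np.asarray(tracks)
    if tracks.shape != (truth.n_individuals, truth.n_sites):
        raise ValueError("tracks must have shape (n_individuals, n_sites)")

    called_alleles = truth.alleles.copy()
    rows: list[tuple] = []
    names = truth.sequence_names()
    max_d = int(tracks.max())
    # decision codes for every (depth, k): fancy-indexable matrix
    decision = np.full((max_d + 1, max_d + 1), -1, dtype=np.int8)
    for d in np.unique(tracks):
        decision[d, : d + 1] = ml_decision_table(int(d), eps)

    for s in range(truth.n_individuals):
        g0 = truth.alleles[s, :, 0].astype(np.int64)
        g1 = truth.alleles[s, :, 1].astype(np.int64)
        depths = tracks[s].astype(np.int64)
        het = g0 != g1

        # homozygous sites: vectorized error-read counts; only sites with at
        # least one error read need base-identity resolution.
        hom_idx = np.flatnonzero(~het)
        k_err = rng.binomial(depths[hom_idx], eps) if hom_idx.size else np.empty(0, int)
        for j, k in zip(hom_idx[k_err > 0], k_err[k_err > 0]):
            d = int(depths[j])
            base = int(g0[j])
            k = int(k)
            # resolve error-base identities; resample the site when the k
            # error reads span more than one alternative base
            for _ in range(10_000):
                alts = (base + rng.integers(1, 4, size=k)) % 4
                if np.unique(alts).size <= 1:
                    break
                k = int(rng.binomial(d, eps))
                if k == 0:
                    break
            else:  # pragma: no cover
                raise RuntimeError("site resampling cap reached")
            if k == 0:
                continue
            alt = int(alts[0])
            code = int(decision[d, k])
            if code == _GT00:
                continue
            called = (base, alt) if code == _GT01 else (alt, alt)
            cls = classify_call((base, base), called)
            committed = _commit(cls, error_mode)
            if committed:
                called_alleles[s, j, 0], called_alleles[s, j, 1] = sorted(called)
            rows.append((locus, names[s], j + 1, d, _gt_string((base, base)),
                         _gt_string(called), cls, committed))

        # heterozygous sites: full per-read simulation
        for j in np.flatnonzero(het):
            reads = simulate_reads((int(g0[j]), int(g1[j])), int(depths[j]), eps, rng)
            call = call_genotype_ml(reads, eps, true_genotype=(int(g0[j]), int(g1[j])))
            if call.error_class == "none":
                continue
            committed = _commit(call.error_class, error_mode)
            if committed:
                called_alleles[s, j, 0], called_alleles[s, j, 1] = sorted(call.called)
            rows.append((locus, names[s], j + 1, int(depths[j]),
                         _gt_string(call.true), _gt_string(call.called),
                         call.error_class, committed))

    ledger = pd.DataFrame(rows, columns=_LEDGER_COLUMNS)
    called = DiploidAlignment(
        individuals=list(truth.individuals),
        alleles=called_alleles,
        phased_truth=False,
    )
    return called, ledger
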