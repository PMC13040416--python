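"""Over-representation analysis with configurable background universes.

For an input gene set against a term annotation (GMT-style), each term is
tested with the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the background-universe size, K the universe genes annotated to
the term, n the mapped input size and k the input genes in the term.
Benjamini-Hochberg step-up adjustment controls the FDR across terms; fold
enrichment (k/n)/(K/N) and rich factor k/K describe effect magnitude.

The background universe matters: a *measured* universe (the genes actually
detectable in the experiment) avoids the significance inflation that a
whole-*genome* universe can produce, so both modes are supported.
Pseudogenes (and other configured biotypes) can be excluded from the input
before testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "UniverseSpec",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "storey_q",
    "build_universe",
    "enrich",
]


@dataclass
class AnnotationSet:
    """term_id -> (name, gene set); the GMT contract in memory."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class UniverseSpec:
    mode: str  # measured | genome
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.mode not in ("measured", "genome"):
            raise ValueError(f"unknown universe mode {self.mode!r}")
        if not self.genes:
            raise ValueError("universe is empty")

    @property
    def N(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float = float("nan")
    q: float = float("nan")
    z: float = float("nan")
    genes: tuple[str, ...] = ()

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n

    @property
    def bg_ratio(self) -> float:
        return self.K / self.N

    @property
    def rich_factor(self) -> float:
        return self.k / self.K

    @property
    def fold_enrichment(self) -> float:
        return (self.k / self.n) / (self.K / self.N)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); survival function in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_q(pvalues, lambdas=None) -> np.ndarray:
    """Storey q-values with a fixed lambda grid pi0 estimate (optional extra).

    Uses the mean of per-lambda pi0 estimates, clipped to (0, 1]; with few
    tests this is conservative but stable.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    pi0s = [np.mean(p > lam) / (1 - lam) for lam in lambdas]
    pi0 = min(1.0, max(float(np.mean(pi0s)), 1.0 / p.size))
    return np.minimum(bh_adjust(p) * pi0, 1.0)


def build_universe(mode: str, genes) -> UniverseSpec:
    """Build a background universe from measured genes or a genome table."""
    gene_set = frozenset(genes)
    if not gene_set:
        raise ValueError("universe source set is empty")
    return UniverseSpec(mode=mode, genes=gene_set)


def _hypergeom_z(k: int, K: int, n: int, N: int) -> float:
    """Normal-approximation score (k - E[X]) / sd(X); descriptive only."""
    mean = n * K / N
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1) if N > 1 else 0.0
    if var <= 0:
        return float("nan")
    return (k - mean) / math.sqrt(var)


def enrich(
    input_genes,
    annotation: AnnotationSet,
    universe: UniverseSpec,
    exclude_biotypes: set[str] | None = None,
    biotypes: dict[str, str] | None = None,
    use_storey_q: bool = False,
    compute_z: bool = False,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Test every annotated term for over-representation of the input set.

    The input is first reduced to the universe (genes outside it are dropped
    with a warning, and reported in the second return value together with
    biotype-excluded genes); terms with no universe gene are skipped. Results
    are BH-adjusted and sorted by (p, term_id) for total, deterministic order.
    """
    exclude_biotypes = exclude_biotypes or set()
    biotypes = biotypes or {}
    raw = list(dict.fromkeys(input_genes))
    dropped: list[str] = []
    mapped: list[str] = []
    for g in raw:
        if exclude_biotypes and biotypes.get(g) in exclude_biotypes:
            dropped.append(g)
        elif g not in universe.genes:
            dropped.append(g)
        else:
            mapped.append(g)
    if dropped:
        warnings.warn(
            f"{len(dropped)} of {len(raw)} input genes dropped "
            "(outside universe or excluded biotype)",
            stacklevel=2,
        )
    if not mapped:
        raise ValueError("no input genes left after mapping and biotype exclusion")

    mapped_set = set(mapped)
    n, N = len(mapped_set), universe.N
    results: list[EnrichmentResult] = []
    for tid in sorted(annotation.terms):
        name, genes = annotation.terms[tid]
        term_in_universe = genes & universe.genes
        K = len(term_in_universe)
        if K == 0:
            continue
        hits = sorted(mapped_set & term_in_universe)
        k = len(hits)
        res = EnrichmentResult(
            term_id=tid, name=name, k=k, K=K, n=n, N=N,
            p=hypergeom_upper_tail(k, K, n, N), genes=tuple(hits),
        )
        if compute_z:
            res.z = _hypergeom_z(k, K, n, N)
        results.append(res)

    if results:
        padj = bh_adjust([r.p for r in results])
        qvals = storey_q([r.p for r in results]) if use_storey_q else padj
        for r, a, q in zip(results, padj, qvals):
            r.p_adj = float(a)
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results, dropped
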