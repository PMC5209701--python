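"""Singular enrichment analysis of GO terms by the hypergeometric test.

For a study set of n genes drawn from a universe of N genes of which K
carry a term, observing k carriers has one-sided upper-tail probability

    p = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n)

and fold enrichment (k/n) / (K/N). Only over-representation is tested. The
universe size N and per-term K may be supplied explicitly to mirror
database-level counts (as annotation servers report them) independently of
the loaded association table; n counts only the study genes present
("registered") in the association. Multiple testing is controlled with
Benjamini-Hochberg FDR across all tested terms; the raw p is always
reported alongside the adjusted one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

__all__ = [
    "GOEnrichmentResult",
    "hypergeom_upper_tail",
    "fold_enrichment",
    "enrichment_from_counts",
    "go_sea",
    "write_go_results",
]


@dataclass(frozen=True, slots=True)
class GOEnrichmentResult:
    term_id: str
    term_name: str
    k: int  # study genes carrying the term
    n: int  # study genes registered in the association
    K: int  # universe genes carrying the term
    N: int  # universe size
    fold: float
    p_raw: float
    p_adj: float

    @property
    def study_fraction(self) -> float:
        """Percent of registered study genes carrying the term (100*k/n)."""
        return 100.0 * self.k / self.n

    @property
    def universe_fraction(self) -> float:
        """Percent of the universe carrying the term (100*K/N)."""
        return 100.0 * self.K / self.N


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated stably.

    The survival function is computed in log space by scipy, so extreme
    tails (p ~ 1e-300) do not underflow to the nearest representable sum.
    """
    _check_counts(N, K, n, k)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Observed over expected term frequency: (k/n) / (K/N)."""
    _check_counts(N, K, n, k)
    if n == 0 or K == 0:
        raise ValueError("fold enrichment undefined for n == 0 or K == 0")
    return (k / n) / (K / N)


def enrichment_from_counts(
    N: int, K: int, n: int, k: int, term_id: str = ".", term_name: str = ".", p_adj: float | None = None
) -> GOEnrichmentResult:
    """Build a single-term result directly from the four counts."""
    p = hypergeom_upper_tail(N, K, n, k)
    return GOEnrichmentResult(
        term_id, term_name, k, n, K, N, fold_enrichment(N, K, n, k), p, p if p_adj is None else p_adj
    )


def go_sea(
    study_genes: Iterable[str],
    association: Mapping[str, set[str]],
    term_names: Mapping[str, str] | None = None,
    universe_n: int | None = None,
    term_k: Mapping[str, int] | None = None,
) -> list[GOEnrichmentResult]:
    """Test every term hit by the study set for over-representation.

    ``association`` maps gene id -> set of term ids. ``n`` counts only study
    genes registered in the association; N defaults to the number of
    registered genes and per-term K to the association counts, both
    overridable via ``universe_n`` / ``term_k`` to use database-level
    numbers. Results (terms with k >= 1) are BH-adjusted over all tested
    terms and sorted by (p_adj, p_raw, term_id).
    """
    study = set(study_genes)
    if not study:
        raise ValueError("empty study gene set")
    if not association:
        raise ValueError("empty association table")
    names = term_names or {}
    registered = [g for g in sorted(study) if g in association]
    n = len(registered)
    if n == 0:
        raise ValueError("no study gene is registered in the association table")
    N = universe_n if universe_n is not None else len(association)
    if N < n:
        raise ValueError(f"universe size {N} smaller than registered study set {n}")

    k_by_term: dict[str, int] = {}
    for gene in registered:
        for term in association[gene]:
            k_by_term[term] = k_by_term.get(term, 0) + 1

    K_default: dict[str, int] = {}
    for terms in association.values():
        for term in terms:
            K_default[term] = K_default.get(term, 0) + 1

    rows = []
    for term in sorted(k_by_term):
        k = k_by_term[term]
        K = term_k.get(term, K_default[term]) if term_k else K_default[term]
        K = max(K, k)  # explicit database K cannot be below the observed carriers
        K = min(K, N)
        rows.append((term, k, K))

    p_raw = [hypergeom_upper_tail(N, K, n, k) for _, k, K in rows]
    p_adj = stats.false_discovery_control(p_raw, method="bh") if rows else []
    results = [
        GOEnrichmentResult(
            term, names.get(term, ""), k, n, K, N,
            fold_enrichment(N, K, n, k), p, min(1.0, max(p, q)),
        )
        for (term, k, K), p, q in zip(rows, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term_id))
    return results


def write_go_results(results: Sequence[GOEnrichmentResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("term_id\tterm_name\tk\tn\tK\tN\tfold\tp_raw\tp_adj\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.fold:.6f}\t{r.p_raw:.6e}\t{r.p_adj:.6e}\n"
            )
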