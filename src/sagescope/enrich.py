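"""Gene-set over-representation and gene-list intersection.

For a differentially expressed (DE) list of size ``n`` drawn from a
background universe of ``N`` genes, a gene set containing ``M``
background genes and ``m`` DE genes is scored by

* fold enrichment  (m/n) / (M/N), and
* the exact hypergeometric upper tail P(X >= m), X ~ Hypergeom(N, M, n).

Results below the significance cutoff (default raw p < 0.05) are flagged;
optional Benjamini-Hochberg correction and the conservative EASE variant
(which substitutes m-1 for m in the tail) are available.  Gene
identifiers are harmonised case-insensitively; DE genes absent from the
background are dropped with a count, never silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id}: empty membership")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    m: int  # DE genes in set
    n: int  # DE genes in background
    M: int  # background genes in set
    N: int  # background size
    fold_enrichment: float
    p_value: float
    significant: bool = False
    p_adjusted: float | None = None


def _check_counts(m: int, n: int, M: int, N: int) -> None:
    if not (0 <= m <= min(n, M) and m <= n <= N and 0 < M <= N):
        raise ValueError(f"inconsistent counts m={m}, n={n}, M={M}, N={N}")


def fold_enrichment(m: int, n: int, M: int, N: int) -> float:
    """(m/n) / (M/N): DE-list representation of the set vs background."""
    if n <= 0:
        raise ValueError("n must be positive")
    _check_counts(m, n, M, N)
    return (m / n) / (M / N)


def hypergeom_p(m: int, n: int, M: int, N: int, ease: bool = False) -> float:
    """Upper-tail P(X >= m) for X ~ Hypergeom(N, M, n).

    ``ease`` applies the jackknifed variant: the tail is evaluated at
    m - 1 successes, penalising sets supported by a single gene.
    """
    _check_counts(m, n, M, N)
    m_eff = max(m - 1, 0) if ease else m
    return float(hypergeom.sf(m_eff - 1, N, M, n))


def _bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    k = len(pvals)
    order = sorted(range(k), key=lambda i: pvals[i])
    adjusted = [0.0] * k
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = k - rank_from_end
        running = min(running, pvals[i] * k / rank)
        adjusted[i] = running
    return adjusted


def enrich(
    de_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background: Iterable[str],
    alpha: float = 0.05,
    ease: bool = False,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Score every gene set with at least one DE member.

    Returns results sorted by p-value (ties broken by set_id).  The
    significance flag uses adjusted p-values when ``bh_correct`` is on.
    """
    if not gene_sets:
        raise ValueError("gene_sets must be non-empty")
    bg = {g.casefold() for g in background}
    de_all = {g.casefold() for g in de_genes}
    de = de_all & bg
    dropped = len(de_all) - len(de)
    if dropped:
        logger.info("dropped %d DE genes absent from background", dropped)
    N = len(bg)
    n = len(de)
    if n == 0:
        return []

    results = []
    for gs in gene_sets:
        members = {g.casefold() for g in gs.members} & bg
        M = len(members)
        if M == 0:
            continue
        m = len(members & de)
        if m == 0:
            continue
        results.append(
            EnrichmentResult(
                set_id=gs.set_id,
                m=m,
                n=n,
                M=M,
                N=N,
                fold_enrichment=fold_enrichment(m, n, M, N),
                p_value=hypergeom_p(m, n, M, N, ease=ease),
            )
        )

    if results:
        padj = _bh_adjust([r.p_value for r in results]) if bh_correct else None
        flagged = []
        for i, r in enumerate(results):
            crit = padj[i] if padj is not None else r.p_value
            flagged.append(
                EnrichmentResult(
                    r.set_id, r.m, r.n, r.M, r.N, r.fold_enrichment, r.p_value,
                    significant=crit < alpha,
                    p_adjusted=padj[i] if padj is not None else None,
                )
            )
        results = flagged
    return sorted(results, key=lambda r: (r.p_value, r.set_id))


def intersect(list_a: Iterable[str], list_b: Iterable[str]) -> tuple[set[str], set[str], set[str]]:
    """Venn partition (common, only_a, only_b) of two gene lists."""
    a = set(list_a)
    b = set(list_b)
    return a & b, a - b, b - a


# ---------------------------------------------------------------------------
# GMT / list IO


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT format: set_id <tab> description <tab> genes..."""
    sets = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets.append(GeneSet(parts[0], parts[1], frozenset(parts[2:])))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    genes = set()
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes
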