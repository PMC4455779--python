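"""Protein-domain enrichment and paralog-retention contrasts.

Enrichment of a Pfam domain (or clan) in an SV gene list is tested with
the hypergeometric upper tail; family-wise multiple-test adjustment uses
min-p resampling: random gene lists of the same size are drawn from the
universe, the minimum raw p over all domains recorded per draw, and the
adjusted p of a domain is the fraction of draws whose minimum raw p is at
or below the domain's raw p.  Significance stars follow the conventional
cutoffs on adjusted p: ``*`` P < 0.01, ``**`` P < 0.001.

The paralog contrast compares the SV rate among genes with a retained
syntenic (whole-genome-duplication) paralog against genes without one,
with a two-sided Fisher exact test on the 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from soysv._rng import rng_for


def hypergeom_test(N: int, K: int, n: int, obs: int) -> tuple[float, float]:
    """Expected overlap and upper-tail P(X >= obs).

    N = universe size, K = genes carrying the domain, n = list size,
    obs = observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("infeasible counts: need K <= N and n <= N")
    if not (0 <= obs <= min(K, n)):
        raise ValueError("infeasible counts: need 0 <= obs <= min(K, n)")
    exp = K * n / N
    p_raw = float(stats.hypergeom.sf(obs - 1, N, K, n))
    return exp, p_raw


@dataclass
class EnrichmentResult:
    domain: str
    category: str
    N: int
    K: int
    n: int
    obs: int
    exp: float
    p_raw: float
    p_adj: float = np.nan

    @property
    def exp_rounded(self) -> int:
        """Expected count rounded to integer, as reported in summary tables."""
        return int(round(self.exp))

    @property
    def stars(self) -> str:
        if self.p_adj < 0.001:
            return "**"
        if self.p_adj < 0.01:
            return "*"
        return ""


class DomainAnnotation:
    """Gene -> domain membership over a fixed universe.

    ``gene_domains`` maps gene_id to an iterable of domain ids (a gene may
    carry several; clan aggregation is the caller's input mapping).
    """

    def __init__(self, gene_domains: dict[str, list[str]]):
        self.genes = list(gene_domains)
        self.domains = sorted({d for ds in gene_domains.values() for d in ds})
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self.membership = np.zeros((len(self.genes), len(self.domains)), dtype=bool)
        dom_index = {d: j for j, d in enumerate(self.domains)}
        for g, ds in gene_domains.items():
            for d in ds:
                self.membership[self._gene_index[g], dom_index[d]] = True

    @property
    def N(self) -> int:
        return len(self.genes)

    def domain_sizes(self) -> np.ndarray:
        return self.membership.sum(axis=0)

    def overlaps(self, gene_list: list[str]) -> np.ndarray:
        idx = [self._gene_index[g] for g in gene_list if g in self._gene_index]
        return self.membership[idx].sum(axis=0)

    @classmethod
    def from_pfam_column(cls, genes: pd.DataFrame) -> "DomainAnnotation":
        """Build from an annotation frame with a ';'-separated pfam column."""
        return cls(
            {
                g: ([] if not p else p.split(";"))
                for g, p in zip(genes.gene_id, genes.pfam)
            }
        )


def _raw_pvals(annotation: DomainAnnotation, overlaps: np.ndarray, n: int) -> np.ndarray:
    K = annotation.domain_sizes()
    return stats.hypergeom.sf(overlaps - 1, annotation.N, K, n)


def null_min_p(
    annotation: DomainAnnotation, n: int, n_sims: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Minimum raw hypergeometric p over domains, for random lists of size n."""
    rng = rng_for(seed, "enrichment-null", n)
    K = annotation.domain_sizes()
    N = annotation.N
    mins = np.empty(n_sims)
    # vectorize in chunks: sample index matrices, gather membership, count
    chunk = max(1, min(n_sims, int(2e7 / max(1, n * len(K)))))
    done = 0
    while done < n_sims:
        b = min(chunk, n_sims - done)
        idx = np.empty((b, n), dtype=np.int64)
        for r in range(b):
            idx[r] = rng.choice(N, size=n, replace=False)
        ov = annotation.membership[idx].sum(axis=1)  # b x domains
        pv = stats.hypergeom.sf(ov - 1, N, K[None, :], n)
        mins[done : done + b] = pv.min(axis=1)
        done += b
    return mins


def resample_adjust(
    p_raw: np.ndarray,
    annotation: DomainAnnotation,
    n: int,
    n_sims: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Family-wise adjusted p-values by min-p resampling (monotone in p_raw)."""
    mins = null_min_p(annotation, n, n_sims=n_sims, seed=seed)
    return np.array([float(np.mean(mins <= p)) for p in p_raw])


def enrich_category(
    annotation: DomainAnnotation,
    gene_list: list[str],
    category: str,
    n_sims: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Test every domain for enrichment in one category's gene list."""
    n = len(gene_list)
    overlaps = annotation.overlaps(gene_list)
    K = annotation.domain_sizes()
    p_raw = _raw_pvals(annotation, overlaps, n)
    p_adj = resample_adjust(p_raw, annotation, n, n_sims=n_sims, seed=seed)
    return [
        EnrichmentResult(
            domain=d,
            category=category,
            N=annotation.N,
            K=int(K[j]),
            n=n,
            obs=int(overlaps[j]),
            exp=float(K[j] * n / annotation.N),
            p_raw=float(p_raw[j]),
            p_adj=float(p_adj[j]),
        )
        for j, d in enumerate(annotation.domains)
    ]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "domain": [r.domain for r in results],
            "category": [r.category for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "obs": [r.obs for r in results],
            "exp": [r.exp_rounded for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "stars": [r.stars for r in results],
        }
    )


# --------------------------------------------------------------------------
# paralog retention


@dataclass
class ParalogContrast:
    """SV rates among genes with vs without a retained syntenic paralog."""

    sv_with: int
    total_with: int
    sv_without: int
    total_without: int
    fisher_p: float = np.nan

    @property
    def rate_with(self) -> float:
        return self.sv_with / self.total_with

    @property
    def rate_without(self) -> float:
        return self.sv_without / self.total_without

    @property
    def fold(self) -> float:
        """How many times higher the SV rate is without a retained paralog."""
        if self.rate_with == 0:
            raise ZeroDivisionError("no SV among paralog-retaining genes")
        return self.rate_without / self.rate_with

    @classmethod
    def from_counts(
        cls, sv_with: int, total_with: int, sv_without: int, total_without: int
    ) -> "ParalogContrast":
        if min(total_with, total_without) <= 0:
            raise ValueError("group totals must be > 0")
        table = [
            [sv_with, total_with - sv_with],
            [sv_without, total_without - sv_without],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return cls(sv_with, total_with, sv_without, total_without, fisher_p=float(p))


def paralog_contrast(
    genes: pd.DataFrame, sv_gene_ids: set[str] | list[str]
) -> ParalogContrast:
    """Build the contrast from an annotation frame (paralog_id column) and
    the set of SV genes."""
    sv = set(sv_gene_ids)
    has_par = genes.paralog_id != ""
    is_sv = genes.gene_id.isin(sv)
    return ParalogContrast.from_counts(
        sv_with=int((has_par & is_sv).sum()),
        total_with=int(has_par.sum()),
        sv_without=int((~has_par & is_sv).sum()),
        total_without=int((~has_par).sum()),
    )
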