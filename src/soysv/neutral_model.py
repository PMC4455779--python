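"""Neutral coalescent null for the reference-based site frequency spectrum.

Simulates independent, non-overlapping loci (each the size of one CGH
segment, ~14 kb) under the standard neutral coalescent with infinite-sites
mutation and intra-locus recombination, in the style of Hudson's ms: rows
are sampled chromosomes, "0" is the ancestral state (presence) and "1" the
derived state (absence).

Because the empirical CNV data are an all-by-one comparison against one
reference genotype, the simulated data are ascertained the same way: the
first sampled chromosome is designated the reference, every site where the
reference carries the derived state is discarded, and the spectrum is
built from the derived-allele counts among the remaining chromosomes.
Under this ascertainment the expected spectrum is proportional to
``(n - k) / (n k)`` for k = 1..n-1 (the theta/k neutral spectrum thinned
by the probability ``(n - k)/n`` that the reference is ancestral).

The recombining coalescent tracks, per ancestral lineage, the intervals of
ancestral material it carries and the descendant-leaf set of each
interval; mutations fall on lineages at rate theta/2 per unit ancestral
material and are assigned the leaf set of the interval they hit.  This is
equivalent to placing Poisson mutations on the marginal trees of the
ancestral recombination graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from soysv._rng import rng_for
from soysv.segments_sfs import Spectrum


@dataclass
class PopGenParams:
    """Population-genetic simulation parameters.

    Defaults follow the emulated study's constants: per-bp mutation rate
    mu = 7e-9, locus = one CGH segment of ~14 kb, population-scaled
    per-locus recombination rate rho = 21.54, sample of 42 chromosomes
    (41 test lines + the designated reference; inbred lines as haploids).
    """

    n_chrom: int = 42
    theta_locus: float = 1.0
    rho_locus: float = 21.54
    n_loci: int = 1000
    locus_bp: int = 14_000
    mu: float = 7e-9
    seed: int = 0

    def validate(self) -> None:
        if self.n_chrom < 2:
            raise ValueError("need >= 2 sampled chromosomes")
        if min(self.theta_locus, self.rho_locus) < 0 or self.n_loci < 1:
            raise ValueError("rates must be >= 0 and n_loci >= 1")


@dataclass
class HaplotypeMatrix:
    """One locus: rows = chromosomes (row 0 = reference), cols = sites."""

    matrix: np.ndarray            # uint8, n_chrom x n_sites
    positions: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def estimate_ne(theta_w_per_bp: float, mu: float = 7e-9) -> int:
    """Effective population size from theta_W = 4 Ne mu (truncated)."""
    if theta_w_per_bp <= 0 or mu <= 0:
        raise ValueError("theta_w and mu must be > 0")
    return int(theta_w_per_bp / (4.0 * mu))


def estimate_theta_locus(s_observed: int, n_chrom: int) -> float:
    """Watterson's estimator: theta = S / a_{n-1}."""
    if s_observed < 0:
        raise ValueError("S must be >= 0")
    if n_chrom < 2:
        raise ValueError("n must be >= 2")
    return s_observed / harmonic(n_chrom - 1)


# --------------------------------------------------------------------------
# coalescent simulation


def _simulate_locus_norec(
    n: int, theta: float, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Kingman coalescent without recombination (fast path).

    Level-wise: while k lineages remain, the waiting time is
    Exp(k(k-1)/2); mutations fall as Poisson(theta/2 * k * t), each on a
    uniformly chosen lineage, marking that lineage's current leaf set.
    """
    leafsets: list[np.ndarray] = [np.array([i]) for i in range(n)]
    cols: list[np.ndarray] = []
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        n_mut = rng.poisson(theta / 2.0 * k * t)
        for _ in range(n_mut):
            lin = int(rng.integers(k))
            col = np.zeros(n, dtype=np.uint8)
            col[leafsets[lin]] = 1
            cols.append(col)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        leafsets[i] = np.concatenate([leafsets[i], leafsets[j]])
        del leafsets[j]
        k -= 1
    mat = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.uint8)
    pos = np.sort(rng.random(mat.shape[1]))
    order = np.argsort(rng.random(mat.shape[1]))  # site order is exchangeable
    return HaplotypeMatrix(matrix=mat[:, order] if cols else mat, positions=pos)


def _simulate_locus_rec(
    n: int, theta: float, rho: float, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Coalescent with recombination on the unit interval.

    Each lineage holds a list of (left, right, leafset) ancestral-material
    intervals.  Coalescence at rate C(k,2); recombination on a lineage at
    rate rho/2 times the span between its leftmost and rightmost ancestral
    endpoints, with the breakpoint uniform on that span.  Intervals whose
    leaf set reaches all n samples have found their MRCA and are removed.
    """
    Segs = list[tuple[float, float, frozenset[int]]]
    full = frozenset(range(n))
    lineages: list[Segs] = [[(0.0, 1.0, frozenset([i]))] for i in range(n)]
    muts: list[tuple[float, frozenset[int]]] = []

    def span(segs: Segs) -> float:
        return segs[-1][1] - segs[0][0]

    def material(segs: Segs) -> float:
        return sum(r - l for l, r, _ in segs)

    while lineages:
        k = len(lineages)
        spans = np.array([span(s) for s in lineages])
        mats = np.array([material(s) for s in lineages])
        rate_c = k * (k - 1) / 2.0
        rate_r = rho / 2.0 * spans.sum()
        rate_m = theta / 2.0 * mats.sum()
        total = rate_c + rate_r + rate_m
        if total == 0:
            break
        # waiting time is exponential(total); only event choice matters for
        # the sampled patterns, so the time itself need not be stored
        u = rng.random() * total
        if u < rate_m:
            lin = int(rng.choice(k, p=mats / mats.sum()))
            x = rng.random() * mats[lin]
            for l, r, ls in lineages[lin]:
                if x < r - l:
                    muts.append((l + x, ls))
                    break
                x -= r - l
        elif u < rate_m + rate_r:
            lin = int(rng.choice(k, p=spans / spans.sum()))
            segs = lineages[lin]
            bp = segs[0][0] + rng.random() * span(segs)
            left = [(l, min(r, bp), ls) for l, r, ls in segs if l < bp]
            right = [(max(l, bp), r, ls) for l, r, ls in segs if r > bp]
            if left and right:
                lineages[lin] = left
                lineages.append(right)
            # a breakpoint outside ancestral material splits nothing
        else:
            i, j = sorted(rng.choice(k, size=2, replace=False))
            merged: Segs = []
            events = []
            for l, r, ls in lineages[int(i)] + lineages[int(j)]:
                events.append((l, 0, ls))
                events.append((r, 1, ls))
            events.sort(key=lambda e: (e[0], e[1]))
            open_sets: list[frozenset[int]] = []
            prev = None
            for x, kind, ls in events:
                if prev is not None and x > prev and open_sets:
                    u_ls = frozenset().union(*open_sets)
                    if u_ls != full:
                        merged.append((prev, x, u_ls))
                if kind == 0:
                    open_sets.append(ls)
                else:
                    open_sets.remove(ls)
                prev = x
            # coalesce overlapping fragments that share identical bounds
            del lineages[int(j)]
            if merged:
                lineages[int(i)] = _normalize(merged)
            else:
                del lineages[int(i)]

    if not muts:
        return HaplotypeMatrix(matrix=np.zeros((n, 0), dtype=np.uint8))
    muts.sort(key=lambda m: m[0])
    mat = np.zeros((n, len(muts)), dtype=np.uint8)
    for c, (_, ls) in enumerate(muts):
        mat[list(ls), c] = 1
    return HaplotypeMatrix(
        matrix=mat, positions=np.array([m[0] for m in muts])
    )


def _normalize(segs):
    """Merge abutting intervals with identical leaf sets."""
    segs = sorted(segs)
    out = [segs[0]]
    for l, r, ls in segs[1:]:
        pl, pr, pls = out[-1]
        if l <= pr and ls == pls:
            out[-1] = (pl, max(pr, r), pls)
        else:
            out.append((l, r, ls))
    return out


def simulate_neutral(params: PopGenParams) -> list[HaplotypeMatrix]:
    """Simulate ``n_loci`` independent loci (row 0 = designated reference)."""
    params.validate()
    out = []
    for i in range(params.n_loci):
        rng = rng_for(params.seed, "locus", i)
        if params.rho_locus == 0:
            out.append(_simulate_locus_norec(params.n_chrom, params.theta_locus, rng))
        else:
            out.append(
                _simulate_locus_rec(
                    params.n_chrom, params.theta_locus, params.rho_locus, rng
                )
            )
    return out


# --------------------------------------------------------------------------
# ascertainment and comparison


def unascertained_sfs(haplotypes: Sequence[HaplotypeMatrix]) -> Spectrum:
    """Standard folded-nothing SFS: counts[k-1] = sites with k derived."""
    n = haplotypes[0].matrix.shape[0]
    counts = np.zeros(n - 1, dtype=int)
    for h in haplotypes:
        if h.n_sites:
            ks = h.matrix.sum(axis=0)
            ks = ks[(ks > 0) & (ks < n)]
            counts += np.bincount(ks, minlength=n)[1:n]
    return Spectrum(counts=counts, label="simulated-unascertained")


def ascertain_reference(haplotypes: Sequence[HaplotypeMatrix]) -> Spectrum:
    """Reference-based spectrum: drop sites derived in row 0; count derived
    alleles among the remaining rows (k = 1..n-1)."""
    n = haplotypes[0].matrix.shape[0]
    counts = np.zeros(n - 1, dtype=int)
    for h in haplotypes:
        if not h.n_sites:
            continue
        keep = h.matrix[0] == 0
        ks = h.matrix[1:, keep].sum(axis=0)
        ks = ks[ks > 0]
        counts += np.bincount(ks, minlength=n)[1 : n]
    return Spectrum(counts=counts, label="simulated-ascertained")


def expected_ascertained_shape(n: int) -> np.ndarray:
    """Normalized expected rSFS (n - k)/(n k), k = 1..n-1."""
    k = np.arange(1, n)
    w = (n - k) / (n * k)
    return w / w.sum()


@dataclass
class SpectrumComparison:
    per_class_diff: np.ndarray    # empirical - simulated proportions
    singleton_excess: float
    chi2_distance: float
    p_value: float


def compare_spectra(
    empirical: Spectrum,
    simulated: Spectrum,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> SpectrumComparison:
    """Compare two spectra as proportions.

    Reports per-class differences, the singleton excess, and a chi-square
    distance with a Monte-Carlo p-value obtained by resampling
    ``empirical.total``-sized multinomial draws from the simulated
    proportions.
    """
    if empirical.n != simulated.n:
        raise ValueError("spectra span different k ranges")
    p_emp = empirical.proportions()
    p_sim = simulated.proportions()
    diff = p_emp - p_sim

    def chi2(p: np.ndarray) -> float:
        m = p_sim > 0
        return float(np.sum((p[m] - p_sim[m]) ** 2 / p_sim[m]))

    obs = chi2(p_emp)
    rng = rng_for(seed, "spectrum-compare")
    n_seg = empirical.total
    draws = rng.multinomial(n_seg, p_sim, size=n_resamples) / n_seg
    m = p_sim > 0
    null = np.sum((draws[:, m] - p_sim[m]) ** 2 / p_sim[m], axis=1)
    p = float((np.sum(null >= obs) + 1) / (n_resamples + 1))
    return SpectrumComparison(
        per_class_diff=diff,
        singleton_excess=float(diff[0]),
        chi2_distance=obs,
        p_value=p,
    )


def per_locus_class_counts(
    haplotypes: Sequence[HaplotypeMatrix], ascertained: bool
) -> np.ndarray:
    """Per-locus spectrum counts (loci x classes k=1..n-1)."""
    n = haplotypes[0].matrix.shape[0]
    out = np.zeros((len(haplotypes), n - 1))
    for l, h in enumerate(haplotypes):
        if not h.n_sites:
            continue
        if ascertained:
            keep = h.matrix[0] == 0
            ks = h.matrix[1:, keep].sum(axis=0)
            ks = ks[ks > 0]
        else:
            ks = h.matrix.sum(axis=0)
            ks = ks[(ks > 0) & (ks < n)]
        out[l] = np.bincount(ks, minlength=n)[1:n]
    return out


def sfs_class_z_scores(
    haplotypes: Sequence[HaplotypeMatrix],
    expected_proportions: np.ndarray,
    ascertained: bool = False,
) -> np.ndarray:
    """Per-class z-scores of the observed spectrum against an expected shape.

    Sites within a locus share one genealogy, so the Monte-Carlo standard
    error of each class proportion is the cluster-robust (ratio-estimator)
    SE over loci, not the naive multinomial one.
    """
    cl = per_locus_class_counts(haplotypes, ascertained)
    total = cl.sum()
    if total == 0:
        raise ValueError("no segregating sites")
    props = cl.sum(axis=0) / total
    t_l = cl.sum(axis=1)
    L = len(cl)
    z = np.zeros(len(props))
    for k in range(len(props)):
        resid = cl[:, k] - props[k] * t_l
        se = np.sqrt(L * resid.var(ddof=1)) / total
        if se > 0:
            z[k] = (props[k] - expected_proportions[k]) / se
    return z


def watterson_theta_check(haplotypes: Sequence[HaplotypeMatrix]) -> float:
    """Mean segregating sites per locus (E[S] = theta * a_{n-1})."""
    return float(np.mean([h.n_sites for h in haplotypes]))


def write_ms(haplotypes: Sequence[HaplotypeMatrix], path, params: PopGenParams) -> None:
    """Write ms-style text output (// blocks, segsites, positions, 0/1 rows)."""
    with open(path, "w") as fh:
        fh.write(
            f"soysv-coalescent {params.n_chrom} {params.n_loci} "
            f"-t {params.theta_locus} -r {params.rho_locus}\n{params.seed}\n"
        )
        for h in haplotypes:
            fh.write("\n//\n")
            fh.write(f"segsites: {h.n_sites}\n")
            if h.n_sites:
                pos = " ".join(f"{p:.5f}" for p in h.positions)
                fh.write(f"positions: {pos}\n")
                for row in h.matrix:
                    fh.write("".join(str(int(v)) for v in row) + "\n")
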