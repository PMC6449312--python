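"""Diversity, differentiation and hierarchical variance partitioning.

* Per-site nucleotide diversity: with n called haplotypes (2 × called
  diploids) and alt-allele count j, pi = 2 j (n - j) / (n (n - 1)) — the
  unbiased average pairwise difference among the sampled haplotypes.
* Weir & Cockerham (1984) theta: per-site variance components a (among
  populations), b (among individuals within populations) and c (within
  individuals, the heterozygosity term) for diploid biallelic data.  The
  genome-wide estimate is the ratio of sums sum(a) / sum(a + b + c).
* AMOVA: nested two-level analysis of molecular variance on
  allele-difference distances with permutation tests for F_CT, F_SC and
  F_ST (each statistic has its own permutation scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


@dataclass
class DiversityResult:
    per_site: np.ndarray  # NaN where fewer than 2 called haplotypes
    mean_pi: float
    n_sites: int  # sites contributing to the mean
    n_excluded: int


@dataclass
class FstResult:
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    per_site_theta: np.ndarray  # NaN where a+b+c == 0
    genomewide_fst: float
    populations: list
    n_excluded: int  # sites skipped entirely (fewer than 2 pops called)


@dataclass
class AmovaResult:
    sigma_among_groups: float
    sigma_among_pops_within: float
    sigma_within: float
    F_CT: float
    F_SC: float
    F_ST: float
    p_F_CT: float | None
    p_F_SC: float | None
    p_F_ST: float | None
    df: tuple  # (among groups, among pops within, within)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(
    m: GenotypeMatrix, sample_subset=None
) -> DiversityResult:
    calls = m.calls
    if sample_subset is not None:
        idx = [m.sample_index(s) if isinstance(s, str) else int(s) for s in sample_subset]
        if not idx:
            raise ValueError("empty sample subset")
        calls = calls[idx, :]
    called = calls != MISSING
    n_hap = 2 * called.sum(axis=0)
    j = np.where(called, calls, 0).sum(axis=0)
    ok = n_hap >= 2
    pi = np.full(m.n_snps, np.nan)
    n, jj = n_hap[ok].astype(float), j[ok].astype(float)
    pi[ok] = 2.0 * jj * (n - jj) / (n * (n - 1.0))
    return DiversityResult(
        per_site=pi,
        mean_pi=float(np.nanmean(pi)) if ok.any() else float("nan"),
        n_sites=int(ok.sum()),
        n_excluded=int((~ok).sum()),
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

def weir_cockerham_fst(m: GenotypeMatrix, partition: dict) -> FstResult:
    """Weir–Cockerham theta for an arbitrary number of populations.

    ``partition`` maps sample id -> population label.  Sites where fewer
    than two populations have a called diploid are excluded; sites
    monomorphic across all populations contribute zero components.
    """
    pops = sorted(set(partition.values()))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    pop_rows = {
        p: np.asarray([i for i, s in enumerate(m.samples) if partition.get(s) == p])
        for p in pops
    }
    for p, rows in pop_rows.items():
        if len(rows) == 0:
            raise ValueError(f"population {p!r} has no samples")

    L = m.n_snps
    n_i = np.zeros((len(pops), L))
    p_i = np.zeros((len(pops), L))
    h_i = np.zeros((len(pops), L))
    for k, p in enumerate(pops):
        sub = m.calls[pop_rows[p], :]
        called = sub != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        het = (sub == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n_i[k] = n
            p_i[k] = np.where(n > 0, alt / (2.0 * n), np.nan)
            h_i[k] = np.where(n > 0, het / n, np.nan)

    pop_called = n_i > 0
    r = pop_called.sum(axis=0).astype(float)
    usable = r >= 2
    a = np.zeros(L)
    b = np.zeros(L)
    c = np.zeros(L)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_i0 = np.where(pop_called, n_i, 0.0)
        p_i0 = np.where(pop_called, p_i, 0.0)
        h_i0 = np.where(pop_called, h_i, 0.0)
        n_tot = n_i0.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (n_i0**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (n_i0 * p_i0).sum(axis=0) / n_tot
        s2 = (n_i0 * (p_i0 - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i0 * h_i0).sum(axis=0) / n_tot
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        av = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        bv = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        cv = hbar / 2.0
    good = usable & np.isfinite(av) & np.isfinite(bv) & np.isfinite(cv)
    a[good], b[good], c[good] = av[good], bv[good], cv[good]
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    total = denom[good].sum()
    fst = float(a[good].sum() / total) if total != 0 else float("nan")
    return FstResult(
        a=a, b=b, c=c, per_site_theta=theta, genomewide_fst=fst,
        populations=pops, n_excluded=int((~usable).sum()),
    )


def pairwise_fst_matrix(m: GenotypeMatrix, partition: dict) -> pd.DataFrame:
    """All pairwise genome-wide FST values (Table-style layout)."""
    pops = sorted(set(partition.values()))
    out = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, p in enumerate(pops):
        for q in pops[i + 1 :]:
            sub = {s: l for s, l in partition.items() if l in (p, q)}
            keep = [s for s in m.samples if s in sub]
            res = weir_cockerham_fst(m.subset_samples(keep), sub)
            out.loc[p, q] = out.loc[q, p] = res.genomewide_fst
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def amova_distance_matrix(m: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-difference distances: sum over co-called sites of
    |g_i - g_j|, normalised by co-called count and rescaled to the full
    site count (comparability under missingness)."""
    calls = m.calls.astype(np.float64)
    called = (calls != MISSING).astype(np.float64)
    g = np.where(calls == MISSING, 0.0, calls)
    n_comp = called @ called.T
    # sum |gi - gj| over co-called sites via the dosage-class indicator trick
    ind = [(m.calls == d).astype(np.float64) for d in (0, 1, 2)]
    diff = np.zeros_like(n_comp)
    for di in range(3):
        for dj in range(3):
            if di == dj:
                continue
            diff += abs(di - dj) * (ind[di] @ ind[dj].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_comp > 0, diff / n_comp, np.nan) * m.n_snps
    np.fill_diagonal(d, 0.0)
    return d


def _amova_components(d2: np.ndarray, group_of: np.ndarray, pop_of: np.ndarray):
    """Variance components of a two-level nested AMOVA from squared distances."""
    N = d2.shape[0]
    pops, pop_idx = np.unique(pop_of, return_inverse=True)
    groups, grp_idx = np.unique(group_of, return_inverse=True)
    P, G = len(pops), len(groups)

    def ssd(idx_sets):
        tot = 0.0
        for idx in idx_sets:
            if len(idx) == 0:
                continue
            sub = d2[np.ix_(idx, idx)]
            tot += sub.sum() / (2.0 * len(idx))
        return tot

    all_idx = [np.arange(N)]
    pop_sets = [np.flatnonzero(pop_idx == k) for k in range(P)]
    grp_sets = [np.flatnonzero(grp_idx == k) for k in range(G)]
    ssd_total = ssd(all_idx)
    ssd_wp = ssd(pop_sets)                     # within populations
    ssd_wg = ssd(grp_sets)                     # within groups
    ssd_ap = ssd_wg - ssd_wp                   # among pops within groups
    ssd_ag = ssd_total - ssd_wg                # among groups

    n_p = np.array([len(s) for s in pop_sets], dtype=float)
    grp_of_pop = np.array([grp_idx[s[0]] for s in pop_sets])
    n_g = np.array([len(s) for s in grp_sets], dtype=float)

    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P
    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp

    if df_ap > 0:
        sum_np2_over_ng = sum(
            (n_p[grp_of_pop == g] ** 2).sum() / n_g[g] for g in range(G)
        )
        n1 = (N - sum_np2_over_ng) / df_ap
        ms_ap = ssd_ap / df_ap
        sigma_b = (ms_ap - sigma_c) / n1 if n1 > 0 else 0.0
    else:
        sigma_b = 0.0
    if df_ag > 0:
        sum_np2_over_ng = sum(
            (n_p[grp_of_pop == g] ** 2).sum() / n_g[g] for g in range(G)
        )
        n2 = (sum_np2_over_ng - (n_p**2).sum() / N) / df_ag
        n3 = (N - (n_g**2).sum() / N) / df_ag
        ms_ag = ssd_ag / df_ag
        sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
    else:
        sigma_a = float("nan")
    return sigma_a, sigma_b, sigma_c, (df_ag, df_ap, df_wp)


def _f_stats(sa, sb, sc):
    # components floored at 0 for the F statistics; raw values kept in output
    a = max(sa, 0.0) if np.isfinite(sa) else np.nan
    b, c = max(sb, 0.0), max(sc, 0.0)
    tot = (0.0 if np.isnan(a) else a) + b + c
    F_CT = a / tot if tot > 0 and np.isfinite(a) else (np.nan if np.isnan(a) else 0.0)
    F_SC = b / (b + c) if (b + c) > 0 else 0.0
    F_ST = ((0.0 if np.isnan(a) else a) + b) / tot if tot > 0 else 0.0
    return F_CT, F_SC, F_ST


def amova(
    m: GenotypeMatrix,
    groups: dict,
    pops: dict,
    n_perm: int = 1023,
    seed: int = 0,
) -> AmovaResult:
    """Two-level nested AMOVA with permutation tests.

    ``groups`` and ``pops`` map sample id -> label, with each population
    nested inside exactly one group.  Permutation schemes: F_CT permutes
    whole populations among groups, F_SC permutes samples among
    populations within their group, F_ST permutes samples among
    populations freely.  p = (hits + 1) / (n_perm + 1).
    """
    samples = m.samples
    group_of = np.asarray([groups[s] for s in samples])
    pop_of = np.asarray([pops[s] for s in samples])
    for p in np.unique(pop_of):
        gset = np.unique(group_of[pop_of == p])
        if len(gset) != 1:
            raise ValueError(f"population {p!r} spans several groups")
    d2 = amova_distance_matrix(m)
    sa, sb, sc, df = _amova_components(d2, group_of, pop_of)
    F_CT, F_SC, F_ST = _f_stats(sa, sb, sc)
    n_groups = len(np.unique(group_of))

    rng = np.random.default_rng(seed)
    p_ct = p_sc = p_st = None
    if n_perm > 0:
        # F_ST: permute samples among populations
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(samples))
            f = _f_stats(*_amova_components(d2, group_of[perm], pop_of[perm])[:3])[2]
            hits += f >= F_ST
        p_st = (hits + 1) / (n_perm + 1)
        # F_SC: permute samples among populations within groups
        hits = 0
        for _ in range(n_perm):
            pop_perm = pop_of.copy()
            for g in np.unique(group_of):
                idx = np.flatnonzero(group_of == g)
                pop_perm[idx] = pop_perm[rng.permutation(idx)]
            f = _f_stats(*_amova_components(d2, group_of, pop_perm)[:3])[1]
            hits += f >= F_SC
        p_sc = (hits + 1) / (n_perm + 1)
        # F_CT: permute whole populations among groups
        if n_groups >= 2:
            pop_labels = np.unique(pop_of)
            grp_of_pop = {p: group_of[pop_of == p][0] for p in pop_labels}
            hits = 0
            for _ in range(n_perm):
                shuffled = rng.permutation([grp_of_pop[p] for p in pop_labels])
                new_map = dict(zip(pop_labels, shuffled))
                new_groups = np.asarray([new_map[p] for p in pop_of])
                f = _f_stats(*_amova_components(d2, new_groups, pop_of)[:3])[0]
                hits += f >= F_CT
            p_ct = (hits + 1) / (n_perm + 1)

    return AmovaResult(
        sigma_among_groups=sa,
        sigma_among_pops_within=sb,
        sigma_within=sc,
        F_CT=F_CT if n_groups >= 2 else float("nan"),
        F_SC=F_SC,
        F_ST=F_ST,
        p_F_CT=p_ct,
        p_F_SC=p_sc,
        p_F_ST=p_st,
        df=df,
    )
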