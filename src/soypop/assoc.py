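"""Conditional case-control association scan, LD and haplotype blocks.

The scan fits, per SNP, a Firth-penalised logistic regression of a
binary phenotype on the SNP's additive dosage plus a fixed set of
conditioning-SNP dosages (population-structure covariates chosen for
extreme between-group frequency differentials, the conditional-GWAS
design for structured germplasm).  Firth's Jeffreys-prior penalty keeps
estimates finite under complete separation — routine for domestication
phenotypes — and p-values come from the penalised likelihood-ratio
test.  Family-wise error is controlled by Bonferroni correction.

Pairwise LD (r-squared and D') is estimated from unphased genotypes by
the standard two-locus EM, with a profile-likelihood confidence
interval for |D'| on a grid; blocks are called with the Gabriel et al.
confidence-interval rules (0.70/0.98 strong LD, 0.90 recombination,
95% informative-pair threshold, longest-first resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .genio import MISSING, GenotypeMatrix


@dataclass
class ConditioningSet:
    snp_ids: list
    perfect_snp: str | None = None
    selection: pd.DataFrame | None = None  # group, snp id, frequency differential

    @property
    def all_ids(self) -> list:
        ids = list(self.snp_ids)
        if self.perfect_snp is not None and self.perfect_snp not in ids:
            ids.append(self.perfect_snp)
        return ids


@dataclass
class AssocResult:
    table: pd.DataFrame  # chrom, pos, id, effect, p, neg_log10_p, significant, converged
    trait: str
    adjusted_alpha: float
    threshold_neg_log10: float
    conditioning: list = field(default_factory=list)


@dataclass
class LdBlock:
    chrom: str
    start: int
    end: int
    snp_ids: list


# ---------------------------------------------------------------------------
# conditioning-SNP selection
# ---------------------------------------------------------------------------

def select_conditioning_snps(
    m: GenotypeMatrix,
    group_labels: dict,
    species: dict | None = None,
    n_per_group: int = 10,
) -> ConditioningSet:
    """Pick structure covariates: per group, the SNPs with the largest
    |freq in group - freq elsewhere|; plus, if present, one perfect
    domestication SNP (alt fixed in one species, absent in the other).

    Ties are broken toward the larger minor-allele count, then the
    smaller SNP id.
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    snp_ids = np.asarray(m.snp_ids)
    called = m.calls != MISSING
    alt = np.where(called, m.calls, 0)
    total_alt = alt.sum(axis=0)
    total_n = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        overall = np.where(total_n > 0, total_alt / total_n, np.nan)
    mac = np.minimum(total_alt, total_n - total_alt)  # minor allele count

    perfect = None
    if species is not None:
        sp = np.asarray([species.get(s, "unknown") for s in m.samples])
        dom_rows = sp == "max"
        wild_rows = sp == "soja"
        if dom_rows.any() and wild_rows.any():
            fd = _group_freq(m, dom_rows)
            fw = _group_freq(m, wild_rows)
            with np.errstate(invalid="ignore"):
                hit = ((fd == 1.0) & (fw == 0.0)) | ((fd == 0.0) & (fw == 1.0))
            hit &= np.isfinite(fd) & np.isfinite(fw)
            if hit.any():
                perfect = str(min(snp_ids[hit]))

    rows = []
    chosen: list = []
    for g in groups:
        in_g = np.asarray([group_labels.get(s) == g for s in m.samples])
        out_g = np.asarray([s in group_labels and group_labels[s] != g for s in m.samples])
        if not in_g.any() or not out_g.any():
            continue
        diff = np.abs(_group_freq(m, in_g) - _group_freq(m, out_g))
        diff = np.where(np.isfinite(diff), diff, -1.0)
        order = sorted(
            range(m.n_snps), key=lambda j: (-diff[j], -mac[j], snp_ids[j])
        )
        for j in order[:n_per_group]:
            rows.append((g, snp_ids[j], float(diff[j])))
            if snp_ids[j] not in chosen and snp_ids[j] != perfect:
                chosen.append(snp_ids[j])
    sel = pd.DataFrame(rows, columns=["group", "snp_id", "freq_differential"])
    return ConditioningSet(snp_ids=chosen, perfect_snp=perfect, selection=sel)


def _group_freq(m: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    sub = m.calls[rows, :]
    called = sub != MISSING
    n = 2 * called.sum(axis=0)
    a = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, a / n, np.nan)


# ---------------------------------------------------------------------------
# Firth-penalised logistic regression
# ---------------------------------------------------------------------------

def _firth_loglik(X, y, beta):
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = float(y @ np.log(p) + (1.0 - y) @ np.log1p(-p))
    W = p * (1.0 - p)
    XtWX = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, p, XtWX
    return ll + 0.5 * logdet, p, XtWX


def firth_logistic(X, y, max_iter: int = 60, tol: float = 1e-8, fixed=None):
    """Fit Firth-penalised logistic regression.

    ``fixed`` lists coefficient indices constrained to 0 while the
    Jeffreys penalty is still evaluated on the full design — the profile
    penalised likelihood used by the penalised likelihood-ratio test
    (the null fit of a tested coefficient lives in the same penalised
    model as the alternative, not in a smaller one).

    Returns (beta, penalised loglik, converged flag).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    free = np.ones(k, dtype=bool)
    if fixed is not None:
        free[list(fixed)] = False
    beta = np.zeros(k)
    ll, p, XtWX = _firth_loglik(X, y, beta)
    for _ in range(max_iter):
        W = p * (1.0 - p)
        XW = X * W[:, None]
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            return beta, ll, False
        # hat diagonal h_i = w_i x_i' (X'WX)^{-1} x_i (full design)
        h = np.einsum("ij,jk,ik->i", XW, XtWX_inv, X)
        resid = y - p + h * (0.5 - p)
        U = X.T @ resid
        Uf = U[free]
        try:
            step_f = np.linalg.solve(XtWX[np.ix_(free, free)], Uf)
        except np.linalg.LinAlgError:
            return beta, ll, False
        step = np.zeros(k)
        step[free] = step_f
        # step-halving to guarantee ascent of the penalised likelihood
        for _half in range(20):
            beta_new = beta + step
            ll_new, p_new, XtWX_new = _firth_loglik(X, y, beta_new)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            return beta, ll, False
        gain = ll_new - ll
        beta, ll, p, XtWX = beta_new, ll_new, p_new, XtWX_new
        if abs(gain) < tol and np.max(np.abs(Uf)) < 1e-3:
            return beta, ll, True
    return beta, ll, True


def logistic_scan(
    m: GenotypeMatrix,
    phenotype,
    conditioning: ConditioningSet | None = None,
    trait: str = "trait",
    alpha: float = 0.01,
    exclude_perfect: bool = False,
    n_tests: int | None = None,
) -> AssocResult:
    """Per-SNP Firth logistic scan conditional on covariate SNPs.

    ``phenotype`` is a 0/1 array or Series aligned to ``m.samples`` (NaN
    allowed; those samples are dropped).  Conditioning SNPs are excluded
    from the scanned set; with ``exclude_perfect`` the perfect
    domestication SNP is dropped from the covariates as well (the scan
    for the domestication trait itself).  Significance is Bonferroni at
    ``alpha`` over the number of scanned SNPs unless ``n_tests`` says
    otherwise.
    """
    pheno = pd.Series(phenotype, index=m.samples) if not isinstance(
        phenotype, pd.Series
    ) else phenotype.reindex(m.samples)
    keep = pheno.notna().to_numpy()
    y = pheno.to_numpy(dtype=float)[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has a single class after NA exclusion")

    cond_ids: list = []
    if conditioning is not None:
        cond_ids = list(conditioning.snp_ids)
        if not exclude_perfect and conditioning.perfect_snp is not None:
            cond_ids.append(conditioning.perfect_snp)
    id_to_col = {sid: j for j, sid in enumerate(m.snp_ids)}
    cond_cols = [id_to_col[s] for s in cond_ids]
    calls = m.calls[keep, :].astype(np.float64)
    if (calls[:, cond_cols] == MISSING).any():
        raise ValueError("conditioning genotypes must be complete")
    C = np.column_stack([np.ones(keep.sum())] + [calls[:, c] for c in cond_cols])

    excluded = set(cond_cols)
    if conditioning is not None and conditioning.perfect_snp is not None:
        excluded.add(id_to_col[conditioning.perfect_snp])
    scan_cols = [j for j in range(m.n_snps) if j not in excluded]
    n_eff = n_tests if n_tests is not None else len(scan_cols)
    adj_alpha, neg_thr = bonferroni_threshold(alpha, n_eff)

    X = np.empty((len(y), C.shape[1] + 1))
    X[:, :-1] = C
    eff = np.full(m.n_snps, np.nan)
    pval = np.full(m.n_snps, np.nan)
    conv = np.zeros(m.n_snps, dtype=bool)
    last = C.shape[1]  # index of the scanned-SNP coefficient
    for j in scan_cols:
        g = calls[:, j]
        miss = g == MISSING
        if miss.any():
            Xj = X[~miss]
            Xj[:, -1] = g[~miss]
            yj = y[~miss]
            if len(np.unique(yj)) < 2:
                continue
        else:
            Xj = X
            Xj[:, -1] = g
            yj = y
        beta, ll_full, ok = firth_logistic(Xj, yj)
        # profile null: same design and penalty, SNP coefficient pinned at 0
        _, ll_red_j, ok_red = firth_logistic(Xj, yj, fixed=[last])
        if not (ok and ok_red) or not np.isfinite(ll_full) or not np.isfinite(ll_red_j):
            continue
        stat = max(2.0 * (ll_full - ll_red_j), 0.0)
        eff[j] = beta[-1]
        pval[j] = sp_stats.chi2.sf(stat, df=1)
        conv[j] = True

    with np.errstate(divide="ignore"):
        nlp = np.where(pval > 0, -np.log10(pval), np.inf)
    table = m.snps[["chrom", "pos", "id"]].copy()
    table["effect"] = eff
    table["p"] = pval
    table["neg_log10_p"] = nlp
    table["significant"] = pval < adj_alpha
    table["converged"] = conv
    table["scanned"] = [j in set(scan_cols) for j in range(m.n_snps)]
    return AssocResult(
        table=table,
        trait=trait,
        adjusted_alpha=adj_alpha,
        threshold_neg_log10=neg_thr,
        conditioning=cond_ids,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> tuple[float, float]:
    """Bonferroni-adjusted alpha and its -log10."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    adjusted = alpha / n_tests
    return adjusted, float(-np.log10(adjusted))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

class EmError(RuntimeError):
    pass


def _haplotype_em(ga, gb, max_iter: int = 200, tol: float = 1e-10):
    """Two-locus haplotype frequencies from unphased dosages (EM).

    Returns (p11, p10, p01, p00) for haplotypes (alt-alt, alt-ref,
    ref-alt, ref-ref) and the count table used.
    """
    both = (ga != MISSING) & (gb != MISSING)
    a, b = ga[both], gb[both]
    n = len(a)
    if n == 0:
        raise EmError("no co-called samples")
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((a == i) & (b == j))
    pA = a.mean() / 2.0
    pB = b.mean() / 2.0
    # start at linkage equilibrium
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    h = np.clip(h, 1e-12, None)
    h /= h.sum()
    n_dh = counts[1, 1]  # double heterozygotes: phase-ambiguous
    for _ in range(max_iter):
        # known haplotype counts from unambiguous genotypes
        c11 = (
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
        )
        c10 = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
        c01 = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
        c00 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = np.array(
            [
                c11 + n_dh * w,
                c10 + n_dh * (1 - w),
                c01 + n_dh * (1 - w),
                c00 + n_dh * w,
            ]
        )
        new /= new.sum()
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    return h, counts


def ld_pair(
    m: GenotypeMatrix, snp_a, snp_b, ci_grid: int = 101, ci_level: float = 0.90
):
    """r², D' and a profile-likelihood CI for |D'| between two SNPs."""
    ja = m.snp_ids.index(snp_a) if isinstance(snp_a, str) else int(snp_a)
    jb = m.snp_ids.index(snp_b) if isinstance(snp_b, str) else int(snp_b)
    h, counts = _haplotype_em(m.calls[:, ja], m.calls[:, jb])
    p11, p10, p01, p00 = h
    pA = p11 + p10
    pB = p11 + p01
    if not (0 < pA < 1) or not (0 < pB < 1):
        raise EmError("monomorphic locus among co-called samples")
    D = p11 - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    sign = 1.0 if D >= 0 else -1.0

    # profile likelihood of |D'| on a grid, allele frequencies fixed
    grid = np.linspace(0.0, 1.0, ci_grid)
    logl = np.full(ci_grid, -np.inf)
    for gi, dp in enumerate(grid):
        Dg = sign * dp * dmax
        q11 = pA * pB + Dg
        q10 = pA * (1 - pB) - Dg
        q01 = (1 - pA) * pB - Dg
        q00 = (1 - pA) * (1 - pB) + Dg
        if min(q11, q10, q01, q00) < -1e-12:
            continue
        q = np.clip([q11, q10, q01, q00], 1e-12, None)
        logl[gi] = _genotype_loglik(counts, q)
    w = np.exp(logl - logl.max())
    w /= w.sum()
    cdf = np.cumsum(w)
    tail = (1.0 - ci_level) / 2.0
    lo = float(grid[int(np.searchsorted(cdf, tail))])
    hi = float(grid[min(int(np.searchsorted(cdf, 1.0 - tail)), ci_grid - 1)])
    return float(r2), float(dprime), (lo, hi)


def _genotype_loglik(counts, q):
    """Multinomial log-likelihood of the 3×3 genotype table given
    haplotype frequencies q = (p11, p10, p01, p00) under HWE."""
    p11, p10, p01, p00 = q
    probs = np.empty((3, 3))
    # genotype (i alt alleles at A, j at B); haplotypes pair independently
    probs[2, 2] = p11 * p11
    probs[2, 1] = 2 * p11 * p10
    probs[2, 0] = p10 * p10
    probs[1, 2] = 2 * p11 * p01
    probs[1, 1] = 2 * (p11 * p00 + p10 * p01)
    probs[1, 0] = 2 * p10 * p00
    probs[0, 2] = p01 * p01
    probs[0, 1] = 2 * p01 * p00
    probs[0, 0] = p00 * p00
    probs = np.clip(probs, 1e-300, None)
    return float((counts * np.log(probs)).sum())


def gabriel_blocks(
    m: GenotypeMatrix,
    region_snps=None,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    informative_frac: float = 0.95,
) -> list:
    """Gabriel confidence-interval LD blocks over position-ordered SNPs.

    A pair is strong LD if its |D'| CI is [>= strong_low, >= strong_high]
    and strong recombination if the CI upper bound < recomb_high; a block
    [i..j] needs a strong-LD outer pair and >= ``informative_frac`` of its
    informative pairs in strong LD.  Overlaps resolve longest-first.
    """
    if region_snps is None:
        cols = list(range(m.n_snps))
    else:
        cols = [
            m.snp_ids.index(s) if isinstance(s, str) else int(s) for s in region_snps
        ]
    pos = m.snps["pos"].to_numpy()
    cols = sorted(cols, key=lambda j: pos[j])
    k = len(cols)
    if k < 2:
        return []
    strong = np.zeros((k, k), dtype=bool)
    informative = np.zeros((k, k), dtype=bool)
    for x in range(k):
        for y in range(x + 1, k):
            try:
                _, _, (lo, hi) = ld_pair(m, cols[x], cols[y])
            except EmError:
                continue
            if lo >= strong_low and hi >= strong_high:
                strong[x, y] = informative[x, y] = True
            elif hi < recomb_high:
                informative[x, y] = True  # strong recombination

    candidates = []
    for x in range(k):
        for y in range(x + 1, k):
            if not strong[x, y]:
                continue
            sub_s = strong[x : y + 1, x : y + 1].sum()
            sub_i = informative[x : y + 1, x : y + 1].sum()
            if sub_i > 0 and sub_s / sub_i >= informative_frac:
                span = pos[cols[y]] - pos[cols[x]]
                candidates.append((span, y - x, x, y))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    taken = np.zeros(k, dtype=bool)
    blocks = []
    snp_ids = m.snp_ids
    for _span, _w, x, y in candidates:
        if taken[x : y + 1].any():
            continue
        taken[x : y + 1] = True
        members = [snp_ids[cols[i]] for i in range(x, y + 1)]
        blocks.append(
            LdBlock(
                chrom=str(m.snps["chrom"].iloc[cols[x]]),
                start=int(pos[cols[x]]),
                end=int(pos[cols[y]]),
                snp_ids=members,
            )
        )
    blocks.sort(key=lambda b: b.start)
    return blocks


# ---------------------------------------------------------------------------
# domestication-SNP partition
# ---------------------------------------------------------------------------

def partition_by_association(
    assoc: AssocResult, neg_log10_cut: float = 17.0
) -> tuple[list, list]:
    """Split SNPs into domestication-associated (−log10 p strictly above
    the cut) and the weakly/not associated remainder (NA-flagged SNPs go
    to the remainder)."""
    t = assoc.table
    nlp = t["neg_log10_p"].to_numpy()
    dom_mask = np.nan_to_num(nlp, nan=-1.0) > neg_log10_cut
    ids = t["id"].to_numpy()
    dom = list(ids[dom_mask])
    neutral = list(ids[~dom_mask])
    return dom, neutral
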