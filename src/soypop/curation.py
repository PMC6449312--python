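"""Duplicate/near-isogenic accession removal and hybrid screening.

Redundancy is measured as the pairwise genotype inconsistency rate —
the fraction of discordant calls among sites called in both samples.
Pairs below a cutoff (default 1.25%) are linked, connected components of
the resulting graph form redundancy groups, and one representative per
group is retained (recurrent parent if annotated, else call-rate
preference).  Hybrids are flagged from model-based ancestry fractions:
a sample whose domesticated-cluster fraction falls inside a closed
window (default [0.30, 0.70]) is classified as a wild × domesticated
hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, SampleStats


class UndefinedComparisonError(ValueError):
    """No co-called site between the two samples."""


@dataclass
class InconsistencyResult:
    pair: tuple
    inconsistency: float
    n_compared: int


@dataclass
class RedundancyGroups:
    groups: list  # list of frozensets of sample ids (size >= 2)
    retained: dict = field(default_factory=dict)  # group index -> sample id
    removed: list = field(default_factory=list)

    @property
    def all_grouped(self) -> set:
        return set().union(*self.groups) if self.groups else set()


@dataclass
class HybridCalls:
    fractions: pd.Series  # sample -> domesticated-cluster ancestry fraction
    is_hybrid: pd.Series
    window: tuple

    @property
    def hybrid_ids(self) -> list:
        return self.is_hybrid[self.is_hybrid].index.tolist()


def pairwise_inconsistency(m: GenotypeMatrix, i, j) -> InconsistencyResult:
    """Discordance rate between two samples over co-called sites.

    Any dosage difference (including het vs homozygote) counts as one
    discordance; sites missing in either sample are excluded.
    """
    if isinstance(i, str):
        i = m.sample_index(i)
    if isinstance(j, str):
        j = m.sample_index(j)
    gi, gj = m.calls[i], m.calls[j]
    both = (gi != MISSING) & (gj != MISSING)
    n = int(both.sum())
    if n == 0:
        raise UndefinedComparisonError(
            f"samples {m.samples[i]!r} and {m.samples[j]!r} share no called site"
        )
    mismatches = int((gi[both] != gj[both]).sum())
    return InconsistencyResult(
        pair=(m.samples[i], m.samples[j]),
        inconsistency=mismatches / n,
        n_compared=n,
    )


def inconsistency_matrix(m: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs inconsistency and co-called counts (vectorised).

    Returns (rate, n_compared) arrays of shape (n, n); rate is NaN where
    no site is co-called.
    """
    calls = m.calls.astype(np.int16)
    called = (calls != MISSING).astype(np.float32)
    g = np.where(calls == MISSING, 0, calls).astype(np.float32)
    n_comp = called @ called.T
    # count matches per dosage class, then mismatches = co-called - matches
    matches = np.zeros_like(n_comp)
    for d in (0, 1, 2):
        ind = ((calls == d).astype(np.float32))
        matches += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_comp > 0, (n_comp - matches) / n_comp, np.nan)
    return rate, n_comp.astype(np.int64)


def find_redundancy_groups(
    m: GenotypeMatrix, cutoff: float = 0.0125, min_compared: int = 100
) -> RedundancyGroups:
    """Single-linkage groups of samples linked at inconsistency < cutoff.

    Pairs with fewer than ``min_compared`` co-called sites are treated as
    uncomparable and never merged.  Only components of size >= 2 are
    reported; singletons are untouched.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rate, n_comp = inconsistency_matrix(m)
    n = m.n_samples
    with np.errstate(invalid="ignore"):
        adj = (rate < cutoff) & (n_comp >= min_compared)
    np.fill_diagonal(adj, False)
    # union-find over the adjacency
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(*np.nonzero(np.triu(adj, 1))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    comps: dict = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(m.samples[i])
    groups = [frozenset(v) for v in comps.values() if len(v) >= 2]
    groups.sort(key=lambda g: sorted(g)[0])
    return RedundancyGroups(groups=groups)


def select_representatives(
    groups: RedundancyGroups,
    sample_stats: SampleStats | pd.DataFrame,
    samples: list | None = None,
    roles: dict | None = None,
) -> RedundancyGroups:
    """Pick one representative per redundancy group.

    Priority: annotated recurrent parent → highest call rate among those
    ≥ 0.99 → highest call rate overall → lexicographically smallest id.
    """
    if isinstance(sample_stats, SampleStats):
        if samples is None:
            raise ValueError("samples list required with a SampleStats object")
        call_rate = dict(zip(samples, sample_stats.call_rate))
    else:
        call_rate = dict(
            zip(sample_stats["sample_id"], sample_stats["call_rate"])
        )
    roles = roles or {}
    retained: dict = {}
    removed: list = []
    for gi, grp in enumerate(groups.groups):
        members = sorted(grp)
        parents = [s for s in members if roles.get(s) == "recurrent_parent"]
        if parents:
            pick = min(parents)
        else:
            high = [s for s in members if call_rate.get(s, 0.0) >= 0.99]
            pool = high if high else members
            best = max(call_rate.get(s, 0.0) for s in pool)
            pick = min(s for s in pool if call_rate.get(s, 0.0) == best)
        retained[gi] = pick
        removed.extend(s for s in members if s != pick)
    return RedundancyGroups(groups=list(groups.groups), retained=retained, removed=removed)


def classify_hybrids(
    q, window: tuple = (0.30, 0.70), sample_ids=None
) -> HybridCalls:
    """Flag samples whose domesticated-ancestry fraction lies in ``window``.

    The window is closed at both ends: q = 0.30 and q = 0.70 are hybrids.
    """
    lo, hi = window
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError(f"invalid hybrid window {window}")
    if isinstance(q, pd.Series):
        fr = q.astype(float)
    else:
        q = np.asarray(q, dtype=float)
        idx = sample_ids if sample_ids is not None else range(len(q))
        fr = pd.Series(q, index=idx)
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("ancestry fractions must lie in [0, 1]")
    flag = (fr >= lo) & (fr <= hi)
    return HybridCalls(fractions=fr, is_hybrid=flag, window=(lo, hi))


def pairs_table(m: GenotypeMatrix, max_rate: float = 1.0) -> pd.DataFrame:
    """All-pairs inconsistency as a tidy TSV-ready table."""
    rate, n_comp = inconsistency_matrix(m)
    rows = []
    for i in range(m.n_samples):
        for j in range(i + 1, m.n_samples):
            if np.isnan(rate[i, j]) or rate[i, j] > max_rate:
                continue
            rows.append(
                (m.samples[i], m.samples[j], int(n_comp[i, j]), float(rate[i, j]))
            )
    return pd.DataFrame(rows, columns=["id1", "id2", "n_compared", "inconsistency"])
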