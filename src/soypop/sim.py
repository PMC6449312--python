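"""Synthetic germplasm-collection simulator with planted ground truth.

The generative model is a hierarchical Balding–Nichols process.  An
ancestral allele frequency per locus is drawn Uniform(0.05, 0.95); each
wild subpopulation draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F)
with its own drift parameter F; the domesticated population re-drifts
from one wild source subpopulation with an additional bottleneck F and
has a fraction of its loci driven to near-fixation (selective sweeps).
Accessions of this selfing species are drawn near-homozygous (an
inbreeding parameter controls the residual Hardy–Weinberg fraction).
On top of the clean populations the
simulator plants the contaminants a real collection carries: wild ×
domesticated hybrids with intermediate ancestry, duplicated accessions
with a small per-call discordance, and uniform missingness.  Binary
phenotypes (flower colour, seed-coat colour, domestication) are assigned
deterministically from causal genotypes with dominant encoding.

Everything planted is recorded in a :class:`SimTruth` so downstream
stages can be scored for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

N_WILD_SUBPOPS = 4

# phenotype architecture: one major locus for flower colour, three for
# seed-coat colour (mirroring a monogenic and a multigenic trait)
PHENOTYPES = {"flower_color": 1, "seed_coat_color": 3}


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic collection.

    Drift parameters are Balding–Nichols F values (0–1, unitless).  The
    defaults encode the study conditions the pipeline is meant to face:
    four geographically graded wild subpopulations, a single bottlenecked
    domesticated derivative of one of them with sweeps at 7% of loci,
    hybrids with 30–70% mixed ancestry and duplicates at 1% discordance.
    """

    n_snps: int = 3000
    n_per_wild_subpop: int = 30
    n_domesticated: int = 40
    n_hybrids: int = 5
    n_duplicate_pairs: int = 3
    wild_divergence_F: tuple = (0.05, 0.10, 0.15, 0.20)
    dom_bottleneck_F: float = 0.35
    source_subpop: int = 3
    sweep_fraction: float = 0.07
    sweep_residual_maf: float = 0.02
    duplicate_discordance: float = 0.01
    missing_rate: float = 0.0
    inbreeding: float = 0.99  # selfing species: accessions are near-homozygous
    phenotype_misclassification: float = 0.0
    admixed_subpop: dict | None = None  # optional: {"subpop": i, "donor": j, "fraction": w}
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.wild_divergence_F) != N_WILD_SUBPOPS:
            raise SimConfigError(f"need {N_WILD_SUBPOPS} wild drift parameters")
        for name in (
            "sweep_fraction",
            "sweep_residual_maf",
            "duplicate_discordance",
            "missing_rate",
            "dom_bottleneck_F",
            "phenotype_misclassification",
            "inbreeding",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        for f in self.wild_divergence_F:
            if not 0.0 < f < 1.0:
                raise SimConfigError("wild drift parameters must lie in (0, 1)")
        for name in ("n_snps", "n_per_wild_subpop", "n_domesticated"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.n_hybrids < 0 or self.n_duplicate_pairs < 0:
            raise SimConfigError("counts must be non-negative")
        if not 0 <= self.source_subpop < N_WILD_SUBPOPS:
            raise SimConfigError("source_subpop out of range")
        n_causal = sum(PHENOTYPES.values())
        if self.n_sweep_loci + n_causal > self.n_snps:
            raise SimConfigError(
                f"n_snps={self.n_snps} too small for "
                f"{self.n_sweep_loci} sweep + {n_causal} causal loci"
            )

    @property
    def n_sweep_loci(self) -> int:
        return int(round(self.sweep_fraction * self.n_snps))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "wild_divergence_F" in d:
            d["wild_divergence_F"] = tuple(d["wild_divergence_F"])
        return cls(**d)


@dataclass
class SimTruth:
    """Planted ground truth of one simulated collection."""

    subpop_label: dict  # sample_id -> label ("dom", "wild0".."wild3", hybrids keep "hybrid")
    hybrid_fraction: dict  # sample_id -> q toward the domesticated pool
    hybrid_wild_subpop: dict  # sample_id -> index of the wild pool it mixes with
    duplicate_groups: list  # list of frozensets of sample ids
    sweep_locus_ids: list
    sweep_direction: dict  # locus id -> +1 (alt fixed) / -1 (ref fixed)
    causal_locus_ids: dict  # phenotype -> list of locus ids
    source_subpop_id: int

    def __post_init__(self) -> None:
        for q in self.hybrid_fraction.values():
            if not 0.30 <= q <= 0.70:
                raise ValueError(f"hybrid fraction {q} outside [0.30, 0.70]")
        seen: set = set()
        for g in self.duplicate_groups:
            if seen & set(g):
                raise ValueError("duplicate groups are not disjoint")
            seen |= set(g)


def _stage_rngs(seed: int):
    """Independent per-stage generators derived from one master seed."""
    root = np.random.SeedSequence(seed)
    names = ("freqs", "genotypes", "hybrids", "duplicates", "missing", "phenotypes")
    return dict(zip(names, (np.random.default_rng(s) for s in root.spawn(len(names)))))


def _balding_nichols(rng, p: np.ndarray, F: float) -> np.ndarray:
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    q = rng.beta(a, b)
    return np.clip(q, 1e-6, 1.0 - 1e-6)


def simulate_collection(config: SimConfig):
    """Simulate a collection; returns (GenotypeMatrix, sample table, SimTruth)."""
    rngs = _stage_rngs(config.seed)
    L = config.n_snps
    rng_f = rngs["freqs"]

    p_anc = rng_f.uniform(0.05, 0.95, size=L)
    wild_freqs = np.stack(
        [_balding_nichols(rng_f, p_anc, F) for F in config.wild_divergence_F]
    )
    if config.admixed_subpop is not None:
        mix = config.admixed_subpop
        i, j, w = int(mix["subpop"]), int(mix["donor"]), float(mix["fraction"])
        wild_freqs[i] = (1.0 - w) * wild_freqs[i] + w * wild_freqs[j]

    dom_freq = _balding_nichols(
        rng_f, wild_freqs[config.source_subpop], config.dom_bottleneck_F
    )

    # selective sweeps: fix the domestication allele, taken as the allele
    # that is minor in the source wild subpopulation (domestication-trait
    # variants are standing rare variants in the wild progenitor), so every
    # sweep plants a real wild/domesticated frequency differential
    locus_order = rng_f.permutation(L)
    n_sweep = config.n_sweep_loci
    sweep_idx = np.sort(locus_order[:n_sweep])
    src_freq = wild_freqs[config.source_subpop][sweep_idx]
    sweep_dir = np.where(src_freq < 0.5, 1, -1)  # +1: alt allele fixed
    resid = rng_f.uniform(0.0, config.sweep_residual_maf, size=n_sweep)
    dom_freq[sweep_idx] = np.where(sweep_dir > 0, 1.0 - resid, resid)

    # causal loci for the colour phenotypes, drawn from non-sweep loci that
    # segregate in domesticates (dominant major-gene architecture); the
    # multigenic trait uses lower-frequency loci so that recessive
    # "absence" phenotypes keep appreciable frequency under dominance
    non_sweep = np.setdiff1d(locus_order, sweep_idx, assume_unique=False)
    windows = {"flower_color": (0.30, 0.70), "seed_coat_color": (0.15, 0.40)}
    causal: dict = {}
    taken: set = set()
    for pheno, k in PHENOTYPES.items():
        lo, hi = windows.get(pheno, (0.25, 0.75))
        pool = [
            j for j in non_sweep
            if lo < dom_freq[j] < hi and j not in taken
        ]
        if len(pool) < k:
            pool = [j for j in non_sweep if j not in taken]
        causal[pheno] = list(pool[:k])
        taken.update(causal[pheno])

    # -- genotypes -------------------------------------------------------
    # accessions of a selfing species are near-homozygous: each locus is
    # homozygous (2 x one allele draw) with probability `inbreeding`,
    # else a Hardy-Weinberg diploid draw
    rng_g = rngs["genotypes"]

    def draw_inbred(freq):
        hom = rng_g.random(L) < config.inbreeding
        g_hom = 2 * rng_g.binomial(1, freq)
        g_hwe = rng_g.binomial(2, freq)
        return np.where(hom, g_hom, g_hwe).astype(np.int8)

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    subpop_label: dict = {}
    species: dict = {}

    for i in range(N_WILD_SUBPOPS):
        for k in range(config.n_per_wild_subpop):
            sid = f"W{i}_{k:03d}"
            sample_ids.append(sid)
            rows.append(draw_inbred(wild_freqs[i]))
            subpop_label[sid] = f"wild{i}"
            species[sid] = "soja"
    for k in range(config.n_domesticated):
        sid = f"D_{k:03d}"
        sample_ids.append(sid)
        rows.append(draw_inbred(dom_freq))
        subpop_label[sid] = "dom"
        species[sid] = "max"

    # -- hybrids ---------------------------------------------------------
    rng_h = rngs["hybrids"]
    hybrid_fraction: dict = {}
    hybrid_wild: dict = {}
    for k in range(config.n_hybrids):
        sid = f"H_{k:03d}"
        q = rng_h.uniform(0.30, 0.70)
        wp = int(rng_h.integers(N_WILD_SUBPOPS))
        from_dom = rng_h.random((2, L)) < q  # each of the two alleles independently
        allele_dom = rng_h.random((2, L)) < dom_freq
        allele_wild = rng_h.random((2, L)) < wild_freqs[wp]
        g = np.where(from_dom, allele_dom, allele_wild).sum(axis=0).astype(np.int8)
        sample_ids.append(sid)
        rows.append(g)
        hybrid_fraction[sid] = q
        hybrid_wild[sid] = wp
        subpop_label[sid] = "hybrid"
        species[sid] = "hybrid"

    # -- duplicates ------------------------------------------------------
    rng_d = rngs["duplicates"]
    n_original = len(sample_ids)
    dup_groups: list = []
    if config.n_duplicate_pairs > 0:
        originals = rng_d.choice(n_original, size=config.n_duplicate_pairs, replace=False)
        for k, oi in enumerate(originals):
            sid = f"DUP_{k:03d}"
            g = rows[oi].copy()
            # plant the configured discordance exactly: the cutoff was set
            # above the observed duplicate discordance range, so the planted
            # rate is a realized fraction, not a per-call probability
            n_flip = int(round(config.duplicate_discordance * L))
            if n_flip:
                flip = rng_d.choice(L, size=n_flip, replace=False)
                shift = rng_d.integers(1, 3, size=n_flip)
                g[flip] = (g[flip] + shift) % 3
            sample_ids.append(sid)
            rows.append(g)
            src = sample_ids[oi]
            dup_groups.append(frozenset({src, sid}))
            subpop_label[sid] = subpop_label[src]
            species[sid] = species[src]

    calls = np.stack(rows)

    # -- missingness -----------------------------------------------------
    if config.missing_rate > 0:
        miss = rngs["missing"].random(calls.shape) < config.missing_rate
        calls = np.where(miss, np.int8(MISSING), calls)

    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, L + 1) * 1000,
            "id": [f"SNP{j:06d}" for j in range(L)],
            "ref": "A",
            "alt": "C",
        }
    )
    m = GenotypeMatrix(sample_ids, snps, calls)

    # -- phenotypes ------------------------------------------------------
    rng_p = rngs["phenotypes"]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species": [species[s] for s in sample_ids],
            "subpop": [subpop_label[s] for s in sample_ids],
            "country_code": [
                {"wild0": "CN", "wild1": "CN", "wild2": "KR", "wild3": "JP"}.get(
                    subpop_label[s], "KR"
                )
                for s in sample_ids
            ],
            "improvement_status": [
                "landrace" if species[s] == "max" else "wild" for s in sample_ids
            ],
        }
    )
    meta["domestication"] = (meta["species"] == "max").astype(int)
    is_dom = meta["domestication"].to_numpy().astype(bool)
    snp_ids = m.snp_ids
    for pheno, loci in causal.items():
        geno = calls[:, loci]
        carrier = (geno > 0).any(axis=1)  # dominant encoding, any causal locus
        value = np.where(is_dom, carrier.astype(int), 1)  # wild fixed at ancestral state
        if config.phenotype_misclassification > 0:
            flip = rng_p.random(len(value)) < config.phenotype_misclassification
            value = np.where(flip, 1 - value, value)
        meta[pheno] = value

    truth = SimTruth(
        subpop_label=subpop_label,
        hybrid_fraction=hybrid_fraction,
        hybrid_wild_subpop=hybrid_wild,
        duplicate_groups=dup_groups,
        sweep_locus_ids=[snp_ids[j] for j in sweep_idx],
        sweep_direction={
            snp_ids[j]: int(d) for j, d in zip(sweep_idx, sweep_dir)
        },
        causal_locus_ids={p: [snp_ids[j] for j in loci] for p, loci in causal.items()},
        source_subpop_id=config.source_subpop,
    )
    return m, meta, truth


def simulate_balding_nichols(
    n_snps: int,
    pop_sizes,
    pop_F,
    seed: int = 0,
    p_range: tuple = (0.05, 0.95),
):
    """Flat Balding–Nichols panel: each population drifts independently
    from a shared ancestral frequency.  Returns (GenotypeMatrix, labels)
    with labels mapping sample id -> population index."""
    if len(pop_sizes) != len(pop_F):
        raise SimConfigError("pop_sizes and pop_F must align")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(*p_range, size=n_snps)
    sample_ids: list[str] = []
    rows = []
    labels: dict = {}
    for k, (nk, Fk) in enumerate(zip(pop_sizes, pop_F)):
        freq = _balding_nichols(rng, p_anc, Fk)
        for i in range(nk):
            sid = f"P{k}_{i:03d}"
            sample_ids.append(sid)
            rows.append(rng.binomial(2, freq).astype(np.int8))
            labels[sid] = k
    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 1000,
            "id": [f"SNP{j:06d}" for j in range(n_snps)],
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(sample_ids, snps, np.stack(rows)), labels


def simulate_hybrid_panel(
    n_snps: int = 3000,
    n_per_pool: int = 50,
    pool_F: float = 0.3,
    n_hybrids: int = 10,
    q_range: tuple = (0.35, 0.65),
    seed: int = 0,
):
    """Two diverged pools plus planted hybrids with known admixture q.

    Pool 0 plays the wild role and pool 1 the domesticated role; each
    hybrid draws each allele from pool 1 with probability q.  Returns
    (GenotypeMatrix, labels, q_true) where labels maps sample id ->
    {'pool0', 'pool1', 'hybrid'}.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    f0 = _balding_nichols(rng, p_anc, pool_F)
    f1 = _balding_nichols(rng, p_anc, pool_F)
    sample_ids, rows, labels = [], [], {}
    q_true: dict = {}
    for k, f in ((0, f0), (1, f1)):
        for i in range(n_per_pool):
            sid = f"P{k}_{i:03d}"
            sample_ids.append(sid)
            rows.append(rng.binomial(2, f).astype(np.int8))
            labels[sid] = f"pool{k}"
    for i in range(n_hybrids):
        sid = f"H_{i:03d}"
        q = rng.uniform(*q_range)
        pick = rng.random((2, n_snps)) < q
        a1 = rng.random((2, n_snps)) < f1
        a0 = rng.random((2, n_snps)) < f0
        rows.append(np.where(pick, a1, a0).sum(axis=0).astype(np.int8))
        sample_ids.append(sid)
        labels[sid] = "hybrid"
        q_true[sid] = q
    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 1000,
            "id": [f"SNP{j:06d}" for j in range(n_snps)],
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(sample_ids, snps, np.stack(rows)), labels, q_true


def simulate_ld_region(
    n_samples: int = 200,
    block_size: int = 5,
    n_flank: int = 3,
    maf: float = 0.3,
    seed: int = 0,
):
    """Block-copy LD fixture: a run of SNPs sharing one haplotype signal
    (perfect pairwise LD) flanked by independent SNPs on each side.

    Returns (GenotypeMatrix, block_snp_ids).  Loci are exchangeable in
    the main simulator; this mode exists to exercise LD-block calling.
    """
    rng = np.random.default_rng(seed)
    core = rng.binomial(2, maf, size=n_samples).astype(np.int8)
    cols = []
    for _ in range(n_flank):
        cols.append(rng.binomial(2, maf, size=n_samples).astype(np.int8))
    block_start = len(cols)
    for _ in range(block_size):
        cols.append(core.copy())
    for _ in range(n_flank):
        cols.append(rng.binomial(2, maf, size=n_samples).astype(np.int8))
    L = len(cols)
    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, L + 1) * 1000,
            "id": [f"SNP{j:06d}" for j in range(L)],
            "ref": "A",
            "alt": "C",
        }
    )
    m = GenotypeMatrix(
        [f"x{i:03d}" for i in range(n_samples)], snps, np.column_stack(cols)
    )
    block_ids = [f"SNP{j:06d}" for j in range(block_start, block_start + block_size)]
    return m, block_ids


def write_truth(truth: SimTruth, prefix) -> None:
    """Serialize the truth tables next to the genotypes (TSV)."""
    prefix = str(prefix)
    rows = [
        {"sample_id": s, "subpop": lab} for s, lab in truth.subpop_label.items()
    ]
    pd.DataFrame(rows).to_csv(prefix + ".subpops.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": s,
                "hybrid_fraction": q,
                "wild_subpop": truth.hybrid_wild_subpop[s],
            }
            for s, q in truth.hybrid_fraction.items()
        ]
    ).to_csv(prefix + ".hybrids.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"group": i, "sample_id": s}
            for i, grp in enumerate(truth.duplicate_groups)
            for s in sorted(grp)
        ]
    ).to_csv(prefix + ".duplicates.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "locus_id": truth.sweep_locus_ids,
            "direction": [truth.sweep_direction[l] for l in truth.sweep_locus_ids],
        }
    ).to_csv(prefix + ".sweeps.tsv", sep="\t", index=False)
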