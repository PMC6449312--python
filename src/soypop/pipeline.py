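"""End-to-end orchestration of the curation and analysis pipeline.

Stage order is fixed: sample QC → imputation → hybrid removal → dedup →
SNP filter → PCA/admixture → diversity/FST/AMOVA → GWAS per binary
trait → LD blocks at significant peaks → domestication-SNP partition →
trees.  Hybrid removal precedes deduplication so that a duplicated
hybrid cannot survive as a group representative.  One master seed
drives every stage; per-stage seeds derive from stable hashes of the
stage names, so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import curation, genio, phylo, popgen, structure
from .sim import SimConfig, simulate_collection, write_truth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of a pipeline run (thresholds as published
    defaults for germplasm SNP-array curation)."""

    genotypes: str | None = None  # VCF or genotype-TSV path
    metadata: str | None = None
    simulate: dict | None = None  # SimConfig fields; used when no input paths
    out_dir: str = "soypop_out"
    seed: int = 0

    min_sample_call_rate: float = 0.97
    max_het: float = 0.02
    min_maf: float = 0.02
    dedup_cutoff: float = 0.0125
    dedup_min_compared: int = 100
    hybrid_window: tuple = (0.30, 0.70)
    hybrid_screen_K: int = 5
    K_list: tuple = (1, 2, 3)
    admixture_K: int = 2
    alpha: float = 0.01
    partition_cut: float = 17.0
    n_perm: int = 1023
    n_bootstrap: int = 1000
    traits: tuple = ("flower_color", "seed_coat_color", "domestication")
    n_conditioning_per_group: int = 10
    run_cv: bool = False
    run_amova: bool = True
    run_trees: bool = True

    def validate(self) -> None:
        for name, lo, hi in [
            ("min_sample_call_rate", 0.0, 1.0),
            ("max_het", 0.0, 1.0),
            ("min_maf", 0.0, 0.5),
            ("dedup_cutoff", 0.0, 1.0),
            ("alpha", 1e-12, 1.0),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        lo, hi = self.hybrid_window
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"hybrid_window {self.hybrid_window} invalid")
        if self.genotypes is None and self.simulate is None:
            raise ValueError("config needs either input paths or a simulate block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hybrid_window", "K_list", "traits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "stages": {},
        "counts": {},
    }

    # -- inputs ----------------------------------------------------------
    if config.genotypes is not None:
        m = genio.read_genotypes(config.genotypes)
        meta = (
            genio.read_metadata(config.metadata)
            if config.metadata
            else pd.DataFrame({"sample_id": m.samples, "species": "unknown"})
        )
        manifest["inputs"] = {
            "genotypes": {"path": config.genotypes, "sha256": _sha256(Path(config.genotypes))}
        }
    else:
        sim_cfg = SimConfig.from_dict({**config.simulate, "seed": config.simulate.get("seed", config.seed)})
        m, meta, truth = simulate_collection(sim_cfg)
        genio.write_genotypes(m, out / "simulated.vcf")
        meta.to_csv(out / "simulated.meta.tsv", sep="\t", index=False)
        write_truth(truth, out / "truth")
        manifest["inputs"] = {"simulated": asdict(sim_cfg)}
    meta = meta.set_index("sample_id", drop=False)
    manifest["counts"]["input"] = {"samples": m.n_samples, "snps": m.n_snps}

    removal_log: list = []

    # -- sample QC -------------------------------------------------------
    m, flog = genio.filter_samples(m, config.min_sample_call_rate)
    removal_log += [{"sample_id": s, "reason": "low_call_rate"} for s in flog.removed_samples]
    manifest["counts"]["after_sample_qc"] = {"samples": m.n_samples, "snps": m.n_snps}

    # keep unimputed calls for the redundancy screen (the published
    # inconsistency excludes missing genotypes rather than imputing them)
    m_unimputed = m

    # -- imputation ------------------------------------------------------
    m = genio.impute_missing(m, seed=_stage_seed(config.seed, "impute"))
    manifest["stages"]["impute"] = {"seed": _stage_seed(config.seed, "impute")}

    # -- hybrid removal --------------------------------------------------
    # Screened at K = hybrid_screen_K (default 5, the number of planted
    # populations): with a domesticated population nested inside one wild
    # subpopulation, low-K solutions assign genuine intermediate fractions
    # to source-subpopulation wild accessions, while at the population-level
    # K those samples resolve to their own cluster and only true hybrids
    # remain in the 30-70% window.
    seed_adm = _stage_seed(config.seed, "admixture")
    model2 = structure.fit_admixture(m, K=config.hybrid_screen_K, seed=seed_adm)
    is_dom_ref = (meta.loc[m.samples, "species"] == "max").to_numpy()
    if is_dom_ref.any():
        q_dom = structure.dominant_cluster_fractions(model2, is_dom_ref)
    else:  # no species labels: use the larger cluster as reference
        q_dom = model2.Q[:, int(np.argmax(model2.Q.mean(axis=0)))]
    hyb = curation.classify_hybrids(q_dom, config.hybrid_window, sample_ids=m.samples)
    hybrid_ids = hyb.hybrid_ids
    removal_log += [{"sample_id": s, "reason": "hybrid"} for s in hybrid_ids]
    keep = [s for s in m.samples if s not in set(hybrid_ids)]
    m = m.subset_samples(keep)
    m_unimputed = m_unimputed.subset_samples(keep)
    manifest["counts"]["after_hybrid_removal"] = {"samples": m.n_samples}
    logger.info("removed %d putative hybrids", len(hybrid_ids))

    # -- deduplication ---------------------------------------------------
    groups = curation.find_redundancy_groups(
        m_unimputed, cutoff=config.dedup_cutoff, min_compared=config.dedup_min_compared
    )
    stats = genio.compute_sample_stats(m_unimputed)
    roles = {}
    if "role" in meta.columns:
        roles = meta["role"].dropna().to_dict()
    groups = curation.select_representatives(
        groups, stats, samples=m_unimputed.samples, roles=roles
    )
    removal_log += [{"sample_id": s, "reason": "duplicate"} for s in groups.removed]
    keep = [s for s in m.samples if s not in set(groups.removed)]
    m = m.subset_samples(keep)
    manifest["counts"]["after_dedup"] = {"samples": m.n_samples}
    logger.info("removed %d redundant accessions", len(groups.removed))

    # -- SNP filter ------------------------------------------------------
    m, snp_log = genio.filter_snps(m, config.max_het, config.min_maf)
    manifest["counts"]["after_snp_filter"] = {"samples": m.n_samples, "snps": m.n_snps}
    logger.info("retained %d SNPs after het/MAF filter", m.n_snps)

    pd.DataFrame(removal_log).to_csv(out / "removal_log.tsv", sep="\t", index=False)
    genio.write_genotypes(m, out / "curated.vcf")

    # -- structure -------------------------------------------------------
    pca = structure.run_pca(m, n_components=min(10, m.n_samples - 1))
    pd.DataFrame(
        pca.scores,
        index=pca.samples,
        columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
    ).to_csv(out / "pca_scores.tsv", sep="\t")
    manifest["stages"]["pca"] = {
        "explained": pca.explained_variance_fraction[:5].round(4).tolist()
    }
    model = structure.fit_admixture(
        m, K=config.admixture_K, seed=_stage_seed(config.seed, "admixture_final")
    )
    pd.DataFrame(
        model.Q, index=m.samples, columns=[f"q_{k+1}" for k in range(model.K)]
    ).to_csv(out / "admixture_Q.tsv", sep="\t")
    if config.run_cv:
        cv = structure.cross_validate_K(
            m, config.K_list, seed=_stage_seed(config.seed, "cv")
        )
        pd.DataFrame({"K": cv.K_values, "cv_error": cv.cv_error}).to_csv(
            out / "cv_curve.tsv", sep="\t", index=False
        )
        manifest["stages"]["cv"] = {"chosen_K": cv.chosen_K}

    # -- diversity / differentiation ------------------------------------
    species = meta.loc[m.samples, "species"]
    partition = {
        s: ("max" if sp == "max" else "soja") for s, sp in species.items()
    }
    have_two_species = len(set(partition.values())) == 2
    pi_rows = []
    for label in sorted(set(species)):
        ids = [s for s in m.samples if species[s] == label]
        if len(ids) >= 2:
            div = popgen.nucleotide_diversity(m, ids)
            pi_rows.append({"group": label, "n": len(ids), "mean_pi": div.mean_pi})
    pd.DataFrame(pi_rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
    manifest["stages"]["diversity"] = {r["group"]: r["mean_pi"] for r in pi_rows}
    if "subpop" in meta.columns:
        subpop = meta.loc[m.samples, "subpop"].to_dict()
        fst_m = popgen.pairwise_fst_matrix(m, subpop)
        fst_m.to_csv(out / "fst_matrix.tsv", sep="\t")
        if config.run_amova and have_two_species:
            am = popgen.amova(
                m,
                groups=partition,
                pops=subpop,
                n_perm=config.n_perm,
                seed=_stage_seed(config.seed, "amova"),
            )
            manifest["stages"]["amova"] = {
                "F_CT": am.F_CT,
                "F_SC": am.F_SC,
                "F_ST": am.F_ST,
                "p_F_CT": am.p_F_CT,
            }

    # -- GWAS ------------------------------------------------------------
    cond = None
    if "subpop" in meta.columns and have_two_species:
        cond = assoc_mod.select_conditioning_snps(
            m,
            group_labels=meta.loc[m.samples, "subpop"].to_dict(),
            species=partition,
            n_per_group=config.n_conditioning_per_group,
        )
    dom_partition = None
    for trait in config.traits:
        if trait == "domestication" and trait not in meta.columns:
            pheno = (species == "max").astype(float)
        elif trait in meta.columns:
            pheno = meta.loc[m.samples, trait].astype(float)
        else:
            continue
        try:
            res = assoc_mod.logistic_scan(
                m,
                pheno,
                conditioning=cond,
                trait=trait,
                alpha=config.alpha,
                exclude_perfect=(trait == "domestication"),
            )
        except ValueError as e:
            logger.warning("skipping trait %s: %s", trait, e)
            continue
        res.table.to_csv(out / f"assoc_{trait}.tsv", sep="\t", index=False)
        manifest["stages"][f"gwas_{trait}"] = {
            "n_significant": int(res.table["significant"].sum()),
            "threshold_neg_log10": res.threshold_neg_log10,
        }
        if trait == "domestication":
            dom_partition = assoc_mod.partition_by_association(
                res, config.partition_cut
            )

    # -- trees -----------------------------------------------------------
    if config.run_trees and m.n_samples >= 3:
        tree = phylo.bootstrap_support(
            m, n_reps=config.n_bootstrap, seed=_stage_seed(config.seed, "bootstrap")
        )
        phylo.write_newick(tree, out / "nj_tree.nwk")
        if dom_partition is not None:
            dom_snps, neutral_snps = dom_partition
            manifest["counts"]["snp_partition"] = {
                "dom": len(dom_snps),
                "neutral": len(neutral_snps),
            }
            if dom_snps and neutral_snps:
                clades = {
                    "domesticated": [s for s in m.samples if partition[s] == "max"]
                }
                report = phylo.compare_partition_trees(
                    m, dom_snps, neutral_snps, clades
                )
                report.to_csv(out / "partition_trees.tsv", sep="\t", index=False)
                for name, t in report.attrs["trees"].items():
                    phylo.write_newick(t, out / f"tree_{name}.nwk")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
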