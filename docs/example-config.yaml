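# Full-pipeline configuration for `soypop run`.
# Either point `genotypes`/`metadata` at real files, or give a
# `simulate` block to analyse a synthetic collection.

simulate:
  n_snps: 3000
  n_per_wild_subpop: 30
  n_domesticated: 40
  n_hybrids: 5
  n_duplicate_pairs: 3
  duplicate_discordance: 0.01
  missing_rate: 0.01

out_dir: soypop_out
seed: 7

# QC thresholds
min_sample_call_rate: 0.97   # keep samples strictly above
max_het: 0.02                # discard SNPs strictly above
min_maf: 0.02                # discard SNPs strictly below

# curation
dedup_cutoff: 0.0125         # pairwise inconsistency, strict <
dedup_min_compared: 100      # pairs with fewer co-called sites never merge
hybrid_window: [0.30, 0.70]  # closed interval on domesticated ancestry
hybrid_screen_K: 5           # ancestry model size used for the screen

# structure
admixture_K: 2
K_list: [1, 2, 3]
run_cv: false                # cross-validated choice of K (slower)

# statistics
n_perm: 1023                 # AMOVA permutations
alpha: 0.01                  # family-wise level before Bonferroni division
partition_cut: 17.0          # -log10 p cut for the domestication-SNP set
n_conditioning_per_group: 10
n_bootstrap: 1000            # NJ bootstrap replicates
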