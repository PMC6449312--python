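"""Genotype matrix container, readers/writers and QC filters.

The universal currency of the pipeline is a samples × SNPs diploid
alt-allele dosage matrix with values in {0, 1, 2} and ``-1`` marking a
missing call.  Two on-disk dialects are supported:

* VCF 4.x (GT field only; diploid biallelic SNP records; ``./.`` missing)
* genotype-TSV: a header row of SNP ids, then one row per sample with the
  sample id in the first column and cells in {0, 1, 2, NA}.

QC follows the array-curation conventions used for large germplasm
collections: samples are screened on call rate first, then SNPs on
heterozygosity and minor allele frequency; missing calls are filled with
the per-SNP modal dosage (frequency-weighted draw on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SNP_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class GenotypeInputError(ValueError):
    """Malformed or inconsistent genotype input."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic dosage matrix.

    Parameters
    ----------
    samples
        Ordered unique sample ids.
    snps
        DataFrame with columns ``chrom, pos, id, ref, alt`` (1-based
        positions, VCF convention).
    calls
        ``int8`` array of shape ``(n_samples, n_snps)`` with entries in
        {0, 1, 2, -1}; ``-1`` is a missing call.
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.samples = list(self.samples)
        if self.calls.ndim != 2:
            raise GenotypeInputError("calls must be 2-D (samples × SNPs)")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise GenotypeInputError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples × {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeInputError("duplicate sample id")
        ids = self.snps["id"]
        if ids.duplicated().any():
            raise GenotypeInputError("duplicate SNP id")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise GenotypeInputError(
                f"{int(bad.sum())} dosage values outside {{0,1,2,missing}}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["id"].tolist()

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def called_mask(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    # -- subsetting ------------------------------------------------------
    def take_samples(self, index: np.ndarray | list) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.samples[i] for i in index],
            self.snps.copy(),
            self.calls[index, :],
        )

    def take_snps(self, index: np.ndarray | list) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            list(self.samples),
            self.snps.iloc[index].reset_index(drop=True),
            self.calls[:, index],
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return self.take_samples(np.asarray(idx))

    # -- frequencies -----------------------------------------------------
    def alt_allele_freq(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP alt allele frequency among called genotypes (NaN if none)."""
        calls = self.calls if sample_index is None else self.calls[sample_index, :]
        called = calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)


@dataclass
class SnpStats:
    call_rate: np.ndarray
    maf: np.ndarray
    het_rate: np.ndarray
    defined: np.ndarray  # False where no sample is called

    def to_frame(self, snp_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": snp_ids,
                "call_rate": self.call_rate,
                "maf": self.maf,
                "het_rate": self.het_rate,
                "defined": self.defined,
            }
        )


@dataclass
class SampleStats:
    call_rate: np.ndarray

    def to_frame(self, samples) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": samples, "call_rate": self.call_rate})


@dataclass
class FilterLog:
    """Record of what a filtering step removed and why."""

    removed_samples: list[str] = field(default_factory=list)
    removed_snps: list[str] = field(default_factory=list)
    reason: str = ""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or genotype-TSV.

    Multiallelic or non-SNP VCF records are excluded (count logged).
    """
    path = str(path)
    if fmt == "auto":
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise GenotypeInputError(f"unknown format {fmt!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise GenotypeInputError("duplicate sample id in VCF header")
    records = []
    columns = []
    n_excluded = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_excluded += 1
            continue
        # gts012: 0/1/2 dosage, 3 = unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        columns.append(g)
        records.append(
            (var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}", var.REF, var.ALT[0])
        )
    vcf.close()
    if n_excluded:
        logger.info("excluded %d multiallelic/non-SNP records", n_excluded)
    snps = pd.DataFrame(records, columns=SNP_COLUMNS)
    calls = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    m = GenotypeMatrix(samples, snps, calls)
    m.n_excluded_records = n_excluded  # type: ignore[attr-defined]
    return m


def _read_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise GenotypeInputError("genotype-TSV must start with a 'sample_id' column")
    samples = df["sample_id"].tolist()
    snp_ids = list(df.columns[1:])
    body = df.iloc[:, 1:].to_numpy(dtype=object)
    calls = np.empty(body.shape, dtype=np.int8)
    lut = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
    for (i, j), v in np.ndenumerate(body):
        try:
            calls[i, j] = lut[str(v)]
        except KeyError:
            raise GenotypeInputError(
                f"bad genotype cell {v!r} at row {i + 2}, SNP {snp_ids[j]}"
            ) from None
    snps = pd.DataFrame(
        {
            "chrom": "0",
            "pos": np.arange(1, len(snp_ids) + 1),
            "id": snp_ids,
            "ref": "A",
            "alt": "B",
        }
    )
    return GenotypeMatrix(samples, snps, calls)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(m: GenotypeMatrix, path, fmt: str = "auto") -> None:
    path = str(path)
    if fmt == "auto":
        fmt = "vcf" if path.endswith(".vcf") else "tsv"
    if fmt == "vcf":
        _write_vcf(m, path)
    elif fmt == "tsv":
        _write_tsv(m, path)
    else:
        raise GenotypeInputError(f"unknown format {fmt!r}")


def _write_vcf(m: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        snps = m.snps
        for j in range(m.n_snps):
            rec = snps.iloc[j]
            gts = "\t".join(_GT_STR[int(g)] for g in m.calls[:, j])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _write_tsv(m: GenotypeMatrix, path: str) -> None:
    inv = {0: "0", 1: "1", 2: "2", MISSING: "NA"}
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(m.snp_ids) + "\n")
        for i, s in enumerate(m.samples):
            fh.write(s + "\t" + "\t".join(inv[int(g)] for g in m.calls[i]) + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, species, country_code, improvement_status
    plus binary phenotype columns (0/1/NA)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise GenotypeInputError("metadata TSV needs a sample_id column")
    return df


# ---------------------------------------------------------------------------
# QC statistics and filters
# ---------------------------------------------------------------------------

def compute_sample_stats(m: GenotypeMatrix) -> SampleStats:
    if m.n_snps == 0:
        raise GenotypeInputError("empty matrix")
    return SampleStats(call_rate=m.called_mask().mean(axis=1))


def compute_snp_stats(m: GenotypeMatrix) -> SnpStats:
    if m.n_samples == 0:
        raise GenotypeInputError("empty matrix")
    called = m.called_mask()
    n_called = called.sum(axis=0)
    defined = n_called > 0
    alt = np.where(called, m.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(defined, alt / (2 * n_called), np.nan)
        het = np.where(defined, (m.calls == 1).sum(axis=0) / n_called, np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    return SnpStats(
        call_rate=n_called / m.n_samples,
        maf=maf,
        het_rate=het,
        defined=defined,
    )


def filter_samples(
    m: GenotypeMatrix, min_call_rate: float = 0.97
) -> tuple[GenotypeMatrix, FilterLog]:
    """Keep samples with call rate strictly above ``min_call_rate``."""
    stats = compute_sample_stats(m)
    keep = stats.call_rate > min_call_rate
    if not keep.any():
        raise GenotypeInputError("sample call-rate filter removed every sample")
    removed = [s for s, k in zip(m.samples, keep) if not k]
    if removed:
        logger.info("sample call-rate filter removed %d samples", len(removed))
    return m.take_samples(keep), FilterLog(removed_samples=removed, reason="call_rate")


def filter_snps(
    m: GenotypeMatrix, max_het: float = 0.02, min_maf: float = 0.02
) -> tuple[GenotypeMatrix, FilterLog]:
    """Discard SNPs with het_rate > ``max_het`` OR maf < ``min_maf``.

    Both inequalities are strict, so boundary values are retained.  A SNP
    with no called genotype has undefined stats and always fails.
    """
    stats = compute_snp_stats(m)
    with np.errstate(invalid="ignore"):
        discard = (stats.het_rate > max_het) | (stats.maf < min_maf)
    discard = discard | ~stats.defined
    keep = ~discard
    removed = [s for s, k in zip(m.snp_ids, keep) if not k]
    if removed:
        logger.info("SNP het/MAF filter removed %d SNPs", len(removed))
    return m.take_snps(keep), FilterLog(removed_snps=removed, reason="het_or_maf")


def impute_missing(m: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Replace missing calls with the per-SNP modal dosage.

    Ties between equally common dosages are broken by a seeded draw
    weighted by the tied dosages' counts (equal weights); the output
    contains no missing values.
    """
    rng = np.random.default_rng(seed)
    calls = m.calls.copy()
    called = calls != MISSING
    if called.all():
        return GenotypeMatrix(list(m.samples), m.snps.copy(), calls)
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        raise GenotypeInputError(
            "cannot impute a SNP with zero called samples; filter first"
        )
    counts = np.stack([(calls == d).sum(axis=0) for d in (0, 1, 2)])  # (3, n_snps)
    for j in np.flatnonzero(~called.all(axis=0)):
        cj = counts[:, j]
        top = np.flatnonzero(cj == cj.max())
        fill = top[0] if len(top) == 1 else rng.choice(top)
        col = calls[:, j]
        col[col == MISSING] = fill
    return GenotypeMatrix(list(m.samples), m.snps.copy(), calls)
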