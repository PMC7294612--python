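"""Genotype data model and quality control.

Dosages count copies of the panel's effect (rare) allele: 0, 1 or 2 per
participant and SNP, with NaN for missing calls. Missing genotypes are
excluded pairwise per SNP, so every frequency and Hardy-Weinberg statistic is
computed over the non-missing participants for that SNP only.

The effect allele is fixed by the panel (the discovery-study definition) and
is never re-oriented to the current cohort: a cohort in which the discovery
rare allele drifts above 0.5 keeps a stable scoring direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SnpPanel

__all__ = [
    "GenotypeMatrix",
    "HweResult",
    "MafComparison",
    "compute_maf",
    "genotype_counts",
    "hwe_test",
    "filter_hwe",
    "compare_maf",
    "maf_table",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_qc_report",
]


class GenotypeMatrix:
    """Participants × SNPs matrix of effect-allele dosages.

    dosage is a float array; entries are 0.0, 1.0, 2.0 or NaN (missing).
    """

    def __init__(
        self,
        participant_ids: Sequence[str],
        snp_ids: Sequence[str],
        dosage: np.ndarray,
    ):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(participant_ids), len(snp_ids)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(participant_ids)} participants x {len(snp_ids)} SNPs"
            )
        valid = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(dosage[~valid])
            raise ValueError(f"dosages must be 0, 1, 2 or missing; found {bad}")
        self.participant_ids = list(participant_ids)
        self.snp_ids = list(snp_ids)
        self.dosage = dosage
        if len(set(self.participant_ids)) != len(self.participant_ids):
            raise ValueError("duplicate participant ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp ids")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP (NaN = missing)."""
        try:
            j = self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"unknown snp_id: {snp_id!r}") from None
        return self.dosage[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.participant_ids, columns=self.snp_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(float))


@dataclass(frozen=True)
class HweResult:
    """1-df Pearson chi-squared test of Hardy-Weinberg genotype proportions."""

    snp_id: Optional[str]
    chi_squared: float
    p_value: float
    passed: bool
    monomorphic: bool = False


@dataclass(frozen=True)
class MafComparison:
    """Allele-count chi-squared comparison of one SNP between two groups."""

    snp_id: Optional[str]
    maf_a: float
    maf_b: float
    chi_squared: float
    p_value: float
    degenerate: bool = False


def compute_maf(matrix: GenotypeMatrix, snp_id: str) -> float:
    """Effect-allele frequency of one SNP over non-missing participants.

    Returns (sum of dosages) / (2 × non-missing participants). The value is
    the panel effect-allele frequency, not re-oriented to the minor allele.
    """
    col = matrix.column(snp_id)
    n = int(np.sum(~np.isnan(col)))
    if n == 0:
        raise ValueError(f"{snp_id}: all genotypes missing")
    return float(np.nansum(col) / (2 * n))


def genotype_counts(matrix: GenotypeMatrix, snp_id: str) -> tuple[int, int, int]:
    """Counts (hom other, het, hom effect) over non-missing participants."""
    col = matrix.column(snp_id)
    col = col[~np.isnan(col)]
    return (int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2)))


def hwe_test(
    counts: tuple[int, int, int],
    alpha: float = 0.05,
    snp_id: Optional[str] = None,
) -> HweResult:
    """Pearson chi-squared (1 df) test of Hardy-Weinberg proportions.

    counts are (n hom-other, n het, n hom-effect). Expected counts use the
    sample effect-allele frequency p̂: n(1-p̂)², 2n·p̂(1-p̂), n·p̂². A
    monomorphic SNP (p̂ = 0 or 1) is returned with chi² = 0, p = 1 and the
    monomorphic flag set rather than raising.
    """
    n_aa, n_ab, n_bb = counts
    if min(counts) < 0 or any(int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n_bb + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(snp_id, 0.0, 1.0, passed=True, monomorphic=True)
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(snp_id, chi2, p_value, passed=p_value >= alpha)


def filter_hwe(
    matrix: GenotypeMatrix, panel: SnpPanel, alpha: float = 0.05
) -> tuple[SnpPanel, list[HweResult]]:
    """Drop panel SNPs whose HWE p-value falls below ``alpha``.

    Returns the retained panel (input order preserved) and the HweResults of
    the excluded SNPs. No multiple-testing correction is applied.
    """
    retained: list[str] = []
    excluded: list[HweResult] = []
    for entry in panel:
        res = hwe_test(genotype_counts(matrix, entry.snp_id), alpha, entry.snp_id)
        if res.passed:
            retained.append(entry.snp_id)
        else:
            excluded.append(res)
    return panel.subset(retained), excluded


def compare_maf(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
    snp_id: Optional[str] = None,
) -> MafComparison:
    """Pearson chi-squared (1 df, uncorrected) on a 2×2 allele-count table.

    ``counts_a``/``counts_b`` are (effect alleles, total alleles) per group.
    A zero marginal (effect allele absent — or fixed — in both groups) yields
    chi² = 0, p = 1 with the degenerate flag set. No Yates continuity
    correction is applied; small-count behaviour is the caller's concern.
    """
    ea, ta = counts_a
    eb, tb = counts_b
    if ta < 2 or tb < 2:
        raise ValueError("each group needs at least 2 alleles (one participant)")
    if not (0 <= ea <= ta and 0 <= eb <= tb):
        raise ValueError("effect-allele counts must lie within totals")
    maf_a, maf_b = ea / ta, eb / tb
    table = np.array([[ea, ta - ea], [eb, tb - eb]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        return MafComparison(snp_id, maf_a, maf_b, 0.0, 1.0, degenerate=True)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = float(np.sum((table - expected) ** 2 / expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return MafComparison(snp_id, maf_a, maf_b, chi2, p_value)


def allele_counts(matrix: GenotypeMatrix, snp_id: str) -> tuple[int, int]:
    """(effect alleles, total alleles) over non-missing participants."""
    col = matrix.column(snp_id)
    col = col[~np.isnan(col)]
    return int(col.sum()), 2 * len(col)


def maf_table(
    matrix: GenotypeMatrix,
    panel: SnpPanel,
    reference_mafs: Optional[Mapping[str, float]] = None,
    reference_n_alleles: Optional[int] = None,
    rare_threshold: float = 0.05,
    hwe_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP QC report: MAF, HWE test, rare flag, optional reference comparison.

    The rare-variant flag is MAF <= ``rare_threshold`` (inclusive boundary).
    When ``reference_mafs`` is given, each SNP is compared against the
    reference cohort by an allele-count chi-squared; ``reference_n_alleles``
    (chromosomes, 2 per participant) is required in that case and reference
    effect-allele counts are rounded to the nearest integer.
    """
    if reference_mafs is not None and reference_n_alleles is None:
        raise ValueError("reference_n_alleles required with reference_mafs")
    rows = []
    for entry in panel:
        maf = compute_maf(matrix, entry.snp_id)
        hwe = hwe_test(genotype_counts(matrix, entry.snp_id), hwe_alpha, entry.snp_id)
        row = {
            "snp_id": entry.snp_id,
            "locus": entry.locus,
            "maf": maf,
            "hwe_chi2": hwe.chi_squared,
            "hwe_p": hwe.p_value,
            "hwe_pass": hwe.passed,
            "rare_flag": maf <= rare_threshold,
            "ref_maf": np.nan,
            "cmp_chi2": np.nan,
            "cmp_p": np.nan,
        }
        if reference_mafs is not None and entry.snp_id in reference_mafs:
            ref = reference_mafs[entry.snp_id]
            cmp_res = compare_maf(
                allele_counts(matrix, entry.snp_id),
                (round(ref * reference_n_alleles), reference_n_alleles),
                entry.snp_id,
            )
            row.update(ref_maf=ref, cmp_chi2=cmp_res.chi_squared, cmp_p=cmp_res.p_value)
        rows.append(row)
    return pd.DataFrame(rows)


# --- I/O --------------------------------------------------------------------

def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a dosage matrix from TSV: first column participant id, header of
    rsIDs, cells in {0, 1, 2, NA}."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix.from_frame(df)


def write_genotypes_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "participant_id"
    out.to_csv(path, sep="\t")


def read_genotypes_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Read panel SNP dosages from a VCF (biallelic sites, GT field).

    REF/ALT are matched against the panel's other/effect alleles; the dosage
    counts copies of the panel effect allele whether it is REF or ALT. A site
    whose alleles do not match the panel raises instead of silently flipping
    strands. Requires cyvcf2 (``pip install n3grs[vcf]``).
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = set(panel.snp_ids)
    data: dict[str, np.ndarray] = {}
    for variant in vcf:
        if variant.ID not in wanted:
            continue
        if len(variant.ALT) != 1:
            raise ValueError(f"{variant.ID}: only biallelic sites are supported")
        entry = panel[variant.ID]
        ref, alt = variant.REF, variant.ALT[0]
        if {ref, alt} != {entry.effect_allele, entry.other_allele}:
            raise ValueError(
                f"{variant.ID}: VCF alleles {ref}/{alt} do not match panel "
                f"{entry.other_allele}/{entry.effect_allele}"
            )
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(=3 in cyvcf2), 2=unknown
        alt_dosage = np.array(
            [gt[0] + gt[1] if gt[0] >= 0 and gt[1] >= 0 else np.nan
             for gt in variant.genotypes],
            dtype=float,
        )
        data[variant.ID] = (
            alt_dosage if alt == entry.effect_allele else 2.0 - alt_dosage
        )
    missing = wanted - set(data)
    if missing:
        raise ValueError(f"panel SNPs absent from VCF: {sorted(missing)}")
    dosage = np.column_stack([data[s] for s in panel.snp_ids])
    return GenotypeMatrix(samples, panel.snp_ids, dosage)


def write_qc_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")
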