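import warnings

import numpy as np
import pandas as pd
import pytest

from n3grs import GenotypeMatrix, SnpPanel, SnpPanelEntry, TgProfile
from n3grs.simulate import simulate_study, study_like_preset


def make_panel(n_snps=3, directions=None, mafs=None, prefix="rs"):
    """Small synthetic panel for unit tests."""
    directions = directions or [+1] * n_snps
    entries = []
    for j in range(n_snps):
        entries.append(
            SnpPanelEntry(
                snp_id=f"{prefix}{j + 1}",
                locus=f"LOC{j + 1}",
                effect_allele="A",
                other_allele="G",
                direction=directions[j],
                maf=None if mafs is None else mafs[j],
            )
        )
    return SnpPanel(entries)


def matrix_from_dosages(dosages, snp_ids=None):
    """GenotypeMatrix from a participants × SNPs nested list (None = missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in dosages]
    )
    n, m = arr.shape
    snp_ids = snp_ids or [f"rs{j + 1}" for j in range(m)]
    return GenotypeMatrix([f"P{i + 1}" for i in range(n)], snp_ids, arr)


def matrix_from_counts(n_hom_other, n_het, n_hom_effect, snp_id="rs1"):
    """Single-SNP matrix realizing the given genotype counts."""
    dosages = [0.0] * n_hom_other + [1.0] * n_het + [2.0] * n_hom_effect
    arr = np.array(dosages).reshape(-1, 1)
    return GenotypeMatrix([f"P{i + 1}" for i in range(len(dosages))], [snp_id], arr)


def hwe_exact_column(n, maf, rng=None):
    """Dosage column whose genotype counts are the rounded HWE expectations.

    The rounded counts keep the HWE chi-squared near zero deterministically,
    so a QC filter at any reasonable alpha retains the SNP; random binomial
    draws would fail at rate alpha per SNP.
    """
    n_hom_effect = round(n * maf**2)
    n_het = round(n * 2 * maf * (1 - maf))
    n_hom_other = n - n_hom_effect - n_het
    col = np.array([0.0] * n_hom_other + [1.0] * n_het + [2.0] * n_hom_effect)
    if rng is not None:
        rng.shuffle(col)
    return col


def covariates_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [p.age for p in profiles],
            "sex": [p.sex for p in profiles],
            "bmi": [p.bmi for p in profiles],
        }
    )


@pytest.fixture(scope="session")
def preset_cohort():
    """One simulated study-like cohort (n=800) shared across model tests."""
    config = study_like_preset(seed=11, n_participants=800)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = simulate_study(config)
    return bundle
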