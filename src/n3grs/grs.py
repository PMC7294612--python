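"""Signed rare-allele genetic risk score.

The score sums, over the (HWE-filtered) panel, the participant's effect-allele
dosage weighted by the panel direction: a heterozygote contributes ±1, a rare
homozygote ±2 and a major-allele homozygote 0. This is allele-count scoring —
each rare-allele copy counts — with unit weights; effect-size magnitudes are
deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, compute_maf
from .panel import SnpPanel

__all__ = ["GrsResult", "direction_from_or", "compute_grs", "grs_frame"]

MissingPolicy = Literal["skip", "strict", "mean_impute"]


@dataclass(frozen=True)
class GrsResult:
    participant_id: str
    score: float  # integer-valued except under mean_impute
    n_snps_used: int
    n_missing: int
    flag_high_missing: bool = False


def direction_from_or(odds_ratio: float) -> int:
    """Scoring sign from a prior association odds ratio.

    +1 for OR > 1 (each rare-allele copy raises the score), -1 for OR < 1.
    OR exactly 1 has no defined direction and raises; such a SNP must be
    excluded or assigned a sign explicitly.
    """
    if not odds_ratio > 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    if odds_ratio == 1.0:
        raise ValueError("odds ratio of exactly 1 has no direction")
    return +1 if odds_ratio > 1 else -1


def compute_grs(
    matrix: GenotypeMatrix,
    panel: SnpPanel,
    missing_policy: MissingPolicy = "skip",
    max_missing_frac: float = 0.2,
) -> list[GrsResult]:
    """Per-participant signed rare-allele score over the panel.

    missing_policy:
      * ``skip`` (default) — a missing genotype contributes 0 and increments
        ``n_missing``; participants missing more than ``max_missing_frac`` of
        the panel are flagged (never dropped silently).
      * ``strict`` — any missing genotype raises, naming participant and SNP.
      * ``mean_impute`` — a missing dosage is replaced by 2×MAF of that SNP in
        this cohort; scores are then non-integer.

    The panel is expected to be HWE-filtered upstream.
    """
    if missing_policy not in ("skip", "strict", "mean_impute"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    snp_ids = panel.snp_ids
    dirs = np.array([panel[s].direction for s in snp_ids], dtype=float)
    dosage = np.column_stack([matrix.column(s) for s in snp_ids])
    missing = np.isnan(dosage)

    if missing_policy == "strict" and missing.any():
        i, j = np.argwhere(missing)[0]
        raise ValueError(
            f"missing genotype for participant {matrix.participant_ids[i]!r} "
            f"at SNP {snp_ids[j]!r} under strict policy"
        )

    filled = dosage.copy()
    if missing_policy == "mean_impute":
        mafs = np.array([compute_maf(matrix, s) for s in snp_ids])
        filled = np.where(missing, 2 * mafs, filled)
    else:
        filled = np.where(missing, 0.0, filled)

    scores = filled @ dirs
    n_missing = missing.sum(axis=1)
    n_used = len(snp_ids) - n_missing
    results = []
    for i, pid in enumerate(matrix.participant_ids):
        used = len(snp_ids) if missing_policy == "mean_impute" else int(n_used[i])
        results.append(
            GrsResult(
                participant_id=pid,
                score=float(scores[i]),
                n_snps_used=used,
                n_missing=int(n_missing[i]),
                flag_high_missing=bool(
                    len(snp_ids) > 0 and n_missing[i] / len(snp_ids) > max_missing_frac
                ),
            )
        )
    return results


def grs_frame(results: list[GrsResult]) -> pd.DataFrame:
    """GRS results as a DataFrame (column order matches the TSV export)."""
    return pd.DataFrame(
        [
            (r.participant_id, r.score, r.n_snps_used, r.n_missing, r.flag_high_missing)
            for r in results
        ],
        columns=["participant_id", "grs", "n_snps_used", "n_missing", "flag_high_missing"],
    )


def write_grs_tsv(results: list[GrsResult], path: str | Path) -> None:
    grs_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
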