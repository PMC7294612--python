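"""SNP panel definitions for the omega-3 triglyceride-response GRS.

A panel entry records, for each biallelic SNP, the effect (rare) allele, the
sign of its prior association with adverse TG response (direction: +1 when the
discovery odds ratio exceeded 1, -1 when below 1), and — for SNPs that could
not be genotyped directly and were substituted by a proxy — the original rsID
and the LD r² of the substitution.

The module also ships the 31-SNP ComparED replication panel as built-in
reference data: per-SNP rare-allele frequencies in the replication (ComparED)
and discovery (FAS) cohorts together with the published 1-df chi-squared
comparison of the two. Per-SNP odds-ratio directions and allele bases were
never published for this panel, so the built-in entries carry a fixed
synthetic direction pattern and placeholder A/G alleles; they are suitable
for simulation and pipeline exercises, not for scoring real genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "SnpPanelEntry",
    "SnpPanel",
    "load_panel",
    "compared_panel",
    "compared_reference",
    "COMPARED_N_PARTICIPANTS",
    "FAS_N_PARTICIPANTS",
]

#: participants of the replication cohort with complete phases and genotypes
COMPARED_N_PARTICIPANTS = 122
#: participants of the discovery cohort
FAS_N_PARTICIPANTS = 208


@dataclass(frozen=True)
class SnpPanelEntry:
    """One SNP of a risk-score panel.

    direction is +1 when the rare allele's discovery odds ratio was > 1
    (each copy adds +1 to the score) and -1 when it was < 1.
    """

    snp_id: str
    locus: str
    effect_allele: str
    other_allele: str
    direction: int
    replaced_from: Optional[str] = None
    ld_r2: Optional[float] = None
    maf: Optional[float] = None  # panel-reference rare-allele frequency

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError(
                f"{self.snp_id}: direction must be +1 or -1, got {self.direction}"
            )
        if (self.replaced_from is None) != (self.ld_r2 is None):
            raise ValueError(
                f"{self.snp_id}: replaced_from and ld_r2 must be given together"
            )
        if self.ld_r2 is not None and not (0.0 < self.ld_r2 <= 1.0):
            raise ValueError(f"{self.snp_id}: ld_r2 must lie in (0, 1]")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"{self.snp_id}: maf must lie in [0, 1]")


class SnpPanel:
    """Ordered collection of :class:`SnpPanelEntry` with unique rsIDs."""

    def __init__(self, entries: Iterable[SnpPanelEntry]):
        self.entries: list[SnpPanelEntry] = list(entries)
        ids = [e.snp_id for e in self.entries]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate snp_ids in panel: {sorted(dupes)}")
        self._by_id = {e.snp_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SnpPanelEntry]:
        return iter(self.entries)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def __getitem__(self, snp_id: str) -> SnpPanelEntry:
        return self._by_id[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    @property
    def directions(self) -> dict[str, int]:
        return {e.snp_id: e.direction for e in self.entries}

    def subset(self, snp_ids: Sequence[str]) -> "SnpPanel":
        """Panel restricted to ``snp_ids``, keeping this panel's order."""
        keep = set(snp_ids)
        missing = keep - set(self._by_id)
        if missing:
            raise KeyError(f"snp_ids not in panel: {sorted(missing)}")
        return SnpPanel(e for e in self.entries if e.snp_id in keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.entries])

    def to_yaml(self, path: str | Path) -> None:
        records = [
            {k: v for k, v in asdict(e).items() if v is not None}
            for e in self.entries
        ]
        Path(path).write_text(yaml.safe_dump(records, sort_keys=False))


def load_panel(path: str | Path) -> SnpPanel:
    """Read a panel from a YAML or JSON list of entry mappings."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        records = json.loads(text)
    else:
        records = yaml.safe_load(text)
    if not isinstance(records, list):
        raise ValueError(f"{path}: expected a list of panel entries")
    return SnpPanel(SnpPanelEntry(**r) for r in records)


# --- Built-in ComparED replication panel -----------------------------------
# Columns: locus, rsID, rare-allele freq (ComparED), rare-allele freq (FAS),
# chi-squared (1 df, cohort comparison), p, original rsID if proxy, LD r².
_COMPARED_ROWS: list[tuple] = [
    ("IQCJ",  "rs62270407",  0.30,  0.28,  0.28,  0.59,    None,          None),
    ("IQCJ",  "rs7639707",   0.06,  0.043, 0.58,  0.45,    None,          None),
    ("NXPH1", "rs12702829",  0.34,  0.43,  4.0,   0.046,   None,          None),
    ("NXPH1", "rs1837523",   0.24,  0.26,  0.25,  0.62,    None,          None),
    ("NXPH1", "rs1990554",   0.01,  0.01,  0.03,  0.87,    None,          None),
    ("NXPH1", "rs6951762",   0.14,  0.16,  0.23,  0.63,    "rs6966968",   0.73),
    ("NXPH1", "rs10224945",  0.11,  0.10,  0.35,  0.55,    "rs78943417",  1.00),
    ("NXPH1", "rs28473103",  0.34,  0.36,  0.24,  0.63,    None,          None),
    ("NXPH1", "rs28673635",  0.16,  0.15,  0.10,  0.75,    None,          None),
    ("NXPH1", "rs293180",    0.11,  0.10,  0.003, 0.96,    None,          None),
    ("NXPH1", "rs61569932",  0.004, 0.01,  0.80,  0.37,    None,          None),
    ("NXPH1", "rs6463808",   0.14,  0.18,  1.19,  0.27,    None,          None),
    ("PHF17", "rs114348423", 0.008, 0.02,  1.52,  0.22,    None,          None),
    ("PHF17", "rs28437435",  0.16,  0.35,  25.65, 4.1e-07, "rs1216346",   0.91),
    ("PHF17", "rs75007521",  0.02,  0.029, 0.89,  0.34,    None,          None),
    ("MYB",   "rs210962",    0.20,  0.25,  1.79,  0.18,    None,          None),
    ("MYB",   "rs2050017",   0.15,  0.15,  0.02,  0.90,    "rs6933462",   1.00),
    ("MYB",   "rs72560788",  0.08,  0.09,  0.09,  0.76,    None,          None),
    ("MYB",   "rs72974149",  0.08,  0.09,  0.38,  0.54,    None,          None),
    ("NELL1", "rs117114492", 0.02,  0.02,  0.05,  0.83,    None,          None),
    ("NELL1", "rs78786240",  0.08,  0.03,  8.07,  0.005,   None,          None),
    ("NELL1", "rs1850875",   0.46,  0.42,  0.91,  0.34,    None,          None),
    ("NELL1", "rs11025436",  0.19,  0.13,  3.07,  0.08,    "rs79624996",  0.97),
    ("SLIT2", "rs143662727", 0.05,  0.02,  3.02,  0.08,    None,          None),
    ("SLIT2", "rs16869663",  0.07,  0.07,  0.08,  0.77,    None,          None),
    ("SLIT2", "rs1216349",   0.31,  0.11,  34.25, 4.9e-09, "rs184945470", 0.96),
    ("SLIT2", "rs61790364",  0.24,  0.18,  2.76,  0.10,    None,          None),
    ("SLIT2", "rs13137813",  0.50,  0.45,  1.55,  0.21,    "rs10009535",  1.00),
    ("SLIT2", "rs73241936",  0.20,  0.15,  1.98,  0.16,    None,          None),
    ("SLIT2", "rs76015249",  0.01,  0.011, 0.03,  0.87,    None,          None),
    ("SLIT2", "rs10009109",  0.44,  0.45,  0.02,  0.88,    None,          None),
]

#: the one panel SNP that failed Hardy-Weinberg QC in the replication cohort
HWE_EXCLUDED_SNP = "rs28473103"


def compared_reference() -> pd.DataFrame:
    """Published per-SNP reference table of the replication panel.

    Columns: locus, snp_id, maf_compared, maf_fas, chi_squared, p_value,
    replaced_from, ld_r2. Frequencies are rare-allele frequencies; the
    chi-squared column is the published 1-df allele-count comparison between
    the two cohorts.
    """
    return pd.DataFrame(
        _COMPARED_ROWS,
        columns=[
            "locus", "snp_id", "maf_compared", "maf_fas",
            "chi_squared", "p_value", "replaced_from", "ld_r2",
        ],
    )


def _synthetic_direction(index: int) -> int:
    # fixed pattern, roughly two thirds risk-increasing; see module docstring
    return -1 if index % 3 == 2 else +1


def compared_panel(mafs: str = "compared") -> SnpPanel:
    """The 31-SNP replication panel as a :class:`SnpPanel`.

    Parameters
    ----------
    mafs
        Which published frequency column to attach as each entry's ``maf``:
        ``"compared"`` (replication cohort) or ``"fas"`` (discovery cohort).

    Directions and allele bases are synthetic placeholders (not published);
    see the module docstring.
    """
    if mafs not in ("compared", "fas"):
        raise ValueError("mafs must be 'compared' or 'fas'")
    entries = []
    for i, (locus, rsid, maf_c, maf_f, _chi2, _p, repl, r2) in enumerate(_COMPARED_ROWS):
        entries.append(
            SnpPanelEntry(
                snp_id=rsid,
                locus=locus,
                effect_allele="A",
                other_allele="G",
                direction=_synthetic_direction(i),
                replaced_from=repl,
                ld_r2=r2,
                maf=maf_c if mafs == "compared" else maf_f,
            )
        )
    return SnpPanel(entries)
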