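"""End-to-end pipeline: QC → score → classify → associate → report.

Per treatment the pipeline runs the Hardy-Weinberg filter, the per-SNP QC
table, the signed GRS, ΔTG computation and responder classification, an
ordinal fit over all three classes, a binary fit with non-responders
excluded, per-SNP subgroup allele-frequency comparisons, and predicted
probability curves. All artifacts are written with fixed precision so a
rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationFit,
    fit_binary,
    fit_ordinal,
    predict_curves,
    subgroup_maf_tests,
    write_fit_json,
)
from .genotypes import (
    GenotypeMatrix,
    filter_hwe,
    maf_table,
    read_genotypes_tsv,
    read_genotypes_vcf,
    write_qc_report,
)
from .grs import compute_grs, grs_frame
from .panel import SnpPanel, load_panel
from .response import (
    TREATMENTS,
    DEFAULT_WINDOW,
    classify_cohort,
    estimate_window,
    labels_frame,
    read_phenotypes_csv,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

SUBGROUP_PAIRS = (("R", "NR"), ("NR", "AR"), ("R", "AR"))


class PipelineError(RuntimeError):
    """Stage failure, carrying the stage name in the message."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """File paths and analysis settings for one pipeline run."""

    genotypes: str
    phenotypes: str
    panel: str
    out_dir: str
    hwe_alpha: float = 0.05
    rare_maf_threshold: float = 0.05
    window: float | str = DEFAULT_WINDOW  # mmol/l, or "estimate"
    missing_policy: str = "skip"
    treatments: Sequence[str] = TREATMENTS
    reference_n_alleles: Optional[int] = None  # enables panel-MAF comparison
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hwe_alpha <= 1.0):
            raise ValueError("hwe_alpha must lie in [0, 1]")
        if not (0.0 <= self.rare_maf_threshold <= 1.0):
            raise ValueError("rare_maf_threshold must lie in [0, 1]")
        if isinstance(self.window, str):
            if self.window != "estimate":
                raise ValueError("window must be a number or 'estimate'")
        elif self.window < 0:
            raise ValueError("window must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_genotypes(path: str, panel: SnpPanel) -> GenotypeMatrix:
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return read_genotypes_vcf(path, panel)
    return read_genotypes_tsv(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    Artifacts written to ``config.out_dir``: qc_report.tsv, grs.tsv,
    classification.tsv, association_<T>_{ordinal,binary}.json,
    curves_<T>_{ordinal,binary}.tsv, subgroup_maf_<T>_<A>_vs_<B>.tsv and
    run_log.json. Any stage error propagates as :class:`PipelineError`
    naming the stage; partial outputs are flagged in the run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "config_hash": config.digest(),
        "versions": _versions(),
        "stages": {},
        "complete": False,
    }
    report: dict = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log["stages"][name] = {"status": "failed", "error": str(exc)}
                    _write_log(out, log)
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    with stage("load"):
        panel = load_panel(config.panel)
        matrix = _load_genotypes(config.genotypes, panel)
        profiles = read_phenotypes_csv(config.phenotypes)
        geno_ids = set(matrix.participant_ids)
        profiles = [p for p in profiles if p.participant_id in geno_ids]
        pheno_ids = {p.participant_id for p in profiles}
        keep = [i for i, pid in enumerate(matrix.participant_ids) if pid in pheno_ids]
        matrix = GenotypeMatrix(
            [matrix.participant_ids[i] for i in keep],
            matrix.snp_ids,
            matrix.dosage[keep],
        )
        order = {pid: i for i, pid in enumerate(matrix.participant_ids)}
        profiles.sort(key=lambda p: order[p.participant_id])
        log["stages"]["load"] = {
            "n_participants": matrix.n_participants,
            "n_snps": len(panel),
        }

    with stage("qc"):
        retained, excluded = filter_hwe(matrix, panel, config.hwe_alpha)
        reference = (
            {e.snp_id: e.maf for e in panel if e.maf is not None}
            if config.reference_n_alleles
            else None
        )
        qc = maf_table(
            matrix,
            panel,
            reference_mafs=reference,
            reference_n_alleles=config.reference_n_alleles,
            rare_threshold=config.rare_maf_threshold,
            hwe_alpha=config.hwe_alpha,
        )
        write_qc_report(qc, out / "qc_report.tsv")
        log["stages"]["qc"] = {
            "n_retained": len(retained),
            "n_excluded_hwe": len(excluded),
            "excluded_snps": [r.snp_id for r in excluded],
            "n_rare": int(qc["rare_flag"].sum()),
        }
        report["qc"] = qc
        report["panel_retained"] = retained

    with stage("score"):
        grs_results = compute_grs(matrix, retained, config.missing_policy)
        gdf = grs_frame(grs_results)
        gdf.to_csv(out / "grs.tsv", sep="\t", index=False, float_format="%.6g")
        log["stages"]["score"] = {
            "n_scored": len(grs_results),
            "n_flag_high_missing": int(gdf["flag_high_missing"].sum()),
        }
        report["grs"] = gdf

    with stage("classify"):
        window = (
            estimate_window(profiles)
            if config.window == "estimate"
            else float(config.window)
        )
        labels = classify_cohort(profiles, window, config.treatments)
        ldf = labels_frame(labels, window)
        ldf.to_csv(out / "classification.tsv", sep="\t", index=False,
                   float_format="%.6g")
        log["stages"]["classify"] = {
            "window": window,
            "n_labelled": len({l.participant_id for l in labels}),
            "class_counts": {
                t: ldf[ldf.treatment == t]["label"].value_counts().to_dict()
                for t in config.treatments
            },
        }
        report["labels"] = labels
        report["window"] = window

    with stage("associate"):
        grs_by_id = dict(zip(gdf["participant_id"], gdf["grs"]))
        cov = pd.DataFrame(
            {
                "age": [p.age for p in profiles],
                "sex": [p.sex for p in profiles],
                "bmi": [p.bmi for p in profiles],
            }
        )
        pids = [p.participant_id for p in profiles]
        grs_vec = np.array([grs_by_id[pid] for pid in pids])
        fits: dict[str, dict[str, AssociationFit]] = {}
        for t in config.treatments:
            by_id = {l.participant_id: l.label for l in labels if l.treatment == t}
            y = pd.Series([by_id[pid] for pid in pids])
            fits[t] = {}
            fits[t]["ordinal"] = fit_ordinal(y, grs_vec, cov)
            mask = (y != "NR").to_numpy()
            fits[t]["binary"] = fit_binary(
                y[mask], grs_vec[mask], cov[mask].reset_index(drop=True)
            )
            for kind, fit in fits[t].items():
                write_fit_json(fit, out / f"association_{t}_{kind}.json")
                grid = np.arange(
                    np.floor(fit.grs_range[0]), np.ceil(fit.grs_range[1]) + 1
                )
                curve = predict_curves(fit, grid)
                curve.to_frame().to_csv(
                    out / f"curves_{t}_{kind}.tsv", sep="\t", index=False,
                    float_format="%.6g",
                )
            for pair in SUBGROUP_PAIRS:
                try:
                    comps = subgroup_maf_tests(matrix, retained, labels, pair, t)
                except ValueError as err:
                    log["stages"].setdefault("subgroup_skipped", []).append(
                        f"{t} {pair[0]}-vs-{pair[1]}: {err}"
                    )
                    continue
                pd.DataFrame(
                    [
                        (c.snp_id, c.maf_a, c.maf_b, c.chi_squared, c.p_value,
                         c.degenerate)
                        for c in comps
                    ],
                    columns=["snp_id", f"maf_{pair[0]}", f"maf_{pair[1]}",
                             "chi_squared", "p_value", "degenerate"],
                ).to_csv(
                    out / f"subgroup_maf_{t}_{pair[0]}_vs_{pair[1]}.tsv",
                    sep="\t", index=False, float_format="%.6g",
                )
        log["stages"]["associate"] = {
            t: {
                kind: {
                    "n_obs": fit.n_obs,
                    "or_grs": fit.or_grs,
                    "wald_p": fit.wald_p,
                    "converged": fit.converged,
                }
                for kind, fit in fits[t].items()
            }
            for t in config.treatments
        }
        report["fits"] = fits

    log["complete"] = True
    _write_log(out, log)
    report["log"] = log
    return report


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "n3grs": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_log(out: Path, log: dict) -> None:
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
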