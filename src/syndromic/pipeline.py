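"""End-to-end pipeline orchestration and the printed-count worked examples.

``run_pipeline`` executes the requested stages in dependency order on a
simulated or supplied cohort and writes a manifest recording inputs, seeds
and SHA-256 hashes of every output, so identical configurations produce
identical manifests. ``reproduce_printed_examples`` recomputes every
quantity derivable from the published summary counts and reports pass/fail
at the display rounding used by the original tables (2 dp for odds ratios,
1 dp for percentages).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import reference as ref
from .cohort import (
    DEFAULT_SEED,
    default_calibration,
    generate_cohort_frame,
)
from .errors import ConfigurationError
from .logistic import MODEL_1A, MODEL_1B, fit_logistic
from .logodds import DirichletLogOddsContrast
from .profiles import band_frequency_matrix, hierarchical_clustering, pca, kmeans_with_silhouette
from .scores import classify_cohort
from .stats import ContingencyTable2x2, fisher_exact_p, odds_ratio, table1_summary

STAGE_ORDER = ("classify", "table1", "regress", "logodds", "profiles")
_NEED_CLASSIFY = ("table1", "regress", "logodds", "profiles")

#: Display rounding matching the published tables.
OR_DECIMALS = 2
PCT_DECIMALS = 1


@dataclass
class PipelineConfig:
    """What to run, on which cohort, and where outputs go."""

    output_dir: str
    input_path: Optional[str] = None
    n_patients: int = ref.N_TOTAL
    seed: int = DEFAULT_SEED
    stages: tuple = STAGE_ORDER

    def validate(self) -> "PipelineConfig":
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigurationError("stages", f"unknown stage(s) {sorted(unknown)}")
        for stage in _NEED_CLASSIFY:
            if stage in self.stages and "classify" not in self.stages:
                raise ConfigurationError(
                    "stages", f"stage {stage!r} requires the classify stage"
                )
        return self


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t_start = time.time()

    def emit_csv(name: str, frame: pd.DataFrame) -> Path:
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        return path

    def emit_json(name: str, payload) -> Path:
        path = outdir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")
        written.append(path)
        return path

    try:
        if config.input_path is not None:
            in_path = Path(config.input_path)
            if not in_path.exists():
                raise FileNotFoundError(f"cohort file not found: {in_path}")
            cohort = pd.read_csv(in_path)
        else:
            cohort = generate_cohort_frame(
                default_calibration(n_patients=config.n_patients, seed=config.seed)
            )

        stages = [s for s in STAGE_ORDER if s in config.stages]
        stage_info = {}

        classified = classify_cohort(cohort)
        if "classify" in stages:
            emit_csv("cohort_classified.csv", classified)
            stage_info["classify"] = dict(
                n_records=int(len(classified)),
                n_meeting=int(classified["meets_definition"].sum()),
            )

        if "table1" in stages:
            emit_csv("table1.csv", table1_summary(classified))
            stage_info["table1"] = dict(n_rows=int(len(table1_summary(classified))))

        if "regress" in stages:
            for label, spec in (("1a", MODEL_1A), ("1b", MODEL_1B)):
                fit = fit_logistic(classified, spec)
                emit_json(
                    f"fit_{label}.json",
                    dict(
                        model=label,
                        terms=fit.terms,
                        estimates=fit.aor,
                        n_used=fit.n_used,
                        converged=bool(fit.converged),
                        iterations=fit.iterations,
                        log_likelihood=fit.log_likelihood,
                    ),
                )
            stage_info["regress"] = dict(models=["1a", "1b"])

        if "logodds" in stages:
            contrast = DirichletLogOddsContrast().fit(classified)
            frame = contrast.transform()
            frame.insert(1, "y_older", contrast.counts_.y_i)
            frame.insert(2, "y_younger", contrast.counts_.y_j)
            emit_csv("logodds.csv", frame)
            stage_info["logodds"] = dict(ranking=contrast.ranking_)

        if "profiles" in stages:
            profile = band_frequency_matrix(classified)
            emit_csv("prof_freq.csv", profile.freq.reset_index(names="band"))
            emit_csv("prof_z.csv", profile.zmat.reset_index(names="band"))
            pca_res = pca(profile)
            scores = pca_res.scores_frame().reset_index(names="band")
            scores["explained_variance_ratio"] = list(
                pca_res.explained_variance_ratio
            ) + [np.nan] * (len(scores) - len(pca_res.explained_variance_ratio))
            emit_csv("prof_pca.csv", scores)
            clusters = kmeans_with_silhouette(
                pca_res.scores[:, :2], seed=config.seed
            )
            emit_csv(
                "prof_clusters.csv",
                pd.DataFrame(
                    dict(
                        band=list(pca_res.row_labels),
                        cluster=clusters.assignments,
                        silhouette=clusters.silhouette_values,
                    )
                ),
            )
            dend = hierarchical_clustering(profile)
            emit_json(
                "prof_dendrogram.json",
                dict(
                    labels=list(dend.labels),
                    linkage=dend.linkage_method,
                    merges=[
                        [int(a), int(b), float(h), int(s)]
                        for a, b, h, s in dend.merges
                    ],
                    tree=dend.tree,
                ),
            )
            stage_info["profiles"] = dict(
                k=clusters.k, mean_silhouette=clusters.mean_silhouette
            )

        manifest = dict(
            version=__version__,
            seed=config.seed,
            n_patients=int(len(cohort)),
            input=str(config.input_path) if config.input_path else "simulated",
            stages=stages,
            stage_info=stage_info,
            outputs={p.name: _sha256(p) for p in sorted(written)},
            wall_time_s=round(time.time() - t_start, 3),
        )
        hashable = {k: v for k, v in manifest.items() if k != "wall_time_s"}
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(hashable, sort_keys=True).encode()
        ).hexdigest()
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        return manifest
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


# ---------------------------------------------------------------------------
# Worked examples from the published counts
# ---------------------------------------------------------------------------


def _check(name, computed, expected, tol):
    return dict(
        name=name,
        computed=float(computed),
        expected=float(expected),
        tolerance=tol,
        passed=bool(abs(computed - expected) <= tol),
    )


def reproduce_printed_examples() -> pd.DataFrame:
    """Recompute every published-count worked example and compare at display rounding.

    Tolerances are half a unit in the last printed digit plus the rounding
    slack of the source (percentages printed to 0.1, odds ratios to 0.01).
    """
    checks = []

    pct = 100.0 * ref.N_MEETING / ref.N_TOTAL
    checks.append(_check("pct_meeting_definition", pct, 48.1, 0.1))

    meet_old, not_old, meet_young, not_young = ref.age_counts_ge_65()
    est = odds_ratio(ContingencyTable2x2(meet_old, not_old, meet_young, not_young))
    checks.append(_check("or_age_ge_65", est.or_point, 0.62, 0.005))
    checks.append(_check("or_age_ge_65_ci_low", est.ci_low, 0.58, 0.005))
    checks.append(_check("or_age_ge_65_ci_high", est.ci_high, 0.66, 0.005))

    dem = ContingencyTable2x2(
        ref.DEMENTIA[1],
        ref.DEMENTIA[0],
        ref.N_MEETING - ref.DEMENTIA[1],
        ref.N_NOT_MEETING - ref.DEMENTIA[0],
    )
    checks.append(_check("or_dementia", odds_ratio(dem).or_point, 0.52, 0.005))

    n_meet_known = ref.N_MEETING - ref.CCI_UNKNOWN[1]
    n_not_known = ref.N_NOT_MEETING - ref.CCI_UNKNOWN[0]
    cci = ContingencyTable2x2(
        ref.CCI_COUNTS[">4"][1],
        ref.CCI_COUNTS[">4"][0],
        n_meet_known - ref.CCI_COUNTS[">4"][1],
        n_not_known - ref.CCI_COUNTS[">4"][0],
    )
    checks.append(_check("or_cci_gt_4", odds_ratio(cci).or_point, 0.78, 0.005))

    male = ContingencyTable2x2(
        ref.MALE_SEX[1],
        ref.MALE_SEX[0],
        ref.N_MEETING - ref.MALE_SEX[1],
        ref.N_NOT_MEETING - ref.MALE_SEX[0],
    )
    checks.append(_check("or_male_sex", odds_ratio(male).or_point, 1.04, 0.005))
    checks.append(
        _check("p_male_sex", fisher_exact_p(male), 0.2, 0.1)
    )

    checks.append(
        _check(
            "pct_sars_cov2_positive",
            100.0 * ref.N_SARS_POSITIVE_TOTAL / ref.N_TOTAL,
            41.5,
            0.05,
        )
    )
    checks.append(
        _check("pct_pneumonia", 100.0 * ref.N_PNEUMONIA / ref.N_TOTAL, 57.5, 0.05)
    )
    checks.append(
        _check(
            "pct_recruited_by_criteria",
            100.0 * ref.N_MEETING_RECRUITMENT_CRITERIA / ref.N_SUSPECTED_ALRTD,
            87.1,
            0.05,
        )
    )
    checks.append(
        _check(
            "pct_care_home_not_meeting",
            100.0 * ref.CARE_HOME[0] / ref.N_NOT_MEETING,
            10.0,
            0.05,
        )
    )
    return pd.DataFrame(checks)
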