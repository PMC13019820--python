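"""End-to-end orchestration of the five-question analysis.

Q1 psychometrics (robust regressions of empathy on the psychopathy factors,
group contrasts, Spearman matrix); Q2 parcel-wise brain-behavior maps with
FDR and partition contrasts; Q3 out-of-sample ridge prediction with a
permutation null; Q4 group differences in cortical structure plus overlap
with binary masks; Q5 structural-covariance gradients, alignment,
compression, and spin-test consistency against a reference cohort.

Every stage writes its artifact files into the output directory and
contributes to ``report.json``; all randomness flows from the config seeds,
and timings go to the log only so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import ParcelAtlas
from .brainmaps import compare_by_partition, map_association, overlap_with_masks
from .cohort import Cohort, MorphometryMatrix, SyntheticConfig, generate_cohort
from .gradients import StructuralCovarianceGradients
from .prediction import RidgePrediction
from .psychometrics import spearman_matrix
from .robust import RobustLinearModel
from .spin import spin_permutation_corr
from .stats import cohens_d_from_samples

logger = logging.getLogger("psychocortex")

SCORE_MAXIMA = {
    "pclr_f1": 16.0,
    "pclr_f2": 20.0,
    "pclr_total": 40.0,
    "iri_pt": 28.0,
    "iri_ec": 28.0,
}


@dataclass
class PipelineConfig:
    """Fully resolved configuration of one pipeline run."""

    output_dir: str = "psychocortex_run"
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # optional TSV paths
    questions: dict = field(
        default_factory=lambda: {f"q{i}": True for i in range(1, 6)}
    )
    fdr_q: float = 0.05
    n_perm_prediction: int = 10000
    n_perm_spin: int = 1000
    test_fraction: float = 0.199
    prediction_targets: tuple = ("pclr_f1", "pclr_f2", "iri_pt", "iri_ec")
    prediction_indices: tuple = ("SA",)
    map_predictors: tuple = ("iri_pt", "iri_ec", "pclr_f1", "pclr_f2")
    map_indices: tuple = ("CT", "SA")
    gradient_indices: tuple = ("CT", "SA")
    reference_n_subjects: int = 250
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("prediction_targets", "prediction_indices", "map_predictors",
                    "map_indices", "gradient_indices"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic_resolved"] = dataclasses.asdict(
            SyntheticConfig(**dict(self.synthetic, seed=self.seed))
        )
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_or_generate(config: PipelineConfig) -> Cohort:
    if config.inputs:
        atlas = ParcelAtlas.from_tsv(config.inputs["parcels"])
        subjects = pd.read_csv(config.inputs["subjects"], sep="\t").set_index(
            "subject_id"
        )
        cov = subjects[["age", "iq", "tiv"]]
        ct = MorphometryMatrix.from_tsv(config.inputs["ct"], "CT", cov)
        sa = MorphometryMatrix.from_tsv(config.inputs["sa"], "SA", cov)
        syn = SyntheticConfig(**dict(config.synthetic, seed=config.seed))
        return Cohort(atlas, subjects, ct, sa, syn)
    syn = SyntheticConfig(**dict(config.synthetic, seed=config.seed))
    return generate_cohort(syn)


def _fit_behavior_regression(subjects, response, predictors):
    res = RobustLinearModel.from_dataframe(subjects, response, predictors).fit()
    return {
        "response": response,
        "predictors": list(predictors),
        "beta_z": res.beta_z.tolist(),
        "beta_z_ci": res.beta_z_ci.tolist(),
        "p": res.pvalues[1:].tolist(),
        "adj_r2": res.adj_r2,
        "n": res.nobs,
    }


def _run_q1(cohort: Cohort) -> dict:
    subj = cohort.subjects
    out = {"regressions": [], "group_contrasts": [], "unique_contrasts": []}
    for factor in ("pclr_f1", "pclr_f2"):
        for iri in ("iri_pt", "iri_ec"):
            fit = _fit_behavior_regression(subj, iri, [factor, "age", "iq"])
            fit["p_bonferroni"] = min(1.0, fit["p"][0] * 2)  # across IRI subscales
            out["regressions"].append(fit)
    two = subj[subj["group"].isin(["low", "high"])].copy()
    two["is_high"] = (two["group"] == "high").astype(float)
    for iri in ("iri_pt", "iri_ec"):
        fit = _fit_behavior_regression(two, iri, ["is_high", "age", "iq"])
        fit["p_bonferroni"] = min(1.0, fit["p"][0] * 2)
        d = cohens_d_from_samples(
            two.loc[two["group"] == "low", iri], two.loc[two["group"] == "high", iri]
        )
        fit["cohens_d"] = d.d
        out["group_contrasts"].append(fit)
        other = "iri_ec" if iri == "iri_pt" else "iri_pt"
        out["unique_contrasts"].append(
            _fit_behavior_regression(two, iri, ["is_high", other, "age", "iq"])
        )
    corr = spearman_matrix(
        subj[["iri_pt", "iri_ec", "pclr_f1", "pclr_f2", "pclr_total",
              "age", "iq", "tiv"]]
    )
    out["spearman"] = {
        "variables": corr.variables,
        "rho": np.round(corr.rho, 6).tolist(),
        "p": corr.p.tolist(),
        "significant_bonferroni": corr.significant.tolist(),
        "m_tests": corr.m_tests,
    }
    return out


def _run_q2(cohort: Cohort, config: PipelineConfig, outdir: Path) -> dict:
    out = {}
    for index_kind in config.map_indices:
        morph = cohort.ct if index_kind == "CT" else cohort.sa
        for predictor in config.map_predictors:
            emap = map_association(
                morph,
                cohort.subjects[predictor],
                atlas=cohort.atlas,
                q_level=config.fdr_q,
            )
            emap.to_tsv(outdir / f"effectmap_{index_kind.lower()}_{predictor}.tsv")
            entry = {"n_significant": emap.n_significant, "partition": {}}
            for part in ("class", "network"):
                comp = compare_by_partition(emap, cohort.atlas, part)
                entry["partition"][part] = comp
            out[f"{index_kind}_{predictor}"] = entry
    return out


def _run_q3(cohort: Cohort, config: PipelineConfig, outdir: Path) -> dict:
    out = {}
    for index_kind in config.prediction_indices:
        morph = cohort.ct if index_kind == "CT" else cohort.sa
        for target in config.prediction_targets:
            y = cohort.subjects[target].dropna()
            model = RidgePrediction(
                morph.values.loc[y.index].to_numpy(),
                y,
                morph.covariates.loc[y.index].to_numpy(),
                SCORE_MAXIMA[target],
                test_fraction=config.test_fraction,
                seed=config.seed,
                target_name=target,
                index_kind=index_kind,
            )
            res = model.fit(n_perm=config.n_perm_prediction)
            key = f"{index_kind}_{target}"
            out[key] = res.to_dict()
            np.savetxt(
                outdir / f"null_mse_{key}.tsv", res.null_mse, header="null_mse",
                comments="",
            )
            with open(outdir / f"prediction_{key}.json", "w") as fh:
                json.dump(res.to_dict(), fh, indent=2, sort_keys=True)
    return out


def _synthetic_masks(atlas: ParcelAtlas) -> dict:
    """Synthetic stand-ins for meta-analytic activation masks.

    Built from the atlas partitions: the 'affective' baseline covers
    paralimbic/somatomotor/limbic cortex, the 'cognitive' baseline covers
    default-mode/frontoparietal cortex; preferential and unique variants
    follow the usual set arithmetic.
    """
    aff = (
        (atlas.mesulam_class == "paralimbic")
        | (atlas.yeo_network == "somatomotor")
        | (atlas.yeo_network == "limbic")
    )
    cog = (atlas.yeo_network == "default_mode") | (
        atlas.yeo_network == "frontoparietal"
    )
    return {
        "affective_baseline": aff,
        "cognitive_baseline": cog,
        "affective_preferential": aff & ~cog,
        "cognitive_preferential": cog & ~aff,
        "affective_unique": aff & ~cog,
        "cognitive_unique": cog & ~aff,
    }


def _run_q4(cohort: Cohort, config: PipelineConfig, outdir: Path) -> dict:
    subj = cohort.subjects
    two = subj[subj["group"].isin(["low", "high"])]
    is_high = (two["group"] == "high").astype(float).rename("is_high")
    out = {}
    for index_kind in ("CT", "SA"):
        morph = cohort.ct if index_kind == "CT" else cohort.sa
        sub_morph = MorphometryMatrix(
            morph.values.loc[two.index], index_kind, morph.covariates.loc[two.index]
        )
        emap = map_association(
            sub_morph, is_high, atlas=cohort.atlas, q_level=config.fdr_q
        )
        emap.to_tsv(outdir / f"effectmap_{index_kind.lower()}_group.tsv")
        increased = emap.table["significant"] & (emap.table["beta_z"] > 0)
        entry = {
            "n_significant": emap.n_significant,
            "n_increased": int(increased.sum()),
            "partition": {
                part: compare_by_partition(emap, cohort.atlas, part)
                for part in ("class", "network")
            },
        }
        # global (total) index ~ group + covariates
        total = sub_morph.values.sum(axis=1).rename(f"total_{index_kind.lower()}")
        frame = pd.concat([total, is_high, sub_morph.covariates], axis=1)
        covs = list(map_covariates(index_kind))
        fit = _fit_behavior_regression(
            frame, total.name, ["is_high"] + covs
        )
        fit["cohens_d"] = cohens_d_from_samples(
            total[two["group"] == "low"], total[two["group"] == "high"]
        ).d
        entry["global"] = fit
        if index_kind == "SA":
            masks = _synthetic_masks(cohort.atlas)
            overlap = overlap_with_masks(
                increased.to_numpy(), masks, cohort.atlas.n_parcels
            )
            overlap.to_csv(outdir / "overlap_sa_group.tsv", sep="\t", index=False)
            entry["overlap"] = overlap.to_dict(orient="records")
        out[index_kind] = entry
    return out


def map_covariates(index_kind: str):
    from .brainmaps import DEFAULT_COVARIATES

    return DEFAULT_COVARIATES[index_kind]


def _run_q5(cohort: Cohort, config: PipelineConfig, outdir: Path) -> dict:
    out = {}
    # reference cohort standing in for a normative external sample
    ref_syn = SyntheticConfig(
        n_subjects={"low": config.reference_n_subjects},
        n_parcels=cohort.atlas.n_parcels,
        gradient_strength=SyntheticConfig(
            **dict(config.synthetic, seed=config.seed)
        ).gradient_strength,
        seed=config.seed + 1,
    )
    reference = generate_cohort(ref_syn, atlas=cohort.atlas)
    for index_kind in config.gradient_indices:
        morph = cohort.ct if index_kind == "CT" else cohort.sa
        model = StructuralCovarianceGradients(
            morph, cohort.subjects["group"], atlas=cohort.atlas
        )
        res = model.fit()
        res.template.to_frame(cohort.atlas).to_csv(
            outdir / f"gradients_{index_kind.lower()}_total.tsv", sep="\t", index=False
        )
        for group, gset in res.aligned.items():
            gset.to_frame(cohort.atlas).to_csv(
                outdir / f"gradients_{index_kind.lower()}_{group}.tsv",
                sep="\t",
                index=False,
            )
        np.savetxt(
            outdir / f"eigenvalues_{index_kind.lower()}_total.tsv",
            res.template.eigenvalues,
            header="eigenvalue",
            comments="",
        )
        entry = {
            "variance_explained": res.template.variance_explained.tolist(),
            "compression": res.compression.to_dict() if res.compression else None,
            "partition": res.partition,
        }
        # consistency of the template gradient with the reference cohort
        ref_morph = reference.ct if index_kind == "CT" else reference.sa
        ref_model = StructuralCovarianceGradients(
            ref_morph, reference.subjects["group"], atlas=reference.atlas
        )
        ref_template = ref_model._embed(
            np.ones(ref_morph.n_subjects, dtype=bool), "reference",
            orient_to=reference.atlas.ap_axis,
        )
        spin = spin_permutation_corr(
            res.template.component(0),
            ref_template.component(0),
            cohort.atlas,
            n_perm=config.n_perm_spin,
            seed=config.seed,
        )
        entry["reference_consistency"] = {
            "r": spin.r_observed,
            "p_spin": spin.p_spin,
            "n_perm": spin.n_perm,
        }
        with open(outdir / f"compression_{index_kind.lower()}.json", "w") as fh:
            json.dump(entry, fh, indent=2, sort_keys=True, default=float)
        out[index_kind] = entry
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write artifacts plus report.json."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    report = {"config": config.resolved(), "questions": {}}
    stage = "simulate"
    try:
        t0 = time.time()
        cohort = _load_or_generate(config)
        cohort.write(outdir)
        logger.info("stage simulate done in %.1fs", time.time() - t0)
        report["n_subjects"] = int(len(cohort.subjects))
        report["n_parcels"] = int(cohort.atlas.n_parcels)
        report["group_counts"] = {
            str(k): int(v)
            for k, v in sorted(cohort.subjects["group"].value_counts().items())
        }

        stages = {
            "q1": lambda: _run_q1(cohort),
            "q2": lambda: _run_q2(cohort, config, outdir),
            "q3": lambda: _run_q3(cohort, config, outdir),
            "q4": lambda: _run_q4(cohort, config, outdir),
            "q5": lambda: _run_q5(cohort, config, outdir),
        }
        for q, fn in stages.items():
            stage = q
            if not config.questions.get(q, True):
                report["questions"][q] = "skipped"
                logger.info("stage %s skipped", q)
                continue
            t0 = time.time()
            report["questions"][q] = fn()
            logger.info("stage %s done in %.1fs", q, time.time() - t0)
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage {stage}: {err}\n")
        logger.removeHandler(handler)
        raise StageError(stage, err) from err

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    logger.removeHandler(handler)
    return report
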