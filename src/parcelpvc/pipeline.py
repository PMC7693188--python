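"""End-to-end orchestration of the three analysis models.

The reference analysis compares three pipelines: (1) rigid coregistration
with no PVC, (2) affine coregistration with constrained GTM PVC, and
(3) nonlinear coregistration with constrained GTM PVC.  ``run_subject``
sequences the per-subject stages in method order — relabel, mask,
register, regional means, GTM inversion, SUVR normalization, goodness of
fit — and ``run_cohort_analysis`` produces the per-parcel regression /
partial-correlation / FDR report tables and the ventricle negative
control.  All randomness flows from ``RunConfig.seed``.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import register as reg
from .forward import PSFModel, build_pet_model, goodness_of_fit
from .parcels import ParcelTable, brain_mask, regional_means, relabel_unsegmented
from .phantom import (
    CohortTable,
    PhantomSpec,
    apply_known_misregistration,
    default_activity_map,
    make_parcellation_phantom,
    simulate_pet,
    split_seed,
)
from .pvc import GTMModel
from .stats import (
    bh_fdr,
    group_summaries,
    multivariable_regression,
    normalize_parcel_trajectories,
    partial_correlation,
    simple_regression,
    significance_stars,
)
from .volumes import LabelVolume, ScalarVolume

__all__ = ["RunConfig", "SubjectResult", "run_subject", "run_cohort_analysis"]

COREG_MODES = ("none", "rigid", "affine", "nonlinear", "exact")
PVC_MODES = ("none", "unconstrained", "constrained")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML-loadable)."""

    coreg: str = "rigid"
    pvc: str = "none"
    fwhm_mm: float = 8.0
    reference: str = "brainstem"
    fdr_q: float = 0.1
    seed: int = 0
    out_dir: str | None = None
    # synthetic inputs
    phantom: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    misregistration: dict | None = None  # {"translation_mm": [...], "rotation_deg": [...]}
    # file inputs (override the phantom when set)
    labels_path: str | None = None
    pet_path: str | None = None
    parcels_path: str | None = None
    cohort_path: str | None = None
    unsegmented_ids: list = field(default_factory=list)
    nonlinear_backend: str = "identity"
    register_levels: tuple = (4, 2, 1)
    model_refinements: int = 1  # re-estimate the model-guided target once
    ci_level: float = 0.95

    def __post_init__(self):
        if self.coreg not in COREG_MODES:
            raise ValueError(f"coreg must be one of {COREG_MODES}")
        if self.pvc not in PVC_MODES:
            raise ValueError(f"pvc must be one of {PVC_MODES}")
        if self.pvc != "none" and self.fwhm_mm <= 0:
            raise ValueError("FWHM must be > 0 when PVC is enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SubjectResult:
    """Per-subject outputs of one pipeline model."""

    config: RunConfig
    suvr: pd.Series
    corrected: pd.Series
    observed_means: pd.DataFrame
    transform: object
    fit_whole_brain: float
    fit_cortex: float
    stage_log: list

    def header_comment(self) -> str:
        return f"# coreg={self.config.coreg} pvc={self.config.pvc} fwhm_mm={self.config.fwhm_mm} seed={self.config.seed}\n"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        suvr_df = pd.DataFrame({"label": self.suvr.index, "suvr": self.suvr.values})
        corr_df = pd.DataFrame(
            {"label": self.corrected.index, "corrected": self.corrected.values}
        )
        for name, df in (("suvr.csv", suvr_df), ("corrected.csv", corr_df)):
            with open(out / name, "w") as fh:
                fh.write(self.header_comment())
                df.to_csv(fh, index=False)
        fits = pd.DataFrame(
            [
                {"mask_name": "whole_brain", "fwhm_mm": self.config.fwhm_mm, "fit": self.fit_whole_brain},
                {"mask_name": "cortex", "fwhm_mm": self.config.fwhm_mm, "fit": self.fit_cortex},
            ]
        )
        with open(out / "fit.csv", "w") as fh:
            fh.write(self.header_comment())
            fits.to_csv(fh, index=False)
        if isinstance(self.transform, (reg.RigidTransform, reg.AffineTransform)):
            m = self.transform.matrix if isinstance(self.transform, reg.RigidTransform) else self.transform.matrix
            np.savetxt(out / "transform.txt", m[:3, :], fmt="%.12g")
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.stage_log, fh, indent=2, default=str)


def _load_inputs(config: RunConfig):
    if config.labels_path:
        labels = LabelVolume.from_nifti(config.labels_path)
        parcels = ParcelTable.from_tsv(config.parcels_path)
        pet = ScalarVolume.from_nifti(config.pet_path)
        return labels, parcels, pet, None
    rng_truth, rng_pet = split_seed(config.seed, 2)
    spec = PhantomSpec(**{**config.phantom, "seed": config.seed})
    labels, parcels = make_parcellation_phantom(spec)
    truth = default_activity_map(parcels, seed=int(rng_truth.integers(2**31)))
    pet = simulate_pet(
        labels, truth, config.fwhm_mm, noise_sd=config.noise_sd,
        seed=int(rng_pet.integers(2**31)),
    )
    if config.misregistration:
        t = reg.RigidTransform(
            np.asarray(config.misregistration.get("translation_mm", [0, 0, 0]), float),
            np.asarray(config.misregistration.get("rotation_deg", [0, 0, 0]), float),
        )
        pet = apply_known_misregistration(pet, t)
    return labels, parcels, pet, truth


def _register(config: RunConfig, pet: ScalarVolume, labels, parcels, psf, log):
    """Registration stage: returns (registered PET, transform used)."""
    if config.coreg == "none":
        return pet, None
    if config.coreg == "exact":
        true_t = getattr(pet, "true_transform", None)
        if true_t is None:
            return pet, None
        inv = true_t.inverse() if hasattr(true_t, "inverse") else None
        return reg.apply_transform(pet, inv, reference=pet), inv
    # model-guided: build a modeled PET from the current regional means,
    # register, then optionally rebuild the model from the registered means
    # and re-register (the spill-biased first model limits alignment)
    levels = tuple(config.register_levels)

    def estimate(target, init):
        if config.coreg == "rigid":
            return reg.estimate_rigid(pet, target, levels=levels, init=init)
        return reg.estimate_affine(pet, target, levels=levels, init=init)

    current = pet
    t = None
    for _ in range(1 + max(0, int(config.model_refinements))):
        means = regional_means(current, labels, parcels).set_index("label")["mean"]
        model = build_pet_model(labels, means.to_dict(), psf)
        t = estimate(model.volume, t)
        current = reg.apply_transform(pet, t, reference=model.volume)
    if config.coreg == "nonlinear":
        field = reg.nonlinear_adapter(current, model.volume, backend=config.nonlinear_backend)
        current = reg.apply_transform(current, field, reference=model.volume)
        log.append({"stage": "nonlinear", "backend": config.nonlinear_backend})
    return current, t


def run_subject(config: RunConfig) -> SubjectResult:
    """Run one subject through the configured coregistration + PVC model.

    Stage order: relabel -> mask -> register -> regional means -> GTM/PVC
    -> SUVR normalization -> goodness of fit (whole brain and cortex).
    Deterministic for a fixed config and seed.
    """
    log: list = []

    def stage(name, **params):
        log.append({"stage": name, "time": time.time(), "seed": config.seed, **params})

    labels, parcels, pet, truth = _load_inputs(config)
    stage("inputs", n_parcels=len(parcels.labels))

    if config.unsegmented_ids:
        labels = relabel_unsegmented(labels, config.unsegmented_ids)
        stage("relabel", unsegmented_ids=list(config.unsegmented_ids))

    mask = brain_mask(labels, dilation_voxels=3)
    stage("mask", dilation_voxels=3)

    psf = PSFModel(config.fwhm_mm)
    pet_reg, transform = _register(config, pet, labels, parcels, psf, log)
    stage("register", coreg=config.coreg)

    means = regional_means(pet_reg, labels, parcels)
    observed = means.set_index("label")["mean"]
    stage("regional_means")

    if config.pvc == "none":
        corrected = observed.copy()
    else:
        gtm = GTMModel(labels, parcels, psf, include_background=True)
        res = gtm.fit(pet_reg, mode=config.pvc)
        corrected = res.corrected.drop(index=0, errors="ignore")
    stage("pvc", mode=config.pvc)

    from .pvc import normalize_suvr

    suvr = normalize_suvr(corrected, parcels, reference=config.reference)
    stage("suvr", reference=config.reference)

    model_values = {int(l): max(float(v), 0.0) for l, v in corrected.items()}
    model_final = build_pet_model(labels, model_values, psf)
    cortex_mask = ScalarVolume(
        np.isin(labels.data, parcels.labels_of_class("cortex")).astype(float),
        labels.affine.copy(),
    )
    fit_wb = goodness_of_fit(pet_reg, model_final.volume, mask)
    fit_ctx = goodness_of_fit(pet_reg, model_final.volume, cortex_mask)
    stage("fit", whole_brain=fit_wb, cortex=fit_ctx)

    result = SubjectResult(
        config=config,
        suvr=suvr,
        corrected=corrected,
        observed_means=means,
        transform=transform,
        fit_whole_brain=fit_wb,
        fit_cortex=fit_ctx,
        stage_log=log,
    )
    if config.out_dir:
        result.write(config.out_dir)
    return result


def run_cohort_analysis(
    config: RunConfig, cohort: CohortTable, parcels: ParcelTable
) -> dict[str, pd.DataFrame]:
    """Per-parcel regional statistics over a cohort.

    Produces the regression table (simple + multivariable per cortical
    parcel), the partial-correlation table with BH-FDR flags and
    per-hemisphere counts of significant parcels, MoCA group summaries,
    normalized parcel trajectories, and the ventricle SUVR-vs-volume
    negative control.
    """
    if cohort.n < 7:
        raise ValueError(f"cohort too small for the multivariable model: n={cohort.n}")
    hemi_of = parcels.df.set_index("label")["hemi"].to_dict()
    cortical = [l for l in cohort.parcel_labels if f"thickness_{l}" in cohort.df.columns]
    if not cortical:
        raise ValueError("cohort has no cortical parcel columns")

    reg_rows, partial_rows = [], []
    for lab in cortical:
        simple = simple_regression(cohort.thickness(lab), cohort.suvr(lab), config.ci_level)
        multi = multivariable_regression(cohort, lab, ci_level=config.ci_level)
        row = {
            "label": lab,
            "hemi": hemi_of.get(lab, "bi"),
            "simple_slope": simple.slope,
            "simple_r": simple.r,
            "simple_p": simple.p,
            "simple_stars": significance_stars(simple.p),
        }
        for name in multi.params.index:
            row[f"mv_{name}_coef"] = multi.params[name]
            row[f"mv_{name}_ci_low"] = multi.conf_int.loc[name, 0]
            row[f"mv_{name}_ci_high"] = multi.conf_int.loc[name, 1]
            row[f"mv_{name}_p"] = multi.pvalues[name]
            row[f"mv_{name}_stars"] = significance_stars(multi.pvalues[name])
        reg_rows.append(row)
        r, p = partial_correlation(cohort, lab)
        partial_rows.append(
            {"label": lab, "hemi": hemi_of.get(lab, "bi"), "partial_r": r, "p": p}
        )

    regression_table = pd.DataFrame(reg_rows)
    partial = pd.DataFrame(partial_rows)
    fdr = bh_fdr(partial["p"].to_numpy(), q=config.fdr_q)
    partial["significant"] = fdr.reject
    counts = (
        partial[partial["significant"]].groupby("hemi").size().to_dict()
    )
    sig_counts = pd.DataFrame(
        [
            {
                "coreg": config.coreg,
                "pvc": config.pvc,
                "lh_significant": int(counts.get("lh", 0)),
                "rh_significant": int(counts.get("rh", 0)),
                "total_significant": fdr.n_rejected,
                "hochberg_p_threshold": fdr.threshold,
                "fdr_q": config.fdr_q,
            }
        ]
    )

    group_summary, per_parcel = group_summaries(cohort)
    trajectories = normalize_parcel_trajectories(per_parcel)

    vent_rows = []
    from scipy import stats as sps

    for lab in parcels.labels_of_class("ventricle"):
        scol, vcol = f"suvr_{int(lab)}", f"volume_{int(lab)}"
        if scol in cohort.df.columns and vcol in cohort.df.columns:
            r, p = sps.pearsonr(cohort.df[scol], cohort.df[vcol])
            vent_rows.append({"label": int(lab), "r": float(r), "p": float(p)})
    ventricle_control = pd.DataFrame(vent_rows)

    tables = {
        "regression_table": regression_table,
        "partial_correlations": partial,
        "significant_parcel_counts": sig_counts,
        "group_summary_table": group_summary,
        "per_parcel_group_means": per_parcel,
        "trajectories": trajectories,
        "ventricle_control": ventricle_control,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# coreg={config.coreg} pvc={config.pvc} fdr_q={config.fdr_q} seed={config.seed}\n"
        for name, df in tables.items():
            with open(out / f"{name}.csv", "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
    return tables
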