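"""Synthetic phantoms and cohorts for end-to-end testing of the pipeline.

The parcellation phantom is a concentric-shell head: an outer CSF shell, a
thin cortical ribbon split into angular sectors, a subcortical WM shell
split into paired sectors, a deep-gray core, two ventricle cavities, a
brainstem, and a cerebellum.  It is deliberately not anatomically realistic:
the geometric transfer matrix depends only on parcel adjacency and the
thickness scale of the ribbon relative to the PET point-spread function,
and the shell model exercises exactly that.

PET is simulated as uniform per-parcel activity convolved with an isotropic
Gaussian PSF (zero-padded air background) plus additive Gaussian noise, and
can be misregistered by a known transform to create a registration test
surface.  The cohort generator emulates a memory-clinic population with
MoCA-stratified severity groups and a configurable per-parcel linear
coupling between cortical thickness and amyloid SUVR.

All generators are bit-reproducible for a fixed seed; one global seed is
expanded into per-stage child seeds with ``numpy.random.SeedSequence(seed)
.spawn()`` in a fixed documented order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import PSFModel, blur_volume, paint_activity
from .parcels import ParcelTable
from .volumes import LabelVolume, ScalarVolume, centered_affine

__all__ = [
    "InfeasibleGeometryError",
    "PhantomSpec",
    "CohortSpec",
    "CohortTable",
    "make_parcellation_phantom",
    "default_activity_map",
    "simulate_pet",
    "apply_known_misregistration",
    "simulate_cohort",
    "coupling_slope_for_partial_r",
    "split_seed",
]

# fixed label scheme for the shell phantom
LABEL_CSF = 1
LABEL_VENT_L = 2
LABEL_VENT_R = 3
LABEL_DEEPGM = 4
LABEL_BRAINSTEM = 5
LABEL_CEREBELLUM = 6
CORTEX_BASE = 100
WM_BASE = 200


class InfeasibleGeometryError(ValueError):
    """The requested grid cannot hold the phantom geometry."""


def split_seed(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one global seed into ``n`` independent child generators."""
    children = np.random.SeedSequence(int(seed)).spawn(n)
    return [np.random.default_rng(c) for c in children]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic parcellated head.

    ``ribbon_thickness_mm`` is the nominal cortical thickness (real cortex is
    2-4.5 mm; the default 4 mm keeps the ribbon at least two voxels thick on
    the default 2 mm grid).  ``ventricle_scale`` scales the ventricle cavities
    and exists for the ventricle-size negative-control family.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_cortical_parcels: int = 8
    ribbon_thickness_mm: float = 4.0
    include_background: bool = True
    ventricle_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 along every axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if self.n_cortical_parcels < 2:
            raise ValueError("need at least 2 cortical parcels")
        if self.ribbon_thickness_mm < min(self.spacing_mm):
            raise InfeasibleGeometryError(
                "ribbon thinner than one voxel: "
                f"{self.ribbon_thickness_mm} mm on spacing {self.spacing_mm}"
            )
        if self.ventricle_scale <= 0:
            raise ValueError("ventricle_scale must be positive")


def make_parcellation_phantom(spec: PhantomSpec) -> tuple[LabelVolume, ParcelTable]:
    """Build the concentric-shell head phantom and its parcel table.

    Every non-background voxel is labeled; parcels are pairwise disjoint by
    construction (each voxel gets exactly one label).  The geometry is fully
    deterministic given the spec.
    """
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    affine = centered_affine(shape, spacing)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    x = (ii - (shape[0] - 1) / 2.0) * spacing[0]
    y = (jj - (shape[1] - 1) / 2.0) * spacing[1]
    z = (kk - (shape[2] - 1) / 2.0) * spacing[2]
    r = np.sqrt(x**2 + y**2 + z**2)

    half_extent = float(np.min((shape - 1) / 2.0 * spacing))
    r_head = 0.86 * half_extent
    t_csf = max(float(np.min(spacing)), 0.10 * r_head)
    r_ctx_out = r_head - t_csf
    r_ctx_in = r_ctx_out - spec.ribbon_thickness_mm
    if r_ctx_in < 3.0 * float(np.min(spacing)):
        raise InfeasibleGeometryError(
            "grid too small to hold CSF shell + cortical ribbon + interior"
        )
    r_wm_in = 0.45 * r_ctx_in

    labels = np.zeros(tuple(shape), dtype=np.int32)
    head = r <= r_head
    labels[head] = LABEL_CSF
    cortex_shell = (r <= r_ctx_out) & (r > r_ctx_in)
    wm_shell = (r <= r_ctx_in) & (r > r_wm_in)
    labels[(r <= r_wm_in)] = LABEL_DEEPGM

    # angular sectors shared by cortex and its paired WM
    n = spec.n_cortical_parcels
    phi = np.arctan2(y, x)  # [-pi, pi)
    sector = np.floor((phi + np.pi) / (2 * np.pi) * n).astype(int) % n
    labels[cortex_shell] = CORTEX_BASE + sector[cortex_shell]
    labels[wm_shell] = WM_BASE + sector[wm_shell]

    # cerebellum: posterior-inferior blob under the ribbon
    cb_center = np.array([0.0, -0.45 * r_head, -0.60 * r_head])
    cb = (
        np.sqrt((x - cb_center[0]) ** 2 + (y - cb_center[1]) ** 2 + (z - cb_center[2]) ** 2)
        <= 0.30 * r_head
    ) & (r <= r_ctx_out)
    labels[cb] = LABEL_CEREBELLUM

    # brainstem: vertical cylinder below center
    bs = (
        (np.sqrt(x**2 + (y + 0.05 * r_ctx_in) ** 2) <= 0.20 * r_ctx_in)
        & (z <= -0.25 * r_ctx_in)
        & (z >= -0.90 * r_ctx_in)
        & (r <= r_ctx_in)
    )
    labels[bs] = LABEL_BRAINSTEM

    # two ventricle cavities inside the WM / deep-gray interior
    vs = spec.ventricle_scale
    semi = np.array([0.15, 0.28, 0.20]) * r_ctx_in * vs
    for lab, cx in ((LABEL_VENT_L, -0.30 * r_ctx_in), (LABEL_VENT_R, 0.30 * r_ctx_in)):
        vent = (
            ((x - cx) / semi[0]) ** 2
            + ((y - 0.10 * r_ctx_in) / semi[1]) ** 2
            + ((z - 0.05 * r_ctx_in) / semi[2]) ** 2
        ) <= 1.0
        vent &= r <= r_ctx_in  # never open into the cortical ribbon
        labels[vent] = lab

    if not spec.include_background:
        labels[~head] = LABEL_CSF  # fill the grid: CSF out to the edges

    rows = [
        (LABEL_CSF, "csf-shell", "csf", "bi", np.nan, False),
        (LABEL_VENT_L, "ventricle-lh", "ventricle", "lh", np.nan, False),
        (LABEL_VENT_R, "ventricle-rh", "ventricle", "rh", np.nan, False),
        (LABEL_DEEPGM, "deep-gray", "deepgm", "bi", np.nan, False),
        (LABEL_BRAINSTEM, "brainstem", "brainstem", "bi", np.nan, True),
        (LABEL_CEREBELLUM, "cerebellum", "cerebellum", "bi", np.nan, False),
    ]
    for s in range(n):
        ang = -np.pi + (s + 0.5) * 2 * np.pi / n
        hemi = "lh" if np.cos(ang) < 0 else "rh"
        rows.append((CORTEX_BASE + s, f"ctx-sector{s:02d}", "cortex", hemi, WM_BASE + s, False))
        rows.append((WM_BASE + s, f"wm-sector{s:02d}", "wm", hemi, np.nan, False))
    table = ParcelTable(
        pd.DataFrame(
            rows,
            columns=["label", "name", "tissue_class", "hemi", "paired_wm_label", "is_reference"],
        )
    )

    vol = LabelVolume(labels, affine)
    present = set(int(v) for v in vol.labels_present())
    required = {LABEL_CSF, LABEL_VENT_L, LABEL_VENT_R, LABEL_DEEPGM, LABEL_BRAINSTEM, LABEL_CEREBELLUM}
    required |= {CORTEX_BASE + s for s in range(n)} | {WM_BASE + s for s in range(n)}
    missing = required - present
    if missing:
        raise InfeasibleGeometryError(f"phantom structures vanished on this grid: {sorted(missing)}")
    return vol, table


def default_activity_map(
    parcels: ParcelTable, seed: int = 0, cortical_base: float = 1.4, cortical_spread: float = 0.25
) -> dict[int, float]:
    """Ground-truth intrinsic activities emulating an amyloid-positive scan.

    Cortical parcels vary around ``cortical_base`` (seeded) so that spill
    between neighboring sectors is informative; CSF spaces are near-cold.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    base = {
        "csf": 0.12,
        "ventricle": 0.12,
        "deepgm": 0.80,
        "brainstem": 0.85,
        "cerebellum": 0.80,
        "wm": 0.90,
        "background": 0.0,
    }
    out: dict[int, float] = {}
    for _, row in parcels.df.iterrows():
        cls = row["tissue_class"]
        if cls == "cortex":
            out[int(row["label"])] = float(
                cortical_base + cortical_spread * rng.uniform(-1.0, 1.0)
            )
        else:
            out[int(row["label"])] = base[cls]
    return out


def simulate_pet(
    labels: LabelVolume,
    truth: dict[int, float],
    fwhm_mm: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_model: str = "gaussian",
) -> ScalarVolume:
    """Paint parcel activities, blur with the PSF, add Gaussian noise.

    The convolution is zero-padded, mirroring an air background around the
    head; with the phantom's margin this preserves total activity in the
    interior.  The additive Gaussian noise model is a desk-scale stand-in
    for the count statistics of reconstructed PET; ``noise_model="scaled"``
    scales the local SD by sqrt(signal) for a Poisson-like alternative.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    present = labels.labels_present()
    missing = [int(l) for l in present if int(l) not in truth]
    if missing:
        raise ValueError(f"activity map missing labels: {missing}")
    painted = paint_activity(labels, truth)
    blurred = blur_volume(painted, PSFModel(fwhm_mm))
    if noise_model not in ("gaussian", "scaled"):
        raise ValueError("noise_model must be 'gaussian' or 'scaled'")
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
        noise = rng.normal(0.0, noise_sd, size=blurred.shape)
        if noise_model == "scaled":
            noise = noise * np.sqrt(np.clip(blurred.data, 0.0, None))
        blurred.data = blurred.data + noise
    return blurred


def apply_known_misregistration(
    vol: ScalarVolume, transform, interpolation: str = "linear"
) -> ScalarVolume:
    """Resample a volume under a known transform (the registration test surface).

    The ground-truth transform is recorded on the result as
    ``out.true_transform`` so recovery tests can compare against it.
    """
    from .register import apply_transform  # local import avoids a cycle

    out = apply_transform(vol, transform, reference=vol, interpolation=interpolation)
    out.true_transform = transform
    return out


# --------------------------------------------------------------------------
# simulated cohort
# --------------------------------------------------------------------------

MOCA_BINS = {"0-10": (0, 10), "11-19": (11, 19), "20-30": (20, 30)}


def coupling_slope_for_partial_r(
    r: float, thickness_sd: float, suvr_noise_sd: float
) -> float:
    """Slope of amyloid on thickness giving population partial correlation r.

    With thickness residual SD s_t and independent SUVR noise SD s_e, the
    partial correlation (covariates removed) is
    ``slope * s_t / sqrt(slope^2 s_t^2 + s_e^2)``; inverting gives the slope.
    """
    if not -1 < r < 1:
        raise ValueError("population r must be in (-1, 1)")
    if thickness_sd <= 0:
        raise ValueError("thickness_sd must be positive")
    return r / np.sqrt(1.0 - r**2) * suvr_noise_sd / thickness_sd


@dataclass(frozen=True)
class CohortSpec:
    """Generating model for a simulated memory-clinic cohort.

    Per subject, covariates are drawn from the stated distributions, a MoCA
    score is drawn within its severity bin, and per-parcel thickness and
    amyloid SUVR follow

        thickness = base + b_thickness_moca * (MoCA - 18) + N(0, thickness_sd)
        SUVR      = base + slope * (thickness - base) + b_age (age - mean)
                    + b_education (edu - mean) + b_sex sex
                    + b_moca (MoCA - 18) + N(0, suvr_sd)

    so the parcel-specific slope sets the thickness-amyloid coupling while
    MoCA drives group-level severity (thinner cortex, higher amyloid at low
    MoCA).  Defaults emulate a 75-patient tertiary memory clinic: age 74.5
    (6.4) y, education 15.2 (3.5) y, 52% female, MoCA groups 0-10 / 11-19 /
    20-30 in proportions 11:31:33.
    """

    n_subjects: int = 75
    parcel_slopes: dict = field(default_factory=dict)  # label -> slope (SUVR/mm)
    thickness_sd: float = 0.25
    suvr_sd: float = 0.15
    moca_group_props: tuple[float, float, float] = (11 / 75, 31 / 75, 33 / 75)
    age_mean: float = 74.5
    age_sd: float = 6.4
    education_mean: float = 15.2
    education_sd: float = 3.5
    sex_p_female: float = 0.52
    thickness_base: float = 2.4
    suvr_base: float = 1.5
    b_thickness_moca: float = 0.008
    b_age: float = 0.008
    b_education: float = -0.03
    b_sex: float = -0.10
    b_moca: float = -0.035
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if abs(sum(self.moca_group_props) - 1.0) > 1e-9:
            raise ValueError("moca_group_props must sum to 1")
        if self.thickness_sd < 0 or self.suvr_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class CohortTable:
    """Per-subject covariates plus per-parcel SUVR / thickness / volume.

    Wide layout: columns ``suvr_<label>``, ``thickness_<label>``,
    ``volume_<label>`` alongside subject_id, age, sex (0 = male, 1 =
    female), education, moca, and moca_group.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        needed = ["subject_id", "age", "sex", "education", "moca", "moca_group"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if ((df["moca"] < 0) | (df["moca"] > 30)).any():
            raise ValueError("MoCA scores must lie in [0, 30]")
        for group, (lo, hi) in MOCA_BINS.items():
            sel = df["moca_group"] == group
            if not df.loc[sel, "moca"].between(lo, hi).all():
                raise ValueError(f"MoCA scores inconsistent with group {group}")
        modeled = [c for c in df.columns if c.startswith(("suvr_", "thickness_"))]
        if df[modeled].isna().any().any():
            raise ValueError("missing values in modeled columns")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def parcel_labels(self) -> list[int]:
        return sorted(
            int(c.split("_", 1)[1])
            for c in self.df.columns
            if c.startswith("suvr_") and c.split("_", 1)[1].isdigit()
        )

    def suvr(self, label: int) -> np.ndarray:
        return self.df[f"suvr_{int(label)}"].to_numpy(dtype=float)

    def thickness(self, label: int) -> np.ndarray:
        return self.df[f"thickness_{int(label)}"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))


def _moca_group_of(moca: int) -> str:
    for group, (lo, hi) in MOCA_BINS.items():
        if lo <= moca <= hi:
            return group
    raise ValueError(moca)


def simulate_cohort(spec: CohortSpec, parcels: ParcelTable) -> CohortTable:
    """Draw a seeded cohort under the CohortSpec generating model.

    Parcels listed in ``spec.parcel_slopes`` get coupled thickness/SUVR
    columns; remaining cortical parcels get null (slope 0) coupling.
    Ventricle parcels get uncoupled volume and SUVR columns for the
    negative-control analysis.
    """
    rng_groups, rng_cov, rng_parc, rng_vent = split_seed(spec.seed, 4)
    n = spec.n_subjects

    props = np.asarray(spec.moca_group_props, dtype=float)
    groups = list(MOCA_BINS)
    counts = np.floor(props * n).astype(int)
    # distribute the remainder to the largest fractional parts, deterministically
    rem = n - counts.sum()
    order = np.argsort(-(props * n - counts), kind="stable")
    counts[order[:rem]] += 1
    for g, c, p in zip(groups, counts, props):
        if p > 0 and c == 0:
            raise ValueError(
                f"MoCA group {g} has proportion {p:.3f} but n={n} is too small to fill it"
            )
    group_of = np.repeat(groups, counts)
    rng_groups.shuffle(group_of)

    moca = np.array(
        [rng_groups.integers(MOCA_BINS[g][0], MOCA_BINS[g][1] + 1) for g in group_of]
    )
    age = rng_cov.normal(spec.age_mean, spec.age_sd, n)
    education = np.clip(rng_cov.normal(spec.education_mean, spec.education_sd, n), 0, None)
    sex = (rng_cov.uniform(size=n) < spec.sex_p_female).astype(int)

    data = {
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "education": education,
        "moca": moca,
        "moca_group": group_of,
    }

    cortical = [int(l) for l in parcels.labels_of_class("cortex")]
    slopes = {int(k): float(v) for k, v in spec.parcel_slopes.items()}
    for lab in sorted(set(cortical) | set(slopes)):
        slope = slopes.get(lab, 0.0)
        thick = (
            spec.thickness_base
            + spec.b_thickness_moca * (moca - 18.0)
            + rng_parc.normal(0.0, spec.thickness_sd, n)
        )
        suvr = (
            spec.suvr_base
            + slope * (thick - spec.thickness_base)
            + spec.b_age * (age - spec.age_mean)
            + spec.b_education * (education - spec.education_mean)
            + spec.b_sex * sex
            + spec.b_moca * (moca - 18.0)
            + rng_parc.normal(0.0, spec.suvr_sd, n)
        )
        data[f"thickness_{lab}"] = thick
        data[f"suvr_{lab}"] = suvr

    for lab in parcels.labels_of_class("ventricle"):
        lab = int(lab)
        data[f"volume_{lab}"] = np.clip(rng_vent.normal(8000.0, 2000.0, n), 500.0, None)
        data[f"suvr_{lab}"] = np.clip(rng_vent.normal(0.30, 0.05, n), 0.0, None)

    return CohortTable(pd.DataFrame(data))
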