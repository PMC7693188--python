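"""Geometric-transfer-matrix partial volume correction.

The geometric transfer matrix (GTM, after Rousset and Labbe) encodes the
fraction of each parcel's intrinsic activity observed in every other
parcel once the image is degraded by the scanner point-spread function:
entry (i, j) is the mean, over parcel i's voxels, of parcel j's blurred
binary indicator.  Given the vector t of observed regional means, the
intrinsic (nonspread) parcel activities T solve G T = t.

Plain least squares can invert the system but is unstable for thin,
adjacent parcels, producing nonphysical (negative or inflated) values; the
remedy used here, as in the clinical method this package implements, is
bounded least squares with a lower limit of 0 on every parcel.

The statsmodels-style surface is :class:`GTMModel` (built from a label
volume, parcel table and PSF) whose :meth:`~GTMModel.fit` returns a
:class:`GTMResults` carrying estimates, residual diagnostics, SUVR
normalization and a summary table.  The underlying operations are also
exposed as plain functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .forward import PSFModel, blur_parcel_indicator
from .parcels import ParcelTable, regional_means
from .volumes import LabelVolume, ScalarVolume

__all__ = [
    "GTMatrix",
    "GTMModel",
    "GTMResults",
    "build_gtm",
    "invert_gtm",
    "normalize_suvr",
    "cortical_wm_ratio",
]

BACKGROUND = 0


@dataclass
class GTMatrix:
    """Spill-over weight matrix with its parcel ordering.

    ``weights[i, j]`` = mean over parcel i's voxels of the blurred indicator
    of parcel j.  With the background included as a parcel, rows form a
    partition of unity and sum to 1.
    """

    weights: np.ndarray
    parcel_order: list[int]
    psf: PSFModel

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.parcel_order)
        if self.weights.shape != (n, n):
            raise ValueError("weights shape inconsistent with parcel order")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.weights))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.weights, index=self.parcel_order, columns=self.parcel_order
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path, psf: PSFModel) -> "GTMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), [int(c) for c in df.columns], psf)


def build_gtm(
    labels: LabelVolume,
    parcels: ParcelTable,
    psf: PSFModel,
    include_background: bool = True,
) -> GTMatrix:
    """Assemble the GTM by blurring each parcel indicator and region-averaging.

    Region-mean weighting is used (consistent with the per-parcel mean
    observations the matrix is inverted against).  ``include_background``
    appends label 0 as an explicit zero-activity-capable parcel so that
    spill off the brain edge is accounted for and rows close to 1.
    """
    order = [int(l) for l in parcels.labels]
    arr = labels.data
    counts = np.array(
        ndimage.sum_labels(np.ones(arr.shape), arr, index=order)
    )
    empty = [lab for lab, c in zip(order, counts) if c == 0]
    if empty:
        raise ValueError(f"empty parcels, cannot assemble GTM: {empty}")
    if include_background:
        if not (arr == BACKGROUND).any():
            raise ValueError("include_background=True but volume has no background")
        order = order + [BACKGROUND]

    n = len(order)
    weights = np.empty((n, n))
    real = [lab for lab in order if lab != BACKGROUND]
    total = np.zeros(arr.shape)
    for j, lab_j in enumerate(order):
        if lab_j == BACKGROUND:
            continue
        blurred = blur_parcel_indicator(labels, lab_j, psf)
        total += blurred.data
        col = ndimage.mean(blurred.data, arr, index=order)
        weights[:, j] = np.asarray(col)
    if include_background:
        # air continues beyond the grid, so the background indicator is the
        # complement of all real parcels; this closes the partition of unity
        j = order.index(BACKGROUND)
        bg_blurred = 1.0 - total
        weights[:, j] = np.asarray(ndimage.mean(bg_blurred, arr, index=order))
    return GTMatrix(weights, order, psf)


@dataclass
class GTMResults:
    """Intrinsic parcel activities recovered by GTM inversion."""

    model: "GTMModel | None"
    gtm: GTMatrix
    observed: pd.Series  # label -> observed regional mean
    corrected: pd.Series  # label -> intrinsic activity
    mode: str
    lower_bound: float
    residual_norm: float
    at_bound: pd.Series  # label -> bool, active lower/upper constraint
    condition_number: float

    def suvr(self, reference: str = "brainstem") -> pd.Series:
        parcels = self._parcels()
        return normalize_suvr(self.corrected, parcels, reference=reference)

    def cortical_wm_ratio(self) -> tuple[pd.Series, float]:
        return cortical_wm_ratio(self.corrected, self._parcels())

    def _parcels(self) -> ParcelTable:
        if self.model is None:
            raise ValueError("results not attached to a GTMModel with a parcel table")
        return self.model.parcels

    def summary(self) -> pd.DataFrame:
        parcels = self.model.parcels if self.model is not None else None
        df = pd.DataFrame(
            {
                "observed_mean": self.observed,
                "corrected": self.corrected,
                "at_bound": self.at_bound,
            }
        )
        df.index.name = "label"
        if parcels is not None:
            meta = parcels.df.set_index("label")[["name", "tissue_class"]]
            df = meta.join(df, how="right")
        df.attrs["mode"] = self.mode
        df.attrs["residual_norm"] = self.residual_norm
        df.attrs["condition_number"] = self.condition_number
        return df

    def to_csv(self, path, reference: str | None = "brainstem") -> None:
        df = self.summary().reset_index()
        if reference is not None:
            suvr = self.suvr(reference)
            df["suvr"] = df["label"].map(suvr)
        df.to_csv(path, index=False)


class GTMModel:
    """Partial-volume-correction model for one parcellation and PSF.

    Parameters
    ----------
    labels : LabelVolume
        The parcellation on the reference grid.
    parcels : ParcelTable
        Parcel metadata; its reference flag sets the SUVR denominator.
    psf : PSFModel
        Isotropic Gaussian PSF (FWHM in mm) assumed for the scanner.
    include_background : bool
        Whether label 0 participates as an explicit parcel (default True,
        which closes the row sums of the transfer matrix).
    """

    def __init__(
        self,
        labels: LabelVolume,
        parcels: ParcelTable,
        psf: PSFModel,
        include_background: bool = True,
    ):
        self.labels = labels
        self.parcels = parcels
        self.psf = psf
        self.include_background = include_background
        self._gtm: GTMatrix | None = None

    @property
    def transfer_matrix(self) -> GTMatrix:
        if self._gtm is None:
            self._gtm = build_gtm(
                self.labels, self.parcels, self.psf, self.include_background
            )
        return self._gtm

    def observed_means(self, pet: ScalarVolume) -> pd.Series:
        """Regional means over the model's parcel order (incl. background)."""
        means = regional_means(pet, self.labels, self.parcels).set_index("label")["mean"]
        if self.include_background:
            bg = float(pet.data[self.labels.data == BACKGROUND].mean())
            means = pd.concat([means, pd.Series({BACKGROUND: bg})])
        return means.reindex(self.transfer_matrix.parcel_order)

    def fit(
        self,
        pet,
        mode: str = "constrained",
        lower_bound: float = 0.0,
        upper_bound: float = np.inf,
    ) -> GTMResults:
        """Invert the transfer matrix against observed regional means.

        ``pet`` may be a ScalarVolume (means computed on the model grid) or
        a mapping / Series of per-label observed means.
        """
        if isinstance(pet, ScalarVolume):
            observed = self.observed_means(pet)
        else:
            observed = pd.Series({int(k): float(v) for k, v in dict(pet).items()})
            missing = [l for l in self.transfer_matrix.parcel_order if l not in observed]
            if missing:
                raise ValueError(f"observed means missing labels: {missing}")
            observed = observed.reindex(self.transfer_matrix.parcel_order)
        res = invert_gtm(
            self.transfer_matrix, observed, mode=mode,
            lower_bound=lower_bound, upper_bound=upper_bound,
        )
        res.model = self
        return res


def invert_gtm(
    g: GTMatrix,
    observed,
    mode: str = "constrained",
    lower_bound: float = 0.0,
    upper_bound: float = np.inf,
) -> GTMResults:
    """Solve G T = t for the intrinsic activities T.

    ``constrained`` solves min ||G T - t||^2 subject to T >= lower_bound
    (and optionally <= upper_bound) by bounded least squares initialized at
    the clipped unconstrained solution; ``unconstrained`` uses plain least
    squares and flags ill-conditioning with a warning.
    """
    if mode not in ("constrained", "unconstrained"):
        raise ValueError("mode must be 'constrained' or 'unconstrained'")
    order = g.parcel_order
    if isinstance(observed, pd.Series):
        t = observed.reindex(order).to_numpy(dtype=float)
    else:
        d = {int(k): float(v) for k, v in dict(observed).items()}
        missing = [l for l in order if l not in d]
        if missing:
            raise ValueError(f"observed means missing labels: {missing}")
        t = np.array([d[l] for l in order])
    if np.isnan(t).any():
        bad = [l for l, v in zip(order, t) if np.isnan(v)]
        raise ValueError(f"observed means undefined for labels: {bad}")

    cond = float(np.linalg.cond(g.weights))
    x_ls, *_ = np.linalg.lstsq(g.weights, t, rcond=None)
    if mode == "unconstrained":
        if cond > 1e8:
            warnings.warn(
                f"GTM is ill-conditioned (cond={cond:.3g}); "
                "unconstrained solution flagged as unstable"
            )
        x = x_ls
        at_bound = np.zeros(len(order), dtype=bool)
    else:
        x0 = np.clip(x_ls, lower_bound, upper_bound)
        sol = optimize.lsq_linear(
            g.weights, t, bounds=(lower_bound, upper_bound), tol=1e-10,
            lsq_solver="exact",
        )
        # keep the better of the solver result and the clipped warm start
        if np.linalg.norm(g.weights @ x0 - t) < np.linalg.norm(g.weights @ sol.x - t):
            x = x0
        else:
            x = sol.x
        at_bound = np.isclose(x, lower_bound) | (
            np.isfinite(upper_bound) & np.isclose(x, upper_bound)
        )
    residual = float(np.linalg.norm(g.weights @ x - t))
    return GTMResults(
        model=None,
        gtm=g,
        observed=pd.Series(t, index=order),
        corrected=pd.Series(x, index=order),
        mode=mode,
        lower_bound=lower_bound,
        residual_norm=residual,
        at_bound=pd.Series(at_bound, index=order),
        condition_number=cond,
    )


def normalize_suvr(
    values: pd.Series, parcels: ParcelTable, reference: str = "brainstem"
) -> pd.Series:
    """Divide every corrected value by the reference region's value.

    ``reference`` is a tissue class name ('brainstem' or 'cerebellum'); the
    reference parcel's SUVR becomes exactly 1.  Normalization is refused if
    the reference value is nonpositive.
    """
    if reference in ("brainstem", "cerebellum"):
        ref_labels = parcels.labels_of_class(reference)
        if len(ref_labels) == 0:
            raise ValueError(f"no parcel of class {reference!r} in the table")
        ref_label = int(ref_labels[0])
    else:
        raise ValueError("reference must be 'brainstem' or 'cerebellum'")
    if ref_label not in values.index:
        raise ValueError(f"reference parcel {ref_label} missing from values")
    ref_value = float(values.loc[ref_label])
    if ref_value <= 0:
        raise ValueError(
            f"reference value must be positive, got {ref_value} for label {ref_label}"
        )
    return values / ref_value


def cortical_wm_ratio(
    values: pd.Series, parcels: ParcelTable
) -> tuple[pd.Series, float]:
    """Per-cortical-parcel ratio to its paired WM parcel, plus the mean ratio.

    Pairs whose WM value is nonpositive get a NaN (flagged undefined) and
    are excluded from the mean.
    """
    ratios = {}
    for ctx, wm in parcels.cortex_wm_pairs():
        wm_val = float(values.loc[wm])
        if wm_val <= 0:
            ratios[ctx] = np.nan
        else:
            ratios[ctx] = float(values.loc[ctx]) / wm_val
    series = pd.Series(ratios)
    mean = float(series.dropna().mean()) if series.notna().any() else np.nan
    return series, mean
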