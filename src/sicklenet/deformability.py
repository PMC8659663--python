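"""Aspect-ratio deformability analysis of paired flow / no-flow masks.

Deformable (partially sickled) cells stretch under shear and relax when
flow stops, so their aspect ratio AR = minor/major changes substantially
between the two captures; non-deformable (highly sickled) cells barely
change. Axis lengths come from the equivalent-ellipse convention — the
eigenvalues lambda of the pixel-coordinate covariance give axis lengths
4*sqrt(lambda), so AR = sqrt(lambda_min / lambda_max) — any consistent
convention cancels in the ratio. The relative change per cell is

    pct_change = 100 * (AR_noflow - AR_flow) / AR_noflow

(the relaxed no-flow state is the denominator; recorded in the output).
The group difference is tested with Welch's unequal-variance two-sample t
by default, with a Mann-Whitney U alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SUBTYPES = ("deformable", "nondeformable")


@dataclass
class PairedCellObservation:
    cell_id: str
    subtype: str                 # "deformable" | "nondeformable"
    mask_flow: np.ndarray
    mask_noflow: np.ndarray


@dataclass
class ARRecord:
    cell_id: str
    subtype: str
    ar_flow: float
    ar_noflow: float
    pct_change: float


@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    mean_deformable: float
    mean_nondeformable: float
    sd_deformable: float
    sd_nondeformable: float
    n_deformable: int
    n_nondeformable: int


def aspect_ratio(mask: np.ndarray) -> float:
    """Minor/major axis ratio of a binary mask's equivalent ellipse."""
    coords = np.argwhere(np.asarray(mask) > 0)
    if len(coords) < 5:
        raise ValueError("mask must contain at least 5 pixels")
    cov = np.cov(coords.astype(np.float64).T)
    lam = np.linalg.eigvalsh(cov)
    if lam[0] <= 1e-12:
        raise ValueError("degenerate (collinear) pixel set")
    return float(np.sqrt(lam[0] / lam[1]))


def percent_change(ar_flow: float, ar_noflow: float) -> float:
    """100 * (AR_noflow - AR_flow) / AR_noflow."""
    for v in (ar_flow, ar_noflow):
        if not (0.0 < v <= 1.0):
            raise ValueError("aspect ratios must lie in (0, 1]")
    return 100.0 * (ar_noflow - ar_flow) / ar_noflow


def analyze_pairs(observations: list[PairedCellObservation]) -> pd.DataFrame:
    """Per-cell AR under both conditions and the relative change."""
    rows = []
    for obs in observations:
        if obs.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {obs.subtype!r}")
        ar_f = aspect_ratio(obs.mask_flow)
        ar_n = aspect_ratio(obs.mask_noflow)
        rows.append(ARRecord(cell_id=obs.cell_id, subtype=obs.subtype,
                             ar_flow=ar_f, ar_noflow=ar_n,
                             pct_change=percent_change(ar_f, ar_n)))
    return pd.DataFrame([r.__dict__ for r in rows])


def group_comparison(records: pd.DataFrame, test: str = "welch"
                     ) -> GroupComparison:
    """Compare pct_change between the two subtypes.

    Requires >= 2 records per group. With zero variance in both groups the
    statistic is undefined and the p-value is reported as NaN (documented
    degenerate behavior), never silently coerced.
    """
    a = records.loc[records.subtype == "deformable", "pct_change"].to_numpy(float)
    b = records.loc[records.subtype == "nondeformable", "pct_change"].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 records per subtype")
    import warnings

    with warnings.catch_warnings():
        # zero-variance groups legitimately produce a NaN statistic
        warnings.simplefilter("ignore", RuntimeWarning)
        if test == "welch":
            res = stats.ttest_ind(a, b, equal_var=False)
        elif test == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
    with np.errstate(invalid="ignore"):
        statistic = float(res.statistic)
        pvalue = float(res.pvalue)
    return GroupComparison(test=test, statistic=statistic, pvalue=pvalue,
                           mean_deformable=float(a.mean()),
                           mean_nondeformable=float(b.mean()),
                           sd_deformable=float(a.std(ddof=1)),
                           sd_nondeformable=float(b.std(ddof=1)),
                           n_deformable=len(a), n_nondeformable=len(b))


def ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                 semi_major: float, semi_minor: float,
                 angle_deg: float = 0.0) -> np.ndarray:
    """Rasterized filled ellipse, used to build synthetic paired masks."""
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    theta = np.deg2rad(angle_deg)
    u = rows * np.sin(theta) + cols * np.cos(theta)
    v = -rows * np.cos(theta) + cols * np.sin(theta)
    return ((u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0).astype(np.uint8)


def synthetic_paired_experiment(n_per_group: int = 7,
                                deformable_delta: float = 20.0,
                                nondeformable_delta: float = 0.0,
                                jitter_sd: float = 5.0,
                                seed: int = 0) -> pd.DataFrame:
    """Paired flow/no-flow ellipse masks with a known AR change per group.

    No-flow ARs are drawn near the relaxed shape; the flow mask elongates
    each cell so its AR drops by the group delta (in percent) plus
    pixelation and cell-to-cell jitter.
    """
    rng = np.random.default_rng(seed)
    observations = []
    for subtype, delta in (("deformable", deformable_delta),
                           ("nondeformable", nondeformable_delta)):
        for i in range(n_per_group):
            ar_noflow = float(rng.uniform(0.75, 0.92))
            d = delta + float(rng.normal(0.0, jitter_sd))
            ar_flow = ar_noflow * max(1.0 - d / 100.0, 0.05)
            a = 22.0
            observations.append(PairedCellObservation(
                cell_id=f"{subtype}_{i}", subtype=subtype,
                mask_flow=ellipse_mask((96, 96), (48, 48), a, a * ar_flow,
                                       float(rng.uniform(-90, 90))),
                mask_noflow=ellipse_mask((96, 96), (48, 48), a, a * ar_noflow,
                                         float(rng.uniform(-90, 90)))))
    return analyze_pairs(observations)
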