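"""Group-level statistics: voxel-wise two-sample t maps, Gaussian random
field (GRF) cluster-level correction, cluster reporting, demographics-table
statistics and clinical correlations.

The group comparison is exposed both as plain functions and as a
model/results pair (:class:`NHGroupModel` / :class:`NHGroupResults`) in the
style of statsmodels: build the model from per-subject standardized NH maps
and group labels, call ``fit()`` and read the cluster table off the results.

GRF correction follows the classical expected-Euler-characteristic /
extent-distribution approach for a 3-D field: field smoothness (FWHM per
axis) is estimated from standardized residuals, the mask's resel counts are
computed by lattice counting, and each suprathreshold cluster's corrected p
is ``1 - exp(-E[m] * P(n >= k))`` with ``P(n >= k) = exp(-beta * k^(2/3))``.
Two-sided inference runs as two one-sided analyses at half the voxel-wise
alpha, so clusters carry the sign of the group difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .homogeneity import NHMap, STANDARDIZED

__all__ = [
    "TMap",
    "SmoothnessEstimate",
    "ClusterResult",
    "voxelwise_two_sample_t",
    "ttest_from_summary",
    "chi_square_2x2",
    "estimate_smoothness",
    "resel_counts",
    "grf_cluster_inference",
    "label_clusters",
    "extract_cluster_means",
    "pearson_corr",
    "demographics_table",
    "NHGroupModel",
    "NHGroupResults",
]

_4LN2 = 4.0 * np.log(2.0)


@dataclass
class TMap:
    t: np.ndarray  # 3-D, NaN outside mask
    p: np.ndarray  # two-sided voxel p, NaN outside mask
    mask: np.ndarray
    affine: np.ndarray
    df: int


@dataclass
class SmoothnessEstimate:
    fwhm_mm: np.ndarray  # per axis
    fwhm_voxels: np.ndarray
    resels: float
    resel_counts: np.ndarray  # R0..R3
    n_maps: int


@dataclass
class ClusterResult:
    label: int
    direction: str  # "patients>controls" | "patients<controls"
    extent: int
    peak_t: float
    peak_index: tuple
    peak_mm: tuple
    p_corrected: float
    voxels: np.ndarray = field(repr=False, default=None)  # (k, 3) indices


def voxelwise_two_sample_t(
    maps_a: list[NHMap], maps_b: list[NHMap], mask: np.ndarray | None = None
) -> TMap:
    """Pooled-variance two-sample t per in-mask voxel, sign convention a - b."""
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least two subjects per group")
    for m in maps_a + maps_b:
        if m.stage != STANDARDIZED:
            raise ValueError("group comparison expects standardized-stage maps")
    mask = maps_a[0].mask if mask is None else mask
    A = np.stack([m.data[mask] for m in maps_a])  # n1 x V
    B = np.stack([m.data[mask] for m in maps_b])
    n1, n2 = A.shape[0], B.shape[0]
    df = n1 + n2 - 2
    mean_diff = A.mean(axis=0) - B.mean(axis=0)
    ss = ((A - A.mean(axis=0)) ** 2).sum(axis=0) + ((B - B.mean(axis=0)) ** 2).sum(axis=0)
    pooled = ss / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)

    tvol = np.full(mask.shape, np.nan)
    pvol = np.full(mask.shape, np.nan)
    tvol[mask] = t
    pvol[mask] = p
    return TMap(t=tvol, p=pvol, mask=mask.copy(), affine=maps_a[0].affine, df=df)


def ttest_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        t = 0.0 if mean1 == mean2 else np.inf * np.sign(mean1 - mean2)
    else:
        t = (mean1 - mean2) / se
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return float(t), df, p


def chi_square_2x2(counts, continuity_correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table (no continuity correction by default)."""
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    total = obs.sum()
    if total <= 0:
        raise ValueError("empty table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal")
    expected = row @ col / total
    diff = np.abs(obs - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, 1))
    return chi2, 1, p


def estimate_smoothness(
    residual_maps: list[np.ndarray],
    mask: np.ndarray,
    voxel_sizes_mm: np.ndarray,
) -> SmoothnessEstimate:
    """Estimate the field's FWHM per axis from standardized residual maps.

    Each residual map is standardized within the mask; the lag-1 spatial
    autocorrelation per axis is estimated from mean squared neighbour
    differences, and inverted under a Gaussian autocorrelation model:
    ``FWHM^2 = -2 ln 2 / ln(rho_1)`` in voxel units.  FWHM is floored at one
    voxel (an unsmoothed field carries no sub-voxel smoothness information).
    """
    if len(residual_maps) < 3:
        raise ValueError("need at least 3 residual maps")
    mask = np.asarray(mask, dtype=bool)
    voxel_sizes_mm = np.asarray(voxel_sizes_mm, dtype=float)
    fwhm_vox = np.empty(3)
    for axis in range(3):
        # neighbouring in-mask pairs along this axis
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        if pair.sum() < 2:
            raise ValueError("mask too small for smoothness estimation")
        num = 0.0
        cnt = 0
        for r in residual_maps:
            v = r[mask]
            sd = v.std()
            if sd == 0:
                continue
            rs = np.where(mask, (r - v.mean()) / sd, 0.0)
            d = rs[tuple(sl_b)] - rs[tuple(sl_a)]
            num += float((d[pair] ** 2).sum())
            cnt += int(pair.sum())
        msd = num / cnt  # E[(x_i+1 - x_i)^2] = 2 (1 - rho(1))
        rho = 1.0 - msd / 2.0
        if rho <= 0:
            fwhm_vox[axis] = 1.0
        else:
            fwhm_vox[axis] = max(np.sqrt(-2.0 * np.log(2.0) / np.log(rho)), 1.0)
    counts = resel_counts(mask, fwhm_vox)
    return SmoothnessEstimate(
        fwhm_mm=fwhm_vox * voxel_sizes_mm,
        fwhm_voxels=fwhm_vox,
        resels=float(counts[3]),
        resel_counts=counts,
        n_maps=len(residual_maps),
    )


def resel_counts(mask: np.ndarray, fwhm_vox: np.ndarray) -> np.ndarray:
    """Resolution-element counts R0..R3 of a mask by lattice counting.

    Counts in-mask points, edges, faces and cubes of the voxel lattice and
    combines them with the per-axis smoothness, following the standard
    volumetrics used for Euler-characteristic expectations.
    """
    m = np.asarray(mask, dtype=bool)
    rx, ry, rz = 1.0 / np.asarray(fwhm_vox, dtype=float)
    P = float(m.sum())
    Ex = float((m[:-1, :, :] & m[1:, :, :]).sum())
    Ey = float((m[:, :-1, :] & m[:, 1:, :]).sum())
    Ez = float((m[:, :, :-1] & m[:, :, 1:]).sum())
    Fxy = float((m[:-1, :-1, :] & m[1:, :-1, :] & m[:-1, 1:, :] & m[1:, 1:, :]).sum())
    Fxz = float((m[:-1, :, :-1] & m[1:, :, :-1] & m[:-1, :, 1:] & m[1:, :, 1:]).sum())
    Fyz = float((m[:, :-1, :-1] & m[:, 1:, :-1] & m[:, :-1, 1:] & m[:, 1:, 1:]).sum())
    C = float(
        (
            m[:-1, :-1, :-1]
            & m[1:, :-1, :-1]
            & m[:-1, 1:, :-1]
            & m[:-1, :-1, 1:]
            & m[1:, 1:, :-1]
            & m[1:, :-1, 1:]
            & m[:-1, 1:, 1:]
            & m[1:, 1:, 1:]
        ).sum()
    )
    r0 = P - (Ex + Ey + Ez) + (Fxy + Fxz + Fyz) - C
    r1 = rx * (Ex - Fxy - Fxz + C) + ry * (Ey - Fxy - Fyz + C) + rz * (Ez - Fxz - Fyz + C)
    r2 = rx * ry * (Fxy - C) + rx * rz * (Fxz - C) + ry * rz * (Fyz - C)
    r3 = rx * ry * rz * C
    return np.array([r0, r1, r2, r3])


def _ec_densities(u: float) -> np.ndarray:
    """Euler-characteristic densities rho_0..rho_3 of a unit Gaussian field."""
    e = np.exp(-(u**2) / 2.0)
    rho0 = sps.norm.sf(u)
    rho1 = np.sqrt(_4LN2) / (2.0 * np.pi) * e
    rho2 = _4LN2 / (2.0 * np.pi) ** 1.5 * u * e
    rho3 = _4LN2**1.5 / (2.0 * np.pi) ** 2 * (u**2 - 1.0) * e
    return np.array([rho0, rho1, rho2, rho3])


def grf_cluster_p(
    extent: int, u_gauss: float, smoothness: SmoothnessEstimate, n_mask_voxels: int
) -> float:
    """Corrected cluster-level p for a cluster of ``extent`` voxels.

    Uses the expected cluster count E[m] from the EC expansion and the
    exponential extent approximation P(n >= k) = exp(-beta k^(2/3)) for a
    3-D field.
    """
    if extent < 1:
        raise ValueError("extent must be >= 1")
    Em = float(np.dot(smoothness.resel_counts, _ec_densities(u_gauss)))
    Em = max(Em, 1e-300)
    EN = n_mask_voxels * sps.norm.sf(u_gauss)  # expected suprathreshold voxels
    En = max(EN / Em, 1e-300)  # expected voxels per cluster
    gamma_52 = 3.0 * np.sqrt(np.pi) / 4.0  # Gamma(D/2 + 1) for D = 3
    beta = (gamma_52 / En) ** (2.0 / 3.0)
    p_extent = np.exp(-beta * extent ** (2.0 / 3.0))
    return float(1.0 - np.exp(-Em * p_extent))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order)


def label_clusters(
    supra: np.ndarray,
    connectivity: int = 26,
    values: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> list[dict]:
    """Connected components of a suprathreshold binary map.

    Per component: extent, peak |value| voxel (ties break to the smallest
    linear index) and its world coordinates if an affine is given.
    """
    structure = _connectivity_structure(connectivity)
    labels, n = ndimage.label(np.asarray(supra, dtype=bool), structure=structure)
    out = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if values is not None:
            mags = np.abs(values[vox[:, 0], vox[:, 1], vox[:, 2]])
            best = np.flatnonzero(mags == mags.max())
            # ties: smallest linear index; argwhere is C-ordered so the first wins
            peak = vox[best[0]]
            peak_val = float(values[tuple(peak)])
        else:
            peak = vox[0]
            peak_val = 1.0
        entry = {
            "label": lab,
            "extent": int(vox.shape[0]),
            "peak_index": tuple(int(x) for x in peak),
            "peak_value": peak_val,
            "voxels": vox,
        }
        if affine is not None:
            world = affine @ np.array([*peak, 1.0])
            entry["peak_mm"] = tuple(float(x) for x in world[:3])
        out.append(entry)
    return out


def grf_cluster_inference(
    tmap: TMap,
    smoothness: SmoothnessEstimate,
    voxel_p: float = 0.001,
    cluster_p: float = 0.01,
    connectivity: int = 26,
) -> list[ClusterResult]:
    """GRF-corrected cluster inference on a two-sided t map.

    The two-sided voxel threshold ``voxel_p`` is split into two one-sided
    analyses at ``voxel_p / 2`` (positive and negative t), so each surviving
    cluster carries a direction.  Clusters with corrected p < ``cluster_p``
    are returned sorted by extent, largest first.
    """
    if not 0 < voxel_p < 1 or not 0 < cluster_p < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    t_thr = sps.t.isf(voxel_p / 2.0, tmap.df)
    u = sps.norm.isf(voxel_p / 2.0)  # Gaussian-equivalent height
    n_mask = int(tmap.mask.sum())
    results: list[ClusterResult] = []
    t = np.where(tmap.mask, tmap.t, 0.0)
    for sign, direction in ((1.0, "patients>controls"), (-1.0, "patients<controls")):
        supra = (sign * t) > t_thr
        for comp in label_clusters(supra, connectivity, values=t, affine=tmap.affine):
            p_corr = grf_cluster_p(comp["extent"], u, smoothness, n_mask)
            if p_corr < cluster_p:
                results.append(
                    ClusterResult(
                        label=comp["label"],
                        direction=direction,
                        extent=comp["extent"],
                        peak_t=comp["peak_value"],
                        peak_index=comp["peak_index"],
                        peak_mm=comp.get("peak_mm"),
                        p_corrected=p_corr,
                        voxels=comp["voxels"],
                    )
                )
    results.sort(key=lambda c: (-c.extent, c.direction))
    return results


def extract_cluster_means(nh_maps: list[NHMap], cluster: ClusterResult) -> np.ndarray:
    """Per-subject mean standardized NH over a cluster's voxels."""
    vox = cluster.voxels
    out = np.empty(len(nh_maps))
    for i, m in enumerate(nh_maps):
        vals = m.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        if np.isnan(vals).any():
            raise ValueError("cluster extends outside the NH mask")
        out[i] = vals.mean()
    return out


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p; missing pairs dropped listwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


_TABLE_VARIABLES = ("age", "education_years", "illness_duration", "reaction_time", "mmse")


def demographics_table(
    records: pd.DataFrame, variables: tuple[str, ...] = _TABLE_VARIABLES
) -> pd.DataFrame:
    """Group mean +/- SD per variable with pooled t (and chi-square for sex)."""
    if set(records["group"]) != {"patient", "control"}:
        raise ValueError("records must contain both groups")
    pat = records[records["group"] == "patient"]
    con = records[records["group"] == "control"]
    rows = []
    if "sex" in records.columns:
        counts = [
            [int((pat["sex"] == "M").sum()), int((pat["sex"] == "F").sum())],
            [int((con["sex"] == "M").sum()), int((con["sex"] == "F").sum())],
        ]
        chi2, _, p = chi_square_2x2(counts)
        rows.append(
            {
                "variable": "sex (M/F)",
                "patients": f"{counts[0][0]}/{counts[0][1]}",
                "controls": f"{counts[1][0]}/{counts[1][1]}",
                "statistic": chi2,
                "test": "chi2",
                "p": p,
            }
        )
    for var in variables:
        if var not in records.columns:
            continue
        a = pat[var].dropna()
        b = con[var].dropna()
        if len(a) >= 2 and len(b) >= 2:
            t, _, p = ttest_from_summary(
                len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1)
            )
            stat, test = t, "t"
        else:
            stat, test, p = np.nan, "none", np.nan
        rows.append(
            {
                "variable": var,
                "patients": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}" if len(a) else "-",
                "controls": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}" if len(b) else "-",
                "statistic": stat,
                "test": test,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


class NHGroupModel:
    """Two-group voxel-wise comparison of standardized NH maps.

    Parameters
    ----------
    maps : list of NHMap
        Standardized-stage maps, one per subject.
    groups : sequence of str
        "patient" / "control" per subject, aligned with ``maps``.
    voxel_sizes_mm : array-like, optional
        Voxel sizes for smoothness estimation; derived from the first map's
        affine when omitted.
    """

    def __init__(self, maps, groups, voxel_sizes_mm=None):
        groups = list(groups)
        if len(maps) != len(groups):
            raise ValueError("maps and groups must align")
        self.maps_a = [m for m, g in zip(maps, groups) if g == "patient"]
        self.maps_b = [m for m, g in zip(maps, groups) if g == "control"]
        if len(self.maps_a) < 2 or len(self.maps_b) < 2:
            raise ValueError("need at least two subjects per group")
        self.maps = list(maps)
        self.groups = groups
        self.mask = maps[0].mask
        aff = maps[0].affine
        self.voxel_sizes_mm = (
            np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
            if voxel_sizes_mm is None
            else np.asarray(voxel_sizes_mm, dtype=float)
        )

    def fit(
        self, voxel_p: float = 0.001, cluster_p: float = 0.01, connectivity: int = 26
    ) -> "NHGroupResults":
        tmap = voxelwise_two_sample_t(self.maps_a, self.maps_b, self.mask)
        residuals = []
        for group_maps in (self.maps_a, self.maps_b):
            stack = np.stack([np.where(self.mask, m.data, 0.0) for m in group_maps])
            residuals.extend(stack - stack.mean(axis=0))
        smoothness = estimate_smoothness(residuals, self.mask, self.voxel_sizes_mm)
        clusters = grf_cluster_inference(
            tmap, smoothness, voxel_p=voxel_p, cluster_p=cluster_p, connectivity=connectivity
        )
        return NHGroupResults(
            model=self,
            tmap=tmap,
            smoothness=smoothness,
            clusters=clusters,
            voxel_p=voxel_p,
            cluster_p=cluster_p,
            connectivity=connectivity,
        )


@dataclass
class NHGroupResults:
    """Fitted group comparison: t map, smoothness, surviving clusters."""

    model: NHGroupModel
    tmap: TMap
    smoothness: SmoothnessEstimate
    clusters: list
    voxel_p: float
    cluster_p: float
    connectivity: int

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            rows.append(
                {
                    "direction": c.direction,
                    "peak_x_mm": c.peak_mm[0] if c.peak_mm else np.nan,
                    "peak_y_mm": c.peak_mm[1] if c.peak_mm else np.nan,
                    "peak_z_mm": c.peak_mm[2] if c.peak_mm else np.nan,
                    "extent_voxels": c.extent,
                    "peak_t": c.peak_t,
                    "p_corrected": c.p_corrected,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "direction",
                "peak_x_mm",
                "peak_y_mm",
                "peak_z_mm",
                "extent_voxels",
                "peak_t",
                "p_corrected",
            ],
        )

    def summary(self) -> str:
        n1, n2 = len(self.model.maps_a), len(self.model.maps_b)
        lines = [
            "Network homogeneity group comparison",
            "====================================",
            f"patients: {n1}   controls: {n2}   df: {self.tmap.df}",
            f"mask voxels: {int(self.tmap.mask.sum())}",
            "smoothness FWHM (mm): "
            + ", ".join(f"{f:.2f}" for f in self.smoothness.fwhm_mm)
            + f"   resels: {self.smoothness.resels:.2f}",
            f"thresholds: voxel p < {self.voxel_p}, cluster p < {self.cluster_p} (GRF)",
            f"surviving clusters: {len(self.clusters)}",
        ]
        table = self.cluster_table()
        if len(table):
            lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
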