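"""Genomic Co-Co (coincidence/concordance) plots.

Each clinal locus is embedded at (midpoint, log|slope|); a 2-D Gaussian
kernel density with cross-validated bandwidths is estimated over the cloud;
highest-density-region (HDR) envelopes at 75/95/99 % of the density mass are
drawn; loci falling outside the 95 % envelope are flagged as outliers —
clines whose location or steepness departs from the genomic consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from sklearn.base import BaseEstimator, OutlierMixin
from statsmodels.nonparametric.kernel_density import KDEMultivariate

from .cline import ClineFit

DEFAULT_MASSES = (0.75, 0.95, 0.99)


def coco_coordinates(fits: list[ClineFit] | pd.DataFrame) -> pd.DataFrame:
    """(midpoint, log|slope|) coordinates for a set of clinal fits.

    Accepts ClineFit objects or a screening frame with midpoint/slope
    columns; slopes are log-transformed in absolute value (natural log) to
    undo the right-skew of raw slopes.
    """
    if isinstance(fits, pd.DataFrame):
        df = fits
        locus = df["locus"] if "locus" in df else pd.RangeIndex(len(df)).astype(str)
        mids = df["midpoint"].to_numpy(float)
        slopes = df["slope"].to_numpy(float)
    else:
        if len(fits) == 0:
            raise ValueError("no fits supplied")
        locus = [getattr(f, "locus", str(i)) for i, f in enumerate(fits)]
        mids = np.array([f.midpoint for f in fits], float)
        slopes = np.array([f.slope for f in fits], float)
    if len(mids) == 0:
        raise ValueError("no fits supplied")
    if np.any(slopes == 0) or np.any(~np.isfinite(mids)) or np.any(~np.isfinite(slopes)):
        raise ValueError("fits must have finite nonzero slopes (clinal screen output)")
    return pd.DataFrame(
        {"locus": list(locus), "midpoint": mids, "log_abs_slope": np.log(np.abs(slopes))}
    )


@dataclass
class DensityField:
    """A KDE evaluated on a rectangular grid over (midpoint, log|slope|)."""

    x: np.ndarray  # grid of midpoints, shape (gx,)
    y: np.ndarray  # grid of log|slope|, shape (gy,)
    density: np.ndarray  # shape (gx, gy)
    bandwidth: np.ndarray  # 2x2 diagonal bandwidth matrix
    method: str

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    @property
    def grid_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


def estimate_density(
    points: pd.DataFrame | np.ndarray,
    bandwidth_method: str = "cv",
    grid_size: int = 256,
    pad_bandwidths: float = 4.0,
    seed: int | None = None,
) -> DensityField:
    """Gaussian-kernel 2-D density of the Co-Co cloud.

    Bandwidths (one per axis; a diagonal bandwidth matrix) are selected by
    least-squares cross-validation (``"cv"``) with a normal-reference
    plug-in fallback when the CV objective degenerates, or directly by
    plug-in (``"plugin"``).  The evaluation grid extends *pad_bandwidths*
    bandwidths beyond the data range so essentially all kernel mass is on
    the grid.
    """
    pts = _as_points(points)
    if len(pts) < 10:
        raise ValueError("need >= 10 points; use bandwidth_method='plugin' on tiny sets")
    if np.allclose(pts.std(axis=0), 0):
        raise ValueError("all points identical; density undefined")
    if bandwidth_method not in ("cv", "plugin"):
        raise ValueError("bandwidth_method must be 'cv' or 'plugin'")

    bw = None
    if bandwidth_method == "cv":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kde = KDEMultivariate(pts, var_type="cc", bw="cv_ls")
        bw = np.asarray(kde.bw, float)
        if not np.all(np.isfinite(bw)) or np.any(bw <= 1e-6 * pts.std(axis=0)):
            bw = None  # degenerate CV objective -> plug-in fallback
    if bw is None:
        kde = KDEMultivariate(pts, var_type="cc", bw="normal_reference")
        bw = np.asarray(kde.bw, float)
        method = "plugin"
    else:
        method = "cv"

    pad = pad_bandwidths * bw
    gx = np.linspace(pts[:, 0].min() - pad[0], pts[:, 0].max() + pad[0], grid_size)
    gy = np.linspace(pts[:, 1].min() - pad[1], pts[:, 1].max() + pad[1], grid_size)
    dens = _eval_gaussian_kde(pts, bw, gx, gy)
    return DensityField(gx, gy, dens, np.diag(bw**2), method)


def _eval_gaussian_kde(pts, bw, gx, gy):
    """Product-Gaussian KDE on a grid, chunked over points."""
    n = len(pts)
    out = np.zeros((len(gx), len(gy)))
    norm = 1.0 / (n * 2 * np.pi * bw[0] * bw[1])
    for start in range(0, n, 256):
        chunk = pts[start : start + 256]
        ex = np.exp(-0.5 * ((gx[:, None] - chunk[None, :, 0]) / bw[0]) ** 2)
        ey = np.exp(-0.5 * ((gy[:, None] - chunk[None, :, 1]) / bw[1]) ** 2)
        out += ex @ ey.T
    return out * norm


def density_at(field: DensityField, points) -> np.ndarray:
    """Bilinear interpolation of the density at arbitrary points (0 outside)."""
    pts = _as_points(points)
    interp = RegularGridInterpolator(
        (field.x, field.y), field.density, bounds_error=False, fill_value=0.0
    )
    return interp(pts)


def hdr_thresholds(
    field: DensityField, masses=DEFAULT_MASSES, points=None
) -> dict[float, float]:
    """Density levels for the highest-density-region envelopes.

    With ``points`` given (the default used for outlier flagging), the level
    for mass m is the (1 - m) quantile of the estimated density evaluated at
    the sample points — the convention of kernel-smoothing contour software,
    which makes the m-envelope contain ~m of the sample by construction.

    With ``points=None`` the level is instead the largest density value
    lambda such that the grid mass of {density >= lambda} reaches m (closest
    from above) — the literal probability-mass HDR of the estimated density,
    which over-covers its own sample slightly because of kernel smoothing.
    """
    for m in masses:
        if not 0 < m <= 1:
            raise ValueError("masses must lie in (0, 1]")
    if points is not None:
        dens = density_at(field, points)
        return {float(m): float(np.quantile(dens, 1.0 - m)) for m in masses}
    flat = np.sort(field.density.ravel())[::-1]
    flat = flat[flat > 0]
    cum = np.cumsum(flat) * field.cell_area
    out = {}
    for m in masses:
        k = int(np.searchsorted(cum, min(m, cum[-1])))
        k = min(k, len(flat) - 1)
        out[float(m)] = float(flat[k])
    return out


def flag_coco_outliers(
    points, field: DensityField, mass: float = 0.95, thresholds: dict | None = None
) -> np.ndarray:
    """Boolean outlier flags: density at the point below the HDR level."""
    if thresholds is None or float(mass) not in thresholds:
        thresholds = hdr_thresholds(field, (mass,), points=points)
    level = thresholds[float(mass)]
    d = density_at(field, points)
    if np.any(d == 0):
        warnings.warn("point(s) outside the density grid; flagged as outliers")
    return d < level


class CoCoOutlierDetector(OutlierMixin, BaseEstimator):
    """HDR-envelope outlier detection on the (midpoint, log|slope|) cloud.

    fit() estimates the cross-validated KDE and the 75/95/99 % HDR levels;
    predict() flags points whose interpolated density falls below the
    ``outlier_mass`` envelope (default 95 %).
    """

    def __init__(
        self,
        bandwidth_method: str = "cv",
        grid_size: int = 256,
        masses: tuple = DEFAULT_MASSES,
        outlier_mass: float = 0.95,
        pad_bandwidths: float = 4.0,
    ):
        self.bandwidth_method = bandwidth_method
        self.grid_size = grid_size
        self.masses = masses
        self.outlier_mass = outlier_mass
        self.pad_bandwidths = pad_bandwidths

    def fit(self, X, y=None):
        pts = _as_points(X)
        self.field_ = estimate_density(
            pts,
            bandwidth_method=self.bandwidth_method,
            grid_size=self.grid_size,
            pad_bandwidths=self.pad_bandwidths,
        )
        all_masses = tuple(sorted(set(self.masses) | {self.outlier_mass}))
        self.thresholds_ = hdr_thresholds(self.field_, all_masses, points=pts)
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        """True for outliers (outside the outlier_mass HDR envelope)."""
        return flag_coco_outliers(
            _as_points(X), self.field_, self.outlier_mass, self.thresholds_
        )

    def score_samples(self, X) -> np.ndarray:
        return density_at(self.field_, _as_points(X))

    def report(self, points: pd.DataFrame) -> pd.DataFrame:
        """Outlier table: locus, coordinates, density and envelope level."""
        pts = _as_points(points)
        dens = density_at(self.field_, pts)
        env = np.full(len(pts), np.inf)  # tightest envelope containing the point
        for m in sorted(self.thresholds_, reverse=True):
            env[dens >= self.thresholds_[m]] = m
        df = points.copy() if isinstance(points, pd.DataFrame) else pd.DataFrame(
            pts, columns=["midpoint", "log_abs_slope"]
        )
        df["density"] = dens
        df["envelope"] = env
        df["outlier"] = self.predict(pts)
        return df


def plot_coco(
    points,
    field: DensityField,
    thresholds: dict[float, float],
    highlight: list[str] | None = None,
    path=None,
):
    """Scatter + HDR contour rendering of the Co-Co plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = _as_points(points)
    fig, ax = plt.subplots(figsize=(6, 5))
    levels = sorted(thresholds.values())
    ax.contour(
        field.x, field.y, field.density.T, levels=levels, colors="black", linewidths=0.8
    )
    out = flag_coco_outliers(pts, field, max(thresholds), thresholds)
    ax.scatter(pts[~out, 0], pts[~out, 1], s=12, c="grey", label="loci")
    if out.any():
        ax.scatter(pts[out, 0], pts[out, 1], s=18, c="red", label="outliers")
    if highlight and isinstance(points, pd.DataFrame) and "locus" in points:
        sel = points["locus"].isin(highlight).to_numpy()
        ax.scatter(pts[sel, 0], pts[sel, 1], s=30, facecolors="none", edgecolors="blue")
    ax.set_xlabel("cline midpoint (degrees latitude)")
    ax.set_ylabel("log |slope|")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def _as_points(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[["midpoint", "log_abs_slope"]].to_numpy(float)
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): midpoint, log|slope|")
    return pts
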