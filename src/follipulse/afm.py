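"""AFM force-curve analysis: contact-point search, Hertz/Sneddon fits, map summaries.

Stiffness of follicle compartments is probed ex vivo by indenting a 15x15 µm
region on an 8x8 grid (64 points) and recording force F versus probe travel z.
Each approach curve is split into a flat pre-contact baseline and a
post-contact rise following a contact-mechanics law:

    sphere (Hertz):  F = (4/3) sqrt(R) * E/(1-nu^2) * delta^{3/2}
    cone (Sneddon):  F = (2/pi) tan(theta) * E/(1-nu^2) * delta^2

with indentation delta = z - z_contact, Poisson ratio nu (0.5 = incompressible
soft tissue) and tip radius R / half-angle theta.  E (Young's modulus, Pa)
falls out of a linear least-squares fit in delta^p because the exponent p is
fixed by the geometry.

Regions are compared nonparametrically (two-sided Mann-Whitney U on pooled
per-point moduli), matching how tissue force maps are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, InsufficientDataError, MapQualityError, ValidationError
from .stats import MannWhitneyResult, mann_whitney_u

_NM = 1e-9
_UM = 1e-6
_PN = 1e-12

GEOMETRIES = ("sphere", "cone")


@dataclass
class ForceCurve:
    """One force-indentation curve: probe travel z (nm) vs force (pN)."""

    z_nm: np.ndarray
    force_pn: np.ndarray
    direction: str = "approach"

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.force_pn = np.asarray(self.force_pn, dtype=float)
        if self.z_nm.size != self.force_pn.size:
            raise ValidationError("z and force must have equal length")
        if self.z_nm.size < 20:
            raise ValidationError("a force curve needs at least 20 samples")
        if np.any(np.diff(self.z_nm) <= 0):
            raise ValidationError("z must be strictly increasing")


@dataclass
class ForceMap:
    """Grid of force curves over one region (bulge / HG / cultured cell)."""

    region: str
    grid: int
    region_size_um: float
    curves: list[ForceCurve]
    positions_um: np.ndarray | None = None  # (n, 2) grid coordinates
    true_e_pa: np.ndarray | None = None  # per-point truth when synthetic

    def __post_init__(self) -> None:
        if len(self.curves) != self.grid**2:
            raise ValidationError(
                f"expected {self.grid ** 2} curves for a {self.grid}x{self.grid} map, "
                f"got {len(self.curves)}"
            )


@dataclass(frozen=True)
class StiffnessResult:
    e_pa: float
    contact_index: int
    rss: float
    geometry: str
    poisson: float
    tip_parameter: float  # radius in µm (sphere) or half-angle in degrees (cone)
    ok: bool = True
    reason: str = ""


@dataclass(frozen=True)
class RegionComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str


def _geometry_prefactor(geometry: str, tip_parameter: float) -> tuple[float, float]:
    """Return (k, p) so that F = k * E/(1-nu^2) * delta^p in SI units."""
    if geometry == "sphere":
        radius_m = tip_parameter * _UM
        if radius_m <= 0:
            raise ValidationError("tip radius must be positive")
        return (4.0 / 3.0) * np.sqrt(radius_m), 1.5
    if geometry == "cone":
        theta = np.deg2rad(tip_parameter)
        if not 0 < theta < np.pi / 2:
            raise ValidationError("half-angle must be in (0, 90) degrees")
        return (2.0 / np.pi) * np.tan(theta), 2.0
    raise ValidationError(f"unknown geometry {geometry!r}; use one of {GEOMETRIES}")


def estimate_contact_point(
    curve: ForceCurve,
    geometry: str = "sphere",
    min_baseline: int = 5,
    min_post: int = 5,
) -> int:
    """Index of the contact point, by piecewise (flat | contact-law) least squares.

    Every admissible split k is scored by the summed residual of a constant
    baseline on z[:k] and a delta^p rise on z[k:]; the minimizer wins.  A curve
    with no positive rise (pure baseline) has no admissible split.
    """
    exponent = _geometry_prefactor(geometry, 1.0 if geometry == "sphere" else 30.0)[1]
    z, f = curve.z_nm, curve.force_pn
    n = z.size
    best_rss, best_k, best_c = np.inf, -1, 0.0
    for k in range(min_baseline, n - min_post):
        baseline = f[:k].mean()
        delta = z[k:] - z[k]
        x = delta**exponent
        denom = float(np.dot(x, x))
        if denom == 0:
            continue
        c = float(np.dot(f[k:] - baseline, x)) / denom
        rss = float(np.sum((f[:k] - baseline) ** 2)) + float(
            np.sum((f[k:] - baseline - c * x) ** 2)
        )
        if rss < best_rss:
            best_rss, best_k, best_c = rss, k, c
    if best_k < 0 or best_c <= 0:
        raise FitError("no admissible contact point (no positive post-contact rise)")
    return best_k


def fit_hertz(
    curve: ForceCurve,
    geometry: str = "sphere",
    poisson: float = 0.5,
    tip_parameter: float = 1.0,
    contact_index: int | None = None,
) -> StiffnessResult:
    """Young's modulus (Pa) from one approach curve.

    ``tip_parameter`` is the sphere radius in µm or the cone half-angle in
    degrees.  With ``contact_index=None`` the contact point is estimated first.
    """
    if not 0 <= poisson <= 0.5:
        raise ValidationError("poisson ratio must lie in [0, 0.5]")
    k_geom, exponent = _geometry_prefactor(geometry, tip_parameter)
    if contact_index is None:
        contact_index = estimate_contact_point(curve, geometry=geometry)
    z, f = curve.z_nm, curve.force_pn
    if not 0 < contact_index < z.size:
        raise ValidationError("contact_index outside curve")
    baseline = f[:contact_index].mean() if contact_index >= 3 else 0.0
    delta_m = (z[contact_index:] - z[contact_index]) * _NM
    force_n = (f[contact_index:] - baseline) * _PN
    post = delta_m > 0
    if int(post.sum()) < 5:
        raise InsufficientDataError("fewer than 5 post-contact points")
    x = delta_m[post] ** exponent
    c = float(np.dot(force_n[post], x) / np.dot(x, x))
    e_pa = c * (1.0 - poisson**2) / k_geom
    rss = float(np.sum((force_n[post] - c * x) ** 2))
    if e_pa <= 0:
        raise FitError("negative fitted modulus")
    return StiffnessResult(e_pa, contact_index, rss, geometry, poisson, tip_parameter)


@dataclass(frozen=True)
class MapSummary:
    results: list[StiffnessResult]
    mean_pa: float
    sd_pa: float
    median_pa: float
    n_ok: int
    n_failed: int


def map_stiffness(
    fmap: ForceMap,
    geometry: str = "sphere",
    poisson: float = 0.5,
    tip_parameter: float = 1.0,
) -> MapSummary:
    """Fit every grid point; failed points are flagged, never silently dropped."""
    results: list[StiffnessResult] = []
    for curve in fmap.curves:
        try:
            results.append(
                fit_hertz(curve, geometry=geometry, poisson=poisson, tip_parameter=tip_parameter)
            )
        except (FitError, InsufficientDataError, ValidationError) as exc:
            reason = (
                "no_contact"
                if "contact" in str(exc)
                else "negative_E"
                if "negative" in str(exc)
                else "short_segment"
            )
            results.append(
                StiffnessResult(np.nan, -1, np.nan, geometry, poisson, tip_parameter, False, reason)
            )
    ok = [r.e_pa for r in results if r.ok]
    n_failed = len(results) - len(ok)
    if n_failed > len(results) / 2:
        raise MapQualityError(f"{n_failed}/{len(results)} points failed to fit")
    arr = np.array(ok)
    return MapSummary(
        results,
        float(arr.mean()),
        float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        float(np.median(arr)),
        len(ok),
        n_failed,
    )


def compare_regions(values_a, values_b) -> RegionComparison:
    """Two-sided Mann-Whitney U comparison of pooled per-point moduli."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("compare_regions needs at least 3 values per group")
    mw = mann_whitney_u(a, b)
    return RegionComparison(
        float(a.mean()),
        float(a.std(ddof=1)),
        float(b.mean()),
        float(b.std(ddof=1)),
        a.size,
        b.size,
        mw.u_statistic,
        mw.p_value,
        mw.method,
    )


def percent_stiffer(mean_a: float, mean_b: float) -> int:
    """How much stiffer region A is than region B, in percent (nearest integer)."""
    if mean_b <= 0:
        raise ValidationError("reference mean must be positive")
    return int(round(100.0 * (mean_a - mean_b) / mean_b))


def plot_map(summary: MapSummary, grid: int, path: str) -> None:
    """Save a heat map of per-point moduli (PNG); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    e = np.array([r.e_pa for r in summary.results]).reshape(grid, grid)
    fig, ax = plt.subplots(figsize=(4, 3.4))
    im = ax.imshow(e, cmap="viridis")
    fig.colorbar(im, ax=ax, label="E (Pa)")
    ax.set_title("Per-point Young's modulus")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
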