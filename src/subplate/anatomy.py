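"""Normalized cortical depth, laminar assignment, and enrichment statistics.

Given manually drawn pial and lower-subplate boundary point clouds, each is
fitted with a least-squares quadratic surface z = f(x, y). A cell's
normalized depth is its Euclidean distance to the pial surface divided by
the local cortical thickness — the length of the segment from the cell's
nearest pial point, through the cell, to the lower-subplate surface — so
depth 0 is the pia and depth 1 the subplate/white-matter boundary. Depths
are mapped to layers by the cumulative relative thicknesses of a per-area
layer scheme, and backlabeled-cell counts are tested for laminar enrichment
against expected neuron proportions (chi-square goodness of fit, followed by
per-layer exact binomial tests; the cell-sparse marginal zone is excluded).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .synthetic import CellCloud, eval_quadratic

LAYER_ORDER = ("MZ", "CP", "L5", "L6", "SP")


# ---------------------------------------------------------------------------
# layer schemes
# ---------------------------------------------------------------------------

@dataclass
class LayerScheme:
    """Per-area layer order, relative thicknesses, and expected neuron proportions."""

    area: str
    layers: tuple[str, ...]
    thickness: dict[str, float]
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        for layer in self.layers:
            if self.thickness[layer] <= 0:
                raise ValueError(f"thickness of {layer} must be > 0")
        s = sum(self.proportions[l] for l in self.layers)
        if not 0.98 <= s <= 1.02:
            raise ValueError(f"expected proportions sum to {s:.3f}, outside 1 +/- 0.02")

    def thickness_renormalized(self) -> np.ndarray:
        t = np.array([self.thickness[l] for l in self.layers], dtype=float)
        return t / t.sum()

    def proportions_renormalized(self, include: Sequence[str] | None = None) -> np.ndarray:
        layers = self.layers if include is None else tuple(include)
        p = np.array([self.proportions[l] for l in layers], dtype=float)
        return p / p.sum()

    def depth_boundaries(self) -> np.ndarray:
        """Cumulative depth bounds [0, c1, ..., 1] in layer order."""
        c = np.concatenate(([0.0], np.cumsum(self.thickness_renormalized())))
        c[-1] = 1.0
        return c


def load_scheme(area: str, thickness_variant: str = "corrected") -> LayerScheme:
    """Load the bundled scheme for one area.

    ``thickness_variant`` is "corrected" (default; S2 L6 = 0.267) or
    "verbatim" (S2 L6 = 0.867 as printed).
    """
    text = resources.files("subplate.data").joinpath("layer_schemes.yaml").read_text()
    raw = yaml.safe_load(text)
    key = {"corrected": "thickness", "verbatim": "thickness_verbatim"}[thickness_variant]
    if area not in raw[key]:
        raise KeyError(f"unknown area {area!r}; known: {sorted(raw[key])}")
    return LayerScheme(
        area=area,
        layers=tuple(raw["layers"]),
        thickness=dict(raw[key][area]),
        proportions=dict(raw["neuron_proportions"][area]),
    )


# ---------------------------------------------------------------------------
# surfaces and depth
# ---------------------------------------------------------------------------

@dataclass
class SurfaceModel:
    """Least-squares quadratic surface z = f(x, y) fitted to boundary points."""

    coeffs: np.ndarray  # raw-space (1, x, y, x^2, xy, y^2)
    bbox: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)
    rms_residual: float

    def __call__(self, x, y):
        return eval_quadratic(self.coeffs, x, y)

    def gradient(self, x, y):
        c = self.coeffs
        return c[1] + 2 * c[3] * x + c[4] * y, c[2] + c[4] * x + 2 * c[5] * y


def fit_surface(points: np.ndarray) -> SurfaceModel:
    """Fit z = c0 + c1 x + c2 y + c3 x^2 + c4 xy + c5 y^2 by least squares.

    Coordinates are centered internally for conditioning; the returned
    coefficients are expanded back to raw space.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if pts.shape[0] < 6:
        raise ValueError("need at least 6 points for a quadratic surface")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    x0, y0 = x.mean(), y.mean()
    u, v = x - x0, y - y0
    design = np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("degenerate boundary points: quadratic design is rank-deficient")
    c, *_ = np.linalg.lstsq(design, z, rcond=None)
    # expand f(x - x0, y - y0) back to raw coordinates
    c0, c1, c2, c3, c4, c5 = c
    raw = np.array(
        [
            c0 - c1 * x0 - c2 * y0 + c3 * x0 * x0 + c4 * x0 * y0 + c5 * y0 * y0,
            c1 - 2 * c3 * x0 - c4 * y0,
            c2 - c4 * x0 - 2 * c5 * y0,
            c3,
            c4,
            c5,
        ]
    )
    resid = z - design @ c
    return SurfaceModel(
        coeffs=raw,
        bbox=(float(x.min()), float(x.max()), float(y.min()), float(y.max())),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def _nearest_points(surface: SurfaceModel, pts: np.ndarray, max_iter: int = 60) -> np.ndarray:
    """Lateral coordinates (x*, y*) of each point's nearest surface point.

    Newton iteration on the squared-distance gradient, vectorized over
    points; non-converged points fall back to a dense lateral grid search.
    """
    px, py, pz = pts[:, 0], pts[:, 1], pts[:, 2]
    x, y = px.copy(), py.copy()
    c = surface.coeffs
    for _ in range(max_iter):
        f = surface(x, y)
        fx, fy = surface.gradient(x, y)
        e = f - pz
        gx = 2 * (x - px) + 2 * e * fx
        gy = 2 * (y - py) + 2 * e * fy
        hxx = 2 + 2 * (fx * fx + e * 2 * c[3])
        hyy = 2 + 2 * (fy * fy + e * 2 * c[5])
        hxy = 2 * (fx * fy + e * c[4])
        det = hxx * hyy - hxy * hxy
        ok = np.abs(det) > 1e-12
        dx = np.where(ok, (hyy * gx - hxy * gy) / np.where(ok, det, 1.0), 0.0)
        dy = np.where(ok, (hxx * gy - hxy * gx) / np.where(ok, det, 1.0), 0.0)
        step = np.clip(np.sqrt(dx * dx + dy * dy), 0.0, None)
        scale = np.where(step > 50.0, 50.0 / np.where(step > 0, step, 1.0), 1.0)
        x -= dx * scale
        y -= dy * scale
        if np.max(np.abs(dx)) < 1e-10 and np.max(np.abs(dy)) < 1e-10:
            break
    # fallback: any point whose gradient is still large gets a grid search
    f = surface(x, y)
    fx, fy = surface.gradient(x, y)
    e = f - pz
    bad = np.sqrt((2 * (x - px) + 2 * e * fx) ** 2 + (2 * (y - py) + 2 * e * fy) ** 2) > 1e-6
    if np.any(bad):
        warnings.warn(f"nearest-point Newton did not converge for {int(bad.sum())} points; "
                      "falling back to grid search", stacklevel=2)
        for i in np.nonzero(bad)[0]:
            gx_ = np.arange(px[i] - 200.0, px[i] + 200.0, 1.0)
            gy_ = np.arange(py[i] - 200.0, py[i] + 200.0, 1.0)
            gxx, gyy = np.meshgrid(gx_, gy_, indexing="ij")
            d2 = (gxx - px[i]) ** 2 + (gyy - py[i]) ** 2 + (surface(gxx, gyy) - pz[i]) ** 2
            k = np.unravel_index(np.argmin(d2), d2.shape)
            x[i], y[i] = gxx[k], gyy[k]
    return np.column_stack([x, y])


def point_surface_distance(surface: SurfaceModel, point) -> float:
    """Signed minimal Euclidean distance from a point to the surface.

    Negative above the surface (smaller z, i.e. outside the pia for the pial
    surface), positive below.
    """
    pt = np.asarray(point, dtype=float).reshape(1, 3)
    xy = _nearest_points(surface, pt)[0]
    zq = float(surface(xy[0], xy[1]))
    d = math.dist((pt[0, 0], pt[0, 1], pt[0, 2]), (xy[0], xy[1], zq))
    sign = 1.0 if pt[0, 2] >= zq else -1.0
    return sign * d


def _ray_quadratic_intersection(coeffs, origin, direction):
    """Smallest positive t with z(origin + t*dir) on the quadratic surface."""
    ox, oy, oz = origin
    ux, uy, uz = direction
    c0, c1, c2, c3, c4, c5 = coeffs
    # f(ox + t ux, oy + t uy) - (oz + t uz) = A t^2 + B t + C
    A = c3 * ux * ux + c4 * ux * uy + c5 * uy * uy
    B = c1 * ux + c2 * uy + 2 * c3 * ox * ux + c4 * (ox * uy + oy * ux) + 2 * c5 * oy * uy - uz
    C = eval_quadratic(np.asarray(coeffs), ox, oy) - oz
    if abs(A) < 1e-15:
        if abs(B) < 1e-15:
            return None
        t = -C / B
        return t if t > 0 else None
    disc = B * B - 4 * A * C
    if disc < 0:
        return None
    roots = sorted(((-B - math.sqrt(disc)) / (2 * A), (-B + math.sqrt(disc)) / (2 * A)))
    for t in roots:
        if t > 1e-9:
            return t
    return None


def normalized_depths(
    cloud: CellCloud,
    pial: SurfaceModel,
    sp: SurfaceModel,
    scheme: LayerScheme | None = None,
) -> pd.DataFrame:
    """Per-cell pial distance, local thickness, normalized depth, and layer.

    Local thickness is measured along the ray from the cell's nearest pial
    point through the cell to the lower-subplate surface. Depths outside
    [0, 1] are clipped (with a warning when the excursion exceeds 0.01);
    cells with no valid thickness are flagged invalid.
    """
    frame = cloud.frame.copy()
    pts = frame[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    xy = _nearest_points(pial, pts)
    zq = pial(xy[:, 0], xy[:, 1])
    near = np.column_stack([xy, zq])
    vec = pts - near
    d_pial = np.linalg.norm(vec, axis=1)

    thickness = np.full(len(frame), np.nan)
    for i in range(len(frame)):
        if d_pial[i] < 1e-9:
            fx, fy = pial.gradient(near[i, 0], near[i, 1])
            u = np.array([-fx, -fy, 1.0])
        else:
            u = vec[i]
        u = u / np.linalg.norm(u)
        if u[2] < 0:
            u = -u  # orient the ray downward, toward the subplate
        t = _ray_quadratic_intersection(sp.coeffs, near[i], u)
        if t is not None:
            thickness[i] = t

    valid = np.isfinite(thickness) & (thickness > 0)
    depth = np.where(valid, d_pial / np.where(valid, thickness, 1.0), np.nan)
    over = np.nanmax(np.abs(np.clip(depth, 0, 1) - depth)) if np.any(valid) else 0.0
    if over > 0.01:
        warnings.warn(f"normalized depths clipped by up to {over:.3f}", stacklevel=2)
    depth = np.clip(depth, 0.0, 1.0)

    frame["distance_to_pial_um"] = d_pial
    frame["local_thickness_um"] = thickness
    frame["normalized_depth"] = depth
    frame["valid"] = valid
    if scheme is not None:
        frame["assigned_layer"] = [
            assign_layer(d, scheme) if ok else "" for d, ok in zip(depth, valid)
        ]
    return frame


def assign_layer(depth: float, scheme: LayerScheme) -> str:
    """Map a normalized depth to a layer via cumulative relative thicknesses.

    Bins are half-open [c_{k-1}, c_k) from the pia down; the deepest bin is
    closed at 1, and a depth exactly on a boundary belongs to the deeper layer.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("normalized depth must be in [0, 1]")
    bounds = scheme.depth_boundaries()[1:-1]
    idx = int(np.searchsorted(bounds, depth, side="right"))
    return scheme.layers[idx]


# ---------------------------------------------------------------------------
# counting and enrichment
# ---------------------------------------------------------------------------

def layer_proportions(
    counts: Mapping[str, int] | pd.Series,
    layers: Sequence[str] = LAYER_ORDER,
) -> pd.DataFrame:
    """Counts and truncated integer percentages per layer.

    Percentages are floored (printed-report convention: 41/111 -> 36%), so
    they may sum to less than 100.
    """
    c = {l: int(counts.get(l, 0)) for l in layers}
    total = sum(c.values())
    if total < 1:
        raise ValueError("need at least one counted cell")
    rows = [
        {"layer": l, "count": c[l], "percent": int(math.floor(100.0 * c[l] / total))}
        for l in layers
    ]
    out = pd.DataFrame(rows)
    out.attrs["total"] = total
    return out


def count_layers(
    frame: pd.DataFrame,
    backlabeled_only: bool = True,
    layer_column: str = "assigned_layer",
) -> pd.Series:
    sel = frame
    if backlabeled_only:
        sel = sel[sel["backlabeled"] == 1]
    return sel[layer_column].value_counts()


@dataclass
class EnrichmentResult:
    """Chi-square goodness of fit plus per-layer binomial follow-ups."""

    layers: tuple[str, ...]
    observed: np.ndarray
    expected_proportions: np.ndarray
    total: int
    chi2: float
    df: int
    p_value: float
    binomial_p: dict[str, float] = field(default_factory=dict)
    direction: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05
    multinomial_fallback: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, l in enumerate(self.layers):
            rows.append(
                {
                    "layer": l,
                    "observed": int(self.observed[i]),
                    "expected": self.expected_proportions[i] * self.total,
                    "binomial_p": self.binomial_p.get(l, float("nan")),
                    "direction": self.direction.get(l, ""),
                }
            )
        return pd.DataFrame(rows)


def enrichment_test(
    observed_counts: Mapping[str, int],
    scheme: LayerScheme,
    exclude: Sequence[str] = ("MZ",),
    alpha: float = 0.05,
    correction: str | None = None,
) -> EnrichmentResult:
    """Laminar enrichment of backlabeled cells against expected neuron proportions.

    Chi-square goodness of fit over the included layers (expected proportions
    renormalized after excluding the marginal zone); per-layer exact two-sided
    binomial tests are computed as follow-ups. No multiple-testing correction
    is applied by default; pass ``correction='bonferroni'`` to enable one.
    """
    layers = tuple(l for l in scheme.layers if l not in exclude)
    obs = np.array([int(observed_counts.get(l, 0)) for l in layers])
    total = int(obs.sum())
    if total < 5:
        raise ValueError("need at least 5 tested cells")
    p_exp = scheme.proportions_renormalized(include=layers)
    expected = total * p_exp
    fallback = bool(np.any(expected < 1))
    if fallback:
        warnings.warn("expected count < 1 in some layer; chi-square approximation is poor",
                      stacklevel=2)
    chi2, p = stats.chisquare(obs, f_exp=expected)
    binom_p, direction = {}, {}
    for i, l in enumerate(layers):
        res = stats.binomtest(int(obs[i]), total, p_exp[i], alternative="two-sided")
        pv = res.pvalue
        if correction == "bonferroni":
            pv = min(1.0, pv * len(layers))
        binom_p[l] = float(pv)
        direction[l] = "enriched" if obs[i] / total > p_exp[i] else "depleted"
    return EnrichmentResult(
        layers=layers,
        observed=obs,
        expected_proportions=p_exp,
        total=total,
        chi2=float(chi2),
        df=len(layers) - 1,
        p_value=float(p),
        binomial_p=binom_p,
        direction=direction,
        alpha=alpha,
        multinomial_fallback=fallback,
    )
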