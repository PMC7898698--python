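"""Fibre and capillarity morphometry on muscle-section geometry.

Implements the standard indices of muscle capillary supply:

* FCSA — fibre-type-specific cross-sectional area (µm², shoelace area
  of each outline polygon), with numerical and areal composition;
* C:F — global capillary-to-fibre ratio; CD — capillary density (mm⁻²);
* CDA — capillary domain area: the Voronoi region of tissue closer to a
  capillary than to any other, clipped to the region of interest;
* LCFR — local capillary-to-fibre ratio of a fibre: the sum over
  capillaries of the fraction of each capillary's domain overlapping
  that fibre (capillary-domain definition, which conserves capillary
  number over gap-free tilings);
* LCD — LCFR divided by the fibre's area, in mm⁻².

Counting uses a Gundersen-style unbiased frame: fibres crossing the
inclusion edges (left, bottom) are kept, fibres touching the exclusion
edges (right, top) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely import voronoi_polygons
from shapely.geometry import LineString, MultiPoint, Point, Polygon, box
from shapely.strtree import STRtree

from .section import Fibre, MuscleSection

UM2_PER_MM2 = 1e6


class MorphometryError(ValueError):
    pass


# ----------------------------------------------------------------------
# Counting frame
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CountingFrame:
    """Rectangular unbiased counting frame inside the ROI.

    Left and bottom edges are inclusion edges; right and top edges are
    exclusion edges.
    """

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise MorphometryError("counting frame must have positive extent")

    @property
    def rect(self) -> Polygon:
        return box(self.x0, self.y0, self.x1, self.y1)

    @property
    def exclusion_edges(self) -> list:
        return [LineString([(self.x1, self.y0), (self.x1, self.y1)]),  # right
                LineString([(self.x0, self.y1), (self.x1, self.y1)])]  # top

    @classmethod
    def from_roi(cls, roi: Polygon) -> "CountingFrame":
        x0, y0, x1, y1 = roi.bounds
        return cls(x0, y0, x1, y1)


def apply_counting_frame(section: MuscleSection, frame: CountingFrame
                         ) -> MuscleSection:
    """Retain fibres by the Gundersen rule and capillaries inside the frame.

    A fibre is kept when it intersects the frame and does not touch an
    exclusion (right/top) edge.  The returned section's ROI is the
    intersection of the frame rectangle with the original ROI.
    """
    rect = frame.rect
    if not section.roi.buffer(1e-6).covers(rect):
        raise MorphometryError("counting frame extends outside the ROI")
    tol = 1e-9
    excl = frame.exclusion_edges
    kept: list[Fibre] = []
    for f in section.fibres:
        if not f.polygon.intersects(rect):
            continue
        if any(f.polygon.distance(e) < tol for e in excl):
            continue
        kept.append(f)
    caps = np.array([(x, y) for x, y in section.capillaries
                     if rect.covers(Point(x, y))], dtype=float).reshape(-1, 2)
    new_roi = rect.intersection(section.roi)
    return MuscleSection(roi=new_roi, fibres=kept, capillaries=caps,
                         meta=dict(section.meta, counting_frame=(frame.x0, frame.y0,
                                                                 frame.x1, frame.y1)))


# ----------------------------------------------------------------------
# Fibre metrics
# ----------------------------------------------------------------------

def shoelace_area(coords: np.ndarray) -> float:
    """Polygon area by the shoelace formula (positive, µm²)."""
    c = np.asarray(coords, dtype=float)
    x, y = c[:, 0], c[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def fibre_metrics(section: MuscleSection) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fibre CSA plus per-type composition.

    Returns ``(per_fibre, composition)``: per_fibre has columns
    fibre_id, type, csa_um2; composition is indexed by type with
    numerical_pct (count share) and areal_pct (area share), mean and SD
    of CSA.
    """
    if section.n_fibres == 0:
        raise MorphometryError("section has no fibres")
    rows = []
    for i, f in enumerate(section.fibres):
        if not f.polygon.is_valid:
            raise MorphometryError(f"fibre {i} polygon is self-intersecting")
        csa = shoelace_area(np.asarray(f.polygon.exterior.coords)[:-1])
        rows.append((i, f.fibre_type, csa))
    per_fibre = pd.DataFrame(rows, columns=["fibre_id", "type", "csa_um2"])
    grp = per_fibre.groupby("type")["csa_um2"]
    comp = pd.DataFrame({
        "n": grp.size(),
        "mean_csa_um2": grp.mean(),
        "sd_csa_um2": grp.std(ddof=1).fillna(0.0),
        "numerical_pct": 100.0 * grp.size() / len(per_fibre),
        "areal_pct": 100.0 * grp.sum() / per_fibre["csa_um2"].sum(),
    })
    return per_fibre, comp


# ----------------------------------------------------------------------
# Capillary domains
# ----------------------------------------------------------------------

@dataclass
class CapillaryDomainMap:
    """Per-capillary Voronoi domains clipped to the ROI.

    ``overlap_fraction[c, i]`` is the fraction of capillary c's domain
    area overlapping fibre i; row sums are at most 1 (the remainder is
    interstitial space).
    """

    domains: list                      # shapely Polygons, one per capillary
    overlap_fraction: np.ndarray       # (n_cap, n_fibre)
    areas: np.ndarray = field(default=None)  # µm², one per capillary

    def __post_init__(self) -> None:
        if self.areas is None:
            self.areas = np.array([d.area for d in self.domains])


def capillary_domains(section: MuscleSection) -> CapillaryDomainMap:
    """Euclidean Voronoi tessellation of capillaries, clipped to the ROI.

    Raises on duplicate capillary coordinates (degenerate tessellation).
    """
    caps = section.capillaries
    if len(caps) == 0:
        raise MorphometryError("section has no capillaries")
    uniq = {(round(x, 9), round(y, 9)) for x, y in caps}
    if len(uniq) < len(caps):
        raise MorphometryError("duplicate capillary coordinates: "
                               "Voronoi tessellation is degenerate")
    roi = section.roi
    if len(caps) == 1:
        domains = [roi]
    else:
        minx, miny, maxx, maxy = roi.bounds
        w, h = maxx - minx, maxy - miny
        envelope = box(minx - w, miny - h, maxx + w, maxy + h)
        vor = voronoi_polygons(MultiPoint(caps), extend_to=envelope, ordered=True)
        domains = [g.intersection(roi) for g in vor.geoms]

    n_fib = section.n_fibres
    frac = np.zeros((len(domains), n_fib))
    if n_fib:
        polys = [f.polygon for f in section.fibres]
        tree = STRtree(polys)
        for c, dom in enumerate(domains):
            if dom.is_empty or dom.area == 0:
                continue
            for i in tree.query(dom):
                inter = dom.intersection(polys[i]).area
                if inter > 0:
                    frac[c, i] = inter / dom.area
    return CapillaryDomainMap(domains=domains, overlap_fraction=frac)


def global_capillarity(section: MuscleSection, domains: CapillaryDomainMap,
                       include_border_domains: bool = True
                       ) -> tuple[float, float, float]:
    """(C:F ratio, capillary density mm⁻², mean capillary domain area µm²).

    ``include_border_domains=False`` drops ROI-boundary-clipped domains
    from the CDA mean (their true extent is censored by the frame).
    """
    if section.n_fibres == 0:
        raise MorphometryError("section has no fibres")
    n_cap = section.n_capillaries
    cf = n_cap / section.n_fibres
    cd = n_cap / section.roi.area * UM2_PER_MM2
    areas = domains.areas
    if not include_border_domains:
        border = section.roi.exterior
        inner = [a for d, a in zip(domains.domains, areas)
                 if d.distance(border) > 1e-9 and not d.intersects(border)]
        areas = np.array(inner) if inner else areas
    cda_mean = float(np.mean(areas)) if len(areas) else float("nan")
    return cf, cd, cda_mean


def local_capillarity(section: MuscleSection, domains: CapillaryDomainMap
                      ) -> pd.DataFrame:
    """Per-fibre LCFR and LCD.

    LCFR_i = Σ_c f[c,i] (capillary-domain fractions overlapping fibre i);
    LCD_i = LCFR_i / CSA_i, converted to mm⁻².
    """
    per_fibre, _ = fibre_metrics(section)
    lcfr = domains.overlap_fraction.sum(axis=0)
    out = per_fibre.copy()
    out["lcfr"] = lcfr
    out["lcd_mm2"] = lcfr / per_fibre["csa_um2"].to_numpy() * UM2_PER_MM2
    return out


# ----------------------------------------------------------------------
# Summary
# ----------------------------------------------------------------------

@dataclass
class CapillaritySummary:
    cf_ratio: float
    cd: float                      # mm⁻²
    cda_mean: float                # µm²
    fcsa: dict                     # type -> (mean µm², sd)
    numerical_pct: dict            # type -> %
    areal_pct: dict                # type -> %
    lcfr: dict                     # type -> mean
    lcd: dict                      # type -> mean mm⁻²
    n_fibres: int = 0
    n_capillaries: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("cf_ratio", "", self.cf_ratio), ("cd_mm2", "", self.cd),
                ("cda_mean_um2", "", self.cda_mean)]
        for t in self.fcsa:
            rows += [("fcsa_mean_um2", t, self.fcsa[t][0]),
                     ("fcsa_sd_um2", t, self.fcsa[t][1]),
                     ("numerical_pct", t, self.numerical_pct[t]),
                     ("areal_pct", t, self.areal_pct[t]),
                     ("lcfr_mean", t, self.lcfr[t]),
                     ("lcd_mean_mm2", t, self.lcd[t])]
        return pd.DataFrame(rows, columns=["metric", "fibre_type", "value"])


def summarize_capillarity(section: MuscleSection,
                          domains: Optional[CapillaryDomainMap] = None,
                          include_border_domains: bool = True
                          ) -> CapillaritySummary:
    """All global and local capillarity indices for one section."""
    if domains is None:
        domains = capillary_domains(section)
    cf, cd, cda = global_capillarity(section, domains, include_border_domains)
    per_fibre, comp = fibre_metrics(section)
    local = local_capillarity(section, domains)
    by_type = local.groupby("type")
    return CapillaritySummary(
        cf_ratio=cf, cd=cd, cda_mean=cda,
        fcsa={t: (comp.loc[t, "mean_csa_um2"], comp.loc[t, "sd_csa_um2"])
              for t in comp.index},
        numerical_pct={t: comp.loc[t, "numerical_pct"] for t in comp.index},
        areal_pct={t: comp.loc[t, "areal_pct"] for t in comp.index},
        lcfr={t: g["lcfr"].mean() for t, g in by_type},
        lcd={t: g["lcd_mm2"].mean() for t, g in by_type},
        n_fibres=section.n_fibres, n_capillaries=section.n_capillaries,
    )
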