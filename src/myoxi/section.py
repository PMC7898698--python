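"""Muscle-section geometry container and GeoJSON serialisation.

A transverse muscle section is represented in physical micrometre
coordinates (origin bottom-left): a region of interest (ROI) polygon, a
set of fibre outline polygons each carrying a fibre-type label, and a
set of capillary point locations.  This is the common currency passed
between the synthetic generator, the morphometry routines and the
oxygen-transport solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon, shape, mapping

FIBRE_TYPES = ("I", "IIa", "IIbx")


class SectionGeometryError(ValueError):
    """Raised when section geometry violates its invariants."""


@dataclass(frozen=True)
class Fibre:
    """A single muscle fibre: outline polygon (µm) plus type label."""

    polygon: Polygon
    fibre_type: str

    def __post_init__(self) -> None:
        if self.fibre_type not in FIBRE_TYPES:
            raise SectionGeometryError(
                f"unknown fibre type {self.fibre_type!r}; expected one of {FIBRE_TYPES}"
            )

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class MuscleSection:
    """ROI polygon, typed fibre polygons and capillary points, in µm.

    Invariants (checked by :meth:`validate`): fibre polygons are simple
    and pairwise interior-disjoint; every capillary lies inside the ROI;
    fibre vertices lie inside or on the ROI boundary.
    """

    roi: Polygon
    fibres: list[Fibre]
    capillaries: np.ndarray  # (N, 2) float array, µm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.capillaries = np.asarray(self.capillaries, dtype=float).reshape(-1, 2)

    @property
    def n_fibres(self) -> int:
        return len(self.fibres)

    @property
    def n_capillaries(self) -> int:
        return len(self.capillaries)

    def fibre_types(self) -> list[str]:
        return [f.fibre_type for f in self.fibres]

    def validate(self, overlap_tol: float = 1e-6) -> None:
        """Check geometric invariants; raise SectionGeometryError on failure."""
        if not self.roi.is_valid or self.roi.is_empty:
            raise SectionGeometryError("ROI polygon is invalid or empty")
        for i, f in enumerate(self.fibres):
            if not f.polygon.is_valid:
                raise SectionGeometryError(f"fibre {i} polygon is not simple/valid")
        if self.fibres:
            min_area = min(f.area for f in self.fibres)
            # pairwise interior overlap bounded relative to the smallest fibre
            from shapely.strtree import STRtree

            polys = [f.polygon for f in self.fibres]
            tree = STRtree(polys)
            for i, p in enumerate(polys):
                for j in tree.query(p):
                    if j <= i:
                        continue
                    inter = p.intersection(polys[j]).area
                    if inter > overlap_tol * min_area:
                        raise SectionGeometryError(
                            f"fibres {i} and {j} overlap by {inter:.3g} µm²"
                        )
        roi_buf = self.roi.buffer(1e-6)
        for x, y in self.capillaries:
            if not roi_buf.covers(Point(x, y)):
                raise SectionGeometryError(f"capillary ({x:.3f}, {y:.3f}) outside ROI")
        for i, f in enumerate(self.fibres):
            if not roi_buf.covers(f.polygon):
                raise SectionGeometryError(f"fibre {i} extends outside ROI")

    # ------------------------------------------------------------------
    # GeoJSON round trip
    # ------------------------------------------------------------------
    def to_geojson(self) -> dict:
        """FeatureCollection: ROI (role=roi), fibres (fibre_type), capillary Points."""
        features: list[dict] = [
            {
                "type": "Feature",
                "geometry": mapping(self.roi),
                "properties": {"role": "roi"},
            }
        ]
        for i, f in enumerate(self.fibres):
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(f.polygon),
                    "properties": {"role": "fibre", "fibre_id": i, "fibre_type": f.fibre_type},
                }
            )
        for i, (x, y) in enumerate(self.capillaries):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                    "properties": {"role": "capillary", "capillary_id": i},
                }
            )
        return {
            "type": "FeatureCollection",
            "features": features,
            "properties": dict(self.meta),
        }

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, sort_keys=True, separators=(",", ":"))
            fh.write("\n")

    @classmethod
    def from_geojson(cls, obj: dict) -> "MuscleSection":
        roi = None
        fibres: list[tuple[int, Fibre]] = []
        caps: list[tuple[int, Sequence[float]]] = []
        for feat in obj["features"]:
            props = feat.get("properties") or {}
            role = props.get("role")
            geom = shape(feat["geometry"])
            if role == "roi":
                roi = geom
            elif role == "fibre":
                fibres.append((props.get("fibre_id", len(fibres)), Fibre(geom, props["fibre_type"])))
            elif role == "capillary":
                caps.append((props.get("capillary_id", len(caps)), feat["geometry"]["coordinates"]))
        if roi is None:
            raise SectionGeometryError("GeoJSON has no feature with role=roi")
        fibres.sort(key=lambda t: t[0])
        caps.sort(key=lambda t: t[0])
        cap_arr = np.array([c for _, c in caps], dtype=float).reshape(-1, 2)
        return cls(roi=roi, fibres=[f for _, f in fibres], capillaries=cap_arr,
                   meta=dict(obj.get("properties") or {}))

    @classmethod
    def read_geojson(cls, path) -> "MuscleSection":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))
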