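"""Point-in-region tests for geography-scoped statements and taxa.

Regions embed raw GeoJSON MultiPolygon coordinates (lon/lat order).  Rings
are treated as planar polygons — no geodesic edges, no antimeridian
splitting — which is the plain GeoJSON reading and adequate for scoping an
identification key to a region.  Containment uses even–odd ray casting per
polygon (outer ring minus holes); a point exactly on a ring is counted as
inside, so the more specific, geography-scoped statement wins on the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .format import ClavisError, Region

__all__ = ["Location", "UnresolvableRegionError", "point_in_region", "point_in_ring"]


class UnresolvableRegionError(ClavisError):
    """The region has no polygon, so containment cannot be decided."""


@dataclass(frozen=True)
class Location:
    """A WGS84 position: lon ∈ [-180, 180], lat ∈ [-90, 90]."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat {self.lat} outside [-90, 90]")


def _on_segment(px: float, py: float, ax: float, ay: float, bx: float, by: float) -> bool:
    """True when point p lies on the closed segment a–b."""
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > 1e-12 * max(1.0, abs(bx - ax), abs(by - ay)):
        return False
    return min(ax, bx) - 1e-12 <= px <= max(ax, bx) + 1e-12 and (
        min(ay, by) - 1e-12 <= py <= max(ay, by) + 1e-12
    )


def point_in_ring(ring: list, lon: float, lat: float) -> str:
    """Classify a point against one linear ring.

    Returns ``"boundary"``, ``"inside"`` or ``"outside"`` (even–odd rule,
    horizontal ray towards +lon).
    """
    inside = False
    n = len(ring)
    for i in range(n - 1):
        ax, ay = ring[i][0], ring[i][1]
        bx, by = ring[i + 1][0], ring[i + 1][1]
        if _on_segment(lon, lat, ax, ay, bx, by):
            return "boundary"
        # standard even-odd crossing test, half-open in lat to avoid
        # double-counting vertices
        if (ay > lat) != (by > lat):
            x_cross = ax + (lat - ay) * (bx - ax) / (by - ay)
            if x_cross > lon:
                inside = not inside
    return "inside" if inside else "outside"


def _point_in_polygon(polygon: list, lon: float, lat: float) -> bool:
    """One GeoJSON polygon: outer ring inclusion minus holes (boundary ⊆ in)."""
    if not polygon:
        return False
    outer = point_in_ring(polygon[0], lon, lat)
    if outer == "outside":
        return False
    if outer == "boundary":
        return True
    for hole in polygon[1:]:
        c = point_in_ring(hole, lon, lat)
        if c == "inside":
            return False
        if c == "boundary":
            return True  # the hole's rim still belongs to the polygon
    return True


def point_in_region(region: Region, loc: Location) -> bool:
    """Whether a location falls inside a region's MultiPolygon.

    Name-only regions carry no geometry and raise
    :class:`UnresolvableRegionError`.
    """
    if region.polygon is None:
        raise UnresolvableRegionError(
            "region has only a name; containment cannot be evaluated"
        )
    return any(_point_in_polygon(poly, loc.lon, loc.lat) for poly in region.polygon)
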