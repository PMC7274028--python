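"""Geographic projection of one site's allele states.

Accessions with provenance coordinates are merged into circles by a greedy
radius rule: repeatedly seed at the unassigned point with the most
neighbours within the merge radius (ties by accession name) and absorb all
unassigned points within the radius of the seed.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import EmptySiteError, ParameterError
from .genotype import GenotypeMatrix
from .io import GTClass, SampleCatalog

EARTH_RADIUS_KM = 6371.0

_POS_RE = re.compile(r"^(.+):(\d+)$")


@dataclass(frozen=True)
class GeoPoint:
    accession_name: str
    latitude: float
    longitude: float
    allele_state: GTClass

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ParameterError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ParameterError(f"longitude out of range: {self.longitude}")


@dataclass
class GeoCircle:
    latitude: float
    longitude: float
    members: list[str]
    pie: dict[str, float]  # allele state -> fraction

    @property
    def size(self) -> int:
        return len(self.members)


def select_site(matrix: GenotypeMatrix, site_spec: str) -> int:
    """Index of the requested site: exact position for ``chr:pos``; else the
    lowest-position variant in the region."""
    from .query import parse_region_spec

    m = _POS_RE.match(site_spec.strip())
    if m and "-" not in m.group(2):
        chrom, pos = m.group(1), int(m.group(2))
        for i, site in enumerate(matrix.sites):
            if site.chrom == chrom and site.pos == pos:
                return i
        # fall through: treat as a 1-bp region, which will also fail below
    region = parse_region_spec(site_spec)
    for i, site in enumerate(matrix.sites):
        if site.chrom == region.chrom and region.start <= site.pos <= region.end:
            return i
    raise EmptySiteError(f"no variant site matches {site_spec!r}")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def points_for_site(
    matrix: GenotypeMatrix,
    site_index: int,
    catalog: SampleCatalog,
    lat_range: Optional[tuple[float, float]] = None,
    lon_range: Optional[tuple[float, float]] = None,
) -> tuple[list[GeoPoint], list[str]]:
    """Allele-state points for located samples; the second element lists
    samples dropped for missing coordinates or the bounding-box filter."""
    points: list[GeoPoint] = []
    dropped: list[str] = []
    row = matrix.cells[site_index]
    for j, acc in enumerate(matrix.samples):
        entry = catalog.entry(acc)
        lat, lon = entry.latitude, entry.longitude
        if lat is None or lon is None:
            dropped.append(acc)
            continue
        if lat_range and not (lat_range[0] <= lat <= lat_range[1]):
            dropped.append(acc)
            continue
        if lon_range and not (lon_range[0] <= lon <= lon_range[1]):
            dropped.append(acc)
            continue
        points.append(GeoPoint(acc, lat, lon, row[j].klass))
    return points, dropped


def merge_points(points: Sequence[GeoPoint], radius_km: float) -> list[GeoCircle]:
    """Greedy radius merge; deterministic given the tie rules.

    Seed choice: the unassigned point with the most unassigned points within
    the radius (itself included), ties broken by lexicographic accession
    name. The circle center is the seed's coordinates.
    """
    if radius_km < 0:
        raise ParameterError("radius_km must be >= 0")
    unassigned = sorted(points, key=lambda p: p.accession_name)
    circles: list[GeoCircle] = []
    while unassigned:
        best_seed = None
        best_count = -1
        for p in unassigned:
            count = sum(
                1
                for q in unassigned
                if haversine_km(p.latitude, p.longitude, q.latitude, q.longitude)
                <= radius_km
            )
            if count > best_count:
                best_seed, best_count = p, count
        members = [
            q
            for q in unassigned
            if haversine_km(
                best_seed.latitude, best_seed.longitude, q.latitude, q.longitude
            )
            <= radius_km
        ]
        member_names = {m.accession_name for m in members}
        unassigned = [q for q in unassigned if q.accession_name not in member_names]
        state_counts: dict[str, int] = {}
        for m in members:
            state_counts[m.allele_state.value] = (
                state_counts.get(m.allele_state.value, 0) + 1
            )
        circles.append(
            GeoCircle(
                latitude=best_seed.latitude,
                longitude=best_seed.longitude,
                members=sorted(member_names),
                pie={k: v / len(members) for k, v in sorted(state_counts.items())},
            )
        )
    return circles


def geo_map_json(matrix: GenotypeMatrix, site_index: int, circles: list[GeoCircle]) -> str:
    site = matrix.sites[site_index]
    payload = {
        "site": {
            "chrom": site.chrom,
            "pos": site.pos,
            "ref": site.ref,
            "alt": list(site.alts),
        },
        "circles": [
            {
                "lat": c.latitude,
                "lon": c.longitude,
                "size": c.size,
                "members": c.members,
                "pie": c.pie,
            }
            for c in circles
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
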