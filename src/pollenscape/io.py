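"""File formats: GeoTIFF landcover, GeoJSON/CSV sites, CSV tables.

Landcover grids travel as single-band integer GeoTIFFs with the
ModelPixelScale / ModelTiepoint geo tags plus a JSON sidecar in the
image description carrying the CRS identifier.  All tabular data is
headered UTF-8 CSV; missing values are empty fields; floats are written
at 6 significant digits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .genetics import MultilocusGenotype
from .raster import InvalidInputError, LandcoverRaster, SamplingSite

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


class SchemaError(ValueError):
    """A table is missing a mandatory column or violates a pairing rule."""


class UnsupportedFormatError(ValueError):
    """A raster file outside the supported GeoTIFF contract."""


# ---------------------------------------------------------------------------
# landcover rasters


def write_landcover(raster: LandcoverRaster, path: str | Path) -> None:
    """Write a landcover raster as a single-band uint8 GeoTIFF.

    The tiepoint maps pixel (0, 0) to the map coordinate of its centre
    (the package's internal convention, recorded in the description).
    """
    desc = json.dumps(
        {"crs_id": raster.crs_id, "convention": "pixel-center", "nodata": 0}
    )
    tifffile.imwrite(
        str(path),
        raster.grid.astype(np.uint8),
        description=desc,
        extratags=[
            (_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
            (
                _MODEL_TIEPOINT,
                "d",
                6,
                (0.0, 0.0, 0.0, raster.origin[0], raster.origin[1], 0.0),
            ),
        ],
    )


def read_landcover(path: str | Path) -> LandcoverRaster:
    """Read a single-band integer GeoTIFF into a LandcoverRaster.

    Float-typed rasters and non-square cells are rejected; cells tagged
    with the nodata value map to the NODATA landcover code.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        if not np.issubdtype(arr.dtype, np.integer):
            raise UnsupportedFormatError(f"{path}: expected integer raster, got {arr.dtype}")
        if arr.ndim != 2:
            raise UnsupportedFormatError(f"{path}: expected a single band")
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise UnsupportedFormatError(f"{path}: missing GeoTIFF geo tags")
        sx, sy = tags[_MODEL_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy):
            raise UnsupportedFormatError(f"{path}: non-square cells ({sx} x {sy})")
        tie = tags[_MODEL_TIEPOINT].value
        origin = (float(tie[3]), float(tie[4]))
        crs_id = "local-metric"
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                crs_id = json.loads(desc.value).get("crs_id", crs_id)
            except (json.JSONDecodeError, AttributeError):
                pass
    return LandcoverRaster(grid=arr, cell_size=float(sx), origin=origin, crs_id=crs_id)


# ---------------------------------------------------------------------------
# sites and plants


def write_sites_geojson(
    sites: list[SamplingSite], path: str | Path, crs_id: str = "local-metric"
) -> None:
    fc = {
        "type": "FeatureCollection",
        "crs_id": crs_id,
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [s.x, s.y]},
                "properties": {"site_id": s.site_id},
            }
            for s in sites
        ],
    }
    Path(path).write_text(json.dumps(fc, indent=1))


def read_sites(path: str | Path) -> list[SamplingSite]:
    """Read sites from GeoJSON points or a CSV with site_id, x, y."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        fc = json.loads(path.read_text())
        sites = []
        for feat in fc.get("features", []):
            props = feat.get("properties", {})
            if "site_id" not in props:
                raise SchemaError(f"{path}: feature missing 'site_id' property")
            x, y = feat["geometry"]["coordinates"][:2]
            sites.append(SamplingSite(site_id=str(props["site_id"]), x=float(x), y=float(y)))
        return sites
    df = pd.read_csv(path)
    _require(df, ["site_id", "x", "y"], path)
    return [
        SamplingSite(site_id=str(r.site_id), x=float(r.x), y=float(r.y))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# tables


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _locus_names(columns) -> list[str]:
    loci = sorted({c[:-2] for c in columns if c.endswith("_1")})
    for locus in loci:
        if f"{locus}_2" not in columns:
            raise SchemaError(f"locus {locus!r} has column {locus}_1 but no {locus}_2")
    return loci


@dataclass
class GenotypeRecord:
    """One genotyped individual with its sampling metadata."""

    genotype: MultilocusGenotype
    mother_id: str | None  # None for maternal plants themselves
    site_id: str
    year: int


def read_genotypes(path: str | Path) -> list[GenotypeRecord]:
    """Genotype CSV: individual_id, mother_id, site_id, year, then two
    columns per locus (`<locus>_1`, `<locus>_2`); blank = missing.

    A locus with exactly one of its two alleles present is a schema
    violation (half-missing genotypes are not representable).
    """
    df = pd.read_csv(path, dtype=str)
    _require(df, ["individual_id", "mother_id", "site_id", "year"], path)
    loci = _locus_names(df.columns)
    if not loci:
        raise SchemaError(f"{path}: no locus columns found")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        geno: dict[str, tuple[str, str] | None] = {}
        for locus in loci:
            a1, a2 = d[f"{locus}_1"], d[f"{locus}_2"]
            a1 = None if (a1 is None or (isinstance(a1, float) and np.isnan(a1)) or a1 == "") else a1
            a2 = None if (a2 is None or (isinstance(a2, float) and np.isnan(a2)) or a2 == "") else a2
            if (a1 is None) != (a2 is None):
                raise SchemaError(
                    f"{path}: individual {d['individual_id']} locus {locus}: "
                    "one allele present, one missing"
                )
            geno[locus] = None if a1 is None else (a1, a2)
        mother = d["mother_id"]
        if mother is None or (isinstance(mother, float) and np.isnan(mother)) or mother == "":
            mother = None
        records.append(
            GenotypeRecord(
                genotype=MultilocusGenotype(individual_id=d["individual_id"], loci=geno),
                mother_id=mother,
                site_id=d["site_id"],
                year=int(d["year"]),
            )
        )
    return records


def write_genotypes(records: list[GenotypeRecord], path: str | Path) -> None:
    loci = sorted({l for r in records for l in r.genotype.loci})
    rows = []
    for r in records:
        row = {
            "individual_id": r.genotype.individual_id,
            "mother_id": r.mother_id or "",
            "site_id": r.site_id,
            "year": r.year,
        }
        for locus in loci:
            g = r.genotype.loci.get(locus)
            row[f"{locus}_1"] = g[0] if g else ""
            row[f"{locus}_2"] = g[1] if g else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_captures(path: str | Path) -> dict[str, dict[str, float]]:
    """Captures CSV (site_id, species, mobility, count) -> per-site
    class totals {'high': n, 'low': n}."""
    df = pd.read_csv(path)
    _require(df, ["site_id", "mobility", "count"], path)
    bad = set(df["mobility"]) - {"high", "low"}
    if bad:
        raise SchemaError(f"{path}: unknown mobility class(es) {sorted(bad)}")
    out: dict[str, dict[str, float]] = {}
    for (site, mobility), grp in df.groupby(["site_id", "mobility"]):
        out.setdefault(str(site), {"high": 0.0, "low": 0.0})[mobility] = float(
            grp["count"].sum()
        )
    return out


def read_responses(path: str | Path) -> dict[str, float]:
    """Responses CSV (site_id, tm_minus_ts) -> per-site values."""
    df = pd.read_csv(path)
    _require(df, ["site_id", "tm_minus_ts"], path)
    return {str(r.site_id): float(r.tm_minus_ts) for r in df.itertuples()}


_METRIC_COLUMNS = [
    "site_id",
    "scale",
    "variant",
    "habitat_def",
    "weighting",
    "gap_mode",
    "value_ha",
    "transformed",
]


def metrics_to_frame(values) -> pd.DataFrame:
    """Flatten MetricValue objects into the long metrics table."""
    rows = []
    for mv in values:
        s = mv.spec
        rows.append(
            {
                "site_id": mv.site_id,
                "scale": s.scale,
                "variant": s.variant or "",
                "habitat_def": s.habitat_def,
                "weighting": s.weighting,
                "gap_mode": s.gap_mode,
                "value_ha": mv.value_ha,
                "transformed": mv.transformed,
            }
        )
    return pd.DataFrame(rows, columns=_METRIC_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Stable column order, 6 significant digits, empty field = missing."""
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    _require(df, _METRIC_COLUMNS, path)
    df["variant"] = df["variant"].fillna("")
    return df
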