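"""Raster I/O (GeoTIFF and NetCDF) and grid alignment.

GeoTIFF files are written and read through ``tifffile`` carrying the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, a minimal
WGS84 GeoKeyDirectory and GDAL_NODATA), one page per band, north-up,
cell-center registered. NetCDF (classic format, scipy backend through
``xarray``) stores monthly cubes with a ``month`` dimension and lat/lon
coordinate vectors. Nodata travels as a sentinel on disk and as NaN in
memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

from .climate import ClimateCube
from .grids import GridSpec, cell_areas

NODATA_SENTINEL = -9999.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GTModelTypeGeoKey = 2 (geographic), GeographicTypeGeoKey = 4326 (WGS84)
_WGS84_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 2, 2048, 0, 1, 4326)


def write_geotiff(
    path: str | Path,
    data: np.ndarray,
    spec: GridSpec,
    nodata: float = NODATA_SENTINEL,
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) array as GeoTIFF.

    NaN cells are replaced by the nodata sentinel, which is declared in
    the GDAL_NODATA tag.
    """
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.shape[1:] != spec.shape:
        raise ValueError("data shape does not match the GridSpec")
    out = np.where(np.isfinite(arr), arr, nodata)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.dlon, spec.dlat, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.lon_min, spec.lat_max, 0.0), True),
        (_TAG_GEO_KEYS, "H", len(_WGS84_GEO_KEYS), _WGS84_GEO_KEYS, True),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata)), True),
    ]
    tifffile.imwrite(
        str(path), out, photometric="minisblack", extratags=extratags
    )


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GridSpec, float | None]:
    """Read a GeoTIFF into (bands, rows, cols) values (NaN = nodata).

    Fails loudly when the georeferencing tags are missing.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        lon_min = float(tie[3] - tie[0] * sx)
        lat_max = float(tie[4] + tie[1] * sy)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None, :, :]
    n_bands, n_rows, n_cols = arr.shape
    spec = GridSpec(
        n_rows=n_rows, n_cols=n_cols,
        lat_min=lat_max - n_rows * float(sy), lat_max=lat_max,
        lon_min=lon_min, lon_max=lon_min + n_cols * float(sx),
    )
    values = np.asarray(arr, dtype=np.float64)
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, spec, nodata


def _spec_coords(spec: GridSpec) -> dict[str, np.ndarray]:
    return {"lat": spec.lat_centers, "lon": spec.lon_centers}


def write_cube_netcdf(path: str | Path, cube: ClimateCube) -> None:
    """Write a monthly climate cube to NetCDF (month, lat, lon)."""
    ds = xr.Dataset(
        {
            "tavg": (("month", "lat", "lon"), cube.tavg),
            "prec": (("month", "lat", "lon"), cube.prec),
        },
        coords={"month": np.arange(1, 13), **_spec_coords(cube.spec)},
        attrs={
            "source": cube.source,
            "lat_min": cube.spec.lat_min, "lat_max": cube.spec.lat_max,
            "lon_min": cube.spec.lon_min, "lon_max": cube.spec.lon_max,
        },
    )
    ds.to_netcdf(str(path), engine="scipy")


def read_cube_netcdf(path: str | Path) -> ClimateCube:
    """Read a monthly cube; months are recovered in order 1..12.

    Cubes carrying only monthly extremes (``tmax``/``tmin``, the form
    projection sources publish) get their mean temperature derived as
    the extreme midpoint.
    """
    with xr.open_dataset(str(path), engine="scipy") as ds:
        ds = ds.sortby("month").load()
        n_rows = ds.sizes["lat"]
        n_cols = ds.sizes["lon"]
        spec = GridSpec(
            n_rows=n_rows, n_cols=n_cols,
            lat_min=float(ds.attrs["lat_min"]), lat_max=float(ds.attrs["lat_max"]),
            lon_min=float(ds.attrs["lon_min"]), lon_max=float(ds.attrs["lon_max"]),
        )
        if "tavg" in ds:
            tavg = ds["tavg"].values
        elif "tmax" in ds and "tmin" in ds:
            from .climate import mean_temperature_from_extremes

            tavg = mean_temperature_from_extremes(ds["tmax"].values, ds["tmin"].values)
        else:
            raise ValueError(f"{path}: no tavg (or tmax/tmin) variable")
        return ClimateCube(
            spec=spec,
            tavg=tavg,
            prec=ds["prec"].values,
            source=str(ds.attrs.get("source", "baseline")),
        )


def align_to(
    spec: GridSpec,
    values: np.ndarray,
    src_spec: GridSpec,
    method: str = "mean",
) -> np.ndarray:
    """Regrid a raster onto a target GridSpec.

    Methods: ``nearest`` (class/mask rasters), ``mean`` (area-weighted
    mean of contributing source cells — continuous stocks), ``sum``
    (mass-conserving total of contributing source cells — production).
    Source cells are assigned to the target cell containing their center;
    extents must overlap.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != src_spec.shape:
        raise ValueError("values shape does not match the source GridSpec")
    if spec == src_spec:
        return values.copy()
    if (src_spec.lat_min >= spec.lat_max or src_spec.lat_max <= spec.lat_min
            or src_spec.lon_min >= spec.lon_max or src_spec.lon_max <= spec.lon_min):
        raise ValueError("source and target extents are disjoint")

    if method == "nearest":
        # sample the source at each target cell center
        rows = np.floor((spec.lat_centers[:, None] - src_spec.lat_max) / -src_spec.dlat).astype(int)
        cols = np.floor((spec.lon_centers[None, :] - src_spec.lon_min) / src_spec.dlon).astype(int)
        rows = np.clip(rows, 0, src_spec.n_rows - 1)
        cols = np.clip(cols, 0, src_spec.n_cols - 1)
        return values[np.broadcast_to(rows, spec.shape), np.broadcast_to(cols, spec.shape)]

    if method not in ("mean", "sum"):
        raise ValueError(f"unknown alignment method '{method}'")

    # bin source cell centers into target cells
    src_lat = src_spec.lat_centers
    src_lon = src_spec.lon_centers
    ti = np.floor((src_lat - spec.lat_max) / -spec.dlat).astype(int)
    tj = np.floor((src_lon - spec.lon_min) / spec.dlon).astype(int)
    ok_i = (ti >= 0) & (ti < spec.n_rows)
    ok_j = (tj >= 0) & (tj < spec.n_cols)
    flat_target = np.where(
        ok_i[:, None] & ok_j[None, :],
        np.clip(ti, 0, spec.n_rows - 1)[:, None] * spec.n_cols
        + np.clip(tj, 0, spec.n_cols - 1)[None, :],
        -1,
    ).ravel()
    v = values.ravel()
    w = cell_areas(src_spec).ravel() if method == "mean" else np.ones(v.size)
    keep = (flat_target >= 0) & np.isfinite(v)
    n = spec.n_rows * spec.n_cols
    sums = np.bincount(flat_target[keep], weights=(v * w)[keep], minlength=n)
    wsum = np.bincount(flat_target[keep], weights=w[keep], minlength=n)
    if method == "sum":
        out = np.where(wsum > 0, sums, np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(wsum > 0, sums / np.maximum(wsum, 1e-300), np.nan)
    return out.reshape(spec.shape)
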