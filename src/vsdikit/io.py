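"""File formats.

* Geometry: one JSON file per slice (geometry is drawn once per slice and
  re-used for every recording of that slice), with 2-column point lists in mm
  and a versioned ``format`` key.
* Movies: multi-page TIFF stacks with a JSON sidecar holding frame rate,
  pixel pitch, and the stimulus frame index.
* Rasters: a CSV value matrix (rows x frames) plus a JSON sidecar with region
  row spans and the time axis.
* Site maps and calibration results: CSV matrices / tables plus JSON metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidParameterError
from .geometry import AnatomyOutline, SegmentedGeometry
from .stats import NullCalibration, SiteMap
from .transform import Movie, Raster

GEOMETRY_FORMAT = "vsdikit-geometry-1"


def save_geometry(outline: AnatomyOutline, path) -> None:
    doc = {
        "format": GEOMETRY_FORMAT,
        "midline": outline.midline.tolist(),
        "boundary_a": outline.boundary_a.tolist(),
        "boundary_b": outline.boundary_b.tolist(),
        "transitions_mm": list(outline.transitions_mm),
        "pixel_pitch_mm": outline.pixel_pitch_mm,
    }
    Path(path).write_text(json.dumps(doc))


def load_geometry(path) -> AnatomyOutline:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != GEOMETRY_FORMAT:
        raise InvalidParameterError(f"unrecognized geometry format in {path}")
    return AnatomyOutline(
        midline=np.asarray(doc["midline"]),
        boundary_a=np.asarray(doc["boundary_a"]),
        boundary_b=np.asarray(doc["boundary_b"]),
        transitions_mm=tuple(doc["transitions_mm"]),
        pixel_pitch_mm=float(doc["pixel_pitch_mm"]),
    )


def export_polygons(geometry: SegmentedGeometry, path) -> None:
    """Plain-text polygon list for plotting/debugging."""
    doc = {
        "segment_width_mm": geometry.segment_width_mm,
        "polygons": [
            {"label": label, "vertices": np.asarray(poly.exterior.coords).tolist()}
            for poly, label in zip(geometry.polygons, geometry.region_labels)
        ],
    }
    Path(path).write_text(json.dumps(doc))


def save_movie(movie: Movie, tiff_path, sidecar_path=None) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, movie.frames.astype(np.float32))
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "frame_rate_hz": movie.frame_rate_hz,
        "stimulus_frame": movie.stimulus_frame,
        "pixel_pitch_mm": movie.pixel_pitch_mm,
    }))


def load_movie(tiff_path, sidecar_path=None) -> Movie:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return Movie(frames=np.asarray(frames, dtype=float),
                 frame_rate_hz=float(meta["frame_rate_hz"]),
                 stimulus_frame=int(meta["stimulus_frame"]),
                 pixel_pitch_mm=float(meta["pixel_pitch_mm"]))


def save_raster(raster: Raster, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    np.savetxt(csv_path, raster.values, delimiter=",")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "region_spans": {k: list(v) for k, v in raster.region_spans.items()},
        "time_ms": raster.time_ms.tolist(),
        "standardized": raster.standardized,
    }))


def load_raster(csv_path, sidecar_path=None) -> Raster:
    csv_path = Path(csv_path)
    values = np.atleast_2d(np.loadtxt(csv_path, delimiter=","))
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return Raster(values=values,
                  region_spans={k: tuple(v) for k, v in meta["region_spans"].items()},
                  time_ms=np.asarray(meta["time_ms"]),
                  standardized=bool(meta.get("standardized", False)))


def save_sitemap(sitemap: SiteMap, prefix) -> None:
    prefix = str(prefix)
    np.savetxt(prefix + ".pvalues.csv", sitemap.p_values, delimiter=",")
    np.savetxt(prefix + ".diff.csv", sitemap.diff, delimiter=",")
    n_sig = int(sitemap.significant_mask.sum())
    Path(prefix + ".json").write_text(json.dumps({
        "alpha": sitemap.alpha,
        "n_perms_used": sitemap.n_perms_used,
        "exact": sitemap.exact,
        "n_significant": n_sig,
        "n_sites": sitemap.n_sites,
        "significant_fraction": sitemap.significant_fraction,
    }))


def save_calibration(calibration: NullCalibration, path) -> None:
    path = Path(path)
    np.savetxt(path, calibration.fractions, delimiter=",",
               header="positive_site_fraction", comments="")
    Path(str(path) + ".json").write_text(json.dumps({
        "alpha": calibration.alpha,
        "exhaustive": calibration.exhaustive,
        "n_splits": int(len(calibration.fractions)),
        "mean_fraction": calibration.mean_fraction,
    }))
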