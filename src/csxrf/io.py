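"""HDF5 persistence and map export.

Scan logs are inherently sparse point lists, so the scan layout stores
parallel per-point datasets rather than a dense image:

    /scan/positions      (N, 2) int32   grid (row, col) indices
    /scan/dwell          (N,)   float64 seconds
    /scan/spectra        (N, channels)  uint32 counts (float64 in expected mode)
    /scan/transmission   (N,)   float64 optional; NaN where not read
    /meta                attrs: schema_version, rows, cols, overhead, seed,
                         stxm_total, expected_mode, strategy, params (JSON)

Dense cubes use:

    /cube/counts   (rows, cols, channels)
    /cube/dwell    (rows, cols) float64
    /cube/missing  (rows, cols) bool
    /cube  attrs: units in {counts, counts_per_second}
    /meta  attrs: schema_version

Phantoms (for the CLI round trip) use /phantom/transmission,
/phantom/concentration/<element>, per-element attribute groups and detector
attrs.  The metadata embedded in a scan file (strategy, parameters, seed)
suffices to regenerate the log from scratch for the parameter-only
strategies (full, conditional, dynamic, priority); see
:func:`regenerate_log`.  Physical step size, if any, is metadata only.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .errors import IntegrityError, SchemaVersionError
from .instrument import AcquiredPoint, AcquisitionLog, ROIWindow
from .phantom import DetectorModel, ElementSpec, Phantom
from .reconstruction import UNITS_COUNTS, UNITS_CPS, ElementMap, SpectrumCube

__all__ = [
    "SCHEMA_VERSION",
    "write_scan",
    "read_scan",
    "write_cube",
    "read_cube",
    "write_phantom",
    "read_phantom",
    "export_map_tiff",
    "export_map_csv",
    "regenerate_log",
]

SCHEMA_VERSION = 1


def _check_version(f: h5py.File, path: str) -> None:
    if "meta" not in f:
        raise IntegrityError(f"{path}: missing /meta group")
    version = f["meta"].attrs.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: schema version {version!r} unsupported (expected {SCHEMA_VERSION})"
        )


def write_scan(log: AcquisitionLog, path) -> None:
    """Persist a scan log; ``read_scan(write_scan(log))`` is the identity."""
    if log.n_points == 0:
        raise IntegrityError("refusing to write an empty scan (no acquired points)")
    log.validate()
    positions = np.array([(p.row, p.col) for p in log.points], dtype=np.int32)
    dwell = np.array([p.dwell for p in log.points])
    spectra = np.stack([np.asarray(p.spectrum) for p in log.points])
    spectra = spectra.astype(np.float64 if log.expected_mode else np.uint32)
    transmission = np.array(
        [np.nan if p.transmission is None else p.transmission for p in log.points]
    )
    with h5py.File(path, "w") as f:
        scan = f.create_group("scan")
        scan.create_dataset("positions", data=positions)
        scan.create_dataset("dwell", data=dwell)
        scan.create_dataset("spectra", data=spectra)
        if not np.all(np.isnan(transmission)):
            scan.create_dataset("transmission", data=transmission)
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["rows"], meta.attrs["cols"] = log.shape
        meta.attrs["overhead"] = log.overhead
        meta.attrs["stxm_total"] = log.stxm_total
        meta.attrs["expected_mode"] = log.expected_mode
        meta.attrs["seed"] = -1 if log.seed is None else int(log.seed)
        meta.attrs["strategy"] = log.strategy or ""
        meta.attrs["params"] = json.dumps(log.params or {})


def read_scan(path) -> AcquisitionLog:
    """Load a scan log, validating schema version and dataset consistency."""
    with h5py.File(path, "r") as f:
        _check_version(f, str(path))
        if "scan" not in f:
            raise IntegrityError(f"{path}: missing /scan group")
        scan = f["scan"]
        for name in ("positions", "dwell", "spectra"):
            if name not in scan:
                raise IntegrityError(f"{path}: missing dataset /scan/{name}")
        positions = scan["positions"][()]
        dwell = scan["dwell"][()]
        spectra = scan["spectra"][()]
        n = len(positions)
        if n == 0:
            raise IntegrityError(f"{path}: empty scan (N=0)")
        if len(dwell) != n or len(spectra) != n:
            raise IntegrityError(f"{path}: /scan datasets disagree on point count")
        transmission = scan["transmission"][()] if "transmission" in scan else np.full(n, np.nan)
        if len(transmission) != n:
            raise IntegrityError(f"{path}: /scan/transmission length mismatch")
        meta = f["meta"].attrs
        seed = int(meta["seed"])
        log = AcquisitionLog(
            shape=(int(meta["rows"]), int(meta["cols"])),
            overhead=float(meta["overhead"]),
            seed=None if seed == -1 else seed,
            stxm_total=float(meta["stxm_total"]),
            expected_mode=bool(meta["expected_mode"]),
            strategy=str(meta["strategy"]) or None,
            params=json.loads(meta["params"]),
        )
        for i in range(n):
            t = float(transmission[i])
            log.points.append(
                AcquiredPoint(
                    row=int(positions[i, 0]), col=int(positions[i, 1]),
                    dwell=float(dwell[i]), spectrum=spectra[i],
                    transmission=None if np.isnan(t) else t, order_index=i,
                )
            )
    log.validate()
    return log


def write_cube(cube: SpectrumCube, path) -> None:
    if cube.units == UNITS_COUNTS:
        cube.validate()
    with h5py.File(path, "w") as f:
        g = f.create_group("cube")
        g.create_dataset("counts", data=cube.counts)
        g.create_dataset("dwell", data=cube.dwell.astype(np.float64))
        g.create_dataset("missing", data=cube.missing)
        g.attrs["units"] = cube.units
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION


def read_cube(path) -> SpectrumCube:
    with h5py.File(path, "r") as f:
        _check_version(f, str(path))
        if "cube" not in f:
            raise IntegrityError(f"{path}: missing /cube group")
        g = f["cube"]
        for name in ("counts", "dwell", "missing"):
            if name not in g:
                raise IntegrityError(f"{path}: missing dataset /cube/{name}")
        units = g.attrs.get("units")
        if units not in (UNITS_COUNTS, UNITS_CPS):
            raise IntegrityError(f"{path}: bad units flag {units!r}")
        cube = SpectrumCube(
            counts=g["counts"][()],
            dwell=g["dwell"][()],
            missing=g["missing"][()].astype(bool),
            units=str(units),
        )
    if cube.units == UNITS_COUNTS:
        cube.validate()  # dwell 0 <=> missing
    return cube


def write_phantom(phantom: Phantom, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("phantom")
        g.create_dataset("transmission", data=phantom.transmission)
        conc = g.create_group("concentration")
        elems = g.create_group("elements")
        for i, e in enumerate(phantom.elements):
            conc.create_dataset(e.name, data=phantom.concentration[e.name])
            eg = elems.create_group(f"{i:03d}_{e.name}")
            eg.attrs.update(
                name=e.name, line_energy=e.line_energy,
                peak_sigma=e.peak_sigma, yield_scale=e.yield_scale,
            )
        det = g.create_group("detector")
        det.attrs.update(
            n_channels=phantom.detector.n_channels, gain=phantom.detector.gain,
            offset=phantom.detector.offset, background_rate=phantom.detector.background_rate,
        )
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION


def read_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        _check_version(f, str(path))
        g = f["phantom"]
        elements = []
        for key in sorted(g["elements"]):
            a = g["elements"][key].attrs
            elements.append(
                ElementSpec(str(a["name"]), float(a["line_energy"]),
                            float(a["peak_sigma"]), float(a["yield_scale"]))
            )
        d = g["detector"].attrs
        detector = DetectorModel(
            n_channels=int(d["n_channels"]), gain=float(d["gain"]),
            offset=float(d["offset"]), background_rate=float(d["background_rate"]),
        )
        concentration = {e.name: g["concentration"][e.name][()] for e in elements}
        return Phantom(
            elements=elements, detector=detector,
            concentration=concentration, transmission=g["transmission"][()],
        )


def export_map_tiff(emap: ElementMap, path) -> None:
    """Write an element map as a float32 TIFF (missing pixels as NaN)."""
    import tifffile

    values = emap.values.astype(np.float32).copy()
    values[emap.missing] = np.nan
    tifffile.imwrite(path, values)


def export_map_csv(emap: ElementMap, path) -> None:
    """Write an element map as CSV (missing pixels as nan)."""
    values = emap.values.astype(float).copy()
    values[emap.missing] = np.nan
    np.savetxt(path, values, delimiter=",")


def export_phantom_tiff(phantom: Phantom, path) -> None:
    """Write the phantom's fields as a multi-page float32 TIFF.

    One page per concentration field (element order) plus a final
    transmission page, for quick inspection in any image viewer.
    """
    import tifffile

    pages = [phantom.concentration[e.name] for e in phantom.elements]
    pages.append(phantom.transmission)
    tifffile.imwrite(path, np.stack(pages).astype(np.float32), photometric="minisblack")


def export_phantom_csv(phantom: Phantom, directory) -> None:
    """Write one CSV per concentration field plus the transmission field."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for e in phantom.elements:
        np.savetxt(directory / f"{e.name}.csv", phantom.concentration[e.name], delimiter=",")
    np.savetxt(directory / "transmission.csv", phantom.transmission, delimiter=",")


def regenerate_log(phantom: Phantom, path) -> AcquisitionLog:
    """Re-run the strategy recorded in a scan file's metadata from scratch.

    Supported for strategies whose parameters are scalars (full,
    conditional, dynamic, priority).  Strategies that depend on an external
    mask or plan (sparse, combined, plan) cannot be rebuilt from scalar
    metadata alone and raise :class:`IntegrityError`.
    """
    from . import strategies as st

    with h5py.File(path, "r") as f:
        _check_version(f, str(path))
        meta = f["meta"].attrs
        strategy = str(meta["strategy"])
        params = json.loads(meta["params"])
        seed = int(meta["seed"])
    if seed == -1:
        raise IntegrityError("scan file records no seed; cannot regenerate")
    if strategy == "full":
        return st.run_full_raster(
            phantom, params["dwell"], seed,
            overhead=params["overhead"], expected_mode=params["expected_mode"])
    if strategy == "conditional":
        rule = st.DecisionRule("transmission", params["threshold"], params["side"])
        return st.run_conditional_scan(
            phantom, rule, params["stxm_dwell"], params["xrf_dwell"], seed,
            overhead=params["overhead"], stxm_noise_sigma=params["stxm_noise_sigma"],
            expected_mode=params["expected_mode"])
    if strategy == "dynamic":
        roi = ROIWindow(params["roi_lo"], params["roi_hi"])
        return st.run_dynamic_scan(
            phantom, roi, params["count_threshold"],
            params["fast_dwell"], params["slow_dwell"], seed,
            overhead=params["overhead"], expected_mode=params["expected_mode"])
    if strategy == "priority":
        rules = st.PriorityRule(
            tuple((ROIWindow(lo, hi), thr, dwell) for lo, hi, thr, dwell in params["rules"]),
            params["default_dwell"])
        return st.run_priority_scan(
            phantom, rules, params["probe_dwell"], seed,
            overhead=params["overhead"], expected_mode=params["expected_mode"])
    raise IntegrityError(f"strategy {strategy!r} cannot be regenerated from metadata alone")
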