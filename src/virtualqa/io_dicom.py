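"""Interoperability helpers: DICOM RT Dose export/import and mask archives.

Only the pieces other dosimetry tools need to ingest our results: a
minimal but standard-conformant RT Dose object (3D grid, mm frame, scaled
uint32 pixels) and a compact on-disk exchange format for ROI masks
(compressed boolean array + JSON sidecar with name and grid frame).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import RTDoseStorage, generate_uid

from .grid import DoseGrid, GridSpec
from .phantom import ROIMask

__all__ = ["export_rtdose", "import_rtdose", "save_mask", "load_mask"]


def export_rtdose(dose: DoseGrid, path: str | Path, description: str = "virtualqa dose") -> None:
    """Write a dose grid as a DICOM RT Dose file (GY units, uint32 pixels)."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTDoseStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTDoseStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesDescription = description
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"

    nx, ny, nz = dose.grid.shape
    sx, sy, sz = dose.grid.spacing
    ax, ay, az = dose.grid.axes()
    # DICOM stores frames as (z, rows=y, cols=x)
    vol_gy = dose.values.transpose(2, 1, 0) / 100.0
    scale = max(vol_gy.max(), 1e-12) / (2**31)
    pixels = np.round(vol_gy / scale).astype(np.uint32)

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    ds.PixelSpacing = [float(sy), float(sx)]
    ds.ImagePositionPatient = [float(ax[0]), float(ay[0]), float(az[0])]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(z - az[0]) for z in az]
    ds.DoseGridScaling = float(scale)
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def import_rtdose(path: str | Path) -> DoseGrid:
    """Read an RT Dose file written by :func:`export_rtdose` back to cGy."""
    ds = pydicom.dcmread(str(path))
    if ds.Modality != "RTDOSE":
        raise ValueError("not an RT Dose file")
    nz = int(ds.NumberOfFrames)
    ny, nx = int(ds.Rows), int(ds.Columns)
    vol = np.frombuffer(ds.PixelData, dtype=np.uint32).reshape(nz, ny, nx)
    values = vol.transpose(2, 1, 0).astype(float) * float(ds.DoseGridScaling) * 100.0
    sy, sx = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    sz = float(offsets[1] - offsets[0]) if nz > 1 else 1.0
    x0, y0, z0 = (float(v) for v in ds.ImagePositionPatient)
    grid = GridSpec(
        shape=(nx, ny, nz), spacing=(sx, sy, sz),
        origin=(x0 - sx / 2.0, y0 - sy / 2.0, z0 - sz / 2.0),
    )
    return DoseGrid(grid, values)


def save_mask(mask: ROIMask, path: str | Path) -> None:
    """Save a mask as <path>.npz (packed bits) + <path>.json (frame sidecar)."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"),
                        bits=np.packbits(mask.voxels.ravel()))
    sidecar = {
        "name": mask.name,
        "shape": list(mask.grid.shape),
        "spacing_mm": list(mask.grid.spacing),
        "origin_mm": list(mask.grid.origin),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_mask(path: str | Path) -> ROIMask:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    shape = tuple(sidecar["shape"])
    bits = np.load(path.with_suffix(".npz"))["bits"]
    voxels = np.unpackbits(bits)[: int(np.prod(shape))].astype(bool).reshape(shape)
    grid = GridSpec(shape=shape, spacing=tuple(sidecar["spacing_mm"]),
                    origin=tuple(sidecar["origin_mm"]))
    return ROIMask(name=sidecar["name"], grid=grid, voxels=voxels)
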