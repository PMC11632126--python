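"""Optional DICOM-RT adapter: RTDOSE grids and RTSTRUCT contour sets.

Maps the DICOM patient coordinate convention (x left, y posterior, z
superior; ``ImagePositionPatient`` at the first voxel center; 1-based
frames) onto the package's 0-based ``(z, y, x)`` grids. RTSTRUCT contours
are rasterized per axial slice with a polygon fill on voxel centers, so a
write -> read round trip reproduces masks only to rasterization tolerance.
The native NRRD bundle is the lossless, tested path; this adapter exists to
ingest TPS exports.
"""

from __future__ import annotations

import datetime

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import generate_uid
from skimage import measure
from skimage.draw import polygon as draw_polygon

from .dvh import DoseGrid, StructureMask
from .structures import StructureSet

RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"


def _file_meta(sop_class: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    return meta


def dose_to_rtdose(dose: DoseGrid) -> Dataset:
    """Build an in-memory RTDOSE dataset from a dose grid."""
    ds = Dataset()
    ds.file_meta = _file_meta(RTDOSE_SOP)
    ds.SOPClassUID = RTDOSE_SOP
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.ContentDate = datetime.date.today().strftime("%Y%m%d")
    nz, ny, nx = dose.shape
    sz, sy, sx = dose.spacing
    oz, oy, ox = dose.origin
    ds.Rows, ds.Columns, ds.NumberOfFrames = ny, nx, nz
    ds.PixelSpacing = [f"{sy:g}", f"{sx:g}"]
    ds.ImagePositionPatient = [f"{ox:g}", f"{oy:g}", f"{oz:g}"]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(i * sz) for i in range(nz)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    scaling = max(dose.values.max(), 1e-9) / (2**32 - 1)
    ds.DoseGridScaling = scaling
    pixels = np.round(dose.values / scaling).astype(np.uint32)
    ds.PixelData = pixels.tobytes()
    return ds


def read_rtdose(ds: Dataset) -> DoseGrid:
    """Dose grid from an RTDOSE dataset (uniform frame spacing required)."""
    nz = int(ds.NumberOfFrames)
    ny, nx = int(ds.Rows), int(ds.Columns)
    pixels = np.frombuffer(ds.PixelData, dtype=np.uint32).reshape(nz, ny, nx)
    values = pixels.astype(np.float64) * float(ds.DoseGridScaling)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(np.diff(offsets).mean()) if nz > 1 else 1.0
    sy, sx = (float(v) for v in ds.PixelSpacing)
    ox, oy, oz = (float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, (dz, sy, sx), (oz + offsets[0], oy, ox))


def structures_to_rtstruct(structures: StructureSet) -> Dataset:
    """Build an in-memory RTSTRUCT with axial contours traced from masks."""
    ds = Dataset()
    ds.file_meta = _file_meta(RTSTRUCT_SOP)
    ds.SOPClassUID = RTSTRUCT_SOP
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "dvhscore"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, name in enumerate(structures.names(), start=1):
        mask = structures[name]
        sz, sy, sx = mask.spacing
        oz, oy, ox = mask.origin
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        occ = mask.occupancy
        for k in range(occ.shape[0]):
            slc = occ[k]
            if not (slc >= 0.5).any():
                continue
            z_mm = oz + k * sz
            # pad so masks clipped by the grid edge still trace closed loops
            padded = np.pad(slc, 1)
            for contour in measure.find_contours(padded, 0.5):
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                pts = []
                for row, col in contour - 1.0:
                    pts += [f"{ox + col * sx:.4f}", f"{oy + row * sy:.4f}",
                            f"{z_mm:.4f}"]
                c.NumberOfContourPoints = len(contour)
                c.ContourData = pts
                rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    return ds


def read_rtstruct(ds: Dataset, grid: DoseGrid) -> StructureSet:
    """Rasterize RTSTRUCT contours onto ``grid`` (XOR for nested contours)."""
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    sz, sy, sx = grid.spacing
    oz, oy, ox = grid.origin
    out = StructureSet()
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        occ = np.zeros(grid.shape, dtype=bool)
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            k = int(round((data[0, 2] - oz) / sz))
            if not 0 <= k < grid.shape[0]:
                continue
            rows = (data[:, 1] - oy) / sy
            cols = (data[:, 0] - ox) / sx
            rr, cc = draw_polygon(rows, cols, shape=grid.shape[1:])
            filled = np.zeros(grid.shape[1:], dtype=bool)
            filled[rr, cc] = True
            occ[k] ^= filled  # XOR handles holes/nested contours
        out.add(StructureMask(name, occ.astype(np.float64),
                              grid.spacing, grid.origin))
    return out
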