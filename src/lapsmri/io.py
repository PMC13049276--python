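"""File formats: HDF5 slice containers, DICOM priors, model checkpoints.

Slice container layout (one file per slice, fastMRI-style naming):

    kspace        float32, shape (n_coils, N, M, 2)  — real/imag pairs
    mask          uint8, (N, M)
    smaps         float32, (n_coils, N, M, 2)        — optional
    reference     float32, (N, M, 2)                 — optional
    attrs: mask_kind, center, R_nominal, R_achieved, sigma, seed, provenance

Checkpoints are single-file ``.npz`` archives holding weights, schedule
parameters, and training config.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

from .codec import Codec, identity_codec
from .masks import SamplingMask
from .operators import MultiCoilKSpace
from .schedule import NoiseSchedule, ScoreModel
from ._nn import ConvNet, MLPNet

__all__ = [
    "SliceContainer", "write_slice", "read_slice",
    "read_prior_dicom", "write_prior_dicom",
    "save_codec", "load_codec", "save_score_model", "load_score_model",
]


@dataclass
class SliceContainer:
    kspace: MultiCoilKSpace
    smaps: Optional[np.ndarray] = None
    reference: Optional[np.ndarray] = None
    attrs: dict = field(default_factory=dict)


def _c2f(x):
    return np.stack([np.asarray(x).real, np.asarray(x).imag], axis=-1).astype(np.float32)


def _f2c(x):
    x = np.asarray(x, dtype=np.float64)
    return x[..., 0] + 1j * x[..., 1]


def write_slice(path, sc: SliceContainer) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=_c2f(sc.kspace.data))
        f.create_dataset("mask", data=sc.kspace.mask.mask.astype(np.uint8))
        if sc.smaps is not None:
            f.create_dataset("smaps", data=_c2f(sc.smaps))
        if sc.reference is not None:
            f.create_dataset("reference", data=_c2f(sc.reference))
        f.attrs["mask_kind"] = sc.kspace.mask.kind
        f.attrs["center"] = sc.kspace.mask.center
        f.attrs["R_nominal"] = sc.kspace.mask.R_nominal
        f.attrs["R_achieved"] = sc.kspace.mask.R_achieved
        f.attrs["sigma"] = sc.kspace.sigma
        for k, v in sc.attrs.items():
            f.attrs[f"x_{k}"] = v


def read_slice(path) -> SliceContainer:
    with h5py.File(path, "r") as f:
        for req in ("kspace", "mask"):
            if req not in f:
                raise KeyError(f"slice container missing required dataset {req!r}")
        mask = SamplingMask(np.asarray(f["mask"], dtype=bool),
                            str(f.attrs.get("mask_kind", "1d")),
                            int(f.attrs.get("center", 0)),
                            float(f.attrs.get("R_nominal", 1.0)))
        ks = MultiCoilKSpace(_f2c(f["kspace"][()]), mask,
                             float(f.attrs.get("sigma", 0.0)))
        smaps = _f2c(f["smaps"][()]) if "smaps" in f else None
        ref = _f2c(f["reference"][()]) if "reference" in f else None
        attrs = {k[2:]: (v.item() if hasattr(v, "item") else v)
                 for k, v in f.attrs.items() if k.startswith("x_")}
        return SliceContainer(ks, smaps, ref, attrs)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_prior_dicom(path):
    """Read a magnitude DICOM; returns (array, metadata dict).

    Rescale slope/intercept are applied (identity with a warning if the
    tags are absent); non-monochrome photometric interpretations are
    rejected.
    """
    import pydicom
    ds = pydicom.dcmread(path)
    photo = getattr(ds, "PhotometricInterpretation", "MONOCHROME2")
    if not str(photo).startswith("MONOCHROME"):
        raise ValueError(f"not a magnitude image: PhotometricInterpretation={photo}")
    arr = ds.pixel_array.astype(np.float64)
    if hasattr(ds, "RescaleSlope") or hasattr(ds, "RescaleIntercept"):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
    else:
        warnings.warn("DICOM has no rescale tags; assuming identity rescale")
        slope, inter = 1.0, 0.0
    arr = arr * slope + inter
    meta = {
        "pixel_spacing": [float(v) for v in getattr(ds, "PixelSpacing", [1.0, 1.0])],
        "orientation": [float(v) for v in
                        getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])],
    }
    return arr, meta


def write_prior_dicom(path, magnitude: np.ndarray, pixel_spacing=(1.0, 1.0)) -> None:
    """Write a minimal magnitude MR DICOM (fixture/export helper)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    mag = np.asarray(magnitude, dtype=np.float64)
    peak = mag.max() or 1.0
    slope = peak / 4095.0
    pix = np.clip(np.round(mag / slope), 0, 4095).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = pix.shape
    ds.SamplesPerPixel = 1
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = "0"
    ds.PixelSpacing = [f"{s:g}" for s in pixel_spacing]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.PixelData = pix.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_codec(path, codec: Codec) -> None:
    np.savez(path, kind="codec", K=codec.K, C=codec.C,
             components=codec.components, dec_W=codec.dec_W, mean=codec.mean,
             latent_scale=codec.latent_scale, identity=codec.identity,
             meta=json.dumps(codec.meta))


def load_codec(path) -> Codec:
    with np.load(path, allow_pickle=False) as f:
        if str(f["kind"]) != "codec":
            raise ValueError("not a codec checkpoint")
        if bool(f["identity"]):
            return identity_codec()
        return Codec(K=int(f["K"]), C=int(f["C"]),
                     components=f["components"], dec_W=f["dec_W"],
                     mean=f["mean"], latent_scale=float(f["latent_scale"]),
                     meta=json.loads(str(f["meta"])))


def save_score_model(path, model: ScoreModel, schedule: NoiseSchedule) -> None:
    if model.net is None:
        raise ValueError("only trained network models can be checkpointed")
    net = model.net
    arch = {
        "net": type(net).__name__,
        "width": net.width, "depth": net.depth, "temb_dim": net.temb_dim,
        "channels": getattr(net, "channels", None), "dim": getattr(net, "dim", None),
    }
    meta = {k: v for k, v in model.meta.items() if k != "loss_history"}
    meta["loss_history"] = model.meta.get("loss_history", {})
    np.savez(path, kind="score", theta=net.get_flat(),
             arch=json.dumps(arch), meta=json.dumps(meta),
             T=schedule.T, beta=schedule.beta)


def load_score_model(path):
    """Returns (ScoreModel, NoiseSchedule)."""
    from .schedule import make_schedule
    with np.load(path, allow_pickle=False) as f:
        if str(f["kind"]) != "score":
            raise ValueError("not a score-model checkpoint")
        arch = json.loads(str(f["arch"]))
        meta = json.loads(str(f["meta"]))
        beta = f["beta"]
        schedule = make_schedule(int(f["T"]), float(beta[0]), float(beta[-1]))
        if arch["net"] == "ConvNet":
            net = ConvNet(arch["channels"], width=arch["width"],
                          depth=arch["depth"], temb_dim=arch["temb_dim"])
        else:
            net = MLPNet(arch["dim"], width=arch["width"], depth=arch["depth"],
                         temb_dim=arch["temb_dim"])
        net.set_flat(f["theta"])

    def eps_fn(z, t):
        out, _ = net.forward(z[None], np.array([float(t)]))
        return out[0]

    def vjp_fn(z, t, u):
        _, caches = net.forward(z[None], np.array([float(t)]))
        dx, _ = net.backward(caches, u[None])
        return dx[0]

    return ScoreModel(eps_fn, vjp_fn, analytic=False, net=net, meta=meta), schedule
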