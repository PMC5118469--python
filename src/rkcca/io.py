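"""Model persistence (HDF5), dataset ingest and archive plumbing.

Archive layout (format version 1)::

    /meta                 attrs: format_version, reg, numCC, ktype,
                          gausigma, degree, cutoff
                          [best_reg, best_numCC when chosen by CV]
    /dataset<i>/weights   canonical weights  (n_features_i x numCC)
    /dataset<i>/comps     training components (n_samples x numCC)
    /dataset<i>/means     training column means
    /cancorrs             canonical correlations
    /validation/<i>/preds, /validation/<i>/corrs   (optional)
    /ev/<i>               (optional)
    /cv/score_grid, /cv/regs, /cv/numccs           (optional)
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Sequence

import h5py
import numpy as np

from ._block import DataBlock
from .exceptions import CorruptArchiveError, UnsupportedVersionError
from .kernels import KernelSpec
from .model_selection import CVResult, GridSearchCCA
from .prediction import EVResult, PredictionResult
from .solver import KernelCCA

__all__ = ["FORMAT_VERSION", "ModelArchive", "save_model", "load_model",
           "read_datasets"]

FORMAT_VERSION = 1


@dataclass
class ModelArchive:
    """Everything persisted for one analysis: the fitted model plus
    optional validation, explained-variance and cross-validation payloads."""

    reg: float
    n_components: int
    ktype: str
    gausigma: float
    degree: int
    cutoff: float
    weights: List[np.ndarray]
    comps: List[np.ndarray]
    means: List[np.ndarray]
    cancorrs: np.ndarray
    best_reg: Optional[float] = None
    best_numcc: Optional[int] = None
    score_grid: Optional[np.ndarray] = None
    cv_regs: Optional[np.ndarray] = None
    cv_numccs: Optional[np.ndarray] = None
    preds: Optional[List[np.ndarray]] = None
    corrs: Optional[List[np.ndarray]] = None
    ev: Optional[List[np.ndarray]] = None

    @classmethod
    def from_model(cls, model, prediction: Optional[PredictionResult] = None,
                   ev: Optional[EVResult] = None,
                   cv: Optional[CVResult] = None) -> "ModelArchive":
        """Wrap a fitted KernelCCA or GridSearchCCA (plus optional results)."""
        if isinstance(model, GridSearchCCA):
            if cv is None:
                cv = model.cv_result_
            base = model.best_model_
        else:
            base = model
        if not hasattr(base, "weights_"):
            raise ValueError("model must be fitted before saving")
        kern = base.kernel
        if isinstance(kern, KernelSpec):
            ktype, gausigma, degree = kern.ktype, kern.gausigma, kern.degree
        else:
            ktype = "none" if kern in (None, "none") else str(kern)
            gausigma, degree = base.gausigma, base.degree
        archive = cls(
            reg=float(base.reg), n_components=int(base.n_components),
            ktype=ktype, gausigma=float(gausigma), degree=int(degree),
            cutoff=float(base.cutoff),
            weights=list(base.weights_), comps=list(base.components_),
            means=list(base.means_), cancorrs=np.asarray(base.cancorrs_))
        if cv is not None:
            archive.best_reg = float(cv.best_reg)
            archive.best_numcc = int(cv.best_numcc)
            archive.score_grid = np.asarray(cv.score_grid)
            archive.cv_regs = np.asarray(cv.regs, dtype=np.float64)
            archive.cv_numccs = np.asarray(cv.numccs, dtype=np.int64)
        if prediction is not None:
            archive.preds = list(prediction.preds)
            archive.corrs = list(prediction.corrs)
        if ev is not None:
            archive.ev = list(ev.ev)
        return archive

    def to_model(self) -> KernelCCA:
        """Reconstruct a fitted KernelCCA usable for prediction."""
        kern = "none" if self.ktype == "none" else KernelSpec(
            self.ktype, self.gausigma, self.degree)
        model = KernelCCA(n_components=self.n_components, reg=self.reg,
                          kernel=kern, gausigma=self.gausigma,
                          degree=self.degree, cutoff=self.cutoff)
        model.weights_ = [np.asarray(w) for w in self.weights]
        model.components_ = [np.asarray(c) for c in self.comps]
        model.means_ = [np.asarray(m) for m in self.means]
        model.cancorrs_ = np.asarray(self.cancorrs)
        model.eigenvalues_ = np.full(self.n_components, np.nan)
        model.n_datasets_ = len(self.weights)
        model.n_samples_ = self.comps[0].shape[0]
        return model


def save_model(archive, path) -> None:
    """Write a ModelArchive (or fitted model) to one HDF5 file."""
    if not isinstance(archive, ModelArchive):
        archive = ModelArchive.from_model(archive)
    try:
        f = h5py.File(path, "w")
    except OSError as exc:
        raise OSError(f"cannot write model archive to {path!r}: {exc}") \
            from exc
    with f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        meta.attrs["reg"] = archive.reg
        meta.attrs["numCC"] = archive.n_components
        meta.attrs["ktype"] = archive.ktype
        meta.attrs["gausigma"] = archive.gausigma
        meta.attrs["degree"] = archive.degree
        meta.attrs["cutoff"] = archive.cutoff
        if archive.best_reg is not None:
            meta.attrs["best_reg"] = archive.best_reg
            meta.attrs["best_numCC"] = archive.best_numcc
        for i, (w, c, mu) in enumerate(zip(archive.weights, archive.comps,
                                           archive.means)):
            g = f.create_group(f"dataset{i}")
            g["weights"] = w
            g["comps"] = c
            g["means"] = mu
        f["cancorrs"] = archive.cancorrs
        if archive.preds is not None:
            for i, (p, r) in enumerate(zip(archive.preds, archive.corrs)):
                g = f.create_group(f"validation/{i}")
                g["preds"] = p
                g["corrs"] = r
        if archive.ev is not None:
            for i, e in enumerate(archive.ev):
                f[f"ev/{i}"] = e
        if archive.score_grid is not None:
            g = f.create_group("cv")
            g["score_grid"] = archive.score_grid
            g["regs"] = archive.cv_regs
            g["numccs"] = archive.cv_numccs


def _require(f, name: str):
    if name not in f:
        raise CorruptArchiveError(f"archive is missing required group or "
                                  f"dataset {name!r}")
    return f[name]


def load_model(path) -> ModelArchive:
    """Read a ModelArchive written by :func:`save_model`."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such model archive: {path!r}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise CorruptArchiveError(f"cannot open {path!r} as an HDF5 "
                                  f"archive: {exc}") from exc
    with f:
        meta = _require(f, "meta")
        version = meta.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise UnsupportedVersionError(
                f"archive {path!r} has format version {version!r}; this "
                f"build reads version {FORMAT_VERSION}")
        weights, comps, means = [], [], []
        i = 0
        while f"dataset{i}" in f:
            g = f[f"dataset{i}"]
            for part in ("weights", "comps", "means"):
                if part not in g:
                    raise CorruptArchiveError(
                        f"archive is missing dataset{i}/{part}")
            weights.append(g["weights"][()])
            comps.append(g["comps"][()])
            means.append(g["means"][()])
            i += 1
        if i < 2:
            raise CorruptArchiveError(
                f"archive holds {i} dataset group(s); expected >= 2")
        archive = ModelArchive(
            reg=float(meta.attrs["reg"]),
            n_components=int(meta.attrs["numCC"]),
            ktype=str(meta.attrs["ktype"]),
            gausigma=float(meta.attrs["gausigma"]),
            degree=int(meta.attrs["degree"]),
            cutoff=float(meta.attrs["cutoff"]),
            weights=weights, comps=comps, means=means,
            cancorrs=_require(f, "cancorrs")[()])
        if "best_reg" in meta.attrs:
            archive.best_reg = float(meta.attrs["best_reg"])
            archive.best_numcc = int(meta.attrs["best_numCC"])
        if "validation" in f:
            archive.preds, archive.corrs = [], []
            j = 0
            while f"validation/{j}" in f:
                archive.preds.append(f[f"validation/{j}/preds"][()])
                archive.corrs.append(f[f"validation/{j}/corrs"][()])
                j += 1
        if "ev" in f:
            archive.ev = []
            j = 0
            while f"ev/{j}" in f:
                archive.ev.append(f[f"ev/{j}"][()])
                j += 1
        if "cv" in f:
            archive.score_grid = f["cv/score_grid"][()]
            archive.cv_regs = f["cv/regs"][()]
            archive.cv_numccs = f["cv/numccs"][()]
    return archive


def read_datasets(paths: Sequence) -> List[DataBlock]:
    """Load datasets from whitespace-delimited text or HDF5 files.

    Text files: rows are samples, columns features; lines starting with
    '#' are comments; no header row. HDF5 files must contain exactly one
    2-D dataset. All files must agree on the sample count. Blocks are
    returned centered, with column means recorded.
    """
    blocks = []
    for path in paths:
        if not os.path.exists(path):
            raise FileNotFoundError(f"no such dataset file: {path!r}")
        if h5py.is_hdf5(path):
            with h5py.File(path, "r") as f:
                found = []
                f.visititems(lambda name, obj: found.append(name)
                             if isinstance(obj, h5py.Dataset)
                             and obj.ndim == 2 else None)
                if len(found) != 1:
                    raise ValueError(
                        f"{path!r} must contain exactly one 2-D dataset, "
                        f"found {len(found)}: {found}")
                arr = f[found[0]][()]
        else:
            try:
                arr = np.loadtxt(path, comments="#", ndmin=2)
            except ValueError as exc:
                raise ValueError(f"cannot parse {path!r} as a numeric "
                                 f"whitespace-delimited table: {exc}") \
                    from exc
        try:
            blocks.append(DataBlock.from_array(arr, name=str(path)))
        except ValueError as exc:
            raise ValueError(f"{path!r}: {exc}") from exc
    n_rows = {b.n_samples for b in blocks}
    if len(n_rows) > 1:
        detail = ", ".join(f"{p!r}: {b.n_samples} rows"
                           for p, b in zip(paths, blocks))
        raise ValueError(f"datasets disagree on sample count ({detail})")
    return blocks
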