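"""In-memory model and I/O for single-cell / spatial multimodal datasets.

A :class:`CellDataset` holds one matrix per modality (e.g. ``rna``,
``atac``) over a shared, ordered cell list, plus embeddings (2-D or 3-D),
per-cell metadata, optional spatial slices with 10x-style scale factors,
and an optional precomputed marker table.  On disk the dataset maps to:

* ``.h5ad`` (one modality): ``X``/``var`` for the matrix, ``obs`` for
  metadata, ``obsm['X_<name>']`` for embeddings, ``obsm['spatial']`` +
  ``uns['spatial'][<slice>]['scalefactors']`` for Visium-style slices and
  ``uns['markers']`` for the marker table;
* ``.h5mu`` / multimodal Zarr: the MuData layout — modalities as AnnData
  groups under ``mod/``, shared ``obs``/``obsm`` at the root (written with
  anndata's element writers; no separate reader package is required);
* ``.zarr`` (one modality): the AnnData Zarr layout.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import anndata as ad
import h5py
import numpy as np
import pandas as pd
from anndata.io import read_elem, write_elem
from scipy import sparse

from ..search import build_index, suggest

MUDATA_KEY = "mod"  # group holding per-modality AnnData subgroups


@dataclass(frozen=True)
class ScaleFactors:
    """10x Visium scale factors tying full-res spot coordinates to images."""

    tissue_hires_scalef: float
    tissue_lowres_scalef: float
    spot_diameter_fullres: float

    def __post_init__(self):
        for f in (self.tissue_hires_scalef, self.tissue_lowres_scalef, self.spot_diameter_fullres):
            if not (f > 0):
                raise ValueError("scale factors must be positive")


@dataclass
class SpatialSlice:
    slice_id: str
    scalefactors: ScaleFactors
    spot_coords: np.ndarray  # (cells-in-slice, 2) full-resolution pixels
    cell_index: np.ndarray  # rows of the parent dataset in this slice
    image_ref: Optional[str] = None

    def __post_init__(self):
        self.spot_coords = np.asarray(self.spot_coords, dtype=float)
        self.cell_index = np.asarray(self.cell_index, dtype=int)
        if self.spot_coords.shape != (len(self.cell_index), 2):
            raise ValueError("spot_coords must be (n_cells_in_slice, 2)")


@dataclass
class Modality:
    """One assay: cells x features matrix plus feature metadata."""

    X: object  # ndarray or scipy sparse, cells x features
    var: pd.DataFrame  # indexed by feature name

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> List[str]:
        return list(self.var.index)


@dataclass
class CellDataset:
    cell_ids: List[str]
    modalities: Dict[str, Modality]
    metadata: pd.DataFrame = None  # per-cell columns, index == cell_ids
    embeddings: Dict[str, np.ndarray] = field(default_factory=dict)
    spatial: List[SpatialSlice] = field(default_factory=list)
    markers: Optional[pd.DataFrame] = None  # feature, group, p_value, score

    def __post_init__(self):
        n = len(self.cell_ids)
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        for name, mod in self.modalities.items():
            if mod.X.shape[0] != n:
                raise ValueError(
                    f"modality {name!r} has {mod.X.shape[0]} cells, dataset has {n}"
                )
        for name, emb in self.embeddings.items():
            emb = np.asarray(emb, dtype=float)
            if emb.shape[0] != n or emb.shape[1] not in (2, 3):
                raise ValueError(f"embedding {name!r} must be ({n}, 2|3)")
            if not np.all(np.isfinite(emb)):
                raise ValueError(f"embedding {name!r} has non-finite values")
            self.embeddings[name] = emb
        if len(self.metadata) != n:
            raise ValueError("metadata length != cell count")
        if not self.embeddings and not self.spatial:
            raise ValueError("dataset needs at least one embedding or spatial slice")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    # -- equality for round-trip tests ------------------------------------
    def equals(self, other: "CellDataset") -> bool:
        if self.cell_ids != other.cell_ids:
            return False
        if set(self.modalities) != set(other.modalities):
            return False
        for k in self.modalities:
            a, b = self.modalities[k], other.modalities[k]
            xa = a.X.toarray() if sparse.issparse(a.X) else np.asarray(a.X)
            xb = b.X.toarray() if sparse.issparse(b.X) else np.asarray(b.X)
            if xa.shape != xb.shape or not np.array_equal(xa, xb):
                return False
            if list(a.var.index) != list(b.var.index):
                return False
        if set(self.embeddings) != set(other.embeddings):
            return False
        for k in self.embeddings:
            if not np.array_equal(self.embeddings[k], other.embeddings[k]):
                return False
        ma = self.metadata.reset_index(drop=True)
        mb = other.metadata.reset_index(drop=True)
        if list(ma.columns) != list(mb.columns):
            return False
        for c in ma.columns:
            if list(map(str, ma[c].tolist())) != list(map(str, mb[c].tolist())):
                return False
        if len(self.spatial) != len(other.spatial):
            return False
        for sa, sb in zip(self.spatial, other.spatial):
            if sa.slice_id != sb.slice_id or sa.scalefactors != sb.scalefactors:
                return False
            if not np.allclose(sa.spot_coords, sb.spot_coords):
                return False
            if not np.array_equal(sa.cell_index, sb.cell_index):
                return False
        if (self.markers is None) != (other.markers is None):
            return False
        if self.markers is not None:
            if not self.markers.reset_index(drop=True).astype(str).equals(
                other.markers.reset_index(drop=True).astype(str)
            ):
                return False
        return True


# ---------------------------------------------------------------------------
# AnnData conversion (single modality)
# ---------------------------------------------------------------------------

def _to_anndata(ds: CellDataset, mod_name: str) -> ad.AnnData:
    mod = ds.modalities[mod_name]
    adata = ad.AnnData(
        X=mod.X,
        obs=ds.metadata.copy(),
        var=mod.var.copy(),
    )
    adata.obs_names = list(ds.cell_ids)
    for name, emb in ds.embeddings.items():
        adata.obsm[f"X_{name}"] = emb.copy()
    if ds.spatial:
        coords = np.full((ds.n_cells, 2), np.nan)
        spatial_uns = {}
        slice_col = np.array([""] * ds.n_cells, dtype=object)
        for sl in ds.spatial:
            coords[sl.cell_index] = sl.spot_coords
            slice_col[sl.cell_index] = sl.slice_id
            spatial_uns[sl.slice_id] = {
                "scalefactors": {
                    "tissue_hires_scalef": sl.scalefactors.tissue_hires_scalef,
                    "tissue_lowres_scalef": sl.scalefactors.tissue_lowres_scalef,
                    "spot_diameter_fullres": sl.scalefactors.spot_diameter_fullres,
                },
                "image_ref": sl.image_ref or "",
            }
        adata.obsm["spatial"] = coords
        adata.obs["_slice_id"] = pd.Categorical(slice_col)
        adata.uns["spatial"] = spatial_uns
    if ds.markers is not None:
        adata.uns["markers"] = ds.markers.copy()
    adata.uns["modality"] = mod_name
    return adata


def _from_anndata(adata: ad.AnnData, default_mod: str = "rna") -> CellDataset:
    mod_name = str(adata.uns.get("modality", default_mod))
    metadata = adata.obs.copy()
    embeddings = {}
    for key in adata.obsm.keys():
        if key.startswith("X_"):
            arr = np.asarray(adata.obsm[key], dtype=float)
            if arr.ndim == 2 and arr.shape[1] in (2, 3):
                embeddings[key[2:]] = arr
    spatial = []
    if "spatial" in adata.obsm.keys() and "spatial" in adata.uns:
        coords = np.asarray(adata.obsm["spatial"], dtype=float)
        slice_col = adata.obs.get("_slice_id")
        for slice_id, info in adata.uns["spatial"].items():
            if slice_col is not None:
                idx = np.where(np.asarray(slice_col.astype(str)) == str(slice_id))[0]
            else:
                idx = np.arange(adata.n_obs)
            sf = info["scalefactors"]
            spatial.append(
                SpatialSlice(
                    slice_id=str(slice_id),
                    scalefactors=ScaleFactors(
                        float(sf["tissue_hires_scalef"]),
                        float(sf["tissue_lowres_scalef"]),
                        float(sf["spot_diameter_fullres"]),
                    ),
                    spot_coords=coords[idx],
                    cell_index=idx,
                    image_ref=str(info.get("image_ref", "")) or None,
                )
            )
        metadata = metadata.drop(columns=["_slice_id"], errors="ignore")
    markers = None
    if "markers" in adata.uns:
        markers = pd.DataFrame(adata.uns["markers"])
    return CellDataset(
        cell_ids=list(adata.obs_names),
        modalities={mod_name: Modality(X=adata.X.copy(), var=adata.var.copy())},
        metadata=metadata,
        embeddings=embeddings,
        spatial=spatial,
        markers=markers,
    )


# ---------------------------------------------------------------------------
# load / save
# ---------------------------------------------------------------------------

def load_cell_dataset(path: str, format: Optional[str] = None) -> CellDataset:
    """Load .h5ad / .h5mu / .zarr into a CellDataset.

    Errors if no 2-D embedding and no spatial coordinates are present, or
    if modalities disagree on cell count.
    """
    fmt = format or _sniff_format(path)
    if fmt == "h5ad":
        return _from_anndata(ad.read_h5ad(path))
    if fmt == "h5mu":
        with h5py.File(path, "r") as f:
            return _read_mudata_group(f)
    if fmt == "zarr":
        import zarr as _zarr

        root = _zarr.open_group(path, mode="r")
        if MUDATA_KEY in root:
            return _read_mudata_group(root)
        return _from_anndata(ad.read_zarr(path))
    raise ValueError(f"unsupported dataset format {fmt!r}")


def save_cell_dataset(ds: CellDataset, path: str, format: Optional[str] = None) -> str:
    fmt = format or _sniff_format(path)
    if fmt == "h5ad":
        if len(ds.modalities) != 1:
            raise ValueError("h5ad holds exactly one modality; use h5mu")
        (mod_name,) = ds.modalities
        _to_anndata(ds, mod_name).write_h5ad(path)
        return path
    if fmt == "h5mu":
        with h5py.File(path, "w") as f:
            _write_mudata_group(f, ds)
        return path
    if fmt == "zarr":
        import zarr as _zarr

        if len(ds.modalities) == 1:
            (mod_name,) = ds.modalities
            _to_anndata(ds, mod_name).write_zarr(path)
        else:
            root = _zarr.open_group(path, mode="w")
            _write_mudata_group(root, ds)
        return path
    raise ValueError(f"unsupported dataset format {fmt!r}")


def _sniff_format(path: str) -> str:
    p = str(path).rstrip("/")
    if p.endswith(".h5ad"):
        return "h5ad"
    if p.endswith(".h5mu"):
        return "h5mu"
    if p.endswith(".zarr"):
        return "zarr"
    raise ValueError(f"cannot infer dataset format from {path!r}")


def _write_mudata_group(root, ds: CellDataset):
    """MuData layout: shared obs/obsm at the root, AnnData groups in mod/."""
    root.attrs["encoding-type"] = "MuData"
    root.attrs["encoding-version"] = "0.1.0"
    mod_group = root.create_group(MUDATA_KEY)
    for name in ds.modalities:
        write_elem(mod_group, name, _to_anndata(ds, name))
    # shared annotations at the root are authoritative on read
    write_elem(root, "obs", ds.metadata.set_axis(pd.Index(ds.cell_ids, name="cell_id")))
    obsm = {f"X_{k}": v for k, v in ds.embeddings.items()}
    if obsm:
        write_elem(root, "obsm", obsm)


def _read_mudata_group(root) -> CellDataset:
    mod_group = root[MUDATA_KEY]
    names = sorted(mod_group.keys())
    modalities = {}
    base = None
    for name in names:
        adata = read_elem(mod_group[name])
        sub = _from_anndata(adata, default_mod=name)
        modalities[name] = sub.modalities[list(sub.modalities)[0]]
        if base is None:
            base = sub
    cell_counts = {m.X.shape[0] for m in modalities.values()}
    if len(cell_counts) != 1:
        raise ValueError(f"modalities disagree on cell count: {sorted(cell_counts)}")
    metadata = base.metadata
    if "obs" in root:
        metadata = pd.DataFrame(read_elem(root["obs"]))
    embeddings = dict(base.embeddings)
    if "obsm" in root:
        for key, arr in dict(read_elem(root["obsm"])).items():
            if key.startswith("X_"):
                embeddings[key[2:]] = np.asarray(arr, dtype=float)
    return CellDataset(
        cell_ids=base.cell_ids,
        modalities=modalities,
        metadata=metadata,
        embeddings=embeddings,
        spatial=base.spatial,
        markers=base.markers,
    )


# ---------------------------------------------------------------------------
# Visium spatial folder
# ---------------------------------------------------------------------------

def load_visium_folder(folder: str, slice_id: str, cell_ids: List[str]) -> SpatialSlice:
    """Attach a 10x Visium spatial folder (tissue_positions.csv +
    scalefactors_json.json) to an existing cell list by barcode."""
    pos_path = None
    for cand in ("tissue_positions.csv", "spatial/tissue_positions.csv"):
        p = os.path.join(folder, cand)
        if os.path.exists(p):
            pos_path = p
            break
    if pos_path is None:
        raise FileNotFoundError(f"no tissue_positions.csv under {folder}")
    sf_path = os.path.join(os.path.dirname(pos_path), "scalefactors_json.json")
    with open(sf_path) as fh:
        sf = json.load(fh)
    pos = pd.read_csv(pos_path)
    pos = pos.set_index("barcode")
    order = {b: i for i, b in enumerate(cell_ids)}
    keep = [b for b in pos.index if b in order and int(pos.loc[b, "in_tissue"]) == 1]
    keep.sort(key=lambda b: order[b])
    coords = pos.loc[keep, ["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(float)
    image_ref = None
    for img in ("tissue_hires_image.png", "tissue_lowres_image.png"):
        p = os.path.join(os.path.dirname(pos_path), img)
        if os.path.exists(p):
            image_ref = p
            break
    return SpatialSlice(
        slice_id=slice_id,
        scalefactors=ScaleFactors(
            float(sf["tissue_hires_scalef"]),
            float(sf["tissue_lowres_scalef"]),
            float(sf["spot_diameter_fullres"]),
        ),
        spot_coords=coords,
        cell_index=np.array([order[b] for b in keep], dtype=int),
        image_ref=image_ref,
    )


# ---------------------------------------------------------------------------
# feature access / spatial mapping / opacity
# ---------------------------------------------------------------------------

class UnknownFeatureError(KeyError):
    def __init__(self, feature, assay, suggestions):
        self.feature = feature
        self.suggestions = suggestions
        msg = f"feature {feature!r} not found in assay {assay!r}"
        if suggestions:
            msg += f"; did you mean: {', '.join(suggestions)}?"
        super().__init__(msg)


def feature_vector(ds: CellDataset, assay: str, feature: str) -> np.ndarray:
    """Per-cell values of one feature, in ``cell_ids`` order."""
    if assay not in ds.modalities:
        raise KeyError(f"unknown assay {assay!r}; have {sorted(ds.modalities)}")
    mod = ds.modalities[assay]
    names = mod.feature_names
    try:
        j = names.index(feature)
    except ValueError:
        idx = build_index([(n, assay) for n in names])
        raise UnknownFeatureError(feature, assay, suggest(idx, feature, k=3))
    col = mod.X[:, j]
    if sparse.issparse(col):
        col = col.toarray().ravel()
    return np.asarray(col, dtype=float).ravel()


def map_spots_to_image(sl: SpatialSlice, resolution: str) -> np.ndarray:
    """Spot centers and radii in image pixels at hires/lowres resolution.

    Returns an (n, 3) array of (x_px, y_px, radius_px):
    ``x_px = x_fullres * scalef`` and ``radius = spot_diameter * scalef / 2``.
    """
    if resolution == "hires":
        f = sl.scalefactors.tissue_hires_scalef
    elif resolution == "lowres":
        f = sl.scalefactors.tissue_lowres_scalef
    else:
        raise ValueError(f"unknown resolution {resolution!r}; use 'hires' or 'lowres'")
    xy = sl.spot_coords * f
    r = np.full((len(xy), 1), sl.scalefactors.spot_diameter_fullres * f / 2.0)
    return np.hstack([xy, r])


def expression_opacity(values: np.ndarray, clip_percentile: float = 99.0) -> np.ndarray:
    """Map expression strength to drawing opacity in [0, 1].

    Values are clipped at the given upper percentile (taming a handful of
    very bright cells), then min-max scaled.  A constant vector maps to
    opacity 1.0 everywhere.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if v.size == 0:
        return v.copy()
    # clip at an observed value (method="higher") so short vectors keep
    # their maximum and only genuine outliers are flattened
    hi = np.percentile(v, clip_percentile, method="higher")
    v = np.minimum(v, hi)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones_like(v)
    return (v - lo) / (hi - lo)
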