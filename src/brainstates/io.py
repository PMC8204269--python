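"""Serialization: HDF5 containers for time series and models, TSV for
contact coordinates, JSON for ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .linkage import ContactGeometry
from .prep import ParcelTimeSeries
from .tdehmm import EmbeddingConfig, HMMModel, HMMPriors, PCABasis

FORMAT_VERSION = 1


def save_timeseries(path, x: ParcelTimeSeries) -> None:
    """Write a recording to an HDF5 container (datasets: data, fs, names)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=x.data, compression="gzip")
        f.create_dataset("fs", data=float(x.fs))
        f.create_dataset(
            "channel_names", data=np.array(x.parcel_ids, dtype=h5py.string_dtype())
        )
        f.attrs["subject_id"] = x.subject_id
        f.attrs["format_version"] = FORMAT_VERSION


def load_timeseries(path) -> ParcelTimeSeries:
    with h5py.File(path, "r") as f:
        return ParcelTimeSeries(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            subject_id=str(f.attrs.get("subject_id", "s00")),
            parcel_ids=[n.decode() for n in f["channel_names"][()]],
        )


def save_coords_tsv(path, geoms: list[ContactGeometry]) -> None:
    """Contact coordinates as TSV: electrode, contact, x, y, z (mm)."""
    rows = [
        {
            "electrode": g.electrode,
            "subject": g.subject,
            "contact": c + 1,
            "x": g.coords[c, 0],
            "y": g.coords[c, 1],
            "z": g.coords[c, 2],
        }
        for g in geoms
        for c in range(g.n_contacts)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_coords_tsv(path) -> list[ContactGeometry]:
    df = pd.read_csv(path, sep="\t")
    geoms = []
    for (el, subj), grp in df.groupby(["electrode", "subject"], sort=False):
        grp = grp.sort_values("contact")
        geoms.append(
            ContactGeometry(
                electrode=str(el),
                subject=str(subj),
                coords=grp[["x", "y", "z"]].to_numpy(float),
            )
        )
    return geoms


def save_ground_truth_json(path, gt) -> None:
    """Ground truth as JSON (arrays become nested lists)."""
    from dataclasses import asdict

    def convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, slice):
            return [obj.start, obj.stop]
        return obj

    Path(path).write_text(json.dumps(convert(asdict(gt)), indent=1))


def save_model(path, model: HMMModel, basis: PCABasis, cfg: EmbeddingConfig) -> None:
    """Single-file container sufficient to reproduce `apply_model` elsewhere:
    posterior hyperparameters, priors, PCA basis and embedding config."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["K"] = model.K
        g = f.create_group("posterior")
        g.create_dataset("trans_alpha", data=model.trans_alpha)
        g.create_dataset("init_alpha", data=model.init_alpha)
        g.create_dataset("prec_scale_inv", data=model.prec_scale_inv)
        g.create_dataset("prec_dof", data=model.prec_dof)
        if model.priors is not None:
            g = f.create_group("priors")
            g.create_dataset("trans_alpha0", data=model.priors.trans_alpha0)
            g.create_dataset("init_alpha0", data=model.priors.init_alpha0)
            g.create_dataset("prec_scale_inv", data=model.priors.prec_scale_inv)
            g.create_dataset("prec_dof", data=float(model.priors.prec_dof))
        g = f.create_group("pca")
        g.create_dataset("components", data=basis.components)
        g.create_dataset("mean", data=basis.mean)
        g.create_dataset("explained_variance", data=basis.explained_variance)
        g = f.create_group("embedding")
        g.create_dataset("lags", data=cfg.lags)
        g.create_dataset("fs", data=float(cfg.fs))


def load_model(path):
    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version > FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        priors = None
        if "priors" in f:
            g = f["priors"]
            priors = HMMPriors(
                trans_alpha0=g["trans_alpha0"][()],
                init_alpha0=g["init_alpha0"][()],
                prec_scale_inv=g["prec_scale_inv"][()],
                prec_dof=float(g["prec_dof"][()]),
            )
        g = f["posterior"]
        model = HMMModel(
            K=int(f.attrs["K"]),
            trans_alpha=g["trans_alpha"][()],
            init_alpha=g["init_alpha"][()],
            prec_scale_inv=g["prec_scale_inv"][()],
            prec_dof=g["prec_dof"][()],
            priors=priors,
        )
        g = f["pca"]
        basis = PCABasis(
            components=g["components"][()],
            mean=g["mean"][()],
            explained_variance=g["explained_variance"][()],
        )
        g = f["embedding"]
        cfg = EmbeddingConfig(lags=g["lags"][()], fs=float(g["fs"][()]))
    return model, basis, cfg
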