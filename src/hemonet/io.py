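"""Serialization: network JSON, ground-truth/field HDF5 collections,
profile CSV, loss-history CSV, and run manifests with checksums."""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .prep import Field2D, KIND_HEMATOCRIT, KIND_VELOCITY, Profile1D
from .synthetic import GroundTruthField, NetworkSpec

__all__ = ["save_network", "load_network", "save_fields", "load_fields",
           "save_profiles_csv", "save_loss_csv", "write_manifest",
           "sha256_file"]


def save_network(net: NetworkSpec, path) -> None:
    Path(path).write_text(json.dumps(net.to_dict(), indent=1))


def load_network(path) -> NetworkSpec:
    net = NetworkSpec.from_dict(json.loads(Path(path).read_text()))
    net.validate()
    return net


def save_fields(fields: dict, path, seed: int | None = None) -> None:
    """Write a ``{(vessel_id, station): GroundTruthField}`` collection to
    HDF5: one group per vessel/station with datasets u, H, mask and
    geometry attributes."""
    with h5py.File(path, "w") as fh:
        if seed is not None:
            fh.attrs["seed"] = seed
        for (vid, station), gt in sorted(fields.items()):
            grp = fh.create_group(f"{vid}/{station}")
            grp.create_dataset("u", data=gt.u.grid)
            grp.create_dataset("H", data=gt.h.grid)
            grp.create_dataset("mask", data=gt.u.mask)
            grp.create_dataset("profile_u", data=gt.profile_u.values)
            grp.create_dataset("profile_H", data=gt.profile_h.values)
            grp.attrs.update({"d_um": gt.d_um, "l_um": gt.l_um, "s": gt.s,
                              "delta_beta": gt.u.delta_beta, "q": gt.q,
                              "h_d": gt.h_d, "u_max": gt.u_max})


def load_fields(path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        for vid in fh:
            for station in fh[vid]:
                grp = fh[vid][station]
                mask = grp["mask"][...].astype(bool)
                n = grp["profile_u"].shape[0]
                xi = np.linspace(0.0, 1.0, n)
                db = float(grp.attrs["delta_beta"])
                out[(vid, station)] = GroundTruthField(
                    vessel_id=vid, s=float(grp.attrs["s"]),
                    u=Field2D(grp["u"][...], mask, db, KIND_VELOCITY),
                    h=Field2D(grp["H"][...], mask, db, KIND_HEMATOCRIT),
                    profile_u=Profile1D(xi, grp["profile_u"][...],
                                        KIND_VELOCITY, "global"),
                    profile_h=Profile1D(xi, grp["profile_H"][...],
                                        KIND_HEMATOCRIT, "global"),
                    d_um=float(grp.attrs["d_um"]),
                    l_um=float(grp.attrs["l_um"]), q=float(grp.attrs["q"]),
                    h_d=float(grp.attrs["h_d"]),
                    u_max=float(grp.attrs["u_max"]))
    return out


def save_profiles_csv(gt: GroundTruthField, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["xi", "u", "H"])
        for xi, u, h in zip(gt.profile_u.xi, gt.profile_u.values,
                            gt.profile_h.values):
            w.writerow([f"{xi:.8g}", f"{u:.8g}", f"{h:.8g}"])


def save_loss_csv(model, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        lrs = getattr(model, "lr_history", None)
        w.writerow(["epoch", "loss"] + (["lr"] if lrs else []))
        for i, loss in enumerate(model.loss_history):
            row = [i + 1, f"{loss:.8g}"]
            if lrs:
                row.append(f"{lrs[i]:.3g}")
            w.writerow(row)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, files: list, extra: dict | None = None) -> Path:
    """Write a manifest listing every produced file with its checksum."""
    out_dir = Path(out_dir)
    manifest = {
        "files": {str(Path(f).relative_to(out_dir)): sha256_file(f)
                  for f in files},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
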