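"""NIfTI / CSV / YAML serialization for studies, maps and designs."""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import nibabel as nib
import yaml

from dscmicro.protocol import AcquisitionProtocol
from dscmicro.synthgen import (
    PhantomSpec, CohortDesign, DynamicStudy, GroundTruth, ClassParams,
)


def _affine(voxel_volume: float) -> np.ndarray:
    edge = voxel_volume ** (1.0 / 3.0)
    return np.diag([edge, edge, edge, 1.0])


def save_study(study: DynamicStudy, out_dir: str | pathlib.Path) -> None:
    """Write 4D signal series (time as 4th dimension) and truth maps."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.protocol.voxel_volume)
    nib.save(nib.Nifti1Image(study.signal_gre, aff), out / "signal_gre.nii.gz")
    if study.signal_se is not None:
        nib.save(nib.Nifti1Image(study.signal_se, aff), out / "signal_se.nii.gz")
    with open(out / "protocol.yaml", "w") as fh:
        yaml.safe_dump(study.protocol.to_dict(), fh)
    if study.truth is not None:
        t = study.truth
        for name in ("cbf", "cbv", "mtt", "cth", "kapp", "gre_se_lag"):
            nib.save(nib.Nifti1Image(getattr(t, name), aff),
                     out / f"truth_{name}.nii.gz")
        nib.save(nib.Nifti1Image(t.tissue_class.astype(np.int16), aff),
                 out / "truth_tissue_class.nii.gz")


def load_study(in_dir: str | pathlib.Path) -> DynamicStudy:
    src = pathlib.Path(in_dir)
    with open(src / "protocol.yaml") as fh:
        protocol = AcquisitionProtocol.from_dict(yaml.safe_load(fh))
    gre = np.asarray(nib.load(src / "signal_gre.nii.gz").dataobj, dtype=float)
    se_path = src / "signal_se.nii.gz"
    se = (np.asarray(nib.load(se_path).dataobj, dtype=float)
          if se_path.exists() else None)
    truth = None
    if (src / "truth_cbf.nii.gz").exists():
        def arr(nm):
            return np.asarray(nib.load(src / f"truth_{nm}.nii.gz").dataobj,
                              dtype=float)
        truth = GroundTruth(
            cbf=arr("cbf"), cbv=arr("cbv"), mtt=arr("mtt"), cth=arr("cth"),
            kapp=arr("kapp"), gre_se_lag=arr("gre_se_lag"),
            tissue_class=np.asarray(
                nib.load(src / "truth_tissue_class.nii.gz").dataobj
            ).astype(np.int8),
        )
    return DynamicStudy(signal_gre=gre, signal_se=se, protocol=protocol,
                        truth=truth)


def save_maps(maps: dict[str, np.ndarray], out_dir: str | pathlib.Path,
              voxel_volume: float = 8.0) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, vol in maps.items():
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=float),
                                 _affine(voxel_volume)),
                 out / f"{name}.nii.gz")


def load_phantom_spec(path: str | pathlib.Path) -> PhantomSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "protocol" in raw:
        raw["protocol"] = AcquisitionProtocol.from_dict(raw["protocol"])
    if "class_params" in raw:
        raw["class_params"] = {
            k: ClassParams(**{kk: tuple(vv) for kk, vv in v.items()})
            for k, v in raw["class_params"].items()
        }
    if "shape" in raw:
        raw["shape"] = tuple(raw["shape"])
    return PhantomSpec(**raw)


def load_cohort_design(path: str | pathlib.Path) -> CohortDesign:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "visit_days" in raw:
        raw["visit_days"] = tuple(raw["visit_days"])
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    return CohortDesign(**raw)


def save_aif_csv(times: np.ndarray, values: np.ndarray,
                 path: str | pathlib.Path) -> None:
    pd.DataFrame({"time_s": times, "delta_r2_per_s": values}).to_csv(
        path, index=False)


def load_aif_csv(path: str | pathlib.Path):
    from dscmicro.curves import ConcentrationCurve

    df = pd.read_csv(path)
    return ConcentrationCurve(df["delta_r2_per_s"].to_numpy(),
                              df["time_s"].to_numpy(), echo="GRE")
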