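"""Readers and writers for the pipeline's on-disk formats.

* epoch activity CSV: ``zt_hours,count[,valid]``, one row per 12-s epoch;
* temperature CSV: ``zt_hours,temp_c``, one row per minute;
* pose CSV in two dialects: the three-header-row table produced by
  markerless pose estimators (scorer / bodyparts / coords) and a flat
  ``frame,part,x,y,likelihood`` table;
* sniff-bout CSV ``mouse_id,start_s,end_s,duration_s`` and manual
  annotation CSV ``mouse_id,start_s,end_s``;
* YAML study config; JSON ground truth; TIFF fluorescence images.

``write_cohort``/``load_cohort`` round-trip a full synthetic cohort
through these formats.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .actigraphy import EpochActivitySeries
from .arena import TrackedSession
from .synthetic import (
    ActigraphyParams,
    Cohort,
    CohortConfig,
    HypothermiaParams,
    ImagingParams,
    MouseData,
    SocialParams,
    SocialPhenotype,
    TemperatureParams,
)
from .thermometry import TemperatureSeries


# ---------------------------------------------------------------------------
# time-series CSV
# ---------------------------------------------------------------------------


def write_epoch_csv(series: EpochActivitySeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_epoch_csv(path: str | Path) -> EpochActivitySeries:
    df = pd.read_csv(path)
    if not {"zt_hours", "count"}.issubset(df.columns):
        raise ValueError(f"{path}: epoch CSV requires columns zt_hours,count")
    missing = None
    if "valid" in df.columns:
        missing = ~df["valid"].astype(bool).to_numpy()
    return EpochActivitySeries(
        counts=df["count"].to_numpy(dtype=int),
        start_zt=float(df["zt_hours"].iloc[0]),
        missing_mask=missing,
    )


def write_temperature_csv(series: TemperatureSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"zt_hours": series.sample_zt, "temp_c": series.temps_c}
    ).to_csv(path, index=False)


def read_temperature_csv(path: str | Path) -> TemperatureSeries:
    df = pd.read_csv(path)
    if not {"zt_hours", "temp_c"}.issubset(df.columns):
        raise ValueError(f"{path}: temperature CSV requires columns zt_hours,temp_c")
    return TemperatureSeries(
        temps_c=df["temp_c"].to_numpy(dtype=float),
        start_zt=float(df["zt_hours"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# pose CSV
# ---------------------------------------------------------------------------


def write_pose_csv(
    session: TrackedSession,
    path: str | Path,
    dialect: str = "dlc",
    scorer: str = "stresssleep",
) -> None:
    """Write per-frame body-part coordinates.

    ``dialect="dlc"`` produces the de-facto pose-estimator table: three
    header rows (scorer / bodyparts / coords) and a frame-index column.
    ``dialect="flat"`` produces ``frame,part,x,y,likelihood`` rows.
    """
    parts = session.parts
    if dialect == "dlc":
        cols = pd.MultiIndex.from_tuples(
            [
                (scorer, part, coord)
                for part in parts
                for coord in ("x", "y", "likelihood")
            ],
            names=["scorer", "bodyparts", "coords"],
        )
        data = np.column_stack([parts[p] for p in parts])
        df = pd.DataFrame(data, columns=cols)
        df.to_csv(path, index_label="frame")
    elif dialect == "flat":
        rows = []
        for part, arr in parts.items():
            for i, (x, y, lk) in enumerate(arr):
                rows.append((i, part, x, y, lk))
        pd.DataFrame(
            rows, columns=["frame", "part", "x", "y", "likelihood"]
        ).to_csv(path, index=False)
    else:
        raise ValueError("dialect must be 'dlc' or 'flat'")


def read_pose_csv(
    path: str | Path, fps: float, session_kind: str = "test"
) -> TrackedSession:
    """Read either pose-CSV dialect (detected from the header)."""
    with open(path) as fh:
        first = fh.readline()
    if first.split(",")[0].strip() in ("scorer", ""):
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        parts = {}
        for part in df.columns.get_level_values(1).unique():
            sub = df.xs(part, axis=1, level=1)
            sub.columns = sub.columns.get_level_values(-1)
            parts[part] = np.column_stack(
                [sub["x"], sub["y"], sub["likelihood"]]
            ).astype(float)
    else:
        df = pd.read_csv(path)
        required = {"frame", "part", "x", "y", "likelihood"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: flat pose CSV requires columns {sorted(required)}")
        parts = {}
        for part, sub in df.groupby("part"):
            sub = sub.sort_values("frame")
            parts[str(part)] = sub[["x", "y", "likelihood"]].to_numpy(dtype=float)
    return TrackedSession(parts=parts, fps=fps, session_kind=session_kind)


# ---------------------------------------------------------------------------
# bouts / annotations
# ---------------------------------------------------------------------------


def write_bouts_csv(bouts_by_mouse: dict[str, list], path: str | Path) -> None:
    rows = []
    for mouse_id, bouts in bouts_by_mouse.items():
        for b in bouts:
            rows.append((mouse_id, b.start_s, b.end_s, b.duration_s))
    pd.DataFrame(
        rows, columns=["mouse_id", "start_s", "end_s", "duration_s"]
    ).to_csv(path, index=False)


def write_annotations_csv(
    intervals_by_mouse: dict[str, list[tuple[float, float]]], path: str | Path
) -> None:
    rows = [
        (mid, s, e) for mid, iv in intervals_by_mouse.items() for s, e in iv
    ]
    pd.DataFrame(rows, columns=["mouse_id", "start_s", "end_s"]).to_csv(
        path, index=False
    )


def read_annotations_csv(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    df = pd.read_csv(path)
    out: dict[str, list[tuple[float, float]]] = {}
    for mid, sub in df.groupby("mouse_id"):
        out[str(mid)] = [
            (float(s), float(e)) for s, e in zip(sub["start_s"], sub["end_s"])
        ]
    return out


# ---------------------------------------------------------------------------
# study config
# ---------------------------------------------------------------------------


def write_config_yaml(cfg: CohortConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def read_config_yaml(path: str | Path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text())
    for key, cls in (
        ("actigraphy", ActigraphyParams),
        ("temperature", TemperatureParams),
        ("hypothermia", HypothermiaParams),
        ("social", SocialParams),
        ("imaging", ImagingParams),
    ):
        if key in raw and isinstance(raw[key], dict):
            sub = raw[key]
            for name in ("stress_effect_window", "sleepdep_window", "mesh_span_cm",
                         "image_shape", "diameter_range_um", "stress_regions"):
                if name in sub and isinstance(sub[name], list):
                    sub[name] = tuple(sub[name])
            if key == "social" and "phenotypes" in sub:
                sub["phenotypes"] = {
                    k: SocialPhenotype(**v) for k, v in sub["phenotypes"].items()
                }
            raw[key] = cls(**sub)
    for name in ("analysis_window",):
        if name in raw and isinstance(raw[name], list):
            raw[name] = tuple(raw[name])
    return CohortConfig(**raw)


# ---------------------------------------------------------------------------
# whole-cohort round trip
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, outdir: str | Path, images: bool = True) -> None:
    """Emit every input modality as plain files plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_config_yaml(cohort.config, out / "config.yaml")
    meta = []
    for m in cohort.mice:
        d = out / m.mouse_id
        d.mkdir(exist_ok=True)
        write_epoch_csv(m.activity, d / "epochs.csv")
        write_temperature_csv(m.temperature, d / "temperature.csv")
        write_pose_csv(m.habituation, d / "pose_habituation.csv")
        write_pose_csv(m.test, d / "pose_test.csv")
        write_annotations_csv(
            {m.mouse_id: m.manual_annotations}, d / "manual_sniffing.csv"
        )
        meta.append({"mouse_id": m.mouse_id, "group": m.group})
    (out / "mice.json").write_text(json.dumps(meta, indent=1))
    cohort.save_truth(out / "truth.json")
    if images and cohort.fos_images:
        import tifffile

        img_dir = out / "fos"
        img_dir.mkdir(exist_ok=True)
        index = []
        for (group, mid, region, hemi), img in cohort.fos_images.items():
            name = f"{group}__{mid}__{region}__{hemi}.tif"
            tifffile.imwrite(img_dir / name, img.data.astype(np.float32))
            index.append(
                {
                    "file": name,
                    "group": group,
                    "mouse_id": mid,
                    "region": region,
                    "hemisphere": hemi,
                    "um_per_px": img.um_per_px,
                }
            )
        (img_dir / "index.json").write_text(json.dumps(index, indent=1))


def load_cohort(indir: str | Path) -> Cohort:
    """Rebuild a cohort from files written by :func:`write_cohort`.

    Phenotype labels are read from truth.json for book-keeping only; the
    analysis never consults them.
    """
    from .fos import FluorescenceImage

    ind = Path(indir)
    cfg = read_config_yaml(ind / "config.yaml")
    truth = json.loads((ind / "truth.json").read_text())
    meta = json.loads((ind / "mice.json").read_text())
    mice = []
    for rec in meta:
        mid = rec["mouse_id"]
        d = ind / mid
        ann = read_annotations_csv(d / "manual_sniffing.csv")
        mice.append(
            MouseData(
                mouse_id=mid,
                group=rec["group"],
                phenotype=truth["mice"][mid]["phenotype"],
                activity=read_epoch_csv(d / "epochs.csv"),
                temperature=read_temperature_csv(d / "temperature.csv"),
                habituation=read_pose_csv(
                    d / "pose_habituation.csv", cfg.social.fps, "habituation"
                ),
                test=read_pose_csv(d / "pose_test.csv", cfg.social.fps, "test"),
                manual_annotations=ann.get(mid, []),
                truth=truth["mice"][mid],
            )
        )
    fos_images: dict = {}
    fos_truth: dict = {}
    img_index = ind / "fos" / "index.json"
    if img_index.exists():
        import tifffile

        h = None
        for rec in json.loads(img_index.read_text()):
            data = tifffile.imread(ind / "fos" / rec["file"]).astype(float)
            roi = np.zeros(data.shape, dtype=bool)
            roi[8:-8, 8:-8] = True
            key = (rec["group"], rec["mouse_id"], rec["region"], rec["hemisphere"])
            fos_images[key] = FluorescenceImage(
                data=data,
                um_per_px=rec["um_per_px"],
                roi_mask=roi,
                region=rec["region"],
                hemisphere=rec["hemisphere"],
            )
            fos_truth[key] = truth["fos"].get("|".join(key))
    return Cohort(
        config=cfg, mice=mice, fos_images=fos_images, fos_truth=fos_truth, truth=truth
    )
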