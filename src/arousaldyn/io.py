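"""On-disk layout: TSV matrices, JSON/YAML sidecars, cohort manifests.

Canonical formats
-----------------
* cortical matrix: TSV, T rows x R columns, header ``p000..p399``;
* subcortical / nuisance series: TSV with labelled columns
  (``lc, bnm, fourth_ventricle, pons``);
* parcel metadata sidecar: TSV with columns ``parcel_id, x_mm, y_mm, z_mm,
  hemisphere, network_label`` (shared across subjects);
* cohort manifest: YAML listing subjects and relative paths plus
  ``tr_seconds``.

All indices on disk are 0-based (stated in file headers where ambiguity
is possible).  Write-then-read reproduces objects bit-for-bit for integer
fields and to full stored precision for reals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    EnergyLandscape,
    EventLockedResponse,
    NullDistribution,
    ParcelTimeSeries,
    PhasicEventSet,
    WaveFit,
)

__all__ = [
    "CohortStore",
    "load_cohort",
    "write_cohort",
    "write_results",
    "read_events",
    "read_landscape",
    "read_event_locked_response",
]

FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass
class CohortStore:
    """Validated view of a cohort on disk."""

    root: Path
    subjects: list[str]
    cortex_paths: dict[str, Path]
    subcortical_paths: dict[str, Path]
    parcel_paths: dict[str, Path]
    tr_seconds: float

    def load_parcels(self, subject: str | None = None) -> pd.DataFrame:
        sid = subject or self.subjects[0]
        return pd.read_csv(self.parcel_paths[sid], sep="\t", comment="#")

    def load_cortex(self, subject: str) -> ParcelTimeSeries:
        data = pd.read_csv(
            self.cortex_paths[subject], sep="\t", comment="#", float_precision="round_trip"
        ).to_numpy(float)
        return ParcelTimeSeries(data, self.tr_seconds, self.load_parcels(subject), subject)

    def load_subcortical(self, subject: str) -> pd.DataFrame:
        return pd.read_csv(
            self.subcortical_paths[subject], sep="\t", comment="#", float_precision="round_trip"
        )

    def series_lengths(self) -> dict[str, int]:
        return {s: self.load_cortex(s).n_timepoints for s in self.subjects}


def load_cohort(manifest_path: str | Path) -> CohortStore:
    """Read and validate a cohort manifest.

    Every referenced file must exist and parse; all subjects must share
    the same parcel count and ordering.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    root = manifest_path.parent
    tr = float(manifest["tr_seconds"])
    if tr <= 0:
        raise ValueError("tr_seconds must be positive")
    subjects, cortex, subcort, parcels = [], {}, {}, {}
    for entry in manifest["subjects"]:
        sid = str(entry["id"])
        subjects.append(sid)
        for key, store in (("cortex", cortex), ("subcortical", subcort), ("parcels", parcels)):
            p = root / entry[key]
            if not p.exists():
                raise FileNotFoundError(f"subject {sid}: missing {key} file {p}")
            store[sid] = p
    store = CohortStore(root, subjects, cortex, subcort, parcels, tr)

    ref = store.load_parcels(subjects[0])
    ref_r = len(ref)
    for sid in subjects:
        n_cols = len(pd.read_csv(store.cortex_paths[sid], sep="\t", comment="#", nrows=1).columns)
        if n_cols != ref_r:
            raise ValueError(
                f"subject {sid}: cortical matrix has {n_cols} parcels, expected {ref_r}"
            )
        pr = store.load_parcels(sid)
        if not pr["parcel_id"].equals(ref["parcel_id"]):
            raise ValueError(f"subject {sid}: parcel ordering differs from {subjects[0]}")
    return store


def _write_matrix(path: Path, data: np.ndarray, header_comment: str | None = None) -> None:
    cols = [f"p{j:03d}" for j in range(data.shape[1])]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(data, columns=cols).to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def write_cohort(cfg, out_dir: str | Path) -> Path:
    """Generate a synthetic cohort and persist it; returns the manifest path.

    Ground truth (planted events, velocity, module labels) is written
    alongside each subject as TSV/JSON so parameter-recovery analyses can
    reload it.
    """
    from .simulate import generate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subject_ids, data, truths = generate_cohort(cfg)

    first_ts = data[subject_ids[0]][0]
    parcels_path = out_dir / "parcels.tsv"
    with open(parcels_path, "w") as fh:
        fh.write("# parcel metadata; parcel_id is 0-based\n")
        first_ts.parcels.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)

    entries = []
    for sid in subject_ids:
        ts, subcort, nuis, truth = data[sid]
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        _write_matrix(sdir / "cortex.tsv", ts.data, "rows are TRs (0-based), columns parcels")
        sub_frame = pd.DataFrame({**subcort, **nuis})
        sub_frame.to_csv(sdir / "subcortical.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        rows = [
            (etype, int(t0))
            for etype, t0s in truth.event_indices.items()
            for t0 in t0s
        ]
        pd.DataFrame(rows, columns=["type", "t0_index"]).to_csv(
            sdir / "truth_events.tsv", sep="\t", index=False
        )
        with open(sdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "velocity_m_per_s": truth.velocity_m_per_s,
                    "module_assignments": truth.module_assignments.tolist(),
                },
                fh,
            )
        entries.append(
            {
                "id": sid,
                "cortex": f"{sid}/cortex.tsv",
                "subcortical": f"{sid}/subcortical.tsv",
                "parcels": "parcels.tsv",
            }
        )
    manifest = {"tr_seconds": cfg.tr_seconds, "subjects": entries}
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


# ---------------------------------------------------------------------------
# pipeline outputs


def write_results(result, out_dir: str | Path) -> list[Path]:
    """Write any pipeline output type to ``out_dir``; returns written paths.

    Layouts (all t0/lag indices 0-based):
      PhasicEventSet       -> events.tsv + events_meta.json
      EnergyLandscape      -> landscape_<condition>.tsv (long format)
      WaveFit              -> wave_parcels.tsv + wave_summary.json
      EventLockedResponse  -> response_<label>.tsv
      NullDistribution     -> null_distribution.tsv + null_meta.json
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create output directory {out_dir}: {err}") from err

    if isinstance(result, PhasicEventSet):
        paths = [out_dir / "events.tsv", out_dir / "events_meta.json"]
        result.events.to_csv(paths[0], sep="\t", index=False, float_format=FLOAT_FMT)
        with open(paths[1], "w") as fh:
            json.dump(
                {
                    "accel_sd": result.accel_sd,
                    "sustain_sd": result.sustain_sd,
                    "sustain_window": result.sustain_window,
                    "boundary": result.boundary,
                },
                fh,
            )
        return paths

    if isinstance(result, EnergyLandscape):
        label = result.condition or "landscape"
        path = out_dir / f"landscape_{label}.tsv"
        lag_col = np.repeat(result.lag_grid, len(result.msd_grid))
        msd_col = np.tile(result.msd_grid, len(result.lag_grid))
        frame = pd.DataFrame(
            {
                "lag_tr": lag_col,
                "msd": msd_col,
                "P": result.P.ravel(),
                "E": result.E.ravel(),
                "flagged": result.flagged.ravel().astype(int),
            }
        )
        frame.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# condition={label}\tn={result.n}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)
        return [path]

    if isinstance(result, WaveFit):
        paths = [out_dir / "wave_parcels.tsv", out_dir / "wave_summary.json"]
        pd.DataFrame(
            {
                "parcel": np.arange(len(result.time_to_peak_s)),
                "ttp_s": result.time_to_peak_s,
                "x_mm": result.coords_mm[:, 0],
                "y_mm": result.coords_mm[:, 1],
                "z_mm": result.coords_mm[:, 2],
            }
        ).to_csv(paths[0], sep="\t", index=False, float_format=FLOAT_FMT)
        with open(paths[1], "w") as fh:
            json.dump(
                {
                    "velocity_m_per_s": result.velocity_m_per_s,
                    "direction_sign": result.direction_sign,
                    "fit_r2": result.fit_r2,
                    "slope_s_per_mm": result.slope_s_per_mm,
                },
                fh,
            )
        return paths

    if isinstance(result, EventLockedResponse):
        label = result.signal_label or "signal"
        path = out_dir / f"response_{label}.tsv"
        frame = pd.DataFrame(
            {
                "lag_tr": result.lags,
                "mean": result.mean,
                "sem": result.sem,
            }
        )
        if result.null_ci_low is not None:
            frame["null_ci_low"] = result.null_ci_low
            frame["null_ci_high"] = result.null_ci_high
        with open(path, "w") as fh:
            fh.write(f"# signal={label}\tlow_power={int(result.low_power)}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)
        return [path]

    if isinstance(result, NullDistribution):
        paths = [out_dir / "null_distribution.tsv", out_dir / "null_meta.json"]
        pd.DataFrame({"sample": result.samples}).to_csv(
            paths[0], sep="\t", index=False, float_format=FLOAT_FMT
        )
        with open(paths[1], "w") as fh:
            json.dump(
                {
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "n_perm": result.n_perm,
                    "exclusion_halfwidth": result.exclusion_halfwidth,
                },
                fh,
            )
        return paths

    raise TypeError(f"unsupported result type: {type(result).__name__}")


def read_events(out_dir: str | Path) -> PhasicEventSet:
    out_dir = Path(out_dir)
    events = pd.read_csv(out_dir / "events.tsv", sep="\t", float_precision="round_trip")
    if events.empty:
        events = pd.DataFrame(columns=list(PhasicEventSet.COLUMNS))
    with open(out_dir / "events_meta.json") as fh:
        meta = json.load(fh)
    return PhasicEventSet(events, **meta)


def read_landscape(path: str | Path) -> EnergyLandscape:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
        meta = dict(kv.split("=") for kv in header.split("\t"))
        frame = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    lag_grid = np.unique(frame["lag_tr"].to_numpy())
    msd_grid = np.unique(frame["msd"].to_numpy())
    shape = (len(lag_grid), len(msd_grid))
    return EnergyLandscape(
        msd_grid=msd_grid,
        lag_grid=lag_grid,
        P=frame["P"].to_numpy().reshape(shape),
        E=frame["E"].to_numpy().reshape(shape),
        n=int(meta["n"]),
        condition=meta["condition"],
        flagged=frame["flagged"].to_numpy().reshape(shape).astype(bool),
    )


def read_event_locked_response(path: str | Path) -> EventLockedResponse:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
        meta = dict(kv.split("=") for kv in header.split("\t"))
        frame = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return EventLockedResponse(
        lags=frame["lag_tr"].to_numpy(dtype=int),
        mean=frame["mean"].to_numpy(),
        sem=frame["sem"].to_numpy(),
        signal_label=meta["signal"],
        null_ci_low=frame["null_ci_low"].to_numpy() if "null_ci_low" in frame else None,
        null_ci_high=frame["null_ci_high"].to_numpy() if "null_ci_high" in frame else None,
        low_power=bool(int(meta["low_power"])),
    )


def roi_mean_timeseries(nifti_4d_path: str | Path, mask_path: str | Path) -> np.ndarray:
    """Mean time series of voxels inside a binary NIfTI mask.

    Only used to reduce voxel data to an ROI series; the pipeline proper
    starts from parcellated matrices.  Requires ``nibabel``.
    """
    import nibabel as nib

    img = nib.load(str(nifti_4d_path)).get_fdata()
    mask = nib.load(str(mask_path)).get_fdata() > 0
    if img.shape[:3] != mask.shape:
        raise ValueError("mask and image grids do not match")
    return img[mask].mean(axis=0)
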