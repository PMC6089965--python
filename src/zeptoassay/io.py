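"""Readers and writers for the package's plain-text interchange formats.

All CSVs are comma-separated with "." decimals; lines starting with "#"
are comment headers.  Artifact files written by the pipeline carry a
provenance header with the tool version, seed and a hash of the resolved
configuration, so identical configurations reproduce identical files.

Formats
-------
transfer CSV   : columns vg_V, id_A[, ig_A]; "# vd_V = <value>" header
dose CSV       : columns conc_zM, cum_lam, response, response_sigma
dilution CSV   : columns step, conc_zM, dilution_sigma_zM, poisson_sigma_zM,
                 total_sigma_zM, lam, cum_lam
trajectory XYZ : one block per frame:
                     <n_records>
                     frame <index>
                     <role> <chain_id> <x> <y> <z>   (roles S, O, D, H, A)
                 D, H, A lines come in consecutive triplets; the donor id
                 is taken from the D line and the acceptor id from the A
                 line of the triplet.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counting import DilutionSeries, series_to_frame
from .dose_model import DoseResponseCurve
from .egofet import TransferCurve
from .traj_analysis import ChainTrajectory

__all__ = [
    "FormatError",
    "read_transfer_csv",
    "write_transfer_csv",
    "read_dose_csv",
    "write_dose_csv",
    "write_dilution_csv",
    "read_trajectory_xyz",
    "write_trajectory_xyz",
    "provenance_header",
    "config_hash",
]

TOOL_VERSION = "0.1.0"


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def config_hash(config: dict) -> str:
    """Short deterministic hash of a resolved configuration mapping."""
    dumped = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(dumped.encode()).hexdigest()[:12]


def provenance_header(seed=None, config: dict | None = None, extra: dict | None = None) -> str:
    """Comment header lines with tool version, seed and config hash."""
    lines = [f"# zeptoassay v{TOOL_VERSION}"]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    if config is not None:
        lines.append(f"# config_sha = {config_hash(config)}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k} = {v}")
    return "\n".join(lines) + "\n"


def _read_commented_csv(path, required: list[str]) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict = {}
    body: list[str] = []
    body_line_numbers: list[int] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if raw.startswith("#"):
            stripped = raw.lstrip("#").strip()
            if "=" in stripped:
                k, _, v = stripped.partition("=")
                meta[k.strip()] = v.strip()
            continue
        if raw.strip() == "":
            continue
        body.append(raw)
        body_line_numbers.append(lineno)
    if not body:
        raise FormatError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("\n".join(body)))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise FormatError(
                f"{path}: non-numeric cell in column {col!r} "
                f"at line {body_line_numbers[row + 1]}"
            )
        df[col] = vals
    df.attrs["line_numbers"] = body_line_numbers[1:]
    return df, meta


def read_transfer_csv(path) -> TransferCurve:
    """Read a transfer curve; validates monotone vg and reports bad lines."""
    df, meta = _read_commented_csv(path, ["vg_V", "id_A"])
    vg = df["vg_V"].to_numpy()
    d = np.diff(vg)
    if len(d) and not (np.all(d > 0) or np.all(d < 0)):
        # first index where monotonicity breaks relative to the initial trend
        trend = 1.0 if d[0] > 0 else -1.0
        bad = int(np.flatnonzero(trend * d <= 0)[0]) + 1
        lineno = df.attrs["line_numbers"][bad]
        raise FormatError(f"{path}: non-monotone vg_V at line {lineno}")
    vd = float(meta.get("vd_V", -0.4))
    curve = TransferCurve(vg=vg, id=df["id_A"].to_numpy(), vd=vd)
    if "ig_A" in df.columns:
        object.__setattr__(curve, "ig", df["ig_A"].to_numpy())
    return curve


def write_transfer_csv(curve: TransferCurve, path, seed=None, config=None) -> None:
    path = Path(path)
    df = pd.DataFrame({"vg_V": curve.vg, "id_A": curve.id})
    ig = getattr(curve, "ig", None)
    if ig is not None:
        df["ig_A"] = ig
    header = provenance_header(seed, config, extra={"vd_V": curve.vd})
    path.write_text(header + df.to_csv(index=False, float_format="%.12g"))


def read_dose_csv(path, noise_mean: float = 0.0, noise_sd: float = 0.0) -> DoseResponseCurve:
    df, meta = _read_commented_csv(path, ["conc_zM", "cum_lam", "response", "response_sigma"])
    return DoseResponseCurve(
        doses=df["cum_lam"].to_numpy(),
        responses=df["response"].to_numpy(),
        sigmas=df["response_sigma"].to_numpy(),
        noise_mean=float(meta.get("noise_mean", noise_mean)),
        noise_sd=float(meta.get("noise_sd", noise_sd)),
    )


def write_dose_csv(
    data: DoseResponseCurve, conc_zm, path, seed=None, config=None
) -> None:
    """Write a dose curve; ``conc_zm`` gives the per-point concentrations."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "conc_zM": np.asarray(conc_zm, dtype=float),
            "cum_lam": data.doses,
            "response": data.responses,
            "response_sigma": data.sigmas,
        }
    )
    header = provenance_header(
        seed, config,
        extra={"noise_mean": data.noise_mean, "noise_sd": data.noise_sd},
    )
    path.write_text(header + df.to_csv(index=False, float_format="%.12g"))


def write_dilution_csv(series: DilutionSeries, path, seed=None, config=None) -> None:
    path = Path(path)
    df = series_to_frame(series)
    header = provenance_header(seed, config, extra={"per_step_cv": series.per_step_cv})
    path.write_text(header + df.to_csv(index=False, float_format="%.12g"))


def write_trajectory_xyz(traj: ChainTrajectory, path, seed=None, config=None) -> None:
    path = Path(path)
    out = [provenance_header(seed, config).rstrip("\n")]
    n_pairs = len(traj.hbond_pairs)
    n_records = 2 * traj.n_chains + 3 * n_pairs
    for f in range(traj.n_frames):
        out.append(str(n_records))
        out.append(f"frame {f}")
        for j, cid in enumerate(traj.chain_ids):
            x, y, z = traj.sulfur[f, j]
            out.append(f"S {cid} {x:.6f} {y:.6f} {z:.6f}")
            x, y, z = traj.oxygen[f, j]
            out.append(f"O {cid} {x:.6f} {y:.6f} {z:.6f}")
        for p, (dnr, acc) in enumerate(traj.hbond_pairs):
            for role, arr, cid in (
                ("D", traj.hbond_donor, dnr),
                ("H", traj.hbond_hydrogen, dnr),
                ("A", traj.hbond_acceptor, acc),
            ):
                x, y, z = arr[f, p]
                out.append(f"{role} {cid} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")


def read_trajectory_xyz(path) -> ChainTrajectory:
    """Parse the XYZ-like trajectory format (see module docstring)."""
    path = Path(path)
    lines = [
        (no, ln.strip())
        for no, ln in enumerate(path.read_text().splitlines(), start=1)
        if ln.strip() and not ln.startswith("#")
    ]
    frames: list[dict] = []
    i = 0
    while i < len(lines):
        no, count_line = lines[i]
        try:
            n_records = int(count_line)
        except ValueError:
            raise FormatError(f"{path}: expected a record count at line {no}") from None
        header_no, header = lines[i + 1]
        if not header.startswith("frame"):
            raise FormatError(f"{path}: expected 'frame <i>' at line {header_no}")
        records = lines[i + 2 : i + 2 + n_records]
        if len(records) < n_records:
            raise FormatError(f"{path}: truncated frame starting at line {no}")
        frame = {"S": {}, "O": {}, "triplets": []}
        pending: list[tuple[str, str, np.ndarray]] = []
        for rec_no, rec in records:
            parts = rec.split()
            if len(parts) != 5:
                raise FormatError(f"{path}: malformed record at line {rec_no}")
            role, cid = parts[0], parts[1]
            try:
                pos = np.array([float(p) for p in parts[2:]])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric coordinate at line {rec_no}"
                ) from None
            if role in ("S", "O"):
                frame[role][cid] = pos
            elif role in ("D", "H", "A"):
                pending.append((role, cid, pos))
                if len(pending) == 3:
                    roles = [p[0] for p in pending]
                    if roles != ["D", "H", "A"]:
                        raise FormatError(
                            f"{path}: triplet near line {rec_no} is not D,H,A ordered"
                        )
                    frame["triplets"].append(
                        ((pending[0][1], pending[2][1]),
                         pending[0][2], pending[1][2], pending[2][2])
                    )
                    pending = []
            else:
                raise FormatError(f"{path}: unknown role {role!r} at line {rec_no}")
        if pending:
            raise FormatError(f"{path}: incomplete D,H,A triplet in frame at line {no}")
        frames.append(frame)
        i += 2 + n_records
    if not frames:
        raise FormatError(f"{path}: no frames")

    chain_ids = tuple(frames[0]["S"].keys())
    pairs = tuple(t[0] for t in frames[0]["triplets"])
    n_frames, n_chains, n_pairs = len(frames), len(chain_ids), len(pairs)
    sulfur = np.empty((n_frames, n_chains, 3))
    oxygen = np.empty((n_frames, n_chains, 3))
    for f, frame in enumerate(frames):
        if tuple(frame["S"].keys()) != chain_ids:
            raise FormatError(f"{path}: chain set changes at frame {f}")
        for j, cid in enumerate(chain_ids):
            sulfur[f, j] = frame["S"][cid]
            oxygen[f, j] = frame["O"][cid]
    if n_pairs:
        donor = np.empty((n_frames, n_pairs, 3))
        hydrogen = np.empty((n_frames, n_pairs, 3))
        acceptor = np.empty((n_frames, n_pairs, 3))
        for f, frame in enumerate(frames):
            if tuple(t[0] for t in frame["triplets"]) != pairs:
                raise FormatError(f"{path}: H-bond pair set changes at frame {f}")
            for p, (_, d, h, a) in enumerate(frame["triplets"]):
                donor[f, p], hydrogen[f, p], acceptor[f, p] = d, h, a
    else:
        donor = hydrogen = acceptor = None
    return ChainTrajectory(
        sulfur=sulfur,
        oxygen=oxygen,
        chain_ids=chain_ids,
        hbond_donor=donor,
        hbond_hydrogen=hydrogen,
        hbond_acceptor=acceptor,
        hbond_pairs=pairs,
    )
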