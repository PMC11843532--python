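"""Plain-text readers/writers for all artifact formats.

Everything is delimited text plus JSON: decay and IRF histograms as
commented CSV, phasor/reference/label/kinetics tables as headed CSV, run
configurations as JSON.  All formats round-trip losslessly.

Decay CSV layout::

    # kind=decay            (or irf)
    # rep_rate_mhz=80.0
    # n_bins=4096
    # window_ns=12.5
    time_ns,counts

Counts are integers for decays and reals for IRFs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig, DecayHistogram, IRFProfile
from .phasor import PhasorPoint
from .regions import ReferencePhasorSet, RegionLabel

__all__ = [
    "read_decay_csv",
    "write_decay_csv",
    "write_phasor_csv",
    "read_phasor_csv",
    "write_reference_csv",
    "read_reference_csv",
    "write_labels_csv",
    "write_pixel_collection",
    "read_pixel_collection",
    "RunConfig",
]


class DecayCSVError(ValueError):
    """Malformed decay/IRF CSV; the message names the offending line."""


def write_decay_csv(obj: DecayHistogram | IRFProfile, path: str | Path,
                    config: AcquisitionConfig | None = None) -> None:
    """Write a decay histogram or IRF profile as commented CSV.

    For an :class:`IRFProfile` the acquisition ``config`` it is bound to must
    be passed explicitly (an IRF does not carry one).
    """
    path = Path(path)
    if isinstance(obj, DecayHistogram):
        kind, cfg = "decay", obj.config
        values = obj.counts
        fmt = "%d" if np.issubdtype(np.asarray(values).dtype, np.integer) else "%.17g"
        centers = obj.bin_centers
    elif isinstance(obj, IRFProfile):
        if config is None:
            raise ValueError("writing an IRF requires the acquisition config")
        kind, cfg = "irf", config
        values, fmt, centers = obj.weights, "%.17g", obj.bin_centers
    else:
        raise TypeError("expected DecayHistogram or IRFProfile")
    with open(path, "w") as fh:
        fh.write(f"# kind={kind}\n")
        fh.write(f"# rep_rate_mhz={cfg.rep_rate_mhz!r}\n")
        fh.write(f"# n_bins={cfg.n_bins}\n")
        fh.write(f"# window_ns={cfg.window_ns!r}\n")
        fh.write("time_ns,counts\n")
        for t, v in zip(centers, values):
            fh.write(f"{float(t)!r},{fmt % v}\n")


def read_decay_csv(path: str | Path) -> DecayHistogram | IRFProfile:
    """Read a decay or IRF CSV; errors name the offending line number."""
    path = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        lines = fh.readlines()
    data_started = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if data_started:
                raise DecayCSVError(f"line {lineno}: comment after data start")
            if "=" not in line:
                raise DecayCSVError(f"line {lineno}: malformed header comment")
            key, _, val = line.lstrip("# ").partition("=")
            header[key.strip()] = val.strip()
            continue
        if line.lower().startswith("time_ns"):
            data_started = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise DecayCSVError(f"line {lineno}: expected two columns")
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError as exc:
            raise DecayCSVError(f"line {lineno}: {exc}") from None

    for key in ("kind", "rep_rate_mhz", "n_bins", "window_ns"):
        if key not in header:
            raise DecayCSVError(f"missing header field '# {key}='")
    kind = header["kind"]
    if kind not in ("decay", "irf"):
        raise DecayCSVError(f"unknown kind {kind!r}")
    cfg = AcquisitionConfig(
        rep_rate_mhz=float(header["rep_rate_mhz"]),
        n_bins=int(header["n_bins"]),
        window_ns=float(header["window_ns"]),
    )
    t = np.asarray(times)
    v = np.asarray(values)
    if t.size != cfg.n_bins:
        raise DecayCSVError(
            f"header n_bins={cfg.n_bins} but {t.size} data rows present"
        )
    if t.size and (t[-1] >= cfg.window_ns or t[0] < 0):
        raise DecayCSVError("time column inconsistent with header window_ns")
    if kind == "irf":
        return IRFProfile(bin_centers=t, weights=v)
    neg = np.nonzero(v < 0)[0]
    if neg.size:
        # +2: one header line offset handled below by locating the row
        row_line = _data_line_number(lines, int(neg[0]))
        raise DecayCSVError(f"line {row_line}: negative count")
    if np.any(v != np.round(v)):
        bad = int(np.nonzero(v != np.round(v))[0][0])
        raise DecayCSVError(f"line {_data_line_number(lines, bad)}: non-integer count")
    return DecayHistogram(bin_centers=t, counts=v.astype(np.int64), config=cfg)


def _data_line_number(lines: list[str], data_index: int) -> int:
    """1-based file line number of the data row with index ``data_index``."""
    seen = -1
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s or s.startswith("#") or s.lower().startswith("time_ns"):
            continue
        seen += 1
        if seen == data_index:
            return lineno
    return len(lines)


def write_pixel_collection(pixels, directory: str | Path) -> None:
    """Write per-pixel decays as a directory of decay CSVs + JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = []
    for i, pixel in enumerate(pixels):
        pid = f"pixel_{i:05d}"
        write_decay_csv(pixel, directory / f"{pid}.csv")
        ids.append(pid)
    with open(directory / "manifest.json", "w") as fh:
        json.dump({"pixel_ids": ids}, fh, indent=2)


def read_pixel_collection(directory: str | Path) -> list[DecayHistogram]:
    """Read a pixel collection written by :func:`write_pixel_collection`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    pixels = []
    for pid in manifest["pixel_ids"]:
        obj = read_decay_csv(directory / f"{pid}.csv")
        if not isinstance(obj, DecayHistogram):
            raise ValueError(f"{pid} is not a decay histogram")
        pixels.append(obj)
    return pixels


# ---------------------------------------------------------------------------
# Phasor / reference / label tables
# ---------------------------------------------------------------------------

def write_phasor_csv(points: list[PhasorPoint], path: str | Path) -> None:
    rows = [
        {
            "meta": json.dumps(p.meta, sort_keys=True, default=str),
            "g": p.g,
            "s": p.s,
            "g_err": np.nan if p.g_err is None else p.g_err,
            "s_err": np.nan if p.s_err is None else p.s_err,
        }
        for p in points
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_phasor_csv(path: str | Path) -> list[PhasorPoint]:
    df = pd.read_csv(path)
    pts = []
    for _, row in df.iterrows():
        pts.append(
            PhasorPoint(
                g=float(row["g"]),
                s=float(row["s"]),
                g_err=None if pd.isna(row["g_err"]) else float(row["g_err"]),
                s_err=None if pd.isna(row["s_err"]) else float(row["s_err"]),
                meta=json.loads(row["meta"]) if isinstance(row.get("meta"), str) else {},
            )
        )
    return pts


def write_reference_csv(ref: ReferencePhasorSet, path: str | Path) -> None:
    rows = []
    conc = ref.concentrations or [np.nan] * len(ref.points)
    for c, p in zip(conc, ref.points):
        rows.append(
            {"label": ref.label, "concentration_uM": c, "g": p.g, "s": p.s,
             "g_err": p.g_err, "s_err": p.s_err}
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_reference_csv(path: str | Path) -> ReferencePhasorSet:
    df = pd.read_csv(path)
    labels = df["label"].unique()
    if len(labels) != 1:
        raise ValueError("reference CSV must contain exactly one label")
    points = [
        PhasorPoint(g=r.g, s=r.s, g_err=r.g_err, s_err=r.s_err)
        for r in df.itertuples()
    ]
    return ReferencePhasorSet(
        label=str(labels[0]),
        points=points,
        concentrations=[float(c) for c in df["concentration_uM"]],
    )


def write_labels_csv(labels: list[RegionLabel], path: str | Path) -> None:
    rows = [
        {
            "segment_start": lab.segment[0],
            "segment_end": lab.segment[1],
            "label": lab.label,
            "overlap_fibril": lab.overlap_fibril,
            "overlap_oligomer": lab.overlap_oligomer,
            "tie": lab.tie,
        }
        for lab in labels
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run.

    Either a ``preset`` name or explicit rates + optical profile; plus
    acquisition, sampling, photon-budget, classification and seeding choices.
    """

    preset: str = "wt_like"
    t_start_h: float = 0.0
    t_end_h: float = 96.0
    dt_h: float = 0.5
    m0_uM: float = 100.0
    photons_per_timepoint: int = 150_000
    rep_rate_mhz: float = 80.0
    n_bins: int = 1024
    irf_fwhm_ns: float = 0.2
    irf_center_ns: float = 1.0
    seed: int = 0
    fit_max_n: int = 2
    n_phasor_replicates: int = 50
    window: int = 5
    overlap_threshold: float = 0.60
    deviation_threshold: float = 0.40
    reference_photons: int = 100_000
    reference_fraction_jitter: float = 0.1
    intensity_noise_sigma: float = 0.0
    out_dir: str = "rotorlife_run"
    explicit_rates: dict | None = None
    ingest_dir: str | None = None

    def timepoints(self) -> np.ndarray:
        if self.t_end_h <= self.t_start_h or self.dt_h <= 0:
            raise ValueError("invalid time axis")
        n = int(round((self.t_end_h - self.t_start_h) / self.dt_h)) + 1
        tp = self.t_start_h + self.dt_h * np.arange(n)
        if tp.size == 0:
            raise ValueError("no timepoints")
        return tp

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)
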