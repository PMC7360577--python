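"""Serialization of fluence fields and dose maps: float32 raw volumes with
sidecar text metadata, plus CSV summaries."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .dosimetry import DoseMap
from .uncollided import FluenceField

__all__ = ["write_field", "read_field", "write_dose", "read_dose"]


def _write_raw(arr: np.ndarray, path: Path) -> None:
    np.ascontiguousarray(arr, dtype="<f4").tofile(path)


def _meta(path: Path, shape, extra=None) -> None:
    with open(path, "w") as fh:
        fh.write("shape: " + " ".join(str(s) for s in shape) + "\n")
        fh.write("dtype: float32\norder: C\n")
        for k, v in (extra or {}).items():
            fh.write(f"{k}: {v}\n")


def write_field(field: FluenceField, outdir, stem: str = "fluence") -> None:
    """One raw volume per (group, component) + metadata + per-group CSV sums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    G = field.G
    for g in range(G):
        _write_raw(field.uncollided[g], outdir / f"{stem}_g{g}_uncollided.raw")
        _write_raw(field.collided[g], outdir / f"{stem}_g{g}_collided.raw")
    _meta(outdir / f"{stem}.meta", field.uncollided.shape[1:], {"groups": G})
    with open(outdir / f"{stem}_summary.csv", "w") as fh:
        fh.write("group,uncollided_sum,collided_sum\n")
        for g in range(G):
            fh.write(f"{g},{field.uncollided[g].sum():.9e},{field.collided[g].sum():.9e}\n")


def read_field(outdir, stem: str = "fluence") -> FluenceField:
    outdir = Path(outdir)
    meta = {}
    with open(outdir / f"{stem}.meta") as fh:
        for ln in fh:
            if ":" in ln:
                k, v = ln.split(":", 1)
                meta[k.strip()] = v.strip()
    shape = tuple(int(x) for x in meta["shape"].split())
    G = int(meta["groups"])
    unc = np.stack(
        [np.fromfile(outdir / f"{stem}_g{g}_uncollided.raw", dtype="<f4").reshape(shape) for g in range(G)]
    )
    col = np.stack(
        [np.fromfile(outdir / f"{stem}_g{g}_collided.raw", dtype="<f4").reshape(shape) for g in range(G)]
    )
    return FluenceField(unc, col)


def write_dose(dose: DoseMap, outdir, stem: str = "dose") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_raw(dose.dose, outdir / f"{stem}.raw")
    _meta(outdir / f"{stem}.meta", dose.dose.shape)
    np.ascontiguousarray(dose.air_mask, dtype="<i2").tofile(outdir / f"{stem}_air.raw")


def read_dose(outdir, stem: str = "dose") -> DoseMap:
    outdir = Path(outdir)
    meta = {}
    with open(outdir / f"{stem}.meta") as fh:
        for ln in fh:
            if ":" in ln:
                k, v = ln.split(":", 1)
                meta[k.strip()] = v.strip()
    shape = tuple(int(x) for x in meta["shape"].split())
    d = np.fromfile(outdir / f"{stem}.raw", dtype="<f4").reshape(shape).astype(float)
    air = np.fromfile(outdir / f"{stem}_air.raw", dtype="<i2").reshape(shape).astype(bool)
    return DoseMap(d, air)
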