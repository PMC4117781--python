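"""Readers/writers for the interchange formats and the run configuration.

Formats:

* ``.dat`` -- 3-column ASCII (q, I, sigma) with ``#`` metadata headers;
  the interchange format for all 1-D profiles.
* PDB subset -- one HETATM record per bead, chain A = DNA, chain B =
  protein (written/read through ``gemmi``).
* PDDF ``.dat`` -- 2-column ASCII (r, P) with a JSON sidecar carrying
  dmax, rg, i0, chi2, alpha.
* HDF5 time series -- datasets /q, /I (n_t x n_q), /sigma, /time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import gemmi
import h5py
import numpy as np
from pydantic import BaseModel, ConfigDict

from .conformers import DNA, PROTEIN, Conformer
from .ift import PDDF
from .kinetics import TimeSeries
from .scatter import ScatteringProfile

__all__ = [
    "read_dat", "write_dat",
    "read_pdb_beads", "write_pdb_beads",
    "read_pddf", "write_pddf",
    "read_timeseries_h5", "write_timeseries_h5",
    "read_detector_image", "write_detector_image",
    "read_geometry", "write_geometry",
    "RunConfig", "config_hash",
]

_META_SCALARS = (int, float, str, bool)


def write_dat(path, profile: ScatteringProfile) -> None:
    path = Path(path)
    lines = []
    for key, val in profile.meta.items():
        if isinstance(val, _META_SCALARS):
            lines.append(f"# {key}: {val}")
    lines.append("# q(1/A)  I(a.u.)  sigma")
    for q, I, s in zip(profile.q, profile.I, profile.sigma):
        lines.append(f"{q:.6e} {I:.6e} {s:.6e}")
    path.write_text("\n".join(lines) + "\n")


def _parse_meta_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text in ("True", "False"):
        return text == "True"
    return text


def read_dat(path) -> ScatteringProfile:
    path = Path(path)
    meta = {}
    rows = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = _parse_meta_value(val.strip())
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 columns, "
                             f"got {len(parts)}")
        try:
            vals = [float(x) for x in parts]
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: non-numeric value") from err
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"{path}:{ln}: non-finite value")
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    return ScatteringProfile(arr[:, 0], arr[:, 1], arr[:, 2], meta=meta)


def write_pdb_beads(path, c: Conformer) -> None:
    st = gemmi.Structure()
    st.name = c.name or "conformer"
    model = gemmi.Model("1")
    chains = {}
    for label in (DNA, PROTEIN):
        chains[label] = gemmi.Chain("A" if label == DNA else "B")
    for i, (xyz, label) in enumerate(zip(c.beads, c.labels), start=1):
        res = gemmi.Residue()
        res.name = "BDN" if label == DNA else "BPR"
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "H"
        atom = gemmi.Atom()
        atom.name = "C1"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        chains[str(label)].add_residue(res)
    for ch in chains.values():
        if len(ch) > 0:
            model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc_lines = [
        f"REMARK   6 bp_total {c.bp_total} released_left {c.released_left} "
        f"released_right {c.released_right}",
    ]
    Path(path).write_text("\n".join(doc_lines) + "\n"
                          + st.make_pdb_string())


def read_pdb_beads(path) -> Conformer:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    bp_total = released_left = released_right = 0
    for line in text.splitlines():
        if line.startswith("REMARK   6 bp_total"):
            parts = line.split()
            bp_total = int(parts[3])
            released_left = int(parts[5])
            released_right = int(parts[7])
    st = gemmi.read_pdb_string(text)
    beads, labels = [], []
    for model in st:
        for chain in model:
            label = DNA if chain.name == "A" else PROTEIN
            for res in chain:
                for atom in res:
                    beads.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    labels.append(label)
    if not beads:
        raise ValueError(f"{path}: no bead records")
    if bp_total == 0:
        bp_total = sum(1 for l in labels if l == DNA) // 2
    return Conformer(np.asarray(beads), np.asarray(labels), bp_total,
                     released_left, released_right, name=path.stem)


def write_pddf(path, d: PDDF) -> None:
    path = Path(path)
    lines = ["# r(A)  P(r)"]
    for r, p in zip(d.r, d.p):
        lines.append(f"{r:.6e} {p:.6e}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "dmax": d.dmax, "rg": d.rg, "i0": d.i0, "chi2": d.chi2,
        "alpha": d.alpha, "qmax_used": d.qmax_used, "flags": list(d.flags),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_pddf(path) -> PDDF:
    path = Path(path)
    arr = np.loadtxt(path)
    side = json.loads(path.with_suffix(".json").read_text())
    return PDDF(r=arr[:, 0], p=arr[:, 1], dmax=side["dmax"], rg=side["rg"],
                i0=side["i0"], chi2=side.get("chi2", 0.0),
                alpha=side.get("alpha", 0.0),
                qmax_used=side.get("qmax_used", 0.0),
                flags=tuple(side.get("flags", [])))


def write_timeseries_h5(path, ts: TimeSeries) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("q", data=ts.q)
        fh.create_dataset("I", data=np.vstack([f.I for f in ts.frames]))
        fh.create_dataset("sigma",
                          data=np.vstack([f.sigma for f in ts.frames]))
        fh.create_dataset("time", data=ts.times)
        fh.attrs["frame_duration"] = ts.frame_duration


def read_timeseries_h5(path) -> TimeSeries:
    with h5py.File(path, "r") as fh:
        q = fh["q"][...]
        I = fh["I"][...]
        S = fh["sigma"][...]
        times = fh["time"][...]
        dur = float(fh.attrs.get("frame_duration", 0.02))
    frames = [ScatteringProfile(q, I[i], S[i], meta={"time": float(times[i])})
              for i in range(len(times))]
    return TimeSeries(frames, times, frame_duration=dur)


def write_detector_image(path, img) -> None:
    """Write a detector frame: TIFF for .tif/.tiff, whitespace text
    grid otherwise."""
    from .reduce import DetectorImage  # noqa: F401  (type of ``img``)

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.counts.astype(np.float32))
    else:
        np.savetxt(path, img.counts, fmt="%.6g")


def read_detector_image(path, exposure: float = 0.017,
                        beam_monitor: float = 1.0):
    """Read a detector frame (TIFF or text grid) into a DetectorImage."""
    from .reduce import DetectorImage

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        counts = np.asarray(tifffile.imread(path), dtype=float)
    else:
        counts = np.loadtxt(path)
    return DetectorImage(counts=counts, exposure=exposure,
                         beam_monitor=beam_monitor)


def write_geometry(path, geometry) -> None:
    Path(path).write_text(json.dumps({
        "beam_center": list(geometry.beam_center),
        "pixel_size": geometry.pixel_size,
        "sample_detector_distance": geometry.sample_detector_distance,
        "wavelength": geometry.wavelength}, indent=1))


def read_geometry(path):
    from .reduce import ReductionGeometry

    d = json.loads(Path(path).read_text())
    return ReductionGeometry(beam_center=tuple(d["beam_center"]),
                             pixel_size=d["pixel_size"],
                             sample_detector_distance=d[
                                 "sample_detector_distance"],
                             wavelength=d["wavelength"])


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    # q-grid
    q_points: int = 200
    qmin: float = 0.007
    qmax: float = 0.25
    # contrast
    rho_solv0: float = 0.334
    rho_prot: float = 0.42
    rho_dna: float = 0.55
    sucrose_match: float = 0.50
    # pool
    bp_total: int = 147
    # IFT protocol
    chi2_slack: float = 1.2
    stability_tol: float = 0.05
    tail_fraction: float = 0.10
    # kinetics thresholds
    svd_ratio: float = 3.0
    svd_autocorr: float = 0.6
    model_improvement: float = 0.15


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
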