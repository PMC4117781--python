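"""Synthetic beamline data with known ground truth.

Every input the analysis pipeline consumes can be generated here:
equilibrium NaCl titrations of nucleosome core particles at 0% and 50%
sucrose, stopped-flow disassembly time series following sequential
first-order kinetic schemes, and Poisson-sampled detector frames.  All
randomness is seeded and all generating parameters are recorded in the
returned manifests, so downstream tests read truth from the manifest
rather than from constants.

Default kinetic schemes encode the two disassembly modes observed for
strong (Widom 601) and weak (5S) positioning sequences: the 601
particle opens into a long-lived "J"-shaped intermediate that holds for
~0.2 s before dissociating at 0.74 /s, while the 5S particle decays in
two phases (41.6 /s then 1.13 /s) with no stable intermediate.  Species
are rigid bead composites; a bound histone core scatters coherently
with its DNA, dissociated parts add incoherently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conformers import (Conformer, HelixParams, PoolSpec, PROTEIN,
                         build_duplex, build_protein_core, build_released,
                         generate_pool, with_protein_core)
from .kinetics import TimeSeries
from .reduce import DetectorImage, ReductionGeometry
from .scatter import (ContrastModel, ScatteringProfile, Solvent,
                      debye_profile, default_qgrid)

__all__ = [
    "NoiseModel",
    "Species",
    "KineticScheme",
    "scheme_601",
    "scheme_5s",
    "species_fractions",
    "simulate_equilibrium_series",
    "simulate_disassembly",
    "render_detector_images",
    "fixture_bundle",
    "DEFAULT_SALT_MAPPING",
]

BEAD_SMEAR_SIGMA = 1.5  # A, Gaussian bead form factor in synthetic profiles


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: relative Gaussian on 1-D profiles, Poisson
    statistics for rendered images, optional flat buffer background."""

    relative_gaussian: float = 0.02
    poisson_flux: float = 1.0
    buffer_level: float = 0.0

    def __post_init__(self) -> None:
        if (self.relative_gaussian < 0 or self.poisson_flux < 0
                or self.buffer_level < 0):
            raise ValueError("noise parameters must be >= 0")


@dataclass
class Species:
    """One kinetic species: coherent particles that scatter independently."""

    name: str
    particles: list

    def profile(self, qgrid, solvent, model) -> np.ndarray:
        total = np.zeros(len(qgrid))
        for particle in self.particles:
            try:
                p = debye_profile(particle, qgrid, solvent, model,
                                  smear_sigma=BEAD_SMEAR_SIGMA)
            except ValueError:
                continue  # particle fully contrast-matched (e.g. protein
                # at the sucrose match point) contributes nothing
            total += p.I
        return total


@dataclass
class KineticScheme:
    """Sequential first-order chain S0 -> S1 -> ... with optional hold.

    ``rates`` has one entry per arrow (1/s).  ``lag`` holds the system
    in S0 for a fixed time before the chain starts (used for the
    metastable 601 intermediate).
    """

    name: str
    species: list
    rates: np.ndarray
    lag: float = 0.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.species) < 2:
            raise ValueError("need at least 2 species")
        if len(self.rates) != len(self.species) - 1:
            raise ValueError("need one rate per transition")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be > 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")


def species_fractions(scheme: KineticScheme, t: np.ndarray) -> np.ndarray:
    """(n_species, n_t) occupancies of the sequential chain (closed form).

    Bateman solution with distinct rates; fractions sum to 1 exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    u = np.clip(t - scheme.lag, 0.0, None)
    k = scheme.rates
    n = len(scheme.species)
    out = np.zeros((n, len(u)))
    # species i (0-based, i < n-1): Bateman sum over the first i+1 decays
    for i in range(n - 1):
        ks = k[: i + 1]
        acc = np.zeros_like(u)
        for j, kj in enumerate(ks):
            denom = np.prod([kl - kj for l, kl in enumerate(ks) if l != j])
            coef = np.prod(ks[:-1]) / denom if len(ks) > 1 else 1.0
            acc += coef * np.exp(-kj * u)
        out[i] = acc
    out[n - 1] = 1.0 - out[: n - 1].sum(axis=0)
    return out


def _core(params: HelixParams | None = None) -> Conformer:
    params = params or HelixParams()
    beads = build_protein_core(params)
    return Conformer(beads, np.full(len(beads), PROTEIN), bp_total=0,
                     name="histone_core")


def scheme_601(params: HelixParams | None = None,
               rate: float = 0.74, lag: float = 0.2) -> KineticScheme:
    """601-NCP disassembly: long-lived J intermediate with bound core,
    then single-exponential dissociation into free DNA + free protein.

    The wrapped-to-J opening completes within the mixing dead time, so
    the first observable species is already the J intermediate; the
    ``lag`` reproduces its ~200 ms metastable hold.
    """
    params = params or HelixParams()
    j_dna = build_released(147, 74, 0, params, name="J_601")
    j_ncp = with_protein_core(j_dna, params)
    j_ncp.name = "J_601_core"
    free_dna = build_duplex(147, params, name="free_dna_601")
    return KineticScheme(
        name="601",
        species=[Species("J_intermediate", [j_ncp]),
                 Species("dissociated", [free_dna, _core(params)])],
        rates=[rate], lag=lag)


def scheme_5s(params: HelixParams | None = None,
              rates: tuple[float, float] = (41.6, 1.13)) -> KineticScheme:
    """5S-NCP disassembly: fast loss of most histone contacts, then a
    slower final release; no metastable hold."""
    params = params or HelixParams()
    wrapped = with_protein_core(build_released(147, 0, 0, params), params)
    wrapped.name = "wrapped_5s_core"
    open_dna = build_released(147, 92, 0, params, name="open_5s")
    half_core_beads = build_protein_core(params, n_beads=4)
    half_core = Conformer(half_core_beads,
                          np.full(len(half_core_beads), PROTEIN),
                          bp_total=0, name="half_core")
    open_hexasome = Conformer(
        np.concatenate([open_dna.beads, half_core_beads]),
        np.concatenate([open_dna.labels,
                        np.full(len(half_core_beads), PROTEIN)]),
        bp_total=147, released_left=92, released_right=0,
        name="open_5s_halfcore")
    free_dna = build_duplex(147, params, name="free_dna_5s")
    return KineticScheme(
        name="5S",
        species=[Species("wrapped", [wrapped]),
                 Species("open_partial_core", [open_hexasome, half_core]),
                 Species("dissociated", [free_dna, _core(params)])],
        rates=list(rates), lag=0.0)


#: default equilibrium mapping: NaCl (M) -> [(pool member, weight), ...]
DEFAULT_SALT_MAPPING = {
    0.2: [("released_L0_R0", 1.0)],
    0.5: [("released_L0_R0", 0.8), ("released_L18_R0", 0.2)],
    1.0: [("released_L55_R0", 0.45), ("released_L74_R0", 0.35),
          ("released_L28_R28", 0.2)],
    1.5: [("released_L74_R0", 0.4), ("released_L92_R0", 0.35),
          ("released_L46_R46", 0.25)],
    2.0: [("released_L147_R0", 0.85), ("released_L128_R0", 0.15)],
}


def simulate_equilibrium_series(salts=None, sucrose: float = 0.0,
                                mapping: dict | None = None,
                                noise: NoiseModel | None = None,
                                seed: int = 0,
                                params: HelixParams | None = None,
                                qgrid: np.ndarray | None = None,
                                contrast: ContrastModel | None = None,
                                include_core: bool = True):
    """Equilibrium salt series of NCP profiles with recorded truth.

    Each salt maps to an ensemble of pool members; the profile is the
    weighted Debye mixture (with the histone core attached to every
    partially wrapped member when ``include_core``) plus relative
    Gaussian noise.  Returns (profiles, manifest).
    """
    params = params or HelixParams()
    mapping = dict(DEFAULT_SALT_MAPPING if mapping is None else mapping)
    salts = sorted(mapping) if salts is None else list(salts)
    noise = noise or NoiseModel()
    qgrid = default_qgrid() if qgrid is None else qgrid
    rng = np.random.default_rng(seed)
    pool = {c.name: c for c in generate_pool(PoolSpec(), params)}
    profiles = []
    manifest = {"sucrose": sucrose, "seed": seed, "salts": {}}
    for salt in salts:
        ensemble = mapping[salt]
        weights = np.array([w for _, w in ensemble], dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights for {salt} M do not sum to 1")
        solvent = Solvent(sucrose=sucrose, nacl=salt)
        if contrast is None and sucrose > 0:
            # each salt condition has its own matching buffer
            model = ContrastModel.matched_at(sucrose, salt)
        else:
            model = contrast
        I = np.zeros(len(qgrid))
        for (name, w) in ensemble:
            c = pool[name]
            total_rel = c.released_left + c.released_right
            if include_core and total_rel < c.bp_total - 10:
                c = with_protein_core(c, params)
            I += w * debye_profile(c, qgrid, solvent,
                                   model,
                                   smear_sigma=BEAD_SMEAR_SIGMA).I
        sig = noise.relative_gaussian * I
        In = I + sig * rng.standard_normal(len(I)) \
            if noise.relative_gaussian else I
        sig_eff = np.where(sig > 0, sig, 1e-12 * max(I.max(), 1.0))
        profiles.append(ScatteringProfile(
            qgrid, In, sig_eff,
            meta={"nacl": salt, "sucrose": sucrose,
                  "label": f"eq_{salt:.1f}M"}))
        manifest["salts"][str(salt)] = {
            "ensemble": [[n, float(w)] for n, w in ensemble]}
    return profiles, manifest


def simulate_disassembly(scheme: KineticScheme, frame_times=None,
                         sucrose: float = 0.0, nacl: float = 1.88,
                         noise: NoiseModel | None = None, seed: int = 0,
                         qgrid: np.ndarray | None = None,
                         contrast: ContrastModel | None = None):
    """Stopped-flow time series under a kinetic scheme.

    Frame intensities are occupancy-weighted mixtures of the species
    profiles plus relative Gaussian noise.  Returns (TimeSeries,
    manifest) with rates, lag, species names and the exact occupancy
    matrix stored in the manifest.
    """
    noise = noise or NoiseModel()
    if frame_times is None:
        frame_times = np.arange(0.02, 60.0, 0.02)
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(frame_times < 0):
        raise ValueError("frame times must be >= 0")
    qgrid = default_qgrid() if qgrid is None else qgrid
    if contrast is None and sucrose > 0:
        # sucrose level is titrated to the protein match point in the
        # working buffer, as at the beamline
        contrast = ContrastModel.matched_at(sucrose, nacl)
    solvent = Solvent(sucrose=sucrose, nacl=nacl)
    rng = np.random.default_rng(seed)
    basis = np.column_stack([sp.profile(qgrid, solvent, contrast)
                             for sp in scheme.species])
    frac = species_fractions(scheme, frame_times)
    frames = []
    for j, t in enumerate(frame_times):
        I = basis @ frac[:, j]
        sig = noise.relative_gaussian * I
        In = I + sig * rng.standard_normal(len(I)) \
            if noise.relative_gaussian else I
        sig_eff = np.where(sig > 0, sig, 1e-12 * max(I.max(), 1.0))
        frames.append(ScatteringProfile(qgrid, In, sig_eff,
                                        meta={"time": float(t),
                                              "sucrose": sucrose,
                                              "nacl": nacl}))
    dt = float(np.median(np.diff(frame_times))) if len(frame_times) > 1 \
        else 0.02
    ts = TimeSeries(frames, frame_times, frame_duration=dt)
    manifest = {
        "scheme": scheme.name,
        "rates": [float(k) for k in scheme.rates],
        "lag": scheme.lag,
        "species": [sp.name for sp in scheme.species],
        "species_i0": [float(b.max()) for b in basis.T],
        "sucrose": sucrose, "nacl": nacl, "seed": seed,
        "noise": noise.relative_gaussian,
        "fractions": frac.tolist(),
    }
    return ts, manifest


def render_detector_images(profile: ScatteringProfile,
                           geometry: ReductionGeometry | None = None,
                           shape: tuple[int, int] = (195, 195),
                           exposure: float = 0.017,
                           flux: float = 1.0,
                           seed: int = 0,
                           sample: bool = True) -> DetectorImage:
    """Render a radially symmetric detector frame from a 1-D profile.

    Expected counts per pixel are flux * exposure * I(q(pixel)),
    Poisson-sampled unless ``sample`` is False; pixels outside the
    profile's q-range are masked.
    """
    if flux <= 0:
        raise ValueError("flux must be > 0")
    geometry = geometry or ReductionGeometry(
        beam_center=((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0))
    rr = geometry.radius_grid(shape)
    qq = (4.0 * np.pi / geometry.wavelength
          * np.sin(0.5 * np.arctan2(rr, geometry.sample_detector_distance)))
    mask = (qq >= profile.q[0]) & (qq <= profile.q[-1])
    lam = np.zeros(shape)
    lam[mask] = flux * exposure * np.interp(qq[mask], profile.q, profile.I)
    if sample:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = lam
    return DetectorImage(counts=counts, mask=mask, exposure=exposure)


def fixture_bundle(seed: int, outdir) -> Path:
    """Write the canonical synthetic test set to ``outdir``.

    Contents: the 32-member pool as PDB + profiles at 0%/50% sucrose,
    a 5-salt equilibrium series at both contrasts, 601 and 5S time
    series (HDF5) at both contrasts, one rendered detector frame with
    its geometry, and ``manifest.json`` holding every generating
    parameter.  Deterministic for a fixed seed.
    """
    from . import io as ncio
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = HelixParams()
    manifest = {"seed": seed}
    # pool
    pool_dir = outdir / "pool"
    pool_dir.mkdir(exist_ok=True)
    pool = generate_pool(PoolSpec(), params)
    qgrid = default_qgrid()
    manifest["pool"] = []
    for c in pool:
        ncio.write_pdb_beads(pool_dir / f"{c.name}.pdb", c)
        for sucrose in (0.0, 0.5):
            prof = debye_profile(c, qgrid, Solvent(sucrose=sucrose, nacl=1.0),
                                 smear_sigma=BEAD_SMEAR_SIGMA)
            prof.sigma = 0.01 * prof.I
            ncio.write_dat(pool_dir / f"{c.name}_s{int(sucrose*100)}.dat",
                           prof)
        manifest["pool"].append({
            "name": c.name, "released_left": c.released_left,
            "released_right": c.released_right})
    # equilibrium series
    eq_dir = outdir / "equilibrium"
    eq_dir.mkdir(exist_ok=True)
    manifest["equilibrium"] = {}
    for sucrose in (0.0, 0.5):
        profiles, man = simulate_equilibrium_series(
            sucrose=sucrose, seed=seed, params=params)
        for p in profiles:
            ncio.write_dat(
                eq_dir / f"{p.meta['label']}_s{int(sucrose*100)}.dat", p)
        manifest["equilibrium"][f"s{int(sucrose*100)}"] = man
    # time series
    tr_dir = outdir / "timeseries"
    tr_dir.mkdir(exist_ok=True)
    manifest["kinetics"] = {}
    times = np.arange(0.02, 30.0, 0.02)
    for label, scheme in (("601", scheme_601(params)),
                          ("5S", scheme_5s(params))):
        for sucrose in (0.0, 0.5):
            ts, man = simulate_disassembly(scheme, times, sucrose=sucrose,
                                           seed=seed)
            ncio.write_timeseries_h5(
                tr_dir / f"{label}_s{int(sucrose*100)}.h5", ts)
            man.pop("fractions")  # recomputable from rates/lag
            manifest["kinetics"][f"{label}_s{int(sucrose*100)}"] = man
    # detector frame for the 0.2 M equilibrium condition
    det_dir = outdir / "detector"
    det_dir.mkdir(exist_ok=True)
    profiles, _ = simulate_equilibrium_series(
        salts=[0.2], sucrose=0.0, seed=seed,
        noise=NoiseModel(relative_gaussian=0.0), params=params)
    geometry = ReductionGeometry()
    img = render_detector_images(profiles[0], geometry, flux=5e-3, seed=seed)
    np.savetxt(det_dir / "frame.txt", img.counts, fmt="%d")
    (det_dir / "geometry.json").write_text(json.dumps({
        "beam_center": list(geometry.beam_center),
        "pixel_size": geometry.pixel_size,
        "sample_detector_distance": geometry.sample_detector_distance,
        "wavelength": geometry.wavelength}, indent=1))
    manifest["detector"] = {"flux": 5e-3, "profile": "eq_0.2M_s0"}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
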