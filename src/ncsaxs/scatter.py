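"""Three-phase contrast model and Debye scattering profiles.

A protein-DNA complex in solution is approximated as three uniform
electron-density phases: solvent (rho_solv), protein (rho_prot) and DNA
(rho_dna).  Scattering contrast is the excess density of each phase over
the solvent, so raising rho_solv with sucrose until it matches rho_prot
"blanks" the protein and leaves a DNA-only signal; the match point here
is 50% (w/w) sucrose.  NaCl also raises the solvent density slightly, so
contrast depends on both.

Profiles I(q) are computed from bead models by the orientationally
averaged Debye sum

    I(q) = sum_ij w_i w_j sin(q r_ij) / (q r_ij),

with per-bead weights w = (rho_phase - rho_solv) * V_bead, optionally
damped by a Gaussian bead form factor.  I(0) = (sum_i w_i)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist

from .conformers import DNA, PROTEIN, Conformer

__all__ = [
    "ContrastModel",
    "Solvent",
    "ScatteringProfile",
    "default_qgrid",
    "contrast_of",
    "bead_weights",
    "debye_profile",
    "kratky",
    "i0_of",
]

#: spec of the measured band: ~0.007 to 0.25 1/A
QMIN_DEFAULT = 0.007
QMAX_DEFAULT = 0.25


def default_qgrid(n: int = 200, qmin: float = QMIN_DEFAULT,
                  qmax: float = QMAX_DEFAULT) -> np.ndarray:
    """Log-spaced q grid over the instrument band (1/A)."""
    return np.geomspace(qmin, qmax, n)


@dataclass(frozen=True)
class Solvent:
    """Solvent condition: sucrose weight fraction and NaCl molarity."""

    sucrose: float = 0.0
    nacl: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sucrose <= 0.6:
            raise ValueError("sucrose weight fraction must be in [0, 0.6]")
        if self.nacl < 0:
            raise ValueError("NaCl molarity must be >= 0")


@dataclass(frozen=True)
class ContrastModel:
    """Electron densities (e/A^3) and bead volumes (A^3) of the phases.

    rho_solv rises linearly with sucrose weight fraction, calibrated so
    the protein match point sits at 50% sucrose, and with NaCl at
    ``drho_per_molar`` per mol/L.  Volumes convert densities into
    per-bead excess-electron weights: the DNA value is per backbone
    bead (two per bp), the protein value per pseudo-histone bead.
    """

    rho_solv0: float = 0.334
    rho_prot: float = 0.42
    rho_dna: float = 0.55
    sucrose_match: float = 0.50
    drho_per_molar: float = 0.009
    bead_volume_dna: float = 300.0
    bead_volume_prot: float = 13500.0

    def __post_init__(self) -> None:
        if not (self.rho_dna > self.rho_prot >= self.rho_solv0):
            raise ValueError("require rho_dna > rho_prot >= rho_solv(0)")
        if self.bead_volume_dna <= 0 or self.bead_volume_prot <= 0:
            raise ValueError("bead volumes must be > 0")

    def rho_solv(self, solvent: Solvent) -> float:
        slope = (self.rho_prot - self.rho_solv0) / self.sucrose_match
        return (self.rho_solv0 + slope * solvent.sucrose
                + self.drho_per_molar * solvent.nacl)

    @classmethod
    def matched_at(cls, sucrose: float, nacl: float,
                   **overrides) -> "ContrastModel":
        """Contrast model calibrated so the protein match point falls
        exactly at (``sucrose``, ``nacl``).

        Mirrors beamline practice: sucrose is titrated until the
        protein signal vanishes in the working buffer, so the salt
        contribution to solvent density is absorbed into the
        calibration.
        """
        base = cls(**overrides)
        drop = base.rho_prot - base.rho_solv0
        salt_term = base.drho_per_molar * nacl
        if salt_term >= drop:
            raise ValueError("salt alone exceeds the protein contrast; "
                             "no sucrose match point exists")
        match = base.sucrose_match * drop / (drop - salt_term) \
            * (sucrose / base.sucrose_match)
        kwargs = dict(overrides)
        kwargs["sucrose_match"] = match
        return cls(**kwargs)


@dataclass
class ScatteringProfile:
    """1-D scattering profile: I(q) with 1-sigma uncertainties.

    ``meta`` carries condition labels (salt, sucrose, time, label).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValueError("q, I, sigma must have equal length")
        if len(self.q) and (np.any(np.diff(self.q) <= 0)
                            or np.any(self.q <= 0)):
            raise ValueError("q must be strictly increasing and > 0")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")

    def __len__(self) -> int:
        return len(self.q)

    def scaled(self, s: float) -> "ScatteringProfile":
        return replace(self, I=s * self.I, sigma=s * self.sigma)

    def guinier_i0_rg(self, qrg_max: float = 1.3) -> tuple[float, float]:
        """Forward intensity and Rg from a Guinier fit ln I = ln I0 - (q Rg)^2/3.

        Iterates the q-window so that q*Rg <= ``qrg_max``.
        """
        rg = 0.0
        sel = self.q < np.inf
        for _ in range(20):
            qsel = self.q[sel]
            Isel = self.I[sel]
            good = Isel > 0
            if good.sum() < 3:
                raise ValueError("too few points for Guinier fit")
            coef = np.polyfit(qsel[good] ** 2, np.log(Isel[good]), 1)
            slope, intercept = coef
            rg_new = float(np.sqrt(max(-3.0 * slope, 0.0)))
            i0 = float(np.exp(intercept))
            if rg_new <= 0:
                return i0, rg_new
            sel_new = self.q * rg_new <= qrg_max
            if sel_new.sum() < 3:
                sel_new = np.zeros_like(sel)
                sel_new[:3] = True
            if abs(rg_new - rg) < 1e-3 * max(rg_new, 1.0):
                return i0, rg_new
            rg, sel = rg_new, sel_new
        return i0, rg_new


def contrast_of(phase: str, solvent: Solvent,
                model: ContrastModel | None = None) -> float:
    """Excess scattering weight (electrons) of one bead of ``phase``.

    weight = (rho_phase - rho_solv) * V_bead.  Protein weight vanishes
    at the sucrose match point (at 0 M NaCl).
    """
    model = model or ContrastModel()
    rho_s = model.rho_solv(solvent)
    if phase == DNA:
        return (model.rho_dna - rho_s) * model.bead_volume_dna
    if phase == PROTEIN:
        return (model.rho_prot - rho_s) * model.bead_volume_prot
    raise ValueError(f"unknown phase {phase!r}")


def bead_weights(c: Conformer, solvent: Solvent,
                 model: ContrastModel | None = None) -> np.ndarray:
    model = model or ContrastModel()
    w_dna = contrast_of(DNA, solvent, model)
    w_prot = contrast_of(PROTEIN, solvent, model)
    return np.where(c.labels == DNA, w_dna, w_prot)


def debye_profile(c: Conformer, qgrid: np.ndarray | None = None,
                  solvent: Solvent | None = None,
                  model: ContrastModel | None = None,
                  smear_sigma: float | None = None,
                  meta: dict | None = None) -> ScatteringProfile:
    """Theoretical I(q) of a conformer by the Debye sum.

    ``smear_sigma`` applies a Gaussian bead form factor exp(-q^2 s^2)
    to the intensity (point beads when None).  Raises if every bead has
    zero weight (all phases contrast-matched).
    """
    solvent = solvent or Solvent()
    model = model or ContrastModel()
    q = default_qgrid() if qgrid is None else np.asarray(qgrid, dtype=float)
    w = bead_weights(c, solvent, model)
    if np.allclose(w, 0.0):
        raise ValueError("degenerate contrast: all bead weights are zero")
    keep = w != 0.0
    w = w[keep]
    xyz = c.beads[keep]
    d = pdist(xyz)
    iu = np.triu_indices(len(w), k=1)
    ww = w[iu[0]] * w[iu[1]]
    qd = np.outer(q, d)
    with np.errstate(invalid="ignore"):
        sinc = np.where(qd > 0, np.sin(qd) / np.where(qd > 0, qd, 1.0), 1.0)
    I = np.sum(w ** 2) + 2.0 * sinc @ ww
    if smear_sigma:
        I = I * np.exp(-(q * smear_sigma) ** 2)
    m = dict(meta or {})
    m.setdefault("label", c.name)
    m.setdefault("sucrose", solvent.sucrose)
    m.setdefault("nacl", solvent.nacl)
    return ScatteringProfile(q, I, np.zeros_like(I), meta=m)


def i0_of(c: Conformer, solvent: Solvent | None = None,
          model: ContrastModel | None = None) -> float:
    """Forward scattering I(0) = (sum of bead weights)^2."""
    solvent = solvent or Solvent()
    w = bead_weights(c, solvent, model)
    if np.allclose(w, 0.0):
        raise ValueError("degenerate contrast: all bead weights are zero")
    return float(w.sum() ** 2)


def kratky(p: ScatteringProfile) -> ScatteringProfile:
    """Kratky transform (q, I q^2, sigma q^2): peaked for globular
    particles, plateaued for extended chains."""
    return replace(p, I=p.I * p.q ** 2, sigma=p.sigma * p.q ** 2)
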