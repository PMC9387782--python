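"""Quasi-harmonic configurational entropy from a covariance model.

Treating the fitted atomic fluctuations as a multivariate Gaussian, the
mass-weighted covariance C_mw defines effective harmonic modes: each
eigenvalue λ_i (amu·Å²) maps to a frequency ω_i = sqrt(k_B·T/λ_i).  Three
estimators are provided:

``andricioaei_karplus``
    The quantum quasi-harmonic estimator.  With α_i = ħω_i/(k_B·T),
    S = k_B · Σ_i [ α_i/(e^{α_i}-1) - ln(1-e^{-α_i}) ].

``schlitter``
    The determinant upper-bound formula
    S = (k_B/2) · ln det[ I + (k_B·T·e²/ħ²)·C_mw ]  (e = Euler's number),
    evaluated over the retained eigen-subspace.  Schlitter ≥ the quantum
    estimator on any covariance.

``classical_gaussian``
    The classical Gaussian differential entropy (k_B/2)·ln((2πe)^d det C).
    Its absolute value is not unit-invariant; it is meaningful only inside
    an entropy *difference* where the unit-bearing factors cancel, and is
    flagged accordingly.

Modes with eigenvalue at or below ``eig_floor`` (residual rigid-body
modes after fitting) are discarded and counted.

Binding entropy change: ΔS = S_complex - S_apo - S_ligand, reported as
-TΔS (kcal/mol) at the stated temperature, the sign convention in which a
loss of configurational freedom upon binding appears as a positive
free-energy penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants
from .essential_dynamics import CovarianceModel
from .model_io import ValidationError

__all__ = ["ThermoParams", "EntropyResult", "qh_entropy", "entropy_change",
           "qh_entropy_from_eigenvalues"]

METHODS = ("andricioaei_karplus", "schlitter", "classical_gaussian")


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic constants in the internal unit system."""

    T: float = constants.DEFAULT_TEMPERATURE       # K
    k_B: float = constants.K_B_KCAL                # kcal/(mol K)
    k_B_mech: float = constants.K_B_AKMA           # amu Å²/(ps² K)
    hbar: float = constants.HBAR_AKMA              # amu Å²/ps
    coulomb_k: float = constants.COULOMB_K         # kcal Å/(mol e²)

    def __post_init__(self):
        for name in ("T", "k_B", "k_B_mech", "hbar", "coulomb_k"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"ThermoParams.{name} must be positive")


@dataclass
class EntropyResult:
    method: str
    S: float                     # kcal/(mol K); difference for ΔS results
    temperature: float           # K
    n_modes_retained: int
    discarded_modes: int
    minus_T_dS: float | None = None   # kcal/mol, set on ΔS results
    absolute: bool = True        # False for classical_gaussian

    @property
    def TS(self) -> float:
        """T·S in kcal/mol."""
        return self.temperature * self.S


def _ak_mode_entropy(alpha: np.ndarray, k_B: float) -> float:
    """Quantum harmonic-oscillator entropy summed over modes, kcal/(mol K)."""
    return float(k_B * np.sum(alpha / np.expm1(alpha) - np.log1p(-np.exp(-alpha))))


def qh_entropy_from_eigenvalues(eigenvalues: np.ndarray, thermo: ThermoParams,
                                method: str = "andricioaei_karplus",
                                eig_floor: float = 1e-8,
                                mass_weighted: bool = True,
                                total_dim: int | None = None) -> EntropyResult:
    """Entropy from a covariance eigen-spectrum (λ in amu·Å² when
    mass-weighted, Å² for the classical estimator on plain covariance)."""
    if method not in METHODS:
        raise ValidationError(f"unknown entropy method {method!r}")
    if eig_floor < 0:
        raise ValidationError("eig_floor must be >= 0")
    lam = np.asarray(eigenvalues, dtype=float)
    total = total_dim if total_dim is not None else lam.size
    retained = lam[lam > eig_floor]
    discarded = total - retained.size
    if retained.size == 0:
        raise ValidationError("no retained modes (all eigenvalues <= eig_floor)")

    T, k_B = thermo.T, thermo.k_B
    if method == "andricioaei_karplus":
        if not mass_weighted:
            raise ValidationError("andricioaei_karplus requires a mass-weighted covariance")
        kT_mech = thermo.k_B_mech * T
        alpha = thermo.hbar / np.sqrt(kT_mech * retained)   # = ħω/(k_B T)
        s = _ak_mode_entropy(alpha, k_B)
    elif method == "schlitter":
        if not mass_weighted:
            raise ValidationError("schlitter requires a mass-weighted covariance")
        kT_mech = thermo.k_B_mech * T
        factor = kT_mech * math.e ** 2 / thermo.hbar ** 2    # 1/(amu Å²)
        s = float(0.5 * k_B * np.sum(np.log1p(factor * retained)))
    else:  # classical_gaussian
        d = retained.size
        s = float(0.5 * k_B * (d * math.log(2.0 * math.pi * math.e)
                               + np.sum(np.log(retained))))
    return EntropyResult(method=method, S=s, temperature=T,
                         n_modes_retained=int(retained.size),
                         discarded_modes=int(discarded),
                         absolute=(method != "classical_gaussian"))


def qh_entropy(model: CovarianceModel, thermo: ThermoParams | None = None,
               method: str = "andricioaei_karplus",
               eig_floor: float = 1e-8) -> EntropyResult:
    """Quasi-harmonic entropy of a fitted covariance model.

    The quantum estimators require a mass-weighted model; the
    ``classical_gaussian`` estimator accepts either weighting but is only
    meaningful inside :func:`entropy_change`.
    """
    thermo = thermo or ThermoParams()
    if method in ("andricioaei_karplus", "schlitter") and not model.mass_weighted:
        raise ValidationError(
            f"{method} needs a mass-weighted covariance model "
            "(build with mass_weighted=True)"
        )
    return qh_entropy_from_eigenvalues(
        model.eigenvalues, thermo, method=method, eig_floor=eig_floor,
        mass_weighted=model.mass_weighted, total_dim=model.n_coords,
    )


def entropy_change(S_complex: EntropyResult, S_apo: EntropyResult,
                   S_ligand: EntropyResult,
                   thermo: ThermoParams | None = None) -> EntropyResult:
    """Binding configurational entropy change ΔS = S_complex - S_apo - S_ligand.

    All three inputs must share method and temperature.  For the
    non-absolute classical estimator the dimensionalities must satisfy
    dim(complex) = dim(apo) + dim(ligand) so the unit-bearing factors
    cancel in the difference.
    """
    thermo = thermo or ThermoParams()
    parts = (S_complex, S_apo, S_ligand)
    methods = {p.method for p in parts}
    if len(methods) != 1:
        raise ValidationError(f"entropy methods differ: {sorted(methods)}")
    temps = {p.temperature for p in parts}
    if len(temps) != 1:
        raise ValidationError(f"entropy temperatures differ: {sorted(temps)}")
    method = S_complex.method
    if method == "classical_gaussian":
        if S_complex.n_modes_retained != S_apo.n_modes_retained + S_ligand.n_modes_retained:
            raise ValidationError(
                "classical_gaussian ΔS needs dim(complex) = dim(apo) + dim(ligand); "
                f"got {S_complex.n_modes_retained} vs "
                f"{S_apo.n_modes_retained} + {S_ligand.n_modes_retained}"
            )
    dS = S_complex.S - S_apo.S - S_ligand.S
    T = S_complex.temperature
    return EntropyResult(
        method=method, S=dS, temperature=T,
        n_modes_retained=S_complex.n_modes_retained,
        discarded_modes=S_complex.discarded_modes,
        minus_T_dS=-T * dS,
        absolute=(method != "classical_gaussian"),
    )
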