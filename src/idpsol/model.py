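"""The pH-dependent solubility surface.

Solubility is modelled as a bivariate polynomial in the whole-chain
lipophilicity L(pH) and the absolute net charge |Q(pH)| — a Taylor
expansion truncated at first order in the lipophilicity and second order
in the net charge:

    S = alpha * L + beta * |Q|**2 + gamma * |Q| + delta

Here "solubility" is the inverse of aggregation propensity in arbitrary
(training-data) units, not a thermodynamic concentration: only relative
values along a pH sweep, and their correlation with experimental
aggregation observables, carry meaning.

The published coefficients (``PUBLISHED_PARAMS``) were obtained by
least-squares fitting against experimental solubility of charge-
engineered variants of a model IDP; ``idpsol.fit`` re-estimates them from
any (L, |Q|, S) dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charge import net_charge
from .profile import lipophilicity_profile
from .scales import IonizationTable, LipophilicityScale
from .sequence_io import ProteinSequence

__all__ = [
    "SolubilityModelParams",
    "PUBLISHED_PARAMS",
    "SolubilityScore",
    "SolubilityCurve",
    "ResidueSolubilityProfile",
    "predict_solubility",
    "solubility_at_ph",
    "ph_sweep",
    "residue_solubility_profile",
]


@dataclass(frozen=True)
class SolubilityModelParams:
    """Coefficients of the solubility surface (solubility-score units)."""

    alpha: float  # weight of the global lipophilicity
    beta: float   # weight of |net charge| squared
    gamma: float  # weight of |net charge|
    delta: float  # intercept

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta])

    @classmethod
    def from_array(cls, theta) -> "SolubilityModelParams":
        a, b, g, d = (float(x) for x in theta)
        return cls(alpha=a, beta=b, gamma=g, delta=d)

    @property
    def charge_vertex(self) -> float:
        """|Q| at which the (concave, beta < 0) charge term peaks: -gamma/(2 beta)."""
        return -self.gamma / (2.0 * self.beta)


#: Published parameterization of the surface.
PUBLISHED_PARAMS = SolubilityModelParams(
    alpha=-97.82, beta=-0.00747, gamma=0.8770, delta=38.24
)


def predict_solubility(
    lipophilicity, abs_net_charge, params: SolubilityModelParams = PUBLISHED_PARAMS
):
    """Evaluate the solubility surface.  Accepts scalars or numpy arrays."""
    lipo = np.asarray(lipophilicity, dtype=float)
    q = np.asarray(abs_net_charge, dtype=float)
    if np.any(q < 0):
        raise ValueError("abs_net_charge must be non-negative")
    s = params.alpha * lipo + params.beta * q**2 + params.gamma * q + params.delta
    return float(s) if s.ndim == 0 else s


@dataclass(frozen=True)
class SolubilityScore:
    """Predicted solubility of one sequence at one pH, with its components."""

    sequence_id: str
    ph: float
    solubility: float
    lipophilicity: float
    net_charge: float

    @property
    def abs_net_charge(self) -> float:
        return abs(self.net_charge)


def solubility_at_ph(
    seq: ProteinSequence,
    ph: float,
    params: SolubilityModelParams,
    scale: LipophilicityScale,
    table: IonizationTable,
    *,
    window: int | None = None,
) -> SolubilityScore:
    """Predicted solubility of ``seq`` at ``ph``.

    Composes the whole-chain lipophilicity (mean of the sliding-window
    profile), the absolute net charge, and the polynomial surface.
    """
    prof = lipophilicity_profile(seq, ph, scale, table, window=window)
    q = net_charge(seq, ph, table)
    s = predict_solubility(prof.global_lipophilicity, q.abs_net_charge, params)
    return SolubilityScore(
        sequence_id=seq.id,
        ph=ph,
        solubility=s,
        lipophilicity=prof.global_lipophilicity,
        net_charge=q.net_charge,
    )


@dataclass(frozen=True)
class SolubilityCurve:
    """Predicted solubility along an ascending pH grid, with components."""

    sequence_id: str
    ph: np.ndarray
    solubility: np.ndarray
    lipophilicity: np.ndarray
    net_charge: np.ndarray

    @property
    def abs_net_charge(self) -> np.ndarray:
        return np.abs(self.net_charge)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.sequence_id,
                "ph": self.ph,
                "solubility": self.solubility,
                "lipophilicity": self.lipophilicity,
                "net_charge": self.net_charge,
                "abs_net_charge": self.abs_net_charge,
            }
        )

    def rescaled(self) -> "SolubilityCurve":
        """Min–max rescaling of the solubility values to [0, 1] (plotting aid)."""
        lo, hi = self.solubility.min(), self.solubility.max()
        span = hi - lo if hi > lo else 1.0
        return SolubilityCurve(
            sequence_id=self.sequence_id,
            ph=self.ph,
            solubility=(self.solubility - lo) / span,
            lipophilicity=self.lipophilicity,
            net_charge=self.net_charge,
        )

    def plot(self, ax=None):
        """Plot solubility vs pH (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ph, self.solubility, marker="o", ms=3)
        ax.set_xlabel("pH")
        ax.set_ylabel("predicted solubility (arbitrary units)")
        ax.set_title(self.sequence_id)
        return ax


def ph_sweep(
    seq: ProteinSequence,
    params: SolubilityModelParams,
    scale: LipophilicityScale,
    table: IonizationTable,
    *,
    ph_min: float = 2.0,
    ph_max: float = 12.0,
    step: float = 0.1,
    window: int | None = None,
) -> SolubilityCurve:
    """Predicted solubility over a regular pH grid (endpoints included)."""
    if not (0.0 < ph_min < ph_max < 14.0):
        raise ValueError(
            f"need 0 < ph_min < ph_max < 14, got [{ph_min}, {ph_max}]"
        )
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    n = int(round((ph_max - ph_min) / step)) + 1
    grid = ph_min + step * np.arange(n)
    grid = grid[grid <= ph_max + 1e-12]
    scores = [
        solubility_at_ph(seq, float(ph), params, scale, table, window=window)
        for ph in grid
    ]
    return SolubilityCurve(
        sequence_id=seq.id,
        ph=grid,
        solubility=np.array([s.solubility for s in scores]),
        lipophilicity=np.array([s.lipophilicity for s in scores]),
        net_charge=np.array([s.net_charge for s in scores]),
    )


@dataclass(frozen=True)
class ResidueSolubilityProfile:
    """Per-position solubility scores at one pH.

    The surface is applied window-by-window: each centre position gets
    its window lipophilicity, while the charge terms use the whole-chain
    |Q| (charge is a global property and is not localized).  The profile
    is a region-ranking heuristic — it highlights the stretches that pull
    the whole-chain score down — not a sum decomposition.
    """

    sequence_id: str
    ph: float
    positions: np.ndarray
    residues: tuple
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.sequence_id,
                "position": self.positions,
                "residue": list(self.residues),
                "solubility": self.values,
            }
        )


def residue_solubility_profile(
    seq: ProteinSequence,
    ph: float,
    params: SolubilityModelParams,
    scale: LipophilicityScale,
    table: IonizationTable,
    *,
    window: int | None = None,
) -> ResidueSolubilityProfile:
    """Window-wise solubility profile of ``seq`` at ``ph``."""
    prof = lipophilicity_profile(seq, ph, scale, table, window=window)
    q = net_charge(seq, ph, table).abs_net_charge
    values = predict_solubility(prof.values, np.full_like(prof.values, q), params)
    return ResidueSolubilityProfile(
        sequence_id=seq.id,
        ph=ph,
        positions=prof.positions,
        residues=prof.residues,
        values=values,
    )
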